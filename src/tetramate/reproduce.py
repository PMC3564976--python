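"""End-to-end reproduction of the study's headline quantities.

Chains the analysis stages over the bundled data: allele richness over
the combined strain tables, the marker-resolution audit, progeny-class
enumeration and sib compatibility for the Lmsa110092 spore family,
prediction-vs-observation concordance for the crossing matrix, and the
minimal-founder reconstruction. The report is deterministic —
byte-identical across runs.
"""

from __future__ import annotations

from . import fixtures
from .mating_model import (
    compare_matrices,
    expected_progeny_classes,
    infer_compatibility_classes,
    predict_matrix,
    sib_compatibility_fraction,
)
from .population import (
    allele_frequencies,
    allele_richness,
    marker_resolution_audit,
    minimal_founders,
    outcrossing_potential,
    single_allele_strain_counts,
)
from .types import Locus, MatingGenotype, Ploidy, PopulationTable

PARENT_STRAIN = "Lmsa110092"


def _combined_population() -> PopulationTable:
    """European dikaryons plus the previously mated monokaryons (their
    proxy genotypes), the full strain set behind the richness counts."""
    entries = list(fixtures.european_strains())
    for pair in fixtures.functional_proxy_pairs():
        entries.append(
            MatingGenotype.make(
                pair.strain_id,
                Ploidy.monokaryon,
                {pair.proxy_a},
                {pair.proxy_b},
            )
        )
    return PopulationTable(entries)


def run_full_analysis() -> dict:
    """Compute every headline quantity from the bundled data."""
    population = _combined_population()
    richness = allele_richness(population)
    freqs = allele_frequencies(population, mode="gene_count")

    audit = marker_resolution_audit(fixtures.functional_proxy_pairs())
    singles = single_allele_strain_counts(fixtures.european_strains())

    parent = fixtures.european_strains().get(PARENT_STRAIN)
    classes = expected_progeny_classes(parent)
    sib_fraction = sib_compatibility_fraction(parent)

    sibs = fixtures.spore_family_monokaryons()
    predicted = predict_matrix(list(sibs))
    observed = fixtures.spore_family_crossings()
    concordance = compare_matrices(predicted, observed)
    inferred = infer_compatibility_classes(observed)

    a_alleles = set()
    b_alleles = set()
    for entry in population:
        a_alleles |= entry.a_alleles
        b_alleles |= entry.b_alleles
    founders = minimal_founders(a_alleles, b_alleles)

    return {
        "richness": {
            "mat_a": richness[Locus.MAT_A],
            "mat_b": richness[Locus.MAT_B],
        },
        "allele_frequencies": {
            "mat_a": freqs[Locus.MAT_A],
            "mat_b": freqs[Locus.MAT_B],
        },
        "outcrossing_potential": outcrossing_potential(
            freqs[Locus.MAT_A], freqs[Locus.MAT_B]
        ),
        "single_allele_dikaryons": {
            convention: {locus.value: n for locus, n in counts.items()}
            for convention, counts in singles.items()
        },
        "resolution_audit": {
            "n_functional_a": audit.n_functional[Locus.MAT_A],
            "n_functional_b": audit.n_functional[Locus.MAT_B],
            "unresolved": sorted(
                audit.unresolved[Locus.MAT_A] + audit.unresolved[Locus.MAT_B]
            ),
            "n_unresolved": audit.n_unresolved,
            "inconsistent": sorted(
                audit.inconsistent[Locus.MAT_A] + audit.inconsistent[Locus.MAT_B]
            ),
        },
        "spore_family": {
            "parent": PARENT_STRAIN,
            "progeny_classes": sorted(g.strain_id for g in classes),
            "n_classes": len(classes),
            "sib_compatibility_fraction": sib_fraction,
        },
        "concordance": {
            "n_pairs_scored": concordance.n_pairs_scored,
            "n_match": concordance.n_match,
            "n_mismatch": concordance.n_mismatch,
            "n_unresolved": concordance.n_unresolved,
            "mismatches": [
                [a, b, pred.value, obs.value]
                for a, b, pred, obs in concordance.mismatches
            ],
        },
        "inferred_classes": {
            "n_classes": len(inferred.classes),
            "class_sizes": sorted(len(c) for c in inferred.classes),
            "polarity": inferred.polarity,
        },
        "minimal_founders": {
            "n_dikaryons": founders.n_dikaryons,
            "assignments": [
                [list(a_pair), list(b_pair)]
                for a_pair, b_pair in founders.assignments
            ],
        },
    }


def render_markdown(report: dict) -> str:
    """Human-readable summary of the reproduction report."""
    lines = [
        "# Mating-type analysis report",
        "",
        f"- MAT A alleles: {report['richness']['mat_a']}",
        f"- MAT B alleles: {report['richness']['mat_b']}",
        f"- Outcrossing potential (random monokaryon pair compatible): "
        f"{report['outcrossing_potential']:.3f}",
        f"- Functional factors unresolved by markers: "
        f"{report['resolution_audit']['n_unresolved']} "
        f"({', '.join(report['resolution_audit']['unresolved'])})",
        f"- Spore-family progeny classes of {report['spore_family']['parent']}: "
        f"{', '.join(report['spore_family']['progeny_classes'])} "
        f"(sib compatibility {report['spore_family']['sib_compatibility_fraction']:.2f})",
        f"- Crossing concordance: {report['concordance']['n_match']} match, "
        f"{report['concordance']['n_mismatch']} mismatch, "
        f"{report['concordance']['n_unresolved']} unresolved "
        f"of {report['concordance']['n_pairs_scored']} scored pairs",
        f"- Inferred polarity: {report['inferred_classes']['polarity']} "
        f"({report['inferred_classes']['n_classes']} compatibility classes)",
        f"- Minimal founding dikaryons: "
        f"{report['minimal_founders']['n_dikaryons']}",
        "",
    ]
    return "\n".join(lines)
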