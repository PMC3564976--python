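"""Pheromone-precursor candidate detection.

Basidiomycete mating pheromone precursors are short peptides whose
C-terminus carries a CaaX prenylation motif: a cysteine, two aliphatic
residues, then any residue. This module finds ORFs in DNA, screens
protein C-termini for the motif, and combines the two into a candidate
scan with length bounds. The precursors' postulated N-terminal cleaving
site is not modeled (no usable rule); every candidate carries a note to
that effect.
"""

from __future__ import annotations

from Bio.Seq import Seq

from .types import OrfRecord, PheromoneCandidate

DEFAULT_ALIPHATIC = frozenset("AVLI")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")
_DNA_CHARS = frozenset("ACGTN")

STOP_CODONS = {"TAA", "TAG", "TGA"}


def _validate_dna(dna: str) -> str:
    dna = dna.upper()
    for pos, ch in enumerate(dna):
        if ch not in _DNA_CHARS:
            raise ValueError(f"invalid DNA character {ch!r} at position {pos}")
    return dna


def _orfs_one_strand(dna: str, source_id: str, min_len_aa: int):
    """Every ATG..stop ORF on the given (forward-oriented) string."""
    n = len(dna)
    for frame in range(3):
        stops_after: dict[int, int] = {}
        # next in-frame stop at or after each codon start
        next_stop = None
        for start in range(n - 3 - (n - frame - 3) % 3, frame - 1, -3):
            if start < 0 or start + 3 > n:
                continue
            if dna[start:start + 3] in STOP_CODONS:
                next_stop = start
            stops_after[start] = next_stop
        for start in range(frame, n - 2, 3):
            if dna[start:start + 3] != "ATG":
                continue
            stop = stops_after.get(start)
            if stop is None:
                continue
            aa_len = (stop - start) // 3
            if aa_len < min_len_aa:
                continue
            protein = str(Seq(dna[start:stop]).translate(table=1))
            yield start, stop + 3, protein


def find_orfs(
    dna: str, min_len_aa: int = 1, source_id: str = "seq"
) -> list[OrfRecord]:
    """All ATG-to-stop ORFs on both strands of a DNA sequence.

    Every in-frame ATG with a downstream stop yields an ORF (nested
    starts included). Coordinates are 0-based half-open on the forward
    strand regardless of the ORF's strand; protein length excludes the
    stop and must be >= ``min_len_aa``.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    dna = _validate_dna(dna)
    records = []
    for start, end, protein in _orfs_one_strand(dna, source_id, min_len_aa):
        records.append(OrfRecord(source_id, "+", start, end, protein))
    rc = str(Seq(dna).reverse_complement())
    n = len(dna)
    for start, end, protein in _orfs_one_strand(rc, source_id, min_len_aa):
        records.append(OrfRecord(source_id, "-", n - end, n - start, protein))
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return records


def scan_caax(
    protein: str, aliphatic: frozenset[str] = DEFAULT_ALIPHATIC
) -> str | None:
    """Return the terminal CaaX tetrapeptide if the protein ends in one.

    Match requires residue -4 to be C and residues -3, -2 in the
    aliphatic set; the final residue (X) is unconstrained. Proteins
    shorter than 4 residues never match (no error).
    """
    protein = protein.upper()
    if len(protein) < 4:
        return None
    tail = protein[-4:]
    if tail[0] == "C" and tail[1] in aliphatic and tail[2] in aliphatic:
        return tail
    return None


def looks_like_dna(sequence: str) -> bool:
    """Alphabet heuristic: all characters in {A,C,G,T,N} reads as DNA."""
    letters = set(sequence.upper())
    return bool(letters) and letters <= _DNA_CHARS


def pheromone_candidates(
    records: list[tuple[str, str]],
    min_len_aa: int = 30,
    max_len_aa: int = 120,
    aliphatic: frozenset[str] = DEFAULT_ALIPHATIC,
    input_type: str = "auto",
) -> list[PheromoneCandidate]:
    """Screen FASTA records for pheromone-precursor candidates.

    ``records`` are (id, sequence) pairs; DNA inputs are six-frame ORF
    scanned first, protein inputs screened directly. A candidate is any
    ORF/protein within the length bounds whose C-terminus matches CaaX.
    Output order is by source id then coordinate, independent of record
    order.
    """
    if min_len_aa > max_len_aa:
        raise ValueError(
            f"contradictory length bounds: min {min_len_aa} > max {max_len_aa}"
        )
    if input_type not in ("auto", "dna", "protein"):
        raise ValueError(f"unknown input_type {input_type!r}")
    notes = ("N-terminal cleaving site unchecked",)
    candidates = []
    for rec_id, sequence in sorted(records, key=lambda r: r[0]):
        kind = input_type
        if kind == "auto":
            kind = "dna" if looks_like_dna(sequence) else "protein"
        if kind == "dna":
            for orf in find_orfs(sequence, min_len_aa=1, source_id=rec_id):
                if not (min_len_aa <= len(orf.protein) <= max_len_aa):
                    continue
                caax = scan_caax(orf.protein, aliphatic)
                if caax is None:
                    continue
                candidates.append(
                    PheromoneCandidate(
                        source_id=rec_id,
                        protein=orf.protein,
                        caax=caax,
                        length_aa=len(orf.protein),
                        strand=orf.strand,
                        start=orf.start,
                        end=orf.end,
                        score_notes=notes,
                    )
                )
        else:
            protein = sequence.upper().rstrip("*")
            if not (min_len_aa <= len(protein) <= max_len_aa):
                continue
            caax = scan_caax(protein, aliphatic)
            if caax is None:
                continue
            candidates.append(
                PheromoneCandidate(
                    source_id=rec_id,
                    protein=protein,
                    caax=caax,
                    length_aa=len(protein),
                    score_notes=notes,
                )
            )
    candidates.sort(key=lambda c: (c.source_id, c.start if c.start is not None else -1))
    return candidates
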