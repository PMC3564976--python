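"""Access to the bundled data tables (see ``data/README.md``)."""

from __future__ import annotations

from importlib import resources

from . import io
from .mating_model import CrossingMatrix
from .types import FunctionalProxyPair, PopulationTable

_DATA = resources.files(__package__) / "data"


def _path(name: str):
    path = _DATA / name
    if not path.is_file():
        raise FileNotFoundError(f"missing bundled fixture: {name}")
    return path


def european_strains() -> PopulationTable:
    """26 dikaryotic European strains with marker genotypes."""
    return io.read_genotype_tsv(_path("european_strain_genotypes.tsv"))


def functional_proxy_pairs() -> list[FunctionalProxyPair]:
    """10 previously mated monokaryons: functional factors vs proxies."""
    return io.read_functional_proxy_tsv(_path("functional_vs_marker_genotypes.tsv"))


def spore_family_monokaryons() -> PopulationTable:
    """The 16 crossed sib monokaryons of the Lmsa110092 spore family."""
    return io.read_genotype_tsv(_path("spore_family_monokaryons.tsv"))


def spore_family_crossings() -> CrossingMatrix:
    """Observed pairwise crossing outcomes over the 16 sibs."""
    return io.read_crossing_csv(_path("spore_family_crossings.csv"))
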