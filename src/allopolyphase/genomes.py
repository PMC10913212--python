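"""Core containers for genomes, subgenome pairs and simulation ground truth.

Coordinates are 0-based, half-open throughout the library; emitted VCF/GFF3
use the 1-based conventions of those formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class Genome:
    """An ordered collection of named chromosome sequences."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.chromosomes) == 0:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def total_length(self) -> int:
        return sum(len(seq) for seq in self.chromosomes.values())


@dataclass
class SubgenomePair:
    """The two parental subgenomes of an allotetraploid.

    ``genome_o`` and ``genome_r`` descend from a common ancestor by
    substitution only, so homeologous chromosomes have identical lengths and
    shared coordinates.  ``true_variants`` holds every planted divergence
    site as ``(o_chromosome, position, allele_o, allele_r)``.
    """

    genome_o: Genome
    genome_r: Genome
    divergence_snp_rate: float
    true_variants: list[tuple[str, int, str, str]]

    def __post_init__(self) -> None:
        lo, lr = self.genome_o.lengths(), self.genome_r.lengths()
        if len(lo) != len(lr):
            raise ValueError("subgenomes must have equal chromosome counts")
        for (no, vo), (nr, vr) in zip(lo.items(), lr.items()):
            if vo != vr:
                raise ValueError(f"homeologous chromosomes {no}/{nr} differ in length")

    def homeolog_name(self, name: str) -> str:
        """Map an O-chromosome name to its R homeolog and vice versa."""
        if name.startswith("O"):
            return "R" + name[1:]
        if name.startswith("R"):
            return "O" + name[1:]
        raise ValueError(f"not a subgenome chromosome name: {name!r}")


@dataclass
class ChimeraJunction:
    """A planted mis-join inside a contig.

    ``position`` is the junction offset in contig coordinates; the left part
    of the contig derives from the contig's primary source chromosome and the
    right part from ``partner_contig``'s source chromosome.
    """

    contig: str
    position: int
    partner_contig: str


@dataclass
class TruthSet:
    """Ground truth recorded by the simulator and consumed by tests.

    he_breakpoints come in reciprocal pairs: the two hybrid chromosomes
    produced by one homeologous exchange carry mirror-image segment labels.
    """

    chimera_junctions: list[ChimeraJunction] = field(default_factory=list)
    he_breakpoints: list[tuple[str, int]] = field(default_factory=list)
    homeolog_pairs_truth: list[tuple[str, str]] = field(default_factory=list)
    crossovers: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    deleted_region: tuple[str, int, int] | None = None

    def breakpoint_of(self, chromosome: str) -> int | None:
        for name, pos in self.he_breakpoints:
            if name == chromosome:
                return pos
        return None


@dataclass
class DepthTrack:
    """Per-window mean read depth of one parental sample on a reference."""

    sample: str
    window_size: int
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for name, arr in self.values.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"negative depth in track for {name!r}")


def n_windows(length: int, window_size: int) -> int:
    """Number of half-open windows covering ``length`` bases (last may be short)."""
    return -(-length // window_size)
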