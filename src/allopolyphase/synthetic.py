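"""Miniature allotetraploid simulator with full ground truth.

This module generates every input the downstream stages consume: two
subgenomes diverged from a common ancestor by substitution, a tetraploid
reference that may carry one reciprocal homeologous exchange (HE), an F2
mapping population with Poisson crossovers, parental read-coverage tracks,
chimeric contig sets, Hi-C contact pairs with power-law distance decay, and
planted gene models for homeolog pairing.

Because divergence is substitution-only, homeologous chromosomes keep equal
lengths and shared coordinates, which makes truth bookkeeping exact: every
planted variant, junction, crossover and breakpoint is recorded in a
:class:`~allopolyphase.genomes.TruthSet`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomes import (
    ChimeraJunction,
    DepthTrack,
    Genome,
    SubgenomePair,
    TruthSet,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

#: default analysis window, matching the 10-kb windows used for
#: parental-coverage subgenome assignment
DEFAULT_WINDOW = 10_000


@dataclass(frozen=True)
class HESpec:
    """Reciprocal homeologous exchange on one chromosome pair.

    ``chrom_index`` is 1-based; ``breakpoint_fraction`` places the exchange
    point as a fraction of chromosome length, strictly inside (0, 1).
    """

    chrom_index: int
    breakpoint_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.breakpoint_fraction < 1.0:
            raise ValueError("breakpoint fraction must lie strictly in (0, 1)")
        if self.chrom_index < 1:
            raise ValueError("chrom_index is 1-based and must be >= 1")


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _array_to_seq(_BASES[rng.integers(0, 4, size=length)])


def make_subgenome_pair(
    n_chromosomes: int,
    chrom_length: int,
    divergence_snp_rate: float,
    seed: int = 0,
) -> SubgenomePair:
    """Diverge two subgenomes (O and R) from a random common ancestor.

    Each ancestral site mutates in the R copy with probability
    ``divergence_snp_rate``; the O copy keeps the ancestral allele.  All
    divergence sites are recorded as true variants.
    """
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if not 0.0 <= divergence_snp_rate < 0.2:
        raise ValueError("divergence_snp_rate must lie in [0, 0.2)")
    rng = np.random.default_rng(seed)
    chroms_o: dict[str, str] = {}
    chroms_r: dict[str, str] = {}
    variants: list[tuple[str, int, str, str]] = []
    for i in range(1, n_chromosomes + 1):
        anc = _BASES[rng.integers(0, 4, size=chrom_length)]
        r = anc.copy()
        sites = np.flatnonzero(rng.random(chrom_length) < divergence_snp_rate)
        if sites.size:
            shift = rng.integers(1, 4, size=sites.size)
            idx = np.searchsorted(_BASES, anc[sites])
            r[sites] = _BASES[(idx + shift) % 4]
        name_o, name_r = f"O{i}", f"R{i}"
        chroms_o[name_o] = _array_to_seq(anc)
        chroms_r[name_r] = _array_to_seq(r)
        for pos in sites:
            variants.append((name_o, int(pos), chr(anc[pos]), chr(r[pos])))
    return SubgenomePair(
        Genome(chroms_o), Genome(chroms_r), divergence_snp_rate, variants
    )


def build_tetraploid(
    pair: SubgenomePair, he_spec: HESpec | None = None
) -> tuple[Genome, list[tuple[str, int]]]:
    """Assemble the tetraploid reference, applying an optional HE.

    The exchanged pair is renamed ``O<i>_R<i>`` / ``R<i>_O<i>``: each hybrid
    keeps its own subgenome up to the breakpoint and switches to the
    homeologous source after it, so the two breakpoints are reciprocal.
    """
    chroms: dict[str, str] = {}
    breakpoints: list[tuple[str, int]] = []
    n = len(pair.genome_o.names)
    he_index = he_spec.chrom_index if he_spec is not None else None
    if he_index is not None and he_index > n:
        raise ValueError("he_spec chromosome index beyond chromosome count")
    for i in range(1, n + 1):
        name_o, name_r = f"O{i}", f"R{i}"
        seq_o, seq_r = pair.genome_o[name_o], pair.genome_r[name_r]
        if i == he_index:
            bp = int(round(he_spec.breakpoint_fraction * len(seq_o)))
            hyb_o = f"O{i}_R{i}"
            hyb_r = f"R{i}_O{i}"
            chroms[hyb_o] = seq_o[:bp] + seq_r[bp:]
            chroms[hyb_r] = seq_r[:bp] + seq_o[bp:]
            breakpoints.extend([(hyb_o, bp), (hyb_r, bp)])
        else:
            chroms[name_o] = seq_o
            chroms[name_r] = seq_r
    return Genome(chroms), breakpoints


def simulate_allotetraploid(
    n_chromosomes: int,
    chrom_length: int,
    divergence_snp_rate: float,
    he_spec: HESpec | None = None,
    seed: int = 0,
    window_size: int = DEFAULT_WINDOW,
) -> tuple[SubgenomePair, Genome, TruthSet]:
    """Simulate a tetraploid genome of ``2 * n_chromosomes`` chromosomes.

    Chromosomes shorter than ten analysis windows are rejected: the
    coverage-based subgenome caller downstream needs a minimal number of
    windows to segment.
    """
    if chrom_length < 10 * window_size:
        raise ValueError(
            f"chrom_length {chrom_length} too short: need >= 10 windows "
            f"of {window_size} bp"
        )
    pair = make_subgenome_pair(n_chromosomes, chrom_length, divergence_snp_rate, seed)
    tetraploid, breakpoints = build_tetraploid(pair, he_spec)
    truth = TruthSet(he_breakpoints=breakpoints)
    return pair, tetraploid, truth


# ---------------------------------------------------------------------------
# F2 mapping population
# ---------------------------------------------------------------------------


@dataclass
class F2Cohort:
    """Genotypes and depths of an F2 population at codominant markers.

    ``genotypes`` holds copies of the parent-2 allele (0, 1 or 2) with shape
    (n_plants, n_markers); ``markers`` lists (chromosome, position) in the
    coordinate system of the genome the markers were placed on.
    """

    plants: list[str]
    markers: pd.DataFrame
    genotypes: np.ndarray
    depths: np.ndarray
    crossover_rate: float | dict[str, float]

    def __post_init__(self) -> None:
        n_plants, n_markers = self.genotypes.shape
        if n_plants != len(self.plants) or n_markers != len(self.markers):
            raise ValueError("genotype matrix dimensions inconsistent")
        if self.depths.shape != self.genotypes.shape:
            raise ValueError("depth matrix shape mismatch")
        if np.any(self.depths < 0):
            raise ValueError("depths must be non-negative")

    @property
    def n_plants(self) -> int:
        return len(self.plants)


def simulate_parent_accessions(
    genome: Genome,
    markers_per_chromosome: int,
    seed: int = 0,
) -> tuple[Genome, dict[str, np.ndarray]]:
    """Create a second accession differing from ``genome`` at marker sites.

    Marker positions are drawn uniformly without replacement on every
    chromosome; the second parent carries a different allele at each of
    them, so the pair segregates 1:2:1 in an F2.
    """
    rng = np.random.default_rng(seed)
    chroms: dict[str, str] = {}
    positions: dict[str, np.ndarray] = {}
    for name, seq in genome.chromosomes.items():
        arr = _seq_to_array(seq)
        pos = np.sort(rng.choice(len(arr), size=markers_per_chromosome, replace=False))
        idx = np.searchsorted(_BASES, arr[pos])
        arr[pos] = _BASES[(idx + rng.integers(1, 4, size=pos.size)) % 4]
        chroms[name] = _array_to_seq(arr)
        positions[name] = pos.astype(np.int64)
    return Genome(chroms), positions


def _gamete_alleles(
    marker_pos: np.ndarray, length: int, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One meiotic product: allele (0/1) at each marker plus crossover sites."""
    n_co = rng.poisson(rate)
    co = np.sort(rng.integers(0, length, size=n_co))
    start = int(rng.integers(0, 2))
    parity = np.searchsorted(co, marker_pos, side="right") % 2
    return (start + parity) % 2, co


def simulate_f2(
    parent1: Genome,
    parent2: Genome,
    marker_positions: dict[str, np.ndarray],
    n_plants: int = 50,
    crossover_rate: float | dict[str, float] = 1.5,
    depth_mean: float = 30.0,
    seed: int = 0,
) -> tuple[F2Cohort, dict[str, dict[str, list[int]]]]:
    """Simulate F2 genotypes under Poisson crossovers (no interference).

    Every plant inherits two independent gametes per chromosome; the
    genotype at a marker is the number of parent-2 alleles.  Crossover
    positions of both gametes are pooled into the returned truth mapping
    ``plant -> chromosome -> sorted positions``.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    lengths = parent1.lengths()
    for chrom, pos in marker_positions.items():
        pos = np.asarray(pos)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"marker positions on {chrom} are not sorted")
        if pos.size and (pos.min() < 0 or pos.max() >= lengths[chrom]):
            raise ValueError(f"marker position out of range on {chrom}")
        for p in pos:
            if parent1[chrom][p] == parent2[chrom][p]:
                raise ValueError(
                    f"parents do not differ at marker {chrom}:{int(p)}"
                )
    rng = np.random.default_rng(seed)
    plants = [f"F2_{i + 1:03d}" for i in range(n_plants)]
    meta_frames = []
    geno_blocks = []
    crossovers: dict[str, dict[str, list[int]]] = {p: {} for p in plants}
    for chrom, pos in marker_positions.items():
        pos = np.asarray(pos, dtype=np.int64)
        rate = (
            crossover_rate[chrom]
            if isinstance(crossover_rate, dict)
            else crossover_rate
        )
        block = np.empty((n_plants, pos.size), dtype=np.int8)
        for ip, plant in enumerate(plants):
            a1, co1 = _gamete_alleles(pos, lengths[chrom], rate, rng)
            a2, co2 = _gamete_alleles(pos, lengths[chrom], rate, rng)
            block[ip] = (a1 + a2).astype(np.int8)
            crossovers[plant][chrom] = sorted(int(c) for c in np.concatenate([co1, co2]))
        geno_blocks.append(block)
        meta_frames.append(
            pd.DataFrame({"chromosome": chrom, "position": pos})
        )
    markers = pd.concat(meta_frames, ignore_index=True)
    genotypes = np.concatenate(geno_blocks, axis=1)
    depths = rng.poisson(depth_mean, size=genotypes.shape)
    cohort = F2Cohort(plants, markers, genotypes, depths, crossover_rate)
    return cohort, crossovers


# ---------------------------------------------------------------------------
# Parental read coverage
# ---------------------------------------------------------------------------


def window_sources(
    genome: Genome,
    window_size: int = DEFAULT_WINDOW,
    he_breakpoints: list[tuple[str, int]] | None = None,
) -> dict[str, np.ndarray]:
    """Subgenome source letter ('O' or 'R') of every window per chromosome.

    Pure chromosomes take the letter of their name; hybrid chromosomes
    (``O7_R7`` style) switch source at the recorded HE breakpoint, assigned
    by window start.
    """
    bp_map = dict(he_breakpoints or [])
    out: dict[str, np.ndarray] = {}
    for name, length in genome.lengths().items():
        starts = np.arange(0, length, window_size)
        if "_" in name and name in bp_map:
            left, right = name.split("_")
            src = np.where(starts < bp_map[name], left[0], right[0])
        else:
            src = np.full(starts.size, name[0])
        out[name] = src
    return out


def simulate_parental_coverage(
    tetraploid: Genome,
    parent_label: str,
    window_size: int = DEFAULT_WINDOW,
    depth_mean: float = 30.0,
    cross_mapping_rate: float = 0.05,
    seed: int = 0,
    he_breakpoints: list[tuple[str, int]] | None = None,
) -> DepthTrack:
    """Per-window depth of one parent's reads mapped on the tetraploid.

    Windows belonging to the parent's own subgenome draw Poisson
    (``depth_mean``); windows from the other subgenome draw Poisson
    (``depth_mean * cross_mapping_rate``), emulating residual cross-mapping
    between the highly similar subgenomes.
    """
    if parent_label not in ("O", "R"):
        raise ValueError("parent_label must be 'O' or 'R'")
    if not 0.0 <= cross_mapping_rate < 0.5:
        raise ValueError("cross_mapping_rate must lie in [0, 0.5)")
    shortest = min(tetraploid.lengths().values())
    if window_size > shortest:
        raise ValueError("window_size larger than the shortest chromosome")
    rng = np.random.default_rng(seed)
    sources = window_sources(tetraploid, window_size, he_breakpoints)
    values: dict[str, np.ndarray] = {}
    for name, src in sources.items():
        mean = np.where(src == parent_label, depth_mean, depth_mean * cross_mapping_rate)
        values[name] = rng.poisson(mean).astype(float)
    return DepthTrack(sample=parent_label, window_size=window_size, values=values)


# ---------------------------------------------------------------------------
# Contigs and chimeras
# ---------------------------------------------------------------------------


@dataclass
class ContigSet:
    """Contigs cut from a genome, with their source segments.

    ``segments[name]`` lists ``(chromosome, start, end)`` source intervals in
    genome coordinates, concatenated left to right to form the contig.
    """

    sequences: dict[str, str]
    segments: dict[str, list[tuple[str, int, int]]]

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


def make_chimeric_contigs(
    genome: Genome,
    n_contigs_per_chrom: int = 10,
    n_chimeras: int = 0,
    seed: int = 0,
    truth: TruthSet | None = None,
) -> tuple[ContigSet, TruthSet]:
    """Cut chromosomes into contigs and plant homeolog-joining chimeras.

    A chimera replaces the right part of a contig from one subgenome with
    the homeologous sequence of the matching contig from the other
    subgenome, mimicking an assembler mis-joining near-identical regions.
    Junctions (contig, offset, partner contig) go into the truth set.
    """
    if n_contigs_per_chrom < 1:
        raise ValueError("n_contigs_per_chrom must be >= 1")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    segments: dict[str, list[tuple[str, int, int]]] = {}
    slot_of: dict[tuple[str, int], str] = {}
    idx = 0
    for name, seq in genome.chromosomes.items():
        bounds = np.linspace(0, len(seq), n_contigs_per_chrom + 1).astype(int)
        for j, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
            tig = f"tig{idx:05d}"
            idx += 1
            sequences[tig] = seq[s:e]
            segments[tig] = [(name, int(s), int(e))]
            slot_of[(name, j)] = tig

    # eligible chimera sites: homeologous contig slots on pure O/R pairs
    pure_pairs = [
        (o, "R" + o[1:])
        for o in genome.names
        if o.startswith("O") and "_" not in o and ("R" + o[1:]) in genome
    ]
    eligible = [
        (slot_of[(o, j)], slot_of[(r, j)])
        for o, r in pure_pairs
        for j in range(n_contigs_per_chrom)
    ]
    if n_chimeras > len(eligible):
        raise ValueError("n_chimeras exceeds the number of eligible contig pairs")
    truth = truth if truth is not None else TruthSet()
    if n_chimeras:
        chosen = rng.choice(len(eligible), size=n_chimeras, replace=False)
        for k in sorted(int(c) for c in chosen):
            tig_o, tig_r = eligible[k]
            chrom_o, s_o, e_o = segments[tig_o][0]
            chrom_r, s_r, e_r = segments[tig_r][0]
            clen = e_o - s_o
            cut = int(rng.integers(int(0.3 * clen), int(0.7 * clen) + 1))
            sequences[tig_o] = sequences[tig_o][:cut] + genome[chrom_r][s_r + cut : e_r]
            segments[tig_o] = [
                (chrom_o, s_o, s_o + cut),
                (chrom_r, s_r + cut, e_r),
            ]
            truth.chimera_junctions.append(ChimeraJunction(tig_o, cut, tig_r))
    return ContigSet(sequences, segments), truth


def markers_on_contigs(
    marker_positions: dict[str, np.ndarray], contigs: ContigSet
) -> pd.DataFrame:
    """Project genome-coordinate markers into contig coordinates.

    Returns one row per marker copy found on a contig: (contig,
    position_in_contig, chromosome, position), ordered by contig then
    offset.  Markers falling in regions displaced by a chimeric join are
    simply absent from the output, as they would be from a real assembly.
    """
    rows = []
    for tig in contigs.sequences:
        offset = 0
        for chrom, s, e in contigs.segments[tig]:
            pos = np.asarray(marker_positions.get(chrom, ()), dtype=np.int64)
            inside = pos[(pos >= s) & (pos < e)]
            for p in inside:
                rows.append((tig, int(p - s + offset), chrom, int(p)))
            offset += e - s
    return pd.DataFrame(
        rows, columns=["contig", "contig_position", "chromosome", "position"]
    )


# ---------------------------------------------------------------------------
# Hi-C contact pairs
# ---------------------------------------------------------------------------


def _power_law_separations(
    n: int, s_min: int, s_max: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-9:
        s = s_min * (s_max / s_min) ** u
    else:
        a = 1.0 - alpha
        s = (s_min**a + u * (s_max**a - s_min**a)) ** (1.0 / a)
    return np.minimum(s.astype(np.int64), s_max)


def simulate_hic_pairs(
    genome: Genome,
    n_pairs: int,
    decay_exponent: float = 1.0,
    trans_fraction: float = 0.05,
    seed: int = 0,
    min_separation: int = 1,
) -> pd.DataFrame:
    """Simulate Hi-C contact pairs on ``genome``.

    Cis separations follow ``P(s) ~ s**(-decay_exponent)``; trans pairs fall
    uniformly on two distinct chromosomes chosen proportionally to length.
    Pairs are reported in the coordinate system of the genome they were
    simulated on.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be positive")
    if not 0.0 <= trans_fraction < 1.0:
        raise ValueError("trans_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = np.array([len(genome[c]) for c in names], dtype=np.int64)
    weights = lengths / lengths.sum()

    is_trans = rng.random(n_pairs) < trans_fraction
    n_cis = int((~is_trans).sum())
    n_trans = n_pairs - n_cis

    rows: list[tuple[str, int, str, int]] = []
    ci = rng.choice(len(names), size=n_cis, p=weights)
    for k in range(n_cis):
        L = int(lengths[ci[k]])
        s = int(
            _power_law_separations(1, min_separation, L - 1, decay_exponent, rng)[0]
        )
        p1 = int(rng.integers(0, L))
        if p1 + s < L and (p1 - s >= 0) and rng.random() < 0.5:
            p2 = p1 - s
        elif p1 + s < L:
            p2 = p1 + s
        elif p1 - s >= 0:
            p2 = p1 - s
        else:
            p1 = int(rng.integers(0, L - s))
            p2 = p1 + s
        rows.append((names[ci[k]], p1, names[ci[k]], p2))
    for _ in range(n_trans):
        a = int(rng.choice(len(names), p=weights))
        b = int(rng.choice(len(names), p=weights))
        while b == a:
            b = int(rng.choice(len(names), p=weights))
        rows.append(
            (
                names[a],
                int(rng.integers(0, lengths[a])),
                names[b],
                int(rng.integers(0, lengths[b])),
            )
        )
    return pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])


# ---------------------------------------------------------------------------
# Gene models for homeolog pairing
# ---------------------------------------------------------------------------


@dataclass
class PlantedGenes:
    """Planted gene models on both subgenomes plus updated sequences."""

    pair: SubgenomePair
    annot_o: list
    annot_r: list
    truth: TruthSet


def _random_orf(length: int, rng: np.random.Generator) -> str:
    """A valid ORF: ATG + non-stop codons + TGA; ``length`` divisible by 3."""
    if length % 3 or length < 9:
        raise ValueError("ORF length must be >= 9 and divisible by 3")
    body = []
    while len(body) < (length - 6) // 3:
        codon = "".join(chr(_BASES[b]) for b in rng.integers(0, 4, size=3))
        if codon not in _STOPS:
            body.append(codon)
    return "ATG" + "".join(body) + "TGA"


def _mutate_orf(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases at ``rate`` without breaking ORF validity."""
    arr = _seq_to_array(cds)
    for pos in np.flatnonzero(rng.random(len(arr)) < rate):
        if pos < 3 or pos >= len(arr) - 3:
            continue  # keep start and stop codons intact
        old = arr[pos]
        for _ in range(4):
            new = _BASES[rng.integers(0, 4)]
            if new == old:
                continue
            arr[pos] = new
            frame = (pos // 3) * 3
            if arr[frame : frame + 3].tobytes().decode() not in _STOPS:
                break
            arr[pos] = old
    return _array_to_seq(arr)


def plant_gene_models(
    pair: SubgenomePair,
    truth: TruthSet,
    genes_per_chromosome: int = 20,
    cds_length: int = 300,
    seed: int = 0,
):
    """Plant homeologous gene pairs into both subgenomes.

    Genes are evenly spaced, identical ORFs written at the same coordinates
    of both subgenomes, after which the R copy is re-diverged at the pair's
    SNP rate (ORF-preserving substitutions only).  True pairs are recorded
    in the truth set; the divergence-variant list is updated for the
    overwritten intervals.

    Imported lazily by callers that need annotation; returns a
    :class:`PlantedGenes` with fresh ``SubgenomePair`` genomes.
    """
    from .homeolog import GeneModel

    rng = np.random.default_rng(seed)
    rate = pair.divergence_snp_rate
    chroms_o = {n: _seq_to_array(s) for n, s in pair.genome_o.chromosomes.items()}
    chroms_r = {n: _seq_to_array(s) for n, s in pair.genome_r.chromosomes.items()}
    annot_o: list[GeneModel] = []
    annot_r: list[GeneModel] = []
    gene_intervals: dict[str, list[tuple[int, int]]] = {}
    for name_o, arr_o in chroms_o.items():
        name_r = pair.homeolog_name(name_o)
        arr_r = chroms_r[name_r]
        L = len(arr_o)
        starts = np.linspace(0, L - cds_length - 1, genes_per_chromosome + 2)[1:-1]
        gene_intervals[name_o] = []
        for g, start in enumerate(starts.astype(int), start=1):
            orf = _random_orf(cds_length, rng)
            orf_r = _mutate_orf(orf, rate, rng)
            end = start + cds_length
            arr_o[start:end] = _seq_to_array(orf)
            arr_r[start:end] = _seq_to_array(orf_r)
            gid_o = f"{name_o}.gene{g:03d}"
            gid_r = f"{name_r}.gene{g:03d}"
            annot_o.append(GeneModel(gid_o, name_o, int(start), int(end), "+", orf))
            annot_r.append(GeneModel(gid_r, name_r, int(start), int(end), "+", orf_r))
            truth.homeolog_pairs_truth.append((gid_r, gid_o))
            gene_intervals[name_o].append((int(start), int(end)))

    # refresh the divergence-variant bookkeeping inside overwritten intervals
    kept = []
    for chrom, pos, a_o, a_r in pair.true_variants:
        if any(s <= pos < e for s, e in gene_intervals.get(chrom, ())):
            continue
        kept.append((chrom, pos, a_o, a_r))
    for name_o in chroms_o:
        arr_o, arr_r = chroms_o[name_o], chroms_r[pair.homeolog_name(name_o)]
        for s, e in gene_intervals[name_o]:
            diff = np.flatnonzero(arr_o[s:e] != arr_r[s:e])
            for d in diff:
                kept.append(
                    (name_o, int(s + d), chr(arr_o[s + d]), chr(arr_r[s + d]))
                )
    kept.sort(key=lambda v: (v[0], v[1]))
    new_pair = SubgenomePair(
        Genome({n: _array_to_seq(a) for n, a in chroms_o.items()}),
        Genome({n: _array_to_seq(a) for n, a in chroms_r.items()}),
        rate,
        kept,
    )
    return PlantedGenes(new_pair, annot_o, annot_r, truth)


def apply_deleted_region(
    planted: PlantedGenes, chromosome_r: str, start: int, end: int, seed: int = 0
) -> PlantedGenes:
    """Make an R-subgenome region with no homologous O counterpart.

    Models a lineage-specific fragment (present in R, absent from O) while
    preserving the substitution-only coordinate frame: the homeologous O
    interval is overwritten with unrelated random sequence and O gene models
    inside it are dropped.  The region is recorded as the truth set's
    ``deleted_region``.
    """
    rng = np.random.default_rng(seed)
    pair = planted.pair
    name_o = pair.homeolog_name(chromosome_r)
    arr = _seq_to_array(pair.genome_o[name_o])
    arr[start:end] = _BASES[rng.integers(0, 4, size=end - start)]
    chroms_o = dict(pair.genome_o.chromosomes)
    chroms_o[name_o] = _array_to_seq(arr)
    dropped = {
        g.id for g in planted.annot_o if g.chromosome == name_o and g.start >= start and g.end <= end
    }
    annot_o = [g for g in planted.annot_o if g.id not in dropped]
    old = planted.truth
    truth = TruthSet(
        chimera_junctions=list(old.chimera_junctions),
        he_breakpoints=list(old.he_breakpoints),
        homeolog_pairs_truth=[
            (r, o) for r, o in old.homeolog_pairs_truth if o not in dropped
        ],
        crossovers=old.crossovers,
        deleted_region=(chromosome_r, start, end),
    )
    variants = [
        v for v in pair.true_variants if not (v[0] == name_o and start <= v[1] < end)
    ]
    new_pair = SubgenomePair(Genome(chroms_o), pair.genome_r, pair.divergence_snp_rate, variants)
    return PlantedGenes(new_pair, annot_o, planted.annot_r, truth)


# ---------------------------------------------------------------------------
# Four-population site patterns for introgression statistics
# ---------------------------------------------------------------------------

_QUARTET_CLASSES = ("p1", "p2", "p3", "p12", "ils")
_DEFAULT_CLASS_WEIGHTS = (0.2, 0.2, 0.2, 0.25, 0.15)


def simulate_quartet_sites(
    n_sites: int,
    n_per_pop: int = 2,
    introgression_fraction: float = 0.0,
    class_weights: tuple[float, ...] = _DEFAULT_CLASS_WEIGHTS,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Haploid 0/1 genotypes for populations P1, P2, P3 and an outgroup.

    Each variable site carries one derived mutation placed on a branch of
    the species tree (((P1,P2),P3),O): private to P1, P2 or P3, shared by
    P1+P2, or an incomplete-lineage-sorting class where two of the three
    ingroups share the derived allele at random.  Under no introgression the
    ABBA and BABA classes are exactly symmetric.  With probability
    ``introgression_fraction`` a site's P2 state is overwritten by P3's
    state, creating the ABBA excess expected from P3->P2 gene flow.  The
    outgroup is always ancestral.
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(class_weights, dtype=float)
    w = w / w.sum()
    cls = rng.choice(len(_QUARTET_CLASSES), size=n_sites, p=w)
    derived = {
        "P1": np.zeros(n_sites, dtype=np.int8),
        "P2": np.zeros(n_sites, dtype=np.int8),
        "P3": np.zeros(n_sites, dtype=np.int8),
        "O": np.zeros(n_sites, dtype=np.int8),
    }
    derived["P1"][cls == 0] = 1
    derived["P2"][cls == 1] = 1
    derived["P3"][cls == 2] = 1
    derived["P1"][cls == 3] = 1
    derived["P2"][cls == 3] = 1
    ils = np.flatnonzero(cls == 4)
    pick = rng.integers(0, 3, size=ils.size)  # 0:(P1,P2) 1:(P1,P3) 2:(P2,P3)
    derived["P1"][ils[pick != 2]] = 1
    derived["P2"][ils[(pick == 0) | (pick == 2)]] = 1
    derived["P3"][ils[pick != 0]] = 1
    if introgression_fraction > 0:
        intro = rng.random(n_sites) < introgression_fraction
        derived["P2"][intro] = derived["P3"][intro]
    return {
        pop: np.tile(state, (n_per_pop, 1)) for pop, state in derived.items()
    }
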