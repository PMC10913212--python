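"""Coverage-based subgenome assignment and HE breakpoint detection.

Reads of each diploid parent are mapped on the tetraploid assembly and the
per-10-kb-window depth contrast between the two parents tells which
subgenome each chromosome (or segment) derives from.  A chromosome whose
log-ratio track switches sign partway is a hybrid produced by homeologous
exchange; the switch point is the exchange breakpoint.

The caller works on the log2 ratio of the two depth tracks, segments it by
binary segmentation (minimising within-segment squared error), labels each
segment by mean sign, and reports per-chromosome calls with breakpoints and
a window-agreement confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomes import DepthTrack, Genome

K_ASSIGN = 31  # k-mer size for the read-assignment validation


@dataclass
class CoverageProfile:
    """Windowed depth of both parental read sets on one chromosome."""

    chromosome: str
    window_size: int
    depth_o: np.ndarray
    depth_r: np.ndarray

    def __post_init__(self) -> None:
        self.depth_o = np.asarray(self.depth_o, dtype=float)
        self.depth_r = np.asarray(self.depth_r, dtype=float)
        if self.depth_o.shape != self.depth_r.shape:
            raise ValueError("depth arrays differ in length")
        if self.depth_o.size == 0:
            raise ValueError("empty coverage profile")
        if np.any(self.depth_o < 0) or np.any(self.depth_r < 0):
            raise ValueError("negative depths")

    @property
    def n_windows(self) -> int:
        return self.depth_o.size


def profiles_from_tracks(
    track_o: DepthTrack, track_r: DepthTrack
) -> list[CoverageProfile]:
    if track_o.window_size != track_r.window_size:
        raise ValueError("depth tracks use different window sizes")
    return [
        CoverageProfile(c, track_o.window_size, track_o.values[c], track_r.values[c])
        for c in track_o.values
    ]


@dataclass
class SubgenomeCall:
    """Subgenome assignment of one chromosome.

    ``segments`` tile the chromosome; a chromosome is ``hybrid`` exactly
    when segments from both sources are present.  ``confidence`` is the
    fraction of windows that are unambiguous and agree with their segment's
    label.
    """

    chromosome: str
    label: str  # O | R | hybrid | unassigned
    segments: list[tuple[int, int, str]] = field(default_factory=list)
    breakpoints: list[int] = field(default_factory=list)
    confidence: float = 0.0


def window_log_ratio(profile: CoverageProfile, pseudocount: float = 1.0) -> np.ndarray:
    """log2((depth_O + pc) / (depth_R + pc)) per window; positive favours O."""
    return np.log2((profile.depth_o + pseudocount) / (profile.depth_r + pseudocount))


def _binary_segmentation(x: np.ndarray, min_size: int, penalty: float) -> list[int]:
    """Breakpoint indices by recursive binary segmentation on squared error.

    A split is accepted while it lowers the within-segment sum of squares by
    more than ``penalty``.  Returns sorted interior boundaries.
    """

    def sse(lo: int, hi: int) -> float:
        seg = x[lo:hi]
        return float(((seg - seg.mean()) ** 2).sum()) if hi > lo else 0.0

    def best_split(lo: int, hi: int) -> tuple[float, int] | None:
        total = sse(lo, hi)
        best = None
        csum = np.cumsum(x[lo:hi])
        csq = np.cumsum(x[lo:hi] ** 2)
        n = hi - lo
        for k in range(min_size, n - min_size + 1):
            left = csq[k - 1] - csum[k - 1] ** 2 / k
            right = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
            gain = total - (left + right)
            if best is None or gain > best[0]:
                best = (gain, lo + k)
        return best

    bounds: list[int] = []
    stack = [(0, x.size)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_size:
            continue
        split = best_split(lo, hi)
        if split is None or split[0] <= penalty:
            continue
        _, k = split
        bounds.append(k)
        stack.append((lo, k))
        stack.append((k, hi))
    return sorted(bounds)


def call_subgenome(
    profile: CoverageProfile,
    min_abs_log_ratio: float = 1.0,
    min_segment_windows: int = 5,
    pseudocount: float = 1.0,
) -> SubgenomeCall:
    """Assign a chromosome (or its segments) to parental subgenomes.

    The defaults make a 2-fold coverage bias decisive: windows with
    |log2 ratio| below ``min_abs_log_ratio`` count against confidence, and
    segments shorter than ``min_segment_windows`` are merged into their
    neighbours before labelling.
    """
    if profile.n_windows < min_segment_windows:
        raise ValueError("chromosome shorter than min_segment_windows windows")
    lr = window_log_ratio(profile, pseudocount)
    unambiguous = np.abs(lr) >= min_abs_log_ratio
    if not unambiguous.any():
        return SubgenomeCall(profile.chromosome, "unassigned")

    noise = np.median(np.abs(np.diff(lr))) / (np.sqrt(2) * 0.6745)
    noise = max(noise, 1e-3)
    penalty = 3.0 * noise**2 * np.log(max(lr.size, 2))
    bounds = _binary_segmentation(lr, min_segment_windows, penalty)

    # label segments by mean sign, then merge adjacent same-label segments
    edges = [0, *bounds, lr.size]
    segments: list[tuple[int, int, str]] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = "O" if lr[lo:hi].mean() >= 0 else "R"
        if segments and segments[-1][2] == label:
            segments[-1] = (segments[-1][0], hi, label)
        else:
            segments.append((lo, hi, label))

    ws = profile.window_size
    length_bp = None  # windows are the native unit; bp via window index
    seg_bp = [
        (lo * ws, hi * ws, label) for lo, hi, label in segments
    ]
    breakpoints = [lo for lo, _, _ in seg_bp[1:]]
    sources = {label for _, _, label in segments}
    label = "hybrid" if len(sources) > 1 else next(iter(sources))

    agree = 0
    for lo, hi, seg_label in segments:
        signs = lr[lo:hi] > 0 if seg_label == "O" else lr[lo:hi] < 0
        agree += int((signs & unambiguous[lo:hi]).sum())
    confidence = agree / lr.size
    return SubgenomeCall(profile.chromosome, label, seg_bp, breakpoints, confidence)


# ---------------------------------------------------------------------------
# Read-assignment validation on a combined reference
# ---------------------------------------------------------------------------


def _kmer_index(genome: Genome, k: int) -> dict[bytes, object]:
    """Map each k-mer to its chromosome, or to a tuple when shared."""
    index: dict[bytes, object] = {}
    for name, seq in genome.chromosomes.items():
        raw = seq.encode()
        for i in range(len(raw) - k + 1):
            kmer = raw[i : i + k]
            hit = index.get(kmer)
            if hit is None:
                index[kmer] = name
            elif isinstance(hit, str):
                if hit != name:
                    index[kmer] = (hit, name)
            elif name not in hit:
                index[kmer] = (*hit, name)
    return index


def validate_assignment_by_simulation(
    pair,
    combined: Genome,
    read_length: int = 150,
    n_reads: int = 10_000,
    seed: int = 0,
    k: int = K_ASSIGN,
) -> dict[str, float]:
    """Fraction of simulated parental reads assigned to the right subgenome.

    Error-free reads are sampled from each parental genome and assigned to
    the combined-reference chromosome sharing the most exact k-mers; ties
    (including the fully identical-subgenome case) leave the read
    unassigned.  Returns ``{"O": fraction, "R": fraction}`` of reads
    assigned to the correct subgenome, the in-silico analogue of mapping
    parental species reads on the merged reference.
    """
    if k > read_length:
        raise ValueError("k-mer size exceeds read length")
    rng = np.random.default_rng(seed)
    index = _kmer_index(combined, k)
    out: dict[str, float] = {}
    for parent_label, genome in (("O", pair.genome_o), ("R", pair.genome_r)):
        names = genome.names
        lengths = np.array([len(genome[c]) for c in names], dtype=float)
        weights = lengths / lengths.sum()
        correct = 0
        for _ in range(n_reads):
            c = int(rng.choice(len(names), p=weights))
            seq = genome[names[c]]
            start = int(rng.integers(0, len(seq) - read_length + 1))
            read = seq[start : start + read_length].encode()
            votes: dict[str, int] = {}
            for i in range(read_length - k + 1):
                hit = index.get(read[i : i + k])
                if hit is None:
                    continue
                for chrom in (hit,) if isinstance(hit, str) else hit:
                    votes[chrom] = votes.get(chrom, 0) + 1
            if not votes:
                continue
            top = max(votes.values())
            winners = [c2 for c2, v in votes.items() if v == top]
            if len(winners) != 1:
                continue
            if winners[0][0] == parent_label:
                correct += 1
        out[parent_label] = correct / n_reads
    return out
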