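"""Pseudoalignments and introgression statistics.

A pseudoalignment is a per-sample sequence rebuilt from the reference by
substituting each sample's SNPs: low-depth sites become N, heterozygous
sites become the two-base IUPAC ambiguity code, and every non-variable
position keeps the reference base.  Because no realignment happens, the
per-chromosome-arm multi-FASTA is positionally homologous by construction
and feeds directly into tree inference or site-pattern statistics.

Patterson's D (ABBA-BABA) and the f4-ratio are computed from derived-allele
frequencies with the outgroup defining the ancestral state; the Z-score
comes from a delete-one block jackknife over contiguous site blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: two-base IUPAC ambiguity codes for heterozygous calls
IUPAC = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

#: reverse lookup: ambiguity code -> the two bases it denotes
IUPAC_BASES = {code: pair for pair, code in IUPAC.items()}

DEFAULT_MIN_DEPTH = 4


@dataclass(frozen=True)
class SampleCall:
    """One sample's call at one site: genotype plus depth."""

    ref: str
    alt: str | None
    n_alt: int  # 0, 1, 2 alternative alleles
    depth: int


# ---------------------------------------------------------------------------
# Site list
# ---------------------------------------------------------------------------


def build_site_list(sample_variants: dict[str, object]) -> pd.DataFrame:
    """Union of biallelic SNP positions across samples, sorted.

    ``sample_variants`` maps sample -> VCF path or iterable of
    ``(chromosome, position, ref, alt)`` tuples (0-based position in tuple
    form).  Indels are excluded; sites where samples disagree on the
    alternative allele are kept and logged.
    """
    seen: dict[tuple[str, int], set[str]] = {}
    ref_of: dict[tuple[str, int], str] = {}
    for sample, source in sample_variants.items():
        for chrom, pos, ref, alt in _iter_snvs(source):
            if len(ref) != 1 or alt is None or len(alt) != 1:
                continue
            key = (chrom, pos)
            seen.setdefault(key, set()).add(alt)
            ref_of[key] = ref
    conflicts = sum(1 for alts in seen.values() if len(alts) > 1)
    if conflicts:
        logger.info("build_site_list: %d sites with conflicting alt alleles kept", conflicts)
    rows = sorted(seen)
    return pd.DataFrame(
        {
            "chromosome": [c for c, _ in rows],
            "position": [p for _, p in rows],
            "ref": [ref_of[k] for k in rows],
            "alts": [",".join(sorted(seen[k])) for k in rows],
        }
    )


def _iter_snvs(source):
    if isinstance(source, (str, Path)):
        import pysam

        with pysam.VariantFile(str(source)) as vcf:
            for rec in vcf:
                alts = rec.alts or ()
                alt = alts[0] if len(alts) == 1 else None
                yield rec.contig, rec.pos - 1, rec.ref, alt
    else:
        yield from source


# ---------------------------------------------------------------------------
# Base substitution rules
# ---------------------------------------------------------------------------


def genotype_to_base(
    ref_base: str, call: SampleCall | None, min_depth: int = DEFAULT_MIN_DEPTH
) -> str:
    """Output base for one sample at one listed site.

    Depth below ``min_depth`` masks the site to N.  A homozygous
    alternative call substitutes the alternative base; a heterozygous call
    becomes the IUPAC code of {ref, alt}; a covered site with no SNP call
    keeps the reference base.
    """
    if ref_base not in "ACGT":
        raise ValueError(f"reference base {ref_base!r} is not a nucleotide")
    if call is None or call.depth < min_depth:
        return "N"
    if call.n_alt == 0 or call.alt is None:
        return ref_base
    if call.alt not in "ACGT":
        raise ValueError(f"allele {call.alt!r} is not a nucleotide")
    if call.n_alt == 2:
        return call.alt
    pair = frozenset((ref_base, call.alt))
    if len(pair) == 1:  # degenerate het call on the same base
        return ref_base
    return IUPAC[pair]


def build_pseudoalignment(
    reference: str,
    region: tuple[str, int, int],
    sites: pd.DataFrame,
    samples: dict[str, dict[int, SampleCall]],
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> dict[str, str]:
    """Multi-sample pseudoalignment of one chromosome-arm region.

    ``reference`` is the full chromosome sequence of ``region`` =
    (chromosome, start, end); ``sites`` is the site list restricted by
    chromosome internally; ``samples`` maps sample -> {position: call}.  A
    sample absent at a listed site (no entry) keeps the reference base only
    if its calls include an explicit covered no-SNP record; an absent entry
    is treated as unknown coverage and masked to N.  The output always
    includes a ``reference`` record and every row has region length.
    """
    chrom, start, end = region
    if not 0 <= start < end <= len(reference):
        raise ValueError("region outside reference")
    local = sites[sites["chromosome"] == chrom]
    pos = local["position"].to_numpy()
    if ((pos < start) | (pos >= end)).any():
        raise ValueError("site list contains positions outside the region")
    ref_seq = reference[start:end]
    out = {"reference": ref_seq}
    for sample, calls in samples.items():
        arr = list(ref_seq)
        for p in pos:
            ref_base = reference[p]
            arr[p - start] = genotype_to_base(ref_base, calls.get(int(p)), min_depth)
        out[sample] = "".join(arr)
    return out


def pairwise_differences(a: str, b: str) -> int:
    """Mismatches between equal-length rows, skipping positions with N."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    n = ord("N")
    mask = (aa != n) & (bb != n)
    return int(((aa != bb) & mask).sum())


# ---------------------------------------------------------------------------
# Patterson's D and f4-ratio
# ---------------------------------------------------------------------------


@dataclass
class DResult:
    """ABBA-BABA result for one quartet."""

    d: float
    z: float
    f4_ratio: float
    n_abba: float
    n_baba: float
    n_sites: int


def derived_frequencies(
    genotypes: dict[str, np.ndarray], outgroup: str = "O"
) -> dict[str, np.ndarray]:
    """Per-population derived-allele frequencies with the outgroup ancestral.

    ``genotypes`` maps population -> (n_samples, n_sites) allele matrix in
    {0, 1} (haploid samples; diploid heterozygotes may be encoded as 0.5).
    Sites where the outgroup is polymorphic are masked (NaN) — the
    ancestral state is then undefined.
    """
    freqs = {pop: np.asarray(g, dtype=float).mean(axis=0) for pop, g in genotypes.items()}
    anc = freqs[outgroup]
    polarized = {}
    undefined = (anc > 0) & (anc < 1)
    for pop, p in freqs.items():
        q = np.where(anc >= 0.5, 1.0 - p, p)  # polarise on the outgroup allele
        q = np.where(undefined, np.nan, q)
        polarized[pop] = q
    return polarized


def patterson_d(
    freqs: dict[str, np.ndarray],
    quartet: tuple[str, str, str, str] = ("P1", "P2", "P3", "O"),
    block_size: int = 1000,
    p3_split: tuple[np.ndarray, np.ndarray] | None = None,
) -> DResult:
    """Patterson's D and f4-ratio from derived-allele frequencies.

    With derived frequencies p1, p2, p3 (the outgroup fixed ancestral),

        D = sum[(1-p1) p2 p3 - p1 (1-p2) p3] / sum[(1-p1) p2 p3 + p1 (1-p2) p3]

    summed over sites where every population has data.  The Z-score uses a
    delete-one block jackknife over contiguous ``block_size``-site blocks.

    The f4-ratio estimates the fraction of P2's ancestry derived from the
    P3 lineage by normalising the D numerator with the value it would take
    under complete introgression (P2 replaced by P3), using two independent
    halves a/b of P3's samples:

        alpha = sum[(1-p1) p2 p3b - p1 (1-p2) p3b]
              / sum[(1-p1) p3a p3b - p1 (1-p3a) p3b]

    When no ``p3_split`` is supplied both halves fall back to the pooled P3
    frequency, which mildly biases alpha upward at polymorphic sites.
    """
    p1_name, p2_name, p3_name, out_name = quartet
    p1, p2, p3 = freqs[p1_name], freqs[p2_name], freqs[p3_name]
    po = freqs[out_name]
    if p3_split is not None:
        p3a, p3b = p3_split
    else:
        p3a, p3b = p3, p3
    valid = ~(
        np.isnan(p1)
        | np.isnan(p2)
        | np.isnan(p3)
        | np.isnan(po)
        | np.isnan(p3a)
        | np.isnan(p3b)
    )
    p1, p2, p3 = p1[valid], p2[valid], p3[valid]
    p3a, p3b = p3a[valid], p3b[valid]
    n_sites = int(valid.sum())
    abba = (1 - p1) * p2 * p3
    baba = p1 * (1 - p2) * p3
    num = abba - baba
    den = abba + baba
    if den.sum() == 0:
        return DResult(np.nan, np.nan, np.nan, float(abba.sum()), float(baba.sum()), n_sites)
    d = float(num.sum() / den.sum())

    # delete-one block jackknife
    n_blocks = n_sites // block_size
    if n_blocks >= 2:
        estimates = []
        for b in range(n_blocks):
            lo, hi = b * block_size, (b + 1) * block_size if b < n_blocks - 1 else n_sites
            mask = np.ones(n_sites, dtype=bool)
            mask[lo:hi] = False
            db_den = den[mask].sum()
            if db_den > 0:
                estimates.append(num[mask].sum() / db_den)
        g = len(estimates)
        if g >= 2:
            est = np.asarray(estimates)
            se = np.sqrt((g - 1) / g * ((est - est.mean()) ** 2).sum())
            z = float(d / se) if se > 0 else np.nan
        else:
            z = np.nan
    else:
        z = np.nan

    f4_num = ((1 - p1) * p2 * p3b - p1 * (1 - p2) * p3b).sum()
    f4_den = ((1 - p1) * p3a * p3b - p1 * (1 - p3a) * p3b).sum()
    f4_ratio = float(f4_num / f4_den) if f4_den != 0 else np.nan
    return DResult(d, z, f4_ratio, float(abba.sum()), float(baba.sum()), n_sites)


def patterson_d_from_genotypes(
    genotypes: dict[str, np.ndarray],
    quartet: tuple[str, str, str, str] = ("P1", "P2", "P3", "O"),
    block_size: int = 1000,
) -> DResult:
    """Polarise genotypes on the outgroup, then compute D and the f4-ratio.

    When P3 has at least two samples its matrix is split into two halves to
    form the independent a/b frequency estimates of the f4-ratio.
    """
    freqs = derived_frequencies(genotypes, outgroup=quartet[3])
    p3 = np.asarray(genotypes[quartet[2]], dtype=float)
    p3_split = None
    if p3.shape[0] >= 2:
        half = p3.shape[0] // 2
        sub = {
            "a": p3[:half],
            "b": p3[half:],
            quartet[3]: np.asarray(genotypes[quartet[3]], dtype=float),
        }
        split_freqs = derived_frequencies(sub, outgroup=quartet[3])
        p3_split = (split_freqs["a"], split_freqs["b"])
    return patterson_d(freqs, quartet, block_size, p3_split=p3_split)


def frequencies_from_alignment(
    alignment: dict[str, str],
    groups: dict[str, list[str]],
    outgroup_pop: str,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Derived-allele frequencies per population from a pseudoalignment.

    Heterozygous IUPAC bases contribute allele frequency 0.5; N bases are
    missing.  Only biallelic sites polymorphic across the ingroup with a
    fixed outgroup allele are retained.  Returns (freqs, site positions).
    """
    samples = [s for pops in groups.values() for s in pops]
    length = len(next(iter(alignment.values())))
    mats = {}
    for pop, members in groups.items():
        mats[pop] = [alignment[s] for s in members]

    freqs: dict[str, list[float]] = {pop: [] for pop in groups}
    positions: list[int] = []
    for i in range(length):
        # collect allele weights at this column
        counts: dict[str, float] = {}
        ok = True
        column: dict[str, dict[str, float]] = {}
        for pop, rows in mats.items():
            w: dict[str, float] = {}
            for row in rows:
                base = row[i]
                if base == "N":
                    continue
                if base in "ACGT":
                    w[base] = w.get(base, 0.0) + 1.0
                elif base in IUPAC_BASES:
                    for b in IUPAC_BASES[base]:
                        w[b] = w.get(b, 0.0) + 0.5
                else:
                    ok = False
            if not w:
                ok = False
                break
            column[pop] = w
            for b, c in w.items():
                counts[b] = counts.get(b, 0.0) + c
        if not ok or len(counts) != 2:
            continue
        out_w = column[outgroup_pop]
        if len(out_w) != 1:
            continue  # outgroup must be fixed to define the ancestral state
        ancestral = next(iter(out_w))
        derived = next(b for b in counts if b != ancestral)
        positions.append(i)
        for pop, w in column.items():
            total = sum(w.values())
            freqs[pop].append(w.get(derived, 0.0) / total)
    return {pop: np.asarray(v) for pop, v in freqs.items()}, np.asarray(positions)
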