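"""F2 genetic-map construction and marker-based assembly checking.

The workflow mirrors how a dense F2 segregation dataset is used to audit a
long-read assembly of a selfing allotetraploid:

1. build a database of markers homozygous for the non-reference allele in
   one F0 parent;
2. call the marker state of every F2 plant (-1 reference homozygote,
   0 heterozygote, +1 alternative homozygote, NaN unidentified);
3. filter markers by missingness and by a Pearson chi-square test of the
   expected 1:2:1 segregation;
4. flag adjacent-marker intervals showing more than ``max_recombinations``
   apparent recombination events as misassemblies — physically joined but
   genetically unlinked sequence produces ~35-40 events per 100 chromosomes
   in a 50-plant F2, far above anything genetic linkage allows over a few
   kilobases;
5. average marker states per contig into A/B/X codes and cluster contigs
   into linkage groups via recombination fractions.

State matrices are numpy arrays of shape (n_markers, n_plants) with values
in {-1, 0, 1} and NaN for missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import F2Cohort

logger = logging.getLogger(__name__)

MISSING = np.nan

#: Pearson chi-square threshold for 1:2:1 segregation (df=2, alpha=0.05)
DEFAULT_CHI2_THRESHOLD = 5.99


def segregation_chi2_critical(alpha: float = 0.05, df: int = 2) -> float:
    """Critical value of the segregation-distortion chi-square test.

    For a codominant F2 marker the three genotype classes give two degrees
    of freedom; at alpha = 0.05 the critical value rounds to 5.99.
    """
    return float(stats.chi2.ppf(1.0 - alpha, df))


# ---------------------------------------------------------------------------
# Marker database and state calling
# ---------------------------------------------------------------------------


@dataclass
class MarkerDB:
    """Homozygous-alternative SNP markers of one F0 parent."""

    records: pd.DataFrame  # columns: contig, position, ref, alt
    source: str = "F0"

    def __len__(self) -> int:
        return len(self.records)


def build_marker_db(
    f0_variants, source: str = "F0"
) -> MarkerDB:
    """Retain biallelic SNPs homozygous for the non-reference allele.

    ``f0_variants`` is either a path to a VCF (parsed with pysam) or an
    iterable of ``(contig, position, ref, alt, genotype)`` tuples where
    genotype is the alternative-allele count (0, 1, 2).  Positions are
    0-based in tuple form and converted from 1-based when read from VCF.
    Indels and multi-allelic records are skipped with a logged count.
    """
    rows = []
    skipped = 0
    for contig, pos, ref, alt, gt in _iter_variants(f0_variants):
        if len(ref) != 1 or alt is None or len(alt) != 1:
            skipped += 1
            continue
        if gt == 2:
            rows.append((contig, pos, ref, alt))
    if skipped:
        logger.info("build_marker_db: skipped %d non-SNP/multi-allelic records", skipped)
    df = pd.DataFrame(rows, columns=["contig", "position", "ref", "alt"])
    df = df.sort_values(["contig", "position"], kind="mergesort").reset_index(drop=True)
    if df.empty:
        logger.warning("build_marker_db: no homozygous-alternative markers found")
    if df.duplicated(["contig", "position"]).any():
        raise ValueError("duplicate marker positions in F0 variants")
    return MarkerDB(df, source=source)


def _iter_variants(source):
    if isinstance(source, (str, Path)):
        import pysam

        with pysam.VariantFile(str(source)) as vcf:
            sample = list(vcf.header.samples)[0]
            for rec in vcf:
                alts = rec.alts or ()
                alt = alts[0] if len(alts) == 1 else None
                gt = rec.samples[sample].get("GT", (None, None))
                n_alt = sum(1 for a in gt if a not in (None, 0)) if gt else None
                yield rec.contig, rec.pos - 1, rec.ref, alt, n_alt
    else:
        yield from source


@dataclass
class MarkerStateTable:
    """Markers x plants matrix of F2 states with marker metadata.

    ``meta`` has columns ``contig`` and ``position``; within each contig the
    marker order equals position order.  States live in {-1, 0, 1, NaN}.
    """

    states: np.ndarray
    meta: pd.DataFrame
    plants: list[str]

    def __post_init__(self) -> None:
        if self.states.shape != (len(self.meta), len(self.plants)):
            raise ValueError("state matrix shape inconsistent with metadata")
        finite = self.states[np.isfinite(self.states)]
        if finite.size and not np.isin(finite, (-1.0, 0.0, 1.0)).all():
            raise ValueError("states must be -1, 0, 1 or NaN")
        for _, grp in self.meta.groupby("contig", sort=False):
            if np.any(np.diff(grp["position"].to_numpy()) < 0):
                raise ValueError("markers not position-ordered within contig")

    @property
    def n_markers(self) -> int:
        return len(self.meta)

    def subset(self, keep: np.ndarray) -> "MarkerStateTable":
        return MarkerStateTable(
            self.states[keep], self.meta.iloc[keep].reset_index(drop=True), self.plants
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.plants)
        return pd.concat([self.meta.reset_index(drop=True), df], axis=1)


def call_marker_states(
    db: MarkerDB,
    plant_variants: dict[str, dict[tuple[str, int], int]],
    plant_depths: dict[str, dict[tuple[str, int], int]],
    min_depth: int = 4,
) -> MarkerStateTable:
    """Call per-plant marker states from SNP calls plus depth.

    ``plant_variants`` maps plant -> {(contig, position): alt-allele count};
    a database site absent from a plant's calls is a reference homozygote
    when covered.  Sites with depth below ``min_depth`` are unidentified.
    Plants missing from ``plant_depths`` get all-missing columns.
    """
    if len(db) == 0:
        raise ValueError("marker database is empty")
    plants = sorted(plant_variants)
    keys = list(zip(db.records["contig"], db.records["position"]))
    states = np.full((len(keys), len(plants)), MISSING)
    for j, plant in enumerate(plants):
        depths = plant_depths.get(plant)
        if depths is None:
            logger.warning("no depth data for plant %s; all markers missing", plant)
            continue
        calls = plant_variants[plant]
        for i, key in enumerate(keys):
            if depths.get(key, 0) < min_depth:
                continue
            states[i, j] = calls.get(key, 0) - 1
    return MarkerStateTable(states, db.records[["contig", "position"]].copy(), plants)


def marker_states_from_cohort(
    cohort: F2Cohort,
    contig_map: pd.DataFrame | None = None,
    min_depth: int = 4,
) -> MarkerStateTable:
    """Vectorised state calling for a simulated F2 cohort.

    Applies the same rules as :func:`call_marker_states` (genotype 0/1/2 ->
    state -1/0/+1, depth below ``min_depth`` -> missing).  When
    ``contig_map`` (from :func:`allopolyphase.synthetic.markers_on_contigs`)
    is given, markers are re-addressed to contig coordinates, so chimeric
    contigs carry markers from both source chromosomes.
    """
    states = cohort.genotypes.T.astype(float) - 1.0
    states[cohort.depths.T < min_depth] = MISSING
    meta = cohort.markers.rename(columns={"chromosome": "contig"})[
        ["contig", "position"]
    ].copy()
    if contig_map is not None:
        # a marker may occur on several contigs (chimeras duplicate sequence)
        markers = cohort.markers[["chromosome", "position"]].reset_index(names="row")
        merged = markers.merge(contig_map, on=["chromosome", "position"], how="inner")
        merged = merged.sort_values(
            ["contig", "contig_position"], kind="mergesort"
        ).reset_index(drop=True)
        meta = pd.DataFrame(
            {
                "contig": merged["contig"].to_numpy(),
                "position": merged["contig_position"].to_numpy(),
            }
        )
        states = states[merged["row"].to_numpy()]
    return MarkerStateTable(states, meta, list(cohort.plants))


# ---------------------------------------------------------------------------
# Marker filtering
# ---------------------------------------------------------------------------


def filter_markers(
    table: MarkerStateTable,
    max_missing_fraction: float = 0.5,
    chi2_threshold: float = DEFAULT_CHI2_THRESHOLD,
) -> tuple[MarkerStateTable, pd.DataFrame]:
    """Remove over-missing and segregation-distorted markers.

    A marker is dropped when unidentified in more than
    ``max_missing_fraction`` of plants, or when its (-1, 0, +1) counts
    deviate from the 1:2:1 F2 expectation by Pearson chi-square above
    ``chi2_threshold``.  Returns the filtered table and a rejection log
    with one row per removed marker.  The operation is idempotent.
    """
    if table.n_markers == 0:
        raise ValueError("marker state table is empty")
    S = table.states
    n_plants = S.shape[1]
    missing = np.isnan(S).sum(axis=1)
    n_obs = n_plants - missing
    counts = np.stack(
        [(S == v).sum(axis=1) for v in (-1.0, 0.0, 1.0)], axis=1
    ).astype(float)
    expected = np.stack([n_obs * 0.25, n_obs * 0.5, n_obs * 0.25], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(
            np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0), axis=1
        )
    too_missing = missing > max_missing_fraction * n_plants
    distorted = ~too_missing & (n_obs > 0) & (chi2 > chi2_threshold)
    empty = ~too_missing & (n_obs == 0)
    drop = too_missing | distorted | empty
    reasons = np.where(
        too_missing | empty, "missingness", np.where(distorted, "segregation", "")
    )
    log = pd.concat(
        [
            table.meta.loc[drop, ["contig", "position"]].reset_index(drop=True),
            pd.DataFrame(
                {
                    "reason": reasons[drop],
                    "missing": missing[drop],
                    "chi2": chi2[drop],
                }
            ),
        ],
        axis=1,
    )
    kept = table.subset(np.flatnonzero(~drop))
    if kept.n_markers == 0:
        raise ValueError("all markers removed by filtering; no map can be built")
    return kept, log


# ---------------------------------------------------------------------------
# Recombination counting and misassembly detection
# ---------------------------------------------------------------------------


def count_interval_recombinations(
    states_m1: np.ndarray, states_m2: np.ndarray
) -> tuple[int, int, float]:
    """Apparent recombination events between two markers across an F2.

    Over plants where both states are known, each unit change in genotype
    counts as one event on one of the two homologous chromosomes (a
    -1 <-> +1 change counts two).  The rate is expressed per 100
    chromosomes: ``100 * events / (2 * informative)``.  With no informative
    plants the rate is NaN.
    """
    s1 = np.asarray(states_m1, dtype=float)
    s2 = np.asarray(states_m2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("state vectors differ in length")
    both = ~np.isnan(s1) & ~np.isnan(s2)
    informative = int(both.sum())
    events = int(np.abs(s1[both] - s2[both]).sum())
    rate = 100.0 * events / (2 * informative) if informative else float("nan")
    return events, informative, rate


def _adjacent_pair_events(table: MarkerStateTable) -> pd.DataFrame:
    """Event/informative counts for every within-contig adjacent marker pair."""
    S = table.states
    contigs = table.meta["contig"].to_numpy()
    same = contigs[1:] == contigs[:-1]
    a, b = S[:-1], S[1:]
    both = ~np.isnan(a) & ~np.isnan(b)
    diff = np.abs(np.where(both, a - b, 0.0))
    events = diff.sum(axis=1)
    informative = both.sum(axis=1)
    idx = np.flatnonzero(same)
    pos = table.meta["position"].to_numpy()
    return pd.DataFrame(
        {
            "contig": contigs[idx],
            "left_index": idx,
            "left_position": pos[idx],
            "right_position": pos[idx + 1],
            "events": events[idx].astype(int),
            "informative": informative[idx].astype(int),
        }
    )


def detect_misassemblies(
    table: MarkerStateTable,
    max_recombinations: int = 2,
    min_rate_per_100: float | None = None,
) -> pd.DataFrame:
    """Flag adjacent-marker intervals with too many apparent recombinations.

    An interval is reported when strictly more than ``max_recombinations``
    events are observed between its two markers — the signature of
    physically joined but genetically unlinked sequence, which shows
    recombination rates far above anything linkage allows (tens of events
    per 100 chromosomes against an expectation well below one over a few
    kilobases).

    ``min_rate_per_100``, when set, additionally requires the
    per-100-chromosome rate to reach that value.  This guards against a
    side effect of the segregation filter: removing a distorted *block* of
    linked markers leaves a wide physical gap whose genuine genetic length
    can exceed the raw event threshold.  True mis-joins sit near the
    unlinked expectation (around 35-40 per 100 chromosomes in an F2), so a
    modest rate floor separates them cleanly.  Contigs with fewer than two
    markers are skipped (and logged).  Returns a BED-like frame of split
    intervals with event counts and rates.
    """
    n_per_contig = table.meta.groupby("contig", sort=False).size()
    short = n_per_contig[n_per_contig < 2]
    if len(short):
        logger.info("detect_misassemblies: %d contigs with < 2 markers skipped", len(short))
    pairs = _adjacent_pair_events(table)
    hits = pairs[pairs["events"] > max_recombinations].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        hits["rate_per_100"] = 100.0 * hits["events"] / (2 * hits["informative"])
    if min_rate_per_100 is not None:
        hits = hits[hits["rate_per_100"] >= min_rate_per_100]
    return hits.reset_index(drop=True)


def remove_noisy_markers(
    table: MarkerStateTable, flagged: pd.DataFrame
) -> MarkerStateTable:
    """Drop markers that participate in two or more flagged intervals.

    Automates the manual clean-up of high-recombination regions: a marker
    whose flanking intervals are both flagged is treated as noise rather
    than as two independent breakpoints.
    """
    votes = np.zeros(table.n_markers, dtype=int)
    for li in flagged["left_index"].to_numpy():
        votes[li] += 1
        votes[li + 1] += 1
    return table.subset(np.flatnonzero(votes < 2))


def apply_splits(table: MarkerStateTable, flagged: pd.DataFrame) -> MarkerStateTable:
    """Split contigs at flagged intervals, renaming the resulting pieces.

    Markers keep their coordinates; contig names gain ``_p1``, ``_p2`` ...
    suffixes so downstream coding treats each piece as a separate contig.
    """
    cut_after = set(flagged["left_index"].to_numpy())
    contigs = table.meta["contig"].to_numpy()
    new_names = []
    part = 1
    for i, contig in enumerate(contigs):
        if i > 0 and contigs[i - 1] == contig and (i - 1) in cut_after:
            part += 1
        elif i > 0 and contigs[i - 1] != contig:
            part = 1
        split_any = any(
            contigs[j] == contig for j in cut_after
        )
        new_names.append(f"{contig}_p{part}" if split_any else contig)
    meta = table.meta.copy()
    meta["contig"] = new_names
    return MarkerStateTable(table.states, meta, table.plants)


# ---------------------------------------------------------------------------
# Contig coding
# ---------------------------------------------------------------------------


@dataclass
class ContigCodeTable:
    """Contigs x plants A/B/X codes stored numerically (-1, +1, 0, NaN).

    ``means`` keeps the per-contig averages the codes were derived from.
    """

    codes: np.ndarray
    means: np.ndarray
    contigs: list[str]
    plants: list[str]

    LETTERS = {-1.0: "A", 1.0: "B", 0.0: "X"}

    def to_letters(self) -> pd.DataFrame:
        out = np.full(self.codes.shape, "-", dtype=object)
        for value, letter in self.LETTERS.items():
            out[self.codes == value] = letter
        return pd.DataFrame(out, index=self.contigs, columns=self.plants)


def code_contig_mean(mean: float) -> float:
    """Map a per-contig mean state to an A/B/X/missing code.

    Means in [-1, -0.8] -> A (-1); [0.8, 1] -> B (+1); [-0.2, 0.2] -> X (0);
    anything else (the ambiguous bands, or an all-missing mean) -> NaN.
    Interval ends are included.
    """
    if np.isnan(mean):
        return MISSING
    if -1.0 <= mean <= -0.8:
        return -1.0
    if 0.8 <= mean <= 1.0:
        return 1.0
    if -0.2 <= mean <= 0.2:
        return 0.0
    return MISSING


def code_contigs(table: MarkerStateTable) -> ContigCodeTable:
    """Average marker states per contig and per plant, then code A/B/X.

    The input should already be filtered and split-corrected; averaging over
    a chimeric contig would blend unlinked signal.
    """
    contigs = list(dict.fromkeys(table.meta["contig"]))
    means = np.full((len(contigs), len(table.plants)), MISSING)
    index = {c: i for i, c in enumerate(contigs)}
    groups = table.meta.groupby("contig", sort=False).indices
    for contig, rows in groups.items():
        sub = table.states[rows]
        with np.errstate(invalid="ignore"):
            means[index[contig]] = np.nanmean(sub, axis=0)
    codes = np.vectorize(code_contig_mean)(means)
    return ContigCodeTable(codes, means, contigs, table.plants)


# ---------------------------------------------------------------------------
# Linkage grouping and ordering
# ---------------------------------------------------------------------------


@dataclass
class LinkageGroup:
    """One linkage group: ordered contigs plus the rf estimates used."""

    group_id: int
    contigs: list[str]
    singleton_no_data: bool = False


@dataclass
class PairwiseLinkage:
    """Pairwise recombination fractions and linkage evidence between contigs."""

    contigs: list[str]
    rf: np.ndarray
    p_value: np.ndarray
    informative: np.ndarray


def pairwise_linkage(codes: ContigCodeTable) -> PairwiseLinkage:
    """Recombination fraction and independence test for every contig pair.

    Events are counted as in :func:`count_interval_recombinations` over
    pairwise-complete plants.  The raw event count is calibrated against its
    expectation under independence *given the observed genotype margins*:
    with balanced 1:2:1 margins the event rate ``events/n`` equals
    ``2r - r^2`` in expectation, so the margin-adjusted estimate

        rf = 1 - sqrt(max(0, 1 - 0.75 * events / E0))

    (``E0`` the independence expectation from the margins) converges to the
    true recombination fraction and to 0.5 for unlinked contigs.  The
    margin conditioning matters: chance segregation skew shared by two
    chromosomes (say, both heterozygote-rich in the same plants' cohort)
    depresses raw event counts between *every* pair of their contigs and
    would otherwise mimic linkage.  Linkage evidence is a Pearson
    chi-square test of independence on the 3x3 joint genotype table, which
    is margin-conditional by construction.
    """
    C = codes.codes
    m = len(codes.contigs)
    onehot = [(C == v).astype(float) for v in (-1.0, 0.0, 1.0)]
    joint = np.empty((3, 3, m, m))
    for a in range(3):
        for b in range(3):
            joint[a, b] = onehot[a] @ onehot[b].T
    n_inf = joint.sum(axis=(0, 1))
    weights = np.abs(np.subtract.outer((-1.0, 0.0, 1.0), (-1.0, 0.0, 1.0)))
    events = np.einsum("ab,abij->ij", weights, joint)
    rows = joint.sum(axis=1)  # (3, m, m)
    cols = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e0 = np.einsum("ab,aij,bij->ij", weights, rows, cols) / n_inf
        ratio = np.clip(1.0 - 0.75 * events / e0, 0.0, 1.0)
        rf = 1.0 - np.sqrt(ratio)
    rf[(n_inf == 0) | (e0 == 0)] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows[:, None] * cols[None, :] / n_inf
        chi2 = np.where(expected > 0, (joint - expected) ** 2 / expected, 0.0).sum(
            axis=(0, 1)
        )
    r_nz = (rows > 0).sum(axis=0)
    c_nz = (cols > 0).sum(axis=0)
    df = np.maximum((r_nz - 1) * (c_nz - 1), 0)
    p = np.ones((m, m))
    ok = df > 0
    p[ok] = stats.chi2.sf(chi2[ok], df[ok])
    return PairwiseLinkage(list(codes.contigs), rf, p, n_inf.astype(int))


def group_and_order(
    codes: ContigCodeTable,
    rf_link_threshold: float = 0.25,
    linkage_alpha: float = 1e-6,
    merge_alpha: float = 1e-3,
    end_merge_alpha: float = 0.02,
    n_groups_target: int | None = None,
    rf_forced: float = 0.45,
    max_group_factor: float = 1.0,
) -> list[LinkageGroup]:
    """Cluster contigs into linkage groups and order each along its map.

    Grouping proceeds in three stages of decreasing stringency.  *Cores*
    are the connected components of the graph joining contigs with
    ``rf < rf_link_threshold`` and independence p-value below
    ``linkage_alpha``; at that stringency spurious edges are essentially
    absent even across tens of thousands of tested pairs, but weak genuine
    links are missed, so chromosomes come out as a handful of fragments.
    *Gated merging* then joins component pairs by single linkage where the
    evidence survives a multiplicity correction — the best pair's p-value
    times the number of cross pairs below ``merge_alpha`` — or where the
    best link connects the *terminal* contigs of both fragments' internal
    orderings (a genuine chain join is always end-to-end, an accidental
    minimum rarely is) at the looser ``end_merge_alpha``.

    When ``n_groups_target`` is given (the known haploid chromosome number;
    genetic maps are routinely closed against it) a final stage merges the
    most significant remaining linkages, with rf eligibility relaxed to
    ``rf_forced``, until the target is reached.  Throughout, merges that
    would exceed ``max_group_factor`` times the average contigs-per-group
    implied by the target are rejected; chance pseudo-linkage typically
    tries to fuse two already-complete chromosomes, which this cap blocks.
    Contigs with no informative plants become flagged singleton groups.

    Within each group, contigs are ordered along the longest path of the
    minimum-spanning tree of the rf graph, refined by 2-opt reversal to
    minimise the summed adjacent rf; ties break lexicographically and each
    group is oriented so its first contig name precedes its last.
    """
    link = pairwise_linkage(codes)
    m = len(link.contigs)
    rf, p = link.rf, link.p_value
    no_data = np.array([np.all(np.isnan(codes.codes[i])) for i in range(m)])

    G = nx.Graph()
    G.add_nodes_from(range(m))
    strict = (rf < rf_link_threshold) & (p < linkage_alpha) & ~np.isnan(rf)
    for i in range(m):
        for j in range(i + 1, m):
            if strict[i, j] and not (no_data[i] or no_data[j]):
                G.add_edge(i, j)
    comps = [set(c) for c in nx.connected_components(G)]

    cap = (
        int(np.ceil(max_group_factor * m / n_groups_target))
        if n_groups_target
        else m
    )
    target = n_groups_target or 0

    def mergeable(a: set[int], b: set[int]) -> bool:
        return (
            len(a) + len(b) <= cap
            and not no_data[next(iter(a))]
            and not no_data[next(iter(b))]
        )

    def ends_of(comp: set[int]) -> list[int]:
        comp_sorted = sorted(comp)
        if len(comp_sorted) <= 2:
            return comp_sorted
        order = _order_component(comp_sorted, link)
        return [order[0], order[-1]]

    # stage 2: gated single-linkage merging
    while len(comps) > target:
        end_sets = [ends_of(c) for c in comps]
        best = None
        for a in range(len(comps)):
            for b in range(a + 1, len(comps)):
                if not mergeable(comps[a], comps[b]):
                    continue
                ia, ib = sorted(comps[a]), sorted(comps[b])
                sub = rf[np.ix_(ia, ib)]
                subp = p[np.ix_(ia, ib)]
                finite = np.isfinite(sub)
                if not finite.any():
                    continue
                mn = np.nanmin(sub)
                adjusted_p = np.nanmin(subp) * finite.sum()
                qual = None
                if mn < rf_link_threshold and adjusted_p < merge_alpha:
                    qual = mn
                else:
                    ee = [
                        (rf[i, j], p[i, j])
                        for i in end_sets[a]
                        for j in end_sets[b]
                        if np.isfinite(rf[i, j])
                    ]
                    if ee:
                        ee_rf, ee_p = min(ee)
                        if ee_rf < rf_link_threshold and ee_p * len(ee) < end_merge_alpha:
                            qual = ee_rf
                if qual is not None and (best is None or qual < best[0]):
                    best = (qual, a, b)
        if best is None:
            break
        _, a, b = best
        comps[a] |= comps[b]
        comps.pop(b)

    # stage 3: close the map against the known chromosome number
    while len(comps) > target > 0:
        best = None
        for a in range(len(comps)):
            for b in range(a + 1, len(comps)):
                if not mergeable(comps[a], comps[b]):
                    continue
                ia, ib = sorted(comps[a]), sorted(comps[b])
                sub = rf[np.ix_(ia, ib)]
                subp = p[np.ix_(ia, ib)]
                eligible = np.isfinite(sub) & (sub < rf_forced)
                if not eligible.any():
                    continue
                mp = subp[eligible].min()
                if best is None or mp < best[0]:
                    best = (mp, a, b)
        if best is None:
            break
        _, a, b = best
        comps[a] |= comps[b]
        comps.pop(b)

    groups: list[LinkageGroup] = []
    ordered_components = sorted(
        (sorted(c) for c in comps), key=lambda c: min(link.contigs[i] for i in c)
    )
    for gid, comp in enumerate(ordered_components, start=1):
        if len(comp) == 1:
            groups.append(
                LinkageGroup(
                    gid,
                    [link.contigs[comp[0]]],
                    singleton_no_data=bool(no_data[comp[0]]),
                )
            )
            continue
        order = _order_component(comp, link)
        groups.append(LinkageGroup(gid, [link.contigs[i] for i in order]))
    return groups


def _two_opt(order: list[int], rf: np.ndarray) -> list[int]:
    """Refine an order by segment reversals minimising summed adjacent rf."""

    def cost(o: list[int]) -> float:
        return sum(
            rf[o[k], o[k + 1]] if np.isfinite(rf[o[k], o[k + 1]]) else 0.5
            for k in range(len(o) - 1)
        )

    best, best_cost = list(order), cost(order)
    improved = True
    while improved:
        improved = False
        for i in range(len(best) - 1):
            for j in range(i + 1, len(best)):
                cand = best[:i] + best[i : j + 1][::-1] + best[j + 1 :]
                c = cost(cand)
                if c < best_cost - 1e-12:
                    best, best_cost = cand, c
                    improved = True
    return best


def _order_component(comp: list[int], link: PairwiseLinkage) -> list[int]:
    """Order contigs along the longest path of the MST of the rf graph."""
    H = nx.Graph()
    for ii, i in enumerate(comp):
        for j in comp[ii + 1 :]:
            w = link.rf[i, j]
            if np.isnan(w):
                w = 0.5
            H.add_edge(i, j, weight=float(w))
    mst = nx.minimum_spanning_tree(H, algorithm="kruskal")

    def farthest(start: int) -> tuple[int, dict[int, int | None]]:
        dist = {start: 0.0}
        parent: dict[int, int | None] = {start: None}
        frontier = [start]
        while frontier:
            nxt = []
            for u in sorted(frontier, key=lambda x: link.contigs[x]):
                for v in sorted(mst.neighbors(u), key=lambda x: link.contigs[x]):
                    if v not in dist:
                        dist[v] = dist[u] + mst[u][v]["weight"]
                        parent[v] = u
                        nxt.append(v)
            frontier = nxt
        far = max(dist, key=lambda v: (dist[v], link.contigs[v]))
        return far, parent

    a, _ = farthest(min(comp, key=lambda i: link.contigs[i]))
    b, parent = farthest(a)
    path = [b]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()

    # insert off-path contigs next to their closest path neighbour
    on_path = set(path)
    order = list(path)
    leftovers = sorted(set(comp) - on_path, key=lambda i: link.contigs[i])
    for node in leftovers:
        anchor = min(
            (x for x in nx.node_connected_component(mst, node) if x in on_path),
            key=lambda x: (nx.shortest_path_length(mst, node, x), link.contigs[x]),
        )
        order.insert(order.index(anchor) + 1, node)
        on_path.add(node)
    order = _two_opt(order, link.rf)
    if link.contigs[order[0]] > link.contigs[order[-1]]:
        order.reverse()
    return order


# ---------------------------------------------------------------------------
# Per-chromosome recombination report
# ---------------------------------------------------------------------------


@dataclass
class RecombinationReport:
    """Recombination event totals per plant and per linkage group."""

    per_plant: pd.DataFrame  # index plants, columns group ids
    per_group_mean: pd.Series

    def group_minimum(self) -> int:
        return int(self.per_group_mean.idxmin())


def recombinations_per_chromosome(
    codes: ContigCodeTable,
    groups: list[LinkageGroup],
    states: MarkerStateTable | None = None,
) -> RecombinationReport:
    """Count state transitions along each ordered linkage group per plant.

    For every plant, missing values are skipped and each unit change
    between consecutive informative positions counts one event
    (|-1 -> +1| counts two).  The per-group mean estimates twice the
    crossover rate of the chromosome (two meioses per F2 plant).

    By default transitions are counted over the contig codes, whose coarse
    resolution absorbs double crossovers within one or two contig spans;
    passing the underlying marker ``states`` table counts transitions over
    the ordered markers of each group's contigs instead, which recovers
    nearly all crossovers when markers are dense.
    """
    per_plant = {}
    if states is not None:
        plants = states.plants
        by_contig = states.meta.groupby("contig", sort=False).indices
        for group in groups:
            rows = np.concatenate(
                [by_contig[c] for c in group.contigs if c in by_contig]
            )
            sub = states.states[rows]
            counts = np.zeros(len(plants))
            for j in range(len(plants)):
                col = sub[:, j]
                col = col[~np.isnan(col)]
                if col.size >= 2:
                    counts[j] = np.abs(np.diff(col)).sum()
            per_plant[group.group_id] = counts
    else:
        plants = codes.plants
        index = {c: i for i, c in enumerate(codes.contigs)}
        for group in groups:
            rows = [index[c] for c in group.contigs]
            sub = codes.codes[rows]
            counts = np.zeros(len(plants))
            for j in range(len(plants)):
                col = sub[:, j]
                col = col[~np.isnan(col)]
                if col.size >= 2:
                    counts[j] = np.abs(np.diff(col)).sum()
            per_plant[group.group_id] = counts
    df = pd.DataFrame(per_plant, index=plants)
    return RecombinationReport(df, df.mean(axis=0))
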