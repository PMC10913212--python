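"""Homeolog pairing, rescue annotation and systematic gene naming.

Gene copies on corresponding chromosomes of the two subgenomes (homeologs)
are matched by sequence similarity with a positional tie-break: when a gene
has several equally good hits on the homeologous chromosome, the candidate
whose ordinal position along the chromosome best matches wins.  Genes left
without a partner go through a rescue round that scans the homeologous
interval between the partners of their nearest paired neighbours; a
sufficiently similar ORF-valid match becomes a new gene model.  Finally,
genes receive systematic names of the form
``Cbp.<chromosome>.g<number>.<At-ortholog>_<method>`` with numbers spaced
by 1000 so later accessions can interleave additional genes.

Similarity is scored by an internal k-mer seed + ungapped diagonal scorer
(match +1 / mismatch -1), which is exact for the substitution-only
divergence the simulator produces; externally computed tabular hits
(outfmt-6 style) are accepted in the same :class:`SimilarityHit` form.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .genomes import Genome

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_VALID_NT = set("ACGTN")


@dataclass
class GeneModel:
    """A gene model with its CDS in chromosome coordinates."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.id}: start must precede end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if self.score < 0 or not 0.0 <= self.identity <= 1.0:
            raise ValueError("invalid similarity hit")


@dataclass(frozen=True)
class HomeologPair:
    gene_r: str
    gene_o: str
    method: str  # primary | rescue


def validate_orf(cds: str) -> bool:
    """True iff the sequence is a complete ORF.

    Requires length >= 6 and divisible by 3, an ATG start, a terminal stop
    codon, and no internal in-frame stop.  Characters outside {A,C,G,T,N}
    are rejected outright.
    """
    if set(cds) - _VALID_NT:
        raise ValueError("non-nucleotide characters in CDS")
    if len(cds) < 6 or len(cds) % 3:
        return False
    if not cds.startswith("ATG") or cds[-3:] not in _STOPS:
        return False
    return all(cds[i : i + 3] not in _STOPS for i in range(3, len(cds) - 3, 3))


# ---------------------------------------------------------------------------
# k-mer seed + ungapped diagonal similarity
# ---------------------------------------------------------------------------


def _diagonal_score(q: str, s: str, offset: int) -> tuple[float, float]:
    """Score the full overlap of query and subject on one diagonal.

    ``offset`` is subject_pos - query_pos.  Returns (score, identity) with
    match +1 / mismatch -1 over the overlapping stretch.
    """
    q_lo = max(0, -offset)
    q_hi = min(len(q), len(s) - offset)
    if q_hi <= q_lo:
        return 0.0, 0.0
    qa = np.frombuffer(q[q_lo:q_hi].encode(), dtype=np.uint8)
    sa = np.frombuffer(s[q_lo + offset : q_hi + offset].encode(), dtype=np.uint8)
    matches = int((qa == sa).sum())
    length = q_hi - q_lo
    return float(2 * matches - length), matches / length


def similarity_search(
    queries: dict[str, str], subjects: dict[str, str], k: int = 11
) -> list[SimilarityHit]:
    """All-vs-all hits between CDS sets sharing at least one exact k-mer.

    For each query/subject pair the seeds are grouped by diagonal and the
    best-scoring diagonal is reported.  Hits are returned best-first per
    query (ties broken by subject id for determinism).
    """
    if not queries or not subjects:
        raise ValueError("similarity_search needs non-empty query and subject sets")
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for sid, seq in subjects.items():
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].append((sid, i))
    hits: list[SimilarityHit] = []
    for qid, qseq in queries.items():
        diagonals: dict[str, set[int]] = defaultdict(set)
        for i in range(len(qseq) - k + 1):
            for sid, j in index.get(qseq[i : i + k], ()):
                diagonals[sid].add(j - i)
        best_per_subject = []
        for sid, offsets in diagonals.items():
            scored = [
                (*_diagonal_score(qseq, subjects[sid], off), off) for off in offsets
            ]
            score, identity, _ = max(scored, key=lambda t: t[0])
            if score > 0:
                best_per_subject.append(SimilarityHit(qid, sid, score, identity))
        best_per_subject.sort(key=lambda h: (-h.score, h.subject))
        hits.extend(best_per_subject)
    return hits


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------


def _ranks(annot: list[GeneModel]) -> dict[str, int]:
    """Ordinal position of each gene along its chromosome."""
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in annot:
        by_chrom[g.chromosome].append(g)
    ranks: dict[str, int] = {}
    for genes in by_chrom.values():
        starts = [g.start for g in genes]
        if starts != sorted(starts):
            raise ValueError("annotation must be sorted by start within chromosomes")
        for r, g in enumerate(genes):
            ranks[g.id] = r
    return ranks


def _best_hits(
    hits: list[SimilarityHit], ranks: dict[str, int]
) -> dict[str, SimilarityHit]:
    """Best hit per query; score ties resolved by positional rank distance."""
    by_query: dict[str, list[SimilarityHit]] = defaultdict(list)
    for h in hits:
        if h.query not in ranks or h.subject not in ranks:
            raise ValueError(f"hit references unknown gene id: {h.query}/{h.subject}")
        by_query[h.query].append(h)
    best = {}
    for qid, cand in by_query.items():
        best[qid] = min(
            cand,
            key=lambda h: (
                -h.score,
                abs(ranks[h.query] - ranks[h.subject]),
                h.subject,
            ),
        )
    return best


def pair_homeologs(
    hits_r_to_o: list[SimilarityHit],
    hits_o_to_r: list[SimilarityHit],
    annot_r: list[GeneModel],
    annot_o: list[GeneModel],
    max_rank_distance: int = 10,
) -> list[HomeologPair]:
    """Pair homeologous genes from reciprocal similarity hits.

    Reciprocal best hits are paired first.  Remaining one-directional best
    hits are accepted in order of positional rank distance (then score,
    then ids) when the candidate is still free and its ordinal position
    differs by at most ``max_rank_distance``.  Each gene joins at most one
    pair, and the procedure is symmetric in the two subgenomes.
    """
    ranks = {**_ranks(annot_r), **_ranks(annot_o)}
    r_ids = {g.id for g in annot_r}
    best_r = _best_hits(hits_r_to_o, ranks)
    best_o = _best_hits(hits_o_to_r, ranks)

    paired: dict[str, str] = {}
    pairs: list[HomeologPair] = []

    def add(gene_r: str, gene_o: str) -> None:
        paired[gene_r] = gene_o
        paired[gene_o] = gene_r
        pairs.append(HomeologPair(gene_r, gene_o, "primary"))

    for rid in sorted(best_r):
        o_hit = best_r[rid].subject
        if best_o.get(o_hit) is not None and best_o[o_hit].subject == rid:
            add(rid, o_hit)

    leftovers = []
    for best in (best_r, best_o):
        for qid, hit in best.items():
            if qid in paired or hit.subject in paired:
                continue
            dist = abs(ranks[qid] - ranks[hit.subject])
            leftovers.append((dist, -hit.score, min(qid, hit.subject), qid, hit.subject))
    for dist, _, _, qid, sid in sorted(leftovers):
        if dist > max_rank_distance or qid in paired or sid in paired:
            continue
        gene_r, gene_o = (qid, sid) if qid in r_ids else (sid, qid)
        add(gene_r, gene_o)
    return pairs


# ---------------------------------------------------------------------------
# Rescue round
# ---------------------------------------------------------------------------


@dataclass
class RescueResult:
    pairs: list[HomeologPair]
    new_genes: list[GeneModel]
    missing: list[str]  # genuinely missing homeologs (gene ids)


def _homeolog_chromosome(chrom: str) -> str:
    if chrom.startswith("O"):
        return "R" + chrom[1:]
    if chrom.startswith("R"):
        return "O" + chrom[1:]
    raise ValueError(f"cannot infer homeologous chromosome of {chrom!r}")


def rescue_missing(
    pairs: list[HomeologPair],
    annot_r: list[GeneModel],
    annot_o: list[GeneModel],
    genomes: Genome,
    min_identity: float = 0.8,
    k: int = 11,
) -> RescueResult:
    """Search homeologous intervals for partners of unpaired genes.

    For an unpaired gene, the interval between the partners of its nearest
    paired neighbours (or a flank-to-chromosome-end interval at chromosome
    ends) is scanned with the k-mer similarity scorer.  A hit with identity
    >= ``min_identity`` whose matched sequence is a valid ORF and overlaps
    no existing gene becomes a new gene model paired by the rescue method.
    Genes whose homeologous interval holds no such match are reported as
    genuinely missing.
    """
    paired_ids = {p.gene_r for p in pairs} | {p.gene_o for p in pairs}
    partner = {p.gene_r: p.gene_o for p in pairs}
    partner.update({p.gene_o: p.gene_r for p in pairs})
    all_genes = {g.id: g for g in annot_r + annot_o}

    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in annot_r + annot_o:
        by_chrom[g.chromosome].append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.start)

    new_pairs: list[HomeologPair] = []
    new_genes: list[GeneModel] = []
    missing: list[str] = []
    occupied: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for g in all_genes.values():
        occupied[g.chromosome].append((g.start, g.end))

    for gene in sorted(all_genes.values(), key=lambda g: g.id):
        if gene.id in paired_ids:
            continue
        target_chrom = _homeolog_chromosome(gene.chromosome)
        if target_chrom not in genomes:
            logger.warning("no homeologous chromosome for %s; skipped", gene.id)
            continue
        siblings = by_chrom[gene.chromosome]
        idx = siblings.index(gene)
        left = next(
            (s for s in reversed(siblings[:idx]) if s.id in paired_ids), None
        )
        right = next((s for s in siblings[idx + 1 :] if s.id in paired_ids), None)
        bounds = []
        for flank in (left, right):
            if flank is None:
                continue
            p = all_genes[partner[flank.id]]
            if p.chromosome != target_chrom:
                logger.warning(
                    "flanking pairs of %s map to %s, not %s; inconsistent synteny",
                    gene.id,
                    p.chromosome,
                    target_chrom,
                )
                bounds = None
                break
            bounds.extend([p.start, p.end])
        if bounds is None:
            continue
        lo = min(bounds) if left is not None else 0
        hi = max(bounds) if right is not None else len(genomes[target_chrom])
        if not bounds:
            lo, hi = 0, len(genomes[target_chrom])
        interval = genomes[target_chrom][lo:hi]
        if len(interval) < k:
            missing.append(gene.id)
            continue
        hit_model = _scan_interval(
            gene, interval, target_chrom, lo, min_identity, k
        )
        if hit_model is None:
            missing.append(gene.id)
            continue
        if any(
            hit_model.start < e and s < hit_model.end
            for s, e in occupied[target_chrom]
        ):
            missing.append(gene.id)
            continue
        occupied[target_chrom].append((hit_model.start, hit_model.end))
        new_genes.append(hit_model)
        gene_r, gene_o = (
            (gene.id, hit_model.id)
            if gene.chromosome.startswith("R")
            else (hit_model.id, gene.id)
        )
        new_pairs.append(HomeologPair(gene_r, gene_o, "rescue"))
        paired_ids.update({gene.id, hit_model.id})
    return RescueResult(new_pairs, new_genes, missing)


def _scan_interval(
    gene: GeneModel,
    interval: str,
    target_chrom: str,
    offset: int,
    min_identity: float,
    k: int,
) -> GeneModel | None:
    try:
        hits = similarity_search({gene.id: gene.cds}, {"interval": interval}, k=k)
    except ValueError:
        return None
    if not hits:
        return None
    # locate the best diagonal placement of the full CDS inside the interval
    best = None
    seeds: dict[int, int] = defaultdict(int)
    for i in range(len(gene.cds) - k + 1):
        kmer = gene.cds[i : i + k]
        j = interval.find(kmer)
        while j != -1:
            seeds[j - i] += 1
            j = interval.find(kmer, j + 1)
    for off, _count in sorted(seeds.items(), key=lambda t: (-t[1], t[0])):
        if off < 0 or off + len(gene.cds) > len(interval):
            continue
        cand = interval[off : off + len(gene.cds)]
        matches = sum(a == b for a, b in zip(gene.cds, cand))
        identity = matches / len(gene.cds)
        if best is None or identity > best[0]:
            best = (identity, off, cand)
    if best is None or best[0] < min_identity:
        return None
    identity, off, cand = best
    try:
        if not validate_orf(cand):
            return None
    except ValueError:
        return None
    start = offset + off
    return GeneModel(
        id=f"{target_chrom}.rescue.{gene.id}",
        chromosome=target_chrom,
        start=start,
        end=start + len(cand),
        strand=gene.strand,
        cds=cand,
    )


# ---------------------------------------------------------------------------
# Systematic gene names
# ---------------------------------------------------------------------------

GENE_NAME_RE = re.compile(
    r"^Cbp\.(?P<chromosome>[A-Za-z0-9_]+)\.g(?P<number>\d{8})"
    r"\.(?P<at_id>[A-Za-z0-9]+|NA)_(?P<method>[OBN])$"
)

#: gene numbers advance by 1000 so further accessions can add genes between
GENE_NUMBER_STEP = 1000


def format_gene_name(
    chromosome: str, number: int, at_id: str | None, method: str
) -> str:
    if method not in ("O", "B", "N"):
        raise ValueError("method letter must be O (orthogroup), B (best-hit) or N")
    return f"Cbp.{chromosome}.g{number:08d}.{at_id or 'NA'}_{method}"


def parse_gene_name(name: str) -> dict[str, object]:
    m = GENE_NAME_RE.match(name)
    if m is None:
        raise ValueError(f"not a systematic gene name: {name!r}")
    d = m.groupdict()
    return {
        "chromosome": d["chromosome"],
        "number": int(d["number"]),
        "at_id": None if d["at_id"] == "NA" else d["at_id"],
        "method": d["method"],
    }


def name_genes(
    annot: list[GeneModel],
    at_orthologs: dict[str, tuple[str, str]] | None = None,
) -> dict[str, str]:
    """Assign systematic names per chromosome.

    The i-th gene along a chromosome (annotation sorted by start) receives
    number ``i * 1000`` zero-padded to eight digits.  ``at_orthologs`` maps
    gene id -> (A. thaliana id, method letter) where the letter is 'O' for
    an orthogroup-derived correspondence and 'B' for a best-hit one; genes
    without a correspondence get 'NA' with method letter 'N'.
    """
    at_orthologs = at_orthologs or {}
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in annot:
        by_chrom[g.chromosome].append(g)
    names: dict[str, str] = {}
    seen: set[str] = set()
    for chrom, genes in by_chrom.items():
        if [g.start for g in genes] != sorted(g.start for g in genes):
            raise ValueError(f"annotation on {chrom} is not sorted by start")
        for i, g in enumerate(genes, start=1):
            at_id, method = at_orthologs.get(g.id, (None, "N"))
            name = format_gene_name(chrom, i * GENE_NUMBER_STEP, at_id, method)
            if name in seen:
                raise ValueError(f"duplicate gene name {name}; input unsorted?")
            seen.add(name)
            names[g.id] = name
    return names
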