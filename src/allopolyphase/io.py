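"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; VCF is written as minimal text (GT and DP
fields) and read back with pysam; depth tracks use 4-column BED-graph TSV;
Hi-C pairs, marker tables and linkage groups are tab-separated tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genomes import DepthTrack, Genome, TruthSet
from .synthetic import F2Cohort


def write_fasta(genome: Genome | dict[str, str], path) -> None:
    chroms = genome.chromosomes if isinstance(genome, Genome) else genome
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in chroms.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Genome:
    return Genome({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


def write_truth_yaml(truth: TruthSet, path) -> None:
    payload = {
        "chimera_junctions": [
            {"contig": j.contig, "position": j.position, "partner_contig": j.partner_contig}
            for j in truth.chimera_junctions
        ],
        "he_breakpoints": [[c, int(p)] for c, p in truth.he_breakpoints],
        "homeolog_pairs_truth": [list(p) for p in truth.homeolog_pairs_truth],
        "crossovers": {
            plant: {c: [int(x) for x in pos] for c, pos in chroms.items()}
            for plant, chroms in truth.crossovers.items()
        },
        "deleted_region": list(truth.deleted_region) if truth.deleted_region else None,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def write_f2_vcf(cohort: F2Cohort, parent1: Genome, parent2: Genome, path) -> None:
    """Multi-sample VCF of the F2 cohort with GT and DP per plant."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for chrom, length in parent1.lengths().items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.plants)
    )
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    for i, (chrom, pos) in enumerate(
        zip(cohort.markers["chromosome"], cohort.markers["position"])
    ):
        ref = parent1[chrom][pos]
        alt = parent2[chrom][pos]
        cells = [
            f"{gt_strings[int(cohort.genotypes[j, i])]}:{int(cohort.depths[j, i])}"
            for j in range(cohort.n_plants)
        ]
        lines.append(
            f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_f2_tsv(cohort: F2Cohort, path) -> None:
    df = cohort.markers.copy()
    for j, plant in enumerate(cohort.plants):
        df[plant] = cohort.genotypes[j]
    df.to_csv(path, sep="\t", index=False)


def write_depth_bedgraph(track: DepthTrack, chrom_lengths: dict[str, int], path) -> None:
    rows = []
    for chrom, values in track.values.items():
        length = chrom_lengths[chrom]
        for w, depth in enumerate(values):
            start = w * track.window_size
            rows.append((chrom, start, min(start + track.window_size, length), depth))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_depth_bedgraph(path, sample: str = "sample") -> DepthTrack:
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "depth"])
    window = int((df["end"] - df["start"]).max())
    values = {
        chrom: grp.sort_values("start")["depth"].to_numpy(dtype=float)
        for chrom, grp in df.groupby("chrom", sort=False)
    }
    return DepthTrack(sample=sample, window_size=window, values=values)


def write_pairs_tsv(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, header=False)


def read_pairs_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=["chrom1", "pos1", "chrom2", "pos2"])


def write_gff3(genes, path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.id}"
        lines.append(
            f"{g.chromosome}\tallopolyphase\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_genes(path, genome: Genome):
    """Load gene models from a GFF3, extracting CDS from the genome."""
    from .homeolog import GeneModel

    genes = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        chrom, _, ftype, start, end, _, strand, _, attrs = line.split("\t")
        if ftype != "gene":
            continue
        gid = dict(kv.split("=", 1) for kv in attrs.split(";"))["ID"]
        s, e = int(start) - 1, int(end)
        cds = genome[chrom][s:e]
        if strand == "-":
            cds = str(Seq(cds).reverse_complement())
        genes.append(GeneModel(gid, chrom, s, e, strand, cds))
    return genes


def write_contact_matrix(matrix, path) -> None:
    np.savetxt(path, matrix.counts, fmt="%d", delimiter="\t")
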