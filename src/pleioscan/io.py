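"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython/pyfaidx, GFF3 via gffutils, VCF via cyvcf2 (read) and
pysam (write), TRANSFAC flat-file matrices via Bio.motifs, tab-separated
phenotype/count tables via pandas, clusters/networks as JSON and GraphML.
Coordinates are 1-based inclusive on disk (VCF/GFF convention) and
0-based half-open inside the package.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import networkx as nx
import numpy as np
import pandas as pd
import pysam
import yaml
from Bio.motifs import transfac
from cyvcf2 import VCF

from .pleio import ClusterSet
from .regulatory import PWM, GeneAnnotation, RegulatoryConsequence, SNPRecord
from .util import logger

TRANSFAC_SCALE = 1000  # frequencies are written as counts out of 1000


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                f"{a.chrom}\tpleioscan\tgene\t{a.start}\t{a.end}\t.\t{a.strand}\t.\t"
                f"ID={a.gene_id}\n"
            )


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        out.append(
            GeneAnnotation(
                gene_id=feat.id, chrom=feat.seqid, start=feat.start, end=feat.end,
                strand=feat.strand,
            )
        )
    return out


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    snps: Sequence[SNPRecord],
    line_ids: Sequence[str],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> None:
    header = pysam.VariantHeader()
    header.add_meta("source", "pleioscan-synthdata")
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for line in line_ids:
        header.add_sample(line)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for snp in snps:
            rec = vcf.new_record(
                contig=snp.chrom, start=snp.pos - 1, stop=snp.pos,
                alleles=(snp.ref, snp.alt), id=snp.id,
            )
            for sample, dosage in zip(line_ids, snp.dosages):
                if np.isnan(dosage):
                    rec.samples[sample]["GT"] = (None, None)
                else:
                    d = int(dosage)
                    rec.samples[sample]["GT"] = (d // 2 if d != 1 else 0, 1 if d >= 1 else 0)
            vcf.write(rec)


def read_vcf(path: str | Path) -> tuple[list[SNPRecord], list[str]]:
    """Biallelic SNP records; multi-allelic rows are split into one record
    per alternate allele before processing."""
    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    snps: list[SNPRecord] = []
    for var in vcf:
        if var.REF is None or len(var.REF) != 1:
            logger.warning("%s:%s: non-SNP record skipped", var.CHROM, var.POS)
            continue
        gts = np.array(var.genotypes, dtype=object)  # [allele1, allele2, phased]
        for ai, alt in enumerate(var.ALT, start=1):
            if len(alt) != 1:
                logger.warning("%s:%s: non-SNP allele %s skipped", var.CHROM, var.POS, alt)
                continue
            dosages = np.empty(len(line_ids))
            for i, gt in enumerate(gts):
                a, b = gt[0], gt[1]
                if a is None or a < 0 or b is None or b < 0:
                    dosages[i] = np.nan
                else:
                    dosages[i] = int(a == ai) + int(b == ai)
            snp_id = var.ID or f"{var.CHROM}_{var.POS}"
            if len(var.ALT) > 1:
                snp_id = f"{snp_id}_{alt}"
            snps.append(
                SNPRecord(
                    id=snp_id, chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=alt,
                    dosages=dosages,
                )
            )
    return snps, line_ids


# ---------------------------------------------------------------------------
# TRANSFAC matrices


def write_transfac(pwms: Sequence[PWM], path: str | Path) -> None:
    rec = transfac.Record()
    for pwm in pwms:
        counts = {
            base: [float(np.round(pwm.freq[i, j] * TRANSFAC_SCALE)) for i in range(pwm.length)]
            for j, base in enumerate("ACGT")
        }
        motif = transfac.Motif(alphabet="GATC", counts=counts)
        motif["ID"] = pwm.name
        rec.append(motif)
    with open(path, "w") as fh:
        fh.write(str(rec))


def read_transfac(path: str | Path) -> list[PWM]:
    """Load ID/P0 matrices; count rows are normalized to frequencies."""
    with open(path) as fh:
        rec = transfac.read(fh, strict=False)
    out = []
    for motif in rec:
        counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float).T  # (L, 4)
        rowsums = counts.sum(axis=1, keepdims=True)
        if np.any(rowsums <= 0):
            raise ValueError(f"matrix {motif.get('ID')}: empty count row")
        out.append(PWM(name=motif.get("ID") or motif.get("AC"), freq=counts / rowsums))
    return out


# ---------------------------------------------------------------------------
# Tables


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index_label="line")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_consequences(consequences: Iterable[RegulatoryConsequence], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(c) for c in consequences]).to_csv(
        path, sep="\t", index=False
    )


def read_consequences(path: str | Path) -> list[RegulatoryConsequence]:
    df = pd.read_csv(path, sep="\t")
    return [RegulatoryConsequence(**row) for row in df.to_dict("records")]


def write_optimal_sets(optimal: dict[str, list[str]], path: str | Path) -> None:
    rows = [
        {"phenotype": p, "snp_id": s} for p in sorted(optimal) for s in sorted(optimal[p])
    ]
    pd.DataFrame(rows, columns=["phenotype", "snp_id"]).to_csv(path, sep="\t", index=False)


def read_optimal_sets(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.phenotype, []).append(row.snp_id)
    return out


# ---------------------------------------------------------------------------
# Clusters and networks


def write_clusters(clusters: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"converged": clusters.converged, "clusters": [list(c) for c in clusters]},
            fh, indent=2,
        )


def read_clusters(path: str | Path) -> ClusterSet:
    with open(path) as fh:
        d = json.load(fh)
    return ClusterSet(d["clusters"], converged=d.get("converged", True))


def write_network_json(G: nx.DiGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(nx.node_link_data(G, edges="links"), fh, indent=2)


def read_network_json(path: str | Path) -> nx.DiGraph:
    with open(path) as fh:
        return nx.node_link_graph(json.load(fh), directed=True, edges="links")


def write_network_graphml(G: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """Paths and tunables for the end-to-end run; see the CLI for overrides."""

    outdir: str = "pleioscan-out"
    vcf: str | None = None
    fasta: str | None = None
    gff: str | None = None
    pwms: str | None = None
    phenotypes: str | None = None
    counts: str | None = None
    seed: int = 0
    # stage toggles
    simulate: bool = True
    run_phase4: bool = True
    # regulatory
    mss_cutoff: float = 0.95
    core_cutoff: float = 0.90
    maf_floor: float = 0.05
    upstream: int = 500
    downstream: int = 100
    # association
    n_trees: int = 500
    max_iter: int = 100
    boruta_alpha: float = 0.01
    stride: int = 1
    k_max: int | None = None
    # clustering
    inflation: float = 2.0
    # expression validation
    alpha: float = 0.05
    het: str = "exclude"
    bh_correct: bool = False
    # synthetic generator overrides (forwarded to SimulationConfig)
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def validate_inputs(self) -> None:
        if self.simulate:
            return
        for name in ("vcf", "fasta", "gff", "pwms", "phenotypes"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} missing: {p}")
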