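"""End-to-end orchestration of the four analysis phases.

Phase 1 scans promoter SNPs for allele-specific TFBS gain/loss, Phase 2
ranks rSNPs per phenotype (Boruta) and picks optimal sets (IFS), Phase 3
clusters rSNP profiles (PSI + MCL) and enforces pleiotropy, Phase 4 builds
the TF -> rSNP(gene) -> phenotype networks and prunes them by allele-split
expression validation.  ``run_pipeline`` drives the whole thing from a
:class:`~pleioscan.io.PipelineConfig` and writes every intermediate
artifact plus a run manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import assoc, io, netmodel, pleio, regulatory as reg, synthdata
from .util import logger, stage_seed


@dataclass
class PipelineResult:
    consequences: list = field(default_factory=list)
    feature_matrix: pd.DataFrame | None = None
    optimal_sets: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)
    summary: pd.DataFrame | None = None
    profile: pleio.ProfileMatrix | None = None
    association_matrix: np.ndarray | None = None
    raw_clusters: pleio.ClusterSet | None = None
    clusters: pleio.ClusterSet | None = None
    size_factors: pd.Series | None = None
    normalized: pd.DataFrame | None = None
    validations: list = field(default_factory=list)
    networks: dict = field(default_factory=dict)  # cluster id -> unpruned graph
    pruned_networks: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def analyze(
    snps: list[reg.SNPRecord],
    line_ids: list[str],
    genome: dict[str, str],
    annotations: list[reg.GeneAnnotation],
    pwms: list[reg.PWM],
    phenotypes: pd.DataFrame,
    counts: pd.DataFrame | None,
    config: io.PipelineConfig,
) -> PipelineResult:
    """Run Phases 1-4 in memory and return every stage output."""
    res = PipelineResult()
    manifest: dict = {"seed": config.seed, "parameters": dataclasses.asdict(config), "counts": {}}

    # Phase 1: rSNP identification
    kept = reg.filter_snps_by_maf(snps, config.maf_floor)
    manifest["counts"]["snps_input"] = len(snps)
    manifest["counts"]["snps_maf_pass"] = len(kept)
    res.consequences = reg.identify_rsnps(
        kept, genome, annotations, pwms,
        mss_cutoff=config.mss_cutoff, core_cutoff=config.core_cutoff,
        upstream=config.upstream, downstream=config.downstream,
    )
    rsnp_ids = sorted({c.snp_id for c in res.consequences})
    manifest["counts"]["consequences"] = len(res.consequences)
    manifest["counts"]["rsnps"] = len(rsnp_ids)
    if not rsnp_ids:
        logger.warning("no rSNPs found; downstream phases skipped")
        res.manifest = manifest
        return res

    # Phase 2: association
    by_id = {s.id: s for s in kept}
    res.feature_matrix = assoc.encode_genotypes([by_id[i] for i in rsnp_ids], line_ids)
    params = assoc.AssociationParams(
        n_trees=config.n_trees, max_iter=config.max_iter, alpha=config.boruta_alpha,
        stride=config.stride, k_max=config.k_max, seed=config.seed,
    )
    res.optimal_sets, res.curves, res.summary = assoc.associate_all(
        res.feature_matrix, phenotypes, params
    )
    manifest["counts"]["phenotypes"] = len(res.optimal_sets)
    manifest["counts"]["optimal_set_total"] = int(sum(len(v) for v in res.optimal_sets.values()))

    # Phase 3: pleiotropy clustering
    res.profile = pleio.build_profile_matrix(res.optimal_sets, res.consequences)
    res.association_matrix = pleio.psi_matrix(res.profile.data)
    res.raw_clusters = pleio.mcl(
        res.association_matrix, ids=res.profile.rsnp_ids, inflation=config.inflation
    )
    res.clusters = pleio.prune_non_pleiotropic(res.raw_clusters, res.profile)
    manifest["counts"]["profile_rows"] = len(res.profile.rsnp_ids)
    manifest["counts"]["clusters_raw"] = len(res.raw_clusters)
    manifest["counts"]["clusters_pleiotropic"] = len(res.clusters)

    # Phase 4: networks and expression validation
    for i, members in enumerate(res.clusters):
        cid = f"Cluster-{i + 1}"
        res.networks[cid] = netmodel.build_hierarchical_network(
            cid, members, res.consequences, res.optimal_sets
        )
    if config.run_phase4 and counts is not None and len(res.clusters):
        res.size_factors, res.normalized = netmodel.median_of_ratios(counts)
        res.validations = netmodel.validate_expression(
            res.clusters, res.consequences, by_id, res.normalized, line_ids,
            alpha=config.alpha, het=config.het, bh_correct=config.bh_correct,
        )
        for cid, G in res.networks.items():
            res.pruned_networks[cid] = netmodel.prune_network_by_expression(G, res.validations)
    else:
        res.pruned_networks = {cid: G.copy() for cid, G in res.networks.items()}
    manifest["counts"]["validations"] = len(res.validations)
    manifest["counts"]["validations_significant"] = int(
        sum(v.significant for v in res.validations)
    )
    res.manifest = manifest
    return res


def run_pipeline(config: io.PipelineConfig) -> dict:
    """Load or simulate inputs, run the analysis, write all artifacts.

    Returns the manifest (also written to ``outdir/manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        dataset = synthdata.generate_dataset(synthdata.SimulationConfig(**sim_kwargs))
        write_dataset(dataset, outdir / "simulated")
        snps, line_ids = dataset.snps, dataset.line_ids
        genome, annotations, pwms = dataset.genome, dataset.annotations, dataset.pwms
        phenotypes, counts = dataset.phenotypes, dataset.counts
    else:
        config.validate_inputs()
        genome = io.read_fasta(config.fasta)
        annotations = io.read_gff3(config.gff)
        pwms = io.read_transfac(config.pwms)
        snps, line_ids = io.read_vcf(config.vcf)
        phenotypes = io.read_phenotypes(config.phenotypes)
        counts = io.read_counts(config.counts) if config.counts else None

    res = analyze(snps, line_ids, genome, annotations, pwms, phenotypes, counts, config)

    io.write_consequences(res.consequences, outdir / "consequences.tsv")
    if res.feature_matrix is not None:
        io.write_optimal_sets(res.optimal_sets, outdir / "optimal_sets.tsv")
        res.summary.to_csv(outdir / "association_summary.tsv", sep="\t", index=False)
        curve_rows = [
            {"phenotype": c.phenotype, "k": k, "r2": r}
            for c in res.curves.values()
            for k, r in zip(c.ks, c.r2)
        ]
        pd.DataFrame(curve_rows, columns=["phenotype", "k", "r2"]).to_csv(
            outdir / "ifs_curves.tsv", sep="\t", index=False
        )
        rank_rows = [
            {"phenotype": c.phenotype, "rank": i + 1, "snp_id": s}
            for c in res.curves.values()
            for i, s in enumerate(c.ranking)
        ]
        pd.DataFrame(rank_rows, columns=["phenotype", "rank", "snp_id"]).to_csv(
            outdir / "rankings.tsv", sep="\t", index=False
        )
    if res.profile is not None:
        res.profile.data.to_csv(outdir / "profile_matrix.tsv", sep="\t")
        pd.DataFrame(
            res.association_matrix, index=res.profile.rsnp_ids, columns=res.profile.rsnp_ids
        ).to_csv(outdir / "association_matrix.tsv", sep="\t")
        io.write_clusters(res.clusters, outdir / "clusters.json")
        summary = pleio.cluster_summary(
            res.clusters, res.profile, pleio.gene_map_from_consequences(res.consequences)
        )
        summary.to_csv(outdir / "cluster_summary.tsv", sep="\t", index=False)
    if res.validations:
        pd.DataFrame([dataclasses.asdict(v) for v in res.validations]).to_csv(
            outdir / "validations.tsv", sep="\t", index=False
        )
        by_id = {s.id: s for s in snps}
        netmodel.grouped_expression_table(
            res.validations, by_id, res.normalized, line_ids, het=config.het
        ).to_csv(outdir / "grouped_expression.tsv", sep="\t", index=False)
    for cid, G in res.pruned_networks.items():
        io.write_network_json(G, outdir / f"network_{cid}.json")
        io.write_network_graphml(G, outdir / f"network_{cid}.graphml")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, default=str)
    return res.manifest


def write_dataset(dataset: synthdata.SyntheticDataset, outdir: str | Path) -> None:
    """Write every simulated input in its standard on-disk format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(dataset.genome, outdir / "genome.fasta")
    io.write_gff3(dataset.annotations, outdir / "genes.gff3")
    io.write_vcf(
        dataset.snps, dataset.line_ids,
        {c: len(s) for c, s in dataset.genome.items()}, outdir / "genotypes.vcf",
    )
    io.write_transfac(dataset.pwms, outdir / "pwms.transfac")
    io.write_phenotypes(dataset.phenotypes, outdir / "phenotypes.tsv")
    io.write_counts(dataset.counts, outdir / "counts.tsv")
    with open(outdir / "ground_truth.json", "w") as fh:
        fh.write(dataset.truth.to_json())


# ---------------------------------------------------------------------------
# Ground-truth recovery metrics


def planted_consequence_recovery(
    consequences: list[reg.RegulatoryConsequence], truth: synthdata.GroundTruth
) -> float:
    """Fraction of planted (snp, TF, effect) triples present in the calls."""
    found = {(c.snp_id, c.pwm_name, c.effect) for c in consequences}
    planted = [
        (p.snp_id, p.pwm_names[0], p.effect) for p in truth.planted_rsnps
    ]
    return sum(t in found for t in planted) / len(planted)


def optimal_set_recall(
    optimal_sets: dict[str, list[str]], truth: synthdata.GroundTruth
) -> float:
    """Over all (planted cluster trait, planted rSNP) pairs: the fraction of
    the cluster's rSNPs present in the trait's optimal set."""
    hits = total = 0
    for rsnp_ids, traits in truth.planted_clusters:
        for t in traits:
            members = set(optimal_sets.get(t, []))
            hits += sum(s in members for s in rsnp_ids)
            total += len(rsnp_ids)
    return hits / total if total else float("nan")


def cluster_recovery_ari(clusters: pleio.ClusterSet, truth: synthdata.GroundTruth) -> float:
    """Adjusted Rand Index between recovered and planted cluster labels,
    over the planted rSNPs (an unclustered planted rSNP gets its own
    singleton label)."""
    true_label: dict[str, int] = {}
    for i, (rsnp_ids, _) in enumerate(truth.planted_clusters):
        for s in rsnp_ids:
            true_label[s] = i
    predicted = clusters.labels()
    items = sorted(true_label)
    next_free = len(clusters)
    y_true, y_pred = [], []
    for s in items:
        y_true.append(true_label[s])
        if s in predicted:
            y_pred.append(predicted[s])
        else:
            y_pred.append(next_free)
            next_free += 1
    return float(adjusted_rand_score(y_true, y_pred))


def cis_pruning_survival(
    pruned_networks: dict[str, nx.DiGraph],
    clusters: pleio.ClusterSet,
    truth: synthdata.GroundTruth,
) -> float:
    """Among planted cis-effect rSNPs that made it into a pleiotropic
    cluster, the fraction still present after expression pruning."""
    clustered = {m for c in clusters for m in c}
    cis_ids = {s for s, _, _ in truth.planted_cis_effects} & clustered
    if not cis_ids:
        return float("nan")
    surviving = {
        d["label"]
        for G in pruned_networks.values()
        for _, d in G.nodes(data=True)
        if d.get("layer") == 2
    }
    return sum(s in surviving for s in cis_ids) / len(cis_ids)
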