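"""Synthetic multi-omics data with planted, machine-readable ground truth.

Emulates the statistical structure of an inbred-line association panel:

* a small genome in which gene promoters carry planted PWM consensus sites
  that one allele of a central SNP creates (Gain) or destroys (Loss);
* a biallelic, mostly homozygous genotype matrix with a controllable minor
  allele frequency spectrum;
* quantitative phenotypes on a BLUP-like scale with additive dosage effects
  planted from overlapping rSNP sets — disjoint rSNP "pleiotropy clusters"
  each driving several phenotypes;
* negative-binomial-like expression counts (gamma-Poisson with per-line
  size factors) with planted cis-allelic shifts.

Every generator is a pure function of (config, seed).  No linkage
disequilibrium, population structure, or kinship is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import regulatory as reg
from .regulatory import PWM, GeneAnnotation, SNPRecord
from .util import logger, substream

PHENOTYPE_PREFIX = "trait"
GENE_LENGTH = 900
GENE_SPACING = 2500
CONTIG_PAD = 700


@dataclass
class SimulationConfig:
    """Knobs of the synthetic panel; defaults are the package's reference
    study conditions (400 inbred lines, 2000 SNPs, 20 traits, 3 planted
    pleiotropy clusters of 4 rSNPs x 4 traits at standardized effect 0.5)."""

    n_lines: int = 400
    n_genes: int = 60
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_phenotypes: int = 20
    n_pwms: int = 30
    pwm_length_range: tuple[int, int] = (8, 14)
    n_planted_clusters: int = 3
    phenotypes_per_cluster: int = 4
    rsnps_per_cluster: int = 4
    effect_size: float = 0.5
    heritability_like_noise: float = 0.3  # fraction of trait variance that is noise
    cis_expression_shift: float = 1.0  # log2-fold shift of alt-homozygote mean
    het_rate: float = 0.0  # inbred panel: no heterozygotes by default
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_lines=self.n_lines, n_genes=self.n_genes, n_snps=self.n_snps,
            n_phenotypes=self.n_phenotypes, n_pwms=self.n_pwms,
            n_planted_clusters=self.n_planted_clusters,
            rsnps_per_cluster=self.rsnps_per_cluster,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.phenotypes_per_cluster < 2:
            raise ValueError("phenotypes_per_cluster must be >= 2 (pleiotropy needs >= 2 traits)")
        if self.n_planted_clusters * self.phenotypes_per_cluster > self.n_phenotypes:
            raise ValueError("planted clusters need more phenotypes than n_phenotypes provides")
        if self.pwm_length_range[0] > self.pwm_length_range[1]:
            raise ValueError(f"degenerate pwm_length_range {self.pwm_length_range}")
        if not 0 <= self.heritability_like_noise < 1:
            raise ValueError("heritability_like_noise must be in [0, 1)")

    @property
    def phenotype_names(self) -> list[str]:
        w = len(str(self.n_phenotypes))
        return [f"{PHENOTYPE_PREFIX}{i + 1:0{w}d}" for i in range(self.n_phenotypes)]


@dataclass
class PlantedRSNP:
    snp_id: str
    gene_id: str
    pwm_names: list[str]
    effect: str  # Gain | Loss
    chrom: str = ""
    pos: int = 0
    ref: str = ""
    alt: str = ""


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    planted_rsnps: list[PlantedRSNP] = field(default_factory=list)
    planted_clusters: list[tuple[list[str], list[str]]] = field(default_factory=list)  # (rSNP ids, phenotypes)
    planted_cis_effects: list[tuple[str, str, int]] = field(default_factory=list)  # (snp, gene, sign)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_rsnps": [asdict(p) for p in self.planted_rsnps],
                "planted_clusters": [
                    {"rsnps": r, "phenotypes": p} for r, p in self.planted_clusters
                ],
                "planted_cis_effects": [
                    {"snp_id": s, "gene_id": g, "sign": sg} for s, g, sg in self.planted_cis_effects
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            planted_rsnps=[PlantedRSNP(**p) for p in d["planted_rsnps"]],
            planted_clusters=[(c["rsnps"], c["phenotypes"]) for c in d["planted_clusters"]],
            planted_cis_effects=[
                (c["snp_id"], c["gene_id"], c["sign"]) for c in d["planted_cis_effects"]
            ],
        )


# ---------------------------------------------------------------------------
# PWM library


def generate_pwm_library(
    n_pwms: int, length_range: tuple[int, int] = (8, 14), seed: int = 0
) -> list[PWM]:
    """Random informative motifs, TRANSFAC-writable, with unique names.

    Each position has a dominant base (frequency 0.6-0.95); one position per
    motif is forced near-deterministic (0.97) so a consensus site is always
    plantable and destroyable by a single-base change.
    """
    lo, hi = length_range
    if lo > hi:
        raise ValueError(f"degenerate length_range {length_range}")
    if lo < 6:
        raise ValueError("motif lengths below 6 are not supported")
    if n_pwms < 1:
        raise ValueError("n_pwms must be >= 1")
    rng = substream(seed, "pwm-library")
    pwms = []
    width = len(str(n_pwms))
    for m in range(n_pwms):
        L = int(rng.integers(lo, hi + 1))
        freq = np.empty((L, 4))
        for i in range(L):
            dom = int(rng.integers(0, 4))
            f_dom = float(rng.uniform(0.6, 0.95))
            rest = rng.dirichlet(np.ones(3)) * (1 - f_dom)
            row = np.insert(rest, dom, f_dom)
            freq[i] = row
        # force one near-deterministic anchor position
        anchor = int(rng.integers(0, L))
        dom = int(np.argmax(freq[anchor]))
        freq[anchor] = 0.01
        freq[anchor, dom] = 0.97
        freq /= freq.sum(1, keepdims=True)
        pwms.append(PWM(name=f"M{m + 1:0{width}d}", freq=freq))
    return pwms


# ---------------------------------------------------------------------------
# Genome with planted promoter sites


def _best_kill_position(pwm: PWM) -> int:
    """Motif position whose consensus->min-base change drops mss the most."""
    weighted = pwm.info[:, None] * pwm.freq
    return int(np.argmax(weighted.max(1) - weighted.min(1)))


def _plan_layout(config: SimulationConfig, rng: np.random.Generator) -> list[GeneAnnotation]:
    genes = []
    w = len(str(config.n_genes))
    for i in range(config.n_genes):
        start = CONTIG_PAD + i * GENE_SPACING + 600
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneAnnotation(
                gene_id=f"gene{i + 1:0{w}d}",
                chrom="chr1",
                start=start,
                end=start + GENE_LENGTH - 1,
                strand=strand,
            )
        )
    return genes


def generate_genome_with_promoters(
    config: SimulationConfig,
    pwm_library: Sequence[PWM],
    planted_plan: Sequence[PlantedRSNP],
    seed: int = 0,
) -> tuple[dict[str, str], list[GeneAnnotation]]:
    """Random genome whose promoters carry the planted allele-specific sites.

    For a Loss rSNP the reference sequence contains the exact motif
    consensus overlapping the SNP and the alternate allele destroys it; for
    a Gain the roles are swapped.  Each planted site is verified against the
    scanner at default cutoffs before being accepted; the plan's ``chrom``,
    ``pos``, ``ref`` and ``alt`` fields are filled in place.
    """
    if len(planted_plan) > config.n_genes:
        raise ValueError("plan requests more planted sites than available promoters")
    rng = substream(seed, "genome")
    genes = _plan_layout(config, rng)
    gene_by_id = {g.gene_id: g for g in genes}
    length = 2 * CONTIG_PAD + config.n_genes * GENE_SPACING + 600
    contig = rng.choice(list("ACGT"), size=length)
    pwm_by_name = {p.name: p for p in pwm_library}

    for planted in planted_plan:
        gene = gene_by_id[planted.gene_id]
        pwm = pwm_by_name[planted.pwm_names[0]]
        consensus = pwm.consensus()
        kill = _best_kill_position(pwm)
        placed = False
        for _attempt in range(40):
            offset = int(rng.integers(-480, 81))  # transcription-direction offset
            if gene.strand == "+":
                pos = gene.tss + offset
            else:
                pos = gene.tss - offset
            start = pos - 1 - kill  # 0-based start of motif on + strand
            if start < reg.FLANK or start + pwm.length >= length - reg.FLANK:
                continue
            # fresh random context around the site, then write the motif
            lo, hi = pos - 1 - reg.FLANK, pos - 1 + reg.FLANK + 1
            contig[lo:hi] = rng.choice(list("ACGT"), size=hi - lo)
            contig[start : start + pwm.length] = list(consensus)
            weak = reg.BASES[int(np.argmin(pwm.freq[kill]))]
            if planted.effect == reg.LOSS:
                ref_base, alt_base = consensus[kill], weak
            else:
                ref_base, alt_base = weak, consensus[kill]
            contig[pos - 1] = ref_base
            window = "".join(contig[lo:hi])
            pair = reg.FlankingPair(
                snp_id="plant", ref_seq=window,
                alt_seq=window[: reg.FLANK] + alt_base + window[reg.FLANK + 1 :],
            )
            if reg.classify_consequence(pair, pwm).effect == planted.effect:
                planted.chrom, planted.pos = "chr1", pos
                planted.ref, planted.alt = ref_base, alt_base
                placed = True
                break
        if not placed:  # pragma: no cover - 40 independent contexts
            raise RuntimeError(f"could not plant {planted.effect} site for {planted.gene_id}")
    genome = {"chr1": "".join(contig)}
    return genome, genes


# ---------------------------------------------------------------------------
# Genotypes


def _draw_dosages(
    rng: np.random.Generator, n_lines: int, p_alt: float, het_rate: float
) -> np.ndarray:
    d = 2.0 * (rng.random(n_lines) < p_alt)
    if het_rate > 0:
        d[rng.random(n_lines) < het_rate] = 1.0
    return d


def generate_genotypes(
    config: SimulationConfig,
    genome: dict[str, str],
    planted_plan: Sequence[PlantedRSNP],
    seed: int = 0,
) -> tuple[list[SNPRecord], list[str]]:
    """Biallelic SNPs over mostly-homozygous lines; realized MAF respects the
    configured floor.  Planted SNP positions come from the genome plan; the
    remaining SNPs are placed uniformly at unused positions and their ref
    allele is read off the genome.  Fills planted snp_id fields in place."""
    rng = substream(seed, "genotypes")
    n = config.n_lines
    lo, hi = config.maf_range
    contig = genome["chr1"]
    used = {p.pos for p in planted_plan}
    records: list[tuple[int, str, str, np.ndarray, PlantedRSNP | None]] = []

    for planted in planted_plan:
        p_alt = float(rng.uniform(max(lo, 0.2), min(hi, 0.45)))
        while True:
            d = _draw_dosages(rng, n, p_alt, config.het_rate)
            if lo <= reg.compute_maf(d) <= 0.5 and np.sum(d == 2) >= 3 and np.sum(d == 0) >= 3:
                break
        records.append((planted.pos, planted.ref, planted.alt, d, planted))

    n_background = config.n_snps - len(planted_plan)
    interior = np.arange(reg.FLANK + 1, len(contig) - reg.FLANK)
    positions = rng.choice(interior, size=min(n_background + len(used), interior.size), replace=False)
    count = 0
    for pos in positions:
        if count >= n_background:
            break
        pos = int(pos)
        if pos in used:
            continue
        used.add(pos)
        ref = contig[pos - 1].upper()
        alt = str(rng.choice([b for b in reg.BASES if b != ref]))
        p_alt = float(rng.uniform(lo, hi))
        while True:
            d = _draw_dosages(rng, n, p_alt, config.het_rate)
            if lo <= reg.compute_maf(d) <= 0.5:
                break
        records.append((pos, ref, alt, d, None))
        count += 1

    records.sort(key=lambda r: r[0])
    w = len(str(len(records)))
    snps = []
    for i, (pos, ref, alt, d, planted) in enumerate(records):
        snp_id = f"snp{i + 1:0{w}d}"
        if planted is not None:
            planted.snp_id = snp_id
        snps.append(SNPRecord(id=snp_id, chrom="chr1", pos=pos, ref=ref, alt=alt, dosages=d))
    line_w = len(str(n))
    line_ids = [f"line{i + 1:0{line_w}d}" for i in range(n)]
    return snps, line_ids


# ---------------------------------------------------------------------------
# Phenotypes

import pandas as pd  # noqa: E402  (after numpy-heavy section on purpose)


def generate_phenotypes(
    snps: Sequence[SNPRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Lines x traits table: each clustered trait is the sum of additive
    standardized-dosage effects of its cluster's rSNPs plus Gaussian noise
    at the configured variance fraction; unclustered traits are pure noise."""
    rng = substream(seed, "phenotypes")
    n = config.n_lines
    dosage = {s.id: np.nan_to_num(s.dosages, nan=0.0) for s in snps}
    cluster_of_trait: dict[str, list[str]] = {}
    for rsnp_ids, trait_names in truth.planted_clusters:
        for t in trait_names:
            cluster_of_trait[t] = rsnp_ids
    out = {}
    for trait in config.phenotype_names:
        if trait in cluster_of_trait and config.effect_size != 0:
            g = np.zeros(n)
            for snp_id in cluster_of_trait[trait]:
                d = dosage[snp_id]
                sd = d.std()
                if sd > 0:
                    g += config.effect_size * (d - d.mean()) / sd
            var_g = g.var()
            f = config.heritability_like_noise
            noise_sd = np.sqrt(var_g * f / (1 - f)) if var_g > 0 else 1.0
            out[trait] = g + rng.normal(0.0, noise_sd, size=n)
        else:
            out[trait] = rng.normal(0.0, 1.0, size=n)
    line_w = len(str(n))
    index = [f"line{i + 1:0{line_w}d}" for i in range(n)]
    return pd.DataFrame(out, index=pd.Index(index, name="line"))


# ---------------------------------------------------------------------------
# Expression counts


def generate_expression(
    snps: Sequence[SNPRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    annotations: Sequence[GeneAnnotation],
    seed: int = 0,
) -> pd.DataFrame:
    """Genes x lines count matrix from a gamma-Poisson (negative-binomial-
    like) model with per-line size factors; planted cis effects shift the
    alt-homozygote mean by ``cis_expression_shift`` log2-fold units (half
    for heterozygotes)."""
    rng = substream(seed, "expression")
    n = config.n_lines
    dosage = {s.id: s.dosages for s in snps}
    cis_by_gene: dict[str, list[tuple[str, int]]] = {}
    for snp_id, gene_id, sign in truth.planted_cis_effects:
        cis_by_gene.setdefault(gene_id, []).append((snp_id, sign))
    dispersion = 0.1
    size_factors = np.exp(rng.normal(0.0, 0.25, size=n))
    rows = {}
    for gene in annotations:
        mu = float(np.exp(rng.normal(np.log(100.0), 0.8)))
        line_mu = np.full(n, mu)
        for snp_id, sign in cis_by_gene.get(gene.gene_id, []):
            d = np.nan_to_num(dosage[snp_id], nan=0.0)
            line_mu = line_mu * 2.0 ** (config.cis_expression_shift * sign * d / 2.0)
        gamma = rng.gamma(1.0 / dispersion, dispersion, size=n)
        rows[gene.gene_id] = rng.poisson(size_factors * line_mu * gamma)
    line_w = len(str(n))
    cols = [f"line{i + 1:0{line_w}d}" for i in range(n)]
    return pd.DataFrame.from_dict(rows, orient="index", dtype=int).set_axis(cols, axis=1)


# ---------------------------------------------------------------------------
# Whole-panel orchestration


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    pwms: list[PWM]
    genome: dict[str, str]
    annotations: list[GeneAnnotation]
    snps: list[SNPRecord]
    line_ids: list[str]
    phenotypes: pd.DataFrame
    counts: pd.DataFrame
    truth: GroundTruth


def plan_ground_truth(
    config: SimulationConfig, pwm_library: Sequence[PWM], seed: int = 0
) -> GroundTruth:
    """Assign disjoint rSNP sets, genes, TFs, effects and trait sets per
    planted pleiotropy cluster.  SNP coordinates are filled later by the
    genome and genotype generators."""
    rng = substream(seed, "plan")
    n_rsnps = config.n_planted_clusters * config.rsnps_per_cluster
    if n_rsnps > config.n_genes:
        raise ValueError("more planted rSNPs than genes with promoters")
    w = len(str(config.n_genes))
    gene_ids = [f"gene{i + 1:0{w}d}" for i in rng.choice(config.n_genes, n_rsnps, replace=False)]
    pwm_names = [pwm_library[i].name for i in rng.choice(len(pwm_library), n_rsnps, replace=False)]
    trait_pool = list(rng.permutation(config.phenotype_names))
    truth = GroundTruth()
    k = 0
    for c in range(config.n_planted_clusters):
        members = []
        for _ in range(config.rsnps_per_cluster):
            effect = reg.GAIN if k % 2 == 0 else reg.LOSS
            planted = PlantedRSNP(
                snp_id="", gene_id=gene_ids[k], pwm_names=[pwm_names[k]], effect=effect
            )
            truth.planted_rsnps.append(planted)
            members.append(planted)
            k += 1
        traits = sorted(trait_pool[c * config.phenotypes_per_cluster : (c + 1) * config.phenotypes_per_cluster])
        truth.planted_clusters.append(([p for p in members], traits))  # placeholder ids
    return truth


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator off the single config seed and return the bundle."""
    seed = config.seed
    pwms = generate_pwm_library(config.n_pwms, config.pwm_length_range, seed)
    truth = plan_ground_truth(config, pwms, seed)
    genome, annotations = generate_genome_with_promoters(config, pwms, truth.planted_rsnps, seed)
    snps, line_ids = generate_genotypes(config, genome, truth.planted_rsnps, seed)
    # snp ids now known: materialize cluster membership and cis effects
    truth.planted_clusters = [
        (sorted(p.snp_id for p in members), traits) for members, traits in truth.planted_clusters
    ]
    truth.planted_cis_effects = [
        (p.snp_id, p.gene_id, 1 if p.effect == reg.GAIN else -1) for p in truth.planted_rsnps
    ]
    phenotypes = generate_phenotypes(snps, truth, config, seed)
    counts = generate_expression(snps, truth, config, annotations, seed)
    return SyntheticDataset(
        config=config, pwms=pwms, genome=genome, annotations=annotations,
        snps=snps, line_ids=line_ids, phenotypes=phenotypes, counts=counts, truth=truth,
    )
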