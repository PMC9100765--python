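# pleioscan

**Pleiotropic signatures of regulatory SNPs** for quantitative-genetics
panels of inbred lines (built with a maize-style association panel in
mind): find promoter SNPs whose alleles create or destroy transcription
factor binding sites, associate them with many phenotypes at once, cluster
their association profiles into pleiotropy groups, and validate each group
against expression data with hierarchical TF → rSNP(gene) → phenotype
network models.

## Who this is for

Researchers analysing a genotyped, multi-phenotyped, RNA-sequenced panel
who want *regulatory* variant candidates with *multi-trait* effects —
rather than single-trait GWAS hits — plus a fully synthetic benchmark
panel with planted ground truth to test the whole workflow.

## The method

Four phases:

1. **rSNP calls.** SNPs with MAF < 0.05 are discarded; SNPs inside a
   promoter window (−500..+100 bp around the TSS, transcription direction)
   are scanned as allele-specific 51-base windows against a PWM library.
   Window-vs-motif similarity is the information-weighted score
   `MSS = (Current − Min)/(Max − Min) ∈ [0, 1]` with
   `Current = Σᵢ I(i)·f(i, sᵢ)`, `I(i) = Σ_b f(i,b)·ln 4f(i,b)`, plus a
   core score over the five most informative consecutive positions.
   A TF site present only with the reference allele is a **Loss**, only
   with the alternate a **Gain**; a SNP with either is an rSNP.
2. **Association.** Per phenotype, a Boruta shadow-feature wrapper around
   Random-Forest regression ranks the rSNP dosages; incremental feature
   selection walks down the ranking and picks the feature count k* with
   the peak out-of-bag R².
3. **Pleiotropy.** Binary rSNP profiles over phenotypes ∪ TFs are compared
   with the Proportional Similarity Index
   `A_kl = 2·Σⱼ min(M_kj, M_lj) / Σⱼ (M_kj + M_lj)` and clustered with the
   Markov clustering algorithm (expansion 2, inflation 2.0); rSNPs
   associated with fewer than two phenotypes are pruned.
4. **Networks.** Each cluster becomes a three-layer TF → rSNP(gene) →
   phenotype graph; expression (median-of-ratios normalized) is compared
   between reference- and alternate-allele lines with a Wilcoxon rank-sum
   test, and rSNPs without a significant shift are pruned with their
   orphaned TFs and phenotypes.

See `docs/methods.md` for formulas, defaults and the synthetic-data model.

## Worked example

Simulate a small panel, call rSNPs, and run the whole pipeline:

```bash
pleioscan simulate --outdir demo --seed 4
pleioscan call-rsnps --vcf demo/genotypes.vcf --fasta demo/genome.fasta \
    --gff demo/genes.gff3 --pwms demo/pwms.transfac --out demo/cons.tsv
```

```
wrote synthetic panel to demo
18 Gain/Loss consequences -> demo/cons.tsv
```

Eighteen (SNP, TF) pairs pass: the twelve planted Gain/Loss events (see
`demo/ground_truth.json`) plus six background sites that arise in random
promoter sequence.  Or in Python, end to end:

```python
from pleioscan import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(outdir="demo-run", seed=1, max_iter=40))
print(manifest["counts"])
```

```
{'snps_input': 2000, 'snps_maf_pass': 2000, 'consequences': 17, 'rsnps': 17,
 'phenotypes': 20, 'optimal_set_total': 61, 'profile_rows': 16,
 'clusters_raw': 6, 'clusters_pleiotropic': 5, 'validations': 14,
 'validations_significant': 12}
```

Reading: of 2000 simulated SNPs, 17 promoter SNPs change a TF binding site;
16 of them land in at least one phenotype's optimal rSNP set.  Markov
clustering of their PSI profiles recovers the 3 planted pleiotropic
clusters exactly (plus two background rSNPs that happened to associate
with two traits each, forming singleton clusters), and 12 of 14
allele-split expression tests are significant, so those rSNPs survive the
final network pruning.  The
per-cluster summary (`cluster_summary.tsv`) lists each cluster's rSNP and
gene counts with the union of associated phenotypes, and
`network_Cluster-*.json` / `.graphml` hold the three-layer models.

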