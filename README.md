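# bindqtl

Genetics of transcription-factor occupancy in a three-generation pedigree.

`bindqtl` is a reusable pipeline for *occupancy-QTL* analysis: given
ChIP-seq for a transcription factor (the motivating case is CTCF, with its
14 bp core motif and ~44 bp protein-DNA contact footprint) across the 12
members of a three-generation family, plus targeted resequencing of the
binding-site landscape, it asks which DNA sequence variants change how much
the factor binds — and why apparently equivalent variants often do not
("buffering"). It is aimed at regulatory-genomics researchers who want the
complete statistical machinery of such a study as tested, scriptable
components, together with a synthetic-data generator that emulates the
entire study so every stage runs and is validated without any external
download.

## What it computes

- **Motif energetics** (`bindqtl.motifs`): PWMs with a 0.01
  pseudo-frequency floor and log-odds in bits; *exact* motif-score p-values
  by dynamic programming over the discretised background score
  distribution; multivalent scanning (core model plus two upstream-module
  variants, both strands, ±15 bp) keeping the best match below p < 1e-2;
  allele log-odds deltas `Δ = |s(a₁) − s(a₂)|` for SNPs inside the core.
- **Signal** (`bindqtl.signal`): sliding 150 bp / 20 bp tag-density tracks,
  per-sample global normalization (median of bins > 15 reads → 25), site
  occupancy as the max normalized density over the motif, and a
  read-simulation mappability filter (every 36-mer within ±147 bp, once per
  allele per SNP, against an exact k-mer index) that also flags
  allele-differential mappability.
- **Genotyping** (`bindqtl.genotyping`): biallelic calls from pileups
  (≥8× coverage, quality ≥30, heterozygotes need ≥20% minor-allele reads),
  a Mendelian screen over every trio of the pedigree, outgroup
  polarization, and concordance against truth.
- **Association** (`bindqtl.assoc`): the headline test — negative-binomial
  GLM of per-replicate counts on genotype (log link, additive coding,
  replicate term), Cox-Reid dispersion with cross-site moderation,
  additive/dominant model choice by AIC, Storey or Benjamini-Hochberg
  q-values, and classification of hits by contact-region membership and
  agreement with the PWM-favored allele.
- **Allele-specific occupancy** (`bindqtl.ascount`): χ²(1) against a 50:50
  read split at heterozygous sites with ≥13 reads.
- **Linkage** (`bindqtl.linkage`): an in-house NB likelihood-ratio test for
  differential occupancy, the NB variance-stabilising transform, and
  aggregate Haseman-Elston regression of squared sib-pair trait differences
  on IBD ∈ {0, ½, 1}, with a structure-preserving permutation p-value; a
  negative slope evidences heritability.
- **Buffering** (`bindqtl.buffering`): per-substitution effect grids,
  occupancy-decile curves, perturbation-vs-motif-strength trends, mutual
  information between core sequence context and SNP effect status (with a
  2000-iteration resampling null), and Ward clustering of standardized
  occupancy.
- **Predictor evaluation** (`bindqtl.evalpred`): tie-grouped ROC curves,
  AUC = normalized Mann-Whitney U (two independent implementations held
  equal), PPV curves, and paired comparison of the PWM allele delta against
  a conservation track.
- **Synthetic study** (`bindqtl.synth`): 12-member pedigree with exact
  truth IBD, PWM-sampled motifs in 134 bp windows, uniformly planted SNPs,
  NB counts whose mean follows a saturating (logistic) function of allele
  binding energy — the threshold mechanism behind buffering —
  allele-partitioned reads, error-bearing pileups and a conservation-like
  track. See `docs/methods.md` for the model and its defaults.

## Worked example

Run the full pipeline on a 300-site synthetic study:

```sh
bindqtl all --seed 42 --outdir run300 --n-sites 300
```

which finishes in a few seconds and prints the run summary:

```json
{
  "config_hash": "f95684d995d9",
  "seed": 42,
  "sites_surveyed": 300,
  "sites_polymorphic": 276,
  "sites_testable": 260,
  "sites_significant": 10,
  "assoc_frac_significant_in_contact": 1.0,
  "assoc_allele_concordance": 1.0,
  "genotype_discordance": 0.006134969325153374,
  "he_slope_associated": -3.417099011836195,
  "he_p_associated": 0.047476261869065464,
  "auc_delta": 0.9035714285714286,
  "auc_conservation": 0.6154761904761905
}
```

Reading it: of 300 surveyed sites, 276 carried a SNP that passed the
genotyping filters and 260 were testable for association; 10 sites were
significant at FDR 1%, every one with its SNP inside the 44 bp
protein-DNA contact region, and in every case the allele with higher
measured occupancy was also the allele the motif model scores higher
(concordance 1.0). Genotype calls disagreed with simulation truth at 0.6%
of comparisons (1% base-call error at ~50×). Among differentially occupied
sites in the six sibs, the SNP-associated stratum shows heritable
occupancy — squared sib-pair differences fall with IBD, slope −3.4,
one-sided permutation p = 0.047 at this small scale — and the PWM allele
delta outperforms the noisy conservation track as a predictor of
functional SNPs (AUC 0.90 vs 0.62). Per-stage tables (`assoc_results.tsv`,
`allele_specific.tsv`, `mutual_information.tsv`, `clusters.tsv`, ...)
land in `run300/`, with a structured log in `log.jsonl`.

The same run is available programmatically:

```python
from bindqtl.cli import RunConfig, run_pipeline
from bindqtl.synth import SimConfig

ctx = run_pipeline(RunConfig(seed=42, outdir="run300",
                             sim=SimConfig(n_sites=300)))
ctx["summary"]["sites_significant"]   # -> 10
```

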