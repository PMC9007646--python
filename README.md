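# spongecerna

Differential lncRNA–miRNA–mRNA sponge (ceRNA) network analysis for
two-risk-group RNA-seq cohorts, with a fully synthetic cohort generator
carrying planted ground truth.

## The problem

In the competing-endogenous-RNA (ceRNA) model, a long non-coding RNA and
an mRNA that share response elements for the same microRNAs compete for
a common miRNA pool: when the lncRNA is abundant it "sponges" the shared
miRNAs and de-represses the mRNA. In a cohort split into clinical risk
groups (here by white-blood-cell count, WBC ≥ 50 ×10⁹/L = high risk, as
in pediatric B-precursor acute lymphoblastic leukemia), comparing the
sponge networks of the two groups highlights hub lncRNAs whose rewired
regulation tracks risk — candidate prognostic markers.

This package implements that analysis as a tested pipeline:

1. **Cohort preprocessing** — duplicate-symbol averaging, exclusion
   criteria, WBC risk stratification, and a baseline-characteristics
   table (Welch's t for continuous rows, Yates-corrected χ² or Fisher's
   exact for categorical rows).
2. **Differential expression** — per RNA class, a negative-binomial Wald
   test built from first principles: median-of-ratios size factors
   s_j = median_g (x_gj / (∏_j x_gj)^(1/m)), method-of-moments dispersion
   α̂ from Var(X) = μ + αμ², log₂ fold change with a 0.5 pseudo-mean,
   delta-method standard error, and Benjamini–Hochberg adjustment.
   Significance at FDR < 0.01 and |log₂FC| > 1.
3. **Sponge network per risk group** — for each candidate (lncRNA, mRNA)
   pair with target sets T_l, T_m in a miRNA universe of size N, the
   shared count M = |T_l ∩ T_m| is tested with the hypergeometric tail
   P(X ≥ M), X ~ Hypergeom(N, |T_l|, |T_m|); pairs pass at M > 2,
   p < 0.01, Pearson r > 0 and BH-adjusted correlation p < 0.05 within
   the group.
4. **Causal scoring** — treating the shared miRNAs as the common causes,
   the lncRNA→mRNA effect is the signed Wald statistic of the lncRNA
   coefficient in z(mRNA) ~ z(lncRNA) + z(shared miRNAs); strength is
   also tested with Fisher's z-transform p = 2(1 − Φ(|atanh(r)|·√(n−3))).
5. **Topology** — top-20%-degree hub lncRNAs; between-group similarity
   Sim = |E_high ∩ E_low| / min(|E_high|, |E_low|) and hub dissimilarity
   1 − |H_high ∩ H_low| / min(|H_high|, |H_low|); scale-free regression
   of log P(k) on log k; Markov clustering (expansion/inflation) into
   modules.
6. **Survival screen** — per differential hub: median-dichotomized
   expression, Kaplan–Meier curves, two-group log-rank test, and a Cox
   proportional-hazards fit (Breslow ties, Newton–Raphson) for the
   hazard ratio; a hub passes at log-rank p < 0.01 and HR > 2.
7. **Enrichment** — hypergeometric over-representation of network mRNAs
   in user-supplied GMT gene sets, BH-adjusted.

Because patient-level data cannot ship with the package, the
`synthetic` module generates the whole study: NB count matrices with
planted differentially expressed genes, sponge triplets coupled through
a latent shared-miRNA activity (target Pearson r = 0.7), interaction
tables, and survival times driven by prognostic hub expression — all
recorded in a ground-truth manifest so every stage is validated by
parameter recovery and null calibration.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (169 low-risk + 92 high-risk samples, 2000 mRNAs,
600 lncRNAs, 150 miRNAs, 50 planted sponge triplets, 10 prognostic
hubs, seed 1), writing all tables under `results/`:

```sh
for s in analysis/0*.py; do python "$s"; done
```

which prints, among other things:

```
cohort: 261 samples -> 169 low-risk (64.8%), 92 high-risk (35.2%)
  age (Welch from summaries 8.11(5.40) vs 7.63(5.02)): p = 0.473
  gender (Yates 85/84 vs 43/49):        p = 0.675
  ETV6-RUNX1 (Yates 19/150 vs 2/90):    p = 0.0195
mRNA: 100 up, 98 down of 2000 genes (FDR<0.01, |log2FC|>1.0)
high-risk network: 50 sponge edges over 50 lncRNAs and 50 mRNAs
high-risk: 50 edges scored, range [2.50, 8.64], 50 positive (100.0%)
DE genes:      precision 1.000, recall 0.992
sponge pairs:  precision 1.000, recall 1.000
prognostic hubs flagged at log-rank p<0.01: 100%
```

The Welch/Yates p-values are the worked examples recomputed from the
printed group summaries of the reference 261-patient cohort table; the
recovery lines compare the pipeline's calls with the generator's
planted truth (`results/inputs/truth.json`). All causal scores are
positive on planted sponge pairs, as the ceRNA model predicts —
sponged mRNAs are up-regulated by their lncRNA partners.

## Layout

```
src/spongecerna/   library: io, config, synthetic, cohort, diffexpr,
                   sponge, causal, topology, survival, enrichment, pipeline
analysis/          numbered narrative drivers (01 simulate ... 09 evaluate)
tests/             pytest suite incl. acceptance checks
scripts/           acceptance.py
docs/methods.md    modelling and design notes
```
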