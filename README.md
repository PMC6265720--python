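# siterates

Site-specific rates of protein sequence evolution, analyzed against three
structural factors: intrinsic disorder, secondary structure, and functional
domain membership.

## The problem

Within a protein, amino-acid replacement rates vary strongly from site to
site, and that variation is shaped by structure and function: disordered
regions drift, packed cores and functional domains are constrained, and —
counter-intuitively — sites that are predicted to be *both* intrinsically
disordered and inside secondary structure tend to be among the slowest of
all, a signature of transient structure that folds upon binding.
Demonstrating this requires a chain of machinery: homolog clustering,
alignment quality control, per-site evolutionary rate inference on a tree,
mapping per-residue structural predictions onto alignment columns, and a
multi-factor statistical analysis over the pooled labeled sites.

`siterates` implements that chain as a tested, desk-scale Python package,
together with a synthetic-family generator that provides ground truth (true
tree, true per-site rates, true site classes) for every stage. It is aimed
at molecular-evolution researchers who want a reproducible, inspectable
version of this analysis to run on their own families or on simulations.

## The model

Substitution follows the 20-state equal-exchangeability model (the
Jukes–Cantor form generalized to amino acids): all exchangeabilities equal,
uniform equilibrium frequencies π = 1/20. With branch lengths t in expected
substitutions per site,

    P(same | t) = 1/20 + (19/20) e^{-(20/19) t}
    P(diff | t) = 1/20 − (1/20) e^{-(20/19) t}

Among-site rate variation is a discrete gamma Γ(α, 1/α) with K = 16
equal-probability categories (bin-mean rates r₁ < … < r₁₆, mean 1). On a
fixed input tree, α is fitted per family by maximum likelihood (Felsenstein
pruning, bounded Brent search), and each column's rate is the empirical-Bayes
posterior mean

    r̂ = Σ_c r_c L(col | r_c) / Σ_c L(col | r_c).

Per family, rates are z-normalized (mean 0, population SD 1), so positive
scores mark faster-than-average sites in every alignment.

Columns are then labeled by *conserved* binary predictions — disordered iff
every sequence's disorder score > 0.4 (ordered iff all < 0.4); structured iff
all helix or all strand (coil iff all coil); domain iff every residue falls
in a domain (linker iff none does) — with any gapped column excluded. The
statistical battery over pooled labeled sites comprises Mann-Whitney
contrasts per factor, Kruskal-Wallis plus mean-rank pairwise comparisons
with a Bonferroni-adjusted critical difference over the eight factor-level
cells, an unbalanced (type III) 2×2×2 factorial ANOVA with zero-sum
contrasts, and a loess regression of family disorder content against the
mean rate of disordered-structured sites.

## Worked example

Run the calibrated synthetic study — 20 families of 16 sequences, with
disordered sites evolving 2× faster, coil 1.3×, linkers 1.5×, but
disordered-structured sites at 0.5× — and print the analysis:

```python
from siterates.pipeline import PipelineConfig, run_all

run = run_all(PipelineConfig(n_families=20, seed=1), "workdir")
print(run.stats.summary())
```

```
Multi-factor site-rate analysis
================================================
tri-factor sites: 1550

Mann-Whitney contrasts (delta = median(second) - median(first)):
  disorder_minus_order         delta_median=+0.1007  U=1110819.5  p=1.65e-08  (n=2572/984, asymptotic)
  coil_minus_structure         delta_median=+0.3939  U=1210432.0  p=2.19e-45  (n=1790/1854, asymptotic)
  linker_minus_domain          delta_median=+0.2210  U=6203820.0  p=4.9e-37  (n=4964/3010, asymptotic)

Kruskal-Wallis over 8 cells: H=218.91 p=1.12e-43
Pairwise mean-rank comparisons: 21/28 significant at alpha=0.05

Type-III factorial ANOVA (zero-sum contrasts):
  disorder               SS=5.699  F=6.29  p=0.0123
  ss                     SS=158.986  F=175.46  p=5.2e-38
  domain                 SS=23.438  F=25.87  p=4.11e-07
  disorder:ss            SS=61.719  F=68.11  p=3.27e-16
  ...
  adjusted R^2 = 0.1585

Cell means (disorder/ss/domain -> mean z-rate):
  ordered/structured/domain   n=398     -0.3271
  ...
  disordered/structured/domain   n=82      -0.5656
  disordered/coil/linker   n=106     +0.9696
```

Reading the output: all three median differences are positive — disordered,
coil and linker sites evolve faster than ordered, structured and domain
sites respectively — yet the disorder × structure interaction is strong
(p ≈ 3×10⁻¹⁶) and the disordered-structured cell means (−0.57, −0.51) lie
*below* the ordered-structured ones (−0.33, −0.05): the rate-reversal this
analysis exists to detect. All of this is recovered through the full
pipeline (QC, rate inference on the tree, conserved labeling with 5%
annotation noise), not read off the simulation truth.

The same stages are available from the shell:

```sh
siterates run-all --seed 1 --out workdir
siterates simulate --seed 2 --n-families 5 --out fams/
siterates qc fams/fam000.fasta
siterates rates fams/fam000.fasta fams/fam000.nwk --out rates.tsv
siterates stats workdir/sites.tsv
```

Per-stage library entry points: `cluster_records` (single-linkage homolog
clustering at 40% identity / 90% coverage), `qc_filter` (the five
alignment-suitability filters), `SiteRateModel(msa, tree).fit()`,
`build_label_table`, and `RateFactorAnalysis(site_table).fit()`.

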