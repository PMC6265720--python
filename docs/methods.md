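# Methods

This note records the models, conventions and design choices behind
`siterates`, in the order the pipeline runs them.

## Scope and data flow

The unit of analysis is the protein family: one multiple sequence alignment,
one tree with branch lengths, and one annotation bundle (per-residue
disorder scores in [0,1], three-state secondary structure H/E/C, and domain
intervals). In real-data mode these are inputs — the package does not run
disorder/secondary-structure/domain predictors, align sequences, or infer
trees by Bayesian/ML search; it consumes predictor output and trees as
given. In synthetic mode the generator produces all of them with known
ground truth. Stages: (clustering) → QC → rate inference → conserved
labeling → pooled statistics, each re-runnable from the previous stage's
files.

## Homolog clustering

Pairs are scored by best local alignment (Smith–Waterman semantics via
Biopython's PairwiseAligner; BLOSUM62; affine gaps costing 11 + k for a gap
of length k). Two sequences link when identity ≥ 40% — counted as exact
matches over *all* footprint columns, gaps included in the denominator —
and the footprint covers ≥ 90% of the longer sequence; both thresholds
inclusive. Clusters are connected components of the link graph, kept at
sizes 10–300. Admission requires length ≥ 30 and no non-standard residues.
A conservative length-ratio prefilter (skip pairs with shorter/longer <
coverage × identity = 0.36) is provably unable to change any component and
is on by default. No E-values or alignment heuristics are modelled: the
linkage *criteria*, not BLAST internals, are what matters downstream.

## Alignment QC

Five filters, all required: (i) minimum pairwise identity (1 − p-distance,
pairwise deletion) ≥ 0.30; (ii) every row covers ≥ 50% of the columns;
(iii) standard residues and `-` only; (iv) conserved-column fraction < 0.90;
(v) ≥ 4 unique ungapped sequences. A "conserved" column in (iv) is gap-free
and invariant; columns containing gaps count as non-conserved. That gap
handling is a choice (the alternative — counting gapped invariant columns —
is defensible); it is consistent with the blanket gap exclusion applied to
all site statistics, and it is configurable via `QcThresholds`.

## Site-rate inference

* **Substitution model.** 20-state equal-exchangeability with uniform
  frequencies; closed-form transition probabilities (see README). The unit
  of branch length is one expected substitution per site. This is the
  deliberate model choice for measuring raw replacement rates; empirical
  matrices (JTT etc.) are out of scope by design, not omission.
* **Rate variation.** Discrete gamma, 16 equal-probability categories,
  category rate = bin mean (computed via the incomplete-gamma identity and
  renormalized so the category mean is exactly 1). α is fitted per family by
  bounded Brent search on [0.05, 50], tolerance 1e-4. A fit pinned at a
  bound (e.g. an invariant alignment) emits a warning rather than failing.
* **Likelihood.** Felsenstein pruning vectorized over columns, per-node
  max-rescaling with the log carried separately, so 300-taxon families do
  not underflow. Gaps and non-standard residues at leaves are missing data
  (all-ones partials). Likelihood is invariant to root placement
  (reversibility), verified against brute-force state enumeration on all
  ≤ 4-leaf topologies.
* **Posterior rates and normalization.** Site rate = posterior mean over
  categories (equal priors). Per family, rates are z-scored with the
  *population* SD; only the zero mean is an external convention, the SD
  choice is ours. A zero-variance family returns all-zero scores with a
  warning.
* **Trees.** Input trees are used as-is. For data without trees a
  neighbor-joining builder on p-distances is provided (3-taxon closed form;
  skbio NJ otherwise; negative branches clamped to 0). It is a convenience,
  not a replacement for proper tree inference on real data.

## Conserved site labeling

Annotations live in residue coordinates; the alignment coordinate map
carries them to columns (internally 0-based half-open; file headers state
the convention). Labels require unanimity: disordered iff every score
> 0.4, ordered iff every score < 0.4 — a score of exactly 0.4 leaves the
site unlabeled, reading "above/below" strictly; structured iff all H or all
E (mixed helix/strand is unlabeled), coil iff all C; domain iff every
residue inside a (merged) interval, linker iff none — domain *identity* is
not required, membership is binary. Columns with any gap are excluded
before labeling. Helix- and strand-conserved sites are collapsed to
"structured" downstream.

## Pooled statistics

Sites are pooled across families and treated as independent observations —
a deliberate replication of the large-scale design this package mirrors,
with its acknowledged pseudo-replication; a per-family stratified variant of
the two-group contrasts can be assembled from the per-family tables but is
not the default. Mann-Whitney contrasts are exact (full enumeration of rank
assignments, midranks for ties, two-sided p as twice the smaller tail) when
both groups have ≤ 8 observations, and the tie-corrected normal
approximation with continuity correction otherwise. Kruskal-Wallis is
tie-corrected with χ²(k−1) p-values; the degenerate all-identical case
returns H = 0, p = 1. Post-hoc pairwise comparisons over the eight
tri-factor cells use the pooled-mean-rank critical difference
|R̄ᵢ − R̄ⱼ| ≥ z₁₋α/(k(k−1)) √(N(N+1)/12 · (1/nᵢ + 1/nⱼ)) at α = 0.05; no
correction is applied *across* the three two-group contrasts. The factorial
ANOVA is type III with zero-sum contrasts (statsmodels OLS + anova_lm),
valid for unbalanced cells; an empty cell raises an explicit
inestimable-term error. Loess is local linear with tricube weights over the
ceil(span·n) nearest neighbors (span 0.75 by default, printed in reports);
the disorder-content regression requires ≥ 10 families contributing a
disordered-structured mean.

## Synthetic-family generator

The generator is the test bed: it emulates the *statistical* structure of
real protein families, not their biochemistry.

* **Tree.** Yule topology; exponential branch lengths rescaled so the mean
  root-to-tip depth equals `tree_height` exactly. Default height 0.6
  substitutions/site: deep enough for rate signal, shallow enough that
  families respect the ≥ 30% identity QC floor that real analyzed families
  satisfy by construction (they enter via 40%-identity clustering).
* **Architecture.** Domains/linkers and disordered/ordered regions are
  independent alternating segment processes with geometric lengths (means
  60/40 and 30/70 residues). Secondary structure is a typed segment process
  whose type probabilities depend on the local disorder state (80% coil
  inside disorder vs 45% outside), so disordered regions are mostly coil —
  as real predictors report — while disordered-structured sites still occur.
* **Rates.** Column rate = class multiplier × i.i.d. Γ(α, 1/α) residual,
  rescaled to mean 1. Default multipliers 2.0 (disorder), 1.3 (coil), 1.5
  (linker) combine multiplicatively, except that disordered-structured
  sites *replace* the disorder factor with 0.5 — the minimal generative
  model that produces positive pooled contrasts for all three factors
  together with the disorder × structure rate reversal. Magnitudes are
  calibrated only to the direction of the real effects, not their size.
* **Sequences.** Root uniform over 20 residues; sites evolve independently
  under the equal-exchange process — the same model the inference assumes,
  so recovery tests measure estimation error, not model misspecification.
* **Family size.** Defaults 16 taxa × 626 columns. The column count is the
  mean alignment length implied by the proteome-scale totals this design is
  scaled down from (≈14.0M sites over ≈22.4k alignments); materially
  shorter families leave the pooled disorder contrast underpowered at 20
  families.
* **Indels.** Columns are marked i.i.d. with probability `indel_rate`
  (default 0.34, matching the ~66% gap-free fraction of the real data);
  marked runs become gap masks over a random proper subset of rows.
  Residues at unmasked cells are untouched. Indels are placed post hoc, not
  evolved: downstream analysis discards gapped columns entirely, so only
  the gap bookkeeping matters.
* **Annotation noise.** Disorder scores are Beta(2,2) draws mapped onto the
  correct side of the 0.4 cutoff and flipped across it with probability
  `annotation_noise` per residue (any distribution with the right side
  would do); SS states flip to a uniform other state; domain boundaries
  jitter by 1–2 residues with the same probability. Noise 0 round-trips
  exactly to the true labels.

What the generator does *not* emulate — alignment error, heterotachy,
among-branch rate variation, non-independent sites, codon-level effects,
predictor biases correlated with rate — bounds what passing tests show:
they validate the machinery and its statistical behaviour under the stated
generative model, not the biological conclusions on real proteomes.

## Determinism and problem sizes

Every stochastic step flows from one integer seed through
`numpy.random.default_rng`; identical configuration and seed give
byte-identical FASTA/Newick/annotation/TSV outputs. The shipped study sizes
— 20 families × 16 taxa × 626 columns for the calibrated analysis, one
16-taxon × 500-column family for rate recovery — run in well under a minute
each on a single CPU and were chosen as the smallest sizes at which the
pooled contrasts are stably powered across seeds.

## Known limitations

* Identity in clustering is footprint-based (gaps in the denominator);
  other tools normalize differently, so cluster boundaries can differ near
  the 40% threshold. The convention is configurable.
* α and the posterior rates are conditioned on the input tree; tree error
  propagates unmodelled into the rates.
* The exact Mann-Whitney path is O(C(n₁+n₂, n₁)) and intentionally capped
  at group sizes of 8.
* Loess standard errors/confidence bands are not computed; the regression
  is descriptive, as in the analysis it mirrors.
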