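# Methods

## Statistics computed

All statistics operate on a probe × sample matrix of positive,
linear-scale intensities. Log-scale inputs (declared in GEO series-matrix
metadata) are un-logged (2^x) at load time, because both the SE ratio and
"expression amount" ranking are ratio/magnitude statements that are
meaningless on a log scale.

**Housekeeping correction.** Every sample column is divided by that
sample's intensity on a single housekeeping probe (default: the GAPDH
probe `217398_x_at` of the HG U133A 2.0 chip). No multi-gene panel is
used. The correction is idempotent and removes any per-sample positive
scale factor exactly, which the paired dissect-and-hybridise design makes
essential. It precedes every downstream statistic — including the
correlations, where the choice is not forced by the ratio algebra; a
`--no-normalize` switch exists for sensitivity analysis.

**SE ratio.** For probe g over tumors t with stroma value s_t and
epithelium value e_t, two estimators are provided:

* `mean_of_paired_ratios` (default): mean_t(s_t / e_t). Each tumor is its
  own control; inter-tumor scale differences cancel within the pair.
* `ratio_of_means`: mean_t(s_t) / mean_t(e_t). Pooled compartment means;
  less variance under heavy noise, but tumors no longer self-control.

The default is the paired form; both are first-class because the pooled
form is an equally defensible reading of "ratio of stroma to epithelium"
and downstream comparisons can be run under either. Tumors with a zero
epithelium value are skipped with a logged warning in paired mode; a probe
whose every tumor is skipped gets an undefined (NaN) ratio and no tier.

**Anchor correlation (R-index).** Pearson product-moment correlation
between a probe's stromal values and the anchor probe's stromal values,
stroma compartment only, across tumors; at least 3 stroma samples are
required. A vector whose centred norm is below 1e-12·√n·max|x| is treated
as constant (the spread is floating-point residue, not signal) and the
correlation is undefined; undefined correlations are excluded from all
threshold counts rather than counted as zero — absence of evidence, not
anti-correlation.

**Tiers.** CAFG: SE ≥ 10; semi-CAFG: 5 ≤ SE < 10; L-CAFG: SE < 5. All
thresholds, including the correlation cut-offs 0.9/0.8/0.6, are inclusive
at the bound.

**Screening is probe-level.** Probes are never collapsed to genes before
statistics (distinct probes of one gene can disagree and that disagreement
is informative). Gene-level decisions — needed when comparing against
gene-symbol reference lists — use the gene's *best probe*, the one with
the highest mean stromal expression (ties by probe id); an any-probe rule
is available as a switch. Reference-set overlap reports: genes on chip,
genes passing R ≥ r_min via their best probe, the passing fraction and the
mean SE over passing genes' best probes. Rounding (R to 2 decimals, SE to
1) happens only in the presentation layer; stored tables keep full
precision.

**Subtype-restricted screen.** Anchor correlations are recomputed over the
stroma samples of one molecular subtype only (≥ 3 tumors required; TNBC
subsets of 4–5 tumors are the motivating case, and the subset size is
reported with the result — no significance filter is applied). A probe is
*shared* when both subset and full-cohort correlations reach r_subset_min
(default 0.9) and *subtype-specific* when the subset correlation reaches
r_subset_min while the full-cohort correlation stays below r_full_max
(default 0.6); with r_full_max ≤ r_subset_min the two lists are disjoint
by construction.

## Synthetic cohorts

The generator emulates the statistical structure the screen assumes, not
any array platform's chemistry. For tumor t (latent CAF-activation factor
f_t ~ N(0,1)) and gene g (baseline b_g, planted SE ratio ρ_g, loading
λ_g):

    stroma_{g,t}     = b_g · ρ_g · exp(λ_g f_t) · ε
    epithelium_{g,t} = b_g · ε′

with ε, ε′ independent log-normal noise of log2-scale sd σ. Defaults: 28
tumors, 5 of them TNBC; σ = 0.3 (a moderate microarray-scale noise level);
baselines log-uniform over ±2 log2 units around 100; anchor-block SE
ratios log-uniform in [5, 25] (CAFG-like) with loadings in [0.6, 0.95] and
the anchor fixed at λ = 1 (the block's largest); background genes λ = 0
with SE ratios log-uniform in [0.5, 2]; a constant housekeeping probe; and
per-sample scale jitter (log2-sd 0.5) multiplying every column so that the
normalization path is always exercised.

Subtype-block genes follow the anchor factor (λ in [0.9, 1.0]) only inside
the subtype tumors; elsewhere they carry gene-private tumor-to-tumor
variability (log-sd 2.0), uncoupled from f_t. The private term is a
deliberate modelling choice: a gene that is flat outside the subtype lets
the few aligned heavy-tailed subtype samples dominate the full-cohort
linear-scale Pearson correlation, which is not how a stromal-content-driven
gene behaves across real tumors. The subtype fixtures use σ = 0.1; with
n = 5 subset samples the subset correlation must survive at R ≥ 0.9, and
this is the noise level at which that operating point is meaningful.

Two analytic facts matter when comparing estimates to truth. First, for
λ > 0 the paired-ratio SE estimator targets ρ_g · E[exp(λ f)] =
ρ_g · exp(λ²/2), not ρ_g; recovery tests therefore use λ = 0 genes (where
the estimator targets ρ_g, with a small positive bias E[ε/ε′] =
exp(σ_ln²) ≈ 1.04 at σ = 0.3). Second, the empirical mean |r| between the
anchor and truly independent background genes is not 0 but the null
sampling level √(2/π)/√(n−1) ≈ 0.153 at n = 28; the generator's tests
check the mean signed correlation is ≈ 0 and the mean |r| matches this
null expectation.

What the generator does **not** emulate: probe-level chemistry and
saturation, MAS5/RMA summarisation artefacts, correlated background
structure (cell-type mixtures other than the single CAF factor), missing
values, and real-cohort marginal distributions. Passing tests therefore
demonstrate the pipeline computes its statistics correctly and recovers
planted structure under log-normal noise — not that any particular
biological list is correct.

## Numerical and design choices

* Sample pairing uses the annotation's tumor_id only, never sample-id
  string patterns; tumors missing a compartment are excluded with a log
  entry, and zero complete pairs is an error.
* Probes absent from the probe map keep their probe id as gene symbol
  (with a warning); gene names are reporting sugar, the screen is
  probe-level.
* Deterministic ordering everywhere: screen tables sort by expression rank
  then probe id; expression ranking breaks ties by probe id ascending;
  design building sorts tumors by tumor_id, making it independent of
  annotation row order.
* Correlations are clipped to [−1, 1] after computation; pipeline outputs
  are reproducible bit-for-bit for identical inputs, and correlations are
  stable across runs to well below 1e-9.
* The built-in reference set carries only the colorectal CAFGs with
  published stromal SE values (16 genes, FAP 20.2 … LRRC15 10.5); full
  catalogues are user-supplied two-column TSVs.
* Test and acceptance problem sizes (50–300-probe cohorts, 1000-gene null
  panels, 100 subtype replicates) were chosen as the smallest scales at
  which the measured quantities are statistically stable; everything runs
  in seconds.

## Limitations

* The screen is purely correlational; no significance testing or multiple
  testing correction is applied (raw R thresholds mirror the screening
  design it implements), so small subsets (TNBC n = 4–5) carry large
  sampling variance — the subset size is attached to every subtype result
  for exactly this reason.
* With ~28 tumors the SE estimator's ~4–6% median relative error is
  irreducible under σ = 0.3 noise; genes within ~20% of a tier boundary
  can flip tiers.
* The GEO series-matrix reader fills compartment/subtype best-effort from
  characteristics lines; a user-supplied annotation table is authoritative
  and required for subtype analyses.
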