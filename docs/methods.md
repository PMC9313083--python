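# Methods

This note documents the statistical procedures degnet implements, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Input model and preprocessing

A study is a genes × samples matrix of log2-scale intensities with a
case/control label per sample and a disease-group tag (LC/BC/LK/OTHER).
Validation requires unique row/column ids, finite values and at least two
samples per arm; values above 30 trigger a warning that the matrix is likely
on the linear scale (no silent transform is applied — hidden transforms hide
bugs). Rows with missing values are dropped at read time with a logged count;
any other non-numeric cell is a hard parse error naming its row and column.

Preprocessing is deliberately generic and per-dataset only:

- **Probe collapsing** keeps, per gene, the probe with the highest variance
  across samples. Max-variance (rather than averaging) preserves dynamic
  range, which matters for the downstream correlation networks.
- **Quantile normalization** replaces each column's sorted values with the
  across-column mean of sorted values; ties within a column receive the mean
  of the quantile values their rank range spans. The procedure is exactly
  idempotent on tie-free data.
- **Variance filtering** keeps the `⌈f·n⌉` most variable genes, preserving
  order. Default `f = 1.0` (off), so results are deterministic functions of
  the input unless filtering is requested.

No cross-dataset normalization is performed: the consensus layer consumes
per-dataset *calls*, never harmonized values, so between-platform scale
differences cannot leak across studies.

## Differential expression

Effect: `Δ = mean(case) − mean(control)` on the log2 matrix. Test: Welch
unequal-variance t with Satterthwaite degrees of freedom (delegated to
`scipy.stats.ttest_ind(equal_var=False)`), two-sided p, Benjamini–Hochberg
step-up correction within the dataset (via `statsmodels`). Calls use
inclusive thresholds, defaults `FDR ≤ 0.05` and `|Δ| ≥ 1`.

Degenerate genes (zero variance in both arms) get `t = 0, p = 1` when the
means agree, and `p = 0` with an explicit `degenerate` flag when they differ:
a noiseless difference is unambiguous evidence, but not evidence the t
distribution can calibrate, so it is flagged rather than silently assimilated.

A moderated (shrinkage) test was deliberately not used: the plain Welch
formula is verifiable against a direct hand evaluation, which the test suite
does to 1e-10, and the consensus layer is robust to per-dataset power
differences by construction.

## Consensus winner calling

For each gene and disease group the up- and down-calls are counted over the
group's datasets. With `d*` the LC majority direction and `c_LC` its count:

- **common winner**: `c_LC ≥ common_lc_min` (default 8) and the
  other-cancer support `oc ≥ oc_min` (default 1). By default `oc` counts
  only `d*`-direction calls in BC/LK (`same_sense`); an `any_sense` mode
  counts deregulation in either direction, because published count tables
  of this kind tally direction-discordant deregulation too.
- **unique-LC winner**: `c_LC ≥ unique_lc_min` (default 7) and *zero*
  other-cancer deregulation **in any direction** — "unique to lung cancer"
  means no other cancer shows the gene moved at all, so the exclusion test
  is any-sense regardless of the support mode. Any-sense zero implies
  same-sense zero, so the two statuses remain mutually exclusive.
- An up/down tie among LC datasets gives direction `mixed` and can never
  win: "the same sense" is undefined for ties.

Thresholds are absolute dataset counts, not fractions; they are not scaled
to the collection size automatically (scaling is the caller's choice).

The descriptive *group-presence pattern* (which of LC/BC/LK show any
deregulated dataset) always uses any-direction counts. The package ships a
published table of 34 winning-TF count triples as reference data; its
partition (13 in all three groups / 9 LC&BC / 6 LC&LK / 6 LC-only) and row
totals are recomputed by `degnet winning-tf-demo`, the test suite and the
acceptance script. The published prose totals (25 common + 6 unique TFs) do
not equal either the table row count (34) or the figure-group sum (28); no
reconciliation rule is available, so the package reports the raw pattern
histogram and the threshold-strict winner counts side by side and does not
guess.

## Coexpression networks

Similarity is `|Pearson r|` across all samples of one dataset by default
(cases + controls; a cases-only switch exists — using both arms measures
coexpression over the full observed dynamic range, and which convention
older studies used is typically unstated). Constant genes get similarity 0
to all others and are flagged. Networks are unsigned; signed or
topological-overlap variants are out of scope.

For each τ on a grid (default 0.01…0.99, step 0.01) the adjacency is
`S ≥ τ` off-diagonal. The observed clustering coefficient is the mean over
nodes of degree ≥ 2 of `2·triangles / (deg·(deg−1))` (0 when no node
qualifies); the random baseline is the closed-form Erdős–Rényi expectation —
the edge density — rather than a rewiring simulation, so threshold selection
is deterministic and auditable from the saved `(τ, C_obs, C_rand, n_edges)`
curves. A seeded Monte-Carlo rewiring baseline could be added without
changing the interface.

**Threshold rule.** Let `D(τ) = C_obs(τ) − C_rand(τ)`. Three modes:

- `first_local_max` (default): the smallest τ with ≥ 1 edge and `D > 0`
  whose difference is not exceeded within the next `patience` (10) grid
  steps. On monotone curves this reduces to the global argmax; on flat
  curves to the smallest τ.
- `max_diff`: global argmax of `D` (smallest τ on ties).
- `first_positive`: first τ with `D > 0` sustained for `k_sustain` (3) steps.

`first_local_max` is the default because the global argmax is degenerate on
sampled data: as τ grows past the point where a module starts to crumble,
the few surviving edges form near-cliques whose *conditional* clustering
stays close to 1 while the density baseline vanishes, so `D` is maximized by
an almost-empty graph. Measured on planted two-module data (within-module
r = 0.9, 40 samples, 10 seeds), component recovery under the global argmax
reaches an adjusted Rand index of only ≈ 0.78, and `first_positive` of 0.0
(it fires before between-module noise edges are excluded), whereas the first
sustained local maximum — the plateau where exactly the module edges remain —
recovers the planted modules with ARI 1.0 on every seed. All three modes are
config-exposed; none is claimed to replicate any particular published study's
unspecified rule.

Degree tiers for reporting: `most` = degree at or above the 90th percentile
of positive degrees, `less` = at or below the 10th percentile (isolated
nodes are always `less`), `average` otherwise.

**CCPs.** A common connectivity pattern between two networks is a connected
component (≥ 2 nodes) of the graph of shared nodes and shared edges, sorted
by size then lexicographically. This label intersection is exact and
symmetric; inexact graph-alignment methods (evolutionary edit-distance
aligners) are out of scope.

## Over-representation analysis

Plain hypergeometric upper tail `P(X ≥ k)` for an overlap of `k` between a
query of `n` genes and a set of `K` genes in a universe of `N`, computed via
`scipy.stats.hypergeom.sf` (log-space internally), BH-corrected over the
tested sets. The conservative EASE-style modification used by web annotation
tools is intentionally not reproduced — those tools' backend annotation
content moves over time, while this statistic is fully specified and is
verified against exact rational-arithmetic enumeration for small universes.
Collections are read from GMT; members outside the declared universe are
dropped with a log message.

## Survival screening

Kaplan–Meier product-limit estimator with the standard tie convention
(events precede censorings at equal times). Two-group log-rank test by
explicit O/E/V tabulation over pooled event times; `χ² = (O−E)²/V` with 1
df; hazard ratio `(O_A/E_A)/(O_B/E_B)` (Mantel–Haenszel style). Zero total
variance yields a flagged degenerate result rather than an error.

Dichotomization defaults to the median split (ties to the low group), which
is unbiased. The `best_cutoff` mode scans observed expression values between
the 25th and 75th quantiles and keeps the chi-square-maximizing cutpoint,
mimicking auto-cutoff survival portals; its p-value is flagged
`cutoff_optimized` because maximizing over cutpoints makes it
anti-conservative. Cox regression and covariate adjustment are out of scope.

## Synthetic-data generator

The generator defines the study conditions the tests and acceptance script
run under. Defaults mirror the target study design: 10 LC + 5 BC + 5 LK
datasets, 20 samples per arm, 2000 genes, baseline expression
`Normal(8, 1)` on the log2 scale.

- **Winners**: gene-level case–control shifts of `effect_size` (in noise-SD
  units; at `noise_sd = 0` a unit reference SD is used so noiseless
  collections still carry effects), applied in a seeded random subset of each
  group's datasets of the configured fraction — the direction-consistency
  the vote counting keys on. Realized shifts are calibrated within ±0.1 SD
  at large n (tested).
- **Modules**: genes load on a shared per-sample latent factor,
  `x = 8 + sd·(√ρ·f + √(1−ρ)·ε)`, giving expected pairwise correlation ρ
  between module genes; realized mean |r| is within ±0.05 of ρ at 40 samples
  (tested over 10 seeds).
- **TF labels**: a seeded random fraction of genes plus explicitly marked
  winners.
- **Survival**: exponential event times with rate
  `base_rate · exp(Σ β_g z_g)` over standardized expression, independent
  exponential censoring whose rate is root-solved so the expected censored
  fraction equals the target. Default `base_rate = 1/24` per month
  (median ≈ 17 months at baseline, a realistic advanced-NSCLC scale);
  default censoring 30 %.

All randomness flows from one integer seed through `numpy.random.SeedSequence`
spawns, so identical configs are byte-reproducible.

What the generator does **not** emulate: probe-level microarray physics,
platform/batch effects, correlated (informative) censoring, non-normal noise
and heavy-tailed intensity distributions. Cohort heterogeneity is represented
only through the per-dataset consistency fractions. Passing the planted
recovery tests therefore demonstrates correctness of the algorithms under
the assumed generative model, not performance on raw public microarray data
— which would additionally require platform preprocessing that is explicitly
out of scope.

## Problem sizes and numerics

The default test and acceptance runs use: winner recovery at 20 datasets ×
300 genes × 20 samples/arm over 10 seeds; module recovery at 20 genes × 40
samples over 10 seeds; null calibration at 1000 genes / 1000 replicates; and
one design-scale end-to-end run (20 datasets × 2000 genes × 40 samples)
through the full file-based pipeline. These sizes give tight binomial error
bars (3 SE windows) while keeping a full run to a few minutes.

Floating-point numbers in all TSV outputs are serialized at 10 significant
digits, making re-runs on identical inputs byte-identical. Threshold grids
are rounded to two decimals to avoid accumulation artifacts from
`arange`. BH adjustment is exactly the step-up rule (verified against an
independent implementation); the boundary convention everywhere is inclusive.

## Known limitations

- Vote counting discards effect magnitudes; a gene barely crossing the call
  threshold in 8 datasets outranks one moving strongly in 7. This is
  inherent to the method, not an implementation choice.
- The unsigned similarity conflates positive and negative coexpression.
- The Erdős–Rényi clustering baseline ignores degree heterogeneity; a
  degree-preserving rewiring baseline would be stricter.
- `best_cutoff` survival p-values are anti-conservative by construction and
  are only suitable for screening, not inference.
- With `same_sense` support counting, a gene consistently up in LC but only
  down elsewhere is neither a common winner (no same-sense support) nor a
  unique winner (other-cancer deregulation exists); such genes land in
  `none`, which is the faithful reading of the rules rather than a gap.
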