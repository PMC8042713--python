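# Methods

This note documents the models behind `deconvbench`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want written down.

## Mixture model and noise

Mixtures are assembled as `M = S × W + ε` with `S` the per-cell-type
expected expression (genes × K), `W` the proportion matrix (K × samples,
columns summing to one) and `ε` sample-to-sample noise. Three noise models
are implemented, each controlled by a perturbation level `p_t` on a
10-element grid and interpreted as follows.

**Normal** (`M = 2^(log2(S×W+1) + N(0, σ·p_t))`) perturbs log2 expression
with Gaussian noise of scale `σ·p_t` (`σ = 10` by default), i.e.
multiplicative noise with a log-normal factor. **Log-normal**
(`M = S×W + 2^N(0, σ·p_t)`) adds a strictly positive log-normal term whose
median is 1. Both formulas include a +1 pseudocount, so the zero-noise limit
is `S×W + 1`, not `S×W`; this is implemented verbatim and matters only at
very low expression. Their grid is `{0, 0.1, …, 0.9}`.

**Negative binomial** (gamma-Poisson) simulates counts per gene from the
expected feature proportions `r` (a simplex over genes) and a library size
`L_j`:

- expected count `μ_i0 = r_i · L_j`;
- per-gene dispersion `σ_i = (1.8·p_t + 1/√μ_i0) · exp(δ/2)` with
  `δ ~ N(0, sd 0.5)` drawn **once per gene** — dispersion is treated as a
  gene property, with a `delta_per_sample` switch for the alternative;
- biological layer `μ_ij ~ Gamma(shape 1/σ_i², scale μ_i0·σ_i²)`
  (mean `μ_i0`, CV `σ_i`);
- technical layer `v_ij ~ Poisson(μ_ij)`.

Its grid is `{0.1, …, 1.0}`: the `1/√μ` floor means the dispersion never
vanishes, so there is no zero-noise member. The law of total variance gives
`Var(v) = μ + μ²σ²`, hence the log-variance/log-mean slope runs from ~1
(Poisson-dominated, low mean) toward 2 (gamma-dominated, high mean) — the
overdispersion signature of real RNA-seq counts.

Two scale conventions are ambiguous in the Gaussian notation `N(0, x)`. The
package reads the second argument of the `σ·p_t` terms as a **standard
deviation** (the convention of the limma-voom simulation lineage these
models descend from), switchable to variance via `NoiseSpec.normal_scale`.
The dispersion jitter uses `delta_sd = 0.5` (variance 0.25) by default, also
configurable.

### Mixing modes for count simulation

The nb model can be applied at two points, selected by `apply_noise(mode=)`:

- `component_level` (default): each cellular component is simulated as an
  independent count realization at the full library size from its own
  feature proportions, and the mixture is the weighted sum
  `Σ_k w_kj · v^(k)`. Because weights sum to one, the expected per-sample
  total is exactly `L_j`. This reads "feature proportion of a cellular
  component" literally and keeps each component's mean-variance structure.
  Weighted sums are real-valued; a rounding flag restores strict integer
  count semantics (on by default).
- `mixture_level`: the expected mixture `S×W` is normalized per sample and
  simulated as a single profile. Simpler, and appropriate when the mixture
  itself is the biological unit of noise.

## Scenario builders

- **sim1_simModel** — all three noise models across their gradients. Three
  independent synthetic source datasets each produce one mixture set and one
  reference; all 3 × 3 mixture-reference pairings are enumerated (9 testing
  environments per level, 6 of them cross-source), so reference-mixture
  mismatch is part of the measured variance. nb library size is fixed at
  12 M reads.
- **sim1_libSize** — nb only; each 20-sample set has samples 1–10 at 12 M
  and 11–20 at 24 M reads, emitted in count, countNorm, cpm and tpm, to
  isolate library-size bias and the mitigating effect of library-size
  normalizing units.
- **sim2** — component-number gradient K = 5…10 with a fixed roster per K
  (T/B split into CD4/CD8 and naive/memory at K = 9/10), crossed with the
  weight regimes, at the low end of the nb gradient ("close to the first
  level" = `p_t = 0.1`).
- **sim3** — each sim2 set re-mixed in count space with a tumor component
  appended to `W`, then converted to the other units; ground truths carried
  on both scales (absolute: immune fractions of the whole mixture; relative:
  renormalized over known types).

J defaults to 20 samples per mixture set throughout, matching the two-group
library design; it is configurable.

## Weight regimes and spike-ins

All generators draw from uniform distributions and rescale columns to sum
one. `orthog` scans 1000 random candidates and keeps the one with the
smallest condition number; the condition number is the 2-norm (SVD ratio)
throughout, and ties break on the first index. `real` samples inside
per-cell-type composition ranges and keeps the J columns whose raw sums are
closest to one before rescaling, resampling any column that escapes its
range after rescaling — so both the sum-to-one and the range constraints
hold exactly in the output. The built-in range table approximates adult
peripheral-blood composition (neutrophils 0.50–0.70, CD4 T 0.04–0.20, …)
with the myeloid DC and CD4 T entries absorbing unmodeled cell types; it is
an explicit, overridable default rather than a calibrated estimate.
`dominant` puts one component at U(0.9, 0.99) with the rest in a narrow tied
band; `uniform` puts all components in [1/K, 1/K + 0.04]. Empirically the
mean condition number orders orthog < uniform < dominant, which is the
designed difficulty ordering.

Tumor spike-ins sample a fraction `t` per sample from the group band (small
0.2–0.3, large 0.7–0.8, mosaic 0.05–0.95). Two arithmetic readings exist and
both are kept: `final_fraction` (default) scales the immune column by
`1 − t` so the tumor fraction of the final mixture lands exactly in the
advertised band; `append_rescale` appends `t` and divides by `1 + t`, which
lands the realized fraction at `t/(1+t)`. Renormalized immune proportions
are identical under either mode, so the relative-scale ground truth is
unaffected by the choice.

## Synthetic source profiles

`generate_source_profiles` stands in for purified immune-cell RNA-seq
datasets. Background gene means are log-normal (median ≈ 200 counts,
log-sd 1) with mild per-cell-type jitter; each cell type owns a disjoint
marker block whose low (non-owner) expression sits in the lower half of the
abundance distribution and whose owner expression is exactly `marker_fold`
times higher — mimicking lineage markers that are silenced outside their
lineage. Replicates are gamma-Poisson draws with dispersion 0.05 (CV ≈ 22%),
typical of biological replicates of purified populations. Gene lengths are
log-uniform in [0.5, 10] kb, fixed by seed; only the tpm-vs-cpm contrast
depends on them.

What this does *not* emulate: correlated gene modules, cross-dataset batch
effects beyond independent seeds, platform-specific biases, zero inflation,
and realistic cross-cell-type expression correlation. Passing tests
demonstrate that the pipeline's machinery and conventions behave as
specified under controlled conditions, not that any deconvolution method
will achieve the same accuracy on real tissue.

## Gene selection

Marker selection is rank-based per sample: percentile thresholds (high 80th,
low 50th) are computed across genes within each sample, which makes the
criterion invariant to library size and quantification unit. A gene marks
type T at sample fraction `p` if it exceeds the high threshold in ≥ `p` of
T's samples and falls below the low threshold in ≥ `p` of every other
type's samples. `p` starts at 0.95 and relaxes by `s = 0.03` until every
type has at least two markers; exhausting `p` is an error naming the failing
types. Marker sets are provably disjoint for `p > 0.5` and asserted disjoint
on every run.

Signature selection consumes any per-gene differential-expression table
(pair, gene, log2 fold change, adjusted p). The built-in test is a Welch
t-test on log2(CPM + 1) with Benjamini–Hochberg adjustment per pair — a
deliberate lightweight default; shrinkage-based DE estimators can be slotted
in through the same table schema. Thresholds default to `padj ≤ 0.01` and
`|log2FC| ≥ 10`; the fold threshold is extreme (1024-fold) and genuinely
useful only where marker structure is strong, so it is configurable. Genes
passing in *any* pair are selected (union rule), with an intersection option.

## Deconvolution baseline and evaluation

The built-in baseline normalizes mixture and reference to counts-per-million,
restricts to a gene list, solves per-sample non-negative least squares
without a sum constraint, and rescales coefficients to sum one. CPM
normalization makes count and cpm inputs of a fixed-library mixture give
identical estimates; it also means the recovered weights are proportions of
*reads* at equal library size — consistent with how the count simulator
mixes components at a common library size. A near-singular reference
(condition number > 1e12) triggers a warning, not an error.

Scoring follows the dual-metric, dual-scale convention. Pearson `r` is NA
when either vector is constant; any NA from the method or the correlation is
replaced by the worst attainable values `r = −1`, `mAD = 1`, and those
penalties flow into averages and rankings unchanged — a method that fails to
return an estimate is scored, not excluded. mAD is retained alongside `r`
because correlation is blind to systematic offset: adding a constant `c` to
all estimates leaves `r` untouched and raises mAD by exactly `c` (when
estimates do not cross the truth). The `all` aggregate is the unweighted
mean over cell types. Raw method outputs are scored on both scales without
renormalization, so a method claiming absolute output is not silently
corrected toward the relative truth.

## Diagnostics

Simulation realism is checked in count space with three views: per-gene
mean-variance moments plus a log10-log10 least-squares slope fit over genes
with mean ≥ 1; per-gene CV with a density-shape summary; and pairwise
sample Spearman correlation / Euclidean distance. Unimodality is
operationalized as the number of kernel-density peaks on a fixed 512-point
grid with prominence at least 5% of the density maximum — a pragmatic,
testable proxy for "unimodal bell-shaped", not a formal dip test.

## Reproducibility and problem sizes

Every random stream derives from a master seed through a named-stream hash
(seed + stage labels → a 31-bit substream), so adding a stage never shifts
existing streams and changing one scenario's seed leaves the others'
outputs untouched. Re-running a configuration reproduces byte-identical
TSVs; run manifests exclude wall-clock time and output location so the same
design always yields the same manifest.

Default problem sizes in the test suite and acceptance script are chosen as
the smallest that make the statistical contracts sharp: 10,000 genes ×
20 samples for library-size recovery (sampling error well under the 1%
tolerance), 5,000 genes, K = 5, 3 seeds for the end-to-end noise-gradient
checks, and 1,000–3,000 genes elsewhere. Scenario builders accept larger
sizes for production benchmarking.

## Known limitations

- The `real` composition ranges are an approximate literature default, not
  fitted to cytometry data.
- The built-in DE test does not shrink dispersion; at 2–5 replicates its
  power is limited and the extreme default fold threshold compensates only
  when marker structure is strong.
- No read-level simulation: positional/GC bias, isoform structure and
  mapping artifacts are out of scope.
- Normal/log-normal models operate on whatever unit the expected mixture is
  in and return real values; only the nb model produces integer counts.
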