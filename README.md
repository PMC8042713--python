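# deconvbench

A simulation and evaluation harness for benchmarking bulk RNA-seq cell-type
deconvolution methods.

Computational deconvolution estimates the cell-type composition of a
heterogeneous tissue sample from its bulk expression profile. Benchmarking
such methods on real tissue is hard because the true composition is rarely
known, so the field relies on *in silico* mixtures: bulk profiles assembled
from purified cell-type expression with known mixing proportions. How those
mixtures are built — the noise model, the conditioning of the proportion
matrix, library-size variation, unknown cell content — strongly shapes which
method looks best. `deconvbench` makes those design axes explicit,
controllable and reproducible, for method developers who want honest stress
tests and for analysts choosing a method for a particular tissue setting.

## Model

Simulated mixtures follow

```
M = S × W + ε
```

where `S` (genes × cell types) holds the component source profiles, `W`
(cell types × samples) the mixing proportions with columns summing to one,
and `ε` is sample-to-sample noise. Three noise models span a 10-step
perturbation gradient `p_t`:

- **normal** — `M = 2^(log2(S×W + 1) + N(0, σ·p_t))`, multiplicative in log
  space; grid `p_t ∈ {0, 0.1, …, 0.9}`, `σ = 10`;
- **log-normal** — `M = S×W + 2^N(0, σ·p_t)`, additive positive noise;
  same grid;
- **negative binomial** (gamma-Poisson) — per gene `i` and sample `j`, with
  feature proportions `r` and library size `L_j`:
  `μ_i0 = r_i·L_j`;
  `σ_i = (1.8·p_t + 1/√μ_i0)·exp(δ/2)`, `δ ~ N(0, sd 0.5)`;
  `μ_ij ~ Gamma(shape 1/σ_i², scale μ_i0·σ_i²)`; `v_ij ~ Poisson(μ_ij)`;
  grid `p_t ∈ {0.1, …, 1.0}`. The gamma layer models biological variance,
  the Poisson layer technical counting noise.

Weight matrices come in four regimes — `orthog` (condition-number-minimized
over 1000 random candidates), `real` (whole-blood composition ranges),
`dominant` (one component at 0.9–0.99) and `uniform` (all near `1/K`) — and
an unknown tumor component can be spiked in at small (20–30%), large
(70–80%) or mosaic (5–95%) fractions. Estimates are scored per cell type
with Pearson `r` and mean absolute deviance `mAD = Σ|x_j − y_j|/J`, with NA
or undefined outcomes penalized at the worst attainable values (`r = −1`,
`mAD = 1`), on both absolute (fractions of the whole mixture) and relative
(renormalized over known cell types) scales.

## Worked example

Simulate a three-cell-type mixture set at a mid-gradient noise level,
deconvolve it with the built-in non-negative least squares baseline, and
score the estimates:

```python
import deconvbench as db

src = db.generate_source_profiles(
    n_genes=2000, cell_types=["T", "B", "monocytes"],
    marker_frac=0.02, marker_fold=50, n_replicates=5, seed=1,
)
w = db.make_orthog(3, 20, cell_types=["T", "B", "monocytes"], seed=2)
spec = db.NoiseSpec(model="nb", p_t=0.3, library_size=12_000_000, seed=3)
mixture = db.apply_noise(db.mix_expected(src, w), spec,
                         mode="component_level", w=w, src=src)
reference = db.build_reference(src, ["T", "B", "monocytes"])
estimate = db.nnls_deconvolve(mixture, reference)
print(db.evaluate_celltype(estimate, w, scale="relative").round(3).to_string(index=False))
```

```
      method    scale cell_type     r   mad
builtin_nnls relative         T 0.981 0.032
builtin_nnls relative         B 0.989 0.031
builtin_nnls relative monocytes 0.986 0.030
builtin_nnls relative       all 0.986 0.031
```

Each row reports, for one cell type across the 20 samples, how well the
estimated proportions track the known mixing weights: `r` close to 1 means
the linear trend is recovered, `mad ≈ 0.03` means estimates deviate from the
truth by about three percentage points on average. The `all` row is the
unweighted mean over cell types. At `p_t = 0.3` the baseline still performs
well; pushing `p_t` toward 1.0 degrades both metrics, which is exactly the
degradation the gradient is designed to expose.

The same pipeline is scriptable from the shell:

```bash
deconvbench simulate --scenario sim2 --seed 7 --out runs/sim2
deconvbench run --config run.yaml --seed 7 --out runs/full
deconvbench diagnose --input runs/sim2/mixtures/pair_0000.tsv --out report/
```

External deconvolution methods are scored by exporting their cell-type ×
sample proportion tables as TSV and reading them with
`deconvbench.read_estimates` (NA cells allowed; they attract the worst-case
penalty).

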