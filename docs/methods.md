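# Methods

## Model

The package operates on an expression matrix **B** ∈ ℝ<sup>n×m</sup>
(rows = samples, columns = genes).  Orientation is handled at the I/O
boundary: files with genes in rows (the common public convention, and the
loader default) are transposed on load.

**Preprocessing.**  Each *row* (sample) of **B** is standardized to mean
0 and SD 1, removing between-sample scale effects so that no single
sample dominates the learned filters.  The SD uses the sample convention
(denominator n−1), set by the single constant `preprocess.STD_DDOF`.
Rows with SD below 1e-12 are mapped to all-zeros with a `RuntimeWarning`
rather than raising: constant genes-by-sample rows carry no differential
signal, and failing a whole run for one flat row would be unhelpful.

**One sparse-filtering layer.**  A layer with input **X** ∈
ℝ<sup>d×m</sup> learns **Y** ∈ ℝ<sup>d×t</sup> and forms
**S** = √((**Y**ᵀ**X**)² + ε), ε = 10⁻⁸.  The soft-absolute activation is
a smooth |·| surrogate; its floor √ε = 10⁻⁴ bounds every activity away
from zero, which also guarantees the row/column norms below can never
vanish.  **S** is L2-normalized by rows (high dispersal: every learned
sample contributes the same total energy) and then by columns (each gene
on the unit L2-ball); the objective is the grand sum of the result —
valid as the sum of column L1 norms because all entries are positive,
and deliberately written without |·| so the gradient has no kink.  For a
t-column filter the objective is bounded: m ≤ J ≤ m√t, with J ≡ m exactly
at t = 1 (each normalized column is the scalar 1 — a useful degenerate
check, and the reason the t = 1 gradient is identically zero).

**Gradient.**  dJ/d**Y** is obtained by back-propagating the all-ones
cotangent through the column normalization (for a column v with norm c,
d(g·(v/c))/dv = g/c − (g·v)v/c³), the row normalization (symmetric
formula), and the activation (dS/dZ = Z/S, which carries the ε term), then
mapping into filter space as **X**Gᵀ.  The test suite checks it against
central finite differences (step 1e-6) on random instances; the
discrepancy is measured relative to the gradient's largest component,
since a per-component relative error divides the difference quotient's
~1e-9 cancellation noise by near-zero true components and reports noise
rather than gradient quality.

**Optimization.**  Each layer is fitted with L-BFGS
(`scipy.optimize.minimize`, method `L-BFGS-B` unconstrained) from an
i.i.d. standard-normal initialization of **Y** drawn from a seeded
generator.  Defaults: `max_iter = 200`, gradient tolerance `gtol = 1e-5`,
history size 10.  These are conventional settings for sparse filtering;
the method is intentionally hyperparameter-light and results are not
sensitive to the history size.  The objective value at initialization and
at every accepted iterate is recorded (`LayerFit.objective_trace`); a
non-finite objective aborts with the function-call count in the message.

**Deep stacking.**  Layers are trained greedily: layer i's optimal **S**
is L2-normalized by rows then by columns and becomes layer i+1's input;
there is no joint fine-tuning.  Layer i draws its initialization from
`seed + i`, so deepening a model never changes the layers already
trained.  All layers default to the same t; per-layer sizes may be given
explicitly.  The soft-absolute function is not re-applied between layers:
the optimal distribution is already strictly positive, so it would be a
near-identity map.

**Gene scoring.**  The evaluating vector is the column-sum vector of the
final layer's (unnormalized) optimal distribution; absolute values are
taken even though entries are provably positive so the function is safe
on arbitrary matrices.  Genes are ranked by score descending; ties break
toward the lower input gene index via a stable sort, making the ranking
deterministic.  `select_top_genes` returns the top h (default 100) as a
rank/gene_id/score table, serialized as TSV with 6-significant-digit
scores.

## Reproducibility design

Two properties are enforced bitwise, not just to tolerance:

- **Determinism**: a run is a pure function of (data, configuration,
  seed).  All randomness flows from explicit seed arguments through
  `numpy.random.default_rng`; no global state is touched.
- **Gene-order invariance**: permuting the input's gene columns permutes
  every output identically.  In real arithmetic this is automatic, but
  floating-point reductions depend on operand order, and ulp-level
  differences amplify chaotically over hundreds of quasi-Newton
  iterations (observed: ~6% score differences from a column permutation).
  Therefore each layer optimizes in a canonical gene order (a lexsort of
  the input columns) and restores the caller's order afterwards, and the
  row-wise reductions in standardization and inter-layer normalization
  sum value-sorted, contiguous operands.  With identical multisets of
  inputs these reductions see identical operand sequences, so equivariance
  holds exactly.

## Synthetic data

`SyntheticSpec`/`generate` emulate the regime the method targets: a
mostly homogeneous background in which a small gene subset carries a
class-structured signal.  Entries are i.i.d. Normal(0, `noise_sd`²);
`n_de` planted genes receive a mean shift of `effect_size · noise_sd` in
class-1 samples only.  Defaults — 40 samples, 500 genes, 25 planted genes,
equal classes, 3 SD shift, unit noise — give a desk-scale problem where a
mean shift of that size is decisively detectable by eye in a volcano plot,
i.e. a "strong but not trivial" differential signal.  `recovery_metrics`
scores a ranking's top h against the planted set (precision and recall).

What the generator does **not** emulate: count-based RNA-Seq marginals
(negative-binomial overdispersion, library-size variation), correlated
gene modules beyond the planted set, batch effects, or class-specific
variance changes.  Row standardization removes scale and location per
sample, so Gaussian additive structure is the relevant abstraction for
the pipeline; passing recovery tests therefore demonstrates the ranking
mechanics, not robustness to real-data artefacts.

## Behaviour of deep rankings — a known limitation

Single-layer rankings recover planted genes essentially perfectly at a
3 SD effect (median top-25 precision 1.0 over 10 seeds) and fall to
chance at the null, with recovery monotone in effect size.  Rankings
taken from the **second or deeper layers do not inherit this**: the
inter-layer column normalization places every gene on the unit L2-ball,
erasing the column-magnitude signal that the evaluating vector reads,
and the next layer's sparsity objective then concentrates the planted
(mutually correlated) gene columns onto few filters — giving them the
*smallest* column sums.  On the synthetic benchmark the two-layer stack
ranks planted genes near the bottom (median top-25 precision 0.0).  The
acceptance report exposes both numbers (`deep_recovery_*` and
`single_layer_recovery_*`) rather than hiding the gap.  Users who want
the scores to track per-gene effect magnitude should rank from a
single layer (`-k 1`); the deep stack is retained because it is the
method's stated design and its representations may still be useful where
gene modules, not magnitudes, matter.

## Numerical choices

- ε = 10⁻⁸ inside the soft absolute (activity floor 10⁻⁴).
- L2 norms below 1e-12 are replaced by 1e-8 before division, in the
  objective and matching gradient alike.  The activation floor makes this
  unreachable in normal operation; it only guards hand-fed degenerate
  matrices.
- Zero-variance rows in standardization: SD replaced by 1 (yields a zero
  row) plus a warning.
- Ranking ties: stable sort, lower gene index wins.
- Scores on disk: 6 significant digits; expression matrices on disk: 17
  significant digits (exact float64 round trip, with
  `float_precision="round_trip"` on load).

## Problem sizes

Tests and the acceptance script run at desk scale: 40 × 500 synthetic
matrices, t = 20 learned samples, one or two layers, 10 seeds per
recovery estimate — small enough to iterate on a laptop while large
enough that chance-level precision (0.05) and perfect recovery (1.0) are
separated by two orders of magnitude.  The defaults (k = 3, t = 200,
h = 100) target real cohort-scale matrices and complete in minutes on a
single CPU for microarray-sized inputs.
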