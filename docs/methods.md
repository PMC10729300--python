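# Methods

## Problem setting

A directed-evolution screen produces a table of variants of one parent
enzyme — each an equal-length sequence carrying a handful of point
substitutions — together with noisy measurements of two properties: a
carboxylation rate to be maximized and an ATP-per-carboxylation ratio to
be minimized. The task is to learn from that table and rank every possible
single substitution of the parent (19·L candidates, minus excluded
positions such as an affinity-tag region) so that only the most promising
few are synthesized and characterized.

## Sequence kernel

Two sequences of equal length L are compared through a substitution
matrix: the raw kernel is the position-summed BLOSUM62 score
k_raw(x, y) = Σ_i B62(x_i, y_i). By default this is cosine-normalized,
k = k_raw(x, y)/√(k_raw(x,x)·k_raw(y,y)), which makes self-similarity
exactly 1 and removes the dependence of the score scale on sequence
length and composition; the raw form is retained behind
`KernelSpec(normalize=False)`. A Hamming kernel (fraction of identical
positions) is provided as the classical alternative; it is an average of
per-position identity kernels and therefore positive semidefinite.
Alignment-based kernels are deliberately absent: variant libraries are
equal-length by construction, so no alignment is ever needed.

BLOSUM62 is a log-odds table, not a Mercer kernel. Two consequences are
worth knowing:

* On a *mutant library* (all sequences within a few substitutions of one
  parent) the normalized Gram matrix is a small perturbation of the
  all-ones matrix; measured minimum eigenvalues on simulated libraries up
  to n = 200 stay above −0.5, so the GP's fixed ridge of 1.0 always
  leaves K + λI positive definite. This is the package's working regime.
* On a set of *unrelated* random sequences the expected off-diagonal
  value is negative (≈ −0.2 after normalization), which produces a
  negative eigenvalue growing like −0.2·n; K + 1.0·I can then fail to
  factor. `psd_repair(..., mode="clip")` (eigenvalue clipping) is
  provided for such inputs, but divergent sequence sets are outside the
  intended use.

## Gaussian-process regression

Exact GP regression on the precomputed Gram matrix, with additive ridge
λ = 1.0 — equivalently, unit observation-noise variance on standardized
targets. Each target is standardized to zero mean and unit (population)
variance on the training data, and one dual-weight vector
α = (K + λI)⁻¹z is solved per target through a single shared Cholesky
factorization: a multitask model with a shared kernel and independent
heads. Predictions use the standard conditionals μ = k*ᵀα and
σ² = k(x*,x*) − k*ᵀ(K+λI)⁻¹k*; variances that go slightly negative from
floating-point cancellation are clamped to zero (logged at debug level).
No hyperparameters are optimized anywhere — λ and the kernel are fixed by
design, which keeps the whole fit a deterministic linear solve.

## Multi-objective combination and acquisition

Raw targets are made commensurable by z-scoring on the training split;
minimized targets are negated after z-scoring so that larger is always
better; the per-variant sum of adjusted z-scores is the combined
performance metric. The combined metric is treated as a third regression
target with its own GP head (default), rather than by summing the two
heads' outputs — an alternative `sum_ucb` ranking mode implements the
latter for comparison. Candidates are ranked by UCB = μ + β·σ of the
combined head with β = 0.5; β = 0 is pure exploitation, β values outside
[0, 1] warn but proceed. Ties break by candidate enumeration order
(position-major, then alphabetical mutant residue), making ranked lists
fully deterministic. Top-fraction selection takes ⌈f·N⌉ rows so a
nonempty set is always returned, and a per-position substitution-site
tally over the selection highlights mutational hotspots.

## Evaluation protocol

k-fold cross-validation (default k = 10) with seeded shuffling and
near-equal contiguous folds. All statistics that could leak — target
means/sds for standardization and for the combined measured metric — are
re-estimated from each training split and applied to its validation
split. The GP is scored by the UCB of the combined head (the quantity
actually used for ranking); the random-forest baseline by its point
prediction. Agreement with held-out combined measurements is summarized
by Spearman ρ (mid-ranks) and Kendall τ-b (tie-adjusted), averaged over
folds; a pooled mode that concatenates held-out scores before correlating
exists for sensitivity analysis. Constant vectors make rank correlation
undefined and are reported as NaN, excluded from fold averages.

The baseline embeds sequences as 20·L one-hot vectors and fits
scikit-learn's `RandomForestRegressor` with default settings and a fixed
seed; externally computed embedding tables (e.g. a 1900-dimensional
averaged-hidden-state protein-language-model representation) can be
loaded from TSV and run through the identical CV path. Note that on the
purely additive synthetic landscapes below, a one-hot random forest is a
*strong* baseline — its features match the generative model exactly — so
GP-vs-RF gaps measured on synthetic data understate what a weaker,
generic embedding would show on real screens.

## Synthetic landscape generator

The generator emulates an error-prone-PCR screen. Defaults, chosen once as
the study conditions:

| parameter | default | meaning |
|---|---|---|
| parent_length | 50 | residues in the simulated parent |
| effect_sd | 1.0 | sd of per-(position, residue) additive effects (assay units) |
| task_correlation | −0.3 | rate-effect vs cost-effect correlation (trade-off) |
| noise_sd | 0.3 | sd of per-measurement Gaussian noise |
| library_size | 200 | screened variants |
| mutations_per_variant | 1.5 | Poisson mean before truncation to [1, 5] |
| epistasis_sd | 0.0 | optional pairwise-interaction sd (off by default) |

Each (position, mutant-residue) pair receives a bivariate-normal effect on
the two objectives; a variant's true values are the parent baseline plus
the sum of its mutations' effects; measurements add independent noise.
Everything is reproducible from one seed. Epistasis defaults off so the
additive ground truth remains an interpretable oracle; a pairwise
interaction term can be switched on to stress-test model robustness.

What the generator does *not* emulate: nucleotide-level mutation spectra
(transition bias, codon structure), plate or batch drift, heavy-tailed or
mostly-deleterious effect distributions, and effect correlations between
chemically similar residues. The last point matters for interpreting
recovery experiments: because true effects are drawn independently per
(position, residue) pair, a substitution never sampled by the library is
*informationally unrecoverable* — no regressor can rank it better than
chance. With a 200-variant library over a 50-residue parent only about a
third of the 950 possible single substitutions are ever observed, and an
oracle that knows the exact truth for every observed pair (and predicts
zero elsewhere) caps at Spearman ρ ≈ 0.53 over all singles. Measured
whole-library recovery correlations (~0.1–0.2 overall, ~0.3–0.5 on the
observed subset) must be read against that ceiling, and passing recovery
tests demonstrate correct mechanics and real enrichment, not a claim
about unobserved sequence space. The actionable statistic is enrichment:
the UCB top 1% beats an equally sized random selection in ≈ 99/100
simulated screens.

## Kinetics computations

Michaelis–Menten curves are fitted by `scipy.optimize.curve_fit` with a
deterministic initialization (Vmax₀ = max v, Km₀ = median S) and
nonnegativity bounds; a Km collapsing to the zero boundary flags fully
saturated data rather than returning a meaningless estimate. Turnover
numbers follow kcat = Vmax·10⁻⁶·M/60 for Vmax in nmol·min⁻¹·mg⁻¹ and
protomer molar mass M in g·mol⁻¹; the default M = 1.30×10⁵ is the value
consistent with the published (Vmax, kcat) pairs of both the parent
carboxylase and its improved variant. Catalytic efficiency is
kcat/(Km·10⁻³) in s⁻¹M⁻¹. The ATP-per-carboxylation ratio of the
ATP-limited coupled assay is (ATP supplied)/(NADPH consumed), with a
Beer–Lambert helper (ε₃₄₀ = 6220 M⁻¹cm⁻¹) converting absorbance changes
to NADPH amounts. Reporting helpers provide fold-change, percent
reduction and significant-figure rounding; note that quotients of
*printed* (already rounded) table values can differ from published
derived cells by a few percent — e.g. a Km printed to two decimals moves
kcat/Km by ~3%.

## Numerical and design notes

* Population (ddof = 0) standard deviations are used for all
  standardization, consistently between the GP targets and the combined
  measured metric.
* Fold assignment: seeded permutation then `np.array_split`; sizes differ
  by at most one; identical seeds give identical folds for every model
  family, so model comparisons are paired.
* Stable sorts everywhere a ranking is produced; all tie-breaks are
  documented enumeration order.
* `fit` refuses constant targets (sd = 0) and n < 2; correlation
  functions refuse n < 2 and return NaN for constant vectors.
* Problem sizes in tests and the acceptance script (libraries of 30–200
  variants, parents of 8–50 residues, 50–100 simulation seeds) were
  chosen to exercise every code path at full statistical fidelity while
  keeping a complete run fast on a laptop.

## Known limitations

* The GP assumes a mostly additive sequence-function relationship; under
  strong epistasis both the kernel and the additive ground truth of the
  generator become misspecified.
* λ = 1.0 on the cosine-normalized kernel is a strong shrinkage prior:
  posterior means are heavily pulled toward zero, which is harmless for
  ranking but makes de-standardized point predictions conservative.
* The random-forest baseline's default one-hot embedding is a stand-in
  with different inductive biases than a pretrained language-model
  embedding; conclusions about the GP-vs-baseline gap on synthetic data
  do not transfer directly to real screens.
* Rank-correlation CV on small folds (≈16 variants) is itself noisy; ±0.1
  fold-to-fold spread in ρ is expected and is why per-fold values are
  reported alongside means.
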