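"""Model assessment: k-fold cross-validation scored by rank correlation.

The screening data are used to decide which variants to synthesize next, so
the quantity of interest is not squared error but how well the acquisition
score orders held-out variants. Each fold fits the model on the training
split (all standardization statistics re-estimated from that split only, to
avoid leakage), scores the held-out variants — UCB of the combined-metric GP
head for the GP family, the point prediction for the random-forest baseline
— and reports Spearman rho and Kendall tau-b against the held-out combined
measurements. Per-fold correlations are averaged; a pooled-prediction
alternative is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import COMBINED, ObjectiveSpec, ucb
from .baseline import onehot_embed, rf_fit_predict
from .gp import SequenceGP
from .kernels import KernelSpec
from .sequence_space import VariantDataset


class EvaluationError(ValueError):
    """Raised for invalid CV configurations."""


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle then contiguous chunking into k near-equal folds.

    Fold sizes are floor(n/k) or ceil(n/k); identical seeds give identical
    folds. Returns validation-index arrays that partition range(n).
    """
    if not 2 <= k <= n:
        raise EvaluationError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho: Pearson correlation of mid-ranks (ties averaged).

    Returns NaN when either vector is constant (correlation undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise EvaluationError("spearman needs two equal-length vectors, n >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.spearmanr(a, b).statistic)


def kendall(a: np.ndarray, b: np.ndarray) -> float:
    """Kendall tau-b (tie-adjusted); NaN for constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise EvaluationError("kendall needs two equal-length vectors, n >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.kendalltau(a, b, variant="b").statistic)


@dataclass(frozen=True)
class FoldResult:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    rho: float
    tau: float


@dataclass
class CVReport:
    """Per-fold and averaged rank correlations for one CV run."""

    folds: list[FoldResult]
    mean_rho: float
    mean_tau: float
    seed: int
    model_family: str
    scored_quantity: str
    k: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "fold": i + 1,
                "n_train": len(f.train_ids),
                "n_val": len(f.val_ids),
                "rho": f.rho,
                "tau": f.tau,
            }
            for i, f in enumerate(self.folds)
        ]
        rows.append(
            {
                "fold": "mean",
                "n_train": "",
                "n_val": "",
                "rho": self.mean_rho,
                "tau": self.mean_tau,
            }
        )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _combined_measured(
    train: VariantDataset, val: VariantDataset, objective: ObjectiveSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Direction-adjusted z-sum for train and validation, using train stats."""
    z_train = np.zeros(len(train))
    z_val = np.zeros(len(val))
    for name, direction in objective.targets:
        y_tr = train.targets[name]
        mean, sd = float(np.mean(y_tr)), float(np.std(y_tr))
        if sd == 0:
            raise EvaluationError(f"constant target {name!r} in training fold")
        sign = -1.0 if direction == "minimize" else 1.0
        z_train += sign * (y_tr - mean) / sd
        z_val += sign * (val.targets[name] - mean) / sd
    return z_train, z_val


def cross_validate(
    dataset: VariantDataset,
    objective: ObjectiveSpec,
    model_family: str = "gp",
    k: int = 10,
    seed: int = 0,
    kernel: KernelSpec | None = None,
    lam: float = 1.0,
    scored_quantity: str | None = None,
    pooled: bool = False,
) -> CVReport:
    """k-fold CV of the GP or the RF baseline on a variant dataset.

    The GP is scored by the UCB of its combined-metric head by default
    (``scored_quantity="ucb"``); the RF baseline by its point prediction of
    the combined metric (``"mean"``). ``pooled=True`` concatenates all
    held-out scores before correlating instead of averaging per-fold values.
    """
    if model_family not in ("gp", "rf"):
        raise EvaluationError(f"unknown model family {model_family!r}")
    if scored_quantity is None:
        scored_quantity = "ucb" if model_family == "gp" else "mean"
    if scored_quantity not in ("ucb", "mean"):
        raise EvaluationError(f"unknown scored quantity {scored_quantity!r}")

    folds = kfold_split(len(dataset), k, seed)
    all_idx = np.arange(len(dataset))
    results: list[FoldResult] = []
    pooled_scores: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []

    for val_idx in folds:
        if len(val_idx) < 2:
            raise EvaluationError("fold too small to correlate (< 2 points)")
        train_idx = np.setdiff1d(all_idx, val_idx)
        train = dataset.subset(train_idx)
        val = dataset.subset(val_idx)
        z_train, z_val = _combined_measured(train, val, objective)

        if model_family == "gp":
            targets = {name: train.targets[name] for name in objective.target_names}
            targets[COMBINED] = z_train
            gp = SequenceGP(kernel=kernel, lam=lam).fit(train, targets)
            mu, sd = gp.predict(val.variants)[COMBINED]
            score = ucb(mu, sd, objective.beta) if scored_quantity == "ucb" else mu
        else:
            emb_train = onehot_embed(train.sequences)
            emb_val = onehot_embed(val.sequences)
            preds = rf_fit_predict(
                emb_train, {COMBINED: z_train}, emb_val, seed=seed
            )
            score = preds[COMBINED]

        results.append(
            FoldResult(
                train_ids=tuple(train.ids),
                val_ids=tuple(val.ids),
                rho=spearman(score, z_val),
                tau=kendall(score, z_val),
            )
        )
        pooled_scores.append(np.asarray(score))
        pooled_truth.append(z_val)

    if pooled:
        s = np.concatenate(pooled_scores)
        t = np.concatenate(pooled_truth)
        mean_rho, mean_tau = spearman(s, t), kendall(s, t)
    else:
        mean_rho = float(np.nanmean([f.rho for f in results]))
        mean_tau = float(np.nanmean([f.tau for f in results]))

    return CVReport(
        folds=results,
        mean_rho=mean_rho,
        mean_tau=mean_tau,
        seed=seed,
        model_family=model_family,
        scored_quantity=scored_quantity,
        k=k,
    )
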