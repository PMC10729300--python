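"""Exact Gaussian-process regression on a precomputed sequence Gram matrix.

The model is kernel ridge / GP regression with a fixed additive ridge
``lam`` on the Gram matrix (equivalently, observation-noise variance
``lam`` on standardized targets; default 1.0). Each named target is
standardized to zero mean, unit variance on the training data, and an
independent dual-weight vector ``alpha = (K + lam·I)^{-1} z`` is solved per
target through one shared Cholesky factorization — a multitask model with a
shared kernel and separate heads. No hyperparameters are optimized.

Predictive equations for a candidate x*:

    mu(x*)     = k*^T alpha                       (standardized scale)
    sigma^2(x*) = k(x*, x*) - k*^T (K + lam·I)^{-1} k*

with the variance clamped at zero before the square root.
"""

from __future__ import annotations

import json
import logging
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .kernels import GramMatrix, KernelSpec, cross_gram, gram, self_kernel
from .sequence_space import Variant, VariantDataset

logger = logging.getLogger(__name__)


class GPError(ValueError):
    """Raised for degenerate training data or failed factorizations."""


@dataclass(frozen=True)
class TargetStats:
    """Training mean and standard deviation used to standardize one target."""

    mean: float
    sd: float


@dataclass(frozen=True)
class Prediction:
    """Posterior mean and standard deviation for one target at one point."""

    mean: float
    std: float
    target: str


@dataclass
class GPModel:
    """Fitted GP posterior: dual weights and a cached Cholesky factor."""

    gram: GramMatrix
    regularization: float
    dual_weights: dict[str, np.ndarray]
    target_stats: dict[str, TargetStats]
    _cho: tuple[np.ndarray, bool]

    @property
    def n(self) -> int:
        return self.gram.n

    @property
    def target_names(self) -> list[str]:
        return list(self.dual_weights)


def standardize(y: np.ndarray) -> tuple[np.ndarray, TargetStats]:
    """Zero-mean unit-variance transform (population sd, ddof=0)."""
    y = np.asarray(y, dtype=float)
    mean = float(np.mean(y))
    sd = float(np.std(y))
    if sd == 0.0 or not np.isfinite(sd):
        raise GPError("constant target: cannot standardize (sd = 0)")
    return (y - mean) / sd, TargetStats(mean=mean, sd=sd)


def fit_gram(
    K: GramMatrix, targets: dict[str, np.ndarray], lam: float = 1.0
) -> GPModel:
    """Fit dual weights for each target on an existing Gram matrix."""
    if lam < 0:
        raise GPError(f"regularization must be nonnegative, got {lam}")
    n = K.n
    if n < 2:
        raise GPError("need at least 2 training points")
    A = K.values + lam * np.eye(n)
    try:
        cho = cho_factor(A, lower=True)
    except np.linalg.LinAlgError as exc:
        raise GPError(
            "Cholesky factorization failed: Gram matrix not positive definite "
            f"with lam={lam}; increase the ridge or use psd_repair"
        ) from exc
    dual: dict[str, np.ndarray] = {}
    stats: dict[str, TargetStats] = {}
    for name, y in targets.items():
        y = np.asarray(y, dtype=float)
        if y.shape != (n,):
            raise GPError(f"target {name!r} has shape {y.shape}, expected ({n},)")
        z, st = standardize(y)
        dual[name] = cho_solve(cho, z)
        stats[name] = st
    return GPModel(
        gram=K, regularization=lam, dual_weights=dual, target_stats=stats, _cho=cho
    )


def predict_gram(
    model: GPModel, K_star: np.ndarray, k_star_diag: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Posterior means and standard deviations from cross-kernel blocks.

    ``K_star`` is (m, n) candidate-by-training; ``k_star_diag`` holds the
    prior variances k(x*, x*). Returns per-target ``(mu, sigma)`` on the
    standardized scale.
    """
    K_star = np.atleast_2d(np.asarray(K_star, dtype=float))
    if K_star.shape[1] != model.n:
        raise GPError(f"cross-kernel has {K_star.shape[1]} columns, expected {model.n}")
    v = cho_solve(model._cho, K_star.T)  # (n, m)
    var = np.asarray(k_star_diag, dtype=float) - np.einsum("mn,nm->m", K_star, v)
    n_neg = int(np.sum(var < 0))
    if n_neg:
        logger.debug("clamping %d negative predictive variances to 0", n_neg)
    sigma = np.sqrt(np.clip(var, 0.0, None))
    return {name: (K_star @ alpha, sigma) for name, alpha in model.dual_weights.items()}


def destandardize_mean(model: GPModel, target: str, mu: np.ndarray) -> np.ndarray:
    """Map standardized posterior means back to the raw measurement scale."""
    st = model.target_stats[target]
    return mu * st.sd + st.mean


class SequenceGP:
    """Convenience wrapper: fit/predict directly on variants or sequences.

    Stores the training sequences and kernel spec so candidates only need to
    be supplied as equal-length sequences (or :class:`Variant` objects).
    """

    def __init__(self, kernel: KernelSpec | None = None, lam: float = 1.0):
        self.kernel = kernel if kernel is not None else KernelSpec()
        self.lam = lam
        self.model: GPModel | None = None
        self._train_sequences: list[str] = []

    def fit(
        self,
        dataset: VariantDataset,
        targets: dict[str, np.ndarray] | None = None,
    ) -> "SequenceGP":
        """Fit on a dataset; ``targets`` defaults to the dataset's own."""
        self._train_sequences = dataset.sequences
        K = gram(self._train_sequences, self.kernel, ids=list(dataset.ids))
        self.model = fit_gram(K, targets if targets is not None else dataset.targets, self.lam)
        return self

    def predict(
        self, candidates: list[Variant] | list[str]
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-target (mu, sigma) on the standardized scale."""
        if self.model is None:
            raise GPError("model not fitted")
        seqs = [c.sequence if isinstance(c, Variant) else c for c in candidates]
        K_star = cross_gram(seqs, self._train_sequences, self.kernel)
        kdiag = self_kernel(seqs, self.kernel)
        return predict_gram(self.model, K_star, kdiag)


# ---------------------------------------------------------------------------
# Serialization (single-archive model dump for the CLI)
# ---------------------------------------------------------------------------

def save_model(gp: SequenceGP, path: str | Path) -> None:
    if gp.model is None:
        raise GPError("cannot save an unfitted model")
    meta = {
        "kernel_family": gp.kernel.family,
        "normalize": gp.kernel.normalize,
        "lam": gp.lam,
        "sequences": gp._train_sequences,
        "sequence_ids": list(gp.model.gram.sequence_ids),
        "target_stats": {
            k: {"mean": s.mean, "sd": s.sd} for k, s in gp.model.target_stats.items()
        },
    }
    with zipfile.ZipFile(str(path), "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for name, alpha in gp.model.dual_weights.items():
            zf.writestr(f"alpha_{name}.json", json.dumps(alpha.tolist()))
        zf.writestr(
            "substitution_matrix.json",
            json.dumps(gp.kernel.substitution_matrix.tolist()),
        )


def load_model(path: str | Path) -> SequenceGP:
    with zipfile.ZipFile(str(path)) as zf:
        meta = json.loads(zf.read("meta.json"))
        B = np.array(json.loads(zf.read("substitution_matrix.json")))
        spec = KernelSpec(
            family=meta["kernel_family"],
            substitution_matrix=B,
            normalize=meta["normalize"],
        )
        gp = SequenceGP(kernel=spec, lam=meta["lam"])
        gp._train_sequences = meta["sequences"]
        K = gram(gp._train_sequences, spec, ids=meta["sequence_ids"])
        targets = {}
        for name in meta["target_stats"]:
            alpha = np.array(json.loads(zf.read(f"alpha_{name}.json")))
            targets[name] = alpha
        # rebuild factorization; dual weights restored verbatim
        A = K.values + gp.lam * np.eye(K.n)
        cho = cho_factor(A, lower=True)
        gp.model = GPModel(
            gram=K,
            regularization=gp.lam,
            dual_weights=targets,
            target_stats={
                k: TargetStats(**v) for k, v in meta["target_stats"].items()
            },
            _cho=cho,
        )
    return gp
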