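"""Multi-objective combination and upper-confidence-bound candidate ranking.

Two measured objectives — a carboxylation rate to maximize and an
ATP-per-carboxylation ratio to minimize — are made commensurable by
z-scoring each on the training data and summing, with minimized targets
negated so that larger combined values always mean better enzymes. A third
GP head is fitted directly to this combined metric, and candidates are
ranked by its upper confidence bound

    UCB_j = mu_j + beta * sigma_j,    beta in [0, 1], default 0.5,

which trades off predicted performance (exploitation) against model
uncertainty (exploration). ``beta = 0`` ranks purely by the posterior mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gp import SequenceGP
from .kernels import KernelSpec
from .sequence_space import Variant, VariantDataset

COMBINED = "combined"


class ObjectiveError(ValueError):
    """Raised for inconsistent objective specifications."""


@dataclass(frozen=True)
class ObjectiveSpec:
    """Named targets with optimization directions and the UCB weight.

    targets: ordered (name, direction) pairs, direction in
        {"maximize", "minimize"}.
    beta: exploration weight of the UCB; values outside [0, 1] trigger a
        warning but are allowed as an explicit deviation hook.
    combination: only "zsum" (z-score then sum) is defined.
    """

    targets: tuple[tuple[str, str], ...] = (
        ("rate", "maximize"),
        ("atp_ratio", "minimize"),
    )
    beta: float = 0.5
    combination: str = "zsum"

    def __post_init__(self) -> None:
        if not self.targets:
            raise ObjectiveError("at least one target required")
        for name, direction in self.targets:
            if direction not in ("maximize", "minimize"):
                raise ObjectiveError(f"bad direction {direction!r} for target {name!r}")
        if self.combination != "zsum":
            raise ObjectiveError(f"unknown combination {self.combination!r}")
        if not 0.0 <= self.beta <= 1.0:
            warnings.warn(
                f"beta={self.beta} outside [0, 1]; proceeding anyway", stacklevel=2
            )

    @property
    def target_names(self) -> list[str]:
        return [name for name, _ in self.targets]


def combine_targets(dataset: VariantDataset, spec: ObjectiveSpec) -> np.ndarray:
    """Per-variant combined metric: sum of direction-adjusted z-scores.

    Each target is z-scored with its own population mean/sd on this dataset;
    minimized targets are negated after z-scoring. The result has mean 0 and
    is invariant under positive affine rescaling of any raw target.
    """
    out = np.zeros(len(dataset))
    for name, direction in spec.targets:
        if name not in dataset.targets:
            raise ObjectiveError(f"target {name!r} missing from dataset")
        y = dataset.targets[name]
        sd = float(np.std(y))
        if sd == 0.0:
            raise ObjectiveError(f"constant target {name!r}: z-score undefined")
        z = (y - float(np.mean(y))) / sd
        out += -z if direction == "minimize" else z
    return out


def ucb(mean: np.ndarray | float, std: np.ndarray | float, beta: float) -> np.ndarray | float:
    """Upper confidence bound mu + beta*sigma."""
    if not 0.0 <= beta <= 1.0:
        warnings.warn(f"beta={beta} outside [0, 1]; proceeding anyway", stacklevel=2)
    return np.asarray(mean) + beta * np.asarray(std) if np.ndim(mean) else mean + beta * std


@dataclass
class RankedCandidateList:
    """Candidates in descending-UCB order with per-target predictions.

    ``table`` columns: rank, id, mutations, per-target mu/sigma, combined
    mu/sigma, ucb. ``variants`` is aligned with the rows.
    """

    table: pd.DataFrame
    variants: list[Variant]
    beta: float

    def __len__(self) -> int:
        return len(self.variants)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fit_ranking_model(
    dataset: VariantDataset,
    objective: ObjectiveSpec,
    kernel: KernelSpec | None = None,
    lam: float = 1.0,
) -> SequenceGP:
    """Fit the multitask GP: one head per raw target plus the combined metric."""
    targets = {name: dataset.targets[name] for name in objective.target_names}
    targets[COMBINED] = combine_targets(dataset, objective)
    return SequenceGP(kernel=kernel, lam=lam).fit(dataset, targets)


def rank_candidates(
    model: SequenceGP,
    candidates: list[Variant],
    objective: ObjectiveSpec,
    mode: str = "combined_gp",
) -> RankedCandidateList:
    """Rank candidates by descending UCB of the combined performance metric.

    ``mode="combined_gp"`` (default) scores the UCB of the GP head fitted
    directly to the combined metric; ``mode="sum_ucb"`` instead sums the
    direction-adjusted per-target UCBs. Ties keep candidate enumeration
    order (stable sort), and every candidate is retained with its rank.
    """
    if not candidates:
        raise ObjectiveError("empty candidate list")
    preds = model.predict(candidates)
    beta = objective.beta
    if mode == "combined_gp":
        if COMBINED not in preds:
            raise ObjectiveError("model has no combined-metric head; use fit_ranking_model")
        mu_c, sd_c = preds[COMBINED]
        scores = ucb(mu_c, sd_c, beta)
    elif mode == "sum_ucb":
        scores = np.zeros(len(candidates))
        mu_c = np.zeros(len(candidates))
        sd_c = np.full(len(candidates), np.nan)
        for name, direction in objective.targets:
            mu, sd = preds[name]
            sign = -1.0 if direction == "minimize" else 1.0
            scores += sign * mu + beta * sd  # sigma is direction-free
            mu_c += sign * mu
    else:
        raise ObjectiveError(f"unknown ranking mode {mode!r}")

    order = np.argsort(-np.asarray(scores), kind="stable")
    cols: dict[str, list | np.ndarray] = {
        "rank": np.arange(1, len(candidates) + 1),
        "mutations": [candidates[i].name for i in order],
    }
    for name, _ in objective.targets:
        mu, sd = preds[name]
        cols[f"mu_{name}"] = np.asarray(mu)[order]
        cols[f"sigma_{name}"] = np.asarray(sd)[order]
    cols["mu_combined"] = np.asarray(mu_c)[order]
    cols["sigma_combined"] = np.asarray(sd_c)[order]
    cols["ucb"] = np.asarray(scores)[order]
    return RankedCandidateList(
        table=pd.DataFrame(cols),
        variants=[candidates[i] for i in order],
        beta=beta,
    )


def top_fraction(ranked: RankedCandidateList, f: float) -> RankedCandidateList:
    """The first ceil(f*N) rows of a ranked list, 0 < f <= 1."""
    if not 0.0 < f <= 1.0:
        raise ObjectiveError(f"fraction must be in (0, 1], got {f}")
    if len(ranked) == 0:
        raise ObjectiveError("empty ranked list")
    k = int(np.ceil(f * len(ranked)))
    return RankedCandidateList(
        table=ranked.table.iloc[:k].reset_index(drop=True),
        variants=ranked.variants[:k],
        beta=ranked.beta,
    )


def position_frequency(ranked: RankedCandidateList) -> dict[int, int]:
    """Count substitution sites among single-mutant candidates.

    Returns position -> count, ordered by count descending then position
    ascending. Sites recurring many times in the top predictions flag
    mutational hotspots worth testing at saturation.
    """
    counts: dict[int, int] = {}
    for v in ranked.variants:
        if len(v.mutations) != 1:
            raise ObjectiveError(
                f"position_frequency expects single mutants, got {v.name!r}"
            )
        (m,) = v.mutations
        counts[m.position] = counts.get(m.position, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
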