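"""Synthetic fitness landscapes emulating a random-mutagenesis screen.

The generator mimics the statistical shape of an error-prone-PCR variant
library screened for two correlated objectives: each library member carries
1–5 random substitutions (truncated-Poisson count), every (position, mutant
residue) pair has a latent additive effect on each objective drawn from a
zero-mean bivariate normal, and measurements add independent Gaussian
noise. The first objective (a catalytic rate) is framed as maximize, the
second (an ATP-per-turnover cost) as minimize; a negative cross-task
correlation mimics the rate-versus-efficiency trade-off seen in enzyme
screens. Epistasis is off by default (an optional pairwise-interaction term
exists) so that the additive ground truth stays an interpretable oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import (
    ObjectiveSpec,
    fit_ranking_model,
    rank_candidates,
    top_fraction,
)
from .kernels import KernelSpec
from .sequence_space import (
    AMINO_ACIDS,
    AA_INDEX,
    Mutation,
    ParentSequence,
    Variant,
    VariantDataset,
)


class SimulationError(ValueError):
    """Raised for invalid landscape configurations."""


@dataclass(frozen=True)
class LandscapeConfig:
    """Study conditions for one simulated screen.

    parent_length : residues in the simulated parent protein.
    effect_sd : sd of per-substitution additive effects (arbitrary assay
        units; both tasks share this scale).
    task_correlation : correlation between a substitution's rate effect and
        its cost effect; negative values encode a trade-off.
    noise_sd : sd of per-measurement Gaussian noise, same units.
    library_size : number of screened variants.
    mutations_per_variant : Poisson mean of the substitution count before
        truncation to [1, 5].
    epistasis_sd : sd of optional pairwise-interaction terms (0 = purely
        additive, the default).
    """

    parent_length: int = 50
    effect_sd: float = 1.0
    task_correlation: float = -0.3
    noise_sd: float = 0.3
    library_size: int = 200
    mutations_per_variant: float = 1.5
    epistasis_sd: float = 0.0
    seed: int = 0
    rate_baseline: float = 1.0
    atp_baseline: float = 4.0

    def __post_init__(self) -> None:
        if self.parent_length < 1:
            raise SimulationError("parent_length must be >= 1")
        if min(self.effect_sd, self.noise_sd, self.epistasis_sd) < 0:
            raise SimulationError("scales must be nonnegative")
        if not -1.0 <= self.task_correlation <= 1.0:
            raise SimulationError("task_correlation must lie in [-1, 1]")
        if self.library_size < 2:
            raise SimulationError("library_size must be >= 2")
        if self.mutations_per_variant <= 0:
            raise SimulationError("mutations_per_variant must be positive")


@dataclass
class GroundTruth:
    """Latent additive effects: (L, 20) tables, wild-type entries zero."""

    parent: ParentSequence
    rate_effects: np.ndarray
    atp_effects: np.ndarray
    rate_baseline: float
    atp_baseline: float

    def effect(self, mutations: frozenset[Mutation] | set[Mutation]) -> tuple[float, float]:
        """Summed true (rate, atp) effect of a mutation set."""
        r = sum(self.rate_effects[m.position - 1, AA_INDEX[m.mut_aa]] for m in mutations)
        a = sum(self.atp_effects[m.position - 1, AA_INDEX[m.mut_aa]] for m in mutations)
        return float(r), float(a)

    def combined_effect(self, mutations: frozenset[Mutation] | set[Mutation]) -> float:
        """Direction-adjusted truth: rate effect minus cost effect."""
        r, a = self.effect(mutations)
        return r - a

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in range(1, len(self.parent) + 1):
            wt = self.parent.residues[pos - 1]
            for aa in AMINO_ACIDS:
                if aa == wt:
                    continue
                rows.append(
                    {
                        "position": pos,
                        "residue": aa,
                        "rate_effect": self.rate_effects[pos - 1, AA_INDEX[aa]],
                        "atp_effect": self.atp_effects[pos - 1, AA_INDEX[aa]],
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson(mean) conditioned on the support {1, ..., 5}."""
    support = np.arange(1, 6)
    logpmf = support * np.log(mean) - mean - np.cumsum(np.log(np.maximum(support, 1)))
    # cumulative log-factorials: log(k!) for k = 1..5
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    return rng.choice(support, size=size, p=pmf)


def simulate_landscape(config: LandscapeConfig) -> tuple[GroundTruth, VariantDataset]:
    """Draw a ground-truth landscape and a noisily measured variant library.

    Fully reproducible from ``config.seed``. With ``noise_sd=0`` the
    measured value of any variant equals the parent baseline plus the sum of
    its mutations' true effects exactly.
    """
    rng = np.random.default_rng(config.seed)
    L = config.parent_length
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    parent = ParentSequence(id=f"synthetic_parent_L{L}", residues=residues)

    s = config.effect_sd
    cov = np.array(
        [[s**2, config.task_correlation * s**2], [config.task_correlation * s**2, s**2]]
    )
    # svd draw handles the singular |correlation| = 1 edge cases
    draws = rng.multivariate_normal(np.zeros(2), cov, size=(L, 20), method="svd")
    rate_eff = draws[:, :, 0].copy()
    atp_eff = draws[:, :, 1].copy()
    for pos in range(L):
        wt_idx = AA_INDEX[residues[pos]]
        rate_eff[pos, wt_idx] = 0.0
        atp_eff[pos, wt_idx] = 0.0
    truth = GroundTruth(
        parent=parent,
        rate_effects=rate_eff,
        atp_effects=atp_eff,
        rate_baseline=config.rate_baseline,
        atp_baseline=config.atp_baseline,
    )

    n = config.library_size
    counts = _truncated_poisson(rng, config.mutations_per_variant, n)
    variants: list[Variant] = []
    epi_cache: dict[tuple, float] = {}
    rate_true = np.empty(n)
    atp_true = np.empty(n)
    for i in range(n):
        m = min(int(counts[i]), L)
        positions = rng.choice(L, size=m, replace=False) + 1
        muts = set()
        for pos in positions:
            wt = residues[pos - 1]
            choices = [aa for aa in AMINO_ACIDS if aa != wt]
            muts.add(Mutation(int(pos), wt, str(rng.choice(choices))))
        v = Variant(parent, frozenset(muts))
        variants.append(v)
        r, a = truth.effect(v.mutations)
        if config.epistasis_sd > 0 and len(muts) > 1:
            ordered = sorted(muts)
            for x in range(len(ordered)):
                for y in range(x + 1, len(ordered)):
                    key = (str(ordered[x]), str(ordered[y]))
                    if key not in epi_cache:
                        epi_cache[key] = float(
                            rng.normal(0.0, config.epistasis_sd)
                        )
                    r += epi_cache[key]
        rate_true[i] = config.rate_baseline + r
        atp_true[i] = config.atp_baseline + a

    rate_meas = rate_true + rng.normal(0.0, config.noise_sd, size=n)
    atp_meas = atp_true + rng.normal(0.0, config.noise_sd, size=n)
    dataset = VariantDataset(
        variants=variants,
        targets={"rate": rate_meas, "atp_ratio": atp_meas},
        ids=[f"v{i + 1:04d}" for i in range(n)],
        provenance=f"simulated(seed={config.seed})",
    )
    return truth, dataset


@dataclass(frozen=True)
class RecoverySummary:
    """How well the fitted model recovers the simulated landscape."""

    rho_all_singles: float
    rho_observed_singles: float
    enrichment_diff: float
    top_mean_true: float
    random_mean_true: float
    n_candidates: int
    n_top: int


def recovery_experiment(
    config: LandscapeConfig,
    objective: ObjectiveSpec | None = None,
    kernel: KernelSpec | None = None,
    lam: float = 1.0,
    top_f: float = 0.01,
    n_random_draws: int = 100,
) -> RecoverySummary:
    """Simulate, fit the GP, rank all single mutants, score against truth.

    Reports the Spearman correlation between predicted UCB and true combined
    effect over all single mutants (and over the subset whose substitution
    was observed in the training library), plus the enrichment of the
    UCB-selected top fraction: mean true combined effect of the top picks
    minus the average over ``n_random_draws`` equally sized random picks.
    """
    from .evaluation import spearman  # local import to avoid a cycle

    if objective is None:
        objective = ObjectiveSpec()
    truth, dataset = simulate_landscape(config)
    model = fit_ranking_model(dataset, objective, kernel=kernel, lam=lam)
    candidates = [
        Variant(truth.parent, frozenset({Mutation(pos, truth.parent.residues[pos - 1], aa)}))
        for pos in range(1, len(truth.parent) + 1)
        for aa in AMINO_ACIDS
        if aa != truth.parent.residues[pos - 1]
    ]
    ranked = rank_candidates(model, candidates, objective)
    true_vals = np.array([truth.combined_effect(v.mutations) for v in ranked.variants])
    scores = ranked.table["ucb"].to_numpy()
    rho_all = spearman(scores, true_vals)

    observed = {
        (m.position, m.mut_aa) for v in dataset.variants for m in v.mutations
    }
    mask = np.array(
        [
            (next(iter(v.mutations)).position, next(iter(v.mutations)).mut_aa) in observed
            for v in ranked.variants
        ]
    )
    rho_obs = (
        spearman(scores[mask], true_vals[mask]) if mask.sum() >= 2 else float("nan")
    )

    top = top_fraction(ranked, top_f)
    n_top = len(top)
    top_mean = float(
        np.mean([truth.combined_effect(v.mutations) for v in top.variants])
    )
    rng = np.random.default_rng(config.seed + 1)
    rand_means = [
        float(np.mean(true_vals[rng.choice(len(true_vals), size=n_top, replace=False)]))
        for _ in range(n_random_draws)
    ]
    random_mean = float(np.mean(rand_means))
    return RecoverySummary(
        rho_all_singles=float(rho_all),
        rho_observed_singles=float(rho_obs),
        enrichment_diff=top_mean - random_mean,
        top_mean_true=top_mean,
        random_mean_true=random_mean,
        n_candidates=len(candidates),
        n_top=n_top,
    )
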