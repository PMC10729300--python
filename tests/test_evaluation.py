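import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mldekit import (
    LandscapeConfig,
    VariantDataset,
    cross_validate,
    kendall,
    kfold_split,
    simulate_landscape,
    spearman,
)
from mldekit.evaluation import EvaluationError


# ---------------------------------------------------------------------------
# Brute-force rank-correlation oracles, independent of scipy
# ---------------------------------------------------------------------------

def _midranks(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(a, b):
    ra, rb = _midranks(list(a)), _midranks(list(b))
    ma, mb = sum(ra) / len(ra), sum(rb) / len(rb)
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    den = (sum((x - ma) ** 2 for x in ra) * sum((y - mb) ** 2 for y in rb)) ** 0.5
    return num / den


def kendall_oracle(a, b):
    n = len(a)
    conc = disc = ties_a = ties_b = 0
    for i, j in itertools.combinations(range(n), 2):
        da, db = a[i] - a[j], b[i] - b[j]
        if da == 0 and db == 0:
            ties_a += 1
            ties_b += 1
        elif da == 0:
            ties_a += 1
        elif db == 0:
            ties_b += 1
        elif da * db > 0:
            conc += 1
        else:
            disc += 1
    P = n * (n - 1) / 2
    return (conc - disc) / ((P - ties_a) * (P - ties_b)) ** 0.5


# ---------------------------------------------------------------------------
# kfold_split
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n, k", [(161, 10), (10, 10), (23, 4), (7, 2)])
def test_kfold_partitions_with_near_equal_sizes(n, k):
    folds = kfold_split(n, k, seed=3)
    sizes = sorted(len(f) for f in folds)
    assert max(sizes) - min(sizes) <= 1
    assert sum(sizes) == n
    assert sorted(np.concatenate(folds)) == list(range(n))
    if (n, k) == (161, 10):
        assert sorted(sizes) == [16] * 9 + [17]
    if (n, k) == (10, 10):
        assert sizes == [1] * 10


def test_kfold_deterministic_and_seed_sensitive():
    a = kfold_split(50, 5, seed=7)
    b = kfold_split(50, 5, seed=7)
    c = kfold_split(50, 5, seed=8)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))
    assert any(not np.array_equal(x, y) for x, y in zip(a, c))


def test_kfold_rejects_bad_k():
    with pytest.raises(EvaluationError):
        kfold_split(5, 6, seed=0)
    with pytest.raises(EvaluationError):
        kfold_split(5, 1, seed=0)


# ---------------------------------------------------------------------------
# Rank correlations
# ---------------------------------------------------------------------------

def test_correlations_on_simple_vectors():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    assert spearman(v, v) == pytest.approx(1.0)
    assert spearman(v, v[::-1]) == pytest.approx(-1.0)
    # one swapped adjacent pair: 1 - 6*2/(4*15) = 0.8
    assert spearman(v, np.array([1.0, 3.0, 2.0, 4.0])) == pytest.approx(0.8)
    w = np.array([1.0, 2.0, 3.0])
    assert kendall(w, w) == pytest.approx(1.0)
    # 2 concordant, 1 discordant of 3 pairs
    assert kendall(w, np.array([1.0, 3.0, 2.0])) == pytest.approx(1 / 3)
    assert kendall(w, np.array([1.0, 3.0, 2.0])) == pytest.approx(
        -kendall(w, -np.array([1.0, 3.0, 2.0]))
    )


def test_constant_vectors_flagged_as_nan():
    c = np.ones(5)
    v = np.arange(5.0)
    assert np.isnan(spearman(c, v))
    assert np.isnan(kendall(v, c))


def test_correlations_match_bruteforce_oracles():
    """100 random (tie-rich) vector pairs, n <= 30, agreement to 1e-12."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(3, 31))
        a = rng.integers(0, 8, size=n).astype(float)  # ties likely
        b = rng.normal(size=n).round(1)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        assert spearman(a, b) == pytest.approx(spearman_oracle(a, b), abs=1e-12)
        assert kendall(a, b) == pytest.approx(kendall_oracle(a, b), abs=1e-12)


@given(st.integers(min_value=0, max_value=10**6))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_correlation_bounds_property(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=12), rng.normal(size=12)
    assert -1.0 <= spearman(a, b) <= 1.0
    assert -1.0 <= kendall(a, b) <= 1.0


# ---------------------------------------------------------------------------
# cross_validate
# ---------------------------------------------------------------------------

def _shuffle_targets(ds: VariantDataset, seed: int) -> VariantDataset:
    perm = np.random.default_rng(seed).permutation(len(ds))
    return VariantDataset(
        variants=ds.variants,
        targets={k: v[perm] for k, v in ds.targets.items()},
        ids=ds.ids,
        provenance="shuffled",
    )


def test_cv_report_reproducible_and_partitions(small_landscape, objective):
    _, ds = small_landscape
    r1 = cross_validate(ds, objective, "gp", k=5, seed=2)
    r2 = cross_validate(ds, objective, "gp", k=5, seed=2)
    assert r1.mean_rho == r2.mean_rho and r1.mean_tau == r2.mean_tau
    val_ids = [vid for f in r1.folds for vid in f.val_ids]
    assert sorted(val_ids) == sorted(ds.ids)
    assert -1.0 <= r1.mean_rho <= 1.0 and -1.0 <= r1.mean_tau <= 1.0
    for f in r1.folds:
        assert set(f.train_ids).isdisjoint(f.val_ids)


def test_gp_and_rf_share_identical_folds(small_landscape, objective):
    _, ds = small_landscape
    gp = cross_validate(ds, objective, "gp", k=5, seed=9)
    rf = cross_validate(ds, objective, "rf", k=5, seed=9)
    assert [f.val_ids for f in gp.folds] == [f.val_ids for f in rf.folds]
    assert gp.scored_quantity == "ucb" and rf.scored_quantity == "mean"


def test_near_perfect_model_on_noise_free_replicated_data(objective):
    """Oracle upper bound: with no measurement noise and every variant
    measured in triplicate, each held-out variant has exact-duplicate
    training points, so a near-interpolating GP reaches mean CV rho ~ 1."""
    from mldekit.kernels import KernelSpec

    config = LandscapeConfig(
        parent_length=10, library_size=30, noise_sd=0.0, seed=13
    )
    _, ds = simulate_landscape(config)
    idx = np.repeat(np.arange(len(ds)), 3)  # triplicate measurements
    replicated = VariantDataset(
        variants=[ds.variants[i] for i in idx],
        targets={k: v[idx] for k, v in ds.targets.items()},
        ids=[f"{ds.ids[i]}_rep{r}" for r, i in enumerate(idx)],
    )
    report = cross_validate(
        replicated, objective, "gp", k=5, seed=1,
        kernel=KernelSpec(family="hamming"), lam=1e-4, scored_quantity="mean",
    )
    assert report.mean_rho > 0.95


def test_shuffled_targets_give_null_correlation(small_landscape, objective):
    """Breaking the sequence-measurement link drives mean CV rho to ~0."""
    _, ds = small_landscape
    rhos = [
        cross_validate(_shuffle_targets(ds, s), objective, "gp", k=5, seed=s).mean_rho
        for s in range(8)
    ]
    fold_size = len(ds) / 5
    assert abs(float(np.mean(rhos))) < 2 / np.sqrt(fold_size)


def test_pooled_aggregation_mode(small_landscape, objective):
    _, ds = small_landscape
    pooled = cross_validate(ds, objective, "gp", k=5, seed=3, pooled=True)
    avg = cross_validate(ds, objective, "gp", k=5, seed=3, pooled=False)
    assert -1.0 <= pooled.mean_rho <= 1.0
    assert pooled.folds[0].rho == avg.folds[0].rho  # per-fold rows unchanged


def test_cv_rejects_singleton_folds_and_unknown_family(small_landscape, objective):
    _, ds = small_landscape
    with pytest.raises(EvaluationError):
        cross_validate(ds, objective, "gp", k=len(ds), seed=0)  # folds of 1
    with pytest.raises(EvaluationError):
        cross_validate(ds, objective, "svm", k=5, seed=0)


def test_cv_report_tsv_shape(tmp_path, small_landscape, objective):
    _, ds = small_landscape
    report = cross_validate(ds, objective, "gp", k=5, seed=4)
    path = tmp_path / "cv.tsv"
    report.write_tsv(path)
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    assert len(df) == 6  # 5 fold rows + 1 summary row
    assert df["fold"].iloc[-1] == "mean"
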