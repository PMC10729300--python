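import numpy as np
import pytest

from mldekit import (
    KernelSpec,
    ObjectiveSpec,
    VariantDataset,
    combine_targets,
    enumerate_single_mutants,
    fit_ranking_model,
    position_frequency,
    rank_candidates,
    top_fraction,
    ucb,
)
from mldekit.acquisition import ObjectiveError, RankedCandidateList
from mldekit.evaluation import spearman

from conftest import random_dataset


def _dataset_with(rate, atp, base):
    return VariantDataset(
        variants=base.variants[: len(rate)],
        targets={"rate": np.asarray(rate, float), "atp_ratio": np.asarray(atp, float)},
        ids=base.ids[: len(rate)],
    )


def test_combine_targets_two_point_example(objective):
    base = random_dataset(2, 8, seed=0)
    ds = _dataset_with([1.0, 3.0], [4.0, 2.0], base)
    combined = combine_targets(ds, objective)
    # z(rate) = [-1, 1]; atp is minimized so -z(atp) = [-1, 1]; sum = [-2, 2]
    assert combined == pytest.approx([-2.0, 2.0])


def test_combine_single_maximize_target_is_its_zscore():
    base = random_dataset(4, 8, seed=1)
    spec = ObjectiveSpec(targets=(("rate", "maximize"),))
    ds = _dataset_with([1.0, 2.0, 3.0, 6.0], [1, 1, 1, 1], base)
    z = (ds.targets["rate"] - 3.0) / np.std(ds.targets["rate"])
    assert combine_targets(ds, spec) == pytest.approx(z)


def test_combined_metric_invariant_under_positive_affine_rescaling(objective):
    base = random_dataset(10, 8, seed=2)
    rng = np.random.default_rng(3)
    rate, atp = rng.normal(size=10), rng.normal(size=10)
    c1 = combine_targets(_dataset_with(rate, atp, base), objective)
    c2 = combine_targets(_dataset_with(3.7 * rate + 11, 0.2 * atp - 5, base), objective)
    assert c1 == pytest.approx(c2)
    assert np.mean(c1) == pytest.approx(0.0, abs=1e-12)


def test_combine_rejects_constant_target(objective):
    base = random_dataset(3, 8, seed=4)
    with pytest.raises(ObjectiveError):
        combine_targets(_dataset_with([1, 2, 3], [2, 2, 2], base), objective)


def test_ucb_arithmetic():
    assert ucb(1.0, 0.4, 0.5) == pytest.approx(1.2)
    assert ucb(1.0, 0.4, 0.0) == pytest.approx(1.0)  # pure exploitation
    assert ucb(1.0, 0.0, 1.0) == pytest.approx(1.0)  # deterministic point


def test_ucb_monotone_in_beta_and_warns_outside_unit_interval():
    mus, sds = np.array([0.1, -0.5]), np.array([0.3, 0.9])
    vals = [ucb(mus, sds, b) for b in (0.0, 0.25, 0.5, 1.0)]
    for lo, hi in zip(vals, vals[1:]):
        assert np.all(hi >= lo)
    with pytest.warns(UserWarning):
        ucb(1.0, 1.0, 1.5)


@pytest.fixture(scope="module")
def ranked_fixture(small_landscape, objective):
    truth, ds = small_landscape
    model = fit_ranking_model(ds, objective)
    candidates = enumerate_single_mutants(truth.parent)
    return candidates, rank_candidates(model, candidates, objective)


def test_rank_candidates_is_sorted_permutation(ranked_fixture):
    candidates, ranked = ranked_fixture
    scores = ranked.table["ucb"].to_numpy()
    assert np.all(np.diff(scores) <= 1e-12)  # nonincreasing
    assert list(ranked.table["rank"]) == list(range(1, len(candidates) + 1))
    assert sorted(v.name for v in ranked.variants) == sorted(v.name for v in candidates)


def test_rank_ties_preserve_enumeration_order(small_landscape, objective):
    truth, ds = small_landscape
    model = fit_ranking_model(ds, objective)
    candidates = enumerate_single_mutants(truth.parent)
    ranked = rank_candidates(model, candidates, objective)
    # identical UCBs (exact float ties) must appear in enumeration order
    order = {v.name: i for i, v in enumerate(candidates)}
    ucbs = ranked.table["ucb"].to_numpy()
    names = [v.name for v in ranked.variants]
    for i in range(len(names) - 1):
        if ucbs[i] == ucbs[i + 1]:
            assert order[names[i]] < order[names[i + 1]]


def test_sum_ucb_mode_agrees_on_direction(small_landscape, objective):
    """Both ranking modes reward high rate and low ATP demand: their scores
    correlate strongly on the same candidates."""
    truth, ds = small_landscape
    model = fit_ranking_model(ds, objective)
    candidates = enumerate_single_mutants(truth.parent)
    r1 = rank_candidates(model, candidates, objective, mode="combined_gp")
    r2 = rank_candidates(model, candidates, objective, mode="sum_ucb")
    s1 = r1.table.set_index("mutations")["ucb"]
    s2 = r2.table.set_index("mutations")["ucb"]
    assert spearman(s1.to_numpy(), s2[s1.index].to_numpy()) > 0.8


def test_noise_free_interpolating_ranking_matches_truth(objective):
    """On a noise-free additive landscape, with beta = 0 and a vanishing
    ridge, the UCB ranking of in-training single mutants equals the ranking
    by their true combined effects (the GP interpolates their measurements).

    Uses the Hamming kernel, which is an average of per-position identity
    kernels and hence PSD, so a tiny ridge is numerically safe."""
    from mldekit import LandscapeConfig, simulate_landscape

    config = LandscapeConfig(
        parent_length=15, library_size=40, noise_sd=0.0, mutations_per_variant=0.5,
        seed=21,
    )
    truth, ds = simulate_landscape(config)
    singles = [i for i, v in enumerate(ds.variants) if len(v.mutations) == 1]
    seen = {}
    for i in singles:  # deduplicate repeated draws of the same substitution
        seen[ds.variants[i].name] = i
    idx = sorted(seen.values())
    assert len(idx) >= 10
    spec = ObjectiveSpec(beta=0.0)
    model = fit_ranking_model(
        ds, spec, kernel=KernelSpec(family="hamming"), lam=1e-8
    )
    cands = [ds.variants[i] for i in idx]
    ranked = rank_candidates(model, cands, spec)
    truth_combined = combine_targets(ds, spec)
    true_by_name = {ds.variants[i].name: truth_combined[i] for i in idx}
    ranked_names = [v.name for v in ranked.variants]
    expected = sorted(ranked_names, key=lambda nm: -true_by_name[nm])
    assert ranked_names == expected


@pytest.mark.parametrize("n, f, expected", [(1000, 0.01, 10), (7, 0.5, 4), (7, 1.0, 7)])
def test_top_fraction_uses_ceiling(ranked_fixture, n, f, expected):
    import pandas as pd

    _, ranked = ranked_fixture
    reps = -(-n // len(ranked))  # tile the fixture up to n rows
    variants = (ranked.variants * reps)[:n]
    table = pd.concat([ranked.table] * reps).head(n).reset_index(drop=True)
    sub = RankedCandidateList(table=table, variants=variants, beta=ranked.beta)
    assert len(top_fraction(sub, f)) == expected


def test_top_fraction_bad_inputs(ranked_fixture):
    _, ranked = ranked_fixture
    with pytest.raises(ObjectiveError):
        top_fraction(ranked, 0.0)
    with pytest.raises(ObjectiveError):
        top_fraction(ranked, 1.2)


def test_position_frequency_counts(parent10):
    from mldekit import apply_mutations, parse_mutation

    variants = [
        apply_mutations(parent10, {parse_mutation(t)})
        for t in ("G2R", "G2K", "L5N")
    ]
    ranked = RankedCandidateList(table=None, variants=variants, beta=0.5)
    freqs = position_frequency(ranked)
    assert freqs == {2: 2, 5: 1}
    assert list(freqs) == [2, 5]  # count-descending order
    assert sum(freqs.values()) == len(variants)


def test_position_frequency_rejects_multi_mutants(parent10):
    from mldekit import apply_mutations, parse_mutation

    v = apply_mutations(parent10, {parse_mutation("G2R"), parse_mutation("L5N")})
    with pytest.raises(ObjectiveError):
        position_frequency(RankedCandidateList(table=None, variants=[v], beta=0.5))
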