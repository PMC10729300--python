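import numpy as np
import pytest

from mldekit import (
    LandscapeConfig,
    ObjectiveSpec,
    ParentSequence,
    Variant,
    VariantDataset,
    simulate_landscape,
)


@pytest.fixture(scope="session")
def parent10() -> ParentSequence:
    return ParentSequence(id="p10", residues="MGGALKVWTN")


@pytest.fixture(scope="session")
def objective() -> ObjectiveSpec:
    return ObjectiveSpec()


@pytest.fixture(scope="session")
def small_landscape():
    """Deterministic small synthetic screen shared across tests."""
    config = LandscapeConfig(parent_length=20, library_size=60, seed=11)
    return simulate_landscape(config)


@pytest.fixture(scope="session")
def noise_free_landscape():
    config = LandscapeConfig(parent_length=20, library_size=60, noise_sd=0.0, seed=7)
    return simulate_landscape(config)


def mutant_library(seed: int, n: int, L: int, max_muts: int = 3) -> list[str]:
    """Sequences of n mutants of one random parent (the package's domain:
    equal-length variant sets, not unrelated proteins)."""
    from mldekit.sequence_space import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    parent = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    out = []
    for _ in range(n):
        s = list(parent)
        for pos in rng.choice(L, size=rng.integers(1, max_muts + 1), replace=False):
            s[pos] = rng.choice([a for a in AMINO_ACIDS if a != s[pos]])
        out.append("".join(s))
    return out


def random_dataset(n: int, L: int, seed: int) -> VariantDataset:
    """A dataset of random full-length sequences with random targets."""
    from mldekit.sequence_space import AMINO_ACIDS, diff_against_parent

    rng = np.random.default_rng(seed)
    parent = ParentSequence(
        id=f"r{seed}", residues="".join(rng.choice(list(AMINO_ACIDS), size=L))
    )
    variants = []
    for _ in range(n):
        seq = list(parent.residues)
        for pos in rng.choice(L, size=rng.integers(1, 4), replace=False):
            seq[pos] = rng.choice([a for a in AMINO_ACIDS if a != seq[pos]])
        variants.append(Variant(parent, diff_against_parent(parent, "".join(seq))))
    return VariantDataset(
        variants=variants,
        targets={
            "rate": rng.normal(size=n),
            "atp_ratio": rng.normal(size=n),
        },
        ids=[f"v{i}" for i in range(n)],
    )
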