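import numpy as np
import pandas as pd
import pytest

from ssgblup.pedigree import PedigreeTable, pedigree_from_records
from ssgblup.simulate import SimConfig, simulate_dataset


def random_pedigree(n: int, seed: int) -> PedigreeTable:
    """Sequentially built random pedigree: parents drawn from earlier animals."""
    rng = np.random.default_rng(seed)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if i >= 2 and rng.random() < 0.8:
            s, d = rng.choice(i, size=2, replace=False)
            sire[i], dam[i] = s, d
    return PedigreeTable([f"a{i}" for i in range(n)], sire, dam)


@pytest.fixture
def trio():
    """Two founders and their offspring."""
    return pedigree_from_records(["A", "B", "C"], ["UNKNOWN", "UNKNOWN", "A"],
                                 ["UNKNOWN", "UNKNOWN", "B"])


@pytest.fixture
def fullsib_mating_ped():
    """Founders P1 x P2 -> full sibs S1, S2; S1 x S2 -> X (F = 0.25)."""
    return pedigree_from_records(
        ["P1", "P2", "S1", "S2", "X"],
        ["UNKNOWN", "UNKNOWN", "P1", "P1", "S1"],
        ["UNKNOWN", "UNKNOWN", "P2", "P2", "S2"],
    )


def small_sim(seed: int = 7, **kw) -> SimConfig:
    base = dict(
        n_founders=40,
        n_generations=3,
        offspring_per_mating=2,
        n_snps=300,
        n_chromosomes=3,
        traits=("T1",),
        h2_targets=(0.3,),
        pe_variance=(0.0,),
        rg_matrix=((1.0,),),
        observed_scale="liability",
        genotyped_fraction=0.6,
        missing_call_rate=0.0,
        seed=seed,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_dataset():
    """A small univariate dataset reused across modules."""
    return simulate_dataset(small_sim())


@pytest.fixture(scope="session")
def default_pheno_spec():
    from ssgblup.mixed_model import ModelSpec

    return ModelSpec(
        traits=["T1"], fixed_factors={"sex": None, "age": None}, covariates=["F"]
    )


def make_pheno(ids, y, **extra) -> pd.DataFrame:
    df = pd.DataFrame({"animal": list(ids), "y": np.asarray(y, dtype=float)})
    for k, v in extra.items():
        df[k] = v
    return df
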