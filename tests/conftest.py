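import numpy as np
import pandas as pd
import pytest

from twinbeliefs import SimulationConfig, compute_phenotypes, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced AE-world cohort used by most unit tests."""
    return SimulationConfig(n_mz_pairs=60, n_dz_pairs=40, seed=11)


@pytest.fixture(scope="session")
def small_trials(small_config) -> pd.DataFrame:
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_phenotypes(small_trials) -> pd.DataFrame:
    return compute_phenotypes(small_trials)


@pytest.fixture(scope="session")
def study_scale_phenotypes() -> pd.DataFrame:
    """One cohort at the study's sample size (184 MZ / 80 DZ pairs)."""
    return compute_phenotypes(simulate_cohort(SimulationConfig(seed=23)))


def simulate_trait_pairs(
    var_a: float, var_c: float, var_e: float, n_mz: int, n_dz: int, seed: int,
    var_d: float = 0.0,
) -> pd.DataFrame:
    """Subject-level phenotype table holding one latent trait directly as
    the phenotype (no trial-level noise) — for fitting-layer tests."""
    from twinbeliefs.synthetic import simulate_latent_traits

    cfg = SimulationConfig(
        n_mz_pairs=n_mz, n_dz_pairs=n_dz, var_a=var_a, var_c=var_c,
        var_d=var_d, var_e=var_e, seed=seed,
    )
    traits = simulate_latent_traits(cfg)
    out = traits[["subject_id", "pair_id", "zygosity", "age", "sex"]].copy()
    out["trait"] = traits["learning_rate"]
    return out
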