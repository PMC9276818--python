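"""Synthetic twin cohorts with known variance-component ground truth.

Latent subject-level traits follow the classical biometric decomposition:
each standardized trait is a weighted sum of an additive-genetic component
(A, correlated 1 within monozygotic pairs and 1/2 within dizygotic pairs),
a shared-environment component (C, correlated 1 in both zygosities), an
optional dominance component (D, correlated 1 in MZ and 1/4 in DZ pairs),
and a unique-environment component (E, uncorrelated within pairs).  The
implied within-pair trait covariances are therefore

    cov_MZ = var_a + var_c + var_d
    cov_DZ = var_a / 2 + var_c + var_d / 4

with unit marginal variance.  Trial-level task records (probability
estimates before and after seeing base-rate information, recall of that
information, and 1-6 ratings) are generated from the traits with simple
linear maps plus noise, with every mapping coefficient exposed on
:class:`SimulationConfig` so the generating phenotypes remain recoverable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_NAMES = (
    "learning_rate",
    "vividness_propensity",
    "negativity_propensity",
    "memory_fidelity",
    "prior_offset",
)

#: nuisance propensities feeding the familiarity / past-experience rating
#: scales; twin-structured like every subject-level trait in a twin cohort
NUISANCE_NAMES = ("familiarity_propensity", "experience_propensity")

ESTIMATE_MIN, ESTIMATE_MAX = 3, 77
INFO_MIN, INFO_MAX = 10, 70
RATING_LEVELS = 6

TRIAL_COLUMNS = [
    "subject_id",
    "pair_id",
    "zygosity",
    "age",
    "sex",
    "event_id",
    "first_estimate",
    "information",
    "second_estimate",
    "recalled_probability",
    "familiarity",
    "past_experience",
    "vividness",
    "negativity",
]


@dataclass
class SimulationConfig:
    """Cohort and generative-model settings.

    Defaults mirror the study design this package analyses: 184 MZ and 80
    DZ same-sex pairs, 40 adverse-event trials per subject of which 20
    randomly chosen ones receive ratings and a recall probe, probability
    estimates restricted to [3, 77]% and event base rates to [10, 70]%.
    Trait variance fractions default to an additive-genetic/unique-
    environment (AE) world with 35% heritability, the middle of the range
    of heritabilities this kind of task phenotype shows.
    """

    n_mz_pairs: int = 184
    n_dz_pairs: int = 80
    n_events: int = 40
    n_rated_events: int = 20
    var_a: float = 0.35
    var_c: float = 0.0
    var_d: float = 0.0
    var_e: float = 0.65
    trait_list: tuple[str, ...] = TRAIT_NAMES
    trial_noise_sd: float = 5.0
    seed: int = 0

    # trial-level generative coefficients (estimate units per latent SD
    # unless noted); all recorded here so ground truth is recoverable
    prior_offset_scale: float = 8.0
    beta_vividness: float = 3.0
    beta_negativity: float = 1.5
    beta_familiarity: float = 2.5
    beta_experience: float = 2.5
    learning_gain_base: float = 0.5
    learning_gain_slope: float = 0.25
    recall_prob_base: float = 0.65
    recall_prob_slope: float = 0.25
    recall_error_max: int = 15
    rating_noise_sd: float = 0.8

    # demographics (pair-level)
    age_mean: float = 52.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (18.0, 90.0)
    prop_female: float = 0.88

    def __post_init__(self) -> None:
        for name in ("var_a", "var_c", "var_d", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.var_e <= 0:
            raise ValueError("var_e must be strictly positive")
        if self.var_c > 0 and self.var_d > 0:
            raise ValueError(
                "var_c and var_d cannot both be positive: simulate either an "
                "ACE world or an ADE world"
            )
        total = self.var_a + self.var_c + self.var_d + self.var_e
        if not np.isclose(total, 1.0):
            # standardized traits: renormalize the fractions to sum to 1
            self.var_a /= total
            self.var_c /= total
            self.var_d /= total
            self.var_e /= total
        if self.n_rated_events > self.n_events:
            raise ValueError("n_rated_events cannot exceed n_events")
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ValueError("pair counts must be nonnegative")

    def variance_fractions(self) -> dict[str, float]:
        return {"a": self.var_a, "c": self.var_c, "d": self.var_d, "e": self.var_e}


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _pair_structured_normal(
    rng: np.random.Generator,
    n_mz: int,
    n_dz: int,
    config: SimulationConfig,
) -> np.ndarray:
    """One standardized trait for 2*(n_mz+n_dz) subjects, twin-structured.

    Returns an array of shape (n_pairs, 2).  MZ pairs occupy the first
    n_mz rows.
    """
    n_pairs = n_mz + n_dz
    a_shared = rng.standard_normal(n_pairs)
    a_unique = rng.standard_normal((n_pairs, 2))
    c_shared = rng.standard_normal(n_pairs)
    d_shared = rng.standard_normal(n_pairs)
    d_unique = rng.standard_normal((n_pairs, 2))
    e_unique = rng.standard_normal((n_pairs, 2))

    mz = np.zeros(n_pairs, dtype=bool)
    mz[:n_mz] = True

    # additive genetic: MZ twins share the whole component; DZ twins share
    # half the additive variance (correlation 1/2)
    a = np.where(
        mz[:, None],
        a_shared[:, None],
        np.sqrt(0.5) * a_shared[:, None] + np.sqrt(0.5) * a_unique,
    )
    # dominance: correlation 1 in MZ, 1/4 in DZ
    d = np.where(
        mz[:, None],
        d_shared[:, None],
        np.sqrt(0.25) * d_shared[:, None] + np.sqrt(0.75) * d_unique,
    )
    c = np.broadcast_to(c_shared[:, None], (n_pairs, 2))
    return (
        np.sqrt(config.var_a) * a
        + np.sqrt(config.var_c) * c
        + np.sqrt(config.var_d) * d
        + np.sqrt(config.var_e) * e_unique
    )


def simulate_latent_traits(config: SimulationConfig) -> pd.DataFrame:
    """Draw subject-level latent traits with the configured twin structure.

    Returns one row per subject with columns ``subject_id``, ``pair_id``,
    ``zygosity``, ``age``, ``sex``, one column per trait in
    ``config.trait_list`` and per nuisance propensity.
    """
    n_pairs = config.n_mz_pairs + config.n_dz_pairs
    rngs = _spawn_rngs(config.seed, len(config.trait_list) + len(NUISANCE_NAMES) + 1)
    demo_rng = rngs[-1]

    traits: dict[str, np.ndarray] = {}
    for i, name in enumerate((*config.trait_list, *NUISANCE_NAMES)):
        traits[name] = _pair_structured_normal(
            rngs[i], config.n_mz_pairs, config.n_dz_pairs, config
        ).ravel()

    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n_pairs, random_state=demo_rng
    )
    sexes = np.where(demo_rng.random(n_pairs) < config.prop_female, "F", "M")

    pair_ids = np.repeat(np.arange(1, n_pairs + 1), 2)
    out = pd.DataFrame(
        {
            "subject_id": np.arange(1, 2 * n_pairs + 1),
            "pair_id": pair_ids,
            "zygosity": np.where(pair_ids <= config.n_mz_pairs, "MZ", "DZ"),
            "age": np.round(np.repeat(ages, 2), 1),
            "sex": np.repeat(sexes, 2),
        }
    )
    for name, values in traits.items():
        out[name] = values
    return out


def _discretize_rating(latent: np.ndarray, noise_sd: float) -> np.ndarray:
    """Map a standard-normal latent (plus N(0, noise_sd) trial noise already
    added) onto 1..6 by equal-probability bins of its marginal."""
    total_sd = np.sqrt(1.0 + noise_sd**2)
    cuts = stats.norm.ppf(np.arange(1, RATING_LEVELS) / RATING_LEVELS, scale=total_sd)
    return np.digitize(latent, cuts) + 1


def simulate_task_trials(traits: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Generate trial-level task records from the latent traits.

    Each subject sees the same ``n_events`` adverse events (integer base
    rates drawn once, uniform on [10, 70]).  First estimates are the base
    rate shifted by the prior-offset trait and the vividness / negativity
    propensities plus noise; second estimates move a trait-dependent
    fraction of the way toward the presented information; a random
    ``n_rated_events``-subset per subject receives ratings and a recall
    probe whose accuracy is governed by the memory-fidelity trait.
    """
    rngs = _spawn_rngs(config.seed + 1_000_003, 6)
    r_event, r_prior, r_update, r_recall, r_rating, r_select = rngs

    n_sub = len(traits)
    n_ev = config.n_events
    info = r_event.integers(INFO_MIN, INFO_MAX + 1, size=n_ev).astype(float)

    lr = traits["learning_rate"].to_numpy()
    viv = traits["vividness_propensity"].to_numpy()
    neg = traits["negativity_propensity"].to_numpy()
    mem = traits["memory_fidelity"].to_numpy()
    off = traits["prior_offset"].to_numpy()
    fam = traits["familiarity_propensity"].to_numpy()
    exp_ = traits["experience_propensity"].to_numpy()

    # trial-level rating latents: subject propensity plus trial variation;
    # the same latent drives both the prior shift and the observed rating,
    # which is what produces within-subject prior/rating correlations
    def latent(trait: np.ndarray) -> np.ndarray:
        return trait[:, None] + config.rating_noise_sd * r_rating.standard_normal((n_sub, n_ev))

    lat_viv = latent(viv)
    lat_neg = latent(neg)
    lat_fam = latent(fam)
    lat_exp = latent(exp_)

    shift = (
        config.prior_offset_scale * off[:, None]
        + config.beta_vividness * lat_viv
        - config.beta_negativity * lat_neg
        + config.beta_familiarity * lat_fam
        + config.beta_experience * lat_exp
    )
    first = np.clip(
        np.round(
            info[None, :]
            + shift
            + config.trial_noise_sd * r_prior.standard_normal((n_sub, n_ev))
        ),
        ESTIMATE_MIN,
        ESTIMATE_MAX,
    )

    gain = np.clip(config.learning_gain_base + config.learning_gain_slope * lr, 0.0, 1.0)
    second = np.clip(
        np.round(
            first
            + gain[:, None] * (info[None, :] - first)
            + config.trial_noise_sd * r_update.standard_normal((n_sub, n_ev))
        ),
        ESTIMATE_MIN,
        ESTIMATE_MAX,
    )

    # per-subject random subset of events gets ratings + recall probe
    rated = np.zeros((n_sub, n_ev), dtype=bool)
    for i in range(n_sub):
        rated[i, r_select.choice(n_ev, size=config.n_rated_events, replace=False)] = True

    p_correct = np.clip(config.recall_prob_base + config.recall_prob_slope * mem, 0.0, 1.0)
    correct = r_recall.random((n_sub, n_ev)) < p_correct[:, None]
    signs = np.where(r_recall.random((n_sub, n_ev)) < 0.5, -1, 1)
    magnitude = r_recall.integers(1, config.recall_error_max + 1, size=(n_sub, n_ev))
    recalled = np.where(correct, info[None, :], info[None, :] + signs * magnitude)
    recalled = np.clip(recalled, ESTIMATE_MIN, ESTIMATE_MAX)
    recalled = np.where(rated, recalled, np.nan)

    def rating(lat: np.ndarray) -> np.ndarray:
        values = _discretize_rating(lat, config.rating_noise_sd).astype(float)
        return np.where(rated, values, np.nan)

    records = pd.DataFrame(
        {
            "subject_id": np.repeat(traits["subject_id"].to_numpy(), n_ev),
            "pair_id": np.repeat(traits["pair_id"].to_numpy(), n_ev),
            "zygosity": np.repeat(traits["zygosity"].to_numpy(), n_ev),
            "age": np.repeat(traits["age"].to_numpy(), n_ev),
            "sex": np.repeat(traits["sex"].to_numpy(), n_ev),
            "event_id": np.tile(np.arange(1, n_ev + 1), n_sub),
            "first_estimate": first.ravel(),
            "information": np.tile(info, n_sub),
            "second_estimate": second.ravel(),
            "recalled_probability": recalled.ravel(),
            "familiarity": rating(lat_fam).ravel(),
            "past_experience": rating(lat_exp).ravel(),
            "vividness": rating(lat_viv).ravel(),
            "negativity": rating(lat_neg).ravel(),
        }
    )
    return records


def event_labels(config: SimulationConfig) -> pd.DataFrame:
    """Assign each event a genetic-predisposition label (half of events),
    emulating stimuli that mix medical conditions with everyday mishaps."""
    rng = np.random.Generator(np.random.PCG64(config.seed + 2_000_003))
    ids = np.arange(1, config.n_events + 1)
    genetic = np.zeros(config.n_events, dtype=bool)
    genetic[rng.choice(config.n_events, size=config.n_events // 2, replace=False)] = True
    return pd.DataFrame({"event_id": ids, "genetic_predisposition": genetic})


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Convenience wrapper: traits then trials in one call."""
    return simulate_task_trials(simulate_latent_traits(config), config)


def write_trial_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write trial records as UTF-8 CSV; missing ratings/recall become empty
    cells.  Output is byte-identical for identical input."""
    out = records.loc[:, TRIAL_COLUMNS].copy()
    for col in (
        "first_estimate",
        "information",
        "second_estimate",
        "recalled_probability",
        "familiarity",
        "past_experience",
        "vividness",
        "negativity",
    ):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out["age"] = out["age"].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
    out.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def _validate_trials(df: pd.DataFrame, source: str) -> None:
    def bad_lines(mask: pd.Series) -> str:
        # +2: header line plus 1-based indexing
        lines = (df.index[mask] + 2).tolist()[:5]
        return ", ".join(map(str, lines))

    for col in ("first_estimate", "second_estimate"):
        mask = df[col].notna() & ((df[col] < ESTIMATE_MIN) | (df[col] > ESTIMATE_MAX))
        if mask.any():
            raise ValueError(
                f"{source}: {col} outside [{ESTIMATE_MIN}, {ESTIMATE_MAX}] "
                f"at line(s) {bad_lines(mask)}"
            )
    mask = df["information"].notna() & (
        (df["information"] < INFO_MIN) | (df["information"] > INFO_MAX)
    )
    if mask.any():
        raise ValueError(
            f"{source}: information outside [{INFO_MIN}, {INFO_MAX}] at line(s) {bad_lines(mask)}"
        )
    for col in ("familiarity", "past_experience", "vividness", "negativity"):
        mask = df[col].notna() & ((df[col] < 1) | (df[col] > RATING_LEVELS))
        if mask.any():
            raise ValueError(
                f"{source}: {col} outside 1..{RATING_LEVELS} at line(s) {bad_lines(mask)}"
            )


def read_trial_csv(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read and validate a trial-level CSV (the dialect written by
    :func:`write_trial_csv`); raises :class:`ValueError` naming the first
    offending line(s) for out-of-range values."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    source = getattr(path, "name", str(path))
    _validate_trials(df, source)
    return df


def rated_event_counts(records: pd.DataFrame) -> pd.Series:
    """Number of rated/recalled events per subject (diagnostic)."""
    return records.groupby("subject_id")["recalled_probability"].apply(lambda s: int(s.notna().sum()))
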