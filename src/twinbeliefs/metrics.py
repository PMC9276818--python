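"""Per-subject phenotypes from trial-level belief-formation data.

The task yields, per trial, a first probability estimate (the prior), the
presented base-rate information, a second estimate (the posterior), an
optional recall of the information, and optional 1-6 ratings.  From these
we derive the subject-level phenotypes analysed downstream:

* **update** — signed change from first to second estimate, positive when
  the change is toward the presented information;
* **estimation error** — |first estimate − information|;
* **learning score** — within-subject Pearson correlation of update with
  estimation error across trials;
* **memory score** — percentage of recall probes matching the presented
  information (exact integer match by default, tolerance configurable);
* **rating means and prior mean** — per-subject averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from twinbeliefs.synthetic import ESTIMATE_MIN, ESTIMATE_MAX, INFO_MIN, INFO_MAX

log = logging.getLogger(__name__)

RATING_SCALES = {
    "vividness": "vividness_mean",
    "negativity": "negativity_mean",
    "familiarity": "familiarity_mean",
    "past_experience": "experience_mean",
}

PHENOTYPE_COLUMNS = [
    "update_mean",
    "learning_score",
    "memory_score",
    "prior_mean",
    "estimation_error_mean",
    "vividness_mean",
    "negativity_mean",
    "familiarity_mean",
    "experience_mean",
]

#: below this fraction of usable inputs a subject's phenotype is set missing
MIN_USABLE_FRACTION = 0.5


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


def signed_update(first: float, information: float, second: float) -> float | None:
    """Signed belief update for one trial.

    Magnitude is |second − first|; the sign is positive when the change is
    toward the presented information (overshooting still counts as toward)
    and negative when away from it.  Trials where the first estimate
    already equals the information have no defined direction and are
    excluded (``None``).
    """
    _check_range("first", first, ESTIMATE_MIN, ESTIMATE_MAX)
    _check_range("second", second, ESTIMATE_MIN, ESTIMATE_MAX)
    _check_range("information", information, INFO_MIN, INFO_MAX)
    if first == information:
        return None
    magnitude = abs(second - first)
    toward = (second - first) * (information - first) > 0
    return magnitude if toward or magnitude == 0 else -magnitude


def estimation_error(first: float, information: float) -> float:
    """Absolute difference between the first estimate and the information."""
    _check_range("first", first, ESTIMATE_MIN, ESTIMATE_MAX)
    _check_range("information", information, INFO_MIN, INFO_MAX)
    return abs(first - information)


def _signed_update_vec(first: np.ndarray, information: np.ndarray, second: np.ndarray):
    """Vectorized signed update; returns (values, usable_mask)."""
    usable = first != information
    magnitude = np.abs(second - first)
    toward = (second - first) * (information - first) > 0
    values = np.where(toward | (magnitude == 0), magnitude, -magnitude)
    return values, usable


def learning_score(updates: np.ndarray, errors: np.ndarray) -> float:
    """Pearson correlation of signed update with estimation error across a
    subject's usable trials; NaN (with a warning in the log) when fewer
    than 3 trials or either series is constant."""
    updates = np.asarray(updates, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if len(updates) < 3 or np.std(updates) == 0 or np.std(errors) == 0:
        log.warning(
            "learning score undefined: n=%d, sd(update)=%.3g, sd(error)=%.3g",
            len(updates),
            np.std(updates) if len(updates) else float("nan"),
            np.std(errors) if len(errors) else float("nan"),
        )
        return float("nan")
    return float(stats.pearsonr(updates, errors).statistic)


def memory_score(recalled: np.ndarray, information: np.ndarray, tolerance: float = 0.0) -> float:
    """Percentage of recall probes within ``tolerance`` of the presented
    information (default exact match); NaN when no recall trials."""
    recalled = np.asarray(recalled, dtype=float)
    information = np.asarray(information, dtype=float)
    have = ~np.isnan(recalled)
    if not have.any():
        return float("nan")
    hits = np.abs(recalled[have] - information[have]) <= tolerance
    return float(100.0 * hits.mean())


def compute_phenotypes(trials: pd.DataFrame, memory_tolerance: float = 0.0) -> pd.DataFrame:
    """Derive the per-subject phenotype table from trial records.

    One row per subject with identifiers, demographics, ``n_trials_used``
    (usable update trials), and the phenotype columns.  Subjects with more
    than half of a phenotype's inputs missing or excluded get NaN for that
    phenotype rather than a noisy value.
    """
    rows = []
    n_excluded_equal = 0
    for subject_id, g in trials.groupby("subject_id", sort=True):
        first = g["first_estimate"].to_numpy(dtype=float)
        second = g["second_estimate"].to_numpy(dtype=float)
        info = g["information"].to_numpy(dtype=float)
        upd, usable = _signed_update_vec(first, info, second)
        n_excluded_equal += int((~usable).sum())
        err = np.abs(first - info)

        n_tot = len(g)
        n_used = int(usable.sum())
        if n_used >= MIN_USABLE_FRACTION * n_tot and n_used > 0:
            update_mean = float(upd[usable].mean())
            lscore = learning_score(upd[usable], err[usable])
        else:
            update_mean = float("nan")
            lscore = float("nan")

        row = {
            "subject_id": subject_id,
            "pair_id": g["pair_id"].iloc[0],
            "zygosity": g["zygosity"].iloc[0],
            "age": g["age"].iloc[0],
            "sex": g["sex"].iloc[0],
            "n_trials_used": n_used,
            "update_mean": update_mean,
            "learning_score": lscore,
            "memory_score": memory_score(
                g["recalled_probability"].to_numpy(dtype=float), info, memory_tolerance
            ),
            "prior_mean": float(first.mean()),
            "estimation_error_mean": float(err.mean()),
        }
        for scale, col in RATING_SCALES.items():
            vals = g[scale].to_numpy(dtype=float)
            have = ~np.isnan(vals)
            row[col] = float(vals[have].mean()) if have.any() else float("nan")
        rows.append(row)
    if n_excluded_equal:
        log.info(
            "excluded %d trials with first estimate equal to information "
            "(update direction undefined)",
            n_excluded_equal,
        )
    return pd.DataFrame(rows)


@dataclass
class AssociationReport:
    """One-sample t-test of per-subject prior/rating correlations vs 0."""

    scale: str
    mean_r: float
    sd_r: float
    t: float
    df: int
    p: float
    n_subjects: int
    n_skipped: int


def prior_rating_associations(
    trials: pd.DataFrame,
    scales: tuple[str, ...] = ("vividness", "negativity", "familiarity", "past_experience", "recalled_probability"),
    min_trials: int = 3,
) -> list[AssociationReport]:
    """Across-trial correlation of each subject's first estimate with each
    rating scale (and with the recalled probability), then a one-sample
    t-test of the coefficients against zero across subjects.

    Subjects with fewer than ``min_trials`` rated trials or a constant
    series on either side are skipped and counted.
    """
    reports = []
    for scale in scales:
        coeffs = []
        skipped = 0
        for _, g in trials.groupby("subject_id", sort=True):
            vals = g[scale].to_numpy(dtype=float)
            first = g["first_estimate"].to_numpy(dtype=float)
            have = ~np.isnan(vals)
            if have.sum() < min_trials or np.std(vals[have]) == 0 or np.std(first[have]) == 0:
                skipped += 1
                continue
            coeffs.append(stats.pearsonr(first[have], vals[have]).statistic)
        coeffs = np.asarray(coeffs)
        res = stats.ttest_1samp(coeffs, 0.0)
        reports.append(
            AssociationReport(
                scale=scale,
                mean_r=float(coeffs.mean()),
                sd_r=float(coeffs.std(ddof=1)),
                t=float(res.statistic),
                df=len(coeffs) - 1,
                p=float(res.pvalue),
                n_subjects=len(coeffs),
                n_skipped=skipped,
            )
        )
    return reports


def group_mean_tests(phenotypes: pd.DataFrame) -> dict[str, dict[str, float]]:
    """One-sample t-tests of mean update and learning score against zero:
    positive means indicate belief change in the direction of, and scaled
    by, the presented information."""
    out: dict[str, dict[str, float]] = {}
    for col in ("update_mean", "learning_score"):
        vals = phenotypes[col].dropna().to_numpy()
        if len(vals) < 2:
            raise ValueError(f"need at least 2 subjects with {col}")
        if vals.std(ddof=1) == 0:
            # degenerate series: a zero mean carries zero evidence of change
            t, p = (0.0, 1.0) if vals.mean() == 0 else (float("inf"), 0.0)
        else:
            res = stats.ttest_1samp(vals, 0.0)
            t, p = float(res.statistic), float(res.pvalue)
        out[col] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "t": t,
            "df": len(vals) - 1,
            "p": p,
        }
    return out


def modelling_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Long-format table (one row per rated trial) for external mixed-model
    tools: first estimate as response, the four ratings as predictors."""
    cols = ["subject_id", "pair_id", "zygosity", "event_id", "first_estimate",
            "vividness", "negativity", "familiarity", "past_experience"]
    rated = trials["vividness"].notna()
    return trials.loc[rated, cols].reset_index(drop=True)
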