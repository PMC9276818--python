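"""Twin similarity via permutation partial correlations.

Within each zygosity group the correlation between "twin A" and "twin B"
on a phenotype depends on the arbitrary assignment of pair members to the
A and B roles.  Following the twin literature, each pair's members are
randomly reassigned to A/B many times (independent fair coin per pair);
each reassignment yields one partial correlation, and the distribution of
these coefficients summarises twin similarity (its mean as the point
estimate, the 2.5/97.5 percentiles as the interval).

Each correlation is partial: it controls for the pair's age (entered at
the pair level — twins share age, so an A−B difference would be a zero
column) and for the within-pair differences of the other task factors
(subject means of first estimate, the four ratings, memory score; plus
estimation error when the focal phenotype is the update; memory is omitted
when the focal phenotype is the prior, which is given before the
information that memory refers to).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: subject-mean control factors, keyed by phenotype column name
CONTROL_FACTORS = (
    "prior_mean",
    "familiarity_mean",
    "experience_mean",
    "vividness_mean",
    "negativity_mean",
    "memory_score",
)

PHENOTYPES = (
    "update_mean",
    "learning_score",
    "memory_score",
    "vividness_mean",
    "negativity_mean",
    "prior_mean",
)


def default_covariate_spec(phenotype: str) -> list[str]:
    """Control-factor columns for a focal phenotype.

    The focal phenotype itself is never among its own controls; update
    additionally controls for estimation error; the prior (first estimate)
    does not control for memory.
    """
    factors = [f for f in CONTROL_FACTORS if f != phenotype]
    if phenotype == "update_mean":
        factors.append("estimation_error_mean")
    if phenotype == "prior_mean":
        factors.remove("memory_score")
    return factors


def build_pair_covariates(
    factors_a: np.ndarray, factors_b: np.ndarray, age: float
) -> np.ndarray:
    """Covariate vector for one pair under a given A/B assignment: the age
    (pair-level) followed by the A−B difference of each control factor."""
    return np.concatenate([[age], np.asarray(factors_a) - np.asarray(factors_b)])


def partial_correlation(x: np.ndarray, y: np.ndarray, Z: np.ndarray | None = None) -> float:
    """Pearson correlation of ``x`` and ``y`` after residualizing both on
    ``Z`` (plus an intercept).  With no covariates this reduces to the
    plain product-moment correlation.  Collinear columns of ``Z`` are
    handled by least-squares projection (a warning is emitted when ``Z``
    is rank-deficient)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z is None or (hasattr(Z, "size") and Z.size == 0):
        Z2 = np.ones((len(x), 1))
    else:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        Z2 = np.column_stack([np.ones(len(x)), Z])
        if np.linalg.matrix_rank(Z2) < Z2.shape[1]:
            warnings.warn("covariate matrix is rank-deficient; collinear columns ignored")
    bx, *_ = np.linalg.lstsq(Z2, x, rcond=None)
    by, *_ = np.linalg.lstsq(Z2, y, rcond=None)
    rx = x - Z2 @ bx
    ry = y - Z2 @ by
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


@dataclass
class PermutationResult:
    """Distribution of twin A/B-reassignment partial correlations for one
    phenotype within one zygosity group."""

    phenotype: str
    zygosity: str
    n_pairs: int
    n_permutations: int
    mean_r: float
    percentile_2_5: float
    percentile_97_5: float
    covariates: list[str]
    seed: int | None
    r_distribution: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "zygosity": self.zygosity,
            "n_pairs": self.n_pairs,
            "n_permutations": self.n_permutations,
            "mean_r": self.mean_r,
            "percentile_2_5": self.percentile_2_5,
            "percentile_97_5": self.percentile_97_5,
            "covariates": list(self.covariates),
            "seed": self.seed,
        }


def _pair_arrays(
    phenotypes: pd.DataFrame, zygosity: str, phenotype: str, factors: list[str]
):
    """Per-pair arrays (twin1/twin2 values, factor means, age) for one
    zygosity, dropping pairs with any missing value listwise."""
    sub = phenotypes[phenotypes["zygosity"] == zygosity].sort_values(
        ["pair_id", "subject_id"]
    )
    cols = [phenotype] + factors
    complete = sub["pair_id"].duplicated(keep=False)  # both members present
    sub = sub[complete]
    rows1 = sub.groupby("pair_id").head(1).set_index("pair_id")
    rows2 = sub.groupby("pair_id").tail(1).set_index("pair_id")
    ok = rows1[cols].notna().all(axis=1) & rows2[cols].notna().all(axis=1)
    if (~ok).any():
        log.info(
            "%s/%s: dropped %d pair(s) with missing phenotype or covariates",
            phenotype, zygosity, int((~ok).sum()),
        )
    rows1, rows2 = rows1[ok], rows2[ok]
    return (
        rows1[phenotype].to_numpy(dtype=float),
        rows2[phenotype].to_numpy(dtype=float),
        rows1[factors].to_numpy(dtype=float),
        rows2[factors].to_numpy(dtype=float),
        rows1["age"].to_numpy(dtype=float),
    )


def _batched_partial_corr(x: np.ndarray, y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Partial correlations for a batch of permutations.

    x, y: (P, n); Z: (P, n, k) already including the intercept column.
    """
    G = np.einsum("pnk,pnl->pkl", Z, Z)
    bx = np.linalg.solve(G, np.einsum("pnk,pn->pk", Z, x)[..., None])[..., 0]
    by = np.linalg.solve(G, np.einsum("pnk,pn->pk", Z, y)[..., None])[..., 0]
    rx = x - np.einsum("pnk,pk->pn", Z, bx)
    ry = y - np.einsum("pnk,pk->pn", Z, by)
    return np.einsum("pn,pn->p", rx, ry) / np.sqrt(
        np.einsum("pn,pn->p", rx, rx) * np.einsum("pn,pn->p", ry, ry)
    )


def _assignment_correlations(
    signs: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    f1: np.ndarray,
    f2: np.ndarray,
    age: np.ndarray,
    chunk: int = 2000,
) -> np.ndarray:
    """r for each row of ``signs`` (+1: member 1 is twin A)."""
    n = len(p1)
    use_age = np.std(age) > 0
    diffs = f1 - f2  # (n, k); flips sign with the assignment
    out = np.empty(len(signs))
    for start in range(0, len(signs), chunk):
        s = signs[start : start + chunk]  # (P, n)
        P = len(s)
        x = np.where(s > 0, p1, p2)
        y = np.where(s > 0, p2, p1)
        blocks = [np.ones((P, n, 1))]
        if use_age:
            blocks.append(np.broadcast_to(age[None, :, None], (P, n, 1)))
        if diffs.shape[1]:
            blocks.append(s[:, :, None] * diffs[None, :, :])
        Z = np.concatenate(blocks, axis=2)
        out[start : start + chunk] = _batched_partial_corr(x, y, Z)
    return out


def permutation_twin_correlation(
    phenotypes: pd.DataFrame,
    phenotype: str,
    covariate_spec: list[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
    keep_distribution: bool = False,
    min_pairs: int = 10,
) -> dict[str, PermutationResult]:
    """Permutation partial-correlation analysis for one phenotype.

    Runs separately for MZ and DZ pairs; per permutation each pair's
    members are independently relabelled A/B with probability 1/2 and the
    partial correlation between the A and B vectors is computed
    controlling for age and the within-pair control-factor differences.
    With ``exhaustive=True`` all 2**n_pairs assignments are enumerated
    instead (only feasible for small groups).
    """
    factors = default_covariate_spec(phenotype) if covariate_spec is None else list(covariate_spec)
    results: dict[str, PermutationResult] = {}
    rng = np.random.Generator(np.random.PCG64(seed))
    for zygosity in ("MZ", "DZ"):
        p1, p2, f1, f2, age = _pair_arrays(phenotypes, zygosity, phenotype, factors)
        n = len(p1)
        if n < min_pairs:
            raise ValueError(
                f"only {n} usable {zygosity} pairs for {phenotype} "
                f"(need >= {min_pairs})"
            )
        if exhaustive:
            if n > 20:
                raise ValueError(f"exhaustive enumeration infeasible for {n} pairs")
            bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
            signs = 2 * bits - 1
        else:
            signs = np.where(rng.random((n_perm, n)) < 0.5, 1, -1)
        r = _assignment_correlations(signs, p1, p2, f1, f2, age)
        results[zygosity] = PermutationResult(
            phenotype=phenotype,
            zygosity=zygosity,
            n_pairs=n,
            n_permutations=len(signs),
            mean_r=float(r.mean()),
            percentile_2_5=float(np.percentile(r, 2.5)),
            percentile_97_5=float(np.percentile(r, 97.5)),
            covariates=factors,
            seed=None if exhaustive else seed,
            r_distribution=r if keep_distribution else None,
        )
    return results


def interval_overlap(res_mz: PermutationResult, res_dz: PermutationResult) -> dict:
    """Do the MZ and DZ 2.5–97.5 percentile intervals intersect?

    Non-overlap with the MZ interval above the DZ interval is the
    qualitative signature of a genetic contribution to the phenotype.
    """
    if res_mz.phenotype != res_dz.phenotype:
        raise ValueError("results are for different phenotypes")
    lo_mz, hi_mz = res_mz.percentile_2_5, res_mz.percentile_97_5
    lo_dz, hi_dz = res_dz.percentile_2_5, res_dz.percentile_97_5
    overlap = (lo_mz <= hi_dz) and (lo_dz <= hi_mz)
    larger = "MZ" if res_mz.mean_r >= res_dz.mean_r else "DZ"
    return {"phenotype": res_mz.phenotype, "overlap": bool(overlap), "larger": larger}
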