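"""Maximum-likelihood ACE/ADE variance decomposition for twin pairs.

The classical biometric model writes a phenotype of twin *i* in pair *j*
as

    y_ij = mu + x_ij' beta + A_ij + C_j + E_ij         (ACE family)

with additive-genetic (A), shared-environment (C) and unique-environment
(E) components.  Under the standard assumptions (C fully shared; E
independent; additive-genetic correlation 1 for monozygotic and 1/2 for
dizygotic pairs) each pair's phenotype vector is bivariate normal with
covariance matrix

    | sA2 + sC2 + sE2      R_j sA2 + sC2    |
    | R_j sA2 + sC2        sA2 + sC2 + sE2  |

where R_j = 1 (MZ) or 1/2 (DZ).  The ADE family replaces C by a dominance
component D whose within-pair correlation is 1 (MZ) or 1/4 (DZ).  Nested
submodels drop components (AE, CE, E); a DE model is not identified
(dominance cannot be estimated without additive effects) and is rejected.

Fitting maximises the summed pair log-likelihoods over path coefficients
(variances enter as squares, which enforces nonnegativity without
explicit constraints), the grand mean and covariate coefficients, with
multiple starting points.  Model comparison uses AIC = -2LL + 2*ep with
ep counting the intercept plus variance components (E: 2, AE/CE: 3,
ACE/ADE: 4).  Confidence intervals for the standardized components are
profile-likelihood intervals at the chi-square(1) cutoff; lower limits
pinned at zero indicate boundary solutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from twinbeliefs.permutation import default_covariate_spec

log = logging.getLogger(__name__)

MODEL_COMPONENTS = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}

#: free-parameter count: intercept + variance components
EP = {"ACE": 4, "ADE": 4, "AE": 3, "CE": 3, "E": 2}

#: within-pair correlation of each component, by zygosity
_A_COEF = {"MZ": 1.0, "DZ": 0.5}
_D_COEF = {"MZ": 1.0, "DZ": 0.25}

DEMOGRAPHIC_COVARIATES = ("age", "sex", "age_x_sex")


def default_biometric_covariates(phenotype: str) -> list[str]:
    """Age, sex, age-by-sex, plus the task control factors appropriate for
    the focal phenotype (same policy as the permutation analysis)."""
    return list(DEMOGRAPHIC_COVARIATES) + default_covariate_spec(phenotype)


@dataclass
class PairData:
    """Pair-structured phenotype data ready for likelihood evaluation."""

    phenotype: str
    y1: np.ndarray
    y2: np.ndarray
    mz: np.ndarray  # boolean mask, True for MZ pairs
    X1: np.ndarray | None = None  # (n_pairs, k) covariates of twin 1
    X2: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)
    n_pairs_dropped: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.y1)

    @property
    def n_subjects(self) -> int:
        return 2 * len(self.y1)


def prepare_pairs(
    phenotypes: pd.DataFrame,
    phenotype: str,
    covariates: list[str] | None = None,
) -> PairData:
    """Assemble :class:`PairData` from a subject-level phenotype table.

    ``covariates`` may mix demographic names (``age``, ``sex``,
    ``age_x_sex``) with phenotype-table column names; ``None`` selects the
    default policy for the phenotype; ``[]`` fits covariate-free.  Sex is
    coded female=1/male=0.  Covariate columns are z-scored internally for
    numerical conditioning (coefficients are reported on that scale);
    constant columns are dropped.  Pairs with any missing value are
    dropped listwise.
    """
    if covariates is None:
        covariates = default_biometric_covariates(phenotype)
    df = phenotypes.copy()
    df["sex"] = df["sex"].map({"F": 1.0, "M": 0.0}) if df["sex"].dtype == object else df["sex"]
    df["age_x_sex"] = df["age"] * df["sex"]

    sub = df.sort_values(["pair_id", "subject_id"])
    sub = sub[sub["pair_id"].duplicated(keep=False)]
    rows1 = sub.groupby("pair_id").head(1).set_index("pair_id")
    rows2 = sub.groupby("pair_id").tail(1).set_index("pair_id")
    cols = [phenotype] + list(covariates)
    ok = rows1[cols].notna().all(axis=1) & rows2[cols].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("%s: dropped %d pair(s) with missing data", phenotype, n_dropped)
    rows1, rows2 = rows1[ok], rows2[ok]

    X1 = X2 = None
    kept: list[str] = []
    if covariates:
        M1 = rows1[list(covariates)].to_numpy(dtype=float)
        M2 = rows2[list(covariates)].to_numpy(dtype=float)
        stacked = np.vstack([M1, M2])
        mean, sd = stacked.mean(axis=0), stacked.std(axis=0)
        keep = sd > 1e-12
        if not keep.all():
            dropped = [c for c, k in zip(covariates, keep) if not k]
            log.info("%s: dropped constant covariate(s) %s", phenotype, dropped)
        kept = [c for c, k in zip(covariates, keep) if k]
        if kept:
            X1 = (M1[:, keep] - mean[keep]) / sd[keep]
            X2 = (M2[:, keep] - mean[keep]) / sd[keep]
    return PairData(
        phenotype=phenotype,
        y1=rows1[phenotype].to_numpy(dtype=float),
        y2=rows2[phenotype].to_numpy(dtype=float),
        mz=(rows1["zygosity"] == "MZ").to_numpy(),
        X1=X1,
        X2=X2,
        covariate_names=kept,
        n_pairs_dropped=n_dropped,
    )


@dataclass
class BiometricFit:
    """One fitted variance-components model on one phenotype."""

    model: str
    phenotype: str
    n_pairs: int
    n_subjects: int
    mu: float
    beta: dict[str, float]
    sigma2: dict[str, float]  # raw variance components (a, c, d, e)
    standardized: dict[str, float]  # percentages, sum to 100
    ci: dict[str, tuple[float, float]]  # profile CIs on the % scale
    minus2ll: float
    ep: int
    df: int
    aic: float
    converged: bool
    boundary: list[str]
    _data: PairData | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "phenotype": self.phenotype,
            "n_pairs": self.n_pairs,
            "n_subjects": self.n_subjects,
            "mu": self.mu,
            "beta": dict(self.beta),
            "sigma2": dict(self.sigma2),
            "standardized": dict(self.standardized),
            "ci": {k: list(v) for k, v in self.ci.items()},
            "minus2LL": self.minus2ll,
            "ep": self.ep,
            "df": self.df,
            "AIC": self.aic,
            "converged": self.converged,
            "boundary": list(self.boundary),
        }


def pair_loglikelihood(
    y1: np.ndarray,
    y2: np.ndarray,
    mz: np.ndarray,
    variances: dict[str, float],
    mean1: np.ndarray | float = 0.0,
    mean2: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Log-likelihood contribution of each pair under given raw variance
    components (keys among a, c, d, e).

    The pair's two phenotype values are bivariate normal with common
    variance sA2+sC2+sD2+sE2 and within-pair covariance R*sA2 + sC2 +
    D*sD2 (R = 1 MZ / 0.5 DZ; D = 1 MZ / 0.25 DZ).  Returns -inf for all
    pairs when the implied matrix is not positive definite.
    """
    va = variances.get("a", 0.0)
    vc = variances.get("c", 0.0)
    vd = variances.get("d", 0.0)
    ve = variances.get("e", 0.0)
    if min(va, vc, vd, ve) < 0:
        raise ValueError("variance components must be nonnegative")
    V = va + vc + vd + ve
    off = np.where(mz, va + vc + vd, 0.5 * va + vc + 0.25 * vd)
    det = V * V - off * off
    r1 = np.asarray(y1, dtype=float) - mean1
    r2 = np.asarray(y2, dtype=float) - mean2
    if V <= 0 or np.any(det <= 0):
        return np.full(len(r1), -np.inf)
    quad = (V * (r1 * r1 + r2 * r2) - 2.0 * off * r1 * r2) / det
    return -0.5 * (2.0 * np.log(2.0 * np.pi) + np.log(det) + quad)


def _m2ll_factory(data: PairData, model: str, e_floor: float):
    """-2LL as a function of the packed parameter vector
    [path coefficients..., e, mu, beta...]; variances are squares of the
    path coefficients, sigma_E^2 floored for numerical stability."""
    comps = [c for c in MODEL_COMPONENTS[model] if c != "e"]
    mz = data.mz
    y1, y2 = data.y1, data.y2
    X1, X2 = data.X1, data.X2
    k = 0 if X1 is None else X1.shape[1]

    def unpack(theta: np.ndarray):
        variances = {c: theta[i] ** 2 for i, c in enumerate(comps)}
        variances["e"] = theta[len(comps)] ** 2 + e_floor
        mu = theta[len(comps) + 1]
        beta = theta[len(comps) + 2 :] if k else None
        return variances, mu, beta

    def m2ll(theta: np.ndarray) -> float:
        variances, mu, beta = unpack(theta)
        mean1 = mu + (X1 @ beta if k else 0.0)
        mean2 = mu + (X2 @ beta if k else 0.0)
        ll = pair_loglikelihood(y1, y2, mz, variances, mean1, mean2)
        total = ll.sum()
        # large finite penalty keeps finite-difference gradients usable
        return 1e15 if not np.isfinite(total) else float(-2.0 * total)

    return m2ll, unpack, comps, k


def _ols_start(data: PairData):
    """OLS of stacked phenotype values on the stacked covariates: start for
    (mu, beta) and the residual phenotypic variance."""
    y = np.concatenate([data.y1, data.y2])
    if data.X1 is not None:
        X = np.column_stack([np.ones(len(y)), np.vstack([data.X1, data.X2])])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return coef[0], coef[1:], float(resid.var())
    return float(y.mean()), np.empty(0), float(y.var())


def _moment_variances(data: PairData, model: str, vp: float) -> dict[str, float]:
    """Falconer-style moment estimates as an optimizer start."""
    def wcorr(mask: np.ndarray) -> float:
        if mask.sum() < 3:
            return 0.0
        a = np.concatenate([data.y1[mask], data.y2[mask]])
        b = np.concatenate([data.y2[mask], data.y1[mask]])
        return float(np.corrcoef(a, b)[0, 1])

    rmz, rdz = wcorr(data.mz), wcorr(~data.mz)
    out = {c: 0.0 for c in ("a", "c", "d")}
    if model in ("ACE", "AE", "ADE"):
        out["a"] = np.clip(2 * (rmz - rdz), 0.02, 0.95) * vp
    if model == "ACE":
        out["c"] = np.clip(2 * rdz - rmz, 0.02, 0.95) * vp
    if model == "ADE":
        out["d"] = np.clip(rmz - out["a"] / vp, 0.02, 0.95) * vp
    if model == "CE":
        out["c"] = np.clip(rmz, 0.02, 0.95) * vp
    used = sum(out[c] for c in out)
    out["e"] = max(vp - used, 0.05 * vp)
    return out


def fit_biometric(
    data: PairData,
    model: str = "ACE",
    n_random_starts: int = 3,
    seed: int = 0,
    extra_starts: list[dict[str, float]] | None = None,
    with_ci: bool = False,
) -> BiometricFit:
    """Maximum-likelihood fit of one biometric model.

    Multi-start quasi-Newton optimisation over path coefficients, the
    grand mean and covariate coefficients.  ``extra_starts`` accepts raw
    variance dictionaries (e.g. a nested model's solution) as additional
    starting points.  ``with_ci=True`` adds profile-likelihood CIs for
    every standardized component.
    """
    model = model.upper()
    if model == "DE":
        raise ValueError("DE model is not identified: dominance effects cannot "
                         "be estimated without additive ones")
    if model not in MODEL_COMPONENTS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_COMPONENTS)}")
    if data.n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    if model in ("ACE", "ADE") and (data.mz.all() or (~data.mz).all()):
        log.warning("%s fit with a single zygosity group: A and %s are not separable",
                    model, "C" if model == "ACE" else "D")

    mu0, beta0, vp = _ols_start(data)
    e_floor = 1e-6 * max(vp, 1e-12)
    m2ll, unpack, comps, k = _m2ll_factory(data, model, e_floor)
    rng = np.random.Generator(np.random.PCG64(seed))

    n_comp = len(comps)
    starts: list[np.ndarray] = []

    def pack(variances: dict[str, float]) -> np.ndarray:
        head = [np.sqrt(max(variances.get(c, 0.0), 0.0)) for c in comps]
        head.append(np.sqrt(max(variances.get("e", vp * 0.5) - e_floor, 1e-8)))
        return np.concatenate([head, [mu0], beta0])

    equal = {c: vp / (n_comp + 1) for c in comps}
    equal["e"] = vp / (n_comp + 1)
    starts.append(pack(equal))
    starts.append(pack(_moment_variances(data, model, vp)))
    for _ in range(n_random_starts):
        fractions = rng.dirichlet(np.ones(n_comp + 1))
        rand = {c: fractions[i] * vp for i, c in enumerate(comps)}
        rand["e"] = max(fractions[-1] * vp, 0.02 * vp)
        starts.append(pack(rand))
    for extra in extra_starts or []:
        starts.append(pack(extra))

    best = None
    for x0 in starts:
        res = optimize.minimize(m2ll, x0, method="L-BFGS-B")
        # polish with a simplex pass; helps when gradients are noisy near
        # the variance boundary
        res2 = optimize.minimize(m2ll, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        cand = res2 if res2.fun <= res.fun else res
        if best is None or cand.fun < best.fun:
            best = cand
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"{model} fit failed to converge on {data.phenotype}")

    variances, mu, beta = unpack(best.x)
    total = sum(variances.values())
    standardized = {c: 100.0 * v / total for c, v in variances.items()}
    boundary = [c for c, s in standardized.items() if s < 0.1]
    minus2ll = float(best.fun)
    ep = EP[model]
    fit = BiometricFit(
        model=model,
        phenotype=data.phenotype,
        n_pairs=data.n_pairs,
        n_subjects=data.n_subjects,
        mu=float(mu),
        beta={name: float(b) for name, b in zip(data.covariate_names, beta if k else [])},
        sigma2={c: float(variances.get(c, 0.0)) for c in ("a", "c", "d", "e")},
        standardized={c: float(standardized.get(c, 0.0)) for c in MODEL_COMPONENTS[model]},
        ci={},
        minus2ll=minus2ll,
        ep=ep,
        df=data.n_subjects - ep,
        aic=minus2ll + 2.0 * ep,
        converged=bool(np.isfinite(minus2ll)),
        boundary=boundary,
        _data=data,
    )
    if with_ci:
        for comp in MODEL_COMPONENTS[model]:
            fit.ci[comp] = profile_ci(fit, comp)
    return fit


def _profile_m2ll_factory(data: PairData, model: str, focal: str, e_floor: float):
    """-2LL profiled at a fixed standardized share ``s`` of the focal
    component.  Free parameters: log total variance, stick-breaking logits
    for the remaining components, mu, beta."""
    comps = list(MODEL_COMPONENTS[model])
    rest = [c for c in comps if c != focal]
    mz, y1, y2 = data.mz, data.y1, data.y2
    X1, X2 = data.X1, data.X2
    k = 0 if X1 is None else X1.shape[1]

    def make(s: float):
        def m2ll(theta: np.ndarray) -> float:
            V = np.exp(theta[0])
            remainder = (1.0 - s) * V
            shares = np.ones(len(rest))
            if len(rest) > 1:
                logits = np.clip(theta[1 : len(rest)], -35.0, 35.0)
                stick = 1.0 / (1.0 + np.exp(-logits))
                shares = np.empty(len(rest))
                left = 1.0
                for i, p in enumerate(stick):
                    shares[i] = left * p
                    left *= 1.0 - p
                shares[-1] = left
            variances = {c: 0.0 for c in ("a", "c", "d", "e")}
            variances[focal] = s * V
            for c, share in zip(rest, shares):
                variances[c] = share * remainder
            variances["e"] = max(variances["e"], e_floor)
            off = max(len(rest) - 1, 0)
            mu = theta[1 + off]
            beta = theta[2 + off :] if k else None
            mean1 = mu + (X1 @ beta if k else 0.0)
            mean2 = mu + (X2 @ beta if k else 0.0)
            ll = pair_loglikelihood(y1, y2, mz, variances, mean1, mean2).sum()
            return 1e15 if not np.isfinite(ll) else float(-2.0 * ll)

        return m2ll

    return make, rest, k


def profile_ci(fit: BiometricFit, component: str, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood confidence interval for a standardized component,
    on the percentage scale.

    The interval is the set of shares whose profiled -2LL stays within the
    chi-square(1) quantile of the minimum; it is truncated to [0, 100].
    Lower limits collapsing to ~0 flag boundary solutions.  The single-
    component E model has a degenerate interval at 100%.
    """
    if component not in MODEL_COMPONENTS[fit.model]:
        raise ValueError(f"component {component!r} not in model {fit.model}")
    if fit._data is None:
        raise ValueError("fit carries no data; refit with fit_biometric")
    if fit.model == "E":
        return (100.0, 100.0)

    data = fit._data
    cutoff = float(stats.chi2.ppf(level, df=1))
    vp = sum(fit.sigma2.values())
    e_floor = 1e-6 * max(vp, 1e-12)
    make, rest, k = _profile_m2ll_factory(data, fit.model, component, e_floor)

    s_hat = fit.standardized.get(component, 0.0) / 100.0
    m2ll_hat = fit.minus2ll

    # warm start vector shared along the search path
    off = max(len(rest) - 1, 0)
    start = np.zeros(2 + off + k)
    start[0] = np.log(max(vp, 1e-10))
    if off:
        rest_vars = np.array([max(fit.sigma2.get(c, 0.0), 1e-8) for c in rest])
        p = rest_vars[0] / rest_vars.sum()
        start[1] = np.log(p / (1 - p)) if 0 < p < 1 else 0.0
    start[1 + off] = fit.mu
    if k:
        start[2 + off :] = [fit.beta[name] for name in data.covariate_names]

    state = {"x": start.copy()}

    def profiled(s: float) -> float:
        s = min(max(s, 1e-12), 1.0 - 1e-12)
        m2ll = make(s)
        res = optimize.minimize(m2ll, state["x"], method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 3000})
        if np.isfinite(res.fun):
            state["x"] = res.x
        return float(res.fun)

    def excess(s: float) -> float:
        return profiled(s) - m2ll_hat - cutoff

    def bisect(s_in: float, s_out: float) -> float:
        # excess(s_in) <= 0 (inside the interval), excess(s_out) > 0
        for _ in range(25):
            mid = 0.5 * (s_in + s_out)
            if excess(mid) > 0:
                s_out = mid
            else:
                s_in = mid
            if abs(s_out - s_in) < 5e-4:
                break
        return 0.5 * (s_in + s_out)

    state["x"] = start.copy()
    lower = 0.0 if excess(1e-9) <= 0 else bisect(s_hat, 1e-9)
    state["x"] = start.copy()
    upper = 1.0 if excess(1.0 - 1e-9) <= 0 else bisect(s_hat, 1.0 - 1e-9)
    return (100.0 * lower, 100.0 * upper)


def model_selection(
    data: PairData,
    models: tuple[str, ...] = ("ACE", "ADE", "AE", "CE", "E"),
    seed: int = 0,
    with_ci: bool = False,
) -> list[BiometricFit]:
    """Fit the candidate models and rank them by AIC (ascending; ties go to
    the model with fewer parameters).

    Nested solutions seed the richer models' optimizers so a richer model
    never fits worse than a submodel it contains.  Non-convergent
    candidates are excluded with a log note.
    """
    order = sorted(models, key=lambda m: EP[m.upper()])  # simple models first
    solutions: dict[str, dict[str, float]] = {}
    fits: dict[str, BiometricFit] = {}
    for model in order:
        model = model.upper()
        extra = []
        for prev, sol in solutions.items():
            if set(MODEL_COMPONENTS[prev]) <= set(MODEL_COMPONENTS[model]):
                extra.append(sol)
        try:
            fit = fit_biometric(data, model, seed=seed, extra_starts=extra, with_ci=with_ci)
        except (RuntimeError, ValueError) as exc:
            log.warning("%s excluded from selection: %s", model, exc)
            continue
        fits[model] = fit
        solutions[model] = {c: fit.sigma2[c] for c in ("a", "c", "d", "e")}
    ranked = sorted(fits.values(), key=lambda f: (round(f.aic, 9), f.ep))
    return ranked


def selection_table(fits: list[BiometricFit]) -> pd.DataFrame:
    """Ranked fits as a flat table (one row per model)."""
    rows = []
    for rank, f in enumerate(fits, start=1):
        row = {
            "phenotype": f.phenotype,
            "model": f.model,
            "rank": rank,
            "winner": rank == 1,
        }
        for comp in ("a", "d", "c", "e"):
            name = comp.upper()
            if comp in MODEL_COMPONENTS[f.model]:
                row[name] = f.standardized[comp]
                lo_hi = f.ci.get(comp)
                row[f"{name}_ci_low"] = lo_hi[0] if lo_hi else np.nan
                row[f"{name}_ci_high"] = lo_hi[1] if lo_hi else np.nan
            else:
                row[name] = np.nan
                row[f"{name}_ci_low"] = np.nan
                row[f"{name}_ci_high"] = np.nan
        row.update(AIC=f.aic, minus2LL=f.minus2ll, ep=f.ep, df=f.df,
                   n_pairs=f.n_pairs, converged=f.converged)
        rows.append(row)
    return pd.DataFrame(rows)
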