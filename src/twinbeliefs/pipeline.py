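"""End-to-end orchestration: simulate/load → phenotypes → twin
correlations → biometric fits, reproducibly from one config and seed.

A master seed streams per-stage sub-seeds (simulation, permutation,
optimizer restarts) so each stage is independently reproducible; the same
config and seed produce byte-identical report files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from twinbeliefs.biometric import (
    default_biometric_covariates,
    fit_biometric,
    model_selection,
    prepare_pairs,
    selection_table,
)
from twinbeliefs.metrics import compute_phenotypes, group_mean_tests
from twinbeliefs.permutation import (
    PHENOTYPES,
    interval_overlap,
    permutation_twin_correlation,
)
from twinbeliefs.synthetic import (
    SimulationConfig,
    event_labels,
    read_trial_csv,
    simulate_cohort,
    write_trial_csv,
)

log = logging.getLogger(__name__)

_version = "0.1.0"

DEFAULT_MODELS = ("ACE", "ADE", "AE", "CE", "E")


@dataclass
class RunConfig:
    """Settings for one full analysis run.

    Either ``input_csv`` (trial-level data) or ``simulation`` must be
    given.  When simulating, the simulation seed is derived from the
    master ``seed`` so one integer reproduces the whole run.
    """

    output_dir: str = "twinbeliefs_run"
    input_csv: str | None = None
    simulation: SimulationConfig | None = None
    phenotypes: tuple[str, ...] = PHENOTYPES
    n_perm: int = 10_000
    seed: int = 0
    memory_tolerance: float = 0.0
    models: tuple[str, ...] = DEFAULT_MODELS
    use_covariates: bool = True
    stratify_prior_by_event_label: bool = False
    event_labels_csv: str | None = None

    def __post_init__(self) -> None:
        if self.input_csv is None and self.simulation is None:
            self.simulation = SimulationConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(3)
    names = ("simulate", "permutation", "fit")
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run(config: RunConfig) -> dict:
    """Execute the full chain and write the report bundle.

    Emits into ``output_dir``: ``trials.csv`` (when simulated),
    ``phenotypes.csv``, ``permutation.json``, ``biometric_table.csv``,
    ``report.json`` (group tests, overlap verdicts, drop accounting, and a
    provenance header with config hash, seed and package version).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    labels = None
    if config.input_csv:
        trials = read_trial_csv(config.input_csv)
        source = str(config.input_csv)
    else:
        sim = dataclasses.replace(config.simulation, seed=seeds["simulate"])
        trials = simulate_cohort(sim)
        write_trial_csv(trials, outdir / "trials.csv")
        labels = event_labels(sim)
        source = "simulated"
    if config.event_labels_csv:
        labels = pd.read_csv(config.event_labels_csv)

    phenotypes = compute_phenotypes(trials, memory_tolerance=config.memory_tolerance)
    phenotypes.to_csv(outdir / "phenotypes.csv", index=False, lineterminator="\n",
                      float_format="%.6g")

    group_tests = group_mean_tests(phenotypes)

    perm_report: dict[str, dict] = {}
    for phenotype in config.phenotypes:
        covariate_spec = None if config.use_covariates else []
        res = permutation_twin_correlation(
            phenotypes, phenotype, covariate_spec=covariate_spec,
            n_perm=config.n_perm, seed=seeds["permutation"],
        )
        perm_report[phenotype] = {
            "MZ": res["MZ"].to_dict(),
            "DZ": res["DZ"].to_dict(),
            "overlap": interval_overlap(res["MZ"], res["DZ"]),
        }
    _json_dump(perm_report, outdir / "permutation.json")

    tables = []
    fit_report: dict[str, dict] = {}
    for phenotype in config.phenotypes:
        covariates = (default_biometric_covariates(phenotype)
                      if config.use_covariates else [])
        data = prepare_pairs(phenotypes, phenotype, covariates)
        ranked = model_selection(data, config.models, seed=seeds["fit"])
        winner = fit_biometric(data, ranked[0].model, seed=seeds["fit"],
                               extra_starts=[ranked[0].sigma2], with_ci=True)
        ranked[0] = winner
        tables.append(selection_table(ranked))
        fit_report[phenotype] = {
            "winner": winner.to_dict(),
            "aic_ranking": [(f.model, f.aic) for f in ranked],
            "n_pairs_dropped": data.n_pairs_dropped,
        }
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(outdir / "biometric_table.csv", index=False, lineterminator="\n",
                 float_format="%.6g")

    stratified = None
    if config.stratify_prior_by_event_label and labels is not None:
        stratified = stratified_fits(
            trials, labels, phenotype="prior_mean", models=config.models,
            use_covariates=config.use_covariates, seed=seeds["fit"],
            memory_tolerance=config.memory_tolerance,
        )
        _json_dump(stratified, outdir / "stratified.json")

    report = {
        "provenance": {
            "version": _version,
            "seed": config.seed,
            "stage_seeds": seeds,
            "config_hash": hashlib.sha256(
                json.dumps(
                    {k: v for k, v in config.to_dict().items() if k != "output_dir"},
                    sort_keys=True, default=str,
                ).encode()
            ).hexdigest(),
            "source": source,
        },
        "n_subjects": int(phenotypes["subject_id"].nunique()),
        "n_pairs": int(phenotypes["pair_id"].nunique()),
        "group_tests": group_tests,
        "interval_overlap": {p: perm_report[p]["overlap"] for p in config.phenotypes},
        "winning_models": {p: fit_report[p]["winner"]["model"] for p in config.phenotypes},
        "biometric": fit_report,
    }
    if stratified is not None:
        report["stratified"] = stratified
    _json_dump(report, outdir / "report.json")
    return report


def stratified_fits(
    trials: pd.DataFrame,
    labels: pd.DataFrame,
    phenotype: str = "prior_mean",
    models: tuple[str, ...] = DEFAULT_MODELS,
    use_covariates: bool = True,
    seed: int = 0,
    memory_tolerance: float = 0.0,
    min_events: int = 5,
) -> dict:
    """Rerun the phenotype → biometric chain separately on event subsets.

    ``labels`` must have columns ``event_id`` and a boolean
    ``genetic_predisposition``; the phenotype is recomputed from each
    subset's trials only, then model selection runs per subset.  Used to
    ask whether risk-perception heritability differs between events that
    are themselves genetically predisposed (e.g. medical conditions) and
    events that are not.
    """
    merged = trials.merge(labels, on="event_id", how="left")
    out: dict[str, dict] = {}
    for name, mask in (
        ("genetic_predisposition", merged["genetic_predisposition"] == True),  # noqa: E712
        ("no_genetic_predisposition", merged["genetic_predisposition"] == False),  # noqa: E712
    ):
        subset = merged[mask]
        per_subject = subset.groupby("subject_id")["event_id"].nunique()
        if (per_subject < min_events).any():
            log.warning("subset %s has subjects with < %d events", name, min_events)
        phen = compute_phenotypes(subset, memory_tolerance=memory_tolerance)
        covariates = default_biometric_covariates(phenotype) if use_covariates else []
        data = prepare_pairs(phen, phenotype, covariates)
        ranked = model_selection(data, models, seed=seed)
        winner = fit_biometric(data, ranked[0].model, seed=seed,
                               extra_starts=[ranked[0].sigma2], with_ci=True)
        out[name] = {
            "n_events": int(subset["event_id"].nunique()),
            "winner": winner.to_dict(),
            "aic_ranking": [(f.model, f.aic) for f in ranked],
        }
    return out


def compare_with_and_without_covariates(config: RunConfig) -> pd.DataFrame:
    """Run permutation and biometric stages twice — with the control
    factors and without any covariates — and tabulate side by side.

    The headline question it answers: does controlling for related task
    factors change the heritability conclusions?
    """
    seeds = _stage_seeds(config.seed)
    if config.input_csv:
        trials = read_trial_csv(config.input_csv)
    else:
        sim = dataclasses.replace(config.simulation, seed=seeds["simulate"])
        trials = simulate_cohort(sim)
    phenotypes = compute_phenotypes(trials, memory_tolerance=config.memory_tolerance)

    rows = []
    for phenotype in config.phenotypes:
        for arm, cov_spec in (("with_covariates", None), ("without_covariates", [])):
            res = permutation_twin_correlation(
                phenotypes, phenotype, covariate_spec=cov_spec,
                n_perm=config.n_perm, seed=seeds["permutation"],
            )
            covariates = (default_biometric_covariates(phenotype)
                          if cov_spec is None else [])
            data = prepare_pairs(phenotypes, phenotype, covariates)
            ranked = model_selection(data, config.models, seed=seeds["fit"])
            winner = fit_biometric(data, ranked[0].model, seed=seeds["fit"],
                                   extra_starts=[ranked[0].sigma2], with_ci=True)
            heritable = [c for c in ("a", "d") if c in winner.standardized]
            a_pct = sum(winner.standardized[c] for c in heritable)
            a_ci = winner.ci.get("a", (float("nan"), float("nan")))
            rows.append({
                "phenotype": phenotype,
                "arm": arm,
                "mean_r_MZ": res["MZ"].mean_r,
                "mean_r_DZ": res["DZ"].mean_r,
                "winning_model": winner.model,
                "A_percent": a_pct,
                "A_ci_low": a_ci[0],
                "A_ci_high": a_ci[1],
                "AIC": winner.aic,
            })
    table = pd.DataFrame(rows)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "covariate_comparison.csv", index=False,
                 lineterminator="\n", float_format="%.6g")
    return table
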