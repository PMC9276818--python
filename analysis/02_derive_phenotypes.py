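"""Derive per-subject phenotypes and the prior/rating associations.

Reads results/trials.csv (from 01_simulate_cohort.py), computes the
subject-level scores — mean update, learning score, memory score, rating
means, mean prior — and reports whether updating/learning differ from
zero and how priors track the subjective ratings within subjects.
"""

import dataclasses
import json
from pathlib import Path

from twinbeliefs import (
    compute_phenotypes,
    group_mean_tests,
    prior_rating_associations,
    read_trial_csv,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    trials = read_trial_csv(OUT / "trials.csv")
    phenotypes = compute_phenotypes(trials)
    phenotypes.to_csv(OUT / "phenotypes.csv", index=False,
                      lineterminator="\n", float_format="%.6g")

    tests = group_mean_tests(phenotypes)
    for name, t in tests.items():
        print(f"{name}: M = {t['mean']:.2f}, SD = {t['sd']:.2f}, "
              f"t({t['df']}) = {t['t']:.3f}, p = {t['p']:.3g}")

    reports = prior_rating_associations(trials)
    for r in reports:
        print(f"prior ~ {r.scale}: mean r = {r.mean_r:.3f} (SD {r.sd_r:.2f}), "
              f"t({r.df}) = {r.t:.2f}, p = {r.p:.3g} "
              f"[{r.n_skipped} subjects skipped]")
    (OUT / "associations.json").write_text(
        json.dumps([dataclasses.asdict(r) for r in reports], indent=2) + "\n")
    print(f"wrote {OUT / 'phenotypes.csv'} and {OUT / 'associations.json'}")


if __name__ == "__main__":
    main()
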