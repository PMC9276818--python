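"""Heritability of prior risk beliefs by event type.

Splits the events into those with and without a genetic predisposition
(e.g. medical conditions vs everyday mishaps), recomputes the prior
phenotype from each subset's trials only, and reruns the variance
decomposition — asking whether the heritability of risk *perception*
depends on the heritability of the risk itself.
"""

import json
from pathlib import Path

import pandas as pd

from twinbeliefs import read_trial_csv
from twinbeliefs.pipeline import stratified_fits

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    trials = read_trial_csv(OUT / "trials.csv")
    labels = pd.read_csv(OUT / "event_labels.csv")
    res = stratified_fits(trials, labels, phenotype="prior_mean", seed=0)
    for name, entry in res.items():
        w = entry["winner"]
        parts = [
            f"{comp.upper()} = {w['standardized'][comp]:.1f}% "
            f"(CI {w['ci'][comp][0]:.1f}/{w['ci'][comp][1]:.1f})"
            for comp in ("a", "d", "c", "e") if comp in w["standardized"]
        ]
        print(f"{name} ({entry['n_events']} events): winner {w['model']}, "
              + ", ".join(parts))
    (OUT / "stratified_priors.json").write_text(
        json.dumps(res, indent=2, sort_keys=True) + "\n")
    print(f"wrote {OUT / 'stratified_priors.json'}")


if __name__ == "__main__":
    main()
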