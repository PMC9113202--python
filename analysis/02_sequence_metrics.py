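#!/usr/bin/env python
"""Score every trial's first five minutes of courtship.

Computes the per-trial complexity metrics (LZ76, entropy, entropy rate) and
courtship-rate proxies, writes the metrics table, and prints group means by
mating outcome.
"""

import csv
from pathlib import Path

import numpy as np

from courtseq.events import read_trials, window_events
from courtseq.metrics import ComplexityProfile, complexity_profile

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    trials = read_trials(ROOT / "data" / "trials.csv", ROOT / "data" / "events.csv")
    rows = []
    for t in trials:
        prof = complexity_profile(window_events(t.events), trial_id=t.trial_id)
        rows.append((t, prof))

    out = ROOT / "metrics.csv"
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ("trial_id", "copulated") + ComplexityProfile.METRIC_FIELDS + ("n_components",)
        )
        for t, p in rows:
            w.writerow(
                [t.trial_id, t.copulated]
                + [f"{getattr(p, m):.6f}" for m in ComplexityProfile.METRIC_FIELDS]
                + [p.n_components]
            )
    print(f"wrote per-trial metrics for {len(rows)} trials to {out}")

    for metric in ComplexityProfile.METRIC_FIELDS:
        v0 = [getattr(p, metric) for t, p in rows if not t.copulated]
        v1 = [getattr(p, metric) for t, p in rows if t.copulated]
        print(
            f"{metric:>20}: non-copulated {np.mean(v0):.3f} +- {np.std(v0, ddof=1):.3f}   "
            f"copulated {np.mean(v1):.3f} +- {np.std(v1, ddof=1):.3f}"
        )


if __name__ == "__main__":
    main()
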