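#!/usr/bin/env python
"""Do males change display complexity between courtship halves?

Simulates a plastic study in which copulating males shorten their rev runs
after the midpoint (bout composition fixed), splits each display at the
temporal midpoint, and runs paired Wilcoxon tests of second-half minus
first-half metrics within each outcome group.  Also reports the mean raw
shifts of entropy and entropy rate side by side, since under this pure
run-length plasticity the two move nearly in lockstep.
"""

import csv
from pathlib import Path

import numpy as np

from courtseq.events import window_events
from courtseq.inference import paired_halves_test
from courtseq.metrics import ComplexityProfile, HalfSplitError, complexity_profile, half_split
from courtseq.simulate import FIXTURE_SEED, simulate_plastic_study

ROOT = Path(__file__).resolve().parent.parent / "results"
DELTA = 0.7  # log-scale shortening of copulators' second-half rev runs


def main() -> None:
    rng = np.random.default_rng(FIXTURE_SEED)
    shifts: dict[int, dict[str, list[float]]] = {0: {}, 1: {}}
    n_males = {0: 0, 1: 0}
    # pool copulators/non-copulators across studies until both groups are
    # well populated
    while min(n_males.values()) < 60:
        trials, _ = simulate_plastic_study(half_shift_delta=DELTA, seed=rng)
        for t in trials:
            try:
                first, second = half_split(window_events(t.events))
            except HalfSplitError:
                continue
            p1 = complexity_profile(first, trial_id=t.trial_id)
            p2 = complexity_profile(second, trial_id=t.trial_id)
            if not (p1.usable and p2.usable):
                continue
            n_males[t.copulated] += 1
            for m in ComplexityProfile.METRIC_FIELDS:
                shifts[t.copulated].setdefault(m, []).append(getattr(p2, m) - getattr(p1, m))

    out = ROOT / "half_shifts.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["group", "metric", "n", "mean_shift", "wilcoxon_stat", "p"])
        for grp in (0, 1):
            print(f"\n{'copulated' if grp else 'non-copulated'} males (n={n_males[grp]}):")
            for m in ComplexityProfile.METRIC_FIELDS:
                d = shifts[grp][m]
                res = paired_halves_test([0.0] * len(d), d, metric_name=m, group=grp)
                w.writerow([grp, m, len(d), f"{np.mean(d):.5f}", f"{res.statistic:.1f}", f"{res.p_value:.4g}"])
                print(f"  {m:<20} mean shift {np.mean(d):+.4f}   Wilcoxon p={res.p_value:.4f}")
    print(f"\nwrote {out}")
    d_ent = np.mean(shifts[1]["entropy_bits"])
    d_rate = np.mean(shifts[1]["entropy_rate_bits"])
    print(
        f"copulators: entropy shift {d_ent:+.4f} vs entropy-rate shift {d_rate:+.4f} "
        "(near-lockstep co-variation under run-length-only plasticity)"
    )


if __name__ == "__main__":
    main()
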