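#!/usr/bin/env python
"""Does display complexity predict mating success?

Fits one binary logistic regression per complexity metric and courtship
rate, reports Wald chi-squared tests, and writes the full report bundle
(group comparisons, metric models, paired half tests) under results/report/.
"""

import json
from pathlib import Path

from courtseq.events import read_trials
from courtseq.inference import analyze_study

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    trials = read_trials(ROOT / "data" / "trials.csv", ROOT / "data" / "events.csv")
    report = analyze_study(trials)

    out = ROOT / "report"
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    print(f"{report.n_usable} usable trials, {report.n_copulated} copulated\n")
    print("metric                    coef      Wald chi2   p")
    for r in report.regressions:
        flag = "  (quasi-separation)" if r.separation_warning else ""
        print(
            f"{r.predictor_name:<22} {r.coefficient:>8.3f} {r.wald_chi2:>10.3f}   "
            f"{r.p_value:.4f}{flag}"
        )
    print("\ngroup comparisons (Welch): variable, t, df, p")
    for g in report.group_comparisons:
        print(f"  {g.variable_name:<16} t={g.t_statistic:+.3f}  df={g.df_welch:.3f}  p={g.p_value:.3f}")
    print(f"\nfull bundle written to {out}")


if __name__ == "__main__":
    main()
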