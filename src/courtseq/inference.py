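"""Statistical layer: does display complexity predict mating success?

The central model is a single-predictor binary logistic regression of
copulation outcome on each complexity metric, with a Wald chi-squared test
(df = 1) on the slope — the squared ratio of the fitted log-odds
coefficient to its standard error.  A likelihood-ratio test is emitted
alongside for transparency.  Group-level descriptive comparisons use
Welch's unequal-variance t-test, and within-male first-half/second-half
plasticity is tested with a paired two-sided Wilcoxon signed-rank test
(paired t selectable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .events import TrialRecord
from .metrics import ComplexityProfile, HalfSplitError, complexity_profile, half_split
from .events import window_events, DEFAULT_WINDOW_S

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "GroupComparison",
    "PairedHalvesResult",
    "fit_logistic",
    "welch_t",
    "paired_halves_test",
    "analyze_study",
]


@dataclass(frozen=True)
class RegressionResult:
    """Single-predictor logistic fit summary for one complexity metric."""

    predictor_name: str
    coefficient: float  # log-odds per predictor unit
    std_error: float
    wald_chi2: float
    df: int
    p_value: float
    n_obs: int
    intercept: float
    lr_chi2: float  # likelihood-ratio statistic vs the intercept-only model
    lr_p_value: float
    converged: bool = True
    separation_warning: bool = False
    profile_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample comparison between outcome groups (0 = non-copulated)."""

    variable_name: str
    mean_0: float
    sd_0: float
    n_0: int
    mean_1: float
    sd_1: float
    n_1: int
    t_statistic: float
    df_welch: float
    p_value: float


@dataclass(frozen=True)
class PairedHalvesResult:
    """Paired second-minus-first-half test of one metric within one group."""

    metric_name: str
    group: int
    statistic: float
    n_pairs: int
    p_value: float
    mean_difference: float
    test: str = "wilcoxon"


def _loglik(beta0: float, beta1: float, y: np.ndarray, x: np.ndarray) -> float:
    eta = beta0 + beta1 * x
    return float((y * eta - np.logaddexp(0.0, eta)).sum())


def _profile_ci(y: np.ndarray, x: np.ndarray, b0: float, b1: float, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood CI for the slope, by bisection on the deviance."""
    crit = stats.chi2.ppf(level, df=1) / 2.0

    def profiled(b1_fixed: float) -> float:
        # maximise over the intercept for fixed slope (1-D Newton)
        b0_hat = b0
        for _ in range(50):
            eta = b0_hat + b1_fixed * x
            mu = stats.logistic.cdf(eta)
            g = float((y - mu).sum())
            h = float((mu * (1 - mu)).sum())
            if h <= 0:
                break
            step = g / h
            b0_hat += step
            if abs(step) < 1e-10:
                break
        return _loglik(b0_hat, b1_fixed, y, x)

    lmax = _loglik(b0, b1, y, x)

    def bound(direction: int) -> float:
        lo, hi = b1, b1 + direction * 1.0
        for _ in range(60):
            if lmax - profiled(hi) > crit:
                break
            hi += direction * abs(hi - b1 + direction)
        else:
            return direction * math.inf
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if lmax - profiled(mid) > crit:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    return bound(-1), bound(+1)


def fit_logistic(
    outcomes: Sequence[int] | np.ndarray,
    predictor: Sequence[float] | np.ndarray,
    predictor_name: str = "x",
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_threshold: float = 15.0,
) -> RegressionResult:
    """Maximum-likelihood logistic fit of outcome on one predictor.

    Fitted by iteratively reweighted least squares to gradient tolerance
    ``tol``.  Reports the Wald chi-squared statistic ``(beta/SE)^2`` on the
    slope with df = 1 (the single-predictor analysis-of-deviance test) and
    the likelihood-ratio statistic against the intercept-only model.

    Quasi-separation is flagged when ``|beta| * sd(x) > separation_threshold``
    on the log-odds scale; the result then carries a profile-likelihood CI
    and a warning rather than silently reporting a diverging Wald test.
    """
    y = np.asarray(outcomes, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("outcomes and predictor must be aligned 1-D vectors")
    if not np.isfinite(x).all():
        raise ValueError("predictor contains non-finite values")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcomes are constant: logistic model is undefined")

    n = y.size
    sd_x = float(np.std(x, ddof=1)) if n > 1 else 0.0
    if sd_x == 0.0:
        logger.warning("predictor %r constant across trials: slope carries no information", predictor_name)
        return RegressionResult(
            predictor_name=predictor_name,
            coefficient=0.0,
            std_error=float("inf"),
            wald_chi2=0.0,
            df=1,
            p_value=1.0,
            n_obs=n,
            intercept=float(sm.families.links.Logit()(y.mean())),
            lr_chi2=0.0,
            lr_p_value=1.0,
            converged=False,
            separation_warning=False,
        )

    X = sm.add_constant(x)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=max_iter, tol=tol, scale=1.0)
    if not res.converged:
        raise RuntimeError(f"logistic fit for {predictor_name!r} did not converge in {max_iter} IRLS iterations")
    b0, b1 = res.params
    se1 = float(res.bse[1])
    wald = (b1 / se1) ** 2 if se1 > 0 else float("inf")
    null = sm.GLM(y, np.ones((n, 1)), family=sm.families.Binomial()).fit(scale=1.0)
    lr = 2.0 * (res.llf - null.llf)
    lr = max(lr, 0.0)

    separated = bool(abs(b1) * sd_x > separation_threshold)
    ci = None
    if separated:
        logger.warning(
            "possible quasi-separation on %r (|beta|*sd(x) = %.1f): Wald statistics unreliable, "
            "reporting profile-likelihood CI",
            predictor_name,
            abs(b1) * sd_x,
        )
        ci = _profile_ci(y, x, b0, b1)

    return RegressionResult(
        predictor_name=predictor_name,
        coefficient=float(b1),
        std_error=se1,
        wald_chi2=float(wald),
        df=1,
        p_value=float(stats.chi2.sf(wald, df=1)),
        n_obs=n,
        intercept=float(b0),
        lr_chi2=float(lr),
        lr_p_value=float(stats.chi2.sf(lr, df=1)),
        converged=bool(res.converged),
        separation_warning=separated,
        profile_ci=ci,
    )


def welch_t(
    group_0: Sequence[float] | np.ndarray,
    group_1: Sequence[float] | np.ndarray,
    variable_name: str = "x",
) -> GroupComparison:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    ``t`` is oriented as (mean of group 0) minus (mean of group 1), i.e.
    non-copulated minus copulated when used for outcome groups.
    """
    a = np.asarray(group_0, dtype=float)
    b = np.asarray(group_1, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in group comparison")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        equal = a.mean() == b.mean()
        return GroupComparison(
            variable_name, a.mean(), 0.0, a.size, b.mean(), 0.0, b.size,
            t_statistic=0.0 if equal else math.copysign(math.inf, a.mean() - b.mean()),
            df_welch=float(a.size + b.size - 2),
            p_value=1.0 if equal else 0.0,
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        variable_name=variable_name,
        mean_0=float(a.mean()),
        sd_0=float(a.std(ddof=1)),
        n_0=int(a.size),
        mean_1=float(b.mean()),
        sd_1=float(b.std(ddof=1)),
        n_1=int(b.size),
        t_statistic=float(res.statistic),
        df_welch=float(res.df),
        p_value=float(res.pvalue),
    )


def paired_halves_test(
    first_half: Sequence[float] | np.ndarray,
    second_half: Sequence[float] | np.ndarray,
    metric_name: str = "metric",
    group: int = -1,
    test: Literal["wilcoxon", "ttest"] = "wilcoxon",
) -> PairedHalvesResult:
    """Two-sided paired test of second-half minus first-half metric values."""
    a = np.asarray(first_half, dtype=float)
    b = np.asarray(second_half, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("half vectors must be aligned by trial")
    if a.size < 5:
        raise ValueError(f"need >= 5 usable pairs, got {a.size}")
    d = b - a
    if np.all(d == 0):
        return PairedHalvesResult(metric_name, group, 0.0, a.size, 1.0, 0.0, test)
    if test == "wilcoxon":
        res = stats.wilcoxon(d, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.ttest_rel(b, a)
        statistic, p = float(res.statistic), float(res.pvalue)
    return PairedHalvesResult(metric_name, group, statistic, int(a.size), p, float(d.mean()), test)


#: Table-1-style descriptive variables taken from trial metadata.
_TRIAL_VARIABLES = ("male_mass_g", "female_mass_g", "mass_ratio", "n_components", "latency_s")


@dataclass
class StudyReport:
    """Full report bundle: group comparisons, per-metric models, half tests."""

    n_trials: int
    n_usable: int
    n_copulated: int
    group_comparisons: list[GroupComparison]
    metric_means: dict[str, dict[str, float]]  # metric -> {mean_0, sd_0, mean_1, sd_1}
    regressions: list[RegressionResult]
    paired_halves: list[PairedHalvesResult]
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "n_trials": self.n_trials,
            "n_usable": self.n_usable,
            "n_copulated": self.n_copulated,
            "group_comparisons": [asdict(g) for g in self.group_comparisons],
            "metric_means": self.metric_means,
            "regressions": [asdict(r) for r in self.regressions],
            "paired_halves": [asdict(p) for p in self.paired_halves],
            "exclusions": [list(e) for e in self.exclusions],
        }


def analyze_study(
    trials: Sequence[TrialRecord],
    window_s: float = DEFAULT_WINDOW_S,
    visual_labels: frozenset[str] | set[str] = frozenset({"leg_tap"}),
    multimodal_rule: str = "double_count_legtap",
    entropy_rate_weights: str = "empirical",
    half_split_rule: Literal["time", "count"] = "time",
    paired_test: Literal["wilcoxon", "ttest"] = "wilcoxon",
    min_usable: int = 10,
) -> StudyReport:
    """End-to-end study analysis reproducing the standard report layout.

    For each trial the first ``window_s`` of courtship is scored into a
    complexity profile; trials with fewer than two windowed events are
    excluded with a logged reason.  The report contains (a) Welch group
    comparisons of masses, mass ratio, component count and latency;
    (b) per-group means +- sd of the five metrics with per-metric logistic
    Wald (and LR) tests; and (c) per-group paired first/second-half
    comparisons of each metric.  Deterministic given inputs and options.
    """
    profiles: list[ComplexityProfile] = []
    exclusions: list[tuple[str, str]] = []
    usable_trials: list[TrialRecord] = []
    for t in trials:
        win = window_events(t.events, window_s)
        prof = complexity_profile(
            win,
            trial_id=t.trial_id,
            visual_labels=visual_labels,
            multimodal_rule=multimodal_rule,  # type: ignore[arg-type]
            entropy_rate_weights=entropy_rate_weights,  # type: ignore[arg-type]
        )
        if not prof.usable:
            logger.info("excluding trial %s: %s", t.trial_id, prof.exclusion_reason)
            exclusions.append((t.trial_id, prof.exclusion_reason or "unusable"))
            continue
        profiles.append(prof)
        usable_trials.append(t)

    if len(profiles) < min_usable:
        raise ValueError(f"only {len(profiles)} usable trials; need >= {min_usable}")
    y = np.array([t.copulated for t in usable_trials])
    if len(set(y.tolist())) < 2:
        raise ValueError("single-outcome dataset: both copulated and non-copulated trials required")

    mask1 = y == 1

    def split(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return values[~mask1], values[mask1]

    comparisons = []
    trial_values = {
        "male_mass_g": np.array([t.male_mass_g for t in usable_trials]),
        "female_mass_g": np.array([t.female_mass_g for t in usable_trials]),
        "mass_ratio": np.array([t.mass_ratio for t in usable_trials]),
        "n_components": np.array([float(p.n_components) for p in profiles]),
        "latency_s": np.array([t.latency_s for t in usable_trials]),
    }
    for name in _TRIAL_VARIABLES:
        g0, g1 = split(trial_values[name])
        comparisons.append(welch_t(g0, g1, variable_name=name))

    metric_means: dict[str, dict[str, float]] = {}
    regressions: list[RegressionResult] = []
    for metric in ComplexityProfile.METRIC_FIELDS:
        vals = np.array([getattr(p, metric) for p in profiles])
        g0, g1 = split(vals)
        metric_means[metric] = {
            "mean_0": float(g0.mean()),
            "sd_0": float(g0.std(ddof=1)),
            "mean_1": float(g1.mean()),
            "sd_1": float(g1.std(ddof=1)),
        }
        regressions.append(fit_logistic(y, vals, predictor_name=metric))

    paired: list[PairedHalvesResult] = []
    half_profiles: dict[str, tuple[ComplexityProfile, ComplexityProfile]] = {}
    for t in usable_trials:
        win = window_events(t.events, window_s)
        try:
            first, second = half_split(win, rule=half_split_rule)
        except HalfSplitError as exc:
            logger.info("half-split exclusion for trial %s: %s", t.trial_id, exc)
            continue
        p1 = complexity_profile(first, trial_id=t.trial_id)
        p2 = complexity_profile(second, trial_id=t.trial_id)
        if p1.usable and p2.usable:
            half_profiles[t.trial_id] = (p1, p2)
    outcome_by_id = {t.trial_id: t.copulated for t in usable_trials}
    for metric in ComplexityProfile.METRIC_FIELDS:
        for grp in (0, 1):
            ids = [tid for tid in half_profiles if outcome_by_id[tid] == grp]
            if len(ids) < 5:
                continue
            a = [getattr(half_profiles[tid][0], metric) for tid in ids]
            b = [getattr(half_profiles[tid][1], metric) for tid in ids]
            paired.append(paired_halves_test(a, b, metric_name=metric, group=grp, test=paired_test))

    return StudyReport(
        n_trials=len(trials),
        n_usable=len(profiles),
        n_copulated=int(mask1.sum()),
        group_comparisons=comparisons,
        metric_means=metric_means,
        regressions=regressions,
        paired_halves=paired,
        exclusions=exclusions,
    )
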