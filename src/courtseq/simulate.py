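"""Synthetic courtship displays with the stereotyped grammar of the study
species, and synthetic mating studies built on them.

Male *Schizocosa stridulans* displays are highly stereotyped: long runs of
``rev`` components are punctuated by short bouts of one or two ``idle`` /
``leg_tap`` components, and bouts of more than two non-rev components are
essentially never observed.  The generator encodes that grammar directly:

* rev-run lengths are geometric with configurable mean (support >= 1) — the
  simplest memoryless choice consistent with "many revs" and a first-order
  Markov analysis;
* each bout has size 1 or 2 (configurable distribution, never more);
* each bout symbol is ``leg_tap`` with probability ``p_legtap_in_bout``,
  else ``idle``;
* event durations and inter-event gaps are exponential with configured
  means, so onset/offset times resemble a real scored trial.

Study-level simulation links a named complexity metric to the binary
copulation outcome through a logistic model, providing a parameter-recovery
and calibration harness for the inference layer; the "plastic" variant
shortens copulating males' rev runs in the second half of the display, the
within-bout composition held fixed, to emulate dynamically increased
temporal complexity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .events import ALPHABET, EventRecord, SymbolSequence, TrialRecord, window_events
from .metrics import complexity_profile

__all__ = [
    "DisplayGrammarConfig",
    "StudyConfig",
    "simulate_sequence",
    "simulate_iid",
    "simulate_study",
    "simulate_plastic_study",
]

#: Seed of the small versioned fixture dataset used by the test suite.
FIXTURE_SEED = 20080517


@dataclass(frozen=True)
class DisplayGrammarConfig:
    """Parameters of the stereotyped display grammar for one male.

    Defaults are set to emulate the observed displays: sequences of roughly
    a hundred components over up to five minutes, with a rev proportion
    around 0.92 (entropy in the observed 0.1-0.5 bit range) and sparse
    leg-taps.
    """

    mean_rev_run: float = 15.0  # expected revs per run, geometric, support >= 1
    bout_size_probs: dict[int, float] = field(default_factory=lambda: {1: 0.7, 2: 0.3})
    p_legtap_in_bout: float = 0.3
    rev_duration_s: float = 1.0
    idle_duration_s: float = 1.5
    gap_s: float = 0.8
    target_n_components: int = 96
    half_shift_delta: float = 0.0  # subtracted from log(mean_rev_run) in the 2nd half

    def __post_init__(self) -> None:
        if self.mean_rev_run < 1.0:
            raise ValueError("mean_rev_run must be >= 1 (a run always has at least one rev)")
        if set(self.bout_size_probs) - {1, 2}:
            raise ValueError("bout sizes are restricted to {1, 2}")
        total = sum(self.bout_size_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("bout_size_probs must sum to 1")
        if not 0.0 <= self.p_legtap_in_bout <= 1.0:
            raise ValueError("p_legtap_in_bout must be a probability")
        if min(self.rev_duration_s, self.idle_duration_s, self.gap_s) <= 0:
            raise ValueError("durations and gaps must be positive")
        if self.target_n_components < 1:
            raise ValueError("target_n_components must be >= 1")

    @property
    def mean_bout_size(self) -> float:
        return sum(k * p for k, p in self.bout_size_probs.items())

    @property
    def expected_rev_proportion(self) -> float:
        """Renewal-theory expectation: mean run / (mean run + mean bout)."""
        return self.mean_rev_run / (self.mean_rev_run + self.mean_bout_size)


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_symbols(cfg: DisplayGrammarConfig, rng: np.random.Generator, n: int, mean_rev_run: float) -> list[str]:
    sizes = sorted(cfg.bout_size_probs)
    size_p = [cfg.bout_size_probs[s] for s in sizes]
    out: list[str] = []
    p_stop = 1.0 / mean_rev_run
    while len(out) < n:
        run = int(rng.geometric(p_stop))
        out.extend(["rev"] * run)
        bout = int(rng.choice(sizes, p=size_p))
        for _ in range(bout):
            out.append("leg_tap" if rng.random() < cfg.p_legtap_in_bout else "idle")
    return out[:n]


def simulate_sequence(
    config: DisplayGrammarConfig,
    seed: int | np.random.Generator | None = None,
    trial_id: str = "sim",
    start_s: float = 0.0,
) -> list[EventRecord]:
    """Generate one display as a timed event list, reproducible from the seed.

    Alternates geometric rev runs with 1-2-symbol bouts until
    ``target_n_components`` components exist, then assigns onsets/offsets
    from exponential durations and gaps starting at ``start_s``.  A nonzero
    ``half_shift_delta`` switches, at the component-count midpoint, to a
    grammar whose log mean run length is reduced by delta (shorter runs,
    more transitions) while the bout composition stays fixed.
    """
    rng = _rng(seed)
    n = config.target_n_components
    if config.half_shift_delta != 0.0:
        h = n // 2
        m2 = max(1.0, config.mean_rev_run * math.exp(-config.half_shift_delta))
        symbols = _draw_symbols(config, rng, h, config.mean_rev_run)
        symbols += _draw_symbols(config, rng, n - h, m2)
    else:
        symbols = _draw_symbols(config, rng, n, config.mean_rev_run)

    mean_dur = np.where(
        np.array(symbols) == "rev", config.rev_duration_s, config.idle_duration_s
    )
    durations = rng.exponential(mean_dur)
    gaps = rng.exponential(config.gap_s, size=n)
    gaps[0] = 0.0
    onsets = start_s + np.cumsum(gaps) + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    return [
        EventRecord(trial_id, sym, float(on), float(on + d))
        for sym, on, d in zip(symbols, onsets, durations)
    ]


def simulate_iid(
    proportions: Sequence[float],
    n: int,
    seed: int | np.random.Generator | None = None,
) -> SymbolSequence:
    """i.i.d. component draws with the given proportions over the alphabet.

    Used to map how the complexity metrics respond to component proportions
    alone, with all temporal structure removed.
    """
    p = np.asarray(proportions, dtype=float)
    if p.shape != (len(ALPHABET),) or (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"proportions must be a {len(ALPHABET)}-simplex vector")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    draws = rng.choice(len(ALPHABET), size=n, p=p)
    return SymbolSequence(tuple(ALPHABET[i] for i in draws))


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of a synthetic mating study.

    The copulation outcome of trial *i* is Bernoulli with
    ``logit p_i = beta0 + beta1 * metric_i`` where ``metric_i`` is the named
    complexity metric computed on the windowed events — so the logistic
    model fitted by the inference layer is correctly specified and its
    estimates can be checked against the generating coefficients.

    ``beta0`` defaults to a value calibrated so that, with the default
    grammar and ``beta1 = 4`` on normalized LZ, about 9 of 44 males
    copulate, matching the observed study size and event count.  Body-mass
    distributions default to the observed group summaries.
    """

    n_trials: int = 44
    beta0: float = -3.05
    beta1: float = 4.0
    metric: str = "lz_normalized"
    grammar: DisplayGrammarConfig = field(default_factory=DisplayGrammarConfig)
    log_rev_run_sd: float = 0.6  # between-male heterogeneity on log mean_rev_run
    male_mass_mean_g: float = 0.040
    male_mass_sd_g: float = 0.008
    female_mass_mean_g: float = 0.052
    female_mass_sd_g: float = 0.010
    latency_mean_s: float = 80.0
    n_components_sigma: float = 0.533  # lognormal spread of per-trial sequence length
    window_s: float = 300.0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if min(self.male_mass_sd_g, self.female_mass_sd_g, self.log_rev_run_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


def _trial_grammar(cfg: StudyConfig, rng: np.random.Generator, delta: float = 0.0) -> DisplayGrammarConfig:
    log_m = math.log(cfg.grammar.mean_rev_run) + rng.normal(0.0, cfg.log_rev_run_sd)
    m = max(1.0, math.exp(log_m))
    # per-trial sequence length: lognormal around the grammar target
    mu = math.log(cfg.grammar.target_n_components) - cfg.n_components_sigma**2 / 2.0
    n = max(10, int(round(rng.lognormal(mu, cfg.n_components_sigma))))
    return replace(cfg.grammar, mean_rev_run=m, target_n_components=n, half_shift_delta=delta)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > floor:
            return float(v)
    return float(floor)


def _simulate_trials(
    cfg: StudyConfig, rng: np.random.Generator, half_shift_delta: float
) -> tuple[list[TrialRecord], dict]:
    trials: list[TrialRecord] = []
    truth: dict = {
        "beta0": cfg.beta0,
        "beta1": cfg.beta1,
        "metric": cfg.metric,
        "mean_rev_run": [],
        "metric_values": [],
        "p_copulate": [],
    }
    for i in range(cfg.n_trials):
        tid = f"T{i + 1:03d}"
        grammar = _trial_grammar(cfg, rng)
        latency = float(rng.exponential(cfg.latency_mean_s))
        events = simulate_sequence(grammar, rng, trial_id=tid, start_s=latency)
        prof = complexity_profile(window_events(events, cfg.window_s), trial_id=tid)
        x = getattr(prof, cfg.metric)
        p = 1.0 / (1.0 + math.exp(-(cfg.beta0 + cfg.beta1 * x)))
        copulated = int(rng.random() < p)
        if copulated and half_shift_delta != 0.0:
            # plastic males: same grammar and length, runs shortened after the
            # count midpoint (bout composition unchanged)
            events = simulate_sequence(
                replace(grammar, half_shift_delta=half_shift_delta),
                rng,
                trial_id=tid,
                start_s=latency,
            )
        trials.append(
            TrialRecord(
                trial_id=tid,
                male_mass_g=_positive_normal(rng, cfg.male_mass_mean_g, cfg.male_mass_sd_g, 0.005),
                female_mass_g=_positive_normal(rng, cfg.female_mass_mean_g, cfg.female_mass_sd_g, 0.005),
                copulated=copulated,
                latency_s=events[0].onset_s,
                events=events,
            )
        )
        truth["mean_rev_run"].append(grammar.mean_rev_run)
        truth["metric_values"].append(float(x))
        truth["p_copulate"].append(p)
    return trials, truth


def simulate_study(
    config: StudyConfig | None = None,
    seed: int | np.random.Generator | None = None,
    max_resample: int = 10,
) -> tuple[list[TrialRecord], dict]:
    """Simulate a full mating study; returns trials plus the ground truth.

    Each trial draws body masses, a male-specific grammar (heterogeneous
    mean run length and sequence length), a timed event stream, and a
    copulation outcome from the logistic link on the named metric.  Studies
    where every outcome is identical are redrawn (up to ``max_resample``
    times) since the downstream logistic model is undefined for them.
    """
    cfg = config or StudyConfig()
    rng = _rng(seed)
    for _ in range(max_resample):
        trials, truth = _simulate_trials(cfg, rng, half_shift_delta=0.0)
        outcomes = {t.copulated for t in trials}
        if outcomes == {0, 1}:
            return trials, truth
    raise RuntimeError(f"all-{trials[0].copulated} outcomes in {max_resample} consecutive study draws")


def simulate_plastic_study(
    config: StudyConfig | None = None,
    half_shift_delta: float = 0.5,
    seed: int | np.random.Generator | None = None,
    max_resample: int = 10,
) -> tuple[list[TrialRecord], dict]:
    """Simulate a study in which copulating males display plastically.

    Copulating males' second-half grammar has its log mean rev-run length
    reduced by ``half_shift_delta`` (shorter runs, more transitions);
    non-copulating males are unshifted.  Feeds the power/size studies of the
    paired first/second-half tests.
    """
    cfg = config or StudyConfig()
    rng = _rng(seed)
    for _ in range(max_resample):
        trials, truth = _simulate_trials(cfg, rng, half_shift_delta=half_shift_delta)
        truth["half_shift_delta"] = half_shift_delta
        outcomes = {t.copulated for t in trials}
        if outcomes == {0, 1}:
            return trials, truth
    raise RuntimeError(f"all-{trials[0].copulated} outcomes in {max_resample} consecutive study draws")
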