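"""Complexity metrics and courtship-rate proxies for display sequences.

Three information-theoretic metrics are computed per trial:

* **LZ76 complexity** — the number of phrases in the exhaustive production
  history of Lempel & Ziv's 1976 copy-based parsing.  A sequence is scanned
  left to right; the current word is extended while it can still be
  reproduced by copying from the prior text (self-overlap allowed), and a
  new phrase begins when it cannot.  The final, possibly reproducible, word
  counts as one phrase.  Reported both raw (``c(n)``) and normalized by the
  asymptotic incompressibility bound ``n / log_k(n)``.
* **Shannon entropy** — of the empirical component proportions (order-free
  "evenness" of component usage), in bits.
* **First-order Markov entropy rate** — the expected conditional entropy of
  the next component given the current one under the plug-in transition
  matrix, in bits.  Sensitive to temporal patterning, not just proportions.

Two traditional rate proxies accompany them: the multi-modal courtship rate
(all signal components per second, with leg-taps counted in both the
vibratory and visual channels because they are produced coincident with an
idle) and the visual-only courtship rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .events import ALPHABET, EventRecord, SymbolSequence, events_to_sequence

__all__ = [
    "TransitionModel",
    "ComplexityProfile",
    "lz76_phrases",
    "lz_normalized",
    "shannon_entropy",
    "markov_entropy_rate",
    "transition_model",
    "courtship_rates",
    "complexity_profile",
    "half_split",
]

# single characters for C-speed substring search in the LZ parse
_CHAR_FOR = {label: chr(97 + i) for i, label in enumerate(ALPHABET)}


def _as_symbols(seq: SymbolSequence | Sequence[str]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    if isinstance(seq, SymbolSequence):
        return seq.symbols, seq.alphabet
    return tuple(seq), ALPHABET


def lz76_phrases(seq: SymbolSequence | Sequence[str]) -> int:
    """Number of phrases ``c(n)`` in the LZ76 exhaustive production history.

    The current word ``s[m:j+1]`` is reproducible from the prior text iff it
    occurs as a substring of ``s[0:j]`` — equivalently, a copy may start
    anywhere before ``m`` and run into the word itself, but must not use the
    word's final character.  A phrase closes at the first non-reproducible
    extension; the trailing word always counts as one phrase.

    Examples: a homogeneous sequence of length >= 2 has c = 2 (first symbol
    is new, the remainder copies it); a sequence of n distinct symbols has
    c = n.
    """
    symbols, alphabet = _as_symbols(seq)
    n = len(symbols)
    if n < 1:
        raise ValueError("sequence must contain at least one symbol")
    chars = {lab: chr(97 + i) for i, lab in enumerate(alphabet)}
    s = "".join(chars[x] for x in symbols)
    c = 0
    m = 0
    while m < n:
        j = m
        # extend while s[m:j+1] is reproducible from s[0:j]
        while j < n and s.find(s[m : j + 1], 0, j) >= 0:
            j += 1
        c += 1
        if j == n:  # trailing (possibly reproducible) word
            break
        m = j + 1
    return c


def lz_normalized(
    seq: SymbolSequence | Sequence[str],
    normalization: Literal["asymptotic"] = "asymptotic",
) -> float:
    """LZ76 phrase count rescaled by the asymptotic bound: ``c(n) log_k(n) / n``.

    Makes sequences of different lengths comparable: an incompressible
    sequence tends to 1, a perfectly repetitive one to 0.  ``normalization``
    is an extension point for alternative rescalings behind the same
    interface.
    """
    symbols, alphabet = _as_symbols(seq)
    n = len(symbols)
    if n < 2:
        raise ValueError("normalized LZ needs a sequence of length >= 2")
    if normalization != "asymptotic":
        raise ValueError(f"unknown normalization {normalization!r}")
    k = len(alphabet)
    return lz76_phrases(seq) * (math.log(n) / math.log(k)) / n


def _proportions(symbols: Sequence[str], alphabet: Sequence[str]) -> np.ndarray:
    idx = {lab: i for i, lab in enumerate(alphabet)}
    counts = np.bincount([idx[x] for x in symbols], minlength=len(alphabet))
    return counts / counts.sum()


def shannon_entropy(seq: SymbolSequence | Sequence[str], base: float = 2.0) -> float:
    """Shannon entropy of the empirical component proportions (0 log 0 = 0)."""
    symbols, alphabet = _as_symbols(seq)
    if len(symbols) < 1:
        raise ValueError("sequence must contain at least one symbol")
    p = _proportions(symbols, alphabet)
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


@dataclass(frozen=True)
class TransitionModel:
    """First-order transition counts, row-stochastic probabilities, and
    empirical source-state weights for a symbol sequence."""

    alphabet: tuple[str, ...]
    counts: np.ndarray  # (k, k) ints, counts[i, j] = transitions i -> j
    probs: np.ndarray  # row-stochastic where the row has any mass; else 0
    source_weights: np.ndarray  # empirical frequency of each source state

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    def stationary_distribution(self) -> np.ndarray:
        """Leading left eigenvector of the transition matrix (unit simplex).

        Rows with no observed transitions are treated as uniform so the
        matrix is stochastic; for short sequences prefer ``source_weights``.
        """
        P = self.probs.copy()
        empty = P.sum(axis=1) == 0
        P[empty] = 1.0 / P.shape[0]
        vals, vecs = np.linalg.eig(P.T)
        v = np.real(vecs[:, np.argmax(np.real(vals))])
        v = np.abs(v)
        return v / v.sum()


def transition_model(seq: SymbolSequence | Sequence[str]) -> TransitionModel:
    """Estimate the plug-in first-order transition model from adjacent pairs."""
    symbols, alphabet = _as_symbols(seq)
    if len(symbols) < 2:
        raise ValueError("transition model needs a sequence of length >= 2")
    k = len(alphabet)
    idx = {lab: i for i, lab in enumerate(alphabet)}
    codes = np.array([idx[x] for x in symbols])
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (codes[:-1], codes[1:]), 1)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row[:, None] > 0, counts / np.where(row[:, None] > 0, row[:, None], 1), 0.0)
    weights = row / row.sum()
    return TransitionModel(tuple(alphabet), counts, probs, weights)


def markov_entropy_rate(
    seq: SymbolSequence | Sequence[str],
    base: float = 2.0,
    weights: Literal["empirical", "stationary"] = "empirical",
) -> float:
    """First-order Markov entropy rate: ``-sum_i w_i sum_j p_ij log p_ij``.

    ``w_i`` defaults to the empirical source frequencies (symbol frequency
    among the first n-1 positions), which is robust for short sequences;
    ``weights="stationary"`` uses the stationary distribution of the
    estimated chain instead.  Rows with no observed transitions contribute 0.
    """
    tm = transition_model(seq)
    P = tm.probs
    with np.errstate(invalid="ignore", divide="ignore"):
        logP = np.where(P > 0, np.log(P) / np.log(base), 0.0)
    row_entropy = -(P * logP).sum(axis=1)
    w = tm.source_weights if weights == "empirical" else tm.stationary_distribution()
    return float((w * row_entropy).sum())


@dataclass(frozen=True)
class ComplexityProfile:
    """Per-trial vector of complexity metrics and courtship-rate proxies."""

    trial_id: str
    lz_phrases: int
    lz_normalized: float
    entropy_bits: float
    entropy_rate_bits: float
    multimodal_rate: float
    visual_rate: float
    n_components: int
    courtship_duration_s: float
    usable: bool = True
    exclusion_reason: str | None = None

    METRIC_FIELDS = (
        "lz_normalized",
        "entropy_bits",
        "entropy_rate_bits",
        "multimodal_rate",
        "visual_rate",
    )


def courtship_rates(
    events: Sequence[EventRecord],
    visual_labels: frozenset[str] | set[str] = frozenset({"leg_tap"}),
    multimodal_rule: Literal["double_count_legtap", "single_count"] = "double_count_legtap",
) -> tuple[float, float]:
    """Multi-modal and visual-only courtship rates (components per second).

    Courtship duration is the span from the first event's onset to the last
    event's offset within the analysis window.  Under the default counting
    rule each leg-tap contributes twice to the multi-modal count — once as a
    vibratory and once as a visual component, since the tap is produced
    coincident with an idle vibration; ``multimodal_rule="single_count"``
    counts every event once.  ``visual_labels`` defaults to ``{leg_tap}``;
    ``{"idle", "leg_tap"}`` treats all visual-associated components as visual.
    """
    if not events:
        raise ValueError("courtship rates need at least one event")
    duration = events[-1].offset_s - events[0].onset_s
    if duration <= 0:
        raise ValueError("courtship duration is zero: cannot form a rate")
    n = len(events)
    n_tap = sum(1 for e in events if e.component == "leg_tap")
    n_visual = sum(1 for e in events if e.component in visual_labels)
    multimodal = (n + n_tap) if multimodal_rule == "double_count_legtap" else n
    return multimodal / duration, n_visual / duration


def complexity_profile(
    events: Sequence[EventRecord],
    trial_id: str | None = None,
    visual_labels: frozenset[str] | set[str] = frozenset({"leg_tap"}),
    multimodal_rule: Literal["double_count_legtap", "single_count"] = "double_count_legtap",
    entropy_base: float = 2.0,
    entropy_rate_weights: Literal["empirical", "stationary"] = "empirical",
) -> ComplexityProfile:
    """All five per-trial statistics from one windowed event list.

    Trials with fewer than two events cannot support the sequence metrics
    and are returned flagged unusable (with the reason) rather than raising,
    so study-level code can log and exclude them.
    """
    tid = trial_id if trial_id is not None else (events[0].trial_id if events else "?")
    if len(events) < 2:
        return ComplexityProfile(
            trial_id=tid,
            lz_phrases=0,
            lz_normalized=float("nan"),
            entropy_bits=float("nan"),
            entropy_rate_bits=float("nan"),
            multimodal_rate=float("nan"),
            visual_rate=float("nan"),
            n_components=len(events),
            courtship_duration_s=0.0,
            usable=False,
            exclusion_reason=f"{len(events)} event(s) in window; need >= 2",
        )
    seq = events_to_sequence(events)
    mm, vis = courtship_rates(events, visual_labels, multimodal_rule)
    return ComplexityProfile(
        trial_id=tid,
        lz_phrases=lz76_phrases(seq),
        lz_normalized=lz_normalized(seq),
        entropy_bits=shannon_entropy(seq, base=entropy_base),
        entropy_rate_bits=markov_entropy_rate(seq, base=entropy_base, weights=entropy_rate_weights),
        multimodal_rate=mm,
        visual_rate=vis,
        n_components=seq.n,
        courtship_duration_s=events[-1].offset_s - events[0].onset_s,
    )


class HalfSplitError(ValueError):
    """Raised when a trial cannot be split into two usable halves."""


def half_split(
    events: Sequence[EventRecord],
    rule: Literal["time", "count"] = "time",
) -> tuple[list[EventRecord], list[EventRecord]]:
    """Split windowed events into first/second halves of the courtship span.

    Under the default ``time`` rule the split point is the temporal midpoint
    ``t0 + duration/2``; events with onset strictly before the midpoint form
    the first half (an onset exactly at the midpoint goes to the second
    half).  ``count`` splits at the middle of the component sequence
    instead.  Trials with fewer than four events, or whose halves would be
    empty, raise :class:`HalfSplitError` so callers can exclude them with a
    logged reason.
    """
    if len(events) < 4:
        raise HalfSplitError(f"{len(events)} events; need >= 4 to split")
    if rule == "time":
        t0 = events[0].onset_s
        midpoint = t0 + (events[-1].offset_s - t0) / 2.0
        first = [e for e in events if e.onset_s < midpoint]
        second = [e for e in events if e.onset_s >= midpoint]
    else:
        h = len(events) // 2
        first, second = list(events[:h]), list(events[h:])
    if not first or not second:
        raise HalfSplitError("temporal midpoint leaves an empty half")
    return first, second
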