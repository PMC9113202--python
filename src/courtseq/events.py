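"""Event tables, analysis windowing, and symbol-sequence encoding.

A courtship trial is scored as an ordered list of classified signal
components (``rev``, ``idle``, ``leg_tap``), each with an onset and offset
in seconds.  All downstream analyses operate either on the windowed event
list (rates, durations) or on the bare label sequence (complexity metrics).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

#: The fixed three-component display alphabet. ``rev`` and ``idle`` are
#: substrate-borne vibratory components; ``leg_tap`` is a dynamic visual
#: component produced coincident with idles.
ALPHABET: tuple[str, ...] = ("rev", "idle", "leg_tap")

#: Default analysis window: the first five minutes of courtship.
DEFAULT_WINDOW_S: float = 300.0

EVENT_COLUMNS = ("trial_id", "component", "onset_s", "offset_s")
TRIAL_COLUMNS = ("trial_id", "male_mass_g", "female_mass_g", "copulated", "latency_s")


class EventValidationError(ValueError):
    """Raised when an event table row violates the schema."""


@dataclass(frozen=True)
class EventRecord:
    """One classified signal component within a trial."""

    trial_id: str
    component: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.component not in ALPHABET:
            raise EventValidationError(
                f"unknown component label {self.component!r} "
                f"(trial {self.trial_id!r}); expected one of {ALPHABET}"
            )
        if self.offset_s < self.onset_s:
            raise EventValidationError(
                f"offset {self.offset_s} precedes onset {self.onset_s} "
                f"(trial {self.trial_id!r})"
            )
        if self.onset_s < 0:
            raise EventValidationError(
                f"negative onset {self.onset_s} (trial {self.trial_id!r})"
            )


@dataclass
class TrialRecord:
    """One mating trial: subject masses, outcome, and the event stream."""

    trial_id: str
    male_mass_g: float
    female_mass_g: float
    copulated: int
    latency_s: float
    events: list[EventRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.copulated not in (0, 1):
            raise ValueError(f"copulated must be 0/1, got {self.copulated!r}")
        if self.male_mass_g <= 0 or self.female_mass_g <= 0:
            raise ValueError(f"non-positive body mass in trial {self.trial_id!r}")

    @property
    def mass_ratio(self) -> float:
        """Female/male body-mass ratio."""
        return self.female_mass_g / self.male_mass_g


@dataclass(frozen=True)
class SymbolSequence:
    """An ordered run of component labels over the 3-letter alphabet."""

    symbols: tuple[str, ...]
    alphabet: tuple[str, ...] = ALPHABET

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError("a symbol sequence needs at least one symbol")
        bad = set(self.symbols) - set(self.alphabet)
        if bad:
            raise ValueError(f"symbols outside alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n(self) -> int:
        return len(self.symbols)

    @property
    def k(self) -> int:
        return len(self.alphabet)


def _sort_events(events: Iterable[EventRecord]) -> list[EventRecord]:
    # deterministic tie-break: onset, then offset, then label
    return sorted(events, key=lambda e: (e.onset_s, e.offset_s, e.component))


def read_events(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    label_map: Mapping[str, str] | None = None,
) -> list[EventRecord]:
    """Read an event table (CSV) into sorted, validated :class:`EventRecord`.

    Parameters
    ----------
    path
        CSV file with header ``trial_id,component,onset_s,offset_s``.
    column_map, label_map
        Optional renamings applied on the way in (external column name ->
        canonical name; external label spelling -> canonical label).  Used by
        the deposit import adapter so third-party files are never hand-edited.
    """
    column_map = dict(column_map or {})
    label_map = dict(label_map or {})
    records: list[EventRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EventValidationError(f"{path}: empty file, expected a header row")
        fields = [column_map.get(c, c) for c in reader.fieldnames]
        missing = set(EVENT_COLUMNS) - set(fields)
        if missing:
            raise EventValidationError(f"{path}: missing columns {sorted(missing)}")
        for i, raw in enumerate(reader, start=2):
            row = {column_map.get(k, k): v for k, v in raw.items()}
            label = row["component"].strip()
            label = label_map.get(label, label)
            try:
                records.append(
                    EventRecord(
                        trial_id=row["trial_id"].strip(),
                        component=label,
                        onset_s=float(row["onset_s"]),
                        offset_s=float(row["offset_s"]),
                    )
                )
            except (EventValidationError, ValueError) as exc:
                raise EventValidationError(f"{path}: row {i}: {exc}") from exc
    return _sort_events(records)


def write_events(events: Iterable[EventRecord], path: str | Path) -> None:
    """Write events as the canonical CSV (round-trips with :func:`read_events`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for e in events:
            writer.writerow([e.trial_id, e.component, repr(e.onset_s), repr(e.offset_s)])


def load_import_mapping(path: str | Path) -> dict:
    """Load a YAML import-adapter config with ``columns:`` and ``labels:`` maps.

    This documents, in a versionable text file, how an external deposit's
    column names and label spellings map onto the canonical schema.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return {"columns": cfg.get("columns", {}) or {}, "labels": cfg.get("labels", {}) or {}}


def read_trials(
    trials_path: str | Path, events_path: str | Path | None = None
) -> list[TrialRecord]:
    """Read the trial metadata CSV, optionally attaching events by trial id."""
    events_by_trial: dict[str, list[EventRecord]] = {}
    if events_path is not None:
        for e in read_events(events_path):
            events_by_trial.setdefault(e.trial_id, []).append(e)
    trials: list[TrialRecord] = []
    with open(trials_path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(TRIAL_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise EventValidationError(f"{trials_path}: missing columns {sorted(missing)}")
        for row in reader:
            tid = row["trial_id"].strip()
            trials.append(
                TrialRecord(
                    trial_id=tid,
                    male_mass_g=float(row["male_mass_g"]),
                    female_mass_g=float(row["female_mass_g"]),
                    copulated=int(row["copulated"]),
                    latency_s=float(row["latency_s"]),
                    events=_sort_events(events_by_trial.get(tid, [])),
                )
            )
    return trials


def write_trials(trials: Iterable[TrialRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_COLUMNS)
        for t in trials:
            writer.writerow(
                [t.trial_id, repr(t.male_mass_g), repr(t.female_mass_g), t.copulated, repr(t.latency_s)]
            )


def window_events(
    events: Sequence[EventRecord], window_s: float = DEFAULT_WINDOW_S
) -> list[EventRecord]:
    """Retain events whose onset falls in the first ``window_s`` of courtship.

    The window is anchored at the onset of the first signal component (the
    start of courtship, not of the trial): an event is kept iff its onset
    lies in the half-open interval ``[t0, t0 + window_s)``.  Offsets may
    overhang the window.  Idempotent by construction.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not events:
        return []
    t0 = events[0].onset_s
    return [e for e in events if e.onset_s < t0 + window_s]


def events_to_sequence(events: Sequence[EventRecord]) -> SymbolSequence:
    """Encode sorted events as their temporal sequence of component labels."""
    if not events:
        raise ValueError("no courtship observed: cannot encode an empty event list")
    return SymbolSequence(tuple(e.component for e in events))
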