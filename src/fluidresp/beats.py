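"""Beat-level dynamic preload indices.

Pulse pressure variation (PPV) and stroke volume variation (SVV) quantify
the respiratory modulation of the arterial pulse under positive-pressure
ventilation. Both are computed per respiratory cycle from the extreme
beat values,

    PPV = 100 * (PPmax - PPmin) / ((PPmax + PPmin) / 2)   [%]

and analogously for SVV, then averaged over a small number of consecutive
cycles (three, by default) to damp beat-to-beat noise. The PEEP-challenge
deltas are the signed differences between the reading during the challenge
(T2) and the zero-PEEP baseline (T1):

    dPPV = PPV(T2) - PPV(T1),    dSVV = SVV(T2) - SVV(T1).

This module deliberately does no waveform processing: it consumes already
beat-detected pulse pressures and stroke volumes. Arrhythmic-beat rejection
is out of scope (the clinical protocol this models excludes arrhythmia);
cycles with fewer than two beats are flagged invalid and excluded rather
than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

TIME_POINTS = ("T1", "T2", "T3", "T4")

__all__ = [
    "BeatSeries",
    "CycleWindow",
    "DynamicIndexReading",
    "IndexDelta",
    "segment_cycles",
    "ppv_one_cycle",
    "svv_one_cycle",
    "averaged_reading",
    "peep_delta",
    "read_beats_csv",
]


@dataclass(frozen=True)
class BeatSeries:
    """Per-beat pulse pressure and stroke volume with respiratory-cycle marks.

    Parameters
    ----------
    beat_time : array of float
        Beat times in seconds, strictly increasing.
    pulse_pressure : array of float
        Pulse pressure per beat in mmHg, strictly positive.
    stroke_volume : array of float
        Stroke volume per beat in mL, strictly positive.
    cycle_marks : array of float
        Start times of respiratory cycles in seconds, strictly increasing.
        Consecutive marks delimit half-open cycle windows ``[m_k, m_{k+1})``;
        the final mark is the end boundary of the last cycle.
    """

    beat_time: np.ndarray
    pulse_pressure: np.ndarray
    stroke_volume: np.ndarray
    cycle_marks: np.ndarray

    def __post_init__(self) -> None:
        for name in ("beat_time", "pulse_pressure", "stroke_volume", "cycle_marks"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.beat_time.size == 0:
            raise ValueError("empty beat series")
        n = self.beat_time.size
        if self.pulse_pressure.size != n or self.stroke_volume.size != n:
            raise ValueError("beat_time, pulse_pressure and stroke_volume must have equal length")
        if np.any(np.diff(self.beat_time) <= 0):
            raise ValueError("beat_time must be strictly increasing")
        if np.any(self.pulse_pressure <= 0):
            raise ValueError("pulse_pressure values must be positive")
        if np.any(self.stroke_volume <= 0):
            raise ValueError("stroke_volume values must be positive")
        if self.cycle_marks.size and np.any(np.diff(self.cycle_marks) <= 0):
            raise ValueError("cycle_marks must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.beat_time.size)


@dataclass(frozen=True)
class CycleWindow:
    """One respiratory-cycle window: beat indices in ``[start, end)``."""

    index: int
    start: float
    end: float
    beat_indices: np.ndarray

    @property
    def valid(self) -> bool:
        """A window needs at least two beats to define a max/min excursion."""
        return self.beat_indices.size >= 2


@dataclass(frozen=True)
class DynamicIndexReading:
    """PPV/SVV in percent averaged over ``n_cycles_averaged`` cycles."""

    ppv: float
    svv: float
    n_cycles_averaged: int
    time_point_label: str

    def __post_init__(self) -> None:
        if self.time_point_label not in TIME_POINTS:
            raise ValueError(f"time_point_label must be one of {TIME_POINTS}")
        if self.ppv < 0 or self.svv < 0:
            raise ValueError("ppv and svv must be non-negative")
        if self.n_cycles_averaged < 1:
            raise ValueError("n_cycles_averaged must be >= 1")


@dataclass(frozen=True)
class IndexDelta:
    """PEEP-challenge-induced change, T2 minus T1, in percentage points."""

    delta_ppv: float
    delta_svv: float


def segment_cycles(beats: BeatSeries) -> list[CycleWindow]:
    """Assign beats to respiratory-cycle windows.

    Windows are half-open ``[mark_k, mark_{k+1})``: a beat exactly on a mark
    belongs to the later cycle. Beats before the first or at/after the last
    mark are unassigned. Windows with fewer than two beats are returned with
    ``valid == False`` and must be excluded from index computation.
    """
    marks = beats.cycle_marks
    if marks.size == 0:
        raise ValueError("cycle_marks is empty; cannot segment cycles")
    if marks.size < 2:
        return []
    # searchsorted(side="right") puts a beat at a mark into the later window
    bucket = np.searchsorted(marks, beats.beat_time, side="right") - 1
    windows = []
    for k in range(marks.size - 1):
        idx = np.nonzero(bucket == k)[0]
        windows.append(CycleWindow(index=k, start=float(marks[k]), end=float(marks[k + 1]), beat_indices=idx))
    return windows


def _variation_percent(values: Sequence[float], what: str) -> float:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"{what}: need at least 2 beats in a cycle, got {v.size}")
    if np.any(v <= 0):
        raise ValueError(f"{what}: all beat values must be positive")
    hi, lo = float(v.max()), float(v.min())
    return 100.0 * (hi - lo) / ((hi + lo) / 2.0)


def ppv_one_cycle(pulse_pressures: Sequence[float]) -> float:
    """PPV (%) of one respiratory cycle: 100*(PPmax-PPmin)/((PPmax+PPmin)/2)."""
    return _variation_percent(pulse_pressures, "ppv_one_cycle")


def svv_one_cycle(stroke_volumes: Sequence[float]) -> float:
    """SVV (%) of one respiratory cycle; same normalized-range formula as PPV."""
    return _variation_percent(stroke_volumes, "svv_one_cycle")


def averaged_reading(beats: BeatSeries, k: int = 3, time_point_label: str = "T1") -> DynamicIndexReading:
    """Average per-cycle PPV/SVV over the first ``k`` consecutive valid cycles.

    The monitor-style reading averages k *consecutive* valid respiratory
    cycles (default 3). A run broken by an invalid (<2-beat) window does not
    count; the first unbroken run of length k is used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    windows = segment_cycles(beats)
    run: list[CycleWindow] = []
    chosen: list[CycleWindow] | None = None
    for w in windows:
        if w.valid:
            run.append(w)
            if len(run) == k:
                chosen = run
                break
        else:
            run = []
    if chosen is None:
        n_valid = sum(w.valid for w in windows)
        raise ValueError(
            f"need {k} consecutive valid cycles, found at most "
            f"{len(run)} consecutive ({n_valid} valid of {len(windows)} total)"
        )
    ppv = float(np.mean([ppv_one_cycle(beats.pulse_pressure[w.beat_indices]) for w in chosen]))
    svv = float(np.mean([svv_one_cycle(beats.stroke_volume[w.beat_indices]) for w in chosen]))
    return DynamicIndexReading(ppv=ppv, svv=svv, n_cycles_averaged=k, time_point_label=time_point_label)


def peep_delta(t1: DynamicIndexReading, t2: DynamicIndexReading) -> IndexDelta:
    """Signed PEEP-challenge change: reading at T2 minus baseline at T1."""
    if t1.time_point_label != "T1" or t2.time_point_label != "T2":
        raise ValueError(
            f"peep_delta expects readings labeled T1 and T2, got "
            f"{t1.time_point_label!r} and {t2.time_point_label!r}"
        )
    return IndexDelta(delta_ppv=t2.ppv - t1.ppv, delta_svv=t2.svv - t1.svv)


def read_beats_csv(path, marks_path=None) -> BeatSeries:
    """Read a beat-level CSV into a :class:`BeatSeries`.

    The beat file must have columns ``beat_time_s, pulse_pressure_mmHg,
    stroke_volume_mL``. Cycle marks come either from a ``resp_cycle_id``
    column (marks are then the first beat time of each cycle, with a sentinel
    end mark one median beat-interval after the last beat) or from a separate
    marks file with a ``cycle_start_s`` column.
    """
    df = pd.read_csv(path)
    required = ["beat_time_s", "pulse_pressure_mmHg", "stroke_volume_mL"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"beat CSV missing columns: {missing}")
    t = df["beat_time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("beat_time_s must be strictly increasing")
    if marks_path is not None:
        marks = pd.read_csv(marks_path)["cycle_start_s"].to_numpy(dtype=float)
    elif "resp_cycle_id" in df.columns:
        cyc = df["resp_cycle_id"].to_numpy()
        first = np.r_[True, cyc[1:] != cyc[:-1]]
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        marks = np.r_[t[first], t[-1] + dt]
    else:
        raise ValueError("provide a resp_cycle_id column or a marks file with cycle_start_s")
    return BeatSeries(
        beat_time=t,
        pulse_pressure=df["pulse_pressure_mmHg"].to_numpy(dtype=float),
        stroke_volume=df["stroke_volume_mL"].to_numpy(dtype=float),
        cycle_marks=marks,
    )
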