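"""Gray-zone (inconclusive-range) analysis of a diagnostic predictor.

Two constructions are implemented side by side, because they answer
slightly different questions and the literature uses both:

* ``bootstrap_ci`` — resample the cohort (stratified by responder status)
  1,000 times, recompute the Youden-optimal cutoff in each replicate, and
  take the 2.5th-97.5th percentile interval of the resampled cutoffs: the
  statistical uncertainty of the optimal threshold itself.
* ``split_curve`` — split the ROC curve into its sensitivity and
  specificity branches and mark the predictor values where neither
  Se >= 90% nor Sp >= 90% holds: the range where a single measurement
  cannot rule fluid responsiveness in or out with 10% diagnostic tolerance.

Both zones are closed intervals; the number of cohort patients falling
inside (inclusive) quantifies how often the test is uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roc import RocCurve, empirical_roc, youden_cutoff

__all__ = [
    "GrayZone",
    "bootstrap_thresholds",
    "gray_zone_from_bootstrap",
    "split_curve_zone",
    "count_inside",
]


@dataclass(frozen=True)
class GrayZone:
    """Inconclusive interval [low, high] of a predictor.

    An empty zone is represented with ``low == high`` and ``is_empty=True``;
    counting patients inside then counts exact ties only.
    """

    method: str  # "bootstrap_ci" or "split_curve"
    low: float
    high: float
    is_empty: bool = False
    n_patients_inside: int | None = None
    n_bootstrap: int | None = None
    se_floor: float | None = None
    sp_floor: float | None = None

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("gray zone requires low <= high")

    @property
    def width(self) -> float:
        return self.high - self.low


def bootstrap_thresholds(scores, labels, B: int = 1000, seed=None) -> np.ndarray:
    """Youden-optimal cutoffs of ``B`` class-stratified bootstrap resamples.

    Each replicate resamples responders and non-responders separately with
    replacement, preserving the group sizes (so no replicate can lose a
    class), and recomputes the Youden cutoff. Deterministic under a fixed
    seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    out = np.empty(B)
    resampled_labels = np.r_[np.ones(pos.size, dtype=bool), np.zeros(neg.size, dtype=bool)]
    for b in range(B):
        s = np.r_[rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        out[b] = youden_cutoff(empirical_roc(s, resampled_labels)).cutoff
    return out


def gray_zone_from_bootstrap(thresholds, level: float = 0.95) -> GrayZone:
    """Percentile interval of bootstrap cutoffs (linear-interpolation quantiles)."""
    thresholds = np.asarray(thresholds, dtype=float)
    tail = 100.0 * (1.0 - level) / 2.0
    low, high = np.percentile(thresholds, [tail, 100.0 - tail], method="linear")
    return GrayZone(
        method="bootstrap_ci",
        low=float(low),
        high=float(high),
        is_empty=bool(low == high),
        n_bootstrap=int(thresholds.size),
    )


def split_curve_zone(curve: RocCurve, se_floor: float = 0.90, sp_floor: float = 0.90) -> GrayZone:
    """Inconclusive zone from the sensitivity/specificity branch curves.

    ``low`` is the largest cutoff still giving Se >= se_floor (sensitivity
    decreases with the cutoff) and ``high`` the smallest cutoff giving
    Sp >= sp_floor; between them neither criterion holds. If the branches
    cross (high <= low) every value is conclusive and the zone is empty,
    collapsed to the crossing midpoint.
    """
    for name, f in (("se_floor", se_floor), ("sp_floor", sp_floor)):
        if not 0.0 < f <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1]")
    ok_se = curve.sensitivity >= se_floor
    ok_sp = curve.specificity >= sp_floor
    low = curve.thresholds[ok_se][-1] if ok_se.any() else -np.inf
    high = curve.thresholds[ok_sp][0] if ok_sp.any() else np.inf
    if high <= low:
        mid = float((low + high) / 2.0)
        return GrayZone(
            method="split_curve", low=mid, high=mid, is_empty=True,
            se_floor=se_floor, sp_floor=sp_floor,
        )
    return GrayZone(
        method="split_curve", low=float(low), high=float(high), is_empty=False,
        se_floor=se_floor, sp_floor=sp_floor,
    )


def count_inside(scores, zone: GrayZone) -> int:
    """Number of patients whose predictor value lies in [low, high], inclusive."""
    scores = np.asarray(scores, dtype=float)
    return int(np.count_nonzero((scores >= zone.low) & (scores <= zone.high)))
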