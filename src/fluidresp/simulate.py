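"""Synthetic cohorts and beat series for the PEEP-challenge analysis.

No patient-level data from the underlying study population are public, so
every downstream stage (responder classification, ROC/gray-zone analysis,
group statistics) is exercised on synthetic cohorts whose group structure
matches the published summary statistics: 18 fluid responders and 22
non-responders, with each hemodynamic/respiratory variable normal within
its group at the printed per-time-point mean and SD.

Two features of the printed summaries constrain the joint distribution:

* The change columns (T2-T1 and T4-T3) are printed with their own SDs.
  Given the marginal SDs s1, s2 and the change SD sd, the within-patient
  correlation of a variable across the pair is implied exactly:
  corr = (s1^2 + s2^2 - sd^2) / (2 s1 s2). The generator uses these
  implied correlations (all lie inside (-1, 1) for the packaged defaults)
  so that simulated deltas reproduce the printed change distributions —
  e.g. responder dSVV ~ Normal(2.3, 1.7). Deltas are always *computed*
  from the drawn T1/T2 values, never drawn separately.
* The PPV-SVV cross-correlation is unreported; both indices reflect the
  same cyclic preload variation, so a configurable common rho (default
  0.6) is applied between PPV and SVV within each challenge phase.

Beat-level series realize a prescribed PPV/SVV as a sinusoidal respiratory
modulation of baseline pulse pressure / stroke volume:

    PP_i = PP0 * (1 + (target_ppv/200) * sin(2 pi f_resp t_i + phase)) + noise

so that with noise off and beats sampling the modulation extremes the
per-cycle index recovers the target exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .beats import BeatSeries, averaged_reading
from .responder import RESPONDER_THRESHOLD_PERCENT
from .roc import empirical_roc

logger = logging.getLogger(__name__)

GROUPS = ("responder", "nonresponder")
TIME_POINTS = ("T1", "T2", "T3", "T4")
#: challenge phases: the PEEP challenge spans (T1, T2), fluid loading (T3, T4)
PHASE_PAIRS = (("T1", "T2"), ("T3", "T4"))
DYNAMIC_INDEX_VARIABLES = ("PPV", "SVV")

__all__ = [
    "GroupDistributionSpec",
    "ChangeSpec",
    "CohortSpec",
    "BeatSimConfig",
    "default_distributions",
    "default_changes",
    "load_distribution_csv",
    "implied_pair_correlation",
    "generate_cohort",
    "generate_beats",
    "end_to_end_cohort",
    "binormal_auc",
    "mean_auc_over_replicates",
]


@dataclass(frozen=True)
class GroupDistributionSpec:
    """Normal parameters of one variable at one time point in one group."""

    group: str
    variable: str
    time_point: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.time_point not in TIME_POINTS:
            raise ValueError(f"time_point must be one of {TIME_POINTS}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class ChangeSpec:
    """Printed mean/SD of a within-patient change (interval 'T2-T1' or 'T4-T3')."""

    group: str
    variable: str
    interval: str
    mean: float
    sd: float


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation settings (defaults: the 18/22 study split)."""

    n_responders: int = 18
    n_nonresponders: int = 22
    correlation_within_patient: float = 0.6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ValueError("both group sizes must be >= 1")
        if not -1.0 < self.correlation_within_patient < 1.0:
            raise ValueError("correlation_within_patient must lie in (-1, 1)")


@dataclass(frozen=True)
class BeatSimConfig:
    """Beat-series simulation settings.

    ``heart_rate / resp_rate`` is the number of beats per respiratory cycle
    (about 6 under the study's ventilation settings); it must be at least 2
    or a cycle cannot resolve a max/min excursion. ``phase`` is "random"
    (offset drawn per series) or "aligned" (beats pinned to the modulation
    extremes; exact index recovery when beats-per-cycle is an even integer).
    """

    target_ppv: float
    target_svv: float
    baseline_pp: float = 50.0
    baseline_sv: float = 65.0
    heart_rate: float = 78.0
    resp_rate: float = 13.0
    noise_sd: float = 0.0
    n_cycles: int = 5
    seed: int | None = None
    phase: str = "random"

    def __post_init__(self) -> None:
        if self.heart_rate / self.resp_rate < 2.0:
            raise ValueError("heart_rate/resp_rate must be >= 2 to resolve a respiratory cycle")
        for name in ("target_ppv", "target_svv"):
            v = getattr(self, name)
            if not 0.0 <= v < 100.0:
                raise ValueError(f"{name} must lie in [0, 100)")
        if self.phase not in ("random", "aligned"):
            raise ValueError("phase must be 'random' or 'aligned'")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def _data_path(name: str):
    return resources.files("fluidresp.data").joinpath(name)


def load_distribution_csv(path) -> list[GroupDistributionSpec]:
    """Read a ``group,variable,time_point,mean,sd`` CSV of distribution specs."""
    df = pd.read_csv(path)
    return [
        GroupDistributionSpec(r.group, r.variable, r.time_point, float(r.mean), float(r.sd))
        for r in df.itertuples()
    ]


def default_distributions() -> list[GroupDistributionSpec]:
    """Packaged per-group, per-time-point normal parameters (study Tables 2-3)."""
    with resources.as_file(_data_path("default_distributions.csv")) as p:
        return load_distribution_csv(p)


def default_changes() -> list[ChangeSpec]:
    """Packaged change-column (T2-T1, T4-T3) means/SDs (study Tables 2-3)."""
    with resources.as_file(_data_path("default_changes.csv")) as p:
        df = pd.read_csv(p)
    return [
        ChangeSpec(r.group, r.variable, r.interval, float(r.mean), float(r.sd))
        for r in df.itertuples()
    ]


def implied_pair_correlation(sd1: float, sd2: float, sd_change: float) -> float:
    """Within-patient correlation implied by the marginal and change SDs.

    From var(X2 - X1) = s1^2 + s2^2 - 2 r s1 s2. Returns 0 when either
    marginal SD is 0 (the pair is then degenerate anyway); the result is
    clipped to (-0.999, 0.999) to keep the joint covariance well posed.
    """
    if sd1 == 0.0 or sd2 == 0.0:
        return 0.0
    r = (sd1**2 + sd2**2 - sd_change**2) / (2.0 * sd1 * sd2)
    return float(np.clip(r, -0.999, 0.999))


def _spec_lookup(dists) -> dict[tuple[str, str, str], GroupDistributionSpec]:
    out: dict[tuple[str, str, str], GroupDistributionSpec] = {}
    for d in dists:
        key = (d.group, d.variable, d.time_point)
        if key in out:
            raise ValueError(f"duplicate distribution spec for {key}")
        out[key] = d
    return out


def _change_lookup(changes) -> dict[tuple[str, str, str], ChangeSpec]:
    return {(c.group, c.variable, c.interval): c for c in (changes or [])}


def _group_mean_cov(group, variables, time_points, dist_map, change_map, rho):
    """Mean vector and covariance over the (variable, time_point) grid."""
    labels = [(v, t) for v in variables for t in time_points]
    d = len(labels)
    mean = np.empty(d)
    sd = np.empty(d)
    for i, (v, t) in enumerate(labels):
        key = (group, v, t)
        if key not in dist_map:
            raise KeyError(f"missing distribution spec for {key}")
        mean[i] = dist_map[key].mean
        sd[i] = dist_map[key].sd
    corr = np.eye(d)
    for i, (vi, ti) in enumerate(labels):
        for j, (vj, tj) in enumerate(labels):
            if j <= i:
                continue
            same_phase = any(ti in pair and tj in pair for pair in PHASE_PAIRS)
            if not same_phase:
                continue
            if vi == vj:
                interval = f"{max(ti, tj)}-{min(ti, tj)}"  # 'T2-T1' or 'T4-T3'
                ch = change_map.get((group, vi, interval))
                c = implied_pair_correlation(sd[i], sd[j], ch.sd) if ch else rho
            elif vi in DYNAMIC_INDEX_VARIABLES and vj in DYNAMIC_INDEX_VARIABLES:
                c = rho
            else:
                c = 0.0
            corr[i, j] = corr[j, i] = c
    cov = corr * np.outer(sd, sd)
    return labels, mean, cov


def _draw_mvn(rng, mean, cov, n):
    """Multivariate-normal draws via an eigenvalue square root.

    Eigenvalues are clipped at zero so that exactly-degenerate specs
    (sd = 0) reproduce the means exactly and near-PSD rounding noise is
    tolerated.
    """
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((n, mean.size))
    return mean + z @ root.T


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    dists=None,
    changes=None,
    variables=None,
    label_mode: str = "by_group",
    truncate_indices_at: float | None = None,
) -> pd.DataFrame:
    """Draw a patient-level cohort table from the group distributions.

    Per group, the (variable, time point) vector is multivariate normal
    with the specified marginal means/SDs, within-variable cross-time
    correlations implied by the change-column SDs, and the configured
    PPV-SVV cross-correlation. ``delta_ppv``/``delta_svv`` are computed
    from the drawn T1/T2 values.

    By default the normal draws are kept as-is, preserving the printed
    group distributions exactly (a few percent of non-responder index
    draws land at or below zero — the tail of the normal approximation,
    harmless to rank-based analysis). Pass ``truncate_indices_at`` (e.g.
    0.1) to clamp PPV/SVV draws to a physical floor instead; truncation
    counts are logged. Beat-level simulation clamps its modulation targets
    regardless, since a negative target is structurally impossible there.

    ``label_mode``: "by_group" assigns the responder flag from group
    membership (how the summary tables define the groups); "derived"
    re-derives it from the simulated T3->T4 stroke-volume change.
    """
    if dists is None:
        dists = default_distributions()
        if changes is None:
            changes = default_changes()
    dist_map = _spec_lookup(dists)
    change_map = _change_lookup(changes)
    if variables is None:
        variables = sorted({v for (_, v, _) in dist_map}, key=str)
    time_points = [t for t in TIME_POINTS if any((g, v, t) in dist_map for g in GROUPS for v in variables)]
    if label_mode not in ("by_group", "derived"):
        raise ValueError("label_mode must be 'by_group' or 'derived'")
    rng = np.random.default_rng(spec.seed)
    frames = []
    n_truncated = 0
    for group, n in (("responder", spec.n_responders), ("nonresponder", spec.n_nonresponders)):
        labels, mean, cov = _group_mean_cov(
            group, variables, time_points, dist_map, change_map, spec.correlation_within_patient
        )
        x = _draw_mvn(rng, mean, cov, n)
        df = pd.DataFrame(x, columns=[f"{v}_{t}" for v, t in labels])
        if truncate_indices_at is not None:
            for col in df.columns:
                if col.split("_")[0] in DYNAMIC_INDEX_VARIABLES:
                    low = df[col] < truncate_indices_at
                    n_truncated += int(low.sum())
                    df.loc[low, col] = truncate_indices_at
        df.insert(0, "group", group)
        frames.append(df)
    if n_truncated:
        logger.info("generate_cohort: truncated %d negative index draws at %s", n_truncated, truncate_indices_at)
    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "patient_id", [f"P{i + 1:03d}" for i in range(len(cohort))])
    if {"PPV_T1", "PPV_T2"} <= set(cohort.columns):
        cohort["delta_ppv"] = cohort["PPV_T2"] - cohort["PPV_T1"]
    if {"SVV_T1", "SVV_T2"} <= set(cohort.columns):
        cohort["delta_svv"] = cohort["SVV_T2"] - cohort["SVV_T1"]
    if label_mode == "by_group":
        cohort["responder"] = cohort["group"] == "responder"
    else:
        from .responder import classify_cohort

        cohort = classify_cohort(cohort)
        cohort["responder"] = cohort["responder"].astype(bool)
    return cohort


def generate_beats(config: BeatSimConfig, rng=None) -> BeatSeries:
    """Simulate a beat series whose respiratory modulation realizes the targets.

    Beat i occurs at ``i * 60/heart_rate`` s; cycle marks at multiples of
    ``60/resp_rate``. The modulation amplitude ``target/200`` makes the
    noise-free envelope's normalized range equal the target index; Gaussian
    noise (SD ``noise_sd`` as a fraction of baseline) is added per beat.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    beat_dt = 60.0 / config.heart_rate
    cycle_len = 60.0 / config.resp_rate
    f_resp = config.resp_rate / 60.0
    n_beats = int(np.ceil(config.n_cycles * cycle_len / beat_dt)) + 1
    t = np.arange(n_beats) * beat_dt
    if config.phase == "aligned":
        phase = np.pi / 2.0  # first beat of each cycle sits on the modulation crest
    else:
        phase = rng.uniform(0.0, 2.0 * np.pi)
    mod = np.sin(2.0 * np.pi * f_resp * t + phase)
    pp = config.baseline_pp * (1.0 + (config.target_ppv / 200.0) * mod)
    sv = config.baseline_sv * (1.0 + (config.target_svv / 200.0) * mod)
    if config.noise_sd > 0.0:
        pp = pp + config.noise_sd * config.baseline_pp * rng.standard_normal(n_beats)
        sv = sv + config.noise_sd * config.baseline_sv * rng.standard_normal(n_beats)
    # indices must stay positive; clip guards extreme noise draws
    pp = np.clip(pp, 1e-6, None)
    sv = np.clip(sv, 1e-6, None)
    marks = np.arange(config.n_cycles + 1) * cycle_len
    return BeatSeries(beat_time=t, pulse_pressure=pp, stroke_volume=sv, cycle_marks=marks)


def end_to_end_cohort(
    spec: CohortSpec = CohortSpec(),
    dists=None,
    changes=None,
    beat_cfg_template: BeatSimConfig | None = None,
    k_cycles: int = 3,
    label_mode: str = "derived",
) -> pd.DataFrame:
    """Cohort whose T1/T2 indices are *computed* from simulated beat series.

    Each patient's drawn PPV/SVV at T1 and T2 become modulation targets for
    two beat-series simulations; the cohort's index columns are replaced by
    the values the dynamic-index pipeline computes from those beats, and the
    deltas are recomputed. This exercises the full measurement path inside
    the generator.
    """
    if beat_cfg_template is None:
        beat_cfg_template = BeatSimConfig(target_ppv=5.0, target_svv=5.0)
    cohort = generate_cohort(spec, dists=dists, changes=changes, label_mode="by_group")
    rng = np.random.default_rng(None if spec.seed is None else spec.seed + 1)
    for tp in ("T1", "T2"):
        ppv_col, svv_col = f"PPV_{tp}", f"SVV_{tp}"
        computed_ppv = np.empty(len(cohort))
        computed_svv = np.empty(len(cohort))
        for i in range(len(cohort)):
            cfg = replace(
                beat_cfg_template,
                target_ppv=max(float(cohort.loc[i, ppv_col]), 0.1),
                target_svv=max(float(cohort.loc[i, svv_col]), 0.1),
                seed=None,
            )
            series = generate_beats(cfg, rng=rng)
            reading = averaged_reading(series, k=k_cycles, time_point_label=tp)
            computed_ppv[i] = reading.ppv
            computed_svv[i] = reading.svv
        cohort[ppv_col] = computed_ppv
        cohort[svv_col] = computed_svv
    cohort["delta_ppv"] = cohort["PPV_T2"] - cohort["PPV_T1"]
    cohort["delta_svv"] = cohort["SVV_T2"] - cohort["SVV_T1"]
    if label_mode == "derived":
        from .responder import classify_cohort

        cohort = classify_cohort(cohort, threshold=RESPONDER_THRESHOLD_PERCENT)
        cohort["responder"] = cohort["responder"].astype(bool)
    return cohort


def binormal_auc(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float) -> float:
    """Closed-form AUC when both classes are normal: Phi(dmu / sqrt(s1^2+s2^2))."""
    return float(stats.norm.cdf((mean_pos - mean_neg) / np.hypot(sd_pos, sd_neg)))


def mean_auc_over_replicates(
    mean_pos: float,
    sd_pos: float,
    n_pos: int,
    mean_neg: float,
    sd_neg: float,
    n_neg: int,
    n_replicates: int = 1000,
    seed: int | None = None,
) -> float:
    """Mean empirical AUC over repeatedly simulated two-group cohorts.

    Each replicate draws ``n_pos`` responder and ``n_neg`` non-responder
    scores from the given normal distributions and computes the trapezoid
    AUC; the average over replicates estimates the finite-sample expected
    AUC (close to, but not exactly, the binormal closed form).
    """
    rng = np.random.default_rng(seed)
    labels = np.r_[np.ones(n_pos, dtype=bool), np.zeros(n_neg, dtype=bool)]
    aucs = np.empty(n_replicates)
    for b in range(n_replicates):
        scores = np.r_[
            rng.normal(mean_pos, sd_pos, n_pos), rng.normal(mean_neg, sd_neg, n_neg)
        ]
        aucs[b] = empirical_roc(scores, labels).auc
    return float(aucs.mean())
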