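"""Closed-loop induction stage: online decoding, feedback disk, bonus, shifts.

Each induction trial presents a neutrally-rated face, lets the subject shape
their target-ROI pattern during a 6 s induction period, and pays back a green
disk whose size is computed from the decoder's estimated rating of that
pattern.  The estimated rating is produced *causally*: only volumes acquired
by the time the feedback must be shown enter the online preprocessing chain.

The feedback rule is group-dependent but range-identical: for the
higher-preference group the disk is proportional to the estimated rating
(r/10), for the lower group to 11 - r ((11 - r)/10), so both groups see disks
in [0.1, 1.0] under identical instructions; the control group sees a random
disk.  The induced activation shift of a trial is the estimated rating minus
the decoder bias, i.e. how far the induced pattern sits from the subject's
average-preference pattern, in rating units.  A daily bonus of up to 3000 JPY
is proportional to the day's mean disk size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoder import PreferenceDecoder, predict_rating
from .preprocess import (
    RunSeries,
    detrend_linear,
    discard_initial,
    extract_trial_samples,
    period_start_volume,
    preprocess_offline,
    shift_hemodynamic,
    zscore_online,
)
from .synth import (
    GroundTruth,
    INDUCTION_PERIODS,
    INDUCTION_PRE_FIXATION_S,
    INDUCTION_TRIAL_S,
    SubjectPolicy,
    TR_S,
    HEMODYNAMIC_LAG_S,
    _coupling_map,
)

__all__ = [
    "GROUPS",
    "InductionSchedule",
    "InductionLog",
    "disk_size",
    "induced_shift",
    "compute_bonus",
    "online_estimate",
    "run_closed_loop",
    "period_shift_analysis",
    "amplitude_contrast",
    "induction_run_events",
]

GROUPS = ("higher", "lower", "control")
MAX_BONUS_JPY = 3000.0


@dataclass(frozen=True)
class InductionSchedule:
    """Day/run structure of the induction stage."""

    days: int = 3
    runs_per_day: int = 10
    trials_per_run: int = 15
    tr_s: float = TR_S
    lag_s: float = HEMODYNAMIC_LAG_S

    def __post_init__(self) -> None:
        if self.runs_per_day > 12:
            raise ValueError("at most 12 runs per day")
        if self.days < 1 or self.runs_per_day < 1 or self.trials_per_run < 1:
            raise ValueError("schedule counts must be positive")

    @property
    def run_duration_s(self) -> float:
        return INDUCTION_PRE_FIXATION_S + self.trials_per_run * INDUCTION_TRIAL_S

    @property
    def volumes_per_run(self) -> int:
        n = self.run_duration_s / self.tr_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("induction run duration is not an integer number of volumes")
        return int(round(n))


@dataclass
class InductionLog:
    """Per-trial closed-loop record plus per-day aggregates."""

    trials: pd.DataFrame
    group: str
    schedule: InductionSchedule
    decoder_bias: float | None = None
    runs: list = field(default_factory=list)  # RunSeries kept for control analyses

    @property
    def day_summary(self) -> pd.DataFrame:
        g = self.trials.groupby("day")
        out = g.agg(
            mean_shift=("induced_shift", "mean"),
            sem_shift=("induced_shift", "sem"),
            mean_disk=("disk_size", "mean"),
            n_trials=("disk_size", "size"),
        ).reset_index()
        out["bonus_jpy"] = [
            compute_bonus(d["disk_size"].to_numpy()) for _, d in g
        ]
        return out

    @property
    def mean_shift(self) -> float:
        return float(self.trials["induced_shift"].mean())


def induction_run_events(
    run_id: int,
    faces: np.ndarray,
    trials_per_run: int,
) -> pd.DataFrame:
    """Event table of one induction run (face/induction/fixation/feedback/ITI)."""
    rows = []
    for k in range(trials_per_run):
        onset = INDUCTION_PRE_FIXATION_S + k * INDUCTION_TRIAL_S
        for period, rel, dur in INDUCTION_PERIODS:
            rows.append(
                {
                    "run": run_id,
                    "trial": k,
                    "face_id": int(faces[k]),
                    "rating": np.nan,
                    "period": period,
                    "onset_s": onset + rel,
                    "duration_s": dur,
                }
            )
    return pd.DataFrame(rows)


def disk_size(r: float, group: str, rng: np.random.Generator | None = None) -> float:
    """Feedback-disk fraction of maximum for an estimated rating in [1, 10].

    higher: r/10; lower: (11 - r)/10; control: uniform on (0, 1] per trial.
    Both decoded rules cover the identical range [0.1, 1.0].
    """
    if group == "control":
        if rng is None:
            raise ValueError("control-group disk sizes need a seeded generator")
        return float(1.0 - rng.random())  # uniform (0, 1]
    if not 1.0 <= r <= 10.0:
        raise ValueError("estimated rating must be clipped to [1, 10] before the disk rule")
    if group == "higher":
        return float(r / 10.0)
    if group == "lower":
        return float((11.0 - r) / 10.0)
    raise ValueError(f"unknown group '{group}'")


def induced_shift(r: float, dec: PreferenceDecoder) -> float:
    """Estimated rating minus decoder bias: the activation shift in rating units."""
    return float(r - dec.bias)


def compute_bonus(disk_sizes) -> int:
    """Daily bonus: 3000 JPY times the day's mean disk size, nearest JPY."""
    disks = np.asarray(disk_sizes, dtype=float)
    if disks.size == 0:
        raise ValueError("cannot compute a bonus for an empty day")
    return int(np.floor(MAX_BONUS_JPY * disks.mean() + 0.5))


def _period_row(run: RunSeries, trial: int, period: str) -> pd.Series:
    ev = run.events
    rows = ev[(ev["trial"] == trial) & (ev["period"] == period)]
    if rows.empty:
        raise ValueError(f"trial {trial} has no '{period}' period in run {run.run_id}")
    return rows.iloc[0]


def online_estimate(
    dec: PreferenceDecoder,
    run: RunSeries,
    trial: int,
    period: str = "induction",
    window_volumes: int | None = None,
    discard_s: float = 10.0,
    lag_s: float = HEMODYNAMIC_LAG_S,
    clip: bool = True,
) -> float:
    """Causal estimated rating for one trial period.

    Uses exactly the volumes required to cover the lag-shifted period window
    — for the induction period these are all acquired before the end of the
    trial's fixation period, so the feedback disk can be computed in time.
    Raises when the required volumes have not been acquired.
    """
    row = _period_row(run, trial, period)
    if window_volumes is None:
        k = float(row["duration_s"]) / run.tr_s
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"'{period}' period needs an explicit window_volumes")
        window_volumes = int(round(k))
    lag_vol = int(round(lag_s / run.tr_s))
    start = period_start_volume(float(row["onset_s"]), run.tr_s)
    needed = start + lag_vol + window_volumes  # scan volumes required
    if needed > run.n_volumes:
        raise ValueError(
            f"causality violation: trial {trial} '{period}' window needs "
            f"{needed} volumes, run has {run.n_volumes}"
        )
    prefix = run.truncated(needed)
    prefix.events = run.events[(run.events["trial"] == trial) & (run.events["period"] == period)]
    chain = zscore_online(
        detrend_linear(shift_hemodynamic(discard_initial(prefix, discard_s), lag_s))
    )
    sm = extract_trial_samples(chain, period, window_volumes)
    if dec.voxel_indices is not None and sm.n_voxels != len(dec.weights):
        sm = sm.select_voxels(dec.voxel_indices)
    return predict_rating(dec, sm.samples[0], clip=clip)


def run_closed_loop(
    gt: GroundTruth,
    dec: PreferenceDecoder,
    policy: SubjectPolicy,
    schedule: InductionSchedule,
    group: str,
    seed: int,
    induction_faces: np.ndarray | None = None,
    modulated_periods: tuple[str, ...] = ("induction",),
    keep_runs: bool = True,
) -> InductionLog:
    """Simulate the full induction stage of one subject.

    Per trial: the policy emits a target-ROI pattern, the pattern is embedded
    into synthetic volumes (plus any coupled off-target leakage), the online
    chain estimates the rating causally, the group's disk rule produces the
    feedback, and the disk is returned to the policy.  ``modulated_periods``
    controls which trial periods carry the pattern (the default models a
    subject who regulates only during the induction period; adding
    "fixation"/"inter_trial" builds the tonic-modulation counterexample).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group '{group}'")
    target_idx = gt.target_indices
    n_target = len(target_idx)
    policy.reset(n_target)
    if induction_faces is None:
        induction_faces = np.arange(1, 16)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    lag_vol = int(round(schedule.lag_s / schedule.tr_s))
    n_vol = schedule.volumes_per_run
    coupled = {r: (c, _coupling_map(gt, r)) for r, c in gt.coupling.items() if c > 0}

    period_windows = {"face": None, "induction": 3, "fixation": 3, "feedback": 1, "inter_trial": 2}
    records = []
    kept_runs: list[RunSeries] = []
    for day in range(1, schedule.days + 1):
        for run_id in range(schedule.runs_per_day):
            faces = rng.permutation(induction_faces)[: schedule.trials_per_run]
            if len(faces) < schedule.trials_per_run:
                faces = rng.choice(induction_faces, schedule.trials_per_run, replace=True)
            signal = (
                rng.normal(0.0, gt.noise_sd, (gt.n_voxels, n_vol))
                if gt.noise_sd > 0
                else np.zeros((gt.n_voxels, n_vol))
            )
            events = induction_run_events(run_id, faces, schedule.trials_per_run)
            run = RunSeries(
                signal=signal,
                tr_s=schedule.tr_s,
                run_id=run_id,
                events=events,
                roi_map={k: np.asarray(v, dtype=int) for k, v in gt.roi_layout.items()},
            )
            for k in range(schedule.trials_per_run):
                if group == "control":
                    disk = disk_size(np.nan, "control", rng)
                    records.append(
                        {
                            "day": day, "run": run_id, "trial": k,
                            "face_id": int(faces[k]),
                            "estimated_rating": np.nan,
                            "induced_shift": np.nan,
                            "disk_size": disk,
                            "group": group,
                        }
                    )
                    continue
                pattern = policy.next_pattern(day)
                if pattern.shape != (n_target,):
                    raise ValueError(
                        f"policy emitted a pattern of shape {pattern.shape}; "
                        f"target ROI has {n_target} voxels"
                    )
                trial_onset = INDUCTION_PRE_FIXATION_S + k * INDUCTION_TRIAL_S
                for period, rel, dur in INDUCTION_PERIODS:
                    if period not in modulated_periods:
                        continue
                    w = period_windows[period]
                    if w is None:
                        continue
                    start = period_start_volume(trial_onset + rel, schedule.tr_s) + lag_vol
                    stop = min(start + w, n_vol)
                    signal[target_idx, start:stop] += pattern[:, None]
                    for roi, (c, M) in coupled.items():
                        signal[np.asarray(gt.roi_layout[roi]), start:stop] += (
                            c * (M @ pattern)
                        )[:, None]
                est = online_estimate(dec, run, k, "induction", lag_s=schedule.lag_s)
                disk = disk_size(est, group)
                policy.observe(disk)
                records.append(
                    {
                        "day": day, "run": run_id, "trial": k,
                        "face_id": int(faces[k]),
                        "estimated_rating": est,
                        "induced_shift": induced_shift(est, dec),
                        "disk_size": disk,
                        "group": group,
                    }
                )
            if keep_runs and group != "control":
                run.events = events.assign(day=day)
                kept_runs.append(run)
    return InductionLog(
        trials=pd.DataFrame(records),
        group=group,
        schedule=schedule,
        decoder_bias=None if group == "control" else dec.bias,
        runs=kept_runs,
    )


def period_shift_analysis(
    dec: PreferenceDecoder,
    log: InductionLog,
    periods: tuple[str, ...] = ("induction", "fixation", "inter_trial"),
) -> pd.DataFrame:
    """Decoder-derived activation shifts per trial period and induction day.

    Applies the decoder (same causal online chain) to the induction,
    fixation, and inter-trial windows of every logged trial.  The
    induction-period values reproduce the logged closed-loop estimates
    exactly since the computation is identical.
    """
    if not log.runs:
        raise ValueError("induction log kept no runs; re-run with keep_runs=True")
    windows = {"induction": 3, "fixation": 3, "inter_trial": 2}
    lag_vol = int(round(log.schedule.lag_s / log.schedule.tr_s))
    rows = []
    for run in log.runs:
        day = int(run.events["day"].iloc[0])
        for trial in sorted(run.events["trial"].unique()):
            for period in periods:
                row = _period_row(run, int(trial), period)
                start = period_start_volume(float(row["onset_s"]), run.tr_s)
                if start + lag_vol + windows[period] > run.n_volumes:
                    continue  # lag-shifted window never acquired (run end)
                est = online_estimate(
                    dec, run, int(trial), period, window_volumes=windows[period],
                    lag_s=log.schedule.lag_s,
                )
                rows.append(
                    {
                        "day": day,
                        "run": run.run_id,
                        "trial": int(trial),
                        "period": period,
                        "shift": induced_shift(est, dec),
                    }
                )
    table = pd.DataFrame(rows)
    return table


def amplitude_contrast(
    runs,
    roi_indices: np.ndarray,
    period_a: str = "induction",
    period_b: str = "inter_trial",
    window_a: int = 3,
    window_b: int = 2,
) -> tuple[np.ndarray, float]:
    """Mean per-voxel z amplitude of ``period_a`` minus ``period_b``.

    Returns the per-voxel contrast over the ROI and its across-voxel mean;
    an overall pattern change with zero voxel-mean leaves the ROI mean near
    zero, which is what distinguishes pattern induction from a gross
    amplitude change.
    """
    roi_indices = np.asarray(roi_indices, dtype=int)
    diffs = []
    for run in runs:
        chain = preprocess_offline(run)
        a = extract_trial_samples(chain, period_a, window_a, drop_incomplete=True)
        b = extract_trial_samples(chain, period_b, window_b, drop_incomplete=True)
        diffs.append(a.samples[:, roi_indices].mean(axis=0) - b.samples[:, roi_indices].mean(axis=0))
    per_voxel = np.mean(diffs, axis=0)
    return per_voxel, float(per_voxel.mean())
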