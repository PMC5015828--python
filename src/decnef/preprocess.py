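"""Run-level BOLD preprocessing and trial-sample extraction.

A scanner run is held as a voxel x volume matrix (:class:`RunSeries`) together
with its event table.  The analysis never models the hemodynamic response
explicitly: the time course is index-shifted by the hemodynamic lag (an exact
multiple of TR), linearly detrended, z-scored, and trial samples are formed by
averaging the volumes covering each task period.  Two normalization variants
exist: the *offline* one (decoder construction) z-scores each voxel over all
volumes past the discarded initial window, while the *online* one (real-time
feedback) may only use a short baseline window near the start of the run and
is applied causally to everything that follows.

Stage bookkeeping: each operation tags the run it returns, and an operation
refuses to run out of order (e.g. detrending after z-scoring), so a pipeline
assembled by hand cannot silently deviate from
``discard -> shift -> detrend -> zscore -> extract``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RunSeries",
    "SampleMatrix",
    "discard_initial",
    "shift_hemodynamic",
    "detrend_linear",
    "zscore_offline",
    "zscore_online",
    "extract_trial_samples",
    "normalize_train_test",
    "preprocess_offline",
    "preprocess_online",
    "extract_session",
]

#: canonical order of preprocessing stages; a stage may only be applied when
#: every stage already applied precedes it in this sequence.
_STAGE_SEQ = ("discard", "shift", "detrend", "zscore")

_EVENT_COLUMNS = ("run", "trial", "face_id", "rating", "period", "onset_s", "duration_s")


@dataclass
class RunSeries:
    """One fMRI run: voxel x volume signal plus event metadata.

    ``signal`` rows are voxels (the full grid of the study), columns volumes.
    ``excluded`` flags volumes that must not enter trend fits or
    normalization statistics but remain addressable so event indexing keeps
    matching scan time.  ``lag_volumes`` records how far the series has been
    re-indexed toward stimulus time by :func:`shift_hemodynamic`.
    """

    signal: np.ndarray
    tr_s: float
    run_id: int
    events: pd.DataFrame
    roi_map: dict[str, np.ndarray] = field(default_factory=dict)
    excluded: np.ndarray | None = None
    stages: tuple[str, ...] = ()
    lag_volumes: int = 0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D voxel x volume array")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.excluded is None:
            self.excluded = np.zeros(self.signal.shape[1], dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != (self.signal.shape[1],):
                raise ValueError("excluded mask must have one entry per volume")

    @property
    def n_voxels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[1]

    @property
    def included(self) -> np.ndarray:
        return ~self.excluded

    def truncated(self, n_volumes: int) -> "RunSeries":
        """Causal prefix of the run (first ``n_volumes`` volumes)."""
        if n_volumes <= 0 or n_volumes > self.n_volumes:
            raise ValueError(f"cannot truncate run to {n_volumes} volumes")
        return replace(
            self,
            signal=self.signal[:, :n_volumes].copy(),
            excluded=self.excluded[:n_volumes].copy(),
        )


@dataclass
class SampleMatrix:
    """Trial x voxel activation samples for one task period."""

    samples: np.ndarray
    run_labels: np.ndarray
    period: str
    window_volumes: int
    trial_index: np.ndarray | None = None
    face_ids: np.ndarray | None = None
    ratings: np.ndarray | None = None
    voxel_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.run_labels = np.asarray(self.run_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (trial x voxel)")
        if len(self.run_labels) != self.samples.shape[0]:
            raise ValueError("one run label per trial row is required")

    @property
    def n_trials(self) -> int:
        return self.samples.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.samples.shape[1]

    def select_voxels(self, indices: np.ndarray) -> "SampleMatrix":
        """Restrict to a voxel subset (e.g. one ROI of the grid)."""
        indices = np.asarray(indices, dtype=int)
        if len(indices) == 0:
            raise ValueError("voxel selection is empty")
        base = self.voxel_indices if self.voxel_indices is not None else None
        return SampleMatrix(
            samples=self.samples[:, indices],
            run_labels=self.run_labels,
            period=self.period,
            window_volumes=self.window_volumes,
            trial_index=self.trial_index,
            face_ids=self.face_ids,
            ratings=self.ratings,
            voxel_indices=indices if base is None else base[indices],
        )

    @staticmethod
    def vstack(parts: Sequence["SampleMatrix"]) -> "SampleMatrix":
        if not parts:
            raise ValueError("nothing to stack")
        first = parts[0]
        for p in parts[1:]:
            if p.samples.shape[1] != first.samples.shape[1]:
                raise ValueError("sample matrices differ in voxel count")
            if p.period != first.period:
                raise ValueError("sample matrices belong to different periods")

        def cat(attr):
            vals = [getattr(p, attr) for p in parts]
            if any(v is None for v in vals):
                return None
            return np.concatenate(vals)

        return SampleMatrix(
            samples=np.vstack([p.samples for p in parts]),
            run_labels=np.concatenate([p.run_labels for p in parts]),
            period=first.period,
            window_volumes=first.window_volumes,
            trial_index=cat("trial_index"),
            face_ids=cat("face_ids"),
            ratings=cat("ratings"),
            voxel_indices=first.voxel_indices,
        )


def _require_stage_order(run: RunSeries, stage: str) -> None:
    if stage in run.stages:
        raise ValueError(f"stage '{stage}' already applied to run {run.run_id}")
    pos = _STAGE_SEQ.index(stage)
    for applied in run.stages:
        if _STAGE_SEQ.index(applied) >= pos:
            raise ValueError(
                f"stage '{stage}' must precede '{applied}' "
                f"(pipeline order is {' -> '.join(_STAGE_SEQ)})"
            )


def _seconds_to_volumes(seconds: float, tr_s: float, what: str) -> int:
    k = seconds / tr_s
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"{what} ({seconds} s) is not a multiple of TR ({tr_s} s)")
    return int(round(k))


def discard_initial(run: RunSeries, seconds: float = 10.0) -> RunSeries:
    """Flag the initial volumes (magnetization equilibration) as excluded.

    Volumes are retained for indexing; they are merely masked out of every
    later trend fit and normalization.
    """
    if seconds < 0:
        raise ValueError("discard window must be non-negative")
    _require_stage_order(run, "discard")
    k = _seconds_to_volumes(seconds, run.tr_s, "discard window")
    if k >= run.n_volumes:
        raise ValueError(
            f"discard window of {seconds} s leaves no volumes in a "
            f"{run.n_volumes * run.tr_s:.0f} s run"
        )
    excluded = run.excluded.copy()
    excluded[:k] = True
    return replace(run, excluded=excluded, stages=run.stages + ("discard",))


def shift_hemodynamic(run: RunSeries, lag_s: float = 4.0) -> RunSeries:
    """Re-index volumes from scan time to stimulus time.

    The volume acquired at scan time ``t`` is moved to stimulus time
    ``t - lag``; the first ``lag/TR`` volumes (which precede any stimulus
    time) and nothing else are dropped, so trailing volumes disappear from
    the stimulus-time frame.
    """
    if lag_s < 0:
        raise ValueError("hemodynamic lag must be non-negative")
    _require_stage_order(run, "shift")
    k = _seconds_to_volumes(lag_s, run.tr_s, "hemodynamic lag")
    if k >= run.n_volumes:
        raise ValueError("lag exceeds run duration")
    return replace(
        run,
        signal=run.signal[:, k:].copy(),
        excluded=run.excluded[k:].copy(),
        stages=run.stages + ("shift",),
        lag_volumes=run.lag_volumes + k,
    )


def detrend_linear(run: RunSeries) -> RunSeries:
    """Remove a per-voxel least-squares line fit on the included volumes."""
    _require_stage_order(run, "detrend")
    inc = run.included
    if inc.sum() < 3:
        raise ValueError("linear detrending needs at least 3 included volumes")
    t = np.arange(run.n_volumes, dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X[inc], run.signal[:, inc].T, rcond=None)
    detrended = run.signal - (X @ beta).T
    return replace(run, signal=detrended, stages=run.stages + ("detrend",))


def zscore_offline(run: RunSeries) -> RunSeries:
    """Z-score each voxel using all included volumes of the run."""
    _require_stage_order(run, "zscore")
    inc = run.included
    mean = run.signal[:, inc].mean(axis=1)
    sd = run.signal[:, inc].std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance voxel(s) {bad.tolist()} in run {run.run_id}")
    z = (run.signal - mean[:, None]) / sd[:, None]
    return replace(run, signal=z, stages=run.stages + ("zscore",))


def zscore_online(
    run: RunSeries,
    baseline_start_s: float = 10.0,
    baseline_len_s: float = 20.0,
) -> RunSeries:
    """Z-score each voxel from a short run-initial baseline window only.

    The baseline window is specified in scan time (default: 20 s starting
    10 s after run onset, i.e. scan volumes 5..14 at TR 2 s); if the series
    has already been lag-shifted the window is mapped into the shifted frame.
    The resulting transform is causal: it depends only on volumes inside the
    baseline window and is then applied to the whole series.
    """
    _require_stage_order(run, "zscore")
    start = _seconds_to_volumes(baseline_start_s, run.tr_s, "baseline start")
    length = _seconds_to_volumes(baseline_len_s, run.tr_s, "baseline length")
    if length < 2:
        raise ValueError("baseline window must span at least 2 volumes")
    lo = start - run.lag_volumes
    hi = lo + length
    if lo < 0:
        raise ValueError("baseline window starts before the shifted series")
    if hi > run.n_volumes:
        raise ValueError("baseline window extends past the end of the run")
    base = run.signal[:, lo:hi]
    mean = base.mean(axis=1)
    sd = base.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance voxel(s) {bad.tolist()} in baseline window")
    z = (run.signal - mean[:, None]) / sd[:, None]
    return replace(run, signal=z, stages=run.stages + ("zscore",))


def period_start_volume(onset_s: float, tr_s: float) -> int:
    """Nearest-volume index of a period onset (stimulus-time frame)."""
    return int(np.floor(onset_s / tr_s + 0.5))


def extract_trial_samples(
    run: RunSeries,
    period: str = "rating",
    window_volumes: int | None = None,
    drop_incomplete: bool = False,
) -> SampleMatrix:
    """Average the volumes covering each trial's period into one sample row.

    ``window_volumes`` defaults to ``duration / TR`` and must be an integer
    number of volumes (the 6 s periods are exactly 3 volumes at TR 2 s);
    periods that do not tile into whole volumes (the 5.5 s inter-trial
    period) require an explicit window.  A window extending past the run is
    an error unless ``drop_incomplete`` is set, in which case the affected
    trials are omitted (the lag-shifted inter-trial window of a run's final
    trial has no acquired volumes).
    """
    ev = run.events
    rows = ev[ev["period"] == period]
    if rows.empty:
        raise ValueError(f"run {run.run_id} has no '{period}' events")
    rows = rows.sort_values(["trial", "onset_s"])

    if window_volumes is None:
        durations = rows["duration_s"].to_numpy(dtype=float)
        k = durations[0] / run.tr_s
        if not np.allclose(durations, durations[0]):
            raise ValueError(f"'{period}' events have mixed durations; pass window_volumes")
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"'{period}' period of {durations[0]} s is not an integer number of "
                f"volumes at TR {run.tr_s} s; pass window_volumes explicitly"
            )
        window_volumes = int(round(k))
    if window_volumes < 1:
        raise ValueError("window must span at least one volume")

    keep = np.ones(len(rows), dtype=bool)
    samples = np.empty((len(rows), run.n_voxels))
    for i, (_, r) in enumerate(rows.iterrows()):
        start = period_start_volume(float(r["onset_s"]), run.tr_s)
        stop = start + window_volumes
        if start < 0 or stop > run.n_volumes:
            if drop_incomplete:
                keep[i] = False
                continue
            raise ValueError(
                f"'{period}' window of trial {int(r['trial'])} "
                f"(volumes {start}..{stop - 1}) extends past run {run.run_id}"
            )
        samples[i] = run.signal[:, start:stop].mean(axis=1)
    if not keep.any():
        raise ValueError(f"no complete '{period}' windows in run {run.run_id}")
    rows = rows[keep]
    samples = samples[keep]

    ratings = rows["rating"].to_numpy(dtype=float) if "rating" in rows else None
    return SampleMatrix(
        samples=samples,
        run_labels=np.full(len(rows), run.run_id),
        period=period,
        window_volumes=window_volumes,
        trial_index=rows["trial"].to_numpy(dtype=int),
        face_ids=rows["face_id"].to_numpy() if "face_id" in rows else None,
        ratings=ratings,
    )


def normalize_train_test(
    train: SampleMatrix, test: SampleMatrix
) -> tuple[SampleMatrix, SampleMatrix]:
    """Scale both matrices by the training mean/sd per voxel.

    Training columns become mean 0, variance 1; the test matrix is moved by
    the same (training-derived) transform, never by its own statistics.
    """
    if train.n_voxels != test.n_voxels:
        raise ValueError("train and test differ in voxel count")
    mean = train.samples.mean(axis=0)
    sd = train.samples.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance training voxel(s) {bad.tolist()}")

    def apply(sm: SampleMatrix) -> SampleMatrix:
        out = SampleMatrix(
            samples=(sm.samples - mean) / sd,
            run_labels=sm.run_labels,
            period=sm.period,
            window_volumes=sm.window_volumes,
            trial_index=sm.trial_index,
            face_ids=sm.face_ids,
            ratings=sm.ratings,
            voxel_indices=sm.voxel_indices,
        )
        return out

    return apply(train), apply(test)


def preprocess_offline(
    run: RunSeries, discard_s: float = 10.0, lag_s: float = 4.0
) -> RunSeries:
    """Full offline chain: discard -> shift -> detrend -> z-score (whole run)."""
    return zscore_offline(detrend_linear(shift_hemodynamic(discard_initial(run, discard_s), lag_s)))


def preprocess_online(
    run: RunSeries,
    discard_s: float = 10.0,
    lag_s: float = 4.0,
    baseline_start_s: float = 10.0,
    baseline_len_s: float = 20.0,
) -> RunSeries:
    """Full online chain: discard -> shift -> detrend -> z-score (baseline window)."""
    shifted = detrend_linear(shift_hemodynamic(discard_initial(run, discard_s), lag_s))
    return zscore_online(shifted, baseline_start_s, baseline_len_s)


def extract_session(
    runs: Sequence[RunSeries],
    period: str = "rating",
    window_volumes: int | None = None,
    mode: str = "offline",
    **chain_kw,
) -> SampleMatrix:
    """Preprocess every run of a session and stack its trial samples."""
    if mode == "offline":
        chain = preprocess_offline
    elif mode == "online":
        chain = preprocess_online
    elif mode == "raw":
        chain = lambda r, **kw: shift_hemodynamic(discard_initial(r, kw.get("discard_s", 10.0)), kw.get("lag_s", 4.0))  # noqa: E731
    else:
        raise ValueError(f"unknown preprocessing mode '{mode}'")
    parts = [
        extract_trial_samples(chain(r, **chain_kw), period, window_volumes) for r in runs
    ]
    return SampleMatrix.vstack(parts)
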