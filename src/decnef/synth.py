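"""Synthetic subjects for the decoded-neurofeedback pipeline.

The generator emulates the statistical structure the analysis assumes, not
the physics of fMRI: a named target ROI on a 3-D voxel grid carries a linear
encoding of facial preference, every other voxel is Gaussian noise, and
off-target ROIs can be coupled to the target pattern through a fixed random
linear map to plant (or withhold) "leakage" for the leak analyses.

Study conditions mirror the experimental design: a 400-face pool rated on a
1-10 Likert scale, 240 selected faces (100 highest, 100 lowest, 40 neutral,
with 15 induction + 15 baseline faces drawn from the neutral set), rating
sessions of 12 runs x 20 trials at TR 2 s (12 s trials, 10 s lead-in fixation,
2 s tail), and induction runs of 15 trials x 20 s after a 30 s fixation.

Encoding model: a trial whose observed rating is r deposits the pattern
``(linearize(r) - mean(linearize(r_session))) * w / ||w||^2`` into the target
ROI at the lag-shifted volumes of its rating period, where w are the
ground-truth weights, so an ideal decoder's read-out w^T A reproduces the
linearized rating deviation from the session mean exactly (amplitudes are in
linearized-rating units, centered on the artanh-domain session mean exactly
as the decoder's bias is; see the methods note).

Everything is a pure function of (config, seed): identical seeds give
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .decoder import linearize_rating
from .preprocess import RunSeries, SampleMatrix, period_start_volume

__all__ = [
    "GroundTruth",
    "FacePool",
    "FaceQuotas",
    "make_ground_truth",
    "block_roi_layout",
    "generate_face_pool",
    "select_faces",
    "simulate_rating_session",
    "couple_rois",
    "make_policy",
    "SubjectPolicy",
    "NonAdaptivePolicy",
    "HillClimbPolicy",
    "OraclePolicy",
    "RATING_TRIAL_S",
    "INDUCTION_TRIAL_S",
]

TR_S = 2.0
HEMODYNAMIC_LAG_S = 4.0

# decoder-construction (rating) trial: face 0.5 s, rating 6 s, report+ITI 5.5 s
RATING_TRIAL_S = 12.0
RATING_PRE_FIXATION_S = 10.0
RATING_POST_FIXATION_S = 2.0

# induction trial: face 0.5, induction 6, fixation 6, feedback 2, inter-trial 5.5
INDUCTION_TRIAL_S = 20.0
INDUCTION_PERIODS = (
    ("face", 0.0, 0.5),
    ("induction", 0.5, 6.0),
    ("fixation", 6.5, 6.0),
    ("feedback", 12.5, 2.0),
    ("inter_trial", 14.5, 5.5),
)
INDUCTION_PRE_FIXATION_S = 30.0


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth generative configuration for one synthetic subject.

    ``roi_layout`` maps ROI names to disjoint flat voxel index sets on the
    grid; ``true_weights`` is the signed encoding vector over the target
    ROI's voxels (units: signal per linearized rating point); ``coupling``
    mixes the target pattern into off-target ROIs (0 = independent noise,
    1 = pure linear image of the target pattern).
    """

    grid_shape: tuple[int, int, int]
    roi_layout: dict[str, np.ndarray]
    true_weights: np.ndarray
    target_roi: str = "CC"
    voxel_dims_mm: tuple[float, float, float] = (3.0, 3.0, 3.5)
    bias_rating: float = 5.5
    rating_noise_sd: float = 0.5
    noise_sd: float = 1.0
    coupling: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        n_grid = int(np.prod(self.grid_shape))
        seen = np.zeros(n_grid, dtype=bool)
        for name, idx in self.roi_layout.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                raise ValueError(f"ROI '{name}' is empty")
            if idx.min() < 0 or idx.max() >= n_grid:
                raise ValueError(f"ROI '{name}' indexes outside the grid")
            if seen[idx].any():
                raise ValueError(f"ROI '{name}' overlaps another ROI; ROIs must be disjoint")
            seen[idx] = True
        if self.target_roi not in self.roi_layout:
            raise ValueError(f"target ROI '{self.target_roi}' not in layout")
        if len(self.true_weights) != len(self.roi_layout[self.target_roi]):
            raise ValueError("true_weights length must match the target ROI size")
        if self.noise_sd < 0 or self.rating_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        for name, c in self.coupling.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling for '{name}' must lie in [0, 1]")
            if name not in self.roi_layout or name == self.target_roi:
                raise ValueError(f"coupling refers to unknown/target ROI '{name}'")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def target_indices(self) -> np.ndarray:
        return np.asarray(self.roi_layout[self.target_roi], dtype=int)

    @property
    def encode_pattern_unit(self) -> np.ndarray:
        """Pattern deposited per linearized rating point: w / ||w||^2."""
        w = np.asarray(self.true_weights, dtype=float)
        return w / float(w @ w)


def block_roi_layout(
    grid_shape: tuple[int, int, int],
    names: Sequence[str],
    voxels_per_roi: int | Sequence[int] = 27,
    block_edge: int = 3,
    gap: int = 1,
) -> dict[str, np.ndarray]:
    """Tile disjoint cubic ROI blocks over the grid (spatially compact ROIs)."""
    if isinstance(voxels_per_roi, int):
        sizes = [voxels_per_roi] * len(names)
    else:
        sizes = list(voxels_per_roi)
    if any(s > block_edge**3 for s in sizes):
        raise ValueError("voxels_per_roi exceeds the block capacity")
    step = block_edge + gap
    origins = [
        (x, y, z)
        for z in range(0, grid_shape[2] - block_edge + 1, step)
        for y in range(0, grid_shape[1] - block_edge + 1, step)
        for x in range(0, grid_shape[0] - block_edge + 1, step)
    ]
    if len(origins) < len(names):
        raise ValueError(
            f"grid {grid_shape} fits only {len(origins)} ROI blocks, {len(names)} requested"
        )
    layout: dict[str, np.ndarray] = {}
    for name, size, (ox, oy, oz) in zip(names, sizes, origins):
        coords = [
            (ox + dx, oy + dy, oz + dz)
            for dz in range(block_edge)
            for dy in range(block_edge)
            for dx in range(block_edge)
        ][:size]
        layout[name] = np.asarray(
            [np.ravel_multi_index(c, grid_shape) for c in coords], dtype=int
        )
    return layout


def make_ground_truth(
    n_other_rois: int = 2,
    roi_voxels: int = 27,
    target_voxels: int | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    coupling: dict[str, float] | None = None,
    other_names: Sequence[str] | None = None,
    weight_scale: float = 1.0,
    gap: int = 1,
    seed: int = 0,
    **kwargs,
) -> GroundTruth:
    """Convenience factory: target ROI "CC" plus ``n_other_rois`` regions.

    ``gap`` spaces the ROI blocks (in voxels); widen it when searchlight
    spheres must not straddle two regions.
    """
    if other_names is None:
        other_names = [f"R{i + 1:02d}" for i in range(n_other_rois)]
    names = ["CC", *other_names]
    block_edge = max(3, int(np.ceil((max(roi_voxels, target_voxels or 1)) ** (1 / 3))))
    if grid_shape is None:
        step = block_edge + gap
        per_row = int(np.ceil(np.sqrt(len(names))))
        rows = int(np.ceil(len(names) / per_row))
        grid_shape = (per_row * step, rows * step, block_edge + 1)
    sizes = [target_voxels or roi_voxels] + [roi_voxels] * len(other_names)
    layout = block_roi_layout(grid_shape, names, sizes, block_edge=block_edge, gap=gap)
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 1.0, len(layout["CC"]))
    # unit-norm (times weight_scale) so the embedded pattern's magnitude is the
    # linearized rating deviation regardless of ROI size
    w = weight_scale * w / np.linalg.norm(w)
    return GroundTruth(
        grid_shape=grid_shape,
        roi_layout=layout,
        true_weights=w,
        coupling=coupling or {},
        seed=seed,
        **kwargs,
    )


@dataclass
class FacePool:
    """Face stimuli with latent preferences and set assignments."""

    face_id: np.ndarray
    latent_preference: np.ndarray
    pretest_rating: np.ndarray
    assigned_set: np.ndarray

    @property
    def n_faces(self) -> int:
        return len(self.face_id)

    def ids_in_set(self, *names: str) -> np.ndarray:
        mask = np.isin(self.assigned_set, names)
        return self.face_id[mask]

    def latent_of(self, face_ids: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(self.face_id, face_ids)
        return self.latent_preference[pos]


@dataclass(frozen=True)
class FaceQuotas:
    highest: int = 100
    lowest: int = 100
    neutral: int = 40
    induction: int = 15
    baseline: int = 15


def _observe_rating(latent: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Likert observation model: clip(round(latent + N(0, sd)), 1, 10)."""
    noisy = latent + (rng.normal(0.0, sd, latent.shape) if sd > 0 else 0.0)
    return np.clip(np.rint(noisy), 1, 10).astype(int)


def generate_face_pool(n_faces: int, gt: GroundTruth, seed: int) -> FacePool:
    """Draw a face pool with uniform latent preferences and pre-test ratings."""
    if n_faces < 240:
        raise ValueError(
            f"n_faces={n_faces} cannot fill the 100+100+40 selection quotas; need >= 240"
        )
    rng = np.random.default_rng(seed)
    latent = rng.uniform(1.0, 10.0, n_faces)
    pretest = _observe_rating(latent, gt.rating_noise_sd, rng)
    return FacePool(
        face_id=np.arange(1, n_faces + 1),
        latent_preference=latent,
        pretest_rating=pretest,
        assigned_set=np.full(n_faces, "unused", dtype="<U10"),
    )


def select_faces(
    pool: FacePool,
    quotas: FaceQuotas = FaceQuotas(),
    seed: int | None = None,
) -> FacePool:
    """Assign faces to the highest/lowest/neutral sets and draw the
    induction and baseline subsets of the neutral set.

    Ranking is by pre-test rating; rating ties that straddle a quota
    boundary are broken by a seeded random key (rank-then-seed) and are an
    error when no seed is given, since the selection would be arbitrary.
    """
    n = pool.n_faces
    need = quotas.highest + quotas.lowest + quotas.neutral
    if n < need:
        raise ValueError(f"pool of {n} faces cannot fill quotas totalling {need}")
    if quotas.induction + quotas.baseline > quotas.neutral:
        raise ValueError("induction + baseline quota exceeds the neutral set")

    ratings = pool.pretest_rating.astype(float)
    rng = np.random.default_rng(seed) if seed is not None else None
    tiebreak = rng.random(n) if rng is not None else np.zeros(n)
    # descending rating, then seeded key, then face id (full determinism)
    order = np.lexsort((pool.face_id, tiebreak, -ratings))

    neutral_start = (n - quotas.neutral) // 2
    boundaries = [
        (quotas.highest - 1, quotas.highest),          # highest | rest
        (n - quotas.lowest - 1, n - quotas.lowest),    # rest | lowest
        (neutral_start - 1, neutral_start),            # rest | neutral
        (neutral_start + quotas.neutral - 1, neutral_start + quotas.neutral),
    ]
    if rng is None:
        for a, b in boundaries:
            if 0 <= a and b < n and ratings[order[a]] == ratings[order[b]]:
                raise ValueError(
                    "rating tie across a selection-quota boundary; "
                    "pass a tie-break seed to select_faces"
                )

    assigned = np.full(n, "unused", dtype="<U10")
    assigned[order[: quotas.highest]] = "highest"
    assigned[order[n - quotas.lowest:]] = "lowest"
    neutral_pos = order[neutral_start: neutral_start + quotas.neutral]
    if np.any(assigned[neutral_pos] != "unused"):
        raise ValueError("neutral window overlaps the highest/lowest quota windows")
    assigned[neutral_pos] = "neutral"

    draw_rng = rng if rng is not None else np.random.default_rng(0)
    picked = draw_rng.choice(neutral_pos, quotas.induction + quotas.baseline, replace=False)
    assigned[picked[: quotas.induction]] = "induction"
    assigned[picked[quotas.induction:]] = "baseline"
    return replace(pool, assigned_set=assigned)


def _coupling_map(gt: GroundTruth, roi: str) -> np.ndarray:
    """Fixed random linear map target-ROI pattern -> off-target ROI pattern.

    Drawn once per (ground truth seed, ROI); leakage is pattern-level, not
    voxel-identity-level.
    """
    roi_names = sorted(gt.roi_layout)
    ss = np.random.SeedSequence([gt.seed, 7919, roi_names.index(roi)])
    rng = np.random.default_rng(ss)
    n_roi = len(gt.roi_layout[roi])
    n_target = len(gt.target_indices)
    # gain 2: the leaked image's per-voxel amplitude is twice the source's,
    # so full coupling is comfortably detectable at desk-scale sample sizes
    return rng.normal(0.0, 2.0 / np.sqrt(n_target), (n_roi, n_target))


def _rating_session_events(
    run_id: int, faces: np.ndarray, ratings: np.ndarray, trials_per_run: int
) -> pd.DataFrame:
    rows = []
    for k in range(trials_per_run):
        onset = RATING_PRE_FIXATION_S + k * RATING_TRIAL_S
        for period, rel, dur in (("face", 0.0, 0.5), ("rating", 0.5, 6.0), ("inter_trial", 6.5, 5.5)):
            rows.append(
                {
                    "run": run_id,
                    "trial": k,
                    "face_id": int(faces[k]),
                    "rating": int(ratings[k]),
                    "period": period,
                    "onset_s": onset + rel,
                    "duration_s": dur,
                }
            )
    return pd.DataFrame(rows)


def simulate_rating_session(
    gt: GroundTruth,
    pool: FacePool,
    n_runs: int = 12,
    trials_per_run: int = 20,
    seed: int = 0,
    tr_s: float = TR_S,
    lag_s: float = HEMODYNAMIC_LAG_S,
) -> tuple[list[RunSeries], pd.DataFrame]:
    """Simulate the decoder-construction stage of one subject.

    Presents the selected faces in randomized order, records a fresh noisy
    Likert rating per trial, and embeds each trial's target-ROI pattern at
    the lag-shifted volumes of its 6 s rating period, on top of i.i.d.
    Gaussian voxel noise.  Coupled off-target ROIs receive the linear image
    of the trial pattern scaled by their coupling.
    """
    run_s = RATING_PRE_FIXATION_S + trials_per_run * RATING_TRIAL_S + RATING_POST_FIXATION_S
    n_vol_f = run_s / tr_s
    if abs(n_vol_f - round(n_vol_f)) > 1e-9:
        raise ValueError(f"run duration {run_s} s is not an integer number of volumes")
    n_vol = int(round(n_vol_f))
    lag_vol = int(round(lag_s / tr_s))
    if abs(lag_s / tr_s - lag_vol) > 1e-9:
        raise ValueError("hemodynamic lag must be a multiple of TR")

    rng = np.random.default_rng(seed)
    selected = pool.ids_in_set("highest", "lowest", "neutral", "induction", "baseline")
    total = n_runs * trials_per_run
    if len(selected) == 0:
        raise ValueError("pool has no selected faces; run select_faces first")
    if total == len(selected):
        face_order = rng.permutation(selected)
    elif total < len(selected):
        face_order = rng.choice(selected, total, replace=False)
    else:
        face_order = rng.choice(selected, total, replace=True)

    latent = pool.latent_of(face_order)
    session_ratings = _observe_rating(latent, gt.rating_noise_sd, rng)
    lin = linearize_rating(session_ratings.astype(float))
    deltas = lin - lin.mean()  # centered on the artanh-domain session mean

    unit = gt.encode_pattern_unit
    target_idx = gt.target_indices
    coupled = {
        roi: (c, _coupling_map(gt, roi)) for roi, c in gt.coupling.items() if c > 0
    }

    runs: list[RunSeries] = []
    tables = []
    for run_id in range(n_runs):
        sl = slice(run_id * trials_per_run, (run_id + 1) * trials_per_run)
        faces, ratings, ds = face_order[sl], session_ratings[sl], deltas[sl]
        signal = rng.normal(0.0, gt.noise_sd, (gt.n_voxels, n_vol)) if gt.noise_sd > 0 else np.zeros((gt.n_voxels, n_vol))
        for k in range(trials_per_run):
            onset = RATING_PRE_FIXATION_S + k * RATING_TRIAL_S + 0.5
            start = period_start_volume(onset, tr_s) + lag_vol
            stop = start + 3
            if stop > n_vol:
                raise ValueError("trial schedule extends past the run")
            pattern = ds[k] * unit
            signal[target_idx, start:stop] += pattern[:, None]
            for roi, (c, M) in coupled.items():
                signal[np.asarray(gt.roi_layout[roi]), start:stop] += (c * (M @ pattern))[:, None]
        events = _rating_session_events(run_id, faces, ratings, trials_per_run)
        runs.append(
            RunSeries(
                signal=signal,
                tr_s=tr_s,
                run_id=run_id,
                events=events,
                roi_map={k: np.asarray(v, dtype=int) for k, v in gt.roi_layout.items()},
            )
        )
        tables.append(events)
    return runs, pd.concat(tables, ignore_index=True)


def couple_rois(
    target_samples: SampleMatrix, gt: GroundTruth, seed: int
) -> dict[str, SampleMatrix]:
    """Sample-level leakage model for each off-target ROI.

    Off-target sample = coupling * (fixed linear image of the target
    pattern) + (1 - coupling) * independent Gaussian noise, per trial.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, SampleMatrix] = {}
    for roi in sorted(gt.coupling):
        c = gt.coupling[roi]
        M = _coupling_map(gt, roi)
        image = target_samples.samples @ M.T
        noise = rng.normal(0.0, gt.noise_sd, image.shape)
        out[roi] = SampleMatrix(
            samples=c * image + (1.0 - c) * noise,
            run_labels=target_samples.run_labels,
            period=target_samples.period,
            window_volumes=target_samples.window_volumes,
            trial_index=target_samples.trial_index,
            face_ids=target_samples.face_ids,
            ratings=target_samples.ratings,
        )
    return out


class SubjectPolicy:
    """How a simulated subject turns scalar disk feedback into a pattern.

    The experiment never observes the subject's strategy, only the pattern it
    produces each induction trial; policies are explicit generative stand-ins
    for "somehow regulating brain activity", not claims about mechanism.
    """

    kind = "abstract"

    def reset(self, n_voxels: int) -> None:
        self.n_voxels = n_voxels

    def next_pattern(self, day: int) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def observe(self, disk: float) -> None:
        pass


class NonAdaptivePolicy(SubjectPolicy):
    """Ignores feedback entirely; emits a null pattern every trial."""

    kind = "non_adaptive"

    def __init__(self, seed: int = 0):
        self.seed = seed

    def next_pattern(self, day: int) -> np.ndarray:
        return np.zeros(self.n_voxels)


class HillClimbPolicy(SubjectPolicy):
    """(1+1) keep-if-improved search using only the scalar feedback history."""

    kind = "hill_climb"

    def __init__(self, step_size: float, seed: int = 0):
        self.step_size = float(step_size)
        self.rng = np.random.default_rng(seed)
        self.best_disk = -np.inf

    def reset(self, n_voxels: int) -> None:
        super().reset(n_voxels)
        self.current = np.zeros(n_voxels)
        self.proposal = self.current
        self.best_disk = -np.inf

    def next_pattern(self, day: int) -> np.ndarray:
        if self.step_size == 0:
            self.proposal = self.current
        else:
            step = self.rng.normal(0.0, 1.0, self.n_voxels) / np.sqrt(self.n_voxels)
            self.proposal = self.current + self.step_size * step
        return self.proposal.copy()

    def observe(self, disk: float) -> None:
        if disk > self.best_disk:
            self.best_disk = disk
            self.current = self.proposal


class OraclePolicy(SubjectPolicy):
    """Moves along the ground-truth weight direction.

    The opening trials probe the direction with alternating sign; the sign
    whose mean disk was larger is kept (so the same oracle learns to
    *descend* for the lower-preference group, where a lower estimated rating
    enlarges the disk — the group assignment is never disclosed).  The
    amplitude then ramps from the base step to ``amp_cap`` times it over
    ``ramp_trials`` trials, yielding the rising day-by-day learning curve
    the closed-loop analyses expect.
    """

    kind = "oracle"

    def __init__(
        self,
        direction: np.ndarray,
        step_size: float,
        amp_cap: float = 4.0,
        probe_trials: int = 10,
        ramp_trials: int = 60,
    ):
        d = np.asarray(direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("oracle direction must be non-zero")
        self.direction = d / nrm
        self.step_size = float(step_size)
        self.amp_cap = float(amp_cap)
        self.probe_trials = int(probe_trials)
        self.ramp_trials = int(ramp_trials)

    def reset(self, n_voxels: int) -> None:
        if n_voxels != len(self.direction):
            raise ValueError("oracle direction length does not match the target ROI")
        super().reset(n_voxels)
        self.trial = 0
        self.sign = 1.0
        self.probe_disks: dict[float, list[float]] = {1.0: [], -1.0: []}

    def _probe_sign(self, trial: int) -> float:
        return 1.0 if trial % 2 == 0 else -1.0

    def next_pattern(self, day: int) -> np.ndarray:
        if self.trial < self.probe_trials:
            # probe at full amplitude: the sign decision must beat the
            # trial-to-trial disk noise, the ramp then restarts at the base
            pat = self._probe_sign(self.trial) * self.amp_cap * self.step_size * self.direction
        else:
            progress = min(1.0, (self.trial - self.probe_trials) / self.ramp_trials)
            amp = self.step_size * (1.0 + (self.amp_cap - 1.0) * progress)
            pat = self.sign * amp * self.direction
        self.trial += 1
        return pat

    def observe(self, disk: float) -> None:
        if self.trial <= self.probe_trials:
            self.probe_disks[self._probe_sign(self.trial - 1)].append(disk)
            if self.trial == self.probe_trials:
                self.sign = (
                    1.0
                    if np.mean(self.probe_disks[1.0]) >= np.mean(self.probe_disks[-1.0])
                    else -1.0
                )


def make_policy(
    kind: str,
    gt: GroundTruth | None = None,
    step_size: float | None = None,
    seed: int = 0,
) -> SubjectPolicy:
    """Instantiate a subject policy by name.

    Default step sizes are expressed in units of the ground truth's voxel
    noise sd so the emitted patterns are commensurate with the signal scale
    the online z-scoring produces.
    """
    if kind == "non_adaptive":
        return NonAdaptivePolicy(seed=seed)
    if kind == "hill_climb":
        if step_size is None:
            step_size = 0.5 * (gt.noise_sd if gt is not None else 1.0)
        return HillClimbPolicy(step_size=step_size, seed=seed)
    if kind == "oracle":
        if gt is None:
            raise ValueError("oracle policy needs the ground truth for its direction")
        if step_size is None:
            # pattern-norm units; the cap (4x) holds the asymptotic induced
            # shift near the ~1-1.5 rating points the closed loop is meant to
            # demonstrate rather than pinning the decoder at its ceiling
            step_size = 0.15 * gt.noise_sd
        return OraclePolicy(direction=gt.true_weights, step_size=step_size, amp_cap=4.0)
    raise ValueError(f"unknown policy kind '{kind}'")
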