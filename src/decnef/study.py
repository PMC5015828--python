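"""End-to-end synthetic studies.

Each function runs one complete experiment of the pipeline at desk scale —
per-subject sessions, decoder training, closed-loop induction, leak
analyses, calibration — and returns the quantities the study design is
meant to produce.  Problem sizes (subjects, runs, replicates) are the
package's standard desk-scale conditions; the methods note motivates them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import leakage as lk
from .decoder import fit_sparse_decoder, linearize_rating, loro_cv, predict_rating, train_preference_decoder
from .neurofeedback import InductionSchedule, amplitude_contrast, period_shift_analysis, run_closed_loop
from .preprocess import extract_session, normalize_train_test
from .stats import permutation_corr
from .synth import (
    GroundTruth,
    generate_face_pool,
    make_ground_truth,
    make_policy,
    select_faces,
    simulate_rating_session,
)

__all__ = [
    "standard_ground_truth",
    "simulate_subject_session",
    "decoder_recovery_study",
    "decoder_cv_study",
    "closed_loop_study",
    "null_policy_study",
    "permutation_type1_study",
    "roi_leak_specificity_study",
    "searchlight_dissociation_study",
    "period_control_study",
]


def _sub_seed(seed: int, *key: int) -> int:
    """Derive a child seed (< 2**31) from a root seed and a key path."""
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def standard_ground_truth(seed: int, coupling: dict[str, float] | None = None,
                          n_other_rois: int = 2, **kw) -> GroundTruth:
    """The study's standard subject: 24-voxel target ROI, unit voxel noise."""
    if coupling is None:
        coupling = {f"R{i + 1:02d}": 0.0 for i in range(n_other_rois)}
    return make_ground_truth(
        n_other_rois=n_other_rois,
        roi_voxels=20,
        target_voxels=24,
        coupling=coupling,
        noise_sd=1.0,
        seed=seed,
        **kw,
    )


def simulate_subject_session(gt: GroundTruth, seed: int, n_runs: int = 12,
                             trials_per_run: int = 20):
    """Pre-test, face selection and decoder-construction session for one subject."""
    pool = generate_face_pool(400, gt, seed=_sub_seed(seed, 1))
    pool = select_faces(pool, seed=_sub_seed(seed, 2))
    runs, table = simulate_rating_session(
        gt, pool, n_runs=n_runs, trials_per_run=trials_per_run, seed=_sub_seed(seed, 3)
    )
    return pool, runs, table


def decoder_cv_study(seed: int) -> dict:
    """Leave-one-run-out decoding performance of one standard subject."""
    gt = standard_ground_truth(_sub_seed(seed, 10))
    _, runs, _ = simulate_subject_session(gt, _sub_seed(seed, 11))
    sm = extract_session(runs, period="rating", mode="offline")
    cv = loro_cv(sm.select_voxels(gt.target_indices), sm.ratings, sm.run_labels)
    return {
        "mean_fisher_z": cv.mean_z,
        "mean_fold_r": float(cv.fold_r.mean()),
        "n_folds": cv.n_folds,
        "n_trials": sm.n_trials,
    }


def decoder_recovery_study(seed: int, n: int = 240, p: int = 50, support: int = 5,
                           noise: float = 0.05) -> dict:
    """Sparse-fit support recovery on a near-noiseless planted problem.

    ``support`` informative voxels carry the linearized rating deviation;
    the remaining ``p - support`` are unit noise.  Held-out performance is
    measured on a 40-trial split against the behavioral ratings.
    """
    rng = np.random.default_rng(seed)
    ratings = rng.integers(1, 11, n).astype(float)
    lin = linearize_rating(ratings)
    deltas = lin - lin.mean()
    w = rng.uniform(0.5, 1.5, support) * rng.choice([-1, 1], support)
    X = rng.normal(0.0, 1.0, (n, p))
    X[:, :support] = np.outer(deltas, w) + rng.normal(0.0, noise, (n, support))

    from .preprocess import SampleMatrix

    sm = SampleMatrix(samples=X, run_labels=np.repeat(np.arange(12), n // 12),
                      period="rating", window_volumes=3)
    train = np.arange(n) < n - 40
    from .decoder import _subset

    tr, te = normalize_train_test(_subset(sm, train), _subset(sm, ~train))
    dec = fit_sparse_decoder(tr, ratings[train])
    pred = predict_rating(dec, te.samples, clip=False)
    r = float(np.corrcoef(pred, ratings[~train])[0, 1])
    recovered = set(range(support)) <= set(dec.selected_voxels.tolist())
    return {
        "held_out_r": r,
        "support_recovered": bool(recovered),
        "n_selected": dec.n_selected,
    }


@dataclass
class ClosedLoopStudy:
    subjects: pd.DataFrame       # subject, group, day-3 shift, total bonus
    day_means: pd.DataFrame      # group x day mean shifts


def closed_loop_study(
    seed: int,
    n_subjects: int = 12,
    groups: tuple[str, ...] = ("higher", "lower"),
    schedule: InductionSchedule | None = None,
    policy_kind: str = "oracle",
) -> ClosedLoopStudy:
    """Full main experiment: per-subject decoder plus 3-day closed loop.

    Each subject gets an independent ground truth, session, decoder and
    feedback loop; the oracle policy stands in for a subject who learns the
    feedback contingency.
    """
    schedule = schedule or InductionSchedule(days=3, runs_per_day=4)
    rows, day_rows = [], []
    for gi, group in enumerate(groups):
        for s in range(n_subjects):
            sub = _sub_seed(seed, 20, gi, s)
            gt = standard_ground_truth(sub)
            _, runs, _ = simulate_subject_session(gt, _sub_seed(sub, 1))
            dec = train_preference_decoder(runs, gt.target_roi)
            pol = make_policy(policy_kind, gt=gt, seed=_sub_seed(sub, 2))
            log = run_closed_loop(
                gt, dec, pol, schedule, group, seed=_sub_seed(sub, 3), keep_runs=False
            )
            ds = log.day_summary
            rows.append(
                {
                    "subject": f"{group}-{s:02d}",
                    "group": group,
                    "day3_shift": float(ds.loc[ds.day == schedule.days, "mean_shift"].iloc[0]),
                    "mean_shift": log.mean_shift,
                    "mean_daily_bonus": float(ds["bonus_jpy"].mean()),
                }
            )
            for _, d in ds.iterrows():
                day_rows.append(
                    {"group": group, "subject": s, "day": int(d["day"]),
                     "mean_shift": float(d["mean_shift"])}
                )
    subjects = pd.DataFrame(rows)
    day_means = (
        pd.DataFrame(day_rows).groupby(["group", "day"])["mean_shift"].mean().reset_index()
    )
    return ClosedLoopStudy(subjects=subjects, day_means=day_means)


def null_policy_study(seed: int, n_subjects: int = 12,
                      schedule: InductionSchedule | None = None) -> pd.DataFrame:
    """Non-adaptive subjects: per-subject mean induced shift (expected null)."""
    schedule = schedule or InductionSchedule(days=1, runs_per_day=4)
    rows = []
    for s in range(n_subjects):
        sub = _sub_seed(seed, 30, s)
        gt = standard_ground_truth(sub)
        _, runs, _ = simulate_subject_session(gt, _sub_seed(sub, 1))
        dec = train_preference_decoder(runs, gt.target_roi)
        log = run_closed_loop(
            gt, dec, make_policy("non_adaptive"), schedule, "higher",
            seed=_sub_seed(sub, 2), keep_runs=False,
        )
        rows.append({"subject": s, "mean_shift": log.mean_shift})
    return pd.DataFrame(rows)


def permutation_type1_study(seed: int, n_tests: int = 1000, n: int = 24,
                            n_perm: int = 200) -> dict:
    """Type-I calibration of the top-5% permutation rule on independent pairs."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for k in range(n_tests):
        x, y = rng.normal(size=(2, n))
        res = permutation_corr(x, y, n_perm=n_perm, seed=_sub_seed(seed, 40, k))
        rejections += bool(res.significant)
    return {"rate": rejections / n_tests, "n_tests": n_tests, "n_perm": n_perm}


def _leak_replicate_data(seed: int, coupling: dict[str, float], n_regions: int,
                         n_runs: int = 4):
    """One subject's sample-level leak inputs (induction-like)."""
    from .synth import couple_rois

    gt = make_ground_truth(
        n_other_rois=n_regions, roi_voxels=12, target_voxels=14,
        coupling=coupling, noise_sd=1.0, seed=_sub_seed(seed, 0),
    )
    pool, runs, _ = simulate_subject_session(gt, _sub_seed(seed, 1), n_runs=n_runs)
    sm = extract_session(runs, period="rating", mode="offline")
    target = sm.select_voxels(gt.target_indices)
    # induction-like target estimates: the decoder read-out of each trial
    tr, _ = normalize_train_test(target, target)
    dec = fit_sparse_decoder(tr, target.ratings)
    estimates = np.asarray(predict_rating(dec, tr.samples, clip=False))
    regions = couple_rois(target, gt, seed=_sub_seed(seed, 2))
    return gt, target, estimates, regions


def roi_leak_specificity_study(
    seed: int,
    n_replicates: int = 200,
    n_regions: int = 6,
    n_perm: int = 239,
    coupled_region: str | None = None,
    coupling: float = 0.0,
) -> dict:
    """Family-wise specificity (and sensitivity) of the ROI leak analysis.

    With all couplings zero, counts the replicates in which any off-target
    region reaches Bonferroni-corrected significance (family-wise false
    positives) under the pipeline permutation of
    :func:`decnef.leakage.roi_leak_significance`.  With one coupled region,
    counts how often that region is detected.  The target region itself is
    the positive control and must dominate every off-target region's
    reconstruction performance.
    """
    coupling_map = {f"R{i + 1:02d}": 0.0 for i in range(n_regions)}
    if coupled_region is not None:
        coupling_map[coupled_region] = coupling
    fp = detected = positive_control_ok = 0
    family = n_regions + 1          # every tested region, target included
    alpha = 0.05 / family
    for rep in range(n_replicates):
        rseed = _sub_seed(seed, 50, rep)
        gt, target, estimates, regions = _leak_replicate_data(
            rseed, coupling_map, n_regions
        )
        z_by_region = {
            gt.target_roi: lk.roi_leak(estimates, target, region=gt.target_roi).mean_z
        }
        any_fp = False
        for i, name in enumerate(sorted(regions)):
            res = lk.roi_leak_significance(
                estimates, regions[name], n_perm=n_perm, alpha=alpha,
                region=name, seed=_sub_seed(rseed, 4, i),
            )
            z_by_region[name] = res["mean_z"]
            if res["significant"]:
                if name == coupled_region:
                    detected += 1
                else:
                    any_fp = True
        fp += any_fp
        cc_z = z_by_region.pop(gt.target_roi)
        positive_control_ok += cc_z >= max(z_by_region.values())
    out = {
        "fwer": fp / n_replicates,
        "positive_control_rate": positive_control_ok / n_replicates,
        "n_replicates": n_replicates,
    }
    if coupled_region is not None:
        out["detection_rate"] = detected / n_replicates
    return out


def searchlight_dissociation_study(seed: int, coupling: float = 0.9,
                                   spheres_per_roi: int = 6) -> dict:
    """Stage contrast of the searchlight maps on one synthetic subject.

    The coupled region mirrors the target pattern in both stages; the
    silent region never does.  Decoder-stage maps should light up the
    target and coupled regions; induction-stage maps should separate the
    coupled region from the silent one while the target stays highest.
    """
    gt = make_ground_truth(
        n_other_rois=2, roi_voxels=24, target_voxels=24,
        coupling={"R01": coupling, "R02": 0.0}, noise_sd=1.0, gap=3,
        seed=_sub_seed(seed, 60),
    )
    pool, runs, _ = simulate_subject_session(gt, _sub_seed(seed, 61), n_runs=6)
    sm = extract_session(runs, period="rating", mode="offline")
    rng = np.random.default_rng(_sub_seed(seed, 62))
    all_spheres = lk.build_spheres(gt.grid_shape, gt.voxel_dims_mm, radius_mm=7.5)
    spheres = {}
    for roi, idx in gt.roi_layout.items():
        for c in rng.choice(np.asarray(idx), spheres_per_roi, replace=False):
            spheres[int(c)] = all_spheres[int(c)]
    cfg = lk.LassoConfig(lam=0.3)

    target = sm.select_voxels(gt.target_indices)
    inner = lk.inner_target_estimates(target, sm.ratings)
    dec_map = lk.searchlight_decoder_stage(sm, inner, spheres, cfg, grid_shape=gt.grid_shape)

    # induction-stage samples: 3-volume averages with induced shifts
    n_ind = 60
    shifts = rng.normal(0.5, 0.8, n_ind)
    X = rng.normal(0.0, gt.noise_sd / np.sqrt(3), (n_ind, gt.n_voxels))
    pattern = np.outer(shifts, gt.encode_pattern_unit)
    X[:, gt.target_indices] += pattern
    from .synth import _coupling_map
    for roi, c in gt.coupling.items():
        if c > 0:
            X[:, np.asarray(gt.roi_layout[roi])] += c * (pattern @ _coupling_map(gt, roi).T)
    from .preprocess import SampleMatrix
    ind_sm = SampleMatrix(samples=X, run_labels=np.repeat(np.arange(4), n_ind // 4),
                          period="induction", window_volumes=3)
    ind_est = X[:, gt.target_indices] @ gt.true_weights
    targets = lk.full_fit_targets(target, sm.ratings)
    ind_map = lk.searchlight_induction_stage(
        sm, targets, ind_sm, ind_est, spheres, cfg, grid_shape=gt.grid_shape
    )

    def roi_means(m):
        out = {}
        for roi, idx in gt.roi_layout.items():
            v = m.values[np.asarray(idx)]
            out[roi] = float(np.nanmean(v[np.isfinite(v)]))
        return out

    return {
        "decoder_stage": roi_means(dec_map),
        "induction_stage": roi_means(ind_map),
        "coupled_region": "R01",
        "silent_region": "R02",
    }


def period_control_study(seed: int) -> dict:
    """S4/S5-style controls on one oracle subject (induction-only modulation).

    Fixation and inter-trial shifts should be indistinguishable from zero
    while the induction-period shift is strongly positive; the ROI-mean
    amplitude contrast stays near zero because the induced pattern has
    (near) zero voxel mean.
    """
    gt = standard_ground_truth(_sub_seed(seed, 70))
    _, runs, _ = simulate_subject_session(gt, _sub_seed(seed, 71))
    dec = train_preference_decoder(runs, gt.target_roi)
    sched = InductionSchedule(days=3, runs_per_day=3)
    log = run_closed_loop(
        gt, dec, make_policy("oracle", gt=gt), sched, "higher",
        seed=_sub_seed(seed, 72), keep_runs=True,
    )
    tab = period_shift_analysis(dec, log)
    out = {}
    for period, grp in tab.groupby("period"):
        t, p = sps.ttest_1samp(grp["shift"], 0.0)
        out[period] = {"mean_shift": float(grp["shift"].mean()), "t": float(t), "p": float(p)}
    per_voxel, roi_mean = amplitude_contrast(log.runs, gt.target_indices)
    n_runs_total = len(log.runs)
    # across-run t of the ROI-mean contrast
    run_means = []
    for run in log.runs:
        pv, _ = amplitude_contrast([run], gt.target_indices)
        run_means.append(pv.mean())
    t_amp, p_amp = sps.ttest_1samp(run_means, 0.0)
    out["amplitude_contrast"] = {
        "roi_mean": float(roi_mean), "t": float(t_amp), "p": float(p_amp),
        "n_runs": n_runs_total,
    }
    return out
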