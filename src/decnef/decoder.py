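"""Sparse multi-voxel preference decoder.

The decoder maps a trial's ROI activation pattern A to an estimated
preference rating on the behavioral 1-10 scale,

    R = delinearize( W^T A + artanh((b - c)/h) ),

where b is the subject's mean behavioral rating over the training trials and
``linearize``/``delinearize`` are the arc-tangent-hyperbolic map used to
treat the bounded Likert scale as an unbounded regression target
(artanh((r - c)/h), center c = 5.5, half-range h = 5, so the 1..10 scale maps
into +/- artanh(0.9)).  W is fit by sparse Bayesian linear regression with an
automatic-relevance-determination prior: each voxel carries its own weight
precision which is iterated to convergence, and voxels whose precision
diverges are pruned, giving automatic voxel selection.  Behind this surface
the estimator is scikit-learn's :class:`~sklearn.linear_model.ARDRegression`
(per-weight relevance, shared noise variance).

Zero activation therefore decodes to the subject's mean rating b, and the
decoder's linear score W^T A is the rating-scale shift statistic used by the
closed-loop stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import ARDRegression

from .preprocess import RunSeries, SampleMatrix, extract_session, normalize_train_test

__all__ = [
    "ARTANH_CENTER",
    "ARTANH_HALF_RANGE",
    "PreferenceDecoder",
    "linearize_rating",
    "delinearize_rating",
    "fit_sparse_decoder",
    "predict_rating",
    "linear_score",
    "loro_cv",
    "CVResult",
    "train_preference_decoder",
    "roi_cv_table",
    "compare_rois",
]

ARTANH_CENTER = 5.5
ARTANH_HALF_RANGE = 5.0

#: ARD weight-precision threshold above which a voxel is pruned (the
#: estimator's default; precisions of irrelevant voxels pass it quickly,
#: informative voxels stay orders of magnitude below)
PRUNE_PRECISION = 1e4
MAX_ITER = 500
TOL = 1e-6


def linearize_rating(
    r,
    center: float = ARTANH_CENTER,
    half_range: float = ARTANH_HALF_RANGE,
):
    """Map Likert ratings through artanh((r - center)/half_range).

    Strictly increasing; :func:`delinearize_rating` inverts it exactly.
    Raises for ratings at or beyond ``center +/- half_range`` where the map
    diverges.
    """
    r = np.asarray(r, dtype=float)
    u = (r - center) / half_range
    if np.any(np.abs(u) >= 1):
        raise ValueError(
            f"rating outside the open interval ({center - half_range}, "
            f"{center + half_range}); the artanh map diverges"
        )
    out = np.arctanh(u)
    return float(out) if out.ndim == 0 else out


def delinearize_rating(
    y,
    center: float = ARTANH_CENTER,
    half_range: float = ARTANH_HALF_RANGE,
):
    """Inverse of :func:`linearize_rating`."""
    y = np.asarray(y, dtype=float)
    out = center + half_range * np.tanh(y)
    return float(out) if out.ndim == 0 else out


@dataclass
class PreferenceDecoder:
    """Sparse linear preference decoder for one ROI."""

    weights: np.ndarray
    bias: float
    center: float = ARTANH_CENTER
    half_range: float = ARTANH_HALF_RANGE
    roi: str | None = None
    #: indices of the ROI's voxels in the study grid (None when the decoder
    #: was fit on an already-restricted matrix)
    voxel_indices: np.ndarray | None = None
    #: per-voxel normalization learned at training time; applied by
    #: :func:`predict_rating` when present
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not 1.0 <= self.bias <= 10.0:
            raise ValueError("decoder bias must lie on the 1-10 rating scale")

    @property
    def selected_voxels(self) -> np.ndarray:
        return np.flatnonzero(self.weights != 0)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.weights))


def _as_matrix(samples) -> np.ndarray:
    if isinstance(samples, SampleMatrix):
        return samples.samples
    return np.asarray(samples, dtype=float)


def fit_sparse_decoder(
    samples,
    ratings,
    center: float = ARTANH_CENTER,
    half_range: float = ARTANH_HALF_RANGE,
    roi: str | None = None,
    voxel_indices: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    prune_precision: float = PRUNE_PRECISION,
) -> PreferenceDecoder:
    """Fit decoder weights by ARD regression on linearized, bias-centered ratings.

    The constant term (bias) is the subject's average behavioral rating of
    the training trials, measured on the linearization scale: the fit is
    centered at the mean of the artanh-linearized ratings and the bias is
    that center's delinearized value (within ~0.2 rating points of the
    arithmetic mean; the arithmetic mean itself is not exactly reachable by
    a fit against mean-centered voxel columns).  The regression carries no
    free intercept, so a zero pattern decodes exactly to the bias.
    Constant ratings are a zero-signal degenerate case: every weight is
    pruned and the decoder predicts the bias everywhere.
    """
    X = _as_matrix(samples)
    ratings = np.asarray(ratings, dtype=float)
    if X.shape[0] != ratings.shape[0]:
        raise ValueError("one rating per sample row is required")
    lin_center = float(np.mean(linearize_rating(ratings, center, half_range)))
    bias = float(delinearize_rating(lin_center, center, half_range))
    y = linearize_rating(ratings, center, half_range) - lin_center
    meta = {"n_samples": int(X.shape[0]), "n_voxels": int(X.shape[1])}
    if np.allclose(y, 0.0):
        weights = np.zeros(X.shape[1])
    else:
        ard = ARDRegression(
            fit_intercept=False,
            max_iter=max_iter,
            tol=tol,
            threshold_lambda=prune_precision,
        )
        ard.fit(X, y)
        weights = np.asarray(ard.coef_, dtype=float)
        if not np.all(np.isfinite(weights)):
            raise RuntimeError(
                "ARD regression failed to converge to finite weights "
                f"(n={X.shape[0]}, p={X.shape[1]}, max_iter={max_iter}); "
                "inspect the sample matrix scaling"
            )
        meta["noise_precision"] = float(ard.alpha_)
    return PreferenceDecoder(
        weights=weights,
        bias=bias,
        center=center,
        half_range=half_range,
        roi=roi,
        voxel_indices=voxel_indices,
        training_meta=meta,
    )


def linear_score(dec: PreferenceDecoder, sample) -> np.ndarray | float:
    """W^T A (plus training normalization if the decoder stores one)."""
    A = np.asarray(sample, dtype=float)
    single = A.ndim == 1
    A2 = A[None, :] if single else A
    if A2.shape[1] != dec.weights.shape[0]:
        raise ValueError(
            f"sample has {A2.shape[1]} voxels, decoder expects {dec.weights.shape[0]}"
        )
    if dec.norm_mean is not None:
        A2 = (A2 - dec.norm_mean) / dec.norm_sd
    s = A2 @ dec.weights
    return float(s[0]) if single else s


def predict_rating(dec: PreferenceDecoder, sample, clip: bool = True):
    """Decode a pattern (or matrix of patterns) to estimated rating(s).

    The linear score is inverted through the tanh map around the decoder
    bias; with ``clip`` the result is forced onto [1, 10], the scale on which
    the feedback rule operates.  Leave ``clip`` off inside cross-validation
    correlations.
    """
    s = linear_score(dec, sample)
    y = np.asarray(s) + linearize_rating(dec.bias, dec.center, dec.half_range)
    r = delinearize_rating(y, dec.center, dec.half_range)
    if clip:
        r = np.clip(r, 1.0, 10.0)
    return float(r) if np.ndim(r) == 0 else r


_R_EPS = 1e-15


def fisher_safe(r: float) -> float:
    """artanh with |r| clipped infinitesimally inside the open interval."""
    return float(np.arctanh(np.clip(r, -1 + _R_EPS, 1 - _R_EPS)))


@dataclass
class CVResult:
    """Leave-one-run-out decoding performance."""

    run_ids: np.ndarray
    fold_r: np.ndarray
    fold_z: np.ndarray
    predictions: np.ndarray  # pooled held-out predictions, trial order
    ratings: np.ndarray
    run_labels: np.ndarray

    @property
    def mean_z(self) -> float:
        """Fold-averaged Fisher z (never the r of pooled predictions)."""
        return float(self.fold_z.mean())

    @property
    def n_folds(self) -> int:
        return len(self.run_ids)


def loro_cv(
    samples,
    ratings,
    run_labels,
    **fit_kw,
) -> CVResult:
    """Leave-one-run-out cross-validated decoding performance.

    One fold per run; train and test are normalized by the training
    statistics only, a decoder is fit per fold, and the per-fold Pearson r
    between held-out predictions (unclipped) and ratings is Fisher
    transformed and averaged over folds.
    """
    if isinstance(samples, SampleMatrix):
        sm = samples
    else:
        sm = SampleMatrix(
            samples=np.asarray(samples, dtype=float),
            run_labels=np.asarray(run_labels),
            period="unspecified",
            window_volumes=0,
        )
    ratings = np.asarray(ratings, dtype=float)
    run_labels = np.asarray(run_labels)
    runs = pd.unique(run_labels)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 distinct runs")
    counts = pd.Series(run_labels).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"run(s) {small} have fewer than 2 trials; fold r undefined")

    fold_r, fold_z = [], []
    predictions = np.full(len(ratings), np.nan)
    for run in runs:
        test_mask = run_labels == run
        train = _subset(sm, ~test_mask)
        test = _subset(sm, test_mask)
        train_n, test_n = normalize_train_test(train, test)
        dec = fit_sparse_decoder(train_n, ratings[~test_mask], **fit_kw)
        pred = predict_rating(dec, test_n.samples, clip=False)
        predictions[test_mask] = pred
        r = float(np.corrcoef(pred, ratings[test_mask])[0, 1]) if np.std(pred) > 0 else 0.0
        fold_r.append(r)
        fold_z.append(fisher_safe(r))
    return CVResult(
        run_ids=np.asarray(runs),
        fold_r=np.asarray(fold_r),
        fold_z=np.asarray(fold_z),
        predictions=predictions,
        ratings=ratings,
        run_labels=run_labels,
    )


def _subset(sm: SampleMatrix, mask: np.ndarray) -> SampleMatrix:
    def take(a):
        return None if a is None else a[mask]

    return SampleMatrix(
        samples=sm.samples[mask],
        run_labels=sm.run_labels[mask],
        period=sm.period,
        window_volumes=sm.window_volumes,
        trial_index=take(sm.trial_index),
        face_ids=take(sm.face_ids),
        ratings=take(sm.ratings),
        voxel_indices=sm.voxel_indices,
    )


def train_preference_decoder(
    runs: Sequence[RunSeries],
    roi: str,
    period: str = "rating",
    **fit_kw,
) -> PreferenceDecoder:
    """Offline-preprocess a session, fit on all trials, store normalization.

    This is the decoder handed to the closed-loop stage: samples are
    extracted with the offline chain, restricted to the ROI, normalized to
    per-voxel mean 0 / variance 1 (the statistics are kept on the decoder so
    online patterns pass through the same transform), and fit on every trial.
    """
    sm = extract_session(runs, period=period, mode="offline")
    roi_idx = runs[0].roi_map.get(roi)
    if roi_idx is None or len(roi_idx) == 0:
        raise ValueError(f"ROI '{roi}' is missing or empty")
    sm_roi = sm.select_voxels(np.asarray(roi_idx, dtype=int))
    mean = sm_roi.samples.mean(axis=0)
    sd = sm_roi.samples.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance training voxel(s) {bad.tolist()} in ROI '{roi}'")
    normed = (sm_roi.samples - mean) / sd
    dec = fit_sparse_decoder(
        normed,
        sm_roi.ratings,
        roi=roi,
        voxel_indices=np.asarray(roi_idx, dtype=int),
        **fit_kw,
    )
    dec.norm_mean = mean
    dec.norm_sd = sd
    dec.training_meta["n_runs"] = len(runs)
    return dec


def roi_cv_table(
    runs: Sequence[RunSeries],
    rois: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    period: str = "rating",
) -> pd.DataFrame:
    """Per-ROI LORO decoding performance with permutation z, one subject.

    Returns one row per ROI with the fold-averaged Fisher z and the
    permutation z of the pooled held-out correlation (the statistic the
    between-subject ROI comparison operates on).
    """
    from .stats import permutation_corr  # local import; stats depends on nothing here

    sm = extract_session(runs, period=period, mode="offline")
    rows = []
    rng_seeds = np.random.SeedSequence(seed).spawn(len(rois))
    for roi, ss in zip(rois, rng_seeds):
        idx = runs[0].roi_map.get(roi)
        if idx is None or len(idx) == 0:
            raise ValueError(f"ROI '{roi}' is missing or empty")
        cv = loro_cv(sm.select_voxels(np.asarray(idx, dtype=int)), sm.ratings, sm.run_labels)
        perm = permutation_corr(
            cv.predictions, cv.ratings, n_perm=n_perm, seed=int(ss.generate_state(1)[0] % (2**31))
        )
        rows.append({"roi": roi, "mean_z": cv.mean_z, "perm_z": perm.z, "r": perm.r})
    return pd.DataFrame(rows)


@dataclass
class RoiComparison:
    ranking: pd.DataFrame
    pairwise: pd.DataFrame


def compare_rois(z_table: pd.DataFrame, alpha: float = 0.05) -> RoiComparison:
    """Rank ROIs and test the best one against the rest across subjects.

    ``z_table``: subjects x ROIs matrix of permutation z-scores (one row per
    subject).  ROIs are ranked by mean z; the top ROI is compared to every
    other by a paired two-tailed t-test on per-subject z-scores with
    Bonferroni correction over the comparison family.
    """
    if z_table.empty or z_table.shape[1] < 2:
        raise ValueError("need at least 2 ROIs to compare")
    means = z_table.mean(axis=0).sort_values(ascending=False)
    ranking = pd.DataFrame({"roi": means.index, "mean_z": means.values})
    best = means.index[0]
    family = z_table.shape[1] - 1
    rows = []
    for other in means.index[1:]:
        t, p = sps.ttest_rel(z_table[best], z_table[other])
        rows.append(
            {
                "roi_a": best,
                "roi_b": other,
                "t": float(t),
                "p_raw": float(p),
                "p_bonf": min(1.0, float(p) * family),
                "significant": float(p) * family <= alpha,
            }
        )
    return RoiComparison(ranking=ranking, pairwise=pd.DataFrame(rows))
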