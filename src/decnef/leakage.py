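"""Leakage analyses: can other regions reconstruct the target-ROI read-out?

If the preference-related pattern induced in the target ROI "leaked out" to
another region, that region's activation patterns should reconstruct the
target's estimated ratings trial by trial.  Two instruments quantify this:

* an ROI-based analysis — a sparse (ARD) regression from each region's
  pattern to the target estimates, scored by leave-one-run-out
  cross-validated correlation (Fisher-transformed), with the target region
  itself as positive control;
* a searchlight map — a sphere (default radius 15 mm) moved over the
  gray-matter grid, with an L1-regularized (LASSO) reconstruction inside
  each sphere.  During the decoder-construction stage the sphere model is
  scored by a nested procedure (an inner leave-one-run-out loop produces the
  target estimates, an outer leave-one-out loop within each held-out run
  produces the reconstructions); during the induction stage a model trained
  on decoder-stage data is applied to the induction samples.

Maps are Fisher-z valued at gray-matter sphere centers (NaN elsewhere) and
can be smoothed with a NaN-aware Gaussian kernel (FWHM in mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .decoder import fisher_safe, fit_sparse_decoder, loro_cv, predict_rating
from .preprocess import SampleMatrix

__all__ = [
    "LassoConfig",
    "LeakResult",
    "SearchlightMap",
    "roi_leak",
    "roi_leak_table",
    "roi_leak_significance",
    "build_spheres",
    "searchlight_decoder_stage",
    "searchlight_induction_stage",
    "select_lambda",
    "smooth_map",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class LassoConfig:
    """L1-regularized reconstruction hyper-parameters.

    ``alpha`` is the elastic-net mixing weight and is fixed to one (pure L1);
    ``lam`` is the penalty weight, selected per subject from ``lambda_grid``
    by :func:`select_lambda`.
    """

    lam: float = 0.05
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-3, 1, 20))
    alpha: float = 1.0
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.alpha != 1.0:
            raise ValueError("the elastic-net mixing parameter is fixed to 1 (pure L1)")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def _lasso(cfg: LassoConfig) -> Lasso:
    return Lasso(alpha=cfg.lam, max_iter=cfg.max_iter)


@dataclass
class LeakResult:
    """Reconstruction performance of the target estimates from one region."""

    region: str
    fold_r: np.ndarray
    fold_z: np.ndarray
    reconstructed: np.ndarray   # pooled held-out reconstructions, trial order
    targets: np.ndarray
    bias: float                 # global mean of the target estimates

    @property
    def mean_z(self) -> float:
        return float(self.fold_z.mean())


def roi_leak(
    target_estimates,
    roi_samples: SampleMatrix,
    run_labels=None,
    region: str = "",
    **ard_kw,
) -> LeakResult:
    """Sparse-regression reconstruction of the target estimates from one ROI.

    The same ARD estimator as the preference decoder maps the region's
    pattern to the target read-out; the constant term is the average of the
    target estimates over the whole stage (a single global constant — a
    fold-local training mean would inject the leave-one-run-out mean of the
    targets into every reconstruction and anti-correlate with the held-out
    run).  Scored by leave-one-run-out CV: per-fold Pearson r of held-out
    reconstructions, Fisher-transformed and averaged.
    """
    y = np.asarray(target_estimates, dtype=float)
    if roi_samples.n_voxels == 0:
        raise ValueError(f"region '{region}' has no voxels")
    if len(y) != roi_samples.n_trials:
        raise ValueError("one target estimate per trial row is required")
    labels = np.asarray(run_labels) if run_labels is not None else roi_samples.run_labels
    runs = pd.unique(labels)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")

    from sklearn.linear_model import ARDRegression

    b = float(y.mean())
    fold_r, fold_z = [], []
    recon = np.full(len(y), np.nan)
    for run in runs:
        te = labels == run
        X_tr, X_te = roi_samples.samples[~te], roi_samples.samples[te]
        ard = ARDRegression(fit_intercept=False, max_iter=300, threshold_lambda=1e4)
        ard.fit(X_tr, y[~te] - b)
        pred = X_te @ ard.coef_ + b
        recon[te] = pred
        r = float(np.corrcoef(pred, y[te])[0, 1]) if np.std(pred) > 0 else 0.0
        fold_r.append(r)
        fold_z.append(fisher_safe(r))
    return LeakResult(
        region=region,
        fold_r=np.asarray(fold_r),
        fold_z=np.asarray(fold_z),
        reconstructed=recon,
        targets=y,
        bias=float(y.mean()),
    )


def roi_leak_table(
    regions: dict[str, SampleMatrix],
    target_estimates,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ROI-based leak analysis over a set of regions, with permutation z.

    One row per region: fold-averaged Fisher z of the reconstruction and the
    permutation z / top-rank p of the pooled reconstruction-vs-target
    correlation.  ``significant`` applies the Bonferroni correction over the
    regions tested.  The permutation is run-aware (runs exchanged as blocks,
    trials shuffled within runs): run-wise normalization couples trials of
    the same run, and a fully free pairing permutation would understate the
    null variance of the pooled correlation.
    """
    from .stats import permutation_corr

    names = sorted(regions)
    seeds = np.random.SeedSequence(seed).spawn(len(names))
    m = len(names)
    rows = []
    for name, ss in zip(names, seeds):
        res = roi_leak(target_estimates, regions[name], region=name)
        perm = permutation_corr(
            res.reconstructed,
            res.targets,
            n_perm=n_perm,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            groups=regions[name].run_labels,
        )
        rows.append(
            {
                "region": name,
                "mean_z": res.mean_z,
                "r": perm.r,
                "perm_z": perm.z,
                "p_one": perm.p_one,
                "p_bonf": min(1.0, perm.p_one * m),
                "significant": perm.p_one * m <= alpha,
            }
        )
    return pd.DataFrame(rows)


def roi_leak_significance(
    target_estimates,
    roi_samples: SampleMatrix,
    n_perm: int = 239,
    alpha: float = 0.05,
    region: str = "",
    seed: int = 0,
) -> dict:
    """Pipeline-permutation significance of a region's reconstruction.

    Correlating *cross-validated* reconstructions with their own targets is
    not exchangeable under a pairing permutation: CV predictions carry a
    systematic anti-correlation of order p/n and an inflated variance, so
    permuting the finished vectors understates the null spread.  Here the
    permutation is applied where the null lives — the targets are permuted
    (run-aware) *before* the reconstruction is refit — giving a calibrated
    top-rank p.  Permutation stops early once significance at ``alpha`` is
    no longer attainable, so null regions cost only a handful of refits.
    """
    from .stats import _group_permutations

    y = np.asarray(target_estimates, dtype=float)
    obs = roi_leak(y, roi_samples, region=region)
    r_obs = float(np.corrcoef(obs.reconstructed, y)[0, 1])
    rng = np.random.default_rng(seed)
    perm_idx = _group_permutations(rng, np.asarray(roi_samples.run_labels), n_perm)
    # significant iff (1 + count)/(n_perm + 1) <= alpha
    max_count = int(np.floor(alpha * (n_perm + 1))) - 1
    count = done = 0
    for k in range(n_perm):
        yp = y[perm_idx[k]]
        rp = roi_leak(yp, roi_samples, region=region)
        r_perm = float(np.corrcoef(rp.reconstructed, yp)[0, 1])
        count += r_perm >= r_obs
        done = k + 1
        if count > max_count:
            break
    exhausted = done == n_perm
    p = (1 + count) / (done + 1) if not exhausted else (1 + count) / (n_perm + 1)
    return {
        "region": region,
        "r": r_obs,
        "mean_z": obs.mean_z,
        "significant": exhausted and count <= max_count,
        "p_upper_bound": p,
        "n_perm_run": done,
    }


def build_spheres(
    grid_shape: tuple[int, int, int],
    voxel_dims_mm: tuple[float, float, float],
    radius_mm: float = 15.0,
    gray_mask: np.ndarray | None = None,
) -> dict[int, np.ndarray]:
    """Searchlight membership: gray voxels within ``radius_mm`` of each center.

    Center-to-center Euclidean distance in mm; spheres are clipped at mask
    borders.  Returns flat center index -> array of member flat indices.
    """
    dims = np.asarray(voxel_dims_mm, dtype=float)
    if np.any(dims <= 0):
        raise ValueError("voxel dimensions must be positive")
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    if gray_mask is None:
        gray = np.ones(grid_shape, dtype=bool)
    else:
        gray = np.asarray(gray_mask, dtype=bool).reshape(grid_shape)

    reach = np.floor(radius_mm / dims).astype(int)
    offsets = []
    for dx in range(-reach[0], reach[0] + 1):
        for dy in range(-reach[1], reach[1] + 1):
            for dz in range(-reach[2], reach[2] + 1):
                if np.sqrt(((np.array([dx, dy, dz]) * dims) ** 2).sum()) <= radius_mm:
                    offsets.append((dx, dy, dz))
    offsets = np.asarray(offsets, dtype=int)

    spheres: dict[int, np.ndarray] = {}
    centers = np.argwhere(gray)
    for cx, cy, cz in centers:
        pts = offsets + (cx, cy, cz)
        ok = np.all((pts >= 0) & (pts < grid_shape), axis=1)
        pts = pts[ok]
        flat = np.ravel_multi_index(pts.T, grid_shape)
        flat = flat[gray.ravel()[flat]]
        spheres[int(np.ravel_multi_index((cx, cy, cz), grid_shape))] = flat
    return spheres


@dataclass
class SearchlightMap:
    """Fisher-z leak map on the voxel grid (NaN outside sphere centers)."""

    values: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_dims_mm: tuple[float, float, float]
    radius_mm: float
    stage: str
    fwhm_mm: float | None = None

    def volume(self) -> np.ndarray:
        return self.values.reshape(self.grid_shape)


def inner_target_estimates(
    target_samples: SampleMatrix, ratings, run_labels=None
) -> np.ndarray:
    """Inner-loop reconstruction targets: LORO-estimated ratings from the
    full target ROI (sparse regression, one fold per run)."""
    labels = run_labels if run_labels is not None else target_samples.run_labels
    cv = loro_cv(target_samples, np.asarray(ratings, dtype=float), labels)
    return cv.predictions


def searchlight_decoder_stage(
    all_samples: SampleMatrix,
    target_estimates,
    spheres: dict[int, np.ndarray],
    cfg: LassoConfig,
    grid_shape: tuple[int, int, int] = None,
    voxel_dims_mm: tuple[float, float, float] = (3.0, 3.0, 3.5),
    radius_mm: float = 15.0,
) -> SearchlightMap:
    """Decoder-construction-stage leak map (nested cross-validation).

    ``target_estimates`` are the inner-loop LORO estimates from the full
    target ROI (:func:`inner_target_estimates`).  Per sphere, each held-out
    run's fold of targets is reconstructed by leave-one-out L1 regression
    over its trials, and the map value is the Fisher z of the pooled
    reconstruction-vs-target correlation over all trials (a within-fold r is
    undefined at fold size one, so pooling is the only coherent choice).
    """
    y = np.asarray(target_estimates, dtype=float)
    labels = all_samples.run_labels
    runs = pd.unique(labels)
    n_grid = all_samples.n_voxels if grid_shape is None else int(np.prod(grid_shape))
    values = np.full(n_grid, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for center, members in spheres.items():
            if len(members) == 0:
                continue
            X = all_samples.samples[:, members]
            recon = np.full(len(y), np.nan)
            for run in runs:
                fold = np.flatnonzero(labels == run)
                Xf, yf = X[fold], y[fold]
                for i in range(len(fold)):
                    keep = np.ones(len(fold), dtype=bool)
                    keep[i] = False
                    model = _lasso(cfg).fit(Xf[keep], yf[keep])
                    recon[fold[i]] = model.predict(Xf[i][None, :])[0]
            if np.std(recon) > 0:
                values[center] = fisher_safe(float(np.corrcoef(recon, y)[0, 1]))
            else:
                values[center] = 0.0
    return SearchlightMap(
        values=values,
        grid_shape=grid_shape or (n_grid, 1, 1),
        voxel_dims_mm=voxel_dims_mm,
        radius_mm=radius_mm,
        stage="decoder_construction",
    )


def searchlight_induction_stage(
    decoder_samples: SampleMatrix,
    decoder_targets,
    induction_samples: SampleMatrix,
    induction_estimates,
    spheres: dict[int, np.ndarray],
    cfg: LassoConfig,
    grid_shape: tuple[int, int, int] = None,
    voxel_dims_mm: tuple[float, float, float] = (3.0, 3.0, 3.5),
    radius_mm: float = 15.0,
) -> SearchlightMap:
    """Induction-stage leak map.

    Per sphere, one L1 model is trained on the decoder-construction samples
    (targets = full-fit estimated ratings of the target ROI) and applied,
    frozen, to the induction-stage samples; the map value is the Fisher z of
    the correlation between the sphere's reconstructions and the logged
    online estimated ratings.  Training never sees induction data.
    """
    y_tr = np.asarray(decoder_targets, dtype=float)
    y_ind = np.asarray(induction_estimates, dtype=float)
    if y_ind.size == 0:
        raise ValueError("missing induction log: no online estimated ratings")
    if len(y_ind) != induction_samples.n_trials:
        raise ValueError("one online estimate per induction trial is required")
    n_grid = decoder_samples.n_voxels if grid_shape is None else int(np.prod(grid_shape))
    values = np.full(n_grid, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for center, members in spheres.items():
            if len(members) == 0:
                continue
            model = _lasso(cfg).fit(decoder_samples.samples[:, members], y_tr)
            pred = model.predict(induction_samples.samples[:, members])
            if np.std(pred) > 0:
                values[center] = fisher_safe(float(np.corrcoef(pred, y_ind)[0, 1]))
            else:
                values[center] = 0.0
    return SearchlightMap(
        values=values,
        grid_shape=grid_shape or (n_grid, 1, 1),
        voxel_dims_mm=voxel_dims_mm,
        radius_mm=radius_mm,
        stage="induction",
    )


def full_fit_targets(target_samples: SampleMatrix, ratings) -> np.ndarray:
    """Estimated ratings from an all-trials sparse fit of the target ROI."""
    dec = fit_sparse_decoder(target_samples, np.asarray(ratings, dtype=float))
    return np.asarray(predict_rating(dec, target_samples.samples, clip=False))


def select_lambda(
    all_samples: SampleMatrix,
    ratings,
    spheres: dict[int, np.ndarray],
    cfg: LassoConfig,
    return_scores: bool = False,
):
    """Choose the L1 penalty maximizing mean sphere decoding performance.

    For each grid value, every sphere decodes the behavioral ratings by
    leave-one-run-out L1 regression; the score is the mean (across spheres)
    Fisher z of the pooled held-out correlation.  Exhaustive over the grid.
    """
    grid = list(cfg.lambda_grid)
    if not grid:
        raise ValueError("empty lambda grid")
    y = np.asarray(ratings, dtype=float)
    labels = all_samples.run_labels
    runs = pd.unique(labels)
    scores = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for lam in grid:
            zs = []
            for members in spheres.values():
                if len(members) == 0:
                    continue
                X = all_samples.samples[:, members]
                pred = np.full(len(y), np.nan)
                for run in runs:
                    te = labels == run
                    model = Lasso(alpha=lam, max_iter=cfg.max_iter).fit(X[~te], y[~te])
                    pred[te] = model.predict(X[te])
                if np.std(pred) > 0:
                    zs.append(fisher_safe(float(np.corrcoef(pred, y)[0, 1])))
                else:
                    zs.append(0.0)
            scores[lam] = float(np.mean(zs)) if zs else 0.0
    best = max(scores, key=lambda k: scores[k])
    if return_scores:
        return best, scores
    return best


def smooth_map(m: SearchlightMap, fwhm_mm: float = 4.0) -> SearchlightMap:
    """NaN-aware 3-D Gaussian smoothing of a searchlight map.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, converted to voxel units by
    the voxel dimensions.  The kernel is renormalized over valid (non-NaN)
    neighbors so mass is conserved away from mask edges; NaN cells stay NaN.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return m
    sigma_vox = [
        fwhm_mm * FWHM_TO_SIGMA / d for d in m.voxel_dims_mm
    ]
    vol = m.volume()
    valid = np.isfinite(vol)
    filled = np.where(valid, vol, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_vox, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(valid.astype(float), sigma_vox, mode="constant", cval=0.0)
    out = np.full_like(vol, np.nan)
    ok = valid & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return SearchlightMap(
        values=out.ravel(),
        grid_shape=m.grid_shape,
        voxel_dims_mm=m.voxel_dims_mm,
        radius_mm=m.radius_mm,
        stage=m.stage,
        fwhm_mm=fwhm_mm,
    )
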