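"""Inference layer: Fisher transforms, permutation-calibrated correlations,
group change tests, guess chi-square, weight-map consistency, report tables.

Correlation significance follows the top-rank permutation criterion: the
pairing of the two vectors is permuted (1000 times by default), and the
observed r is significant when it ranks within the top 5% of the permutation
distribution.  The same distribution standardizes the observed r into a
permutation z-score, which is what between-subject t-tests operate on.  All
multiple-comparison corrections are Bonferroni.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "fisher_z",
    "permutation_corr",
    "paired_change_tests",
    "guess_chisq",
    "correlation_with_group_removed",
    "weight_consistency_map",
    "one_sample_t_map",
    "build_report",
]


def fisher_z(r):
    """Fisher's variance-stabilizing transform artanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher transform requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


@dataclass
class PermutationResult:
    """Observed correlation against its label-permutation null."""

    r: float
    n: int
    n_perm: int
    perm_mean: float
    perm_sd: float
    p_one: float      # top-rank criterion on r itself
    p_two: float      # two-sided, via |r|
    z: float          # (r - perm_mean) / perm_sd
    seed: int | None

    @property
    def significant(self) -> bool:
        """Top-5% rank criterion of the permutation distribution."""
        return self.p_one <= 0.05


def _pearson_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of x against each row of Y (vectorized)."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = Yc @ xc
    den = np.sqrt((Yc**2).sum(axis=1) * (xc**2).sum())
    return num / den


def _group_permutations(
    rng: np.random.Generator, groups: np.ndarray, n_perm: int
) -> np.ndarray:
    """Index matrix of run-aware permutations.

    Whole groups (runs) are permuted as units and trials are shuffled within
    each group, so the permuted vector keeps any run-level dependence aligned
    with a run partition.  Requires equal group sizes.
    """
    labels = pd.unique(groups)
    members = [np.flatnonzero(groups == g) for g in labels]
    sizes = {len(m) for m in members}
    if len(sizes) != 1:
        raise ValueError("run-aware permutation needs equal-sized runs")
    out = np.empty((n_perm, len(groups)), dtype=int)
    for k in range(n_perm):
        order = rng.permutation(len(members))
        row = np.concatenate([rng.permutation(members[g]) for g in order])
        # place permuted blocks back at the original block positions
        positions = np.concatenate(members)
        out[k, positions] = row
    return out


def permutation_corr(
    x,
    y,
    n_perm: int = 1000,
    seed: int | None = 0,
    groups=None,
) -> PermutationResult:
    """Permutation test of the correlation between two vectors.

    ``p_one`` uses the add-one rule (1 + #{r_perm >= r_obs}) / (n_perm + 1),
    so it is never exactly zero; ``p_two`` replaces r by |r|.  The z-score
    standardizes the observed r by the permutation mean and sd.

    When ``groups`` (e.g. scanner-run labels) are given, the null is built
    from run-aware permutations: runs are exchanged as blocks and trials
    shuffled within runs.  Samples that share a run are not exchangeable
    with samples from other runs (run-wise normalization couples them), and
    a fully free permutation is anticonservative in that case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    if groups is None:
        perm_idx = np.argsort(rng.random((n_perm, len(y))), axis=1)
    else:
        perm_idx = _group_permutations(rng, np.asarray(groups), n_perm)
    r_perm = _pearson_many(x, y[perm_idx])
    p_one = (1 + int(np.sum(r_perm >= r_obs))) / (n_perm + 1)
    p_two = (1 + int(np.sum(np.abs(r_perm) >= abs(r_obs)))) / (n_perm + 1)
    mean, sd = float(r_perm.mean()), float(r_perm.std(ddof=1))
    z = (r_obs - mean) / sd if sd > 0 else np.nan
    return PermutationResult(
        r=r_obs, n=len(x), n_perm=n_perm, perm_mean=mean, perm_sd=sd,
        p_one=p_one, p_two=p_two, z=float(z), seed=seed,
    )


def paired_change_tests(data: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Paired two-tailed t-tests of post - pre per (group, face type) cell.

    ``data`` columns: subject, group, face_type, pre, post.  Bonferroni
    correction over the family of cells (raw p times family size, capped at
    one).
    """
    required = {"subject", "group", "face_type", "pre", "post"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"change table lacks column(s) {sorted(missing)}")
    cells = list(data.groupby(["group", "face_type"], sort=True))
    family = len(cells)
    rows = []
    for (group, face_type), cell in cells:
        if len(cell) < 2:
            raise ValueError(f"cell ({group}, {face_type}) has fewer than 2 subjects")
        change = cell["post"].to_numpy(float) - cell["pre"].to_numpy(float)
        if np.allclose(change.std(ddof=1), 0) and np.allclose(change.mean(), 0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(cell["post"], cell["pre"])
        rows.append(
            {
                "group": group,
                "face_type": face_type,
                "n": len(cell),
                "mean_change": float(change.mean()),
                "sem_change": float(sps.sem(change)) if len(change) > 1 else np.nan,
                "t": float(t),
                "df": len(cell) - 1,
                "p_raw": float(p),
                "p_bonf": min(1.0, float(p) * family),
                "significant": float(p) * family <= alpha,
            }
        )
    return pd.DataFrame(rows)


def guess_chisq(correct: int, total: int) -> tuple[float, float]:
    """Goodness-of-fit chi-square of guess accuracy against chance (50/50).

    One degree of freedom, no continuity correction.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError("correct count must lie in [0, total]")
    expected = total / 2.0
    chi2 = (correct - expected) ** 2 / expected + ((total - correct) - expected) ** 2 / expected
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class GroupRemovedCorrelation:
    """Correlation between shifts and behavior with the group effect removed."""

    flipped: PermutationResult       # sign of lower-group data reversed
    pooled_r: float                  # raw pooled correlation
    slope: float                     # OLS slope of changes on shifts (raw)
    intercept: float


def correlation_with_group_removed(
    shifts,
    changes,
    groups,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> GroupRemovedCorrelation:
    """Shift/behavior correlation that survives removal of the group effect.

    Both variables are multiplied by -1 for lower-group subjects (the
    higher group is untouched) before the permutation test, which destroys a
    correlation driven purely by the between-group offset; the ordinary
    pooled correlation and least-squares line are reported alongside.
    """
    shifts = np.asarray(shifts, dtype=float)
    changes = np.asarray(changes, dtype=float)
    groups = np.asarray(groups)
    unknown = set(np.unique(groups)) - {"higher", "lower"}
    if unknown:
        raise ValueError(f"unknown group label(s) {sorted(unknown)}")
    flip = np.where(groups == "lower", -1.0, 1.0)
    perm = permutation_corr(shifts * flip, changes * flip, n_perm=n_perm, seed=seed)
    pooled = float(np.corrcoef(shifts, changes)[0, 1])
    slope, intercept, *_ = sps.linregress(shifts, changes)
    return GroupRemovedCorrelation(
        flipped=perm, pooled_r=pooled, slope=float(slope), intercept=float(intercept)
    )


def one_sample_t_map(values: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Column-wise one-sample two-tailed t against 0, Bonferroni over columns.

    Columns whose values are identically zero across rows have an undefined
    t; they are reported as non-significant with ``degenerate`` set.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 rows (subjects)")
    m = X.shape[1]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    t = np.full(m, np.nan)
    p = np.ones(m)
    ok = ~degenerate
    if ok.any():
        t[ok], p[ok] = sps.ttest_1samp(X[:, ok], 0.0)
    p_bonf = np.minimum(1.0, p * m)
    return pd.DataFrame(
        {
            "mean": mean,
            "t": t,
            "p_raw": p,
            "p_bonf": p_bonf,
            "significant": (p_bonf <= alpha) & ~degenerate,
            "degenerate": degenerate,
        }
    )


def weight_consistency_map(weight_rows: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Across-subject consistency of decoder weight maps, per voxel.

    One-sample two-tailed t of each voxel's weight across subjects
    (Bonferroni over voxels), with the positive and negative mean-weight
    spatial splits attached.  Subjects must share a voxel space.
    """
    W = np.asarray(weight_rows, dtype=float)
    if W.ndim != 2:
        raise ValueError("expected subjects x voxels weight matrix")
    if W.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    table = one_sample_t_map(W, alpha=alpha)
    table["mean_positive"] = np.where(table["mean"] > 0, table["mean"], 0.0)
    table["mean_negative"] = np.where(table["mean"] < 0, table["mean"], 0.0)
    return table


_REPORT_SECTIONS = {
    "changes": ("change_scores.tsv", ["subject", "group", "face_type", "pre", "post"]),
    "shifts": ("induced_shifts.tsv", None),
    "bonuses": ("bonuses.tsv", None),
    "leak": ("leak_z_scores.tsv", None),
}


def build_report(results: dict, outdir, figures: bool = False) -> dict[str, Path]:
    """Write the study's summary tables (and optional figures) to a directory.

    ``results`` must provide the upstream artifacts: ``changes`` (per-subject
    pre/post ratings per group and face type, the layout the omnibus ANOVA
    consumes), ``shifts`` (per-subject or per-trial induced shifts),
    ``bonuses`` and ``leak`` tables.  Every emitted number comes from an
    upstream operation; a missing artifact is an error naming the stage.
    Output is deterministic for identical inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for key, (fname, columns) in _REPORT_SECTIONS.items():
        if key not in results:
            raise ValueError(f"report input missing upstream artifact '{key}'")
        table = results[key]
        if not isinstance(table, pd.DataFrame):
            raise ValueError(f"artifact '{key}' must be a DataFrame")
        if columns is not None:
            missing = set(columns) - set(table.columns)
            if missing:
                raise ValueError(f"artifact '{key}' lacks column(s) {sorted(missing)}")
            table = table[columns + [c for c in table.columns if c not in columns]]
        if key == "changes" and "change" not in table.columns:
            table = table.assign(change=table["post"] - table["pre"])
        path = outdir / fname
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written[key] = path

    summary = {
        "sections": sorted(_REPORT_SECTIONS),
        "n_rows": {k: int(len(results[k])) for k in _REPORT_SECTIONS},
    }
    spath = outdir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written["summary"] = spath

    if figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ch = results["changes"]
        fig, ax = plt.subplots(figsize=(5, 4))
        for (group, face_type), cell in ch.groupby(["group", "face_type"]):
            delta = cell["post"] - cell["pre"]
            ax.errorbar(
                [f"{group}\n{face_type}"], [delta.mean()],
                yerr=[sps.sem(delta)] if len(delta) > 1 else None,
                fmt="o", capsize=4,
            )
        ax.axhline(0, color="gray", lw=0.8)
        ax.set_ylabel("rating change (post - pre)")
        fig.tight_layout()
        fpath = outdir / "change_scores.png"
        fig.savefig(fpath, dpi=120)
        plt.close(fig)
        written["figure_changes"] = fpath
    return written
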