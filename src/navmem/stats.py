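"""Group inference for the subsequent-memory and navigation analyses.

Implements subject-level contrast construction, one/two-sample t tests,
cluster-based permutation statistics on time(-frequency) maps with a
sign-flip null, pooled sign-flip thresholds for vertex maps, spatial
aggregation of electrode effects onto abstract 3-D point clouds, the
hemisphere x condition lateralization ANOVA, narrowband-oscillation
detection against a robust 1/f fit, and within-subject SEMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import ndimage
from scipy import stats as sp_stats

__all__ = [
    "build_contrast",
    "group_ttest",
    "paired_ttest",
    "two_sample_ttest",
    "cluster_permutation",
    "signflip_map_threshold",
    "spatial_aggregate",
    "laterality_anova",
    "narrowband_detect",
    "within_subject_sem",
    "Cluster",
    "ClusterResult",
    "NarrowbandResult",
]


# ---------------------------------------------------------------------------
# contrasts and t tests
# ---------------------------------------------------------------------------

def build_contrast(
    band_values: np.ndarray,
    condition_a: np.ndarray,
    condition_b: np.ndarray,
    channels: pd.DataFrame,
    subject: str,
    contrast: str,
    band: str,
    region: str | None = "hippocampus",
) -> pd.DataFrame:
    """Subject-level z-power contrast rows (one per hemisphere).

    ``band_values`` is events x channels; ``condition_a``/``condition_b``
    are boolean event masks (e.g. remembered vs forgotten).  Per electrode
    the contrast is the difference of condition means (nan-aware, so
    rejected cells drop out); electrodes are then averaged within each
    hemisphere after an optional region filter.  Electrodes lacking events
    in either condition are skipped with a warning.
    """
    rows = []
    for hemi in ("L", "R"):
        sel = channels["hemisphere"] == hemi
        if region is not None:
            sel &= channels["region"] == region
        idx = np.flatnonzero(sel.to_numpy())
        diffs = []
        for c in idx:
            a = band_values[condition_a, c]
            b = band_values[condition_b, c]
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if a.size == 0 or b.size == 0:
                warnings.warn(
                    f"electrode {channels['channel'].iloc[c]} has an empty condition; skipped",
                    stacklevel=2,
                )
                continue
            diffs.append(a.mean() - b.mean())
        if diffs:
            rows.append(
                {
                    "subject": subject,
                    "hemisphere": hemi,
                    "band": band,
                    "contrast": contrast,
                    "value": float(np.mean(diffs)),
                    "n_electrodes": len(diffs),
                }
            )
    return pd.DataFrame(rows)


def _check_var(x: np.ndarray) -> None:
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")


def group_ttest(values) -> tuple[float, int, float]:
    """Two-sided one-sample t test of subject values against zero."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    _check_var(x)
    res = sp_stats.ttest_1samp(x, 0.0)
    return float(res.statistic), x.size - 1, float(res.pvalue)


def paired_ttest(a, b) -> tuple[float, int, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    _check_var(a - b)
    res = sp_stats.ttest_rel(a, b)
    return float(res.statistic), a.size - 1, float(res.pvalue)


def two_sample_ttest(a, b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    res = sp_stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), a.size + b.size - 2, float(res.pvalue)


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    bins: np.ndarray  # indices into the flattened map
    mass: float
    p: float
    sign: int


@dataclass
class ClusterResult:
    clusters: list
    t_map: np.ndarray
    threshold: float
    null_max: np.ndarray
    n_permutations: int

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p < 0.05]


def _grid_structure(ndim_map: int) -> np.ndarray:
    """Adjacency for labeling a (perm, *map) stack without cross-perm links.

    4-connectivity in the frequency x time plane; 1-D chain for time-only
    maps.  The leading axis (permutations) is never connected.
    """
    if ndim_map == 1:
        s = np.zeros((3, 3), dtype=int)
        s[1, :] = 1
        return s
    s = np.zeros((3, 3, 3), dtype=int)
    s[1] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    return s


def _stack_cluster_masses(t_stack: np.ndarray, threshold: float):
    """Max |cluster mass| per slice of a (n_slices, *map) t stack.

    Labels positive and negative supra-threshold clusters in one call using
    an adjacency that does not connect slices, then reduces cluster masses
    to a per-slice maximum.
    """
    n_slices = t_stack.shape[0]
    structure = _grid_structure(t_stack.ndim - 1)
    out = np.zeros(n_slices)
    slice_idx = np.arange(n_slices).reshape((n_slices,) + (1,) * (t_stack.ndim - 1))
    slice_idx = np.broadcast_to(slice_idx, t_stack.shape)
    for sign in (1, -1):
        mask = sign * t_stack > threshold
        labels, n_lab = ndimage.label(mask, structure=structure)
        if n_lab == 0:
            continue
        ids = np.arange(1, n_lab + 1)
        masses = np.abs(ndimage.sum_labels(t_stack, labels, ids))
        owner = ndimage.maximum(slice_idx, labels, ids).astype(int)
        np.maximum.at(out, owner, masses)
    return out


def _t_from_signs(maps2d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Group t maps for many sign assignments at once.

    ``maps2d`` is subjects x bins; ``signs`` is perms x subjects.  Sign flips
    leave per-bin sums of squares unchanged, so only the flipped means need
    recomputing.
    """
    n = maps2d.shape[0]
    ss = np.sum(maps2d**2, axis=0)  # invariant under sign flips
    mean = signs @ maps2d / n
    var = (ss[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def cluster_permutation(
    subject_maps: np.ndarray,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Cluster-mass permutation test on subject time(-frequency) maps.

    Per-bin one-sample t across subjects; bins exceeding the two-sided
    ``cluster_alpha`` parametric critical value form same-sign clusters
    under 4-connectivity (1-D adjacency for time-only maps); cluster mass is
    the summed t.  The null flips each subject's whole map sign at random
    per permutation and records the maximum |mass|; cluster p values carry
    the +1 correction.
    """
    maps = np.asarray(subject_maps, dtype=float)
    n = maps.shape[0]
    if n < 5:
        raise ValueError("need >= 5 subjects")
    shape = maps.shape[1:]
    flat = maps.reshape(n, -1)
    if not np.any(flat):
        return ClusterResult([], np.zeros(shape), np.nan, np.zeros(n_perm), n_perm)
    threshold = float(sp_stats.t.ppf(1 - cluster_alpha / 2, n - 1))
    t_obs = _t_from_signs(flat, np.ones((1, n)))[0].reshape(shape)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = _t_from_signs(flat, signs).reshape((n_perm,) + shape)
    null_max = _stack_cluster_masses(t_null, threshold)

    clusters = []
    # observed clusters via the same stack machinery (single slice)
    obs_stack = t_obs[None]
    struct3 = _grid_structure(t_obs.ndim)
    for sign in (1, -1):
        mask = sign * obs_stack > threshold
        labels, n_lab = ndimage.label(mask, structure=struct3)
        for lab in range(1, n_lab + 1):
            members = np.flatnonzero((labels == lab).reshape(-1))
            mass = float(t_obs.reshape(-1)[members].sum())
            p = (1 + int(np.sum(null_max >= abs(mass)))) / (n_perm + 1)
            clusters.append(Cluster(bins=members, mass=mass, p=p, sign=sign))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(clusters, t_obs, threshold, null_max, n_perm)


# ---------------------------------------------------------------------------
# sign-flip vertex-map thresholds
# ---------------------------------------------------------------------------

def signflip_map_threshold(
    subject_point_values: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    min_subjects: int = 5,
) -> tuple[float, float]:
    """Pooled sign-flip null thresholds for per-point group t statistics.

    Per permutation and point, a uniformly random half (floor(n/2)) of the
    subject values flip sign and the group t is recomputed; the 2.5th and
    97.5th percentiles of the null t pooled over permutations x points are
    the (lower, upper) significance thresholds.
    """
    x = np.asarray(subject_point_values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, n_points = x.shape
    if n < min_subjects:
        raise ValueError(f"need >= {min_subjects} subjects per point")
    rng = np.random.default_rng(seed)
    k = n // 2
    ss = np.sum(x**2, axis=0)
    null = np.empty((n_perm, n_points))
    base_sum = x.sum(axis=0)
    for p in range(n_perm):
        # random half per point: ranks of uniforms
        order = np.argsort(rng.random((n, n_points)), axis=0)
        flip = order < k
        mean = (base_sum - 2 * np.sum(np.where(flip, x, 0.0), axis=0)) / n
        var = (ss - n * mean**2) / (n - 1)
        null[p] = mean / np.sqrt(np.maximum(var, 1e-300) / n)
    pooled = null.ravel()
    return float(np.percentile(pooled, 2.5)), float(np.percentile(pooled, 97.5))


# ---------------------------------------------------------------------------
# spatial aggregation
# ---------------------------------------------------------------------------

def spatial_aggregate(
    electrode_effects: pd.DataFrame,
    target_points: np.ndarray,
    radius: float = 12.5,
    smooth_fwhm: float | None = None,
    min_subjects: int = 5,
):
    """Project per-electrode effects onto target points in a shared mm frame.

    ``electrode_effects`` needs columns subject, x, y, z, value.  Each point
    takes the mean effect of a subject's electrodes within ``radius`` mm
    (12.5 mm cortical / 3 mm hippocampal defaults in the callers); optional
    Gaussian smoothing (``smooth_fwhm`` mm) runs over each subject's
    assigned points.  Returns (per-subject point maps as a subjects x points
    array with NaN where unassigned, excluded-point mask with fewer than
    ``min_subjects`` contributors, subject index).
    """
    pts = np.asarray(target_points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty target point set")
    subjects = sorted(electrode_effects["subject"].unique())
    maps = np.full((len(subjects), len(pts)), np.nan)
    for si, subj in enumerate(subjects):
        sub = electrode_effects[electrode_effects["subject"] == subj]
        coords = sub[["x", "y", "z"]].to_numpy(float)
        vals = sub["value"].to_numpy(float)
        d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
        within = d <= radius
        counts = within.sum(axis=1)
        with np.errstate(invalid="ignore"):
            maps[si] = np.where(counts > 0, (within @ vals) / np.maximum(counts, 1), np.nan)
        if smooth_fwhm:
            maps[si] = _gaussian_point_smooth(pts, maps[si], smooth_fwhm)
    excluded = np.sum(~np.isnan(maps), axis=0) < min_subjects
    return maps, excluded, subjects


def _gaussian_point_smooth(points: np.ndarray, values: np.ndarray, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    ok = ~np.isnan(values)
    if not ok.any():
        return values
    d2 = np.sum((points[:, None, :] - points[None, ok, :]) ** 2, axis=2)
    w = np.exp(-d2 / (2 * sigma**2))
    out = values.copy()
    out[ok] = (w[ok] @ values[ok]) / w[ok].sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# lateralization ANOVA
# ---------------------------------------------------------------------------

def laterality_anova(effects: pd.DataFrame, factor_b: str = "contrast") -> dict:
    """Two-way fixed-effects ANOVA: hemisphere x condition, type-II SS.

    ``effects`` is a long SubjectEffectTable slice with columns hemisphere,
    ``factor_b`` (two levels) and value.  Returns the interaction F, dofs
    and p plus per-cell one-sample post-hoc t tests and the two-sample
    hemisphere comparisons within each condition.
    """
    df = effects.rename(columns={factor_b: "cond"}).copy()
    levels_h = sorted(df["hemisphere"].unique())
    levels_c = sorted(df["cond"].unique())
    if len(levels_h) != 2 or len(levels_c) != 2:
        raise ValueError("need exactly 2 hemispheres and 2 conditions")
    counts = df.groupby(["hemisphere", "cond"]).size()
    if len(counts) < 4 or counts.min() < 2:
        raise ValueError("need >= 2 observations in every cell")
    model = smf.ols("value ~ C(hemisphere) * C(cond)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter = table.loc["C(hemisphere):C(cond)"]
    resid = table.loc["Residual"]
    result = {
        "F_interaction": float(inter["F"]),
        "dof": (int(inter["df"]), int(resid["df"])),
        "p_interaction": float(inter["PR(>F)"]),
        "F_hemisphere": float(table.loc["C(hemisphere)", "F"]),
        "p_hemisphere": float(table.loc["C(hemisphere)", "PR(>F)"]),
        "F_condition": float(table.loc["C(cond)", "F"]),
        "p_condition": float(table.loc["C(cond)", "PR(>F)"]),
        "cells": {},
        "hemisphere_comparisons": {},
    }
    for h in levels_h:
        for c in levels_c:
            vals = df[(df["hemisphere"] == h) & (df["cond"] == c)]["value"].to_numpy()
            t, dof, p = group_ttest(vals)
            result["cells"][f"{h}:{c}"] = {"t": t, "dof": dof, "p": p, "n": vals.size}
    for c in levels_c:
        a = df[(df["hemisphere"] == levels_h[0]) & (df["cond"] == c)]["value"].to_numpy()
        b = df[(df["hemisphere"] == levels_h[1]) & (df["cond"] == c)]["value"].to_numpy()
        t, dof, p = two_sample_ttest(a, b)
        result["hemisphere_comparisons"][c] = {"t": t, "dof": dof, "p": p}
    return result


# ---------------------------------------------------------------------------
# narrowband oscillation detection
# ---------------------------------------------------------------------------

@dataclass
class NarrowbandResult:
    slope: float
    intercept: float
    residual_sd: float
    flagged: np.ndarray  # Hz
    residuals: np.ndarray
    freqs: np.ndarray


def narrowband_detect(freqs: np.ndarray, log_power: np.ndarray) -> NarrowbandResult:
    """Detect narrowband peaks above a robust 1/f background fit.

    Fits log-power against log-frequency by iteratively reweighted least
    squares with bisquare (Tukey biweight, c=4.685) weights, then flags any
    frequency whose residual exceeds one SD of the residuals.  The fitted
    slope estimates minus the background exponent.
    """
    freqs = np.asarray(freqs, float)
    y = np.asarray(log_power, float)
    if freqs.size < 10:
        raise ValueError("need >= 10 frequencies for a background fit")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite spectrum values")
    X = sm.add_constant(np.log(freqs))
    fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit(
        maxiter=50, tol=1e-8
    )
    resid = y - fit.fittedvalues
    sd = float(np.std(resid, ddof=1))
    flagged = freqs[resid > sd] if sd > 0 else np.array([])
    return NarrowbandResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        residual_sd=sd,
        flagged=flagged,
        residuals=resid,
        freqs=freqs,
    )


# ---------------------------------------------------------------------------
# within-subject SEM
# ---------------------------------------------------------------------------

def within_subject_sem(matrix: np.ndarray) -> np.ndarray:
    """Per-condition SEM after removing between-subject offsets.

    Each subject's row is centered on its own mean and the grand mean is
    restored before computing the per-condition SEM (Loftus-Masson style
    normalization for within-subject error bars).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected subjects x conditions matrix")
    if np.isnan(x).any():
        raise ValueError("missing cells")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects for a SEM")
    centered = x - x.mean(axis=1, keepdims=True) + x.mean()
    return centered.std(axis=0, ddof=1) / np.sqrt(n)
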