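"""Mass-univariate voxelwise screening with permutation-based FWE control.

Step one of the two-stage analysis: per-voxel ordinary least squares of
brain maps on the memory score with nuisance covariates (age, gender,
handedness, ethnicity), followed by family-wise-error correction by
permutation of the maximum statistic.  Three correction flavours are
provided — maxT on the voxel t-statistic, threshold-free cluster
enhancement (TFCE), and cluster-level inference at a height threshold
(cluster mass by default, extent optionally) — all calibrated through
Freedman–Lane permutation: the maps are residualised
against the nuisance covariates, the residual maps are row-permuted and
the covariate fit added back before the statistic is recomputed.

Significant-region masks feed `extract_roi_means`, whose per-subject ROI
means are the predictors of the second-stage varying-coefficient model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "StatMapResult",
    "massunivariate_glm",
    "permutation_fwe",
    "tfce_enhance",
    "cluster_threshold",
    "extract_roi_means",
    "fisher_r_to_z",
]

T_CAP = 1e6  # |t| reported for exact fits (zero residual variance)


# ------------------------------------------------------------------ types
@dataclass
class StatMapResult:
    """Voxelwise statistics with corrected p-values and significance mask."""

    tmap: np.ndarray
    pmap_fwe: np.ndarray
    mask: np.ndarray
    method: str
    n_perm: int
    null_max: np.ndarray
    alpha: float


# ------------------------------------------------------------------ GLM
def _design(outcome, covariates, n):
    outcome = np.asarray(outcome, dtype=float).ravel()
    if len(outcome) != n:
        raise ValueError("outcome length does not match number of maps")
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate rows do not match number of maps")
        for k in range(C.shape[1]):
            cols.append(C[:, k])
            names.append(f"covar{k}")
    cols.append(outcome)
    names.append("outcome")
    X = np.column_stack(cols)
    Xc = X[:, :-1]
    rank_c = np.linalg.matrix_rank(Xc)
    if rank_c < Xc.shape[1]:
        bad = []
        for j in range(Xc.shape[1]):
            keep = [k for k in range(Xc.shape[1]) if k != j]
            if np.linalg.matrix_rank(Xc[:, keep]) == rank_c:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    # outcome fully inside the covariate span carries no unique variance:
    # its t is 0 by construction rather than an error
    outcome_collinear = np.linalg.matrix_rank(X) == rank_c
    return X, outcome_collinear


def _tmaps(Y, X, j):
    """t-statistic of column j of X, per column of Y (vectorised OLS)."""
    n, q = X.shape
    dof = n - q
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T
    beta = pinv @ Y
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    var0 = Y.var(axis=0) <= 1e-30
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof * XtX_inv[j, j])
        t = beta[j] / se
    exact = (rss <= 1e-25) & ~var0
    t[exact] = np.sign(beta[j][exact]) * T_CAP
    t[var0] = 0.0
    t[~np.isfinite(t)] = 0.0
    return t, dof


def massunivariate_glm(maps, outcome, covariates=None, analysis_mask=None):
    """Per-voxel OLS t-map for the outcome coefficient.

    maps: (n_subjects, *grid).  Voxels with zero variance get t = 0;
    exact fits are capped at |t| = 1e6.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    X, outcome_collinear = _design(outcome, covariates, n)
    if n < X.shape[1] + 1:
        raise ValueError("too few subjects for the design")
    grid = maps.shape[1:]
    if analysis_mask is None:
        analysis_mask = np.ones(grid, dtype=bool)
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    if outcome_collinear:
        warnings.warn("outcome lies in the covariate span; t = 0 everywhere",
                      UserWarning)
        return np.zeros(grid)
    Y = maps.reshape(n, -1)[:, analysis_mask.ravel()]
    t, _ = _tmaps(Y, X, X.shape[1] - 1)
    tmap = np.zeros(grid)
    tmap[analysis_mask] = t
    return tmap


# ------------------------------------------------------------------ TFCE
def tfce_enhance(statmap, E: float = 0.5, H: float = 2.0, dh: float | None = None,
                 connectivity: int = 26) -> np.ndarray:
    """Threshold-free cluster enhancement of a (nonnegative) statistic map.

    enhanced(v) = sum over heights h <= stat(v) of extent_h(v)^E * h^H * dh
    where extent_h(v) is the size of the connected suprathreshold cluster
    containing v at height h.  Default dh = max(statmap)/100; default
    connectivity is full (26-neighbour in 3-D).
    """
    if E < 0 or H < 0:
        raise ValueError("TFCE exponents E and H must be nonnegative")
    statmap = np.asarray(statmap, dtype=float)
    top = float(statmap.max(initial=0.0))
    if top <= 0:
        return np.zeros_like(statmap)
    if dh is None:
        dh = top / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    if connectivity == 26 or statmap.ndim != 3:
        structure = np.ones((3,) * statmap.ndim, dtype=int)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 18:
        structure = ndimage.generate_binary_structure(3, 2)
    else:
        raise ValueError(f"unsupported connectivity {connectivity}")
    enhanced = np.zeros_like(statmap)
    heights = np.arange(dh, top + dh / 2, dh)
    for h in heights:
        sup = statmap >= h
        if not sup.any():
            break
        labels, n_lab = ndimage.label(sup, structure=structure)
        sizes = np.bincount(labels.ravel())
        enhanced[sup] += sizes[labels[sup]] ** float(E) * h ** float(H) * dh
    return enhanced


# ------------------------------------------------------------------ permutation
def _freedman_lane_fields(maps, X):
    """Reduced-model (covariates-only) hat projection and residual maps."""
    n = maps.shape[0]
    Y = maps.reshape(n, -1)
    Xc = X[:, :-1]  # everything but the regressor of interest
    Hc = Xc @ np.linalg.inv(Xc.T @ Xc) @ Xc.T
    fit = Hc @ Y
    return fit, Y - fit


def _cluster_stat(tmap_flat, grid, analysis_mask, thr, structure, stat="mass"):
    """(max cluster statistic, labels, per-cluster stats) of |t| >= thr.

    stat ``mass`` sums the suprathreshold excess |t| - thr over each
    cluster (continuous, so the permutation null has no ties); ``extent``
    counts voxels.
    """
    vol = np.zeros(grid)
    vol[analysis_mask] = tmap_flat
    sup = (np.abs(vol) >= thr) & analysis_mask
    labels, n_lab = ndimage.label(sup, structure=structure)
    if n_lab == 0:
        return 0.0, labels, np.zeros(1)
    if stat == "extent":
        vals = np.bincount(labels.ravel()).astype(float)
    else:
        vals = np.bincount(labels.ravel(), weights=(np.abs(vol) - thr).clip(0).ravel())
    vals[0] = 0.0
    return float(vals.max()), labels, vals


def permutation_fwe(maps, outcome, covariates=None, n_perm: int = 1000,
                    method: str = "maxT", seed: int = 0, alpha: float = 0.05,
                    analysis_mask=None, height_p: float = 0.01,
                    tfce_E: float = 0.5, tfce_H: float = 2.0,
                    connectivity: int = 26,
                    cluster_stat: str = "mass") -> StatMapResult:
    """FWE-corrected voxel/cluster inference by max-statistic permutation.

    Freedman–Lane scheme: the maps are residualised against the nuisance
    covariates; permutations shuffle the residual maps (adding the
    covariate fit back) before the full-model t is recomputed.  The
    chosen statistic's maximum over the analysis mask forms the null;
    corrected p-values are (1 + #{null >= observed}) / (n_perm + 1).

    method: ``maxT`` (voxelwise |t|), ``tfce`` (max enhanced |t|), or
    ``cluster`` / ``cluster-extent`` (max suprathreshold cluster size at
    the two-sided ``height_p`` threshold; the p-map is cluster-level).
    """
    if method not in ("maxT", "tfce", "cluster", "cluster-extent"):
        raise ValueError(f"unknown correction method {method!r}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives a coarse FWE estimate", UserWarning)
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    grid = maps.shape[1:]
    if analysis_mask is None:
        analysis_mask = np.ones(grid, dtype=bool)
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    if not analysis_mask.any():
        raise ValueError("empty analysis mask")
    X, outcome_collinear = _design(outcome, covariates, n)
    if outcome_collinear:
        raise ValueError("outcome lies in the covariate span; nothing to test")
    j = X.shape[1] - 1
    dof = n - X.shape[1]
    fit_c, resid = _freedman_lane_fields(maps, X)
    mvox = analysis_mask.ravel()
    Yobs = maps.reshape(n, -1)[:, mvox]
    t_obs, _ = _tmaps(Yobs, X, j)
    tmap = np.zeros(grid)
    tmap[analysis_mask] = t_obs

    structure = (np.ones((3,) * len(grid), dtype=int)
                 if connectivity == 26 or len(grid) != 3
                 else ndimage.generate_binary_structure(3, {6: 1, 18: 2}[connectivity]))
    cluster_mode = method.startswith("cluster")
    if cluster_mode:
        thr = float(stats.t.ppf(1 - height_p / 2, dof))
        obs_max, labels, sizes = _cluster_stat(t_obs, grid, analysis_mask, thr,
                                               structure, cluster_stat)

    def stat_of(t_flat):
        if method == "maxT":
            return np.abs(t_flat), float(np.max(np.abs(t_flat)))
        if method == "tfce":
            vol = np.zeros(grid)
            vol[analysis_mask] = np.abs(t_flat)
            enh = tfce_enhance(vol, E=tfce_E, H=tfce_H, connectivity=connectivity)
            ev = enh[analysis_mask]
            return ev, float(ev.max(initial=0.0))
        mx, _, _ = _cluster_stat(t_flat, grid, analysis_mask, thr, structure,
                                 cluster_stat)
        return None, float(mx)

    obs_stat, _ = (None, None) if cluster_mode else stat_of(t_obs)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for pidx in range(n_perm):
        perm = rng.permutation(n)
        Ystar = (resid[perm] + fit_c)[:, mvox]
        t_perm, _ = _tmaps(Ystar, X, j)
        _, null_max[pidx] = stat_of(t_perm)

    pmap = np.ones(grid)
    if cluster_mode:
        # cluster-level p for each observed cluster's extent
        for lab in range(1, len(sizes)):
            if sizes[lab] == 0:
                continue
            p = (1 + np.sum(null_max >= sizes[lab])) / (n_perm + 1)
            pmap[labels == lab] = p
    else:
        exceed = (null_max[None, :] >= obs_stat[:, None]).sum(axis=1)
        pv = (1 + exceed) / (n_perm + 1)
        pmap[analysis_mask] = pv
    sig = (pmap < alpha) & analysis_mask
    return StatMapResult(tmap=tmap, pmap_fwe=pmap, mask=sig, method=method,
                         n_perm=n_perm, null_max=null_max, alpha=alpha)


def cluster_threshold(maps, outcome, covariates=None, height_p: float = 0.01,
                      n_perm: int = 1000, seed: int = 0, alpha: float = 0.05,
                      analysis_mask=None, connectivity: int = 26,
                      cluster_stat: str = "mass") -> StatMapResult:
    """Suprathreshold clustering with a permutation cluster-extent null.

    Permutation analogue of parametric random-field cluster correction:
    voxels passing the two-sided ``height_p`` threshold form clusters
    whose extents are compared with the permutation distribution of the
    maximal null cluster extent.
    """
    if not 0 < height_p < 1:
        raise ValueError("height_p must be in (0, 1)")
    return permutation_fwe(maps, outcome, covariates=covariates, n_perm=n_perm,
                           method="cluster", seed=seed, alpha=alpha,
                           analysis_mask=analysis_mask, height_p=height_p,
                           connectivity=connectivity, cluster_stat=cluster_stat)


# ------------------------------------------------------------------ ROI
def extract_roi_means(maps, mask_set: dict) -> pd.DataFrame:
    """Per-subject mean of each map over each named ROI mask.

    Returns a DataFrame with one column per ROI; an empty mask yields a
    NaN column with a warning.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    flat = maps.reshape(n, -1)
    out = {}
    for name, mask in mask_set.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != maps.shape[1:]:
            raise ValueError(f"ROI mask {name!r} grid does not match the maps")
        if not mask.any():
            warnings.warn(f"ROI mask {name!r} is empty; extracting NaN", UserWarning)
            out[name] = np.full(n, np.nan)
        else:
            out[name] = flat[:, mask.ravel()].mean(axis=1)
    return pd.DataFrame(out)


def fisher_r_to_z(r):
    """Fisher transform z = arctanh(r) for correlation maps."""
    return np.arctanh(np.clip(np.asarray(r, dtype=float), -1 + 1e-15, 1 - 1e-15))
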