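"""Sparse varying-coefficient (SVC) regression on a disease-severity axis.

The model for memory score y_i observed at dementia severity t_i
(CDR-SB) with predictors x_ij is

    y_i = sum_j beta_j(t_i) x_ij + eps_i,

with each coefficient function beta_j(t) expanded in L B-spline basis
functions.  Estimation minimises the penalised least squares

    (1/2n) sum_i [y_i - sum_j x_ij beta_j(t_i)]^2
        + lambda sum_j sqrt( int beta_j(t)^2 dt ),

a functional group LASSO that zeroes whole coefficient functions, with
lambda chosen by five-fold cross-validation.  `SVCModel.fit` returns an
`SVCResults` carrying the fitted coefficient functions, the selected
predictor set, the lambda path and CV curve; `stability_replicates`
produces bootstrap stability bands and selection frequencies, and
`permutation_specificity` runs the null-permutation specificity check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BSplineBasis, CoefficientFunction, PenaltyGram, build_basis
from .grouplasso import GroupLassoProblem

__all__ = [
    "SVCModel",
    "SVCResults",
    "StabilityBands",
    "SpecificityResult",
    "standardize_predictors",
    "expand_design",
    "cross_validate_lambda",
    "fit_svc",
    "evaluate_trajectories",
    "stability_replicates",
    "permutation_specificity",
]


# ------------------------------------------------------------------ data prep
@dataclass(frozen=True)
class ScalingRecord:
    """Column means/SDs used to standardize predictors (for back-transform)."""

    mean: np.ndarray
    scale: np.ndarray
    names: tuple


def standardize_predictors(X, names=None):
    """Scale each column to mean 0 and unit variance.

    Raises ValueError naming any zero-variance column: a constant
    predictor cannot carry a severity-varying coefficient and would make
    the penalty degenerate.
    """
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    bad = [str(names[j]) for j in np.nonzero(sd <= 1e-12)[0]]
    if bad:
        raise ValueError(f"zero-variance predictor column(s): {', '.join(bad)}")
    Xs = (X - mu) / sd
    return Xs, ScalingRecord(mean=mu, scale=sd, names=tuple(names))


def expand_design(X, t, basis: BSplineBasis) -> np.ndarray:
    """Column (j, l) of the returned n x (p*L) matrix is x_ij * B_l(t_i).

    Blocks are predictor-major: columns [j*L, (j+1)*L) belong to
    predictor j, in basis order.
    """
    X = np.asarray(X, dtype=float)
    B = basis.design_matrix(np.asarray(t, dtype=float))  # (n, L)
    n, p = X.shape
    L = basis.n_basis
    Z = np.empty((n, p * L))
    for j in range(p):
        Z[:, j * L:(j + 1) * L] = X[:, [j]] * B
    return Z


def _default_lambda_grid(lmax: float, n_lambdas: int = 50, min_ratio: float = 1e-3):
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def _cv_folds(n: int, n_folds: int, seed: int):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, n_folds)
    for f in folds:
        if f.size < 2:
            raise ValueError(f"cross-validation fold with fewer than 2 subjects (n={n})")
    return folds


# ------------------------------------------------------------------ model
class SVCModel:
    """Sparse varying-coefficient model of an outcome on a severity axis.

    Parameters
    ----------
    y : (n,) outcome (memory z-scores).
    t : (n,) severity at which each subject is observed (CDR-SB units).
    X : (n, p) predictor matrix (brain measures + nuisance covariates).
    predictor_names : length-p names; defaults to x0..x{p-1}.
    L, degree : basis size and spline degree (defaults 4, cubic: no
        interior knots, the minimal basis of that size).
    basis : pass an explicit basis to share one domain across refits
        (bootstrap replicates use the full-sample basis).
    standardize : standardize predictor columns before fitting (the
        reference analysis always does); the scaling record is kept so
        raw-scale predictions can be reconstructed.
    """

    def __init__(self, y, t, X, predictor_names=None, L=4, degree=3,
                 basis=None, standardize=True):
        y = np.asarray(y, dtype=float)
        t = np.asarray(t, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x predictors)")
        if not (len(y) == len(t) == X.shape[0]):
            raise ValueError("y, t and X must have one row per subject")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite outcome values")
        self.predictor_names = (
            tuple(predictor_names) if predictor_names is not None
            else tuple(f"x{j}" for j in range(X.shape[1]))
        )
        if len(self.predictor_names) != X.shape[1]:
            raise ValueError("predictor_names length mismatch")
        self.y_raw = y
        self.t = t
        self.X_raw = X
        if standardize:
            self.X, self.scaling = standardize_predictors(X, self.predictor_names)
        else:
            self.X, self.scaling = X, None
        self.basis = basis if basis is not None else build_basis(t, L=L, degree=degree)
        self.gram: PenaltyGram = self.basis.penalty_gram()
        # centre both the response and the design columns: the model has
        # no intercept term, and double centring makes the fit invariant
        # to any constant offset without biasing the coefficient functions
        self.y_mean = float(y.mean())
        self.y = y - self.y_mean
        self.Z_raw = expand_design(self.X, t, self.basis)
        self.z_mean = self.Z_raw.mean(axis=0)
        self.Z = self.Z_raw - self.z_mean
        self._problem = GroupLassoProblem(
            self.Z, self.y, self.gram.cholesky, n_groups=self.n_predictors
        )

    # -------------------------------------------------------------- props
    @property
    def n_subjects(self) -> int:
        return len(self.y)

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    @property
    def L(self) -> int:
        return self.basis.n_basis

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome="memory_z",
                       severity="severity", predictors=None, **kwargs):
        if predictors is None:
            drop = {outcome, severity, "id", "group"}
            predictors = [c for c in df.columns if c not in drop]
        return cls(
            df[outcome].to_numpy(), df[severity].to_numpy(),
            df[list(predictors)].to_numpy(), predictor_names=list(predictors),
            **kwargs,
        )

    # -------------------------------------------------------------- fitting
    def lambda_max(self) -> float:
        return self._problem.lambda_max()

    def cross_validate(self, lambda_grid=None, n_folds=5, seed=0,
                       tol=1e-5, max_sweeps=10_000):
        """Mean held-out squared error per lambda over seeded folds.

        Returns (lambda_star, curve) where curve is a DataFrame with
        columns (lambda, cv_error).  Ties in CV error resolve to the
        larger lambda (the sparser model) because the grid is decreasing.
        """
        if lambda_grid is None:
            lambda_grid = _default_lambda_grid(self.lambda_max())
        lambda_grid = np.asarray(lambda_grid, dtype=float)
        folds = _cv_folds(self.n_subjects, n_folds, seed)
        errs = np.zeros((len(folds), len(lambda_grid)))
        all_idx = np.arange(self.n_subjects)
        for fi, hold in enumerate(folds):
            train = np.setdiff1d(all_idx, hold)
            ytr = self.y_raw[train]
            ytr_mean = ytr.mean()
            Ztr = self.Z_raw[train]
            ztr_mean = Ztr.mean(axis=0)
            prob = GroupLassoProblem(
                Ztr - ztr_mean, ytr - ytr_mean, self.gram.cholesky,
                n_groups=self.n_predictors,
            )
            us = prob.path(lambda_grid, tol=tol, max_sweeps=max_sweeps)
            Zt_hold = (self.Z_raw[hold] - ztr_mean) @ np.linalg.inv(
                np.kron(np.eye(self.n_predictors), self.gram.cholesky)
            )
            pred = ytr_mean + us @ Zt_hold.T
            errs[fi] = np.mean((self.y_raw[hold] - pred) ** 2, axis=1)
        curve = pd.DataFrame({"lambda": lambda_grid, "cv_error": errs.mean(axis=0)})
        lam_star = float(lambda_grid[int(np.argmin(curve["cv_error"].to_numpy()))])
        return lam_star, curve

    def fit(self, lam=None, lambda_grid=None, n_folds=5, seed=0,
            tol=1e-7, max_sweeps=10_000) -> "SVCResults":
        """Standardize -> expand -> (CV for lambda) -> final fit on all data."""
        cv_curve = None
        if lam is None:
            lam, cv_curve = self.cross_validate(
                lambda_grid=lambda_grid, n_folds=n_folds, seed=seed,
                max_sweeps=max_sweeps,
            )
        # warm-start the final fit down a short path so small lambdas on
        # ill-conditioned designs converge quickly
        lmax = self.lambda_max()
        u = None
        if 0 < lam < lmax:
            warm_grid = np.geomspace(lmax, lam, 15)[:-1]
            u = self._problem.path(warm_grid, tol=1e-5, max_sweeps=max_sweeps)[-1]
        u = self._problem.solve(lam, u0=u, tol=tol, max_sweeps=max_sweeps)
        gamma = self._problem.to_gamma(u).reshape(self.n_predictors, self.L)
        kkt = self._problem.kkt_residual(u, lam)
        obj = self._problem.objective(u, lam)
        fitted = self.y_mean + self.Z @ gamma.ravel()
        return SVCResults(
            model=self, gamma=gamma, lambda_=float(lam), cv_curve=cv_curve,
            kkt_residual=kkt, objective=float(obj),
            fitted_values=fitted, residuals=self.y_raw - fitted,
        )


# ------------------------------------------------------------------ results
@dataclass
class SVCResults:
    """Fitted SVC: coefficient functions, selection set and diagnostics."""

    model: SVCModel
    gamma: np.ndarray          # (p, L) spline weights per predictor
    lambda_: float
    cv_curve: pd.DataFrame | None
    kkt_residual: float
    objective: float
    fitted_values: np.ndarray
    residuals: np.ndarray

    @property
    def predictor_names(self):
        return self.model.predictor_names

    @property
    def selected(self) -> dict:
        """Predictor -> True when its coefficient function is nonzero."""
        return {
            name: bool(np.linalg.norm(g) > 0)
            for name, g in zip(self.predictor_names, self.gamma)
        }

    @property
    def selected_set(self) -> frozenset:
        return frozenset(n for n, s in self.selected.items() if s)

    def coef_function(self, name: str) -> CoefficientFunction:
        j = self.predictor_names.index(name)
        return CoefficientFunction(gamma=self.gamma[j], basis=self.model.basis, name=name)

    def default_grid(self, step: float = 0.1) -> np.ndarray:
        lo, hi = self.model.basis.domain
        return np.arange(lo, hi + step / 2, step)

    def trajectories(self, t_grid=None) -> pd.DataFrame:
        """beta_hat_j(t) on a severity grid, one column per predictor."""
        if t_grid is None:
            t_grid = self.default_grid()
        t_grid = np.asarray(t_grid, dtype=float)
        B = self.model.basis.design_matrix(t_grid)
        out = pd.DataFrame({"severity": t_grid})
        for name, g in zip(self.predictor_names, self.gamma):
            out[name] = B @ g
        return out.set_index("severity")

    def peaks(self, t_grid=None) -> pd.DataFrame:
        """Signed extremum (max |beta|) and its severity, per predictor."""
        traj = self.trajectories(t_grid)
        rows = []
        for name in self.predictor_names:
            vals = traj[name].to_numpy()
            k = int(np.argmax(np.abs(vals)))
            rows.append({
                "predictor": name,
                "peak_beta": float(vals[k]),
                "peak_severity": float(traj.index[k]),
                "selected": self.selected[name],
            })
        return pd.DataFrame(rows).set_index("predictor")

    def functional_norms(self) -> dict:
        return {
            name: self.model.gram.functional_norm(g)
            for name, g in zip(self.predictor_names, self.gamma)
        }

    def summary(self) -> str:
        pk = self.peaks()
        lines = [
            "Sparse varying-coefficient model",
            "=" * 64,
            f"n subjects: {self.model.n_subjects:>6}    predictors: {self.model.n_predictors}"
            f"    basis L: {self.model.L} (degree {self.model.basis.degree})",
            f"lambda:     {self.lambda_:.5g}    objective: {self.objective:.5g}"
            f"    KKT resid: {self.kkt_residual:.2e}",
            "-" * 64,
            f"{'predictor':<16}{'selected':>9}{'peak beta':>12}{'at CDR-SB':>11}{'||beta||':>11}",
        ]
        norms = self.functional_norms()
        for name, row in pk.iterrows():
            lines.append(
                f"{name:<16}{('yes' if row['selected'] else 'no'):>9}"
                f"{row['peak_beta']:>12.3f}{row['peak_severity']:>11.1f}"
                f"{norms[name]:>11.3f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_trajectories(self, t_grid=None, ax=None):
        import matplotlib.pyplot as plt

        traj = self.trajectories(t_grid)
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        for name in self.predictor_names:
            if self.selected[name]:
                ax.plot(traj.index, traj[name], label=name)
        ax.axhline(0.0, color="k", lw=0.8, ls="--")
        ax.set_xlabel("dementia severity (CDR-SB)")
        ax.set_ylabel(r"$\hat\beta(t)$")
        ax.legend(fontsize=8)
        return ax


# ------------------------------------------------------------------ bands
@dataclass
class StabilityBands:
    """Replicate mean trajectories, pointwise SEs and selection counts."""

    t_grid: np.ndarray
    mean: pd.DataFrame          # grid x predictor
    se: pd.DataFrame
    selection_count: pd.Series  # per predictor, out of n_rep
    n_rep: int
    scheme: str
    n_failed: int = 0
    low_support_above: float | None = None

    @property
    def stably_selected(self) -> frozenset:
        return frozenset(self.selection_count.index[self.selection_count == self.n_rep])

    def band(self, name, k: float = 2.0):
        m = self.mean[name]
        s = self.se[name]
        return m - k * s, m + k * s

    def plot(self, name: str, ax=None, band_k: float = 2.0):
        """Mean trajectory for one predictor with the +/- k*SE band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 3.2))
        lo, hi = self.band(name, band_k)
        ax.plot(self.t_grid, self.mean[name], color="C0",
                label=f"{name} ({int(self.selection_count[name])}/{self.n_rep})")
        ax.plot(self.t_grid, lo, "--", color="C0", lw=0.9)
        ax.plot(self.t_grid, hi, "--", color="C0", lw=0.9)
        ax.axhline(0.0, color="k", lw=0.8, ls=":")
        if self.low_support_above is not None:
            ax.axvspan(self.low_support_above, self.t_grid[-1], alpha=0.08,
                       color="grey")
        ax.set_xlabel("dementia severity (CDR-SB)")
        ax.set_ylabel(r"$\hat\beta(t)$")
        ax.legend(fontsize=8, loc="best")
        return ax

    def to_table(self) -> pd.DataFrame:
        rows = []
        for name in self.mean.columns:
            for t, m, s in zip(self.t_grid, self.mean[name], self.se[name]):
                rows.append({
                    "predictor": name, "severity": t, "beta_mean": m,
                    "beta_se": s,
                    "selected_freq": int(self.selection_count[name]),
                })
        return pd.DataFrame(rows)


@dataclass
class SpecificityResult:
    """Outcome of the permuted-outcome specificity experiment."""

    stable_sets: list
    n_perm: int
    n_rep: int
    frequency: pd.Series   # per predictor: permutations in which it was stable

    @property
    def n_empty(self) -> int:
        return sum(1 for s in self.stable_sets if len(s) == 0)

    @property
    def modal_outcome_empty(self) -> bool:
        from collections import Counter

        counts = Counter(frozenset(s) for s in self.stable_sets)
        return counts.most_common(1)[0][0] == frozenset()


# ------------------------------------------------------------------ resampling
def stability_replicates(model: SVCModel, n_rep: int = 100, seed: int = 0,
                         scheme: str = "bootstrap", t_grid=None,
                         n_folds: int = 5, lambda_grid=None,
                         low_support_above: float | None = 10.0) -> StabilityBands:
    """Refit the full SVC pipeline on resampled cohorts.

    scheme:
      * ``bootstrap``  — n subjects drawn with replacement (default);
      * ``subsample``  — 80% of subjects without replacement;
      * ``cv-refit``   — refit on the full data with re-randomised CV folds.

    All replicates share the full-sample basis so trajectories live on a
    common severity grid.  Replicates whose fit fails are dropped and
    counted; more than 10% failures raises.
    """
    if scheme not in ("bootstrap", "subsample", "cv-refit"):
        raise ValueError(f"unknown replicate scheme: {scheme!r}")
    rng = np.random.default_rng(seed)
    n = model.n_subjects
    if t_grid is None:
        lo, hi = model.basis.domain
        t_grid = np.arange(lo, hi + 0.05, 0.1)
    t_grid = np.asarray(t_grid, dtype=float)
    B = model.basis.design_matrix(t_grid)
    curves, sel_counts = [], np.zeros(model.n_predictors, dtype=int)
    n_failed = 0
    for _ in range(n_rep):
        cv_seed = int(rng.integers(0, 2**31 - 1))
        if scheme == "cv-refit":
            idx = np.arange(n)
        elif scheme == "bootstrap":
            idx = rng.integers(0, n, size=n)
        else:
            idx = rng.choice(n, size=max(2, int(round(0.8 * n))), replace=False)
        try:
            rep = SVCModel(
                model.y_raw[idx], model.t[idx], model.X_raw[idx],
                predictor_names=model.predictor_names, basis=model.basis,
            )
            res = rep.fit(lambda_grid=lambda_grid, n_folds=n_folds, seed=cv_seed)
        except Exception as exc:  # noqa: BLE001 — replicate-level robustness
            warnings.warn(f"replicate failed and was dropped: {exc}", RuntimeWarning)
            n_failed += 1
            continue
        curves.append(B @ res.gamma.T)           # (grid, p)
        sel_counts += np.array([res.selected[nm] for nm in model.predictor_names])
    if n_failed > 0.1 * n_rep:
        raise RuntimeError(f"{n_failed}/{n_rep} stability replicates failed")
    arr = np.stack(curves)                        # (reps, grid, p)
    mean = arr.mean(axis=0)
    se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    names = list(model.predictor_names)
    return StabilityBands(
        t_grid=t_grid,
        mean=pd.DataFrame(mean, index=t_grid, columns=names),
        se=pd.DataFrame(se, index=t_grid, columns=names),
        selection_count=pd.Series(sel_counts, index=names),
        n_rep=len(curves), scheme=scheme, n_failed=n_failed,
        low_support_above=low_support_above,
    )


def permutation_specificity(model: SVCModel, n_perm: int = 100, n_rep: int = 100,
                            seed: int = 0, scheme: str = "bootstrap",
                            n_folds: int = 5, lambda_grid=None) -> SpecificityResult:
    """Null specificity check: permute the outcome, rerun stability selection.

    For each of ``n_perm`` random permutations of y the full stability
    pipeline runs with ``n_rep`` replicates; a predictor is *stably
    selected* for that permutation when chosen in every replicate.  On
    exchangeable null data most permutations should produce an empty
    stable set.
    """
    rng = np.random.default_rng(seed)
    names = list(model.predictor_names)
    stable_sets = []
    freq = np.zeros(len(names), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(model.n_subjects)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        m = SVCModel(
            model.y_raw[perm], model.t, model.X_raw,
            predictor_names=names, basis=model.basis,
        )
        bands = stability_replicates(
            m, n_rep=n_rep, seed=rep_seed, scheme=scheme,
            n_folds=n_folds, lambda_grid=lambda_grid,
        )
        stable = bands.stably_selected
        stable_sets.append(stable)
        freq += np.array([nm in stable for nm in names])
    return SpecificityResult(
        stable_sets=stable_sets, n_perm=n_perm, n_rep=n_rep,
        frequency=pd.Series(freq, index=names),
    )


# ------------------------------------------------------------------ wrappers
def cross_validate_lambda(y, t, X, predictor_names=None, lambda_grid=None,
                          n_folds=5, seed=0, **model_kw):
    """Five-fold CV for lambda; returns (lambda_star, cv_curve)."""
    model = SVCModel(y, t, X, predictor_names=predictor_names, **model_kw)
    return model.cross_validate(lambda_grid=lambda_grid, n_folds=n_folds, seed=seed)


def fit_svc(data: pd.DataFrame, config: dict | None = None) -> SVCResults:
    """One-call pipeline: standardize, build basis, CV, final fit.

    ``data`` columns: id/group (ignored), severity, memory_z, predictors.
    ``config`` keys (all optional): L, degree, n_folds, seed, lam,
    lambda_grid, predictors.
    """
    config = dict(config or {})
    model = SVCModel.from_dataframe(
        data,
        predictors=config.pop("predictors", None),
        L=config.pop("L", 4),
        degree=config.pop("degree", 3),
    )
    return model.fit(
        lam=config.pop("lam", None),
        lambda_grid=config.pop("lambda_grid", None),
        n_folds=config.pop("n_folds", 5),
        seed=config.pop("seed", 0),
    )


def evaluate_trajectories(fit: SVCResults, t_grid) -> pd.DataFrame:
    """beta_hat_j(t) on an explicit grid (must lie inside the basis domain)."""
    return fit.trajectories(t_grid)
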