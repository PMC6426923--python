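"""Synthetic AD-continuum cohorts, brain measures, diffusion voxels, maps.

Generates seeded data with the statistical structure the downstream
analysis assumes: three diagnostic groups (HC / aMCI / AD) with CDR-SB
severity distributions matching the reference cohort's demographics and
diagnostic bounds (HC exactly 0, aMCI < 4, AD >= 4); six brain measures
deteriorating monotonically with severity; memory z-scores produced by
the varying-coefficient model y_i = sum_j beta_j(t_i) x_ij + eps_i with
severity-dependent generating trajectories; bi-tensor diffusion-weighted
voxel signals (61 directions at b = 1150 s/mm^2 plus 7 b0); and 3-D
statistical map stacks with embedded effect clusters for screening
calibration.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm

__all__ = [
    "GroupSpec",
    "TrajectorySpec",
    "default_group_specs",
    "default_trajectory_scenario",
    "group_specs_from_config",
    "scenario_from_config",
    "sample_severities",
    "generate_cohort",
    "generate_predictors",
    "generate_memory",
    "generate_dataset",
    "default_gradient_table",
    "generate_dwi_voxel",
    "generate_stat_maps",
    "BRAIN_MEASURES",
    "NUISANCE_COLUMNS",
    "FREE_WATER_DIFFUSIVITY",
]

FREE_WATER_DIFFUSIVITY = 3.0e-3  # mm^2/s, free water at body temperature

BRAIN_MEASURES = ("FW", "FA_T-fornix", "GMV-mPFC", "GMV-PCC", "GMV-HIP", "FC-DMN")
NUISANCE_COLUMNS = ("age", "gender", "handedness", "ethnicity")

# CDR-SB is scored in half-point increments
SEVERITY_STEP = 0.5


# ------------------------------------------------------------------ specs
@dataclass(frozen=True)
class GroupSpec:
    """Severity and demographic generating distribution for one group.

    severity_bounds is (lo, hi, upper_inclusive): HC (0, 0, True),
    aMCI [0, 4), AD [4, 18].
    """

    label: str
    n: int
    severity_mean: float
    severity_sd: float
    severity_bounds: tuple
    age_mean: float = 73.0
    age_sd: float = 7.0
    p_female: float = 0.6
    p_lefthand: float = 0.05
    p_minority: float = 0.15
    education_mean: float = 7.0
    education_sd: float = 5.0

    def __post_init__(self):
        lo, hi, _inc = self.severity_bounds
        if self.n <= 0:
            raise ValueError(f"group {self.label!r}: n must be positive")
        if self.severity_sd < 0:
            raise ValueError(f"group {self.label!r}: severity_sd must be >= 0")
        if lo > hi:
            raise ValueError(f"group {self.label!r}: invalid severity bounds {lo} > {hi}")


def default_group_specs(scale: float = 1.0) -> list[GroupSpec]:
    """The reference three-group cohort: 51 HC, 54 aMCI, 46 AD.

    CDR-SB generating means (SDs): HC 0 (0), aMCI 0.8 (0.8), AD 6.7 (2.8),
    truncated to the diagnostic bounds.  ``scale`` multiplies each group's
    n (rounded) while preserving proportions.
    """
    return [
        GroupSpec("HC", max(1, round(51 * scale)), 0.0, 0.0, (0.0, 0.0, True),
                  age_mean=72.0, age_sd=4.1, p_female=35 / 51, p_lefthand=3 / 51,
                  p_minority=8 / 51, education_mean=8.8, education_sd=4.6),
        GroupSpec("aMCI", max(1, round(54 * scale)), 0.8, 0.8, (0.0, 4.0, False),
                  age_mean=73.5, age_sd=7.9, p_female=31 / 54, p_lefthand=3 / 54,
                  p_minority=7 / 54, education_mean=6.8, education_sd=5.1),
        GroupSpec("AD", max(1, round(46 * scale)), 6.7, 2.8, (4.0, 18.0, True),
                  age_mean=75.2, age_sd=7.9, p_female=31 / 46, p_lefthand=1 / 46,
                  p_minority=8 / 46, education_mean=5.0, education_sd=4.7),
    ]


def group_specs_from_config(entries) -> list[GroupSpec]:
    """Build group specs from YAML/JSON-friendly dicts.

    Each entry needs label, n, severity_mean, severity_sd and
    severity_bounds = [lo, hi, upper_inclusive]; demographic fields are
    optional and default to `GroupSpec`'s values.
    """
    specs = []
    for entry in entries:
        e = dict(entry)
        lo, hi, inc = e.pop("severity_bounds")
        specs.append(GroupSpec(
            label=str(e.pop("label")), n=int(e.pop("n")),
            severity_mean=float(e.pop("severity_mean")),
            severity_sd=float(e.pop("severity_sd")),
            severity_bounds=(float(lo), float(hi), bool(inc)), **e,
        ))
    return specs


def scenario_from_config(entries) -> list[TrajectorySpec]:
    """Build trajectory specs from YAML/JSON-friendly dicts."""
    return [
        TrajectorySpec(
            str(e["predictor_name"]),
            tuple((float(s), float(b)) for s, b in e["control_points"]),
            e.get("interpolation", "cubic"),
        )
        for e in entries
    ]


def sample_severities(spec: GroupSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal CDR-SB draws rounded to the 0.5-point instrument grid.

    Rounding happens before the final clip so a draw near an open upper
    bound cannot round onto it (aMCI values stay strictly below 4).
    """
    lo, hi, inclusive = spec.severity_bounds
    hi_allowed = hi if inclusive else hi - SEVERITY_STEP
    if spec.severity_sd == 0 or hi <= lo:
        return np.full(size, np.clip(spec.severity_mean, lo, hi_allowed))
    a = (lo - spec.severity_mean) / spec.severity_sd
    b = (hi - spec.severity_mean) / spec.severity_sd
    raw = truncnorm.rvs(a, b, loc=spec.severity_mean, scale=spec.severity_sd,
                        size=size, random_state=rng)
    vals = np.round(raw / SEVERITY_STEP) * SEVERITY_STEP
    return np.clip(vals, lo, hi_allowed)


def generate_cohort(group_specs=None, seed: int = 0) -> pd.DataFrame:
    """Seeded cohort table: id, group, severity, demographics, memory_z.

    memory_z is initialised to 0 and filled by `generate_memory`.
    """
    if group_specs is None:
        group_specs = default_group_specs()
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for spec in group_specs:
        sev = sample_severities(spec, spec.n, rng)
        frames.append(pd.DataFrame({
            "id": [f"S{offset + i:05d}" for i in range(spec.n)],
            "group": spec.label,
            "severity": sev,
            "age": rng.normal(spec.age_mean, spec.age_sd, spec.n),
            "gender": (rng.random(spec.n) < spec.p_female).astype(int),
            "handedness": (rng.random(spec.n) < spec.p_lefthand).astype(int),
            "ethnicity": (rng.random(spec.n) < spec.p_minority).astype(int),
            "education": np.clip(
                rng.normal(spec.education_mean, spec.education_sd, spec.n), 0, None),
            "memory_z": 0.0,
        }))
        offset += spec.n
    return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------------ trajectories
@dataclass(frozen=True)
class TrajectorySpec:
    """A generating coefficient function beta_j(t) over CDR-SB severity.

    Encoded as control points interpolated with a shape-preserving
    (monotone piecewise-cubic) or piecewise-linear rule; outside the
    control range the trajectory is held constant at the boundary value.
    A single control point encodes a constant trajectory.
    """

    predictor_name: str
    control_points: tuple            # ((severity, beta), ...)
    interpolation: str = "cubic"

    def __post_init__(self):
        sev = [s for s, _ in self.control_points]
        if any(not (0.0 <= s <= 18.0) for s in sev):
            raise ValueError(f"{self.predictor_name}: control severities must lie in [0, 18]")
        if any(b <= a for a, b in zip(sev, sev[1:])):
            raise ValueError(f"{self.predictor_name}: control severities must strictly increase")
        if self.interpolation not in ("cubic", "piecewise-linear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        sev = np.array([s for s, _ in self.control_points])
        beta = np.array([b for _, b in self.control_points])
        if len(sev) == 1:
            return np.full(t.shape, beta[0])
        tc = np.clip(t, sev[0], sev[-1])
        if self.interpolation == "cubic":
            return PchipInterpolator(sev, beta)(tc)
        return np.interp(tc, sev, beta)


def default_trajectory_scenario() -> list[TrajectorySpec]:
    """The default generating scenario for the six brain measures.

    Shapes mirror the reported severity-dependent associations: FW most
    negative (-0.9) in early aMCI with a smaller secondary negative bump
    in the AD range; fornix FA_T and mPFC GMV peaking at +4.5 early and
    diminishing; PCC GMV peaking at +1.4 early; hippocampal GMV peaking
    at +2.4 near the aMCI/AD boundary; DMN connectivity constant and
    positive; all four nuisance trajectories identically zero.
    """
    return [
        TrajectorySpec("FW", (
            (0, -0.839), (0.5, -0.869), (1, -0.8886), (1.5, -0.8984),
            (1.8, -0.9), (2, -0.8993), (2.5, -0.8919), (3, -0.8769),
            (3.5, -0.8551), (4, -0.827), (4.5, -0.7935), (5, -0.7552),
            (5.5, -0.7129), (6, -0.6671), (6.5, -0.6187), (7, -0.5684),
            (7.5, -0.5167), (8, -0.4646), (8.5, -0.4125), (9, -0.3613),
            (9.5, -0.3116), (10, -0.2642), (10.5, -0.2197), (11, -0.1789),
            (11.5, -0.1424), (12, -0.111), (12.5, -0.0854), (13, -0.0662),
            (13.5, -0.0542), (14, -0.05), (14.5, -0.0544), (15, -0.0681),
            (15.5, -0.0917), (16, -0.126), (16.5, -0.1717), (17, -0.2295),
            (17.5, -0.3), (18, -0.384))),
        TrajectorySpec("FA_T-fornix", (
            (0, 4.1916), (0.5, 4.3431), (1, 4.4421), (1.5, 4.4921),
            (1.8, 4.5), (2, 4.4966), (2.5, 4.4592), (3, 4.3834),
            (3.5, 4.2728), (4, 4.1309), (4.5, 3.9614), (5, 3.7677),
            (5.5, 3.5534), (6, 3.322), (6.5, 3.0772), (7, 2.8224),
            (7.5, 2.5612), (8, 2.2971), (8.5, 2.0338), (9, 1.7747),
            (9.5, 1.5235), (10, 1.2836), (10.5, 1.0587), (11, 0.8522),
            (11.5, 0.6677), (12, 0.5088), (12.5, 0.379), (13, 0.2819),
            (13.5, 0.2211), (14, 0.2), (14.5, 0.2223), (15, 0.2914),
            (15.5, 0.411), (16, 0.5846), (16.5, 0.8157), (17, 1.1079),
            (17.5, 1.4648), (18, 1.8898))),
        TrajectorySpec("GMV-mPFC", (
            (0, 4.188), (0.5, 4.3413), (1, 4.4414), (1.5, 4.492), (1.8, 4.5),
            (2, 4.4965), (2.5, 4.4587), (3, 4.382), (3.5, 4.2701),
            (4, 4.1267), (4.5, 3.9551), (5, 3.7592), (5.5, 3.5424),
            (6, 3.3083), (6.5, 3.0606), (7, 2.8029), (7.5, 2.5386),
            (8, 2.2715), (8.5, 2.0051), (9, 1.7431), (9.5, 1.4889),
            (10, 1.2462), (10.5, 1.0186), (11, 0.8097), (11.5, 0.6231),
            (12, 0.4624), (12.5, 0.3311), (13, 0.2329), (13.5, 0.1713),
            (14, 0.15), (14.5, 0.1725), (15, 0.2425), (15.5, 0.3634),
            (16, 0.539), (16.5, 0.7728), (17, 1.0685), (17.5, 1.4295),
            (18, 1.8595))),
        TrajectorySpec("GMV-PCC", (
            (0, 1.3068), (0.5, 1.3526), (1, 1.3825), (1.5, 1.3976),
            (1.8, 1.4), (2, 1.399), (2.5, 1.3877), (3, 1.3647),
            (3.5, 1.3313), (4, 1.2884), (4.5, 1.2372), (5, 1.1786),
            (5.5, 1.1138), (6, 1.0439), (6.5, 0.9698), (7, 0.8928),
            (7.5, 0.8138), (8, 0.734), (8.5, 0.6544), (9, 0.5761),
            (9.5, 0.5001), (10, 0.4276), (10.5, 0.3596), (11, 0.2972),
            (11.5, 0.2414), (12, 0.1934), (12.5, 0.1541), (13, 0.1248),
            (13.5, 0.1064), (14, 0.1), (14.5, 0.1067), (15, 0.1276),
            (15.5, 0.1638), (16, 0.2163), (16.5, 0.2861), (17, 0.3745),
            (17.5, 0.4824), (18, 0.6109))),
        TrajectorySpec("GMV-HIP", (
            (0, 0.4036), (0.5, 0.8447), (1, 1.2225), (1.5, 1.5407),
            (2, 1.8027), (2.5, 2.0122), (3, 2.1727), (3.5, 2.2877),
            (4, 2.3609), (4.5, 2.3958), (4.75, 2.4), (5, 2.396),
            (5.5, 2.3649), (6, 2.3063), (6.5, 2.2236), (7, 2.1204),
            (7.5, 2.0003), (8, 1.8668), (8.5, 1.7236), (9, 1.5741),
            (9.5, 1.4219), (10, 1.2706), (10.5, 1.1238), (11, 0.985),
            (11.5, 0.8577), (12, 0.7457), (12.5, 0.6523), (13, 0.5812),
            (13.5, 0.5359), (14, 0.52), (14.5, 0.5371), (15, 0.5907),
            (15.5, 0.6843), (16, 0.8217), (16.5, 1.0062), (17, 1.2415),
            (17.5, 1.5312), (18, 1.8787))),
        TrajectorySpec("FC-DMN", ((0.0, 0.8),)),
        TrajectorySpec("age", ((0.0, 0.0),)),
        TrajectorySpec("gender", ((0.0, 0.0),)),
        TrajectorySpec("handedness", ((0.0, 0.0),)),
        TrajectorySpec("ethnicity", ((0.0, 0.0),)),
    ]


# ------------------------------------------------------------------ predictors
# raw-scale severity trends: (intercept, slope per CDR-SB point, noise SD)
_MEASURE_MODELS = {
    "FW": (0.16, +0.006, 0.020),
    "FA_T-fornix": (0.45, -0.008, 0.025),
    "GMV-mPFC": (0.62, -0.010, 0.035),
    "GMV-PCC": (0.55, -0.009, 0.030),
    "GMV-HIP": (0.58, -0.012, 0.035),
    "FC-DMN": (0.42, -0.010, 0.040),
}


def generate_predictors(cohort: pd.DataFrame, scenario=None, noise_sd: float = 1.0,
                        seed: int = 0) -> pd.DataFrame:
    """Brain measures with monotone severity-dependent means plus noise.

    ``noise_sd`` scales each measure's baseline measurement noise (1.0 =
    default level, 0 = deterministic functions of severity).  Nuisance
    columns are copied from the cohort demographics.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    t = cohort["severity"].to_numpy(dtype=float)
    out = {}
    for name, (b0, slope, sd) in _MEASURE_MODELS.items():
        out[name] = b0 + slope * t + rng.normal(0.0, sd * noise_sd, len(t))
    for col in NUISANCE_COLUMNS:
        out[col] = cohort[col].to_numpy(dtype=float)
    return pd.DataFrame(out, index=cohort.index)


def generate_memory(cohort: pd.DataFrame, predictors: pd.DataFrame, scenario=None,
                    eps_sd: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Memory z-scores from the varying-coefficient generating model.

    Predictors are standardized (zero mean, unit variance, as in the
    fitting pipeline) before multiplication, so the generating betas are
    on the per-SD scale the model estimates:

        y_i = sum_j beta_j(t_i) * x~_ij + eps_i,  eps_i ~ N(0, eps_sd^2).

    Returns a copy of the cohort with memory_z filled in.
    """
    from .svc import standardize_predictors

    if eps_sd < 0:
        raise ValueError("eps_sd must be nonnegative")
    if len(cohort) != len(predictors):
        raise ValueError("cohort and predictor tables have different row counts")
    if scenario is None:
        scenario = default_trajectory_scenario()
    rng = np.random.default_rng(seed)
    t = cohort["severity"].to_numpy(dtype=float)
    names = [tr.predictor_name for tr in scenario]
    missing = [nm for nm in names if nm not in predictors.columns]
    if missing:
        raise ValueError(f"predictor table lacks scenario columns: {missing}")
    X = predictors[names].to_numpy(dtype=float)
    Xs, _ = standardize_predictors(X, names)
    signal = np.zeros(len(t))
    for j, tr in enumerate(scenario):
        signal += tr(t) * Xs[:, j]
    y = signal + rng.normal(0.0, eps_sd, len(t))
    out = cohort.copy()
    out["memory_z"] = y
    return out


def generate_dataset(group_specs=None, scenario=None, noise_sd: float = 1.0,
                     eps_sd: float = 1.0, seed: int = 0):
    """Cohort + predictors + memory in one seeded call.

    Returns (data, predictors, scenario) where ``data`` is the cohort
    table with memory_z filled and the predictor columns joined on — the
    frame `SVCModel.from_dataframe` consumes directly.
    """
    if scenario is None:
        scenario = default_trajectory_scenario()
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    cohort = generate_cohort(group_specs, seed=s1)
    predictors = generate_predictors(cohort, scenario, noise_sd=noise_sd, seed=s2)
    cohort = generate_memory(cohort, predictors, scenario, eps_sd=eps_sd, seed=s3)
    names = [tr.predictor_name for tr in scenario]
    data = pd.concat(
        [cohort[["id", "group", "severity", "memory_z"]],
         predictors[[nm for nm in names if nm not in ("age", "gender",
                                                      "handedness", "ethnicity")]],
         cohort[["age", "gender", "handedness", "ethnicity"]]],
        axis=1,
    )
    return data, predictors, scenario


# ------------------------------------------------------------------ diffusion
def _sphere_directions(n: int) -> np.ndarray:
    """Deterministic, roughly uniform unit directions (golden-spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    d = np.stack([np.sin(phi) * np.cos(theta),
                  np.sin(phi) * np.sin(theta),
                  np.cos(phi)], axis=1)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def default_gradient_table():
    """The acquisition protocol: 7 b0 volumes then 61 DW at b=1150 s/mm^2."""
    from .freewater import GradientTable

    bvals = np.concatenate([np.zeros(7), np.full(61, 1150.0)])
    bvecs = np.concatenate([np.zeros((7, 3)), _sphere_directions(61)])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def generate_dwi_voxel(f: float, tensor, gradient_table, S0: float = 1000.0,
                       noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Bi-tensor voxel signal: free-water fraction f plus a tissue tensor.

    S(g, b) = S0 [ f exp(-b d_fw) + (1-f) exp(-b g'Dg) ] with
    d_fw = 3e-3 mm^2/s; optional Rician noise of scale ``noise_sd * S0``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"free-water fraction f={f} outside [0, 1]")
    tensor = np.asarray(tensor, dtype=float)
    eigs = np.linalg.eigvalsh((tensor + tensor.T) / 2)
    if np.min(eigs) < -1e-12:
        raise ValueError("tissue tensor must be positive semidefinite")
    b = np.asarray(gradient_table.bvals, dtype=float)
    g = np.asarray(gradient_table.bvecs, dtype=float)
    quad = np.einsum("ij,jk,ik->i", g, tensor, g)
    signal = S0 * (f * np.exp(-b * FREE_WATER_DIFFUSIVITY)
                   + (1.0 - f) * np.exp(-b * quad))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_sd * S0
        signal = np.sqrt((signal + rng.normal(0, sigma, signal.shape)) ** 2
                         + rng.normal(0, sigma, signal.shape) ** 2)
    return signal


# ------------------------------------------------------------------ stat maps
def generate_stat_maps(grid_shape, effect_clusters, cohort: pd.DataFrame,
                       noise_sd: float = 1.0, seed: int = 0):
    """Per-subject 3-D maps with cluster-localised memory-coupled effects.

    Each cluster is a dict with keys ``center`` (3 ints), ``radius``
    (voxels) and ``amplitude``; subject i's map gains
    amplitude * memory_z_i inside the cluster, on top of iid Gaussian
    noise.  Returns (maps, truth_mask) with maps of shape
    (n_subjects, *grid_shape); the truth mask marks voxels with any
    nonzero effect amplitude.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if any(s <= 0 for s in grid_shape):
        raise ValueError("grid dimensions must be positive")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    y = cohort["memory_z"].to_numpy(dtype=float)
    maps = rng.normal(0.0, noise_sd, size=(n,) + grid_shape)
    truth = np.zeros(grid_shape, dtype=bool)
    coords = np.indices(grid_shape)
    for cl in effect_clusters:
        center = np.asarray(cl["center"], dtype=float)
        if np.any(center < 0) or np.any(center >= np.array(grid_shape)):
            raise ValueError(f"cluster center {cl['center']} outside the grid")
        dist2 = sum((coords[k] - center[k]) ** 2 for k in range(3))
        inside = dist2 <= float(cl["radius"]) ** 2
        if cl["amplitude"] != 0.0:
            truth |= inside
            maps[:, inside] += cl["amplitude"] * y[:, None]
    return maps, truth
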