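"""Synthetic longitudinal atrophy study with known ground truth.

Emulates the data structure of a PFF-inoculation experiment in M83 mice:
balanced sex x injection-group cells scanned at fixed days post-injection
(dpi), hazard-linked attrition (humane endpoints), per-scan log-Jacobian
volumes built from planted smooth spatial atrophy components whose subject
loadings follow a group x sex x dpi linear model, and motor-behavior trial
tables with task-specific latency caps (pole-test failures capped at 120 s,
wire-hang successes at 150 s).

Every downstream stage of the pipeline (matrix assembly, OPNMF, voxelwise
mixed models, survival/motor statistics) can therefore be validated against
the generating parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .prep import JacobianImage

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "brain_mask",
    "generate_components",
    "generate_parcellation",
    "default_truth",
    "generate_cohort",
    "generate_jacobians",
    "generate_behavior",
    "POLE_CAP_S",
    "WIREHANG_CAP_S",
    "EXPERIMENT_END_DPI",
]

logger = logging.getLogger(__name__)

POLE_CAP_S = 120.0  # pole-test failure cap: max 2 min to descend
WIREHANG_CAP_S = 150.0  # wire-hang success cap: recorded maximum
EXPERIMENT_END_DPI = 130.0  # administrative censoring of survival

#: loading-model design columns, in order
LOADING_TERMS = ("intercept", "group", "sex", "dpi", "group:dpi", "group:sex:dpi")


@dataclass
class CohortSpec:
    """Size and sampling grid of the synthetic study.

    ``n_per_cell`` mice per sex x injection cell (the study design aimed for
    ~30 per injection group, i.e. ~15 per cell, thinning to ~8 per cell by the
    last timepoint through attrition and diversion).
    """

    n_per_cell: int = 15
    timepoints_dpi: tuple[int, ...] = (-7, 30, 90, 120)
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (0.1, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        tp = tuple(self.timepoints_dpi)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints_dpi must be strictly increasing")
        self.timepoints_dpi = tp
        if any(d < 8 for d in self.grid_shape):
            raise ValueError("all grid dimensions must be >= 8")
        self.grid_shape = tuple(int(d) for d in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)


@dataclass
class GroundTruth:
    """Generating model: spatial components, loading model, hazards, behavior.

    ``components`` is a (k0, *grid) stack of smooth non-negative fields with
    pairwise disjoint supports.  ``loadings_model`` is (k0, 6): coefficients
    for intercept, group, sex, dpi, group:dpi, group:sex:dpi (group: PFF=1,
    sex: male=1, dpi in days).  ``hazard_model`` gives the exponential
    proportional-hazards generator for humane-endpoint times.
    """

    components: np.ndarray
    loadings_model: np.ndarray
    noise_sd: float = 0.05
    # per-subject anatomical variability of each component's expression, the
    # source of structural covariance; sits well above scan noise, as in real
    # morphometry
    loading_noise_sd: float = 0.15
    global_size_sd: float = 0.05  # absolute-flavor per-subject size offset
    hazard_model: dict = field(
        default_factory=lambda: {
            # baseline: PBS female; chosen so controls essentially all survive
            "baseline": 8e-5,  # events/day
            "group": 2.3,  # log-HR of PFF (female)
            "sex": 0.0,  # log-HR of male (PBS)
            "group_sex": 1.3,  # extra log-HR for male PFF
        }
    )
    onset_model: dict = field(
        default_factory=lambda: {"mean_dpi": 95.0, "sd": 8.0, "sex_shift": 0.0}
    )
    weight_model: dict = field(
        default_factory=lambda: {
            "base_male": 27.0,
            "base_female": 22.0,
            "base_sd": 1.5,
            "growth_per_day": 0.01,
            # PFF inverted-U: a*t - b*t^2 with peak at a/(2b) = 90 dpi
            "pff_quad": 2.0e-4,
            "obs_sd": 0.3,
        }
    )
    behavior_model: dict = field(
        default_factory=lambda: {
            "pole": {"base_log": np.log(8.0), "sd": 0.4, "slow_per_day": 0.012,
                     "fail_intercept": -4.0, "fail_slope_per_day": 0.035},
            "wirehang": {"base_log": np.log(240.0), "sd": 0.5,
                         "decline_per_day": 0.018, "ph_hr": None,
                         "ph_base_rate": 1.0 / 100.0},
            "rotarod": {"base_log": np.log(60.0), "sd": 0.3,
                        "decline_per_day": 0.008},
        }
    )
    end_dpi: float = EXPERIMENT_END_DPI

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.loadings_model = np.atleast_2d(np.asarray(self.loadings_model, dtype=float))
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        k0 = self.components.shape[0]
        if self.loadings_model.shape != (k0, len(LOADING_TERMS)):
            raise ValueError(
                f"loadings_model must be ({k0}, {len(LOADING_TERMS)}), "
                f"got {self.loadings_model.shape}"
            )
        supports = self.components > 0
        for i in range(k0):
            for j in range(i + 1, k0):
                if np.any(supports[i] & supports[j]):
                    raise ValueError(f"components {i} and {j} have overlapping support")

    @property
    def k0(self) -> int:
        return self.components.shape[0]


def brain_mask(spec: CohortSpec) -> np.ndarray:
    """Ellipsoidal 'brain' mask inscribed in the grid (semi-axes 0.45*dim)."""
    grids = np.meshgrid(
        *[np.arange(d) - (d - 1) / 2.0 for d in spec.grid_shape], indexing="ij"
    )
    semi = [0.45 * d for d in spec.grid_shape]
    r2 = sum((g / s) ** 2 for g, s in zip(grids, semi))
    return r2 <= 1.0


def _sphere_directions(k: int) -> np.ndarray:
    """k well-separated unit directions (Fibonacci spiral on the sphere)."""
    if k == 1:
        return np.array([[0.0, 0.0, 0.0]])
    i = np.arange(k) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / k)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def generate_components(
    spec: CohortSpec, k0: int, seed: int | None = None
) -> np.ndarray:
    """Plant ``k0`` smooth non-negative blobs with pairwise disjoint supports.

    Each component is a Gaussian-smoothed ellipsoid indicator, truncated at
    15% of its peak to keep a compact support, normalized to peak 1, and
    placed fully inside the brain mask.  Disjoint supports mirror the voxel
    exclusivity of the orthogonal decomposition, making recovery well-posed.

    Placement is deterministic-template based: blob centers sit on
    well-separated directions from the grid center at a radius solved from the
    separation geometry, with seeded jitter on centers and per-axis radii.  If
    the geometry leaves no room for blobs of at least ~1 voxel radius (or a
    jittered draw keeps colliding after bounded retries) an explicit error is
    raised.
    """
    if k0 < 1:
        raise ValueError("k0 must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mask = brain_mask(spec)
    shape = spec.grid_shape
    smooth_sigma = 0.7
    spread = 2.0 * smooth_sigma  # support halo beyond the ellipsoid after truncation
    s_min = 0.45 * min(shape)  # smallest brain-mask semi-axis

    dirs = _sphere_directions(k0)
    if k0 == 1:
        support_radius = min(s_min - 1.0, 1.0 + min(shape) / 6.0)
    else:
        # min pairwise angle between template directions
        cosines = dirs @ dirs.T
        np.fill_diagonal(cosines, -1.0)
        theta_min = np.arccos(np.clip(cosines.max(), -1.0, 1.0))
        sin_half = np.sin(theta_min / 2.0)
        # centers at rho = s_min - R give separation 2 rho sin(theta/2) >= 2R
        support_radius = min(s_min * sin_half / (1.0 + sin_half), 1.0 + min(shape) / 6.0)
    r_max = support_radius - spread
    if r_max < 1.0:
        raise RuntimeError(
            f"grid {shape} is too small to place {k0} disjoint blobs "
            f"(feasible radius {r_max:.2f} voxel)"
        )
    rho = max(s_min - support_radius, 0.0)
    grid_center = np.array([(d - 1) / 2.0 for d in shape])
    coords = np.meshgrid(*[np.arange(d) for d in shape], indexing="ij")

    components: list[np.ndarray] = []
    max_tries = 50
    for c in range(k0):
        placed = False
        for attempt in range(max_tries):
            jitter_scale = 0.5 if attempt < max_tries // 2 else 0.0
            center = grid_center + rho * dirs[c] + rng.uniform(-jitter_scale, jitter_scale, 3)
            rad = r_max * rng.uniform(0.75, 1.0, size=3)
            r2 = sum(((g - ctr) / rr) ** 2 for g, ctr, rr in zip(coords, center, rad))
            blob = (r2 <= 1.0).astype(float)
            if not blob.any():
                continue
            smooth = ndimage.gaussian_filter(blob, smooth_sigma, mode="constant")
            smooth[smooth < 0.15 * smooth.max()] = 0.0
            support = smooth > 0
            if not np.all(mask[support]):
                continue
            if any(np.any(support & (prev > 0)) for prev in components):
                continue
            smooth /= smooth.max()
            components.append(smooth)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place component {c} of {k0} disjointly after "
                f"{max_tries} tries; grid {shape} is too small"
            )
    return np.stack(components)


def generate_parcellation(
    spec: CohortSpec, k0: int, seed: int | None = None
) -> np.ndarray:
    """Plant ``k0`` smooth disjoint components that tile the whole mask.

    Structural-covariance decompositions of real morphometry partition the
    entire brain: every voxel expresses some component.  This layout emulates
    that: seed points on well-separated directions define a nearest-seed
    parcellation of the mask, each parcel's indicator is smoothed, and voxels
    are owned by their argmax component, so supports stay pairwise disjoint
    while covering every in-mask voxel.
    """
    if k0 < 1:
        raise ValueError("k0 must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mask = brain_mask(spec)
    shape = spec.grid_shape
    grid_center = np.array([(d - 1) / 2.0 for d in shape])
    radius = 0.5 * 0.45 * min(shape)
    seeds = grid_center + _sphere_directions(k0) * radius + rng.uniform(-0.5, 0.5, (k0, 3))

    coords = np.argwhere(mask).astype(float)  # n_mask x 3
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)

    smoothed = np.zeros((k0,) + shape)
    for c in range(k0):
        indicator = np.zeros(shape)
        vox = coords[labels == c].astype(int)
        if len(vox) == 0:
            raise RuntimeError(f"parcel {c} of {k0} is empty; grid {shape} is too small")
        indicator[vox[:, 0], vox[:, 1], vox[:, 2]] = 1.0
        smoothed[c] = ndimage.gaussian_filter(indicator, 1.0, mode="constant")
    owner = np.argmax(smoothed, axis=0)
    components = np.zeros_like(smoothed)
    for c in range(k0):
        field = np.where(mask & (owner == c), smoothed[c], 0.0)
        if field.max() <= 0:
            raise RuntimeError(f"parcel {c} of {k0} lost all voxels after smoothing")
        components[c] = field / field.max()
    return components


def default_loadings(k0: int) -> np.ndarray:
    """Default loading-model coefficients for ``k0`` planted components.

    The first components carry the effects of interest (PFF atrophy accruing
    with dpi, a male-PFF accelerated slope, a constant sex offset, slow
    aging); further components repeat the cycle at half amplitude.  Values are
    on the log-Jacobian scale (a loading of 0.24 at a component peak means a
    ~21% local volume loss by 120 dpi).
    """
    templates = np.array(
        [
            # int    group   sex     dpi      g:dpi    g:s:dpi
            [0.00, 0.00, 0.00, 0.0000, 0.0030, 0.0000],  # PFF atrophy over time
            [0.00, 0.00, 0.00, 0.0000, 0.0012, 0.0018],  # male-PFF accelerated
            [0.05, 0.00, 0.10, 0.0000, 0.0000, 0.0000],  # constant sex offset
            [0.00, 0.00, 0.00, 0.0006, 0.0000, 0.0000],  # shared aging drift
        ]
    )
    rows = [templates[i % len(templates)] * (1.0 if i < len(templates) else 0.5)
            for i in range(k0)]
    return np.array(rows)


def default_truth(
    spec: CohortSpec,
    k0: int = 6,
    seed: int | None = None,
    layout: str = "tiling",
    **kwargs,
) -> GroundTruth:
    """Ground truth with planted components and the default effect structure.

    ``layout='tiling'`` (default) plants components that partition the whole
    mask, the structure a covariance decomposition of real morphometry sees;
    ``layout='blobs'`` plants compact isolated lesions in an otherwise
    unstructured background (focal-atrophy scenarios).
    """
    if layout == "tiling":
        comps = generate_parcellation(spec, k0, seed=spec.seed if seed is None else seed)
    elif layout == "blobs":
        comps = generate_components(spec, k0, seed=spec.seed if seed is None else seed)
    else:
        raise ValueError(f"unknown component layout {layout!r}")
    return GroundTruth(components=comps, loadings_model=default_loadings(k0), **kwargs)


def _subjects_frame(spec: CohortSpec) -> pd.DataFrame:
    rows = []
    idx = 0
    for sex in ("M", "F"):
        for group in ("PBS", "PFF"):
            for _ in range(spec.n_per_cell):
                rows.append({"subject_id": f"sub{idx:03d}", "sex": sex, "group": group})
                idx += 1
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, truth: GroundTruth) -> pd.DataFrame:
    """Sample the cohort table: covariates, survival, motor onset, weights.

    Survival times are exponential proportional hazards with log-linear
    predictor ``group + sex + group:sex``, administratively censored at
    ``truth.end_dpi`` (event_flag 1 = humane endpoint, 0 = censored).  Motor
    onset is drawn for PFF mice around ~95 dpi and recorded only if it precedes
    the subject's endpoint.  Per-timepoint weights follow sex-specific
    baselines with slow growth and an inverted-U PFF trajectory peaking at
    ~90 dpi; weights after a subject's endpoint are missing.
    """
    rng = np.random.default_rng([int(spec.seed), 17])
    df = _subjects_frame(spec)
    g = (df["group"] == "PFF").to_numpy(float)
    s = (df["sex"] == "M").to_numpy(float)
    hz = truth.hazard_model
    rate = hz["baseline"] * np.exp(hz["group"] * g + hz["sex"] * s + hz["group_sex"] * g * s)
    t_event = rng.exponential(1.0 / rate)
    event = t_event <= truth.end_dpi
    df["survival_dpi"] = np.where(event, t_event, truth.end_dpi)
    df["event_flag"] = event.astype(int)

    om = truth.onset_model
    onset = rng.normal(om["mean_dpi"] + om["sex_shift"] * s, om["sd"])
    onset = np.where((g > 0) & (onset <= df["survival_dpi"]), onset, np.nan)
    df["motor_onset_dpi"] = onset

    wm = truth.weight_model
    base = np.where(s > 0, wm["base_male"], wm["base_female"]) + rng.normal(
        0, wm["base_sd"], len(df)
    )
    b = wm["pff_quad"]
    a = 2.0 * b * 90.0  # peak of the PFF inverted-U at 90 dpi
    t0 = spec.timepoints_dpi[0]
    for tp in spec.timepoints_dpi:
        t_pos = max(tp, 0)
        w = (
            base
            + wm["growth_per_day"] * (tp - t0)
            + g * (a * t_pos - b * t_pos**2)
            + rng.normal(0, wm["obs_sd"], len(df))
        )
        w = np.where(tp <= df["survival_dpi"], w, np.nan)
        df[f"weight_{tp}"] = w
    return df


def _loading_design(g: float, s: float, t: float) -> np.ndarray:
    return np.array([1.0, g, s, t, g * t, g * s * t])


def generate_jacobians(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    spec: CohortSpec,
    flavor: str = "relative",
) -> list[JacobianImage]:
    """Synthesize one log-Jacobian volume per surviving subject-timepoint.

    ``log J = -sum_c loading(subject, dpi, c) * component_c + noise`` so a
    positive loading means local contraction (atrophy).  Loadings are the
    linear model ``truth.loadings_model`` plus a per-subject random component
    (held fixed across that subject's timepoints, the source of structural
    covariance).  The absolute flavor adds a per-subject global brain-size
    offset.  Scans after a subject's endpoint are excluded and logged.
    """
    if flavor not in ("relative", "absolute"):
        raise ValueError(f"unknown flavor {flavor!r}")
    rng = np.random.default_rng([int(spec.seed), 29])
    k0 = truth.k0
    comp_flat = truth.components.reshape(k0, -1)
    n_sub = len(cohort)
    u = rng.normal(0, truth.loading_noise_sd, size=(n_sub, k0))
    size_offset = rng.normal(0, truth.global_size_sd, size=n_sub)
    affine = np.diag(list(spec.voxel_size_mm) + [1.0])

    images: list[JacobianImage] = []
    n_skipped = 0
    for i, row in enumerate(cohort.to_dict("records")):
        g = 1.0 if row["group"] == "PFF" else 0.0
        s = 1.0 if row["sex"] == "M" else 0.0
        for tp in spec.timepoints_dpi:
            if tp > row["survival_dpi"]:
                n_skipped += 1
                continue
            loadings = truth.loadings_model @ _loading_design(g, s, float(tp)) + u[i]
            vol = -(loadings @ comp_flat)
            vol = vol.reshape(spec.grid_shape)
            vol = vol + rng.normal(0, truth.noise_sd, size=spec.grid_shape)
            if flavor == "absolute":
                vol = vol + size_offset[i]
            images.append(
                JacobianImage(
                    data=vol,
                    voxel_size_mm=spec.voxel_size_mm,
                    flavor=flavor,
                    subject_id=row["subject_id"],
                    dpi=float(tp),
                    is_log=True,
                    affine=affine,
                )
            )
    if n_skipped:
        logger.info("excluded %d scans after subjects' endpoints", n_skipped)
    return images


def generate_behavior(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    spec: CohortSpec,
    seed: int | None = None,
    tasks: Sequence[str] = ("pole", "wirehang", "rotarod"),
) -> pd.DataFrame:
    """Sample per-trial motor-task latencies with the task scoring rules.

    Three trials per surviving subject-timepoint-task.  Latencies are
    log-normal with a group x dpi location shift (PFF mice slow down on the
    pole, fall earlier from the wire, fall sooner from the accelerating rod).
    Scoring: pole failures (refusal or exceeding 2 min) record the 120 s cap
    with outcome=failure; wire-hang times reaching the cap record 150 s with
    outcome=success; rotarod has no cutoff.  If ``wirehang ph_hr`` is set in
    the truth, wire-hang times are instead exponential proportional hazards
    with that hazard ratio for PFF (an exactly PH generating model).
    """
    for task in tasks:
        if task not in ("pole", "wirehang", "rotarod"):
            raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng([int(spec.seed if seed is None else seed), 43])
    bm = truth.behavior_model
    rows = []
    for row in cohort.to_dict("records"):
        g = 1.0 if row["group"] == "PFF" else 0.0
        for tp in spec.timepoints_dpi:
            if tp > row["survival_dpi"]:
                continue
            t_pos = max(float(tp), 0.0)
            weight = row[f"weight_{tp}"]
            for task in tasks:
                p = bm[task]
                for trial in (1, 2, 3):
                    if task == "pole":
                        fail_logit = p["fail_intercept"] + p["fail_slope_per_day"] * g * t_pos
                        forced_fail = rng.random() < 1.0 / (1.0 + np.exp(-fail_logit))
                        lat = float(
                            np.exp(rng.normal(p["base_log"] + p["slow_per_day"] * g * t_pos, p["sd"]))
                        )
                        if forced_fail or lat >= POLE_CAP_S:
                            lat, outcome = POLE_CAP_S, "failure"
                        else:
                            outcome = "success"
                    elif task == "wirehang":
                        if p.get("ph_hr"):
                            rate = p["ph_base_rate"] * (p["ph_hr"] ** g)
                            lat = float(rng.exponential(1.0 / rate))
                        else:
                            lat = float(
                                np.exp(rng.normal(p["base_log"] - p["decline_per_day"] * g * t_pos, p["sd"]))
                            )
                        if lat >= WIREHANG_CAP_S:
                            lat, outcome = WIREHANG_CAP_S, "success"
                        else:
                            outcome = "failure"
                    else:  # rotarod, no cutoff
                        lat = float(
                            np.exp(rng.normal(p["base_log"] - p["decline_per_day"] * g * t_pos, p["sd"]))
                        )
                        outcome = "success"
                    rows.append(
                        {
                            "subject_id": row["subject_id"],
                            "sex": row["sex"],
                            "group": row["group"],
                            "task": task,
                            "dpi": float(tp),
                            "trial": trial,
                            "latency_s": lat,
                            "outcome": outcome,
                            "weight_g": weight,
                        }
                    )
    return pd.DataFrame(rows)
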