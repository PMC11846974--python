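"""Mass-univariate trajectory statistics and post-hoc GLMs on subject weights.

The longitudinal model at every voxel is

    relative volume ~ group * sex * dpi + (1 | subject)

fit with the vectorized random-intercept engine; Wald t and p per fixed term
are corrected across voxels with Benjamini-Hochberg FDR.  Subject weights
from the covariance decomposition are examined post hoc with ordinary GLMs
(weight ~ group * sex) including Cohen's d effect sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .mixedlm import fit_random_intercept_lme

__all__ = [
    "VoxelStatMap",
    "GLMResult",
    "FORMULA",
    "build_design",
    "fit_voxelwise_lme",
    "fdr_correct",
    "subject_weight_glm",
    "cohens_d",
]

logger = logging.getLogger(__name__)

FORMULA = "volume ~ group * sex * dpi + (1 | subject_id)"

#: fixed-effect terms of the full factorial group x sex x dpi design
TERMS = [
    "Intercept",
    "group[PFF]",
    "sex[M]",
    "dpi",
    "group[PFF]:sex[M]",
    "group[PFF]:dpi",
    "sex[M]:dpi",
    "group[PFF]:sex[M]:dpi",
]


@dataclass
class VoxelStatMap:
    """Per-voxel Wald statistics for one fixed-effect term."""

    term: str
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray | None = None
    significant: np.ndarray | None = None
    df: float = np.nan
    formula: str = FORMULA
    n_obs: int = 0
    n_failed: int = 0


@dataclass
class GLMResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cohens_d: dict = field(default_factory=dict)
    d_variant: str = "pooled-sd"  # effect-size formula tag (mandatory in reports)
    n_obs: int = 0
    formula: str = ""
    notes: list = field(default_factory=list)


def build_design(meta: pd.DataFrame, quadratic_time: bool = False) -> tuple[np.ndarray, list[str]]:
    """Full-factorial design matrix for group (PFF=1) x sex (M=1) x dpi.

    ``quadratic_time`` appends dpi^2 and its group interaction (used for
    inverted-U weight trajectories).
    """
    g = (meta["group"] == "PFF").to_numpy(float)
    s = (meta["sex"] == "M").to_numpy(float)
    t = meta["dpi"].to_numpy(float)
    cols = [np.ones_like(g), g, s, t, g * s, g * t, s * t, g * s * t]
    names = list(TERMS)
    if quadratic_time:
        cols += [t * t, g * t * t]
        names += ["dpi2", "group[PFF]:dpi2"]
    return np.column_stack(cols), names


def fit_voxelwise_lme(
    matrix: np.ndarray,
    meta: pd.DataFrame,
    q_level: float = 0.01,
    quadratic_time: bool = False,
) -> dict[str, VoxelStatMap]:
    """Fit the longitudinal mixed model at every voxel.

    ``matrix`` is voxels x scans (relative-flavor blurred log-Jacobians);
    ``meta`` has one row per scan with subject_id, group, sex, dpi.  Returns a
    map per fixed term with BH-corrected q-values at ``q_level``.  Voxels
    whose fit fails (non-finite statistics) are flagged and excluded from the
    correction, not silently dropped.
    """
    matrix = np.asarray(matrix, dtype=float)
    for col in ("subject_id", "group", "sex", "dpi"):
        if col not in meta.columns:
            raise ValueError(f"column_meta lacks required column {col!r}")
    if matrix.shape[1] != len(meta):
        raise ValueError("matrix columns and metadata rows differ")
    X, names = build_design(meta, quadratic_time=quadratic_time)
    fit = fit_random_intercept_lme(
        matrix.T, X, meta["subject_id"].to_numpy(), term_names=names
    )
    out: dict[str, VoxelStatMap] = {}
    for j, term in enumerate(fit.term_names):
        p = fit.pvalues[j].copy()
        t = fit.tvalues[j].copy()
        bad = ~np.isfinite(p)
        n_failed = int(bad.sum())
        if n_failed:
            logger.warning("%s: %d voxels failed to converge (p set to NaN)", term, n_failed)
        q, sig = fdr_correct(p, q_level)
        out[term] = VoxelStatMap(
            term=term,
            t=t,
            p=p,
            q=q,
            significant=sig,
            df=float(fit.df[j]),
            n_obs=fit.n_obs,
            n_failed=n_failed,
        )
    return out


def fdr_correct(p: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction.

    Returns monotone q-values and the significance mask ``q <= q_level``.
    NaN entries (failed fits) are excluded from the correction and stay NaN /
    not significant.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    ok = np.isfinite(p)
    if np.any((p[ok] <= 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = np.full(p.shape, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    if ok.any():
        rej, qvals, _, _ = multipletests(p[ok], alpha=q_level, method="fdr_bh")
        q[ok] = qvals
        sig[ok] = qvals <= q_level
    return q, sig


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Pooled-SD Cohen's d, (mean_a - mean_b) / s_pooled (first minus second)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def subject_weight_glm(
    H: np.ndarray, component: int, metadata: pd.DataFrame
) -> GLMResult:
    """OLS of one component's subject weights on group * sex.

    ``H`` is the k x n weight matrix with one column per subject (columns must
    align with ``metadata`` rows).  If a sex x group cell is empty the
    interaction is dropped with a warning.  Cohen's d (pooled-SD variant) is
    reported for the group and sex contrasts.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if not 0 <= component < H.shape[0]:
        raise ValueError(f"component {component} out of range for k={H.shape[0]}")
    if H.shape[1] != len(metadata):
        raise ValueError("weight columns and metadata rows differ")
    w = H[component]
    df = metadata.copy()
    df["weight"] = w
    g = (df["group"] == "PFF").to_numpy(float)
    s = (df["sex"] == "M").to_numpy(float)
    notes = []
    cells = df.groupby(["group", "sex"]).size()
    drop_interaction = len(cells) < 4
    cols = {"Intercept": np.ones_like(g), "group[PFF]": g, "sex[M]": s}
    if drop_interaction:
        msg = "empty sex x group cell: interaction term dropped"
        warnings.warn(msg)
        notes.append(msg)
    else:
        cols["group[PFF]:sex[M]"] = g * s
    X = pd.DataFrame(cols)
    fit = sm.OLS(w, X).fit()
    pvalues = fit.pvalues.copy()
    if fit.ssr < 1e-12 * max(float(np.sum(w * w)), 1.0):
        # degenerate perfect fit (e.g. constant weights): no evidence against
        # any zero effect
        zero = np.abs(fit.params) < 1e-10
        pvalues[zero.index[zero]] = 1.0
    d = {}
    for key, sel in (("group[PFF]", g), ("sex[M]", s)):
        if (sel == 1).sum() >= 2 and (sel == 0).sum() >= 2:
            try:
                d[key] = cohens_d(w[sel == 1], w[sel == 0])
            except ValueError:  # zero pooled SD (constant weights)
                pass
    return GLMResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=pvalues,
        cohens_d=d,
        d_variant="pooled-sd",
        n_obs=int(fit.nobs),
        formula="weight ~ group * sex",
        notes=notes,
    )
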