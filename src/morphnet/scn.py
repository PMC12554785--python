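"""Seed-based structural covariance networks and their group difference.

Structural covariance treats the across-subject correlation of regional
gray-matter volume as a measure of morphological synchronization.  The
group comparison uses the pooled interaction model

    target ~ seed + group + seed x group + covariates

whose interaction Wald z tests whether the seed-target covariance slope
differs between patients and controls (negative z: patient covariance
lower).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .morphostats import fdr_bh

__all__ = ["seed_covariance", "covariance_group_difference"]


def _covariate_matrix(subjects: pd.DataFrame, covariates: tuple[str, ...],
                      mask: np.ndarray | None = None) -> np.ndarray:
    cols = []
    for c in covariates:
        v = subjects[c]
        if v.dtype == object:
            v = (v == "M").astype(float)
        v = v.to_numpy(dtype=float)
        cols.append(v[mask] if mask is not None else v)
    if not cols:
        n = int(mask.sum()) if mask is not None else len(subjects)
        return np.empty((n, 0))
    return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """beta, standard errors, df."""
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    return beta, se, df


def seed_covariance(data: pd.DataFrame, seed: str, subjects: pd.DataFrame,
                    group: str = "patient",
                    covariates: tuple[str, ...] = ("age", "sex", "tiv")
                    ) -> pd.DataFrame:
    """Within-group regression of every target parcel on the seed.

    Returns a frame indexed by target with the seed slope and the partial
    correlation (sign-matched to the slope, from the seed t-statistic).
    """
    if seed not in data.columns:
        raise KeyError(f"unknown seed parcel: {seed!r}")
    mask = (subjects["group"] == group).to_numpy()
    if mask.sum() < 4:
        raise ValueError(f"group {group!r} has fewer than 4 subjects")
    s = data[seed].to_numpy(dtype=float)[mask]
    C = _covariate_matrix(subjects, covariates, mask)
    X = np.column_stack([np.ones(mask.sum()), s, C])
    rows = []
    for tgt in data.columns:
        if tgt == seed:
            continue
        y = data[tgt].to_numpy(dtype=float)[mask]
        beta, se, df = _ols(X, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[1] / se[1]
        r = t / np.sqrt(t * t + df) if np.isfinite(t) else np.sign(beta[1]) * 1.0
        rows.append({"target": tgt, "slope": beta[1], "r": float(r)})
    return pd.DataFrame(rows).set_index("target")


def covariance_group_difference(data: pd.DataFrame, seed: str,
                                subjects: pd.DataFrame,
                                covariates: tuple[str, ...] = ("age", "sex", "tiv"),
                                patient_level: str = "patient") -> pd.DataFrame:
    """Seed x group interaction test of covariance differences.

    Pooled model per target: target ~ seed + group + seed x group +
    covariates; z = interaction coefficient / SE (Wald), two-sided normal p,
    BH q across targets.  Negative z means the patient slope is lower.
    """
    if seed not in data.columns:
        raise KeyError(f"unknown seed parcel: {seed!r}")
    g = (subjects["group"] == patient_level).to_numpy(dtype=float)
    for grp, cnt in zip(*np.unique(subjects["group"], return_counts=True)):
        if cnt < 4:
            raise ValueError(f"group {grp!r} has fewer than 4 subjects")
    s = data[seed].to_numpy(dtype=float)
    C = _covariate_matrix(subjects, covariates, None)
    for j, c in enumerate(covariates):
        col = C[:, j]
        if col.std() > 0 and g.std() > 0:
            if abs(np.corrcoef(g, col)[0, 1]) > 1 - 1e-12:
                raise ValueError(f"group is collinear with covariate {c!r}")
    X = np.column_stack([np.ones(len(g)), s, g, s * g, C])
    rows = []
    for tgt in data.columns:
        if tgt == seed:
            continue
        y = data[tgt].to_numpy(dtype=float)
        beta, se, _ = _ols(X, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta[3] / se[3]
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"target": tgt, "beta_interaction": beta[3],
                     "z_interaction": float(z), "p_interaction": p})
    out = pd.DataFrame(rows).set_index("target")
    ok = out["p_interaction"].notna()
    qv = np.full(len(out), np.nan)
    if ok.any():
        _, qv_ok = fdr_bh(out.loc[ok, "p_interaction"].to_numpy())
        qv[ok.to_numpy()] = qv_ok
    out["q"] = qv
    return out
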