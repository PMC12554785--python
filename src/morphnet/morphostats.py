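"""Mass-univariate group statistics for morphometry.

Per-unit (parcel or voxel) ordinary-least-squares group comparison with
age/sex/TIV covariates, Gaussian volume smoothing, permutation-based
cluster-level family-wise-error control (Freedman–Lane residual
permutation), Benjamini–Hochberg FDR, covariate-adjusted (partial) Pearson
correlation, and the Mann–Whitney U test with exact small-sample
enumeration.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatMap",
    "ClusterSet",
    "build_design",
    "fit_group_glm",
    "smooth_volume",
    "permutation_cluster_fwe",
    "fdr_bh",
    "adjusted_correlation",
    "mann_whitney",
]


@dataclass
class StatMap:
    """Per-unit group-effect statistics from a mass-univariate GLM."""

    domain: str                 # "parcel" | "voxel"
    t: np.ndarray
    p: np.ndarray
    df: int
    beta_group: np.ndarray
    names: list[str] | None = None
    corrected: np.ndarray | None = None
    mask: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.names if self.names is not None else np.arange(self.t.size)
        d = {"t": self.t, "p": self.p, "beta_group": self.beta_group}
        if self.corrected is not None:
            d["q"] = self.corrected
        return pd.DataFrame(d, index=idx)


@dataclass
class ClusterSet:
    """Suprathreshold clusters with permutation FWE p-values."""

    clusters: list[dict] = field(default_factory=list)  # voxels, size, stat, p_fwe
    forming_threshold: float = 0.001
    connectivity: int = 26
    n_perm: int = 0

    def significant(self, alpha: float = 0.05) -> list[dict]:
        return [c for c in self.clusters if c["p_fwe"] < alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"size": c["size"], "stat": c["stat"], "p_fwe": c["p_fwe"]}
             for c in self.clusters])


def build_design(subjects: pd.DataFrame, group_col: str = "group",
                 covariates: tuple[str, ...] = ("age", "sex", "tiv"),
                 patient_level: str = "patient") -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, group indicator, covariates].

    The group indicator is 1 for ``patient_level``, so a negative group beta
    means lower values in patients.  ``sex`` is coded M=1/F=0 (reference
    configurable by recoding upstream).
    """
    n = len(subjects)
    cols = [np.ones(n), (subjects[group_col] == patient_level).to_numpy(dtype=float)]
    names = ["intercept", "group"]
    for c in covariates:
        v = subjects[c]
        if v.dtype == object:
            v = (v == "M").astype(float)
        cols.append(v.to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def _ols_t(X: np.ndarray, Y: np.ndarray, col: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized OLS t-statistic for one design column across response
    columns.  Returns (beta_col, t, df)."""
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T
    B = pinv @ Y
    resid = Y - X @ B
    df = n - k
    sigma2 = (resid ** 2).sum(axis=0) / df
    var = sigma2 * XtX_inv[col, col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[col] / np.sqrt(var)
    return B[col], t, df


def fit_group_glm(data: pd.DataFrame | np.ndarray,
                  subjects: pd.DataFrame | None = None,
                  design: np.ndarray | None = None,
                  group_index: int = 1,
                  covariates: tuple[str, ...] = ("age", "sex", "tiv"),
                  domain: str = "parcel") -> StatMap:
    """Per-unit OLS group comparison with covariate adjustment.

    Either pass ``subjects`` (a design is built with intercept, group and
    ``covariates``) or a prebuilt ``design`` whose column ``group_index``
    carries the group contrast.  Two-sided p from the t distribution with
    n - rank(design) degrees of freedom.  Units with zero residual variance
    get p = NaN and a warning.
    """
    if isinstance(data, pd.DataFrame):
        Y = data.to_numpy(dtype=float)
        names = list(data.columns)
    else:
        Y = np.asarray(data, dtype=float)
        names = None
    if Y.ndim == 1:
        Y = Y[:, None]
    if design is None:
        if subjects is None:
            raise ValueError("need subjects or an explicit design")
        design, _ = build_design(subjects, covariates=covariates)
    X = np.asarray(design, dtype=float)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design matrix")
    if n <= k:
        raise ValueError("more design columns than subjects")
    beta, t, df = _ols_t(X, Y, group_index)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} unit(s) with zero residual variance: p set to NaN")
        p[bad] = np.nan
    # identical groups at a unit: beta 0 and zero t -> p 1 (finite case)
    return StatMap(domain=domain, t=t, p=p, df=df, beta_group=beta, names=names)


def smooth_volume(volume: np.ndarray, fwhm: float, voxel_size: float = 1.0) -> np.ndarray:
    """Gaussian smoothing with kernel width given as FWHM in mm.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis; nearest-replicate boundaries.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return np.array(volume, dtype=float, copy=True)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma, mode="nearest")


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _cluster_sizes(tmap: np.ndarray, thr: float, structure: np.ndarray
                   ) -> tuple[np.ndarray, int, np.ndarray]:
    lab, nlab = ndimage.label(np.abs(tmap) > thr, structure=structure)
    if nlab == 0:
        return lab, 0, np.zeros(0, dtype=int)
    sizes = np.bincount(lab.ravel())[1:]
    return lab, nlab, sizes


def permutation_cluster_fwe(stack: np.ndarray,
                            subjects: pd.DataFrame | None = None,
                            design: np.ndarray | None = None,
                            group_index: int = 1,
                            covariates: tuple[str, ...] = ("age", "sex", "tiv"),
                            forming_p: float = 0.001,
                            n_perm: int = 1000,
                            alpha: float = 0.05,
                            connectivity: int = 26,
                            seed: int = 0) -> ClusterSet:
    """Cluster-extent FWE control by permutation of group labels.

    Observed clusters are connected components of the suprathreshold |t|
    map at the voxel-forming threshold.  The null is the maximum cluster
    size over Freedman–Lane permutations: residuals from the reduced
    (covariates-only) model are permuted, the reduced fit added back, and
    the full-model t-map recomputed.  FWE p = (1 + #{null >= obs}) /
    (1 + n_perm), so the smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    shape = stack.shape[1:]
    Y = stack.reshape(stack.shape[0], -1)
    if design is None:
        if subjects is None:
            raise ValueError("need subjects or an explicit design")
        design, _ = build_design(subjects, covariates=covariates)
    X = np.asarray(design, dtype=float)
    n, k = X.shape
    structure = _STRUCTURES[connectivity]

    _, t_obs, df = _ols_t(X, Y, group_index)
    t_obs = np.nan_to_num(t_obs, nan=0.0, posinf=0.0, neginf=0.0)
    thr = stats.t.isf(forming_p / 2.0, df)
    tmap = t_obs.reshape(shape)
    lab, nlab, sizes = _cluster_sizes(tmap, thr, structure)
    cs = ClusterSet(forming_threshold=forming_p, connectivity=connectivity, n_perm=n_perm)
    if nlab == 0:
        return cs

    # reduced model: all columns except the group contrast
    keep = [j for j in range(k) if j != group_index]
    Xr = X[:, keep]
    Hr = Xr @ np.linalg.inv(Xr.T @ Xr) @ Xr.T
    fitted_r = Hr @ Y
    resid_r = Y - fitted_r

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yp = fitted_r + resid_r[perm]
        _, t_p, _ = _ols_t(X, Yp, group_index)
        t_p = np.nan_to_num(t_p, nan=0.0, posinf=0.0, neginf=0.0)
        _, nl, sz = _cluster_sizes(t_p.reshape(shape), thr, structure)
        null_max[b] = sz.max() if nl else 0
    for i in range(nlab):
        size = int(sizes[i])
        p_fwe = (1.0 + np.sum(null_max >= size)) / (1.0 + n_perm)
        members = np.argwhere(lab == i + 1)
        cs.clusters.append({
            "voxels": members, "size": size,
            "stat": float(np.abs(tmap)[lab == i + 1].max()),
            "p_fwe": float(p_fwe),
        })
    cs.clusters.sort(key=lambda c: -c["size"])
    return cs


def fdr_bh(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (rejection mask, q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, qvals


def adjusted_correlation(x: np.ndarray, y: np.ndarray,
                         covariates: np.ndarray | None = None
                         ) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    Partial correlation: both variables are residualized on
    [intercept, covariates] and the residuals correlated; p from the t
    transform with df = n - #covariates - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([np.ones(n), C])
    ncov = Z.shape[1] - 1
    if n <= ncov + 2:
        raise ValueError("too few observations for the requested adjustment")
    H = Z @ np.linalg.pinv(Z)
    rx = x - H @ x
    ry = y - H @ y
    sx, sy = rx.std(), ry.std()
    if sx <= 1e-12 * (x.std() + 1) or sy <= 1e-12 * (y.std() + 1):
        raise ValueError("zero residual variance")
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - ncov - 2
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return r, float(p)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample a over b with half-counts for ties."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mann–Whitney U (of the first sample) with a two-sided p.

    Exact by full enumeration of group assignments when both samples have
    at most 8 observations (valid under ties); otherwise the normal
    approximation with tie correction.  All values tied gives p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    u_obs = _u_statistic(a, b)
    if np.unique(np.concatenate([a, b])).size == 1:
        return u_obs, 1.0
    if n1 <= 8 and n2 <= 8:
        pooled = np.concatenate([a, b])
        mid = n1 * n2 / 2.0
        d_obs = abs(u_obs - mid)
        count = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mid) >= d_obs - 1e-12:
                count += 1
        return u_obs, count / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)
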