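"""Causal structural covariance networks on a duration-ordered pseudotime.

Patients sorted by disease duration stand in for successive time points of
one progression trajectory; gray-matter volumes residualized for age, sex
and total intracranial volume and standardized per parcel form the
"pseudotime series".  A bivariate signed-path-coefficient Granger model

    y_t = b0 + b1 * y_{t-1} + beta * x_{t-1} + e_t

yields, per ordered region pair, the signed lagged influence beta with a
Wald z and two-sided p.  Only positive coefficients are retained
(progression forecasting), thresholded by Benjamini–Hochberg FDR, and the
surviving directed edges are summarized by out- and in-degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .morphostats import fdr_bh

__all__ = [
    "PseudotimeSeries",
    "GCResult",
    "CausalNetwork",
    "build_pseudotime",
    "gc_path_coefficient",
    "seed_to_map_gc",
    "roi_network_gc",
    "export_causal_network",
]


@dataclass
class PseudotimeSeries:
    """Duration-ordered, covariate-residualized, standardized GMV matrix."""

    order: list[str]
    values: pd.DataFrame             # rows follow `order`
    covariates_removed: list[str]
    dropped: list[str] = field(default_factory=list)

    @property
    def parcels(self) -> list[str]:
        return list(self.values.columns)


class GCResult(NamedTuple):
    source: str
    target: str
    beta: float
    se: float
    z: float
    p: float
    q: float = float("nan")


@dataclass
class CausalNetwork:
    """Thresholded directed network with signed path-coefficient weights."""

    nodes: list[str]
    weights: pd.DataFrame            # source x target, 0 where not retained
    binary: pd.DataFrame
    out_degree: pd.Series
    in_degree: pd.Series
    q_level: float
    results: list[GCResult] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return int(self.binary.to_numpy().sum())


def build_pseudotime(data: pd.DataFrame, subjects: pd.DataFrame,
                     covariates: tuple[str, ...] = ("age", "sex", "tiv"),
                     min_n: int = 10) -> PseudotimeSeries:
    """Sort patients by (duration, id), residualize parcels, standardize.

    Ties in duration break by subject id (stable).  Parcels whose residual
    variance vanishes (e.g. a parcel collinear with a covariate) are
    dropped with a warning.
    """
    pats = subjects[subjects["group"] == "patient"] if "group" in subjects else subjects
    if pats["duration"].isna().any():
        bad = pats.loc[pats["duration"].isna(), "id"].tolist()
        raise ValueError(f"missing duration for: {bad}")
    if len(pats) < min_n:
        raise ValueError(f"need at least {min_n} patients for a pseudotime series")
    order = pats.sort_values(["duration", "id"], kind="stable")["id"].tolist()
    sub = pats.set_index("id").loc[order]
    Y = data.loc[order]

    cols = [np.ones(len(order))]
    for c in covariates:
        v = sub[c]
        if v.dtype == object:
            v = (v == "M").astype(float)
        cols.append(v.to_numpy(dtype=float))
    Z = np.column_stack(cols)
    H = Z @ np.linalg.pinv(Z)

    resid = Y.to_numpy(dtype=float) - H @ Y.to_numpy(dtype=float)
    scale = np.abs(Y.to_numpy()).mean() + 1e-30
    keep, dropped = [], []
    for j, name in enumerate(Y.columns):
        if resid[:, j].std() <= 1e-10 * scale:
            dropped.append(name)
        else:
            keep.append(j)
    if dropped:
        warnings.warn(f"parcels dropped (zero residual variance): {dropped}")
    R = resid[:, keep]
    R = (R - R.mean(axis=0)) / R.std(axis=0)
    values = pd.DataFrame(R, index=order, columns=[Y.columns[j] for j in keep])
    return PseudotimeSeries(order=order, values=values,
                            covariates_removed=list(covariates), dropped=dropped)


def gc_path_coefficient(x: np.ndarray, y: np.ndarray, lag: int = 1,
                        include_ar: bool = True) -> GCResult:
    """Signed path coefficient of x on y at the given lag.

    OLS of y_t on [1, y_{t-lag..t-1} (optional AR terms), x_{t-lag..t-1}]
    over t = lag..n-1; ``beta`` is the coefficient of x_{t-lag}, z its Wald
    statistic (beta / SE) with a two-sided normal p.  Inputs are used as
    given — the pipeline standardizes upstream so betas are comparable
    across pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if x.size != n:
        raise ValueError("series lengths differ")
    if n < lag + 3:
        raise ValueError(f"need at least lag + 3 = {lag + 3} points, got {n}")
    rows = []
    for j in range(1, lag + 1):
        rows.append(y[lag - j:n - j])
    ar = np.column_stack(rows) if include_ar else np.empty((n - lag, 0))
    xr = np.column_stack([x[lag - j:n - j] for j in range(1, lag + 1)])
    X = np.column_stack([np.ones(n - lag), ar, xr])
    yt = y[lag:]
    k = X.shape[1]
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("collinear lagged regressors")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta_all = XtX_inv @ X.T @ yt
    resid = yt - X @ beta_all
    df = (n - lag) - k
    if df < 1:
        raise ValueError("insufficient points for the lag order")
    sigma2 = float(resid @ resid) / df
    # x_{t-lag} is the LAST x column (j = lag)
    idx = X.shape[1] - 1
    se = float(np.sqrt(sigma2 * XtX_inv[idx, idx]))
    b = float(beta_all[idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b / se if se > 0 else np.inf * np.sign(b) if b != 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return GCResult(source="x", target="y", beta=b, se=se, z=float(z), p=float(p))


def seed_to_map_gc(pseudo: PseudotimeSeries, seed: str, q: float = 0.05,
                   lag: int = 1, include_ar: bool = True) -> list[GCResult]:
    """Granger influence of the seed on every other parcel.

    Only positive path coefficients are retained; BH-FDR runs across the
    retained tests; significance is q below the requested level.
    """
    if seed not in pseudo.values.columns:
        if seed in pseudo.dropped:
            raise ValueError(f"seed {seed!r} was dropped during residualization")
        raise KeyError(f"unknown seed parcel: {seed!r}")
    s = pseudo.values[seed].to_numpy()
    results = []
    for tgt in pseudo.values.columns:
        if tgt == seed:
            continue
        r = gc_path_coefficient(s, pseudo.values[tgt].to_numpy(), lag=lag,
                                include_ar=include_ar)
        results.append(r._replace(source=seed, target=tgt))
    retained = [r for r in results if r.beta > 0]
    if retained:
        _, qv = fdr_bh(np.array([r.p for r in retained]), q=q)
        retained = [r._replace(q=float(qq)) for r, qq in zip(retained, qv)]
    return retained


def roi_network_gc(pseudo: PseudotimeSeries, rois: Sequence[str],
                   q: float = 0.05, lag: int = 1,
                   include_ar: bool = True) -> CausalNetwork:
    """Directed causal network over the ROI set.

    Every ordered pair is tested; positive coefficients are retained and
    BH-corrected jointly; the binary adjacency keeps edges with q below the
    level, and node out-/in-degrees are its row/column sums.
    """
    rois = list(rois)
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs")
    if len(set(rois)) != len(rois):
        raise ValueError("duplicate ROI names")
    missing = [r for r in rois if r not in pseudo.values.columns]
    if missing:
        raise KeyError(f"ROIs absent from pseudotime series: {missing}")
    results = []
    for s in rois:
        for t in rois:
            if s == t:
                continue
            r = gc_path_coefficient(pseudo.values[s].to_numpy(),
                                    pseudo.values[t].to_numpy(),
                                    lag=lag, include_ar=include_ar)
            results.append(r._replace(source=s, target=t))
    retained = [r for r in results if r.beta > 0]
    if retained:
        _, qv = fdr_bh(np.array([r.p for r in retained]), q=q)
        retained = [r._replace(q=float(qq)) for r, qq in zip(retained, qv)]
    W = pd.DataFrame(0.0, index=rois, columns=rois)
    B = pd.DataFrame(0, index=rois, columns=rois)
    for r in retained:
        if r.q < q:
            W.loc[r.source, r.target] = r.beta
            B.loc[r.source, r.target] = 1
    return CausalNetwork(nodes=rois, weights=W, binary=B,
                         out_degree=B.sum(axis=1), in_degree=B.sum(axis=0),
                         q_level=q, results=retained)


def export_causal_network(net: CausalNetwork, coords: Mapping[str, np.ndarray],
                          node_path: str | Path, edge_path: str | Path) -> None:
    """Write BrainNet-style .node (x y z color size label) and .edge files.

    Node size encodes out-degree + 1; color the node index.  The .edge file
    is the square weight matrix, tab-delimited, in node order.
    """
    missing = [nm for nm in net.nodes if nm not in coords]
    if missing:
        raise ValueError(f"missing coordinates for nodes: {missing}")
    lines = []
    for i, nm in enumerate(net.nodes):
        x, y, z = (float(v) for v in coords[nm])
        size = float(net.out_degree[nm] + 1)
        lines.append(f"{x:.3f}\t{y:.3f}\t{z:.3f}\t{i + 1}\t{size:.3f}\t{nm}")
    Path(node_path).write_text("\n".join(lines) + "\n")
    np.savetxt(edge_path, net.weights.to_numpy(), delimiter="\t", fmt="%.6f")
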