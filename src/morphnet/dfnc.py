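"""Sliding-window dynamic connectivity, state clustering, dwell statistics.

Windowed Fisher-z correlations among component time series (rectangular
window convolved with a Gaussian taper, the common sliding-window
convention) are pooled across subjects and clustered with k-means into
recurring connectivity states; per-subject occupancy and mean dwell time
per state are then compared between groups with Mann–Whitney tests under
FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .morphostats import fdr_bh, mann_whitney

__all__ = [
    "WindowedFC",
    "StateModel",
    "window_weights",
    "sliding_window_fc",
    "cluster_states",
    "dwell_statistics",
    "compare_dwell",
    "elbow_inertia",
]


@dataclass
class WindowedFC:
    """Per-subject windows x pairs matrix of Fisher-z correlations."""

    subject: str
    z: np.ndarray
    pairs: list[tuple[int, int]]
    window_length: int
    step: int
    taper_sd: float

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]


@dataclass
class StateModel:
    """k-means connectivity states over pooled windows."""

    k: int
    centroids: np.ndarray            # k x pairs
    assignments: dict[str, np.ndarray]
    inertia: float
    distance: str = "cityblock"

    def pooled_labels(self) -> np.ndarray:
        return np.concatenate([self.assignments[s] for s in self.assignments])


def window_weights(window_length: int, taper_sd: float) -> np.ndarray:
    """Rectangle of the window length convolved with a Gaussian taper,
    truncated to the window and normalized to sum 1."""
    if window_length < 3:
        raise ValueError("window length must be >= 3")
    rect = np.ones(window_length)
    if taper_sd > 0:
        half = int(np.ceil(4 * taper_sd))
        t = np.arange(-half, half + 1)
        g = np.exp(-0.5 * (t / taper_sd) ** 2)
        full = np.convolve(rect, g, mode="full")
        start = (full.size - window_length) // 2
        w = full[start:start + window_length]
    else:
        w = rect
    return w / w.sum()


def _weighted_corr_z(seg: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, bool]:
    """Upper-triangle weighted correlations of one window, Fisher-z."""
    mu = w @ seg
    d = seg - mu
    cov = (d * w[:, None]).T @ d
    var = np.diag(cov).copy()
    flagged = False
    # relative to the component's second moment, so an exactly constant
    # component is caught despite float residue in the weights
    bad = var <= 1e-12 * (w @ (seg ** 2) + 1e-30)
    if bad.any():
        flagged = True
        var[bad] = 1.0
    denom = np.sqrt(np.outer(var, var))
    r = cov / denom
    if bad.any():
        r[bad, :] = 0.0
        r[:, bad] = 0.0
    iu = np.triu_indices(seg.shape[1], k=1)
    rv = np.clip(r[iu], -1 + 1e-7, 1 - 1e-7)
    return np.arctanh(rv), flagged


def sliding_window_fc(series: np.ndarray, window_length: int = 22,
                      step: int = 1, taper_sd: float = 3.0,
                      subject: str = "s") -> WindowedFC:
    """Windowed Fisher-z correlations for one (time x components) series.

    Number of windows = floor((T - L) / step) + 1.  A zero-variance
    component within a window sets its pairs to 0 with a warning.
    """
    X = np.asarray(series, dtype=float)
    T, d = X.shape
    if window_length > T:
        raise ValueError(f"window length {window_length} exceeds series length {T}")
    w = window_weights(window_length, taper_sd)
    n_win = (T - window_length) // step + 1
    pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
    Z = np.empty((n_win, len(pairs)))
    any_flag = False
    for b in range(n_win):
        seg = X[b * step: b * step + window_length]
        Z[b], fl = _weighted_corr_z(seg, w)
        any_flag = any_flag or fl
    if any_flag:
        warnings.warn("zero-variance component in at least one window; "
                      "affected pairs set to 0")
    return WindowedFC(subject=subject, z=Z, pairs=pairs,
                      window_length=window_length, step=step, taper_sd=taper_sd)


def _kmeans_once(X: np.ndarray, k: int, rng: np.random.Generator,
                 distance: str, max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        if distance == "cityblock":
            D = np.abs(X[:, None, :] - centers[None, :, :]).sum(axis=2)
        else:
            D = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = D.argmin(axis=1)
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        for c in range(k):
            m = labels == c
            if not m.any():
                centers[c] = X[rng.integers(n)]
            elif distance == "cityblock":
                centers[c] = np.median(X[m], axis=0)
            else:
                centers[c] = X[m].mean(axis=0)
    if distance == "cityblock":
        D = np.abs(X[:, None, :] - centers[None, :, :]).sum(axis=2)
    else:
        D = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = D.argmin(axis=1)
    inertia = float(D[np.arange(n), labels].sum())
    return labels, centers, inertia


def cluster_states(windows: Sequence[WindowedFC], k: int = 5,
                   n_init: int = 100, distance: str = "cityblock",
                   seed: int = 0) -> StateModel:
    """k-means over all subjects' windows, best of ``n_init`` restarts.

    ``distance`` is cityblock (median centroid update, the dynamic-FC
    convention) or euclidean.  State labels are canonicalized by descending
    occupancy so label 0 is the most visited state.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.concatenate([w.z for w in windows])
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of windows")
    if distance not in ("cityblock", "euclidean"):
        raise ValueError("distance must be cityblock or euclidean")
    if k == 1:
        centers = (np.median(X, axis=0) if distance == "cityblock"
                   else X.mean(axis=0))[None, :]
        labels = np.zeros(X.shape[0], dtype=int)
        if distance == "cityblock":
            inertia = float(np.abs(X - centers).sum())
        else:
            inertia = float(((X - centers) ** 2).sum())
    else:
        best = None
        ss = np.random.SeedSequence([seed, 7])
        for child in ss.spawn(n_init):
            rng = np.random.default_rng(child)
            lab, cen, inertia = _kmeans_once(X, k, rng, distance)
            if best is None or inertia < best[2]:
                best = (lab, cen, inertia)
        labels, centers, inertia = best
    # canonical order: descending occupancy, centroid-norm tiebreak
    counts = np.bincount(labels, minlength=k)
    order = np.lexsort((np.linalg.norm(centers, axis=1), -counts))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    centers = centers[order]
    assignments, pos = {}, 0
    for w in windows:
        assignments[w.subject] = labels[pos: pos + w.n_windows]
        pos += w.n_windows
    return StateModel(k=k, centroids=centers, assignments=assignments,
                      inertia=inertia, distance=distance)


def _runs(seq: np.ndarray) -> list[tuple[int, int]]:
    """(state, run length) for each maximal constant run."""
    out = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            out.append((int(seq[start]), i - start))
            start = i
    return out


def dwell_statistics(model: StateModel) -> pd.DataFrame:
    """Mean dwell time (windows), occupancy fraction and visit count per
    subject per state.  States a subject never enters get NaN mean dwell
    (excluded from group tests)."""
    rows = []
    for subj, seq in model.assignments.items():
        runs = _runs(seq)
        total = len(seq)
        n_trans = len(runs) - 1
        for s in range(model.k):
            lens = [ln for st, ln in runs if st == s]
            rows.append({
                "subject": subj, "state": s,
                "mean_dwell": float(np.mean(lens)) if lens else np.nan,
                "fraction_time": sum(lens) / total,
                "n_visits": len(lens),
                "n_transitions": n_trans,
            })
    return pd.DataFrame(rows)


def compare_dwell(dwell: pd.DataFrame, groups: Mapping[str, str],
                  group_a: str = "patient", group_b: str = "control"
                  ) -> pd.DataFrame:
    """Per-state Mann–Whitney comparison of mean dwell times, BH across
    states.  States lacking defined dwell values in either group are
    reported as skipped."""
    dwell = dwell.copy()
    dwell["group"] = dwell["subject"].map(groups)
    rows = []
    for s, sub in dwell.groupby("state"):
        a = sub.loc[(sub["group"] == group_a) & sub["mean_dwell"].notna(), "mean_dwell"]
        b = sub.loc[(sub["group"] == group_b) & sub["mean_dwell"].notna(), "mean_dwell"]
        if len(a) < 2 or len(b) < 2:
            rows.append({"state": s, "U": np.nan, "p": np.nan, "skipped": True,
                         "n_a": len(a), "n_b": len(b)})
            continue
        U, p = mann_whitney(a.to_numpy(), b.to_numpy())
        rows.append({"state": s, "U": U, "p": p, "skipped": False,
                     "n_a": len(a), "n_b": len(b)})
    out = pd.DataFrame(rows).set_index("state")
    ok = ~out["skipped"]
    qv = np.full(len(out), np.nan)
    if ok.any():
        _, qv_ok = fdr_bh(out.loc[ok, "p"].to_numpy())
        qv[ok.to_numpy()] = qv_ok
    out["q"] = qv
    return out


def elbow_inertia(windows: Sequence[WindowedFC], k_range: Sequence[int] = range(2, 9),
                  n_init: int = 10, distance: str = "cityblock",
                  seed: int = 0) -> pd.Series:
    """Within-cluster cost over candidate k (a diagnostic helper; the state
    count is never chosen automatically)."""
    out = {}
    for k in k_range:
        model = cluster_states(windows, k=k, n_init=n_init,
                               distance=distance, seed=seed)
        out[k] = model.inertia
    return pd.Series(out, name="inertia")
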