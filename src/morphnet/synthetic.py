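"""Synthetic cohorts with planted ground truth.

Every structure the downstream analyses assume is planted explicitly and
recorded, so each stage can be validated by parameter recovery instead of
against private patient data:

* group atrophy on named parcels (standardized mean differences),
* group-dependent seed->target covariance slopes,
* a lag-1 causal chain along the duration-ordered patient axis
  (the "pseudotime" construction used by causal structural covariance),
* hidden-Markov state-switching covariance in component time series,
* DBS outcome labels with planted feature signal plus a stimulation-volume
  (VTA) confound.

All generators are deterministic functions of ``GroundTruth.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DEFAULT_PARCELS, LabelVolume

__all__ = [
    "GroundTruth",
    "gen_subject_table",
    "gen_gmv_parcels",
    "gen_gmv_volumes",
    "gen_component_timeseries",
    "gen_dbs_outcomes",
]

#: VTA subregions of the subthalamic target: hemisphere x functional zone.
VTA_SUBREGIONS = [
    "vta_left_sensorimotor", "vta_left_associative",
    "vta_right_sensorimotor", "vta_right_associative",
]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and sd."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _default_state_covariances(k: int = 5, n_components: int = 6,
                               rho: float = 0.8) -> list[np.ndarray]:
    """k well-separated correlation structures over the components.

    Each state carries correlation ``rho`` on its own signature set of
    component pairs (state k-1 is a weakly coupled state), mimicking
    connectivity states dominated by different network pairings.
    """
    pairs = [(i, j) for i in range(n_components) for j in range(i + 1, n_components)]
    covs = []
    for s in range(k):
        c = np.eye(n_components)
        if s < k - 1:
            # disjoint signature pairs per state, alternating sign
            sig = [pairs[(s * 3 + m) % len(pairs)] for m in range(3)]
            for m, (i, j) in enumerate(sig):
                val = rho if (s + m) % 2 == 0 else -rho
                c[i, j] = c[j, i] = val
        # shrink toward identity until positive definite
        lam = 1.0
        while np.linalg.eigvalsh(lam * c + (1 - lam) * np.eye(n_components)).min() < 1e-3:
            lam *= 0.9
        covs.append(lam * c + (1 - lam) * np.eye(n_components))
    return covs


@dataclass
class GroundTruth:
    """Planted generative parameters for one synthetic study.

    Effects are on the standardized (noise-sd) scale.  ``covariance_slopes``
    maps group -> {(seed, target): slope}; ``causal_edges`` lists
    (source, target, path coefficient) applied along the duration-ordered
    patient axis with lag 1.
    """

    seed: int = 0
    atrophy_effects: dict[str, float] = field(default_factory=dict)
    covariance_slopes: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    causal_edges: list[tuple[str, str, float]] = field(default_factory=list)
    state_covariances: list[np.ndarray] = field(default_factory=lambda: _default_state_covariances())
    # slow state switching (mean dwell ~100 samples) so that 22-sample
    # windows resolve the states rather than straddling transitions
    state_transition: np.ndarray = field(
        default_factory=lambda: 0.99 * np.eye(5) + 0.01 / 4 * (np.ones((5, 5)) - np.eye(5)))
    outcome_signal: dict[str, float] = field(default_factory=dict)
    vta_confound: float = 0.0
    noise_sd: float = 1.0
    parcel_noise_sd: dict[str, float] = field(default_factory=dict)
    # linear covariate effects on parcel volume: per year of age, per sex
    # indicator (M=1), per sd of TIV
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": -0.02, "sex": 0.3, "tiv": 0.5})
    parcels: list[str] = field(default_factory=lambda: list(DEFAULT_PARCELS))

    def __post_init__(self) -> None:
        self.state_transition = np.asarray(self.state_transition, dtype=float)
        self.state_covariances = [np.asarray(c, dtype=float) for c in self.state_covariances]
        self.validate()

    def validate(self) -> None:
        P = self.state_transition
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("state transition matrix must be square")
        if (P < -1e-12).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("state transition matrix must be row-stochastic")
        if len(self.state_covariances) != P.shape[0]:
            raise ValueError("one covariance per state required")
        for c in self.state_covariances:
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError("state covariance must be symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError("state covariance must be positive-definite")
        known = set(self.parcels)
        named = set(self.atrophy_effects) | set(self.parcel_noise_sd)
        for g in self.covariance_slopes.values():
            for s, t in g:
                named |= {s, t}
        for s, t, _ in self.causal_edges:
            named |= {s, t}
        unknown = named - known
        if unknown:
            raise ValueError(f"effects name parcels outside the atlas set: {sorted(unknown)}")

    @classmethod
    def paper_like(cls, seed: int = 0) -> "GroundTruth":
        """Default study conditions: pallidal/precuneus atrophy, reduced
        patient covariance of the pallidal seed with precentral gyrus, and a
        pallidum -> precuneus -> temporal causal chain, mirroring the
        tremor-dominant progression hypothesis the analyses probe."""
        return cls(
            seed=seed,
            atrophy_effects={"PCUN.L": -0.8, "PCUN.R": -0.8, "FFG.R": -0.6, "HIP.L": -0.5},
            covariance_slopes={
                "control": {("PAL.L", "PreCG.L"): 0.8},
                "patient": {("PAL.L", "PreCG.L"): 0.0},
            },
            causal_edges=[("PAL.L", "PCUN.L", 0.6), ("PCUN.L", "ITG.L", 0.6)],
            outcome_signal={"PCUN.L": 0.8, "PAL.L": 0.6, "updrs3_on": 0.6},
            vta_confound=0.5,
        )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["state_covariances"] = [c.tolist() for c in self.state_covariances]
        d["state_transition"] = self.state_transition.tolist()
        d["covariance_slopes"] = {
            g: {f"{s}->{t}": b for (s, t), b in m.items()}
            for g, m in self.covariance_slopes.items()
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["covariance_slopes"] = {
            g: {tuple(k.split("->")): v for k, v in m.items()}
            for g, m in d["covariance_slopes"].items()
        }
        d["causal_edges"] = [tuple(e) for e in d["causal_edges"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# subjects

def gen_subject_table(n_patient: int, n_control: int, seed: int) -> pd.DataFrame:
    """Demographics and clinical scores for a patient/control cohort.

    Patients receive a right-skewed (lognormal) disease duration with
    arithmetic mean ~8 y and sd ~5 y; ages ~N(63, 6.7) and sex ~Bernoulli(1/2)
    in both groups, so the groups are balanced in expectation.  Tremor and
    postural-instability sub-score means are drawn so the cohort is
    tremor-dominant (ratio mostly >= 1.15).
    """
    if n_patient < 2:
        raise ValueError("need at least 2 patients")
    if n_control < 0:
        raise ValueError("n_control must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_patient + n_control
    ids = [f"p{i:03d}" for i in range(n_patient)] + [f"c{i:03d}" for i in range(n_control)]
    group = ["patient"] * n_patient + ["control"] * n_control
    age = np.clip(rng.normal(63.4, 6.7, n), 40, 85)
    sex = rng.choice(["M", "F"], size=n)
    tiv = np.clip(rng.normal(1.45e6, 1.2e5, n), 1.0e6, 1.9e6)  # mm^3

    mu, sg = _lognormal_params(8.34, 5.34)
    duration = np.full(n, np.nan)
    duration[:n_patient] = np.maximum(rng.lognormal(mu, sg, n_patient), 0.25)

    def pat(meanv, sdv, lo, hi):
        col = np.full(n, np.nan)
        col[:n_patient] = np.clip(rng.normal(meanv, sdv, n_patient), lo, hi)
        return col

    updrs3_on = pat(45.61, 16.47, 5, 100)
    updrs3_off = pat(22.49, 12.11, 1, 80)
    tremor = pat(2.0, 0.6, 0.2, 4)
    # TD cohort: postural sub-score low so tremor/PIGD ratio lands >= 1.15
    pigd = np.full(n, np.nan)
    pigd[:n_patient] = np.clip(tremor[:n_patient] / rng.uniform(1.2, 3.0, n_patient), 0.05, 4)
    hy = np.full(n, np.nan)
    hy[:n_patient] = rng.choice([1.0, 1.5, 2.0, 2.5, 3.0, 4.0], size=n_patient,
                                p=[0.2, 0.2, 0.25, 0.15, 0.15, 0.05])
    df = pd.DataFrame({
        "id": ids, "group": group, "age": age, "sex": sex, "tiv": tiv,
        "duration": duration,
        "updrs3_on": updrs3_on, "updrs3_off": updrs3_off,
        "tremor_mean": tremor, "pigd_mean": pigd, "hy": hy,
        "mmse": pat(26.28, 2.27, 10, 30), "moca": pat(21.61, 3.42, 5, 30),
        "hama": pat(14.03, 6.99, 0, 50), "hamd": pat(15.48, 8.47, 0, 50),
        "vhi": pat(28.41, 27.80, 0, 120), "led": pat(831.08, 497.87, 0, 3000),
    })
    return df


# ---------------------------------------------------------------------------
# gray-matter volumes

def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def gen_gmv_parcels(subjects: pd.DataFrame, truth: GroundTruth) -> pd.DataFrame:
    """Subjects x parcels gray-matter volume matrix with planted structure.

    Construction order: positive baseline + covariate effects + noise;
    patient atrophy per ``truth.atrophy_effects``; within-group covariance
    slopes (target += slope * z(seed)); causal edges applied sequentially
    along the duration-ordered patient axis (target at duration rank r gains
    beta * z(source at rank r-1)), so chains propagate.
    """
    if subjects.empty:
        raise ValueError("empty subject table")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    parcels = truth.parcels
    n = len(subjects)
    is_pat = (subjects["group"] == "patient").to_numpy()
    sexn = (subjects["sex"] == "M").to_numpy().astype(float)
    age = subjects["age"].to_numpy(dtype=float)
    tivz = _zscore(subjects["tiv"].to_numpy(dtype=float))
    ce = truth.covariate_effects

    base = 5.0 + 0.1 * np.arange(len(parcels))
    G = np.empty((n, len(parcels)))
    for j, name in enumerate(parcels):
        sd = truth.parcel_noise_sd.get(name, truth.noise_sd)
        G[:, j] = (base[j]
                   + ce.get("age", 0.0) * (age - 63.0)
                   + ce.get("sex", 0.0) * sexn
                   + ce.get("tiv", 0.0) * tivz
                   + rng.normal(0.0, sd, n))
        eff = truth.atrophy_effects.get(name, 0.0)
        if eff:
            G[is_pat, j] += eff * truth.noise_sd

    gmv = pd.DataFrame(G, index=subjects["id"].to_numpy(), columns=parcels)

    for grp, slopes in truth.covariance_slopes.items():
        m = (subjects["group"] == grp).to_numpy()
        if not m.any():
            continue
        for (s, t), b in slopes.items():
            if b:
                gmv.loc[m, t] = gmv.loc[m, t].to_numpy() + b * _zscore(gmv.loc[m, s].to_numpy())

    if truth.causal_edges:
        pats = subjects.loc[is_pat, ["id", "duration"]]
        if pats["duration"].isna().any():
            raise ValueError("causal edges need patient durations")
        order = pats.sort_values(["duration", "id"], kind="stable")["id"].to_numpy()
        for s, t, b in truth.causal_edges:
            src = _zscore(gmv.loc[order, s].to_numpy())
            add = np.zeros(len(order))
            add[1:] = b * src[:-1]
            gmv.loc[order, t] = gmv.loc[order, t].to_numpy() + add
    return gmv


def gen_gmv_volumes(parcels: pd.DataFrame, atlas: LabelVolume,
                    noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Paint parcel values onto the atlas grid per subject.

    Every voxel of label L receives the subject's parcel-L value plus
    i.i.d. Gaussian noise; background stays 0.  Returns an (n, x, y, z)
    stack aligned with ``parcels`` row order.
    """
    missing = [p for p in parcels.columns if p not in atlas.names]
    if missing:
        raise ValueError(f"parcels absent from atlas: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n = len(parcels)
    stack = np.zeros((n,) + atlas.data.shape)
    for name in parcels.columns:
        mask = atlas.data == atlas.label_of(name)
        nv = int(mask.sum())
        if nv == 0:
            continue
        vals = parcels[name].to_numpy()[:, None]
        noise = rng.normal(0.0, noise_sd, (n, nv)) if noise_sd > 0 else 0.0
        stack[:, mask] = vals + noise
    return stack


# ---------------------------------------------------------------------------
# component time series (hidden-Markov state switching)

def gen_component_timeseries(n_subjects: int, T: int, truth: GroundTruth,
                             ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-subject (T x components) series from a hidden Markov chain.

    Each subject follows a state path drawn from ``truth.state_transition``
    (uniform initial state); samples are zero-mean Gaussian with the active
    state's covariance.  Returns (series list, true state path list).
    """
    P = truth.state_transition
    k = P.shape[0]
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 3]))
    chols = [np.linalg.cholesky(c) for c in truth.state_covariances]
    d = chols[0].shape[0]
    series, paths = [], []
    for _ in range(n_subjects):
        states = np.empty(T, dtype=int)
        states[0] = rng.integers(k)
        for t in range(1, T):
            states[t] = rng.choice(k, p=P[states[t - 1]])
        z = rng.standard_normal((T, d))
        x = np.empty((T, d))
        for s in range(k):
            m = states == s
            if m.any():
                x[m] = z[m] @ chols[s].T
        series.append(x)
        paths.append(states)
    return series, paths


# ---------------------------------------------------------------------------
# DBS outcomes

def gen_dbs_outcomes(subjects: pd.DataFrame, truth: GroundTruth,
                     features: pd.DataFrame | None = None,
                     n_noise_features: int = 20,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome records (and a feature table) for the patient subset.

    Improvement percent = 35 + 15*(planted feature signal + vta_confound *
    z(total VTA) + unit noise), clipped to [-50, 100].  Signal features named
    in ``truth.outcome_signal`` are taken from ``features`` when supplied
    (e.g. the GMV matrix joined with clinical scores) and standardized;
    otherwise drawn standard normal.  Noise features pad the table.
    """
    pats = subjects[subjects["group"] == "patient"]
    if pats.empty:
        raise ValueError("no patients in subject table")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 4]))
    n = len(pats)
    ids = pats["id"].to_numpy()

    cols: dict[str, np.ndarray] = {}
    for name in truth.outcome_signal:
        if features is not None and name in features.columns:
            cols[name] = features.loc[ids, name].to_numpy(dtype=float)
        elif name in pats.columns:
            cols[name] = pats[name].to_numpy(dtype=float)
        else:
            cols[name] = rng.standard_normal(n)
    for i in range(n_noise_features):
        cols[f"noise{i:02d}"] = rng.standard_normal(n)
    feat = pd.DataFrame(cols, index=ids)

    mu, sg = _lognormal_params(60.0, 30.0)  # mm^3, plausible VTA overlap volumes
    vta = pd.DataFrame({r: rng.lognormal(mu, sg, n) for r in VTA_SUBREGIONS}, index=ids)
    vta_total_z = _zscore(vta.sum(axis=1).to_numpy())

    signal = np.zeros(n)
    for name, eff in truth.outcome_signal.items():
        signal += eff * _zscore(feat[name].to_numpy())
    improvement = 35.0 + 15.0 * (signal + truth.vta_confound * vta_total_z
                                 + rng.standard_normal(n))
    improvement = np.clip(improvement, -50.0, 100.0)

    baseline = np.clip(rng.normal(45.0, 16.0, n), 10.0, 100.0)
    post = baseline * (1.0 - improvement / 100.0)
    out = pd.DataFrame({"baseline": baseline, "post": post}, index=ids)
    out = pd.concat([out, vta], axis=1)
    out["improvement"] = improvement
    out["efficacy"] = np.where(improvement < 30.0, "poor", "good")
    return feat, out
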