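"""Clinical bookkeeping: subtype classification, severity subgrouping,
improvement rates and efficacy dichotomization.

Rules follow the tremor-dominant DBS literature: the tremor/PIGD mean-score
ratio classifies subtype (>=1.15 tremor-dominant, <0.9 postural-instability,
between: intermediate); postoperative improvement below 30% counts as poor
efficacy.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import pandas as pd

__all__ = [
    "classify_subtype",
    "assign_subgroups",
    "improvement_rate",
    "dichotomize_efficacy",
]

TD_RATIO = 1.15
PIGD_RATIO = 0.9
EFFICACY_CUT = 30.0  # percent improvement


def classify_subtype(tremor_mean: float, pigd_mean: float) -> str:
    """Tremor/PIGD ratio rule: ``TD`` | ``PIGD`` | ``intermediate``.

    A zero PIGD mean with positive tremor is TD by convention (infinite
    ratio); both zero is unclassifiable.
    """
    if tremor_mean < 0 or pigd_mean < 0:
        raise ValueError("sub-score means must be non-negative")
    if pigd_mean == 0:
        if tremor_mean > 0:
            return "TD"
        raise ValueError("both sub-score means zero: unclassifiable")
    ratio = tremor_mean / pigd_mean
    if ratio >= TD_RATIO:
        return "TD"
    if ratio < PIGD_RATIO:
        return "PIGD"
    return "intermediate"


def assign_subgroups(records: pd.DataFrame, score: str = "updrs3_on",
                     hy: str = "hy") -> pd.DataFrame:
    """Severity subgroups by Hoehn–Yahr stage and motor-score tertile.

    H&Y in [1, 2.5] -> HY_I, (2.5, 4] -> HY_II (2.5 sits in both printed
    ranges; we close the lower one).  Motor score <= 38 -> T1, [40, 51] -> T2,
    > 51 -> T3; the printed tertiles leave (38, 40) unassigned — such scores
    fall to T1 with a warning.  H&Y above 4 is left unassigned with a warning.
    """
    out = []
    for _, r in records.iterrows():
        h, s = r[hy], r[score]
        if pd.isna(h) or pd.isna(s):
            raise ValueError(f"missing H&Y or motor score for id {r.get('id', '?')!r}")
        if h > 4:
            warnings.warn(f"H&Y stage {h} above 4 for id {r.get('id', '?')!r}: unassigned")
            hy_grp = "unassigned"
        elif h <= 2.5:
            hy_grp = "HY_I"
        else:
            hy_grp = "HY_II"
        if s <= 38:
            tert = "T1"
        elif s < 40:
            warnings.warn(f"motor score {s} falls in the (38, 40) tertile gap; "
                          "assigned to the lower tertile")
            tert = "T1"
        elif s <= 51:
            tert = "T2"
        else:
            tert = "T3"
        out.append({"id": r["id"], "hy_group": hy_grp, "tertile": tert})
    return pd.DataFrame(out)


def improvement_rate(baseline: float, post: float) -> float:
    """Percent improvement: (baseline - post) / baseline * 100.

    Negative when the score worsened.  Undefined at baseline 0.
    """
    if baseline == 0:
        raise ValueError("improvement rate undefined for baseline 0")
    return (baseline - post) / baseline * 100.0


def dichotomize_efficacy(improvement: float) -> str:
    """``poor`` below 30% improvement, ``good`` at or above (strict cut)."""
    if not pd.notna(improvement) or improvement in (float("inf"), float("-inf")):
        raise ValueError("improvement must be finite")
    return "poor" if improvement < EFFICACY_CUT else "good"


def outcome_table(baseline: Mapping[str, float], post: Mapping[str, float]) -> pd.DataFrame:
    """Improvement rate and efficacy per score shared by both maps."""
    rows = []
    for k in baseline:
        if k in post and baseline[k] != 0:
            imp = improvement_rate(baseline[k], post[k])
            rows.append({"score": k, "improvement": imp,
                         "efficacy": dichotomize_efficacy(imp)})
    return pd.DataFrame(rows)
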