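"""Maturity-status classification and group summaries.

Subjects are classified from their estimated age at peak height velocity
(APHV) into early (below the within-sample 16th percentile), average
(between the 16th and 84th) and late (above the 84th) maturers.  Under
normality the percentile rule nearly coincides with a mean +/- 1 SD rule,
which is available behind ``rule="sd"`` for comparison.

Classification uses posterior-mean individual APHV point estimates;
per-draw label uncertainty is an optional diagnostic
(:func:`label_uncertainty`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateDistributionError
from .landmarks import IndividualLandmarks

__all__ = [
    "MaturityClassification",
    "classify",
    "group_summary",
    "timing_tempo_correlations",
    "label_uncertainty",
]

GROUPS = ("early", "average", "late")
LANDMARK_ORDER = ("atgv", "tgv", "aphv", "phv")


@dataclass(frozen=True)
class MaturityClassification:
    """Per-subject maturity labels and the thresholds that produced them."""

    table: pd.DataFrame  # id, aphv, label
    threshold_low: float
    threshold_high: float
    rule: str = "percentile"

    def ids_in(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["label"] == group, "id"])

    def to_frame(self, sex: str = "") -> pd.DataFrame:
        out = self.table.copy()
        out.insert(1, "sex", sex)
        out["threshold_low"] = self.threshold_low
        out["threshold_high"] = self.threshold_high
        return out


def classify(
    individual_aphv: pd.DataFrame,
    percentiles: tuple[float, float] = (16.0, 84.0),
    rule: str = "percentile",
    min_subjects: int = 10,
) -> MaturityClassification:
    """Label subjects early/average/late from within-sample APHV.

    ``individual_aphv`` needs ``id`` and ``aphv`` columns (one sex at a
    time; the study design always classifies within sex).  Thresholds are
    the requested percentiles with linear interpolation between order
    statistics; labels use strict inequalities below/above the thresholds.
    ``rule="sd"`` uses mean -/+ 1 SD thresholds instead.
    """
    frame = individual_aphv[["id", "aphv"]].copy()
    if len(frame) < min_subjects:
        raise ContractError(f"need >= {min_subjects} subjects to classify, got {len(frame)}")
    values = frame["aphv"].to_numpy(dtype=float)
    if np.ptp(values) == 0.0:
        raise DegenerateDistributionError("all APHV estimates are identical")
    if rule == "percentile":
        lo = float(np.percentile(values, percentiles[0]))
        hi = float(np.percentile(values, percentiles[1]))
    elif rule == "sd":
        lo = float(values.mean() - values.std(ddof=1))
        hi = float(values.mean() + values.std(ddof=1))
    else:
        raise ContractError(f"unknown classification rule {rule!r}")
    label = np.where(values < lo, "early", np.where(values > hi, "late", "average"))
    frame["label"] = label
    return MaturityClassification(
        table=frame, threshold_low=lo, threshold_high=hi, rule=rule
    )


def group_summary(
    classification: MaturityClassification, landmarks: IndividualLandmarks
) -> pd.DataFrame:
    """Per-group landmark means with 68% intervals from pooled draws.

    Rows are ordered early/average/late within ATGV, TGV, APHV, PHV.  The
    group mean averages subject point estimates; the interval is the
    16th-84th percentile of the pooled subject-level posterior draws.
    Empty groups yield rows with missing markers.
    """
    ids = set(classification.table["id"])
    if ids != set(landmarks.subject_ids):
        raise ContractError("classification and landmark draws cover different subjects")
    col = {sid: j for j, sid in enumerate(landmarks.subject_ids)}
    rows = []
    for name in LANDMARK_ORDER:
        mat = landmarks.draws[name]
        est = landmarks.estimates.set_index("id")[name]
        for group in GROUPS:
            members = classification.ids_in(group)
            if not members:
                rows.append(
                    {"measure": name, "group": group, "mean": np.nan,
                     "ci68_low": np.nan, "ci68_high": np.nan, "n": 0}
                )
                continue
            pooled = mat[:, [col[m] for m in members]].ravel()
            rows.append(
                {
                    "measure": name,
                    "group": group,
                    "mean": float(est.loc[members].mean()),
                    "ci68_low": float(np.percentile(pooled, 16)),
                    "ci68_high": float(np.percentile(pooled, 84)),
                    "n": len(members),
                }
            )
    out = pd.DataFrame(rows)
    # expected maturity gradient (report flag, not a hard error)
    flags = []
    for name in LANDMARK_ORDER:
        sub = out[out["measure"] == name].set_index("group")["mean"]
        if sub.isna().any():
            continue
        increasing = sub.loc["early"] <= sub.loc["average"] <= sub.loc["late"]
        decreasing = sub.loc["early"] >= sub.loc["average"] >= sub.loc["late"]
        expected = increasing if name in ("atgv", "aphv") else decreasing
        if not expected:
            flags.append(name)
    out.attrs["ordering_flags"] = flags
    return out


def timing_tempo_correlations(
    landmarks: IndividualLandmarks, classification: MaturityClassification | None = None
) -> pd.DataFrame:
    """Pearson correlations of (ATGV, TGV) and (APHV, PHV) point estimates.

    Computed for the full sample and, when a classification is given,
    within each maturity group; strata with fewer than 3 subjects get
    missing markers.
    """
    est = landmarks.estimates
    strata = {"all": list(est["id"])}
    if classification is not None:
        for group in GROUPS:
            strata[group] = classification.ids_in(group)
    rows = []
    for stratum, members in strata.items():
        sub = est[est["id"].isin(members)]
        for a, b in (("atgv", "tgv"), ("aphv", "phv")):
            if len(sub) < 3:
                r = np.nan
            else:
                r = float(np.corrcoef(sub[a], sub[b])[0, 1])
            rows.append({"stratum": stratum, "pair": f"{a}_vs_{b}", "r": r, "n": len(sub)})
    return pd.DataFrame(rows)


def label_uncertainty(
    landmarks: IndividualLandmarks, percentiles: tuple[float, float] = (16.0, 84.0)
) -> pd.DataFrame:
    """Per-draw classification: the share of draws labelling each subject
    early/average/late (diagnostic view of label stability)."""
    mat = landmarks.draws["aphv"]  # (S, n)
    lo = np.percentile(mat, percentiles[0], axis=1, keepdims=True)
    hi = np.percentile(mat, percentiles[1], axis=1, keepdims=True)
    early = (mat < lo).mean(axis=0)
    late = (mat > hi).mean(axis=0)
    return pd.DataFrame(
        {
            "id": landmarks.subject_ids,
            "p_early": early,
            "p_average": 1.0 - early - late,
            "p_late": late,
        }
    )
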