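"""Subfamily band assignment on the E-value axis.

Well-resolved subfamilies occupy separated score clusters under a refined
profile.  A boundary between two adjacent clusters is placed halfway (in
linear E-value space) between the worst member of the better-scoring group
and the best member of the worse-scoring group.  Four bands partition the
axis from best to worst E-value: PriA, subHisA, the transition zone (TZ)
where candidate evolutionary intermediates fall, and HisA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ThresholdError

BANDS = ("PriA", "subHisA", "TZ", "HisA")


@dataclass(frozen=True)
class ThresholdSet:
    """Band boundaries, strictly increasing along the E-value axis.

    ``t_pria_subhisa`` separates PriA from subHisA, ``t_subhisa_tz`` the
    subHisA cluster from the transition zone, ``t_tz_hisa`` the transition
    zone from HisA.  ``provenance`` records the boundary statistics used.
    """

    t_pria_subhisa: float
    t_subhisa_tz: float
    t_tz_hisa: float
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        ts = (self.t_pria_subhisa, self.t_subhisa_tz, self.t_tz_hisa)
        if any(t < 0 for t in ts):
            raise ThresholdError("thresholds must be non-negative E-values")
        if not (ts[0] < ts[1] < ts[2]):
            raise ThresholdError(f"thresholds must strictly increase, got {ts}")


@dataclass
class SubfamilyCall:
    """Per-sequence classification with optional residue-level annotation."""

    sequence_id: str
    evalue: float
    band: str
    diagnostic_residue: str | None = None
    npbs_motif: str | None = None
    intermediate_flag: bool = False


def compute_threshold(better_group_max_e: float, worse_group_min_e: float) -> float:
    """Midpoint boundary between two separated E-value groups.

    The worst (largest) E-value of the better-scoring group is subtracted
    from the best (smallest) E-value of the worse-scoring group; half that
    difference is added back to the better group's worst E-value.  The
    arithmetic is in linear E-value space.
    """
    if better_group_max_e < 0 or worse_group_min_e < 0:
        raise ValueError("E-values must be non-negative")
    if better_group_max_e >= worse_group_min_e:
        raise ThresholdError(
            f"groups overlap on the E-value axis "
            f"({better_group_max_e:.4g} >= {worse_group_min_e:.4g}); "
            "manual review required"
        )
    return better_group_max_e + (worse_group_min_e - better_group_max_e) / 2.0


def log10_gap_thresholds(
    better_group_max_e: float, worse_group_min_e: float
) -> tuple[float, float]:
    """Carve a transition zone out of a score gap with no TZ exemplars.

    Returns the (lower, upper) boundaries delimiting the central half of the
    gap between two clusters measured in log10 E-value.  Fallback used only
    when no intermediate-labelled validation sequences exist.
    """
    if not (0 < better_group_max_e < worse_group_min_e):
        raise ThresholdError("need strictly separated positive E-values")
    lo, hi = math.log10(better_group_max_e), math.log10(worse_group_min_e)
    return 10 ** (lo + (hi - lo) / 4.0), 10 ** (lo + 3.0 * (hi - lo) / 4.0)


def thresholds_from_groups(
    pria_evalues,
    subhisa_evalues,
    hisa_evalues,
    tz_evalues=None,
    space: str = "linear",
) -> ThresholdSet:
    """Derive the full band structure from labelled validation groups.

    Each adjacent boundary is the midpoint between the worst member of the
    better group and the best member of the worse group.  When ``tz_evalues``
    (e.g. known intermediates) is given, the TZ boundaries are computed
    against that group; otherwise the subHisA-HisA gap is trisected in log10
    space and its central half becomes the TZ.
    """
    if space not in ("linear", "log10"):
        raise ValueError(f"unknown threshold space {space!r}")

    def mid(a, b):
        if space == "linear":
            return compute_threshold(a, b)
        if not 0 < a < b:
            raise ThresholdError("log-space midpoint needs separated positive E-values")
        return 10 ** ((math.log10(a) + math.log10(b)) / 2.0)

    pria, sub, hisa = map(np.asarray, (pria_evalues, subhisa_evalues, hisa_evalues))
    for name, arr in [("PriA", pria), ("subHisA", sub), ("HisA", hisa)]:
        if arr.size == 0:
            raise ThresholdError(f"empty {name} validation group")
    prov = {
        "max_e_pria": float(pria.max()),
        "min_e_subhisa": float(sub.min()),
        "max_e_subhisa": float(sub.max()),
        "min_e_hisa": float(hisa.min()),
        "space": space,
    }
    t1 = mid(prov["max_e_pria"], prov["min_e_subhisa"])
    if tz_evalues is not None and len(tz_evalues) > 0:
        tz = np.asarray(tz_evalues)
        prov["min_e_tz"] = float(tz.min())
        prov["max_e_tz"] = float(tz.max())
        t2 = mid(prov["max_e_subhisa"], prov["min_e_tz"])
        t3 = mid(prov["max_e_tz"], prov["min_e_hisa"])
    else:
        t2, t3 = log10_gap_thresholds(prov["max_e_subhisa"], prov["min_e_hisa"])
        prov["tz_rule"] = "log10 gap trisection (no TZ exemplars)"
    return ThresholdSet(t1, t2, t3, provenance=prov)


def assign_band(evalue: float, thresholds: ThresholdSet) -> str:
    """Map an E-value to its band; boundary values go to the better band."""
    if evalue < 0:
        raise ValueError("E-values must be non-negative")
    if evalue <= thresholds.t_pria_subhisa:
        return "PriA"
    if evalue <= thresholds.t_subhisa_tz:
        return "subHisA"
    if evalue <= thresholds.t_tz_hisa:
        return "TZ"
    return "HisA"


def classify_scores(scores: pd.DataFrame, thresholds: ThresholdSet) -> list[SubfamilyCall]:
    """Band-assign a score table (columns: id, evalue)."""
    return [
        SubfamilyCall(row["id"], float(row["evalue"]), assign_band(float(row["evalue"]), thresholds))
        for _, row in scores.iterrows()
    ]


def summarize_distribution(calls) -> dict[str, float]:
    """Per-band percentages (to 0.1%) over a set of calls."""
    if not calls:
        raise ValueError("cannot summarize an empty call set")
    total = len(calls)
    return {
        band: round(100.0 * sum(c.band == band for c in calls) / total, 1)
        for band in BANDS
    }


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.sequence_id,
                "evalue": c.evalue,
                "band": c.band,
                "diagnostic_residue": c.diagnostic_residue or "",
                "npbs_motif": c.npbs_motif or "",
                "intermediate_flag": c.intermediate_flag,
            }
            for c in calls
        ]
    )


def thresholds_to_dict(t: ThresholdSet) -> dict:
    return {
        "t_pria_subhisa": t.t_pria_subhisa,
        "t_subhisa_tz": t.t_subhisa_tz,
        "t_tz_hisa": t.t_tz_hisa,
        "provenance": dict(t.provenance),
    }
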