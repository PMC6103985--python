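"""Post-ectopic change statistics and per-patient aggregation.

The core statistic: for each eligible extrasystole and each variable
(SBP, PEP, PP, dP/dt), the difference between the post-ectopic beat's value
and the median of the ten preceding sinus beats — reported on both the
absolute (native-unit) and relative (%) scale.  Per patient, the ten most
recent eligible extrasystoles inside the lookback window contribute, and the
per-variable aggregate is their median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .features import BeatFeatures

__all__ = [
    "VARIABLES",
    "EctopicDeltas",
    "PatientSummary",
    "post_ectopic_delta",
    "aggregate_patient",
    "summaries_to_frame",
]

#: Analysis variables and the BeatFeatures attribute each one reads.
VARIABLES: dict[str, str] = {
    "sbp": "sbp_mmHg",
    "pep": "pep_ms",
    "pp": "pp_mmHg",
    "dpdt": "dpdt_max",
}


@dataclass
class EctopicDeltas:
    """Per-extrasystole absolute and relative post-ectopic changes.

    Variables whose inputs were invalid are absent from the dicts.
    """

    ectopic_time_s: float
    delta_abs: dict[str, float] = field(default_factory=dict)
    delta_rel: dict[str, float] = field(default_factory=dict)


@dataclass
class PatientSummary:
    patient_id: str
    n_eligible: int
    delta_abs: dict[str, float]
    delta_rel: dict[str, float]
    sv_baseline_ml: float
    sv_post_ml: float
    dsv_rel_pct: float
    responder_10: bool
    responder_15: bool
    excluded_vars: set[str] = field(default_factory=set)


def post_ectopic_delta(
    baseline: list[BeatFeatures],
    post: BeatFeatures,
    ectopic_time_s: Optional[float] = None,
) -> EctopicDeltas:
    """Change of each variable from the 10-beat sinus baseline median to the
    post-ectopic beat.

    A variable contributes only when the post-ectopic beat and all ten
    baseline beats are valid for it (no imputation); otherwise it is marked
    missing for this extrasystole.  Relative deltas are undefined for a zero
    baseline median.
    """
    if len(baseline) != 10:
        raise ValueError(f"baseline must contain exactly 10 beats, got {len(baseline)}")
    t = ectopic_time_s if ectopic_time_s is not None else post.r_index / 1000.0
    out = EctopicDeltas(ectopic_time_s=float(t))
    for var, attr in VARIABLES.items():
        vals = [getattr(b, attr) for b in baseline]
        pv = getattr(post, attr)
        if not post.valid or not all(b.valid for b in baseline):
            continue
        if any(not math.isfinite(v) for v in vals) or not math.isfinite(pv):
            continue
        med = float(np.median(vals))
        d = float(pv - med)
        out.delta_abs[var] = d
        if med != 0:
            out.delta_rel[var] = 100.0 * d / med
    return out


def aggregate_patient(
    deltas: list[EctopicDeltas],
    sv,
    patient_id: Optional[str] = None,
    max_es: int = 10,
    window_s: float = 1800.0,
    t_end: Optional[float] = None,
    strict_thresholds: bool = False,
) -> Optional[PatientSummary]:
    """Aggregate a patient's extrasystole deltas and label the SV response.

    Keeps the ``max_es`` most recent extrasystoles whose time lies inside the
    lookback window ending at ``t_end`` (default: time of the last
    extrasystole).  The per-variable aggregate is the median of non-missing
    contributions; a variable with zero contributions is excluded for this
    patient.  Responder flags compare the relative SV change against 10% and
    15% (>= by default; > when ``strict_thresholds``).

    Returns None when no extrasystole is available (method not applicable).
    """
    from .io import sv_response

    if not deltas:
        return None
    deltas = sorted(deltas, key=lambda d: d.ectopic_time_s)
    end = t_end if t_end is not None else deltas[-1].ectopic_time_s
    kept = [d for d in deltas if d.ectopic_time_s >= end - window_s and d.ectopic_time_s <= end]
    kept = kept[-max_es:]
    if not kept:
        return None

    agg_abs: dict[str, float] = {}
    agg_rel: dict[str, float] = {}
    excluded: set[str] = set()
    for var in VARIABLES:
        vals_a = [d.delta_abs[var] for d in kept if var in d.delta_abs]
        vals_r = [d.delta_rel[var] for d in kept if var in d.delta_rel]
        if vals_a:
            agg_abs[var] = float(np.median(vals_a))
        else:
            excluded.add(var)
        if vals_r:
            agg_rel[var] = float(np.median(vals_r))

    dsv = sv_response(sv)
    op = (lambda x, t: x > t) if strict_thresholds else (lambda x, t: x >= t)
    return PatientSummary(
        patient_id=patient_id or sv.patient_id,
        n_eligible=len(kept),
        delta_abs=agg_abs,
        delta_rel=agg_rel,
        sv_baseline_ml=float(np.mean(sv.baseline_values)),
        sv_post_ml=float(np.mean(sv.post_values)),
        dsv_rel_pct=float(dsv),
        responder_10=bool(op(dsv, 10.0)),
        responder_15=bool(op(dsv, 15.0)),
        excluded_vars=excluded,
    )


def summaries_to_frame(summaries: list[PatientSummary]) -> pd.DataFrame:
    """Patient-summary table: the interchange format between the signal tier
    and the cohort statistics (and the cohort-level simulator)."""
    rows = []
    for s in summaries:
        row = {
            "patient_id": s.patient_id,
            "n_eligible": s.n_eligible,
            "sv_baseline_ml": s.sv_baseline_ml,
            "sv_post_ml": s.sv_post_ml,
            "dsv_rel_pct": s.dsv_rel_pct,
            "responder_10": s.responder_10,
            "responder_15": s.responder_15,
        }
        for var in VARIABLES:
            row[f"delta_abs_{var}"] = s.delta_abs.get(var, math.nan)
            row[f"delta_rel_{var}"] = s.delta_rel.get(var, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
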