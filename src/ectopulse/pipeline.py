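"""End-to-end orchestration: resample → detect → classify → delineate →
post-ectopic deltas → per-patient aggregation → cohort statistics.

Every exclusion (artifact beats, ineligible extrasystoles, QC-dropped
variables, patients without extrasystoles) is recorded as one structured log
line so the accounting of the analysis is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import beats as _beats
from . import deltas as _deltas
from . import features as _features
from . import io as _io
from . import stats as _stats

logger = logging.getLogger("ectopulse")

__all__ = ["RunConfig", "PatientResult", "analyze_record", "run_analysis"]


@dataclass
class RunConfig:
    """Analysis settings (YAML round-trippable)."""

    window_s: float = 1800.0          # lookback window before volume expansion
    max_es: int = 10                  # most recent extrasystoles kept
    coupling_ref: str = "median10"    # median10 | last
    prematurity: float = 0.80         # coupling-ratio eligibility bound
    sv_thresholds: tuple = (10.0, 15.0)
    strict_thresholds: bool = False
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if any(t <= 0 for t in self.sv_thresholds):
            raise ValueError("SV thresholds must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "sv_thresholds" in raw:
            raw["sv_thresholds"] = tuple(raw["sv_thresholds"])
        return cls(**raw)


@dataclass
class PatientResult:
    patient_id: str
    beats: list = field(default_factory=list)
    features: list = field(default_factory=list)
    eligibles: list = field(default_factory=list)
    deltas: list = field(default_factory=list)
    summary: Optional[_deltas.PatientSummary] = None
    qc_log: list = field(default_factory=list)

    @property
    def applicable(self) -> bool:
        return self.summary is not None


def _log(result: PatientResult, rule: str, **kv) -> None:
    line = f"EXCLUDE patient={result.patient_id} rule={rule}" + "".join(
        f" {k}={v}" for k, v in kv.items()
    )
    result.qc_log.append(line)
    logger.info(line)


def analyze_record(rec: _io.WaveformRecord, sv: Optional[_io.SvSeries], cfg: RunConfig) -> PatientResult:
    """Run the full signal pipeline on one patient record.

    ``rec`` may be at any supported rate; it is resampled to 1 kHz first.
    When ``sv`` is None the summary is left empty (signal stages only).
    """
    res = PatientResult(patient_id=rec.patient_id)
    rec1k = _io.resample_to_1khz(rec)
    raw = _beats.detect_r_peaks(rec1k)
    res.beats = _beats.classify_beats(raw, prematurity=cfg.prematurity, coupling_ref=cfg.coupling_ref)
    for b in res.beats:
        if b.label == _beats.ARTIFACT:
            _log(res, "artifact-beat", r_index=b.r_index)
    res.features = _features.features_for_record(rec1k, res.beats)
    feat_by_index = {f.r_index: f for f in res.features}

    res.eligibles = _beats.find_eligible_ectopics(
        res.beats, window_s=cfg.window_s, coupling_max=cfg.prematurity
    )
    n_ectopic = sum(1 for b in res.beats if b.label == _beats.ECTOPIC)
    if n_ectopic > len(res.eligibles):
        _log(res, "ineligible-ectopics", n=n_ectopic - len(res.eligibles))

    for el in res.eligibles:
        baseline = [feat_by_index[b.r_index] for b in el.baseline]
        post = feat_by_index[el.post_ectopic.r_index]
        d = _deltas.post_ectopic_delta(baseline, post, ectopic_time_s=el.ectopic.r_time_s)
        missing = [v for v in _deltas.VARIABLES if v not in d.delta_abs]
        if missing:
            _log(res, "invalid-beat-feature", ectopic_t=round(el.ectopic.r_time_s, 3),
                 variables=",".join(missing))
        res.deltas.append(d)

    if sv is None:
        return res
    if not res.deltas:
        _log(res, "no-eligible-extrasystoles", verdict="method not applicable")
        return res
    res.summary = _deltas.aggregate_patient(
        res.deltas, sv, patient_id=rec.patient_id, max_es=cfg.max_es,
        window_s=cfg.window_s, t_end=rec1k.t_start + rec1k.duration_s,
        strict_thresholds=cfg.strict_thresholds,
    )
    if res.summary is not None:
        for var in res.summary.excluded_vars:
            _log(res, "variable-excluded", variable=var)
    else:
        _log(res, "no-eligible-extrasystoles", verdict="method not applicable")
    return res


def run_analysis(records, sv_series: dict, cfg: RunConfig):
    """Analyze a cohort of records against an SV table.

    Returns ``(summaries_df, classification, comparisons, patient_results)``.
    Patients absent from the SV table are excluded (logged); patients without
    eligible extrasystoles get a "method not applicable" verdict.  With fewer
    than 2 patients per response class, classification rows are reported
    missing rather than raising.
    """
    results: list[PatientResult] = []
    for rec in records:
        sv = sv_series.get(rec.patient_id)
        res = analyze_record(rec, sv, cfg)
        if sv is None:
            _log(res, "missing-sv-series")
        results.append(res)
    summaries = [r.summary for r in results if r.summary is not None]
    df = _deltas.summaries_to_frame(summaries)
    if len(df):
        classification, comparisons = _stats.run_classification(
            df, sv_thresholds=cfg.sv_thresholds
        )
    else:
        classification, comparisons = [], []
    return df, classification, comparisons, results
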