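"""Synthetic-data generation, two interchangeable tiers.

Tier (a) — cohort summaries: per-patient aggregated post-ectopic deltas drawn
from responder / non-responder normal distributions, in the patient-summary
schema consumed by :mod:`ectopulse.stats`.  Default group parameters are the
published responder/non-responder means and SDs of the clinical cohort this
package models (SBP −0.1(5.6) vs 5.9(6.6) mmHg, PEP 4.0(5.3) vs 7.5(2.9) ms,
PP 4.0(6.7) vs 10.6(7.0) mmHg, dP/dt 0.08(0.11) vs 0.16(0.08) mmHg/ms;
n = 20 non-responders, 6 responders).

Tier (b) — beat-resolved ECG + ABP waveforms: a sinus schedule with
respiratory RR modulation and Gaussian jitter, isolated premature beats with
(full or partial) compensatory pauses, a logistic Frank–Starling map from
filling time to stroke volume, a single-exponential windkessel diastolic
decay, and a linear preload–PEP link.  All functional forms are package
inventions standing in for physiology; see docs/methods.md.  Output is at
125 Hz so the analysis pipeline's own resampling path is always exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .io import SvSeries, WaveformRecord

__all__ = [
    "GroupParams",
    "CohortSimConfig",
    "StarlingParams",
    "PatientSimConfig",
    "simulate_cohort_summaries",
    "starling_sv",
    "simulate_patient_waveforms",
    "responder_config",
    "nonresponder_config",
    "ground_truth_deltas",
    "aggregate_ground_truth",
    "calibrate_starling_slope",
    "simulate_waveform_cohort",
]


# ---------------------------------------------------------------------------
# Tier (a): cohort-level summaries
# ---------------------------------------------------------------------------

@dataclass
class GroupParams:
    """(mean, SD) per response group for one quantity."""

    mu_nonresp: float
    sd_nonresp: float
    mu_resp: float
    sd_resp: float

    def __post_init__(self):
        if not (self.sd_nonresp > 0 and self.sd_resp > 0):
            raise ValueError("group SDs must be positive")


#: published cohort group parameters: absolute post-ectopic deltas
DELTA_ABS_DEFAULTS = {
    "sbp": GroupParams(-0.1, 5.6, 5.9, 6.6),   # mmHg
    "pep": GroupParams(4.0, 5.3, 7.5, 2.9),    # ms
    "pp": GroupParams(4.0, 6.7, 10.6, 7.0),    # mmHg
    "dpdt": GroupParams(0.08, 0.11, 0.16, 0.08),  # mmHg/ms
}

#: published cohort group parameters: sinus-beat baselines
BASELINE_DEFAULTS = {
    "sbp": GroupParams(116, 21, 125, 35),
    "pep": GroupParams(212, 39, 212, 34),
    "pp": GroupParams(58, 21, 65, 22),
    "dpdt": GroupParams(0.88, 0.47, 0.94, 0.39),
}

_BASELINE_FLOOR = {"sbp": 40.0, "pep": 80.0, "pp": 10.0, "dpdt": 0.05}


@dataclass
class CohortSimConfig:
    n_nonresp: int = 20
    n_resp: int = 6
    delta_abs: dict = field(default_factory=lambda: dict(DELTA_ABS_DEFAULTS))
    baseline: dict = field(default_factory=lambda: dict(BASELINE_DEFAULTS))
    dsv_range_nonresp: tuple = (-8.0, 8.0)   # % SV change, uniform
    dsv_range_resp: tuple = (10.0, 30.0)
    sv_baseline_mean_ml: float = 72.0
    sv_baseline_sd_ml: float = 23.0

    def __post_init__(self):
        if self.n_nonresp < 0 or self.n_resp < 0 or self.n_nonresp + self.n_resp < 1:
            raise ValueError("cohort must contain at least one patient")


def _truncated_normal(rng, mu, sd, lo, size):
    out = rng.normal(mu, sd, size)
    for _ in range(100):
        bad = out <= lo
        if not bad.any():
            break
        out[bad] = rng.normal(mu, sd, bad.sum())
    return np.clip(out, lo, None)


def simulate_cohort_summaries(cfg: CohortSimConfig | None = None, seed=None) -> pd.DataFrame:
    """Draw one synthetic cohort of patient summaries.

    Absolute deltas come from the group normal distributions; baselines from
    truncated group normals; relative deltas are derived as
    ``100 * delta_abs / baseline``; the relative SV change is uniform on the
    group's range.  Reproducible under ``seed`` (int or Generator).
    """
    cfg = cfg or CohortSimConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_nonresp + cfg.n_resp
    resp = np.repeat([False, True], [cfg.n_nonresp, cfg.n_resp])
    data = {
        "patient_id": [f"sim{i + 1:03d}" for i in range(n)],
        "group": np.where(resp, "responder", "non-responder"),
    }
    dsv = np.where(
        resp,
        rng.uniform(*cfg.dsv_range_resp, n),
        rng.uniform(*cfg.dsv_range_nonresp, n),
    )
    sv_base = _truncated_normal(rng, cfg.sv_baseline_mean_ml, cfg.sv_baseline_sd_ml, 15.0, n)
    for var, gp in cfg.delta_abs.items():
        d = np.where(
            resp,
            rng.normal(gp.mu_resp, gp.sd_resp, n),
            rng.normal(gp.mu_nonresp, gp.sd_nonresp, n),
        )
        bp = cfg.baseline[var]
        base = np.where(
            resp,
            _truncated_normal(rng, bp.mu_resp, bp.sd_resp, _BASELINE_FLOOR[var], n),
            _truncated_normal(rng, bp.mu_nonresp, bp.sd_nonresp, _BASELINE_FLOOR[var], n),
        )
        data[f"delta_abs_{var}"] = d
        data[f"delta_rel_{var}"] = 100.0 * d / base
        data[f"baseline_{var}"] = base
    data["n_eligible"] = rng.integers(1, 11, n)
    data["sv_baseline_ml"] = sv_base
    data["sv_post_ml"] = sv_base * (1.0 + dsv / 100.0)
    data["dsv_rel_pct"] = dsv
    data["responder_10"] = dsv >= 10.0
    data["responder_15"] = dsv >= 15.0
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Tier (b): beat-resolved waveforms
# ---------------------------------------------------------------------------

@dataclass
class StarlingParams:
    """Logistic Frank–Starling surrogate: SV = sv_max / (1 + exp(-(x - p50)/k)).

    ``x`` is dimensionless preload (nominal sinus filling = 1).  The operating
    point relative to p50 sets responder status: on the steep limb a preload
    shift raises SV by >= 10%, on the plateau it does not.
    """

    sv_max_ml: float = 110.0
    p50: float = 0.47
    slope_k: float = 0.83


def starling_sv(preload, params: StarlingParams):
    """Stroke volume (ml) at dimensionless preload; monotone nondecreasing."""
    x = np.asarray(preload, dtype=float)
    sv = params.sv_max_ml / (1.0 + np.exp(-(x - params.p50) / params.slope_k))
    return float(sv) if np.isscalar(preload) else sv


@dataclass
class PatientSimConfig:
    patient_id: str = "sim"
    duration_s: float = 1800.0
    hr_bpm: float = 90.0
    rr_sd_ms: float = 20.0
    resp_rate_hz: float = 0.25
    resp_rr_mod_ms: float = 20.0
    p_ectopic: float = 0.02            # per sinus beat, given >= 12-beat sinus run
    coupling_range: tuple = (0.5, 0.8)  # fractions of the local sinus RR
    es_type_mix: float = 0.5            # fraction ventricular (full pause)
    starling: StarlingParams = field(default_factory=StarlingParams)
    residual_bonus: float = 0.3         # preload credit for the ectopic's poor ejection
    compliance_ml_per_mmHg: float = 1.24
    tau_windkessel_s: float = 0.67
    notch_frac: float = 0.10            # dicrotic-notch height as fraction of PP
    p_inf_mmHg: float = 50.0            # windkessel decay asymptote
    dicrotic_amp_mmHg: float = 1.5
    pep0_ms: float = 212.0
    pep_preload_coef_ms: float = -15.0  # negative: higher preload lengthens PEP
    pep_noise_ms: float = 1.5
    ecg_noise: float = 0.01             # SD, fraction of R amplitude 1.0
    abp_noise_mmHg: float = 0.3
    sv_noise_ml: float = 2.0            # per monitor reading
    fluid_bolus_preload_shift: float = 0.3
    fs_out: float = 125.0

    def __post_init__(self):
        rr_nom = 60000.0 / self.hr_bpm
        if rr_nom - 3 * self.rr_sd_ms - self.resp_rr_mod_ms < 300.0:
            raise ValueError("configuration yields RR intervals below 300 ms")
        lo, hi = self.coupling_range
        if not (0.0 < lo <= hi <= 0.8):
            raise ValueError("coupling_range must lie within (0, 0.8]")
        if not (0.0 <= self.p_ectopic < 0.5):
            raise ValueError("p_ectopic must be in [0, 0.5)")

    @property
    def rr_nominal_ms(self) -> float:
        return 60000.0 / self.hr_bpm


def responder_config(**overrides) -> PatientSimConfig:
    """Patient on the steep Frank–Starling limb (fluid responder)."""
    return PatientSimConfig(**overrides)


def nonresponder_config(**overrides) -> PatientSimConfig:
    """Patient on the Frank–Starling plateau (fluid non-responder)."""
    overrides.setdefault("starling", StarlingParams(sv_max_ml=75.0, p50=-0.144, slope_k=0.36))
    return PatientSimConfig(**overrides)


def _beat_schedule(cfg: PatientSimConfig, rng) -> pd.DataFrame:
    """Beat times and labels: sinus rhythm with premature beats and pauses."""
    rr_nom = cfg.rr_nominal_ms
    rows = []  # (time_s, label, is_vent, coupling_frac)
    t = 0.3
    rows.append((t, "sinus", False, np.nan))
    sinus_run = 1
    while True:
        rr = rr_nom + cfg.rr_sd_ms * rng.standard_normal() + cfg.resp_rr_mod_ms * math.sin(
            2 * math.pi * cfg.resp_rate_hz * t
        )
        rr = max(rr, 320.0)
        make_ectopic = (
            sinus_run >= 12
            and rng.random() < cfg.p_ectopic
            and t + 2.2 * rr / 1000.0 < cfg.duration_s
        )
        if make_ectopic:
            c_frac = rng.uniform(*cfg.coupling_range)
            c = c_frac * rr
            is_vent = rng.random() < cfg.es_type_mix
            t_ect = t + c / 1000.0
            rows.append((t_ect, "ectopic", is_vent, c_frac))
            if is_vent:
                t_next = t + 2.0 * rr / 1000.0  # full compensatory pause
            else:
                t_next = t_ect + (1.5 * rr - 0.5 * c) / 1000.0  # partial pause
            rows.append((t_next, "post_ectopic", False, np.nan))
            t = t_next
            sinus_run = 0
        else:
            t_next = t + rr / 1000.0
            if t_next > cfg.duration_s - 0.5:
                break
            rows.append((t_next, "sinus", False, np.nan))
            t = t_next
            sinus_run += 1
    df = pd.DataFrame(rows, columns=["time_s", "label", "is_vent", "coupling_frac"])
    df["rr_prev_ms"] = df["time_s"].diff() * 1000.0
    return df


def _hemodynamics(cfg: PatientSimConfig, beats: pd.DataFrame, rng, preload_shift: float = 0.0) -> pd.DataFrame:
    """Per-beat preload, SV, pressures, and PEP from the beat schedule."""
    n = len(beats)
    rr_nom = cfg.rr_nominal_ms
    sv_ref = starling_sv(1.0 + preload_shift, cfg.starling)
    labels = beats["label"].to_numpy()
    rr = beats["rr_prev_ms"].to_numpy()

    x = np.empty(n)
    sv = np.empty(n)
    for i in range(n):
        xi = 1.0 if i == 0 or not np.isfinite(rr[i]) else rr[i] / rr_nom
        if i > 0 and labels[i - 1] == "ectopic":
            deficit = max(0.0, 1.0 - sv[i - 1] / sv_ref)
            xi += cfg.residual_bonus * deficit
        x[i] = xi + preload_shift
        sv[i] = starling_sv(x[i], cfg.starling)

    pp = sv / cfg.compliance_ml_per_mmHg
    pep = (
        cfg.pep0_ms
        - cfg.pep_preload_coef_ms * (x - 1.0 - preload_shift)
        + cfg.pep_noise_ms * rng.standard_normal(n)
    )
    foot = beats["time_s"].to_numpy() + pep / 1000.0

    # segment geometry and windkessel diastolic decay
    seg = np.empty(n)
    seg[:-1] = np.diff(foot)
    seg[-1] = rr_nom / 1000.0
    t_rise = np.minimum(0.11, 0.30 * seg)
    t_fall = np.minimum(0.19, 0.25 * seg)
    decay = np.maximum(seg - t_rise - t_fall, 0.01)

    dbp = np.empty(n)
    # steady-state diastolic pressure for the nominal beat
    q0 = math.exp(-(rr_nom / 1000.0 - 0.11 - 0.19) / cfg.tau_windkessel_s)
    pp_nom = sv_ref / cfg.compliance_ml_per_mmHg
    dbp[0] = (cfg.p_inf_mmHg * (1 - q0) + q0 * cfg.notch_frac * pp_nom) / (1 - q0)
    for i in range(n - 1):
        p_notch = dbp[i] + cfg.notch_frac * pp[i]
        q = math.exp(-decay[i] / cfg.tau_windkessel_s)
        dbp[i + 1] = cfg.p_inf_mmHg + (p_notch - cfg.p_inf_mmHg) * q

    out = beats.copy()
    out["preload"] = x
    out["sv_ml"] = sv
    out["pp_mmHg"] = pp
    out["dbp_mmHg"] = dbp
    out["sbp_mmHg"] = dbp + pp
    out["pep_ms"] = pep
    out["foot_time_s"] = foot
    out["t_rise_s"] = t_rise
    out["t_fall_s"] = t_fall
    out["dpdt_max"] = (pp * math.pi / 2.0) / (t_rise * 1000.0)  # mmHg/ms, sine-rise slope
    return out


def _render_abp(cfg: PatientSimConfig, hemo: pd.DataFrame, t: np.ndarray) -> np.ndarray:
    abp = np.full_like(t, hemo["dbp_mmHg"].iloc[0])
    tau = cfg.tau_windkessel_s
    n = len(hemo)
    foot = hemo["foot_time_s"].to_numpy()
    for i in range(n):
        t0 = foot[i]
        t1 = foot[i + 1] if i + 1 < n else t[-1] + 1.0 / cfg.fs_out
        lo = int(np.searchsorted(t, t0, side="left"))
        hi = int(np.searchsorted(t, t1, side="left"))
        if hi <= lo:
            continue
        tt = t[lo:hi] - t0
        dbp = hemo["dbp_mmHg"].iat[i]
        pp = hemo["pp_mmHg"].iat[i]
        sbp = dbp + pp
        tr = hemo["t_rise_s"].iat[i]
        tf = hemo["t_fall_s"].iat[i]
        p_notch = dbp + cfg.notch_frac * pp
        segp = np.empty_like(tt)
        rise = tt < tr
        fall = (~rise) & (tt < tr + tf)
        dec = ~(rise | fall)
        segp[rise] = dbp + pp * np.sin(0.5 * math.pi * tt[rise] / tr)
        segp[fall] = p_notch + (sbp - p_notch) * 0.5 * (1 + np.cos(math.pi * (tt[fall] - tr) / tf))
        segp[dec] = cfg.p_inf_mmHg + (p_notch - cfg.p_inf_mmHg) * np.exp(-(tt[dec] - tr - tf) / tau)
        # dicrotic hump, cosmetic
        segp[dec] += cfg.dicrotic_amp_mmHg * np.exp(-((tt[dec] - (tr + tf + 0.06)) ** 2) / (2 * 0.025**2))
        abp[lo:hi] = segp
    return abp


def _render_ecg(cfg: PatientSimConfig, hemo: pd.DataFrame, t: np.ndarray) -> np.ndarray:
    ecg = np.zeros_like(t)
    fs = cfg.fs_out
    for _, b in hemo.iterrows():
        tr = b["time_s"]
        vent = bool(b["is_vent"]) and b["label"] == "ectopic"
        amp, sig = (1.35, 0.022) if vent else (1.0, 0.010)
        lo = max(0, int((tr - 5 * sig) * fs))
        hi = min(len(t), int((tr + 5 * sig) * fs) + 1)
        ecg[lo:hi] += amp * np.exp(-((t[lo:hi] - tr) ** 2) / (2 * sig**2))
        if not vent:  # T wave
            lo = max(0, int((tr + 0.25 - 0.16) * fs))
            hi = min(len(t), int((tr + 0.25 + 0.16) * fs) + 1)
            ecg[lo:hi] += 0.15 * np.exp(-((t[lo:hi] - tr - 0.25) ** 2) / (2 * 0.04**2))
    return ecg


def simulate_patient_waveforms(cfg: PatientSimConfig | None = None, seed=None):
    """Simulate one patient: 125 Hz record, ground truth, and SV series.

    Returns ``(WaveformRecord, ground_truth DataFrame, SvSeries)``.  Ground
    truth carries every beat's time, label, RR, preload, SV, SBP/DBP/PP, PEP
    and foot time.  The SV series contains ten pre-fluid readings around the
    patient's sinus-beat SV and ten post-fluid readings around the SV after
    the configured preload shift, with monitor noise.
    """
    cfg = cfg or PatientSimConfig()
    rng = np.random.default_rng(seed)
    beats = _beat_schedule(cfg, rng)
    hemo = _hemodynamics(cfg, beats, rng)

    n_samp = int(cfg.duration_s * cfg.fs_out) + 1
    t = np.arange(n_samp) / cfg.fs_out
    abp = _render_abp(cfg, hemo, t) + cfg.abp_noise_mmHg * rng.standard_normal(n_samp)
    ecg = _render_ecg(cfg, hemo, t) + cfg.ecg_noise * rng.standard_normal(n_samp)
    rec = WaveformRecord(cfg.patient_id, cfg.fs_out, ecg, abp, 0.0, {"source": "ectopulse-sim"})

    sinus = hemo["label"] == "sinus"
    sv_pre = float(hemo.loc[sinus, "sv_ml"].mean())
    hemo_post = _hemodynamics(cfg, beats, np.random.default_rng(rng.integers(2**31)),
                              preload_shift=cfg.fluid_bolus_preload_shift)
    sv_post = float(hemo_post.loc[sinus, "sv_ml"].mean())
    sv = SvSeries(
        cfg.patient_id,
        np.clip(sv_pre + cfg.sv_noise_ml * rng.standard_normal(10), 1.0, None),
        np.clip(sv_post + cfg.sv_noise_ml * rng.standard_normal(10), 1.0, None),
    )
    return rec, hemo, sv


# ---------------------------------------------------------------------------
# Ground-truth analysis helpers (calibration / parameter recovery)
# ---------------------------------------------------------------------------

_GT_COLS = {"sbp": "sbp_mmHg", "pep": "pep_ms", "pp": "pp_mmHg", "dpdt": "dpdt_max"}


def ground_truth_deltas(hemo: pd.DataFrame) -> pd.DataFrame:
    """Post-ectopic deltas computed directly from simulator ground truth.

    Applies the same rule as the pipeline — post-ectopic value minus the
    median of the ten preceding sinus beats — but on the noiseless per-beat
    truth, for every ectopic with ten clean sinus predecessors.
    """
    labels = hemo["label"].to_numpy()
    rows = []
    for i in np.flatnonzero(labels == "ectopic"):
        if i < 10 or i + 1 >= len(labels):
            continue
        if not (labels[i - 10 : i] == "sinus").all() or labels[i + 1] != "post_ectopic":
            continue
        row = {"ectopic_time_s": hemo["time_s"].iat[i]}
        for var, col in _GT_COLS.items():
            base = float(np.median(hemo[col].iloc[i - 10 : i]))
            row[f"delta_abs_{var}"] = float(hemo[col].iat[i + 1]) - base
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_ground_truth(gt_deltas: pd.DataFrame, max_es: int = 10) -> dict:
    """Median over the <= max_es most recent ground-truth deltas, per variable."""
    kept = gt_deltas.sort_values("ectopic_time_s").tail(max_es)
    return {var: float(kept[f"delta_abs_{var}"].median()) for var in _GT_COLS}


def calibrate_starling_slope(
    cfg: PatientSimConfig,
    target_delta_sbp_mmHg: float = 6.0,
    n_patients: int = 4,
    seed: int = 0,
    tol: float = 0.1,
) -> PatientSimConfig:
    """Tune the Starling slope so the *ground-truth* mean post-ectopic SBP
    change equals the target.

    The Starling midpoint ``p50`` is co-adjusted so the operating stroke
    volume at nominal preload (x = 1) stays fixed; the mean delta is then
    monotone decreasing in ``slope_k`` (a flatter curve converts the
    pause-driven preload surplus into less extra stroke volume), so a
    bisection on log(slope_k) converges.  Only the beat-domain model is
    evaluated — no waveform rendering.
    """
    sv_op = starling_sv(1.0, cfg.starling)
    logit = math.log(sv_op / (cfg.starling.sv_max_ml - sv_op))

    def mean_dsbp(k: float) -> float:
        c = replace(cfg, starling=replace(cfg.starling, slope_k=k, p50=1.0 - k * logit))
        vals = []
        ss = np.random.SeedSequence(seed)
        for child in ss.spawn(n_patients):
            rng = np.random.default_rng(child)
            hemo = _hemodynamics(c, _beat_schedule(c, rng), rng)
            d = ground_truth_deltas(hemo)
            if len(d):
                vals.append(d["delta_abs_sbp"].mean())
        return float(np.mean(vals))

    lo, hi = 0.1, 4.0  # slope_k bracket: steep ... nearly flat
    f_lo, f_hi = mean_dsbp(lo), mean_dsbp(hi)
    if not (f_hi <= target_delta_sbp_mmHg <= f_lo):
        raise ValueError(
            f"target {target_delta_sbp_mmHg} outside attainable range [{f_hi:.2f}, {f_lo:.2f}]"
        )
    for _ in range(40):
        mid = math.sqrt(lo * hi)
        f_mid = mean_dsbp(mid)
        if abs(f_mid - target_delta_sbp_mmHg) < tol:
            lo = hi = mid
            break
        if f_mid > target_delta_sbp_mmHg:
            lo = mid
        else:
            hi = mid
    k = math.sqrt(lo * hi)
    return replace(cfg, starling=replace(cfg.starling, slope_k=k, p50=1.0 - k * logit))


def simulate_waveform_cohort(
    n_resp: int,
    n_nonresp: int,
    seed: int = 0,
    duration_s: float = 1800.0,
    p_ectopic: float = 0.02,
    jitter: bool = True,
):
    """Yield ``(config, seed)`` pairs for a mixed responder/non-responder cohort.

    Per-patient nuisance parameters (heart rate, PEP offset, compliance,
    pump size) are mildly jittered so patients are not clones.
    """
    ss = np.random.SeedSequence(seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    children = np.random.SeedSequence(seed + 1).generate_state(n_resp + n_nonresp) % (2**31)
    out = []
    for i in range(n_resp + n_nonresp):
        is_resp = i < n_resp
        kw = dict(patient_id=f"{'R' if is_resp else 'N'}{i + 1:03d}",
                  duration_s=duration_s, p_ectopic=p_ectopic)
        if jitter:
            kw["hr_bpm"] = float(meta_rng.uniform(75, 100))
            kw["pep0_ms"] = float(meta_rng.uniform(195, 230))
            kw["compliance_ml_per_mmHg"] = float(meta_rng.uniform(1.1, 1.4))
        cfg = responder_config(**kw) if is_resp else nonresponder_config(**kw)
        if jitter:
            cfg = replace(
                cfg,
                starling=replace(cfg.starling, sv_max_ml=cfg.starling.sv_max_ml * meta_rng.uniform(0.9, 1.1)),
            )
        out.append((cfg, int(children[i])))
    return out


def config_to_dict(cfg) -> dict:
    """Config metadata for sidecar files (self-describing simulations)."""
    d = asdict(cfg)
    d["model"] = {
        "starling": "SV = sv_max / (1 + exp(-(preload - p50)/k))",
        "windkessel": "diastolic decay P(t) = P_inf + (P_notch - P_inf) exp(-t/tau)",
        "pep": "PEP = pep0 - coef * (preload - 1) + noise",
        "preload": "previous RR / nominal RR + residual bonus after ectopic ejection",
    }
    return d
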