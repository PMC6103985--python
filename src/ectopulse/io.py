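"""Waveform and stroke-volume table I/O, validation, and resampling.

Records hold paired ECG and invasive arterial blood pressure (ABP) channels
sampled on a uniform grid.  Bedside exports are nominally 125 Hz; the analysis
pipeline runs at 1000 Hz, so :func:`resample_to_1khz` interpolates both
channels onto a 1 ms grid with a cubic spline before any beat detection.

File format (delimited text, UTF-8):

    # patient_id=P01 fs=125 t_start=0.0
    time,ecg,abp
    0.000,0.012,78.25
    ...

Metadata lines start with ``#`` and carry ``key=value`` pairs.  The ``time``
column is optional when ``fs`` is declared; when present it must be uniform.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "WaveformRecord",
    "SvSeries",
    "WaveformFormatError",
    "read_waveform",
    "write_waveform",
    "resample_to_1khz",
    "read_sv_table",
    "write_sv_table",
    "sv_response",
]


class WaveformFormatError(ValueError):
    """Raised when a waveform or SV file violates the declared format."""


@dataclass
class WaveformRecord:
    """Two-channel (ECG, ABP) uniformly sampled waveform for one patient.

    Parameters
    ----------
    patient_id : str
        Free-text patient identifier.
    fs : float
        Sampling rate in Hz, > 0.
    ecg : ndarray
        ECG samples (millivolt scale; the unit is not interpreted).
    abp : ndarray
        Arterial pressure samples in mmHg.
    t_start : float
        Time of sample 0 in seconds (sample index 0 corresponds to t_start).
    """

    patient_id: str
    fs: float
    ecg: np.ndarray
    abp: np.ndarray
    t_start: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if self.ecg.ndim != 1 or self.abp.ndim != 1:
            raise WaveformFormatError("channels must be 1-D sample vectors")
        if len(self.ecg) != len(self.abp):
            raise WaveformFormatError(
                f"channel length mismatch: ecg={len(self.ecg)} abp={len(self.abp)}"
            )
        if len(self.ecg) < 1:
            raise WaveformFormatError("record must contain at least one sample")
        if not self.fs > 0:
            raise WaveformFormatError(f"sampling rate must be positive, got {self.fs}")
        if not (np.isfinite(self.ecg).all() and np.isfinite(self.abp).all()):
            raise WaveformFormatError("record contains missing/non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        """Span between first and last sample: (n − 1) / fs seconds."""
        return (self.n_samples - 1) / self.fs

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.fs


@dataclass
class SvSeries:
    """Stroke-volume readings (ml) around a fluid bolus.

    ``baseline_values`` are the readings in the 5-min window before the
    infusion; ``post_values`` the 5-min window immediately after.  The
    reference protocol averages ten consecutive readings per window; any
    count >= 1 is accepted and a QC note is attached when it differs.
    """

    patient_id: str
    baseline_values: np.ndarray
    post_values: np.ndarray
    qc_notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.baseline_values = np.asarray(self.baseline_values, dtype=float)
        self.post_values = np.asarray(self.post_values, dtype=float)
        for name, vals in (("baseline", self.baseline_values), ("post", self.post_values)):
            if vals.size < 1:
                raise ValueError(f"{name} SV window for {self.patient_id} is empty")
            if not (vals > 0).all():
                raise ValueError(f"{name} SV window for {self.patient_id} has non-positive values")
        for name, vals in (("baseline", self.baseline_values), ("post", self.post_values)):
            if vals.size != 10:
                self.qc_notes.append(f"{name} window has {vals.size} readings (expected 10)")


def sv_response(sv: SvSeries) -> float:
    """Relative stroke-volume change (%) of the post window vs baseline.

    Returns ``100 * (mean(post) - mean(baseline)) / mean(baseline)``.
    """
    base = float(np.mean(sv.baseline_values))
    post = float(np.mean(sv.post_values))
    return 100.0 * (post - base) / base


# ---------------------------------------------------------------------------
# Delimited-text waveform reader/writer
# ---------------------------------------------------------------------------

def _parse_meta(line: str, meta: dict) -> None:
    for tok in line.lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k.strip()] = v.strip()


def read_waveform(path, format: str = "delimited-text") -> WaveformRecord:
    """Read a two-channel waveform file into a validated :class:`WaveformRecord`.

    Channel order in the returned record is always (ecg, abp) regardless of
    column order in the file.  Errors name the offending line (1-based).
    """
    if format != "delimited-text":
        raise ValueError(f"unsupported waveform format: {format!r}")
    meta: dict = {}
    header = None
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                _parse_meta(line, meta)
                continue
            if header is None:
                header = [c.strip().lower() for c in line.split(",")]
                for required in ("ecg", "abp"):
                    if required not in header:
                        raise WaveformFormatError(
                            f"{path}: line {lineno}: missing required column {required!r}"
                        )
                continue
            parts = line.split(",")
            if len(parts) != len(header):
                raise WaveformFormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise WaveformFormatError(
                    f"{path}: line {lineno}: non-numeric sample {line!r}"
                ) from None
    if header is None or not rows:
        raise WaveformFormatError(f"{path}: no samples found")
    data = np.asarray(rows, dtype=float)
    cols = {name: data[:, i] for i, name in enumerate(header)}

    t_start = float(meta.get("t_start", 0.0))
    fs = float(meta["fs"]) if "fs" in meta else None
    if "time" in cols:
        t = cols["time"]
        if len(t) >= 2:
            dt = np.diff(t)
            if dt.min() <= 0 or (abs(dt - dt.mean()) > 1e-6 + 1e-6 * dt.mean()).any():
                bad = int(np.argmax(abs(dt - dt.mean()))) + 2  # data row index
                raise WaveformFormatError(
                    f"{path}: non-uniform time column near data row {bad}"
                )
            fs_time = 1.0 / dt.mean()
            if fs is None:
                fs = fs_time
            elif abs(fs_time - fs) > 1e-3 * fs:
                raise WaveformFormatError(
                    f"{path}: time column implies fs={fs_time:.6g} but header declares fs={fs:.6g}"
                )
        t_start = float(t[0])
    if fs is None:
        raise WaveformFormatError(f"{path}: sampling rate undeclared (no fs= and no time column)")
    return WaveformRecord(
        patient_id=str(meta.get("patient_id", "unknown")),
        fs=fs,
        ecg=cols["ecg"],
        abp=cols["abp"],
        t_start=t_start,
        meta=meta,
    )


def write_waveform(rec: WaveformRecord, path, precision: int = 6) -> None:
    """Write a record in the delimited-text format read by :func:`read_waveform`."""
    fmt = f"%.{precision}f"
    buf = _io.StringIO()
    extra = " ".join(
        f"{k}={v}" for k, v in rec.meta.items() if k not in ("patient_id", "fs", "t_start")
    )
    buf.write(f"# patient_id={rec.patient_id} fs={rec.fs:g} t_start={rec.t_start:g}")
    if extra:
        buf.write(" " + extra)
    buf.write("\necg,abp\n")
    for e, a in zip(rec.ecg, rec.abp):
        buf.write(fmt % e + "," + fmt % a + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_1khz(rec: WaveformRecord) -> WaveformRecord:
    """Interpolate both channels onto a 1 kHz grid with a cubic spline.

    The output grid runs 0 ... (n-1)/fs seconds inclusive in 1 ms steps and
    reproduces input samples exactly at coincident grid points.  The spline is
    evaluated only inside the input support (no extrapolation).  A record
    already at 1000 Hz is returned as an identical copy.
    """
    if rec.fs > 1000:
        raise ValueError(f"downsampling unsupported: fs={rec.fs} > 1000 Hz")
    if rec.fs == 1000:
        return WaveformRecord(
            rec.patient_id, 1000.0, rec.ecg.copy(), rec.abp.copy(), rec.t_start, dict(rec.meta)
        )
    if rec.n_samples < 2:
        raise ValueError("resampling requires at least 2 samples")
    t_in = np.arange(rec.n_samples) / rec.fs
    n_out = int(np.floor(t_in[-1] * 1000.0 + 1e-9)) + 1
    t_out = np.arange(n_out) / 1000.0
    ecg = CubicSpline(t_in, rec.ecg)(t_out)
    abp = CubicSpline(t_in, rec.abp)(t_out)
    meta = dict(rec.meta)
    meta["resampled_from_hz"] = f"{rec.fs:g}"
    meta["interpolation"] = "cubic-spline"
    return WaveformRecord(rec.patient_id, 1000.0, ecg, abp, rec.t_start, meta)


# ---------------------------------------------------------------------------
# SV tables
# ---------------------------------------------------------------------------

def read_sv_table(path) -> dict[str, SvSeries]:
    """Read a ``patient_id,window,sv_ml`` table into per-patient :class:`SvSeries`.

    ``window`` must be ``baseline`` or ``post``.
    """
    per: dict[str, dict[str, list[float]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1 and parts[:1] == ["patient_id"]:
                continue
            if len(parts) != 3:
                raise WaveformFormatError(f"{path}: line {lineno}: expected 3 fields")
            pid, window, sv = parts
            if window not in ("baseline", "post"):
                raise WaveformFormatError(
                    f"{path}: line {lineno}: window must be baseline|post, got {window!r}"
                )
            try:
                val = float(sv)
            except ValueError:
                raise WaveformFormatError(
                    f"{path}: line {lineno}: non-numeric sv_ml {sv!r}"
                ) from None
            per.setdefault(pid, {"baseline": [], "post": []})[window].append(val)
    out = {}
    for pid, d in per.items():
        out[pid] = SvSeries(pid, np.asarray(d["baseline"]), np.asarray(d["post"]))
    return out


def write_sv_table(series: dict[str, SvSeries] | list[SvSeries], path) -> None:
    if isinstance(series, dict):
        series = list(series.values())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id,window,sv_ml\n")
        for sv in series:
            for v in sv.baseline_values:
                fh.write(f"{sv.patient_id},baseline,{v:.4f}\n")
            for v in sv.post_values:
                fh.write(f"{sv.patient_id},post,{v:.4f}\n")
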