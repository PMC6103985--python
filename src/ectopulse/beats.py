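"""R-peak detection, beat classification, and extrasystole eligibility.

A beat is *ectopic* (an extrasystole) when it arrives prematurely: its RR
interval is at most 80% of the reference sinus RR.  The beat that follows an
ectopic is the *post-ectopic* beat; after the compensatory pause it contracts
under increased preload and is the unit of analysis downstream.

Eligibility for analysis requires an ectopic to be preceded by ten clean
sinus beats (the baseline window), to have a coupling ratio <= 0.80, and to
be followed by a post-ectopic beat.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
from scipy import signal as _sig

__all__ = [
    "SINUS",
    "ECTOPIC",
    "POST_ECTOPIC",
    "ARTIFACT",
    "BeatAnnotation",
    "EligibleEctopic",
    "DetectorParams",
    "detect_r_peaks",
    "classify_beats",
    "find_eligible_ectopics",
    "annotations_from_rr",
    "write_annotations",
    "read_annotations",
]

SINUS = "sinus"
ECTOPIC = "ectopic"
POST_ECTOPIC = "post_ectopic"
ARTIFACT = "artifact"

#: RR intervals at or below this bound are physiologically impossible beats
#: and are flagged as artifacts (ventricular refractory period).
REFRACTORY_MS = 150.0


@dataclass
class BeatAnnotation:
    """One detected R-peak.

    ``r_index`` is a 0-based sample index on the 1 kHz grid; ``rr_prev_ms`` is
    the interval to the previous detected beat (None for the first beat).
    ``coupling_ratio`` is filled by :func:`classify_beats` for ectopic beats.
    """

    r_index: int
    r_time_s: float
    label: Optional[str] = None
    rr_prev_ms: Optional[float] = None
    coupling_ratio: Optional[float] = None


@dataclass
class EligibleEctopic:
    """An extrasystole passing all eligibility rules."""

    ectopic: BeatAnnotation
    post_ectopic: BeatAnnotation
    baseline: list[BeatAnnotation]  # exactly 10 sinus beats, time-ordered
    coupling_ratio: float
    pause_ratio: float


@dataclass
class DetectorParams:
    """R-peak detector settings (band-pass + energy integration)."""

    band_hz: tuple[float, float] = (5.0, 30.0)
    integration_ms: float = 150.0
    refractory_ms: float = 250.0
    threshold_frac: float = 0.10  # of the 98th percentile of integrated energy
    refine_ms: float = 80.0  # window around energy peak searched for the R max


def detect_r_peaks(rec, params: DetectorParams | None = None) -> list[BeatAnnotation]:
    """Detect R-peaks in the ECG channel of a 1 kHz record.

    Pan–Tompkins-style pipeline: zero-phase band-pass (5–30 Hz), derivative,
    squaring, moving-window integration, fixed-fraction threshold on the
    integrated energy with a refractory period, then refinement of each
    detection to the local ECG maximum.
    """
    if params is None:
        params = DetectorParams()
    if rec.fs != 1000:
        raise ValueError("detector expects a 1 kHz record; run resample_to_1khz first")
    ecg = np.asarray(rec.ecg, dtype=float)
    if len(ecg) < 2000:
        raise ValueError("record shorter than 2 s")
    if np.ptp(ecg) < 1e-9:
        raise ValueError("no QRS energy: flat-line ECG channel")

    sos = _sig.butter(2, params.band_hz, btype="bandpass", fs=1000.0, output="sos")
    filt = _sig.sosfiltfilt(sos, ecg)
    if np.max(np.abs(filt)) < 1e-9:
        raise ValueError("no QRS energy: ECG has no power in the QRS band")
    energy = np.diff(filt, prepend=filt[0]) ** 2
    win = max(3, int(params.integration_ms))
    integ = _sig.convolve(energy, np.ones(win) / win, mode="same")

    thr = params.threshold_frac * np.percentile(integ, 98)
    cand, _ = _sig.find_peaks(integ, height=thr, distance=int(params.refractory_ms))

    # refine each energy peak to the ECG maximum nearby (R waves are upright
    # in this convention; ventricular beats remain dominant-positive)
    half = int(params.refine_ms)
    r_locs: list[int] = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(ecg), c + half + 1)
        r = lo + int(np.argmax(ecg[lo:hi]))
        r_locs.append(r)
    # deduplicate refinements that landed on the same R, enforce refractory
    r_locs = sorted(set(r_locs))
    kept: list[int] = []
    for r in r_locs:
        if kept and (r - kept[-1]) < params.refractory_ms:
            if ecg[r] > ecg[kept[-1]]:
                kept[-1] = r
        else:
            kept.append(r)

    beats: list[BeatAnnotation] = []
    prev = None
    for r in kept:
        rr = None if prev is None else float(r - prev)
        beats.append(BeatAnnotation(r_index=int(r), r_time_s=rec.t_start + r / 1000.0, rr_prev_ms=rr))
        prev = r
    return beats


def annotations_from_rr(rr_ms: Iterable[float], t0_s: float = 0.0) -> list[BeatAnnotation]:
    """Build unlabeled annotations from a sequence of RR intervals (ms).

    The first beat is placed at ``t0_s``; convenient for constructing test
    schedules without waveforms.
    """
    beats = [BeatAnnotation(r_index=int(round(t0_s * 1000)), r_time_s=t0_s)]
    t = t0_s * 1000.0
    for rr in rr_ms:
        t += float(rr)
        beats.append(
            BeatAnnotation(r_index=int(round(t)), r_time_s=t / 1000.0, rr_prev_ms=float(rr))
        )
    return beats


def classify_beats(
    beats: list[BeatAnnotation],
    prematurity: float = 0.80,
    coupling_ref: str = "median10",
    long_rr_factor: float = 1.8,
) -> list[BeatAnnotation]:
    """Label beats as sinus / ectopic / post_ectopic / artifact.

    A beat is ectopic when its RR interval is <= ``prematurity`` times the
    reference sinus RR — by default the median RR of the up-to-10 most recent
    sinus beats (``coupling_ref='median10'``); ``'last'`` uses the single most
    recent sinus RR instead.  The beat immediately following an ectopic is
    post-ectopic (consecutive premature beats are each ectopic).  The first 11
    beats of a record are never labeled ectopic (insufficient sinus context).
    RR intervals at or below the refractory bound, or implausibly long ones
    not explained by a compensatory pause, are artifacts.
    """
    if len(beats) < 12:
        raise ValueError("classification requires at least 12 beats")
    if coupling_ref not in ("median10", "last"):
        raise ValueError(f"coupling_ref must be median10|last, got {coupling_ref!r}")
    out: list[BeatAnnotation] = []
    sinus_rr: list[float] = []  # RR of recent sinus beats, newest last
    tol = 1.0 + 1e-9
    for k, b in enumerate(beats):
        nb = replace(b, label=None, coupling_ratio=None)
        rr = nb.rr_prev_ms
        if rr is None:
            nb.label = SINUS
            out.append(nb)
            continue
        if rr <= REFRACTORY_MS:
            nb.label = ARTIFACT
            out.append(nb)
            continue
        ref = None
        if sinus_rr:
            recent = sinus_rr[-10:]
            ref = float(np.median(recent)) if coupling_ref == "median10" else recent[-1]
        premature = ref is not None and k >= 11 and rr <= prematurity * ref * tol
        prev_label = out[-1].label
        if premature:
            nb.label = ECTOPIC
            nb.coupling_ratio = rr / ref
        elif prev_label == ECTOPIC:
            nb.label = POST_ECTOPIC
        elif ref is not None and rr > long_rr_factor * ref:
            # long gap with no preceding ectopic: likely a missed beat
            nb.label = ARTIFACT
        else:
            nb.label = SINUS
            sinus_rr.append(rr)
        out.append(nb)
    return out


def find_eligible_ectopics(
    beats: list[BeatAnnotation],
    window_s: float = 1800.0,
    coupling_max: float = 0.80,
) -> list[EligibleEctopic]:
    """Return every eligible extrasystole, in time order.

    Eligibility: the beat is labeled ectopic; it lies inside the lookback
    window ending at the last beat; its 10 immediately preceding beats are all
    sinus; the coupling interval is at most ``coupling_max`` of the baseline
    median RR; and the next beat exists and is the post-ectopic beat.  An
    empty result means the method is not applicable to the record.
    """
    if any(b.label is None for b in beats):
        raise ValueError("beats must be labeled; run classify_beats first")
    if not beats:
        return []
    t_end = beats[-1].r_time_s
    out: list[EligibleEctopic] = []
    tol = 1.0 + 1e-9
    for i, b in enumerate(beats):
        if b.label != ECTOPIC:
            continue
        if b.r_time_s < t_end - window_s:
            continue
        if i < 10 or i + 1 >= len(beats):
            continue
        baseline = beats[i - 10 : i]
        if any(x.label != SINUS for x in baseline):
            continue
        if any(x.rr_prev_ms is None for x in baseline):
            continue
        post = beats[i + 1]
        if post.label != POST_ECTOPIC:
            continue
        ref = float(np.median([x.rr_prev_ms for x in baseline]))
        ratio = b.rr_prev_ms / ref
        if ratio > coupling_max * tol:
            continue
        pause = post.rr_prev_ms / ref if post.rr_prev_ms is not None else float("nan")
        out.append(
            EligibleEctopic(
                ectopic=b,
                post_ectopic=post,
                baseline=list(baseline),
                coupling_ratio=float(ratio),
                pause_ratio=float(pause),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Annotation file round-trip
# ---------------------------------------------------------------------------

def write_annotations(beats: list[BeatAnnotation], path, patient_id: str = "unknown") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id,r_index,r_time_s,label,rr_prev_ms,coupling_ratio\n")
        for b in beats:
            rr = "" if b.rr_prev_ms is None else f"{b.rr_prev_ms:.3f}"
            cr = "" if b.coupling_ratio is None else f"{b.coupling_ratio:.6f}"
            fh.write(f"{patient_id},{b.r_index},{b.r_time_s:.6f},{b.label or ''},{rr},{cr}\n")


def read_annotations(path) -> tuple[str, list[BeatAnnotation]]:
    beats: list[BeatAnnotation] = []
    pid = "unknown"
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("patient_id"):
            raise ValueError(f"{path}: unexpected annotation header")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            pid, r_index, r_time, label, rr, cr = line.split(",")
            beats.append(
                BeatAnnotation(
                    r_index=int(r_index),
                    r_time_s=float(r_time),
                    label=label or None,
                    rr_prev_ms=float(rr) if rr else None,
                    coupling_ratio=float(cr) if cr else None,
                )
            )
    return pid, beats
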