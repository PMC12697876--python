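"""Fiber-photometry ΔF/F, peri-event alignment/AUC, and paired-pulse ratio.

ΔF/F uses the isosbestic 410-nm channel as a motion/bleaching control:
the control is regressed onto the 470-nm signal channel (affine least
squares over the whole recording) and the fitted trace serves as F₀,
so ΔF/F = (F470 − fit)/fit. If the control carries no variance the
routine falls back to a percentile baseline of the signal channel and
warns.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .containers import DFFTrace, PairedPulsePair, PhotometryRecording, ValidationError

__all__ = ["compute_dff", "peri_event", "PeriEventMatrix", "auc", "ppr"]

log = logging.getLogger(__name__)


def compute_dff(rec: PhotometryRecording, baseline_percentile: float = 10.0) -> DFFTrace:
    """Isosbestic-corrected ΔF/F for a dual-channel recording."""
    f470, f410 = rec.f470, rec.f410
    if len(f470) < 2:
        raise ValidationError("recording too short for ΔF/F")
    if np.ptp(f410) == 0:
        warnings.warn(
            "isosbestic channel has zero variance; using percentile-baseline ΔF/F",
            RuntimeWarning,
            stacklevel=2,
        )
        f0 = float(np.percentile(f470, baseline_percentile))
        if f0 == 0:
            raise ValidationError("baseline fluorescence is zero; ΔF/F undefined")
        dff = (f470 - f0) / f0
        fit_params = {"method": "percentile", "percentile": baseline_percentile, "f0": f0}
    else:
        slope, intercept = np.polyfit(f410, f470, 1)
        fitted = slope * f410 + intercept
        if (fitted <= 0).any():
            raise ValidationError("fitted control crosses zero; ΔF/F undefined")
        dff = (f470 - fitted) / fitted
        fit_params = {"method": "affine", "slope": float(slope), "intercept": float(intercept)}
    return DFFTrace(
        t_s=rec.t_s,
        dff=dff,
        sample_rate=rec.sample_rate,
        fit_params=fit_params,
        event_times_s=rec.event_times_s,
    )


@dataclass
class PeriEventMatrix:
    """Event-aligned, baseline-subtracted ΔF/F segments (trials x time)."""

    time_s: np.ndarray  # relative to event, length T
    traces: np.ndarray  # n_trials x T
    event_times_s: np.ndarray  # events actually used
    n_dropped: int
    sample_rate: float = 0.0

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]


def peri_event(
    dff: DFFTrace,
    window_pre_s: float,
    window_post_s: float,
    event_times_s: Optional[np.ndarray] = None,
) -> PeriEventMatrix:
    """Align ΔF/F segments to events and subtract the pre-window mean.

    Events whose window extends beyond the recording are dropped and
    logged. The per-trial baseline is the mean over [−pre, 0), so a
    constant trace aligns to exactly zero.
    """
    if window_pre_s <= 0 or window_post_s <= 0:
        raise ValidationError("peri-event windows must be positive")
    events = np.asarray(
        dff.event_times_s if event_times_s is None else event_times_s, float
    )
    if events.size == 0:
        raise ValidationError("no events to align to")
    sr = dff.sample_rate
    n_pre = int(round(window_pre_s * sr))
    n_post = int(round(window_post_s * sr))
    t0 = dff.t_s[0]
    n = len(dff.dff)
    rows, used = [], []
    dropped = 0
    for ev in np.sort(events):
        center = int(round((ev - t0) * sr))
        lo, hi = center - n_pre, center + n_post + 1
        if lo < 0 or hi > n:
            dropped += 1
            continue
        seg = dff.dff[lo:hi].copy()
        seg -= seg[:n_pre].mean()
        rows.append(seg)
        used.append(ev)
    if dropped:
        log.info("peri_event: dropped %d events with out-of-range windows", dropped)
    if not rows:
        raise ValidationError("no usable events: every window fell outside the recording")
    rel_t = (np.arange(-n_pre, n_post + 1)) / sr
    return PeriEventMatrix(
        time_s=rel_t,
        traces=np.vstack(rows),
        event_times_s=np.asarray(used),
        n_dropped=dropped,
        sample_rate=sr,
    )


def auc(
    peri: PeriEventMatrix, window_s: Optional[tuple[float, float]] = None
) -> np.ndarray:
    """Per-trial trapezoidal area under the aligned ΔF/F curve.

    ``window_s`` is (start, end) relative to the event; default spans
    event onset to the end of the post window. Units: ΔF/F · s.
    """
    if window_s is None:
        window_s = (0.0, float(peri.time_s[-1]))
    lo, hi = window_s
    if hi <= lo:
        raise ValidationError("AUC window must have positive length")
    if lo < peri.time_s[0] - 1e-9 or hi > peri.time_s[-1] + 1e-9:
        raise ValidationError("AUC window outside the peri-event range")
    mask = (peri.time_s >= lo - 1e-12) & (peri.time_s <= hi + 1e-12)
    if mask.sum() < 2:
        raise ValidationError("AUC window contains fewer than 2 samples")
    t = peri.time_s[mask]
    return np.trapezoid(peri.traces[:, mask], t, axis=1)


def ppr(pair: Union[PairedPulsePair, tuple[float, float]]) -> float:
    """Paired-pulse ratio: second peak magnitude over first peak magnitude.

    Peaks are amplitude magnitudes of evoked inward currents (sign is
    handled upstream at extraction). PPR > 1 indicates facilitation,
    < 1 depression.
    """
    if not isinstance(pair, PairedPulsePair):
        pair = PairedPulsePair(peak1=float(pair[0]), peak2=float(pair[1]))
    return pair.peak2 / pair.peak1
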