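"""EEG post-processing: clipping removal, smoothing/tapering, resampling to
200 Hz, zero-phase equiripple band-pass filtering, and spline reconstruction
of brief NREMS outliers.

The pipeline order is fixed: clipping detection -> 3-point moving average +
Fermi taper -> resample to 200 Hz -> 0.5-30 Hz zero-phase FIR band-pass ->
IQR-based outlier reconstruction within scored NREMS. ``preprocess``
runs all steps and records each one, with parameters, in the output's
provenance list.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from fractions import Fraction

from .core import (AlignmentError, ArtifactEvent, ArtifactMask, CleanRecording,
                   Hypnogram, ParameterError, RawRecording, sample_to_epoch_mask)

__all__ = [
    "FilterDesign", "detect_clipping", "smooth_and_taper", "resample_to_200hz",
    "bandpass_zero_phase", "reconstruct_nrem_outliers", "preprocess",
]


@dataclass(frozen=True)
class FilterDesign:
    """Equiripple FIR design parameters for the 0.5-30 Hz band-pass.

    The pass band is bounded by ``hp_trans`` (stop edge, pass edge) on the
    low side and ``lp_trans`` (pass edge, stop edge) on the high side.
    ``atten_db`` is the stop-band attenuation target of each single pass;
    both filters are applied forward and backward, so the effective
    attenuation of the cascade is twice this.
    """

    hp_trans: tuple = (0.25, 0.5)
    lp_trans: tuple = (30.0, 33.0)
    atten_db: float = 40.0
    pass_ripple_db: float = 0.5


def _runs(mask: np.ndarray):
    """Maximal runs of True in a boolean array, as (start, end) pairs."""
    m = np.asarray(mask, bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, m.size]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_clipping(rec: RawRecording, threshold_frac: float = 0.999,
                    min_run: int = 2, epoch_len_s: float = 4.0) -> ArtifactMask:
    """Flag digitizer-saturation (clipping) events.

    A clipping event is a maximal run of at least ``min_run`` consecutive
    samples with ``|x| >= threshold_frac * input_range``. Epochs containing
    any flagged sample are marked artifactual.
    """
    if not 0 < threshold_frac <= 1:
        raise ParameterError("threshold_frac must be in (0, 1]")
    if min_run < 1:
        raise ParameterError("min_run must be >= 1")
    if rec.n_samples == 0:
        raise ParameterError("empty signal")
    thr = threshold_frac * rec.rail_uv
    over = np.abs(rec.samples) >= thr
    sample_mask = np.zeros(rec.n_samples, dtype=bool)
    events = []
    for a, b in _runs(over):
        if b - a >= min_run:
            sample_mask[a:b] = True
            events.append(ArtifactEvent(a, b, "clipping"))
    n_epochs = int(np.ceil(rec.duration_s / epoch_len_s))
    epoch_mask = sample_to_epoch_mask(sample_mask, rec.fs, n_epochs, epoch_len_s)
    return ArtifactMask(sample_mask, epoch_mask, events)


def _fermi_taper(n: int, edge_frac: float) -> np.ndarray:
    """Fermi-Dirac-shaped taper for a segment of ``n`` samples.

    Value ~1 in the interior with a smooth roll-off at both edges; the taper
    equals 0.5 exactly at the segment boundary (distance 0), the Fermi
    function's half-occupation point. ``edge_frac`` sets the roll-off width
    as a fraction of the segment length; 0 disables tapering.
    """
    if edge_frac <= 0 or n == 0:
        return np.ones(n)
    kT = max(edge_frac * n / 4.0, 0.5)  # roll-off essentially complete by 4 kT
    d = np.arange(n, dtype=float)
    left = 1.0 / (1.0 + np.exp(-d / kT))
    right = 1.0 / (1.0 + np.exp(-(n - 1 - d) / kT))
    return left * right


def smooth_and_taper(rec: RawRecording, mask: ArtifactMask | None = None,
                     fermi_edge_frac: float = 0.01) -> RawRecording:
    """3-point moving average followed by a per-segment Fermi taper.

    Artifact samples (from ``mask``) are zeroed and each contiguous
    non-artifact segment is tapered at its edges, so excised stretches do
    not introduce step discontinuities into the later FIR filtering.
    Endpoints of the moving average use a shrinking window (mean of the two
    available samples) rather than zero-padding.
    """
    x = rec.samples
    if x.size < 3:
        raise ParameterError("signal too short for a 3-point moving average")
    sm = np.convolve(x, np.ones(3) / 3.0, mode="same")
    sm[0] = (x[0] + x[1]) / 2.0
    sm[-1] = (x[-2] + x[-1]) / 2.0
    if mask is not None and mask.sample_mask.any():
        good = ~mask.sample_mask
        out = np.zeros_like(sm)
        for a, b in _runs(good):
            out[a:b] = sm[a:b] * _fermi_taper(b - a, fermi_edge_frac)
    else:
        out = sm * _fermi_taper(sm.size, fermi_edge_frac)
    return rec.replace(samples=out)


def resample_to_200hz(rec: RawRecording) -> RawRecording:
    """Polyphase-resample the recording to exactly 200 Hz.

    The native rate must lie in [150, 250] Hz (the acquisition hardware is
    nominally ~200 Hz); the rational resampling ratio is recovered from the
    stated rate, which preserves band content below 30 Hz essentially
    exactly.
    """
    if not 150.0 <= rec.fs <= 250.0:
        raise ParameterError(f"native rate {rec.fs} Hz outside [150, 250]")
    if rec.fs == 200.0:
        return rec.replace(samples=rec.samples.copy())
    ratio = Fraction(200.0 / rec.fs).limit_denominator(10000)
    y = signal.resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    return rec.replace(samples=y, fs=200.0)


@lru_cache(maxsize=8)
def _design_fir(kind: str, f1: float, f2: float, fs: float,
                atten_db: float, pass_ripple_db: float) -> np.ndarray:
    """Parks-McClellan equiripple FIR (high- or low-pass), cached."""
    df = f2 - f1
    numtaps = int(np.ceil(atten_db * fs / (22.0 * df)))
    numtaps += 1 - numtaps % 2  # odd length -> symmetric, integer group delay
    delta_stop = 10 ** (-atten_db / 20.0)
    r = 10 ** (pass_ripple_db / 20.0)
    delta_pass = (r - 1) / (r + 1)
    if kind == "highpass":
        bands, desired = [0, f1, f2, fs / 2], [0, 1]
        weight = [1.0 / delta_stop, 1.0 / delta_pass]
    else:
        bands, desired = [0, f1, f2, fs / 2], [1, 0]
        weight = [1.0 / delta_pass, 1.0 / delta_stop]
    try:
        return signal.remez(numtaps, bands, desired, weight=weight, fs=fs)
    except Exception as exc:  # pragma: no cover - design failure surface
        raise ParameterError(f"unmeetable FIR design spec: {exc}") from exc


def _zero_phase_fir(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Apply FIR ``h`` forward and backward (zero net phase).

    Uses FFT overlap-add convolution (the kernels here run to thousands of
    taps, where lfilter-based filtfilt is impractical) with odd-reflection
    edge padding as in filtfilt.
    """
    n = x.size
    pad = min(3 * h.size, n - 1)
    left = 2 * x[0] - x[pad:0:-1]
    right = 2 * x[-1] - x[-2:-pad - 2:-1]
    xp = np.concatenate([left, x, right])
    y = signal.oaconvolve(xp, h, mode="same")
    y = signal.oaconvolve(y[::-1], h, mode="same")[::-1]
    return y[pad:pad + n]


def bandpass_zero_phase(rec: RawRecording, low_hz: float = 0.5, high_hz: float = 30.0,
                        design: FilterDesign | None = None) -> CleanRecording:
    """Band-pass between ``low_hz`` and ``high_hz`` with zero-phase equiripple FIRs.

    A high-pass at ``low_hz`` and a low-pass at ``high_hz`` are each applied
    in both directions, so the cascade has exactly zero phase (a pass-band
    sinusoid's input/output cross-correlation peaks at lag 0).
    """
    design = design or FilterDesign()
    if not 0 < low_hz < high_hz < rec.fs / 2:
        raise ParameterError("require 0 < low < high < fs/2")
    hp = _design_fir("highpass", design.hp_trans[0], design.hp_trans[1], rec.fs,
                     design.atten_db, design.pass_ripple_db)
    lp = _design_fir("lowpass", design.lp_trans[0], design.lp_trans[1], rec.fs,
                     design.atten_db, design.pass_ripple_db)
    y = _zero_phase_fir(rec.samples, hp)
    y = _zero_phase_fir(y, lp)
    out = CleanRecording(y, fs=rec.fs, input_range_mv=rec.input_range_mv,
                         zt0_offset_h=rec.zt0_offset_h, subject_id=rec.subject_id)
    out.log("bandpass_zero_phase", low_hz=low_hz, high_hz=high_hz,
            hp_trans=design.hp_trans, lp_trans=design.lp_trans,
            atten_db=design.atten_db, hp_taps=hp.size, lp_taps=lp.size)
    return out


def reconstruct_nrem_outliers(rec: CleanRecording, hyp: Hypnogram,
                              iqr_mult: float = 8.0, max_run: int = 7,
                              ) -> tuple[CleanRecording, ArtifactMask]:
    """Reconstruct brief extreme excursions within scored NREMS.

    A single interquartile range is computed over all scored-NREMS samples
    of the recording. Runs of fewer than ``max_run`` consecutive samples
    exceeding ``± iqr_mult × IQR`` are replaced by piecewise cubic-spline
    interpolation through flanking non-flagged samples; longer runs are
    flagged as regional artifacts and their epochs excluded instead.
    """
    if iqr_mult <= 0:
        raise ParameterError("iqr_mult must be > 0")
    spe = int(round(rec.fs * hyp.epoch_len_s))  # samples per epoch (800 at 200 Hz)
    if abs(rec.n_samples - hyp.n_epochs * spe) > spe:
        raise AlignmentError(
            f"recording ({rec.n_samples} samples) does not match hypnogram "
            f"({hyp.n_epochs} epochs x {spe})")
    nrem_epochs = np.flatnonzero(hyp.state_mask("NREM"))
    sample_state = np.zeros(rec.n_samples, dtype=bool)
    for e in nrem_epochs:
        sample_state[e * spe:(e + 1) * spe] = True
    x = rec.samples
    nrem_x = x[sample_state]
    if nrem_x.size == 0:
        raise ParameterError("no scored NREMS samples to compute the IQR over")
    q75, q25 = np.percentile(nrem_x, [75, 25])
    iqr = q75 - q25
    thr = iqr_mult * iqr
    flagged = sample_state & (np.abs(x) > thr)
    if flagged.sum() == nrem_x.size:
        raise ParameterError("degenerate input: all NREMS samples exceed threshold")
    y = x.copy()
    sample_mask = np.zeros(rec.n_samples, dtype=bool)
    events = []
    n_ctx = 6  # flanking good samples used per side of the spline
    for a, b in _runs(flagged):
        if b - a < max_run:
            lo = max(a - n_ctx, 0)
            hi = min(b + n_ctx, x.size)
            idx = np.r_[np.arange(lo, a), np.arange(b, hi)]
            idx = idx[~flagged[idx]]
            if idx.size >= 2:
                y[a:b] = CubicSpline(idx, x[idx])(np.arange(a, b))
                events.append(ArtifactEvent(int(a), int(b), "reconstructed"))
                sample_mask[a:b] = True
                continue
        sample_mask[a:b] = True
        events.append(ArtifactEvent(int(a), int(b), "regional"))
    epoch_mask = np.zeros(hyp.n_epochs, dtype=bool)
    for ev in events:
        if ev.kind == "regional":
            e0 = ev.start // spe
            e1 = min((ev.end - 1) // spe, hyp.n_epochs - 1)
            epoch_mask[e0:e1 + 1] = True
    out = CleanRecording(y, fs=rec.fs, input_range_mv=rec.input_range_mv,
                         zt0_offset_h=rec.zt0_offset_h, subject_id=rec.subject_id,
                         provenance=list(rec.provenance))
    out.log("reconstruct_nrem_outliers", iqr_mult=iqr_mult, max_run=max_run,
            iqr=float(iqr), n_reconstructed=len([e for e in events
                                                 if e.kind == "reconstructed"]),
            n_regional=len([e for e in events if e.kind == "regional"]))
    return out, ArtifactMask(sample_mask, epoch_mask, events)


def preprocess(rec: RawRecording, hyp: Hypnogram, *,
               clip_threshold_frac: float = 0.999, clip_min_run: int = 2,
               fermi_edge_frac: float = 0.01, iqr_mult: float = 8.0,
               max_run: int = 7, design: FilterDesign | None = None,
               ) -> tuple[CleanRecording, Hypnogram, ArtifactMask]:
    """Run the full post-processing stack in its fixed order.

    Returns the cleaned 200 Hz recording, the hypnogram with artifactual
    epochs relabelled, and the combined artifact mask (epoch level; event
    lists carry sample indices at the stage each event was found).
    """
    clip = detect_clipping(rec, clip_threshold_frac, clip_min_run, hyp.epoch_len_s)
    sm = smooth_and_taper(rec, clip, fermi_edge_frac)
    rs = resample_to_200hz(sm)
    bp = bandpass_zero_phase(rs, design=design)
    bp.provenance.insert(0, {"step": "detect_clipping",
                             "threshold_frac": clip_threshold_frac,
                             "min_run": clip_min_run, "n_events": clip.n_events})
    bp.provenance.insert(1, {"step": "smooth_and_taper",
                             "fermi_edge_frac": fermi_edge_frac})
    bp.provenance.insert(2, {"step": "resample_to_200hz", "fs_native": rec.fs})
    n_epochs = hyp.n_epochs
    clip_epochs = clip.epoch_mask[:n_epochs]
    hyp1 = hyp.with_artifacts(np.pad(clip_epochs, (0, n_epochs - clip_epochs.size)))
    clean, rmask = reconstruct_nrem_outliers(bp, hyp1, iqr_mult, max_run)
    epoch_mask = hyp1.state_mask("ARTIFACT") | rmask.epoch_mask
    hyp2 = hyp.with_artifacts(epoch_mask)
    events = list(clip.events) + list(rmask.events)
    mask = ArtifactMask(rmask.sample_mask, epoch_mask, events)
    return clean, hyp2, mask
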