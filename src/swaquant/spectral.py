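"""Epoch spectra, band power, hourly aggregation and delta-activity gain.

Each scored 4-s epoch receives a relative power spectrum on a 0.25 Hz grid
from 0.5 to 30 Hz (119 bins), expressed as percent of total 0.5-30 Hz power.
Spectra come from Hamming-windowed 4-s analysis segments advanced by 2 s;
an epoch's spectrum averages the segments whose centers fall inside it.

Delta-activity gain is the treatment-day minus baseline-day NREMS relative
delta power at matched ZT hours, in percentage points (p.p.); its scalar
summary is the mean over the two hours following the second (ZT9) drug
administration.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AlignmentError, CleanRecording, Hypnogram, ParameterError

__all__ = ["EpochSpectra", "DeltaGainSeries", "epoch_spectra", "band_power",
           "hourly_state_band_power", "delta_gain", "nrem_time_metrics",
           "DELTA_BAND"]

#: default delta (slow-wave activity) band, Hz — rodent SWA convention
DELTA_BAND = (0.5, 4.0)

_FREQ_LO, _FREQ_HI, _FREQ_STEP = 0.5, 30.0, 0.25


@dataclass
class EpochSpectra:
    """Relative power spectra for consecutive 4-s epochs.

    ``power`` has one row per epoch and one column per 0.25 Hz bin from
    0.5 to 30 Hz inclusive; every row sums to 100 (percent of total
    0.5-30 Hz power).
    """

    power: np.ndarray            # (n_epochs, 119), percent
    freqs: np.ndarray            # (119,), Hz
    states: np.ndarray           # (n_epochs,), vigilance label per epoch
    epoch_len_s: float = 4.0
    zt0_offset_h: float = 0.0

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    def epoch_zt_hours(self) -> np.ndarray:
        return self.zt0_offset_h + np.arange(self.n_epochs) * self.epoch_len_s / 3600.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.power, columns=[f"{f:.2f}" for f in self.freqs])
        df.insert(0, "state", self.states)
        df.insert(0, "epoch", np.arange(self.n_epochs))
        return df


@dataclass
class DeltaGainSeries:
    """Per-ZT-hour delta power gain (treatment − baseline), in p.p."""

    per_hour: pd.DataFrame  # columns: zt_hour, gain_pp, n_epochs_baseline, n_epochs_treatment
    summary_hours: tuple = (9, 10)
    summary_mode: str = "mean"  # "mean" | "sum"
    subject_id: str = ""

    @property
    def summary(self) -> float:
        """Gain over the post-ZT9 window (mean of the two hourly gains, or sum)."""
        sel = self.per_hour[self.per_hour["zt_hour"].isin(self.summary_hours)]
        if len(sel) < len(self.summary_hours) or sel["gain_pp"].isna().any():
            return float("nan")
        v = sel["gain_pp"].to_numpy()
        return float(v.sum() if self.summary_mode == "sum" else v.mean())


def epoch_spectra(rec: CleanRecording, hyp: Hypnogram) -> EpochSpectra:
    """Per-epoch relative power spectra (percent of total 0.5-30 Hz power).

    Analysis segments are 4 s (800 samples at 200 Hz, 0.25 Hz resolution),
    Hamming-windowed, advanced by 2 s; each scored epoch averages the
    (up to two) segments whose centers fall inside it.
    """
    fs = rec.fs
    win = int(round(hyp.epoch_len_s * fs))        # 800
    step = win // 2                               # 400 (2-s overlap)
    n_epochs = hyp.n_epochs
    if abs(rec.n_samples - n_epochs * win) > win:
        raise AlignmentError("hypnogram not aligned to recording")
    x = rec.samples[:n_epochs * win]
    if x.size < win:
        raise AlignmentError("recording shorter than one epoch")
    freqs_all = np.fft.rfftfreq(win, 1.0 / fs)
    lo = int(round(_FREQ_LO / _FREQ_STEP))        # bin index of 0.5 Hz
    hi = int(round(_FREQ_HI / _FREQ_STEP))        # bin index of 30 Hz
    freqs = freqs_all[lo:hi + 1]
    window = np.hamming(win)
    n_win = (x.size - win) // step + 1
    # chunked sliding-window periodograms to bound memory on 24-h traces
    P = np.empty((n_win, freqs.size))
    chunk = 4096
    sw = np.lib.stride_tricks.sliding_window_view(x, win)[::step]
    for i in range(0, n_win, chunk):
        seg = sw[i:i + chunk] * window
        X = np.fft.rfft(seg, axis=1)
        P[i:i + chunk] = np.abs(X[:, lo:hi + 1]) ** 2
    # epoch e averages segments 2e (aligned) and 2e-1 (straddling the
    # previous epoch); the first epoch has only its aligned segment
    nE = min(n_epochs, (n_win + 1) // 2)
    aligned = P[0::2][:nE]
    prev = np.empty_like(aligned)
    prev[0] = aligned[0]
    prev[1:] = P[1::2][:nE - 1]
    S = (aligned + prev) / 2.0
    tot = S.sum(axis=1, keepdims=True)
    tot[tot == 0] = np.nan
    S = 100.0 * S / tot
    return EpochSpectra(S, freqs, hyp.labels[:nE].copy(),
                        epoch_len_s=hyp.epoch_len_s, zt0_offset_h=hyp.zt0_offset_h)


def _band_slice(freqs: np.ndarray, band: tuple) -> slice:
    lo, hi = band
    if not (_FREQ_LO <= lo < hi <= _FREQ_HI):
        raise ParameterError(f"band {band} outside {_FREQ_LO}-{_FREQ_HI} Hz")
    for edge in (lo, hi):
        if abs(edge / _FREQ_STEP - round(edge / _FREQ_STEP)) > 1e-9:
            raise ParameterError(f"band edge {edge} not on the {_FREQ_STEP} Hz grid")
    i0 = int(np.argmin(np.abs(freqs - lo)))
    i1 = int(np.argmin(np.abs(freqs - hi)))
    return slice(i0, i1 + 1)


def band_power(spectra: EpochSpectra, band: tuple = DELTA_BAND) -> np.ndarray:
    """Per-epoch relative power (percent) summed over ``band`` (edges inclusive)."""
    sl = _band_slice(spectra.freqs, band)
    return spectra.power[:, sl].sum(axis=1)


def hourly_state_band_power(spectra: EpochSpectra, hyp: Hypnogram | None = None,
                            state: str = "NREM", band: tuple = DELTA_BAND,
                            min_epochs: int = 15) -> pd.DataFrame:
    """Mean per-epoch band power per ZT hour for one vigilance state.

    Only non-artifact epochs of the requested state contribute; hours with
    fewer than ``min_epochs`` qualifying epochs get a missing value.
    """
    states = hyp.labels[:spectra.n_epochs] if hyp is not None else spectra.states
    bp = band_power(spectra, band)
    hours = np.floor(spectra.epoch_zt_hours()).astype(int)
    ok = (states == state) & ~np.isnan(bp)
    rows = []
    for h in np.unique(hours):
        sel = ok & (hours == h)
        n = int(sel.sum())
        mean = float(bp[sel].mean()) if n >= min_epochs else float("nan")
        rows.append({"zt_hour": int(h), "state": state, "band_low_hz": band[0],
                     "band_high_hz": band[1], "mean_power_pct": mean, "n_epochs": n})
    return pd.DataFrame(rows)


def delta_gain(treatment: pd.DataFrame, baseline: pd.DataFrame,
               summary_hours: tuple = (9, 10), summary_mode: str = "mean",
               subject_id: str = "") -> DeltaGainSeries:
    """Per-hour delta power difference treatment − baseline, in p.p.

    Hours present in only one day, or with a missing hourly value in either
    day, are missing in the output.
    """
    t = treatment.set_index("zt_hour")["mean_power_pct"]
    b = baseline.set_index("zt_hour")["mean_power_pct"]
    nt = treatment.set_index("zt_hour")["n_epochs"]
    nb = baseline.set_index("zt_hour")["n_epochs"]
    hours = sorted(set(t.index) & set(b.index))
    rows = [{"zt_hour": h, "gain_pp": float(t[h] - b[h]),
             "n_epochs_baseline": int(nb[h]), "n_epochs_treatment": int(nt[h])}
            for h in hours]
    return DeltaGainSeries(pd.DataFrame(rows,
                                        columns=["zt_hour", "gain_pp",
                                                 "n_epochs_baseline",
                                                 "n_epochs_treatment"]),
                           summary_hours=summary_hours, summary_mode=summary_mode,
                           subject_id=subject_id)


def nrem_time_metrics(hyp_baseline: Hypnogram, hyp_treatment: Hypnogram,
                      ) -> tuple[float, float, float]:
    """NREMS time as percent of scored time per day, and their difference.

    Returns ``(baseline_pct, treatment_pct, delta_nrem_pp)`` with the
    difference in percentage points (treatment − baseline).
    """
    if hyp_baseline.n_epochs != hyp_treatment.n_epochs:
        raise AlignmentError("hypnograms cover different durations")
    b = 100.0 * hyp_baseline.fraction("NREM")
    t = 100.0 * hyp_treatment.fraction("NREM")
    return b, t, t - b
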