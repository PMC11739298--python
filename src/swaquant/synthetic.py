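"""Synthetic cohort generator with known ground truth.

Emulates everything the analysis consumes — EEG recordings, hypnograms,
T-maze scores, ELISA tables and plaque masks — with the statistical
structure the real study assumes, so every downstream stage is testable
without animal data.

Sleep architecture is a semi-Markov chain over WAKE/NREM/REM with geometric
dwell times (REM entered only from NREM). EEG epochs are colored noise
shaped to a per-state power spectral density (1/f trend plus a Gaussian
band peak: delta in NREM, theta in REM), synthesized independently per 4-s
epoch in the frequency domain. A treatment-induced delta-activity gain is
injected by scaling delta-band amplitude in NREM epochs after each
administration (ZT1/ZT9 by default) with an exponentially decaying target
gain; the scaling factor comes from a closed-form renormalization so the
*relative* delta power — as measured by the standard post-processing stack,
whose 3-point moving-average transfer function the generator accounts
for — lands on the target. Clipping (digitizer saturation) and brief
high-amplitude transients are injected at configurable rates and logged as
ground truth.

Absolute EEG amplitudes and per-state power levels are conventions (the
field reports only relative power); defaults put NREM relative delta power
near 50% of total 0.5-30 Hz power.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .core import (DesignError, Hypnogram, ParameterError, RawRecording)

__all__ = ["SimParams", "StateSpectrum", "GroundTruth", "CohortBundle",
           "simulate_hypnogram", "synthesize_recording", "simulate_cohort",
           "simulate_plaque_mask", "example_design",
           "TMAZE_BASELINE", "TMAZE_POST", "ELISA_GROUPS", "BURDEN_TARGETS"]


@dataclass(frozen=True)
class StateSpectrum:
    """Target PSD for one vigilance state: S(f) = (f+0.5)^-alpha + peak."""

    alpha: float
    peak_center_hz: float | None = None
    peak_width_hz: float = 1.0
    peak_amp: float = 0.0
    target_sd_uv: float = 40.0

    def psd(self, f: np.ndarray) -> np.ndarray:
        s = np.where(f > 0, (f + 0.5) ** -self.alpha, 0.0)
        if self.peak_center_hz is not None and self.peak_amp > 0:
            s = s + self.peak_amp * np.exp(
                -((f - self.peak_center_hz) ** 2) / (2 * self.peak_width_hz ** 2))
        return np.where(f > 0, s, 0.0)


DEFAULT_STATE_SPECTRA = {
    # NREM: 1/f with a delta bump -> relative delta power ~50% of 0.5-30 Hz
    "NREM": StateSpectrum(alpha=1.0, peak_center_hz=2.0, peak_width_hz=1.0,
                          peak_amp=0.25, target_sd_uv=45.0),
    # REM: theta-dominated
    "REM": StateSpectrum(alpha=0.8, peak_center_hz=7.0, peak_width_hz=1.0,
                         peak_amp=0.3, target_sd_uv=30.0),
    # WAKE: low-amplitude mixed activity
    "WAKE": StateSpectrum(alpha=0.5, target_sd_uv=25.0),
}


@dataclass(frozen=True)
class SimParams:
    """Design constants of the simulated study.

    The acquisition constants mirror the real setup: 4-s scoring epochs, a
    native rate near (but not exactly) 200 Hz, a ±200 mV digitizer range,
    24-h recordings on a ZT axis starting at lights-on, and drug
    administration at ZT1 and ZT9. ``delta_gain_effect_pp`` is the target
    NREMS relative delta power increase (percentage points) immediately
    after each administration, decaying exponentially with time constant
    ``effect_decay_h``.
    """

    epoch_len_s: float = 4.0
    fs_native: float = 198.7
    input_range_mv: float = 200.0
    recording_hours: float = 24.0
    state_dwell_mean_s: dict = field(default_factory=lambda: {
        "WAKE": 120.0, "NREM": 240.0, "REM": 60.0})
    state_spectra: dict = field(default_factory=lambda: dict(DEFAULT_STATE_SPECTRA))
    p_nrem_to_rem: float = 0.3
    p_rem_to_wake: float = 0.6
    treatment_admin_zt: tuple = (1.0, 9.0)
    delta_gain_effect_pp: float = 8.0
    effect_decay_h: float = 2.0
    clipping_rate_per_h: float = 1.0
    spike_rate_per_h: float = 4.0
    spike_amp_iqr_mult: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if abs(3600.0 / self.epoch_len_s - round(3600.0 / self.epoch_len_s)) > 1e-9:
            raise ParameterError("epoch length must divide one hour")
        if any(m <= 0 for m in self.state_dwell_mean_s.values()):
            raise ParameterError("state dwell means must be > 0")
        if not 150.0 <= self.fs_native <= 250.0:
            raise ParameterError("fs_native must lie in [150, 250] Hz")
        if self.effect_decay_h < 0:
            raise ParameterError("effect decay must be >= 0")
        if self.recording_hours < 0:
            raise ParameterError("recording_hours must be >= 0")

    @property
    def epochs_per_hour(self) -> int:
        return int(round(3600.0 / self.epoch_len_s))


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery checks."""

    epoch_true_delta_pct: np.ndarray     # per-epoch target NREMS relative delta (%)
    epoch_gain_pp: np.ndarray            # per-epoch injected gain (p.p.; 0 off-NREM)
    hourly_nrem_delta: pd.DataFrame      # zt_hour, true_delta_pct, n_epochs
    hourly_gain: pd.DataFrame            # zt_hour, true_gain_pp (NREM-epoch mean)
    artifact_events: list = field(default_factory=list)  # (start, end, kind)
    base_delta_pct: float = float("nan")  # state-level NREM relative delta, no effect

    @property
    def n_clipping(self) -> int:
        return sum(1 for e in self.artifact_events if e[2] == "clipping")

    @property
    def n_spikes(self) -> int:
        return sum(1 for e in self.artifact_events if e[2] == "spike")


def simulate_hypnogram(params: SimParams, seed: int | None = None) -> Hypnogram:
    """Semi-Markov vigilance-state sequence with geometric dwell times.

    REM is entered only from NREM; dwell times (in epochs) are geometric
    with the configured per-state means.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_epochs = int(round(params.recording_hours * 3600.0 / params.epoch_len_s))
    if n_epochs == 0:
        return Hypnogram(np.array([], dtype="U8"), params.epoch_len_s)
    mean_ep = {s: max(m / params.epoch_len_s, 1.0)
               for s, m in params.state_dwell_mean_s.items()}
    labels = np.empty(n_epochs, dtype="U8")
    state = "WAKE"
    i = 0
    while i < n_epochs:
        dwell = rng.geometric(1.0 / mean_ep[state])
        labels[i:i + dwell] = state
        i += dwell
        if state == "WAKE":
            state = "NREM"
        elif state == "NREM":
            state = "REM" if rng.random() < params.p_nrem_to_rem else "WAKE"
        else:  # REM
            state = "WAKE" if rng.random() < params.p_rem_to_wake else "NREM"
    return Hypnogram(labels, params.epoch_len_s)


# grid on which target relative delta power is defined (matches the
# estimator: 0.5-30 Hz in 0.25 Hz steps, delta = 0.5-4 Hz inclusive)
_GRID = np.arange(0.5, 30.0 + 1e-9, 0.25)
_DELTA_SEL = _GRID <= 4.0


def _ma3_power_response(f: np.ndarray, fs: float) -> np.ndarray:
    """Power transfer of the pipeline's 3-point moving average."""
    return ((1.0 + 2.0 * np.cos(2.0 * np.pi * f / fs)) / 3.0) ** 2


@lru_cache(maxsize=32)
def _estimator_expectation(spec: StateSpectrum, fs_native: float,
                           ) -> tuple[float, float, float, float]:
    """Expected measured spectrum sums for one state under the standard pipeline.

    Ground truth is referenced to what the default post-processing stack
    *measures*: the state PSD is weighted by the pipeline power transfer
    (3-point moving average at the native rate, then each zero-phase FIR
    applied twice, i.e. |H|^4) and convolved with the spectral kernel of
    the per-epoch estimator (the mix of full- and half-Hamming windows the
    2-s-overlap averaging produces). Delta-band amplitude scaling by k
    multiplies the delta part of the source PSD, so the expected measured
    spectrum is *linear* in k; this returns the delta/total sums of the
    base and delta-only components, (b_d, b_t, a_d, a_t), from which the
    measured delta fraction is r(k) = (b_d + (k-1) a_d) / (b_t + (k-1) a_t).
    """
    from scipy.signal import freqz
    from .preprocessing import FilterDesign, _design_fir

    df = 0.025
    f = np.arange(0.0, 100.0 + df, df)
    s = spec.psd(f)
    design = FilterDesign()
    hp = _design_fir("highpass", design.hp_trans[0], design.hp_trans[1], 200.0,
                     design.atten_db, design.pass_ripple_db)
    lp = _design_fir("lowpass", design.lp_trans[0], design.lp_trans[1], 200.0,
                     design.atten_db, design.pass_ripple_db)
    t = _ma3_power_response(f, fs_native)
    for h in (hp, lp):
        _, resp = freqz(h, worN=f, fs=200.0)
        t = t * np.abs(resp) ** 4  # forward+backward -> power |H|^4
    st = s * t

    # estimator kernel: average of one full 4-s Hamming window and one
    # window straddling two independently generated epochs (two half windows)
    n_win = 800
    pad = int(round(200.0 / df))
    w = np.hamming(n_win)
    k_full = np.abs(np.fft.fft(w, pad)) ** 2
    k_half = np.abs(np.fft.fft(w[:n_win // 2], pad)) ** 2
    kern = np.fft.fftshift(k_full / 2.0 + k_half)
    kf = (np.arange(pad) - pad // 2) * df
    keep = np.abs(kf) <= 5.0  # sidelobes < -43 dB; truncate support
    kern = kern[keep]

    def _smear(y: np.ndarray) -> np.ndarray:
        # even extension handles the negative-frequency fold near DC
        ext = np.concatenate([y[:0:-1], y])
        sm = np.convolve(ext, kern, mode="same")
        return sm[y.size - 1:]

    base = _smear(st)
    delta_part = _smear(np.where((f >= 0.5) & (f <= 4.0), st, 0.0))
    bins = np.clip(np.round(_GRID / df).astype(int), 0, f.size - 1)
    b = base[bins]
    a = delta_part[bins]
    return (float(b[_DELTA_SEL].sum()), float(b.sum()),
            float(a[_DELTA_SEL].sum()), float(a.sum()))


def _measured_delta_fraction(spec: StateSpectrum, fs: float) -> float:
    """State-level relative delta power as the standard pipeline measures it."""
    b_d, b_t, _, _ = _estimator_expectation(spec, fs)
    return b_d / b_t


def _k_for_gain(spec: StateSpectrum, fs: float, r_target: np.ndarray) -> np.ndarray:
    """Delta-band power scaling k that moves the *measured* delta fraction
    to ``r_target`` (solved exactly; the expectation is linear in k)."""
    b_d, b_t, a_d, a_t = _estimator_expectation(spec, fs)
    return 1.0 + (r_target * b_t - b_d) / (a_d - r_target * a_t)


def _gain_profile_pp(t_h: np.ndarray, params: SimParams) -> np.ndarray:
    """Injected delta gain (p.p.) at ZT times ``t_h``: exponential decay
    from each administration."""
    g = np.zeros_like(t_h, dtype=float)
    for a in params.treatment_admin_zt:
        if params.effect_decay_h > 0:
            mask = t_h >= a
            g[mask] += params.delta_gain_effect_pp * np.exp(
                -(t_h[mask] - a) / params.effect_decay_h)
    return g


def synthesize_recording(hyp: Hypnogram, params: SimParams,
                         seed: int | None = None, treated: bool = True,
                         ) -> tuple[RawRecording, GroundTruth]:
    """Colored-noise EEG shaped per state, with injected effect and artifacts.

    ``treated`` recordings receive the delta-gain effect after each
    administration; baseline recordings (``treated=False``) have zero
    effect but the same spectral model. All injected artifacts are logged.
    """
    params.validate()
    if hyp.n_epochs == 0:
        raise ParameterError("hypnogram is empty")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    fs = params.fs_native
    nE = hyp.n_epochs
    bounds = np.round(np.arange(nE + 1) * hyp.epoch_len_s * fs).astype(np.int64)
    n_total = int(bounds[-1])
    x = np.empty(n_total)

    # per-epoch target gain (p.p.) on NREM epochs of a treated recording
    t_h = hyp.epoch_zt_hours() + hyp.epoch_len_s / 7200.0  # epoch centers
    gain_pp = np.zeros(nE)
    if treated and params.delta_gain_effect_pp != 0:
        gain_pp = _gain_profile_pp(t_h, params)
    gain_pp[~hyp.state_mask("NREM")] = 0.0

    r0 = {s: _measured_delta_fraction(spec, fs)
          for s, spec in params.state_spectra.items()}
    true_delta = np.array([100.0 * r0[s] for s in hyp.labels])
    rp = np.clip(true_delta / 100.0 + gain_pp / 100.0, 0.0, 0.999)
    true_delta = 100.0 * rp
    # closed-form renormalization: delta-band power scaling that moves each
    # epoch's *measured* relative delta onto its target
    k = np.ones(nE)
    for s, spec in params.state_spectra.items():
        sel = hyp.labels == s
        if sel.any():
            k[sel] = _k_for_gain(spec, fs, rp[sel])

    # frequency-domain synthesis, batched over epochs of equal length
    shaping = {}

    def _shaping(state: str, n: int):
        key = (state, n)
        if key not in shaping:
            spec = params.state_spectra[state]
            f = np.fft.rfftfreq(n, 1.0 / fs)
            amp = np.sqrt(spec.psd(f))
            # scale so the synthesized signal has the state's target SD
            full = np.concatenate([amp, amp[-2:0:-1]])  # both-sided spectrum
            sd = np.sqrt(np.mean(full ** 2))
            amp *= spec.target_sd_uv / sd
            shaping[key] = (f, amp)
        return shaping[key]

    for e in range(nE):
        n = int(bounds[e + 1] - bounds[e])
        f, amp = _shaping(str(hyp.labels[e]), n)
        X = np.fft.rfft(rng.standard_normal(n))
        a = amp
        if k[e] != 1.0:
            a = amp.copy()
            a[(f >= 0.5) & (f <= 4.0)] *= np.sqrt(k[e])
        x[bounds[e]:bounds[e + 1]] = np.fft.irfft(X * a, n)

    events = []
    rail = params.input_range_mv * 1000.0
    hours = hyp.duration_s / 3600.0

    # clipping: digitizer saturation for 0.1-1 s
    n_clip = rng.poisson(params.clipping_rate_per_h * hours)
    occupied = np.zeros(n_total, dtype=bool)
    for _ in range(n_clip):
        for _try in range(200):
            dur = int(rng.uniform(0.1, 1.0) * fs)
            a = int(rng.integers(0, max(n_total - dur, 1)))
            if not occupied[max(a - 2, 0):a + dur + 2].any():
                break
        else:  # pragma: no cover - pathological packing
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        x[a:a + dur] = sign * rail
        occupied[a:a + dur] = True
        events.append((a, a + dur, "clipping"))

    # brief transients well beyond the NREMS IQR, inside NREM epochs
    nrem_sd = params.state_spectra["NREM"].target_sd_uv
    spike_amp = params.spike_amp_iqr_mult * 1.349 * nrem_sd
    nrem_epochs = np.flatnonzero(hyp.state_mask("NREM"))
    n_spike = rng.poisson(params.spike_rate_per_h * hours) if nrem_epochs.size else 0
    for _ in range(n_spike):
        e = int(rng.choice(nrem_epochs))
        a = int(rng.integers(bounds[e] + 4, bounds[e + 1] - 8))
        if occupied[a - 2:a + 5].any():
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        x[a:a + 3] += sign * spike_amp * np.array([0.6, 1.0, 0.6])
        occupied[a:a + 3] = True
        events.append((a, a + 3, "spike"))

    rec = RawRecording(x, fs=fs, input_range_mv=params.input_range_mv)

    eph = np.floor(hyp.epoch_zt_hours()).astype(int)
    nrem = hyp.state_mask("NREM")
    rows_d, rows_g = [], []
    for h in np.unique(eph):
        sel = nrem & (eph == h)
        n = int(sel.sum())
        rows_d.append({"zt_hour": int(h),
                       "true_delta_pct": float(true_delta[sel].mean()) if n else float("nan"),
                       "n_epochs": n})
        rows_g.append({"zt_hour": int(h),
                       "true_gain_pp": float(gain_pp[sel].mean()) if n else float("nan")})
    gt = GroundTruth(true_delta, gain_pp, pd.DataFrame(rows_d),
                     pd.DataFrame(rows_g), events,
                     base_delta_pct=100.0 * r0["NREM"])
    return rec, gt


# ---------------------------------------------------------------------------
# cohort-level generation

# baseline T-maze percent-correct by (cohort, genotype): printed group values
TMAZE_BASELINE = {
    ("early", "Tg2576"): (42.65, 14.99),
    ("early", "WT"): (79.63, 28.18),
    ("late", "Tg2576"): (53.75, 29.43),
    ("late", "WT"): (75.93, 18.28),
}

# post-treatment T-maze by (cohort, genotype, treatment); WT unchanged
TMAZE_POST = {
    ("early", "Tg2576", "SO"): (70.24, 9.45),
    ("early", "Tg2576", "placebo"): (42.50, 28.18),
    ("late", "Tg2576", "SO"): (63.33, 31.23),
    ("late", "Tg2576", "placebo"): (46.67, 27.27),
}

# ELISA pg/mg by (analyte, fraction) -> treatment -> (mean, sd). Insoluble
# Ab-40 carries the reported group difference; the rest are null contrasts
# at plausible levels (the study prints no group summaries for them).
ELISA_GROUPS = {
    ("ab40", "insoluble"): {"SO": (4.982, 0.379), "placebo": (4.459, 0.158)},
    ("ab42", "insoluble"): {"SO": (1.05, 0.45), "placebo": (1.20, 0.40)},
    ("ab40", "soluble"): {"SO": (2.05, 0.50), "placebo": (2.00, 0.50)},
    ("ab42", "soluble"): {"SO": (1.00, 0.30), "placebo": (0.98, 0.30)},
}

# plaque area fraction targets by (genotype, treatment), with between-subject SD
BURDEN_TARGETS = {
    ("Tg2576", "placebo"): 0.075,
    ("Tg2576", "SO"): 0.035,
    ("WT", "placebo"): 0.004,
    ("WT", "SO"): 0.004,
}
BURDEN_SD = 0.015

_REGION_FRAME_UM = {"hippocampus": 150.0, "cortex": 200.0}


def example_design(cohort: str = "early") -> pd.DataFrame:
    """A design table with the study's EEG group sizes for one cohort."""
    sizes = {("early", "WT", "placebo"): 9, ("early", "WT", "SO"): 9,
             ("early", "Tg2576", "placebo"): 8, ("early", "Tg2576", "SO"): 6,
             ("late", "WT", "placebo"): 9, ("late", "WT", "SO"): 6,
             ("late", "Tg2576", "placebo"): 12, ("late", "Tg2576", "SO"): 7}
    rows = []
    for (c, g, t), n in sizes.items():
        if c != cohort:
            continue
        for i in range(n):
            rows.append({"subject_id": f"{c[0]}_{g.lower()[:2]}_{t.lower()[:2]}_{i:02d}",
                         "genotype": g, "cohort": c, "treatment": t,
                         "sex": "f" if i % 2 == 0 else "m"})
    return pd.DataFrame(rows)


@dataclass
class CohortBundle:
    """Everything the generator produced for one cohort run."""

    metadata: pd.DataFrame
    tmaze: pd.DataFrame        # subject_id, phase, percent_correct, n_trials, n_correct
    elisa: pd.DataFrame        # subject_id, analyte, fraction, pg, tissue_mg
    masks: dict                # (subject_id, region) -> (mask, roi, um_per_pixel, true_fraction)
    recordings: dict           # subject_id -> {"baseline"/"treatment": (rec, hyp, gt)}
    ground_truth: dict


def simulate_cohort(design: pd.DataFrame, params: SimParams, seed: int = 0,
                    include_recordings: bool = True, include_masks: bool = True,
                    mask_um: float = 1500.0, mask_um_per_pixel: float = 2.0,
                    ) -> CohortBundle:
    """Draw a full cohort bundle with known ground truth.

    SO-treated subjects receive the configured delta-gain effect, placebo
    subjects zero. Behavioral and ELISA values are drawn from the printed
    group means/SDs; plaque masks from genotype/treatment burden targets.
    Deterministic under ``seed``.
    """
    params.validate()
    req = {"subject_id", "genotype", "cohort", "treatment"}
    missing = req - set(design.columns)
    if missing:
        raise DesignError(f"design table lacks columns: {sorted(missing)}")
    counts = design.groupby(["genotype", "treatment"]).size()
    if (counts < 2).any() or len(counts) < design["genotype"].nunique() * \
            design["treatment"].nunique():
        raise DesignError("need >= 2 subjects in every genotype x treatment cell")

    root = np.random.SeedSequence(seed)
    subj_seeds = root.spawn(len(design))
    tmaze_rows, elisa_rows = [], []
    masks, recordings = {}, {}
    truth = {"tmaze": {}, "elisa": {}, "burden": {}, "params": params}

    for (_, row), ss in zip(design.iterrows(), subj_seeds):
        sid, gen, coh, trt = (row["subject_id"], row["genotype"],
                              row["cohort"], row["treatment"])
        rng = np.random.default_rng(ss)

        m, sd = TMAZE_BASELINE[(coh, gen)]
        bl = float(rng.normal(m, sd))
        m2, sd2 = TMAZE_POST.get((coh, gen, trt), TMAZE_BASELINE[(coh, gen)])
        post = float(rng.normal(m2, sd2))
        for phase, pct in (("baseline", bl), ("post", post)):
            n_corr = int(np.clip(round(pct / 25.0), 0, 4))
            tmaze_rows.append({"subject_id": sid, "phase": phase,
                               "percent_correct": pct, "n_trials": 4,
                               "n_correct": n_corr})
        truth["tmaze"][sid] = {"baseline": bl, "post": post}

        if gen == "Tg2576":
            for (analyte, fraction), groups in ELISA_GROUPS.items():
                gm, gsd = groups[trt]
                val = float(rng.normal(gm, gsd))
                mg = float(rng.normal(420.0, 25.0))
                elisa_rows.append({"subject_id": sid, "analyte": analyte,
                                   "fraction": fraction, "pg": val * mg,
                                   "tissue_mg": mg})
                truth["elisa"][(sid, analyte, fraction)] = val

        if include_masks:
            base = BURDEN_TARGETS[(gen, trt)]
            for region in _REGION_FRAME_UM:
                target = float(np.clip(rng.normal(base, BURDEN_SD), 5e-4, 0.45))
                mask, roi, frac = simulate_plaque_mask(
                    mask_um, mask_um, mask_um_per_pixel, target,
                    seed=int(rng.integers(2 ** 31)))
                masks[(sid, region)] = (mask, roi, mask_um_per_pixel, frac)
                truth["burden"][(sid, region)] = frac

        if include_recordings:
            # sleep architecture varies between the two recorded days; the
            # treatment affects delta power, not NREMS time
            hyp_b = simulate_hypnogram(params, seed=int(rng.integers(2 ** 31)))
            hyp_t = simulate_hypnogram(params, seed=int(rng.integers(2 ** 31)))
            effect = params.delta_gain_effect_pp if trt == "SO" else 0.0
            p_subj = replace(params, delta_gain_effect_pp=effect)
            rec_b, gt_b = synthesize_recording(
                hyp_b, p_subj, seed=int(rng.integers(2 ** 31)), treated=False)
            rec_t, gt_t = synthesize_recording(
                hyp_t, p_subj, seed=int(rng.integers(2 ** 31)), treated=True)
            for r in (rec_b, rec_t):
                r.subject_id = sid
            recordings[sid] = {"baseline": (rec_b, hyp_b, gt_b),
                               "treatment": (rec_t, hyp_t, gt_t)}

    return CohortBundle(design.reset_index(drop=True), pd.DataFrame(tmaze_rows),
                        pd.DataFrame(elisa_rows,
                                     columns=["subject_id", "analyte", "fraction",
                                              "pg", "tissue_mg"]),
                        masks, recordings, truth)


def simulate_plaque_mask(width_um: float, height_um: float, um_per_pixel: float,
                         target_fraction: float, n_plaques: int = 40,
                         seed: int = 0, roi_margin_frac: float = 0.0,
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Random non-overlapping plaque disks inside an ROI.

    Disk radii are drawn with moderate spread and rescaled so the summed
    analytic disk area equals ``target_fraction`` of the ROI; the returned
    ``true_fraction`` is the exact pixel-count ratio after rasterization.
    """
    if not 0.0 <= target_fraction <= 0.5:
        raise ParameterError("target_fraction must be in [0, 0.5]")
    if um_per_pixel <= 0:
        raise ParameterError("um_per_pixel must be > 0")
    rng = np.random.default_rng(seed)
    H = int(round(height_um / um_per_pixel))
    W = int(round(width_um / um_per_pixel))
    roi = np.zeros((H, W), dtype=bool)
    my = int(round(roi_margin_frac * H))
    mx = int(round(roi_margin_frac * W))
    roi[my:H - my or None, mx:W - mx or None] = True
    mask = np.zeros((H, W), dtype=bool)
    if target_fraction == 0 or n_plaques == 0:
        return mask, roi, 0.0
    roi_area = float(roi.sum())
    radii = rng.uniform(0.6, 1.4, n_plaques)
    radii *= np.sqrt(target_fraction * roi_area / np.sum(np.pi * radii ** 2))
    radii = np.sort(radii)[::-1]  # place large disks first
    centers = []
    max_tries = 500 * n_plaques
    tries = 0
    yy = np.arange(H)[:, None]
    xx = np.arange(W)[None, :]
    for r in radii:
        while True:
            tries += 1
            if tries > max_tries:
                raise ParameterError(
                    f"cannot pack {n_plaques} disks at fraction {target_fraction}")
            cy = rng.uniform(my + r, H - my - r)
            cx = rng.uniform(mx + r, W - mx - r)
            if all((cy - oy) ** 2 + (cx - ox) ** 2 > (r + orad + 1) ** 2
                   for oy, ox, orad in centers):
                break
        centers.append((cy, cx, r))
        y0, y1 = max(int(cy - r - 1), 0), min(int(np.ceil(cy + r + 1)), H - 1)
        x0, x1 = max(int(cx - r - 1), 0), min(int(np.ceil(cx + r + 1)), W - 1)
        sub = ((yy[y0:y1 + 1] - cy) ** 2 + (xx[:, x0:x1 + 1] - cx) ** 2) <= r ** 2
        mask[y0:y1 + 1, x0:x1 + 1] |= sub
    true_fraction = float((mask & roi).sum() / roi.sum())
    return mask, roi, true_fraction
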