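"""Shared domain types for the slow-wave-activity pipeline.

Conventions used throughout the package:

* EEG samples are in microvolts (µV); the digitizer input range is given in
  millivolts (±200 mV by default) and converted to µV where a rail value is
  needed.
* Vigilance states are scored in fixed 4-s epochs with labels
  ``WAKE``/``NREM``/``REM``/``ARTIFACT``.
* Time of day is Zeitgeber time (ZT): hours since lights-on. A recording's
  ``zt0_offset_h`` is the ZT of its first sample (0 for a lights-on start).
"""
from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

STATES = ("WAKE", "NREM", "REM", "ARTIFACT")

#: short single-letter codes used in hypnogram TSV files
STATE_CODES = {"WAKE": "w", "NREM": "n", "REM": "r", "ARTIFACT": "a"}
CODE_STATES = {v: k for k, v in STATE_CODES.items()}


class ParameterError(ValueError):
    """Invalid parameter value for an operation or simulation."""


class DesignError(ValueError):
    """Invalid experimental design table (e.g. an empty factor cell)."""


class AlignmentError(ValueError):
    """Recording and hypnogram do not describe the same time span."""


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels aligned to a recording."""

    labels: np.ndarray  # array of strings from STATES
    epoch_len_s: float = 4.0
    zt0_offset_h: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U8")
        bad = set(np.unique(self.labels)) - set(STATES)
        if self.labels.size and bad:
            raise ParameterError(f"unknown vigilance labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s

    def state_mask(self, state: str) -> np.ndarray:
        return self.labels == state

    def epoch_zt_hours(self) -> np.ndarray:
        """ZT hour (float) of each epoch's start."""
        return self.zt0_offset_h + np.arange(self.n_epochs) * self.epoch_len_s / 3600.0

    def fraction(self, state: str, scored_only: bool = True) -> float:
        """Fraction of (scored) time spent in ``state``."""
        if scored_only:
            scored = self.labels != "ARTIFACT"
            denom = int(scored.sum())
        else:
            denom = self.n_epochs
        if denom == 0:
            return float("nan")
        return float((self.labels == state).sum()) / denom

    def with_artifacts(self, epoch_mask: np.ndarray) -> "Hypnogram":
        """Return a copy with epochs flagged in ``epoch_mask`` relabelled ARTIFACT."""
        labels = self.labels.copy()
        labels[np.asarray(epoch_mask, bool)] = "ARTIFACT"
        return Hypnogram(labels, self.epoch_len_s, self.zt0_offset_h)


@dataclass
class RawRecording:
    """A uniformly sampled single-channel EEG trace (µV)."""

    samples: np.ndarray
    fs: float
    input_range_mv: float = 200.0
    zt0_offset_h: float = 0.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def rail_uv(self) -> float:
        """Digitizer saturation level in µV."""
        return self.input_range_mv * 1000.0

    def replace(self, **kw) -> "RawRecording":
        d = dict(samples=self.samples, fs=self.fs, input_range_mv=self.input_range_mv,
                 zt0_offset_h=self.zt0_offset_h, subject_id=self.subject_id)
        d.update(kw)
        return RawRecording(**d)


@dataclass
class CleanRecording:
    """A post-processed recording: exactly 200 Hz, band-limited 0.5-30 Hz.

    ``provenance`` is an ordered list of the applied processing steps with
    their parameters, so any downstream number can be traced to its inputs.
    """

    samples: np.ndarray
    fs: float = 200.0
    input_range_mv: float = 200.0
    zt0_offset_h: float = 0.0
    subject_id: str = ""
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs != 200.0:
            raise ParameterError("CleanRecording must be sampled at exactly 200 Hz")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def rail_uv(self) -> float:
        return self.input_range_mv * 1000.0

    def log(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})


@dataclass(frozen=True)
class ArtifactEvent:
    """A contiguous artifactual sample range [start, end) with a kind tag."""

    start: int
    end: int
    kind: str  # "clipping" | "reconstructed" | "regional"

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class ArtifactMask:
    """Sample- and epoch-level artifact annotation for one recording."""

    sample_mask: np.ndarray  # bool per sample (at the fs the events refer to)
    epoch_mask: np.ndarray   # bool per 4-s epoch
    events: list = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def events_of_kind(self, kind: str) -> list:
        return [e for e in self.events if e.kind == kind]


def epoch_index_of_sample(sample: int, fs: float, epoch_len_s: float = 4.0) -> int:
    return int(sample / (fs * epoch_len_s))


def sample_to_epoch_mask(sample_mask: np.ndarray, fs: float, n_epochs: int,
                         epoch_len_s: float = 4.0) -> np.ndarray:
    """Epochs containing at least one flagged sample."""
    out = np.zeros(n_epochs, dtype=bool)
    idx = np.flatnonzero(sample_mask)
    if idx.size:
        ep = (idx / (fs * epoch_len_s)).astype(int)
        ep = ep[ep < n_epochs]
        out[np.unique(ep)] = True
    return out
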