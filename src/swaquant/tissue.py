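"""Amyloid burden stereology, ELISA normalization, and T-maze scoring.

Plaque burden is estimated with the area-fraction fractionator: a seeded
random-origin sampling grid tiles the region of interest, plaque-positive
and ROI pixels are counted inside each counting frame, and burden is the
ratio of the summed areas. With grid size equal to frame size the probe
scans the entire ROI and the estimate equals exhaustive pixel counting
exactly. Default frame sizes follow the study's stereology protocol:
150 µm (hippocampus) and 200 µm (cortex), grid = frame.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ParameterError

__all__ = ["FractionatorConfig", "BurdenEstimate", "TMazeResult",
           "area_fraction_fractionator", "subject_burden", "elisa_normalize",
           "tmaze_score", "REGION_FRAME_UM"]

REGION_FRAME_UM = {"hippocampus": 150.0, "cortex": 200.0}


@dataclass(frozen=True)
class FractionatorConfig:
    """Counting-frame and sampling-grid geometry (µm, square)."""

    frame_um: float = 150.0
    grid_um: float | None = None  # None -> grid = frame (scan the whole ROI)

    def __post_init__(self):
        if self.frame_um <= 0:
            raise ParameterError("frame size must be > 0")
        if self.grid_um is not None and self.grid_um < self.frame_um:
            raise ParameterError("grid size must be >= frame size")

    @property
    def effective_grid_um(self) -> float:
        return self.frame_um if self.grid_um is None else self.grid_um


@dataclass
class BurdenEstimate:
    """Area-fraction estimate for one section."""

    plaque_area_um2: float
    roi_area_um2: float
    sampled_roi_area_um2: float

    @property
    def burden(self) -> float:
        """Plaque area as a fraction of sampled ROI area."""
        if self.sampled_roi_area_um2 == 0:
            return float("nan")
        return self.plaque_area_um2 / self.sampled_roi_area_um2


def area_fraction_fractionator(mask: np.ndarray, roi: np.ndarray,
                               um_per_pixel: float,
                               cfg: FractionatorConfig | None = None,
                               seed: int = 0) -> BurdenEstimate:
    """Estimate the plaque area fraction of an ROI by systematic sampling.

    Counting frames occupy the first ``frame`` pixels of each grid cell;
    the grid origin is a seeded uniform random offset, so each pixel is
    sampled with probability (frame/grid)². Frames clipped at the ROI
    boundary contribute their ROI-intersected pixels.
    """
    cfg = cfg or FractionatorConfig()
    mask = np.asarray(mask, bool)
    roi = np.asarray(roi, bool)
    if mask.shape != roi.shape:
        raise ParameterError("plaque mask and ROI mask must share dimensions")
    if um_per_pixel <= 0:
        raise ParameterError("um_per_pixel must be > 0")
    if not roi.any():
        raise ParameterError("ROI is empty")
    frame_px = max(int(round(cfg.frame_um / um_per_pixel)), 1)
    grid_px = max(int(round(cfg.effective_grid_um / um_per_pixel)), frame_px)
    H, W = roi.shape
    if grid_px == frame_px:
        sel = np.ones((H, W), dtype=bool)  # grid = frame: the probe scans everything
    else:
        rng = np.random.default_rng(seed)
        oy, ox = rng.integers(0, grid_px, size=2)
        sy = ((np.arange(H) - oy) % grid_px) < frame_px
        sx = ((np.arange(W) - ox) % grid_px) < frame_px
        sel = sy[:, None] & sx[None, :]
    px_area = um_per_pixel ** 2
    sampled_roi = roi & sel
    plaque = int((mask & sampled_roi).sum())
    return BurdenEstimate(plaque_area_um2=plaque * px_area,
                          roi_area_um2=float(roi.sum()) * px_area,
                          sampled_roi_area_um2=float(sampled_roi.sum()) * px_area)


def subject_burden(sections: list) -> float:
    """Per-subject burden over sections: total plaque area / total ROI area.

    Ratio of summed areas (not the mean of per-section ratios), mirroring
    the burden definition; invariant to section ordering.
    """
    if not sections:
        raise ParameterError("need at least one section")
    num = sum(s.plaque_area_um2 for s in sections)
    den = sum(s.sampled_roi_area_um2 for s in sections)
    if den == 0:
        return float("nan")
    return num / den


def elisa_normalize(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize ELISA readouts to tissue mass and form Aβ-42/Aβ-40 ratios.

    ``records`` needs columns subject_id, analyte ("ab40"/"ab42"), fraction
    ("soluble"/"insoluble"), pg, tissue_mg. Returns the table with a
    ``pg_per_mg`` column, and a per-subject ratio table (one row per
    subject × fraction) with the ratio missing and flagged when either
    analyte of the pair is absent.
    """
    df = records.copy()
    if (df["pg"] <= 0).any() or (df["tissue_mg"] <= 0).any():
        raise ParameterError("pg and tissue_mg must be positive")
    df["pg_per_mg"] = df["pg"] / df["tissue_mg"]
    wide = df.pivot_table(index=["subject_id", "fraction"], columns="analyte",
                          values="pg_per_mg", aggfunc="first")
    ratios = wide.reset_index()
    for col in ("ab40", "ab42"):
        if col not in ratios:
            ratios[col] = np.nan
    ratios["ratio_42_40"] = ratios["ab42"] / ratios["ab40"]
    ratios["incomplete_pair"] = ratios["ab40"].isna() | ratios["ab42"].isna()
    ratios.loc[ratios["incomplete_pair"], "ratio_42_40"] = np.nan
    return df, ratios[["subject_id", "fraction", "ab40", "ab42",
                       "ratio_42_40", "incomplete_pair"]]


@dataclass
class TMazeResult:
    """Forced-alternation T-maze outcome for one subject and phase."""

    n_correct: int
    n_trials: int

    @property
    def percent_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_trials

    @property
    def outcome_class(self) -> str:
        """"success" iff percent > 50; exactly 50 counts as "fail"."""
        return "success" if self.percent_correct > 50.0 else "fail"


def tmaze_score(trials) -> TMazeResult:
    """Score a list of trial outcomes (truthy/"correct" = correct entry)."""
    outcomes = list(trials)
    if not outcomes:
        raise ParameterError("need at least one trial")

    def _is_correct(t) -> bool:
        if isinstance(t, str):
            return t.strip().lower() in ("correct", "c", "1", "true")
        return bool(t)

    n_correct = sum(_is_correct(t) for t in outcomes)
    return TMazeResult(n_correct=n_correct, n_trials=len(outcomes))
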