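"""End-to-end per-image analysis, per-condition summaries and trend fits.

``analyze_image`` chains the pipeline — neuron discrimination, grid
segmentation, neuronal flagging, orientation estimation, correlation scan,
thresholding — and yields exactly one record per tile.  ``summarize``
condenses records from one experimental condition into the two headline
quantities: the *abundance* (fraction of analyzed tiles whose best R_P
exceeds the calibrated threshold) and the *regularity* (mean best R_P over
detected tiles), plus a tile-resolution binary detection map.  ``fit_trend``
fits abundance-versus-age curves (days in vitro) with a four-parameter
logistic, whose midpoint is the half-height time, or with a saturating
exponential that only conveys the increasing trend.

Tiles whose orientation estimate is ambiguous (no dominant angular
cluster) are discarded: they enter neither the abundance numerator nor its
denominator by default.  Set ``ambiguous_as_negative=True`` in
``summarize`` to count them as analyzed-but-not-detected instead; the
choice materially affects abundance fractions in dense cultures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import RunConfig
from .correlation import scan
from .discrimination import discriminate
from .segmentation import estimate_direction, flag_neuronal, segment_grid

__all__ = [
    "SubregionRecord",
    "BatchSummary",
    "TrendFit",
    "analyze_image",
    "records_to_frame",
    "summarize",
    "fit_trend",
]

RECORD_COLUMNS = [
    "image_id", "tile_row", "tile_col", "neuronal", "direction_valid",
    "theta_n_deg", "best_rp", "best_theta_deg", "best_phi_rad", "detected",
]


@dataclass(frozen=True)
class SubregionRecord:
    image_id: str
    tile_row: int
    tile_col: int
    neuronal: bool
    direction_valid: bool
    theta_n: float | None = None
    best_rp: float | None = None
    best_theta: float | None = None
    best_phi: float | None = None
    detected: bool = False


@dataclass(frozen=True)
class BatchSummary:
    n_analyzed: int
    n_detected: int
    abundance: float | None          # None when no tile was analyzable
    mean_rp_above: float | None      # None when nothing was detected
    detection_map: np.ndarray        # binary, tile resolution
    threshold: float


@dataclass(frozen=True)
class TrendFit:
    model: str
    params: dict
    midpoint: float | None           # half-height covariate value
    converged: bool


def analyze_image(image: np.ndarray, pixel_size: float, config: RunConfig,
                  threshold: float, image_id: str = "") -> list[SubregionRecord]:
    """Run the full detection pipeline on one image.

    Every grid tile yields exactly one record.  Non-neuronal tiles carry no
    orientation; direction-ambiguous tiles carry no correlation; detection
    requires a valid R_P strictly above the threshold.
    """
    neuron = discriminate(image, pixel_size, config.mask)
    tiles, _ = segment_grid(image.shape, pixel_size, config.l_sr_nm)
    records = []
    for tile in tiles:
        neuronal = flag_neuronal(tile, neuron.mask, config.min_neuronal_fraction)
        if not neuronal:
            records.append(SubregionRecord(image_id, tile.row, tile.col,
                                           neuronal=False, direction_valid=False))
            continue
        est = estimate_direction(neuron.mask[tile.slices()], config.hough)
        if not est.valid:
            records.append(SubregionRecord(image_id, tile.row, tile.col,
                                           neuronal=True, direction_valid=False))
            continue
        result = scan(
            image[tile.slices()], neuron.mask[tile.slices()], est.theta_n,
            config.pattern, pixel_size,
            theta_halfrange=config.theta_halfrange_deg,
            theta_step=config.theta_step_deg, n_phi=config.n_phi,
            min_mask_fraction=config.min_mask_fraction,
            origin=(tile.row0, tile.col0),
        )
        if result.degenerate:
            records.append(SubregionRecord(image_id, tile.row, tile.col,
                                           neuronal=True, direction_valid=False,
                                           theta_n=est.theta_n))
            continue
        records.append(SubregionRecord(
            image_id, tile.row, tile.col, neuronal=True, direction_valid=True,
            theta_n=est.theta_n, best_rp=result.best_rp,
            best_theta=result.best_theta, best_phi=result.best_phi,
            detected=bool(result.best_rp > threshold),
        ))
    return records


def records_to_frame(records: list[SubregionRecord]) -> pd.DataFrame:
    """Tabulate records with the canonical column set."""
    return pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "tile_row": r.tile_row,
                "tile_col": r.tile_col,
                "neuronal": r.neuronal,
                "direction_valid": r.direction_valid,
                "theta_n_deg": r.theta_n,
                "best_rp": r.best_rp,
                "best_theta_deg": r.best_theta,
                "best_phi_rad": r.best_phi,
                "detected": r.detected,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def summarize(records: list[SubregionRecord], threshold: float,
              ambiguous_as_negative: bool = False) -> BatchSummary:
    """Condense one condition's records into abundance and regularity.

    ``analyzed`` tiles are those that are neuronal and direction-valid with
    a non-degenerate R_P; with ``ambiguous_as_negative`` the neuronal but
    direction-ambiguous tiles are also counted in the denominator.
    """
    analyzed = [r for r in records if r.neuronal and r.direction_valid and r.best_rp is not None]
    n_analyzed = len(analyzed)
    if ambiguous_as_negative:
        n_analyzed += sum(1 for r in records if r.neuronal and r.best_rp is None)
    detected = [r for r in analyzed if r.detected]

    n_rows = max((r.tile_row for r in records), default=-1) + 1
    n_cols = max((r.tile_col for r in records), default=-1) + 1
    det_map = np.zeros((n_rows, n_cols), dtype=np.uint8)
    for r in detected:
        det_map[r.tile_row, r.tile_col] = 1

    return BatchSummary(
        n_analyzed=n_analyzed,
        n_detected=len(detected),
        abundance=(len(detected) / n_analyzed) if n_analyzed else None,
        mean_rp_above=float(np.mean([r.best_rp for r in detected])) if detected else None,
        detection_map=det_map,
        threshold=float(threshold),
    )


def _logistic(x, y0, y1, x50, tau):
    return y0 + (y1 - y0) / (1.0 + np.exp(-(x - x50) / tau))


def _saturating_exp(x, y0, y1, tau):
    return y0 + (y1 - y0) * (1.0 - np.exp(-x / tau))


def fit_trend(x, y, model: str = "sigmoid") -> TrendFit:
    """Least-squares trend fit of abundance (or regularity) versus age.

    ``sigmoid`` is the four-parameter logistic
    ``y = y0 + (y1 - y0) / (1 + exp(-(x - x50)/tau))`` whose midpoint
    ``x50`` is the half-height time; ``exponential`` is a saturating
    exponential used only to display an increasing trend.  Non-convergence
    (including unidentifiable midpoints on flat data) is flagged, never
    raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if model == "sigmoid":
        if x.size < 4:
            raise ValueError("sigmoid fit needs >= 4 points (4 parameters)")
        if np.ptp(y) == 0.0:
            return TrendFit("sigmoid", {}, None, converged=False)
        p0 = [y.min(), y.max(), float(np.median(x)), max(np.ptp(x) / 8.0, 1e-3)]
        try:
            popt, pcov = curve_fit(_logistic, x, y, p0=p0, maxfev=20000)
        except RuntimeError:
            return TrendFit("sigmoid", {}, None, converged=False)
        if not np.all(np.isfinite(pcov)):
            return TrendFit("sigmoid", {}, None, converged=False)
        params = dict(zip(["y0", "y1", "x50", "tau"], map(float, popt)))
        return TrendFit("sigmoid", params, params["x50"], converged=True)
    if model == "exponential":
        if x.size < 3:
            raise ValueError("exponential fit needs >= 3 points")
        if np.ptp(y) == 0.0:
            return TrendFit("exponential", {}, None, converged=False)
        p0 = [y.min(), y.max(), max(float(np.median(x)), 1e-3)]
        try:
            popt, _ = curve_fit(_saturating_exp, x, y, p0=p0, maxfev=20000)
        except RuntimeError:
            return TrendFit("exponential", {}, None, converged=False)
        params = dict(zip(["y0", "y1", "tau"], map(float, popt)))
        return TrendFit("exponential", params, None, converged=True)
    raise ValueError(f"unknown trend model {model!r}")
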