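"""Image and result file I/O.

Images travel as single-channel TIFF (8/16-bit integer or float); per-tile
records as CSV; calibration records and batch summaries as JSON; detection
maps as 8-bit TIFF.  Physical pixel size is taken from TIFF resolution
metadata when present and from the configuration otherwise.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .batch import BatchSummary, SubregionRecord, records_to_frame

__all__ = ["load_image", "save_image", "write_records_csv", "read_records_csv",
           "write_summary_json"]


def load_image(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Load a single-channel 2D TIFF; returns (image, pixel_size_nm or None).

    Multi-page and RGB TIFFs are rejected: the pipeline is defined on one
    grayscale super-resolution channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path.name}: multi-page TIFF; supply single-channel 2D images")
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(f"{path.name}: expected a 2D grayscale image, got shape {data.shape} "
                             "(RGB/multi-channel TIFFs are not supported)")
        pixel_size = None
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and unit is not None:
            num, den = res.value
            if num > 0 and den > 0:
                per_unit = num / den      # pixels per unit
                unit_nm = {2: 2.54e7, 3: 1e7}.get(int(unit.value))  # inch, cm
                if unit_nm:
                    pixel_size = unit_nm / per_unit
    return data, pixel_size


def save_image(path: str | Path, image: np.ndarray, pixel_size_nm: float | None = None) -> None:
    """Write a 2D array as TIFF, embedding the pixel size when given."""
    kwargs = {}
    if pixel_size_nm:
        per_cm = 1e7 / pixel_size_nm
        kwargs = {"resolution": (per_cm, per_cm), "resolutionunit": 3}
    tifffile.imwrite(Path(path), np.asarray(image), **kwargs)


def write_records_csv(path: str | Path, records: list[SubregionRecord]) -> None:
    records_to_frame(records).to_csv(Path(path), index=False)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_summary_json(path: str | Path, summary: BatchSummary) -> None:
    data = asdict(summary)
    data["detection_map"] = np.asarray(summary.detection_map).tolist()
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
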