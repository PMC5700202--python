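"""Analysis configuration: defaults, file loading and round-tripping.

Every pipeline parameter has a documented default, so a fully defaulted
configuration runs end-to-end on simulator output.  Configurations are flat
YAML or JSON mappings; unknown keys are rejected to catch typos early.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .discrimination import MaskParams
from .pattern import PatternParams
from .segmentation import HoughParams

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Full parameter set of an analysis run.

    Attributes
    ----------
    pixel_size_nm : physical pixel size of the input images; used whenever
        the TIFF carries no resolution metadata.
    modality : free-text label (e.g. "STED", "STORM") keyed into the
        calibration record; nothing in the math depends on it.
    pattern : reference-pattern parameters (T = 190 nm, P = 6 by default;
        A = 0, B = 1 since the correlation is invariant to affine intensity
        scaling of the pattern).
    mask : neuron-discrimination settings (Gaussian width and threshold).
    hough : orientation-estimation settings.
    l_sr_nm : subregion side length.
    min_neuronal_fraction : minimum mask coverage for a tile to count as
        neuronal.
    theta_halfrange_deg, theta_step_deg, n_phi : correlation scan grid.
    min_mask_fraction : minimum masked fraction of a tile for a
        non-degenerate correlation.
    n_sigma : threshold multiplier for calibration.
    seed : global seed for every randomized step.
    """

    pixel_size_nm: float = 20.0
    modality: str = ""
    pattern: PatternParams = field(default_factory=PatternParams)
    mask: MaskParams = field(default_factory=MaskParams)
    hough: HoughParams = field(default_factory=HoughParams)
    l_sr_nm: float = 1000.0
    min_neuronal_fraction: float = 0.2
    theta_halfrange_deg: float = 20.0
    theta_step_deg: float = 1.0
    n_phi: int = 20
    min_mask_fraction: float = 0.1
    n_sigma: float = 2.5
    seed: int = 0

    # flat-file key <-> attribute path
    _KEYS = {
        "pixel_size_nm": ("pixel_size_nm",),
        "modality": ("modality",),
        "A": ("pattern", "A"),
        "B": ("pattern", "B"),
        "P": ("pattern", "P"),
        "T_nm": ("pattern", "T"),
        "phi_rad": ("pattern", "phi"),
        "theta_deg": ("pattern", "theta"),
        "sigma_gf_nm": ("mask", "sigma_gf"),
        "k_thresh": ("mask", "k_thresh"),
        "min_size_px": ("mask", "min_size_px"),
        "hough_min_len_frac": ("hough", "min_len_frac"),
        "hough_max_gap_frac": ("hough", "max_gap_frac"),
        "hough_threshold": ("hough", "threshold"),
        "cluster_tol_deg": ("hough", "cluster_tol_deg"),
        "length_weighted": ("hough", "length_weighted"),
        "l_sr_nm": ("l_sr_nm",),
        "min_neuronal_fraction": ("min_neuronal_fraction",),
        "theta_halfrange_deg": ("theta_halfrange_deg",),
        "theta_step_deg": ("theta_step_deg",),
        "n_phi": ("n_phi",),
        "min_mask_fraction": ("min_mask_fraction",),
        "n_sigma": ("n_sigma",),
        "seed": ("seed",),
    }

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(cls._KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        pattern_kw, mask_kw, hough_kw, top_kw = {}, {}, {}, {}
        groups = {"pattern": pattern_kw, "mask": mask_kw, "hough": hough_kw}
        for key, value in data.items():
            path = cls._KEYS[key]
            if len(path) == 1:
                top_kw[path[0]] = value
            else:
                groups[path[0]][path[1]] = value
        return cls(pattern=PatternParams(**pattern_kw), mask=MaskParams(**mask_kw),
                   hough=HoughParams(**{"seed": top_kw.get("seed", 0), **hough_kw}),
                   **top_kw)

    def to_mapping(self) -> dict:
        out = {}
        for key, path in self._KEYS.items():
            obj = self
            for attr in path:
                obj = getattr(obj, attr)
            out[key] = obj
        return out

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_mapping(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_mapping()
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))

    def replace_from_mapping(self, overrides: dict) -> "RunConfig":
        """Apply flat-key overrides (CLI flags beat file values)."""
        data = self.to_mapping()
        data.update({k: v for k, v in overrides.items() if v is not None})
        return self.from_mapping(data)
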