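"""Parametric periodic reference pattern.

The reference model for the membrane-associated periodic skeleton (MPS) is a
raised, sharpened sine::

    f(x) = A + B * sin(pi * x / T + phi) ** P

with baseline ``A``, amplitude ``B``, period ``T`` (nm), phase ``phi`` (rad)
and an even sharpness power ``P``.  Because ``P`` is even, ``sin**P`` has
period ``T`` in ``x`` (the even power halves the sine's natural ``2T``
period), so consecutive intensity maxima are spaced exactly ``T`` apart and
the profile is bounded in ``[A, A + B]``.

Two-dimensional patterns are produced by evaluating the profile along a
variation axis at in-plane angle ``theta``; stripes run perpendicular to that
axis.  Conventions used throughout the package:

* pixel centers sit at ``(index + 0.5) * pixel_size`` nanometres;
* ``theta`` is measured counter-clockwise from the image column axis
  (axis 1), so at ``theta = 0`` intensity varies along a row and every
  column of the image is constant;
* ``theta`` is stored modulo 180 degrees and ``phi`` wrapped to ``[0, 2pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["PatternParams", "evaluate_profile", "render_pattern", "TabulatedPattern",
           "phase_distance"]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PatternParams:
    """Parameters of the periodic reference pattern.

    Attributes
    ----------
    A : float
        Baseline intensity (arbitrary units).
    B : float
        Amplitude (arbitrary units, >= 0).
    P : int
        Sharpness power; positive even integer.
    T : float
        Period in nm (> 0).
    phi : float
        Phase in radians, wrapped to [0, 2pi).
    theta : float
        In-plane orientation of the variation axis, degrees mod 180.
    """

    A: float = 0.0
    B: float = 1.0
    P: int = 6
    T: float = 190.0
    phi: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.T) or self.T <= 0:
            raise ValueError(f"period T must be positive and finite, got {self.T}")
        if not np.isfinite(self.B) or self.B < 0:
            raise ValueError(f"amplitude B must be non-negative, got {self.B}")
        if int(self.P) != self.P or self.P <= 0 or self.P % 2 != 0:
            raise ValueError(f"sharpness P must be a positive even integer, got {self.P}")
        if not np.isfinite(self.A):
            raise ValueError("baseline A must be finite")
        object.__setattr__(self, "P", int(self.P))
        object.__setattr__(self, "phi", float(np.mod(self.phi, _TWO_PI)))
        object.__setattr__(self, "theta", float(np.mod(self.theta, 180.0)))

    def with_angles(self, *, theta: float | None = None, phi: float | None = None) -> "PatternParams":
        """Copy with replaced orientation and/or phase (wrapped on construction)."""
        kw = {}
        if theta is not None:
            kw["theta"] = theta
        if phi is not None:
            kw["phi"] = phi
        return replace(self, **kw)


def evaluate_profile(x, params: PatternParams) -> np.ndarray:
    """Evaluate the 1D periodic profile at positions ``x`` (nm).

    Returns ``A + B * sin(pi * x / T + phi) ** P`` elementwise.
    """
    x = np.asarray(x, dtype=float)
    return params.A + params.B * np.sin(np.pi * x / params.T + params.phi) ** params.P


def _projected_coordinate(shape, pixel_size: float, theta_deg: float,
                          origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Pixel-center coordinates projected onto the variation axis at ``theta``.

    ``origin`` is a (row, col) offset in pixels, used so tiles of a larger
    image can be rendered in the image's global coordinate frame.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    t = np.deg2rad(theta_deg)
    y = (np.arange(rows) + origin[0] + 0.5) * pixel_size
    x = (np.arange(cols) + origin[1] + 0.5) * pixel_size
    return x[None, :] * np.cos(t) + y[:, None] * np.sin(t)


def render_pattern(shape, pixel_size: float, params: PatternParams,
                   origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Render the rotated 2D reference pattern analytically at pixel centers.

    Parameters
    ----------
    shape : (rows, cols)
        Output image size in pixels.
    pixel_size : float
        Physical pixel size in nm/pixel.
    params : PatternParams
        Pattern parameters including the orientation ``theta``.
    origin : (row, col), optional
        Pixel offset of the tile within a larger image; phases stay globally
        consistent when rendering tiles.
    """
    u = _projected_coordinate(shape, pixel_size, params.theta, origin)
    return evaluate_profile(u, params)


def phase_distance(phi_a: float, phi_b: float, period: float = np.pi) -> float:
    """Shortest circular distance between two phases.

    Because the sine is raised to an even power, the rendered pattern is
    invariant under a phase shift of pi: sin**P(x + pi) = sin**P(x).  The
    identifiable phase therefore lives on a circle of circumference pi,
    which is the default period here.
    """
    d = np.mod(phi_a - phi_b, period)
    return float(min(d, period - d))


class TabulatedPattern:
    """Numerically tabulated 1D reference profile.

    Alternative to the analytic model for structures without a closed-form
    profile: a sampled intensity profile over one period is interpolated
    periodically.  Exposes the same rendering interface as the analytic
    pattern via :meth:`render`.
    """

    def __init__(self, x: np.ndarray, values: np.ndarray, period: float):
        x = np.asarray(x, dtype=float)
        values = np.asarray(values, dtype=float)
        if x.ndim != 1 or x.shape != values.shape or x.size < 2:
            raise ValueError("x and values must be matching 1D arrays with >= 2 samples")
        if period <= 0:
            raise ValueError("period must be positive")
        order = np.argsort(x)
        self.x = np.mod(x[order], period)
        self.values = values[order]
        self.period = float(period)

    def profile(self, x, phase_nm: float = 0.0) -> np.ndarray:
        xm = np.mod(np.asarray(x, dtype=float) + phase_nm, self.period)
        return np.interp(xm, self.x, self.values, period=self.period)

    def render(self, shape, pixel_size: float, theta_deg: float,
               phase_nm: float = 0.0, origin=(0.0, 0.0)) -> np.ndarray:
        u = _projected_coordinate(shape, pixel_size, theta_deg, origin)
        return self.profile(u, phase_nm)
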