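"""Phasor population codes: 2D vectors as sinusoidal activity across columns.

A planar vector is carried by a population of ``n_columns`` rate units with
evenly spaced preferred directions ``theta_i = 2*pi*i/N``.  The vector's angle
is the phase and its length the amplitude of the sinusoidal activity profile

    rate_i = baseline + magnitude * cos(angle - theta_i)

which is the columnar encoding used by heading (TB1-like) and displacement
(CPU4-like) populations in the insect central complex.  Vector addition is
element-wise rate addition (minus one redundant baseline), because sinusoids
of equal period are closed under addition.

Conventions: angles in radians, counter-clockwise positive, 0 = allocentric
+x (east).  Rates are non-negative whenever magnitude <= baseline; `encode`
raises on saturation rather than clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, SaturationError

__all__ = [
    "PhasorActivity",
    "DecodedVector",
    "encode",
    "encode_xy",
    "decode",
    "decode_xy",
    "phasor_add",
    "phasor_scale",
    "phasor_rotate",
    "preferred_directions",
]

#: magnitudes below this decode as a flagged zero vector
_ZERO_TOL = 1e-12


def preferred_directions(n_columns: int) -> np.ndarray:
    """Evenly spaced column preferred directions ``2*pi*i/N``."""
    return 2.0 * np.pi * np.arange(n_columns) / n_columns


@dataclass(frozen=True)
class PhasorActivity:
    """Rate vector encoding a 2D vector as a sinusoid across columns."""

    rates: np.ndarray
    baseline: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        if self.rates.ndim != 1 or self.rates.size < 3:
            raise ConfigurationError(
                f"need a 1D rate vector with >= 3 columns, got shape {self.rates.shape}"
            )

    @property
    def n_columns(self) -> int:
        return self.rates.size


@dataclass(frozen=True)
class DecodedVector:
    """Result of reading a phasor out: polar vector plus a zero flag.

    ``undefined`` is True when the magnitude is (numerically) zero, in which
    case ``angle`` is reported as 0 by convention — a zero home vector at the
    nest is legitimate, not an error.
    """

    angle: float
    magnitude: float
    undefined: bool = False

    @property
    def xy(self) -> tuple[float, float]:
        return (
            self.magnitude * float(np.cos(self.angle)),
            self.magnitude * float(np.sin(self.angle)),
        )


def encode(
    angle: float,
    magnitude: float,
    n_columns: int = 8,
    baseline: float = 1.0,
) -> PhasorActivity:
    """Encode a polar vector into columnar rates.

    Raises
    ------
    SaturationError
        if ``magnitude > baseline`` (rates would go negative).
    ConfigurationError
        if ``n_columns < 3`` (phase not recoverable from fewer samples).
    """
    if n_columns < 3:
        raise ConfigurationError(f"n_columns must be >= 3, got {n_columns}")
    if magnitude < 0:
        raise SaturationError(f"magnitude must be >= 0, got {magnitude}")
    if magnitude > baseline:
        raise SaturationError(
            f"magnitude {magnitude} exceeds baseline {baseline}: phasor saturated"
        )
    theta = preferred_directions(n_columns)
    return PhasorActivity(baseline + magnitude * np.cos(angle - theta), baseline)


def encode_xy(x: float, y: float, n_columns: int = 8, baseline: float = 1.0) -> PhasorActivity:
    """Encode a Cartesian vector (convenience wrapper around `encode`)."""
    return encode(float(np.arctan2(y, x)), float(np.hypot(x, y)), n_columns, baseline)


def decode(p: PhasorActivity) -> DecodedVector:
    """First-harmonic readout: project ``rates - baseline`` onto the
    fundamental Fourier component.

    Exact inverse of `encode` for any sinusoidal profile; for arbitrary rate
    vectors it returns the least-squares sinusoid's amplitude and phase.
    """
    theta = preferred_directions(p.n_columns)
    z = (2.0 / p.n_columns) * np.sum((p.rates - p.baseline) * np.exp(1j * theta))
    magnitude = float(np.abs(z))
    if magnitude < _ZERO_TOL:
        return DecodedVector(angle=0.0, magnitude=0.0, undefined=True)
    return DecodedVector(angle=float(np.angle(z)), magnitude=magnitude)


def decode_xy(p: PhasorActivity) -> tuple[float, float]:
    return decode(p).xy


def _check_compatible(a: PhasorActivity, b: PhasorActivity) -> None:
    if a.n_columns != b.n_columns:
        raise ConfigurationError(
            f"column count mismatch: {a.n_columns} vs {b.n_columns}"
        )
    if not np.isclose(a.baseline, b.baseline):
        raise ConfigurationError(
            f"baseline mismatch: {a.baseline} vs {b.baseline}"
        )


def phasor_add(a: PhasorActivity, b: PhasorActivity) -> PhasorActivity:
    """Vector addition in the phasor domain: element-wise rate sum minus one
    baseline.  The result decodes to the complex sum of the operands."""
    _check_compatible(a, b)
    return PhasorActivity(a.rates + b.rates - a.baseline, a.baseline)


def phasor_scale(p: PhasorActivity, factor: float) -> PhasorActivity:
    """Scale the encoded vector by ``factor`` (gain on the deviation from
    baseline).  Linear, so no decode/re-encode round trip is needed."""
    return PhasorActivity(p.baseline + factor * (p.rates - p.baseline), p.baseline)


def phasor_rotate(p: PhasorActivity, dtheta: float) -> PhasorActivity:
    """Rotate the encoded vector by ``dtheta`` radians (counter-clockwise)
    via a decode/re-encode round trip.  A flagged-zero phasor is returned
    unchanged."""
    v = decode(p)
    if v.undefined:
        return PhasorActivity(p.rates.copy(), p.baseline)
    return encode(v.angle + dtheta, min(v.magnitude, p.baseline), p.n_columns, p.baseline)
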