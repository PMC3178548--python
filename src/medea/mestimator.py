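"""Redescending M-estimator weights with deterministic annealing.

A robust location estimate solves an iteratively reweighted mean where each
observation's weight depends on its standardized residual ``r = (x - mu) / sigma``.
The weight family used here is

    w(r; c, T) = exp(-r^2 / 2T) / (exp(-r^2 / 2T) + exp(-c^2 / 2T)),

where ``c`` is the cutoff and ``T`` the annealing temperature.  Key
properties, all exploited by the clustering loop:

* ``w(c) = 0.5`` for every temperature — the cutoff marks the half-weight
  point, placed on the tolerance-box edge by standardizing with
  ``sigma = delta / 3`` and ``c = 3``.
* ``T -> inf``: ``w -> 1/2`` everywhere, i.e. an ordinary (least-squares) mean.
* ``T -> 0``: ``w`` becomes the indicator of ``|r| < c`` — the skipped mean,
  which discards everything outside the box.
* The influence function ``psi(r) = r * w(r)`` redescends to zero for large
  ``|r|``, so distant outliers are effectively ignored.

Weights are evaluated as a logistic sigmoid of ``(c^2 - r^2) / (2T)``, which
is exact and immune to overflow for any residual or temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .tolerance import CUTOFF, ToleranceModel

__all__ = ["WeightParams", "weight", "psi", "combined_weight"]


def _validate(cutoff: float, temperature: float) -> None:
    if not cutoff > 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")


@dataclass(frozen=True)
class WeightParams:
    """Cutoff ``c`` and temperature ``T`` of the weight function (both > 0)."""

    cutoff: float = CUTOFF
    temperature: float = 1.0

    def __post_init__(self) -> None:
        _validate(self.cutoff, self.temperature)

    def weight(self, r):
        return weight(r, self.cutoff, self.temperature)

    def psi(self, r):
        return psi(r, self.cutoff, self.temperature)


def weight(r, cutoff: float = CUTOFF, temperature: float = 1.0):
    """Annealed redescending weight of a standardized residual.

    Even in ``r``, non-increasing in ``|r|``, strictly between 0 and 1
    (up to floating-point underflow far beyond the cutoff), and exactly
    0.5 at ``|r| = cutoff`` for every temperature.

    Accepts scalars or arrays; returns the matching shape.
    """
    _validate(cutoff, temperature)
    r = np.asarray(r, dtype=float)
    out = expit((cutoff * cutoff - r * r) / (2.0 * temperature))
    return out if out.ndim else float(out)


def psi(r, cutoff: float = CUTOFF, temperature: float = 1.0):
    """Influence function ``psi(r) = r * w(r)``: odd, redescending to zero."""
    w = weight(r, cutoff, temperature)
    r = np.asarray(r, dtype=float)
    out = r * w
    return out if out.ndim else float(out)


def combined_weight(mz, rt, center_mz: float, center_rt: float,
                    tol: ToleranceModel, temperature: float = 1.0):
    """Product of the per-coordinate weights of peaks against a center.

    Each coordinate is standardized with ``sigma = delta / 3`` (the m/z
    half-width evaluated at the center's m/z) and cutoff ``c = 3``, so a
    peak offset by exactly one half-width in a coordinate has ``r = c``
    there and contributes a factor of 0.5.

    ``mz``/``rt`` may be scalars or equal-length arrays.
    """
    if not center_mz > 0:
        raise ValueError(f"center m/z must be > 0, got {center_mz}")
    d1 = float(tol.delta_mz(center_mz))
    r_mz = (np.asarray(mz, dtype=float) - center_mz) * (CUTOFF / d1)
    r_rt = (np.asarray(rt, dtype=float) - center_rt) * (CUTOFF / tol.rt_halfwidth)
    out = weight(r_mz, CUTOFF, temperature) * weight(r_rt, CUTOFF, temperature)
    return out if np.ndim(out) else float(out)
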