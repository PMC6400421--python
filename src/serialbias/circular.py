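"""Circular helpers for orientation data (period 180 degrees).

Orientations live on a half-circle: 0 and 179 degrees are near neighbors.
All signed differences are therefore wrapped to (-90, +90], and circular
means are computed after doubling the angles so that standard directional
statistics apply.
"""
from __future__ import annotations

import numpy as np

DEG = np.pi / 180.0


def wrap_orientation(theta):
    """Wrap orientation(s) to [0, 180)."""
    m = np.mod(theta, 180.0)
    # guard against float rounding pushing a tiny negative onto 180.0 exactly
    return np.where(m >= 180.0, 0.0, m)


def wrap_delta(a, b):
    """Signed circular difference a - b on the orientation circle, in (-90, +90].

    Values exactly at -90 are mapped to +90 (tie-break at the boundary).
    """
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 180.0)
    return np.where(d > 90.0, d - 180.0, d)


def orientation_cos(delta_deg, mapping="double"):
    """Cosine of an orientation difference under a chosen angle mapping.

    mapping="double" maps the 180-degree orientation circle onto the full
    circle (delta -> 2*delta) before taking the cosine, so that wrap-around
    at 0/180 is respected.  mapping="identity" takes cos(delta) directly,
    treating orientation values as angles on a 360-degree circle.
    """
    delta = np.asarray(delta_deg, dtype=float)
    if mapping == "double":
        return np.cos(2.0 * delta * DEG)
    if mapping == "identity":
        return np.cos(delta * DEG)
    raise ValueError(f"unknown angle mapping: {mapping!r}")


def circular_mean_orientation(orientations_deg, weights=None):
    """Weighted circular mean of orientations, computed in doubled-angle space."""
    theta = np.asarray(orientations_deg, dtype=float)
    w = np.ones_like(theta) if weights is None else np.asarray(weights, dtype=float)
    z = np.sum(w * np.exp(2j * theta * DEG))
    if np.abs(z) == 0.0:
        raise ValueError("circular mean undefined: resultant vector has zero length")
    return wrap_orientation(np.angle(z) / 2.0 / DEG)


def beta_to_fwhm(beta, mapping="double"):
    """Full width at half height (orientation degrees) of exp(beta*(cos(delta)-1)).

    Under angle doubling the width in orientation space is half the width of
    the corresponding full-circle profile.
    """
    half = np.arccos(1.0 - np.log(2.0) / beta) / DEG
    return 2.0 * half / (2.0 if mapping == "double" else 1.0)


def fwhm_to_beta(fwhm_deg, mapping="double"):
    """Inverse of :func:`beta_to_fwhm`."""
    half = fwhm_deg / 2.0 * (2.0 if mapping == "double" else 1.0)
    return np.log(2.0) / (1.0 - np.cos(half * DEG))
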