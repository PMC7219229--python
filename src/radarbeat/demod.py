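"""Diagnostic phase demodulation: imbalance compensation + extended DACM.

This reconstructs the chest displacement from I/Q for inspection and
for round-trip checks against the simulator.  The detection path never
uses it -- the detector is calibration-free by design -- so the module
lives off to the side of the pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .signal_core import TimeSeries

__all__ = [
    "Calibration",
    "DisplacementTrace",
    "compensate_imbalance",
    "dacm_demodulate",
    "fit_calibration",
]


class Calibration(NamedTuple):
    """Quadrature front-end calibration: amplitudes, offsets, phase error."""

    A_I: float
    A_Q: float
    DC_I: float
    DC_Q: float
    dphi: float


IDENTITY_CALIBRATION = Calibration(1.0, 1.0, 0.0, 0.0, 0.0)


@dataclass
class DisplacementTrace:
    """Relative displacement (metres), defined up to an additive constant."""

    x: TimeSeries
    lambda_used: float


def compensate_imbalance(i_ch: TimeSeries, q_ch: TimeSeries,
                         calib: Calibration) -> tuple:
    """Remove offsets, equalize amplitudes and orthogonalize the channels.

    With ``I = A_I*cos(p) + DC_I`` and ``Q = A_Q*sin(p + dphi) + DC_Q``
    the corrected pair ``I' = (I-DC_I)/A_I`` and
    ``Q' = ((Q-DC_Q)/A_Q - sin(dphi)*I') / cos(dphi)`` satisfies
    ``I'^2 + Q'^2 = 1`` exactly in the noise-free case.
    """
    a_i, a_q, dc_i, dc_q, dphi = calib
    if abs(np.cos(dphi)) < 1e-6:
        raise ValueError("degenerate phase imbalance: |cos(dphi)| ~ 0")
    ip = (i_ch.values - dc_i) / a_i
    qp = ((q_ch.values - dc_q) / a_q - np.sin(dphi) * ip) / np.cos(dphi)
    return (TimeSeries(ip, i_ch.rate, i_ch.t0),
            TimeSeries(qp, q_ch.rate, q_ch.t0))


def dacm_demodulate(i_ch: TimeSeries, q_ch: TimeSeries,
                    wavelength: float) -> DisplacementTrace:
    """Extended differentiate-and-cross-multiply phase demodulation.

    Integrates the discretized phase derivative

        x_n = (lambda / 4 pi) * sum_{k<=n} (I_k dQ_k - Q_k dI_k) / (I_k^2 + Q_k^2)

    with first differences ``dI_k = I_k - I_{k-1}`` and ``x_0 = 0``.
    Unlike an arctangent demodulator this accumulates phase increments
    and therefore tracks displacements across multiples of lambda/4
    without wrap discontinuities.
    """
    if i_ch.rate != q_ch.rate or len(i_ch) != len(q_ch):
        raise ValueError("channels must share rate and length")
    i = i_ch.values
    q = q_ch.values
    mag2 = i * i + q * q
    if np.any(mag2 < 1e-12):
        raise ValueError("I^2 + Q^2 vanishes: phase undefined")
    dphase = np.zeros(len(i))
    if len(i) > 1:
        dphase[1:] = (i[1:] * np.diff(q) - q[1:] * np.diff(i)) / mag2[1:]
    x = (wavelength / (4 * np.pi)) * np.cumsum(dphase)
    return DisplacementTrace(TimeSeries(x, i_ch.rate, i_ch.t0), wavelength)


def fit_calibration(i_ch: TimeSeries, q_ch: TimeSeries) -> Calibration:
    """Estimate the calibration by a least-squares conic (ellipse) fit.

    The noise-free I/Q locus is the ellipse image of the unit circle
    under ``[[A_I, 0], [A_Q sin(dphi), A_Q cos(dphi)]]`` plus the DC
    offset.  Fitting ``a x^2 + b x y + c y^2 + d x + e y = 1`` by least
    squares, re-centering, and inverting the quadratic form recovers
    amplitudes, offsets and the phase error.  Needs the trajectory to
    sweep a reasonable arc of the ellipse.
    """
    x = i_ch.values
    y = q_ch.values
    if len(x) < 5:
        raise ValueError("need at least 5 samples for the conic fit")
    design = np.column_stack([x * x, x * y, y * y, x, y])
    coef, *_ = np.linalg.lstsq(design, np.ones_like(x), rcond=None)
    a, b, c, d, e = coef
    S = np.array([[a, b / 2], [b / 2, c]])
    center = -0.5 * np.linalg.solve(S, np.array([d, e]))
    radius = 1.0 + center @ S @ center
    if radius <= 0 or np.linalg.det(S) <= 0:
        raise ValueError("conic fit did not produce an ellipse")
    B = np.linalg.inv(S / radius)  # = M M^T for the mixing matrix M
    a_i = float(np.sqrt(B[0, 0]))
    a_q = float(np.sqrt(B[1, 1]))
    sin_dphi = float(np.clip(B[0, 1] / (a_i * a_q), -1.0, 1.0))
    return Calibration(a_i, a_q, float(center[0]), float(center[1]),
                       float(np.arcsin(sin_dphi)))
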