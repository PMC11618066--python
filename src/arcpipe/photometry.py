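"""Isosbestic correction and %dF/F for two-channel fibre photometry.

A GCaMP recording carries a calcium-dependent channel (465 nm excitation)
and a calcium-independent isosbestic channel (405 nm excitation). Bleaching
and movement artifacts are removed by least-squares-fitting a polynomial in
the 405 nm signal to the 465 nm trace (the fitted series is the "405
fitted" reference), after which

    %dF/F = 100 * (F465 - F405_fitted) / F405_fitted.

The corrected trace is then smoothed with a centred moving average and
decimated (default factor 20), the moving average acting as the
anti-aliasing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from arcpipe.errors import (
    ConfigurationError,
    CorrectionInfeasibleError,
    DegenerateInputError,
)


@dataclass
class PhotometrySession:
    """Paired 465/405 nm traces on one uniform timebase.

    ``events`` optionally carries the session's
    :class:`~arcpipe.events.EventSchedule`.
    """

    time: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    sampling_rate: float
    events: Any | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if not (len(self.time) == len(self.f465) == len(self.f405)):
            raise ConfigurationError("time, f465 and f405 must have equal length")
        if len(self.time) < 2:
            raise ConfigurationError("session needs at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ConfigurationError("timebase must be strictly increasing")
        step = 1.0 / self.sampling_rate
        if np.max(np.abs(dt - step)) > 1e-6 * step:
            raise ConfigurationError(
                "sampling_rate inconsistent with time grid (rel. tol. 1e-6)"
            )

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "f465": self.f465, "f405": self.f405}
        )


@dataclass
class CorrectionFit:
    """Polynomial-in-F405 least-squares fit predicting F465.

    ``coefficients`` are in ascending power order (numpy polynomial
    convention): fitted = c0 + c1*F405 + ... + ck*F405**k.
    """

    order: int
    coefficients: np.ndarray
    fitted_405: np.ndarray
    residual_rms: float


@dataclass
class DffTrace:
    """%dF/F series with provenance of the fit/filter parameters."""

    time: np.ndarray
    dff: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if len(self.time) != len(self.dff):
            raise ConfigurationError("time and dff must have equal length")
        if not np.all(np.isfinite(self.dff)):
            raise ConfigurationError("dff contains non-finite values")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "dff_percent": self.dff})


def fit_isosbestic(session: PhotometrySession, order: int = 1) -> CorrectionFit:
    """Least-squares polynomial in F405 predicting F465 over the full recording.

    Parameters
    ----------
    session : PhotometrySession
    order : int
        Polynomial order, >= 1. The default affine fit (order 1) captures
        channel-specific gain plus offset; higher orders accommodate a
        curved channel relation.

    Raises
    ------
    DegenerateInputError
        If F405 is constant (singular design matrix).
    CorrectionInfeasibleError
        If any fitted value is <= 0, which would make the ratiometric
        %dF/F undefined.
    """
    if order < 1:
        raise ConfigurationError("polynomial order must be >= 1")
    x, y = session.f405, session.f465
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant 405 nm channel; fit is singular")
    # centre/scale for conditioning, then map coefficients back
    coeffs = np.polynomial.polynomial.polyfit(x, y, deg=order)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    if np.any(fitted <= 0):
        raise CorrectionInfeasibleError(
            "fitted 405 reference is not strictly positive; baseline too low "
            "for a ratiometric correction"
        )
    rms = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return CorrectionFit(order=order, coefficients=coeffs, fitted_405=fitted,
                         residual_rms=rms)


def compute_dff(session: PhotometrySession, fit: CorrectionFit) -> DffTrace:
    """%dF/F = 100 * (F465 - F405_fitted) / F405_fitted, no filtering."""
    fitted = fit.fitted_405
    if len(fitted) != len(session):
        raise ConfigurationError("fit length does not match session length")
    if np.any(fitted <= 0):
        raise CorrectionInfeasibleError("fitted 405 reference must be > 0")
    dff = 100.0 * (session.f465 - fitted) / fitted
    return DffTrace(
        time=session.time.copy(),
        dff=dff,
        provenance={"fit_order": fit.order, "residual_rms": fit.residual_rms},
    )


def smooth_downsample(
    trace: DffTrace, window_s: float = 1.0, factor: int = 20
) -> DffTrace:
    """Centred moving average (edges shrink to the valid span) then decimation.

    The window width is ``round(window_s * fs)`` samples; decimation keeps
    every ``factor``-th sample starting at index 0.
    """
    if window_s < 0:
        raise ConfigurationError("window_s must be >= 0")
    if factor < 1:
        raise ConfigurationError("factor must be >= 1")
    if factor > len(trace):
        raise ConfigurationError("downsample factor exceeds trace length")
    fs = trace.sampling_rate
    w = int(round(window_s * fs))
    if w > 1:
        smoothed = (
            pd.Series(trace.dff).rolling(window=w, center=True, min_periods=1)
            .mean().to_numpy()
        )
    else:
        smoothed = trace.dff.copy()
    out_time = trace.time[::factor]
    out_dff = smoothed[::factor]
    prov = dict(trace.provenance)
    prov.update({"filter_window_s": window_s, "downsample_factor": factor})
    return DffTrace(time=out_time, dff=out_dff, provenance=prov)


def process_session(
    session: PhotometrySession,
    order: int = 1,
    window_s: float = 1.0,
    factor: int = 20,
) -> DffTrace:
    """Full correction chain: fit -> %dF/F -> moving average -> decimate."""
    fit = fit_isosbestic(session, order=order)
    dff = compute_dff(session, fit)
    return smooth_downsample(dff, window_s=window_s, factor=factor)
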