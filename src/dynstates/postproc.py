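"""Time-course postprocessing: polynomial detrending, outlier replacement
(despiking) and zero-phase low-pass filtering.

Input is a per-subject matrix of network time courses (T time points x N
networks).  The canonical cleaning order is detrend -> despike -> lowpass;
:func:`postprocess` applies all three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy.interpolate import CubicSpline

__all__ = ["TimecourseSet", "CleaningReport", "detrend", "despike", "lowpass", "postprocess"]


@dataclass
class TimecourseSet:
    """One subject's T x N network time courses sampled every ``tr`` seconds."""

    data: np.ndarray
    tr: float
    network_names: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-course data must be 2-D (T x N)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if self.data.shape[1] != len(self.network_names):
            raise ValueError("network_names length must match number of columns")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite values in time courses")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_networks(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "TimecourseSet":
        return TimecourseSet(data=data, tr=self.tr,
                             network_names=list(self.network_names),
                             subject_id=self.subject_id)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.data, columns=self.network_names).to_csv(
            path, sep="\t", index=False, float_format="%.6f"
        )


@dataclass
class CleaningReport:
    """What despiking changed: per-network outlier positions (0-based time
    indices) and, after detrending, the removed trend coefficients."""

    outlier_positions: dict[str, list[int]] = field(default_factory=dict)
    trend_coefficients: dict[str, list[float]] = field(default_factory=dict)
    filter_settings: dict = field(default_factory=dict)

    @property
    def outlier_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.outlier_positions.items()}

    def to_dict(self) -> dict:
        return {
            "outlier_positions": self.outlier_positions,
            "outlier_counts": self.outlier_counts,
            "trend_coefficients": self.trend_coefficients,
            "filter_settings": self.filter_settings,
        }


def _poly_basis(T: int, max_order: int) -> np.ndarray:
    """Orthonormal polynomial basis (Legendre-style via QR) incl. intercept."""
    t = np.linspace(-1.0, 1.0, T)
    V = np.column_stack([t**k for k in range(max_order + 1)])
    Q, _ = np.linalg.qr(V)
    return Q


def detrend(tc: TimecourseSet, max_order: int = 3,
            report: CleaningReport | None = None) -> TimecourseSet:
    """Remove each column's least-squares projection onto polynomials up to
    ``max_order`` (intercept included).  Residuals are exactly orthogonal to
    the polynomial basis; applying twice equals applying once."""
    T = tc.n_timepoints
    if T <= max_order + 1:
        raise ValueError(f"T={T} too short to remove order-{max_order} trends")
    Q = _poly_basis(T, max_order)
    coef = Q.T @ tc.data
    out = tc.data - Q @ coef
    if report is not None:
        for j, name in enumerate(tc.network_names):
            report.trend_coefficients[name] = coef[:, j].tolist()
    return tc.with_data(out)


def despike(
    tc: TimecourseSet,
    mad_threshold: float = 4.0,
    window: int = 11,
    report: CleaningReport | None = None,
) -> tuple[TimecourseSet, CleaningReport]:
    """Flag points deviating from a running median by more than
    ``mad_threshold`` robust SDs and replace them with a cubic-spline fit
    through the clean points.

    The robust scale is the MAD (x1.4826) of the deviations inside a sliding
    window of ``window`` points, floored at the column's global deviation
    MAD.  A flagged point must additionally exceed twice the column's
    overall robust SD, so smooth oscillations (whose running-median
    deviations are tiny but structured) are never despiked — only gross
    outliers relative to the signal's own amplitude are.
    """
    if report is None:
        report = CleaningReport()
    data = tc.data.copy()
    T = tc.n_timepoints
    t = np.arange(T, dtype=float)
    for j, name in enumerate(tc.network_names):
        x = data[:, j]
        med = ndimage.median_filter(x, size=window, mode="reflect")
        dev = x - med
        local_mad = ndimage.median_filter(np.abs(dev), size=window, mode="reflect")
        global_mad = np.median(np.abs(dev))
        scale = 1.4826 * np.maximum(local_mad, global_mad)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(scale > 0, np.abs(dev) / scale, np.where(dev != 0, np.inf, 0.0))
        amplitude_floor = 2.0 * 1.4826 * np.median(np.abs(x - np.median(x)))
        flagged = (ratio > mad_threshold) & (np.abs(dev) > amplitude_floor)
        positions = np.flatnonzero(flagged)
        report.outlier_positions[name] = positions.tolist()
        if positions.size == 0:
            continue
        clean = ~flagged
        if clean.sum() < 4:
            raise ValueError(
                f"network {name!r}: too few clean points ({int(clean.sum())}) to fit spline"
            )
        spline = CubicSpline(t[clean], x[clean])
        data[positions, j] = spline(t[positions])
    return tc.with_data(data), report


def lowpass(
    tc: TimecourseSet,
    cutoff_hz: float = 0.15,
    order: int = 5,
    report: CleaningReport | None = None,
) -> TimecourseSet:
    """Zero-phase Butterworth low-pass (forward-backward, so the effective
    gain at the cutoff is 1/2 rather than 1/sqrt(2)).  DC is preserved.
    Edges are handled by odd-reflection padding of length 3 x order."""
    nyquist = 1.0 / (2.0 * tc.tr)
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency "
            f"{nyquist:.4f} Hz for TR={tc.tr}s"
        )
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    b, a = signal.butter(order, cutoff_hz / nyquist, btype="low")
    out = signal.filtfilt(b, a, tc.data, axis=0, padlen=3 * order)
    if report is not None:
        report.filter_settings = {
            "type": "butterworth-lowpass", "order": order,
            "cutoff_hz": cutoff_hz, "zero_phase": True,
        }
    return tc.with_data(out)


def postprocess(
    tc: TimecourseSet,
    max_order: int = 3,
    mad_threshold: float = 4.0,
    despike_window: int = 11,
    cutoff_hz: float = 0.15,
    filter_order: int = 5,
) -> tuple[TimecourseSet, CleaningReport]:
    """Full cleaning chain: detrend -> despike -> lowpass."""
    report = CleaningReport()
    tc = detrend(tc, max_order=max_order, report=report)
    tc, report = despike(tc, mad_threshold=mad_threshold, window=despike_window, report=report)
    tc = lowpass(tc, cutoff_hz=cutoff_hz, order=filter_order, report=report)
    return tc, report
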