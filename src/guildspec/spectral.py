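"""Pairwise coupling metrics from z-scored abundance series.

Four measures of increasing temporal sophistication:

* ``C0`` — equal-time correlation C_ij(0) = (1/T) sum_t s_i(t) s_j(t);
* ``absC0`` — its absolute value;
* ``total_cpsd`` — the integrated cross-power-spectral-density magnitude
  P_ij = sum_k |P_ij(f_k)| df;
* ``total_coherence`` — the integrated magnitude-squared coherence
  TC_ij = sum_k Coh_ij(f_k) df, with
  Coh_ij = |P_ij|^2 / (P_ii P_jj) in [0, 1].

Spectra are Welch estimates (Hamming window, 50% overlap, per-segment
mean removal); coherence is only meaningful when several segments are
averaged (a single segment gives coherence identically 1).  The
frequency grid runs from 0 to the Nyquist frequency f_max = 1/(2 dt) in
steps of df (default f_max / 15), and the totals are rectangular sums
over all kmax + 1 bins including DC and Nyquist, so the coherence
diagonal equals (kmax + 1) df rather than f_max exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .ecrm import ZScoreSeries

__all__ = [
    "SpectralEstimate",
    "MetricMatrix",
    "METRIC_NAMES",
    "equal_time_corr",
    "cross_correlation",
    "welch_spectra",
    "total_cpsd_magnitude",
    "total_coherence",
    "pairwise_metrics",
    "InsufficientDataError",
]

METRIC_NAMES = ("C0", "absC0", "total_cpsd", "total_coherence")


class InsufficientDataError(ValueError):
    """Series too short for the requested frequency resolution."""


@dataclass
class MetricMatrix:
    """A symmetric species x species matrix for one pairwise measure."""

    values: np.ndarray
    metric: str

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle (i < j) entries as a flat vector."""
        iu, ju = np.triu_indices(self.n_species, k=1)
        return self.values[iu, ju]


@dataclass
class SpectralEstimate:
    """Welch auto-/cross-spectra on the grid f_k = k df, k = 0..kmax."""

    frequencies: np.ndarray
    cpsd: np.ndarray  # (N, N, F) complex, P_ij(f)
    psd: np.ndarray  # (N, F) real, P_ii(f)
    coherence: np.ndarray  # (N, N, F) in [0, 1]
    delta_f: float
    n_segments: int

    @property
    def f_max(self) -> float:
        return float(self.frequencies[-1])


def _scores(s: ZScoreSeries | np.ndarray) -> np.ndarray:
    arr = s.scores if isinstance(s, ZScoreSeries) else np.asarray(s, dtype=float)
    if arr.ndim != 2:
        raise ValueError("need a 2-D species x time array")
    return arr


def equal_time_corr(s: ZScoreSeries | np.ndarray) -> MetricMatrix:
    """Equal-time correlation matrix C(0), normalized by T.

    For z-scored input (population sd) the diagonal is exactly 1.
    """
    arr = _scores(s)
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    c = arr @ arr.T / arr.shape[1]
    return MetricMatrix(values=c, metric="C0")


def cross_correlation(s_i: np.ndarray, s_j: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Time-delayed cross correlation C_ij(tau) for |tau| <= max_lag.

    C_ij(tau) = <s_i(t) s_j(t + tau)>, averaged over the overlapping
    window (T - |tau| terms) to avoid the taper of the biased estimator.
    Returns (lags, values).
    """
    a = np.asarray(s_i, dtype=float)
    b = np.asarray(s_j, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    t = a.size
    if max_lag >= t:
        raise ValueError("max_lag must be smaller than the series length")
    # full[T - 1 + tau] = sum_t s_i(t) s_j(t + tau)
    full = signal.correlate(b, a, mode="full", method="auto")
    lags = np.arange(-max_lag, max_lag + 1)
    counts = t - np.abs(lags)
    values = full[t - 1 + lags] / counts
    return lags, values


def welch_spectra(
    s: ZScoreSeries | np.ndarray,
    sampling_interval: float,
    delta_f: float | None = None,
    window: str = "hamming",
    overlap: float = 0.5,
) -> SpectralEstimate:
    """Welch-averaged auto- and cross-spectra for all species pairs.

    The segment length is round(1 / (delta_f * dt)) samples so the grid
    step equals ``delta_f`` (default f_max / 15).  Requires at least two
    segments' worth of data (T >= 2 * segment length).  One-sided spectra
    with density scaling; per-segment mean removal.
    """
    arr = _scores(s)
    n, t = arr.shape
    fs = 1.0 / sampling_interval
    f_max = fs / 2.0
    if delta_f is None:
        delta_f = f_max / 15.0
    if delta_f <= 0 or delta_f > f_max:
        raise ValueError("delta_f must lie in (0, f_max]")
    nperseg = int(round(1.0 / (delta_f * sampling_interval)))
    if nperseg < 2:
        raise ValueError("frequency resolution too coarse for this sampling interval")
    if t < 2 * nperseg:
        raise InsufficientDataError(
            f"need at least {2 * nperseg} samples for delta_f={delta_f:g} "
            f"at sampling interval {sampling_interval:g}; got {t}"
        )
    noverlap = int(nperseg * overlap)
    n_segments = 1 + (t - nperseg) // (nperseg - noverlap)

    n_freq = nperseg // 2 + 1
    cpsd = np.empty((n, n, n_freq), dtype=complex)
    freqs = None
    for i in range(n):
        freqs, row = signal.csd(
            arr[i][None, :],
            arr,
            fs=fs,
            window=window,
            nperseg=nperseg,
            noverlap=noverlap,
            detrend="constant",
            scaling="density",
            axis=-1,
        )
        cpsd[i] = row
    psd = np.real(cpsd[np.arange(n), np.arange(n)])
    denom = psd[:, None, :] * psd[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        coherence = np.where(denom > 0, np.abs(cpsd) ** 2 / denom, 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)
    actual_df = float(freqs[1] - freqs[0]) if n_freq > 1 else delta_f
    return SpectralEstimate(
        frequencies=freqs,
        cpsd=cpsd,
        psd=psd,
        coherence=coherence,
        delta_f=actual_df,
        n_segments=n_segments,
    )


def total_cpsd_magnitude(est: SpectralEstimate, include_dc: bool = True) -> MetricMatrix:
    """Integrated CPSD magnitude: sum_k |P_ij(f_k)| df.

    ``include_dc=False`` drops the f = 0 bin from the sum (per-segment
    mean removal makes it nearly empty anyway).
    """
    start = 0 if include_dc else 1
    values = np.abs(est.cpsd[..., start:]).sum(axis=-1) * est.delta_f
    return MetricMatrix(values=values, metric="total_cpsd")


def total_coherence(est: SpectralEstimate, include_dc: bool = True) -> MetricMatrix:
    """Integrated coherence: sum_k Coh_ij(f_k) df.

    Rejects single-segment estimates, whose coherence is identically 1.
    """
    if est.n_segments < 2:
        raise ValueError("total coherence needs a Welch estimate with >= 2 segments")
    start = 0 if include_dc else 1
    values = est.coherence[..., start:].sum(axis=-1) * est.delta_f
    return MetricMatrix(values=values, metric="total_coherence")


def pairwise_metrics(
    s: ZScoreSeries | np.ndarray,
    sampling_interval: float,
    delta_f: float | None = None,
) -> dict[str, MetricMatrix]:
    """All four pairwise measures of one series set, keyed by metric name."""
    c0 = equal_time_corr(s)
    est = welch_spectra(s, sampling_interval, delta_f=delta_f)
    return {
        "C0": c0,
        "absC0": MetricMatrix(values=np.abs(c0.values), metric="absC0"),
        "total_cpsd": total_cpsd_magnitude(est),
        "total_coherence": total_coherence(est),
    }
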