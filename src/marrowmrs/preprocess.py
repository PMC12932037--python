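"""Coil combination and frequency/phase alignment of raw MRS averages.

Two steps, applied per contrast before fitting:

* whitened-SVD channel combination: channels are decorrelated with the
  inverse Cholesky factor of the measured channel-noise covariance, the
  rank-1 SVD of the whitened channel-by-time matrix gives the combined
  FID (maximum-SNR linear combination), and a fixed phase convention
  (first point real-positive) is applied;
* spectral registration in the time domain: each average's frequency and
  phase offset relative to a reference average is estimated by nonlinear
  least squares on a signal-dominated early window of the FID and
  removed before averaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .synthetic import SpectrumSeries

__all__ = [
    "CombinationReport",
    "estimate_noise_covariance",
    "wsvd_combine",
    "spectral_register",
    "preprocess_series",
]


@dataclass
class CombinationReport:
    """How a multi-channel FID was collapsed to one channel."""

    weights: np.ndarray  # complex, unit-norm in whitened space
    noise_covariance: np.ndarray
    snr_estimate: float
    phase_convention: str = "first-point-real-positive"
    rank_deficient: bool = False


def estimate_noise_covariance(
    fids: np.ndarray, noise_window: float = 0.25
) -> np.ndarray:
    """Channel noise covariance from the signal-free tail of the FID.

    ``fids`` is (channels, time); ``noise_window`` is the trailing
    fraction of samples used.  Returns the covariance of the real part
    (imaginary part assumed identically distributed).  Warns if the
    window magnitude still trends downward (signal contamination) and if
    the covariance is numerically rank-deficient.
    """
    fids = np.atleast_2d(np.asarray(fids, dtype=complex))
    nt = fids.shape[-1]
    m = int(round(noise_window * nt))
    if m < 128:
        raise ValueError("noise window must contain at least 128 samples")
    tail = fids[:, -m:]
    mags = np.abs(tail).mean(axis=0)
    q = m // 4
    scale = float(np.abs(fids).max())
    if (
        q > 0
        and mags[:q].mean() > 1.5 * max(mags[-q:].mean(), 1e-30)
        and mags[:q].mean() > 1e-9 * scale
    ):
        warnings.warn(
            "noise window magnitude trends downward; it may overlap signal",
            stacklevel=2,
        )
    cov = 0.5 * (np.cov(tail.real) + np.cov(tail.imag))
    cov = np.atleast_2d(cov)
    if np.trace(cov) > 0:
        eigs = np.linalg.eigvalsh(cov)
        if eigs[0] <= 0 or eigs[-1] / max(eigs[0], 1e-300) > 1e8:
            warnings.warn(
                "channel noise covariance is rank-deficient or ill-conditioned",
                stacklevel=2,
            )
    return cov


def _whitener(cov: np.ndarray) -> np.ndarray:
    """Inverse Cholesky factor, regularized; identity for zero covariance."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    n = cov.shape[0]
    tr = np.trace(cov)
    if tr <= 0:
        return np.eye(n)
    eigs = np.linalg.eigvalsh(cov)
    if eigs[0] <= 0 or eigs[-1] / max(eigs[0], 1e-300) > 1e8:
        cov = cov + 1e-8 * (tr / n) * np.eye(n)
    L = np.linalg.cholesky(cov)
    return np.linalg.inv(L)


def wsvd_combine(
    fids: np.ndarray, covariance: np.ndarray | None = None
) -> tuple[np.ndarray, CombinationReport]:
    """Whitened-SVD combination of a (channels, time) FID block."""
    fids = np.atleast_2d(np.asarray(fids, dtype=complex))
    if not np.any(fids):
        raise ValueError("all-zero input cannot be combined")
    if covariance is None:
        covariance = estimate_noise_covariance(fids)
    covariance = np.atleast_2d(np.asarray(covariance, dtype=float))
    # a covariance at numerical-noise level (noiseless data) must not be
    # whitened against: it would rescale each block by an arbitrary factor
    floor = (1e-12 * np.abs(fids).max()) ** 2
    if np.trace(covariance) < floor:
        covariance = np.zeros_like(covariance)
    W = _whitener(covariance)
    Xw = W @ fids
    U, s, Vh = np.linalg.svd(Xw, full_matrices=False)
    combined = s[0] * Vh[0]
    # fixed phase convention: rotate the dominant channel weight so the
    # combined FID's first point is real-positive
    phase = np.angle(combined[0]) if combined[0] != 0 else 0.0
    combined = combined * np.exp(-1j * phase)
    weights = (U[:, 0] * np.exp(1j * phase)).conj() @ W
    rank_def = s.size > 1 and s[0] > 0 and s[1] / s[0] > 0.5
    tail = combined[-combined.size // 4 :]
    noise = float(np.std(tail.real)) or 1.0
    snr = float(np.abs(combined).max() / noise)
    return combined, CombinationReport(
        weights=weights,
        noise_covariance=np.atleast_2d(np.asarray(covariance, dtype=float)),
        snr_estimate=snr,
        rank_deficient=bool(rank_def),
    )


def spectral_register(
    avgs: np.ndarray,
    dwell: float,
    reference: int | str = "first",
    window_s: float = 0.2,
    max_nfev: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align averages to a reference by time-domain least squares.

    ``avgs`` is (n_averages, time).  Returns ``(aligned, shifts,
    converged)`` where ``shifts[a] = (df_hz, dphi_deg)`` is the estimated
    drift of average ``a`` (the correction applied is its negative).
    Non-converged averages are flagged and passed through unaligned.
    """
    avgs = np.atleast_2d(np.asarray(avgs, dtype=complex))
    na, nt = avgs.shape
    if na < 2:
        raise ValueError("at least two averages required for registration")
    ref_idx = 0 if reference == "first" else int(reference)
    ref = avgs[ref_idx]
    t = np.arange(nt) * dwell
    win = t <= window_s
    tw, refw = t[win], ref[win]

    aligned = np.empty_like(avgs)
    shifts = np.zeros((na, 2))
    converged = np.ones(na, dtype=bool)
    npad = 8 * tw.size  # zero-padded correlation grid for the coarse search
    fgrid = np.fft.fftfreq(npad, dwell)
    for a in range(na):
        if a == ref_idx:
            aligned[a] = avgs[a]
            continue
        x = avgs[a][win]

        # coarse init: x * conj(ref) oscillates at the frequency offset;
        # its FFT peak locates df to a fraction of a bin, avoiding local
        # minima of the least-squares cost at large offsets
        g = x * np.conj(refw)
        df0 = float(fgrid[np.argmax(np.abs(np.fft.fft(g, npad)))])
        phi0 = float(np.angle(np.sum(g * np.exp(-2j * math.pi * df0 * tw))))

        def resid(p):
            m = x * np.exp(-1j * (2.0 * math.pi * p[0] * tw + p[1]))
            d = m - refw
            return np.concatenate([d.real, d.imag])

        sol = least_squares(resid, x0=[df0, phi0], max_nfev=max_nfev)
        if not sol.success:
            converged[a] = False
            aligned[a] = avgs[a]
            continue
        df, dphi = sol.x
        shifts[a] = (df, math.degrees(dphi))
        aligned[a] = avgs[a] * np.exp(-1j * (2.0 * math.pi * df * t + dphi))
    return aligned, shifts, converged


def preprocess_series(
    series: SpectrumSeries,
    register: bool = True,
    noise_window: float = 0.25,
) -> tuple[np.ndarray, list[CombinationReport], np.ndarray]:
    """Combine channels, align and average each contrast of a series.

    Returns ``(fids, reports, shifts)`` with ``fids`` of shape
    (n_contrast, n_points), one combination report per contrast (the
    report of the first average's combination) and the per-average
    registration shifts, shape (n_contrast, n_averages, 2).
    """
    nc_contrast = series.contrasts.size
    out = np.empty((nc_contrast, series.n_points), dtype=complex)
    reports: list[CombinationReport] = []
    shifts = np.zeros((nc_contrast, series.n_averages, 2))
    for i in range(nc_contrast):
        block = series.fids[i]  # (channels, averages, time)
        if series.n_channels > 1:
            # covariance from the signal-free FID tails, pooled over averages
            m = int(round(noise_window * series.n_points))
            tails = block[:, :, -m:].reshape(series.n_channels, -1)
            cov = estimate_noise_covariance(tails, noise_window=1.0)
            combined = np.empty((series.n_averages, series.n_points), dtype=complex)
            rep = None
            for a in range(series.n_averages):
                combined[a], r = wsvd_combine(block[:, a, :], cov)
                rep = rep or r
            reports.append(rep)
        else:
            combined = block[0].copy()
            reports.append(
                CombinationReport(
                    weights=np.ones(1, dtype=complex),
                    noise_covariance=np.atleast_2d(
                        estimate_noise_covariance(
                            block.reshape(1, -1), noise_window
                        )
                    ),
                    snr_estimate=float("nan"),
                )
            )
        if register and series.n_averages > 1:
            combined, shifts[i], _ = spectral_register(combined, series.acq.dwell)
        out[i] = combined.mean(axis=0)
    return out, reports, shifts
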