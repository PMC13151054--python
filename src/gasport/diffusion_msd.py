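"""Mean squared displacement and the subdiffusion exponent α.

MSD(Δ) = ⟨|x(t+Δ) − x(t)|²⟩ is time-averaged over all overlapping origins
(FFT-based, O(n log n) per molecule) and ensemble-averaged over molecules.
The exponent α is the least-squares slope of log MSD versus log Δ over a
fit window; free diffusion gives MSD = 6DΔ and α = 1, while cavity trapping
pushes α below 1 at intermediate lags — the caveat that MSM timescales for
trapped gases inherit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import RelativeTrajectory

__all__ = ["MSDResult", "msd_alpha", "ensemble_msd"]


@dataclass
class MSDResult:
    """MSD curve plus the fitted power-law exponent."""

    lags: np.ndarray  # ps, lag 0 included (MSD(0) = 0)
    msd: np.ndarray  # Å²
    alpha: float  # slope of log MSD vs log lag over the fit window
    alpha_se: float
    fit_window: tuple[float, float]  # ps
    ensemble: bool = True


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Time-averaged MSD for one molecule, positions (n, 3).

    MSD(k) = S1(k) − 2 S2(k) with S2 the positional autocorrelation
    (computed by FFT) and S1 by the standard backward recursion over the
    squared norms.
    """
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    sq = np.sum(x**2, axis=1)
    counts = n - np.arange(n)
    S2 = np.zeros(n)
    for d in range(3):
        f = np.fft.rfft(x[:, d], nfft)
        S2 += np.fft.irfft(f * np.conj(f), nfft)[:n]
    S2 /= counts
    D = np.append(sq, 0.0)
    S1 = np.empty(n)
    Q = 2.0 * sq.sum()
    for k in range(n):
        Q -= D[k - 1] + D[n - k]
        S1[k] = Q / (n - k)
    return S1 - 2.0 * S2


def ensemble_msd(traj: RelativeTrajectory, max_lag: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Lags (ps) and ensemble/time-averaged MSD (Å²)."""
    n = traj.n_frames
    if max_lag is None:
        max_lag = (n - 1) * traj.stride
    k_max = int(round(max_lag / traj.stride))
    if not 1 <= k_max <= n - 1:
        raise ValueError("max_lag must be positive and below the trajectory length")
    msd = np.zeros(n)
    for mi in range(traj.n_molecules):
        msd += _msd_fft(traj.positions[:, mi, :])
    msd /= traj.n_molecules
    lags = np.arange(n) * traj.stride
    return lags[: k_max + 1], msd[: k_max + 1]


def msd_alpha(
    traj: RelativeTrajectory,
    max_lag: float | None = None,
    fit_window: tuple[float, float] | None = None,
) -> MSDResult:
    """MSD curve and fitted subdiffusion exponent.

    The default fit window is one decade centered at the geometric mean of
    the available (nonzero) lags.  An immobile trajectory (MSD ≡ 0) has no
    defined exponent and raises ``ValueError``.
    """
    lags, msd = ensemble_msd(traj, max_lag)
    if np.allclose(msd, 0.0):
        raise ValueError("MSD is identically zero (immobile particles); α undefined")
    if fit_window is None:
        lo_all, hi_all = lags[1], lags[-1]
        center = np.sqrt(lo_all * hi_all)
        fit_window = (center / np.sqrt(10.0), center * np.sqrt(10.0))
    lo, hi = fit_window
    sel = (lags >= lo) & (lags <= hi) & (lags > 0) & (msd > 0)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 MSD points in the fit window")
    X = np.log(lags[sel])
    Y = np.log(msd[sel])
    A = np.vstack([X, np.ones_like(X)]).T
    coef, res, *_ = np.linalg.lstsq(A, Y, rcond=None)
    alpha = float(coef[0])
    dof = sel.sum() - 2
    if dof > 0 and res.size:
        s2 = float(res[0]) / dof
        sxx = float(np.sum((X - X.mean()) ** 2))
        alpha_se = np.sqrt(s2 / sxx)
    else:
        alpha_se = float("nan")
    return MSDResult(
        lags=lags, msd=msd, alpha=alpha, alpha_se=alpha_se, fit_window=(lo, hi)
    )
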