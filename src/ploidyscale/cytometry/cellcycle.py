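"""Dean-Jett-Fox deconvolution of DNA-content histograms.

The DNA (Hoechst) histogram is modeled as the sum of a Gaussian G0/G1
peak, a Gaussian G2/M peak, and an S-phase component: a second-order
polynomial of underlying DNA content between the two peak means,
convolved with the G1 Gaussian width (the classical Dean-Jett-Fox
formulation).  Following the "no synchronized peak, no peak
constraints" setting, the G2/M mean is initialized at twice the G1
mean but left free during the fit.

Fractions are component areas over the total fitted area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal


class CellCycleFitError(RuntimeError):
    pass


@dataclass
class DJFConfig:
    n_bins: int = 256
    upper_percentile: float = 99.9   # histogram upper bound, excludes aggregates
    n_s_grid: int = 64               # quadrature nodes for the S convolution
    min_events_warn: int = 1000
    # ridge penalty on the S polynomial coefficients (on the G1-normalized
    # axis): breaks the degeneracy where an S spike at the support edge
    # mimics a peak flank, while leaving a genuine broad S essentially
    # unshrunk (its coefficients are an order of magnitude smaller)
    s_ridge: float = 0.1


@dataclass
class CellCycleFit:
    g1_mean: float
    g1_sigma: float
    g2_mean: float
    g2_sigma: float
    s_coeffs: np.ndarray          # polynomial coefficients on normalized [0,1]
    weights: dict                 # {"g0g1", "s", "g2m"} fractions, sum 1
    rss: float
    n_events: int
    bin_centers: np.ndarray
    histogram: np.ndarray
    model: np.ndarray


def _gauss(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


def _s_component(x, mu1, mu2, sigma, coeffs, n_grid):
    """Quadratic S density between the peaks, broadened by the G1 width.

    The broadening width grows proportionally with DNA content
    (sigma(u) = sigma_G1 * u / mu1), matching the constant-CV noise of
    DNA-dye measurements: the G2 peak is twice as wide as G1 on a
    linear axis.
    """
    u = np.linspace(mu1, mu2, n_grid)
    t = (u - mu1) / max(mu2 - mu1, 1e-12)
    q = coeffs[0] + coeffs[1] * t + coeffs[2] * t * t
    q = np.clip(q, 0.0, None)
    du = (mu2 - mu1) / (n_grid - 1)
    # x (bins) by u (grid) kernel matrix
    sig_u = sigma * u / max(mu1, 1e-12)
    k = _gauss(x[:, None], u[None, :], sig_u[None, :])
    return (k * q[None, :]).sum(axis=1) * du


def _locate_g1(centers, counts):
    smooth = signal.savgol_filter(counts.astype(float), 11, 3, mode="interp")
    peaks, props = signal.find_peaks(smooth, prominence=smooth.max() * 0.05)
    if len(peaks) == 0:
        raise CellCycleFitError("failed to locate a G1 mode in the DNA histogram")
    # G0/G1 is the dominant mode in brain tissue
    return float(centers[peaks[np.argmax(smooth[peaks])]])


def fit_djf(hoechst_values: np.ndarray, cfg: DJFConfig | None = None) -> CellCycleFit:
    """Fit the DJF model to raw Hoechst intensities by bounded least squares."""
    cfg = cfg or DJFConfig()
    x = np.asarray(hoechst_values, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < cfg.min_events_warn:
        warnings.warn(f"only {len(x)} events; DJF fit may be unstable")
    if len(x) < 10:
        raise CellCycleFitError("too few events for a DJF fit")

    hi = np.percentile(x, cfg.upper_percentile)
    counts, edges = np.histogram(x[x <= hi], bins=cfg.n_bins, range=(0.0, hi))
    raw_centers = 0.5 * (edges[:-1] + edges[1:])
    raw_width = edges[1] - edges[0]

    mu1_raw = _locate_g1(raw_centers, counts)
    # fit on the G1-normalized axis z = x / mu1_raw (density order 1)
    scale = mu1_raw
    centers = raw_centers / scale
    width = raw_width / scale
    density = counts / counts.sum() / width

    mu1_0, sigma_0, mu2_0 = 1.0, 0.05, 2.0

    def model(theta):
        a1, mu1, s1, a2, mu2, s2, c0, c1, c2 = theta
        y = a1 * _gauss(centers, mu1, s1) + a2 * _gauss(centers, mu2, s2)
        y = y + _s_component(centers, mu1, mu2, s1, (c0, c1, c2), cfg.n_s_grid)
        return y

    def resid(theta):
        return np.concatenate([model(theta) - density, cfg.s_ridge * theta[6:9]])

    theta0 = np.array([0.7, mu1_0, sigma_0, 0.1, mu2_0, sigma_0 * 2.0,
                       0.05, 0.0, 0.0])
    lo = np.array([0.0, 0.7, sigma_0 * 0.2, 0.0, 1.2, sigma_0 * 0.2,
                   0.0, -np.inf, -np.inf])
    hi_b = np.array([np.inf, 1.3, sigma_0 * 5.0, np.inf, 3.0, sigma_0 * 10.0,
                     np.inf, np.inf, np.inf])
    sol = optimize.least_squares(resid, theta0, bounds=(lo, hi_b), xtol=1e-12, ftol=1e-12)
    a1, mu1, s1, a2, mu2, s2, c0, c1, c2 = sol.x

    # component areas on the fitted support
    s_area = float(_s_component(centers, mu1, mu2, s1, (c0, c1, c2), cfg.n_s_grid).sum() * width)
    g1_area = float(a1 * _gauss(centers, mu1, s1).sum() * width)
    g2_area = float(a2 * _gauss(centers, mu2, s2).sum() * width)
    total = g1_area + s_area + g2_area
    if total <= 0:
        raise CellCycleFitError("degenerate DJF fit: zero total area")
    weights = {"g0g1": g1_area / total, "s": s_area / total, "g2m": g2_area / total}

    return CellCycleFit(
        g1_mean=float(mu1 * scale), g1_sigma=float(s1 * scale),
        g2_mean=float(mu2 * scale), g2_sigma=float(s2 * scale),
        s_coeffs=np.array([c0, c1, c2]),
        weights=weights,
        rss=float(np.sum((model(sol.x) - density) ** 2)),
        n_events=len(x),
        bin_centers=raw_centers, histogram=density / scale, model=model(sol.x) / scale,
    )
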