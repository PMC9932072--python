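"""EMCCD noise model and photon-count calibration.

The electron-multiplying gain register of an EMCCD turns each photoelectron
into an approximately exponentially distributed number of output electrons,
so the camera output for a pixel receiving a Poisson number of photons is a
Poisson-weighted mixture of Erlang (Gamma) distributions on top of a
factory offset ``s0``:

    p(s | s0, gamma, E) = delta(s - s0) * exp(-E)
        + sqrt(gamma * E / x) * exp(-gamma * x - E) * I1(2 * sqrt(gamma * E * x))

with ``x = s - s0`` the offset-corrected count, ``gamma`` the inverse gain
(photons per count) and ``E`` the expected photon number.  The delta term is
the zero-photon event.  Fitting this three-parameter density to the count
histograms of particle-free pixels yields ``s0`` and ``gamma``, after which
any count converts to photons by ``n = (s - <s0>) * <gamma>``.

The continuous part is evaluated on the offset-corrected argument; only that
convention satisfies the zero-photon limit and the mean identity
``<s> = s0 + E / gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "CameraModel",
    "PixelHistogram",
    "PixelFit",
    "pixel_pdf",
    "pixel_cdf",
    "sample_counts",
    "histogram_pixel",
    "fit_pixel",
    "calibrate",
    "to_photons",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CameraModel:
    """Calibrated EMCCD parameters averaged over accepted pixel fits."""

    s0: float
    gamma: float
    E: float = np.nan
    n_pixels_fit: int = 0
    n_pixels_accepted: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.n_pixels_accepted > self.n_pixels_fit:
            raise ValueError("accepted fits cannot exceed attempted fits")

    def to_dict(self) -> dict:
        return {
            "s0": float(self.s0),
            "gamma": float(self.gamma),
            "E": float(self.E),
            "n_pixels_fit": int(self.n_pixels_fit),
            "n_pixels_accepted": int(self.n_pixels_accepted),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            s0=float(d["s0"]),
            gamma=float(d["gamma"]),
            E=float(d.get("E", np.nan)),
            n_pixels_fit=int(d.get("n_pixels_fit", 0)),
            n_pixels_accepted=int(d.get("n_pixels_accepted", 0)),
        )


@dataclass
class PixelHistogram:
    """Integer-count histogram of one pixel across all frames."""

    bin_edges: np.ndarray  # half-integer edges, len = nbins + 1
    frequencies: np.ndarray  # int, len = nbins
    pixel_xy: tuple[int, int] = (0, 0)

    @property
    def n_obs(self) -> int:
        return int(self.frequencies.sum())


@dataclass
class PixelFit:
    s0: float
    gamma: float
    E: float
    chi2: float
    dof: int
    pvalue: float
    ok: bool
    message: str = ""


# ---------------------------------------------------------------------------
# density


def _poisson_weights(E: float, kmax: int) -> np.ndarray:
    k = np.arange(1, kmax + 1)
    return stats.poisson.pmf(k, E)


def _kmax(E: float) -> int:
    return int(max(20, np.ceil(E + 10.0 * np.sqrt(max(E, 1.0)) + 10)))


def pixel_pdf(s, s0: float, gamma: float, E: float):
    """Continuous part of the pixel-count density at counts ``s``.

    The zero-photon delta mass ``exp(-E)`` at ``s == s0`` is not included in
    the returned array (it is not a density value); use :func:`pixel_cdf`
    for probabilities of count intervals.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if E < 0:
        raise ValueError("E must be non-negative")
    s = np.asarray(s, dtype=float)
    x = s - s0
    out = np.zeros_like(x)
    pos = x > 0
    if E > 0 and np.any(pos):
        xp = x[pos]
        z = 2.0 * np.sqrt(gamma * E * xp)
        # I1(z) = i1e(z) * exp(z); keep everything in the exponent for stability
        out[pos] = (
            np.sqrt(gamma * E / xp)
            * special.i1e(z)
            * np.exp(z - gamma * xp - E)
        )
    return out


def pixel_cdf(s, s0: float, gamma: float, E: float):
    """P(count <= s) under the Poisson-Erlang camera model.

    Computed as the Poisson mixture of Gamma CDFs,
    ``exp(-E) * 1[x >= 0] + sum_k pois(k; E) * P(Gamma(k, gamma) <= x)``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if E < 0:
        raise ValueError("E must be non-negative")
    s = np.asarray(s, dtype=float)
    x = s - s0
    out = np.where(x >= 0, np.exp(-E), 0.0).astype(float)
    if E > 0:
        kmax = _kmax(E)
        w = _poisson_weights(E, kmax)  # (kmax,)
        pos = x > 0
        if np.any(pos):
            k = np.arange(1, kmax + 1)[:, None]
            g = special.gammainc(k, gamma * x[pos][None, :])  # regularized
            out[pos] += w @ g
    return out


def sample_counts(E, s0: float, gamma: float, rng: np.random.Generator):
    """Sample raw camera counts: ``s = s0 + Gamma(shape=Poisson(E), rate=gamma)``.

    Zero Poisson draws collapse to exactly ``s0``.  ``E`` may be an array
    of per-pixel photon expectations; the output has the same shape.
    """
    E = np.asarray(E, dtype=float)
    n = rng.poisson(E)
    out = np.full(E.shape, float(s0))
    hot = n > 0
    if np.any(hot):
        out[hot] += rng.gamma(shape=n[hot], scale=1.0 / gamma)
    return out


# ---------------------------------------------------------------------------
# fitting


def histogram_pixel(values: np.ndarray, pixel_xy: tuple[int, int] = (0, 0)) -> PixelHistogram:
    """Integer-count histogram with half-integer bin edges."""
    values = np.asarray(values)
    v = np.round(values).astype(int)
    lo, hi = v.min(), v.max()
    edges = np.arange(lo - 0.5, hi + 1.5)
    freq, _ = np.histogram(v, bins=edges)
    return PixelHistogram(bin_edges=edges, frequencies=freq, pixel_xy=pixel_xy)


def _moment_init(hist: PixelHistogram) -> tuple[float, float, float]:
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    f = hist.frequencies
    n = f.sum()
    mean = float((centers * f).sum() / n)
    var = float((((centers - mean) ** 2) * f).sum() / n)
    # delta spike sits at the histogram minimum when E is moderate
    s0 = float(centers[np.argmax(f > 0)])
    excess = max(mean - s0, 1e-6)
    gamma = max(2.0 * excess / max(var, 1e-9), 1e-6)
    E = gamma * excess
    return s0, gamma, E


def _merge_bins(edges: np.ndarray, freq: np.ndarray, probs: np.ndarray, n: int,
                min_expected: float = 5.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedily merge adjacent integer bins until expected count >= min_expected."""
    new_edges = [edges[0]]
    new_freq, new_prob = [], []
    acc_f = 0
    acc_p = 0.0
    for i in range(len(freq)):
        acc_f += freq[i]
        acc_p += probs[i]
        if acc_p * n >= min_expected:
            new_edges.append(edges[i + 1])
            new_freq.append(acc_f)
            new_prob.append(acc_p)
            acc_f, acc_p = 0, 0.0
    if acc_f > 0 or acc_p > 0:
        # fold the remainder into the last bin
        if new_freq:
            new_edges[-1] = edges[-1]
            new_freq[-1] += acc_f
            new_prob[-1] += acc_p
        else:
            new_edges.append(edges[-1])
            new_freq.append(acc_f)
            new_prob.append(acc_p)
    return np.asarray(new_edges), np.asarray(new_freq), np.asarray(new_prob)


def fit_pixel(hist: PixelHistogram) -> PixelFit:
    """Minimum-chi-square fit of the camera density to one pixel histogram.

    Integer-count bins are merged until the expected count per bin (under a
    moment-based initial estimate) is at least 5, the zero-photon spike being
    naturally captured by the bin containing ``s0``.  The p-value uses
    ``bins - 3 - 1`` degrees of freedom.
    """
    n = hist.n_obs
    if n < 100:
        raise ValueError("need at least 100 observations per pixel")
    if len(hist.frequencies) < 2 or np.count_nonzero(hist.frequencies) < 2:
        return PixelFit(np.nan, np.nan, np.nan, np.nan, 0, 0.0, False,
                        "degenerate histogram")
    s0_0, g_0, E_0 = _moment_init(hist)

    p0 = np.diff(pixel_cdf(hist.bin_edges, s0_0, g_0, E_0))
    # keep the chi-square valid (expected >= 5) while capping the bin count
    # so the per-pixel fit stays cheap
    min_expected = max(5.0, n / 80.0)
    edges, freq, _ = _merge_bins(hist.bin_edges, hist.frequencies, p0, n,
                                 min_expected=min_expected)
    if len(freq) < 5:
        return PixelFit(np.nan, np.nan, np.nan, np.nan, 0, 0.0, False,
                        "too few bins after merging")

    scale = np.array([max(abs(s0_0), 1.0), g_0, E_0])

    def chi2_stat(theta: np.ndarray) -> float:
        s0, g, E = theta * scale
        if g <= 0 or E <= 0:
            return 1e12
        cdf = pixel_cdf(edges, s0, g, E)
        p = np.diff(cdf)
        # open tails: fold the untouched probability mass into the end bins
        p = p.copy()
        p[0] += cdf[0]
        p[-1] += 1.0 - cdf[-1]
        exp = n * p
        bad = exp <= 1e-12
        if np.any(bad & (freq > 0)):
            return 1e12
        keep = ~bad
        return float((((freq - exp) ** 2)[keep] / exp[keep]).sum())

    from scipy.optimize import minimize

    res = minimize(chi2_stat, x0=np.ones(3), method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-6, "maxiter": 2000})
    s0, g, E = res.x * scale
    dof = len(freq) - 3 - 1
    chi2 = float(res.fun)
    pvalue = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 0.0
    ok = bool(res.success or chi2 < 1e11) and g > 0 and E > 0 and dof > 0
    return PixelFit(float(s0), float(g), float(E), chi2, dof, pvalue, ok,
                    "" if ok else "optimizer failure")


def calibrate(control_movie, n_pixels: int = 400, seed: int = 0,
              p_threshold: float = 0.01) -> CameraModel:
    """Fit the camera model on random pixels of a particle-free stack.

    ``n_pixels`` random pixels are selected without replacement, each fit by
    minimum chi-square, and ``s0`` and ``gamma`` averaged over fits with
    goodness p-value above ``p_threshold`` (default 1%).  Fewer than 10
    accepted fits makes the calibration unusable and raises.
    """
    data = np.asarray(getattr(control_movie, "data", control_movie))
    if data.ndim != 3:
        raise ValueError("control movie must be a (frames, H, W) stack")
    frames, H, W = data.shape
    rng = np.random.default_rng(seed)
    n_avail = H * W
    n_sel = min(n_pixels, n_avail)
    flat = rng.choice(n_avail, size=n_sel, replace=False)
    ys, xs = np.unravel_index(flat, (H, W))

    s0s, gammas, Es = [], [], []
    n_fit = 0
    for y, x in zip(ys, xs):
        hist = histogram_pixel(data[:, y, x], pixel_xy=(int(x), int(y)))
        try:
            fit = fit_pixel(hist)
        except ValueError:
            continue
        n_fit += 1
        if fit.ok and fit.pvalue > p_threshold:
            s0s.append(fit.s0)
            gammas.append(fit.gamma)
            Es.append(fit.E)
    if len(s0s) < 10:
        raise RuntimeError(
            f"camera calibration unusable: only {len(s0s)} of {n_fit} pixel "
            f"fits accepted (p > {p_threshold})"
        )
    return CameraModel(
        s0=float(np.mean(s0s)),
        gamma=float(np.mean(gammas)),
        E=float(np.mean(Es)),
        n_pixels_fit=n_fit,
        n_pixels_accepted=len(s0s),
    )


def to_photons(s, model: CameraModel):
    """Convert raw counts to photons: ``n = (s - <s0>) * <gamma>``.

    Applied elementwise; negative photon values are legitimate noise
    fluctuations around zero and are kept.
    """
    return (np.asarray(s, dtype=float) - model.s0) * model.gamma
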