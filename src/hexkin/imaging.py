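"""From photon-calibrated movies to background-corrected particle traces.

Stages, in pipeline order: estimate the Gaussian illumination profile from
the time-averaged movie, divide it out, detect diffraction-limited spots on
the time average (band-pass + local maxima, integrated-mass threshold),
refine each candidate with a least-squares 2-D Gaussian fit, integrate a
circular 9-pixel-diameter ROI per frame with baseline subtraction
(``f = sum(s) - b * N_pixels``), and apply the aggregate / bleaching /
blinking quality controls.

Conventions: coordinates are 0-based with pixel centers at integers and the
origin at the top-left; the temporal smoothing used to boost detection
contrast is never applied to the frames used for photometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

__all__ = [
    "Movie",
    "IlluminationProfile",
    "ParticleLocation",
    "PhotonTrace",
    "estimate_illumination",
    "correct_movie",
    "locate_particles",
    "extract_trace",
    "qc_traces",
    "bleach_blink_qc",
    "roi_mask",
    "locations_to_frame",
]


@dataclass
class Movie:
    """Image stack with its acquisition frame interval.

    ``units`` records whether pixel values are raw camera counts or
    calibrated photons.
    """

    data: np.ndarray  # (frames, H, W)
    frame_interval: float = 0.15
    units: str = "counts"  # "counts" | "photons"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("movie must be a non-empty (frames, H, W) stack")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class IlluminationProfile:
    profile: np.ndarray  # (H, W), strictly positive
    smoothing_sigma: float = 30.0

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if np.any(self.profile <= 0):
            raise ValueError("illumination profile must be strictly positive")


@dataclass
class ParticleLocation:
    x: float  # sub-pixel, 0-based, pixel centers at integers
    y: float
    amplitude: float  # peak height of the fitted Gaussian (photons)
    sigma_x: float
    sigma_y: float
    baseline: float  # b, used for ROI background subtraction
    mass: float  # integrated photons 2*pi*A*sx*sy
    roundness: float  # max(sx, sy) / min(sx, sy)
    particle_id: int = -1

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("fitted widths must be positive")


@dataclass
class PhotonTrace:
    particle: ParticleLocation
    photons: np.ndarray  # per-frame background-corrected photon counts
    frame_interval: float = 0.15
    qc_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.photons = np.asarray(self.photons, dtype=float)


# ---------------------------------------------------------------------------
# illumination


def estimate_illumination(movie: Movie, smoothing_sigma: float = 30.0) -> IlluminationProfile:
    """Gaussian-smoothed time average as the illumination profile.

    The wide smoothing kernel (sigma = 30 px by default, reflective
    boundaries) suppresses particle-scale structure, leaving the
    slowly-varying excitation profile.
    """
    avg = movie.data.mean(axis=0)
    prof = ndimage.gaussian_filter(avg, sigma=smoothing_sigma, mode="reflect")
    if np.any(prof <= 0):
        raise ValueError("non-positive illumination profile; check input movie")
    return IlluminationProfile(profile=prof, smoothing_sigma=smoothing_sigma)


def correct_movie(movie: Movie, profile: IlluminationProfile,
                  temporal_sigma: float = 3.0,
                  renormalize: bool = True) -> tuple[Movie, Movie]:
    """Divide out the illumination profile; return (photometry, detection) movies.

    With ``renormalize`` (default) the division is rescaled by the profile
    maximum, so pixel values stay in photon units referenced to the
    illumination peak — a spot of N detected photons at the peak still
    reads N photons after correction, and equally bright spots anywhere in
    the field read the same.  ``renormalize=False`` gives the bare
    pixelwise division (values relative to the local profile).

    The first returned movie is the corrected stack used for photometry;
    the second additionally has a Gaussian temporal smoothing
    (sigma = 3 frames by default) that sharpens detection contrast but
    would distort dwell kinetics if used for photometry.
    """
    if profile.profile.shape != movie.frame_shape:
        raise ValueError("profile shape does not match movie frames")
    if np.any(profile.profile <= 0):
        raise ValueError("cannot divide by a non-positive profile")
    scale = float(profile.profile.max()) if renormalize else 1.0
    corrected = movie.data * (scale / profile.profile[None, :, :])
    photometry = Movie(corrected, movie.frame_interval, movie.units)
    if temporal_sigma > 0 and movie.n_frames > 1:
        det = ndimage.gaussian_filter1d(corrected, sigma=temporal_sigma, axis=0,
                                        mode="reflect")
    else:
        det = corrected.copy()
    detection = Movie(det, movie.frame_interval, movie.units)
    return photometry, detection


# ---------------------------------------------------------------------------
# localization


def _bandpass(img: np.ndarray, short_sigma: float, long_size: int) -> np.ndarray:
    """Difference of a short-scale Gaussian and a long-scale boxcar; the
    standard single-particle band-pass that flattens background and keeps
    diffraction-limited peaks."""
    smooth = ndimage.gaussian_filter(img, short_sigma, mode="reflect")
    background = ndimage.uniform_filter(img, size=long_size, mode="reflect")
    out = smooth - background
    out[out < 0] = 0.0
    return out


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dx**2 + dy**2 <= radius**2
    return dy[keep], dx[keep]


def roi_mask(radius: float = 4.5) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel offsets of the circular ROI (default: 69 pixels for the
    9-pixel-diameter aperture)."""
    return _disk_offsets(radius)


def _gauss2d_residual(theta, xs, ys, z):
    x0, y0, amp, sx, sy, b = theta
    model = b + amp * np.exp(-((xs - x0) ** 2) / (2 * sx**2)
                             - ((ys - y0) ** 2) / (2 * sy**2))
    return (model - z).ravel()


def _refine_gaussian(avg: np.ndarray, x0: int, y0: int, window: int,
                     psf_guess: float) -> tuple | None:
    H, W = avg.shape
    half = window // 2
    if not (half <= x0 < W - half and half <= y0 < H - half):
        return None
    sub = avg[y0 - half:y0 + half + 1, x0 - half:x0 + half + 1]
    ys, xs = np.mgrid[y0 - half:y0 + half + 1, x0 - half:x0 + half + 1]
    b0 = float(np.percentile(sub, 20))
    a0 = max(float(sub.max() - b0), 1e-6)
    theta0 = [x0, y0, a0, psf_guess, psf_guess, b0]
    lb = [x0 - half, y0 - half, 0.0, 0.3, 0.3, -np.inf]
    ub = [x0 + half, y0 + half, np.inf, window, window, np.inf]
    try:
        res = optimize.least_squares(_gauss2d_residual, theta0, args=(xs, ys, sub),
                                     bounds=(lb, ub), max_nfev=400)
    except Exception:
        return None
    if not np.all(np.isfinite(res.x)):
        return None
    return tuple(res.x)


def locate_particles(detection_movie: Movie, diameter: int = 11,
                     separation: int = 6, minmass_factor: float = 0.4,
                     roundness_window: tuple[float, float] = (1.0, 1.6),
                     psf_sigma_guess: float = 1.5) -> list[ParticleLocation]:
    """Detect and sub-pixel-refine immobile spots on the time-averaged movie.

    Candidates are local maxima of the band-passed average separated by at
    least ``separation`` pixels; candidates whose integrated mass within a
    ``diameter``-wide disk falls below ``minmass_factor`` times the mean of
    the averaged movie are discarded; survivors are refined with a 2-D
    Gaussian least-squares fit, and fits whose axial ratio falls outside
    ``roundness_window`` (merged or distorted spots) are rejected.
    """
    avg = detection_movie.data.mean(axis=0)
    H, W = avg.shape
    bp = _bandpass(avg, short_sigma=psf_sigma_guess, long_size=diameter)
    from skimage.feature import peak_local_max

    thresh = bp.max() * 0.05 if bp.max() > 0 else 0.0
    peaks = peak_local_max(bp, min_distance=separation, threshold_abs=thresh,
                           exclude_border=diameter // 2)
    if len(peaks) == 0:
        return []
    minmass = float(avg.mean()) * minmass_factor
    dy, dx = _disk_offsets(diameter / 2.0)
    out: list[ParticleLocation] = []
    pid = 0
    for (py, px) in peaks:
        yy = np.clip(py + dy, 0, H - 1)
        xx = np.clip(px + dx, 0, W - 1)
        mass = float(bp[yy, xx].sum())
        if mass < minmass:
            continue
        fit = _refine_gaussian(avg, int(px), int(py), window=diameter, psf_guess=psf_sigma_guess)
        if fit is None:
            continue
        x0, y0, amp, sx, sy, b = fit
        roundness = max(sx, sy) / min(sx, sy)
        if not (roundness_window[0] <= roundness <= roundness_window[1]):
            continue
        out.append(ParticleLocation(
            x=float(x0), y=float(y0), amplitude=float(amp),
            sigma_x=float(sx), sigma_y=float(sy), baseline=float(b),
            mass=float(2 * np.pi * amp * sx * sy), roundness=float(roundness),
            particle_id=pid,
        ))
        pid += 1
    return out


def locations_to_frame(locations: list[ParticleLocation]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "particle_id": p.particle_id, "x": p.x, "y": p.y,
            "amplitude": p.amplitude, "sigma_x": p.sigma_x, "sigma_y": p.sigma_y,
            "baseline": p.baseline, "roundness": p.roundness, "mass": p.mass,
        }
        for p in locations
    ])


# ---------------------------------------------------------------------------
# photometry


def extract_trace(photometry_movie: Movie, particle: ParticleLocation,
                  roi_diameter: float = 9.0) -> PhotonTrace:
    """Aperture photometry: ``f = sum_ROI(s) - b * N_pixels`` per frame.

    The ROI is the discrete circular mask of the given diameter centered on
    the rounded centroid; the baseline ``b`` comes from the particle's
    Gaussian fit on the time average and is reused for every frame.  An ROI
    clipped by the image edge invalidates the trace.
    """
    H, W = photometry_movie.frame_shape
    cy, cx = int(round(particle.y)), int(round(particle.x))
    dy, dx = _disk_offsets(roi_diameter / 2.0)
    yy, xx = cy + dy, cx + dx
    if yy.min() < 0 or xx.min() < 0 or yy.max() >= H or xx.max() >= W:
        raise ValueError("ROI clipped by the image edge; trace excluded")
    n_pix = len(dy)
    f = photometry_movie.data[:, yy, xx].sum(axis=1) - particle.baseline * n_pix
    return PhotonTrace(particle=particle, photons=f,
                       frame_interval=photometry_movie.frame_interval)


# ---------------------------------------------------------------------------
# quality control


def qc_traces(traces: list[PhotonTrace], aggregate_threshold: float = 500.0,
              smoothing_sigma: float | None = None) -> list[PhotonTrace]:
    """Drop higher-order aggregates and optionally smooth low-SNR traces.

    Any trace with a frame exceeding ``aggregate_threshold`` photons
    (default 500) is discarded as a higher-order aggregate.  When
    ``smoothing_sigma`` is given, surviving traces are Gaussian-smoothed
    along time (the low signal-to-noise variant).
    """
    kept: list[PhotonTrace] = []
    for tr in traces:
        if np.any(tr.photons > aggregate_threshold):
            tr.qc_flags["aggregate"] = True
            continue
        photons = tr.photons
        if smoothing_sigma is not None and smoothing_sigma > 0:
            photons = ndimage.gaussian_filter1d(photons, sigma=smoothing_sigma,
                                                mode="reflect")
        kept.append(PhotonTrace(particle=tr.particle, photons=photons,
                                frame_interval=tr.frame_interval,
                                qc_flags=dict(tr.qc_flags)))
    return kept


def bleach_blink_qc(traces: list[PhotonTrace], block: int = 400,
                    bleach_mean: float = 30.0,
                    blink_window: tuple[int, int] = (100, 1000),
                    blink_k: float = 3.0) -> pd.DataFrame:
    """Bleaching and blinking report for monomeric control traces.

    Per 400-frame block a particle counts as bleached once the block mean
    drops to ``bleach_mean`` photons or below.  Blinking is scored inside
    ``blink_window`` (frames 100-1000 by default, away from bleaching
    bias): frames whose deviation from the trace mean reaches ``blink_k``
    trace standard deviations are flagged, both as an absolute-deviation
    count and, for dark-state semantics, counting only negative
    excursions.
    """
    rows = []
    for i, tr in enumerate(traces):
        x = tr.photons
        n = len(x)
        short = n < block
        nblocks = max(1, int(np.ceil(n / block)))
        bleached_blocks = []
        for b in range(nblocks):
            seg = x[b * block:(b + 1) * block]
            if len(seg) and seg.mean() <= bleach_mean:
                bleached_blocks.append(b)
        lo, hi = blink_window
        seg = x[lo:min(hi, n)]
        if len(seg) > 1:
            mu, sd = seg.mean(), seg.std(ddof=1)
            if sd > 0:
                dev = seg - mu
                blink_abs = np.flatnonzero(np.abs(dev) >= blink_k * sd) + lo
                blink_dark = np.flatnonzero(dev <= -blink_k * sd) + lo
            else:
                blink_abs = blink_dark = np.array([], dtype=int)
        else:
            blink_abs = blink_dark = np.array([], dtype=int)
        rows.append({
            "trace_id": i,
            "n_frames": n,
            "short_trace": short,
            "bleached": len(bleached_blocks) > 0,
            "first_bleached_block": bleached_blocks[0] if bleached_blocks else -1,
            "n_blink_frames_abs": len(blink_abs),
            "n_blink_frames_dark": len(blink_dark),
            "blink_frames": blink_dark.tolist(),
        })
    return pd.DataFrame(rows)
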