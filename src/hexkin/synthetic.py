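"""Ground-truth generators for single-particle assembly experiments.

A surface-immobilized particle is an oligomer that grows and shrinks by
binding and unbinding species from solution.  Its oligomeric state S1..S6
(monomer..hexamer) evolves as a continuous-time Markov chain: from state
``i`` the assembly channel ``i -> j`` (j > i) fires with propensity
``k_assoc[i, j] * c[j - i]`` where ``c[m]`` is the molar concentration of
the free m-mer in solution, and the disassembly channel ``i -> j`` (j < i)
fires with unimolecular propensity ``k_dissoc[i, j]``.

On top of a state path the module renders (a) per-frame photon traces with
the acquisition's exposure/dead-time structure (50 ms exposure in a 150 ms
frame by default, so only a third of each frame interval is observed) and
(b) full camera movies: diffraction-limited Gaussian spots under a Gaussian
illumination profile, digitized through the EMCCD Poisson-Erlang noise
model.  Every stochastic operation takes an explicit integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import sample_counts

__all__ = [
    "SurfaceKineticModel",
    "GroundTruthPath",
    "IlluminationSpec",
    "CameraSpec",
    "MovieConfig",
    "simulate_state_path",
    "render_photon_trace",
    "render_movie",
    "psf_image",
    "write_movie",
    "read_movie",
    "write_ground_truth",
    "read_ground_truth",
]

ALLOWED_STEPS_DEFAULT = (1, 2, 4)  # monomer, dimer, tetramer additions


# ---------------------------------------------------------------------------
# kinetic model and state paths


@dataclass
class SurfaceKineticModel:
    """Rates governing the state switching of a surface-bound oligomer.

    ``assoc_rates[(i, j)]`` are bimolecular constants (M^-1 s^-1) for the
    addition of a free (j - i)-mer; ``dissoc_rates[(i, j)]`` are
    unimolecular constants (s^-1); ``solution_conc[m]`` is the molar
    concentration of the free m-mer.
    """

    assoc_rates: dict[tuple[int, int], float] = field(default_factory=dict)
    dissoc_rates: dict[tuple[int, int], float] = field(default_factory=dict)
    solution_conc: dict[int, float] = field(default_factory=dict)
    n_states: int = 6
    allowed_steps: tuple[int, ...] = ALLOWED_STEPS_DEFAULT

    def __post_init__(self) -> None:
        for (i, j), k in self.assoc_rates.items():
            if k < 0:
                raise ValueError(f"negative association rate for {i}->{j}")
            if not (1 <= i < j <= self.n_states):
                raise ValueError(f"invalid association transition {i}->{j}")
            if (j - i) not in self.allowed_steps:
                raise ValueError(
                    f"step size {j - i} for {i}->{j} not in allowed_steps"
                )
            if (j - i) not in self.solution_conc:
                raise ValueError(
                    f"solution_conc missing species of size {j - i} used by {i}->{j}"
                )
        for (i, j), k in self.dissoc_rates.items():
            if k < 0:
                raise ValueError(f"negative dissociation rate for {i}->{j}")
            if not (1 <= j < i <= self.n_states):
                raise ValueError(f"invalid dissociation transition {i}->{j}")
        for m, c in self.solution_conc.items():
            if c < 0:
                raise ValueError(f"negative concentration for {m}-mer")

    def exit_channels(self, state: int) -> list[tuple[int, float]]:
        """(target state, propensity in s^-1) for every channel out of ``state``."""
        out = []
        for (i, j), k in self.assoc_rates.items():
            if i == state:
                out.append((j, k * self.solution_conc[j - i]))
        for (i, j), k in self.dissoc_rates.items():
            if i == state:
                out.append((j, k))
        return out


@dataclass
class GroundTruthPath:
    """Piecewise-constant state trajectory: state ``states[n]`` holds on
    ``[jump_times[n-1], jump_times[n])`` with the conventions
    ``jump_times[-1] -> duration`` and start at t = 0."""

    jump_times: np.ndarray  # strictly increasing, seconds
    states: np.ndarray  # len = len(jump_times) + 1, values in 1..6
    duration: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if len(self.states) != len(self.jump_times) + 1:
            raise ValueError("need len(states) == len(jump_times) + 1")
        if len(self.jump_times) and np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump_times must be strictly increasing")
        if np.any(self.states[:-1] == self.states[1:]):
            raise ValueError("consecutive states must differ")

    def state_at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float),
                              side="right")
        return self.states[idx]

    def mean_state(self, t0: float, t1: float) -> float:
        """Time-weighted mean state over the window [t0, t1]."""
        if t1 <= t0:
            raise ValueError("empty window")
        knots = np.concatenate(
            [[t0], self.jump_times[(self.jump_times > t0) & (self.jump_times < t1)], [t1]]
        )
        mids = 0.5 * (knots[:-1] + knots[1:])
        return float(np.sum(self.state_at(mids) * np.diff(knots)) / (t1 - t0))


def simulate_state_path(model: SurfaceKineticModel, initial_state: int,
                        duration: float, seed: int) -> GroundTruthPath:
    """Exact (Gillespie) stochastic simulation of the state-switching chain.

    A state with zero total exit propensity is absorbing: the path simply
    stays there until ``duration``.
    """
    if not (1 <= initial_state <= model.n_states):
        raise ValueError("initial_state out of range")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    # precompute channels per state
    channels = {s: model.exit_channels(s) for s in range(1, model.n_states + 1)}
    t = 0.0
    state = initial_state
    jump_times: list[float] = []
    states = [state]
    while True:
        ch = channels[state]
        total = sum(a for _, a in ch)
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        r = rng.uniform(0.0, total)
        acc = 0.0
        for target, a in ch:
            acc += a
            if r < acc:
                state = target
                break
        jump_times.append(t)
        states.append(state)
    return GroundTruthPath(np.asarray(jump_times), np.asarray(states),
                           duration=duration, seed=seed)


# ---------------------------------------------------------------------------
# acquisition configuration


@dataclass
class IlluminationSpec:
    """2-D Gaussian illumination profile, peak-normalized to 1.

    ``profile(x, y) = floor + (1 - floor) * exp(-r^2 / (2 sigma^2))`` with
    ``r`` the distance to ``center``.  ``sigma=None`` means flat
    illumination.
    """

    sigma: float | None = None
    center: tuple[float, float] | None = None  # (x, y); default image center
    floor: float = 0.1

    def profile(self, shape: tuple[int, int]) -> np.ndarray:
        H, W = shape
        if self.sigma is None:
            return np.ones((H, W))
        cx, cy = self.center if self.center is not None else ((W - 1) / 2, (H - 1) / 2)
        y, x = np.mgrid[0:H, 0:W]
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        return self.floor + (1.0 - self.floor) * np.exp(-r2 / (2.0 * self.sigma**2))


@dataclass
class CameraSpec:
    """Generative EMCCD parameters (the inverse of the calibration fit)."""

    s0: float = 100.0
    gamma: float = 0.02  # photons per count
    dark_photons: float = 5.0  # expected background photons per pixel per frame


@dataclass
class MovieConfig:
    shape: tuple[int, int, int] = (400, 64, 64)  # frames, H, W
    frame_interval: float = 0.15  # s; 50 ms exposure + 100 ms wait
    exposure: float = 0.05  # s
    psf_sigma: float = 1.5  # px
    photons_per_monomer_mean: float = 46.0
    photons_per_monomer_sd: float = 16.0
    illumination: IlluminationSpec = field(default_factory=IlluminationSpec)
    camera: CameraSpec = field(default_factory=CameraSpec)
    bleach_rate: float = 0.0  # s^-1, whole-fluorophore loss (monomer controls)
    blink_on_rate: float = 0.0  # s^-1, dark -> emitting
    blink_off_rate: float = 0.0  # s^-1, emitting -> dark
    noise_scaling: str = "sqrt"  # "sqrt": sd scales with sqrt(state), or "constant"

    def __post_init__(self) -> None:
        if not (self.frame_interval >= self.exposure > 0):
            raise ValueError("need frame_interval >= exposure > 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.noise_scaling not in ("sqrt", "constant"):
            raise ValueError("noise_scaling must be 'sqrt' or 'constant'")

    @property
    def n_frames(self) -> int:
        return self.shape[0]

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "frame_interval": self.frame_interval,
            "exposure": self.exposure,
            "psf_sigma": self.psf_sigma,
            "photons_per_monomer_mean": self.photons_per_monomer_mean,
            "photons_per_monomer_sd": self.photons_per_monomer_sd,
            "illumination": {
                "sigma": self.illumination.sigma,
                "center": list(self.illumination.center) if self.illumination.center else None,
                "floor": self.illumination.floor,
            },
            "camera": {
                "s0": self.camera.s0,
                "gamma": self.camera.gamma,
                "dark_photons": self.camera.dark_photons,
            },
            "bleach_rate": self.bleach_rate,
            "blink_on_rate": self.blink_on_rate,
            "blink_off_rate": self.blink_off_rate,
            "noise_scaling": self.noise_scaling,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MovieConfig":
        ill = d.get("illumination", {})
        cam = d.get("camera", {})
        return cls(
            shape=tuple(d.get("shape", (400, 64, 64))),
            frame_interval=d.get("frame_interval", 0.15),
            exposure=d.get("exposure", 0.05),
            psf_sigma=d.get("psf_sigma", 1.5),
            photons_per_monomer_mean=d.get("photons_per_monomer_mean", 46.0),
            photons_per_monomer_sd=d.get("photons_per_monomer_sd", 16.0),
            illumination=IlluminationSpec(
                sigma=ill.get("sigma"),
                center=tuple(ill["center"]) if ill.get("center") else None,
                floor=ill.get("floor", 0.1),
            ),
            camera=CameraSpec(
                s0=cam.get("s0", 100.0),
                gamma=cam.get("gamma", 0.02),
                dark_photons=cam.get("dark_photons", 5.0),
            ),
            bleach_rate=d.get("bleach_rate", 0.0),
            blink_on_rate=d.get("blink_on_rate", 0.0),
            blink_off_rate=d.get("blink_off_rate", 0.0),
            noise_scaling=d.get("noise_scaling", "sqrt"),
        )


# ---------------------------------------------------------------------------
# photon traces


def _emission_mask(cfg: MovieConfig, duration: float, rng: np.random.Generator):
    """Optional bleaching/blinking gate, returned as a piecewise on/off path.

    Modeled at the whole-particle level (the intended use is the monomeric
    control, which carries one fluorophore): a single exponential bleach
    time plus a two-state blink telegraph.  Returns (times, on_flags) or
    None when neither process is configured.
    """
    if cfg.bleach_rate <= 0 and cfg.blink_off_rate <= 0:
        return None
    knots = [0.0]
    flags = [True]
    t = 0.0
    on = True
    while t < duration:
        rates = []
        if on:
            r = cfg.blink_off_rate
        else:
            r = cfg.blink_on_rate
        if r <= 0:
            break
        t += rng.exponential(1.0 / r)
        if t >= duration:
            break
        on = not on
        knots.append(t)
        flags.append(on)
    if cfg.bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / cfg.bleach_rate)
        if t_bleach < duration:
            keep = [i for i, k in enumerate(knots) if k < t_bleach]
            knots = [knots[i] for i in keep] + [t_bleach]
            flags = [flags[i] for i in keep] + [False]
    return np.asarray(knots), np.asarray(flags)


def _gate_fraction(gate, t0: float, t1: float) -> float:
    if gate is None:
        return 1.0
    knots, flags = gate
    edges = np.concatenate([knots[(knots > t0) & (knots < t1)], [t1]])
    edges = np.concatenate([[t0], edges])
    mids = 0.5 * (edges[:-1] + edges[1:])
    idx = np.searchsorted(knots, mids, side="right") - 1
    return float(np.sum(flags[idx] * np.diff(edges)) / (t1 - t0))


def mean_state_per_frame(path: GroundTruthPath, cfg: MovieConfig) -> np.ndarray:
    """Exposure-weighted mean oligomeric state for each frame.

    Only the exposure window at the start of each frame interval is
    integrated; the dead time between exposures is unobserved.
    """
    n = cfg.n_frames
    if path.duration < n * cfg.frame_interval - 1e-9:
        raise ValueError("path shorter than the movie")
    out = np.empty(n)
    for f in range(n):
        t0 = f * cfg.frame_interval
        out[f] = path.mean_state(t0, t0 + cfg.exposure)
    return out


def render_photon_trace(path: GroundTruthPath, cfg: MovieConfig, seed: int) -> np.ndarray:
    """Noisy per-frame photon counts for one particle.

    Frame f reports the exposure-weighted state occupancy scaled by
    ``state * photons_per_monomer_mean`` plus Gaussian noise of width
    ``photons_per_monomer_sd * sqrt(state)`` (independent fluorophores add
    in variance; set ``noise_scaling='constant'`` for a fixed width).
    """
    rng = np.random.default_rng(seed)
    mean_state = mean_state_per_frame(path, cfg)
    gate = _emission_mask(cfg, cfg.n_frames * cfg.frame_interval, rng)
    if gate is not None:
        gates = np.array([
            _gate_fraction(gate, f * cfg.frame_interval, f * cfg.frame_interval + cfg.exposure)
            for f in range(cfg.n_frames)
        ])
        mean_state = mean_state * gates
    photons = mean_state * cfg.photons_per_monomer_mean
    if cfg.photons_per_monomer_sd > 0:
        if cfg.noise_scaling == "sqrt":
            sd = cfg.photons_per_monomer_sd * np.sqrt(np.maximum(mean_state, 0.0))
        else:
            sd = np.full_like(mean_state, cfg.photons_per_monomer_sd)
        photons = photons + rng.normal(0.0, 1.0, size=photons.shape) * sd
    return photons


def random_segment_trace(rng: np.random.Generator, n_frames: int = 400,
                         min_dwell: int = 5, mean_extra: float = 10.0,
                         noise_sd: float = 14.0,
                         state_means=(20.0, 50.0, 100.0, 150.0,
                                      200.0, 250.0, 300.0),
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Frame-aligned piecewise-constant trace for idealization benchmarks.

    States hop uniformly among all seven levels with dwell lengths of at
    least ``min_dwell`` frames (plus a geometric tail); emissions are the
    state means plus Gaussian noise of width ``noise_sd``.  Returns
    (states, photons).
    """
    means = np.asarray(state_means, dtype=float)
    n_levels = len(means)
    states: list[int] = []
    s = int(rng.integers(0, n_levels))
    while len(states) < n_frames:
        dwell = min_dwell + int(rng.geometric(1.0 / mean_extra))
        states.extend([s] * dwell)
        nxt = int(rng.integers(0, n_levels))
        while nxt == s:
            nxt = int(rng.integers(0, n_levels))
        s = nxt
    out = np.array(states[:n_frames])
    photons = means[out] + rng.normal(0.0, noise_sd, n_frames)
    return out, photons


# ---------------------------------------------------------------------------
# movies


def psf_image(shape: tuple[int, int], x: float, y: float, total_photons: float,
              sigma: float) -> np.ndarray:
    """Pixel-integrated 2-D Gaussian spot (erf differences per pixel).

    Coordinates are 0-based with pixel centers at integers.
    """
    from scipy.special import erf

    H, W = shape
    xs = np.arange(W)
    ys = np.arange(H)
    sx = (erf((xs + 0.5 - x) / (np.sqrt(2) * sigma))
          - erf((xs - 0.5 - x) / (np.sqrt(2) * sigma))) / 2.0
    sy = (erf((ys + 0.5 - y) / (np.sqrt(2) * sigma))
          - erf((ys - 0.5 - y) / (np.sqrt(2) * sigma))) / 2.0
    return total_photons * np.outer(sy, sx)


def render_movie(particles: list[tuple[float, float, GroundTruthPath]],
                 cfg: MovieConfig, seed: int) -> np.ndarray:
    """Raw camera-count stack for a field of immobilized particles.

    Per frame, the expected photon image is the sum of pixel-integrated
    Gaussian spots, multiplied by the illumination profile, plus the dark
    level; counts are then sampled through the EMCCD noise model
    (``s = s0 + Gamma(shape=Poisson(E), rate=gamma)``) and rounded to
    16-bit integers.  Overlapping particles are allowed and produce merged
    spots.
    """
    rng = np.random.default_rng(seed)
    frames, H, W = cfg.shape
    margin = 3.0 * cfg.psf_sigma
    for x, y, _ in particles:
        if not (margin <= x <= W - 1 - margin and margin <= y <= H - 1 - margin):
            raise ValueError(f"particle at ({x:.1f}, {y:.1f}) too close to the edge")
    profile = cfg.illumination.profile((H, W))
    mean_states = [mean_state_per_frame(p, cfg) for _, _, p in particles]
    movie = np.empty((frames, H, W), dtype=np.uint16)
    for f in range(frames):
        # background is excitation-driven (scatter/autofluorescence), so the
        # dark photon level is modulated by the illumination profile too
        E = np.full((H, W), cfg.camera.dark_photons, dtype=float)
        for (x, y, _), ms in zip(particles, mean_states):
            tot = ms[f] * cfg.photons_per_monomer_mean
            if tot > 0:
                E += psf_image((H, W), x, y, tot, cfg.psf_sigma)
        E *= profile
        counts = sample_counts(E, cfg.camera.s0, cfg.camera.gamma, rng)
        movie[f] = np.clip(np.round(counts), 0, 65535).astype(np.uint16)
    return movie


# ---------------------------------------------------------------------------
# I/O


def write_movie(path: str | Path, stack: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.uint16))


def read_movie(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))


def write_ground_truth(path: str | Path,
                       particles: list[tuple[float, float, GroundTruthPath]]) -> None:
    payload = [
        {
            "x": float(x),
            "y": float(y),
            "jump_times": p.jump_times.tolist(),
            "states": p.states.tolist(),
            "duration": p.duration,
            "seed": p.seed,
        }
        for x, y, p in particles
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> list[tuple[float, float, GroundTruthPath]]:
    payload = json.loads(Path(path).read_text())
    return [
        (
            d["x"],
            d["y"],
            GroundTruthPath(np.asarray(d["jump_times"]), np.asarray(d["states"]),
                            duration=d["duration"], seed=d.get("seed", 0)),
        )
        for d in payload
    ]
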