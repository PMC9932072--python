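"""Shared synthetic-data fixtures.

The expensive ground-truth ensembles (calibration stack, particle movie,
trace ensembles) are built once per session and reused by the unit and
acceptance tests.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from hexkin import camera as cam
from hexkin import hmm as hx_hmm
from hexkin import imaging, kinetics, synthetic


TRUE_S0 = 100.0
TRUE_GAMMA = 0.02
TRUE_DARK = 5.0


@pytest.fixture(scope="session")
def control_stack():
    """4000-frame particle-free EMCCD stack at known (s0, gamma)."""
    cfg = synthetic.MovieConfig(
        shape=(4000, 48, 48),
        camera=synthetic.CameraSpec(s0=TRUE_S0, gamma=TRUE_GAMMA,
                                    dark_photons=TRUE_DARK))
    return synthetic.render_movie([], cfg, seed=101)


@pytest.fixture(scope="session")
def camera_model(control_stack):
    return cam.calibrate(control_stack, n_pixels=400, seed=11)


@pytest.fixture(scope="session")
def photometry_experiment(camera_model):
    """50 static monomers on a Gaussian-illuminated field, fully processed.

    Returns (locations, traces, true_positions, config).
    """
    rng = np.random.default_rng(77)
    cfg = synthetic.MovieConfig(
        shape=(200, 128, 128), psf_sigma=1.5,
        illumination=synthetic.IlluminationSpec(sigma=150.0),
        camera=synthetic.CameraSpec(TRUE_S0, TRUE_GAMMA, TRUE_DARK))
    duration = cfg.n_frames * cfg.frame_interval + 1.0
    particles = []
    for i in range(50):
        gx, gy = i % 8, i // 8
        x = 12 + gx * 14 + rng.uniform(-3, 3)
        y = 12 + gy * 16 + rng.uniform(-3, 3)
        path = synthetic.GroundTruthPath(np.array([]), np.array([1]),
                                         duration=duration)
        particles.append((x, y, path))
    counts = synthetic.render_movie(particles, cfg, seed=78)
    photons = cam.to_photons(counts, camera_model)
    movie = imaging.Movie(photons, cfg.frame_interval, "photons")
    profile = imaging.estimate_illumination(movie)
    photometry, detection = imaging.correct_movie(movie, profile)
    locations = imaging.locate_particles(detection)
    traces = []
    for p in locations:
        try:
            traces.append(imaging.extract_trace(photometry, p))
        except ValueError:
            pass
    truth = np.array([(x, y) for x, y, _ in particles])
    return locations, traces, truth, cfg


make_segment_trace = synthetic.random_segment_trace


@pytest.fixture(scope="session")
def hmm_ensemble():
    """200 noisy traces with known state sequences (dwells >= 5 frames,
    sigma = 14 photons) and their HMM idealizations."""
    rng = np.random.default_rng(55)
    truth, idealized = [], []
    for i in range(200):
        states, photons = make_segment_trace(rng)
        tr = imaging.PhotonTrace(particle=None, photons=photons)
        idealized.append(hx_hmm.fit_hmm(tr, trace_id=i))
        truth.append(states)
    return truth, idealized


KIN_C1 = 10e-9  # molar free monomer in the recovery experiment
KIN_K12 = 5e6  # /M/s planted association constant
KIN_K21 = 0.05  # /s planted dissociation constant


@pytest.fixture(scope="session")
def kinetics_recovery():
    """Full trace-level recovery experiment: monomer<->dimer switching at
    known rates, 170 traces of 4000 frames, HMM-idealized.

    Returns (idealized traces, clusters, chess table).
    """
    model = synthetic.SurfaceKineticModel(
        assoc_rates={(1, 2): KIN_K12}, dissoc_rates={(2, 1): KIN_K21},
        solution_conc={1: KIN_C1})
    cfg = synthetic.MovieConfig(shape=(4000, 32, 32),
                                photons_per_monomer_sd=16.0)
    rng = np.random.default_rng(42)
    idealized = []
    for i in range(170):
        path = synthetic.simulate_state_path(
            model, 1, 4000 * 0.15 + 0.2, seed=int(rng.integers(2**31)))
        photons = synthetic.render_photon_trace(
            path, cfg, seed=int(rng.integers(2**31)))
        tr = imaging.PhotonTrace(particle=None, photons=photons)
        idealized.append(hx_hmm.fit_hmm(tr, trace_id=i, video_id=i % 5))
    records, clusters = kinetics.extract_transitions(idealized)
    comp = kinetics.SolutionComposition(
        weights={1: 1.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0},
        concentrations={1: KIN_C1, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0},
        total_monomer_equiv=KIN_C1)
    chess = kinetics.build_chess(clusters, comp, seed=0)
    return idealized, records, clusters, chess
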