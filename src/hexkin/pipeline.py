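"""End-to-end orchestration of the single-particle analysis.

Stage order mirrors the experimental workflow: EMCCD calibration on a
particle-free control stack -> photon conversion -> illumination
correction -> particle localization -> trace extraction -> quality
control -> HMM idealization -> transition kinetics and thermodynamics ->
optional mass-action extrapolation.  Every stage writes its intermediate
artifact (CSV/JSON) into the output directory and the final report keys
each number to the file it came from.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import camera as cam
from . import imaging, kinetics, ode, synthetic
from .hmm import HMMSpec, MonomerCalibration, fit_hmm, residual_qc

logger = logging.getLogger("hexkin")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "hexkin_out",
    "condition": "HI",
    "total_monomer_equiv": 10e-9,  # molar
    "frame_interval": 0.15,
    "calibration_n_pixels": 400,
    "aggregate_threshold": 500.0,
    "trace_smoothing_sigma": None,
    "monomer_mu": 46.0,
    "monomer_sigma": 16.0,
    "roi_diameter": 9.0,
    "locate": {"diameter": 11, "separation": 6, "minmass_factor": 0.4},
}


def _deep_update(base: dict, upd: dict) -> dict:
    out = dict(base)
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        return _deep_update(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


def simulate_inputs(config: dict, out_dir: Path) -> dict:
    """Generate a synthetic experiment (control stack + particle movie).

    The synthetic section of the config carries the kinetic model (rates
    and solution concentrations), field geometry, and noise settings.
    Returns paths of the written TIFFs and ground-truth sidecar.
    """
    syn = config.get("synthetic", {})
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    cfg = synthetic.MovieConfig.from_dict(syn.get("movie", {}))
    n_particles = int(syn.get("n_particles", 20))
    duration = cfg.n_frames * cfg.frame_interval

    model = synthetic.SurfaceKineticModel(
        assoc_rates={tuple(int(v) for v in k.split("->")): float(r)
                     for k, r in syn.get("assoc_rates", {}).items()},
        dissoc_rates={tuple(int(v) for v in k.split("->")): float(r)
                      for k, r in syn.get("dissoc_rates", {}).items()},
        solution_conc={int(k): float(v)
                       for k, v in syn.get("solution_conc", {"1": 10e-9}).items()},
    )
    frames, H, W = cfg.shape
    margin = 3.0 * cfg.psf_sigma + 5
    particles = []
    for i in range(n_particles):
        x = rng.uniform(margin, W - 1 - margin)
        y = rng.uniform(margin, H - 1 - margin)
        path = synthetic.simulate_state_path(
            model, initial_state=int(syn.get("initial_state", 1)),
            duration=duration + cfg.frame_interval,
            seed=int(rng.integers(2**31)))
        particles.append((x, y, path))

    movie = synthetic.render_movie(particles, cfg, seed=int(rng.integers(2**31)))
    # the control stack needs enough frames per pixel for stable noise fits,
    # independent of how long the particle movie is
    n_control = int(syn.get("control_frames", 2000))
    control_cfg = synthetic.MovieConfig.from_dict(
        {**cfg.to_dict(), "shape": [n_control, H, W]})
    control = synthetic.render_movie([], control_cfg, seed=int(rng.integers(2**31)))

    movie_path = out_dir / "movie.tif"
    control_path = out_dir / "control.tif"
    truth_path = out_dir / "ground_truth.json"
    synthetic.write_movie(movie_path, movie)
    synthetic.write_movie(control_path, control)
    synthetic.write_ground_truth(truth_path, particles)
    (out_dir / "movie_config.json").write_text(json.dumps(cfg.to_dict(), indent=1))
    return {"movie": str(movie_path), "control": str(control_path),
            "ground_truth": str(truth_path)}


def run_pipeline(config: dict) -> dict:
    """Execute the full analysis described by ``config``; return the report.

    Raises with a stage-tagged message on failure; intermediates written
    up to the failing stage are preserved in ``out_dir``.
    """
    t_start = time.time()
    out_dir = Path(config.get("out_dir", "hexkin_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in config.items()},
                    "stages": {}, "results": {}, "provenance": {}}
    stage = "inputs"
    try:
        if "synthetic" in config:
            paths = simulate_inputs(config, out_dir)
        else:
            paths = {"movie": config.get("movie"), "control": config.get("control")}
            if not paths["control"] or not Path(paths["control"]).exists():
                raise FileNotFoundError(
                    "calibration stack missing: config key 'control' must point "
                    "to a particle-free TIFF")
            if not paths["movie"] or not Path(paths["movie"]).exists():
                raise FileNotFoundError("config key 'movie' must point to a TIFF")
        report["stages"]["inputs"] = paths

        stage = "calibrate"
        t0 = time.time()
        control = synthetic.read_movie(paths["control"])
        model = cam.calibrate(control,
                              n_pixels=int(config.get("calibration_n_pixels", 400)),
                              seed=int(config.get("seed", 0)))
        cam_path = out_dir / "camera.json"
        cam_path.write_text(json.dumps(model.to_dict(), indent=1))
        report["provenance"]["camera"] = str(cam_path)
        logger.info("calibrate: s0=%.2f gamma=%.4f (%d/%d accepted) [%.1fs]",
                    model.s0, model.gamma, model.n_pixels_accepted,
                    model.n_pixels_fit, time.time() - t0)

        stage = "correct"
        raw = synthetic.read_movie(paths["movie"])
        photons = cam.to_photons(raw, model)
        movie = imaging.Movie(photons, config.get("frame_interval", 0.15), "photons")
        profile = imaging.estimate_illumination(movie)
        photometry, detection = imaging.correct_movie(movie, profile)

        stage = "locate"
        loc_cfg = config.get("locate", {})
        locations = imaging.locate_particles(
            detection,
            diameter=int(loc_cfg.get("diameter", 11)),
            separation=int(loc_cfg.get("separation", 6)),
            minmass_factor=float(loc_cfg.get("minmass_factor", 0.4)))
        loc_path = out_dir / "locations.csv"
        imaging.locations_to_frame(locations).to_csv(loc_path, index=False)
        report["provenance"]["locations"] = str(loc_path)
        logger.info("locate: %d particles", len(locations))

        stage = "trace"
        traces = []
        for p in locations:
            try:
                traces.append(imaging.extract_trace(
                    photometry, p, roi_diameter=float(config.get("roi_diameter", 9.0))))
            except ValueError:
                continue

        stage = "qc"
        traces = imaging.qc_traces(
            traces,
            aggregate_threshold=float(config.get("aggregate_threshold", 500.0)),
            smoothing_sigma=config.get("trace_smoothing_sigma"))
        trace_path = out_dir / "traces.csv"
        pd.DataFrame({f"p{t.particle.particle_id}": t.photons for t in traces}
                     ).to_csv(trace_path, index=False)
        report["provenance"]["traces"] = str(trace_path)
        logger.info("qc: %d traces retained", len(traces))

        stage = "hmm"
        spec = HMMSpec.from_dict(config["hmm_spec"]) if "hmm_spec" in config else HMMSpec()
        idealized = []
        for i, tr in enumerate(traces):
            try:
                idealized.append(fit_hmm(tr, spec, trace_id=i))
            except ValueError:
                continue
        rq = residual_qc(idealized) if idealized else {}
        ideal_rows = []
        for t in idealized:
            for f in range(len(t.states)):
                ideal_rows.append((t.trace_id, f, t.trace.photons[f],
                                   int(t.states[f]), t.idealized_photons[f],
                                   t.residuals[f]))
        ideal_path = out_dir / "idealized.csv"
        pd.DataFrame(ideal_rows, columns=["trace_id", "frame", "raw_photons",
                                          "state", "idealized_photons",
                                          "residual"]).to_csv(ideal_path, index=False)
        report["provenance"]["idealized"] = str(ideal_path)
        report["results"]["residual_qc"] = rq

        stage = "kinetics"
        records, clusters = kinetics.extract_transitions(
            idealized, frame_interval=float(config.get("frame_interval", 0.15)))
        cal = MonomerCalibration(mu=float(config.get("monomer_mu", 46.0)),
                                 sigma=float(config.get("monomer_sigma", 16.0)),
                                 n_particles=0)
        steps = np.array([r.photon_after - r.photon_before for r in records
                          if r.state_after > r.state_before])
        if len(steps) >= 100:
            comp = kinetics.estimate_solution_composition(
                steps, cal, float(config.get("total_monomer_equiv", 10e-9)))
        else:
            total = float(config.get("total_monomer_equiv", 10e-9))
            comp = kinetics.SolutionComposition(
                weights={1: 1.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0},
                concentrations={1: total, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0},
                total_monomer_equiv=total)
            report["results"]["composition_note"] = (
                "fewer than 100 assembly steps; monomer-only composition assumed")
        chess = kinetics.build_chess(clusters, comp, seed=int(config.get("seed", 0)))
        chess_path = out_dir / "chess.csv"
        chess.to_csv(chess_path, index=False)
        report["provenance"]["chess"] = str(chess_path)
        report["results"]["composition"] = {
            "weights": comp.weights, "concentrations": comp.concentrations}
        report["results"]["n_transitions"] = len(records)

        stage = "occupancy"
        if idealized:
            pooled = np.concatenate([t.idealized_photons for t in idealized])
            occ, occ_err = kinetics.occupancy(pooled, spec.state_means,
                                              spec.state_sds,
                                              seed=int(config.get("seed", 0)))
            report["results"]["occupancy"] = {
                f"S{i}": [float(occ[i]), float(occ_err[i])] for i in range(7)}

        stage = "thermo"
        thermo_rows = []
        by_key = {(int(r.state_before), int(r.state_after)): r
                  for r in chess.itertuples()}
        for (i, j), r in by_key.items():
            rev = by_key.get((j, i))
            if (rev is not None and j > i and r.defined and rev.defined
                    and r.rate_constant > 0 and rev.rate_constant > 0):
                K = kinetics.equilibrium_constant(r.rate_constant, rev.rate_constant)
                thermo_rows.append({
                    "pair": f"{i}<->{j}", "K_eq_per_molar": K,
                    "dG_kJ_per_mol": kinetics.free_energy(K) / 1e3,
                    "dG_act_assembly_kJ_per_mol":
                        kinetics.activation_energy(r.rate_constant) / 1e3,
                })
        report["results"]["thermodynamics"] = thermo_rows

        if "ode" in config:
            stage = "ode"
            scheme = ode.SolutionScheme.from_dict(config["ode"].get("scheme", {}))
            sweep = ode.default_sweep(
                float(config["ode"].get("sweep_low", 1e-9)),
                float(config["ode"].get("sweep_high", 1e-3)),
                int(config["ode"].get("sweep_n", 25)))
            table = ode.endpoint_fractions(sweep, scheme)
            frac_path = out_dir / "fractions.csv"
            table.to_frame().to_csv(frac_path, index=False)
            report["provenance"]["fractions"] = str(frac_path)
            hf = ode.hill_fit(table)
            report["results"]["hill"] = {
                "K_molar": hf.K, "n_h": hf.n_h, "B_max": hf.B_max, "ok": hf.ok}

        report["elapsed_s"] = time.time() - t_start
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=1, default=str))
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
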