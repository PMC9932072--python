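"""Seven-state hidden Markov idealization of photon traces.

The photon level of a surface-bound particle switches between seven
discrete emission states — background (S0) plus monomer through hexamer
(S1..S6).  Because the higher oligomers are rare, the Gaussian emission
parameters are frozen (means 20, 50, 100, ..., 300 photons; SDs 25/25/35...)
and only the transition matrix and initial distribution are learned per
trace by expectation-maximization; the state path is then decoded with
Viterbi, whose self-consistent segmentation is what dwell-time analysis
requires.  Residuals between trace and idealization diagnose model
adequacy: an adequate fit leaves a zero-centered Gaussian.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .imaging import PhotonTrace
from .mixtures import fit_mixture

__all__ = [
    "HMMSpec",
    "IdealizedTrace",
    "MonomerCalibration",
    "fit_hmm",
    "residual_qc",
    "calibrate_photons_per_monomer",
]

# frozen-emission fits legitimately leave unvisited states with empty
# transmat rows; the repair below handles it, so silence the library notice
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

# Default frozen emission table: background + monomer..hexamer
DEFAULT_STATE_MEANS = (20.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0)
DEFAULT_STATE_SDS = (25.0, 25.0, 35.0, 35.0, 35.0, 35.0, 35.0)


@dataclass
class HMMSpec:
    state_means: tuple[float, ...] = DEFAULT_STATE_MEANS
    state_sds: tuple[float, ...] = DEFAULT_STATE_SDS
    frozen: bool = True  # freeze emission means and SDs during EM
    labels: tuple[str, ...] = tuple(f"S{i}" for i in range(7))

    def __post_init__(self) -> None:
        if len(self.state_means) != 7 or len(self.state_sds) != 7:
            raise ValueError("the model has exactly 7 states (S0..S6)")
        if np.any(np.diff(self.state_means) <= 0):
            raise ValueError("state means must be strictly increasing")

    def to_dict(self) -> dict:
        return {"state_means": list(self.state_means),
                "state_sds": list(self.state_sds),
                "frozen": self.frozen, "labels": list(self.labels)}

    @classmethod
    def from_dict(cls, d: dict) -> "HMMSpec":
        return cls(state_means=tuple(d["state_means"]),
                   state_sds=tuple(d["state_sds"]),
                   frozen=d.get("frozen", True),
                   labels=tuple(d.get("labels", [f"S{i}" for i in range(7)])))


@dataclass
class IdealizedTrace:
    states: np.ndarray  # per-frame integer state index 0..6 (S0..S6)
    idealized_photons: np.ndarray  # per-frame state mean
    residuals: np.ndarray  # raw - idealized
    loglik: float
    converged: bool
    trace: PhotonTrace | None = None
    trace_id: int = -1
    video_id: int = 0
    startprob: np.ndarray | None = None
    transmat: np.ndarray | None = None

    @property
    def frame_interval(self) -> float:
        return self.trace.frame_interval if self.trace is not None else 0.15


@dataclass
class MonomerCalibration:
    """Photons emitted per labeled monomer: Gaussian (mu, sigma)."""

    mu: float
    sigma: float
    n_particles: int
    multimodal_warning: bool = False

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("calibration mu and sigma must be positive")

    def to_dict(self) -> dict:
        return {"mu": self.mu, "sigma": self.sigma,
                "n_particles": self.n_particles,
                "multimodal_warning": self.multimodal_warning}


def fit_hmm(trace: PhotonTrace, spec: HMMSpec | None = None,
            max_iter: int = 500, tol: float = 1e-6,
            trace_id: int = -1, video_id: int = 0) -> IdealizedTrace:
    """Fit the frozen-emission HMM to one trace and Viterbi-decode it.

    The transition matrix and initial distribution start uniform and are
    re-estimated by EM; with ``spec.frozen`` (default) the emission means
    and SDs stay at their table values throughout.  Traces shorter than 10
    frames carry too little information and are rejected.
    """
    from hmmlearn.hmm import GaussianHMM

    if spec is None:
        spec = HMMSpec()
    x = np.asarray(trace.photons, dtype=float)
    if len(x) < 10:
        raise ValueError("trace shorter than 10 frames")
    n = 7
    params = "st" if spec.frozen else "stmc"
    model = GaussianHMM(n_components=n, covariance_type="diag",
                        init_params="", params=params, n_iter=max_iter,
                        tol=tol)
    model.startprob_ = np.full(n, 1.0 / n)
    model.transmat_ = np.full((n, n), 1.0 / n)
    model.means_ = np.asarray(spec.state_means, dtype=float)[:, None]
    model.covars_ = np.asarray(spec.state_sds, dtype=float)[:, None] ** 2
    X = x[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X)
        converged = bool(model.monitor_.converged)
        # states never visited leave zero-sum transmat rows; make them inert
        rows = model.transmat_.sum(axis=1)
        bad = ~np.isclose(rows, 1.0)
        if np.any(bad):
            tm = model.transmat_.copy()
            tm[bad] = np.eye(n)[bad]
            model.transmat_ = tm
        sp = model.startprob_
        if not np.isclose(sp.sum(), 1.0):
            model.startprob_ = np.full(n, 1.0 / n)
        loglik, states = model.decode(X, algorithm="viterbi")
    means = np.asarray(spec.state_means, dtype=float)
    if not spec.frozen:
        means = model.means_[:, 0]
    ideal = means[states]
    return IdealizedTrace(states=states, idealized_photons=ideal,
                          residuals=x - ideal, loglik=float(loglik),
                          converged=converged, trace=trace,
                          trace_id=trace_id, video_id=video_id,
                          startprob=model.startprob_.copy(),
                          transmat=model.transmat_.copy())


def path_log_probability(photons: np.ndarray, states: np.ndarray,
                         spec: HMMSpec, startprob: np.ndarray,
                         transmat: np.ndarray) -> float:
    """Joint log-probability of a given state path and the observations.

    Useful for checking Viterbi optimality: the decoded path must score at
    least as high as any other path — the ground truth included — under
    the same fitted model.
    """
    x = np.asarray(photons, dtype=float)
    s = np.asarray(states, dtype=int)
    mu = np.asarray(spec.state_means)[s]
    sd = np.asarray(spec.state_sds)[s]
    emit = stats.norm.logpdf(x, mu, sd).sum()
    with np.errstate(divide="ignore"):
        lp = np.log(startprob[s[0]])
        lp += np.log(transmat[s[:-1], s[1:]]).sum()
    return float(emit + lp)


def residual_qc(idealized: list[IdealizedTrace]) -> dict:
    """Pool residuals across traces and fit a single Gaussian.

    Returns the pooled mean and SD plus a normality report (D'Agostino
    K^2); an all-zero residual pool is flagged degenerate rather than
    tested.
    """
    if not idealized:
        raise ValueError("need at least one idealized trace")
    res = np.concatenate([t.residuals for t in idealized])
    mu = float(res.mean())
    sigma = float(res.std(ddof=1)) if len(res) > 1 else 0.0
    report = {"mu": mu, "sigma": sigma, "n": len(res), "degenerate": False,
              "normality_stat": np.nan, "normality_p": np.nan}
    if sigma == 0.0:
        report["degenerate"] = True
        return report
    if len(res) >= 20:
        stat, p = stats.normaltest(res)
        report["normality_stat"] = float(stat)
        report["normality_p"] = float(p)
    return report


def calibrate_photons_per_monomer(monomer_traces: list[PhotonTrace],
                                  bleach_report=None) -> MonomerCalibration:
    """Gaussian fit of the pooled per-frame photon distribution of
    monomeric control particles.

    When a bleaching report (from ``imaging.bleach_blink_qc``) is given,
    only pre-bleach frames enter the pool.  Contamination by aggregates
    shows up as multimodality; a two-component mixture fit that clearly
    beats the single Gaussian raises a warning and the dominant mode is
    reported.
    """
    pools = []
    for i, tr in enumerate(monomer_traces):
        x = tr.photons
        if bleach_report is not None:
            row = bleach_report[bleach_report["trace_id"] == i]
            if len(row) and row.iloc[0]["bleached"]:
                first = int(row.iloc[0]["first_bleached_block"])
                x = x[: first * 400]
        if len(x):
            pools.append(x)
    if not pools:
        raise ValueError("no frames available for calibration")
    x = np.concatenate(pools)
    mu = float(x.mean())
    sigma = float(x.std(ddof=1))
    multimodal = False
    if len(x) >= 200 and sigma > 0:
        one = fit_mixture(x, np.array([mu]), np.array([sigma]),
                          freeze_means=False, freeze_sds=False)
        two = fit_mixture(x, np.array([mu - sigma, mu + sigma]),
                          np.array([sigma, sigma]),
                          freeze_means=False, freeze_sds=False)
        # BIC comparison: the 2-component fit pays for 3 extra parameters
        bic1 = -2 * one.loglik + 2 * np.log(len(x))
        bic2 = -2 * two.loglik + 5 * np.log(len(x))
        if bic2 + 10 < bic1:
            multimodal = True
            warnings.warn("monomer photon distribution looks multimodal; "
                          "reporting the dominant mode", RuntimeWarning)
            k = int(np.argmax(two.weights))
            mu = float(two.means[k])
            sigma = float(two.sds[k])
    return MonomerCalibration(mu=mu, sigma=sigma,
                              n_particles=len(monomer_traces),
                              multimodal_warning=multimodal)
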