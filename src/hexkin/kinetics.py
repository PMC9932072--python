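"""Dwell-time kinetics: from idealized traces to the CHESS table.

Every state change in an idealized trace is a transition record carrying
the dwell time spent in the departing state.  Records sharing the same
(before, after) pair form a cluster — the grid of the transition density
plot, aligned with the HMM emission table, 42 clusters for the six
non-background states.  Each cluster's dwell distribution is fit with a
single-exponential maximum-likelihood estimate (rate = 1 / mean dwell,
dwells above 75 s excluded as non-exponential outliers).  Disassembly
rates are reported as-is (s^-1); assembly decay rates are divided by the
solution concentration of the added species to give bimolecular constants
(M^-1 s^-1).  The solution composition is itself estimated from the
histogram of assembly photon steps with a five-Gaussian mixture anchored
at integer multiples of the monomer photon calibration.

The per-cluster single-exponential fit is the field's transition-density
convention: with competing exit channels from one state it reports the
channel-apparent rate (every channel sees the total-exit dwell
distribution, so per-channel rates do not sum to the total exit rate
unless corrected).  A competing-risks-corrected estimate
(rate * channel fraction of events) is available as a diagnostic.

Thermodynamics follow transition-state theory: K_eq = k_ij / k_ji,
dG = -RT ln K_eq, and the activation barrier dG# = -RT ln(h k / (k_B T))
at T = 298 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import IdealizedTrace, MonomerCalibration
from .mixtures import fit_mixture

__all__ = [
    "ThermoConstants",
    "TransitionRecord",
    "DwellCluster",
    "DwellFit",
    "SolutionComposition",
    "extract_transitions",
    "fit_dwell",
    "estimate_solution_composition",
    "build_chess",
    "occupancy",
    "equilibrium_constant",
    "free_energy",
    "activation_energy",
    "compare_conditions",
    "fold_ratio",
]


@dataclass(frozen=True)
class ThermoConstants:
    R: float = 8.314  # J mol^-1 K^-1
    T: float = 298.0  # K
    k_B: float = 1.380649e-23  # J K^-1
    h: float = 6.62607015e-34  # J s


CONSTANTS = ThermoConstants()
DWELL_CUTOFF_S = 75.0
LOW_N = 10


# ---------------------------------------------------------------------------
# transition enumeration


@dataclass
class TransitionRecord:
    state_before: int  # 1..6
    state_after: int  # 1..6
    dwell: float  # seconds in state_before ending at this transition
    censored_entry: bool  # True when the dwell started before observation
    photon_before: float
    photon_after: float
    trace_id: int
    video_id: int


@dataclass
class DwellCluster:
    key: tuple[int, int]  # (state_before, state_after)
    dwells: np.ndarray  # interior (uncensored) dwells, seconds
    video_ids: np.ndarray
    density: int  # total observed transitions, censored included
    cutoff: float = DWELL_CUTOFF_S

    @property
    def retained(self) -> np.ndarray:
        return self.dwells[self.dwells <= self.cutoff]


def _segments(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(state, start_frame, length) run-length encoding."""
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(states)]])
    return [(int(states[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def extract_transitions(idealized: list[IdealizedTrace],
                        frame_interval: float = 0.15,
                        ) -> tuple[list[TransitionRecord], dict[tuple[int, int], DwellCluster]]:
    """Enumerate state changes and cluster them on the (before, after) grid.

    Transitions touching the background state S0 are excluded from the
    6 x 6 grid.  Dwells for rate fitting use only interior segments — the
    entry AND the exit of the dwell were observed; the first segment of a
    trace (unobserved entry) contributes to the transition density only.
    """
    records: list[TransitionRecord] = []
    for t in idealized:
        segs = _segments(np.asarray(t.states))
        for n in range(len(segs) - 1):
            s_before, start, length = segs[n]
            s_after = segs[n + 1][0]
            if s_before == 0 or s_after == 0:
                continue
            records.append(TransitionRecord(
                state_before=s_before, state_after=s_after,
                dwell=length * frame_interval,
                censored_entry=(n == 0),
                photon_before=float(t.idealized_photons[start]),
                photon_after=float(t.idealized_photons[segs[n + 1][1]]),
                trace_id=t.trace_id, video_id=t.video_id,
            ))
    clusters: dict[tuple[int, int], DwellCluster] = {}
    for key in {(r.state_before, r.state_after) for r in records}:
        rs = [r for r in records if (r.state_before, r.state_after) == key]
        interior = [r for r in rs if not r.censored_entry]
        clusters[key] = DwellCluster(
            key=key,
            dwells=np.array([r.dwell for r in interior]),
            video_ids=np.array([r.video_id for r in interior]),
            density=len(rs),
        )
    return records, clusters


# ---------------------------------------------------------------------------
# dwell-time MLE


@dataclass
class DwellFit:
    rate: float  # s^-1 apparent decay rate of the cluster
    bootstrap_se: float
    per_video_sd: float
    n_used: int
    n_excluded: int  # dwells above the cutoff
    low_n_flag: bool
    defined: bool


def fit_dwell(cluster: DwellCluster, n_boot: int = 1000, seed: int = 0) -> DwellFit:
    """Single-exponential maximum-likelihood fit of a dwell cluster.

    The exponential MLE is rate = 1 / mean of the retained dwells (those
    at or below the 75 s cutoff; longer dwells are long-lived outliers that
    do not follow a single exponential).  The error is a nonparametric
    bootstrap SE, with the spread of per-video refits reported alongside.
    """
    d = cluster.retained
    n_exc = len(cluster.dwells) - len(d)
    if len(d) < 2:
        return DwellFit(np.nan, np.nan, np.nan, len(d), n_exc,
                        low_n_flag=True, defined=False)
    rate = 1.0 / float(d.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(d), size=(n_boot, len(d)))
    boot_rates = 1.0 / d[idx].mean(axis=1)
    se = float(boot_rates.std(ddof=1))
    keep = cluster.dwells <= cluster.cutoff
    vids = cluster.video_ids[keep]
    per_video = [1.0 / d[vids == v].mean() for v in np.unique(vids)
                 if np.sum(vids == v) >= 2]
    pv_sd = float(np.std(per_video, ddof=1)) if len(per_video) >= 2 else np.nan
    return DwellFit(rate=rate, bootstrap_se=se, per_video_sd=pv_sd,
                    n_used=len(d), n_excluded=n_exc,
                    low_n_flag=len(d) < LOW_N, defined=True)


def competing_risks_rates(clusters: dict[tuple[int, int], DwellCluster],
                          ) -> dict[tuple[int, int], float]:
    """Channel-resolved exit rates, correcting the per-cluster convention.

    With several exit channels from one state, every channel's dwell
    sample follows the total-exit exponential, so the per-cluster MLE
    estimates the total exit rate.  The channel's true rate is that total
    rate times the fraction of exits taking the channel; this diagnostic
    reports exactly that, per (before, after) pair.
    """
    out: dict[tuple[int, int], float] = {}
    by_state: dict[int, list[DwellCluster]] = {}
    for (i, _), c in clusters.items():
        by_state.setdefault(i, []).append(c)
    for i, cs in by_state.items():
        pooled = np.concatenate([c.retained for c in cs])
        if len(pooled) < 2:
            continue
        total_rate = 1.0 / pooled.mean()
        n_all = sum(len(c.retained) for c in cs)
        for c in cs:
            out[c.key] = total_rate * len(c.retained) / n_all
    return out


# ---------------------------------------------------------------------------
# solution composition


@dataclass
class SolutionComposition:
    """Free-oligomer make-up of the solution (monomer..pentamer).

    ``weights[m]`` is the number fraction of free m-mers among observed
    addition events; ``concentrations[m]`` the molar concentration under
    monomer-equivalent conservation: c_m = w_m * C_N with
    C_N = total_monomer_equiv / sum(m * w_m).
    """

    weights: dict[int, float]
    concentrations: dict[int, float]
    total_monomer_equiv: float

    def __post_init__(self) -> None:
        s = sum(self.weights.values())
        if not np.isclose(s, 1.0, atol=1e-6):
            raise ValueError("weights must sum to 1")
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")


def estimate_solution_composition(assembly_steps: np.ndarray,
                                  cal: MonomerCalibration,
                                  total_monomer_equiv: float,
                                  ) -> SolutionComposition:
    """Five-Gaussian fit of the assembly-step histogram.

    Component m (m = 1..5) is anchored at mean ``m * cal.mu`` with SD
    ``sqrt(m) * cal.sigma`` (independent fluorophores add in variance);
    only the weights are free.  Weights are number fractions of the free
    species; molar concentrations follow from monomer-equivalent
    conservation.
    """
    steps = np.asarray(assembly_steps, dtype=float)
    if len(steps) < 100:
        raise ValueError("need at least 100 assembly steps")
    m = np.arange(1, 6)
    fit = fit_mixture(steps, means=m * cal.mu, sds=np.sqrt(m) * cal.sigma,
                      freeze_means=True, freeze_sds=True)
    w = np.maximum(fit.weights, 0.0)
    w = w / w.sum()
    mean_size = float((m * w).sum())
    c_n = total_monomer_equiv / mean_size
    weights = {int(i): float(wi) for i, wi in zip(m, w)}
    conc = {int(i): float(wi * c_n) for i, wi in zip(m, w)}
    return SolutionComposition(weights=weights, concentrations=conc,
                               total_monomer_equiv=total_monomer_equiv)


# ---------------------------------------------------------------------------
# CHESS table


def build_chess(clusters: dict[tuple[int, int], DwellCluster],
                composition: SolutionComposition,
                n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Rate constants and densities for every observed transition.

    Disassembly (j < i): the rate constant is the fitted decay rate
    (s^-1).  Assembly (j > i): the decay rate is divided by the solution
    concentration of the added (j - i)-mer to give a bimolecular constant
    (M^-1 s^-1).  Clusters with fewer than 10 retained dwells are flagged
    (the triangle on the published heatmap); a missing added-species
    concentration leaves the entry unconvertible.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for (i, j), cluster in sorted(clusters.items()):
        fit = fit_dwell(cluster, n_boot=n_boot, seed=int(rng.integers(2**31)))
        is_assembly = j > i
        rate_constant = np.nan
        error = np.nan
        unconvertible = False
        if fit.defined:
            if is_assembly:
                step = j - i
                c = composition.concentrations.get(step)
                if c is None or c <= 0:
                    unconvertible = True
                else:
                    rate_constant = fit.rate / c
                    error = fit.bootstrap_se / c
            else:
                rate_constant = fit.rate
                error = fit.bootstrap_se
        rows.append({
            "state_before": i, "state_after": j,
            "kind": "assembly" if is_assembly else "disassembly",
            "density": cluster.density,
            "decay_rate": fit.rate,
            "rate_constant": rate_constant,
            "error": error,
            "per_video_sd": fit.per_video_sd,
            "n_dwells": fit.n_used,
            "n_excluded": fit.n_excluded,
            "low_n_flag": fit.low_n_flag,
            "defined": fit.defined,
            "unconvertible": unconvertible,
        })
    return pd.DataFrame(rows)


def plot_chess(chess: pd.DataFrame, layer: str = "density", ax=None):
    """Render the 6 x 6 transition heatmap (state before vs state after).

    ``layer`` selects "density" or "rate_constant"; cells with fewer than
    10 dwells carry the customary triangle marker, cells with no data stay
    gray.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.2))
    grid = np.full((6, 6), np.nan)
    for r in chess.itertuples():
        grid[r.state_after - 1, r.state_before - 1] = getattr(r, layer)
    from matplotlib import colors

    norm = colors.LogNorm() if layer == "rate_constant" else None
    mesh = ax.imshow(grid, origin="lower", cmap="viridis", norm=norm,
                     extent=(0.5, 6.5, 0.5, 6.5))
    for r in chess.itertuples():
        val = getattr(r, layer)
        if np.isfinite(val):
            ax.text(r.state_before, r.state_after,
                    f"{val:.3g}" + (" ▲" if r.low_n_flag else ""),
                    ha="center", va="center", fontsize=7, color="w")
    ax.set_xlabel("state before")
    ax.set_ylabel("state after")
    ax.set_xticks(range(1, 7), [f"S{i}" for i in range(1, 7)])
    ax.set_yticks(range(1, 7), [f"S{i}" for i in range(1, 7)])
    ax.figure.colorbar(mesh, ax=ax, label=layer.replace("_", " "))
    return ax


# ---------------------------------------------------------------------------
# occupancies


def occupancy(photon_values: np.ndarray,
              state_means=None, state_sds=None,
              n_boot: int = 10, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """State occupancies S0..S6 from the pooled photon histogram.

    A seven-Gaussian mixture with means frozen to the emission table gives
    the weights; the error is the SD over ``n_boot`` parametric-bootstrap
    refits (resample from the fitted mixture, refit, repeat).
    Returns (fractions, errors), fractions summing to 1.
    """
    from .hmm import DEFAULT_STATE_MEANS, DEFAULT_STATE_SDS

    if state_means is None:
        state_means = DEFAULT_STATE_MEANS
    if state_sds is None:
        state_sds = DEFAULT_STATE_SDS
    x = np.asarray(photon_values, dtype=float)
    mu = np.asarray(state_means, dtype=float)
    sd = np.asarray(state_sds, dtype=float)
    fit = fit_mixture(x, mu, sd, freeze_means=True, freeze_sds=True)
    w = fit.weights / fit.weights.sum()
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        xb = fit.sample(len(x), rng)
        fb = fit_mixture(xb, mu, sd, freeze_means=True, freeze_sds=True)
        boots.append(fb.weights / fb.weights.sum())
    errs = np.std(boots, axis=0, ddof=1) if n_boot > 1 else np.full(7, np.nan)
    return w, errs


# ---------------------------------------------------------------------------
# thermodynamics


def equilibrium_constant(k_ij: float, k_ji: float) -> float:
    """K_eq = k_ij / k_ji (units follow the inputs, e.g. M^-1)."""
    if k_ij <= 0 or k_ji <= 0:
        raise ValueError("rates must be positive")
    return k_ij / k_ji


def free_energy(K_eq: float, T: float = CONSTANTS.T,
                constants: ThermoConstants = CONSTANTS) -> float:
    """dG = -RT ln(K_eq), joules per mole."""
    if K_eq <= 0:
        raise ValueError("K_eq must be positive")
    return -constants.R * T * np.log(K_eq)


def activation_energy(k: float, T: float = CONSTANTS.T,
                      constants: ThermoConstants = CONSTANTS) -> float:
    """Transition-state-theory barrier dG# = -RT ln(h k / (k_B T)), J/mol."""
    if k <= 0:
        raise ValueError("rate must be positive")
    return -constants.R * T * np.log(constants.h * k / (constants.k_B * T))


# ---------------------------------------------------------------------------
# condition comparison


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def compare_conditions(mean_a: float, sd_a: float, n_a: int,
                       mean_b: float, sd_b: float, n_b: int,
                       ) -> tuple[float, float, str]:
    """Welch's unequal-variance t-test from summary statistics.

    Returns (t, p, stars) with the conventional star mapping
    (* p < 0.05, ** p < 0.01, *** p < 0.001).  Typical n here is the
    number of videos per condition (4-7).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per condition")
    t, p = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                      equal_var=False)
    stars = ""
    for thresh, s in _STAR_LEVELS:
        if p < thresh:
            stars = s
            break
    return float(t), float(p), stars


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return float(round(x, -int(np.floor(np.log10(abs(x)))) + (sig - 1)))


def fold_ratio(k_num: float, e_num: float, k_den: float, e_den: float,
               sig_figs: int = 2) -> tuple[float, float]:
    """Ratio of two rate constants with first-order error propagation.

    sigma_r = r * sqrt((e_num/k_num)^2 + (e_den/k_den)^2), both rounded to
    the requested significant figures.
    """
    if k_num <= 0 or k_den <= 0:
        raise ValueError("rate constants must be positive")
    r = k_num / k_den
    e = r * np.sqrt((e_num / k_num) ** 2 + (e_den / k_den) ** 2)
    return _round_sig(r, sig_figs), _round_sig(e, sig_figs)
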