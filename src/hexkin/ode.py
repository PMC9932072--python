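"""Mass-action simulation of insulin oligomer assembly in solution.

The reaction scheme couples six species S1..S6 (monomer..hexamer) through
monomer additions (S_m + S1 <-> S_{m+1}), dimer self-association
(S2 + S2 <-> S4), and tetramer addition to the dimer (S2 + S4 <-> S6, with
two experimentally distinct reverse channels k62 and k64 acting as parallel
first-order losses of the hexamer, each regenerating one dimer and one
tetramer).  Association constants are bimolecular (M^-1 s^-1), dissociation
constants unimolecular (s^-1).

Stoichiometric conventions: with d[S2]/dt = +k12 [S1]^2, the monomer
equation carries -2 k12 [S1]^2 (two monomers consumed per dimer formed),
and symmetrically +2 k21 [S2]; the same factor 2 applies to the dimer in
S2 + S2 <-> S4.  Monomer equivalents sum(m * [S_m]) are conserved exactly
by the scheme and to integrator tolerance by the solver.

Endpoint fractions over a concentration sweep are particle-number
normalized (f_m = [S_m] / sum_j [S_j]); the mean oligomeric state is
mu = sum(m * f_m).  The hexamer fraction versus initial concentration is
summarized by the Hill equation f(x) = Bmax x^n_h / (K^n_h + x^n_h), whose
K is the apparent affinity (half-maximal concentration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

__all__ = [
    "SolutionScheme",
    "TimeCourse",
    "FractionTable",
    "HillFit",
    "integrate",
    "endpoint_fractions",
    "hill_fit",
    "hill_curve",
    "gillespie_check",
]

AVOGADRO = 6.02214076e23


@dataclass
class SolutionScheme:
    """Rate constants of the solution assembly network.

    Association (M^-1 s^-1): k12, k23, k34, k45, k56 (monomer additions),
    k24 (dimer + dimer), k26 (dimer + tetramer).  Dissociation (s^-1):
    k21, k32, k43, k54, k65 (monomer losses), k42 (tetramer -> 2 dimers),
    k62 + k64 (parallel reverse channels of S2 + S4 <-> S6).  k64 defaults
    to the 0.01 s^-1 upper-bound convention; k26 and k62 are zero except
    under Zn2+ + phenol.  ``use_k46`` optionally substitutes
    max(k26, k46) as the S2 + S4 forward rate when a tetramer-side
    measurement is available.
    """

    k12: float = 0.0
    k21: float = 0.0
    k23: float = 0.0
    k32: float = 0.0
    k34: float = 0.0
    k43: float = 0.0
    k45: float = 0.0
    k54: float = 0.0
    k56: float = 0.0
    k65: float = 0.0
    k24: float = 0.0
    k42: float = 0.0
    k26: float = 0.0
    k62: float = 0.0
    k64: float = 0.01
    k46: float = 0.0
    use_k46: bool = False

    def __post_init__(self) -> None:
        for name, value in self.rate_dict().items():
            if value < 0:
                raise ValueError(f"negative rate constant {name}")

    def rate_dict(self) -> dict[str, float]:
        d = asdict(self)
        d.pop("use_k46")
        return d

    @property
    def k26_effective(self) -> float:
        return max(self.k26, self.k46) if self.use_k46 else self.k26

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SolutionScheme":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


def _rhs(scheme: SolutionScheme):
    s = scheme
    k26 = s.k26_effective
    krev26 = s.k62 + s.k64

    def f(t, y):
        S1, S2, S3, S4, S5, S6 = y
        a12 = s.k12 * S1 * S1
        a23 = s.k23 * S2 * S1
        a34 = s.k34 * S3 * S1
        a45 = s.k45 * S4 * S1
        a56 = s.k56 * S5 * S1
        a24 = s.k24 * S2 * S2
        a26 = k26 * S2 * S4
        d21 = s.k21 * S2
        d32 = s.k32 * S3
        d43 = s.k43 * S4
        d54 = s.k54 * S5
        d65 = s.k65 * S6
        d42 = s.k42 * S4
        d62 = krev26 * S6
        return [
            -2 * a12 + 2 * d21 - a23 + d32 - a34 + d43 - a45 + d54 - a56 + d65,
            a12 - d21 - a23 + d32 - 2 * a24 + 2 * d42 - a26 + d62,
            a23 - d32 - a34 + d43,
            a34 - d43 + a24 - d42 - a45 + d54 - a26 + d62,
            a45 - d54 - a56 + d65,
            a56 - d65 + a26 - d62,
        ]

    return f


@dataclass
class TimeCourse:
    times: np.ndarray  # seconds
    concentrations: np.ndarray  # (n_times, 6) molar, columns S1..S6
    initial_monomer: float

    @property
    def endpoint(self) -> np.ndarray:
        return self.concentrations[-1]

    def monomer_equivalents(self) -> np.ndarray:
        m = np.arange(1, 7)
        return self.concentrations @ m


def integrate(scheme: SolutionScheme, initial_monomer: float,
              t_end: float = 300.0, n_steps: int = 200,
              rtol: float = 1e-8) -> TimeCourse:
    """Stiff integration of the mass-action equations from pure monomer.

    Defaults follow the published protocol: 300 s of reaction in 200
    reporting steps.  The solver is BDF with relative tolerance 1e-8 and
    an absolute tolerance scaled to the initial concentration, which keeps
    monomer-equivalent conservation at the 1e-9 relative level.
    """
    if initial_monomer <= 0:
        raise ValueError("initial monomer concentration must be positive")
    y0 = [initial_monomer, 0, 0, 0, 0, 0]
    t_eval = np.linspace(0.0, t_end, n_steps + 1)
    sol = solve_ivp(_rhs(scheme), (0.0, t_end), y0, method="BDF",
                    t_eval=t_eval, rtol=rtol, atol=initial_monomer * 1e-14)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    conc = np.clip(sol.y.T, 0.0, None)
    return TimeCourse(times=sol.t, concentrations=conc,
                      initial_monomer=initial_monomer)


@dataclass
class FractionTable:
    initial_concentrations: np.ndarray  # molar
    fractions: np.ndarray  # (n_conc, 6) endpoint fractions f1..f6
    mean_state: np.ndarray  # mu per concentration
    normalization: str = "particle"  # or "monomer_equivalent"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, columns=[f"f{m}" for m in range(1, 7)])
        df.insert(0, "initial_monomer", self.initial_concentrations)
        df["mean_state"] = self.mean_state
        return df


def endpoint_fractions(sweep: np.ndarray, scheme: SolutionScheme,
                       t_end: float = 300.0, n_steps: int = 200,
                       normalization: str = "particle") -> FractionTable:
    """Endpoint oligomer fractions across an initial-concentration sweep.

    ``normalization='particle'`` (default) divides by the particle-number
    total sum_j [S_j]; ``'monomer_equivalent'`` weights each species by its
    size first.  The mean oligomeric state is mu = sum(m * f_m) under the
    particle normalization.
    """
    sweep = np.asarray(sweep, dtype=float)
    m = np.arange(1, 7)
    fracs = np.empty((len(sweep), 6))
    mus = np.empty(len(sweep))
    for i, c0 in enumerate(sweep):
        tc = integrate(scheme, c0, t_end=t_end, n_steps=n_steps)
        end = tc.endpoint
        if normalization == "particle":
            f = end / end.sum()
        elif normalization == "monomer_equivalent":
            f = (m * end) / (m * end).sum()
        else:
            raise ValueError("unknown normalization")
        fracs[i] = f
        mus[i] = float((m * (end / end.sum())).sum())
    return FractionTable(initial_concentrations=sweep, fractions=fracs,
                         mean_state=mus, normalization=normalization)


def default_sweep(low: float = 1e-9, high: float = 1e-3, n: int = 25) -> np.ndarray:
    """Logarithmic initial-concentration grid, 1 nM to 1 mM by default."""
    return np.logspace(np.log10(low), np.log10(high), n)


def plot_fractions(table: FractionTable, ax=None):
    """Stacked endpoint-fraction plot over the concentration sweep."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 3.5))
    labels = [f"S{m}" for m in range(1, 7)]
    ax.stackplot(table.initial_concentrations, table.fractions.T,
                 labels=labels)
    ax.set_xscale("log")
    ax.set_xlabel("initial monomer concentration (M)")
    ax.set_ylabel("endpoint fraction")
    ax.set_ylim(0, 1)
    ax.legend(loc="center left", fontsize=7)
    return ax


# ---------------------------------------------------------------------------
# Hill fit


@dataclass
class HillFit:
    K: float  # molar, half-maximal concentration (apparent affinity)
    n_h: float  # Hill coefficient
    B_max: float  # maximal hexamer fraction
    covariance: np.ndarray
    ok: bool = True

    def __post_init__(self) -> None:
        if self.ok and not (self.K > 0 and 0 < self.B_max <= 1.0 + 1e-9):
            raise ValueError("invalid Hill parameters")


def hill_curve(x, B_max: float, K: float, n_h: float):
    x = np.asarray(x, dtype=float)
    return B_max * x**n_h / (K**n_h + x**n_h)


def hill_fit(table: FractionTable, species: int = 6) -> HillFit:
    """Fit the chosen species' endpoint fraction with the Hill equation.

    Nonlinear least squares with positivity bounds; the half-maximal
    concentration K is the apparent affinity.  Flat (non-sigmoidal) data
    return a flagged failure instead of a spurious fit.
    """
    x = table.initial_concentrations
    y = table.fractions[:, species - 1]
    if len(x) < 5:
        raise ValueError("need at least 5 concentration points")
    if y.max() - y.min() < 1e-6:
        return HillFit(np.nan, np.nan, np.nan, np.full((3, 3), np.nan), ok=False)
    half = y.min() + 0.5 * (y.max() - y.min())
    K0 = float(np.interp(half, y, x)) if np.all(np.diff(y) >= 0) else float(np.median(x))
    p0 = [min(max(y.max(), 1e-6), 1.0), K0, 1.0]
    try:
        popt, pcov = curve_fit(hill_curve, x, y, p0=p0,
                               bounds=([1e-12, 1e-15, 1e-3], [1.0, 1.0, 10.0]),
                               maxfev=20000)
    except RuntimeError:
        return HillFit(np.nan, np.nan, np.nan, np.full((3, 3), np.nan), ok=False)
    B_max, K, n_h = popt
    return HillFit(K=float(K), n_h=float(n_h), B_max=float(B_max),
                   covariance=pcov, ok=True)


# ---------------------------------------------------------------------------
# stochastic cross-check


def _reactions(scheme: SolutionScheme):
    """(stoichiometry vector, order-2 pair or order-1 index, k) triples.

    Bimolecular propensities convert as a = k n_i n_j / (N_A V) for
    distinct reactants and a = k n (n - 1) / (N_A V) for identical ones —
    the count-space image of the deterministic terms k [S_i][S_j] and
    k [S_i]^2 used above.
    """
    s = scheme
    rx = []

    def add(stoich, kind, who, k):
        if k > 0:
            rx.append((np.array(stoich, dtype=np.int64), kind, who, k))

    # monomer additions S_m + S1 -> S_{m+1}
    add([-2, 1, 0, 0, 0, 0], "homo2", 0, s.k12)
    add([-1, -1, 1, 0, 0, 0], "bi", (0, 1), s.k23)
    add([-1, 0, -1, 1, 0, 0], "bi", (0, 2), s.k34)
    add([-1, 0, 0, -1, 1, 0], "bi", (0, 3), s.k45)
    add([-1, 0, 0, 0, -1, 1], "bi", (0, 4), s.k56)
    add([0, -2, 0, 1, 0, 0], "homo2", 1, s.k24)
    add([0, -1, 0, -1, 0, 1], "bi", (1, 3), s.k26_effective)
    # dissociations
    add([2, -1, 0, 0, 0, 0], "uni", 1, s.k21)
    add([1, 1, -1, 0, 0, 0], "uni", 2, s.k32)
    add([1, 0, 1, -1, 0, 0], "uni", 3, s.k43)
    add([1, 0, 0, 1, -1, 0], "uni", 4, s.k54)
    add([1, 0, 0, 0, 1, -1], "uni", 5, s.k65)
    add([0, 2, 0, -1, 0, 0], "uni", 3, s.k42)
    add([0, 1, 0, 1, 0, -1], "uni", 5, s.k62 + s.k64)
    return rx


def gillespie_check(scheme: SolutionScheme, initial_monomer: float,
                    volume: float, seed: int, t_end: float = 300.0,
                    n_report: int = 200,
                    max_events: int = 50_000_000) -> TimeCourse:
    """Exact stochastic simulation of the same network in a finite volume.

    Counts start as pure monomer, n = round(C0 * N_A * V); concentrations
    are reported on the same time grid as :func:`integrate` so the two can
    be compared directly.  At >= 1e4 particles the mean trajectory should
    track the ODE within Monte-Carlo error.
    """
    nav = AVOGADRO * volume
    n0 = int(round(initial_monomer * nav))
    if n0 < 1:
        raise ValueError("volume too small: fewer than one particle")
    rng = np.random.default_rng(seed)
    rx = _reactions(scheme)
    if not rx:
        times = np.linspace(0.0, t_end, n_report + 1)
        conc = np.zeros((n_report + 1, 6))
        conc[:, 0] = n0 / nav
        return TimeCourse(times, conc, initial_monomer)
    stoich = np.stack([r[0] for r in rx])
    n = np.zeros(6, dtype=np.int64)
    n[0] = n0
    report_t = np.linspace(0.0, t_end, n_report + 1)
    out = np.zeros((n_report + 1, 6))
    out[0] = n
    t = 0.0
    next_report = 1
    events = 0
    props = np.empty(len(rx))
    while t < t_end and events < max_events:
        for i, (_, kind, who, k) in enumerate(rx):
            if kind == "uni":
                props[i] = k * n[who]
            elif kind == "bi":
                props[i] = k * n[who[0]] * n[who[1]] / nav
            else:  # homo2
                props[i] = k * n[who] * (n[who] - 1) / nav
        total = props.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        while next_report <= n_report and report_t[next_report] <= t:
            out[next_report] = n
            next_report += 1
        if t >= t_end:
            break
        r = rng.random() * total
        acc = 0.0
        i = len(rx) - 1
        for j in range(len(rx)):
            acc += props[j]
            if r < acc:
                i = j
                break
        n += stoich[i]
        events += 1
    while next_report <= n_report:
        out[next_report] = n
        next_report += 1
    return TimeCourse(times=report_t, concentrations=out / nav,
                      initial_monomer=initial_monomer)
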