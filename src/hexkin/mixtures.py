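"""1-D Gaussian mixture EM with optionally frozen means and widths.

Shared by the state-occupancy fit (seven components anchored at the HMM
emission means) and the solution-composition fit (five components anchored
at integer multiples of the monomer photon calibration).  Freezing the
component locations keeps low-weight components identifiable, which free
EM cannot guarantee when a species contributes a percent or less of the
events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MixtureFit", "fit_mixture"]


@dataclass
class MixtureFit:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        return rng.normal(self.means[comp], self.sds[comp])


def _log_gauss(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    # (n, k) log densities
    z = (x[:, None] - mu[None, :]) / sd[None, :]
    return -0.5 * z**2 - np.log(sd[None, :]) - 0.5 * np.log(2 * np.pi)


def fit_mixture(x: np.ndarray, means: np.ndarray, sds: np.ndarray,
                weights: np.ndarray | None = None,
                freeze_means: bool = True, freeze_sds: bool = True,
                max_iter: int = 500, tol: float = 1e-8,
                min_sd: float = 1e-3) -> MixtureFit:
    """EM fit of a k-component 1-D Gaussian mixture.

    ``means``/``sds`` are the (initial or frozen) component parameters;
    weights start uniform unless given.  A component whose responsibility
    mass empties out keeps weight 0 without erroring.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(means, dtype=float).copy()
    sd = np.asarray(sds, dtype=float).copy()
    k = len(mu)
    w = (np.full(k, 1.0 / k) if weights is None
         else np.asarray(weights, dtype=float).copy())
    w = w / w.sum()
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    prev_ll = -np.inf
    ll = prev_ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = _log_gauss(x, mu, sd) + np.log(np.maximum(w, 1e-300))[None, :]
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float((np.log(tot[:, 0]) + m[:, 0]).sum())
        nk = resp.sum(axis=0)
        w = nk / n
        if not freeze_means:
            upd = nk > 1e-12
            mu[upd] = (resp[:, upd] * x[:, None]).sum(axis=0)[upd] / nk[upd]
        if not freeze_sds:
            upd = nk > 1e-12
            var = (resp[:, upd] * (x[:, None] - mu[None, upd]) ** 2).sum(axis=0) / nk[upd]
            sd[upd] = np.sqrt(np.maximum(var, min_sd**2))
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll
    return MixtureFit(means=mu, sds=sd, weights=w, loglik=ll, n_iter=it,
                      converged=converged)
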