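"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed-form code paths they are used to check:
the PDE oracle is a Crank-Nicolson finite-difference solver of the same
initial/boundary-value problem, and the bootstrap oracle enumerates the full
resampling distribution on tiny samples.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import solve_banded


def crank_nicolson_profile(
    tau_out: list[float], n_nodes: int = 4001, n_steps: int = 20_000, tau0: float = 1e-9
) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    """Solve dc/dtau = d2c/du2 on u in [0,1], c(0,tau)=1, c(1,tau)=0, c(u,0)=0.

    tau = DL2 * t is dimensionless time.  Geometrically graded time steps
    resolve the sharp front near tau = 0.  Returns the node grid and the
    dimensionless concentration (units of the surface value) at each requested
    tau.  Multiply by K * Cveh for physical concentrations.
    """
    u = np.linspace(0.0, 1.0, n_nodes)
    h = u[1] - u[0]
    taus = np.concatenate([[0.0], np.geomspace(tau0, max(tau_out), n_steps)])
    c = np.zeros(n_nodes)
    c[0] = 1.0
    out: dict[float, np.ndarray] = {}
    targets = sorted(tau_out)
    ti = 0
    n_int = n_nodes - 2
    for k in range(1, len(taus)):
        dt = taus[k] - taus[k - 1]
        r = dt / (2.0 * h * h)
        ab = np.zeros((3, n_int))
        ab[0, 1:] = -r
        ab[1, :] = 1.0 + 2.0 * r
        ab[2, :-1] = -r
        rhs = c[1:-1] + r * (c[2:] - 2.0 * c[1:-1] + c[:-2])
        rhs[0] += r  # left boundary value 1 on the implicit side
        c = np.concatenate([[1.0], solve_banded((1, 1), ab, rhs), [0.0]])
        while ti < len(targets) and taus[k] >= targets[ti] - 1e-15:
            out[targets[ti]] = c.copy()
            ti += 1
    return u, out


def exhaustive_bootstrap_ratio_ci(
    test: np.ndarray, reference: np.ndarray, confidence: float = 0.90
) -> tuple[float, float]:
    """Exact percentile bootstrap CI of mean(test)/mean(reference).

    Enumerates every resample with replacement of both samples (n^n each), so
    it is only feasible for very small n; used to check the seeded Monte Carlo
    bootstrap.
    """
    def all_means(x: np.ndarray) -> np.ndarray:
        idx = np.array(list(itertools.product(range(x.size), repeat=x.size)))
        return x[idx].mean(axis=1)

    ratios = np.divide.outer(all_means(np.asarray(test)), all_means(np.asarray(reference))).ravel()
    lo, hi = np.quantile(ratios, [(1 - confidence) / 2, (1 + confidence) / 2])
    return float(lo), float(hi)
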