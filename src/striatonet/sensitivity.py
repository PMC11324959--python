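"""Polynomial chaos expansion (PCE) and Sobol sensitivity indices.

Uniform inputs are mapped affinely to [-1, 1]^d and expanded in a
total-degree-truncated tensor Legendre basis.  Coefficients come from
pseudo-spectral projection: the model is evaluated on the full
Gauss-Legendre tensor grid with (p+1) nodes per dimension — (p+1)^d model
runs — and each coefficient is the quadrature inner product
c_n = <Y, Psi_n> / <Psi_n, Psi_n>.  First- and higher-order Sobol indices
follow from the coefficient norms: the variance share of the basis terms
involving exactly the inputs of the index.

The quantity of interest for the network studies is the windowed firing
rate; indices are reported per 10 ms bin plus the window average, with a
common simulation seed across quadrature nodes so index fluctuation
reflects the parameters and not realisation noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from numpy.polynomial.legendre import leggauss

from .connectome import SpatialNetwork
from .dynamics import DBSParams, ModelParams, simulate

__all__ = [
    "PCEConfig",
    "PCEResult",
    "SobolResult",
    "legendre",
    "total_degree_multi_indices",
    "pce_fit",
    "sobol_indices",
    "run_sensitivity",
]


def legendre(n: int, x):
    """Legendre polynomial P_n(x) on [-1, 1] via the three-term recurrence
    (n+1) P_{n+1} = (2n+1) x P_n - n P_{n-1}."""
    if n < 0:
        raise ValueError("polynomial degree must be >= 0")
    x = np.asarray(x, float)
    p_prev = np.ones_like(x)
    if n == 0:
        return p_prev
    p = x.copy()
    for k in range(1, n):
        p, p_prev = ((2 * k + 1) * x * p - k * p_prev) / (k + 1), p
    return p


def total_degree_multi_indices(p: int, d: int) -> list[tuple[int, ...]]:
    """Multi-indices with total degree <= p, graded-lexicographic order."""
    out = [idx for idx in product(range(p + 1), repeat=d) if sum(idx) <= p]
    out.sort(key=lambda idx: (sum(idx), idx))
    return out


@dataclass
class PCEConfig:
    """Pseudo-spectral projection setup for d uniform inputs."""

    ranges: list[tuple[float, float]]
    order: int = 3
    names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("polynomial order must be >= 1")
        for lo, hi in self.ranges:
            if hi < lo:
                raise ValueError("input range must have hi >= lo")
        if self.names is None:
            self.names = [f"x{i}" for i in range(self.d)]

    @property
    def d(self) -> int:
        return len(self.ranges)

    @property
    def n_samples(self) -> int:
        return (self.order + 1) ** self.d

    def nodes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(physical nodes (n_s, d), reference nodes in [-1,1]^d, weights).

        Weights are normalised to the uniform probability measure
        (sum of weights = 1).
        """
        x1, w1 = leggauss(self.order + 1)
        Z = np.array(list(product(x1, repeat=self.d)))
        W = np.prod(np.array(list(product(w1 / 2.0, repeat=self.d))), axis=1)
        lo = np.array([r[0] for r in self.ranges])
        hi = np.array([r[1] for r in self.ranges])
        X = lo + (Z + 1.0) / 2.0 * (hi - lo)
        return X, Z, W


@dataclass
class PCEResult:
    config: PCEConfig
    multi_indices: list[tuple[int, ...]]
    coefficients: np.ndarray  # (N_p,) or (N_p, n_outputs)
    norms: np.ndarray  # <Psi_n, Psi_n> under the uniform measure

    def mean(self) -> np.ndarray:
        return self.coefficients[0]

    def variance(self) -> np.ndarray:
        c = self.coefficients[1:]
        return (c.T**2 * self.norms[1:]).T.sum(axis=0)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the surrogate at physical points X (n, d)."""
        X = np.atleast_2d(np.asarray(X, float))
        lo = np.array([r[0] for r in self.config.ranges])
        hi = np.array([r[1] for r in self.config.ranges])
        span = np.where(hi > lo, hi - lo, 1.0)
        Z = 2.0 * (X - lo) / span - 1.0
        Psi = np.array(
            [np.prod([legendre(k, Z[:, j]) for j, k in enumerate(idx)], axis=0) for idx in self.multi_indices]
        )
        return Psi.T @ self.coefficients


def pce_fit(model, config: PCEConfig, seed: int | None = None) -> PCEResult:
    """Fit the PCE surrogate by pseudo-spectral projection.

    ``model`` maps a length-d parameter vector to a scalar or 1-D output
    vector (e.g. a binned time trace); it is evaluated at all (p+1)^d
    Gauss-Legendre tensor nodes.  ``seed`` is forwarded to the model if it
    accepts one (common random numbers across nodes).
    """
    X, Z, W = config.nodes()
    outputs = []
    for xi in X:
        try:
            y = model(xi, seed=seed) if seed is not None else model(xi)
        except TypeError:
            y = model(xi)
        except Exception as exc:  # noqa: BLE001 - abort with node coordinates
            raise RuntimeError(f"model evaluation failed at node {xi.tolist()}") from exc
        y = np.atleast_1d(np.asarray(y, float))
        if not np.isfinite(y).all():
            raise RuntimeError(f"model returned non-finite output at node {xi.tolist()}")
        outputs.append(y)
    Y = np.array(outputs)  # (n_s, n_out)

    indices = total_degree_multi_indices(config.order, config.d)
    # Psi_n at reference nodes; 1-D norms: int_{-1}^{1} P_k^2 dx/2 = 1/(2k+1)
    Psi = np.array(
        [np.prod([legendre(k, Z[:, j]) for j, k in enumerate(idx)], axis=0) for idx in indices]
    )  # (N_p, n_s)
    norms = np.array([np.prod([1.0 / (2 * k + 1) for k in idx]) for idx in indices])
    coeffs = (Psi * W) @ Y / norms[:, None]
    if coeffs.shape[1] == 1:
        coeffs = coeffs.ravel()
    return PCEResult(config=config, multi_indices=indices, coefficients=coeffs, norms=norms)


@dataclass
class SobolResult:
    """First- and higher-order Sobol indices (per output bin if the QoI is
    a trace)."""

    first_order: dict[str, np.ndarray]
    higher_order: dict[tuple[str, ...], np.ndarray]
    variance: np.ndarray
    qoi: np.ndarray | None = None  # surrogate-mean QoI trace
    t: np.ndarray | None = None
    degenerate: np.ndarray | None = None  # bins where total variance ~ 0

    def time_average(self, name_or_tuple) -> float:
        """Variance-weighted average over defined bins of one index."""
        s = (
            self.first_order[name_or_tuple]
            if isinstance(name_or_tuple, str)
            else self.higher_order[tuple(name_or_tuple)]
        )
        s = np.atleast_1d(s)
        ok = ~np.atleast_1d(self.degenerate) if self.degenerate is not None else np.isfinite(s)
        if not np.any(ok):
            raise ValueError("all bins degenerate: zero output variance")
        return float(np.mean(s[ok]))


def sobol_indices(pce: PCEResult, rel_tol: float = 1e-12) -> SobolResult:
    """PC-based Sobol indices from the coefficient norms.

    S_u = sum of c_n^2 <Psi_n, Psi_n> over basis terms whose active inputs
    are exactly the set u, divided by the total variance.  Bins with (near)
    zero variance are flagged degenerate rather than NaN-propagated.
    """
    names = pce.config.names
    c = np.atleast_2d(pce.coefficients.T).T  # (N_p, n_out)
    contrib = (c**2) * pce.norms[:, None]
    var_total = contrib[1:].sum(axis=0)
    scale = np.maximum(contrib.sum(axis=0), 1e-300)
    degenerate = var_total <= rel_tol * scale
    denom = np.where(degenerate, 1.0, var_total)

    first: dict[str, np.ndarray] = {nm: np.zeros(c.shape[1]) for nm in names}
    higher: dict[tuple[str, ...], np.ndarray] = {}
    for n_i, idx in enumerate(pce.multi_indices):
        active = tuple(j for j, k in enumerate(idx) if k > 0)
        if not active:
            continue
        if len(active) == 1:
            first[names[active[0]]] += contrib[n_i]
        else:
            key = tuple(names[j] for j in active)
            higher.setdefault(key, np.zeros(c.shape[1]))
            higher[key] += contrib[n_i]
    for d_ in (first, higher):
        for k in d_:
            d_[k] = np.where(degenerate, np.nan, d_[k] / denom)
            if d_[k].size == 1:
                d_[k] = d_[k].ravel()
    return SobolResult(
        first_order=first,
        higher_order=higher,
        variance=var_total if var_total.size > 1 else var_total.ravel(),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# striatal parameter studies
# ---------------------------------------------------------------------------

DRIVE_RANGES = {"I0": (1.5, 5.0), "g_MM": (0.0, 0.1)}  # printed study intervals


def run_sensitivity(
    net: SpatialNetwork,
    params: ModelParams,
    study: str = "drive",
    ranges: dict[str, tuple[float, float]] | None = None,
    window: tuple[float, float] = (200.0, 400.0),
    bin_ms: float = 10.0,
    order: int = 3,
    dt: float = 0.05,
    seed: int = 0,
    dbs_template: DBSParams | None = None,
) -> SobolResult:
    """PCE Sobol study of the windowed firing rate.

    ``study="drive"`` varies (I0, g_MM) on the printed intervals;
    ``study="dbs"`` varies (A_DBS, f_DBS) and requires explicit ``ranges``
    (the study intervals are not printed) plus a ``dbs_template`` carrying
    electrode position, pulse width and spread.
    """
    from dataclasses import replace

    from .observables import mean_activity

    t0, t1 = window
    n_bins = int(round((t1 - t0) / bin_ms))

    if study == "drive":
        names = ["I0", "g_MM"]
        rr = [DRIVE_RANGES["I0"], DRIVE_RANGES["g_MM"]] if ranges is None else [ranges[n] for n in names]
    elif study == "dbs":
        names = ["A_DBS", "f_DBS"]
        if ranges is None:
            raise ValueError("the DBS study requires explicit ranges for A_DBS and f_DBS")
        rr = [ranges[n] for n in names]
        if dbs_template is None:
            raise ValueError("the DBS study requires a dbs_template (position, delta, sigma)")
    else:
        raise ValueError(f"unknown study {study!r}")

    def model(x, seed=seed):
        if study == "drive":
            p = replace(
                params,
                drive=replace(params.drive, I0=float(x[0])),
                syn=replace(params.syn, g_MM=float(x[1])),
            )
            dbs = dbs_template
        else:
            p = params
            dbs = replace(dbs_template, amplitude=float(x[0]), frequency=float(x[1]))
        res = simulate(net, p, dbs=dbs, t_end=t1, dt=dt, seed=seed)
        clipped = [s[(s >= t0) & (s < t1)] - t0 for s in res.spikes]
        act = mean_activity(clipped, net.n, t1 - t0, window=bin_ms)
        return act.rate

    cfg = PCEConfig(ranges=rr, order=order, names=names)
    pce = pce_fit(model, cfg, seed=seed)
    result = sobol_indices(pce)
    result.qoi = np.atleast_1d(pce.mean())
    result.t = t0 + np.arange(n_bins) * bin_ms
    return result
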