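"""Conductance-based striatal network dynamics.

Two cell classes are integrated on the directed connectome:

* **MSN** (medium spiny neuron): fast Na (m^3 h), delayed-rectifier K (m^4),
  leak and a non-inactivating M-type K current (m^1), with the classic
  alpha/beta rate functions of the predecessor striatal MSN model.
* **FS** (fast-spiking interneuron): fast Na with instantaneous activation
  (m_inf^3 h), Kv3-type K (n^2), leak, and a fast-activating slowly
  inactivating dendritic D-current (m^3 h) that delays firing onset.

All synapses are GABAergic: each neuron carries a first-order gate
``ds/dt = alpha (1 - s) H(V) - beta s`` with the smooth activation
``H(V) = 1 + tanh(V/10)``, and a postsynaptic neuron i receives
``g_XY (V_i - E_GABA) sum_j A_ij s_j`` split by presynaptic class.

DBS is a pulsed current with unnormalised Gaussian spatial falloff around
the electrode: within each period ``T = 1000/f`` the pulse is on during the
window ``(T/2 - delta, T/2)`` (duty cycle ``delta/T``).

Units: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2.

Parameter provenance
--------------------
The printed model constants are E_GABA = -80 mV, the gate rates
(alpha=4, beta=1/13 for MSN sources, 1/11 for FS sources) and the drive
levels I0 = 5 (healthy) / 1.5 (abnormal).  Membrane conductances, reversal
potentials and capacitances are inherited from the predecessor MSN and FS
models whose rate functions this module reproduces; they are tagged
``provenance="inherited"`` in :mod:`striatonet.config`.  Coupling
conductances and the DBS spatial spread are unprinted and tagged
``provenance="chosen"`` (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .connectome import SpatialNetwork

__all__ = [
    "MSNParams",
    "FSParams",
    "SynapseParams",
    "DriveParams",
    "DBSParams",
    "ModelParams",
    "SimulationResult",
    "msn_rates",
    "fs_steady_states",
    "fs_time_constants",
    "synaptic_gate_rhs",
    "synaptic_current",
    "dbs_pulse",
    "dbs_current",
    "simulate",
    "single_neuron_network",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MSNParams:
    """MSN membrane constants (inherited from the predecessor MSN model)."""

    C: float = 1.0
    g_Na: float = 100.0
    g_K: float = 80.0
    g_leak: float = 0.1
    g_M: float = 1.3
    E_Na: float = 50.0
    E_K: float = -100.0
    E_leak: float = -67.0
    # M-current kinetics: "mccarthy" (default) uses the predecessor model's
    # slow M-current rates; "as_printed" duplicates the fast-K kinetics as
    # the source description (likely erroneously) prints them.  Only the
    # default reproduces the low-drive firing regime (see docs/methods.md).
    m_current_kinetics: str = "mccarthy"


@dataclass(frozen=True)
class FSParams:
    """FS membrane constants (inherited from the predecessor FS model)."""

    C: float = 1.0
    g_Na: float = 112.5
    g_K: float = 225.0
    g_leak: float = 0.25
    g_D: float = 0.39
    E_Na: float = 50.0
    E_K: float = -90.0
    E_leak: float = -70.0
    # Na inactivation steepness as printed is increasing in V; set True to
    # restore the conventional decreasing (inactivating) sigmoid.
    h_inactivating: bool = False
    tau_mD: float = 2.0
    tau_hD: float = 150.0


@dataclass(frozen=True)
class SynapseParams:
    """GABAergic gate rates and coupling conductances.

    alpha/beta are per presynaptic class (MSN sources decay at 1/13 per ms,
    FS sources at 1/11).  Coupling conductances g_XY are presynaptic X ->
    postsynaptic Y.
    """

    alpha: float = 4.0
    beta_msn: float = 1.0 / 13.0
    beta_fs: float = 1.0 / 11.0
    g_MM: float = 0.003
    g_FM: float = 0.033
    g_FF: float = 0.01
    g_MF: float = 0.002
    E_GABA: float = -80.0


@dataclass(frozen=True)
class DriveParams:
    """Cortico-striatal / dopaminergic drive I0 (uA/cm^2), plus optional
    zero-mean membrane noise amplitude (off by default)."""

    I0: float = 5.0
    noise_amp: float = 0.0


@dataclass(frozen=True)
class DBSParams:
    """Pulsed DBS: electrode centre (mm), amplitude (uA/cm^2), frequency
    (Hz), pulse width delta (ms), Gaussian spread sigma (mm)."""

    x0: float = 0.0
    y0: float = 0.0
    z0: float = 0.0
    amplitude: float = 0.0
    frequency: float = 130.0
    delta: float = 1.0
    sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("f_DBS must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("A_DBS must be non-negative")
        if not 0 < self.delta < self.period:
            raise ValueError("pulse width delta must lie in (0, T_DBS)")

    @property
    def period(self) -> float:
        return 1000.0 / self.frequency

    @property
    def centre(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.z0])

    @property
    def r(self) -> np.ndarray:
        """The 5-vector (x0, y0, z0, A_DBS, f_DBS)."""
        return np.array([self.x0, self.y0, self.z0, self.amplitude, self.frequency])


@dataclass(frozen=True)
class ModelParams:
    msn: MSNParams = field(default_factory=MSNParams)
    fs: FSParams = field(default_factory=FSParams)
    syn: SynapseParams = field(default_factory=SynapseParams)
    drive: DriveParams = field(default_factory=DriveParams)

    def with_drive(self, I0: float) -> "ModelParams":
        return replace(self, drive=replace(self.drive, I0=I0))


# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------


def _lin_over_expm1(c: float, v_half: float, scale: float, V: np.ndarray) -> np.ndarray:
    """c * (V - v_half) / (1 - exp(-(V - v_half)/scale)), limit c*scale at v_half."""
    x = np.asarray(V, float) - v_half
    with np.errstate(over="ignore", invalid="ignore"):
        out = c * x / (1.0 - np.exp(-x / scale))
    return np.where(np.abs(x) < 1e-7, c * scale, out)


def msn_rates(V, kinetics: str = "as_printed"):
    """alpha/beta rates (1/ms) for the four MSN gates (m_Na, h_Na, m_K, m_M).

    Removable singularities are evaluated by their limits.
    """
    V = np.asarray(V, float)
    a_m = _lin_over_expm1(0.32, -54.0, 4.0, V)
    # 0.28 (V+27)/(e^{(V+27)/5} - 1) == -0.28 (V+27)/(1 - e^{-(V+27)/(-5)})
    b_m = _lin_over_expm1(-0.28, -27.0, -5.0, V)
    a_h = 0.128 * np.exp(-(V + 50.0) / 18.0)
    b_h = 4.0 / (1.0 + np.exp(-(V + 27.0) / 5.0))
    a_n = _lin_over_expm1(0.032, -52.0, 5.0, V)
    b_n = 0.5 * np.exp(-(V + 57.0) / 40.0)
    if kinetics == "as_printed":
        # the M-current rates are printed identically to the fast-K rates
        a_M, b_M = a_n, b_n
    elif kinetics == "mccarthy":
        a_M = _lin_over_expm1(3.209e-4, -30.0, 9.0, V)
        b_M = _lin_over_expm1(-3.209e-4, -30.0, -9.0, V)
    else:
        raise ValueError(f"unknown M-current kinetics {kinetics!r}")
    return a_m, b_m, a_h, b_h, a_n, b_n, a_M, b_M


def _sigmoid(V, v_half, slope):
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, float) - v_half) / slope))


def fs_steady_states(V, h_inactivating: bool = False):
    """Steady-state activations (m_Na, h_Na, n_K, m_D, h_D) of the FS gates."""
    m_na = _sigmoid(V, -24.0, 11.5)
    h_na = _sigmoid(V, -58.3, -6.7) if h_inactivating else _sigmoid(V, -58.3, 6.7)
    n_k = _sigmoid(V, -12.4, 6.8)
    m_d = _sigmoid(V, -50.0, 20.0)
    h_d = _sigmoid(V, -70.0, -6.0) if h_inactivating else _sigmoid(V, -70.0, 6.0)
    return m_na, h_na, n_k, m_d, h_d


def fs_time_constants(V, tau_mD: float = 2.0, tau_hD: float = 150.0):
    """Voltage-dependent time constants (ms) of the FS gates (h_Na, n_K,
    m_D, h_D); inherited from the predecessor FS model (only steady states
    are printed)."""
    V = np.asarray(V, float)
    tau_h = 0.5 + 14.0 / (1.0 + np.exp((V + 60.0) / 12.0))
    tau_n = (0.087 + 11.4 / (1.0 + np.exp((V + 14.6) / 8.6))) * (
        0.087 + 11.4 / (1.0 + np.exp(-(V - 1.3) / 18.7))
    )
    ones = np.ones_like(V)
    return tau_h, tau_n, tau_mD * ones, tau_hD * ones


# ---------------------------------------------------------------------------
# synapses and DBS
# ---------------------------------------------------------------------------


def smooth_heaviside(V):
    """H(V) = 1 + tanh(V/10): ~0 at rest, ~2 at spike peak."""
    return 1.0 + np.tanh(np.asarray(V, float) / 10.0)


def synaptic_gate_rhs(s, V_pre, alpha: float, beta: float):
    """ds/dt = alpha (1 - s) H(V_pre) - beta s."""
    return alpha * (1.0 - np.asarray(s, float)) * smooth_heaviside(V_pre) - beta * np.asarray(s, float)


def synaptic_current(i: int, V_i: float, s_vector, net: SpatialNetwork, syn: SynapseParams) -> float:
    """Total GABAergic current onto neuron i (reference implementation).

    The simulator uses the equivalent vectorised sparse product; this direct
    per-neuron sum is retained for spec-level clarity and testing.
    """
    s = np.asarray(s_vector, float)
    row = net.A.getrow(i).toarray().ravel()
    msn = net.table.msn_mask
    sum_m = float((row * s)[msn].sum())
    sum_f = float((row * s)[~msn].sum())
    if net.table.cell_type[i] == "MSN":
        g_m, g_f = syn.g_MM, syn.g_FM
    else:
        g_m, g_f = syn.g_MF, syn.g_FF
    return (V_i - syn.E_GABA) * (g_m * sum_m + g_f * sum_f)


def dbs_pulse(t, params: DBSParams):
    """Temporal pulse factor in {0, 1}: H(sin(2 pi t/T)) (1 - H(sin(2 pi (t+delta)/T)))
    with the sharp step H; on during (T/2 - delta, T/2) within each period."""
    t = np.asarray(t, float)
    T = params.period
    on = (np.sin(2 * np.pi * t / T) > 0) & ~(np.sin(2 * np.pi * (t + params.delta) / T) > 0)
    return on.astype(float)


def dbs_current(pos, t, params: DBSParams):
    """I_DBS at position(s) ``pos`` (mm) and time(s) ``t`` (ms)."""
    if params.amplitude == 0.0:
        return np.zeros(np.broadcast(np.asarray(pos)[..., 0], np.asarray(t)).shape)
    pos = np.atleast_2d(np.asarray(pos, float))
    d2 = ((pos - params.centre) ** 2).sum(axis=-1)
    spatial = params.amplitude * np.exp(-d2 / params.sigma**2)
    out = np.squeeze(np.multiply.outer(spatial, dbs_pulse(t, params)))
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Output of :func:`simulate`."""

    t: np.ndarray  # ms, uniform grid
    spikes: list[np.ndarray]  # spike times per neuron, strictly increasing
    mean_V: np.ndarray  # population-mean membrane potential per step
    V: np.ndarray | None  # traces of recorded neurons, shape (len(record), nt)
    record: np.ndarray | None  # indices of recorded neurons
    s: np.ndarray | None  # gate traces of recorded neurons (optional)
    dbs_waveform: np.ndarray  # A_DBS * pulse(t) at the electrode centre
    dt: float
    n_neurons: int

    def spike_counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spikes])

    def mean_rate(self) -> float:
        """Time-averaged per-neuron firing rate in Hz."""
        dur_s = (self.t[-1] - self.t[0] + self.dt) / 1000.0
        return float(self.spike_counts().sum() / (self.n_neurons * dur_s))


class SimulationBlowup(RuntimeError):
    pass


def single_neuron_network(cell_type: str = "MSN", pos=(0.0, 0.0, 0.0)) -> SpatialNetwork:
    """An isolated single neuron, for fixtures and single-cell studies."""
    from .geometry import NeuronTable

    table = NeuronTable(
        pos=np.array([pos], float),
        nucleus=np.array(["caudate"], object),
        cell_type=np.array([cell_type], object),
    )
    A = sp.csr_matrix((1, 1), dtype=np.int8)
    return SpatialNetwork(table=table, A=A)


def simulate(
    net: SpatialNetwork,
    params: ModelParams | None = None,
    dbs: DBSParams | None = None,
    t_end: float = 1000.0,
    dt: float = 0.05,
    seed: int = 0,
    record: np.ndarray | list[int] | None = None,
    record_s: bool = False,
    v_init_range: tuple[float, float] = (-80.0, -50.0),
    spike_threshold: float = -15.0,
    refractory: float = 1.0,
) -> SimulationResult:
    """Integrate the full network with fixed-step RK4.

    Initial conditions: V uniform over ``v_init_range`` (seeded), gates at
    their steady state for that voltage, s = 0.  Spikes are strict upward
    crossings of ``spike_threshold`` with a ``refractory`` ms lockout.
    Aborts with :class:`SimulationBlowup` naming the first offending neuron
    if the state leaves the finite range.
    """
    if params is None:
        params = ModelParams()
    n = net.n
    msn_idx = np.flatnonzero(net.table.msn_mask)
    fs_idx = np.flatnonzero(net.table.fs_mask)
    nm, nf = len(msn_idx), len(fs_idx)
    mp, fp, syn, drive = params.msn, params.fs, params.syn, params.drive

    # presynaptic-class-split adjacency (CSR slices of columns)
    A_m = net.A[:, msn_idx].tocsr() if nm else None
    A_f = net.A[:, fs_idx].tocsr() if nf else None

    # per-neuron synaptic conductances and gate decay rates
    is_msn = net.table.msn_mask
    g_pre_m = np.where(is_msn, syn.g_MM, syn.g_MF)  # conductance for MSN inputs
    g_pre_f = np.where(is_msn, syn.g_FM, syn.g_FF)  # conductance for FS inputs
    beta = np.where(is_msn, syn.beta_msn, syn.beta_fs)

    # DBS spatial factor per neuron
    if dbs is not None and dbs.amplitude > 0:
        d2 = ((net.table.pos - dbs.centre) ** 2).sum(axis=1)
        dbs_gain = dbs.amplitude * np.exp(-d2 / dbs.sigma**2)
    else:
        dbs_gain = None

    rng = np.random.default_rng(seed)
    V = rng.uniform(*v_init_range, size=n)
    s = np.zeros(n)
    a_m, b_m, a_h, b_h, a_n, b_n, a_M, b_M = msn_rates(V[msn_idx], mp.m_current_kinetics)
    gm = np.vstack([a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n), a_M / (a_M + b_M)]) if nm else np.zeros((4, 0))
    _, h_inf, n_inf, mD_inf, hD_inf = fs_steady_states(V[fs_idx], fp.h_inactivating)
    gf = np.vstack([h_inf, n_inf, mD_inf, hD_inf]) if nf else np.zeros((4, 0))

    nt = int(round(t_end / dt))
    t_grid = np.arange(nt) * dt
    record = np.asarray(record, int) if record is not None else None
    V_rec = np.empty((len(record), nt)) if record is not None else None
    s_rec = np.empty((len(record), nt)) if (record is not None and record_s) else None
    mean_V = np.empty(nt)
    dbs_wave = np.zeros(nt)
    if dbs is not None and dbs.amplitude > 0:
        dbs_wave = dbs.amplitude * dbs_pulse(t_grid, dbs)

    spikes: list[list[float]] = [[] for _ in range(n)]
    last_spike = np.full(n, -np.inf)

    I0 = drive.I0
    noise = drive.noise_amp

    def rhs(t, V, s, gm, gf):
        dV = np.empty(n)
        # synaptic drive
        if nm:
            sum_m = A_m @ s[msn_idx]
        else:
            sum_m = 0.0
        if nf:
            sum_f = A_f @ s[fs_idx]
        else:
            sum_f = 0.0
        I_gaba = (V - syn.E_GABA) * (g_pre_m * sum_m + g_pre_f * sum_f)
        I_app = I0 - I_gaba
        if dbs_gain is not None:
            I_app = I_app + dbs_gain * float(dbs_pulse(t, dbs))

        if nm:
            Vm = V[msn_idx]
            mNa, hNa, nK, mM = gm
            I_ion = (
                mp.g_Na * mNa**3 * hNa * (Vm - mp.E_Na)
                + mp.g_K * nK**4 * (Vm - mp.E_K)
                + mp.g_M * mM * (Vm - mp.E_K)
                + mp.g_leak * (Vm - mp.E_leak)
            )
            dV[msn_idx] = (I_app[msn_idx] - I_ion) / mp.C
            am, bm, ah, bh, an, bn, aM, bM = msn_rates(Vm, mp.m_current_kinetics)
            dgm = np.vstack(
                [
                    am * (1 - mNa) - bm * mNa,
                    ah * (1 - hNa) - bh * hNa,
                    an * (1 - nK) - bn * nK,
                    aM * (1 - mM) - bM * mM,
                ]
            )
        else:
            dgm = gm
        if nf:
            Vf = V[fs_idx]
            hNa_f, nK_f, mD, hD = gf
            m_inf = _sigmoid(Vf, -24.0, 11.5)
            I_ion_f = (
                fp.g_Na * m_inf**3 * hNa_f * (Vf - fp.E_Na)
                + fp.g_K * nK_f**2 * (Vf - fp.E_K)
                + fp.g_D * mD**3 * hD * (Vf - fp.E_K)
                + fp.g_leak * (Vf - fp.E_leak)
            )
            dV[fs_idx] = (I_app[fs_idx] - I_ion_f) / fp.C
            _, h_inf, n_inf, mD_inf, hD_inf = fs_steady_states(Vf, fp.h_inactivating)
            tau_h, tau_n, tau_mD, tau_hD = fs_time_constants(Vf, fp.tau_mD, fp.tau_hD)
            dgf = np.vstack(
                [
                    (h_inf - hNa_f) / tau_h,
                    (n_inf - nK_f) / tau_n,
                    (mD_inf - mD) / tau_mD,
                    (hD_inf - hD) / tau_hD,
                ]
            )
        else:
            dgf = gf
        ds = syn.alpha * (1.0 - s) * smooth_heaviside(V) - beta * s
        return dV, ds, dgm, dgf

    check_every = max(1, int(round(5.0 / dt)))
    for it in range(nt):
        t = t_grid[it]
        mean_V[it] = V.mean()
        if record is not None:
            V_rec[:, it] = V[record]
            if s_rec is not None:
                s_rec[:, it] = s[record]

        k1 = rhs(t, V, s, gm, gf)
        k2 = rhs(t + dt / 2, V + dt / 2 * k1[0], s + dt / 2 * k1[1], gm + dt / 2 * k1[2], gf + dt / 2 * k1[3])
        k3 = rhs(t + dt / 2, V + dt / 2 * k2[0], s + dt / 2 * k2[1], gm + dt / 2 * k2[2], gf + dt / 2 * k2[3])
        k4 = rhs(t + dt, V + dt * k3[0], s + dt * k3[1], gm + dt * k3[2], gf + dt * k3[3])
        V_new = V + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        s = s + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        gm = gm + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        gf = gf + dt / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        if noise > 0:
            V_new = V_new + noise * np.sqrt(dt) * rng.standard_normal(n)

        # gate bound audit: RK4 may overshoot [0,1] by O(dt^5); anything
        # larger signals a genuine instability
        for g in (s, gm.ravel(), gf.ravel()):
            if g.size and (g.min() < -1e-6 or g.max() > 1.0 + 1e-6):
                raise SimulationBlowup(
                    f"gating variable left [0,1] at t={t + dt:.3f} ms"
                )
        np.clip(s, 0.0, 1.0, out=s)
        np.clip(gm, 0.0, 1.0, out=gm)
        np.clip(gf, 0.0, 1.0, out=gf)

        # spike detection: strict upward crossing of threshold
        crossed = (V < spike_threshold) & (V_new >= spike_threshold)
        if crossed.any():
            t_new = t + dt
            for i in np.flatnonzero(crossed):
                if t_new - last_spike[i] >= refractory:
                    spikes[i].append(t_new)
                    last_spike[i] = t_new
        V = V_new

        if it % check_every == 0 and not np.isfinite(V).all():
            bad = int(np.flatnonzero(~np.isfinite(V))[0])
            raise SimulationBlowup(
                f"non-finite membrane potential for neuron {bad} at t={t:.3f} ms"
            )

    if not np.isfinite(V).all():
        bad = int(np.flatnonzero(~np.isfinite(V))[0])
        raise SimulationBlowup(f"non-finite membrane potential for neuron {bad} at end of run")

    return SimulationResult(
        t=t_grid,
        spikes=[np.array(sp_) for sp_ in spikes],
        mean_V=mean_V,
        V=V_rec,
        record=record,
        s=s_rec,
        dbs_waveform=dbs_wave,
        dt=dt,
        n_neurons=n,
    )
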