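"""Reduced mean-field model of coupled neural ensembles.

Each brain region is an infinite ensemble of phase oscillators with
Lorentzian-distributed natural frequencies (center ``Omega``, half-width
``Delta``).  The Ott-Antonsen reduction collapses every ensemble onto its
complex Kuramoto order parameter ``z_n = r_n e^{i psi_n}``, whose dynamics
are

    dr_n/dt  = -Delta r_n + (L_n/2)(1 - r_n^2) r_n
               + (G/2E)(1 - r_n^2) sum_p A_np r_p(t - tau_np)
                 cos(psi_p(t - tau_np) - psi_n)
    dpsi_n/dt = Omega + (G/2E)(r_n + 1/r_n) sum_p A_np r_p(t - tau_np)
                 sin(psi_p(t - tau_np) - psi_n)

with local coupling ``L_n``, global coupling ``G`` and axonal delays
``tau_np = D_np / v``.  An isolated ensemble (G = 0) synchronizes when
``L_n > 2 Delta`` and settles at ``r_eq = sqrt(1 - 2 Delta / L_n)``.

Integration uses the time-delayed first-order Euler method with the delay
buffer pre-filled by evolving every ensemble independently from the
longest delay up to t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kernels import decoupled_history, integrate_delayed
from .connectome import Connectome, compute_delays

__all__ = [
    "ModelParams",
    "EnsembleState",
    "Trajectory",
    "ensemble_equilibrium",
    "rhs",
    "init_history",
    "integrate",
    "find_critical_coupling",
    "save_trajectory",
    "load_trajectory",
    "export_trajectory_text",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass
class ModelParams:
    """Parameters of the reduced model.

    Rates (``G``, ``L``, ``delta``) are in s^-1; ``omega_hz`` is the center
    natural frequency in Hz and is converted to rad/s inside the equations.
    ``v`` is the spike-propagation velocity in m/s (``np.inf`` disables
    delays).  ``r_floor`` bounds the synchrony modulus away from zero,
    where the phase equation's 1/r term is singular.
    """

    G: float = 0.0
    L: float | np.ndarray = 0.0
    omega_hz: float = 10.5
    delta: float = 1.0
    v: float = np.inf
    dt: float = 1e-3
    t_total: float = 66.0
    t_transient: float = 19.0
    seed: int = 0
    r_floor: float = 1e-3

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.G < 0:
            raise ValueError("G must be nonnegative")
        if not (self.t_total > self.t_transient >= 0):
            raise ValueError("require t_total > t_transient >= 0")
        if not (0 < self.r_floor < 1):
            raise ValueError("r_floor must lie in (0, 1)")

    @property
    def omega_rad(self) -> float:
        return 2.0 * np.pi * self.omega_hz

    def local_couplings(self, n_regions: int) -> np.ndarray:
        """Per-ensemble local couplings as an array of length ``n_regions``."""
        L = np.asarray(self.L, dtype=float)
        if L.ndim == 0:
            return np.full(n_regions, float(L))
        if L.shape != (n_regions,):
            raise ValueError(f"L has length {L.shape[0]}, expected {n_regions}")
        return L.copy()


@dataclass
class EnsembleState:
    """Instantaneous synchrony moduli and mean phases of all ensembles."""

    r: np.ndarray
    psi: np.ndarray


@dataclass
class Trajectory:
    """Time-resolved synchrony of all ensembles on a uniform grid."""

    times: np.ndarray
    r: np.ndarray
    psi: np.ndarray
    dt: float

    @property
    def n_regions(self) -> int:
        return self.r.shape[1]

    def from_time(self, t_start: float) -> "Trajectory":
        """Sub-trajectory with the prefix before ``t_start`` discarded."""
        i0 = int(round(t_start / self.dt))
        i0 = max(0, min(i0, len(self.times) - 1))
        return Trajectory(self.times[i0:], self.r[i0:], self.psi[i0:], self.dt)


def ensemble_equilibrium(L: float, delta: float) -> float:
    """Steady-state synchrony of an isolated ensemble.

    Returns ``sqrt(1 - 2*delta/L)`` above the critical coupling
    ``L_c = 2*delta`` and 0 below it.
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    if L > 2.0 * delta:
        return float(np.sqrt(1.0 - 2.0 * delta / L))
    return 0.0


def rhs(
    state: EnsembleState,
    delayed_z: np.ndarray,
    params: ModelParams,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dr/dt, dpsi/dt) of the reduced equations.

    ``delayed_z[n, p]`` is the complex order parameter of ensemble ``p``
    seen by ensemble ``n``, i.e. ``z_p(t - tau_np)``.  This reference
    implementation is vectorized NumPy; the integrator uses the compiled
    kernel, which this function cross-checks in the test suite.
    """
    r = np.asarray(state.r, dtype=float)
    psi = np.asarray(state.psi, dtype=float)
    E = r.shape[0]
    if np.any(r < params.r_floor):
        raise ValueError("state has r below r_floor")
    A = np.asarray(weights, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    # S_n e^{-i psi_n}: phase differences via complex arithmetic
    S = (A * delayed_z).sum(axis=1) * np.exp(-1j * psi)
    gfac = params.G / (2.0 * E)
    one_m_r2 = 1.0 - r * r
    Ln = params.local_couplings(E)
    dr = -params.delta * r + 0.5 * Ln * one_m_r2 * r + gfac * one_m_r2 * S.real
    dpsi = params.omega_rad + gfac * (r + 1.0 / r) * S.imag
    return dr, dpsi


def _delay_steps(params: ModelParams, connectome: Connectome) -> np.ndarray:
    tau = compute_delays(connectome, params.v)
    return np.rint(tau / params.dt).astype(np.int64)


def init_history(
    params: ModelParams,
    connectome: Connectome,
    rng: np.random.Generator,
    initial_state: EnsembleState | None = None,
) -> tuple[EnsembleState, np.ndarray]:
    """Draw initial conditions and fill the delay buffer.

    Phases at t = -tau_max are uniform on [-pi, pi); the synchrony modulus
    starts at the isolated-ensemble equilibrium (floored at ``r_floor``).
    Each ensemble is then advanced independently (G forced to 0) up to
    t = 0, storing z every step.  Returns the state at t = 0 and the
    history buffer (depth x E complex), whose last row is the t = 0 state.
    """
    E = connectome.n_regions
    Ln = params.local_couplings(E)
    if initial_state is None:
        psi0 = rng.uniform(-np.pi, np.pi, size=E)
        r0 = np.array(
            [max(ensemble_equilibrium(l, params.delta), params.r_floor) for l in Ln]
        )
    else:
        r0 = np.clip(np.asarray(initial_state.r, dtype=float), params.r_floor, 1.0)
        psi0 = np.asarray(initial_state.psi, dtype=float).copy()
    depth = int(_delay_steps(params, connectome).max()) + 1
    z_hist, r_t0, psi_t0 = decoupled_history(
        r0, psi0, Ln, params.delta, params.omega_rad, params.dt, depth, params.r_floor
    )
    return EnsembleState(r=r_t0, psi=psi_t0), z_hist


def integrate(
    params: ModelParams,
    connectome: Connectome,
    rng: np.random.Generator | None = None,
    initial_state: EnsembleState | None = None,
) -> Trajectory:
    """Simulate the full network with the time-delayed Euler method.

    After every step ``r`` is clamped to [r_floor, 1] and the phase is
    wrapped to [-pi, pi).  The trajectory is recorded at every step from
    t = 0 to ``t_total`` inclusive.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state0, z_hist = init_history(params, connectome, rng, initial_state)
    d_steps = _delay_steps(params, connectome)
    n_steps = int(round(params.t_total / params.dt))
    Ln = params.local_couplings(connectome.n_regions)
    r, psi, err = integrate_delayed(
        z_hist,
        state0.r,
        state0.psi,
        connectome.weights,
        d_steps,
        params.G,
        Ln,
        params.delta,
        params.omega_rad,
        params.dt,
        n_steps,
        params.r_floor,
    )
    if err >= 0:
        raise IntegrationError(
            f"non-finite state at step {err} (t = {err * params.dt:.3f} s); "
            "consider a smaller dt"
        )
    times = np.arange(n_steps + 1) * params.dt
    return Trajectory(times, r, psi, params.dt)


def find_critical_coupling(
    delta: float = 1.0,
    lo: float = 0.0,
    hi: float = 6.0,
    r_start: float = 0.5,
    horizon: float = 1000.0,
    tol: float = 0.005,
    omega_hz: float = 10.5,
    dt: float = 1e-3,
    r_floor: float = 1e-3,
) -> float:
    """Locate the synchronization threshold of an isolated ensemble by bisection.

    An ensemble is classed as synchronizing when its long-run r stays
    strictly above the integrator floor.  Near the threshold the decay
    rate |L/2 - delta| vanishes (critical slowing), so the horizon must be
    long for the transient from ``r_start`` to clear; the default 1000 s
    resolves the threshold to well within 1% of ``2*delta``.
    """
    single = Connectome(1, np.zeros((1, 1)), np.zeros((1, 1)))

    def synchronizes(L: float) -> bool:
        p = ModelParams(
            G=0.0,
            L=L,
            omega_hz=omega_hz,
            delta=delta,
            dt=dt,
            t_total=horizon,
            t_transient=0.0,
            r_floor=r_floor,
        )
        traj = integrate(
            p, single, initial_state=EnsembleState(np.array([r_start]), np.array([0.0]))
        )
        return float(traj.r[-1, 0]) > r_floor

    if not synchronizes(hi):
        raise ValueError("upper bracket does not synchronize")
    if synchronizes(lo):
        raise ValueError("lower bracket already synchronizes")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if synchronizes(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def save_trajectory(traj: Trajectory, path: str | Path, params: ModelParams | None = None) -> None:
    """Write a trajectory to an HDF5 container (/times, /r, /psi)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("r", data=traj.r)
        f.create_dataset("psi", data=traj.psi)
        f.attrs["dt"] = traj.dt
        if params is not None:
            for key in ("G", "omega_hz", "delta", "v", "dt", "t_total", "t_transient", "seed", "r_floor"):
                f.attrs[f"params_{key}"] = getattr(params, key)
            f.attrs["params_L"] = np.atleast_1d(np.asarray(params.L, dtype=float))


def load_trajectory(path: str | Path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as f:
        return Trajectory(f["times"][:], f["r"][:], f["psi"][:], float(f.attrs["dt"]))


def export_trajectory_text(traj: Trajectory, path: str | Path, decimate: int = 10) -> None:
    """Decimated delimited-text export: time, r_0..r_E-1, psi_0..psi_E-1."""
    sl = slice(None, None, max(1, int(decimate)))
    data = np.column_stack([traj.times[sl], traj.r[sl], traj.psi[sl]])
    np.savetxt(path, data, fmt="%.9g")
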