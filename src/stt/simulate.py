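"""Stochastic multistable gene-circuit simulators with ground truth.

Two benchmark circuits are shipped:

* a symmetric two-gene toggle switch (mutual Hill inhibition) that is
  bistable with a saddle between the two attractors;
* a seven-gene epithelial-mesenchymal transition (EMT) core circuit
  driven by an external TGFB-like signal, built from a SNAIL/miR-34
  switch cascaded into a ZEB/miR-200 switch plus slaved marker genes,
  with a verified tristable signal window (epithelial E, intermediate
  ICS, mesenchymal M states).

Each gene i carries an unspliced/spliced pair obeying

    dU_i = (f_i(S) - beta_i U_i) dt + sigma_i dW_i
    dS_i = (beta_i U_i - gamma_i S_i) dt + sigma_i dZ_i

integrated with the Euler-Maruyama scheme; negative values are clamped
to zero after every step.  Ground-truth velocities are the drift terms
evaluated at the sampled states, and each sampled cell is labelled by
the basin of the deterministic fixed point reached by noise-free
integration from its state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .datasets import ExpressionDataset


class CircuitConfigurationError(ValueError):
    """Raised when circuit parameters do not produce the required attractors."""


class IntegrationError(RuntimeError):
    """Raised when the drift becomes non-finite during integration."""


@dataclass
class CircuitSpec:
    """A splicing-aware gene circuit: production function plus rates.

    ``production(S, signal)`` maps the spliced-state vector (and an
    external scalar signal) to per-gene production rates; it must return
    finite nonnegative rates for any nonnegative state.
    """

    n_genes: int
    production: Callable[[np.ndarray, float], np.ndarray]
    beta: np.ndarray
    gamma: np.ndarray
    sigma: np.ndarray
    signal_levels: Sequence[float] = field(default_factory=lambda: [0.0])

    def __post_init__(self):
        self.beta = np.broadcast_to(np.asarray(self.beta, float), (self.n_genes,)).copy()
        self.gamma = np.broadcast_to(np.asarray(self.gamma, float), (self.n_genes,)).copy()
        self.sigma = np.broadcast_to(np.asarray(self.sigma, float), (self.n_genes,)).copy()
        for name in ("beta", "gamma"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive componentwise")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")

    def drift(self, u: np.ndarray, s: np.ndarray, signal: float = 0.0):
        """Deterministic drift ``(dU/dt, dS/dt)`` of the splicing SDE."""
        f = self.production(s, signal)
        return f - self.beta * u, self.beta * u - self.gamma * s


@dataclass
class SimulationResult:
    """Sampled cells with ground-truth velocities and attractor labels."""

    dataset: ExpressionDataset
    true_velocity_u: np.ndarray
    true_velocity_s: np.ndarray
    attractor_label: np.ndarray
    fixed_points: np.ndarray  # (n_attractors, 2*n_genes) as [U, S]
    signal_per_cell: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Euler-Maruyama integration
# ---------------------------------------------------------------------------

def euler_maruyama(
    spec: CircuitSpec,
    x0: np.ndarray,
    dt: float,
    n_steps: int,
    seed: int,
    signal: float = 0.0,
    record_every: int = 1,
) -> np.ndarray:
    """Integrate the splicing SDE; returns states of shape (n_rec, 2*n_genes).

    The state is the concatenation ``[U, S]``.  After each step negative
    entries are clamped to zero.  Identical seeds give identical paths.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ng = spec.n_genes
    x = np.asarray(x0, dtype=float).copy()
    if x.shape != (2 * ng,):
        raise ValueError(f"x0 must have shape ({2 * ng},)")
    if x.min() < 0:
        raise ValueError("x0 must be nonnegative")
    rng = np.random.default_rng(seed)
    sqdt = np.sqrt(dt)
    out = []
    for step in range(n_steps):
        du, ds = spec.drift(x[:ng], x[ng:], signal)
        if not (np.all(np.isfinite(du)) and np.all(np.isfinite(ds))):
            raise IntegrationError(f"non-finite drift at step {step}")
        noise = rng.standard_normal(2 * ng) * sqdt
        x[:ng] += du * dt + spec.sigma * noise[:ng]
        x[ng:] += ds * dt + spec.sigma * noise[ng:]
        np.maximum(x, 0.0, out=x)
        if (step + 1) % record_every == 0:
            out.append(x.copy())
    return np.array(out) if out else np.empty((0, 2 * ng))


# ---------------------------------------------------------------------------
# deterministic fixed-point machinery
# ---------------------------------------------------------------------------

def _ode_rhs(spec: CircuitSpec, signal: float):
    ng = spec.n_genes

    def rhs(t, x):
        du, ds = spec.drift(x[:ng], x[ng:], signal)
        return np.concatenate([du, ds])

    return rhs


def _integrate_to_rest(spec, x0, signal, t_end=400.0):
    sol = solve_ivp(
        _ode_rhs(spec, signal), (0.0, t_end), x0, rtol=1e-9, atol=1e-11
    )
    return sol.y[:, -1]


def _jacobian(spec, x, signal, h=1e-6):
    rhs = _ode_rhs(spec, signal)
    f0 = rhs(0.0, x)
    n = x.size
    J = np.empty((n, n))
    for i in range(n):
        xp = x.copy()
        xp[i] += h
        J[:, i] = (rhs(0.0, xp) - f0) / h
    return J


def find_stable_fixed_points(
    spec: CircuitSpec,
    signal: float = 0.0,
    n_starts: int = 60,
    s_max: float = 3.0,
    seed: int = 0,
    merge_tol: float = 1e-3,
    residual_tol: float = 1e-5,
) -> np.ndarray:
    """Census of stable fixed points by noise-free integration.

    Integrates from random nonnegative initial conditions, keeps
    converged endpoints with a strictly stable numerical Jacobian, and
    merges duplicates.  Returns an array of ``[U, S]`` states.
    """
    rng = np.random.default_rng(seed)
    rhs = _ode_rhs(spec, signal)
    found: list[np.ndarray] = []
    for _ in range(n_starts):
        s0 = rng.uniform(0.0, s_max, spec.n_genes)
        u0 = spec.production(s0, signal) / spec.beta
        xf = _integrate_to_rest(spec, np.concatenate([u0, s0]), signal)
        if np.linalg.norm(rhs(0.0, xf)) > residual_tol:
            continue
        if np.linalg.eigvals(_jacobian(spec, xf, signal)).real.max() > -1e-6:
            continue
        if not any(np.linalg.norm(xf - fp) < merge_tol for fp in found):
            found.append(xf)
    order = np.argsort([fp[spec.n_genes] for fp in found])  # sort by S of gene 0
    return np.array([found[i] for i in order])


def assign_basin(spec: CircuitSpec, states: np.ndarray, fixed_points: np.ndarray,
                 signal, dt: float = 0.02, t_end: float = 400.0) -> np.ndarray:
    """Label each state by the fixed point its noise-free flow converges to.

    All states are integrated in one batched RK4 sweep (the production
    functions broadcast over a leading cell axis), stopping early when
    every trajectory is stationary.
    """
    ng = spec.n_genes
    X = np.asarray(states, float).copy()                 # (n, 2*ng)
    sig = np.broadcast_to(np.asarray(signal, float), (X.shape[0],))

    def batch_rhs(Y):
        u, s = Y[:, :ng], Y[:, ng:]
        f = spec.production(s, sig)
        du = f - spec.beta * u
        ds = spec.beta * u - spec.gamma * s
        return np.concatenate([du, ds], axis=1)

    for _ in range(int(t_end / dt)):
        k1 = batch_rhs(X)
        k2 = batch_rhs(X + 0.5 * dt * k1)
        k3 = batch_rhs(X + 0.5 * dt * k2)
        k4 = batch_rhs(X + dt * k3)
        step = (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        X += step
        if np.abs(step).max() < 1e-9:
            break
    d = np.linalg.norm(X[:, None, :] - fixed_points[None, :, :], axis=2)
    return d.argmin(axis=1)


# ---------------------------------------------------------------------------
# the two shipped circuits
# ---------------------------------------------------------------------------

TOGGLE_PARAMS = dict(a=2.0, basal=0.1, k=1.0, hill=4.0, beta=1.0, gamma=1.0,
                     sigma=0.1)

# EMT circuit constants; genes ordered SNAIL, miR34, ZEB, miR200, ECAD, VIM,
# TWIST.  Tristable for signal in roughly [1.4, 2.0] (verified by census).
EMT_PARAMS = dict(beta=1.0, gamma=1.0, sigma=0.08)
EMT_TRISTABLE_WINDOW = (1.4, 2.0)
EMT_GENES = ["SNAIL", "miR34", "ZEB", "miR200", "ECAD", "VIM", "TWIST"]


def _hillp(x, k, n):
    xn = np.power(np.maximum(x, 0.0), n)
    return xn / (k ** n + xn)


def _hillm(x, k, n):
    return k ** n / (k ** n + np.power(np.maximum(x, 0.0), n))


def toggle_switch_spec(**overrides) -> CircuitSpec:
    """Symmetric mutual-inhibition toggle; bistable at the defaults."""
    p = {**TOGGLE_PARAMS, **overrides}

    def production(s, signal=0.0):
        s = np.asarray(s, float)
        return p["basal"] + p["a"] / (1.0 + (s[..., ::-1] / p["k"]) ** p["hill"])

    return CircuitSpec(
        n_genes=2, production=production, beta=p["beta"], gamma=p["gamma"],
        sigma=p["sigma"],
    )


def emt_circuit_spec(**overrides) -> CircuitSpec:
    """Seven-gene EMT cascade with an additive TGFB-like input on SNAIL."""
    p = {**EMT_PARAMS, **overrides}

    def production(s, signal=0.0):
        s = np.asarray(s, float)
        sn, m34, zeb, m200 = s[..., 0], s[..., 1], s[..., 2], s[..., 3]
        one = np.ones_like(sn)
        return np.stack([
            0.1 + 1.8 * _hillm(m34, 1.0, 4) + 0.35 * signal * one,     # SNAIL
            0.1 + 1.8 * _hillm(sn, 1.5, 4),                            # miR34
            0.1 + 2.2 * _hillm(m200, 1.0, 4) * _hillp(sn, 1.8, 4),     # ZEB
            0.1 + 1.8 * _hillm(zeb, 1.2, 4) * _hillm(sn, 3.0, 6),      # miR200
            0.2 + 2.0 * _hillm(sn, 1.5, 2) * _hillm(zeb, 1.0, 2),      # ECAD
            0.1 + 2.0 * _hillp(zeb, 1.0, 2),                           # VIM
            (0.1 + 1.5 * signal / (1.0 + signal)) * one,               # TWIST
        ], axis=-1)

    return CircuitSpec(
        n_genes=7, production=production, beta=p["beta"], gamma=p["gamma"],
        sigma=p["sigma"],
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _sample_cells(spec, n_cells, seed, signal, starts, dt=0.01,
                  burn_in_steps=500, record_every=50):
    """Pool trajectory snapshots after burn-in across initial conditions."""
    rng = np.random.default_rng(seed)
    per_traj = int(np.ceil(n_cells / len(starts)))
    states, signals = [], []
    for i, x0 in enumerate(starts):
        traj_seed = int(rng.integers(0, 2**31 - 1))
        n_steps = burn_in_steps + per_traj * record_every
        traj = euler_maruyama(
            spec, x0, dt, n_steps, traj_seed, signal=signal,
            record_every=record_every,
        )
        keep = traj[burn_in_steps // record_every:]
        states.append(keep[:per_traj])
        signals.extend([signal] * len(keep[:per_traj]))
    X = np.vstack(states)[:n_cells]
    return X, np.array(signals)[:n_cells]


def _result_from_states(spec, X, signals, fixed_points, gene_names, extra_obs=None):
    ng = spec.n_genes
    U, S = X[:, :ng], X[:, ng:]
    f = spec.production(S, signals)
    vu = f - spec.beta * U
    vs = spec.beta * U - spec.gamma * S
    labels = assign_basin(spec, X, fixed_points, signals)
    ds = ExpressionDataset(
        U=U, S=S, gene_names=list(gene_names),
        initial_labels=np.array([f"attr{l}" for l in labels]),
        true_velocity_u=vu, true_velocity_s=vs,
    )
    if extra_obs:
        for k, v in extra_obs.items():
            ds.obs[k] = v
    ds.obs["basin"] = labels
    return SimulationResult(
        dataset=ds, true_velocity_u=vu, true_velocity_s=vs,
        attractor_label=labels, fixed_points=fixed_points,
        signal_per_cell=signals,
    )


def simulate_toggle_switch(
    n_cells: int = 2000, seed: int = 0, params: Optional[dict] = None,
    dt: float = 0.01, burn_in_steps: int = 500, record_every: int = 50,
) -> SimulationResult:
    """Sample cells from the bistable toggle switch with ground truth.

    Trajectories start from a grid of spliced-space initial conditions so
    both basins and the saddle region are populated; cells are snapshots
    at regular intervals after a burn-in.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    spec = toggle_switch_spec(**(params or {}))
    fps = find_stable_fixed_points(spec, n_starts=40, seed=0)
    if len(fps) != 2:
        raise CircuitConfigurationError(
            f"circuit not bistable under supplied parameters ({len(fps)} stable "
            "fixed points)"
        )
    g = np.linspace(0.1, 2.5, 5)
    starts = [
        np.concatenate([spec.production(np.array([x, y]), 0.0), [x, y]])
        for x in g for y in g
    ]
    X, signals = _sample_cells(
        spec, n_cells, seed, 0.0, starts, dt=dt,
        burn_in_steps=burn_in_steps, record_every=record_every,
    )
    return _result_from_states(spec, X, signals, fps, ["gene0", "gene1"])


def simulate_emt_circuit(
    n_cells: int = 600,
    signal_levels: Sequence[float] = (0.0, 1.0, 1.8, 2.5, 4.0),
    seed: int = 0,
    params: Optional[dict] = None,
    dt: float = 0.01,
    burn_in_steps: int = 500,
    record_every: int = 50,
) -> SimulationResult:
    """Sample cells from the EMT circuit pooled across TGFB signal levels.

    The default levels span the epithelial-only, bistable, tristable and
    mesenchymal-only regimes of the bifurcation diagram.  Fixed points
    are taken from the census at a level inside the tristable window so
    all three macroscopic states (E, ICS, M) are represented.
    """
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    if len(signal_levels) == 0:
        raise ValueError("signal_levels must be nonempty")
    spec = emt_circuit_spec(**(params or {}))
    window_sig = float(np.mean(EMT_TRISTABLE_WINDOW))
    fps = find_stable_fixed_points(spec, signal=window_sig, n_starts=80, seed=0)
    if len(fps) != 3:
        raise CircuitConfigurationError(
            f"circuit not tristable under supplied parameters ({len(fps)} stable "
            f"fixed points at signal {window_sig})"
        )
    rng = np.random.default_rng(seed)
    per_level = int(np.ceil(n_cells / len(signal_levels)))
    all_states, all_sigs = [], []
    for j, sig in enumerate(signal_levels):
        level_fps = find_stable_fixed_points(spec, signal=sig, n_starts=40, seed=1)
        starts = list(level_fps) if len(level_fps) else [
            np.concatenate([spec.production(np.ones(7), sig), np.ones(7)])
        ]
        # also start from perturbed states to populate transition regions
        starts = starts + [
            np.maximum(st + rng.normal(0, 0.4, st.size), 0.0) for st in starts
        ]
        X, sg = _sample_cells(
            spec, per_level, int(rng.integers(0, 2**31 - 1)), sig, starts,
            dt=dt, burn_in_steps=burn_in_steps, record_every=record_every,
        )
        all_states.append(X)
        all_sigs.append(sg)
    X = np.vstack(all_states)[:n_cells]
    signals = np.concatenate(all_sigs)[:n_cells]
    # basins are defined at the tristable reference signal so each cell maps
    # to one of E / ICS / M
    res = _result_from_states(
        spec, X, np.full(len(X), window_sig), fps, EMT_GENES,
        extra_obs={"signal": signals},
    )
    res.signal_per_cell = signals
    return res


def linear_multistable_dataset(
    n_cells: int = 2000,
    n_genes: int = 5,
    n_attractors: int = 2,
    beta: float | np.ndarray = 1.0,
    noise: float = 0.1,
    seed: int = 0,
) -> tuple[ExpressionDataset, np.ndarray, np.ndarray]:
    """Draw cells directly from the linearized attractor model.

    Per attractor c and gene g the steady state is ``U = alpha[c,g]/beta[g]``,
    ``S = beta[g]*U`` (degradation rate fixed at 1); Gaussian residuals with
    standard deviation ``noise`` times the signal scale are added and
    negative values clamped.  Returns (dataset, alpha, beta) for parameter-
    recovery experiments.
    """
    rng = np.random.default_rng(seed)
    beta = np.broadcast_to(np.asarray(beta, float), (n_genes,)).copy()
    alpha = rng.uniform(0.5, 3.0, size=(n_attractors, n_genes))
    labels = rng.integers(0, n_attractors, size=n_cells)
    m = alpha[labels] / beta  # steady-state U per cell
    scale = noise * m.mean(axis=0)
    U = np.maximum(m + rng.normal(0, 1, m.shape) * scale, 0.0)
    S = np.maximum(beta * U + rng.normal(0, 1, m.shape) * scale, 0.0)
    ds = ExpressionDataset(
        U=U, S=S, initial_labels=np.array([f"attr{l}" for l in labels])
    )
    return ds, alpha, beta
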