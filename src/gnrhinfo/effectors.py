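"""Stochastic effector layer: exponentiated Ornstein–Uhlenbeck totals.

Cell–cell variability enters the model through the two effector totals,
GnRHR (R_T) and calmodulin (M_T).  Each follows the exponential of an
Ornstein–Uhlenbeck process in log space, i.e. a positive, lognormally
distributed, mean-reverting level whose autocorrelation time is the
fluctuation lifetime FL:

    Y_0     ~  Normal(mu, s^2)
    Y_{k+1} =  mu + (Y_k - mu) a + s sqrt(1 - a^2) eps_k,   a = exp(-dt/FL)
    X_k     =  exp(Y_k)

with s^2 = ln(1 + cv^2) and mu = ln(mean) - s^2/2 so that the stationary
marginal has the requested mean and coefficient of variation at every FL.
Small FL means an unstable effector (rapidly refreshing heterogeneity);
FL = 10,000 min is effectively a static cell-to-cell lognormal spread.
Paths are piecewise constant between updates so the ODE integrator sees
exactly the sampled values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (CellTrajectory, ModelParameters, StimulusProtocol,
                    nfat_nuclear_fraction, simulate_population_states)

__all__ = ["OUSpec", "EffectorPath", "PopulationRun", "sample_effector_path",
           "sample_effector_paths", "hybrid_simulate", "calibrate_cv"]


@dataclass(frozen=True)
class OUSpec:
    """Stationary spec of one exponentiated-OU effector."""

    fl: float                 # fluctuation lifetime tau, minutes
    mean: float = 1.0         # stationary mean of exp(Y)
    cv: float = 0.3           # stationary coefficient of variation
    dt_update: float = 0.5    # path update interval, minutes

    def __post_init__(self) -> None:
        if not self.fl > 0:
            raise ValueError("fl must be > 0")
        if not self.mean > 0:
            raise ValueError("mean must be > 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not self.dt_update > 0:
            raise ValueError("dt_update must be > 0")

    @property
    def log_var(self) -> float:
        return float(np.log1p(self.cv**2))

    @property
    def log_mean(self) -> float:
        return float(np.log(self.mean) - 0.5 * self.log_var)


@dataclass(frozen=True)
class EffectorPath:
    """Piecewise-constant effector time course on a uniform update grid."""

    t: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.x <= 0):
            raise ValueError("effector levels must be positive")


def _sample_log_paths(spec: OUSpec, n_updates: int, n_paths: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Exact OU discretization in log space, (n_paths, n_updates)."""
    mu, s = spec.log_mean, np.sqrt(spec.log_var)
    if s == 0.0:
        return np.full((n_paths, n_updates), mu)
    a = np.exp(-spec.dt_update / spec.fl)
    innov_sd = s * np.sqrt(1.0 - a * a)
    y = np.empty((n_paths, n_updates))
    y[:, 0] = mu + s * rng.standard_normal(n_paths)
    eps = rng.standard_normal((n_paths, n_updates - 1))
    for k in range(1, n_updates):
        y[:, k] = mu + (y[:, k - 1] - mu) * a + innov_sd * eps[:, k - 1]
    return y


def sample_effector_path(spec: OUSpec, horizon: float,
                         rng: np.random.Generator) -> EffectorPath:
    """One exponentiated-OU path covering ``[0, horizon]`` minutes."""
    if horizon < spec.dt_update:
        raise ValueError("horizon must cover at least one update interval")
    n = int(np.floor(horizon / spec.dt_update)) + 1
    t = np.arange(n) * spec.dt_update
    y = _sample_log_paths(spec, n, 1, rng)[0]
    return EffectorPath(t=t, x=np.exp(y))


def sample_effector_paths(spec: OUSpec, horizon: float, n_paths: int,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised path matrix: (update grid, (n_paths, n_updates) levels)."""
    n = int(np.floor(horizon / spec.dt_update)) + 1
    t = np.arange(n) * spec.dt_update
    return t, np.exp(_sample_log_paths(spec, n, n_paths, rng))


@dataclass
class PopulationRun:
    """Hybrid-simulation output for one (concentration, FL) condition."""

    t: np.ndarray               # output grid, minutes
    nfat_nf: np.ndarray         # (n_cells, len(t))
    r_paths: np.ndarray         # (n_cells, n_updates) GnRHR totals
    m_paths: np.ndarray         # (n_cells, n_updates) calmodulin totals
    effector_t: np.ndarray
    fl: float
    concentration: float
    seed: int
    states: np.ndarray | None = None   # (6, n_cells, len(t)) if kept

    @property
    def n_cells(self) -> int:
        return self.nfat_nf.shape[0]

    def cell(self, i: int) -> CellTrajectory:
        if self.states is None:
            raise ValueError("full states were not kept for this run")
        st = self.states[:, i, :]
        return CellTrajectory(t=self.t, state=st, nfat_nf=self.nfat_nf[i])


def _cell_rngs(seed: int, n_cells: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n_cells)]


def hybrid_simulate(
    params: ModelParameters,
    protocol: StimulusProtocol,
    n_cells: int,
    fl: float,
    cv_r: float = 0.3,
    cv_m: float = 0.3,
    seed: int = 0,
    t_out: np.ndarray | None = None,
    burn_in: float = 60.0,
    dt_update: float = 0.5,
    dt_out: float = 1.0,
    keep_states: bool = False,
) -> PopulationRun:
    """Per-cell hybrid (ODE + exponentiated-OU) simulation.

    Each cell draws independent GnRHR and calmodulin paths sharing the
    fluctuation lifetime ``fl`` (per-cell RNG substreams keyed by cell
    index, so results are reproducible and independent of evaluation
    order), then integrates the deterministic cascade with those
    piecewise-constant totals.  The simulation starts ``burn_in`` minutes
    before the protocol at the per-cell steady state so the NFAT state is
    equilibrated to the fluctuating effector ensemble by t = 0.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    horizon_end = protocol.end if t_out is None else max(protocol.end, t_out[-1])
    if t_out is None:
        t_out = np.arange(0.0, horizon_end + dt_out / 2, dt_out)
    t0 = -float(burn_in)
    horizon = horizon_end - t0

    spec_r = OUSpec(fl=fl, mean=params.R_T, cv=cv_r, dt_update=dt_update)
    spec_m = OUSpec(fl=fl, mean=params.M_T, cv=cv_m, dt_update=dt_update)
    n_upd = int(np.ceil(horizon / dt_update)) + 1
    r = np.empty((n_cells, n_upd))
    m = np.empty((n_cells, n_upd))
    for i, rng in enumerate(_cell_rngs(seed, n_cells)):
        r[i] = np.exp(_sample_log_paths(spec_r, n_upd, 1, rng)[0])
        m[i] = np.exp(_sample_log_paths(spec_m, n_upd, 1, rng)[0])
    eff_t = t0 + np.arange(n_upd) * dt_update

    grid = np.unique(np.concatenate([[t0], t_out]))
    states = simulate_population_states(
        params, protocol, grid, r_values=r, m_values=m, effector_t=eff_t
    )
    keep = np.isin(np.round(grid, 9), np.round(t_out, 9))
    states = states[:, :, keep]
    nf = nfat_nuclear_fraction(states)
    return PopulationRun(
        t=np.asarray(t_out, dtype=float), nfat_nf=nf, r_paths=r, m_paths=m,
        effector_t=eff_t, fl=fl, concentration=protocol.max_concentration,
        seed=seed, states=states if keep_states else None,
    )


def calibrate_cv(
    params: ModelParameters,
    target_cv: float = 0.25,
    concentration: float = 1e-7,
    pulse_min: float = 15.0,
    n_cells: int = 300,
    fl: float = 10000.0,
    seed: int = 0,
    cv_grid: np.ndarray | None = None,
) -> float:
    """Tune the effector cv so the pulse-response CV matches a target.

    The calibration metric is the coefficient of variation of the
    baseline-subtracted maximum nuclear fraction during a single pulse at
    ``concentration`` (the spread the live-cell experiments constrain).
    Returns the cv (applied to both effectors) whose response CV is
    closest to ``target_cv`` on a small grid.
    """
    if cv_grid is None:
        cv_grid = np.arange(0.1, 0.85, 0.05)
    protocol = StimulusProtocol.constant(concentration, pulse_min)
    best_cv, best_err = float(cv_grid[0]), np.inf
    for cv in cv_grid:
        run = hybrid_simulate(params, protocol, n_cells, fl=fl, cv_r=cv, cv_m=cv,
                              seed=seed, t_out=np.arange(0.0, pulse_min + 0.5, 0.5))
        baseline = run.nfat_nf[:, 0]
        resp = run.nfat_nf.max(axis=1) - baseline
        mean = resp.mean()
        cv_resp = resp.std() / mean if mean > 0 else np.inf
        err = abs(cv_resp - target_cv)
        if err < best_err:
            best_cv, best_err = float(cv), err
    return best_cv
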