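"""Compartmental models of steady-state labeling dynamics.

A compartmental model (CM) splits a metabolic system into well-mixed pools
connected by material-transfer fluxes.  For wash-out labeling the vector of
per-pool labeled fractions obeys the linear ODE

    df/dt = M f,    f(0) = 1,

where M is the state-transition matrix of *contributed turnovers*:
off-diagonal M[i, j] is the flux j -> i divided by the size of the receiving
pool i, and the diagonal M[i, i] is minus the total influx turnover into i
(internal plus external feed).  The solution is the matrix exponential
f(t) = e^{Mt} 1, and the observed (system) curve is s^T e^{Mt} 1 with s the
relative pool sizes.  Under balanced growth at rate mu mass balance requires
M^T s <= -mu s componentwise, which holds iff all eigenvalues of M have real
part <= -mu.

Closed forms for the cumulative dynamic parameters (mean ages -M^{-1} 1,
mean residence time -1/(s^T M 1), growth-weighted residence quantities via
(M + mu I)^{-1}, ...) are implemented here and cross-checked against
numerical quadrature in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .curves import DynamicParameters, LabelingCurve

__all__ = [
    "CompartmentalModel",
    "ValidationReport",
    "ModelTemplate",
    "ModelError",
    "validate",
    "labeling",
    "mean_ages",
    "system_parameters",
    "reduce",
    "compose_delayed",
    "build_template",
]

_RTOL = 1e-9
_MAX_STATES = 12


class ModelError(ValueError):
    """Invalid compartmental model or template."""


@dataclass(frozen=True)
class CompartmentalModel:
    """State-transition matrix M, relative pool sizes s, growth rate mu.

    Parameters
    ----------
    M:
        n x n state-transition matrix (per minute).  Off-diagonal entries
        are contributed turnovers (inflow flux / receiving-pool size) and
        must be >= 0; diagonal entries are negative.
    s:
        Relative pool sizes, strictly positive, summing to 1.
    mu:
        Balanced growth rate (per minute), >= 0.
    observed:
        Boolean mask over states marking the experimentally observed pools.
    labels:
        Optional state names.
    """

    M: np.ndarray
    s: np.ndarray
    mu: float = 0.0
    observed: np.ndarray | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        M = np.atleast_2d(np.asarray(self.M, dtype=float))
        n = M.shape[0]
        if M.shape != (n, n):
            raise ModelError("M must be square")
        if n > _MAX_STATES:
            raise ModelError(f"more than {_MAX_STATES} states is unsupported")
        off = M[~np.eye(n, dtype=bool)]
        if np.any(off < -_RTOL):
            raise ModelError("off-diagonal entries of M must be >= 0")
        if np.any(np.diag(M) >= 0):
            raise ModelError("diagonal entries of M must be < 0")
        s = np.asarray(self.s, dtype=float).ravel()
        if s.shape != (n,) or np.any(s <= 0):
            raise ModelError("s must be strictly positive with one entry per state")
        if abs(s.sum() - 1.0) > 1e-6:
            raise ModelError("pool sizes s must sum to 1")
        s = s / s.sum()
        if self.mu < 0:
            raise ModelError("mu must be >= 0")
        obs = self.observed
        obs = np.ones(n, dtype=bool) if obs is None else np.asarray(obs, dtype=bool)
        if obs.shape != (n,):
            raise ModelError("observed mask length must equal n")
        labels = self.labels or tuple(f"state_{i}" for i in range(n))
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def n(self) -> int:
        return self.M.shape[0]

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.M)


@dataclass(frozen=True)
class ValidationReport:
    eigenvalues: np.ndarray
    eigen_ok: bool
    mass_balance_residual: np.ndarray   # M^T s + mu s, must be <= tol
    balance_ok: bool

    @property
    def ok(self) -> bool:
        return self.eigen_ok and self.balance_ok


@dataclass(frozen=True)
class ModelTemplate:
    """A serial input chain feeding parallel observed (protein) pools.

    ``input_states`` upstream pools model the delay with which the label
    reaches the observed subsystem (0 = direct labeling); ``protein_pools``
    parallel pools with distinct decay rates model complex degradation.
    The terminal chain state feeds all pools through an instantaneous mixer
    (zero-size source pool: it contributes no age).

    Free parameters: one rate per input state, one decay rate per pool
    (unless ``nondegraded``), and pool-size fractions on the simplex
    (protein_pools - 1 free values).  Input-state sizes are derived from
    flux balance, not fitted.
    """

    input_states: int = 0
    protein_pools: int = 1
    mu: float = 0.0
    nondegraded: bool = False          # fix all pool decay rates at 0
    fixed_input_rates: tuple[float, ...] | None = None
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.input_states <= 3):
            raise ModelError("input_states must be between 0 and 3")
        if not (1 <= self.protein_pools <= 3):
            raise ModelError("protein_pools must be between 1 and 3")
        if self.fixed_input_rates is not None:
            fr = tuple(float(r) for r in self.fixed_input_rates)
            if len(fr) != self.input_states or any(r <= 0 for r in fr):
                raise ModelError("fixed_input_rates must be positive, one per input state")
            object.__setattr__(self, "fixed_input_rates", fr)
        if not self.name:
            object.__setattr__(self, "name", f"in{self.input_states}_pool{self.protein_pools}")

    @property
    def k_params(self) -> int:
        """Number of free parameters."""
        k = 0
        if self.fixed_input_rates is None:
            k += self.input_states
        if not self.nondegraded:
            k += self.protein_pools
        k += self.protein_pools - 1
        return k


# ---------------------------------------------------------------------------
# validation and propagation
# ---------------------------------------------------------------------------

def validate(model: CompartmentalModel, rtol: float = _RTOL) -> ValidationReport:
    """Check the growth-adjusted eigenvalue condition and mass balance.

    eigen_ok requires every eigenvalue real part <= -mu (within tolerance);
    balance_ok requires every component of M^T s + mu s <= tolerance.  The
    boundary (equality) is the nondegraded-pool limit and is accepted.
    """
    eig = model.eigenvalues()
    scale = max(1.0, float(np.max(np.abs(model.M))))
    tol = rtol * scale
    eigen_ok = bool(np.all(eig.real <= -model.mu + tol))
    residual = model.M.T @ model.s + model.mu * model.s
    balance_ok = bool(np.all(residual <= tol))
    return ValidationReport(eigenvalues=eig, eigen_ok=eigen_ok,
                            mass_balance_residual=residual, balance_ok=balance_ok)


def _require_valid(model: CompartmentalModel) -> None:
    rep = validate(model)
    if not rep.ok:
        raise ModelError(
            f"invalid compartmental model: eigen_ok={rep.eigen_ok} "
            f"(eigenvalues {np.round(rep.eigenvalues, 6)}, mu={model.mu:g}), "
            f"balance_ok={rep.balance_ok} "
            f"(residual {np.round(rep.mass_balance_residual, 9)})")


def _propagator(M: np.ndarray, times: np.ndarray) -> np.ndarray:
    """f(t) = e^{Mt} 1 for each t; shape (n_times, n).

    Uses the eigendecomposition (sum-of-exponentials) path when the
    eigenvalues are distinct and the eigenvector basis is well conditioned;
    falls back to scaling-and-squaring (Pade) matrix exponentials otherwise
    (repeated-eigenvalue chains break the naive eigendecomposition).
    """
    times = np.asarray(times, dtype=float)
    n = M.shape[0]
    one = np.ones(n)
    lam, V = np.linalg.eig(M)
    gaps = np.abs(np.subtract.outer(lam, lam))
    gaps[np.eye(n, dtype=bool)] = np.inf
    distinct = bool(np.min(gaps) > 1e-9 * max(1.0, float(np.max(np.abs(lam)))))
    if distinct and np.linalg.cond(V) < 1e8:
        c = np.linalg.solve(V, one)
        out = (V * c) @ np.exp(np.outer(lam, times))
        return np.real(out.T)
    return np.stack([expm(M * t) @ one for t in times])


def labeling(model: CompartmentalModel, times: Sequence[float]
             ) -> tuple[list[LabelingCurve], LabelingCurve]:
    """Exact per-state and system labeling curves f(t) = e^{Mt} 1, fs = s^T f.

    Returns ``(per_state, system)``.  All values lie in [0, 1] and are
    non-increasing for valid models (up to numerical round-off).
    """
    _require_valid(model)
    times = np.asarray(times, dtype=float)
    F = np.clip(_propagator(model.M, times), 0.0, 1.0)
    per_state = [LabelingCurve(species_id=model.labels[i], times=times,
                               values=F[:, i]) for i in range(model.n)]
    fs = np.clip(F @ model.s, 0.0, 1.0)
    system = LabelingCurve(species_id="system", times=times, values=fs)
    return per_state, system


def observed_curve(model: CompartmentalModel, times: Sequence[float]) -> np.ndarray:
    """Labeling of the observed subsystem: size-weighted mean over observed pools."""
    times = np.asarray(times, dtype=float)
    F = _propagator(model.M, times)
    w = model.s * model.observed
    w = w / w.sum()
    return np.clip(F @ w, 0.0, 1.0)


# ---------------------------------------------------------------------------
# closed-form dynamic parameters
# ---------------------------------------------------------------------------

def mean_ages(model: CompartmentalModel) -> tuple[np.ndarray, float]:
    """Per-state mean ages -M^{-1} 1 and the system mean age -s^T M^{-1} 1."""
    _require_valid(model)
    one = np.ones(model.n)
    abar = -np.linalg.solve(model.M, one)
    return abar, float(model.s @ abar)


def _fs(model: CompartmentalModel, t: float) -> float:
    return float(model.s @ expm(model.M * t) @ np.ones(model.n))


def half_life(model: CompartmentalModel) -> float:
    """Median system age: t such that s^T e^{Mt} 1 = 1/2, by bracketed root finding."""
    eig = model.eigenvalues()
    t_hi = 20.0 / abs(max(eig.real))
    g = lambda t: _fs(model, t) - 0.5
    if g(t_hi) > 0:   # extremely slow boundary (nondegraded, mu -> 0)
        while g(t_hi) > 0:
            t_hi *= 2
    return float(brentq(g, 0.0, t_hi, xtol=1e-6))


def system_parameters(model: CompartmentalModel,
                      conditioning_age: float = 0.0) -> DynamicParameters:
    """Closed-form cumulative dynamic parameters of the whole system.

    Growth corrections enter through (M + mu I)^{-1}, which exists because
    all eigenvalues of a valid model satisfy Re(lambda) <= -mu (quantities
    that need strict inequality return inf on the boundary).
    """
    _require_valid(model)
    M, s, mu, n = model.M, model.s, model.mu, model.n
    one = np.ones(n)

    abar = float(-s @ np.linalg.solve(M, one))
    m1 = M @ one
    kbar = float(-s @ m1 - mu)
    eig_max = max(model.eigenvalues().real)
    A = M + mu * np.eye(n)
    if eig_max < -mu - 1e-12:
        Ainv1 = np.linalg.solve(A, one)
        tbar = float(-s @ M @ Ainv1 / (s @ m1))
        lr = float(-s @ Ainv1)
    else:  # boundary: e^{mu t} fs does not decay; residence moments diverge
        tbar = np.inf
        lr = np.inf
    lbar = abar + lr
    t_half = half_life(model)

    a = float(conditioning_age)
    k_a = t_a = esc_a = np.nan
    if a > 0:
        E = expm(M * a)
        fs_a = float(s @ E @ one)
        if fs_a < 1e-12:
            raise ModelError(
                f"conditioning age {a:g} min beyond numerical support "
                f"(fs({a:g}) = {fs_a:.3g})")
        fsp_a = float(s @ M @ E @ one)
        esc_a = -fsp_a / fs_a
        k_a = esc_a - mu
        if eig_max < -mu - 1e-12:
            # int_a^inf e^{mu t} fs' dt = -s M (M+muI)^{-1} e^{(M+muI)a} 1
            #                           = -e^{mu a} s M (M+muI)^{-1} e^{Ma} 1
            num = float(-s @ M @ np.linalg.solve(A, E @ one))
            t_a = a + num / fsp_a
        else:
            t_a = np.inf
    else:
        k_a, t_a = kbar, tbar
        esc_a = kbar + mu

    return DynamicParameters(
        mean_age=abar, half_life=t_half, expected_decay_rate=kbar,
        mean_residence_time=tbar, mean_rtl=lbar, mean_rrtl=lr,
        conditioning_age=a, conditioned_decay_rate=k_a,
        conditioned_residence_time=t_a, conditioned_escape_rate=esc_a)


# ---------------------------------------------------------------------------
# reduction and delayed-input composition
# ---------------------------------------------------------------------------

def reduce(model: CompartmentalModel,
           observed: Sequence[bool] | None = None) -> CompartmentalModel:
    """Reduce to the observed subsystem (delay compensation).

    Removes the rows and columns of all unobserved pools from M and
    renormalizes the remaining pool sizes.  The result behaves as if the
    observed pools were fed directly (particle ages reset to zero on entry),
    so its dynamic parameters are the delay-compensated ones.
    """
    mask = model.observed if observed is None else np.asarray(observed, dtype=bool)
    if mask.shape != (model.n,):
        raise ModelError("observed mask length must equal the number of states")
    if not mask.any():
        raise ModelError("observed mask must select at least one state")
    idx = np.nonzero(mask)[0]
    Mr = model.M[np.ix_(idx, idx)]
    sr = model.s[idx]
    return CompartmentalModel(M=Mr, s=sr / sr.sum(), mu=model.mu,
                              labels=tuple(model.labels[i] for i in idx))


def compose_delayed(f_input: Callable[[np.ndarray], np.ndarray] | np.ndarray,
                    f_reduced: Callable[[np.ndarray], np.ndarray] | np.ndarray,
                    grid: Sequence[float],
                    refine: int = 4,
                    tol: float = 1e-4) -> np.ndarray:
    """Observed labeling under serial delayed input.

    When an observed subsystem is fed by a single source with labeling
    f_input (and the age of entering particles is distributed as the input
    age), the observed curve is

        f(t) = f_input(t) - (df_input/dt * f_reduced)(t),

    the convolution taken over [0, t].  Mean ages add:
    Abar(f) = Abar(f_input) + Abar(f_reduced).

    Inputs may be callables (evaluated on an internally refined uniform
    grid) or arrays sampled on ``grid`` (interpolated).  The quadrature
    error is estimated by comparing two refinement levels; if it exceeds
    ``tol`` the grid is reported as too coarse.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0:
        raise ModelError("composition grid must start at t = 0")

    def as_fn(f):
        if callable(f):
            return f
        arr = np.asarray(f, dtype=float)
        if arr.shape != grid.shape:
            raise ModelError("array inputs must be sampled on the given grid")
        return lambda t: np.interp(t, grid, arr)

    fi, fr = as_fn(f_input), as_fn(f_reduced)

    def conv_on(factor: int) -> np.ndarray:
        m = (len(grid) - 1) * factor + 1
        tt = np.linspace(grid[0], grid[-1], m)
        h = tt[1] - tt[0]
        gi, gr = fi(tt), fr(tt)
        dgi = np.gradient(gi, h, edge_order=2)
        full = np.convolve(dgi, gr)[:m] * h
        # trapezoid end-corrections for the [0, t] convolution
        full -= 0.5 * h * (dgi[0] * gr[:m] + dgi[:m] * gr[0])
        out = gi - full
        return np.interp(grid, tt, out)

    c1, c2 = conv_on(refine), conv_on(2 * refine)
    err = float(np.max(np.abs(c1 - c2)))
    if err > tol:
        raise ModelError(
            f"composition grid too coarse: quadrature error estimate {err:.2e} "
            f"exceeds tolerance {tol:.0e}")
    return np.clip(c2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# template assembly
# ---------------------------------------------------------------------------

def build_template(spec: ModelTemplate,
                   input_rates: Sequence[float] = (),
                   pool_rates: Sequence[float] = (),
                   pool_fractions: Sequence[float] = (1.0,),
                   pool_total_size: float = 0.5) -> CompartmentalModel:
    """Assemble the serial-input / parallel-pool compartmental model.

    Parameters
    ----------
    input_rates:
        Turnover rate of each serial input state (per minute), upstream
        first.  Each must exceed mu.  Ignored entries are overridden by
        ``spec.fixed_input_rates`` when set.
    pool_rates:
        Decay rate of each observed pool (per minute, >= 0); forced to zero
        when ``spec.nondegraded``.  Total escape of a pool is decay + mu.
    pool_fractions:
        Relative sizes of the observed pools (positive, normalized to 1).
    pool_total_size:
        Fraction of the whole system held in the observed pools (the input
        chain sizes are derived from flux balance with zero decay in the
        chain, so the assembled model is exactly mass-balanced).

    The terminal input state feeds every pool through an instantaneous
    mixer (a zero-size source pool contributes no age), so the observed
    curve depends only on the stage rates and pool parameters.
    """
    k, p, mu = spec.input_states, spec.protein_pools, spec.mu
    r = np.asarray(spec.fixed_input_rates if spec.fixed_input_rates is not None
                   else input_rates, dtype=float)
    if r.shape != (k,):
        raise ModelError(f"expected {k} input rates, got {r.shape}")
    if np.any(r <= mu):
        raise ModelError("every input-state rate must exceed the growth rate mu")
    d = (np.zeros(p) if spec.nondegraded
         else np.asarray(pool_rates, dtype=float))
    if d.shape != (p,):
        raise ModelError(f"expected {p} pool decay rates, got {d.shape}")
    if np.any(d < 0):
        raise ModelError("pool decay rates must be >= 0")
    w = np.asarray(pool_fractions, dtype=float)
    if w.shape != (p,) or np.any(w <= 0):
        raise ModelError(f"expected {p} positive pool fractions")
    w = w / w.sum()
    if not (0 < pool_total_size < 1) and k > 0:
        raise ModelError("pool_total_size must lie in (0, 1) when input states exist")

    n = k + p
    M = np.zeros((n, n))
    for j in range(k):
        M[j, j] = -r[j]
        if j > 0:
            M[j, j - 1] = r[j]
    for i in range(p):
        esc = d[i] + mu
        if esc <= 0:    # nondegraded, non-growing: no escape at all
            raise ModelError("pool with zero decay requires mu > 0 "
                             "(otherwise its turnover is zero)")
        M[k + i, k + i] = -esc
        if k > 0:
            M[k + i, k - 1] = esc

    if k == 0:
        s = w
    else:
        s_pool = pool_total_size * w
        # flux balance with zero decay in the chain:
        #   external feed v -> stage 1; stage j passes v * prod(1 - mu/r_j)
        # terminal transfer must equal total pool influx sum(s_i (d_i + mu))
        pool_influx = float(np.sum(s_pool * (d + mu)))
        pass_frac = np.cumprod(1.0 - mu / r)
        v = pool_influx / pass_frac[-1]
        s_in = v * np.concatenate([[1.0], pass_frac[:-1]]) / r
        s = np.concatenate([s_in, s_pool])
        s = s / s.sum()

    labels = tuple(f"input_{j + 1}" for j in range(k)) + \
        tuple(f"pool_{i + 1}" for i in range(p))
    observed = np.concatenate([np.zeros(k, dtype=bool), np.ones(p, dtype=bool)])
    return CompartmentalModel(M=M, s=s, mu=mu, observed=observed, labels=labels)


def input_mean_age(spec: ModelTemplate, input_rates: Sequence[float] = ()) -> float:
    """Mean age of the input subsystem: sum of the serial stage mean times 1/r_j."""
    r = (spec.fixed_input_rates if spec.fixed_input_rates is not None
         else tuple(input_rates))
    if len(r) != spec.input_states:
        raise ModelError("rate count must match input_states")
    return float(sum(1.0 / rj for rj in r))
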