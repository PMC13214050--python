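"""Synthetic labeling data and a stochastic particle oracle.

Two roles:

* :func:`simulate_dataset` produces noisy discrete labeling datasets from
  compartmental models — the stand-in for a dynamic-SILAC time course
  (per-species curves, relative abundances, and a matching exponential
  biomass series for growth-rate estimation).

* :func:`particle_oracle` simulates individual particle "life tracks"
  through the continuous-time Markov process a compartmental model defines
  (entry per external inflows, jumps per contributed turnovers, escape by
  decay plus growth dilution at rate mu).  The empirical distributions of
  metabolic age A, residence time T and residence-time-of-the-living L it
  yields validate every analytic formula without sharing any code with
  them.

Randomness discipline: one root seed per call, spawned into independent
child streams per component; all stochastic outputs carry their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cmodel import CompartmentalModel, ModelTemplate, build_template, validate, _propagator
from .curves import GrowthModel, LabelingCurve

__all__ = [
    "SimulationSpec",
    "ParticleEnsemble",
    "LabelingDataset",
    "simulate_dataset",
    "simulate_proteome",
    "particle_oracle",
]


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: model, sampling grid, noise level, counts, seed."""

    model: CompartmentalModel
    times: np.ndarray
    noise_sd: float = 0.01
    n_replicates: int = 1
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("a seed is mandatory for stochastic output")


@dataclass
class LabelingDataset:
    """Curves keyed by species plus abundances and the growth model."""

    curves: dict[str, LabelingCurve]
    abundance: dict[str, float] = field(default_factory=dict)
    growth: GrowthModel = GrowthModel(0.0)
    biomass_times: np.ndarray | None = None
    biomass_values: np.ndarray | None = None
    truth: dict = field(default_factory=dict)   # generating parameters, for recovery tests

    def species(self) -> list[str]:
        return sorted(self.curves)


@dataclass(frozen=True)
class ParticleEnsemble:
    """Empirical samples of particle life-track quantities.

    ``ages_at_observation``, ``rtl`` and ``state_at_observation`` describe
    the particles present at the stationary observation time; ``residence_times``
    are total system dwell times of all entering particles; ``decay_exit``
    marks which of those left by decay (vs. growth dilution).
    """

    ages_at_observation: np.ndarray
    residence_times: np.ndarray
    rtl: np.ndarray
    state_at_observation: np.ndarray
    entry_state: np.ndarray
    decay_exit: np.ndarray
    seed: int | None = None


def _noisy(values: np.ndarray, noise_sd: float, rng: np.random.Generator):
    if noise_sd == 0:
        return values.copy(), 0
    noisy = values + rng.normal(0.0, noise_sd, size=values.shape)
    clipped = int(np.sum((noisy < 0) | (noisy > 1)))
    return np.clip(noisy, 0.0, 1.0), clipped


def simulate_dataset(spec: SimulationSpec) -> LabelingDataset:
    """Noisy replicate curves from one model, plus abundance and biomass series.

    Exact curves come from the matrix-exponential solution; independent
    additive Gaussian noise (sd = noise_sd) is applied per sample and the
    result clipped to [0, 1] (clip counts recorded in the curve metadata).
    """
    rep = validate(spec.model)
    if not rep.ok:
        raise ValueError("model fails validation; refusing to simulate")
    rng = np.random.default_rng(spec.seed)
    w = spec.model.s * spec.model.observed
    w = w / w.sum()
    F = _propagator(spec.model.M, spec.times)
    exact = np.clip(F @ w, 0.0, 1.0)

    curves = {}
    for r in range(spec.n_replicates):
        vals, n_clip = _noisy(exact, spec.noise_sd, rng)
        sid = "species_1" if spec.n_replicates == 1 else f"species_1/rep{r + 1}"
        curves[sid] = LabelingCurve(
            species_id="species_1", times=spec.times, values=vals,
            replicate=None if spec.n_replicates == 1 else f"rep{r + 1}",
            meta={"seed": spec.seed, "n_clipped": n_clip})

    mu = spec.model.mu
    bt = np.linspace(0.0, spec.times[-1], 9)
    biomass = 0.1 * np.exp(mu * bt)
    return LabelingDataset(
        curves=curves, abundance={"species_1": 1.0},
        growth=GrowthModel(mu, source="given"),
        biomass_times=bt, biomass_values=biomass,
        truth={"exact": exact, "model": spec.model, "noise_sd": spec.noise_sd,
               "seed": spec.seed})


def simulate_proteome(n_species: int,
                      times: np.ndarray,
                      mu: float,
                      input_rates: tuple[float, ...] = (0.02, 0.05),
                      frac_two_pool: float = 0.10,
                      decay_range: tuple[float, float] = (5e-4, 2e-2),
                      frac_nondegraded: float = 0.05,
                      noise_sd: float = 0.01,
                      biomass_noise: float = 0.02,
                      seed: int = 0) -> LabelingDataset:
    """A synthetic proteome time course with shared delayed lysine input.

    Emulates the structure of a dynamic-SILAC wash-out: every species is a
    compartmental model sharing one serial input chain (default 2 states)
    and differing in its protein subsystem — mostly single pools with
    log-uniform decay rates, a fraction with two pools of well-separated
    rates, and a few nondegraded species whose labeling is pure growth
    dilution.  Log-normal abundances and a noisy exponential biomass curve
    are attached; generating truth is stored for recovery tests.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    curves: dict[str, LabelingCurve] = {}
    abundance: dict[str, float] = {}
    truth_species: dict[str, dict] = {}

    n_two = int(round(frac_two_pool * n_species))
    n_nondeg = int(round(frac_nondegraded * n_species))
    kinds = (["two_pool"] * n_two + ["nondegraded"] * n_nondeg
             + ["one_pool"] * (n_species - n_two - n_nondeg))
    rng.shuffle(kinds)

    lo, hi = np.log(decay_range[0]), np.log(decay_range[1])
    for i, kind in enumerate(kinds):
        sid = f"prot_{i + 1:04d}"
        if kind == "two_pool":
            d_slow = float(np.exp(rng.uniform(lo, hi - np.log(10))))
            d = np.array([d_slow * rng.uniform(8, 20), d_slow])
            w = np.array([rng.uniform(0.2, 0.5), 0.0])
            w[1] = 1.0 - w[0]
            tpl = ModelTemplate(input_states=len(input_rates), protein_pools=2, mu=mu)
            model = build_template(tpl, input_rates=input_rates,
                                   pool_rates=d, pool_fractions=w)
            truth_species[sid] = {"kind": kind, "pool_rates": d.tolist(),
                                  "pool_fractions": w.tolist()}
        elif kind == "nondegraded":
            tpl = ModelTemplate(input_states=len(input_rates), protein_pools=1,
                                mu=mu, nondegraded=True)
            model = build_template(tpl, input_rates=input_rates,
                                   pool_fractions=(1.0,))
            truth_species[sid] = {"kind": kind, "pool_rates": [0.0],
                                  "pool_fractions": [1.0]}
        else:
            d = float(np.exp(rng.uniform(lo, hi)))
            tpl = ModelTemplate(input_states=len(input_rates), protein_pools=1, mu=mu)
            model = build_template(tpl, input_rates=input_rates,
                                   pool_rates=(d,), pool_fractions=(1.0,))
            truth_species[sid] = {"kind": kind, "pool_rates": [d],
                                  "pool_fractions": [1.0]}
        w_obs = model.s * model.observed
        w_obs = w_obs / w_obs.sum()
        exact = np.clip(_propagator(model.M, times) @ w_obs, 0.0, 1.0)
        vals, n_clip = _noisy(exact, noise_sd, rng)
        curves[sid] = LabelingCurve(species_id=sid, times=times, values=vals,
                                    meta={"n_clipped": n_clip})
        abundance[sid] = float(rng.lognormal(mean=0.0, sigma=1.0))
        # nondegraded species are typically abundant housekeeping proteins;
        # bias them upward so abundance filtering retains them
        if kind == "nondegraded":
            abundance[sid] *= 10.0

    bt = np.linspace(0.0, times[-1], 10)
    biomass = 0.1 * np.exp(mu * bt)
    if biomass_noise > 0:
        biomass = biomass * np.exp(rng.normal(0.0, biomass_noise, size=bt.shape))
    return LabelingDataset(
        curves=curves, abundance=abundance, growth=GrowthModel(mu, source="given"),
        biomass_times=bt, biomass_values=biomass,
        truth={"species": truth_species, "input_rates": list(input_rates),
               "mu": mu, "noise_sd": noise_sd, "seed": seed,
               "input_mean_age": float(sum(1.0 / r for r in input_rates))})


# ---------------------------------------------------------------------------
# particle oracle
# ---------------------------------------------------------------------------

def _hazards(model: CompartmentalModel):
    """Per-particle hazards implied by (M, s, mu).

    From state j: jump to i at M[i, j] s[i] / s[j]; decay at
    -(M^T s + mu s)[j] / s[j]; growth-dilution escape at mu.  The total
    equals the influx turnover -M[j, j], consistent with steady state.
    """
    M, s, mu, n = model.M, model.s, model.mu, model.n
    jump = np.zeros((n, n))     # jump[j, i]: rate j -> i
    for j in range(n):
        for i in range(n):
            if i != j:
                jump[j, i] = max(M[i, j] * s[i] / s[j], 0.0)
    resid = -(M.T @ s + mu * s) / s          # decay hazard per state
    decay = np.clip(resid, 0.0, None)
    total = jump.sum(axis=1) + decay + mu
    return jump, decay, total


def _entry_weights(model: CompartmentalModel) -> np.ndarray:
    """External inflow per state: -s_i (M 1)_i (zero for internally fed states)."""
    w = -model.s * (model.M @ np.ones(model.n))
    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        raise ValueError("model has no external inflow; no particles can enter")
    return w / w.sum()


def particle_oracle(model: CompartmentalModel, n_particles: int,
                    seed: int, burn_in_factor: float = 20.0) -> ParticleEnsemble:
    """Empirical life tracks of particles through the Markov process.

    Particles enter the system over a window long enough for stationarity
    (burn-in 20 / |slowest eigenvalue|): uniformly in time for a constant-
    size system, with exponentially growing intensity e^{mu u} under
    balanced growth (every per-volume flux scales with the culture).  Each
    particle then propagates by competing exponential clocks — inter-state
    jumps at the contributed turnovers and *decay*.  Growth dilution does
    not destroy a particle (it only moves it outside a fixed reference
    volume), so the residence time T is the time from entry to decay; an
    independent Exp(mu) dilution clock is raced against the decay
    trajectory only to attribute fixed-volume exits (``decay_exit``).

    Observation at the window end records ages, states, and the RTL (the
    full entry-to-decay span of the particles still present); residence
    times are collected for all entrants.  Particles of nondegraded pools
    never decay and carry T = inf.
    """
    if n_particles < 1000:
        raise ValueError("particle oracle needs n >= 1000 for stable histograms")
    rep = validate(model)
    if not rep.ok:
        raise ValueError("model fails validation; oracle undefined")
    rng = np.random.default_rng(seed)
    jump, decay, total = _hazards(model)
    entry_p = _entry_weights(model)
    mu = model.mu
    eig = model.eigenvalues()
    window = burn_in_factor / abs(max(eig.real))

    if mu > 0:  # entry intensity proportional to e^{mu u} on [0, window]
        u = rng.random(n_particles)
        entry_t = np.log1p(u * np.expm1(mu * window)) / mu
    else:
        entry_t = rng.uniform(0.0, window, size=n_particles)
    entry_state = rng.choice(model.n, size=n_particles, p=entry_p)

    n = model.n
    # death happens only by decay; jumps keep the trajectory alive
    exit_rate = total - mu                      # jump + decay hazard per state
    dest_p = np.zeros((n, n + 1))               # destinations: states..., decay
    for j in range(n):
        dest_p[j, :n] = jump[j]
        dest_p[j, n] = decay[j]
        tot = dest_p[j].sum()
        if tot > 0:
            dest_p[j] /= tot

    res_t = np.full(n_particles, np.inf)        # time from entry to decay
    obs_mask = np.zeros(n_particles, dtype=bool)
    obs_state = np.full(n_particles, -1, dtype=np.int64)

    state = entry_state.copy()
    clock = np.zeros(n_particles)
    alive = np.ones(n_particles, dtype=bool)
    max_events = 100_000
    for _ in range(max_events):
        if not alive.any():
            break
        idx = np.nonzero(alive)[0]
        st = state[idx]
        rate = exit_rate[st]
        dwell = np.full(len(idx), np.inf)
        active = rate > 0
        dwell[active] = rng.exponential(1.0 / rate[active])
        t_abs = entry_t[idx] + clock[idx]
        straddle = (t_abs < window) & (t_abs + dwell >= window)
        hit = idx[straddle]
        obs_mask[hit] = True
        obs_state[hit] = st[straddle]
        # absorbing states (no decay, no outgoing jumps): observed, never die
        stuck = idx[~active]
        alive[stuck] = False
        idx, st, dwell = idx[active], st[active], dwell[active]
        clock[idx] += dwell
        uu = rng.random(len(idx))
        cum = np.cumsum(dest_p[st], axis=1)
        dest = (uu[:, None] < cum).argmax(axis=1)
        dying = dest == n
        dead = idx[dying]
        res_t[dead] = clock[dead]
        alive[dead] = False
        state[idx[~dying]] = dest[~dying]

    # present at observation = entered before the window end and not yet
    # decayed by then (growth dilution does not remove particles)
    present = obs_mask
    ages = window - entry_t[present]
    if mu > 0:  # fixed-volume exit attribution: decay vs dilution
        dilution_t = rng.exponential(1.0 / mu, size=n_particles)
        dec_exit = res_t < dilution_t
    else:
        dec_exit = np.isfinite(res_t)
    return ParticleEnsemble(
        ages_at_observation=ages,
        residence_times=res_t,
        rtl=res_t[present],
        state_at_observation=obs_state[present],
        entry_state=entry_state,
        decay_exit=dec_exit,
        seed=seed)
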