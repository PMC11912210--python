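"""Iterative Boltzmann inversion of backbone dihedral potentials.

Given a target Ramachandran distribution P_target and a sampler that
turns a trial potential into a sampled distribution P_sampled, each
iteration

1. samples with the current potential,
2. forms the potential-of-mean-force difference
   dV = kB*T * ln(P_sampled / P_target) on bins where both
   probabilities exceed a floor (others are masked out of the fit),
3. fits the separable Fourier form to dV, and
4. updates the coefficients, k <- k + damping * dk.

Positive dV marks bins the sampler over-populates relative to the
target, so adding it to the potential suppresses them.  With an exact
(noise-free) Boltzmann sampler and a target inside the representable
span, a single undamped step lands on the target potential; stochastic
samplers converge to within their sampling noise.

The sampler is any callable ``sampler(potential, temperature, seed) ->
RamaDistribution`` on the working grid; MD-derived histograms plug in
through the same contract.  Two built-in surrogates are provided: the
exact Boltzmann distribution (the modeled system being a single
(phi, psi) pair, its equilibrium distribution is available in closed
form) and a multi-walker Metropolis random walk for realistic-noise
testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol

import numpy as np

from .grid import KB, AngleGrid, RamaDistribution, hellinger_distance
from .potentials import (
    FourierDihedralPotential,
    boltzmann_distribution,
    combine_potentials,
    fit_fourier_to_surface,
)

__all__ = [
    "SamplerContract",
    "IBIConfig",
    "IBIState",
    "delta_v_surface",
    "ibi_step",
    "run_ibi",
    "ExactBoltzmannSampler",
    "MetropolisSampler",
]


class SamplerContract(Protocol):
    """Callable producing a sampled distribution for a trial potential."""

    def __call__(
        self, potential: FourierDihedralPotential, temperature: float, seed: int
    ) -> RamaDistribution: ...


@dataclass(frozen=True)
class IBIConfig:
    """Knobs of the inversion loop.

    ``floor`` masks bins where either distribution falls below it before
    the logarithm (masked, not clamped, so the fit is not biased toward
    an arbitrary floor value).  ``damping`` scales each coefficient
    update; 1.0 is the undamped fixed-point iteration.  ``phases="free"``
    fits both cosine and sine components per term, required for chiral
    targets; ``"fixed"`` restricts to pure cosines at the given phases.
    """

    temperature: float = 300.0
    max_iterations: int = 20
    hellinger_tol: float = 0.01
    floor: float = 1e-8
    damping: float = 1.0
    n_terms: int = 5
    m_terms: int = 5
    phases: str = "free"
    base_seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (0.0 < self.damping <= 1.0):
            raise ValueError("damping must lie in (0, 1]")
        if self.hellinger_tol <= 0 or self.floor <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class IBIState:
    """Record of one iteration: potential, sample, and convergence metrics.

    ``history`` holds one dict per completed iteration (including this
    one) with keys iteration, hellinger, fit_residual_rms, potential.
    """

    iteration: int
    potential: FourierDihedralPotential
    sampled: RamaDistribution
    hellinger: float
    fit_residual_rms: float
    converged: bool
    history: tuple[dict, ...] = ()

    def best(self) -> dict:
        """History entry with the smallest Hellinger distance to target."""
        return min(self.history, key=lambda h: h["hellinger"])


def delta_v_surface(
    P_target: RamaDistribution,
    P_sampled: RamaDistribution,
    temperature: float = 300.0,
    floor: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """PMF difference kB*T*ln(P_sampled/P_target) and its validity mask.

    Bins where either probability is below ``floor`` are masked (mask
    False) and carry NaN in the returned surface.
    """
    if not P_target.same_grid(P_sampled):
        raise ValueError("target and sampled distributions are on different grids")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    mask = (P_target.p >= floor) & (P_sampled.p >= floor)
    if not mask.any():
        raise ValueError("no bin exceeds the probability floor in both distributions")
    dv = np.full_like(P_target.p, np.nan)
    dv[mask] = KB * temperature * np.log(P_sampled.p[mask] / P_target.p[mask])
    return dv, mask


def _initial_state(
    potential: FourierDihedralPotential,
    target: RamaDistribution,
    sampler: SamplerContract,
    cfg: IBIConfig,
    iteration: int = 0,
) -> IBIState:
    sampled = sampler(potential, cfg.temperature, cfg.base_seed + iteration)
    h = hellinger_distance(sampled, target)
    entry = {
        "iteration": iteration,
        "hellinger": h,
        "fit_residual_rms": float("nan"),
        "potential": potential,
    }
    return IBIState(
        iteration=iteration,
        potential=potential,
        sampled=sampled,
        hellinger=h,
        fit_residual_rms=float("nan"),
        converged=h <= cfg.hellinger_tol,
        history=(entry,),
    )


def ibi_step(
    state: IBIState,
    target: RamaDistribution,
    sampler: SamplerContract,
    cfg: IBIConfig,
) -> IBIState:
    """Advance the inversion by one iteration.

    Uses the sample already held in ``state``, fits the PMF difference,
    applies the damped coefficient update, and re-samples with the new
    potential.  Sampler errors are re-raised with iteration context.
    """
    dv, mask = delta_v_surface(target, state.sampled, cfg.temperature, cfg.floor)
    fit = fit_fourier_to_surface(
        dv, target.grid, n_terms=cfg.n_terms, m_terms=cfg.m_terms,
        phases=cfg.phases, mask=mask,
    )
    new_pot = combine_potentials(state.potential, fit.potential, cfg.damping)
    it = state.iteration + 1
    try:
        sampled = sampler(new_pot, cfg.temperature, cfg.base_seed + it)
    except Exception as err:
        raise RuntimeError(f"sampler failed at IBI iteration {it}") from err
    h = hellinger_distance(sampled, target)
    entry = {
        "iteration": it,
        "hellinger": h,
        "fit_residual_rms": fit.residual_rms,
        "potential": new_pot,
    }
    return IBIState(
        iteration=it,
        potential=new_pot,
        sampled=sampled,
        hellinger=h,
        fit_residual_rms=fit.residual_rms,
        converged=h <= cfg.hellinger_tol,
        history=state.history + (entry,),
    )


def run_ibi(
    target: RamaDistribution,
    sampler: SamplerContract,
    cfg: IBIConfig | None = None,
    initial: FourierDihedralPotential | None = None,
) -> IBIState:
    """Iterate until the sampled distribution matches the target.

    Starts from ``initial`` (default: the zero potential) and stops when
    Hellinger(P_sampled, P_target) <= ``cfg.hellinger_tol`` or after
    ``cfg.max_iterations`` updates.  Non-convergence is not an error:
    the final state is returned with ``converged=False`` and the full
    history attached.
    """
    cfg = cfg or IBIConfig()
    initial = initial or FourierDihedralPotential.zero(cfg.n_terms, cfg.m_terms)
    state = _initial_state(initial, target, sampler, cfg)
    while not state.converged and state.iteration < cfg.max_iterations:
        state = ibi_step(state, target, sampler, cfg)
    return state


@dataclass(frozen=True)
class ExactBoltzmannSampler:
    """Noise-free sampler: the closed-form Boltzmann distribution.

    The seed argument of the contract is accepted and ignored.
    """

    grid: AngleGrid = field(default_factory=AngleGrid)

    def __call__(
        self, potential: FourierDihedralPotential, temperature: float, seed: int = 0
    ) -> RamaDistribution:
        return boltzmann_distribution(potential, temperature, self.grid)


@dataclass(frozen=True)
class MetropolisSampler:
    """Metropolis random walk on the (phi, psi) torus.

    ``n_walkers`` independent chains are advanced in parallel for
    ``n_steps // n_walkers`` sweeps each; walkers start uniformly at
    random and the first ``burn_in`` sweeps per walker are discarded.
    Proposals are uniform displacements in [-step_size, step_size] per
    angle, accepted with min(1, exp(-dV/kBT)); visited states are
    histogrammed on the grid.  Deterministic given the seed.

    Raises if every proposal across 10^4 consecutive walker-updates is
    rejected (step size too large for the potential's wells).
    """

    grid: AngleGrid = field(default_factory=AngleGrid)
    n_steps: int = 1_000_000
    step_size: float = 25.0
    n_walkers: int = 100
    burn_in: int = 100

    def __call__(
        self, potential: FourierDihedralPotential, temperature: float, seed: int = 0
    ) -> RamaDistribution:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        nw = max(1, min(self.n_walkers, self.n_steps))
        sweeps = max(1, self.n_steps // nw)
        rng = np.random.default_rng(seed)
        phi = rng.uniform(-180.0, 180.0, nw)
        psi = rng.uniform(-180.0, 180.0, nw)
        e = potential.energy_phi(phi) + potential.energy_psi(psi)
        beta = 1.0 / (KB * temperature)
        counts = np.zeros(self.grid.n_bins, dtype=np.int64)
        n_psi_bins = self.grid.n_psi
        burn = min(self.burn_in, sweeps // 2)
        rejected_run = 0
        for sweep in range(sweeps):
            prop_phi = phi + rng.uniform(-self.step_size, self.step_size, nw)
            prop_psi = psi + rng.uniform(-self.step_size, self.step_size, nw)
            prop_phi = (prop_phi + 180.0) % 360.0 - 180.0
            prop_psi = (prop_psi + 180.0) % 360.0 - 180.0
            e_prop = potential.energy_phi(prop_phi) + potential.energy_psi(prop_psi)
            accept = rng.random(nw) < np.exp(-beta * np.maximum(e_prop - e, 0.0))
            phi = np.where(accept, prop_phi, phi)
            psi = np.where(accept, prop_psi, psi)
            e = np.where(accept, e_prop, e)
            if accept.any():
                rejected_run = 0
            else:
                rejected_run += nw
                if rejected_run >= 10_000:
                    raise RuntimeError(
                        "Metropolis sampler: 10^4 consecutive proposals rejected; "
                        "reduce step_size"
                    )
            if sweep >= burn:
                i, j = self.grid.indices_of(phi, psi)
                np.add.at(counts, i * n_psi_bins + j, 1)
        total = counts.sum()
        if total == 0:
            raise RuntimeError("Metropolis sampler produced no post-burn-in samples")
        p = counts.astype(float).reshape(self.grid.n_phi, self.grid.n_psi) / total
        return RamaDistribution(grid=self.grid, p=p, meta="histogram")
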