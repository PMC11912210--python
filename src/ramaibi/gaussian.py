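"""Gaussian superposition model of residue-specific Ramachandran ensembles.

A conformational ensemble is modeled as a weighted sum of axis-aligned
two-dimensional Gaussians, one per mesostate, each located at a
(phi_max, psi_max) center with per-axis half-widths (standard
deviations).  The weights are the mesostate mole fractions.  Densities
are wrapped periodically onto the torus by summing images shifted by
+/-360 deg along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import AngleGrid, RamaDistribution, wrap_angles

__all__ = [
    "GaussianComponent",
    "GaussianRamaModel",
    "evaluate_model",
    "sample_model",
]

_IMAGE_SHIFTS = (-360.0, 0.0, 360.0)


@dataclass(frozen=True)
class GaussianComponent:
    """One mesostate sub-distribution: weight, center, per-axis widths."""

    name: str
    weight: float
    center: tuple[float, float]
    widths: tuple[float, float]

    def __post_init__(self):
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"component {self.name!r}: weight must be in [0, 1]")
        if min(self.widths) <= 0:
            raise ValueError(f"component {self.name!r}: widths must be positive")
        for c in self.center:
            if not (-180.0 < c <= 180.0):
                raise ValueError(
                    f"component {self.name!r}: center angle {c} outside (-180, 180]"
                )


@dataclass(frozen=True)
class GaussianRamaModel:
    """Weighted sum of Gaussian mesostate components.

    With ``normalization="exact"`` the weights must sum to one (within
    1e-9); with ``"renormalize"`` any positive total is rescaled.
    """

    components: tuple[GaussianComponent, ...]
    normalization: str = "exact"

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        if self.normalization not in ("exact", "renormalize"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        total = sum(c.weight for c in self.components)
        if total <= 0:
            raise ValueError("total component weight must be positive")
        if self.normalization == "exact" and abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total!r}")

    def weights(self) -> np.ndarray:
        w = np.array([c.weight for c in self.components])
        return w / w.sum()


def _wrapped_gauss_1d(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Periodic Gaussian density on [-180, 180) via three images.

    Truncation error is below 1e-12 of the peak for sigma <= 60 deg.
    """
    g = np.zeros_like(x)
    for s in _IMAGE_SHIFTS:
        d = x - center - s
        g += np.exp(-0.5 * (d / sigma) ** 2)
    return g / (sigma * np.sqrt(2.0 * np.pi))


def evaluate_model(model: GaussianRamaModel, grid: AngleGrid | None = None) -> RamaDistribution:
    """Evaluate the mixture density at bin centers and normalize on the grid."""
    grid = grid or AngleGrid()
    w = model.weights()
    p = np.zeros((grid.n_phi, grid.n_psi))
    for wi, comp in zip(w, model.components):
        gp = _wrapped_gauss_1d(grid.centers_phi, comp.center[0], comp.widths[0])
        gs = _wrapped_gauss_1d(grid.centers_psi, comp.center[1], comp.widths[1])
        p += wi * np.outer(gp, gs)
    p /= p.sum()
    return RamaDistribution(grid=grid, p=p, meta="gaussian_model")


def sample_model(model: GaussianRamaModel, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` (phi, psi) pairs from the mixture, wrapped into [-180, 180).

    Deterministic given ``seed``: a component is chosen per draw according
    to the weights, then the pair is drawn from that component's Gaussian.
    Returns an (n, 2) array in degrees.
    """
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    w = model.weights()
    comp_idx = rng.choice(len(w), size=n, p=w)
    centers = np.array([c.center for c in model.components])
    widths = np.array([c.widths for c in model.components])
    z = rng.standard_normal((n, 2))
    angles = centers[comp_idx] + z * widths[comp_idx]
    return wrap_angles(angles)
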