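"""Separable Fourier-series backbone dihedral potentials.

The potential is a sum of two cosine series in the Amber proper-dihedral
form, one per backbone angle:

    V(phi, psi) = sum_n k_n_phi * (1 + cos(n*phi - gamma_n))
                + sum_m k_m_psi * (1 + cos(m*psi - gamma_m)) + offset

with multiplicities n = 1..N and m = 1..M (default N = M = 5) and
per-term phases gamma in degrees.  Phases of 0/180 deg give pure cosine
terms (even in the angle); arbitrary phases add the sine component
needed to represent chiral (inversion-asymmetric) distributions.

Because k*cos(n*t - g) = a*cos(n*t) + b*sin(n*t) with a = k*cos(g),
b = k*sin(g), fitting with free phases is an ordinary linear
least-squares problem in (a, b); the amplitude/phase form is recovered
as k = hypot(a, b), gamma = atan2(b, a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import KB, AngleGrid, RamaDistribution

__all__ = [
    "FourierDihedralPotential",
    "FitResult",
    "evaluate_potential",
    "boltzmann_distribution",
    "fit_fourier_to_surface",
    "rescale_potential",
    "combine_potentials",
    "cosine_sine_coefficients",
]


@dataclass(frozen=True)
class FourierDihedralPotential:
    """Separable dihedral potential; coefficients in kJ/mol, phases in degrees."""

    k_phi: np.ndarray
    k_psi: np.ndarray
    gamma_phi: np.ndarray | None = None
    gamma_psi: np.ndarray | None = None
    offset: float = 0.0

    def __post_init__(self):
        k_phi = np.atleast_1d(np.asarray(self.k_phi, dtype=float))
        k_psi = np.atleast_1d(np.asarray(self.k_psi, dtype=float))
        g_phi = (np.zeros_like(k_phi) if self.gamma_phi is None
                 else np.atleast_1d(np.asarray(self.gamma_phi, dtype=float)))
        g_psi = (np.zeros_like(k_psi) if self.gamma_psi is None
                 else np.atleast_1d(np.asarray(self.gamma_psi, dtype=float)))
        if k_phi.size < 1 or k_psi.size < 1:
            raise ValueError("at least one Fourier term per angle is required")
        if g_phi.shape != k_phi.shape or g_psi.shape != k_psi.shape:
            raise ValueError("phase arrays must match coefficient arrays")
        for arr in (k_phi, k_psi, g_phi, g_psi):
            if not np.all(np.isfinite(arr)):
                raise ValueError("potential parameters must be finite")
        if not math.isfinite(self.offset):
            raise ValueError("offset must be finite")
        object.__setattr__(self, "k_phi", k_phi)
        object.__setattr__(self, "k_psi", k_psi)
        object.__setattr__(self, "gamma_phi", g_phi)
        object.__setattr__(self, "gamma_psi", g_psi)

    @property
    def n_terms(self) -> int:
        return self.k_phi.size

    @property
    def m_terms(self) -> int:
        return self.k_psi.size

    @classmethod
    def zero(cls, n_terms: int = 5, m_terms: int = 5) -> "FourierDihedralPotential":
        return cls(k_phi=np.zeros(n_terms), k_psi=np.zeros(m_terms))

    def energy_phi(self, phi) -> np.ndarray:
        """V_phi(phi) in kJ/mol for angles in degrees (periodic)."""
        return _series(np.asarray(phi, dtype=float), self.k_phi, self.gamma_phi)

    def energy_psi(self, psi) -> np.ndarray:
        return _series(np.asarray(psi, dtype=float), self.k_psi, self.gamma_psi)

    def energy(self, phi, psi) -> np.ndarray:
        return self.energy_phi(phi) + self.energy_psi(psi) + self.offset


def _series(theta_deg: np.ndarray, k: np.ndarray, gamma_deg: np.ndarray) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    g = np.deg2rad(gamma_deg)
    v = np.zeros_like(t, dtype=float)
    for n in range(1, k.size + 1):
        v += k[n - 1] * (1.0 + np.cos(n * t - g[n - 1]))
    return v


def cosine_sine_coefficients(
    pot: FourierDihedralPotential,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Phase-free representation (a_phi, b_phi, a_psi, b_psi).

    ``a_n = k_n cos(gamma_n)``, ``b_n = k_n sin(gamma_n)`` — invariant
    under the (k, gamma) -> (-k, gamma+180) gauge, so suitable for
    comparing potentials fitted in different phase conventions.
    """
    gp = np.deg2rad(pot.gamma_phi)
    gs = np.deg2rad(pot.gamma_psi)
    return (pot.k_phi * np.cos(gp), pot.k_phi * np.sin(gp),
            pot.k_psi * np.cos(gs), pot.k_psi * np.sin(gs))


def evaluate_potential(
    pot: FourierDihedralPotential, grid: AngleGrid | None = None
) -> np.ndarray:
    """Energy surface V(phi, psi) (kJ/mol) at grid bin centers."""
    grid = grid or AngleGrid()
    vp = pot.energy_phi(grid.centers_phi)
    vs = pot.energy_psi(grid.centers_psi)
    return vp[:, None] + vs[None, :] + pot.offset


def boltzmann_distribution(
    pot: FourierDihedralPotential,
    temperature: float = 300.0,
    grid: AngleGrid | None = None,
) -> RamaDistribution:
    """Boltzmann distribution p ~ exp(-V / kB T) on the grid.

    The surface is shifted by its minimum before exponentiation, so the
    result is overflow-safe and invariant to the additive offset.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    grid = grid or AngleGrid()
    v = evaluate_potential(pot, grid)
    w = np.exp(-(v - v.min()) / (KB * temperature))
    return RamaDistribution(grid=grid, p=w / w.sum(), meta="boltzmann")


@dataclass(frozen=True)
class FitResult:
    """Least-squares fit of a separable cosine series to a surface."""

    potential: FourierDihedralPotential
    residual_rms: float


def fit_fourier_to_surface(
    delta_v: np.ndarray,
    grid: AngleGrid | None = None,
    n_terms: int = 5,
    m_terms: int = 5,
    phases: str = "fixed",
    gamma_phi: np.ndarray | None = None,
    gamma_psi: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> FitResult:
    """Fit the separable Fourier form to an energy surface by least squares.

    Parameters
    ----------
    delta_v : ndarray, shape (n_phi, n_psi)
        Target surface in kJ/mol at bin centers; entries excluded by
        ``mask`` may be non-finite.
    phases : {"fixed", "free"}
        With "fixed" the per-term phases are held at ``gamma_phi`` /
        ``gamma_psi`` (default 0) and the signed amplitudes are the
        unknowns.  With "free" both cosine and sine components of every
        term are fitted (still linear) and returned in amplitude/phase
        form with k >= 0.
    mask : boolean ndarray, optional
        True for bins that enter the loss; defaults to all bins.

    The loss is the unweighted sum of squared deviations over unmasked
    bins.  The additive constant is always fitted and absorbed into the
    potential's ``offset``.
    """
    grid = grid or AngleGrid()
    delta_v = np.asarray(delta_v, dtype=float)
    if delta_v.shape != (grid.n_phi, grid.n_psi):
        raise ValueError("surface shape does not match grid")
    if mask is None:
        mask = np.ones_like(delta_v, dtype=bool)
    if not mask.any():
        raise ValueError("all bins are masked; nothing to fit")
    if phases not in ("fixed", "free"):
        raise ValueError(f"phases must be 'fixed' or 'free', got {phases!r}")
    y = delta_v[mask]
    if not np.all(np.isfinite(y)):
        raise ValueError("surface contains non-finite values on unmasked bins")

    phi, psi = grid.mesh()
    tp = np.deg2rad(phi[mask])
    ts = np.deg2rad(psi[mask])
    g_phi = np.zeros(n_terms) if gamma_phi is None else np.asarray(gamma_phi, float)
    g_psi = np.zeros(m_terms) if gamma_psi is None else np.asarray(gamma_psi, float)

    cols = [np.ones_like(y)]
    if phases == "fixed":
        for n in range(1, n_terms + 1):
            cols.append(np.cos(n * tp - math.radians(g_phi[n - 1])))
        for m in range(1, m_terms + 1):
            cols.append(np.cos(m * ts - math.radians(g_psi[m - 1])))
    else:
        for n in range(1, n_terms + 1):
            cols.append(np.cos(n * tp))
            cols.append(np.sin(n * tp))
        for m in range(1, m_terms + 1):
            cols.append(np.cos(m * ts))
            cols.append(np.sin(m * ts))
    A = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    rms = float(np.sqrt(np.mean(resid**2)))

    c0 = coef[0]
    if phases == "fixed":
        k_phi = coef[1 : 1 + n_terms]
        k_psi = coef[1 + n_terms :]
        pot = FourierDihedralPotential(
            k_phi=k_phi, k_psi=k_psi,
            gamma_phi=g_phi.copy(), gamma_psi=g_psi.copy(),
            offset=float(c0 - k_phi.sum() - k_psi.sum()),
        )
    else:
        ab = coef[1:].reshape(-1, 2)
        a_phi, b_phi = ab[:n_terms, 0], ab[:n_terms, 1]
        a_psi, b_psi = ab[n_terms:, 0], ab[n_terms:, 1]
        k_phi = np.hypot(a_phi, b_phi)
        k_psi = np.hypot(a_psi, b_psi)
        pot = FourierDihedralPotential(
            k_phi=k_phi, k_psi=k_psi,
            gamma_phi=np.rad2deg(np.arctan2(b_phi, a_phi)),
            gamma_psi=np.rad2deg(np.arctan2(b_psi, a_psi)),
            offset=float(c0 - k_phi.sum() - k_psi.sum()),
        )
    return FitResult(potential=pot, residual_rms=rms)


def rescale_potential(
    pot: FourierDihedralPotential, factor: float
) -> FourierDihedralPotential:
    """Multiply all periodic coefficients by ``factor`` (offset unchanged).

    This is the "manual rescaling" knob used to shrink potential
    magnitudes after inversion while preserving the shape of the surface.
    """
    if not math.isfinite(factor):
        raise ValueError("rescale factor must be finite")
    return FourierDihedralPotential(
        k_phi=pot.k_phi * factor, k_psi=pot.k_psi * factor,
        gamma_phi=pot.gamma_phi.copy(), gamma_psi=pot.gamma_psi.copy(),
        offset=pot.offset,
    )


def combine_potentials(
    pot: FourierDihedralPotential,
    delta: FourierDihedralPotential,
    damping: float = 1.0,
) -> FourierDihedralPotential:
    """Return ``pot + damping * delta`` term-by-term.

    Terms are added in the phase-free (cosine, sine) representation, so
    potentials with different phase conventions combine exactly; the
    result carries k >= 0 with phases in (-180, 180].
    """
    n = max(pot.n_terms, delta.n_terms)
    m = max(pot.m_terms, delta.m_terms)

    def _pad(a: np.ndarray, size: int) -> np.ndarray:
        return np.pad(a, (0, size - a.size))

    ap, bp, as_, bs = cosine_sine_coefficients(pot)
    dap, dbp, das, dbs = cosine_sine_coefficients(delta)
    ap = _pad(ap, n) + damping * _pad(dap, n)
    bp = _pad(bp, n) + damping * _pad(dbp, n)
    as_ = _pad(as_, m) + damping * _pad(das, m)
    bs = _pad(bs, m) + damping * _pad(dbs, m)
    k_phi, k_psi = np.hypot(ap, bp), np.hypot(as_, bs)
    # preserve the total constant: each term contributes its k through the
    # "1 +" in k*(1 + cos), and sum(k) changes under recombination
    const = (pot.offset + pot.k_phi.sum() + pot.k_psi.sum()
             + damping * (delta.offset + delta.k_phi.sum() + delta.k_psi.sum()))
    return FourierDihedralPotential(
        k_phi=k_phi, k_psi=k_psi,
        gamma_phi=np.rad2deg(np.arctan2(bp, ap)),
        gamma_psi=np.rad2deg(np.arctan2(bs, as_)),
        offset=float(const - k_phi.sum() - k_psi.sum()),
    )
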