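"""Spectroscopic forward models and goodness-of-fit metrics.

Scalar NMR J-couplings are predicted from a Ramachandran distribution by
ensemble-averaging the Karplus relation

    J(theta) = A cos^2(theta + theta0) + B cos(theta + theta0) + C

over the bin centers of the relevant backbone angle (phi for the 3J
couplings, psi for 1J(N,CA)).  Per-coupling uncertainties combine the
experimental error with the published uncertainties of the Karplus
parameters, propagated in quadrature and ensemble-averaged.  Agreement
with experiment is summarized by the reduced chi^2 over all couplings
and over the phi-dependent subset.

Vibrational circular dichroism of the amide I' band is modeled with a
two-oscillator degenerate exciton model: per conformer the coupling
splits the band into an in-phase and out-of-phase mode carrying
rotational strengths of equal magnitude and opposite sign (a
conservative couplet); profiles are population-averaged and convolved
with a Gaussian or Lorentzian line shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .grid import AngleGrid, RamaDistribution

__all__ = [
    "KarplusParameters",
    "JCouplingObservation",
    "JCouplingReport",
    "VCDProfile",
    "OscillatorModelConfig",
    "karplus_value",
    "ensemble_average",
    "coupling_uncertainty",
    "chi2_j",
    "jcoupling_report",
    "vcd_profile",
    "chi2_vcd",
]


@dataclass(frozen=True)
class KarplusParameters:
    """Karplus constants for one coupling; A, B, C in Hz, theta0 in degrees.

    ``depends_on`` names the backbone angle the coupling reports on.
    Parameter uncertainties (s_A, s_B, s_C) may be ``None`` when the
    source did not publish them (the 1J(N,CA) case).
    """

    coupling_name: str
    A: float
    B: float
    C: float
    theta0: float
    depends_on: str
    s_A: float | None = None
    s_B: float | None = None
    s_C: float | None = None

    def __post_init__(self):
        if self.depends_on not in ("phi", "psi"):
            raise ValueError(
                f"{self.coupling_name}: depends_on must be 'phi' or 'psi', "
                f"got {self.depends_on!r}"
            )
        for label, s in (("s_A", self.s_A), ("s_B", self.s_B), ("s_C", self.s_C)):
            if s is not None and s < 0:
                raise ValueError(f"{self.coupling_name}: {label} must be >= 0")

    @property
    def has_uncertainties(self) -> bool:
        return None not in (self.s_A, self.s_B, self.s_C)


@dataclass(frozen=True)
class JCouplingObservation:
    """Experimental coupling value and its uncertainty (both Hz)."""

    coupling_name: str
    J_exp: float
    s_J: float

    def __post_init__(self):
        if self.s_J <= 0:
            raise ValueError(f"{self.coupling_name}: s_J must be positive")


def karplus_value(theta, params: KarplusParameters):
    """Karplus J(theta) in Hz; 360-degree periodic in theta (degrees)."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("dihedral angle must be finite")
    c = np.cos(np.deg2rad(theta + params.theta0))
    out = params.A * c * c + params.B * c + params.C
    return float(out) if out.ndim == 0 else out


def ensemble_average(P: RamaDistribution, q: Callable[[np.ndarray, np.ndarray], np.ndarray]) -> float:
    """Population-weighted mean of q(phi, psi) over bin centers.

    ``q`` receives the full (n_phi, n_psi) center meshes and must return
    an array of matching shape.  Non-finite values of q on occupied bins
    raise; masked (zero-probability) bins may be non-finite.
    """
    phi, psi = P.grid.mesh()
    vals = np.asarray(q(phi, psi), dtype=float)
    if vals.shape != P.p.shape:
        raise ValueError("observable function must return one value per bin")
    occupied = P.p > 0
    if not np.all(np.isfinite(vals[occupied])):
        raise ValueError("observable is non-finite on an occupied bin")
    return float(np.sum(P.p[occupied] * vals[occupied]))


def _angle_of(params: KarplusParameters, phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    return phi if params.depends_on == "phi" else psi


def average_coupling(P: RamaDistribution, params: KarplusParameters) -> float:
    """Ensemble-averaged J for one coupling, in Hz."""
    return ensemble_average(P, lambda phi, psi: karplus_value(_angle_of(params, phi, psi), params))


def coupling_uncertainty(
    P: RamaDistribution,
    params: KarplusParameters,
    obs: JCouplingObservation,
) -> float:
    """Total per-coupling uncertainty s_i in Hz.

    The pointwise uncertainty combines the Karplus-parameter errors and
    the experimental error in quadrature,

        s(theta) = sqrt( (s_A cos^2)^2 + (s_B cos)^2 + s_C^2 + s_J^2 ),

    with cos evaluated at theta + theta0, and is then ensemble-averaged
    over the distribution; s_i >= s_J always.

    Raises ``ValueError`` when parameter uncertainties are missing — for
    such couplings (1J(N,CA)) use the experimental ``s_J`` alone.
    """
    if not params.has_uncertainties:
        raise ValueError(
            f"{params.coupling_name}: Karplus parameter uncertainties are "
            "missing; use the experimental uncertainty s_J alone for this coupling"
        )

    def sbar(phi, psi):
        c = np.cos(np.deg2rad(_angle_of(params, phi, psi) + params.theta0))
        return np.sqrt((params.s_A * c * c) ** 2 + (params.s_B * c) ** 2
                       + params.s_C**2 + obs.s_J**2)

    return ensemble_average(P, sbar)


def total_uncertainty(
    P: RamaDistribution, params: KarplusParameters, obs: JCouplingObservation
) -> float:
    """s_i when parameter uncertainties exist, else the experimental s_J."""
    if params.has_uncertainties:
        return coupling_uncertainty(P, params, obs)
    return obs.s_J


def chi2_j(
    j_calc: Sequence[float],
    j_exp: Sequence[float],
    s: Sequence[float],
) -> float:
    """Reduced chi^2 = (1/N) * sum ((J_calc - J_exp)/s_i)^2."""
    j_calc = np.asarray(j_calc, dtype=float)
    j_exp = np.asarray(j_exp, dtype=float)
    s = np.asarray(s, dtype=float)
    if j_calc.size == 0:
        raise ValueError("chi2 of an empty coupling set is undefined")
    if not (j_calc.shape == j_exp.shape == s.shape):
        raise ValueError("coupling lists must have equal length")
    if np.any(s <= 0):
        raise ValueError("uncertainties must be positive")
    return float(np.mean(((j_calc - j_exp) / s) ** 2))


@dataclass(frozen=True)
class JCouplingReport:
    """Per-coupling predictions and the aggregate reduced chi^2 values.

    ``table`` has one row per coupling with columns coupling_name,
    depends_on, J_calc, J_exp, abs_dev, s_i.  ``chi2_jphi`` covers the
    phi-dependent subset only.
    """

    table: pd.DataFrame
    chi2_j: float
    chi2_jphi: float


def jcoupling_report(
    P: RamaDistribution,
    karplus: Sequence[KarplusParameters],
    observations: Sequence[JCouplingObservation],
) -> JCouplingReport:
    """Score a distribution against a set of experimental couplings.

    Couplings are matched by name; a missing or extra name raises with
    the offending labels listed.
    """
    kmap = {k.coupling_name: k for k in karplus}
    missing = [o.coupling_name for o in observations if o.coupling_name not in kmap]
    if missing:
        raise ValueError(f"no Karplus parameters for couplings: {missing}")
    rows = []
    for o in observations:
        k = kmap[o.coupling_name]
        jc = average_coupling(P, k)
        si = total_uncertainty(P, k, o)
        rows.append((o.coupling_name, k.depends_on, jc, o.J_exp, abs(jc - o.J_exp), si))
    table = pd.DataFrame(
        rows, columns=["coupling_name", "depends_on", "J_calc", "J_exp", "abs_dev", "s_i"]
    )
    full = chi2_j(table.J_calc, table.J_exp, table.s_i)
    phi_rows = table[table.depends_on == "phi"]
    chi2_phi = (chi2_j(phi_rows.J_calc, phi_rows.J_exp, phi_rows.s_i)
                if len(phi_rows) else float("nan"))
    return JCouplingReport(table=table, chi2_j=full, chi2_jphi=chi2_phi)


# --------------------------------------------------------------------------
# VCD amide I' forward model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VCDProfile:
    """Molar dichroism spectrum on a wavenumber grid (cm^-1).

    ``s_k`` is the per-point standard error for experimental profiles;
    calculated profiles may leave it ``None``.
    """

    wavenumbers: np.ndarray
    delta_epsilon: np.ndarray
    s_k: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        de = np.asarray(self.delta_epsilon, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "delta_epsilon", de)
        if w.shape != de.shape or w.ndim != 1:
            raise ValueError("wavenumber and dichroism arrays must be aligned 1-D")
        if self.s_k is not None:
            s = np.asarray(self.s_k, dtype=float)
            object.__setattr__(self, "s_k", s)
            if s.shape != w.shape:
                raise ValueError("s_k must align with the wavenumber grid")
            if np.any(s <= 0):
                raise ValueError("s_k must be positive")


def _default_orientation(phi, psi):
    """Inter-dipole angle rule: the second oscillator is rotated by
    phi + psi (degrees) relative to the first — odd under inversion of
    the conformer, as required for a chirality-sensitive signal."""
    return phi + psi


@dataclass(frozen=True)
class OscillatorModelConfig:
    """Two-oscillator degenerate exciton model of the amide I' couplet.

    Two local amide I oscillators share intrinsic wavenumber ``nu0``.
    For a conformer (phi, psi) the second transition dipole is rotated by
    ``orientation(phi, psi)`` degrees (default phi + psi) in the plane
    perpendicular to the inter-oscillator axis, giving

        coupling      V  = coupling_constant * cos(delta)   [cm^-1]
        rot. strength R+- = -/+ (rotational_strength_scale/2) * sin(delta)

    for the in-phase (nu0 + V) and out-of-phase (nu0 - V) exciton modes.
    The two rotational strengths always sum to zero (conservative
    couplet); parallel dipoles give a zero couplet, not an error.  Bands
    are drawn with a peak-normalized Gaussian (sigma = half_width) or
    Lorentzian (HWHM = half_width) line shape.

    All geometric constants are configurable; the defaults are a generic
    stand-in for published coupled-oscillator parametrizations of the
    amide I' band.
    """

    nu0: float = 1658.0
    coupling_constant: float = 5.0
    rotational_strength_scale: float = 1.0
    half_width: float = 12.0
    shape: str = "gaussian"
    wavenumbers: np.ndarray = field(
        default_factory=lambda: np.arange(1580.0, 1741.0, 1.0)
    )
    orientation: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.nu0 <= 0:
            raise ValueError("intrinsic wavenumber must be positive")
        if self.half_width <= 0:
            raise ValueError("band half-width must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")
        object.__setattr__(
            self, "wavenumbers", np.asarray(self.wavenumbers, dtype=float)
        )

    def orientation_rule(self):
        return self.orientation or _default_orientation


def _lineshape(x: np.ndarray, half_width: float, shape: str) -> np.ndarray:
    if shape == "gaussian":
        return np.exp(-0.5 * (x / half_width) ** 2)
    return 1.0 / (1.0 + (x / half_width) ** 2)


def conformer_rotational_strengths(
    phi, psi, cfg: OscillatorModelConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exciton wavenumbers and rotational strengths for conformers.

    Returns (nu_plus, nu_minus, R_plus, R_minus) elementwise over the
    inputs; R_plus + R_minus = 0 exactly.
    """
    delta = np.deg2rad(np.asarray(cfg.orientation_rule()(np.asarray(phi, float),
                                                         np.asarray(psi, float)), float))
    v = cfg.coupling_constant * np.cos(delta)
    r = 0.5 * cfg.rotational_strength_scale * np.sin(delta)
    return cfg.nu0 + v, cfg.nu0 - v, -r, r


def vcd_profile(P: RamaDistribution, cfg: OscillatorModelConfig | None = None) -> VCDProfile:
    """Population-averaged VCD amide I' profile of a distribution.

    Each occupied bin contributes its conformer couplet convolved with
    the configured line shape, weighted by the bin probability; the
    result is linear in P.
    """
    cfg = cfg or OscillatorModelConfig()
    phi, psi = P.grid.mesh()
    occ = P.p > 0
    w = P.p[occ]
    nu_p, nu_m, r_p, r_m = conformer_rotational_strengths(phi[occ], psi[occ], cfg)
    nu = cfg.wavenumbers
    # (bins, wavenumbers) outer evaluation of both bands
    de = (w * r_p) @ _lineshape(nu[None, :] - nu_p[:, None], cfg.half_width, cfg.shape)
    de += (w * r_m) @ _lineshape(nu[None, :] - nu_m[:, None], cfg.half_width, cfg.shape)
    return VCDProfile(wavenumbers=nu.copy(), delta_epsilon=de)


def chi2_vcd(calc: VCDProfile, exp: VCDProfile) -> float:
    """Reduced chi^2 between calculated and experimental VCD profiles.

    Profiles must share the wavenumber grid; the experimental profile
    must carry per-point standard errors s_k.
    """
    if calc.wavenumbers.shape != exp.wavenumbers.shape or not np.allclose(
        calc.wavenumbers, exp.wavenumbers
    ):
        raise ValueError("VCD profiles are on different wavenumber grids")
    if exp.s_k is None:
        raise ValueError("experimental profile must provide s_k")
    r = (calc.delta_epsilon - exp.delta_epsilon) / exp.s_k
    return float(np.mean(r**2))
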