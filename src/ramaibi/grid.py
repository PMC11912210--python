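"""Binned Ramachandran distributions and the metrics used to compare them.

The working representation throughout the toolkit is a normalized
probability histogram over the backbone dihedral angles (phi, psi),
discretized on a regular grid of square bins.  The default grid uses
2 deg x 2 deg bins with centers at -179, -177, ..., 177, 179 on each
axis, i.e. 180 x 180 = 32400 bins.

Distributions are compared with the Hellinger distance and coarse-grained
into named mesostate regions (pPII, antiparallel beta, transitional beta,
right-handed helix, and three turn-supporting regions), with populations
and per-region free energies reported relative to the unoccupied-bin
reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "KB",
    "AngleGrid",
    "RamaDistribution",
    "MesostateDefinition",
    "MesostateReport",
    "DEFAULT_MESOSTATES",
    "wrap_angles",
    "histogram_from_angles",
    "hellinger_distance",
    "classify_hellinger",
    "mesostate_report",
]

#: Boltzmann constant in kJ/(mol K); energies are kJ/mol throughout.
KB = 0.0083144621

_NORM_TOL = 1e-9


def wrap_angles(a):
    """Wrap angles (degrees) into [-180, 180).

    +180 maps onto -180, so every angle lands in exactly one half-open
    bin of a grid whose edges sit at even degrees.
    """
    a = np.asarray(a, dtype=float)
    return (a + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class AngleGrid:
    """Regular square binning of the (phi, psi) torus.

    Parameters
    ----------
    bin_width : float
        Bin edge length in degrees; must divide 360 evenly.  The default
        of 2 deg gives bin centers -179, -177, ..., 179 on each axis.
    """

    bin_width: float = 2.0

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        n = 360.0 / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"bin_width must evenly divide 360 degrees, got {self.bin_width}"
            )

    @property
    def n_phi(self) -> int:
        return int(round(360.0 / self.bin_width))

    @property
    def n_psi(self) -> int:
        return self.n_phi

    @property
    def n_bins(self) -> int:
        return self.n_phi * self.n_psi

    @property
    def centers_phi(self) -> np.ndarray:
        w = self.bin_width
        return -180.0 + w / 2.0 + w * np.arange(self.n_phi)

    @property
    def centers_psi(self) -> np.ndarray:
        return self.centers_phi

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(PHI, PSI) center meshes with phi varying along axis 0."""
        return np.meshgrid(self.centers_phi, self.centers_psi, indexing="ij")

    def indices_of(self, phi, psi) -> tuple[np.ndarray, np.ndarray]:
        """Bin indices of angle pairs; inputs are wrapped first."""
        w = self.bin_width
        i = np.floor((wrap_angles(phi) + 180.0) / w).astype(np.intp)
        j = np.floor((wrap_angles(psi) + 180.0) / w).astype(np.intp)
        # guard against the pathological a = 180 - eps float edge
        i = np.clip(i, 0, self.n_phi - 1)
        j = np.clip(j, 0, self.n_psi - 1)
        return i, j


@dataclass(frozen=True)
class RamaDistribution:
    """Normalized probability histogram over an :class:`AngleGrid`.

    ``p[i, j]`` is the probability mass of the bin centered at
    ``(centers_phi[i], centers_psi[j])``.  The array is validated on
    construction (non-negative, sums to one within 1e-9) but is *not*
    renormalized, so file round-trips are bit-faithful.
    """

    grid: AngleGrid
    p: np.ndarray
    meta: str = "histogram"

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.shape != (self.grid.n_phi, self.grid.n_psi):
            raise ValueError(
                f"probability array shape {p.shape} does not match grid "
                f"({self.grid.n_phi}, {self.grid.n_psi})"
            )
        if not np.all(np.isfinite(p)):
            raise ValueError("probabilities must be finite")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        total = float(p.sum())
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")

    def same_grid(self, other: "RamaDistribution") -> bool:
        return self.grid == other.grid


def histogram_from_angles(
    angles: Iterable[tuple[float, float]] | np.ndarray,
    grid: AngleGrid | None = None,
) -> RamaDistribution:
    """Histogram (phi, psi) samples into a normalized distribution.

    Each sample is wrapped into [-180, 180) and counted in exactly one
    bin (half-open membership; +180 wraps to the -180 side).

    Raises
    ------
    ValueError
        If the input is empty or contains a non-finite angle (the error
        message carries the offending sample index).
    """
    grid = grid or AngleGrid()
    a = np.asarray(list(angles) if not isinstance(angles, np.ndarray) else angles,
                   dtype=float)
    if a.size == 0:
        raise ValueError("cannot histogram an empty angle sequence")
    a = a.reshape(-1, 2)
    bad = ~np.isfinite(a).all(axis=1)
    if bad.any():
        idx = int(np.nonzero(bad)[0][0])
        raise ValueError(f"non-finite angle pair at index {idx}: {a[idx]}")
    i, j = grid.indices_of(a[:, 0], a[:, 1])
    counts = np.bincount(i * grid.n_psi + j, minlength=grid.n_bins).astype(float)
    p = (counts / len(a)).reshape(grid.n_phi, grid.n_psi)
    return RamaDistribution(grid=grid, p=p, meta="histogram")


def hellinger_distance(P: RamaDistribution, Q: RamaDistribution) -> float:
    """Hellinger distance between two distributions on the same grid.

    Computed in the numerically stable square-root form

        H(P, Q) = sqrt( (1/2) * sum_ij (sqrt(p_ij) - sqrt(q_ij))^2 )

    which is exactly zero for identical arrays and one for disjoint
    supports; bounded in [0, 1].
    """
    if not P.same_grid(Q):
        raise ValueError("distributions are defined on different grids")
    d = np.sqrt(P.p) - np.sqrt(Q.p)
    return float(min(1.0, math.sqrt(0.5 * float(np.dot(d.ravel(), d.ravel())))))


#: (upper bound, label) pairs; intervals are closed on the right.
_HELLINGER_CLASSES = (
    (0.1, "very similar"),
    (0.25, "moderately similar"),
    (0.4, "moderately dissimilar"),
)


def classify_hellinger(h: float) -> str:
    """Similarity label for a Hellinger distance.

    0 <= H <= 0.1 is "very similar", 0.1 < H <= 0.25 "moderately
    similar", 0.25 < H <= 0.4 "moderately dissimilar" and H > 0.4
    "very dissimilar" (the Schweitzer-Stenner/Toal criteria).
    """
    if not np.isfinite(h) or h < 0.0 or h > 1.0:
        raise ValueError(f"Hellinger distance must lie in [0, 1], got {h!r}")
    for upper, label in _HELLINGER_CLASSES:
        if h <= upper:
            return label
    return "very dissimilar"


@dataclass(frozen=True)
class MesostateDefinition:
    """Open rectangular region of the Ramachandran plot.

    Membership is strict: a bin belongs to the region iff its *center*
    satisfies ``phi_range[0] < phi < phi_range[1]`` and likewise for psi.
    """

    name: str
    phi_range: tuple[float, float]
    psi_range: tuple[float, float]
    chirality: str = "n/a"

    def __post_init__(self):
        for lo, hi in (self.phi_range, self.psi_range):
            if not (-180.0 <= lo < hi <= 180.0):
                raise ValueError(
                    f"region {self.name!r}: interval ({lo}, {hi}) must satisfy "
                    "-180 <= lo < hi <= 180"
                )
        if self.chirality not in ("right", "left", "n/a"):
            raise ValueError(f"unknown chirality {self.chirality!r}")

    def mask(self, grid: AngleGrid) -> np.ndarray:
        phi, psi = grid.mesh()
        (plo, phi_hi), (slo, shi) = self.phi_range, self.psi_range
        return (phi > plo) & (phi < phi_hi) & (psi > slo) & (psi < shi)


#: The seven standard mesostate regions for chiral guest residues.
DEFAULT_MESOSTATES: tuple[MesostateDefinition, ...] = (
    MesostateDefinition("pPII", (-90.0, -42.0), (100.0, 180.0), "right"),
    MesostateDefinition("abeta", (-180.0, -130.0), (130.0, 180.0), "right"),
    MesostateDefinition("betat", (-130.0, -90.0), (130.0, 180.0), "right"),
    MesostateDefinition("alpha", (-90.0, -32.0), (-60.0, -14.0), "right"),
    MesostateDefinition("typeI/II'beta_i+2", (-110.0, -30.0), (-20.0, 20.0), "right"),
    MesostateDefinition("typeI'/IIbeta_i+2", (50.0, 110.0), (-20.0, 20.0), "left"),
    MesostateDefinition("asx", (70.0, 110.0), (75.0, 170.0), "left"),
)


@dataclass(frozen=True)
class MesostateReport:
    """Mesostate mole fractions and relative free energies (kJ/mol)."""

    populations: Mapping[str, float]
    free_energies: Mapping[str, float]
    other_fraction: float
    temperature: float = 300.0


def mesostate_report(
    P: RamaDistribution,
    definitions: Sequence[MesostateDefinition] = DEFAULT_MESOSTATES,
    temperature: float = 300.0,
) -> MesostateReport:
    """Coarse-grain a distribution into mesostate populations.

    The population of a region is the probability mass of the bins whose
    centers fall strictly inside it.  The free energy of a region is the
    population-weighted mean of ``-kB*T*ln(p / p_ref)`` over its occupied
    bins, with ``p_ref = 1/n_bins`` (the uniform, "unoccupied" reference);
    empty bins contribute zero and an entirely unoccupied region reports
    zero free energy.  If user-supplied regions overlap, mass in the
    overlap is counted in every matching region, while ``other_fraction``
    is always computed against the union.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    p = P.p
    p_ref = 1.0 / P.grid.n_bins
    populations: dict[str, float] = {}
    free_energies: dict[str, float] = {}
    union = np.zeros_like(p, dtype=bool)
    for d in definitions:
        m = d.mask(P.grid)
        union |= m
        pop = float(p[m].sum())
        populations[d.name] = pop
        occ = m & (p > 0)
        if pop > 0:
            g = -KB * temperature * np.log(p[occ] / p_ref)
            free_energies[d.name] = float(np.sum(p[occ] * g) / pop)
        else:
            free_energies[d.name] = 0.0
    other = float(p[~union].sum())
    return MesostateReport(
        populations=populations,
        free_energies=free_energies,
        other_fraction=other,
        temperature=temperature,
    )
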