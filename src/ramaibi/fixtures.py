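"""Synthetic ground-truth fixtures: targets, angle series, observables.

Everything the toolkit needs for end-to-end exercise is generated here
with known ground truth, so no downloaded data is required.

Two named scenarios emulate the qualitative structure of guest-residue
ensembles in GxG peptides:

* ``glycine_like`` — achiral: components come in mirror pairs at
  +/-(center) with equal weights, so the density is exactly
  inversion-symmetric about the origin, P(phi, psi) = P(-phi, -psi).
* ``alanine_like`` — chiral, dominated by a broad polyproline II basin
  with antiparallel/transitional beta neighbors at similar psi and a
  minor right-handed helical component.

The scenario parameter values are illustrative defaults chosen to give
realistic mesostate structure; they are not fitted to any experimental
data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .gaussian import GaussianComponent, GaussianRamaModel, evaluate_model
from .grid import AngleGrid, RamaDistribution
from .observables import (
    JCouplingObservation,
    KarplusParameters,
    OscillatorModelConfig,
    VCDProfile,
    average_coupling,
    total_uncertainty,
    vcd_profile,
)

__all__ = [
    "FixtureSpec",
    "make_target",
    "make_synthetic_experiment",
    "GLYCINE_LIKE_COMPONENTS",
    "ALANINE_LIKE_COMPONENTS",
]

#: Mirror-paired components for the achiral scenario.
GLYCINE_LIKE_COMPONENTS: tuple[GaussianComponent, ...] = (
    GaussianComponent("pPII_R", 0.25, (-65.0, 150.0), (18.0, 18.0)),
    GaussianComponent("pPII_L", 0.25, (65.0, -150.0), (18.0, 18.0)),
    GaussianComponent("abeta_R", 0.15, (-150.0, 160.0), (18.0, 14.0)),
    GaussianComponent("abeta_L", 0.15, (150.0, -160.0), (18.0, 14.0)),
    GaussianComponent("alpha_R", 0.10, (-60.0, -40.0), (14.0, 14.0)),
    GaussianComponent("alpha_L", 0.10, (60.0, 40.0), (14.0, 14.0)),
)

#: Chiral, pPII-dominated scenario: three extended-region basins that
#: differ in phi but share one broad psi profile (at lower psi than the
#: glycine-like pPII).  Sharing the psi profile keeps the ensemble
#: compatible with a separable dihedral potential — the regime in which
#: the alanine-like reparametrization converges in a single inversion
#: step.  Minor turn/helical populations are omitted.
ALANINE_LIKE_COMPONENTS: tuple[GaussianComponent, ...] = (
    GaussianComponent("pPII", 0.62, (-70.0, 140.0), (25.0, 22.0)),
    GaussianComponent("betat", 0.18, (-110.0, 140.0), (15.0, 22.0)),
    GaussianComponent("abeta", 0.20, (-155.0, 140.0), (18.0, 22.0)),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic target ensemble.

    ``components`` overrides the scenario's default component list
    (required for ``scenario="custom"``).  Noise levels apply to the
    synthetic experiments derived from the target.
    """

    scenario: str = "alanine_like"
    components: tuple[GaussianComponent, ...] | None = None
    s_J_default: float = 0.3
    vcd_noise: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in ("glycine_like", "alanine_like", "custom"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "custom" and self.components is None:
            raise ValueError("custom scenario requires an explicit component list")


def make_target(
    spec: FixtureSpec, grid: AngleGrid | None = None
) -> tuple[GaussianRamaModel, RamaDistribution]:
    """Build the scenario's Gaussian model and its distribution on the grid.

    The model parameters are the ground truth; weights must sum to one.
    """
    if spec.components is not None:
        components = spec.components
    elif spec.scenario == "glycine_like":
        components = GLYCINE_LIKE_COMPONENTS
    else:
        components = ALANINE_LIKE_COMPONENTS
    total = sum(c.weight for c in components)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"component weights must sum to 1, got {total!r}")
    model = GaussianRamaModel(components=tuple(components), normalization="exact")
    return model, evaluate_model(model, grid or AngleGrid())


def make_synthetic_experiment(
    model: GaussianRamaModel,
    karplus: Sequence[KarplusParameters],
    seed: int,
    grid: AngleGrid | None = None,
    s_J: float | Mapping[str, float] = 0.3,
    noise: str = "matched",
    vcd_config: OscillatorModelConfig | None = None,
    vcd_noise: float = 1e-3,
    include_vcd: bool = True,
) -> tuple[list[JCouplingObservation], VCDProfile | None, dict]:
    """Forward-model a synthetic "experiment" from a known ensemble.

    J-couplings are the ensemble averages under the model plus Gaussian
    noise; with ``noise="matched"`` the noise standard deviation per
    coupling equals the full propagated uncertainty s_i (experimental
    s_J plus Karplus-parameter errors, when available), so the reduced
    chi-squared of the generating model against its own experiment is
    calibrated to one in expectation.  ``noise="experimental"`` draws
    with s_J only; ``noise="none"`` returns the noiseless averages.

    The VCD profile is the model profile plus i.i.d. Gaussian noise of
    standard deviation ``vcd_noise``, which is also reported as s_k.

    Returns (observations, vcd_profile, ground_truth) where
    ground_truth records the noiseless averages and profile.
    """
    if noise not in ("matched", "experimental", "none"):
        raise ValueError(f"unknown noise mode {noise!r}")
    rng = np.random.default_rng(seed)
    dist = evaluate_model(model, grid or AngleGrid())
    observations: list[JCouplingObservation] = []
    truth_j: dict[str, float] = {}
    for params in karplus:
        sj = s_J[params.coupling_name] if isinstance(s_J, Mapping) else float(s_J)
        j_true = average_coupling(dist, params)
        truth_j[params.coupling_name] = j_true
        if noise == "none":
            sigma = 0.0
        elif noise == "experimental" or not params.has_uncertainties:
            sigma = sj
        else:
            sigma = total_uncertainty(
                dist, params, JCouplingObservation(params.coupling_name, j_true, sj)
            )
        observations.append(
            JCouplingObservation(
                coupling_name=params.coupling_name,
                J_exp=j_true + sigma * rng.standard_normal(),
                s_J=sj,
            )
        )
    exp_profile = None
    clean = None
    if include_vcd:
        cfg = vcd_config or OscillatorModelConfig()
        clean = vcd_profile(dist, cfg)
        noisy = clean.delta_epsilon + (
            vcd_noise * rng.standard_normal(clean.delta_epsilon.shape)
            if noise != "none" else 0.0
        )
        exp_profile = VCDProfile(
            wavenumbers=clean.wavenumbers,
            delta_epsilon=noisy,
            s_k=np.full_like(clean.delta_epsilon, vcd_noise),
        )
    ground_truth = {"J": truth_j, "vcd": clean, "seed": seed}
    return observations, exp_profile, ground_truth
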