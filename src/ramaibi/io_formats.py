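"""Readers and writers for the plain-text formats the toolkit touches.

Formats
-------
* gmx-rama style ``.xvg`` dihedral series: "phi psi label" per line,
  ``#``/``@`` headers skipped.
* Plain-text probability grid matrices with ``# phi_centers:`` /
  ``# psi_centers:`` headers (17 significant digits, lossless for
  float64).
* GROMACS topology ``[ dihedraltypes ]`` fragments, proper-dihedral
  function type 9 (angles printed with 2 decimals, energies with 6).
* Gaussian-model and potential parameter files (YAML).
* Delimited Karplus / observation tables and 2-3 column VCD profiles.

All readers reject malformed input with the offending line identified;
every writer's output is accepted by its paired reader.
"""

from __future__ import annotations

import io
import math
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .gaussian import GaussianComponent, GaussianRamaModel
from .grid import AngleGrid, RamaDistribution, wrap_angles
from .observables import JCouplingObservation, KarplusParameters, VCDProfile
from .potentials import FourierDihedralPotential

__all__ = [
    "RamaXvgRecord",
    "read_rama_xvg",
    "write_rama_xvg",
    "read_grid_matrix",
    "write_grid_matrix",
    "read_gaussian_model",
    "write_gaussian_model",
    "read_potential",
    "write_potential",
    "read_karplus_table",
    "default_karplus_table",
    "read_observations",
    "write_observations",
    "read_vcd_profile",
    "write_vcd_profile",
    "read_gromacs_dihedraltypes",
    "write_gromacs_dihedraltypes",
    "potential_from_dihedraltypes",
]


def _as_text_stream(source, mode: str = "r"):
    """Accept a path or an open text stream; returns (stream, should_close)."""
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


# -- gmx rama xvg ----------------------------------------------------------


@dataclass(frozen=True)
class RamaXvgRecord:
    """One dihedral sample: phi, psi (degrees, wrapped on read) and a label."""

    phi: float
    psi: float
    label: str


def read_rama_xvg(source, label_filter: str | None = None) -> list[RamaXvgRecord]:
    """Parse a gmx-rama style xvg stream into ordered records.

    Lines starting with ``#`` or ``@`` are headers.  Data lines must be
    "phi psi label"; a malformed line raises with its line number.
    """
    stream, close = _as_text_stream(source)
    records: list[RamaXvgRecord] = []
    try:
        for lineno, line in enumerate(stream, start=1):
            text = line.strip()
            if not text or text.startswith(("#", "@")):
                continue
            parts = text.split()
            if len(parts) != 3:
                raise ValueError(
                    f"xvg line {lineno}: expected 'phi psi label', got {text!r}"
                )
            try:
                phi, psi = float(parts[0]), float(parts[1])
            except ValueError as err:
                raise ValueError(f"xvg line {lineno}: non-numeric angle in {text!r}") from err
            if not (math.isfinite(phi) and math.isfinite(psi)):
                raise ValueError(f"xvg line {lineno}: non-finite angle in {text!r}")
            if label_filter is not None and parts[2] != label_filter:
                continue
            records.append(
                RamaXvgRecord(float(wrap_angles(phi)), float(wrap_angles(psi)), parts[2])
            )
    finally:
        if close:
            stream.close()
    return records


def write_rama_xvg(records: Iterable[RamaXvgRecord], dest) -> None:
    """Write records in the dialect :func:`read_rama_xvg` accepts (6 decimals)."""
    stream, close = _as_text_stream(dest, "w")
    try:
        stream.write("# phi psi label\n@ generated by ramaibi\n")
        for r in records:
            stream.write(f"{r.phi:.6f} {r.psi:.6f} {r.label}\n")
    finally:
        if close:
            stream.close()


# -- grid matrices ---------------------------------------------------------


def write_grid_matrix(dist: RamaDistribution, dest, meta: str | None = None) -> None:
    """Write a distribution as a plain-text matrix (17 significant digits)."""
    stream, close = _as_text_stream(dest, "w")
    g = dist.grid
    try:
        stream.write("# phi_centers: " + " ".join(f"{c:.17g}" for c in g.centers_phi) + "\n")
        stream.write("# psi_centers: " + " ".join(f"{c:.17g}" for c in g.centers_psi) + "\n")
        stream.write(f"# meta: {meta if meta is not None else dist.meta}\n")
        for row in dist.p:
            stream.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    finally:
        if close:
            stream.close()


def read_grid_matrix(source) -> RamaDistribution:
    """Read a distribution written by :func:`write_grid_matrix` (bit-exact)."""
    stream, close = _as_text_stream(source)
    try:
        lines = stream.readlines()
    finally:
        if close:
            stream.close()
    headers: dict[str, str] = {}
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines, start=1):
        text = line.strip()
        if not text:
            continue
        if text.startswith("#"):
            body = text[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                headers[key.strip()] = value.strip()
            continue
        try:
            rows.append([float(v) for v in text.split()])
        except ValueError as err:
            raise ValueError(f"grid matrix line {lineno}: non-numeric entry") from err
    for key in ("phi_centers", "psi_centers"):
        if key not in headers:
            raise ValueError(f"grid matrix is missing the '# {key}:' header")
    phi_centers = np.array([float(v) for v in headers["phi_centers"].split()])
    psi_centers = np.array([float(v) for v in headers["psi_centers"].split()])
    if len(phi_centers) < 2:
        raise ValueError("grid matrix must have at least two phi centers")
    width = phi_centers[1] - phi_centers[0]
    grid = AngleGrid(bin_width=float(width))
    if (not np.array_equal(grid.centers_phi, phi_centers)
            or not np.array_equal(grid.centers_psi, psi_centers)):
        raise ValueError("grid matrix centers do not form a regular 360-degree grid")
    p = np.array(rows)
    return RamaDistribution(grid=grid, p=p, meta=headers.get("meta", "file"))


# -- Gaussian model parameter files (YAML) ---------------------------------

_MODEL_KEYS = {"components", "normalization"}
_COMPONENT_KEYS = {"name", "weight", "center", "widths"}


def write_gaussian_model(model: GaussianRamaModel, dest) -> None:
    doc = {
        "normalization": model.normalization,
        "components": [
            {
                "name": c.name,
                "weight": float(c.weight),
                "center": [float(c.center[0]), float(c.center[1])],
                "widths": [float(c.widths[0]), float(c.widths[1])],
            }
            for c in model.components
        ],
    }
    stream, close = _as_text_stream(dest, "w")
    try:
        yaml.safe_dump(doc, stream, sort_keys=False)
    finally:
        if close:
            stream.close()


def read_gaussian_model(source) -> GaussianRamaModel:
    """Read a Gaussian-model parameter file; unknown keys are rejected."""
    stream, close = _as_text_stream(source)
    try:
        doc = yaml.safe_load(stream)
    finally:
        if close:
            stream.close()
    if not isinstance(doc, dict):
        raise ValueError("model file must be a mapping")
    unknown = set(doc) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"model file has unknown keys: {sorted(unknown)}")
    comps = []
    for i, c in enumerate(doc.get("components", [])):
        bad = set(c) - _COMPONENT_KEYS
        if bad:
            raise ValueError(f"component {i}: unknown keys {sorted(bad)}")
        comps.append(
            GaussianComponent(
                name=str(c["name"]), weight=float(c["weight"]),
                center=(float(c["center"][0]), float(c["center"][1])),
                widths=(float(c["widths"][0]), float(c["widths"][1])),
            )
        )
    return GaussianRamaModel(
        components=tuple(comps), normalization=doc.get("normalization", "exact")
    )


# -- potential parameter files (YAML) --------------------------------------

_POTENTIAL_KEYS = {"n_terms", "m_terms", "offset", "phi_terms", "psi_terms"}


def write_potential(pot: FourierDihedralPotential, dest) -> None:
    doc = {
        "n_terms": int(pot.n_terms),
        "m_terms": int(pot.m_terms),
        "offset": float(pot.offset),
        "phi_terms": [
            {"n": n + 1, "k": float(pot.k_phi[n]), "gamma": float(pot.gamma_phi[n])}
            for n in range(pot.n_terms)
        ],
        "psi_terms": [
            {"n": m + 1, "k": float(pot.k_psi[m]), "gamma": float(pot.gamma_psi[m])}
            for m in range(pot.m_terms)
        ],
    }
    stream, close = _as_text_stream(dest, "w")
    try:
        yaml.safe_dump(doc, stream, sort_keys=False)
    finally:
        if close:
            stream.close()


def read_potential(source) -> FourierDihedralPotential:
    stream, close = _as_text_stream(source)
    try:
        doc = yaml.safe_load(stream)
    finally:
        if close:
            stream.close()
    if not isinstance(doc, dict):
        raise ValueError("potential file must be a mapping")
    unknown = set(doc) - _POTENTIAL_KEYS
    if unknown:
        raise ValueError(f"potential file has unknown keys: {sorted(unknown)}")
    n, m = int(doc["n_terms"]), int(doc["m_terms"])
    k_phi, g_phi = np.zeros(n), np.zeros(n)
    k_psi, g_psi = np.zeros(m), np.zeros(m)
    for t in doc.get("phi_terms", []):
        k_phi[int(t["n"]) - 1] = float(t["k"])
        g_phi[int(t["n"]) - 1] = float(t.get("gamma", 0.0))
    for t in doc.get("psi_terms", []):
        k_psi[int(t["n"]) - 1] = float(t["k"])
        g_psi[int(t["n"]) - 1] = float(t.get("gamma", 0.0))
    return FourierDihedralPotential(
        k_phi=k_phi, k_psi=k_psi, gamma_phi=g_phi, gamma_psi=g_psi,
        offset=float(doc.get("offset", 0.0)),
    )


# -- Karplus / observation tables ------------------------------------------


def read_karplus_table(source) -> list[KarplusParameters]:
    """Read a delimited Karplus table.

    Columns: coupling_name, A, B, C, theta0, depends_on, s_A, s_B, s_C.
    Empty uncertainty cells mean "not published".
    """
    df = pd.read_csv(source, comment="#")
    required = {"coupling_name", "A", "B", "C", "theta0", "depends_on"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Karplus table is missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        def _opt(col):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        out.append(
            KarplusParameters(
                coupling_name=str(row.coupling_name),
                A=float(row.A), B=float(row.B), C=float(row.C),
                theta0=float(row.theta0), depends_on=str(row.depends_on),
                s_A=_opt("s_A"), s_B=_opt("s_B"), s_C=_opt("s_C"),
            )
        )
    return out


def default_karplus_table() -> list[KarplusParameters]:
    """The Karplus table shipped with the package (editable data file)."""
    ref = resources.files("ramaibi").joinpath("data/karplus_hu_bax.csv")
    with ref.open("r") as fh:
        return read_karplus_table(fh)


def read_observations(source) -> list[JCouplingObservation]:
    """Read a delimited table of experimental couplings (name, J_exp, s_J)."""
    df = pd.read_csv(source, comment="#")
    required = {"coupling_name", "J_exp", "s_J"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation table is missing columns: {sorted(missing)}")
    return [
        JCouplingObservation(str(r.coupling_name), float(r.J_exp), float(r.s_J))
        for r in df.itertuples()
    ]


def write_observations(observations: Sequence[JCouplingObservation], dest) -> None:
    df = pd.DataFrame(
        [(o.coupling_name, o.J_exp, o.s_J) for o in observations],
        columns=["coupling_name", "J_exp", "s_J"],
    )
    if isinstance(dest, (str, Path)):
        df.to_csv(dest, index=False)
    else:
        df.to_csv(dest, index=False)


# -- VCD profiles ----------------------------------------------------------


def read_vcd_profile(source) -> VCDProfile:
    """Read a 2- or 3-column (wavenumber, delta_eps[, s_k]) text profile."""
    stream, close = _as_text_stream(source)
    try:
        data = np.loadtxt(stream, comments="#", ndmin=2)
    finally:
        if close:
            stream.close()
    if data.shape[1] not in (2, 3):
        raise ValueError("VCD profile must have 2 or 3 columns")
    s_k = data[:, 2] if data.shape[1] == 3 else None
    return VCDProfile(wavenumbers=data[:, 0], delta_epsilon=data[:, 1], s_k=s_k)


def write_vcd_profile(profile: VCDProfile, dest) -> None:
    stream, close = _as_text_stream(dest, "w")
    try:
        stream.write("# wavenumber delta_epsilon" + (" s_k" if profile.s_k is not None else "") + "\n")
        for i, (w, de) in enumerate(zip(profile.wavenumbers, profile.delta_epsilon)):
            if profile.s_k is not None:
                stream.write(f"{w:.17g} {de:.17g} {profile.s_k[i]:.17g}\n")
            else:
                stream.write(f"{w:.17g} {de:.17g}\n")
    finally:
        if close:
            stream.close()


# -- GROMACS [ dihedraltypes ] fragments -----------------------------------

_DEFAULT_QUARTETS: Mapping[str, tuple[str, str, str, str]] = {
    "phi": ("C", "N", "CT", "C"),
    "psi": ("N", "CT", "C", "N"),
}


def write_gromacs_dihedraltypes(
    pot: FourierDihedralPotential,
    atom_quartets: Mapping[str, tuple[str, str, str, str]] | None = None,
    dest=None,
    emit_zeros: bool = False,
) -> None:
    """Write proper-dihedral (function type 9) lines for a potential.

    One line per term, ordered phi terms then psi terms by ascending
    multiplicity; zero-coefficient terms are skipped unless
    ``emit_zeros``.  Phases are printed with 2 decimals, force constants
    with 6.  Multiplicities above 5 are rejected.
    """
    quartets = dict(atom_quartets or _DEFAULT_QUARTETS)
    for angle, (k, g) in (("phi", (pot.k_phi, pot.gamma_phi)),
                          ("psi", (pot.k_psi, pot.gamma_psi))):
        if k.size > 5:
            raise ValueError(
                f"{angle}: multiplicity {k.size} exceeds 5 (GROMACS type-9 limit)"
            )
    stream, close = _as_text_stream(dest, "w")
    try:
        stream.write("; ramaibi backbone dihedral parameters\n")
        stream.write("[ dihedraltypes ]\n")
        stream.write(";      i        j        k        l  func     phase        kd  pn\n")
        for angle in ("phi", "psi"):
            a1, a2, a3, a4 = quartets[angle]
            ks = pot.k_phi if angle == "phi" else pot.k_psi
            gs = pot.gamma_phi if angle == "phi" else pot.gamma_psi
            for n in range(1, ks.size + 1):
                if ks[n - 1] == 0.0 and not emit_zeros:
                    continue
                stream.write(
                    f"{a1:>8} {a2:>8} {a3:>8} {a4:>8}     9 "
                    f"{gs[n - 1]:9.2f} {ks[n - 1]:9.6f} {n:3d}\n"
                )
    finally:
        if close:
            stream.close()


def read_gromacs_dihedraltypes(
    source,
) -> dict[tuple[str, str, str, str], list[tuple[float, float, int]]]:
    """Parse a [ dihedraltypes ] fragment into per-quartet term lists.

    Returns a mapping quartet -> list of (phase_deg, k, multiplicity) in
    file order.  Function types other than 9 are rejected with the
    offending line.
    """
    stream, close = _as_text_stream(source)
    out: dict[tuple[str, str, str, str], list[tuple[float, float, int]]] = {}
    try:
        for lineno, line in enumerate(stream, start=1):
            text = line.split(";")[0].strip()
            if not text or text.startswith("["):
                continue
            parts = text.split()
            if len(parts) != 8:
                raise ValueError(
                    f"dihedraltypes line {lineno}: expected 8 fields, got {text!r}"
                )
            quartet = tuple(parts[:4])
            if parts[4] != "9":
                raise ValueError(
                    f"dihedraltypes line {lineno}: unsupported function type "
                    f"{parts[4]!r} (only proper dihedrals, type 9)"
                )
            phase, k, mult = float(parts[5]), float(parts[6]), int(parts[7])
            if not (1 <= mult <= 5):
                raise ValueError(f"dihedraltypes line {lineno}: multiplicity {mult} outside 1..5")
            out.setdefault(quartet, []).append((phase, k, mult))
    finally:
        if close:
            stream.close()
    return out


def potential_from_dihedraltypes(
    terms: Mapping[tuple[str, str, str, str], list[tuple[float, float, int]]],
    atom_quartets: Mapping[str, tuple[str, str, str, str]] | None = None,
    n_terms: int = 5,
    m_terms: int = 5,
) -> FourierDihedralPotential:
    """Reassemble a potential from parsed dihedraltypes entries."""
    quartets = dict(atom_quartets or _DEFAULT_QUARTETS)
    k_phi, g_phi = np.zeros(n_terms), np.zeros(n_terms)
    k_psi, g_psi = np.zeros(m_terms), np.zeros(m_terms)
    for angle, (karr, garr) in (("phi", (k_phi, g_phi)), ("psi", (k_psi, g_psi))):
        for phase, k, mult in terms.get(tuple(quartets[angle]), []):
            karr[mult - 1] = k
            garr[mult - 1] = phase
    return FourierDihedralPotential(k_phi=k_phi, k_psi=k_psi,
                                    gamma_phi=g_phi, gamma_psi=g_psi)
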