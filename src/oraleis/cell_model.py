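"""Cell-scale models: nested-compartment cells, bricked tessellation,
symmetry-unit impedance, and conversion to effective layer properties.

A generic epithelial cell is a nested box: extracellular space (ECS) shell,
cell membrane, cytoplasm, and optionally a voxelized spherical nucleus
(karyoplasm inside a spherical-shell nuclear envelope).  Cells tessellate in
a "bricked" arrangement: successive layers in depth (Z) are offset by half a
cell pitch along X, while Y is unstaggered.  The ECS is split half-and-half
between neighbouring cells so that tessellation produces a single
extracellular gap of the full stated width between adjacent membranes.

Because the bricked packing has mirror symmetry about vertical planes
through cell centres and through the centres of the lateral ECS gaps (and,
along Y and through cell mid-height, the analogous planes), a small
symmetry unit bounded by such planes with zero-normal-current sides
reproduces the response of an infinite layer.  A 1 V harmonic potential
difference applied across the unit gives a complex impedance Z*; this is
made size independent as the impedivity rho* = Z*A/l and finally split into
an effective resistivity (the real part of rho*) and relative permittivity
(from the imaginary admittance), per frequency and per direction (Z through
the layer, XY in the plane).  These effective anisotropic properties are
what the tissue-scale model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fem_core
from .materials import (EPS0, AnisotropicMaterial, CompartmentPropertySet,
                        DispersiveMaterial)

__all__ = [
    "CellMorphology",
    "SymmetryUnit",
    "EffectiveProperties",
    "build_cell",
    "build_symmetry_unit",
    "unit_impedance",
    "impedivity",
    "to_resistivity_permittivity",
    "homogenize",
    "scaled_membrane_props",
]


@dataclass(frozen=True)
class CellMorphology:
    """Geometry of one epithelial cell plus its share of extracellular space.

    ``size_um`` is the outer extent of the cell membrane box (x, y, z);
    flattened superficial cells have small z.  ``ecs_half_um`` is the ECS
    shell thickness carried by this cell on each face, i.e. half the full
    membrane-to-membrane gap of the tessellated layer.  The nucleus, when
    enabled, is a sphere of fixed radius at the cell centre surrounded by a
    spherical-shell nuclear envelope; it must fit strictly inside the
    cytoplasm.
    """

    size_um: tuple[float, float, float]
    membrane_nm: float = 8.0
    ecs_half_um: float = 0.05
    nucleated: bool = False
    nucleus_radius_um: float = 2.0
    nuclear_membrane_nm: float = 40.0
    name: str = "cell"

    def __post_init__(self):
        sx, sy, sz = self.size_um
        m = self.membrane_nm * 1e-3
        if min(sx, sy, sz) <= 0 or self.membrane_nm <= 0 or self.ecs_half_um <= 0:
            raise ValueError("all cell dimensions must be positive")
        if 2 * m >= min(sx, sy, sz):
            raise ValueError("membrane thicker than the cell")
        if self.nucleated:
            rn = self.nucleus_radius_um
            if rn <= self.nuclear_membrane_nm * 1e-3:
                raise ValueError("nuclear membrane thicker than the nucleus")
            if 2 * (rn + self.nucleus_shell_um) >= min(sx, sy, sz) - 2 * m:
                raise ValueError("nucleus does not fit inside the cytoplasm")

    @property
    def nucleus_shell_um(self) -> float:
        """Meshed thickness (um) of the voxelized nuclear-envelope band.

        The true envelope (tens of nm) cannot be resolved by centroid
        voxelization, so a one-voxel band just outside the karyoplasm
        sphere represents it; the envelope material is rescaled at
        assembly time to preserve the per-area trans-envelope admittance.
        """
        if not self.nucleated:
            return 0.0
        return max(self.nuclear_membrane_nm * 1e-3, self.nucleus_radius_um / 4.0)

    # geometry in metres -------------------------------------------------
    @property
    def size_m(self):
        return tuple(s * 1e-6 for s in self.size_um)

    @property
    def membrane_m(self):
        return self.membrane_nm * 1e-9

    @property
    def ecs_half_m(self):
        return self.ecs_half_um * 1e-6

    @property
    def pitch_m(self):
        """Tessellation pitch per axis: cell size plus the full ECS gap."""
        e = self.ecs_half_m
        return tuple(s + 2 * e for s in self.size_m)

    @property
    def key(self) -> str:
        return (f"{self.name}|{self.size_um}|{self.membrane_nm}|"
                f"{self.ecs_half_um}|{self.nucleated}|"
                f"{self.nucleus_radius_um}|{self.nuclear_membrane_nm}")


_BASE_REGIONS = ("ecs", "membrane", "cytoplasm")
_NUC_REGIONS = ("nuclear_membrane", "nucleoplasm")


def _labeller(morph: CellMorphology, names):
    """Element labeller for the infinite bricked tiling.

    Layer k (depth index) is offset by half a pitch in X when k is odd.
    Local coordinates are taken from the nearest cell centre.
    """
    px, py, pz = morph.pitch_m
    sx, sy, sz = morph.size_m
    m = morph.membrane_m
    idx = {n: i for i, n in enumerate(names)}

    def fn(cx, cy, cz):
        k = np.floor(cz / pz).astype(np.int64)
        ox = (k % 2) * (px / 2.0)
        u = np.abs(((cx - ox) % px) - px / 2.0)
        v = np.abs((cy % py) - py / 2.0)
        w = np.abs((cz % pz) - pz / 2.0)
        in_mem = (u < sx / 2) & (v < sy / 2) & (w < sz / 2)
        in_cyt = (u < sx / 2 - m) & (v < sy / 2 - m) & (w < sz / 2 - m)
        out = np.full(cx.shape, idx["ecs"], dtype=np.int32)
        out[in_mem] = idx["membrane"]
        out[in_cyt] = idx["cytoplasm"]
        if morph.nucleated:
            rn = morph.nucleus_radius_um * 1e-6
            shell = morph.nucleus_shell_um * 1e-6
            r = np.sqrt(u ** 2 + v ** 2 + w ** 2)
            out[in_cyt & (r < rn + shell)] = idx["nuclear_membrane"]
            out[in_cyt & (r < rn)] = idx["nucleoplasm"]
        return out

    return fn


def _axis_planes(window, pitch, half_size, membrane, offsets, extra=()):
    """Interface coordinates of the tiling within an axis window."""
    x0, x1 = window
    planes = {x0, x1}
    dists = [half_size, half_size - membrane] + list(extra)
    for ox in offsets:
        i0 = int(np.floor((x0 - ox) / pitch)) - 1
        i1 = int(np.ceil((x1 - ox) / pitch)) + 1
        for i in range(i0, i1 + 1):
            c = ox + (i + 0.5) * pitch
            for d in dists:
                for s in (c - d, c + d):
                    if x0 < s < x1:
                        planes.add(s)
    out = np.array(sorted(planes))
    # drop numerically duplicate planes (coincident interfaces)
    keep = np.concatenate([[True], np.diff(out) > 1e-13])
    return out[keep]


def _tiling_mesh(morph: CellMorphology, xwin, ywin, zwin, resolution=6):
    """Conforming graded tensor mesh of the tiling restricted to a box."""
    px, py, pz = morph.pitch_m
    sx, sy, sz = morph.size_m
    m = morph.membrane_m
    extra = ()
    if morph.nucleated:
        rn = morph.nucleus_radius_um * 1e-6
        extra = (rn, rn + morph.nucleus_shell_um * 1e-6)

    xp = _axis_planes(xwin, px, sx / 2, m, offsets=(0.0, px / 2.0), extra=extra)
    yp = _axis_planes(ywin, py, sy / 2, m, offsets=(0.0,), extra=extra)
    zp = _axis_planes(zwin, pz, sz / 2, m, offsets=(0.0,),
                      extra=extra + (pz / 2.0,))

    targets = [s / resolution for s in (sx, sy, sz)]
    if morph.nucleated:
        rn = morph.nucleus_radius_um * 1e-6
        # resolve the voxelized sphere well enough for <=5% volume error
        targets = [min(t, rn / 6.0) for t in targets]

    axes = [fem_core.graded_axis(p, t) for p, t in zip((xp, yp, zp), targets)]
    mesh = fem_core.HexMesh(*axes)
    names = list(_BASE_REGIONS) + (list(_NUC_REGIONS) if morph.nucleated else [])
    mesh.label_regions(_labeller(morph, names), names)
    # keep only names actually present (anuclear cells have exactly 3)
    present = np.unique(mesh.region)
    if present.size != len(names):
        remap = -np.ones(len(names), dtype=np.int32)
        kept = []
        for new, old in enumerate(present):
            remap[old] = new
            kept.append(names[old])
        mesh.region = remap[mesh.region]
        mesh.region_names = kept
    if morph.nucleated:
        # envelope meshed thicker than reality: rescale its material so the
        # per-area trans-envelope admittance is preserved
        mesh.material_scale = {
            "nuclear_membrane":
                morph.nucleus_shell_um * 1e3 / morph.nuclear_membrane_nm}
    return mesh


def build_cell(morph: CellMorphology, resolution=6) -> fem_core.HexMesh:
    """Mesh one cell (plus its ECS shell) with compartment region labels.

    The box spans a single tessellation pitch per axis with the cell at the
    centre; region labels are ``ecs``, ``membrane``, ``cytoplasm`` and, for
    nucleated cells, ``nuclear_membrane`` and ``nucleoplasm``.
    """
    px, py, pz = morph.pitch_m
    return _tiling_mesh(morph, (0.0, px), (0.0, py), (0.0, pz), resolution)


def region_volume(mesh: fem_core.HexMesh, region: str) -> float:
    """Total volume (m^3) of all elements labelled ``region``."""
    a, b, c = mesh.element_sizes()
    vol = a * b * c
    ridx = mesh.region_names.index(region)
    return float(vol[mesh.region == ridx].sum())


@dataclass
class SymmetryUnit:
    """Smallest repeating unit of the bricked packing for one direction.

    ``area`` is the cross-section normal to the applied potential
    difference and ``length`` the distance between the two electrode
    planes, as required for the impedance-to-impedivity conversion.
    Node sets ``drive`` and ``ground`` mark the electrode planes.
    """

    mesh: fem_core.HexMesh
    direction: str  # "Z" or "XY"
    area: float
    length: float
    morphology: CellMorphology


def build_symmetry_unit(morph: CellMorphology, direction: str,
                        n_units: int = 1, resolution: int = 6) -> SymmetryUnit:
    """Build the symmetry unit for the Z (through-layer) or XY (in-plane)
    direction.

    The unit is bounded laterally by mirror planes of the tiling (through
    cell centres and gap centres), which carry the natural zero-current
    condition exactly.  For Z the electrodes are the horizontal mid-gap
    planes bounding two cell layers (capturing the half-pitch brick offset);
    for XY the drive is applied along the unstaggered lateral axis between
    vertical mid-gap planes one pitch apart.  ``n_units`` tiles the unit
    laterally for convergence studies.
    """
    px, py, pz = morph.pitch_m
    if direction not in ("Z", "XY"):
        raise ValueError("direction must be 'Z' or 'XY'")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    n = n_units
    if direction == "Z":
        xwin = (px / 2.0, px / 2.0 + n * px / 2.0)
        ywin = (0.0, n * py / 2.0)
        zwin = (0.0, 2.0 * pz)
        area = (xwin[1] - xwin[0]) * (ywin[1] - ywin[0])
        length = zwin[1] - zwin[0]
        axis, lo, hi = "z", zwin[0], zwin[1]
    else:
        xwin = (px / 2.0, px / 2.0 + n * px / 2.0)
        ywin = (0.0, py)
        zwin = (pz / 2.0, pz / 2.0 + n * pz)
        area = (xwin[1] - xwin[0]) * (zwin[1] - zwin[0])
        length = ywin[1] - ywin[0]
        axis, lo, hi = "y", ywin[0], ywin[1]

    mesh = _tiling_mesh(morph, xwin, ywin, zwin, resolution)
    mesh.plane_node_set("ground", axis, lo)
    mesh.plane_node_set("drive", axis, hi)
    return SymmetryUnit(mesh=mesh, direction=direction, area=area,
                        length=length, morphology=morph)


def _materials_for(mesh: fem_core.HexMesh, props: CompartmentPropertySet):
    table = {
        "ecs": props.ecs,
        "membrane": props.membrane,
        "cytoplasm": props.cytoplasm,
        "nucleoplasm": props.nucleoplasm,
        "nuclear_membrane": props.nuclear_membrane,
    }
    scales = getattr(mesh, "material_scale", {})
    out = {}
    for name in mesh.region_names:
        mat = table[name]
        k = scales.get(name)
        if k is not None and k != 1.0:
            mat = DispersiveMaterial(
                name=f"{mat.name}_x{k:g}",
                rho=lambda fr, _m=mat, _k=k: _m.resistivity(fr) / _k,
                eps_r=lambda fr, _m=mat, _k=k: _m.rel_permittivity(fr) * _k,
                f_range=mat.f_range,
                key=f"{mat.key}|scaled{k:g}")
        out[name] = mat
    return out


def unit_impedance(unit: SymmetryUnit, props: CompartmentPropertySet,
                   f: float) -> complex:
    """Complex impedance of the symmetry unit at frequency ``f``.

    A 1 V peak sinusoidal potential difference is applied between the
    coupled electrode planes; all other faces carry zero normal current,
    confining current to the unit.  Z* = V / I* with I* the complex
    reaction current at the driven plane.
    """
    system = fem_core.assemble(unit.mesh, _materials_for(unit.mesh, props), f)
    sol = fem_core.solve(system, fem_core.BoundaryConditions(
        fixed={"drive": 1.0 + 0.0j, "ground": 0.0 + 0.0j}))
    current = fem_core.reaction_current(sol, system, "drive")
    return 1.0 / current


def impedivity(z: complex, area: float, length: float) -> complex:
    """Size-independent impedivity rho* = Z*A/l (ohm-m)."""
    if area <= 0 or length <= 0:
        raise ValueError("area and length must be positive")
    return z * area / length


def to_resistivity_permittivity(rho_star: complex, f: float):
    """Split an impedivity into (resistivity, relative permittivity).

    Resistivity is the real component of the impedivity.  Permittivity
    comes from the imaginary admittance: for a block of geometry (A, l),
    Y'' = -Z''/(Z'^2 + Z''^2), C = Y''/omega and eps_r = C*l/(eps0*A);
    expressed on the impedivity (which already absorbs A/l) this is
    eps_r = Im(1/rho*) / (omega * eps0).  The geometry factors cancel, so
    only rho* and the frequency are needed.
    """
    if f <= 0:
        raise ValueError("frequency must be positive (omega division)")
    omega = 2.0 * np.pi * f
    resistivity = float(np.real(rho_star))
    y_imag = -np.imag(rho_star) / (abs(rho_star) ** 2)
    eps_r = float(y_imag / (omega * EPS0))
    return resistivity, eps_r


def scaled_membrane_props(props: CompartmentPropertySet, k: float
                          ) -> CompartmentPropertySet:
    """Membrane material adjusted for a k-times thickened membrane.

    Dividing resistivity by k and multiplying permittivity by k preserves
    the per-area trans-membrane admittance, capping element aspect ratios
    without changing the physics (to leading order in membrane thickness).
    """
    if k <= 0:
        raise ValueError("scale factor must be positive")
    mem = props.membrane
    scaled = DispersiveMaterial(
        name=f"{mem.name}_x{k:g}",
        rho=lambda fr, _m=mem, _k=k: _m.resistivity(fr) / _k,
        eps_r=lambda fr, _m=mem, _k=k: _m.rel_permittivity(fr) * _k,
        f_range=mem.f_range,
        key=f"{mem.key}|scaled{k:g}",
    )
    return CompartmentPropertySet(
        ecs=props.ecs, membrane=scaled, cytoplasm=props.cytoplasm,
        nucleoplasm=props.nucleoplasm, nuclear_membrane=props.nuclear_membrane)


def _scaled_morphology(morph: CellMorphology, k: float) -> CellMorphology:
    return CellMorphology(
        size_um=morph.size_um,
        membrane_nm=morph.membrane_nm * k,
        ecs_half_um=morph.ecs_half_um,
        nucleated=morph.nucleated,
        nucleus_radius_um=morph.nucleus_radius_um,
        nuclear_membrane_nm=morph.nuclear_membrane_nm,
        name=morph.name,
    )


@dataclass
class EffectiveProperties:
    """Homogenized anisotropic properties of one epithelial stratum."""

    freqs: np.ndarray
    rho_z: np.ndarray
    eps_z: np.ndarray
    rho_xy: np.ndarray
    eps_xy: np.ndarray
    name: str = "stratum"

    def as_material(self) -> AnisotropicMaterial:
        """Dispersion-table materials (log-log interpolated) for the
        tissue-scale model."""
        if self.freqs.size == 1:  # single-frequency run: constant materials
            return AnisotropicMaterial(
                z=DispersiveMaterial.constant(
                    f"{self.name}_z", float(self.rho_z[0]), float(self.eps_z[0])),
                xy=DispersiveMaterial.constant(
                    f"{self.name}_xy", float(self.rho_xy[0]),
                    float(self.eps_xy[0])),
            )
        return AnisotropicMaterial(
            z=DispersiveMaterial.from_table(
                f"{self.name}_z", self.freqs, self.rho_z, self.eps_z),
            xy=DispersiveMaterial.from_table(
                f"{self.name}_xy", self.freqs, self.rho_xy, self.eps_xy),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "frequency_hz": self.freqs,
            "rho_z": self.rho_z,
            "eps_z": self.eps_z,
            "rho_xy": self.rho_xy,
            "eps_xy": self.eps_xy,
        })

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path, name="stratum") -> "EffectiveProperties":
        import pandas as pd

        df = pd.read_csv(path)
        return EffectiveProperties(
            freqs=df["frequency_hz"].to_numpy(),
            rho_z=df["rho_z"].to_numpy(), eps_z=df["eps_z"].to_numpy(),
            rho_xy=df["rho_xy"].to_numpy(), eps_xy=df["eps_xy"].to_numpy(),
            name=name)


_homog_cache: dict = {}


def homogenize(morph: CellMorphology, props: CompartmentPropertySet,
               freqs, membrane_scale: float = 1.0,
               resolution: int = 6) -> EffectiveProperties:
    """Effective (rho, eps_r) of a tessellated cell layer, per frequency and
    direction.

    Runs the symmetry-unit solve in the Z and XY directions at every
    frequency of ``freqs`` and converts the impedances to size-independent
    properties.  ``membrane_scale`` > 1 enables the thickened-membrane mode
    (admittance-preserving material rescaling) to cap element aspect
    ratios; the default meshes the membrane at true thickness.
    Results are cached per (morphology, properties, grid).
    """
    freqs = np.asarray(freqs, dtype=float)
    key = (morph.key, props.key, membrane_scale, resolution,
           freqs.tobytes())
    hit = _homog_cache.get(key)
    if hit is not None:
        return hit

    if membrane_scale != 1.0:
        morph_used = _scaled_morphology(morph, membrane_scale)
        props_used = scaled_membrane_props(props, membrane_scale)
    else:
        morph_used, props_used = morph, props

    out = {}
    for direction in ("Z", "XY"):
        unit = build_symmetry_unit(morph_used, direction, resolution=resolution)
        rho = np.empty(freqs.size)
        eps = np.empty(freqs.size)
        for i, f in enumerate(freqs):
            z = unit_impedance(unit, props_used, f)
            rs = impedivity(z, unit.area, unit.length)
            rho[i], eps[i] = to_resistivity_permittivity(rs, f)
        out[direction] = (rho, eps)

    result = EffectiveProperties(
        freqs=freqs,
        rho_z=out["Z"][0], eps_z=out["Z"][1],
        rho_xy=out["XY"][0], eps_xy=out["XY"][1],
        name=morph.name)
    _homog_cache[key] = result
    return result
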