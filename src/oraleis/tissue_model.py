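"""Tissue-scale layered model and tetrapolar transfer-impedance spectra.

The tissue is a 40 mm x 40 mm x 5 mm cuboid of horizontal layers, surface
down: a thin saliva film, an optional keratinised layer, the three
epithelial strata (superficial, prickle, basal — each an anisotropic
homogenized cell layer), stroma, and optionally a sub-stromal substrate
(fat, bone or muscle) below a 1 mm stroma.  The depth axis is +Z downward
with the electrode surface at z = 0.

Four circular electrodes sit on the surface: the drive electrode injects a
fixed AC current (6.08 uA peak by default), the receive electrode is
grounded, and two floating measurement electrodes — each a coupled
equipotential node set — sense the potential difference.  The tetrapolar
transfer impedance is Z = (phi_m1 - phi_m2) / I_drive, evaluated per
frequency over the 76 Hz - 625 kHz grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fem_core
from .cell_model import EffectiveProperties
from .materials import AnisotropicMaterial, DispersiveMaterial

__all__ = [
    "TissueCase",
    "Layer",
    "LayerStack",
    "ElectrodeLayout",
    "MeshResolution",
    "RESOLUTIONS",
    "TransferImpedanceSpectrum",
    "default_frequency_grid",
    "build_layer_stack",
    "build_tissue_mesh",
    "tetrapolar_impedance",
    "spectrum",
]

#: Lateral footprint of the simulated tissue block (m): large enough that
#: the outer boundary does not influence the measurement.
LATERAL_EXTENT = 40e-3
#: Total tissue depth (m).
TOTAL_DEPTH = 5e-3
#: Saliva film thickness (m).
SALIVA_THICKNESS = 0.01e-3
#: Stroma thickness when an explicit substrate is present (m).
STROMA_OVER_SUBSTRATE = 1.0e-3
#: Drive current, AC peak (A).
DRIVE_CURRENT = 6.08e-6

EPITHELIAL_STRATA = ("superficial", "prickle", "basal")


def default_frequency_grid(n: int = 14) -> np.ndarray:
    """Geometric frequency grid spanning the device range 76 Hz - 625 kHz."""
    return np.geomspace(76.0, 625_000.0, n)


@dataclass(frozen=True)
class TissueCase:
    """One histology-derived tissue description.

    Layer thicknesses are (mean, standard deviation) in micrometres;
    ``keratinised_um`` is ``None`` for non-keratinised sites.
    """

    case_id: int
    diagnosis: str
    keratinisation: str
    site: str
    basal_um: tuple[float, float]
    prickle_um: tuple[float, float]
    superficial_um: tuple[float, float]
    keratinised_um: tuple[float, float] | None = None
    #: which cell-morphology grade the strata follow (normal / moderate /
    #: severe), mapping dysplasia grade to the equivalent cervical CIN grade
    cell_grade: str = "normal"

    def __post_init__(self):
        for key in ("basal_um", "prickle_um", "superficial_um", "keratinised_um"):
            val = getattr(self, key)
            if val is None:
                continue
            mean, sd = val
            if mean < 0 or sd < 0:
                raise ValueError(f"case {self.case_id}: {key} must be >= 0")

    @property
    def keratinised(self) -> bool:
        return self.keratinised_um is not None


@dataclass(frozen=True)
class Layer:
    name: str
    thickness: float  # m
    material: AnisotropicMaterial

    @property
    def key(self):
        return (self.name, round(self.thickness, 12), self.material.key)


@dataclass(frozen=True)
class LayerStack:
    """Ordered layers from the surface down; total depth is fixed."""

    layers: tuple[Layer, ...]
    case_id: int | None = None
    label: str = ""

    def __post_init__(self):
        total = sum(l.thickness for l in self.layers)
        if abs(total - TOTAL_DEPTH) > 1e-9:
            raise ValueError(f"stack depth {total * 1e3:.4f} mm != "
                             f"{TOTAL_DEPTH * 1e3} mm")
        if any(l.thickness <= 0 for l in self.layers):
            raise ValueError("all layer thicknesses must be positive")

    @property
    def key(self):
        return tuple(l.key for l in self.layers)

    def interfaces(self):
        """Depths of internal layer interfaces (m, surface excluded)."""
        return np.cumsum([l.thickness for l in self.layers])[:-1]


def _as_material(m) -> AnisotropicMaterial:
    if isinstance(m, EffectiveProperties):
        return m.as_material()
    if isinstance(m, DispersiveMaterial):
        return AnisotropicMaterial.isotropic(m)
    if isinstance(m, AnisotropicMaterial):
        return m
    raise TypeError(f"cannot interpret {m!r} as a layer material")


def _thickness(case: TissueCase, key: str, mode: str) -> float:
    mean, sd = getattr(case, f"{key}_um")
    if mode == "mean":
        t = mean
    elif mode == "mean+sd":
        t = mean + sd
    elif mode == "mean-sd":
        t = mean - sd
    else:
        raise ValueError(f"unknown thickness mode {mode!r}")
    if t <= 0:
        raise ValueError(f"case {case.case_id}: {key} thickness {t:.1f} um "
                         f"is not positive under mode {mode!r}")
    return t * 1e-6


def build_layer_stack(case: TissueCase, epithelial_props: dict,
                      keratin=None, substrate=None,
                      thickness_mode: str = "mean",
                      saliva_material=None, stroma_material=None,
                      keratin_thickness_um: float | None = None) -> LayerStack:
    """Assemble the layered model for one tissue case.

    ``epithelial_props`` maps each stratum name to its homogenized
    properties.  ``keratin`` is the keratinised-layer material (required for
    keratinised cases), ``substrate`` an optional fat/bone/muscle material;
    with a substrate the stroma is limited to 1 mm and the substrate fills
    the remaining depth, otherwise stroma fills to the full 5 mm.
    ``keratin_thickness_um`` overrides the histology value (thickness
    sweeps).
    """
    from .materials import saliva as saliva_fn, stroma as stroma_fn

    missing = [s for s in EPITHELIAL_STRATA if s not in epithelial_props]
    if missing:
        raise KeyError(f"epithelial_props missing strata {missing}")

    layers = [Layer("saliva", SALIVA_THICKNESS,
                    _as_material(saliva_material or saliva_fn()))]
    if keratin_thickness_um is not None or case.keratinised:
        if keratin is None:
            raise ValueError(f"case {case.case_id} is keratinised: a keratin "
                             "material is required")
        t = (keratin_thickness_um * 1e-6 if keratin_thickness_um is not None
             else _thickness(case, "keratinised", thickness_mode))
        layers.append(Layer("keratinised", t, _as_material(keratin)))
    for stratum in EPITHELIAL_STRATA:
        layers.append(Layer(stratum, _thickness(case, stratum, thickness_mode),
                            _as_material(epithelial_props[stratum])))

    used = sum(l.thickness for l in layers)
    stroma_mat = _as_material(stroma_material or stroma_fn())
    if substrate is None:
        layers.append(Layer("stroma", TOTAL_DEPTH - used, stroma_mat))
    else:
        sub = _as_material(substrate)
        layers.append(Layer("stroma", STROMA_OVER_SUBSTRATE, stroma_mat))
        layers.append(Layer(f"substrate_{sub.z.name}",
                            TOTAL_DEPTH - used - STROMA_OVER_SUBSTRATE, sub))
    return LayerStack(tuple(layers), case_id=case.case_id,
                      label=f"case{case.case_id}:{thickness_mode}")


# --------------------------------------------------------------------------
# Electrodes and mesh
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeLayout:
    """Four circular surface electrodes: drive, two measurement, receive.

    The default is a collinear tetrapolar row along x, centred on the
    origin, with equal radii.  The exact radii and spacing of the clinical
    probe are not published; this placeholder geometry is a configuration
    input meant to be replaced with device values when available.
    """

    centres: dict = field(default_factory=dict)  # name -> (x, y) in m
    radius: float = 0.3e-3
    drive_current: float = DRIVE_CURRENT

    @staticmethod
    def collinear(pitch: float = 1.6e-3, radius: float = 0.3e-3,
                  drive_current: float = DRIVE_CURRENT) -> "ElectrodeLayout":
        return ElectrodeLayout(
            centres={
                "drive": (-1.5 * pitch, 0.0),
                "m1": (-0.5 * pitch, 0.0),
                "m2": (+0.5 * pitch, 0.0),
                "receive": (+1.5 * pitch, 0.0),
            },
            radius=radius, drive_current=drive_current)

    def __post_init__(self):
        names = set(self.centres)
        if names != {"drive", "m1", "m2", "receive"}:
            raise ValueError("layout must define drive, m1, m2, receive")
        if self.radius <= 0 or self.drive_current == 0:
            raise ValueError("radius must be > 0 and drive current nonzero")
        pts = list(self.centres.items())
        for i, (na, (xa, ya)) in enumerate(pts):
            if max(abs(xa), abs(ya)) + self.radius > LATERAL_EXTENT / 2:
                raise ValueError(f"electrode {na!r} outside the surface")
            for nb, (xb, yb) in pts[i + 1:]:
                if np.hypot(xa - xb, ya - yb) < 2 * self.radius:
                    raise ValueError(f"electrodes {na!r} and {nb!r} overlap")

    @property
    def key(self):
        return (tuple(sorted((n, round(x, 9), round(y, 9))
                             for n, (x, y) in self.centres.items())),
                round(self.radius, 9), self.drive_current)


@dataclass(frozen=True)
class MeshResolution:
    """Mesh grading targets for the tissue model.

    ``core_h`` is the lateral element size under and around the electrodes;
    outside the core the grid coarsens geometrically towards the far
    boundary.  ``layer_elems`` counts elements across each thin layer, and
    the stroma/substrate grow geometrically from ``stroma_h0``.
    """

    core_h: float = 0.2e-3
    core_margin: float = 0.6e-3
    growth: float = 1.5
    layer_elems: dict = field(default_factory=lambda: {
        "saliva": 1, "keratinised": 2, "superficial": 2,
        "prickle": 2, "basal": 1})
    stroma_h0: float = 0.08e-3
    stroma_growth: float = 1.7

    @property
    def key(self):
        return (self.core_h, self.core_margin, self.growth,
                tuple(sorted(self.layer_elems.items())),
                self.stroma_h0, self.stroma_growth)


RESOLUTIONS = {
    "coarse": MeshResolution(),
    "standard": MeshResolution(
        core_h=0.075e-3, core_margin=0.8e-3, growth=1.4,
        layer_elems={"saliva": 1, "keratinised": 2, "superficial": 3,
                     "prickle": 3, "basal": 2},
        stroma_h0=0.05e-3, stroma_growth=1.5),
}


def _resolve(resolution) -> MeshResolution:
    if isinstance(resolution, MeshResolution):
        return resolution
    return RESOLUTIONS[resolution]


def _lateral_axis(centres, radius, res: MeshResolution, half_extent):
    lo = min(c for c in centres) - radius - res.core_margin
    hi = max(c for c in centres) + radius + res.core_margin
    core = fem_core.graded_axis([lo, hi], res.core_h)
    left = fem_core.geometric_axis(lo, -half_extent, res.core_h, res.growth)
    right = fem_core.geometric_axis(hi, half_extent, res.core_h, res.growth)
    return np.unique(np.concatenate([left, core, right]))


def build_tissue_mesh(stack: LayerStack, layout: ElectrodeLayout,
                      resolution="coarse", half_extent=None):
    """Graded 40 x 40 x 5 mm grid conforming to every layer interface, with
    electrode footprints realised as surface node sets.

    The footprint of each electrode is the set of surface elements whose
    centre falls inside the circle (a pixelated disc); its nodes form the
    coupled set.  The mesh records the pixelated footprint areas for
    resolution checks.
    """
    res = _resolve(resolution)
    if half_extent is None:
        half_extent = LATERAL_EXTENT / 2

    xs = _lateral_axis([c[0] for c in layout.centres.values()],
                       layout.radius, res, half_extent)
    # a layout collinear on y = 0 is mirror symmetric about that plane:
    # model the y >= 0 half with the natural zero-current condition on the
    # mirror and halve the injected current
    mirror_y = all(abs(c[1]) < 1e-12 for c in layout.centres.values())
    if mirror_y:
        core = fem_core.graded_axis(
            [0.0, layout.radius + res.core_margin], res.core_h)
        outer = fem_core.geometric_axis(
            layout.radius + res.core_margin, half_extent,
            res.core_h, res.growth)
        ys = np.unique(np.concatenate([core, outer]))
    else:
        ys = _lateral_axis([c[1] for c in layout.centres.values()],
                           layout.radius, res, half_extent)

    zp = [np.array([0.0])]
    depth = 0.0
    for layer in stack.layers:
        z1 = depth + layer.thickness
        if layer.name.startswith(("stroma", "substrate")):
            seg = fem_core.geometric_axis(depth, z1, res.stroma_h0,
                                          res.stroma_growth)
        else:
            n = res.layer_elems.get(layer.name, 2)
            seg = np.linspace(depth, z1, n + 1)
        zp.append(seg[1:])
        depth = z1
    zs = np.concatenate(zp)

    mesh = fem_core.HexMesh(xs, ys, zs)
    names = [l.name for l in stack.layers]
    if len(set(names)) != len(names):
        raise ValueError("duplicate layer names in stack")
    bounds = np.concatenate([[0.0], np.cumsum([l.thickness
                                               for l in stack.layers])])

    def labeller(cx, cy, cz):
        return np.clip(np.searchsorted(bounds, cz) - 1, 0, len(names) - 1)

    mesh.label_regions(labeller, names)

    # electrode footprints: surface elements whose centre is in the circle
    exc = 0.5 * (xs[:-1] + xs[1:])
    eyc = 0.5 * (ys[:-1] + ys[1:])
    dx = np.diff(xs)
    dy = np.diff(ys)
    EX, EY = np.meshgrid(exc, eyc, indexing="ij")
    AREA = np.outer(dx, dy)
    footprint_area = {}
    nx = xs.size
    for name, (cx0, cy0) in layout.centres.items():
        inside = (EX - cx0) ** 2 + (EY - cy0) ** 2 <= layout.radius ** 2
        ii, jj = np.nonzero(inside)
        if ii.size == 0:
            raise ValueError(f"electrode {name!r} footprint resolves to no "
                             "surface elements; refine the lateral mesh")
        factor = 2.0 if mirror_y else 1.0
        footprint_area[name] = factor * float(AREA[inside].sum())
        corners = np.concatenate([
            ii + nx * jj, ii + 1 + nx * jj,
            ii + nx * (jj + 1), ii + 1 + nx * (jj + 1)])
        mesh.node_sets[name] = np.unique(corners)  # k = 0 plane: node id = i + nx*j
    mesh.electrode_area = footprint_area
    mesh.symmetry_factor = 2.0 if mirror_y else 1.0
    return mesh


def _materials_of(stack: LayerStack) -> dict:
    return {l.name: l.material for l in stack.layers}


def tetrapolar_impedance(mesh, materials, layout: ElectrodeLayout,
                         f: float) -> complex:
    """Tetrapolar transfer impedance at one frequency.

    The drive set injects the complex drive current, the receive set is
    grounded, and the two measurement sets float as coupled equipotential
    sets with zero net current.  Z = (phi_m1 - phi_m2) / I_drive.
    """
    factor = getattr(mesh, "symmetry_factor", 1.0)
    system = fem_core.assemble(mesh, materials, f)
    bc = fem_core.BoundaryConditions(
        fixed={"receive": 0.0 + 0.0j},
        currents={"drive": layout.drive_current / factor},
        coupled=("m1", "m2"))
    sol = fem_core.solve(system, bc)
    return ((sol.set_potential["m1"] - sol.set_potential["m2"])
            / layout.drive_current)


@dataclass
class TransferImpedanceSpectrum:
    """Frequency-resolved complex tetrapolar transfer impedance."""

    freqs: np.ndarray
    z: np.ndarray  # complex, ohms
    meta: dict = field(default_factory=dict)

    @property
    def abs_z(self):
        return np.abs(self.z)

    @property
    def phase_deg(self):
        return np.degrees(np.angle(self.z))

    def at(self, f: float) -> complex:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if not np.isclose(self.freqs[i], f, rtol=1e-6):
            raise KeyError(f"frequency {f} Hz not in spectrum grid")
        return complex(self.z[i])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "frequency_hz": self.freqs,
            "re_z_ohm": self.z.real,
            "im_z_ohm": self.z.imag,
            "abs_z_ohm": self.abs_z,
            "phase_deg": self.phase_deg,
        })

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


_spectrum_cache: dict = {}


def spectrum(stack: LayerStack, layout: ElectrodeLayout, freqs=None,
             resolution="coarse", half_extent=None,
             meta=None) -> TransferImpedanceSpectrum:
    """Tetrapolar impedance at every frequency of the grid.

    Individual (stack, layout, resolution, frequency) solves are cached, so
    repeated studies sharing templates do not recompute.
    """
    freqs = (default_frequency_grid() if freqs is None
             else np.asarray(freqs, dtype=float))
    res = _resolve(resolution)
    base_key = (stack.key, layout.key, res.key, half_extent)
    z = np.empty(freqs.size, dtype=complex)
    mesh = None
    materials = None
    for i, f in enumerate(freqs):
        key = base_key + (float(f),)
        hit = _spectrum_cache.get(key)
        if hit is None:
            if mesh is None:
                mesh = build_tissue_mesh(stack, layout, res, half_extent)
                materials = _materials_of(stack)
            hit = tetrapolar_impedance(mesh, materials, layout, f)
            _spectrum_cache[key] = hit
        z[i] = hit
    md = {"case": stack.case_id, "label": stack.label,
          "resolution": getattr(resolution, "key", resolution)}
    if meta:
        md.update(meta)
    return TransferImpedanceSpectrum(freqs=freqs, z=z, meta=md)
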