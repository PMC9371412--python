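"""Frequency-dependent electrical property models for tissue compartments.

Every material in the simulator is described by two scalar functions of
frequency: resistivity ``rho(f)`` in ohm-metres and relative permittivity
``eps_r(f)`` (dimensionless).  Under the quasi-static, e^{+j omega t}
convention these combine into the complex admittivity

    sigma*(f) = 1/rho(f) + j * 2*pi*f * eps0 * eps_r(f)   [S/m]

which is the quantity the finite-element assembly consumes.  Cell
compartments and simple fluids are frequency independent; the keratinised
surface layer and the sub-stromal tissues (fat, bone, muscle) are dispersive
and represented by log-log interpolated tables.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

EPS0 = 8.854e-12  # vacuum permittivity, F/m

#: Frequency window of the measurement device (Hz).  Materials must be
#: defined at least on this interval.
F_MIN = 76.0
F_MAX = 625_000.0


class MaterialRangeError(ValueError):
    """Raised when a material is evaluated outside its defined range."""


@dataclass(frozen=True)
class DispersiveMaterial:
    """A (possibly dispersive) isotropic electrical material.

    Parameters
    ----------
    name:
        Label used in meshes, configs and output metadata.
    rho:
        Resistivity in ohm-m as a function of frequency (Hz).
    eps_r:
        Relative permittivity as a function of frequency (Hz).
    f_range:
        Closed interval of frequencies (Hz) on which the material is
        defined; evaluation outside raises :class:`MaterialRangeError`.
    key:
        Content fingerprint used for caching; two materials with the same
        key are treated as identical.
    """

    name: str
    rho: Callable[[np.ndarray], np.ndarray]
    eps_r: Callable[[np.ndarray], np.ndarray]
    f_range: tuple[float, float] = (0.0, np.inf)
    key: str = ""

    def __post_init__(self):
        if not self.key:
            object.__setattr__(self, "key", self.name)

    def _check(self, f):
        f = np.asarray(f, dtype=float)
        if np.any(f <= 0):
            raise MaterialRangeError(f"{self.name}: frequency must be > 0")
        lo, hi = self.f_range
        if np.any(f < lo) or np.any(f > hi):
            raise MaterialRangeError(
                f"{self.name}: frequency outside defined range [{lo}, {hi}] Hz"
            )
        return f

    def resistivity(self, f):
        """Resistivity rho(f) in ohm-m."""
        return self.rho(self._check(f))

    def rel_permittivity(self, f):
        """Relative permittivity eps_r(f)."""
        return self.eps_r(self._check(f))

    def admittivity(self, f):
        """Complex admittivity sigma*(f) = 1/rho + j*omega*eps0*eps_r (S/m)."""
        f = self._check(f)
        return 1.0 / self.rho(f) + 1j * 2.0 * np.pi * f * EPS0 * self.eps_r(f)

    @staticmethod
    def constant(name: str, rho_ohm_m: float, eps_r: float) -> "DispersiveMaterial":
        """Frequency-independent material."""
        if rho_ohm_m <= 0:
            raise ValueError(f"{name}: resistivity must be > 0")
        if eps_r < 0:
            raise ValueError(f"{name}: relative permittivity must be >= 0")
        r, e = float(rho_ohm_m), float(eps_r)
        return DispersiveMaterial(
            name=name,
            rho=lambda f, _r=r: np.broadcast_to(_r, np.shape(f)).copy()
            if np.ndim(f)
            else _r,
            eps_r=lambda f, _e=e: np.broadcast_to(_e, np.shape(f)).copy()
            if np.ndim(f)
            else _e,
            key=f"{name}|const|{r!r}|{e!r}",
        )

    @staticmethod
    def from_table(
        name: str,
        freq_hz,
        rho_ohm_m,
        eps_r,
        interp: str = "loglog",
    ) -> "DispersiveMaterial":
        """Material defined by a sampled dispersion table.

        Values between samples follow log-log linear interpolation by
        default (the standard choice for broad dielectric dispersions);
        ``interp='linear'`` interpolates on linear axes.  Evaluation is
        restricted to the tabulated frequency span.
        """
        f = np.asarray(freq_hz, dtype=float)
        r = np.asarray(rho_ohm_m, dtype=float)
        e = np.asarray(eps_r, dtype=float)
        if f.ndim != 1 or f.size < 2 or not (r.shape == e.shape == f.shape):
            raise ValueError(f"{name}: table needs >=2 matching rows")
        if np.any(np.diff(f) <= 0):
            raise ValueError(f"{name}: table frequencies must be increasing")
        if np.any(r <= 0) or np.any(e < 0):
            raise ValueError(f"{name}: rho must be > 0 and eps_r >= 0")

        if interp == "loglog":
            lf = np.log(f)

            def rho_fn(x, _lf=lf, _lr=np.log(r)):
                return np.exp(np.interp(np.log(x), _lf, _lr))

            if np.any(e == 0):  # log interp undefined at zero
                def eps_fn(x, _lf=lf, _e=e):
                    return np.interp(np.log(x), _lf, _e)
            else:
                def eps_fn(x, _lf=lf, _le=np.log(e)):
                    return np.exp(np.interp(np.log(x), _lf, _le))
        elif interp == "linear":
            def rho_fn(x, _f=f, _r=r):
                return np.interp(x, _f, _r)

            def eps_fn(x, _f=f, _e=e):
                return np.interp(x, _f, _e)
        else:
            raise ValueError(f"unknown interpolation rule {interp!r}")

        return DispersiveMaterial(
            name=name,
            rho=rho_fn,
            eps_r=eps_fn,
            f_range=(float(f[0]), float(f[-1])),
            key=f"{name}|table|{interp}|{f.tobytes().hex()}|"
            f"{r.tobytes().hex()}|{e.tobytes().hex()}",
        )


@dataclass(frozen=True)
class AnisotropicMaterial:
    """Transversely isotropic material: distinct through-thickness (Z) and
    in-plane (XY) components, as produced by cell-layer homogenization."""

    z: DispersiveMaterial
    xy: DispersiveMaterial

    @property
    def key(self) -> str:
        return f"aniso[{self.z.key};{self.xy.key}]"

    @staticmethod
    def isotropic(m: DispersiveMaterial) -> "AnisotropicMaterial":
        return AnisotropicMaterial(z=m, xy=m)


def admittivity_at(material: DispersiveMaterial, f) -> complex:
    """Complex admittivity of ``material`` at frequency ``f`` (Hz)."""
    out = material.admittivity(f)
    return complex(out) if np.ndim(out) == 0 else out


# --------------------------------------------------------------------------
# Shipped materials
# --------------------------------------------------------------------------

def saliva() -> DispersiveMaterial:
    """Thin conductive fluid film between the electrodes and the tissue.

    Generic isotropic biological-fluid values: rho = 1 ohm-m, eps_r = 72.
    """
    return DispersiveMaterial.constant("saliva", 1.0, 72.0)


def keratin_dry(rho_ohm_m: float = 1.0e5) -> DispersiveMaterial:
    """Frequency-independent dry-keratin surface layer.

    Literature dry keratin: rho = 0.1 MOhm-m, eps_r = 1.17.  The resistivity
    is configurable down to 1 kOhm-m for hydration sensitivity sweeps (the
    lower bound keeps the keratinised layer more resistive than the
    superficial cell layer beneath it).
    """
    if not (1.0e3 <= rho_ohm_m <= 1.0e6):
        raise ValueError("dry keratin resistivity expected in [1e3, 1e6] ohm-m")
    return DispersiveMaterial.constant(f"keratin_dry_{rho_ohm_m:g}", rho_ohm_m, 1.17)


#: Stratum-corneum dispersion anchors: (f Hz, rho ohm-m, eps_r).
SC_ANCHORS = ((76.0, 4.9e4, 30.0), (625_000.0, 65.0, 5.7))


def keratin_stratum_corneum(hydration_factor: float = 1.0) -> DispersiveMaterial:
    """Dispersive keratinised-layer model based on human stratum corneum.

    Anchored at rho = 0.049 MOhm-m, eps_r = 30 (76 Hz) and rho = 65 ohm-m,
    eps_r = 5.7 (625 kHz); log-log interpolated between the anchors.  Oral
    keratin is hydrated relative to the skin surface, which lowers its
    resistivity: ``hydration_factor`` divides rho uniformly at every
    frequency, by up to a factor of forty (at 40 the layer is still more
    resistive than the underlying epithelium).  Permittivity is unaffected
    by hydration in this model.  Isotropic.
    """
    h = float(hydration_factor)
    if not (1.0 <= h <= 40.0):
        raise ValueError(f"hydration_factor must lie in [1, 40], got {h}")
    f = np.array([a[0] for a in SC_ANCHORS])
    r = np.array([a[1] for a in SC_ANCHORS]) / h
    e = np.array([a[2] for a in SC_ANCHORS])
    return DispersiveMaterial.from_table(f"keratin_sc_h{h:g}", f, r, e)


_SUBSTRATE_KINDS = ("fat", "bone", "muscle")


def substrate_material(kind: str) -> DispersiveMaterial:
    """Sub-stromal tissue: ``fat`` (buccal), ``bone`` (hard palate) or
    ``muscle`` (tongue).

    Dispersion tables bundled as CSV (frequency_hz, resistivity_ohm_m,
    rel_permittivity), spanning 76 Hz - 625 kHz, log-log interpolated.
    The tables are replaceable configuration data, not measurements made by
    this package.
    """
    if kind not in _SUBSTRATE_KINDS:
        raise ValueError(f"unknown substrate kind {kind!r}; expected one of "
                         f"{_SUBSTRATE_KINDS}")
    ref = importlib.resources.files("oraleis.data.materials") / f"{kind}.csv"
    rows = np.loadtxt(str(ref), delimiter=",", skiprows=1)
    return DispersiveMaterial.from_table(kind, rows[:, 0], rows[:, 1], rows[:, 2])


def stroma() -> DispersiveMaterial:
    """Connective tissue (lamina propria) beneath the epithelium.

    Default is a mildly dispersive isotropic placeholder of order a few
    ohm-m, electrically close to skeletal muscle — the lamina propria is a
    well-perfused, cell-sparse connective tissue, and published oral-mucosa
    models treat the sub-epithelial layers as comparably conductive.
    Override via configuration when better site-specific data are
    available.
    """
    f = np.array([76.0, 1.0e3, 1.0e4, 1.0e5, 6.25e5])
    r = np.array([3.6, 3.2, 2.9, 2.7, 2.1])
    e = np.array([8.0e4, 3.0e4, 1.2e4, 4.0e3, 2.0e3])
    return DispersiveMaterial.from_table("stroma", f, r, e)


@dataclass(frozen=True)
class CompartmentPropertySet:
    """Electrical properties of the five cell-scale compartments.

    The membrane is the resistive, capacitive barrier that produces the
    beta dispersion; intra- and extracellular fluids are good conductors.
    Default values are provisional, averaged from the cervical-epithelium
    modelling literature, and fully overridable through configuration.
    """

    ecs: DispersiveMaterial = field(
        default_factory=lambda: DispersiveMaterial.constant("ecs", 0.7, 72.0))
    membrane: DispersiveMaterial = field(
        default_factory=lambda: DispersiveMaterial.constant("membrane", 1.0e7, 9.0))
    cytoplasm: DispersiveMaterial = field(
        default_factory=lambda: DispersiveMaterial.constant("cytoplasm", 2.0, 72.0))
    nucleoplasm: DispersiveMaterial = field(
        default_factory=lambda: DispersiveMaterial.constant("nucleoplasm", 1.1, 72.0))
    nuclear_membrane: DispersiveMaterial = field(
        default_factory=lambda: DispersiveMaterial.constant(
            "nuclear_membrane", 1.0e5, 20.0))

    def __post_init__(self):
        f = F_MIN
        if self.membrane.resistivity(f) <= self.cytoplasm.resistivity(f):
            raise ValueError(
                "membrane resistivity must exceed cytoplasm resistivity "
                "(the membrane is the resistive barrier)")

    @property
    def key(self) -> str:
        return "|".join(m.key for m in (self.ecs, self.membrane, self.cytoplasm,
                                        self.nucleoplasm, self.nuclear_membrane))
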