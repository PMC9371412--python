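"""Scripted simulation studies over the tissue templates.

Each study sweeps one axis of the tissue model — keratinised-layer
resistivity, keratin hydration, pathology template, keratinised-layer
thickness or sub-stromal substrate — and returns the resulting tetrapolar
transfer-impedance spectra in a tabular :class:`StudyResult`.  The studies
are deterministic: every spectrum is fully reproducible from the
configuration that produced it.

"Low frequency" below means the lowest grid point (76 Hz) and "high
frequency" the highest (625 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cell_model, materials, tissue_model
from .cli_io import RunConfig, default_config
from .tissue_model import TransferImpedanceSpectrum

__all__ = [
    "StudyResult",
    "epithelial_properties",
    "template_spectrum",
    "keratin_resistivity_sweep",
    "hydration_fit_study",
    "pathology_templates",
    "keratin_thickness_sweep",
    "substrate_study",
]


@dataclass
class StudyResult:
    """Spectra of one study, indexed by the swept parameter."""

    study: str
    parameter: str
    values: list
    spectra: dict  # parameter value -> TransferImpedanceSpectrum
    bounds: dict = field(default_factory=dict)
    # parameter value -> (lower TransferImpedanceSpectrum, upper ...)

    def abs_z(self, value) -> np.ndarray:
        return self.spectra[value].abs_z

    def to_frame(self):
        import pandas as pd

        frames = []
        for v in self.values:
            df = self.spectra[v].to_frame()
            df.insert(0, self.parameter, [v] * len(df))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def low_frequency_magnitudes(self) -> dict:
        """|Z| at the lowest grid frequency, per parameter value."""
        return {v: float(self.spectra[v].abs_z[0]) for v in self.values}


def epithelial_properties(config: RunConfig, grade: str,
                          freqs=None) -> dict:
    """Homogenized anisotropic properties for the three strata of one
    dysplasia grade (cached through the cell-model layer)."""
    freqs = config.freqs if freqs is None else np.asarray(freqs, dtype=float)
    return {
        stratum: cell_model.homogenize(config.morphologies[grade][stratum],
                                       config.compartments, freqs)
        for stratum in tissue_model.EPITHELIAL_STRATA
    }


def _stack_for(config, case, keratin=None, substrate=None,
               thickness_mode="mean", keratin_thickness_um=None, freqs=None):
    props = epithelial_properties(config, case.cell_grade, freqs)
    if keratin is None and case.keratinised:
        keratin = config.keratin()
    return tissue_model.build_layer_stack(
        case, props, keratin=keratin, substrate=substrate,
        thickness_mode=thickness_mode, stroma_material=config.stroma,
        keratin_thickness_um=keratin_thickness_um)


def template_spectrum(config: RunConfig, case_id: int, freqs=None,
                      thickness_mode="mean", **kwargs
                      ) -> TransferImpedanceSpectrum:
    """Spectrum of one tissue case with the fitted keratin model."""
    case = config.cases[case_id]
    stack = _stack_for(config, case, thickness_mode=thickness_mode,
                       freqs=freqs, **kwargs)
    return tissue_model.spectrum(stack, config.layout,
                                 config.freqs if freqs is None else freqs,
                                 config.resolution)


def keratin_resistivity_sweep(resistivities=None, case_id: int = 2,
                              config: RunConfig | None = None,
                              freqs=None) -> StudyResult:
    """Frequency-independent keratin with swept resistivity.

    The keratinised layer takes dry-keratin permittivity (1.17) and a
    constant resistivity swept from 1 kOhm-m up to the dry-keratin bound of
    0.1 MOhm-m; the lower bound keeps the layer more resistive than the
    superficial cells beneath.  Highly resistive keratin suppresses the
    beta dispersion entirely; below ~5 kOhm-m the dispersion above 10 kHz
    reappears.
    """
    config = config or default_config()
    if case_id not in (2, 4):
        raise ValueError("the keratin sensitivity study uses the normal (2) "
                         "or OPMD (4) keratinised case")
    if resistivities is None:
        resistivities = [1e3, 5e3, 1e4, 1e5]
    case = config.cases[case_id]
    spectra = {}
    for rho in resistivities:
        stack = _stack_for(config, case, keratin=materials.keratin_dry(rho),
                           freqs=freqs)
        spectra[rho] = tissue_model.spectrum(
            stack, config.layout, config.freqs if freqs is None else freqs,
            config.resolution, meta={"keratin_rho_ohm_m": rho})
    return StudyResult("keratin_resistivity_sweep", "keratin_rho_ohm_m",
                       list(resistivities), spectra)


def hydration_fit_study(hydration_factors=(1.0, 10.0, 40.0),
                        case_ids=(2, 4), config: RunConfig | None = None,
                        freqs=None) -> dict:
    """Stratum-corneum keratin with swept hydration adjustment.

    Returns one StudyResult per case (normal and OPMD); increasing the
    hydration factor lowers the keratin resistivity and the low-frequency
    impedance, recovering the expected separation with pathology at the
    maximum factor of forty.
    """
    config = config or default_config()
    out = {}
    for cid in case_ids:
        case = config.cases[cid]
        spectra = {}
        for h in hydration_factors:
            stack = _stack_for(config, case,
                               keratin=materials.keratin_stratum_corneum(h),
                               freqs=freqs)
            spectra[h] = tissue_model.spectrum(
                stack, config.layout,
                config.freqs if freqs is None else freqs,
                config.resolution, meta={"hydration_factor": h})
        out[cid] = StudyResult(f"hydration_fit_case{cid}", "hydration_factor",
                               list(hydration_factors), spectra)
    return out


def pathology_templates(case_ids=None, with_bounds=True,
                        config: RunConfig | None = None,
                        freqs=None) -> StudyResult:
    """Template spectra for every tissue case, with mean +/- SD layer
    thickness bounds.

    Keratinised cases use the fitted keratin model (hydration factor from
    the configuration).  The lower/upper bound spectra use every layer at
    mean -/+ one standard deviation.
    """
    config = config or default_config()
    case_ids = list(config.cases) if case_ids is None else list(case_ids)
    spectra = {}
    bounds = {}
    fgrid = config.freqs if freqs is None else freqs
    for cid in case_ids:
        case = config.cases[cid]
        spectra[cid] = tissue_model.spectrum(
            _stack_for(config, case, freqs=freqs), config.layout, fgrid,
            config.resolution, meta={"case": cid, "mode": "mean"})
        if with_bounds:
            lo = tissue_model.spectrum(
                _stack_for(config, case, thickness_mode="mean-sd", freqs=freqs),
                config.layout, fgrid, config.resolution,
                meta={"case": cid, "mode": "mean-sd"})
            hi = tissue_model.spectrum(
                _stack_for(config, case, thickness_mode="mean+sd", freqs=freqs),
                config.layout, fgrid, config.resolution,
                meta={"case": cid, "mode": "mean+sd"})
            bounds[cid] = (lo, hi)
    return StudyResult("pathology_templates", "case_id", case_ids, spectra,
                       bounds)


def keratin_thickness_sweep(thicknesses_um=(15.0, 30.0, 60.0, 90.0),
                            underlying: str = "opmd",
                            config: RunConfig | None = None,
                            freqs=None) -> StudyResult:
    """Variable keratinised-layer thickness over fixed underlying tissue.

    ``underlying='healthy'`` uses the normal hard-palate structure (case 2)
    and ``'opmd'`` the severely dysplastic structure (case 3); the
    keratinised layer thickness sweeps 15-90 um, the histological range.
    Thickening the keratin over dysplastic tissue raises the low-frequency
    impedance towards healthy values.
    """
    config = config or default_config()
    case_id = {"healthy": 2, "opmd": 3}.get(underlying)
    if case_id is None:
        raise ValueError("underlying must be 'healthy' (case 2) or "
                         "'opmd' (case 3)")
    if min(thicknesses_um) < 15.0 or max(thicknesses_um) > 90.0:
        raise ValueError("keratin thickness must lie in the measured "
                         "15-90 um range")
    case = config.cases[case_id]
    spectra = {}
    for t in thicknesses_um:
        stack = _stack_for(config, case, keratin_thickness_um=t, freqs=freqs)
        spectra[t] = tissue_model.spectrum(
            stack, config.layout, config.freqs if freqs is None else freqs,
            config.resolution, meta={"keratin_thickness_um": t,
                                     "underlying": underlying})
    return StudyResult(f"keratin_thickness_{underlying}",
                       "keratin_thickness_um", list(thicknesses_um), spectra)


#: site -> substrate kind beneath the stroma
SUBSTRATE_FOR_CASE = {1: "fat", 2: "bone", 3: "muscle"}


def substrate_study(case_ids=(1, 2, 3), config: RunConfig | None = None,
                    freqs=None) -> dict:
    """Explicit sub-stromal layers: fat (buccal), bone (hard palate),
    muscle (tongue).

    For each case the stroma is limited to 1 mm with the site-appropriate
    substrate below, and the spectrum is compared with the all-stroma
    model.  Returns per case a dict with both spectra and the relative
    |Z| difference per frequency.
    """
    config = config or default_config()
    out = {}
    fgrid = config.freqs if freqs is None else freqs
    for cid in case_ids:
        kind = SUBSTRATE_FOR_CASE.get(cid)
        if kind is None:
            raise ValueError(f"no substrate assignment for case {cid}")
        case = config.cases[cid]
        base = tissue_model.spectrum(
            _stack_for(config, case, freqs=freqs), config.layout, fgrid,
            config.resolution, meta={"case": cid, "substrate": None})
        sub = tissue_model.spectrum(
            _stack_for(config, case, freqs=freqs,
                       substrate=materials.substrate_material(kind)),
            config.layout, fgrid, config.resolution,
            meta={"case": cid, "substrate": kind})
        out[cid] = {
            "substrate": kind,
            "without": base,
            "with": sub,
            "rel_diff": np.abs(sub.abs_z - base.abs_z) / base.abs_z,
        }
    return out
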