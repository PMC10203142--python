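"""Built-in parameter registries for the cardiac model.

Three immutable tables, keyed by tissue/region name:

- ``WINDKESSEL``: three-element Windkessel forcing constants at the six
  inlet/outlet subdomains (aorta, epicardial/coronary, pulmonary veins,
  pulmonary artery, superior and inferior vena cava).
- ``FUNG_MATERIALS``: Fung strain-energy constants per cardiac component
  (c in kPa; dimensionless exponents along fiber / sheet / sheet-normal;
  calibrated against ex-vivo biaxial stress–strain data).
- ``CONDUCTIVITIES``: intra-/extracellular principal conductivities per
  conductive medium (mS/mm), with the PDE form and membrane model used on
  it.  Fast bundles and the Purkinje network are listed directly with
  their reduced monodomain conductivities.

Registry version: 1 (bumped only if the transcription changes).
"""

from __future__ import annotations

from types import MappingProxyType

from .ep_solver import ConductivitySet
from .mechanics import FungMaterial

__all__ = ["WINDKESSEL", "FUNG_MATERIALS", "CONDUCTIVITIES",
           "REGISTRY_VERSION", "lookup_windkessel", "lookup_material",
           "lookup_conductivity"]

REGISTRY_VERSION = 1

# alpha: kg m^-3 s^-1, beta: kg m^-3 s^-2, gamma: kg m^-2 s^-2 (SI)
WINDKESSEL = MappingProxyType({
    "omega_ao":  dict(alpha=3.13e6, beta=2.96e6, gamma=18.43e6),
    "omega_epi": dict(alpha=16.62e6, beta=10.36e6, gamma=25.68e6),
    "omega_pv":  dict(alpha=0.062e6, beta=0.059e6, gamma=0.00),
    "omega_pa":  dict(alpha=20.78e6, beta=1.18e6, gamma=4.17e6),
    "omega_vcs": dict(alpha=0.39e6, beta=0.11e6, gamma=0.00),
    "omega_vci": dict(alpha=0.39e6, beta=0.11e6, gamma=0.00),
})

FUNG_MATERIALS = MappingProxyType({
    "LV":      FungMaterial(c=11.59, a_par=9.97, a_sheet=3.17, a_norm=3.17),
    "LA":      FungMaterial(c=8.31, a_par=3.77, a_sheet=3.52, a_norm=3.52),
    "RV":      FungMaterial(c=9.20, a_par=8.22, a_sheet=4.09, a_norm=4.09),
    "RA":      FungMaterial(c=2.95, a_par=6.50, a_sheet=6.52, a_norm=6.52),
    "vessels": FungMaterial(c=16.77, a_par=16.39, a_sheet=15.76,
                            a_norm=15.76),
    "mitral_tricuspid_valve": FungMaterial(c=0.149, a_par=8.58,
                                           a_sheet=71.24, a_norm=71.24),
    "aortic_pulmonary_valve": FungMaterial(c=0.0093, a_par=120.88,
                                           a_sheet=5.87, a_norm=5.87),
})

CONDUCTIVITIES = MappingProxyType({
    "ventricle": dict(
        pde="bidomain", cell_model="tentusscher_panfilov",
        conductivity=ConductivitySet(m_int=(0.17, 0.019, 0.019),
                                     m_ext=(0.62, 0.24, 0.24))),
    "atrium": dict(
        pde="bidomain", cell_model="courtemanche",
        conductivity=ConductivitySet(m_int=(0.18, 0.02, 0.02),
                                     m_ext=(0.66, 0.25, 0.25)),
        calibration_cv=0.5),   # m/s, longitudinal
    "purkinje": dict(
        pde="monodomain", cell_model="stewart",
        conductivity=ConductivitySet(m_int=(3.95, 3.95, 3.95),
                                     monodomain_only=True),
        calibration_cv=4.0),
    "internodal_bundle": dict(
        pde="monodomain", cell_model="courtemanche",
        conductivity=ConductivitySet(m_int=(1.29, 1.29, 1.29),
                                     monodomain_only=True),
        calibration_cv=1.54),
})

_WK_ALIASES = {"ao": "omega_ao", "epi": "omega_epi", "pv": "omega_pv",
               "pa": "omega_pa", "vcs": "omega_vcs", "vci": "omega_vci"}


def lookup_windkessel(name: str) -> dict:
    key = name.lower().replace("Ω", "omega").replace("ω", "omega")
    key = key.replace("omega_", "omega_") if key.startswith("omega_") \
        else _WK_ALIASES.get(key, key)
    try:
        return dict(WINDKESSEL[key])
    except KeyError:
        raise KeyError(f"unknown Windkessel region {name!r}; "
                       f"known: {sorted(WINDKESSEL)}") from None


def lookup_material(name: str) -> FungMaterial:
    try:
        return FUNG_MATERIALS[name]
    except KeyError:
        raise KeyError(f"unknown tissue {name!r}; "
                       f"known: {sorted(FUNG_MATERIALS)}") from None


def lookup_conductivity(name: str) -> dict:
    try:
        entry = CONDUCTIVITIES[name]
    except KeyError:
        raise KeyError(f"unknown conductive medium {name!r}; "
                       f"known: {sorted(CONDUCTIVITIES)}") from None
    return dict(entry)
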