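"""Culture-media and field reference quantities.

Small, explicit computations of the nutrient and density contrasts that
frame the experimental design: how strongly f/2 medium enriches nitrate
over basal seawater, the stoichiometry of the mesocosm nutrient additions,
and how far nutrient-amended blooms overshoot the densities at which viral
infection is known to occur in nature.
"""

from __future__ import annotations

__all__ = [
    "F2_NITRATE_UM",
    "BASAL_SEAWATER_NITRATE_UM",
    "MESOCOSM_NO3_UM_PER_DAY",
    "MESOCOSM_PO4_UM_PER_DAY",
    "MESOCOSM_PEAK_DENSITY_PER_ML",
    "MAX_ENVIRONMENTAL_DENSITY_PER_ML",
    "f2_nitrate_enrichment",
    "mesocosm_n_to_p",
    "bloom_density_excess",
]

#: NaNO3 concentration added by f/2 enrichment (uM)
F2_NITRATE_UM = 882.0
#: typical basal seawater nitrate (uM)
BASAL_SEAWATER_NITRATE_UM = 10.0

#: daily mesocosm nutrient additions (uM)
MESOCOSM_NO3_UM_PER_DAY = 1.5
MESOCOSM_PO4_UM_PER_DAY = 0.1

#: peak host density reached in nutrient-amended mesocosm blooms (cells/mL)
MESOCOSM_PEAK_DENSITY_PER_ML = 1.0e5
#: maximal environmental host density at which infection/lysis is observed
MAX_ENVIRONMENTAL_DENSITY_PER_ML = 1.0e3


def f2_nitrate_enrichment(f2_um: float = F2_NITRATE_UM,
                          basal_um: float = BASAL_SEAWATER_NITRATE_UM) -> float:
    """Fold-enrichment of nitrate in f/2 medium over basal seawater (~88x)."""
    if basal_um <= 0:
        raise ValueError("basal concentration must be > 0")
    return f2_um / basal_um


def mesocosm_n_to_p(no3_um: float = MESOCOSM_NO3_UM_PER_DAY,
                    po4_um: float = MESOCOSM_PO4_UM_PER_DAY) -> float:
    """N:P ratio of the daily mesocosm nutrient additions (Redfield-style, 15)."""
    if po4_um <= 0:
        raise ValueError("phosphate addition must be > 0")
    return no3_um / po4_um


def bloom_density_excess(peak_per_ml: float = MESOCOSM_PEAK_DENSITY_PER_ML,
                         environmental_per_ml: float = MAX_ENVIRONMENTAL_DENSITY_PER_ML
                         ) -> float:
    """Fold-excess of peak amended-bloom density over the maximal natural
    density at which viral lysis is observed (~100x): the gap a purely
    density-dependent virulent virus should not allow."""
    if environmental_per_ml <= 0:
        raise ValueError("environmental density must be > 0")
    return peak_per_ml / environmental_per_ml
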