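"""Beam models of the two instruments behind the published transmission data.

The rotational C-arm carries a 0.3 mm Cu + 2.6 mm Al prefilter (manufacturer
data) on top of a typical angio-tube window; the CT on which the patient
table was measured applied 2.5 mm added Al on top of a CT tube's much heavier
inherent + shaped-filter center-beam filtration.  Neither inherent value is
published: both are estimated instrument parameters (see docs/methods.md).
"""

from __future__ import annotations

from .spectra import EnergySpectrum, FilterStack, generate_spectrum

__all__ = [
    "CARM_WINDOW_MM_AL",
    "CT_INHERENT_MM_AL",
    "CARM_PREFILTER",
    "carm_spectrum",
    "ct_spectrum",
    "ANODE_ANGLE_DEG",
]

#: Anode takeoff angle used for all generated spectra (deg); config default.
ANODE_ANGLE_DEG = 12.0

#: C-arm tube window, mm Al equivalent.
CARM_WINDOW_MM_AL = 1.5

#: CT center-beam inherent + shaped-filter filtration, mm Al equivalent.
CT_INHERENT_MM_AL = 6.0


def CARM_PREFILTER() -> FilterStack:
    """Manufacturer prefilter of the rotational unit: 0.3 mm Cu + 2.6 mm Al."""
    return FilterStack.of(("copper", 0.3), ("aluminum", 2.6))


def carm_spectrum(kvp: float, prefilter: FilterStack | None = None) -> EnergySpectrum:
    """C-arm beam at ``kvp``: tube window plus the Cu/Al prefilter."""
    stack = FilterStack.of(("aluminum", CARM_WINDOW_MM_AL))
    stack = stack + (CARM_PREFILTER() if prefilter is None else prefilter)
    return generate_spectrum(kvp, ANODE_ANGLE_DEG, stack)


def ct_spectrum(kvp: float, added_mm_al: float = 2.5) -> EnergySpectrum:
    """CT beam at ``kvp`` with ``added_mm_al`` of added flat Al filtration."""
    stack = FilterStack.of(("aluminum", CT_INHERENT_MM_AL + added_mm_al))
    return generate_spectrum(kvp, ANODE_ANGLE_DEG, stack)
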