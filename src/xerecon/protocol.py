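"""Acquisition-protocol arithmetic: spoke budgets, breath-holds, gas dosing.

Small exact computations tying the sequence parameters to their operational
consequences: how many radial spokes survive a given acceleration factor,
how long the breath-hold lasts, and how enriched and natural-abundance (NA)
xenon doses compare in 129Xe signal content.
"""

from __future__ import annotations

from .trajectory import round_half_up

__all__ = [
    "spokes_retained",
    "breath_hold_s",
    "isotope_concentration_ratio",
    "dose_equivalent_volume_ml",
    "ENRICHED_XE129_FRACTION",
    "NATURAL_XE129_FRACTION",
]

#: Isotopic 129Xe fraction of enriched gas (86%) and natural abundance (26%).
ENRICHED_XE129_FRACTION = 0.86
NATURAL_XE129_FRACTION = 0.26

FULL_SPOKES = 934


def spokes_retained(n_spokes: int = FULL_SPOKES, af: float = 1.0) -> int:
    """Spokes kept at acceleration factor ``af`` (round-half-up of S/af)."""
    if af < 1:
        raise ValueError("acceleration factor must be >= 1")
    return min(n_spokes, round_half_up(n_spokes / af))


def breath_hold_s(n_spokes: int = FULL_SPOKES, tr_ms: float = 15.0) -> float:
    """Breath-hold duration in seconds: one TR per imaging excitation."""
    return n_spokes * tr_ms * 1e-3


def isotope_concentration_ratio(
    enriched_fraction: float = ENRICHED_XE129_FRACTION,
    natural_fraction: float = NATURAL_XE129_FRACTION,
) -> float:
    """129Xe concentration ratio of enriched to natural-abundance xenon."""
    return enriched_fraction / natural_fraction


def dose_equivalent_volume_ml(
    volume_l: float,
    xe129_fraction: float,
    polarization: float,
) -> float:
    """Dose-equivalent volume: inhaled volume x isotopic fraction x polarization.

    Expresses a hyperpolarized xenon dose as the volume of fully polarized,
    isotopically pure 129Xe carrying the same signal (mL).
    """
    if not 0 < xe129_fraction <= 1 or not 0 < polarization <= 1:
        raise ValueError("fractions must lie in (0, 1]")
    return volume_l * 1e3 * xe129_fraction * polarization
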