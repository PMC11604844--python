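"""Gas-exchange ratio mapping from reconstructed spectral component images.

The clinical readouts of dissolved-phase 129Xe imaging are the voxelwise
signal ratios RBC:M, RBC:Gas and M:Gas inside the lung.  Before forming the
gas-referenced ratios, the gas image must be rescaled to account for the
deliberately asymmetric excitation (large flip on the dissolved resonances,
tiny flip on the gas to preserve the reservoir) and, where applicable, the
differential T2* decay of gas and dissolved signal during the readout
window.  The lung mask is obtained automatically by thresholding the
membrane image against its background-noise statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .decomposition import ResonanceModel
from .phantom import SequenceParams

__all__ = [
    "ComponentImages",
    "LungMask",
    "RatioMaps",
    "correct_gas_signal",
    "gas_correction_factor",
    "make_mask",
    "compute_ratio_maps",
]


@dataclass
class ComponentImages:
    """Complex gas/membrane/RBC volumes on a shared grid."""

    gas: np.ndarray
    membrane: np.ndarray
    rbc: np.ndarray
    recon_label: str = "gridding"  # {"gridding", "cs"}
    voxel_mm: tuple[float, float, float] = (12.5, 12.5, 12.5)

    def __post_init__(self) -> None:
        if not (self.gas.shape == self.membrane.shape == self.rbc.shape):
            raise ValueError("component images must share one grid")

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name if name != "m" else "membrane")


@dataclass
class LungMask:
    mask: np.ndarray
    threshold_value: float
    source: str = "membrane_gridding"

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class RatioMaps:
    """RBC:M, RBC:Gas, M:Gas maps on the mask; zero outside/excluded voxels."""

    rbc_m: np.ndarray
    rbc_gas: np.ndarray
    m_gas: np.ndarray
    mask: np.ndarray = field(repr=False)
    exclusion_count: dict[str, int] = field(default_factory=dict)

    def mean(self, name: str) -> float:
        m = getattr(self, name)
        valid = self.mask & np.isfinite(m) & (m > 0)
        return float(m[valid].mean())

    def summary(self) -> dict:
        out = {}
        for name in ("rbc_m", "rbc_gas", "m_gas"):
            m = getattr(self, name)
            vals = m[self.mask & (m > 0)]
            out[name] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
                "cv": float(vals.std(ddof=1) / vals.mean()),
                "n": int(vals.size),
                "excluded": int(self.exclusion_count.get(name, 0)),
            }
        return out


def _mean_readout_attenuation(t2star_ms: float, window_ms: float) -> float:
    """Mean of exp(-t/T2*) over the readout window [0, tau].

    Closed form ``T2*/tau * (1 - exp(-tau/T2*))``; tends to 1 as T2* grows.
    """
    if window_ms <= 0:
        return 1.0
    r = t2star_ms / window_ms
    return float(r * (1.0 - np.exp(-1.0 / r)))


def gas_correction_factor(
    seq: SequenceParams,
    model: ResonanceModel | None = None,
    t2star_mode: str = "none",
    readout_window_ms: float | None = None,
    dissolved_compartment: str = "membrane",
) -> float:
    """Scale factor applied to the gas image before ratio formation.

    Always includes the flip-angle term ``sin(flip_dissolved)/sin(flip_gas)``
    (~97.6 for 22deg/0.22deg).  ``t2star_mode``:

    - ``"none"``: flip-angle correction only (appropriate when the
      chemical-shift inversion already removed per-echo decay);
    - ``"window"``: additionally multiply by the ratio of mean T2*
      attenuation over the readout window, dissolved vs gas;
    - ``"point"``: single-point attenuation ratio at the window midpoint.
    """
    if seq.flip_gas_deg <= 0 or seq.flip_dissolved_deg <= 0:
        raise ValueError("flip angles must be positive")
    factor = np.sin(np.radians(seq.flip_dissolved_deg)) / np.sin(
        np.radians(seq.flip_gas_deg)
    )
    if t2star_mode == "none":
        return float(factor)
    if model is None:
        raise ValueError("a resonance model is required for T2* correction")
    tau = (
        readout_window_ms
        if readout_window_ms is not None
        else seq.readout_window_ms
    )
    t2_d = model.t2star_ms[dissolved_compartment]
    t2_g = model.t2star_ms["gas"]
    if t2star_mode == "window":
        att_d = _mean_readout_attenuation(t2_d, tau)
        att_g = _mean_readout_attenuation(t2_g, tau)
    elif t2star_mode == "point":
        att_d = float(np.exp(-0.5 * tau / t2_d))
        att_g = float(np.exp(-0.5 * tau / t2_g))
    else:
        raise ValueError(f"unknown t2star_mode {t2star_mode!r}")
    return float(factor * att_d / att_g)


def correct_gas_signal(
    gas: np.ndarray,
    seq: SequenceParams,
    model: ResonanceModel | None = None,
    t2star_mode: str = "none",
    readout_window_ms: float | None = None,
) -> np.ndarray:
    """Rescale the gas image so dissolved/gas ratios are excitation-unbiased."""
    return gas * gas_correction_factor(
        seq, model, t2star_mode=t2star_mode, readout_window_ms=readout_window_ms
    )


def make_mask(
    membrane: np.ndarray,
    k_sigma: float = 3.0,
    n_edge_slices: int = 3,
    slice_axis: int = 2,
    min_component_frac: float = 0.25,
    source: str = "membrane_gridding",
) -> LungMask:
    """Noise-threshold lung mask from a (gridding) membrane magnitude image.

    Background statistics (mean, SD of the magnitude) come from
    ``n_edge_slices`` slices at each end of ``slice_axis`` — six outer slices
    in total by default — and the threshold is ``mu_bg + k_sigma * sd_bg``.
    Connected components smaller than ``min_component_frac`` of the largest
    are discarded (keeps both lungs, drops speckle).
    """
    mag = np.abs(np.asarray(membrane))
    if mag.size == 0:
        raise ValueError("empty membrane image")
    edges = [np.take(mag, range(n_edge_slices), axis=slice_axis),
             np.take(mag, range(-n_edge_slices, 0), axis=slice_axis)]
    bg = np.concatenate([e.ravel() for e in edges])
    threshold = float(bg.mean() + k_sigma * bg.std())
    raw = mag > threshold
    if not raw.any():
        raise ValueError(
            f"noise threshold {threshold:.3g} removed every voxel — "
            "no signal above background"
        )
    labels, n_lab = ndimage.label(raw)
    if n_lab > 0:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_lab + 1))
        keep = np.flatnonzero(sizes >= min_component_frac * sizes.max()) + 1
        raw = np.isin(labels, keep)
    return LungMask(mask=raw, threshold_value=threshold, source=source)


def compute_ratio_maps(
    components: ComponentImages,
    mask: LungMask,
    seq: SequenceParams,
    model: ResonanceModel | None = None,
    t2star_mode: str = "none",
    denominator_eps: float = 0.01,
) -> RatioMaps:
    """Voxelwise magnitude ratio maps on the lung mask.

    Voxels whose denominator magnitude falls below ``denominator_eps`` times
    the in-mask mean denominator are excluded (set to zero) and counted —
    these are the low-signal periphery voxels that otherwise produce extreme
    ratio outliers.
    """
    if components.gas.shape != mask.mask.shape:
        raise ValueError("mask grid does not match the component images")
    m = mask.mask
    gas_corr = np.abs(
        correct_gas_signal(components.gas, seq, model, t2star_mode=t2star_mode)
    )
    mem = np.abs(components.membrane)
    rbc = np.abs(components.rbc)

    maps, excl = {}, {}
    for name, num, den in (
        ("rbc_m", rbc, mem),
        ("rbc_gas", rbc, gas_corr),
        ("m_gas", mem, gas_corr),
    ):
        den_mean = den[m].mean()
        valid = m & (den > denominator_eps * den_mean)
        out = np.zeros_like(den)
        out[valid] = num[valid] / den[valid]
        maps[name] = out
        excl[name] = int(m.sum() - valid.sum())
    return RatioMaps(
        rbc_m=maps["rbc_m"],
        rbc_gas=maps["rbc_gas"],
        m_gas=maps["m_gas"],
        mask=m,
        exclusion_count=excl,
    )
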