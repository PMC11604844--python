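"""Digital lung phantoms and the multi-echo radial k-space forward model.

The phantom is a pair of ellipsoidal "lungs" on a cubic grid carrying three
non-negative density maps — gaseous xenon in the airspaces, xenon dissolved
in the alveolar membrane, and xenon in capillary red blood cells — whose
ratios are set to configurable gas-exchange targets (healthy defaults
RBC:M = 0.41, M:Gas = 0.0098).  Spherical "defects" attenuate a chosen
compartment locally, emulating regional gas-transfer impairment.

The simulator evaluates, for echo ``e`` and k-sample ``j`` on spoke ``s``,

    y_e(k_j) = d(t_s) * sum_c sin(alpha_c) * DFT{rho_c}(k_j)
               * exp(i 2 pi df_c TE_e) * exp(-TE_e / T2*_c)  +  v

with ``v`` i.i.d. complex Gaussian measurement noise and ``d(t)`` an
optional per-excitation decay of the shared hyperpolarized magnetization
reservoir (RF depletion plus T1 relaxation).  The dissolved compartments are
excited with the large flip angle, the gas compartment with the small one.

For small problems the off-grid transform is the exact (chunked) DFT over
the phantom's support; large problems fall back to a highly oversampled
Kaiser-Bessel interpolation, with the exact DFT as the accuracy oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .decomposition import COMPARTMENTS, ResonanceModel, build_phase_matrix
from .trajectory import RadialTrajectory

__all__ = [
    "DigitalLungPhantom",
    "SequenceParams",
    "SimulationParams",
    "KSpaceData",
    "make_lung_phantom",
    "simulate_kspace",
    "spoke_decay_factors",
]

#: Per-excitation survival of the hyperpolarized gas reservoir when
#: depolarization is simulated.  The dissolved magnetization is replenished
#: from this reservoir every TR, so all compartments decay together; the
#: default corresponds to ~1% reservoir consumption per excitation, which
#: depresses the end-of-scan signal by roughly four orders of magnitude over
#: a 934-spoke acquisition — a deliberately strong, order-of-magnitude-scale
#: decay of the kind visible on logarithmic SNR-vs-AF plots.
DEFAULT_SURVIVAL = 0.99


@dataclass
class SequenceParams:
    """Multi-echo radial sequence timing and excitation parameters."""

    te_ms: tuple[float, ...] = (0.57, 1.27, 1.97, 2.67)
    tr_ms: float = 15.0
    flip_dissolved_deg: float = 22.0
    flip_gas_deg: float = 0.22
    n_dummy: int = 20
    bandwidth_hz: float = 31.25e3

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.tr_ms <= 0 or self.bandwidth_hz <= 0:
            raise ValueError("TR and bandwidth must be positive")

    def flip_rad(self, compartment: str) -> float:
        deg = self.flip_gas_deg if compartment == "gas" else self.flip_dissolved_deg
        return float(np.radians(deg))

    @property
    def readout_window_ms(self) -> float:
        """Duration of one echo readout implied by the receiver bandwidth."""
        # one complex sample per dwell; set by the caller's samples-per-spoke
        return 1e3 / self.bandwidth_hz


@dataclass
class SimulationParams:
    """Measurement-noise and magnetization-decay settings for the simulator.

    The default ``noise_sigma`` is calibrated so the default healthy phantom
    reconstructs with a gridding RBC SNR of ~9, the healthy-cohort ballpark;
    SNR scales inversely with ``noise_sigma``.
    """

    noise_sigma: float = 0.022
    depolarization: str = "off"  # {"off", "per_spoke"}
    survival_per_excitation: float = DEFAULT_SURVIVAL
    t1_decay_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.depolarization not in ("off", "per_spoke"):
            raise ValueError(f"unknown depolarization mode {self.depolarization!r}")
        if not 0 < self.survival_per_excitation <= 1:
            raise ValueError("survival_per_excitation must lie in (0, 1]")


@dataclass
class DigitalLungPhantom:
    """Three-compartment source densities plus the ground-truth lung mask."""

    matrix: int
    rho: dict[str, np.ndarray]
    lung_mask: np.ndarray
    defect_spec: list = field(default_factory=list)
    rbc_to_m: float = 0.41
    m_to_gas: float = 0.0098

    def density(self, compartment: str) -> np.ndarray:
        return self.rho[compartment]


@dataclass
class KSpaceData:
    """Simulated multi-echo radial samples, shape (n_echo, n_spokes, n_samp)."""

    data: np.ndarray
    te_ms: tuple[float, ...]
    traj: RadialTrajectory

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    def flat(self, spokes: np.ndarray | None = None) -> np.ndarray:
        """Samples flattened to (n_echo, M), optionally spoke-subset."""
        d = self.data if spokes is None else self.data[:, spokes]
        return d.reshape(self.n_echoes, -1)


def make_lung_phantom(
    matrix: int = 32,
    rbc_to_m: float = 0.41,
    m_to_gas: float = 0.0098,
    defect_spec: list | None = None,
    seed: int = 0,
    dissolved_gain: float = 1.0,
    texture_amplitude: float = 0.10,
) -> DigitalLungPhantom:
    """Build a two-lung ellipsoidal phantom with smooth gas-density variation.

    Parameters
    ----------
    matrix : grid size per axis (>= 8).
    rbc_to_m, m_to_gas : target density ratios inside the lung, outside any
        defect.  Healthy-cohort defaults.
    defect_spec : list of ``(center, radius_vox, compartment, attenuation)``
        spheres multiplying the named compartment by ``attenuation`` inside.
    seed : seeds the smooth random texture on the gas density.
    dissolved_gain : extra gain G on the dissolved densities
        (``rho_m = m_to_gas * G * rho_gas``); the default 1.0 leaves the
        dissolved pool at the physiological ~1-2% of the gas pool.
    texture_amplitude : fractional amplitude of the smooth random texture.
    """
    if matrix < 8:
        raise ValueError("matrix must be >= 8")
    if rbc_to_m <= 0 or m_to_gas <= 0:
        raise ValueError("ratio targets must be positive")
    n = matrix
    z, y, x = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")

    def ellipsoid(center, semi):
        u2 = sum(((g - c) / s) ** 2 for g, c, s in zip((z, y, x), center, semi))
        return u2

    semi = (0.38 * n, 0.19 * n, 0.22 * n)
    left = ellipsoid((0.50 * n, 0.295 * n, 0.50 * n), semi)
    right = ellipsoid((0.50 * n, 0.705 * n, 0.50 * n), semi)
    u2 = np.minimum(left, right)
    lung_mask = u2 <= 1.0
    if not lung_mask.any():
        raise ValueError("degenerate phantom: empty lung mask")

    # Smooth interior profile: parabolic taper toward the pleural boundary
    # plus a gravity-like ventilation gradient and a little smooth texture.
    rng = np.random.default_rng(seed)
    texture = ndimage.gaussian_filter(rng.standard_normal((n,) * 3), sigma=n / 8)
    texture /= max(np.abs(texture).max(), 1e-30)
    profile = (1.0 - 0.4 * np.clip(u2, 0.0, 1.0)) * (
        1.0 + 0.25 * (z / max(n - 1, 1) - 0.5)
    )
    rho_gas = np.where(lung_mask, profile * (1.0 + texture_amplitude * texture), 0.0)
    rho_gas = np.clip(rho_gas, 0.0, None)

    rho_m = m_to_gas * dissolved_gain * rho_gas
    rho_rbc = rbc_to_m * rho_m
    rho = {"gas": rho_gas, "membrane": rho_m, "rbc": rho_rbc}

    for center, radius, compartment, attenuation in defect_spec or []:
        center = np.asarray(center, dtype=float)
        if np.any(center < 0) or np.any(center > n - 1):
            raise ValueError(f"defect center {center} outside the grid")
        if compartment not in rho:
            raise ValueError(f"unknown compartment {compartment!r}")
        sphere = ((z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2) <= radius**2
        rho[compartment] = np.where(sphere, attenuation * rho[compartment], rho[compartment])

    return DigitalLungPhantom(
        matrix=n,
        rho=rho,
        lung_mask=lung_mask,
        defect_spec=list(defect_spec or []),
        rbc_to_m=rbc_to_m,
        m_to_gas=m_to_gas,
    )


def spoke_decay_factors(
    n_spokes: int, seq: SequenceParams, sim: SimulationParams
) -> np.ndarray:
    """Per-temporal-index reservoir decay d(t), t = 0..n_spokes-1.

    ``d(t) = survival^t * exp(-t TR / T1)``; identically 1 when
    depolarization is off.  Applied to every compartment, since the dissolved
    signal is refreshed from the same decaying gas reservoir each excitation.
    """
    t = np.arange(n_spokes, dtype=float)
    if sim.depolarization == "off":
        return np.ones(n_spokes)
    d = sim.survival_per_excitation**t
    if sim.t1_decay_s is not None:
        d = d * np.exp(-t * seq.tr_ms * 1e-3 / sim.t1_decay_s)
    return d


def _direct_dft_multi(
    volumes: list[np.ndarray], k_flat: np.ndarray, chunk: int = 2048
) -> list[np.ndarray]:
    """Exact DFT of several same-grid volumes at arbitrary k-points.

    Phase convention: ``F(k) = sum_r rho(r) exp(-i 2 pi k . (r - N//2))``
    with r in voxel units and k in cycles per voxel.  The (chunked) phase
    matrix over the union support is shared across the volumes.
    """
    n = volumes[0].shape[0]
    support = np.nonzero(sum(np.abs(v) for v in volumes))
    coords = np.column_stack(support).astype(float) - n // 2
    vals = np.column_stack([v[support] for v in volumes])  # (nnz, n_vol)
    out = np.empty((k_flat.shape[0], vals.shape[1]), dtype=complex)
    for start in range(0, k_flat.shape[0], chunk):
        kk = k_flat[start : start + chunk]
        phase = np.exp(-2j * np.pi * (kk @ coords.T))
        out[start : start + chunk] = phase @ vals
    return [out[:, i] for i in range(vals.shape[1])]


def _direct_dft(rho: np.ndarray, k_flat: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Exact DFT of one volume at arbitrary k-points (see `_direct_dft_multi`)."""
    return _direct_dft_multi([rho], k_flat, chunk)[0]


def _nufft_dft(rho: np.ndarray, k_flat: np.ndarray) -> np.ndarray:
    from .gridding import NufftOperator

    op = NufftOperator(k_flat, rho.shape[0], oversampling=2.0, kernel_width=8)
    return op.forward(rho.astype(complex))


def simulate_kspace(
    phantom: DigitalLungPhantom,
    traj: RadialTrajectory,
    model: ResonanceModel,
    seq: SequenceParams,
    sim: SimulationParams,
    method: str = "auto",
) -> KSpaceData:
    """Simulate noisy multi-echo radial k-space data from a phantom.

    ``method`` selects the off-grid transform: ``"dft"`` (exact, chunked),
    ``"nufft"`` (oversampled Kaiser-Bessel interpolation), or ``"auto"``
    (exact DFT unless support x samples exceeds ~5e8 products).
    """
    traj.validate()
    k_flat = traj.flat_coords()
    m = k_flat.shape[0]
    nnz = int(np.count_nonzero(phantom.lung_mask))
    if method == "auto":
        method = "dft" if nnz * m <= 5e8 else "nufft"
    if method not in ("dft", "nufft"):
        raise ValueError(f"unknown simulation method {method!r}")

    phi = build_phase_matrix(model, seq.te_ms, allow_underdetermined=True).entries
    n_echo = phi.shape[0]

    # Per-compartment DFT is echo-independent (flyback: same k each echo).
    f_c = {}
    if method == "dft":
        transformed = _direct_dft_multi([phantom.rho[c] for c in COMPARTMENTS], k_flat)
        for c, f in zip(COMPARTMENTS, transformed):
            f_c[c] = f * np.sin(seq.flip_rad(c))
    else:
        for c in COMPARTMENTS:
            rho = phantom.rho[c]
            f_c[c] = (
                np.zeros(m, dtype=complex)
                if not np.any(rho)
                else _nufft_dft(rho, k_flat) * np.sin(seq.flip_rad(c))
            )

    signal = np.zeros((n_echo, m), dtype=complex)
    for ci, c in enumerate(COMPARTMENTS):
        signal += phi[:, ci][:, None] * f_c[c][None, :]

    decay = spoke_decay_factors(traj.n_spokes, seq, sim)[traj.order]
    signal *= np.repeat(decay, traj.samples_per_spoke)[None, :]

    if sim.noise_sigma > 0:
        rng = np.random.default_rng(sim.seed)
        noise = sim.noise_sigma * (
            rng.standard_normal((n_echo, m)) + 1j * rng.standard_normal((n_echo, m))
        )
        signal = signal + noise

    data = signal.reshape(n_echo, traj.n_spokes, traj.samples_per_spoke)
    return KSpaceData(data=data, te_ms=tuple(seq.te_ms), traj=traj)
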