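"""3D radial k-space trajectories for multi-echo spectroscopic lung imaging.

A fully sampled acquisition consists of ``n_spokes`` radial spokes whose
directions tile the unit sphere near-uniformly and which are played out in a
randomized temporal order.  Every echo of a multi-echo (flyback) readout
revisits the same spoke, so one trajectory serves all spectral echoes.

k-space coordinates are dimensionless, normalized so that the Nyquist limit
of the reconstructed matrix sits at ``|k| = 0.5`` (cycles per voxel spacing);
the DC sample is the k-space origin.  The image grid is 0-based with the DC
voxel at index ``N // 2`` on each axis (numpy ``fftshift`` convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RadialTrajectory",
    "UndersamplingPlan",
    "generate_spoke_directions",
    "randomize_order",
    "sample_positions",
    "select_spokes",
    "round_half_up",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))  # 2*pi / phi^2


@dataclass
class RadialTrajectory:
    """Radial spoke geometry plus per-spoke temporal acquisition order.

    Attributes
    ----------
    directions : (S, 3) float array of unit vectors, one per spoke.
    order : (S,) int array; ``order[s]`` is the temporal index (0-based) at
        which spoke ``s`` is acquired.  A bijection over spokes.
    samples_per_spoke : number of k-space samples along each spoke.
    k_coords : (S, samples_per_spoke, 3) normalized coordinates in
        [-0.5, 0.5].
    spoke_style : ``"center_out"`` (sample 0 at the origin) or
        ``"full_diameter"`` (spoke spans -0.5..+0.5 through the origin).
    """

    directions: np.ndarray
    order: np.ndarray
    samples_per_spoke: int
    k_coords: np.ndarray
    spoke_style: str = "center_out"

    @property
    def n_spokes(self) -> int:
        return self.directions.shape[0]

    @property
    def n_samples(self) -> int:
        return self.n_spokes * self.samples_per_spoke

    def flat_coords(self, spokes: np.ndarray | None = None) -> np.ndarray:
        """k-space coordinates flattened to (M, 3), optionally spoke-subset."""
        k = self.k_coords if spokes is None else self.k_coords[spokes]
        return k.reshape(-1, 3)

    def subset(self, spokes: np.ndarray) -> "RadialTrajectory":
        """Trajectory restricted to the given spokes (temporal order re-ranked)."""
        spokes = np.asarray(spokes)
        sub_order = np.argsort(np.argsort(self.order[spokes]))
        return RadialTrajectory(
            directions=self.directions[spokes],
            order=sub_order,
            samples_per_spoke=self.samples_per_spoke,
            k_coords=self.k_coords[spokes],
            spoke_style=self.spoke_style,
        )

    def validate(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("spoke directions must be unit vectors")
        if np.abs(self.k_coords).max() > 0.5 + 1e-12:
            raise ValueError("k-space coordinates exceed the Nyquist box")
        if sorted(self.order.tolist()) != list(range(self.n_spokes)):
            raise ValueError("order must be a permutation of spoke indices")
        if self.spoke_style == "center_out":
            if np.abs(self.k_coords[:, 0, :]).max() > 1e-12:
                raise ValueError("center_out spokes must start at the origin")


@dataclass
class UndersamplingPlan:
    """Retrospective spoke-subset selection.

    ``retained`` holds sorted spoke indices; with ``mode="first_n"`` these are
    the temporally earliest ``round_half_up(S / af)`` spokes, with
    ``mode="random"`` a uniform sample without replacement.
    """

    af: float
    mode: str
    seed: int
    retained: np.ndarray = field(repr=False)

    @property
    def n_retained(self) -> int:
        return int(self.retained.size)


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 rounding away from zero (upward)."""
    return int(math.floor(x + 0.5))


def generate_spoke_directions(n: int, method: str = "phyllotaxis") -> np.ndarray:
    """Near-uniform unit vectors on the sphere for ``n`` radial spokes.

    The default ``"phyllotaxis"`` scheme is the generalized-Fibonacci (spiral
    phyllotaxis) lattice: point ``i`` sits at height
    ``z_i = 1 - (2 i + 1)/n`` and azimuth ``i`` times the golden angle.
    Deterministic for fixed ``n``.
    """
    if n < 1:
        raise ValueError(f"need at least one spoke, got n={n}")
    if method != "phyllotaxis":
        raise ValueError(f"unknown direction scheme {method!r}")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def randomize_order(n_spokes: int, seed: int) -> np.ndarray:
    """Uniformly random temporal permutation of spokes, reproducible by seed."""
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.permutation(n_spokes)


def sample_positions(
    directions: np.ndarray,
    samples_per_spoke: int,
    spoke_style: str = "center_out",
    order: np.ndarray | None = None,
) -> RadialTrajectory:
    """Lay out k-space sample positions radially along each spoke direction.

    ``center_out`` spokes run |k| = 0 .. 0.5 in ``samples_per_spoke`` uniform
    steps; ``full_diameter`` spokes run -0.5 .. +0.5.
    """
    if samples_per_spoke < 2:
        raise ValueError("samples_per_spoke must be >= 2")
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if spoke_style == "center_out":
        radii = np.linspace(0.0, 0.5, samples_per_spoke)
    elif spoke_style == "full_diameter":
        radii = np.linspace(-0.5, 0.5, samples_per_spoke)
    else:
        raise ValueError(f"unknown spoke_style {spoke_style!r}")
    k = directions[:, None, :] * radii[None, :, None]
    if order is None:
        order = np.arange(directions.shape[0])
    return RadialTrajectory(
        directions=directions,
        order=np.asarray(order),
        samples_per_spoke=samples_per_spoke,
        k_coords=k,
        spoke_style=spoke_style,
    )


def select_spokes(
    traj: RadialTrajectory, af: float, mode: str = "first_n", seed: int = 0
) -> UndersamplingPlan:
    """Retain ``round_half_up(S / af)`` spokes for retrospective undersampling.

    ``first_n`` keeps the temporally earliest spokes (consecutive ordering);
    ``random`` keeps a uniform subset drawn from the whole acquisition.
    """
    if af < 1:
        raise ValueError(f"acceleration factor must be >= 1, got {af}")
    s = traj.n_spokes
    n_keep = min(s, round_half_up(s / af))
    if mode == "first_n":
        retained = np.flatnonzero(traj.order < n_keep)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        retained = np.sort(rng.choice(s, size=n_keep, replace=False))
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return UndersamplingPlan(af=af, mode=mode, seed=seed, retained=retained)


def trajectory_to_csv(traj: RadialTrajectory, path) -> None:
    """Plain-text (spoke, sample, kx, ky, kz) export for debugging."""
    s_idx, m_idx = np.meshgrid(
        np.arange(traj.n_spokes), np.arange(traj.samples_per_spoke), indexing="ij"
    )
    flat = np.column_stack(
        [s_idx.ravel(), m_idx.ravel(), traj.k_coords.reshape(-1, 3)]
    )
    np.savetxt(
        path,
        flat,
        delimiter=",",
        header="spoke,sample,kx,ky,kz",
        comments="",
        fmt=["%d", "%d", "%.9f", "%.9f", "%.9f"],
    )
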