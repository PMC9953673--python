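"""Reference conformation generators.

These provide ensembles with analytically known scaling behaviour, used both
as fixtures and as physical baselines:

* :func:`make_rod` — the fully extended limit (scaling exponent ν = 1).
* :func:`make_compact` — a space-filling (Hilbert) path on a cubic lattice,
  the compact limit (ν = 1/3).
* :func:`sample_ideal_chain` — freely jointed chains, the ideal-coil limit
  (ν = 1/2, RMS internal distance b·√s exactly in expectation).
* :func:`sample_saw_chain` — self-avoiding configurations from the pivot
  algorithm (swollen coil, ν ≈ 0.59).
* :func:`sample_ou_series` — a stationary AR(1)/Ornstein–Uhlenbeck series
  with exactly known autocorrelation time, for validating relaxation-time
  fits.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .chain import ChainSpec, Ensemble, Frame

__all__ = [
    "make_rod",
    "make_compact",
    "sample_ideal_chain",
    "sample_saw_chain",
    "sample_ou_series",
]


def make_rod(spec: ChainSpec) -> Ensemble:
    """Single-frame ensemble of a perfectly straight chain along x."""
    n, b = spec.n_residues, spec.bond_length
    coords = np.zeros((n, 3))
    coords[:, 0] = b * np.arange(n)
    frame = Frame(chain_coords=coords, frame_index=0)
    return Ensemble(spec=spec, frames=[frame],
                    metadata={"generator": "rod", "spacing_unit": "frame"})


# ------------------------------------------------------------- Hilbert path

def _hilbert_point(index: int, order: int) -> tuple[int, int, int]:
    # Skilling's transpose algorithm, 3 dimensions.
    n_dims = 3
    x = [0, 0, 0]
    for i in range(n_dims * order):
        bit = (index >> (n_dims * order - 1 - i)) & 1
        x[i % n_dims] = (x[i % n_dims] << 1) | bit
    # Gray decode
    t = x[n_dims - 1] >> 1
    for i in range(n_dims - 1, 0, -1):
        x[i] ^= x[i - 1]
    x[0] ^= t
    # undo excess work
    n_cells = 2 << (order - 1)
    q = 2
    while q != n_cells:
        p = q - 1
        for i in range(n_dims - 1, -1, -1):
            if x[i] & q:
                x[0] ^= p
            else:
                t = (x[0] ^ x[i]) & p
                x[0] ^= t
                x[i] ^= t
        q <<= 1
    return x[0], x[1], x[2]


def make_compact(n_side: int, bond_length: float = 3.8) -> Ensemble:
    """Space-filling chain through an ``n_side``³ cubic lattice.

    Beads follow a 3-D Hilbert curve, so consecutive beads are lattice
    neighbours (every step has length ``bond_length``) and the chain fills a
    cube of edge ``(n_side − 1)·bond_length`` — the maximally compact
    self-avoiding reference with scaling exponent 1/3.
    """
    if n_side not in (2, 4, 8, 16):
        raise ValueError(
            f"n_side must be a power of two in {{2,4,8,16}}, got {n_side}"
        )
    order = int(np.log2(n_side))
    n_beads = n_side ** 3
    lattice = np.array(
        [_hilbert_point(i, order) for i in range(n_beads)], dtype=float
    )
    coords = lattice * bond_length
    labels = ("X",) * n_beads
    spec = ChainSpec(n_residues=n_beads, residue_labels=labels,
                     bead_charge=(0.0,) * n_beads, bond_length=bond_length)
    frame = Frame(chain_coords=coords, frame_index=0)
    return Ensemble(spec=spec, frames=[frame],
                    metadata={"generator": "hilbert_compact",
                              "spacing_unit": "frame"})


# ------------------------------------------------------------- ideal chain

def sample_ideal_chain(spec: ChainSpec, n_frames: int, seed: int) -> Ensemble:
    """Independent freely jointed chains (no excluded volume, no ions)."""
    if n_frames < 1:
        raise ValueError("n_frames must be ≥ 1")
    rng = np.random.default_rng(seed)
    n, b = spec.n_residues, spec.bond_length
    # unit step directions uniform on the sphere
    steps = rng.normal(size=(n_frames, n - 1, 3))
    steps /= np.linalg.norm(steps, axis=2, keepdims=True)
    coords = np.zeros((n_frames, n, 3))
    coords[:, 1:] = np.cumsum(b * steps, axis=1)
    frames = [Frame(chain_coords=coords[k], frame_index=k)
              for k in range(n_frames)]
    return Ensemble(spec=spec, frames=frames,
                    metadata={"generator": "ideal_chain", "seed": seed,
                              "spacing_unit": "frame"})


# ------------------------------------------------------------- SAW (pivot)

def _saw_overlap(head: np.ndarray, tail: np.ndarray, diameter: float) -> bool:
    d = cdist(head, tail)
    return bool((d < diameter).any())


def sample_saw_chain(spec: ChainSpec, n_frames: int, seed: int,
                     pivots_per_frame: int | None = None,
                     equilibration_pivots: int | None = None,
                     max_attempt_factor: int = 200) -> Ensemble:
    """Self-avoiding chain ensemble from the pivot algorithm.

    Starting from a rod, a random bead is chosen as pivot and the shorter arm
    is rotated by a uniform random rotation; moves producing any non-bonded
    pair closer than ``bead_diameter`` are rejected.  Frames are stored every
    ``pivots_per_frame`` *accepted* pivots (default 2·N) after
    ``equilibration_pivots`` accepted pivots (default 10·N), which
    decorrelates global observables such as Rg.
    """
    if spec.bead_diameter >= 2 * spec.bond_length:
        raise ValueError("bead_diameter must be < 2 × bond_length")
    rng = np.random.default_rng(seed)
    n, b, sigma = spec.n_residues, spec.bond_length, spec.bead_diameter
    if pivots_per_frame is None:
        pivots_per_frame = 2 * n
    if equilibration_pivots is None:
        equilibration_pivots = 10 * n

    coords = np.zeros((n, 3))
    coords[:, 0] = b * np.arange(n)

    needed = equilibration_pivots + n_frames * pivots_per_frame
    budget = max_attempt_factor * needed
    accepted = attempts = 0
    frames: list[Frame] = []
    next_store = equilibration_pivots + pivots_per_frame

    while len(frames) < n_frames:
        if attempts >= budget:
            raise RuntimeError(
                "pivot acceptance too low; reduce bead_diameter "
                f"({accepted}/{attempts} accepted)"
            )
        attempts += 1
        p = int(rng.integers(1, n - 1))
        rot = Rotation.random(rng=rng).as_matrix()
        if p >= n // 2:          # rotate the tail (shorter or equal arm)
            moved = (coords[p + 1:] - coords[p]) @ rot.T + coords[p]
            # only cross head/tail pairs can newly overlap; exclude the
            # bonded pair (p, p+1) whose distance is rotation-invariant
            if _saw_overlap(coords[: p], moved, sigma) or (
                np.linalg.norm(moved[1:] - coords[p], axis=1) < sigma
            ).any():
                continue
            coords = coords.copy()
            coords[p + 1:] = moved
        else:                    # rotate the head
            moved = (coords[: p] - coords[p]) @ rot.T + coords[p]
            bad = _saw_overlap(moved, coords[p + 1:], sigma)
            if not bad and p >= 2:
                # moved beads other than the bonded neighbour p-1 vs bead p
                bad = bool((np.linalg.norm(
                    moved[: p - 1] - coords[p], axis=1) < sigma).any())
            if bad:
                continue
            coords = coords.copy()
            coords[: p] = moved
        accepted += 1
        if accepted >= next_store:
            frames.append(Frame(chain_coords=coords.copy(),
                                frame_index=len(frames)))
            next_store += pivots_per_frame

    return Ensemble(spec=spec, frames=frames,
                    metadata={"generator": "saw_pivot", "seed": seed,
                              "pivots_per_frame": pivots_per_frame,
                              "spacing_unit": "accepted-pivot-block"})


# ------------------------------------------------------------- OU series

def sample_ou_series(mean: float, variance: float, tau: float,
                     n_points: int, spacing: float = 1.0,
                     seed: int = 0) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck (AR(1)) observable series.

    The series has the given stationary mean and variance and autocorrelation
    ``exp(−Δ/τ)`` at lag Δ (in the units of ``spacing``); the discrete lag-1
    coefficient is φ = exp(−spacing/τ).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if variance <= 0:
        raise ValueError("variance must be positive")
    if n_points < 1:
        raise ValueError("n_points must be ≥ 1")
    rng = np.random.default_rng(seed)
    phi = np.exp(-spacing / tau)
    innov_sd = np.sqrt(variance * (1.0 - phi ** 2))
    x0 = rng.normal(0.0, np.sqrt(variance))
    eps = rng.normal(0.0, innov_sd, size=n_points - 1)
    # x_t = phi x_{t-1} + eps_t, run through an IIR filter seeded at x0
    zi = np.array([phi * x0])
    rest, _ = lfilter([1.0], [1.0, -phi], eps, zi=zi)
    return mean + np.concatenate([[x0], rest])
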