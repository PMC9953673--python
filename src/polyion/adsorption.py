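"""Ion adsorption statistics.

An ion is adsorbed in a frame when its minimum-image, center-to-center
distance to *any* chain bead is ≤ the cutoff (default 4 Å, boundary
inclusive).  The default species filter counts counterions — ions whose
charge sign opposes the chain's net charge — matching the convention of
plotting Na⁺/Mg²⁺ adsorption for anionic chains and Cl⁻ for cationic ones;
``species="all"`` counts every ion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import Ensemble, Frame
from .metrics import rg_series

__all__ = ["AdsorptionResult", "count_adsorbed", "adsorption_series"]

DEFAULT_CUTOFF = 4.0


@dataclass
class AdsorptionResult:
    cutoff: float
    species_filter: str
    per_frame_counts: np.ndarray
    mean_count: float
    joint_hist: np.ndarray | None = None
    rg_bin_edges: np.ndarray | None = None
    count_bin_edges: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "species_filter": self.species_filter,
            "mean_count": self.mean_count,
            "n_frames": int(len(self.per_frame_counts)),
        }


def _species_mask(frame: Frame, species_filter: str,
                  chain_net_charge: float) -> np.ndarray:
    valences = frame.ion_valences()
    if species_filter == "all":
        return np.ones(len(valences), dtype=bool)
    if species_filter == "cations":
        return valences > 0
    if species_filter == "anions":
        return valences < 0
    if species_filter == "counterions":
        if chain_net_charge == 0:
            return np.ones(len(valences), dtype=bool)
        return (valences * chain_net_charge) < 0
    raise ValueError(f"unknown species filter {species_filter!r}")


def count_adsorbed(frame: Frame, cutoff: float = DEFAULT_CUTOFF,
                   species_filter: str = "all",
                   chain_net_charge: float = 0.0) -> int:
    """Ions within ``cutoff`` (minimum image) of any chain bead, inclusive."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not frame.ions:
        return 0
    mask = _species_mask(frame, species_filter, chain_net_charge)
    ion_xyz = frame.ion_coords()[mask]
    if len(ion_xyz) == 0:
        return 0
    delta = ion_xyz[:, None, :] - frame.chain_coords[None, :, :]
    if frame.box_edge > 0:
        delta -= frame.box_edge * np.rint(delta / frame.box_edge)
    dmin = np.sqrt((delta ** 2).sum(axis=2)).min(axis=1)
    return int((dmin <= cutoff).sum())


def adsorption_series(ensemble: Ensemble, cutoff: float = DEFAULT_CUTOFF,
                      species_filter: str = "counterions",
                      joint_histogram: bool = True) -> AdsorptionResult:
    """Per-frame adsorbed-ion counts, their mean and a joint (Rg, count)
    histogram with 1 Å Rg bins and unit count bins."""
    if ensemble.n_frames < 1:
        raise ValueError("empty ensemble")
    net = ensemble.spec.net_charge
    counts = np.array([
        count_adsorbed(fr, cutoff=cutoff, species_filter=species_filter,
                       chain_net_charge=net)
        for fr in ensemble
    ])
    result = AdsorptionResult(
        cutoff=cutoff, species_filter=species_filter,
        per_frame_counts=counts, mean_count=float(counts.mean()),
    )
    if joint_histogram:
        rgs = rg_series(ensemble).values
        rg_edges = np.arange(np.floor(rgs.min()), np.ceil(rgs.max()) + 1.0, 1.0)
        if len(rg_edges) < 2:
            rg_edges = np.array([rgs.min() - 0.5, rgs.min() + 0.5])
        count_edges = np.arange(-0.5, counts.max() + 1.5, 1.0)
        hist, _, _ = np.histogram2d(rgs, counts, bins=[rg_edges, count_edges])
        result.joint_hist = hist
        result.rg_bin_edges = rg_edges
        result.count_bin_edges = count_edges
    return result
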