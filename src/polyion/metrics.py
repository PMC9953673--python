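"""Per-frame chain geometry: radius of gyration and end-to-end distance.

Beads are weighted uniformly (at one-bead-per-residue resolution there are
no atomic masses to weight by); ions are excluded from all chain metrics.
The chain is assumed whole (never wrapped across the periodic boundary); a
validation check rejects ensembles with any bond longer than half the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import Ensemble, Frame

__all__ = ["radius_of_gyration", "rg_series", "end_to_end", "RgSeries"]

_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass
class RgSeries:
    """Per-frame Rg values with summary statistics."""

    values: np.ndarray
    frame_indices: np.ndarray
    spacing: float
    unit: str
    summary: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.summary["mean"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frame_indices, "rg": self.values})

    def to_dict(self) -> dict:
        return {
            "spacing": self.spacing,
            "unit": self.unit,
            "n_frames": int(len(self.values)),
            "summary": self.summary,
        }


def _check_whole(frame: Frame) -> None:
    if frame.box_edge > 0:
        bonds = np.linalg.norm(np.diff(frame.chain_coords, axis=0), axis=1)
        if (bonds > frame.box_edge / 2).any():
            raise ValueError(
                "chain appears wrapped across the periodic boundary "
                "(bond longer than box_edge/2); unwrap before analysis"
            )


def radius_of_gyration(frame: Frame) -> float:
    """Root-mean-square distance of chain beads from their centroid, Å."""
    coords = frame.chain_coords
    if coords.shape[0] < 2:
        raise ValueError("radius of gyration requires ≥ 2 beads")
    _check_whole(frame)
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred ** 2, axis=1))))


def end_to_end(frame: Frame) -> float:
    """Euclidean distance between the first and last bead, Å."""
    return float(np.linalg.norm(frame.chain_coords[-1] - frame.chain_coords[0]))


def rg_series(ensemble: Ensemble) -> RgSeries:
    """Per-frame Rg in frame order plus mean/sd/quantile summary."""
    if ensemble.n_frames < 1:
        raise ValueError("empty ensemble")
    values = np.array([radius_of_gyration(fr) for fr in ensemble])
    indices = np.array([fr.frame_index for fr in ensemble])
    summary = {
        "mean": float(values.mean()),
        "std": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "quantiles": {f"q{int(q * 100):02d}": float(np.quantile(values, q))
                      for q in _QUANTILES},
    }
    return RgSeries(values=values, frame_indices=indices,
                    spacing=ensemble.frame_spacing,
                    unit=ensemble.spacing_unit, summary=summary)
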