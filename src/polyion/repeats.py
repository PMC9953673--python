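"""Homorepeat detection in protein sequences.

A repeat is a *maximal* run of consecutive residues drawn from one charge
class — {D, E} for acidic or {K, R} for basic runs; any other character
(including ambiguity codes) breaks a run.  Protein-level curves count each
protein at most once per length threshold, using its longest run.  Two
counting modes are provided for the threshold curve: ``cumulative`` counts
a protein at threshold L when its longest run r satisfies
min_length ≤ r ≤ L, and ``at_least`` counts it when r ≥ L.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RepeatHit", "RepeatCurve", "find_repeats", "cumulative_curve",
           "composition_ratio", "CHARGE_CLASSES"]

CHARGE_CLASSES = {"DE": ("D", "E"), "KR": ("K", "R")}
DEFAULT_MIN_LENGTH = 10


@dataclass(frozen=True)
class RepeatHit:
    protein_id: str
    start: int                  # 0-based
    length: int
    charge_class: str
    composition: dict = field(default_factory=dict)


@dataclass
class RepeatCurve:
    thresholds: np.ndarray
    counts: np.ndarray
    charge_class: str
    total_proteins: int
    mode: str = "cumulative"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "n_proteins": self.counts,
            "charge_class": self.charge_class,
            "mode": self.mode,
        })


def find_repeats(sequence: str, charge_class: str,
                 min_length: int = DEFAULT_MIN_LENGTH,
                 protein_id: str = "") -> list[RepeatHit]:
    """All maximal runs of class residues with length ≥ min_length."""
    if charge_class not in CHARGE_CLASSES:
        raise ValueError(
            f"charge_class must be one of {sorted(CHARGE_CLASSES)}, "
            f"got {charge_class!r}"
        )
    alphabet = set(CHARGE_CLASSES[charge_class])
    hits: list[RepeatHit] = []
    run_start = None
    for i, ch in enumerate(sequence + "\0"):   # sentinel terminates last run
        if ch in alphabet:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                length = i - run_start
                if length >= min_length:
                    comp = dict(Counter(sequence[run_start:i]))
                    hits.append(RepeatHit(protein_id=protein_id,
                                          start=run_start, length=length,
                                          charge_class=charge_class,
                                          composition=comp))
                run_start = None
    return hits


def _longest_run(sequence: str, charge_class: str) -> int:
    alphabet = set(CHARGE_CLASSES[charge_class])
    best = cur = 0
    for ch in sequence:
        if ch in alphabet:
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


def cumulative_curve(proteome: list[tuple[str, str]], charge_class: str,
                     min_length: int = DEFAULT_MIN_LENGTH,
                     mode: str = "cumulative") -> RepeatCurve:
    """Protein counts versus repeat-length threshold.

    ``cumulative``: a protein contributes at threshold L iff its longest
    run r satisfies min_length ≤ r ≤ L.  ``at_least``: iff r ≥ L.
    Thresholds span min_length … the longest observed run.
    """
    if mode not in ("cumulative", "at_least"):
        raise ValueError(f"unknown mode {mode!r}")
    if not proteome:
        warnings.warn("empty proteome: returning empty curve", stacklevel=2)
        return RepeatCurve(thresholds=np.array([], dtype=int),
                           counts=np.array([], dtype=int),
                           charge_class=charge_class, total_proteins=0,
                           mode=mode)
    longest = np.array([_longest_run(seq, charge_class)
                        for _, seq in proteome])
    max_run = int(longest.max()) if longest.size else 0
    thresholds = np.arange(min_length, max(max_run, min_length) + 1)
    if mode == "cumulative":
        counts = np.array([
            int(((longest >= min_length) & (longest <= L)).sum())
            for L in thresholds
        ])
    else:
        counts = np.array([int((longest >= L).sum()) for L in thresholds])
    return RepeatCurve(thresholds=thresholds, counts=counts,
                       charge_class=charge_class,
                       total_proteins=len(proteome), mode=mode)


def composition_ratio(hits: list[RepeatHit]) -> float:
    """Ratio of the first class member to the second across all hits
    (E/D for acidic runs, K/R for basic).  All-first-member hit sets give
    ``inf``; an empty hit list is an error."""
    if not hits:
        raise ValueError("composition_ratio requires at least one hit")
    charge_class = hits[0].charge_class
    first, second = {"DE": ("E", "D"), "KR": ("K", "R")}[charge_class]
    n_first = sum(h.composition.get(first, 0) for h in hits)
    n_second = sum(h.composition.get(second, 0) for h in hits)
    if n_second == 0:
        return float("inf")
    return n_first / n_second
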