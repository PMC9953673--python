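"""Coarse-grained explicit-ion polyelectrolyte Monte Carlo.

A bead-spring chain (one bead per residue, each carrying its residue charge)
and explicit salt/counter-ions move in a cubic periodic box under

* harmonic bonds between consecutive beads (default stiffness 100 kT/Å²,
  rest length = bond_length),
* Weeks–Chandler–Andersen (WCA) excluded volume between all non-bonded
  pairs, with per-species diameters combined by arithmetic mixing,
* pairwise Coulomb interactions in kT units through the Bjerrum length
  λ_B = e²/(4πε₀ ε_r k_B T) (≈ 7.1 Å in water at 300 K), evaluated with the
  minimum-image convention and truncated at ``coulomb_cutoff``.

Sampling is Metropolis Monte Carlo with single-particle displacements plus
chain pivot moves.  The displacement amplitude is auto-tuned toward a
30–50 % acceptance rate during equilibration only and frozen for
production, so the production chain is Markovian.  Bonded (1–2) neighbours
interact through the bond and Coulomb terms but are excluded from WCA.

Ion content is derived from a :class:`~polyion.chain.SaltSpec`: monovalent
counterions first cancel the net chain charge exactly, then whole salt
formula units are added (one cation and one anion for 1:1 salt; one divalent
cation and two anions for 2:1 salt), so every generated frame is exactly
charge-neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import constants

from .chain import (
    ANION_DIAMETER,
    DIVALENT_CATION_DIAMETER,
    MONOVALENT_CATION_DIAMETER,
    ChainSpec,
    Ensemble,
    Frame,
    IonRecord,
    SaltSpec,
)

__all__ = ["MCParams", "bjerrum_length", "salt_ion_counts", "run_cg_simulation"]

DEFAULT_BOX_EDGE = 75.0  # Å
BOND_STIFFNESS = 100.0   # kT/Å²


def bjerrum_length(temperature: float = 300.0,
                   relative_permittivity: float = 78.5) -> float:
    """Bjerrum length in Å for the given temperature and permittivity."""
    lb_m = constants.e ** 2 / (
        4.0 * math.pi * constants.epsilon_0 * relative_permittivity
        * constants.k * temperature
    )
    return lb_m * 1e10


@dataclass(frozen=True)
class MCParams:
    """Monte Carlo run parameters.

    ``max_displacement`` is the initial per-particle trial step (Å); it is
    auto-tuned during equilibration.  ``pivot_probability`` is the fraction
    of chain-bead moves attempted as pivots rather than displacements.
    ``coulomb_cutoff=None`` means half the box edge.
    """

    n_sweeps: int = 50_000
    equilibration_sweeps: int = 10_000
    sample_interval: int = 100
    max_displacement: float = 3.0
    pivot_probability: float = 0.2
    temperature: float = 300.0
    relative_permittivity: float = 78.5
    bond_stiffness: float = BOND_STIFFNESS
    coulomb_cutoff: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_sweeps > self.equilibration_sweeps >= 0:
            raise ValueError("need n_sweeps > equilibration_sweeps ≥ 0")
        if not 0.0 <= self.pivot_probability <= 1.0:
            raise ValueError("pivot_probability must be in [0, 1]")
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be ≥ 1")


def salt_ion_counts(salt: SaltSpec, box_edge: float,
                    chain_net_charge: float) -> dict[str, int]:
    """Whole-formula-unit ion counts for a box, preserving exact neutrality.

    The number of salt formula units is ``round(c · N_A · V)``.  Counterions
    are monovalent, of sign opposite to the chain's net charge.
    """
    volume_l = (box_edge * 1e-8) ** 3 / 1.0e3  # Å → cm, cm³ → L
    n_units = int(round(salt.concentration * constants.N_A * volume_l))
    counts = {"n_salt_units": n_units, "n_counterions": 0}
    if salt.neutralize_chain and abs(chain_net_charge) > 0:
        n_counter = abs(chain_net_charge)
        if abs(n_counter - round(n_counter)) > 1e-9:
            raise ValueError("net chain charge must be an integer to neutralize")
        counts["n_counterions"] = int(round(n_counter))
    counts["n_cations"] = n_units
    counts["n_anions"] = n_units * (2 if salt.cation_valence == 2 else 1)
    return counts


# ----------------------------------------------------------------- kernel

@njit(cache=True)
def _segment_energy(pos, seg_lo, seg_hi, seg_coords, charge, diam, n_beads,
                    box, lb, rcut2, bond_k, bond_r0):
    """Energy (kT) between particles seg_lo..seg_hi-1 at ``seg_coords`` and
    every particle outside that index range; includes bonds crossing the
    segment boundary."""
    e = 0.0
    n = pos.shape[0]
    for a in range(seg_hi - seg_lo):
        i = seg_lo + a
        xi0 = seg_coords[a, 0]
        xi1 = seg_coords[a, 1]
        xi2 = seg_coords[a, 2]
        qi = charge[i]
        di = diam[i]
        for j in range(n):
            if seg_lo <= j < seg_hi:
                continue
            dx = xi0 - pos[j, 0]
            dy = xi1 - pos[j, 1]
            dz = xi2 - pos[j, 2]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            bonded = i < n_beads and j < n_beads and (i - j == 1 or j - i == 1)
            if bonded:
                r = np.sqrt(r2)
                e += 0.5 * bond_k * (r - bond_r0) ** 2
            else:
                sij = 0.5 * (di + diam[j])
                s2 = sij * sij
                if r2 < s2 * 1.2599210498948732:  # 2^(1/3) · σ² = (2^(1/6) σ)²
                    inv6 = (s2 / r2) ** 3
                    e += 4.0 * (inv6 * inv6 - inv6) + 1.0
            qq = qi * charge[j]
            if qq != 0.0 and r2 < rcut2:
                e += lb * qq / np.sqrt(r2)
    return e


@njit(cache=True)
def _rotation_matrix(ax, ay, az, theta):
    c = np.cos(theta)
    s = np.sin(theta)
    t = 1.0 - c
    r = np.empty((3, 3))
    r[0, 0] = c + ax * ax * t
    r[0, 1] = ax * ay * t - az * s
    r[0, 2] = ax * az * t + ay * s
    r[1, 0] = ax * ay * t + az * s
    r[1, 1] = c + ay * ay * t
    r[1, 2] = ay * az * t - ax * s
    r[2, 0] = ax * az * t - ay * s
    r[2, 1] = ay * az * t + ax * s
    r[2, 2] = c + az * az * t
    return r


@njit(cache=True)
def _run_kernel(pos, charge, diam, n_beads, box, lb, rcut, bond_k, bond_r0,
                n_sweeps, equil, sample_interval, max_disp0, pivot_prob,
                seed, frames_out):
    np.random.seed(seed)
    n_part = pos.shape[0]
    rcut2 = rcut * rcut
    max_disp = max_disp0
    tune_att = 0
    tune_acc = 0
    prod_disp_att = 0
    prod_disp_acc = 0
    prod_piv_att = 0
    prod_piv_acc = 0
    fidx = 0
    trial = np.empty((1, 3))
    for sweep in range(n_sweeps):
        production = sweep >= equil
        for _ in range(n_part):
            i = np.random.randint(0, n_part)
            if i < n_beads and n_beads > 2 and np.random.random() < pivot_prob:
                # ---- pivot move
                p = np.random.randint(1, n_beads - 1)
                if p >= n_beads // 2:
                    lo, hi = p + 1, n_beads
                else:
                    lo, hi = 0, p
                seg_old = pos[lo:hi]
                ax = np.random.normal(0.0, 1.0)
                ay = np.random.normal(0.0, 1.0)
                az = np.random.normal(0.0, 1.0)
                norm = np.sqrt(ax * ax + ay * ay + az * az)
                if norm == 0.0:
                    continue
                theta = np.random.random() * 2.0 * np.pi
                rot = _rotation_matrix(ax / norm, ay / norm, az / norm, theta)
                seg_new = np.empty_like(seg_old)
                for a in range(hi - lo):
                    vx = seg_old[a, 0] - pos[p, 0]
                    vy = seg_old[a, 1] - pos[p, 1]
                    vz = seg_old[a, 2] - pos[p, 2]
                    seg_new[a, 0] = (rot[0, 0] * vx + rot[0, 1] * vy
                                     + rot[0, 2] * vz + pos[p, 0])
                    seg_new[a, 1] = (rot[1, 0] * vx + rot[1, 1] * vy
                                     + rot[1, 2] * vz + pos[p, 1])
                    seg_new[a, 2] = (rot[2, 0] * vx + rot[2, 1] * vy
                                     + rot[2, 2] * vz + pos[p, 2])
                e0 = _segment_energy(pos, lo, hi, seg_old, charge, diam,
                                     n_beads, box, lb, rcut2, bond_k, bond_r0)
                e1 = _segment_energy(pos, lo, hi, seg_new, charge, diam,
                                     n_beads, box, lb, rcut2, bond_k, bond_r0)
                de = e1 - e0
                if production:
                    prod_piv_att += 1
                if de <= 0.0 or np.random.random() < np.exp(-de):
                    pos[lo:hi] = seg_new
                    if production:
                        prod_piv_acc += 1
            else:
                # ---- single-particle displacement
                trial[0, 0] = pos[i, 0] + (np.random.random() * 2.0 - 1.0) * max_disp
                trial[0, 1] = pos[i, 1] + (np.random.random() * 2.0 - 1.0) * max_disp
                trial[0, 2] = pos[i, 2] + (np.random.random() * 2.0 - 1.0) * max_disp
                e0 = _segment_energy(pos, i, i + 1, pos[i:i + 1], charge, diam,
                                     n_beads, box, lb, rcut2, bond_k, bond_r0)
                e1 = _segment_energy(pos, i, i + 1, trial, charge, diam,
                                     n_beads, box, lb, rcut2, bond_k, bond_r0)
                de = e1 - e0
                accepted = de <= 0.0 or np.random.random() < np.exp(-de)
                if accepted:
                    if i >= n_beads:
                        # wrap ions into the primary box
                        for k in range(3):
                            pos[i, k] = trial[0, k] - box * np.floor(
                                trial[0, k] / box)
                    else:
                        for k in range(3):
                            pos[i, k] = trial[0, k]
                if production:
                    prod_disp_att += 1
                    if accepted:
                        prod_disp_acc += 1
                else:
                    tune_att += 1
                    if accepted:
                        tune_acc += 1
        # step-size tuning, equilibration only
        if not production and (sweep + 1) % 100 == 0 and tune_att > 0:
            rate = tune_acc / tune_att
            if rate > 0.5:
                max_disp = min(max_disp * 1.1, box / 4.0)
            elif rate < 0.3:
                max_disp = max(max_disp * 0.9, 0.05)
            tune_att = 0
            tune_acc = 0
        if production and (sweep - equil + 1) % sample_interval == 0:
            if fidx < frames_out.shape[0]:
                frames_out[fidx] = pos
                fidx += 1
    disp_rate = prod_disp_acc / prod_disp_att if prod_disp_att else 0.0
    piv_rate = prod_piv_acc / prod_piv_att if prod_piv_att else 0.0
    return disp_rate, piv_rate, max_disp, fidx


# ----------------------------------------------------------------- setup

def _initial_positions(spec: ChainSpec, counts: dict[str, int], box: float,
                       rng: np.random.Generator) -> np.ndarray:
    n_beads = spec.n_residues
    n_ions = counts["n_counterions"] + counts["n_cations"] + counts["n_anions"]
    pos = np.empty((n_beads + n_ions, 3))
    # chain starts as a rod through the box centre (relaxes in equilibration)
    pos[:n_beads] = 0.0
    pos[:n_beads, 0] = spec.bond_length * np.arange(n_beads)
    pos[:n_beads] += box / 2.0 - pos[:n_beads].mean(axis=0)
    # ions uniformly at random, rejecting hard overlaps with what is placed
    placed = pos[:n_beads]
    for j in range(n_ions):
        for _ in range(1000):
            cand = rng.uniform(0.0, box, size=3)
            delta = placed - cand
            delta -= box * np.rint(delta / box)
            if (np.linalg.norm(delta, axis=1) > 2.0).all():
                break
        pos[n_beads + j] = cand
        placed = pos[: n_beads + j + 1]
    return pos


def _ion_arrays(spec: ChainSpec, salt: SaltSpec, counts: dict[str, int]
                ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, float]]]:
    species: list[tuple[str, int, float]] = []
    net = spec.net_charge
    if counts["n_counterions"]:
        if net < 0:
            species += [("NA", 1, MONOVALENT_CATION_DIAMETER)] * counts["n_counterions"]
        else:
            species += [("CL", -1, ANION_DIAMETER)] * counts["n_counterions"]
    if salt.cation_valence == 2:
        cat = ("MG", 2, DIVALENT_CATION_DIAMETER)
    else:
        cat = ("NA", 1, MONOVALENT_CATION_DIAMETER)
    species += [cat] * counts["n_cations"]
    species += [("CL", -1, ANION_DIAMETER)] * counts["n_anions"]
    valences = np.array([s[1] for s in species], dtype=float)
    diameters = np.array([s[2] for s in species], dtype=float)
    return valences, diameters, species


def run_cg_simulation(spec: ChainSpec, salt: SaltSpec,
                      box_edge: float = DEFAULT_BOX_EDGE,
                      params: MCParams | None = None) -> Ensemble:
    """Run the coarse-grained Metropolis simulation and return its ensemble.

    Frames are stored every ``params.sample_interval`` sweeps after
    ``params.equilibration_sweeps``; ``frame_spacing`` is therefore in
    sweeps.  Acceptance rates, the tuned step size and the full parameter
    set are recorded in the ensemble metadata.
    """
    params = params or MCParams()
    salt.validate_for_chain(spec)
    rcut = params.coulomb_cutoff if params.coulomb_cutoff is not None else box_edge / 2.0
    if rcut > box_edge / 2.0 + 1e-9:
        raise ValueError("coulomb_cutoff must be ≤ box_edge / 2")
    if box_edge <= 2 * spec.bond_length:
        raise ValueError("box_edge must exceed 2 × bond_length")

    counts = salt_ion_counts(salt, box_edge, spec.net_charge)
    valences, ion_diams, species = _ion_arrays(spec, salt, counts)
    total_charge = spec.net_charge + valences.sum()
    if abs(total_charge) > 1e-9:
        raise RuntimeError(
            f"internal consistency error: system charge {total_charge} ≠ 0"
        )

    n_beads = spec.n_residues
    charge = np.concatenate([spec.charges, valences])
    diam = np.concatenate([np.full(n_beads, spec.bead_diameter), ion_diams])
    rng = np.random.default_rng(params.seed)
    pos = _initial_positions(spec, counts, box_edge, rng)

    lb = bjerrum_length(params.temperature, params.relative_permittivity)
    n_frames = (params.n_sweeps - params.equilibration_sweeps) // params.sample_interval
    frames_out = np.empty((n_frames, pos.shape[0], 3))

    disp_rate, piv_rate, tuned_disp, n_stored = _run_kernel(
        pos, charge, diam, n_beads, box_edge, lb, rcut,
        params.bond_stiffness, spec.bond_length,
        params.n_sweeps, params.equilibration_sweeps, params.sample_interval,
        params.max_displacement, params.pivot_probability,
        params.seed % (2 ** 31), frames_out,
    )

    warnings: list[str] = []
    if not 0.05 < disp_rate < 0.95:
        warnings.append(
            f"displacement acceptance rate {disp_rate:.3f} outside (0.05, 0.95)"
        )

    frames = []
    for k in range(n_stored):
        snap = frames_out[k]
        ions = [
            IonRecord(species_label=species[j][0], valence=species[j][1],
                      position=tuple(snap[n_beads + j]),
                      diameter=species[j][2])
            for j in range(len(species))
        ]
        frames.append(Frame(chain_coords=snap[:n_beads].copy(), ions=ions,
                            box_edge=box_edge, frame_index=k,
                            frame_spacing=float(params.sample_interval)))
    metadata = {
        "generator": "cg_mc",
        "seed": params.seed,
        "spacing_unit": "sweep",
        "bjerrum_length": lb,
        "coulomb_cutoff": rcut,
        "ion_counts": counts,
        "displacement_acceptance": disp_rate,
        "pivot_acceptance": piv_rate,
        "tuned_max_displacement": tuned_disp,
        "warnings": warnings,
        "params": {
            "n_sweeps": params.n_sweeps,
            "equilibration_sweeps": params.equilibration_sweeps,
            "sample_interval": params.sample_interval,
            "pivot_probability": params.pivot_probability,
            "temperature": params.temperature,
            "relative_permittivity": params.relative_permittivity,
            "bond_stiffness": params.bond_stiffness,
        },
    }
    return Ensemble(spec=spec, salt=salt, frames=frames, metadata=metadata)
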