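"""Coarse-grained Monte Carlo engine: bookkeeping, detailed balance,
sampler equivalence.

MC runs here use short desk-scale sweep counts; the statistical checks are
sized so the tested effects are well above their sampling noise.
"""

import numpy as np
import pytest
from scipy import integrate, stats

from polyion.chain import ChainSpec, SaltSpec, poly_e, poly_gs
from polyion.generators import sample_saw_chain
from polyion.mc import (
    MCParams,
    bjerrum_length,
    run_cg_simulation,
    salt_ion_counts,
)
from polyion.metrics import rg_series


def short_params(seed=0, sweeps=6000, equil=2000, interval=20, **kw):
    return MCParams(n_sweeps=sweeps, equilibration_sweeps=equil,
                    sample_interval=interval, seed=seed, **kw)


def test_bjerrum_length_in_water_at_300K():
    assert bjerrum_length(300.0, 78.5) == pytest.approx(7.1, abs=0.05)


class TestIonCounts:
    def test_formula_units_at_standard_box(self):
        counts = salt_ion_counts(SaltSpec(concentration=0.125), 75.0, -30.0)
        assert counts["n_salt_units"] == 32
        assert counts["n_counterions"] == 30
        assert counts["n_cations"] == 32 and counts["n_anions"] == 32

    def test_divalent_salt_has_two_anions_per_unit(self):
        counts = salt_ion_counts(
            SaltSpec(concentration=0.125, cation_valence=2), 75.0, -30.0)
        assert counts["n_anions"] == 2 * counts["n_cations"]

    def test_cationic_chain_gets_anionic_counterions(self):
        ens = run_cg_simulation(
            ChainSpec(5, ("K",) * 5, (1.0,) * 5), SaltSpec(),
            box_edge=40.0, params=short_params(sweeps=200, equil=50))
        valences = ens.frames[0].ion_valences()
        assert (valences == -1).all() and len(valences) == 5


class TestInvariants:
    @pytest.fixture(scope="class")
    def charged_run(self):
        return run_cg_simulation(poly_e(30), SaltSpec(), params=short_params())

    def test_every_frame_exactly_neutral(self, charged_run):
        for fr in charged_run:
            assert fr.total_charge(charged_run.spec) == 0.0

    def test_seed_determinism_bit_identical(self):
        a = run_cg_simulation(poly_e(10), SaltSpec(), box_edge=50.0,
                              params=short_params(seed=3, sweeps=800, equil=200))
        b = run_cg_simulation(poly_e(10), SaltSpec(), box_edge=50.0,
                              params=short_params(seed=3, sweeps=800, equil=200))
        np.testing.assert_array_equal(a.coordinates(), b.coordinates())
        np.testing.assert_array_equal(
            np.array([i.position for f in a for i in f.ions]),
            np.array([i.position for f in b for i in f.ions]))

    def test_bond_integrity(self, charged_run):
        # thermal width of a k=100 kT/Å² bond is 0.1 Å; allow 5 sigma
        for fr in charged_run:
            bonds = np.linalg.norm(np.diff(fr.chain_coords, axis=0), axis=1)
            assert np.all(np.abs(bonds - 3.8) < 5 * 0.1)

    def test_acceptance_rate_in_band(self, charged_run):
        rate = charged_run.metadata["displacement_acceptance"]
        assert 0.05 < rate < 0.95
        assert charged_run.metadata["warnings"] == []


class TestBoltzmannSampling:
    def test_harmonic_bond_samples_boltzmann(self):
        """Two-bead chain, no charges: bond length r follows
        p(r) ∝ r² exp(−βk(r−r0)²/2).  χ² against the exact density."""
        spec = ChainSpec(2, ("G", "G"), (0.0, 0.0), bead_diameter=0.5)
        ens = run_cg_simulation(
            spec, SaltSpec(), box_edge=30.0,
            params=short_params(seed=5, sweeps=101_000, equil=1000,
                                interval=1, pivot_probability=0.0))
        r = np.array([np.linalg.norm(f.chain_coords[1] - f.chain_coords[0])
                      for f in ens])
        r = r[::10]                       # thin to ~independent samples
        edges = np.linspace(3.8 - 0.35, 3.8 + 0.35, 12)
        obs, _ = np.histogram(r, bins=edges)
        centers = 0.5 * (edges[1:] + edges[:-1])
        dens = centers ** 2 * np.exp(-0.5 * 100.0 * (centers - 3.8) ** 2)
        expected = dens / dens.sum() * obs.sum()
        chi2 = stats.chisquare(obs, expected, ddof=0)
        assert chi2.pvalue > 0.01

    def test_opposite_charges_follow_boltzmann_pair_distance(self):
        """One Na⁺/Cl⁻ pair in a small box (plus an inert neutral dimer):
        p(r) ∝ 4πr² exp(+λ_B/r − u_WCA(r)) for r < box/2, where the
        minimum-image shell is a full sphere.  Compared by χ² to the
        numerically normalized density over that window."""
        box = 24.0
        # concentration giving exactly one salt formula unit in this box
        conc = 1.0 / (6.02214076e23 * (box * 1e-8) ** 3 / 1e3)
        spec = ChainSpec(2, ("G", "G"), (0.0, 0.0), bead_diameter=0.5)
        ens = run_cg_simulation(
            spec, SaltSpec(concentration=conc), box_edge=box,
            params=short_params(seed=6, sweeps=301_000, equil=1000,
                                interval=3, pivot_probability=0.0))
        assert len(ens.frames[0].ions) == 2
        lb = ens.metadata["bjerrum_length"]
        d = []
        for f in ens:
            na, cl = f.ion_coords()
            delta = na - cl
            delta -= box * np.rint(delta / box)
            d.append(np.linalg.norm(delta))
        d = np.array(d)[::15]             # thin to ~independent samples
        sigma = 0.5 * (2.3 + 3.6)         # Na/Cl arithmetic mixing

        def density(r):
            u = 0.0
            if r < sigma * 2 ** (1 / 6):
                inv6 = (sigma / r) ** 6
                u = 4 * (inv6 ** 2 - inv6) + 1
            return r ** 2 * np.exp(lb / r - u)

        lo, hi = 2.4, 11.0
        edges = np.linspace(lo, hi, 10)
        obs, _ = np.histogram(d[(d >= lo) & (d < hi)], bins=edges)
        # per-bin mass by numeric integration of the two-particle density
        mass = np.array([integrate.quad(density, a, b, limit=200)[0]
                         for a, b in zip(edges[:-1], edges[1:])])
        expected = mass / mass.sum() * obs.sum()
        assert obs.sum() > 2000
        assert stats.chisquare(obs, expected).pvalue > 0.01

    def test_neutral_chain_matches_pivot_saw_sampler(self):
        """Zero-charge chain without salt is a hard-sphere polymer; its Rg
        distribution must match the independent pivot SAW sampler."""
        spec = poly_e(20, bead_diameter=3.8)
        neutral = ChainSpec(20, spec.residue_labels, (0.0,) * 20,
                            bead_diameter=3.8)
        mc = run_cg_simulation(
            neutral, SaltSpec(), box_edge=75.0,
            params=short_params(seed=7, sweeps=42_000, equil=2000,
                                interval=40, pivot_probability=0.3))
        saw = sample_saw_chain(spec, 600, seed=8)
        rg_mc = rg_series(mc).values
        rg_saw = rg_series(saw).values
        # subsample MC to ~independent frames (spacing 40 sweeps ≳ τ here)
        ks = stats.ks_2samp(rg_mc[::4], rg_saw[::2])
        assert ks.pvalue > 0.01
        assert np.mean(rg_mc) == pytest.approx(np.mean(rg_saw), rel=0.05)
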