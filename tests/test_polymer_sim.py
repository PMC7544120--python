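"""Energy terms against brute-force pair-loop oracles, and integrator physics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadfold import polymer_sim as ps


def brute_force_energies(conf, p, chromatin_like=False):
    """Independent double-loop evaluation of every energy term."""
    n = len(conf)
    bonded = sum(
        p.bond_k * (np.linalg.norm(conf[i + 1] - conf[i]) - p.bond_r0) ** 2
        for i in range(n - 1)
    )
    softcore = collapse = specific = 0.0
    rcut = 2.0 ** (1 / 6) * 1.0  # repulsive cutoff for 1-sigma bead diameter
    for i in range(n):
        for j in range(i + 2, n):
            r = np.linalg.norm(conf[i] - conf[j])
            if r < rcut:
                s6 = (1.0 / max(r, 1e-12)) ** 6
                u = 4.0 * (s6 * s6 - s6) + 1.0
                softcore += 0.5 * p.softcore_cap * (
                    1.0 + math.tanh(2.0 * min(u, 1e6) / p.softcore_cap - 1.0)
                )
            collapse += 0.5 * p.collapse_alpha * (
                1.0 + math.tanh(p.collapse_eta * (p.collapse_rc - r))
            )
            same = (i < p.domain_split) == (j < p.domain_split)
            if chromatin_like and same:
                specific += 0.5 * p.specific_alpha * (
                    1.0 + math.tanh(p.collapse_eta * (p.collapse_rc - r))
                )
    return bonded, softcore, collapse, specific


def random_conf(n, rng, spread=2.0):
    conf = np.cumsum(rng.normal(0, spread, size=(n, 3)), axis=0)
    return conf


class TestEnergyTerms:
    def test_bond_at_equilibrium_is_zero(self):
        p = ps.PolymerModelParams(n_beads=2)
        conf = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert ps.bonded_energy(conf, p) == pytest.approx(0.0)

    def test_bond_convention_k_times_square(self):
        p = ps.PolymerModelParams(n_beads=2)
        conf = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert ps.bonded_energy(conf, p) == pytest.approx(1.0)

    def test_straight_chain_bond_sum(self):
        p = ps.PolymerModelParams()
        conf = np.zeros((28, 3))
        conf[:, 0] = np.arange(28) * 2.5
        assert ps.bonded_energy(conf, p) == pytest.approx(27 * 0.25)

    def test_single_bead_rejected(self):
        with pytest.raises(ValueError):
            ps.PolymerModelParams(n_beads=1)

    def test_softcore_zero_beyond_cutoff(self):
        p = ps.PolymerModelParams(n_beads=3)
        conf = np.array([[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
        assert ps.softcore_energy(conf, p) == 0.0

    def test_softcore_cap_at_overlap(self):
        p = ps.PolymerModelParams(n_beads=3)
        conf = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 0, 0]])
        u = ps.softcore_energy(conf, p)
        assert np.isfinite(u)
        assert u == pytest.approx(p.softcore_cap)

    def test_collapse_half_alpha_at_rc(self):
        p = ps.PolymerModelParams(n_beads=3)
        conf = np.array([[0.0, 0, 0], [100.0, 0, 0], [3.0, 0, 0]])
        # only the (0, 2) pair is near; it sits exactly at r_c -> alpha/2
        assert ps.collapse_energy(conf, p, alpha=-0.04) == pytest.approx(-0.02, abs=1e-9)

    def test_collapse_vanishes_at_long_range(self):
        p = ps.PolymerModelParams(n_beads=3)
        conf = np.array([[0.0, 0, 0], [100.0, 0, 0], [200.0, 0, 0]])
        assert abs(ps.collapse_energy(conf, p)) < 1e-8

    def test_specific_half_alpha_at_rc(self):
        p = ps.PolymerModelParams(n_beads=6, domain_split=3, specific_alpha=-0.1)
        # only non-bonded same-half pair near range: (0, 2) at exactly r_c
        conf = np.array(
            [[0.0, 0, 0], [0.0, 50, 0], [3.0, 0, 0],
             [1000.0, 0, 0], [1000.0, 50, 0], [1000.0, 100, 0]]
        )
        assert ps.specific_energy_delta(conf, p) == pytest.approx(-0.05, abs=1e-9)

    def test_specific_zero_when_far(self):
        p = ps.PolymerModelParams(n_beads=4, domain_split=2)
        conf = np.array([[0.0, 0, 0], [50.0, 0, 0], [100.0, 0, 0], [150.0, 0, 0]])
        assert abs(ps.specific_energy_delta(conf, p)) < 1e-8

    @pytest.mark.parametrize("chromatin_like", [False, True])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_terms_match_brute_force(self, seed, chromatin_like):
        rng = np.random.default_rng(seed)
        n = 10
        p = ps.PolymerModelParams(n_beads=n, domain_split=5)
        conf = random_conf(n, rng)
        b, s, c, sp = brute_force_energies(conf, p, chromatin_like)
        dec = ps.total_energy(conf, p, chromatin_like=chromatin_like)
        assert dec.bonded == pytest.approx(b, rel=1e-9, abs=1e-12)
        assert dec.softcore == pytest.approx(s, rel=1e-9, abs=1e-12)
        assert dec.collapse == pytest.approx(c, rel=1e-9, abs=1e-12)
        assert dec.specific == pytest.approx(sp, rel=1e-9, abs=1e-12)
        assert dec.total == pytest.approx(b + s + c + sp, rel=1e-9)

    def test_collapse_matches_brute_force_28_beads(self):
        rng = np.random.default_rng(7)
        p = ps.PolymerModelParams()
        conf = random_conf(28, rng, spread=1.2)
        _, _, c, _ = brute_force_energies(conf, p)
        assert ps.collapse_energy(conf, p) == pytest.approx(c, rel=1e-9)

    def test_reference_has_no_specific_term(self):
        rng = np.random.default_rng(3)
        p = ps.PolymerModelParams()
        conf = random_conf(28, rng)
        assert ps.total_energy(conf, p, chromatin_like=False).specific == 0.0

    def test_chromatin_total_minus_reference_is_specific(self):
        rng = np.random.default_rng(4)
        p = ps.PolymerModelParams()
        conf = random_conf(28, rng, spread=1.0)
        ref = ps.total_energy(conf, p, chromatin_like=False)
        chrom = ps.total_energy(conf, p, chromatin_like=True)
        assert chrom.total - ref.total == pytest.approx(
            ps.specific_energy_delta(conf, p), rel=1e-9
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 10))
    def test_energy_oracle_property(self, seed, n):
        rng = np.random.default_rng(seed)
        p = ps.PolymerModelParams(n_beads=n, domain_split=n // 2)
        conf = random_conf(n, rng)
        b, s, c, sp = brute_force_energies(conf, p, chromatin_like=True)
        dec = ps.total_energy(conf, p, chromatin_like=True)
        for got, want in [(dec.bonded, b), (dec.softcore, s), (dec.collapse, c),
                          (dec.specific, sp)]:
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


class TestForces:
    @pytest.mark.parametrize("chromatin_like", [False, True])
    def test_forces_match_numerical_gradient(self, chromatin_like):
        rng = np.random.default_rng(5)
        p = ps.PolymerModelParams(n_beads=8, domain_split=4)
        conf = random_conf(8, rng, spread=1.0)
        f = ps.forces(conf, p, chromatin_like)
        h = 1e-6
        for b in range(8):
            for k in range(3):
                cp, cm = conf.copy(), conf.copy()
                cp[b, k] += h
                cm[b, k] -= h
                num = -(
                    ps.total_energy(cp, p, chromatin_like).total
                    - ps.total_energy(cm, p, chromatin_like).total
                ) / (2 * h)
                assert f[b, k] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestLangevin:
    def test_zero_temperature_minimizes_bonds(self):
        p = ps.PolymerModelParams(
            n_beads=6, temperature=0.0, collapse_alpha=0.0, specific_alpha=0.0
        )
        rng = np.random.default_rng(0)
        init = np.zeros((6, 3))
        init[:, 0] = np.arange(6) * 2.3  # stretched, no overlap
        init += 0.01 * rng.standard_normal(init.shape)
        frames = ps.run_langevin(
            p, 60_000, 60_000, seed=0, n_equilibration=0, initial=init
        )
        r = np.linalg.norm(np.diff(frames[-1], axis=0), axis=1)
        assert np.allclose(r, 2.0, atol=1e-3)

    def test_equipartition_temperature(self, ref_ensemble, params):
        _, kinetic = ref_ensemble
        mean_ke = float(np.mean(kinetic))
        assert abs(mean_ke - 1.5 * params.temperature) < 0.075  # 5%

    def test_same_seed_identical_trajectories(self, params):
        a = ps.run_langevin(params, 2_000, 500, seed=42, n_equilibration=100)
        b = ps.run_langevin(params, 2_000, 500, seed=42, n_equilibration=100)
        assert np.array_equal(a, b)

    def test_adjacent_contact_probability_near_point_eight(self, ref_ensemble):
        frames, _ = ref_ensemble
        adj = np.mean(
            [np.mean(np.diag(ps.contacts_from_conformation(f, 3.0), k=1)) for f in frames]
        )
        assert 0.75 <= adj <= 0.85

    def test_chromatin_model_enriches_within_half_contacts(
        self, ref_ensemble, chrom_ensemble, params
    ):
        from scipy.stats import mannwhitneyu

        s = params.domain_split
        i, j = np.triu_indices(params.n_beads, k=2)
        same = ((i < s) & (j < s)) | ((i >= s) & (j >= s))

        def counts(traj):
            return np.array(
                [
                    ps.contacts_from_conformation(f, 3.0)[i[same], j[same]].sum()
                    for f in traj
                ]
            )

        c_ref = counts(ref_ensemble[0])
        c_chrom = counts(chrom_ensemble)
        assert c_chrom.mean() > c_ref.mean()
        res = mannwhitneyu(c_chrom, c_ref, alternative="greater")
        assert res.pvalue < 0.01

    def test_invalid_step_counts_rejected(self, params):
        with pytest.raises(ValueError):
            ps.run_langevin(params, 10, 20, seed=0)


class TestContacts:
    def test_cutoff_boundary(self):
        conf = np.array([[0.0, 0, 0], [2.9, 0, 0]])
        assert ps.contacts_from_conformation(conf, 3.0)[0, 1] == 1
        conf[1, 0] = 3.1
        assert ps.contacts_from_conformation(conf, 3.0)[0, 1] == 0

    def test_straight_chain_contacts_only_adjacent(self):
        conf = np.zeros((28, 3))
        conf[:, 0] = np.arange(28) * 2.0
        q = ps.contacts_from_conformation(conf, 3.0)
        i, j = np.where(np.triu(q, k=1))
        assert np.all(j - i == 1)

    def test_diagonal_is_one(self):
        conf = np.random.default_rng(0).normal(size=(5, 3))
        q = ps.contacts_from_conformation(conf, 3.0)
        assert np.all(np.diag(q) == 1)


class TestTrajectoryIO:
    def test_xyz_round_trip(self, tmp_path, params):
        traj = ps.run_langevin(params, 1_000, 500, seed=3, n_equilibration=0)
        path = tmp_path / "traj.xyz"
        ps.write_xyz(traj, path)
        back = ps.read_xyz(path, params.n_beads)
        assert np.allclose(back, traj, atol=1e-6)
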