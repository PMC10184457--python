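"""Generators: determinism, distributional structure, validator compliance."""

import numpy as np
import pytest
from scipy import stats

from oakniche.dstat import count_patterns
from oakniche.grafting import graft_fossil
from oakniche.koppen import classify_niche, snap_to_cells, koppen_profile
from oakniche.simulate import (
    PatchSpec,
    SpeciesRangeSpec,
    cerris_like_fossils,
    cerris_like_leaf_matrix,
    cerris_like_niche_states,
    cerris_like_tree,
    cerris_like_world,
    sim_dated_tree,
    sim_fossils,
    sim_koppen_world,
    sim_mk_characters,
    sim_quartet_sites,
)
from oakniche.trees import parse_tree


def simple_pure_birth_root_ages(n_tips, lam, n_rep, seed):
    """Independent minimal sampler of the same stopped pure-birth process:
    root age = sum of Exp(i*lam) waiting times for i = 2..n_tips."""
    rng = np.random.default_rng(seed)
    ages = np.zeros(n_rep)
    for i in range(2, n_tips + 1):
        ages += rng.exponential(1.0 / (i * lam), size=n_rep)
    return ages


class TestDatedTree:
    def test_two_tip_cherry(self):
        tree = sim_dated_tree(2, seed=0)
        assert len(tree.tips()) == 2
        assert tree.age[tree.root] > 0

    def test_same_seed_same_newick(self):
        assert sim_dated_tree(12, seed=9).to_newick() == sim_dated_tree(12, seed=9).to_newick()

    def test_different_seeds_differ(self):
        assert sim_dated_tree(12, seed=1).to_newick() != sim_dated_tree(12, seed=2).to_newick()

    def test_pure_birth_root_age_distribution(self):
        # compare generator root ages against the independent sampler
        gen = []
        for s in range(300):
            t = sim_dated_tree(20, birth=1.0, seed=s)
            gen.append(t.age[t.root])
        gen = np.array(gen)
        oracle = simple_pure_birth_root_ages(20, 1.0, 300, seed=999)
        # same distribution (two-sample KS at alpha = 0.01) and close means
        assert stats.ks_2samp(gen, oracle).pvalue > 0.01
        expected = sum(1.0 / i for i in range(2, 21))
        assert gen.mean() == pytest.approx(expected, rel=0.1)

    def test_birth_death_survives_and_is_ultrametric(self):
        tree = sim_dated_tree(10, birth=1.0, death=0.5, seed=4)
        assert len(tree.tips()) == 10
        assert tree.is_ultrametric(tol=1e-6)

    def test_nonviable_rates_error(self):
        with pytest.raises(RuntimeError):
            sim_dated_tree(50, birth=0.1, death=2.0, seed=0, max_retries=5)


class TestMkCharacters:
    def test_zero_rate_gives_constant_characters(self):
        tree = sim_dated_tree(8, seed=1)
        for char in sim_mk_characters(tree, k=4, q=0.0, n_chars=5, seed=2):
            assert len(set(char.states.values())) == 1

    def test_reproducible(self):
        tree = sim_dated_tree(8, seed=1)
        a = sim_mk_characters(tree, k=3, q=0.5, n_chars=10, seed=5)
        b = sim_mk_characters(tree, k=3, q=0.5, n_chars=10, seed=5)
        assert [c.states for c in a] == [c.states for c in b]

    def test_high_rate_star_tips_near_uniform(self):
        tree = parse_tree("(A:50,B:50,C:50,D:50);")
        chars = sim_mk_characters(tree, k=4, q=2.0, n_chars=500, seed=3)
        counts = np.zeros(4)
        for c in chars:
            for s in c.states.values():
                counts[s] += 1
        assert stats.chisquare(counts).pvalue > 0.01


class TestKoppenWorld:
    def test_one_patch_species_single_class(self):
        grid, occ, _ = sim_koppen_world(
            [PatchSpec("Csa", 0, 0, 60, 40)],
            [SpeciesRangeSpec("sp", 2.5, 31.5, 0.4, 200)],
            seed=0,
        )
        prof = koppen_profile("sp", snap_to_cells(occ, grid)["sp"], grid)
        assert prof.fractions == {"Csa": 1.0}

    def test_straddling_species_matches_construction(self):
        # patch boundary placed so that ~60/40 of the density mass falls on
        # each side of the range centre
        grid, occ, _ = sim_koppen_world(
            [PatchSpec("Csa", 0, 0, 30, 40), PatchSpec("Cfa", 30, 0, 60, 40)],
            [SpeciesRangeSpec("sp", 2.5, 31.5, 1.2, 10_000)],
            seed=1,
        )
        boundary = grid.lon_min + 30 * grid.res_deg
        frac_left = stats.norm.cdf(boundary, loc=2.5, scale=1.2)
        prof = koppen_profile("sp", snap_to_cells(occ, grid)["sp"], grid)
        assert prof.fractions["Csa"] == pytest.approx(frac_left, abs=0.08)

    def test_center_outside_grid_errors(self):
        with pytest.raises(ValueError, match="centre outside"):
            sim_koppen_world(
                [PatchSpec("Csa", 0, 0, 10, 10)],
                [SpeciesRangeSpec("sp", 500.0, 31.0, 1.0, 10)],
                n_lon=10, n_lat=10,
            )

    def test_same_seed_identical_tables(self):
        args = ([PatchSpec("Csa", 0, 0, 10, 10)], [SpeciesRangeSpec("sp", 0.4, 30.4, 0.2, 50)])
        _, occ1, _ = sim_koppen_world(*args, n_lon=10, n_lat=10, seed=7)
        _, occ2, _ = sim_koppen_world(*args, n_lon=10, n_lat=10, seed=7)
        assert occ1.equals(occ2)


class TestQuartetSites:
    def test_equal_probabilities_expect_zero_d(self):
        tot = np.zeros(2)
        for rep in range(30):
            qd = sim_quartet_sites(("a", "b", "c", "o"), 10, 500, p_abba=0.04, p_baba=0.04, seed=rep)
            tot += count_patterns(qd)
        d = (tot[0] - tot[1]) / tot.sum()
        assert abs(d) < 0.05

    def test_admixture_mode_plants_expected_d(self):
        qd = sim_quartet_sites(("a", "b", "c", "o"), 100, 500, gamma=0.3, seed=1)
        a, b = count_patterns(qd)
        assert (a - b) / (a + b) == pytest.approx(0.5, abs=0.05)

    def test_counts_match_multinomial_expectation(self):
        n_loci, spl = 200, 250
        qd = sim_quartet_sites(("a", "b", "c", "o"), n_loci, spl, p_abba=0.06, p_baba=0.02, seed=9)
        a, b = count_patterns(qd)
        n = n_loci * spl
        obs = [a, b, n - a - b]
        exp = [0.06 * n, 0.02 * n, 0.92 * n]
        assert stats.chisquare(obs, exp).pvalue > 0.01

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            sim_quartet_sites(("a", "b", "c", "o"), 5, 10, p_abba=0.7, p_baba=0.4)


class TestFossils:
    def test_zero_fossils_empty_list(self):
        tree = sim_dated_tree(6, seed=0)
        assert sim_fossils(tree, 0, seed=1) == []

    def test_all_specs_graftable_by_construction(self):
        tree = sim_dated_tree(10, seed=3)
        for spec in sim_fossils(tree, 30, seed=4):
            graft_fossil(tree, spec)  # must not raise

    def test_oldest_ages_uniform_on_a_fixed_branch(self):
        tree = parse_tree("((A:5,B:5):10,C:15);")
        draws = []
        for s in range(2000):
            for spec in sim_fossils(tree, 1, seed=s):
                if spec.anchor == frozenset({"A", "B"}):
                    draws.append(spec.oldest_age)
        draws = np.array(draws)
        assert stats.kstest(draws, "uniform", args=(5, 10)).pvalue > 0.01


class TestPreset:
    def test_tree_shape_and_ages(self):
        tree = cerris_like_tree()
        assert len(tree.tips()) == 15
        assert tree.age[tree.root] == pytest.approx(36.7)
        west = tree.mrca({"Q_suber", "Q_cerris"})
        assert tree.age[west] == pytest.approx(24.3)
        assert tree.is_ultrametric(tol=1e-6)

    def test_niche_states_cover_all_species(self):
        tree = cerris_like_tree()
        states = cerris_like_niche_states()
        assert set(states) == set(tree.tip_labels())
        assert set(states.values()) == {0, 1, 2, 3, 4}

    def test_fossil_set_is_graftable_and_mostly_assignable(self):
        fossils = cerris_like_fossils(seed=0)
        assert len(fossils) == 47
        assignable = [f for f in fossils if f.assignable]
        assert len(assignable) > 30
        from oakniche.grafting import graft_all

        grafted = graft_all(cerris_like_tree(), fossils)
        assert len(grafted.tips()) == 15 + len(assignable)

    def test_world_profiles_classify_like_the_emulated_signatures(self):
        grid, occ, biomes = cerris_like_world(seed=1)
        cells = snap_to_cells(occ, grid)
        for sp in ("Q_chenii", "Q_suber", "Q_castaneifolia", "Q_crenata"):
            prof = koppen_profile(sp, cells[sp], grid)
            cat = classify_niche(prof, biomes[sp])
            expected = {"Q_chenii": 0, "Q_crenata": 2, "Q_castaneifolia": 3, "Q_suber": 4}
            assert int(cat) == expected[sp]
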