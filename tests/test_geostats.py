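"""Haversine distances, p-distances, Mantel IBD and AMOVA — including
exhaustive brute-force oracles on tiny inputs."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from wolfdemes.geostats import (
    EARTH_RADIUS_KM,
    amova,
    genetic_distance_matrix,
    geographic_distance_matrix,
    haversine_km,
    mantel_ibd,
)


class TestHaversine:
    def test_identical_points(self):
        assert haversine_km(10.0, 20.0, 10.0, 20.0) == 0.0

    def test_quarter_great_circle(self):
        assert haversine_km(0, 0, 0, 90) == pytest.approx(math.pi * EARTH_RADIUS_KM / 2)

    def test_antipodal(self):
        assert haversine_km(0, 0, 0, 180) == pytest.approx(math.pi * EARTH_RADIUS_KM)

    def test_radius_override_scales_linearly(self):
        assert haversine_km(0, 0, 0, 90, r=1.0) == pytest.approx(math.pi / 2)

    @pytest.mark.parametrize("bad", [(91, 0, 0, 0), (0, 0, -95, 0), (0, 400, 0, 0)])
    def test_out_of_range_coordinates(self, bad):
        with pytest.raises(ValueError):
            haversine_km(*bad)

    def test_matrix_is_symmetric_zero_diagonal(self):
        m = geographic_distance_matrix([0, 10, 50], [0, 20, 100], ids=list("abc"))
        assert np.allclose(m, m.T) and np.all(np.diag(m) == 0)


class TestGeneticDistance:
    def test_identical_sequences(self):
        d = genetic_distance_matrix({"a": "ACGT", "b": "ACGT"})
        assert d.loc["a", "b"] == 0.0

    def test_one_quarter_different(self):
        d = genetic_distance_matrix({"a": "ACGT", "b": "ACGA"})
        assert d.loc["a", "b"] == 0.25

    def test_pairwise_deletion_of_missing(self):
        # N site excluded: 0 mismatches over 3 comparable sites
        d = genetic_distance_matrix({"a": "ACGN", "b": "ACGA"})
        assert d.loc["a", "b"] == 0.0
        d = genetic_distance_matrix({"a": "TCGN", "b": "ACG-"})
        assert d.loc["a", "b"] == pytest.approx(1 / 3)

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            genetic_distance_matrix({"a": "NN", "b": "AC"})

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            genetic_distance_matrix({"a": "ACGT", "b": "ACG"})

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(0)
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGTN"), size=50)) for i in range(5)
        }
        d = genetic_distance_matrix(seqs)
        assert ((d.values >= 0) & (d.values <= 1)).all()


def brute_force_mantel(geo, gen):
    """Exhaustive Mantel test: permuted rho over all n! joint relabelings."""
    n = geo.shape[0]
    iu = np.triu_indices(n, k=1)

    def rho_of(m):
        return np.corrcoef(geo[iu], m[iu])[0, 1]

    obs = rho_of(gen)
    count = 0
    total = 0
    for p in itertools.permutations(range(n)):
        p = np.array(p)
        count += rho_of(gen[np.ix_(p, p)]) >= obs
        total += 1
    return obs, count / total


class TestMantel:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(0)
        geo = geographic_distance_matrix(
            rng.uniform(-60, 60, 8), rng.uniform(0, 120, 8)
        ).to_numpy()
        gen = 0.001 * geo + 0.02
        rho, p = mantel_ibd(geo, gen, n_perm=499, seed=1)
        assert rho == pytest.approx(1.0)
        # generic configuration: only the identity reproduces rho = 1
        assert p <= 0.05

    def test_matches_exhaustive_oracle_on_four_samples(self):
        rng = np.random.default_rng(42)
        a = rng.random((4, 4))
        geo = (a + a.T) / 2
        np.fill_diagonal(geo, 0)
        b = rng.random((4, 4))
        gen = (b + b.T) / 2
        np.fill_diagonal(gen, 0)
        rho_o, p_o = brute_force_mantel(geo, gen)
        rho, p = mantel_ibd(geo, gen, n_perm=5000, seed=0)
        assert rho == pytest.approx(rho_o)
        # permutation p converges to the exhaustive proportion
        assert abs(p - p_o) < 3 * math.sqrt(p_o * (1 - p_o) / 5000) + 1 / 5000

    def test_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(3)
        a = rng.random((6, 6))
        geo = (a + a.T) / 2
        np.fill_diagonal(geo, 0)
        b = rng.random((6, 6))
        gen = (b + b.T) / 2
        np.fill_diagonal(gen, 0)
        rho1, _ = mantel_ibd(geo, gen, n_perm=10, seed=0)
        p = np.random.default_rng(9).permutation(6)
        rho2, _ = mantel_ibd(geo[np.ix_(p, p)], gen[np.ix_(p, p)], n_perm=10, seed=0)
        assert rho1 == pytest.approx(rho2)

    def test_spearman_option(self):
        geo = geographic_distance_matrix([0, 10, 20, 35], [0, 0, 0, 0]).to_numpy()
        gen = np.exp(geo / 2000) - 1  # monotone, nonlinear
        np.fill_diagonal(gen, 0)
        rho, _ = mantel_ibd(geo, gen, n_perm=99, seed=0, method="spearman")
        assert rho == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        m = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="constant"):
            mantel_ibd(m, m, n_perm=10, seed=0)


def brute_force_amova(d, labels):
    """Independent AMOVA implementation from the sums-of-squares
    definitions, with explicit loops."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        members = [i for i in range(n) if labels[i] == g]
        acc = 0.0
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                acc += d[members[a], members[b]] ** 2
        ss_within += acc / len(members)
    ss_among = ss_total - ss_within
    df_a = len(groups) - 1
    df_w = n - len(groups)
    ms_a = ss_among / df_a
    ms_w = ss_within / df_w
    n0 = (n - sum(len([i for i in range(n) if labels[i] == g]) ** 2 for g in groups) / n) / df_a
    s2w = ms_w
    s2a = (ms_a - ms_w) / n0
    return s2a, s2w, 100 * s2a / (s2a + s2w)


class TestAmova:
    def toy_matrix(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        a = rng.random((n, n)) * 0.1
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        return d

    def test_two_tight_groups_explain_everything(self):
        # identical within groups, distance d between
        d = np.zeros((4, 4))
        d[np.ix_([0, 1], [2, 3])] = 0.2
        d[np.ix_([2, 3], [0, 1])] = 0.2
        res = amova(d, ["x", "x", "y", "y"], n_perm=0)
        assert res.pct_among == pytest.approx(100.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        d = self.toy_matrix(seed=5)
        labels = ["p", "p", "q", "q", "q", "r"]
        res = amova(d, labels, n_perm=0)
        s2a, s2w, pct = brute_force_amova(d, labels)
        assert res.sigma2_among == pytest.approx(s2a)
        assert res.sigma2_within == pytest.approx(s2w)
        assert res.pct_among == pytest.approx(pct)

    def test_invariant_to_sample_reordering(self):
        d = self.toy_matrix(seed=7)
        labels = ["p", "q", "p", "q", "r", "r"]
        res1 = amova(d, labels, n_perm=0)
        p = np.random.default_rng(1).permutation(6)
        res2 = amova(d[np.ix_(p, p)], [labels[i] for i in p], n_perm=0)
        assert res1.pct_among == pytest.approx(res2.pct_among)
        assert res1.phi_st == pytest.approx(res2.phi_st)

    def test_percentage_invariant_to_distance_scaling(self):
        d = self.toy_matrix(seed=9)
        labels = ["p", "p", "p", "q", "q", "q"]
        r1 = amova(d, labels, n_perm=0)
        r2 = amova(5.0 * d, labels, n_perm=0)
        assert r1.pct_among == pytest.approx(r2.pct_among)

    def test_exhaustive_permutation_p_value_on_toy(self):
        """Permutation p approximates the exact label-permutation null."""
        d = self.toy_matrix(seed=11, n=5)
        labels = ["p", "p", "p", "q", "q"]
        res = amova(d, labels, n_perm=4000, seed=0)
        # exact: evaluate Phi over all distinct label arrangements
        phis = []
        for combo in itertools.permutations(range(5)):
            perm_labels = [labels[i] for i in combo]
            s2a, s2w, _ = brute_force_amova(d, perm_labels)
            phis.append(s2a / (s2a + s2w))
        obs = res.phi_st
        exact = np.mean([p >= obs for p in phis])
        assert abs(res.p_value - exact) < 3 * math.sqrt(exact * (1 - exact) / 4000) + 1e-3

    def test_single_group_rejected(self):
        d = self.toy_matrix()
        with pytest.raises(ValueError, match="2 groups"):
            amova(d, ["p"] * 6, n_perm=0)

    def test_homogeneous_data_gives_small_component(self):
        rng = np.random.default_rng(12)
        a = rng.random((20, 20)) * 0.01
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        labels = ["p"] * 10 + ["q"] * 10
        res = amova(d, labels, n_perm=300, seed=0)
        assert abs(res.pct_among) < 15.0
        assert res.p_value > 0.01
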