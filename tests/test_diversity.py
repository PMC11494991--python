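import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.ordination import pcoa as skbio_pcoa

from gmrc_screen.diversity import (
    alpha_diversity,
    anosim,
    bray_curtis,
    fb_ratio,
    pcoa,
    rarefaction_expected,
    top_genera,
)
from gmrc_screen.tables import TaxonomyMap

from conftest import make_table


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "counts, observed, chao1, shannon",
        [
            ((1, 1, 1, 1), 4, 10.0, math.log(4)),       # F1=4, F2=0
            ((5, 3, 1, 1, 2), 5, 5.5, None),            # F1=2, F2=1
            ((7,), 1, 1.0, 0.0),
        ],
    )
    def test_hand_values(self, counts, observed, chao1, shannon):
        rec = alpha_diversity(make_table(np.array(counts)[:, None])).iloc[0]
        assert rec["observed"] == observed
        assert rec["chao1"] == pytest.approx(chao1, abs=1e-12)
        if shannon is not None:
            assert rec["shannon"] == pytest.approx(shannon, abs=1e-12)

    def test_invariants_on_random_tables(self):
        rng = np.random.default_rng(3)
        ft = make_table(rng.integers(0, 40, size=(30, 8)) * rng.integers(0, 2, size=(30, 8)))
        rec = alpha_diversity(ft)
        assert (rec["chao1"] >= rec["observed"] - 1e-9).all()
        assert (rec["shannon"] >= 0).all()
        assert (rec["shannon"] <= np.log(rec["observed"]) + 1e-9).all()

    def test_empty_sample_named(self):
        with pytest.raises(ValueError, match="s1"):
            alpha_diversity(make_table([[1, 0], [1, 0]]))


class TestRarefaction:
    def test_two_singletons_depth_one(self):
        assert rarefaction_expected(np.array([1, 1]), 1) == pytest.approx(1.0, abs=1e-12)

    def test_full_depth_recovers_observed(self):
        x = np.array([5, 3, 9, 1])
        assert rarefaction_expected(x, int(x.sum())) == pytest.approx(4.0, abs=1e-12)

    def test_monotone_in_depth(self):
        x = np.array([10, 5, 2, 1, 1])
        vals = [rarefaction_expected(x, n) for n in range(0, 20)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_matches_monte_carlo_subsampling(self):
        rng = np.random.default_rng(4)
        x = rng.integers(1, 30, size=12)
        depth, reps = 10, 50_000
        draws = rng.multivariate_hypergeometric(x, depth, size=reps)
        richness = (draws > 0).sum(axis=1)
        mc, se = richness.mean(), richness.std(ddof=1) / math.sqrt(reps)
        assert rarefaction_expected(x, depth) == pytest.approx(mc, abs=3 * se)

    def test_depth_beyond_library_errors(self):
        with pytest.raises(ValueError):
            rarefaction_expected(np.array([1, 1]), 3)


def brute_force_bray_curtis(rel: np.ndarray) -> np.ndarray:
    n = rel.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(abs(rel[t, i] - rel[t, j]) for t in range(rel.shape[0]))
            den = sum(rel[t, i] + rel[t, j] for t in range(rel.shape[0]))
            d[i, j] = num / den if den else 0.0
    return d


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        dm = bray_curtis(make_table([[2, 2, 0], [1, 1, 0], [0, 0, 3]]))
        assert dm[0, 1] == pytest.approx(0.0, abs=1e-15)
        assert dm[0, 2] == pytest.approx(1.0, abs=1e-15)

    def test_hand_value(self):
        dm = bray_curtis(make_table([[2, 0], [2, 2], [0, 2]]))
        assert dm[0, 1] == pytest.approx(0.5, abs=1e-15)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            ft = make_table(rng.integers(0, 50, size=(10, 20)) + (rng.uniform(size=(10, 20)) < 0.2))
            rel = ft.relative_abundance().to_numpy()
            np.testing.assert_allclose(
                bray_curtis(ft).data, brute_force_bray_curtis(rel), atol=1e-12
            )


class TestPCoA:
    def test_three_collinear_points(self):
        d = DistanceMatrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids=list("abc"))
        res = pcoa(d)
        np.testing.assert_allclose(res.eigenvalues, [2.0, 0.0, 0.0], atol=1e-12)
        axis1 = res.coordinates["PC1"].to_numpy()
        assert np.allclose(axis1, [-1, 0, 1], atol=1e-9) or np.allclose(
            axis1, [1, 0, -1], atol=1e-9
        )

    def test_two_identical_samples(self):
        res = pcoa(DistanceMatrix([[0, 0], [0, 0]], ids=["a", "b"]))
        np.testing.assert_allclose(res.coordinates.to_numpy(), 0.0, atol=1e-12)

    def test_euclidean_self_consistency(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 2))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(12)]))
        c = res.coordinates.to_numpy()
        d_rec = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        np.testing.assert_allclose(d_rec, d, atol=1e-8)
        assert res.n_negative == 0

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(7)
        ft = make_table(rng.integers(1, 60, size=(15, 7)))
        dm = bray_curtis(ft)
        ours = pcoa(dm)
        ref = skbio_pcoa(dm, method="eigh")
        lam_ref = ref.eigvals.to_numpy()
        lam_ref = lam_ref[lam_ref > 1e-10]
        np.testing.assert_allclose(
            ours.eigenvalues[: len(lam_ref)], lam_ref, atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates.iloc[:, 0].to_numpy()),
            np.abs(ref.samples.iloc[:, 0].to_numpy()),
            atol=1e-8,
        )


class TestAnosim:
    @staticmethod
    def _toy():
        # two tight pairs far apart
        d = np.full((4, 4), 0.9)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        return DistanceMatrix(d, ids=list("wxyz")), ["A", "A", "B", "B"]

    def test_perfect_separation_r_and_exhaustive_p(self):
        dm, labels = self._toy()
        r, p = anosim(dm, labels, n_perm=999, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_exhaustive_p_ignores_seed(self):
        dm, labels = self._toy()
        assert anosim(dm, labels, seed=1) == anosim(dm, labels, seed=99)

    def test_null_r_centered_near_zero(self):
        rng = np.random.default_rng(8)
        n = 10
        pts = rng.normal(size=(n, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(n)])
        rs = []
        for s in range(40):
            labels = rng.permutation(["A"] * 5 + ["B"] * 5)
            r, _ = anosim(dm, list(labels), n_perm=99, seed=s)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1

    def test_r_statistic_matches_skbio(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(9, 3))
        pts[:4] += 1.5
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(9)])
        labels = ["A"] * 4 + ["B"] * 5
        r, _ = anosim(dm, labels, n_perm=99, seed=0)
        ref = skbio_anosim(dm, grouping=np.array(labels), permutations=0)
        assert r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_single_group_errors(self):
        dm, _ = self._toy()
        with pytest.raises(ValueError, match="2 groups"):
            anosim(dm, ["A"] * 4)


class TestFBRatioAndTopGenera:
    def test_fb_hand_values(self):
        tax = TaxonomyMap(
            {
                "f1": ("k__B", "p__Firmicutes", "c", "o", "f", "g__f1"),
                "b1": ("k__B", "p__Bacteroidetes", "c", "o", "f", "g__b1"),
            }
        )
        ft = make_table([[60, 0], [30, 30]], taxa=["f1", "b1"])
        r = fb_ratio(ft, tax)
        assert r["s0"] == pytest.approx(2.0)
        assert r["s1"] == pytest.approx(0.0)

    def test_phylum_synonyms_unified(self):
        tax = TaxonomyMap(
            {
                "f1": ("k__B", "p__Bacillota", "c", "o", "f", "g__f1"),
                "b1": ("k__B", "p__Bacteroidota", "c", "o", "f", "g__b1"),
            }
        )
        r = fb_ratio(make_table([[10], [5]], taxa=["f1", "b1"]), tax)
        assert r["s0"] == pytest.approx(2.0)

    def test_zero_bacteroidetes_is_inf_with_warning(self):
        tax = TaxonomyMap(
            {
                "f1": ("k__B", "p__Firmicutes", "c", "o", "f", "g__f1"),
                "b1": ("k__B", "p__Bacteroidota", "c", "o", "f", "g__b1"),
            }
        )
        with pytest.warns(UserWarning, match="undefined"):
            r = fb_ratio(make_table([[10], [0]], taxa=["f1", "b1"]), tax)
        assert np.isinf(r["s0"])

    def test_top_genera_brute_force_and_ties(self):
        rng = np.random.default_rng(10)
        counts = rng.integers(0, 100, size=(5, 4))
        ft = make_table(counts, taxa=list("edcba"))
        got = top_genera(ft, 3)
        means = ft.relative_abundance().mean(axis=1)
        expect = sorted(means.index, key=lambda t: (-means[t], t))[:3]
        assert got == expect
        # exact tie broken lexicographically
        tied = make_table([[5, 5], [5, 5], [1, 1]], taxa=["b", "a", "c"])
        assert top_genera(tied, 2) == ["a", "b"]

    def test_k_truncated_to_available(self):
        ft = make_table([[1], [2]])
        assert len(top_genera(ft, 10)) == 2
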