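"""AMOVA variance partition, permutation test and diversity indices."""

import math

import numpy as np
import pandas as pd
import pytest

import indelpop as ip
from indelpop.io import BandMatrix, ComputationError, ValidationError

from conftest import make_panel


def random_band_matrix(rng, n_samples, n_bands, mask_rate=0.0) -> BandMatrix:
    values = rng.integers(0, 2, size=(n_samples, n_bands)).astype(np.int8)
    mask = rng.random((n_samples, n_bands)) < mask_rate
    # keep every pair comparable: first column always unmasked
    mask[:, 0] = False
    return BandMatrix(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        band_ids=[f"b{j}" for j in range(n_bands)],
        values=values,
        mask=mask,
        band_marker=[f"m{j}" for j in range(n_bands)],
    )


def brute_force_ss(d2: np.ndarray, groups: list[list[int]]) -> tuple[float, float]:
    """Independent double-loop evaluation of the AMOVA sums of squares."""
    n = d2.shape[0]
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d2[i, j]
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        acc = 0.0
        for a in range(len(g)):
            for b in range(a + 1, len(g)):
                acc += d2[g[a], g[b]]
        ss_within += acc / len(g)
    return ss_total, ss_within


class TestBandDistance:
    def test_identical_rows_distance_zero(self, rng):
        bm = random_band_matrix(rng, 3, 6)
        bm.values[1] = bm.values[0]
        d = ip.band_sq_distance(bm)
        assert d.data[0, 1] == 0.0

    def test_fully_opposed_rows(self):
        bm = BandMatrix(["a", "b"], ["b1", "b2", "b3", "b4"],
                        np.array([[1, 0, 1, 0], [0, 1, 0, 1]]),
                        np.zeros((2, 4), bool), ["m1", "m1", "m2", "m2"])
        assert ip.band_sq_distance(bm).data[0, 1] == 4.0

    def test_partial_mismatch_counts_columns(self):
        bm = BandMatrix(["a", "b"], ["b1", "b2", "b3"],
                        np.array([[1, 1, 0], [1, 0, 1]]),
                        np.zeros((2, 3), bool), ["m"] * 3)
        assert ip.band_sq_distance(bm).data[0, 1] == 2.0

    def test_masked_columns_excluded_pairwise(self):
        values = np.array([[1, 0], [0, 0]])
        mask = np.array([[False, True], [False, False]])
        bm = BandMatrix(["a", "b"], ["b1", "b2"], values, mask, ["m1", "m2"])
        assert ip.band_sq_distance(bm).data[0, 1] == 1.0

    def test_no_shared_columns_is_an_error(self):
        mask = np.array([[False, True], [True, False]])
        bm = BandMatrix(["a", "b"], ["b1", "b2"],
                        np.ones((2, 2), dtype=np.int8), mask, ["m1", "m2"])
        with pytest.raises(ComputationError, match="'a'.*'b'"):
            ip.band_sq_distance(bm)


class TestAmovaOracle:
    @pytest.mark.parametrize("n_samples, seed", [(4, 0), (6, 1), (8, 2), (8, 3)])
    def test_grouped_formulas_match_double_loop(self, n_samples, seed):
        rng = np.random.default_rng(seed)
        bm = random_band_matrix(rng, n_samples, 12, mask_rate=0.05)
        d = ip.band_sq_distance(bm)
        labels = ["p1"] * (n_samples // 2) + ["p2"] * (n_samples - n_samples // 2)
        res = ip.amova(d, labels, n_perm=0)
        groups = [
            [i for i, l in enumerate(labels) if l == "p1"],
            [i for i, l in enumerate(labels) if l == "p2"],
        ]
        ss_total, ss_within = brute_force_ss(d.data, groups)
        assert res.ss_total == pytest.approx(ss_total, abs=1e-9)
        assert res.ss_within == pytest.approx(ss_within, abs=1e-9)
        assert res.ss_among == pytest.approx(ss_total - ss_within, abs=1e-9)

    def test_ss_additivity_and_df_bookkeeping(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 16))
            bm = random_band_matrix(rng, n, 10)
            d = ip.band_sq_distance(bm)
            k = int(rng.integers(2, 4))
            labels = [f"p{i % k}" for i in range(n)]
            if min(labels.count(f"p{i}") for i in range(k)) < 2:
                continue
            res = ip.amova(d, labels, n_perm=0)
            assert res.ss_among + res.ss_within == pytest.approx(res.ss_total)
            assert res.df_among + res.df_within == n - 1
            assert res.pct_among + res.pct_within == pytest.approx(100.0)
            assert res.phi_pt == pytest.approx(res.va / (res.va + res.vw))


class TestAmovaBehaviour:
    def test_fixed_differences_give_phi_one(self):
        markers = [ip.MarkerDef(f"M{k}", 1, (200 + k, 150 + k), 200 + k,
                                150 + k, 50) for k in range(6)]
        rows = {f"i{n}": ["II"] * 6 for n in range(4)}
        rows |= {f"j{n}": ["JJ"] * 6 for n in range(4)}
        g = make_panel(rows, markers)
        d = ip.band_sq_distance(ip.to_band_matrix(g))
        labels = ["p1"] * 4 + ["p2"] * 4
        res = ip.amova(d, labels, n_perm=999, seed=0)
        assert res.phi_pt == pytest.approx(1.0)
        assert res.vw == 0.0
        # only the exact split (or its mirror) reaches phi = 1 under
        # permutation: 2 of the 70 equally likely 4+4 assignments
        assert res.perm_p < 0.06

    def test_singleton_population_rejected(self, rng):
        bm = random_band_matrix(rng, 5, 8)
        d = ip.band_sq_distance(bm)
        with pytest.raises(ValidationError, match="fewer than 2"):
            ip.amova(d, ["a", "a", "a", "a", "b"], n_perm=0)

    def test_no_permutations_leaves_p_absent(self, rng):
        bm = random_band_matrix(rng, 6, 8)
        d = ip.band_sq_distance(bm)
        res = ip.amova(d, ["a"] * 3 + ["b"] * 3, n_perm=0)
        assert res.perm_p is None

    def test_phi_invariant_to_relabeling_and_order(self, rng):
        bm = random_band_matrix(rng, 10, 12)
        d = ip.band_sq_distance(bm)
        labels = ["a"] * 5 + ["b"] * 5
        res1 = ip.amova(d, labels, n_perm=0)
        res2 = ip.amova(d, ["b"] * 5 + ["a"] * 5, n_perm=0)
        assert res1.phi_pt == pytest.approx(res2.phi_pt)
        perm = rng.permutation(10)
        d_perm = ip.DistanceMatrix(
            ids=[d.ids[i] for i in perm], data=d.data[np.ix_(perm, perm)],
            metric=d.metric,
        )
        res3 = ip.amova(d_perm, [labels[i] for i in perm], n_perm=0)
        assert res1.phi_pt == pytest.approx(res3.phi_pt)

    def test_permutation_p_reproducible_under_seed(self, rng):
        bm = random_band_matrix(rng, 12, 14)
        d = ip.band_sq_distance(bm)
        labels = ["a"] * 6 + ["b"] * 6
        p1 = ip.amova(d, labels, n_perm=200, seed=42).perm_p
        p2 = ip.amova(d, labels, n_perm=200, seed=42).perm_p
        assert p1 == p2

    def test_phi_increases_with_divergence_gradient(self):
        """Phi_PT rank-orders with the generating allele-frequency gap."""
        phis = []
        for alpha in (6.0, 12.0, 18.0):
            cfg = ip.SimPanelConfig(
                populations=(
                    ip.PopulationSpec("p1", 20, 2.0, 18.0),
                    ip.PopulationSpec("p2", 20, alpha, 20.0 - alpha),
                ),
                seed=3,
            )
            g, _ = ip.simulate_panel(cfg)
            d = ip.band_sq_distance(ip.to_band_matrix(g))
            labels = g.sample_meta["population"]
            phis.append(ip.amova(d, labels, n_perm=0).phi_pt)
        assert phis[0] < phis[1] < phis[2]

    def test_phi_from_printed_components(self):
        assert ip.phi_from_components(13.94, 7.77) == pytest.approx(0.642, abs=5e-4)
        assert ip.phi_from_components(-1.0, 5.0) == 0.0


class TestDiversity:
    def test_fixed_locus(self, biallelic_markers):
        g = make_panel({f"s{i}": ["II"] for i in range(10)}, biallelic_markers[:1])
        stats = ip.diversity_stats(g, ["pop"] * 10)[0]
        row = stats.per_locus.iloc[0]
        assert row["na"] == 1 and row["ne"] == 1.0
        assert row["i"] == 0.0 and row["he"] == 0.0

    def test_balanced_locus_closed_forms(self, biallelic_markers):
        rows = {f"s{i}": ["II" if i < 5 else "JJ"] for i in range(10)}
        g = make_panel(rows, biallelic_markers[:1])
        stats = ip.diversity_stats(g, ["pop"] * 10)[0]
        row = stats.per_locus.iloc[0]
        assert row["ne"] == pytest.approx(2.0)
        assert row["i"] == pytest.approx(math.log(2))
        assert row["he"] == pytest.approx(0.5)
        assert row["uhe"] == pytest.approx(20 / 19 * 0.5)

    def test_invariants_on_simulated_panel(self, preset_panel):
        g, _ = preset_panel
        labels = g.sample_meta["population"]
        for stats in ip.diversity_stats(g, labels):
            pl = stats.per_locus
            assert (pl["ne"] <= pl["na"] + 1e-12).all()
            assert ((0 <= pl["he"]) & (pl["he"] <= 1)).all()
            assert (pl["uhe"] >= pl["he"] - 1e-12).all()
            assert (stats.se[["na", "ne", "i", "he", "uhe"]] >= 0).all()

    def test_misaligned_partition_rejected(self, biallelic_markers):
        g = make_panel({"s1": ["II"], "s2": ["II"]}, biallelic_markers[:1])
        with pytest.raises(ValidationError, match="length"):
            ip.diversity_stats(g, ["a", "a", "b"])
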