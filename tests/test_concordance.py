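"""DEG concordance, TSS-window annotation, Fisher/binomial oracles, ORA/GSEA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gastrufate import concordance as cc


class TestDegOverlap:
    def test_identical_sets_full_overlap(self):
        uni = [f"g{i}" for i in range(50)]
        degs = {g: ("up" if i % 2 else "down") for i, g in enumerate(uni[:20])}
        rep = cc.deg_overlap(degs, dict(degs), uni)
        assert rep.loc["up", "percent"] == 100.0
        assert rep.loc["down", "percent"] == 100.0

    def test_worked_binomial_toy(self):
        """Universe 100, external-up 20, self-up 10 with 8 overlapping:
        percent = 80 and p = P(Bin(10, 0.2) >= 8)."""
        uni = [f"g{i}" for i in range(100)]
        external = {g: "up" for g in uni[:20]}
        self_degs = {g: "up" for g in uni[12:22]}  # overlap = g12..g19 -> 8
        rep = cc.deg_overlap(self_degs, external, uni)
        assert rep.loc["up", "n_overlap"] == 8
        assert rep.loc["up", "percent"] == pytest.approx(80.0)
        # closed-form tail: sum_{j>=8} C(10,j) 0.2^j 0.8^(10-j)
        closed = sum(math.comb(10, j) * 0.2 ** j * 0.8 ** (10 - j)
                     for j in range(8, 11))
        assert rep.loc["up", "binomial_p"] == pytest.approx(closed, rel=1e-12)
        assert closed == pytest.approx(7.79e-5, rel=0.01)

    @pytest.mark.parametrize("n,k,p0", [(5, 2, 0.3), (12, 7, 0.5), (30, 3, 0.1)])
    def test_binomial_tail_matches_closed_form(self, n, k, p0):
        """Binomial p equals an explicit tail sum for small n."""
        closed = sum(math.comb(n, j) * p0 ** j * (1 - p0) ** (n - j)
                     for j in range(k, n + 1))
        assert stats.binom.sf(k - 1, n, p0) == pytest.approx(closed, rel=1e-12)

    def test_null_uniform_overlap(self):
        rng = np.random.default_rng(0)
        uni = [f"g{i}" for i in range(500)]
        external = {g: "up" for g in uni[:50]}  # 10% density
        pcts = []
        for _ in range(30):
            picks = rng.choice(uni, size=60, replace=False)
            rep = cc.deg_overlap({g: "up" for g in picks}, external, uni)
            pcts.append(rep.loc["up", "percent"])
        assert abs(np.mean(pcts) - 10.0) < 3.0

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            cc.deg_overlap({}, {}, [])


class TestFoldchangeRegression:
    def test_identity_slope_one(self):
        lfc = {f"g{i}": float(i) / 10 - 1 for i in range(30)}
        res = cc.foldchange_regression(lfc, dict(lfc))
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert res["r"] == pytest.approx(1.0)

    def test_halved_effects_slope_half(self):
        ext = {f"g{i}": float(i) - 5 for i in range(11)}
        mine = {g: 0.5 * v for g, v in ext.items()}
        res = cc.foldchange_regression(mine, ext)
        assert res["slope"] == pytest.approx(0.5)

    def test_noisy_attenuated_slope_recovered(self):
        rng = np.random.default_rng(1)
        slopes = []
        for _ in range(50):
            x = rng.normal(0, 1, 500)
            y = 0.8 * x + rng.normal(0, 0.3, 500)
            ext = {f"g{i}": x[i] for i in range(500)}
            mine = {f"g{i}": y[i] for i in range(500)}
            slopes.append(cc.foldchange_regression(mine, ext)["slope"])
        assert abs(np.mean(slopes) - 0.8) < 0.05

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError, match="variance"):
            cc.foldchange_regression({"a": 1.0, "b": 2.0, "c": 3.0},
                                     {"a": 1.0, "b": 1.0, "c": 1.0})


class TestTssAnnotation:
    def _gm(self, chrom, strand, start, end):
        return pd.DataFrame({"chromosome": [chrom], "strand": [strand],
                             "start": [start], "end": [end]}, index=["g"])

    def _peaks(self, chrom, start, end):
        return pd.DataFrame({"chromosome": [chrom], "start": [start],
                             "end": [end]})

    def test_peak_covering_tss(self):
        ann = cc.annotate_tss_peaks(self._gm("chr1", "+", 1000, 2000),
                                    self._peaks("chr1", 990, 1010))
        assert ann.loc["g", "has_site"]

    def test_boundary_distance_250_hits_251_misses_plus_strand(self):
        gm = self._gm("chr1", "+", 1000, 2000)  # TSS = 1000
        # peak ending at base 750 (half-open end 751): distance 250 -> hit
        assert cc.annotate_tss_peaks(gm, self._peaks("chr1", 700, 751)).loc["g", "has_site"]
        # peak ending at base 749: distance 251 -> miss
        assert not cc.annotate_tss_peaks(gm, self._peaks("chr1", 700, 750)).loc["g", "has_site"]
        # downstream: window closes at 1250
        assert cc.annotate_tss_peaks(gm, self._peaks("chr1", 1250, 1300)).loc["g", "has_site"]
        assert not cc.annotate_tss_peaks(gm, self._peaks("chr1", 1251, 1300)).loc["g", "has_site"]

    def test_minus_strand_tss_arithmetic(self):
        # minus-strand gene [1000, 2000): TSS = 1999; peak [2200, 2260)
        gm = self._gm("chr2", "-", 1000, 2000)
        assert cc.annotate_tss_peaks(gm, self._peaks("chr2", 2200, 2260)).loc["g", "has_site"]
        # first covered base 2250 sits exactly at 1999 + 251 -> miss
        assert not cc.annotate_tss_peaks(gm, self._peaks("chr2", 2250, 2300)).loc["g", "has_site"]
        # first covered base 2249 at distance 250 -> hit
        assert cc.annotate_tss_peaks(gm, self._peaks("chr2", 2249, 2300)).loc["g", "has_site"]

    def test_unknown_chromosome_warns(self):
        gm = self._gm("chr1", "+", 1000, 2000)
        with pytest.warns(UserWarning, match="absent"):
            cc.annotate_tss_peaks(gm, self._peaks("chrUn", 0, 100))


class TestFisher:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_hypergeometric_enumeration(self, seed):
        """One-sided Fisher p equals brute-force enumeration over all more
        extreme tables with the same margins (N <= 50)."""
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 13, size=4)
        N = a + b + c + d
        row1, col1 = a + b, a + c
        # enumerate all feasible values of the top-left cell
        lo = max(0, row1 + col1 - N)
        hi = min(row1, col1)
        def table_p(x):
            return (math.comb(col1, x) * math.comb(N - col1, row1 - x)
                    / math.comb(N, row1))
        brute = sum(table_p(x) for x in range(a, hi + 1))
        _, p = cc.fisher_one_sided(np.array([[a, b], [c, d]]))
        assert p == pytest.approx(brute, rel=1e-9)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="margin"):
            _, p = cc.fisher_one_sided(np.array([[0, 0], [5, 5]]))
        assert p == 1.0

    def test_binding_site_enrichment_null_calibrated(self):
        rng = np.random.default_rng(2)
        uni = [f"g{i}" for i in range(200)]
        ann = pd.DataFrame({"has_site": rng.random(200) < 0.3,
                            "n_sites": 0}, index=uni)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            deg = {g: bool(r) for g, r in zip(uni, rng.random(200) < 0.2)}
            res = cc.binding_site_enrichment(deg, ann, uni)
            rejections += res["p"] < 0.05
        assert rejections / n_rep <= 0.06


class TestOra:
    def test_full_set_is_most_enriched(self):
        uni = [f"g{i}" for i in range(300)]
        sets = {"hit": uni[:20], "other": uni[100:140]}
        res = cc.ora(uni[:20], sets, uni)
        assert res["p"].idxmin() == "hit"
        assert res.loc["hit", "Q"] < 0.05

    def test_random_genes_rarely_significant(self):
        rng = np.random.default_rng(3)
        uni = [f"g{i}" for i in range(400)]
        sets = {f"s{j}": list(rng.choice(uni, 30, replace=False))
                for j in range(10)}
        n_sig = 0
        for _ in range(30):
            goi = rng.choice(uni, 40, replace=False)
            res = cc.ora(list(goi), sets, uni)
            n_sig += int((res["Q"] < 0.05).sum())
        assert n_sig <= 3

    def test_shares_hypergeometric_kernel_with_binding_enrichment(self):
        uni = [f"g{i}" for i in range(25)]
        goi = uni[:10]
        members = uni[:1] + uni[10:19]  # a=1, b=9, c=9... construct 2x2
        res = cc.ora(goi, {"s": members}, uni)
        a = len(set(goi) & set(members))
        b = len(set(goi) - set(members))
        c = len(set(members) - set(goi))
        d = 25 - a - b - c
        _, p = cc.fisher_one_sided(np.array([[a, b], [c, d]]))
        assert res.loc["s", "p"] == pytest.approx(p)


class TestGsea:
    def _stat(self, n=100, seed=4):
        rng = np.random.default_rng(seed)
        vals = np.sort(rng.normal(size=n))[::-1]
        return {f"g{i}": float(vals[i]) for i in range(n)}

    def test_top_ranked_set_maximally_enriched(self):
        stat = self._stat()
        genes = list(stat)
        res = cc.gsea(stat, {"top": genes[:10]}, n_perm=200, seed=0)
        assert res.loc["top", "ES"] > 0
        # minimal attainable p given the sign-conditional permutation null
        assert res.loc["top", "p"] <= 2 / (200 * 0.3)

    def test_reversed_ranking_flips_es_sign(self):
        stat = self._stat()
        flipped = {g: -v for g, v in stat.items()}
        sets = {"s": list(stat)[5:25]}
        a = cc.gsea(stat, sets, n_perm=100, seed=1)
        b = cc.gsea(flipped, sets, n_perm=100, seed=1)
        assert np.sign(a.loc["s", "ES"]) == -np.sign(b.loc["s", "ES"])

    def test_random_sets_null_calibrated(self):
        rng = np.random.default_rng(5)
        stat = self._stat(n=150, seed=6)
        genes = list(stat)
        ps = []
        for j in range(25):
            members = rng.choice(genes, 15, replace=False)
            res = cc.gsea(stat, {"s": list(members)}, n_perm=200, seed=j)
            ps.append(res.loc["s", "p"])
        # uniform-ish p-values: no mass collapse at the extremes
        assert (np.array(ps) < 0.05).mean() <= 0.2
        assert np.mean(ps) == pytest.approx(0.5, abs=0.2)

    def test_small_sets_skipped_and_nonfinite_rejected(self):
        stat = self._stat()
        res = cc.gsea(stat, {"tiny": list(stat)[:3]}, n_perm=50, seed=0)
        assert len(res) == 0
        bad = dict(stat)
        bad["g0"] = float("nan")
        with pytest.raises(ValueError, match="finite"):
            cc.gsea(bad, {"s": list(stat)[:10]}, n_perm=50, seed=0)
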