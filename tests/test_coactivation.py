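import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromatlas.atlas import TSSRecord
from chromatlas.coactivation import (
    assign_closest,
    correlate_pairs,
    filter_significant_pairs,
    pooled_spearman,
    promoter_mark_expression_corr,
    quantile_normalize,
    resampling_pvalue,
)
from chromatlas.genomic import GenomicInterval, ValidationError


class TestQuantileNormalize:
    def test_worked_example(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [4, 5, 6]})
        out = quantile_normalize(df)
        assert list(out["a"]) == [2.5, 3.5, 4.5]
        assert list(out["b"]) == [2.5, 3.5, 4.5]

    def test_identical_columns_fixed_point(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(df)
        assert np.allclose(out.values, df.values)

    def test_columns_share_sorted_multiset(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((50, 4)))
        out = quantile_normalize(df)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 4):
            assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)

    def test_ties_get_rank_range_mean(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [10.0, 20.0, 30.0]})
        out = quantile_normalize(df)
        assert out["a"][0] == out["a"][1]
        means = np.sort(df.values, axis=0).mean(axis=1)
        assert out["a"][0] == pytest.approx(means[:2].mean())

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((30, 3)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert np.allclose(once.values, twice.values)


class TestPromoterExpressionCorr:
    def _mats(self, cov, ex):
        cols = [f"s{j}" for j in range(cov.shape[1])]
        ids = [f"t{i}" for i in range(cov.shape[0])]
        return (pd.DataFrame(cov, index=ids, columns=cols),
                pd.DataFrame(ex, index=ids, columns=cols),
                {f"t{i}": f"g{i}" for i in range(cov.shape[0])})

    def test_monotone_gives_r_one(self):
        cov = np.arange(12.0).reshape(4, 3)
        ex = cov ** 2 + 1
        c, e, gmap = self._mats(cov, ex)
        res, _ = promoter_mark_expression_corr(c, e, gmap)
        assert res.spearman_r == pytest.approx(1.0)

    def test_average_rank_ties(self):
        r = pooled_spearman(np.array([1, 2, 2, 3]), np.array([10, 20, 20, 40]))
        assert r == pytest.approx(1.0)

    def test_planted_rho_recovered(self):
        # 2,000 (promoter, sample) points with planted Spearman 0.6
        rng = np.random.default_rng(2)
        n_t, n_s = 250, 8
        lat = 2 * math.sin(math.pi * 0.6 / 6)
        z = rng.standard_normal((n_t, n_s))
        x = stats.norm.cdf(z)
        y = stats.norm.cdf(lat * z + math.sqrt(1 - lat ** 2)
                           * rng.standard_normal((n_t, n_s)))
        c, e, gmap = self._mats(x * 100, y * 1000)
        res, summary = promoter_mark_expression_corr(c, e, gmap)
        assert res.spearman_r == pytest.approx(0.6, abs=0.05)
        # quantile summaries increase in coverage with expression
        assert summary["mean_coverage"].is_monotonic_increasing

    def test_transcript_selection_per_gene(self):
        cov = pd.DataFrame({"s0": [1.0, 9.0], "s1": [2.0, 8.0]},
                           index=["t1", "t2"])
        ex = pd.DataFrame({"s0": [5.0, 7.0], "s1": [6.0, 8.0]},
                          index=["t1", "t2"])
        res, _ = promoter_mark_expression_corr(cov, ex, {"t1": "g", "t2": "g"})
        # only the higher-coverage transcript (t2) survives: 2 points
        assert res.n_pairs == 2


class TestAssignClosest:
    def tssrec(self, tid, pos, chrom="chr1"):
        return TSSRecord(tid, f"g_{tid}", chrom, "+", pos)

    def test_nearest_and_stratum_boundaries(self):
        enh = [GenomicInterval("chr1", 10_000, 11_000, name="e")]
        recs = [self.tssrec("t1", 15_000), self.tssrec("t2", 40_000)]
        df = assign_closest(enh, recs)
        row = df.iloc[0]
        assert (row.transcript_id, row.distance, row.stratum) == \
            ("t1", 4000.0, "proximal")

    @pytest.mark.parametrize("dist,stratum", [
        (19_999, "proximal"), (20_000, "mid"), (200_000, "mid"),
        (200_001, "distal"), (250_000, "distal"),
    ])
    def test_stratum_boundary_rules(self, dist, stratum):
        enh = [GenomicInterval("chr1", 1000, 2000, name="e")]
        df = assign_closest(enh, [self.tssrec("t", 2000 + dist)])
        assert df.iloc[0].stratum == stratum

    def test_chromosome_without_transcripts(self):
        enh = [GenomicInterval("chr2", 0, 1000, name="e")]
        df = assign_closest(enh, [self.tssrec("t", 500)])
        row = df.iloc[0]
        assert np.isnan(row.distance) and row.stratum == "distal"

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        recs = [self.tssrec(f"t{i}", int(p))
                for i, p in enumerate(np.sort(rng.integers(0, 1_000_000, 60)))]
        enh = [GenomicInterval("chr1", int(s), int(s) + 500, name=f"e{k}")
               for k, s in enumerate(rng.integers(0, 999_000, 40))]
        df = assign_closest(enh, recs).set_index("enhancer_id")
        for e in enh:
            def dist(r):
                if e.start <= r.tss < e.end:
                    return 0
                return e.start - r.tss if r.tss < e.start else r.tss - e.end
            best = min(recs, key=lambda r: (dist(r), r.tss))
            assert df.at[e.name, "transcript_id"] == best.transcript_id
            assert df.at[e.name, "distance"] == dist(best)


class TestCorrelatePairs:
    def test_contact_multi_promoter_mean(self):
        pairs = pd.DataFrame({
            "enhancer_id": ["e", "e"], "transcript_id": ["t1", "t2"],
            "distance": [1e4, 2e4], "source": "contact", "stratum": "mid",
        })
        cov = pd.DataFrame({"s1": [5.0], "s2": [1.0]}, index=["e"])
        expr = pd.DataFrame({"s1": [10.0, 30.0], "s2": [2.0, 4.0]},
                            index=["t1", "t2"])
        from chromatlas.coactivation import _pair_points
        x, y, n = _pair_points(pairs, cov, expr)
        assert n == 2
        assert list(y) == [20.0, 3.0]  # mean of contacted transcripts

    def test_rank_identical_group_r_one(self):
        pairs = pd.DataFrame({
            "enhancer_id": ["e1", "e2"], "transcript_id": ["t1", "t2"],
            "distance": 1e4, "source": "closest", "stratum": "proximal",
        })
        cov = pd.DataFrame(np.array([[1.0, 2.0], [3.0, 4.0]]),
                           index=["e1", "e2"], columns=["s1", "s2"])
        expr = pd.DataFrame(np.array([[10.0, 20.0], [30.0, 40.0]]),
                            index=["t1", "t2"], columns=["s1", "s2"])
        res = correlate_pairs(pairs, cov, expr)
        assert len(res) == 1
        assert res[0].spearman_r == pytest.approx(1.0)

    def test_planted_group_difference(self):
        rng = np.random.default_rng(4)
        n_pairs, n_s = 150, 10
        lat = 2 * math.sin(math.pi * 0.5 / 6)
        z = rng.standard_normal((n_pairs, n_s))
        y_corr = lat * z + math.sqrt(1 - lat ** 2) * \
            rng.standard_normal((n_pairs, n_s))
        y_null = rng.standard_normal((n_pairs, n_s))
        eids = [f"e{i}" for i in range(n_pairs)]
        t_c = [f"tc{i}" for i in range(n_pairs)]
        t_n = [f"tn{i}" for i in range(n_pairs)]
        cov = pd.DataFrame(z, index=eids)
        expr = pd.DataFrame(np.vstack([y_corr, y_null]), index=t_c + t_n)
        pairs = pd.DataFrame({
            "enhancer_id": eids * 2, "transcript_id": t_c + t_n,
            "distance": [50_000.0] * n_pairs + [300_000.0] * n_pairs,
            "source": ["contact"] * n_pairs + ["closest"] * n_pairs,
            "stratum": ["mid"] * n_pairs + ["distal"] * n_pairs,
        })
        res = {r.label: r.spearman_r
               for r in correlate_pairs(pairs, cov, expr)}
        assert res["contact/mid"] - res["closest/distal"] == pytest.approx(
            0.5, abs=0.08)


class TestResampling:
    def _population(self, rng, n):
        eids = [f"e{i}" for i in range(n)]
        tids = [f"t{i}" for i in range(n)]
        cov = pd.DataFrame(rng.standard_normal((n, 8)), index=eids)
        expr = pd.DataFrame(rng.standard_normal((n, 8)), index=tids)
        pairs = pd.DataFrame({
            "enhancer_id": eids, "transcript_id": tids, "distance": 3e5,
            "source": "closest", "stratum": "distal",
        })
        return pairs, cov, expr

    def test_determinism(self):
        rng = np.random.default_rng(5)
        pairs, cov, expr = self._population(rng, 100)
        focal = pairs.iloc[:20]
        a = resampling_pvalue(pairs, focal, cov, expr, 20, 99, seed=11)
        b = resampling_pvalue(pairs, focal, cov, expr, 20, 99, seed=11)
        assert a == b

    def test_separation_gives_minimal_p(self):
        rng = np.random.default_rng(6)
        pairs, cov, expr = self._population(rng, 200)
        # focal pairs with strong planted correlation
        f_eids = [f"f{i}" for i in range(30)]
        f_tids = [f"ft{i}" for i in range(30)]
        z = rng.standard_normal((30, 8))
        fcov = pd.DataFrame(z, index=f_eids)
        fexpr = pd.DataFrame(z + 0.1 * rng.standard_normal((30, 8)),
                             index=f_tids)
        focal = pd.DataFrame({
            "enhancer_id": f_eids, "transcript_id": f_tids, "distance": 5e4,
            "source": "closest", "stratum": "mid",
        })
        cov_all = pd.concat([cov, fcov])
        expr_all = pd.concat([expr, fexpr])
        obs, p = resampling_pvalue(pairs, focal, cov_all, expr_all,
                                   draw_size=30, reps=500, seed=1)
        assert obs > 0.8
        assert p == pytest.approx(1 / 501)

    def test_draw_size_validation(self):
        rng = np.random.default_rng(7)
        pairs, cov, expr = self._population(rng, 10)
        with pytest.raises(ValidationError):
            resampling_pvalue(pairs, pairs, cov, expr, 11, 10, 0)


class TestFilterSignificantPairs:
    def test_gate_enumeration(self):
        # 8 pairs spanning all gate combinations
        combos = list(itertools.product([0.9, 0.5], [True, False], [25, 19]))
        n_s = 12
        rng = np.random.default_rng(8)
        rows, covs, exprs, counts = [], {}, {}, {}
        for k, (rho, low_p, max_count) in enumerate(combos):
            e, t = f"e{k}", f"t{k}"
            base = np.arange(n_s, dtype=float)
            covs[e] = base
            if rho > 0.7 and low_p:
                exprs[t] = base + 0.01 * rng.standard_normal(n_s)
            elif rho > 0.7:
                exprs[t] = base + 0.01 * rng.standard_normal(n_s)
            else:
                exprs[t] = rng.standard_normal(n_s)
            counts[t] = np.full(n_s, float(max_count))
            rows.append((e, t))
        pairs = pd.DataFrame(rows, columns=["enhancer_id", "transcript_id"])
        pairs["distance"], pairs["source"], pairs["stratum"] = 1e4, "contact", "proximal"
        cov = pd.DataFrame(covs).T
        expr = pd.DataFrame(exprs).T
        cts = pd.DataFrame(counts).T
        out = filter_significant_pairs(pairs, cov, expr, cts)
        out = out.set_index("enhancer_id")
        # brute-force gate application
        for k, (rho, low_p, max_count) in enumerate(combos):
            row = out.loc[f"e{k}"]
            want = (row.fdr < 0.1) and (row.R > 0.7) and (max_count >= 20)
            assert bool(row.kept) == want
        # strongly correlated, high-count pairs are kept
        assert out.loc["e0"].kept

    def test_count_gate_alone_drops(self):
        n_s = 12
        base = np.arange(n_s, dtype=float)
        pairs = pd.DataFrame({
            "enhancer_id": ["e1", "e2"], "transcript_id": ["t1", "t2"],
            "distance": 1e4, "source": "contact", "stratum": "proximal",
        })
        cov = pd.DataFrame([base, base], index=["e1", "e2"])
        expr = pd.DataFrame([base, base], index=["t1", "t2"])
        cts = pd.DataFrame([np.full(n_s, 25.0), np.full(n_s, 19.0)],
                           index=["t1", "t2"])
        out = filter_significant_pairs(pairs, cov, expr, cts)
        assert list(out.kept) == [True, False]

    def test_bh_monotone_in_fdr_max(self):
        rng = np.random.default_rng(9)
        n_pairs, n_s = 40, 10
        ids = [f"x{i}" for i in range(n_pairs)]
        cov = pd.DataFrame(rng.standard_normal((n_pairs, n_s)), index=ids)
        expr = pd.DataFrame(
            cov.to_numpy() * 0.8 + 0.6 * rng.standard_normal((n_pairs, n_s)),
            index=ids)
        cts = pd.DataFrame(100.0, index=ids, columns=range(n_s))
        pairs = pd.DataFrame({"enhancer_id": ids, "transcript_id": ids,
                              "distance": 1e4, "source": "contact",
                              "stratum": "proximal"})
        kept_sets = []
        for fdr_max in (0.2, 0.1, 0.05, 0.01):
            out = filter_significant_pairs(pairs, cov, expr, cts,
                                           fdr_max=fdr_max)
            kept_sets.append(set(out[out.kept].enhancer_id))
        for a, b in zip(kept_sets, kept_sets[1:]):
            assert b <= a

    def test_exact_permutation_small_n(self):
        # n = 6 samples: p from the exact permutation distribution
        base = np.arange(6, dtype=float)
        pairs = pd.DataFrame({"enhancer_id": ["e"], "transcript_id": ["t"],
                              "distance": 1e4, "source": "contact",
                              "stratum": "proximal"})
        cov = pd.DataFrame([base], index=["e"])
        expr = pd.DataFrame([base], index=["t"])
        cts = pd.DataFrame([[100.0] * 6], index=["t"])
        out = filter_significant_pairs(pairs, cov, expr, cts)
        # perfect rank agreement: 2 of 720 permutations reach |r| = 1
        assert out.p[0] == pytest.approx(2 / 720)


class TestSpearmanInvariance:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        r = pooled_spearman(x, y)
        assert pooled_spearman(np.exp(x), y) == pytest.approx(r)
        assert pooled_spearman(x, y ** 3) == pytest.approx(r)
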