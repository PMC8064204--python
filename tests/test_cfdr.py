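import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpgcfdr import (
    CFDRResult,
    GenotypePanel,
    MergedPanel,
    StratumSpec,
    call_significant,
    compute_cfdr,
    conditional_qq,
    conjunction_cfdr,
    empirical_cfdr,
    exclude_known,
    fold_enrichment,
    genomic_lambda,
    manhattan_data,
)


def brute_cfdr(p1, p2):
    """Double-loop counting oracle for the empirical cFDR."""
    n = len(p1)
    out = np.empty(n)
    for i in range(n):
        n2 = sum(p2[k] <= p2[i] for k in range(n))
        n12 = sum(p1[k] <= p1[i] and p2[k] <= p2[i] for k in range(n))
        out[i] = min(1.0, p1[i] * n2 / n12)
    return out


def panel_from_pvals(p1, p2, chrom=None):
    n = len(p1)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": chrom if chrom is not None else ["1"] * n,
            "pos": np.arange(1, n + 1) * 1000,
            "p1": p1,
            "p2": p2,
            "z1": 0.0,
            "z2": 0.0,
            "cpg_flag": True,
        }
    )
    return MergedPanel("t1", "t2", df)


class TestGenomicLambda:
    def test_half_pvalues_give_unit_lambda(self):
        assert genomic_lambda(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_uniform_null_lambda_near_one(self):
        rng = np.random.default_rng(0)
        lam = genomic_lambda(rng.random(100_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_inflated_chisquare_recovers_scaling(self):
        rng = np.random.default_rng(1)
        chi = 1.2 * rng.chisquare(1, size=200_000)
        p = stats.chi2.sf(chi, 1)
        assert genomic_lambda(p) == pytest.approx(1.2, rel=0.02)

    def test_empty_input_is_hard_error(self):
        with pytest.raises(ValueError):
            genomic_lambda(np.array([]))


class TestConditionalQQ:
    def test_uniform_grid_baseline_lies_on_diagonal(self):
        n = 2000
        p1 = (np.arange(1, n + 1)) / (n + 1)
        panel = panel_from_pvals(p1, np.full(n, 0.5), None)
        qq = conditional_qq(panel, StratumSpec((1.0,)))
        df = next(iter(qq.strata.values()))
        assert np.max(np.abs(df["nominal"] - df["empirical"])) < 1e-12

    def test_single_member_stratum_gives_single_point(self):
        p2 = np.array([0.5, 0.5, 0.0005])
        panel = panel_from_pvals(np.array([0.1, 0.2, 0.3]), p2)
        qq = conditional_qq(panel, StratumSpec((1.0, 0.001)))
        assert qq.sizes["-log10(p2)>3"] == 1
        assert len(qq.strata["-log10(p2)>3"]) == 1

    def test_empty_stratum_omitted(self):
        panel = panel_from_pvals(np.array([0.1, 0.2]), np.array([0.5, 0.6]))
        qq = conditional_qq(panel, StratumSpec((1.0, 0.001)))
        assert "-log10(p2)>3" not in qq.strata

    def test_pleiotropic_mixture_deflects_strata_monotonically(self, mixture_bundle):
        qq = conditional_qq(mixture_bundle["panel"])
        defl = list(qq.deflection(at_empirical=2.0).values())
        assert all(b > a for a, b in zip(defl, defl[1:]))

    def test_strata_thresholds_must_decrease(self):
        with pytest.raises(ValueError):
            StratumSpec((1.0, 0.1, 0.1))
        with pytest.raises(ValueError):
            StratumSpec((0.5, 0.1))


class TestFoldEnrichment:
    def test_baseline_stratum_is_unity(self):
        rng = np.random.default_rng(0)
        panel = panel_from_pvals(rng.random(500), rng.random(500))
        fe = fold_enrichment(panel, StratumSpec((1.0,)), gc_correct=False)
        base = fe.strata["-log10(p2)>0"]
        assert np.allclose(base[~np.isnan(base)], 1.0)

    def test_counts_forced_example(self):
        # stratum = the 10 smallest-p1 SNPs of 100; at the 10th smallest p1
        # FE = (10/10) / (10/100) = 10
        rng = np.random.default_rng(3)
        p1 = np.sort(rng.random(100))
        p2 = np.full(100, 0.5)
        p2[:10] = 0.0005  # conditioning selects exactly the 10 smallest p1
        sel_thr = p1[9]
        panel = panel_from_pvals(p1, p2)
        strata = StratumSpec((1.0, 0.001))
        fe = fold_enrichment(panel, strata, gc_correct=False, n_grid=50)
        p1_all = panel.df["p1"].to_numpy()
        num = (p1_all[p2 <= 0.001] <= sel_thr).sum() / 10
        den = (p1_all <= sel_thr).sum() / 100
        assert num / den == pytest.approx(10.0)
        # and the computed curve honours the same counting at grid points
        grid_p = 10 ** (-fe.grid_neglog10)
        for gp, val in zip(grid_p, fe.strata["-log10(p2)>3"]):
            if np.isnan(val):
                continue
            expect = ((p1_all[p2 <= 0.001] <= gp).mean()) / ((p1_all <= gp).mean())
            assert val == pytest.approx(expect, rel=1e-9)

    def test_mixture_enrichment_monotone_across_strata(self, mixture_bundle):
        fe = fold_enrichment(mixture_bundle["panel"])
        at3 = np.argmin(np.abs(fe.grid_neglog10 - 3.0))
        vals = [curve[at3] for curve in fe.strata.values()]
        vals = [v for v in vals if not np.isnan(v)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_lambda_correction_attenuates_inflated_stats(self):
        rng = np.random.default_rng(5)
        chi = 1.5 * rng.chisquare(1, 5000)
        p1 = stats.chi2.sf(chi, 1)
        panel = panel_from_pvals(np.clip(p1, 1e-300, 1), rng.random(5000))
        fe = fold_enrichment(panel, StratumSpec((1.0,)), gc_correct=True)
        assert fe.lambda_gc == pytest.approx(1.5, rel=0.1)


class TestEmpiricalCfdr:
    def test_constant_p2_reduces_to_empirical_fdr(self):
        p1 = np.array([0.01, 0.2, 0.5, 0.9, 1.0])
        p2 = np.full(5, 0.3)
        got = empirical_cfdr(p1, p2)
        ranks = np.array([1, 2, 3, 4, 5])
        expected = np.minimum(1.0, p1 * 5 / ranks)
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        assert got[0] == pytest.approx(0.05)

    def test_single_snp_returns_p1(self):
        np.testing.assert_allclose(empirical_cfdr([0.037], [0.5]), [0.037])

    def test_eight_snp_table_matches_double_loop_oracle(self):
        p1 = np.array([0.001, 0.02, 0.02, 0.15, 0.3, 0.55, 0.8, 1.0])
        p2 = np.array([0.004, 0.9, 0.01, 0.01, 0.7, 0.2, 0.9, 0.05])
        np.testing.assert_allclose(empirical_cfdr(p1, p2), brute_cfdr(p1, p2), rtol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("tie_round", [None, 1])
    def test_random_panels_match_oracle(self, seed, tie_round):
        rng = np.random.default_rng(seed)
        p1, p2 = rng.random(200), rng.random(200)
        if tie_round:  # heavy ties
            p1, p2 = np.round(p1, tie_round), np.round(p2, tie_round)
            p1[p1 == 0] = 0.05
            p2[p2 == 0] = 0.05
        np.testing.assert_allclose(empirical_cfdr(p1, p2), brute_cfdr(p1, p2), rtol=1e-12)

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(ValueError):
            empirical_cfdr(np.ones(3), np.ones(4))

    def test_invariant_to_monotone_transform_of_p2(self):
        rng = np.random.default_rng(7)
        p1, p2 = rng.random(300), rng.random(300)
        base = empirical_cfdr(p1, p2)
        np.testing.assert_allclose(base, empirical_cfdr(p1, p2**3), rtol=1e-12)
        np.testing.assert_allclose(base, empirical_cfdr(p1, 0.5 * p2), rtol=1e-12)

    def test_bh_stepup_equivalence_with_constant_p2(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p1 = np.concatenate([rng.random(400), rng.random(100) * 1e-3])
        p2 = np.full_like(p1, 0.4)
        cfdr = empirical_cfdr(p1, p2)
        # enforce step-up (running-minimum) monotonicity along sorted p1
        order = np.argsort(p1)
        mono = np.minimum.accumulate(cfdr[order][::-1])[::-1]
        adj = np.empty_like(mono)
        adj[order] = mono
        reject, bh_adj, *_ = multipletests(p1, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, bh_adj, rtol=1e-10)
        np.testing.assert_array_equal(adj <= 0.05, reject)
        # without monotonicity the raw pointwise calls are a subset
        assert set(np.flatnonzero(cfdr <= 0.05)) <= set(np.flatnonzero(reject))


class TestConjunctionAndCalls:
    def test_elementwise_maximum(self):
        np.testing.assert_allclose(conjunction_cfdr([0.01, 0.2], [0.2, 0.01]), [0.2, 0.2])
        x = np.array([0.3, 0.5])
        np.testing.assert_allclose(conjunction_cfdr(x, x), x)

    def test_dominates_both_inputs(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(100), rng.random(100)
        cc = conjunction_cfdr(a, b)
        assert (cc >= a).all() and (cc >= b).all()

    def test_boundary_value_is_significant(self):
        assert call_significant(np.array([0.05]), 0.05)[0]
        assert not call_significant(np.array([1.0]), 0.05)[0]

    def test_alpha_outside_unit_interval_is_error(self):
        with pytest.raises(ValueError):
            call_significant(np.array([0.5]), 1.5)

    def test_tight_calls_subset_of_loose(self, mixture_bundle):
        res = compute_cfdr(mixture_bundle["panel"])
        assert (res.df["sig01"] <= res.df["sig05"]).all()
        assert (res.df["pleio01"] <= res.df["pleio05"]).all()
        np.testing.assert_allclose(
            res.df["ccfdr"], np.maximum(res.df["cfdr_12"], res.df["cfdr_21"])
        )


class TestNovelty:
    def _result(self, n=6):
        panel = panel_from_pvals(np.linspace(0.001, 0.5, n), np.linspace(0.002, 0.6, n))
        return compute_cfdr(panel)

    def test_empty_known_list_all_novel(self):
        out = exclude_known(self._result(), [])
        assert out.df["novel"].all()

    def test_known_id_not_novel(self):
        out = exclude_known(self._result(), ["rs2"])
        assert not out.df.set_index("snp_id").loc["rs2", "novel"]
        assert out.df["novel"].sum() == 5

    def test_ld_proxy_of_known_snp_not_novel(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(50, 1)).astype(float)
        dosages = np.hstack([g, g, rng.integers(0, 3, size=(50, 4)).astype(float)])
        panel = GenotypePanel(
            dosages, [f"rs{i}" for i in range(6)], np.array(["1"] * 6, dtype=object),
            np.arange(6) * 1000,
        )
        out = exclude_known(self._result(), ["rs0"], panel=panel, r2_link=0.2)
        flags = out.df.set_index("snp_id")["novel"]
        assert not flags["rs0"]
        assert not flags["rs1"]  # perfect LD with the known SNP


class TestManhattan:
    def test_reference_line_is_minus_log10_alpha(self):
        res = compute_cfdr(panel_from_pvals(np.array([0.05, 0.5]), np.array([0.5, 0.5])))
        man = manhattan_data(res)
        assert man.attrs["sig_line"] == pytest.approx(1.3010, abs=1e-4)
        row = man.set_index("snp_id").loc["rs0"]
        assert row["neglog10"] == pytest.approx(-np.log10(row["value"]))

    def test_single_chromosome_uses_raw_positions(self):
        res = compute_cfdr(panel_from_pvals(np.linspace(0.01, 0.9, 5), np.full(5, 0.5)))
        man = manhattan_data(res)
        np.testing.assert_allclose(man["cum_pos"], man["pos"])

    def test_multichromosome_offsets_strictly_increase(self):
        n = 9
        chrom = ["1"] * 3 + ["2"] * 3 + ["3"] * 3
        res = compute_cfdr(
            panel_from_pvals(np.linspace(0.01, 0.9, n), np.full(n, 0.5), chrom=chrom)
        )
        man = manhattan_data(res, "ccfdr")
        # recompute offsets: each chromosome shifted by cumulative max pos
        offsets = {}
        running = 0
        for ch in ["1", "2", "3"]:
            offsets[ch] = running
            running += int(man.loc[man["chrom"] == ch, "pos"].max())
        expected = man["pos"] + man["chrom"].map(offsets)
        np.testing.assert_allclose(man["cum_pos"], expected)
        assert man["cum_pos"].is_monotonic_increasing


def test_null_panel_cfdr_calls_conservative_small():
    """All-null quick check (the full 200-replicate battery lives in the
    acceptance suite): mean call fraction at 0.05 stays below 0.05."""
    fracs = []
    for s in range(20):
        rng = np.random.default_rng(900 + s)
        fracs.append((empirical_cfdr(rng.random(2000), rng.random(2000)) <= 0.05).mean())
    assert np.mean(fracs) <= 0.05
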