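import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from xppav import (
    GwasRecord,
    empirical_p,
    gwas_scan,
    pooled_t,
    scaled_vector,
    significant,
    standardize_t,
    welch_t,
    xppav_scan,
)
from xppav.genotype_io import MISSING, flip_column

from conftest import make_panel


def welch_oracle(x, y):
    """Textbook Welch formula, coded independently of the implementation."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((xi - mx) ** 2 for xi in x) / (nx - 1)
    vy = sum((yi - my) ** 2 for yi in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


class TestScaledVector:
    def test_direct_multiplication(self):
        sv = scaled_vector(np.array([0, 1, 2, 0]), 0.5)
        np.testing.assert_allclose(sv.values, [0, 0.5, 1.0, 0])

    def test_zero_beta_annihilates(self):
        assert not scaled_vector(np.array([2, 1, 0]), 0.0).values.any()

    def test_negative_beta_sign(self):
        np.testing.assert_allclose(
            scaled_vector(np.array([2, 2, 2]), -1.0).values, [-2, -2, -2]
        )

    def test_missing_rejected(self):
        with pytest.raises(ValueError, match="MISSING"):
            scaled_vector(np.array([0, MISSING]), 1.0)

    def test_nonfinite_beta_rejected(self):
        with pytest.raises(ValueError):
            scaled_vector(np.array([0, 1]), math.nan)


class TestWelchT:
    def test_identical_multisets_give_zero(self):
        t, _ = welch_t(np.array([0.0, 0.5, 1.0]), np.array([1.0, 0.0, 0.5]))
        assert t == pytest.approx(0.0, abs=1e-15)

    def test_equal_scaled_inputs_give_zero(self):
        x = scaled_vector(np.array([0, 0, 2, 2]), 0.7)
        y = scaled_vector(np.array([0, 0, 2, 2]), 0.7)
        t, _ = welch_t(x, y)
        assert t == pytest.approx(0.0, abs=1e-15)

    def test_textbook_oracle_example(self):
        x = [0, 0.5, 1.0, 0.5]
        y = [0, 0, 1.2, 1.2, 0.6, 0.6]
        t, df = welch_t(np.array(x), np.array(y))
        t0, df0 = welch_oracle(x, y)
        assert t == pytest.approx(t0, abs=1e-12)
        assert df == pytest.approx(df0, abs=1e-12)

    def test_many_random_pairs_match_oracle_and_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            nx, ny = rng.integers(3, 51, size=2)
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            t, df = welch_t(x, y)
            t0, df0 = welch_oracle(list(x), list(y))
            assert t == pytest.approx(t0, abs=1e-12)
            assert df == pytest.approx(df0, abs=1e-12)
            res = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(res.statistic, abs=1e-10)
            assert df == pytest.approx(res.df, abs=1e-10)

    def test_both_variances_zero_degenerate(self):
        t, df = welch_t(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert math.isnan(t) and math.isnan(df)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            welch_t(np.array([1.0]), np.array([0.0, 1.0]))

    def test_pooled_matches_scipy(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=10), rng.normal(size=14)
        t, df = pooled_t(x, y)
        res = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(res.statistic, abs=1e-12)
        assert df == 22


class TestStandardizeT:
    def test_output_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        z, _ = standardize_t(rng.normal(2.0, 5.0, size=200))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_input_reduces_to_scaling(self):
        t = np.array([-3.0, 0.0, 3.0])
        z, _ = standardize_t(t)
        np.testing.assert_allclose(z, t / t.std(ddof=1), atol=1e-14)

    def test_normal_cdf_oracle(self):
        # independent normal-CDF oracle via the error function: for every
        # emitted z, p must equal 2*(1 - Phi(|z|))
        rng = np.random.default_rng(44)
        t = rng.normal(size=60)
        t[0] = 6.0  # push one marker near z ~ 1.96-plus territory
        z, p = standardize_t(t)
        for zj, pj in zip(z, p):
            p_oracle = 2.0 * (1.0 - 0.5 * (1.0 + math.erf(abs(zj) / math.sqrt(2.0))))
            assert pj == pytest.approx(p_oracle, abs=1e-12)
        # spot value: z = 1.959964 corresponds to p ~ 0.05
        p_ref = 2.0 * (1.0 - 0.5 * (1.0 + math.erf(1.959964 / math.sqrt(2.0))))
        assert p_ref == pytest.approx(0.05, abs=1e-6)

    def test_zero_spread_errors(self):
        with pytest.raises(ValueError, match="spread"):
            standardize_t([1.0, 1.0, 1.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            standardize_t([1.0, math.inf])


class TestEmpiricalP:
    def test_largest_gets_one_over_m(self):
        p = empirical_p([0.1, -5.0, 2.0, 0.0])
        assert p[1] == pytest.approx(0.25)

    def test_complete_ties_give_one(self):
        np.testing.assert_allclose(empirical_p([2.0, -2.0, 2.0]), 1.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.normal(size=int(rng.integers(2, 50)))
            if rng.random() < 0.3:  # inject ties
                t[: len(t) // 2] = t[0]
            p = empirical_p(t)
            m = len(t)
            for j in range(m):
                expected = (1 + sum(abs(t[k]) >= abs(t[j]) for k in range(m) if k != j)) / m
                assert p[j] == pytest.approx(expected, abs=1e-14)

    def test_never_zero_and_at_most_one(self):
        p = empirical_p(np.linspace(-4, 4, 99))
        assert (p > 0).all() and (p <= 1).all()


def _scan_from_sim(sim):
    p1, ph1, p2, ph2, truth = sim
    r1 = gwas_scan(p1, ph1)
    r2 = gwas_scan(p2, ph2)
    return xppav_scan(p1, r1, p2, r2), truth


class TestXppavScan:
    def test_equal_betas_equal_counts_give_zero_t(self):
        codes = np.array([[0, 0], [1, 2], [2, 1], [0, 0], [1, 2], [2, 1]])
        recs_a = [GwasRecord("s1", 0.8, 0.1, 1.0, 0.5, 6),
                  GwasRecord("s2", 1.0, 0.1, 1.0, 0.5, 6)]
        recs_b = [GwasRecord("s1", 0.8, 0.1, 1.0, 0.5, 6),
                  GwasRecord("s2", -1.0, 0.1, 1.0, 0.5, 6)]
        # s1: same beta, same genotype-count distribution -> t = 0;
        # s2 differs so the genome-wide spread is nonzero
        pa = make_panel(codes, sample_ids=[f"a{i}" for i in range(6)])
        pb = make_panel(codes, sample_ids=[f"b{i}" for i in range(6)])
        out = xppav_scan(pa, recs_a, pb, recs_b)
        assert out[0].t_raw == pytest.approx(0.0, abs=1e-12)
        assert out[0].mean_effect_pop1 == pytest.approx(out[0].mean_effect_pop2)

    def test_all_het_columns_are_degenerate(self):
        codes1 = np.array([[1, 0], [1, 1], [1, 2], [1, 0]])
        codes2 = np.array([[1, 2], [1, 1], [1, 0], [1, 1]])
        pa = make_panel(codes1, sample_ids=[f"a{i}" for i in range(4)])
        pb = make_panel(codes2, sample_ids=[f"b{i}" for i in range(4)])
        recs1 = [GwasRecord("s1", 1.0, 0.1, 1.0, 0.5, 4),
                 GwasRecord("s2", 0.5, 0.1, 1.0, 0.5, 4)]
        recs2 = [GwasRecord("s1", -1.0, 0.1, 1.0, 0.5, 4),
                 GwasRecord("s2", 0.5, 0.1, 1.0, 0.5, 4)]
        with pytest.raises(ValueError, match="non-degenerate"):
            # only one non-degenerate SNP -> standardization impossible
            xppav_scan(pa, recs1, pb, recs2)

    def test_mean_effects_match_definition(self, small_sim):
        records, _ = _scan_from_sim(small_sim)
        p1 = small_sim[0]
        r1 = gwas_scan(p1, small_sim[1])
        beta = {r.snp_id: r.beta for r in r1}
        codes = dict(zip(p1.snp_ids, p1.genotypes.T))
        for rec in records[:25]:
            if rec.status != "ok":
                continue
            expected = codes[rec.snp_id].mean() * beta[rec.snp_id]
            assert rec.mean_effect_pop1 == pytest.approx(expected, rel=1e-10)

    def test_welch_agrees_with_scipy_on_scaled_vectors(self, small_sim):
        records, _ = _scan_from_sim(small_sim)
        p1, ph1, p2, ph2, _ = small_sim
        r1 = {r.snp_id: r for r in gwas_scan(p1, ph1)}
        r2 = {r.snp_id: r for r in gwas_scan(p2, ph2)}
        for j, rec in enumerate(records[:20]):
            if rec.status != "ok":
                continue
            x = p1.genotypes[:, j].astype(float) * r1[rec.snp_id].beta
            y = p2.genotypes[:, j].astype(float) * r2[rec.snp_id].beta
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert rec.t_raw == pytest.approx(ref.statistic, abs=1e-9)

    def test_unharmonized_panels_rejected(self, small_sim):
        p1, ph1, p2, ph2, _ = small_sim
        r1, r2 = gwas_scan(p1, ph1), gwas_scan(p2, ph2)
        flipped = p2.genotypes.copy()
        flipped[:, 0] = flip_column(flipped[:, 0])
        snps = list(p2.snps)
        snps[0] = snps[0].flipped()
        p2f = dataclasses.replace(p2, snps=snps, genotypes=flipped)
        with pytest.raises(ValueError, match="harmonized"):
            xppav_scan(p1, r1, p2f, r2)

    def test_coding_flip_changes_t(self, small_sim):
        # flipping one population's coding (and negating its beta, as the
        # flipped GWAS would) changes t_raw: harmonization is load-bearing
        p1, ph1, p2, ph2, _ = small_sim
        r1, r2 = gwas_scan(p1, ph1), gwas_scan(p2, ph2)
        base = xppav_scan(p1, r1, p2, r2)
        flipped_codes = np.apply_along_axis(flip_column, 0, p2.genotypes)
        p2f = dataclasses.replace(
            p2, snps=[s.flipped() for s in p2.snps], genotypes=flipped_codes
        )
        p1f = dataclasses.replace(p1, snps=[s.flipped() for s in p1.snps])
        r2f = [dataclasses.replace(r, beta=-r.beta if np.isfinite(r.beta) else r.beta)
               for r in r2]
        alt = xppav_scan(p1f, r1, p2f, r2f)
        diffs = [
            abs(a.t_raw - b.t_raw)
            for a, b in zip(base, alt)
            if a.status == b.status == "ok"
        ]
        assert np.median(diffs) > 1e-6

    def test_common_scale_invariance(self, small_sim):
        p1, ph1, p2, ph2, _ = small_sim
        r1, r2 = gwas_scan(p1, ph1), gwas_scan(p2, ph2)
        base = xppav_scan(p1, r1, p2, r2)

        def scale(recs, c):
            return [dataclasses.replace(r, beta=c * r.beta) for r in recs]

        for c, sign in ((3.7, 1.0), (-2.0, -1.0)):
            alt = xppav_scan(p1, scale(r1, c), p2, scale(r2, c))
            for a, b in zip(base, alt):
                if a.status == "ok":
                    assert b.t_raw == pytest.approx(sign * a.t_raw, rel=1e-9)

    def test_degenerate_exclusion_conservation(self, small_sim):
        records, _ = _scan_from_sim(small_sim)
        n_ok = sum(r.status == "ok" for r in records)
        n_deg = sum(r.status == "degenerate" for r in records)
        assert n_ok + n_deg == len(records) == small_sim[0].n_snps

    def test_z_contract_on_full_scan(self, small_sim):
        records, _ = _scan_from_sim(small_sim)
        z = np.array([r.z for r in records if r.status == "ok"])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestSignificant:
    def _recs(self, ps):
        from xppav import XpPavRecord

        out = []
        for i, p in enumerate(ps):
            status = "degenerate" if math.isnan(p) else "ok"
            out.append(
                XpPavRecord(f"s{i}", "1", i + 1, 0.0, 0.0, p, p, 0.0, 0.0, 0.0, 0.0, status)
            )
        return out

    def test_vacuous_alpha_returns_all_ok(self):
        recs = self._recs([0.2, 0.5, 0.9])
        assert significant(recs, alpha=0.9999) == {"s0", "s1", "s2"}

    def test_degenerate_never_returned(self):
        recs = self._recs([0.001, math.nan])
        assert significant(recs, alpha=0.5) == {"s0"}

    def test_brute_force_membership(self):
        rng = np.random.default_rng(6)
        ps = rng.uniform(size=20)
        recs = self._recs(list(ps))
        assert significant(recs, alpha=0.3) == {
            f"s{i}" for i, p in enumerate(ps) if p < 0.3
        }

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            significant(self._recs([0.5]), alpha=0.0)


@given(
    t=st.lists(
        st.floats(-50, 50, allow_nan=False).filter(lambda v: abs(v) > 1e-6),
        min_size=3,
        max_size=40,
        unique=True,
    )
)
@settings(deadline=None, max_examples=50)
def test_empirical_p_is_rank_consistent(t):
    """Property: larger |t| never gets a larger empirical p."""
    p = empirical_p(np.array(t))
    order = np.argsort(np.abs(t))  # ascending |t| -> non-increasing p
    assert all(p[order[i]] >= p[order[i + 1]] - 1e-12 for i in range(len(t) - 1))
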