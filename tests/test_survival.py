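import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from cilgibbs.survival import (BandTest, associate_group, band_association,
                               compute_mim, establishment_point,
                               fisher_exact_2x2, km_logrank, loess_smooth,
                               ordered_series, split_cil)


def make_group(n=40, seed=0, mim=None, survival=None):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n) if mim is None else np.asarray(mim)
    df = pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "z_L_r": z, "z_G_r": z,     # MIM equals z exactly
        "survival_days": (rng.exponential(300, n) if survival is None
                          else np.asarray(survival)),
    })
    return df


class TestComputeMim:
    def test_arithmetic(self):
        assert compute_mim({"z_L_r": 1.0, "z_G_r": 2.0}) == 1.5
        assert compute_mim({"z_L_r": 0.4, "z_G_r": 0.4}) == pytest.approx(0.4)

    def test_cohort_mean_zero_after_zscoring(self):
        from cilgibbs.clustering import zscore_metrics

        rng = np.random.default_rng(2)
        df = pd.DataFrame({"L_r": rng.normal(10, 2, 30),
                           "G_r": rng.normal(12, 3, 30)})
        z = zscore_metrics(df)
        assert abs(compute_mim(z).mean()) < 1e-9

    def test_missing_coordinate_errors(self):
        with pytest.raises((ValueError, KeyError)):
            compute_mim({"z_L_r": 1.0})


class TestLoess:
    def test_exact_on_linear_input(self):
        y = 0.7 * np.arange(50) - 3.0
        np.testing.assert_allclose(loess_smooth(y, span=0.4), y, atol=1e-8)

    def test_constant_input(self):
        np.testing.assert_allclose(loess_smooth(np.full(20, 2.5)), 2.5)

    def test_pointwise_tricube_wls_oracle(self):
        """Smoothed value equals a direct weighted-least-squares solve
        with tricube weights over the span window."""
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        span = 0.5
        sm = loess_smooth(y, span=span)
        n = len(y)
        q = int(np.ceil(span * n))
        x = np.arange(n, dtype=float)
        for i in [0, 7, 15, 29]:
            d = np.abs(x - x[i])
            dmax = np.sort(d)[q - 1]
            w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
            A = np.column_stack([np.ones(n), x - x[i]])
            Aw = A * w[:, None]
            coef = np.linalg.lstsq(Aw.T @ A, Aw.T @ y, rcond=None)[0]
            assert sm[i] == pytest.approx(coef[0], abs=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError):
            loess_smooth(np.arange(5))
        with pytest.raises(ValueError):
            loess_smooth(np.arange(20), span=1.5)
        with pytest.raises(ValueError):
            loess_smooth(np.arange(20), span=0.05)


class TestOrderedSeries:
    def test_survival_order_and_tie_break(self):
        df = make_group(12, seed=1)
        df.loc[3, "survival_days"] = df.loc[8, "survival_days"]  # tie
        s = ordered_series(df)
        assert (np.diff(s.survival_days) >= 0).all()
        tied = [df.loc[3, "patient_id"], df.loc[8, "patient_id"]]
        i, j = (s.patient_ids.index(t) for t in tied)
        assert (i < j) == (tied[0] < tied[1])

    def test_randomized_reproducible(self):
        df = make_group(15, seed=2)
        a = ordered_series(df, "randomized", seed=42)
        b = ordered_series(df, "randomized", seed=42)
        assert a.patient_ids == b.patient_ids

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            ordered_series(make_group(10), "alphabetical")


class TestFisher:
    def test_identical_series_p_one(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=20)
        bt = band_association(s, s, 0.0, 1.0)
        assert bt.p_value == 1.0

    def test_example_table_matches_enumeration(self):
        """p for [[8,2],[1,9]] equals the exhaustive hypergeometric sum
        over tables with the same margins."""
        from scipy.special import comb

        table = [[8, 2], [1, 9]]
        m1, m2, k = 10, 10, 9
        total = comb(20, 9)
        p_obs = comb(m1, 8) * comb(m2, 1) / total
        p = 0.0
        for a in range(max(0, k - m2), min(k, m1) + 1):
            pa = comb(m1, a) * comb(m2, k - a) / total
            if pa <= p_obs * (1 + 1e-7):
                p += pa
        assert fisher_exact_2x2(table) == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_on_margin_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(0, 12, size=(2, 2))
            ours = fisher_exact_2x2(t)
            _, ref = scipy_fisher(t)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_zero_width_band_rejected(self):
        with pytest.raises(ValueError):
            band_association([1.0] * 5, [1.0] * 5, 0.0, 0.0)


class TestEstablishment:
    def _band(self, center=0.0, sd=1.0, mult=1.0):
        return BandTest(center=center, sd=sd, multiplier=mult,
                        table=np.zeros((2, 2)), p_value=1.0,
                        inside_increasing=np.array([]),
                        inside_randomized=np.array([]))

    def test_entirely_inside_gives_first_index(self):
        idx, days = establishment_point(
            np.zeros(10), self._band(), np.arange(10.0) + 1)
        assert idx == 0 and days == 1.0

    def test_entirely_outside_not_established(self):
        idx, days = establishment_point(
            np.full(10, 5.0), self._band(), np.arange(10.0))
        assert idx is None and days is None

    def test_planted_entry_index_recovered(self):
        series = np.concatenate([np.full(7, 5.0), np.zeros(13)])
        idx, days = establishment_point(
            series, self._band(), np.arange(20.0) * 10)
        assert idx == 7 and days == 70.0

    def test_monotone_in_band_multiplier(self):
        rng = np.random.default_rng(9)
        series = np.cumsum(rng.normal(size=40)) / 10
        t = np.arange(40.0)
        prev = None
        for mult in (1.0, 2.0, 4.0, 8.0):
            idx, _ = establishment_point(series, self._band(mult=mult), t)
            if prev is not None and idx is not None and prev is not None:
                assert prev is None or idx <= prev
            prev = idx if idx is not None else prev


class TestSplitCil:
    def test_partition_is_exact(self):
        df = make_group(25, seed=5)
        sub = split_cil(df, establishment_days=250.0)
        assert len(sub) == 25
        assert set(sub) <= {"LH-CIL", "H-CIL"}
        assert ((df["survival_days"] < 250.0)
                == (sub == "LH-CIL")).all()


class TestKmLogrank:
    def test_identical_groups_p_one(self):
        df = make_group(20, seed=6)
        two = pd.concat([df.assign(group="A"), df.assign(group="B")])
        two["event"] = 1
        _, stat, p, reliable = km_logrank(two)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert reliable

    def test_product_limit_hand_computed(self):
        """KM on {2+, 3, 5, 7+}: S(3) = 2/3, S(5) = 1/3."""
        df = pd.DataFrame({
            "survival_days": [2.0, 3.0, 5.0, 7.0],
            "event": [0, 1, 1, 0],
            "group": ["A"] * 4,
        })
        other = pd.DataFrame({"survival_days": [1.0, 4.0],
                              "event": [1, 1], "group": ["B"] * 2})
        fitters, _, _, _ = km_logrank(pd.concat([df, other]))
        km = fitters["A"].survival_function_
        assert km.loc[3.0].iloc[0] == pytest.approx(2 / 3)
        assert km.loc[5.0].iloc[0] == pytest.approx(1 / 3)

    def test_all_censored_group_flagged(self):
        df = pd.concat([
            make_group(10, seed=7).assign(group="A", event=0),
            make_group(10, seed=8).assign(group="B", event=1),
        ])
        _, _, _, reliable = km_logrank(df)
        assert not reliable

    def test_phenotype_survival_power(self):
        """Cohorts with scales (600, 150) days separate at p < 0.01 in
        nearly every replicate."""
        from cilgibbs.synthetic import CohortSpec, gen_cohort

        hits = 0
        n_rep = 20
        for s in range(n_rep):
            _, t = gen_cohort(CohortSpec(n_gibbs=40, n_invasion=20, seed=s),
                              with_patterns=False)
            t = t.rename(columns={"phenotype": "group"})
            _, _, p, _ = km_logrank(t)
            hits += p < 0.01
        assert hits >= 0.9 * n_rep

    def test_equal_scales_null_calibration(self):
        """With equal survival scales the phenotype log-rank test is
        non-significant at alpha = 0.05 in at least 90% of replicates."""
        from cilgibbs.synthetic import CohortSpec, gen_cohort

        non_sig = 0
        n_rep = 50
        for s in range(n_rep):
            _, t = gen_cohort(
                CohortSpec(n_gibbs=30, n_invasion=30, seed=1000 + s,
                           survival_scale_gibbs=300.0,
                           survival_scale_invasion=300.0),
                with_patterns=False)
            t = t.rename(columns={"phenotype": "group"})
            _, _, p, _ = km_logrank(t)
            non_sig += p >= 0.05
        assert non_sig >= 0.9 * n_rep


class TestAssociateGroup:
    def test_bundle_structure_and_determinism(self):
        df = make_group(40, seed=10)
        a1 = associate_group(df, [0.0, 0.0], seed=1)
        a2 = associate_group(df, [0.0, 0.0], seed=1)
        assert a1["band"].p_value == a2["band"].p_value
        assert a1["band"].table.sum() == 2 * len(df)
        if a1["established"]:
            assert len(a1["cil_subgroup"]) == len(df)

    def test_planted_drift_recovers_establishment(self):
        """MIM drifting from far outside the band into it at a known
        survival rank is located exactly."""
        n = 60
        rng = np.random.default_rng(11)
        surv = np.sort(rng.exponential(300, n))
        mim = np.concatenate([np.full(20, 8.0),
                              rng.normal(0, 0.05, 40)])
        df = pd.DataFrame({
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "z_L_r": mim, "z_G_r": mim, "survival_days": surv})
        a = associate_group(df, [0.0, 0.0], span=0.2, seed=3)
        assert a["established"]
        # smoothing blurs the planted step at index 20 by less than the
        # local window half-width
        assert abs(a["establishment_index"] - 20) <= 6
        assert a["band"].p_value < 0.05
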