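import numpy as np
import pandas as pd
import pytest

import framebias as fb
from framebias.weighting import WeightingError, _collapse_groups


def _toy(age, sex, area, sizes=None, cluster=None):
    n = len(age)
    return pd.DataFrame({
        "age_group": age, "sex": sex, "area": area,
        "household_size_eligible": sizes if sizes is not None else [1] * n,
        "cluster_id": cluster if cluster is not None else range(n),
    })


class TestDesignWeight:
    def test_single_member_households_equal_weights(self):
        df = _toy(["25-29"] * 4, ["male"] * 4, ["metro"] * 4)
        w = fb.design_weight(df).to_numpy()
        assert np.allclose(w, 1.0)

    def test_weight_ratio_follows_household_size(self):
        df = _toy(["25-29"] * 2, ["male"] * 2, ["metro"] * 2, sizes=[1, 3])
        w = fb.design_weight(df).to_numpy()
        assert w[1] / w[0] == pytest.approx(3.0)
        assert w.sum() == pytest.approx(2.0)  # normalised to n

    def test_missing_metadata_rejected(self):
        df = _toy(["25-29"], ["male"], ["metro"])
        df.loc[0, "household_size_eligible"] = np.nan
        with pytest.raises(WeightingError):
            fb.design_weight(df)

    def test_horvitz_thompson_unbiased_total(self):
        """Unnormalised inverse-probability weights estimate the
        population smoker total with <1% relative bias over replicates."""
        cfg = fb.ScenarioConfig(
            population_size=4000, n_clusters=40, seed=13,
            health_spec={"current_smoker": {"baseline": 0.25}})
        pop = fb.generate_population(cfg)
        true_total = pop["current_smoker"].sum()
        from framebias.sampling import HouseholdIndex
        index = HouseholdIndex.from_population(pop)
        design = fb.SampleDesign(n_clusters=15, response_rate=1.0)
        rng = np.random.default_rng(14)
        totals = []
        for _ in range(1000):
            s = fb.draw_survey(pop, design, rng=rng, index=index)
            w = fb.design_weight(s, normalize=False).to_numpy()
            totals.append(float(w @ s.data["current_smoker"].to_numpy()))
        rel_bias = (np.mean(totals) - true_total) / true_total
        assert abs(rel_bias) < 0.01


class TestPoststratify:
    def _bench(self, rows):
        return pd.DataFrame(rows, columns=["age_group", "sex", "area",
                                           "count"])

    def test_two_cell_forced_arithmetic(self):
        df = _toy(["25-29", "25-29", "30-34", "30-34"], ["male"] * 4,
                  ["metro"] * 4)
        w = np.array([5.0, 5.0, 5.0, 5.0])
        bench = self._bench([("25-29", "male", "metro", 100),
                             ("30-34", "male", "metro", 300)])
        pw = fb.poststratify(df, w, bench).to_numpy()
        assert np.allclose(pw[:2], 50.0)   # factor 10
        assert np.allclose(pw[2:], 150.0)  # factor 30

    def test_proportional_sample_uniform_factor(self):
        df = _toy(["25-29"] * 2 + ["30-34"] * 6, ["male"] * 8, ["metro"] * 8)
        w = np.ones(8)
        bench = self._bench([("25-29", "male", "metro", 50),
                             ("30-34", "male", "metro", 150)])
        pw = fb.poststratify(df, w, bench).to_numpy()
        assert np.allclose(pw / w, 25.0)

    def test_margins_match_benchmark_exactly(self, bundle):
        dw = fb.design_weight(bundle.sample)
        pw = fb.poststratify(bundle.sample, dw, bundle.benchmark)
        got = (bundle.sample.data.assign(_w=pw.to_numpy())
               .groupby(["sex", "area"], observed=True)["_w"].sum())
        want = bundle.benchmark.groupby(["sex", "area"],
                                        observed=True)["count"].sum()
        for key in want.index:
            assert got[key] == pytest.approx(want[key], rel=1e-9)
        assert pw.to_numpy().sum() == pytest.approx(
            bundle.benchmark["count"].sum(), rel=1e-9)

    def test_idempotent(self, bundle):
        dw = fb.design_weight(bundle.sample)
        once = fb.poststratify(bundle.sample, dw, bundle.benchmark)
        twice = fb.poststratify(bundle.sample, once, bundle.benchmark)
        assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-9

    def test_scale_invariant(self, bundle):
        dw = fb.design_weight(bundle.sample)
        a = fb.poststratify(bundle.sample, dw, bundle.benchmark).to_numpy()
        b = fb.poststratify(bundle.sample, 37.5 * dw.to_numpy(),
                            bundle.benchmark).to_numpy()
        assert np.allclose(a, b, rtol=1e-12)

    def test_collapse_preserves_collapsed_margins(self):
        """A missing age band is merged with its neighbour; the merged
        group's weighted total matches the summed benchmark counts."""
        df = _toy(["25-29", "25-29"], ["male"] * 2, ["metro"] * 2)
        bench = self._bench([("25-29", "male", "metro", 100),
                             ("30-34", "male", "metro", 40)])
        pw = fb.poststratify(df, np.ones(2), bench)
        assert pw.to_numpy().sum() == pytest.approx(140.0)

    def test_empty_stratum_rejected(self):
        df = _toy(["25-29"], ["male"], ["metro"])
        bench = self._bench([("25-29", "male", "metro", 100),
                             ("25-29", "female", "metro", 120)])
        with pytest.raises(WeightingError):
            fb.poststratify(df, np.ones(1), bench)

    def test_collapse_groups_unit(self):
        group = _collapse_groups(list("abcde"),
                                 np.array([0.0, 2.0, 0.0, 0.0, 1.0]))
        assert group.tolist() == [0, 0, 0, 0, 1]


class TestReweightSubsample:
    def test_full_sample_identity(self, bundle):
        dw = fb.design_weight(bundle.sample)
        post = fb.poststratify(bundle.sample, dw, bundle.benchmark)
        rw = fb.reweight_subsample(bundle.sample.data, dw, bundle.benchmark)
        assert np.allclose(rw.to_numpy(), post.to_numpy(), rtol=1e-12)
        assert rw.stage == "reweighted"

    def test_random_thinning_unbiased(self, calibration_population):
        """Re-weighted prevalence from a 50% random thinning stays
        unbiased for the population prevalence over replicate surveys."""
        pop = calibration_population
        bench = fb.benchmark_from_population(pop)
        truth = 100.0 * pop["current_smoker"].mean()
        from framebias.sampling import HouseholdIndex
        index = HouseholdIndex.from_population(pop)
        design = fb.SampleDesign(n_clusters=60, response_rate=1.0)
        rng = np.random.default_rng(77)
        ests = []
        for _ in range(250):
            s = fb.draw_survey(pop, design, rng=rng, index=index)
            keep = rng.random(len(s.data)) < 0.5
            sub = s.data.loc[keep]
            dw = fb.design_weight(s).to_numpy()[keep]
            rw = fb.reweight_subsample(sub, dw, bench)
            est = fb.weighted_prevalence(sub, rw, "current_smoker")
            ests.append(est.percent)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - truth) < 3 * mc_se


class TestRake:
    def test_matches_poststratification_margins(self, bundle):
        dw = fb.design_weight(bundle.sample)
        data = bundle.sample.data
        margins = {
            "sex": bundle.benchmark.groupby("sex")["count"].sum(),
            "area": bundle.benchmark.groupby("area")["count"].sum(),
        }
        rw = fb.rake(data, dw, margins)
        for var, margin in margins.items():
            got = (data.assign(_w=rw.to_numpy())
                   .groupby(var, observed=True)["_w"].sum())
            for cat in margin.index:
                assert got[cat] == pytest.approx(margin[cat], rel=1e-8)
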