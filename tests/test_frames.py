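import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import framebias as fb
from framebias.frames import FrameDefinition

from helpers import toy_sample


def _records(statuses, listed_ll=None, listed_mob=None, y=None):
    n = len(statuses)
    return pd.DataFrame({
        "cluster_id": np.arange(n),
        "telephone_status": statuses,
        "listed_landline": listed_ll if listed_ll is not None else [False] * n,
        "listed_mobile": listed_mob if listed_mob is not None else [False] * n,
        "y": y if y is not None else np.zeros(n),
    })


class TestMembership:
    def test_both_listed_landline_in_both_frames(self):
        df = _records(["both"], listed_ll=[True])
        assert fb.RDD_LANDLINE.mask(df)[0]
        assert fb.DIRECTORY_LISTED.mask(df)[0]

    def test_unlisted_mobile_only_in_neither_frame(self):
        df = _records(["mobile_only"])
        assert not fb.RDD_LANDLINE.mask(df)[0]
        assert not fb.DIRECTORY_LISTED.mask(df)[0]

    def test_no_telephone_not_covered_by_either_frame(self):
        df = _records(["neither"])
        assert not fb.RDD_LANDLINE.mask(df)[0]
        assert not fb.DIRECTORY_LISTED.mask(df)[0]

    def test_partition_exhaustive_disjoint(self, bundle):
        part = fb.build_frame(bundle.sample, "rdd_landline")
        assert len(part.covered) + len(part.not_covered) == len(
            bundle.sample.data)
        assert not set(part.covered.index) & set(part.not_covered.index)

    def test_frame_fractions_track_configured_ownership(self):
        """On 2012-like and 2010-like populations the RDD frame covers
        ~72-78% and the directory frame ~50-60% of people, the shares
        the frames were calibrated to."""
        cfg12 = fb.scenario_for_year(2012, population_size=40_000, seed=6,
                                     with_gradients=False)
        pop12 = fb.generate_population(cfg12)
        rdd_cov = 1 - fb.coverage_fraction(pop12, None, "rdd_landline",
                                           weighted=False)
        assert 0.72 < rdd_cov < 0.78
        cfg10 = fb.scenario_for_year(2010, population_size=40_000, seed=6,
                                     with_gradients=False)
        pop10 = fb.generate_population(cfg10)
        dir_cov = 1 - fb.coverage_fraction(pop10, None, "directory_listed",
                                           weighted=False)
        assert 0.50 < dir_cov < 0.62


class TestCoverageFraction:
    def test_all_covered_f_zero(self):
        df = _records(["both", "landline_only"])
        assert fb.coverage_fraction(df, np.ones(2), "rdd_landline") == 0.0

    def test_partition_identity(self, bundle):
        w = fb.design_weight(bundle.sample)
        f = fb.coverage_fraction(bundle.sample, w, "rdd_landline")
        part = fb.build_frame(bundle.sample, "rdd_landline")
        wv = w.to_numpy()
        covered_share = wv[part.mask].sum() / wv.sum()
        assert f + covered_share == pytest.approx(1.0, abs=1e-12)

    def test_mobile_only_share_drives_rdd_noncoverage(self):
        cfg = fb.scenario_for_year(2013, population_size=50_000, seed=2,
                                   with_gradients=False)
        pop = fb.generate_population(cfg)
        f = fb.coverage_fraction(pop, None, "rdd_landline", weighted=False)
        expected = (cfg.telephone_mixture["mobile_only"]
                    + cfg.telephone_mixture["neither"])
        assert abs(f - expected) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(Exception):
            fb.coverage_fraction(_records([]).iloc[:0], None, "rdd_landline")


class TestRcbFormula:
    def test_equal_prevalences_give_zero(self):
        for f in (0.0, 0.3, 1.0):
            assert fb.rcb(f, 18.0, 18.0, 20.0) == 0.0

    def test_hand_evaluated_example(self):
        assert fb.rcb(0.5, 10.0, 30.0, 20.0) == pytest.approx(-0.5)

    def test_back_solved_published_example(self):
        """Inverting the formula at the printed smoking figures
        (f=0.504, p_c=13.7, P=19.0, RCB=-0.244) recovers p_nc; the
        forward evaluation reproduces the printed three-decimal value."""
        f, p_c, P, printed = 0.504, 13.7, 19.0, -0.244
        p_nc = p_c - printed * P / f  # algebraic inversion oracle
        assert round(fb.rcb(f, p_c, p_nc, P), 3) == printed

    @pytest.mark.parametrize("args", [
        (-0.1, 10, 20, 15), (1.1, 10, 20, 15),  # f out of range
        (0.5, 10, 20, 0.0), (0.5, 10, 20, -3),  # P not positive
    ])
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            fb.rcb(*args)

    def test_mixed_scales_rejected(self):
        with pytest.raises(ValueError):
            fb.rcb(0.5, 13.7, 0.2, 19.0, scale="proportion")
        # scale-consistent inputs are equivalent across scales
        assert fb.rcb(0.3, 10.0, 20.0, 15.0) == pytest.approx(
            fb.rcb(0.3, 0.10, 0.20, 0.15))

    @given(f=st.floats(0.01, 0.99), pc=st.floats(0.5, 99.5),
           pnc=st.floats(0.5, 99.5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_consistent_identity_randomized(self, f, pc, pnc):
        """With P the coverage-weighted mixture of p_c and p_nc,
        RCB == (p_c - P)/P identically."""
        P = (1 - f) * pc + f * pnc
        assert fb.rcb(f, pc, pnc, P) == pytest.approx((pc - P) / P,
                                                      abs=1e-9)


class TestRcbFromSample:
    def _weighted_bundle(self, bundle):
        dw = fb.design_weight(bundle.sample)
        pw = fb.poststratify(bundle.sample, dw, bundle.benchmark)
        return dw, pw

    def test_full_coverage_frame_zero_bias(self, bundle):
        everyone = FrameDefinition("everyone", lambda df: pd.Series(
            True, index=df.index))
        dw, pw = self._weighted_bundle(bundle)
        for mode, kw in (("consistent", {}),
                         ("reweighted", {"benchmark": bundle.benchmark,
                                         "design_weights": dw})):
            res = fb.rcb_from_sample(bundle.sample, pw, everyone,
                                     "current_smoker", mode=mode, **kw)
            assert res.rcb == 0.0
            assert res.abs_diff == pytest.approx(0.0, abs=1e-9)

    def test_consistent_mode_identity_bruteforce(self, bundle):
        dw, pw = self._weighted_bundle(bundle)
        for fname in fb.FRAMES:
            for ind in ("current_smoker", "mental_health", "obese"):
                res = fb.rcb_from_sample(bundle.sample, pw, fname, ind,
                                         mode="consistent")
                # brute-force recomputation from raw columns
                w = pw.to_numpy()
                m = fb.FRAMES[fname].mask(bundle.sample.data)
                y = bundle.sample.data[ind].to_numpy(dtype=float)
                P = np.dot(w, y) / w.sum()
                pc = np.dot(w[m], y[m]) / w[m].sum()
                assert res.rcb == pytest.approx((pc - P) / P, abs=1e-9)
                assert np.sign(res.rcb) == np.sign(res.p_c - res.p_nc) or \
                    res.rcb == 0.0

    def test_complement_antisymmetry(self, bundle):
        """Swapping covered/not-covered maps f -> 1-f and p_c <-> p_nc:
        rcb_complement = (1-f)(p_nc - p_c)/P."""
        dw, pw = self._weighted_bundle(bundle)
        res = fb.rcb_from_sample(bundle.sample, pw, "rdd_landline",
                                 "current_smoker")
        complement = FrameDefinition(
            "not_rdd", lambda df: ~fb.RDD_LANDLINE.mask(df))
        comp = fb.rcb_from_sample(bundle.sample, pw, complement,
                                  "current_smoker")
        expected = (1 - res.f) * (res.p_nc - res.p_c) / res.p_overall
        assert comp.rcb == pytest.approx(expected, abs=1e-9)

    def test_reweighted_mode_requires_inputs(self, bundle):
        dw, pw = self._weighted_bundle(bundle)
        with pytest.raises(ValueError):
            fb.rcb_from_sample(bundle.sample, pw, "rdd_landline",
                               "current_smoker", mode="reweighted")

    def test_smoking_bias_negative_on_2013_like_survey(self):
        """Mobile-only households smoke more, so both landline-based
        frames understate smoking: RCB < 0 for both frames."""
        cfg = fb.scenario_for_year(2013, population_size=60_000, seed=31)
        pop = fb.generate_population(cfg)
        bench = fb.benchmark_from_population(pop)
        design = fb.SampleDesign(n_clusters=250)
        s = fb.draw_survey(pop, design, rng=np.random.default_rng(32))
        dw = fb.design_weight(s)
        pw = fb.poststratify(s, dw, bench)
        for fname in fb.FRAMES:
            res = fb.rcb_from_sample(s, pw, fname, "current_smoker")
            assert res.rcb < 0
            rw = fb.rcb_from_sample(s, pw, fname, "current_smoker",
                                    mode="reweighted", benchmark=bench,
                                    design_weights=dw)
            assert rw.rcb < 0


class TestReporting:
    @pytest.mark.parametrize("frame,overall,expected", [
        (16.9, 20.2, 3.3),
        (15.9, 19.0, 3.1),
        (12.5, 12.5, 0.0),
    ])
    def test_absolute_difference(self, frame, overall, expected):
        assert round(fb.absolute_difference(frame, overall), 1) == expected

    def test_summarize_range(self):
        assert fb.summarize_range([3.1, 2.9, 3.4, 3.1]) == (2.9, 3.4)
        assert fb.summarize_range([3.3, 4.4, 3.8, 5.3]) == (3.3, 5.3)
        assert fb.summarize_range([7.0]) == (7.0, 7.0)
        with pytest.raises(ValueError):
            fb.summarize_range([])
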