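"""Posterior indices (pd, HDI, ROPE decision) and mixed-model fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from selstop.bayes_contrasts import (
    ContrastDef,
    ModelSpec,
    PosteriorDraws,
    contrast,
    default_rope,
    fit_model,
    hdi,
    hdi_rope_decision,
    probability_of_direction,
    rope_percentage,
    summarize_contrast,
)


def brute_force_hdi(draws, prob=0.89):
    """Independent O(n^2) oracle: every draw pair as candidate endpoints."""
    d = np.sort(np.asarray(draws, dtype=float))
    n = d.size
    need = int(np.ceil(prob * n))
    best = (np.inf, None)
    for i in range(n):
        j = i + need - 1
        if j >= n:
            break
        if d[j] - d[i] < best[0]:
            best = (d[j] - d[i], (d[i], d[j]))
    return best[1]


def brute_force_pd(draws, null=0.0):
    d = np.asarray(draws) - null
    return 100.0 * max((d > 0).sum(), (d < 0).sum(), d.size / 2) / d.size


class TestIndices:
    def test_pd_one_signed(self):
        assert probability_of_direction(np.abs(np.random.default_rng(0)
                                               .normal(size=500)) + 0.1) == 100.0

    def test_pd_symmetric_near_half(self):
        d = np.random.default_rng(1).normal(0, 1, 20000)
        assert probability_of_direction(d) == pytest.approx(50.0, abs=1.5)

    def test_pd_matches_brute_force_exactly(self):
        d = np.random.default_rng(2).gamma(2, 1, 10_000) - 1.7
        assert probability_of_direction(d) == brute_force_pd(d)

    def test_hdi_matches_brute_force_exactly(self):
        d = np.random.default_rng(3).gamma(2, 1, 10_000)
        assert hdi(d) == brute_force_hdi(d)

    def test_hdi_of_standard_normal(self):
        d = np.random.default_rng(4).standard_normal(12_000)
        lo, hi = hdi(d)
        assert lo == pytest.approx(-1.598, abs=0.08)
        assert hi == pytest.approx(1.598, abs=0.08)

    def test_hdi_agrees_with_arviz(self):
        # arviz windows one extra order statistic (floor(p*n)+1 draws vs
        # ceil(p*n) here), so endpoints agree up to one draw spacing
        az = pytest.importorskip("arviz")
        d = np.random.default_rng(5).lognormal(0, 0.6, 8000)
        lo, hi = hdi(d)
        ref = az.hdi(d, hdi_prob=0.89)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)

    def test_hdi_refuses_few_draws(self):
        with pytest.raises(ValueError, match="100"):
            hdi(np.arange(50.0))

    def test_rope_percentage_containment(self):
        d = np.concatenate([np.zeros(900), np.full(100, 10.0)])
        pct = rope_percentage(d, (-0.5, 0.5), hdi_bounds=(-0.5, 0.5))
        assert pct == 100.0


class TestDecisionRule:
    @pytest.mark.parametrize("bounds,rope,expected", [
        ((-0.01, 0.02), (-0.05, 0.05), "accept_null"),
        ((0.10, 0.30), (-0.05, 0.05), "reject_null"),
        ((-0.20, -0.06), (-0.05, 0.05), "reject_null"),
        ((0.02, 0.30), (-0.05, 0.05), "undecided"),
        ((-0.05, 0.05), (-0.05, 0.05), "accept_null"),  # boundary inclusive
    ])
    def test_cases(self, bounds, rope, expected):
        assert hdi_rope_decision(bounds, rope) == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(st.floats(-2, 2), st.floats(-2, 2)),
           st.tuples(st.floats(-2, 2), st.floats(-2, 2)))
    def test_totality(self, b, r):
        bounds = tuple(sorted(b))
        rope = tuple(sorted(r))
        assert hdi_rope_decision(bounds, rope) in (
            "accept_null", "reject_null", "undecided")

    def test_default_ropes(self):
        assert default_rope("percent_change") == (-5.0, 5.0)
        assert default_rope("ratio") == (0.95, 1.05)
        assert default_rope("log_odds") == (-0.05, 0.05)
        assert default_rope("ms", reference=400.0) == (-20.0, 20.0)
        with pytest.raises(ValueError):
            default_rope("ms")

    def test_summary_invariants(self):
        d = np.random.default_rng(6).normal(0.1, 0.05, 5000)
        s = summarize_contrast(PosteriorDraws(d, "percent_change", "x"))
        assert s.hdi89_low <= s.median <= s.hdi89_high
        assert 50.0 <= s.pd <= 100.0
        assert 0.0 <= s.pct_hdi_in_rope <= 100.0


def _smoke_spec(family, response, factors=(), **kw):
    return ModelSpec(family=family, response=response,
                     fixed_factors=list(factors), chains=2, warmup_draws=400,
                     post_warmup_draws_per_chain=400, **kw)


class TestFits:
    def test_gaussian_intercept_recovers_mean(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.normal(2.0, 0.5, 160),
                           "subject_id": np.repeat(list("ABCDEFGH"), 20)})
        fit = fit_model(_smoke_spec("gaussian_identity", "y",
                                    random_cell_effects=False), df, 1)
        assert np.mean(fit.draws["intercept"]) == pytest.approx(2.0, abs=0.15)

    def test_gamma_intercept_back_transform(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "y": rng.gamma(2.5, 2.15 / 2.5, 600),
            "subject_id": np.repeat([f"S{i}" for i in range(6)], 100)})
        fit = fit_model(_smoke_spec("gamma_log", "y"), df, 2)
        assert np.exp(np.median(fit.draws["intercept"])) == pytest.approx(
            2.15, rel=0.12)

    def test_two_level_gamma_ratio_contrast(self):
        rng = np.random.default_rng(2)
        rows = []
        for s in range(6):
            g = np.exp(rng.normal(0, 0.2))
            for lev, m in (("a", 1.12), ("b", 0.87)):
                rows += [{"subject_id": f"S{s}", "lev": lev, "y": v}
                         for v in rng.gamma(4.0, g * m / 4.0, 80)]
        df = pd.DataFrame(rows)
        fit = fit_model(_smoke_spec("gamma_log", "y", ["lev"]), df, 3)
        pdr = contrast(fit, ContrastDef("ab", plus=["a"], minus=["b"],
                                        scale="ratio"))
        assert np.median(pdr.draws) == pytest.approx(1.287, rel=0.06)

    def test_self_contrast_is_null(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.normal(1.0, 0.2, 200),
                           "subject_id": np.repeat(list("ABCD"), 50)})
        fit = fit_model(_smoke_spec("gaussian_identity", "y",
                                    random_cell_effects=False), df, 4)
        pdr = contrast(fit, ContrastDef("self", plus=["intercept"],
                                        minus=["intercept"], scale="response"))
        assert np.all(pdr.draws == 0.0)

    def test_deterministic_percent_transform(self):
        fit_like = type("F", (), {})()
        # exercised through PosteriorDraws directly: ln(0.9) -> -10%
        d = np.full(500, np.log(0.9))
        pct = 100.0 * (np.exp(d) - 1.0)
        assert np.allclose(pct, -10.0)

    def test_reproducible_draws(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"y": rng.normal(0.0, 1.0, 120),
                           "subject_id": np.repeat(list("ABC"), 40)})
        spec = _smoke_spec("gaussian_identity", "y", random_cell_effects=False)
        a = fit_model(spec, df, 42).draws["intercept"]
        b = fit_model(spec, df, 42).draws["intercept"]
        assert np.array_equal(a, b)

    def test_unknown_cell_in_contrast_rejected(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"y": rng.normal(0.0, 1.0, 120),
                           "subject_id": np.repeat(list("ABC"), 40)})
        fit = fit_model(_smoke_spec("gaussian_identity", "y",
                                    random_cell_effects=False), df, 7)
        with pytest.raises(ValueError, match="unknown coefficient"):
            contrast(fit, ContrastDef("bad", plus=["nope"], minus=[]))

    def test_family_support_validation(self):
        df = pd.DataFrame({"y": [-1.0, 2.0], "subject_id": ["A", "A"]})
        with pytest.raises(ValueError, match="positive"):
            fit_model(_smoke_spec("gamma_log", "y"), df, 0)
        with pytest.raises(ValueError, match="0/1"):
            fit_model(_smoke_spec("bernoulli_logit", "y"), df, 0)

    def test_shifted_lognormal_requires_support(self):
        df = pd.DataFrame({"y": [100.0, 400.0], "subject_id": ["A", "A"]})
        with pytest.raises(ValueError, match="shift"):
            fit_model(_smoke_spec("shifted_lognormal_identity", "y",
                                  shift=150.0), df, 0)


class TestStoppingSuccessModel:
    def _fixture(self, slope, n=600, seed=0):
        rng = np.random.default_rng(seed)
        amp = rng.gamma(2.5, 1.7 / 2.5, n)
        eta = slope * amp
        y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        return pd.DataFrame({
            "amplitude": amp, "success": y.astype(int),
            "subject_id": np.repeat([f"S{i}" for i in range(6)], n // 6),
            "tms_timepoint": "IS"})

    def test_null_coupling_centres_on_zero(self):
        from selstop.bayes_contrasts import stopping_success_model
        out = stopping_success_model(self._fixture(0.0), rng_seed=1)
        s = out["IS"]
        assert s.hdi89_low < 0.0 < s.hdi89_high

    def test_planted_positive_coupling_detected(self):
        from selstop.bayes_contrasts import stopping_success_model
        out = stopping_success_model(self._fixture(1.5), rng_seed=2)
        assert out["IS"].pd > 99.0
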