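import subprocess
import textwrap

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import kstest

from kinetime.decoding import (DecodingSeries, decode_summary, pointwise_model,
                               sliding_decode)


def make_glmm_data(seed=0, n_sub=20, n_tr=50, coef_m=3.0, re_sd=0.8):
    rng = np.random.default_rng(seed)
    subj = np.repeat(np.arange(n_sub), n_tr)
    d = rng.choice(np.geomspace(1000, 4000, 7), size=n_sub * n_tr)
    m = rng.normal(0.5, 0.15, n_sub * n_tr)
    b = rng.normal(0, re_sd, n_sub)
    eta = 0.8 * (np.log(d) - np.log(2000)) + coef_m * (m - 0.5) + b[subj]
    y = (rng.random(len(eta)) < 1 / (1 + np.exp(-eta))).astype(float)
    return y, d, m, subj


class TestPointwiseModel:
    def test_zero_random_effect_reduces_to_logit(self):
        """With no subject effect in the data the GLMM slope matches a plain
        logistic regression within 5%."""
        y, d, m, subj = make_glmm_data(seed=3, coef_m=2.0, re_sd=0.0)
        res = pointwise_model(y, d, m, subj, include_duration=False)
        X = sm.add_constant(m - m.mean())
        logit = sm.Logit(y, X).fit(disp=0)
        assert res["coef_M"] == pytest.approx(logit.params[1], rel=0.05)

    def test_matches_lme4_laplace(self, tmp_path):
        """Cross-check coefficient, SE and variance against R lme4::glmer
        (Laplace, nAGQ=1) on the same data."""
        y, d, m, subj = make_glmm_data(seed=0)
        res = pointwise_model(y, d, m, subj)
        dstd = (d - d.mean()) / d.std()
        csv = tmp_path / "dat.csv"
        np.savetxt(csv, np.column_stack([y, dstd, m - m.mean(), subj]),
                   delimiter=",", header="y,d,m,s", comments="")
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            df <- read.csv("{csv}")
            fit <- glmer(y ~ 1 + d + m + (1|s), data=df, family=binomial, nAGQ=1)
            s <- summary(fit)
            cat(s$coefficients["m",1], s$coefficients["m",2],
                attr(VarCorr(fit)$s, "stddev"), sep=",")
        """)
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        coef_r, se_r, sd_r = map(float, out.stdout.strip().split(","))
        assert res["coef_M"] == pytest.approx(coef_r, rel=0.02)
        assert res["se_M"] == pytest.approx(se_r, rel=0.05)
        assert np.exp(res["theta"][-1]) == pytest.approx(sd_r, rel=0.05)

    def test_perfect_separation_flagged(self):
        rng = np.random.default_rng(1)
        subj = np.repeat(np.arange(10), 20)
        y = rng.integers(0, 2, 200).astype(float)
        m = y.copy()  # M == Y exactly
        d = np.full(200, 2000.0)
        res = pointwise_model(y, d, m, subj, include_duration=False)
        assert res["flag"] == "separation" and np.isnan(res["p_M"])

    def test_null_p_uniform(self):
        """Under a readout independent of choice the Wald p-values are
        approximately uniform (KS test over repeated simulations)."""
        ps = []
        for rep in range(120):
            rng = np.random.default_rng(200 + rep)
            subj = np.repeat(np.arange(12), 30)
            b = rng.normal(0, 0.8, 12)
            y = (rng.random(360) < 1 / (1 + np.exp(-b[subj]))).astype(float)
            m = rng.normal(0.5, 0.15, 360)
            d = rng.choice([1000.0, 2000.0, 4000.0], 360)
            ps.append(pointwise_model(y, d, m, subj)["p_M"])
        ps = np.asarray(ps)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError):
            pointwise_model([1, 0], [1000, 2000], [0.4, 0.6], ["a", "a"])


class TestSlidingDecode:
    def test_bonferroni_arithmetic_1000_tests(self):
        """1000 columns at alpha 0.05 give the adjusted threshold 5e-5."""
        rng = np.random.default_rng(0)
        n = 240
        subj = np.repeat(np.arange(12), 20)
        y = rng.integers(0, 2, n).astype(float)
        d = rng.choice([1000.0, 2000.0, 4000.0], n)
        mat = rng.normal(0.5, 0.1, (n, 1000))
        times = np.arange(-1000, 0)
        # only a handful of columns need fitting to check the arithmetic:
        # make all but 3 columns constant (degenerate -> NaN p, fast path)
        mat[:, :-3] = 0.5
        series = sliding_decode(y, d, subj, times, mat)
        assert series.alpha_adj == pytest.approx(0.05 / 1000)
        assert len(series.p_M) == 1000

    def test_signal_growing_toward_offset_detected(self):
        """A readout whose separation ramps up toward tone offset yields a
        contiguous significant run ending at offset."""
        rng = np.random.default_rng(5)
        n_sub, n_tr, n_t = 16, 40, 40
        subj = np.repeat(np.arange(n_sub), n_tr)
        n = n_sub * n_tr
        b = rng.normal(0, 0.5, n_sub)
        y = (rng.random(n) < 1 / (1 + np.exp(-b[subj]))).astype(float)
        d = rng.choice(np.geomspace(1000, 4000, 7), n)
        gain = np.linspace(0, 0.25, n_t)  # separation grows toward offset
        mat = 0.5 + np.outer(2 * y - 1, gain) + rng.normal(0, 0.12, (n, n_t))
        times = np.arange(-n_t * 25 + 24, 0, 25)
        series = sliding_decode(y, d, subj, times, mat)
        assert series.earliest_sig_ms is not None
        assert series.sig_mask[-1]
        assert series.earliest_sig_ms >= 25

    def test_null_has_no_run_at_offset(self):
        rng = np.random.default_rng(9)
        subj = np.repeat(np.arange(12), 25)
        n = 300
        y = rng.integers(0, 2, n).astype(float)
        d = rng.choice([1000.0, 2000.0, 4000.0], n)
        mat = rng.normal(0.5, 0.1, (n, 20))
        series = sliding_decode(y, d, subj, np.arange(-20, 0), mat)
        assert series.earliest_sig_ms is None or series.earliest_sig_ms <= 2

    def test_middle_only_restricts_trials(self):
        rng = np.random.default_rng(3)
        subj = np.repeat(np.arange(10), 30)
        n = 300
        d = rng.choice([1000.0, 2000.0, 4000.0], n)
        y = rng.integers(0, 2, n).astype(float)
        mat = rng.normal(0.5, 0.1, (n, 5))
        s = sliding_decode(y, d, subj, np.arange(-5, 0), mat, variant="middle_only",
                           middle_duration_ms=2000.0)
        assert len(s.p_M) == 5  # runs on the restricted subset without error

    def test_unknown_variant_raises(self):
        with pytest.raises(ValueError):
            sliding_decode([1, 0], [1, 2], [0, 1], [0], np.zeros((2, 1)),
                           variant="nope")


class TestDecodeSummary:
    def make_series(self, sig):
        sig = np.asarray(sig, bool)
        n = len(sig)
        return DecodingSeries(times_ms=np.arange(-n, 0), coef_M=np.zeros(n),
                              p_M=np.where(sig, 1e-9, 0.5), alpha=0.05,
                              alpha_adj=0.05 / n, sig_mask=sig,
                              earliest_sig_ms=float(n) if sig.all() else None)

    def test_identical_inputs_zero_difference(self):
        a = self.make_series([True] * 5)
        b = self.make_series([True] * 5)
        out = decode_summary(a, b)
        assert out["earliest_sig_ms"].nunique() == 1
        assert out["n_sig_corrected"].nunique() == 1

    def test_empty_masks_both_none(self):
        out = decode_summary(self.make_series([False] * 4),
                             self.make_series([False] * 4))
        assert out["earliest_sig_ms"].isna().all()

    def test_mismatched_windows_raise(self):
        with pytest.raises(ValueError):
            decode_summary(self.make_series([True] * 4), self.make_series([True] * 5))
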