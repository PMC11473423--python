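import itertools
import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

from frontolimbic import (
    GeneratorConfig,
    SmoothSpec,
    fdr_adjust,
    fit_all_regions,
    fit_trajectory,
    group_anova_lsd,
    select_by_bic,
    simulate_cohort,
)
from frontolimbic.gam import _SmoothBasis, _penalized_fit


def brute_force_bh(p):
    """Step-up BH by direct definition: q_i = min over j>=i of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestPenalizedSolver:
    def test_matches_augmented_least_squares(self, ages57):
        """Penalized normal equations equal lstsq on the sqrt-penalty
        augmented system (independent oracle for the solver)."""
        rng = np.random.default_rng(5)
        basis = _SmoothBasis(ages57, 6)
        n = len(ages57)
        X = np.column_stack([np.ones(n), rng.random(n), basis.Z])
        S_full = np.zeros((X.shape[1],) * 2)
        S_full[2:, 2:] = basis.S
        y = rng.normal(0, 1, n)
        lam = 3.7
        beta, *_ = _penalized_fit(X, y, S_full, lam)
        ev, U = np.linalg.eigh(lam * S_full)
        ev = np.clip(ev, 0, None)
        root = U @ np.diag(np.sqrt(ev)) @ U.T
        Xa = np.vstack([X, root])
        ya = np.concatenate([y, np.zeros(X.shape[1])])
        beta_oracle = np.linalg.lstsq(Xa, ya, rcond=None)[0]
        assert np.allclose(beta, beta_oracle, atol=1e-8)

    def test_infinite_penalty_reproduces_linear_fit(self, ages57):
        rng = np.random.default_rng(6)
        basis = _SmoothBasis(ages57, 6)
        n = len(ages57)
        sex = (rng.random(n) < 0.7).astype(float)
        X = np.column_stack([np.ones(n), sex, basis.Z])
        S_full = np.zeros((X.shape[1],) * 2)
        S_full[2:, 2:] = basis.S
        y = rng.normal(0, 1, n) + 0.03 * ages57
        beta, rss, *_ = _penalized_fit(X, y, S_full, 1e12)
        Xl = np.column_stack([np.ones(n), sex, ages57])
        bl, *_ = np.linalg.lstsq(Xl, y, rcond=None)
        fitted_lin = Xl @ bl
        assert np.allclose(X @ beta, fitted_lin, atol=1e-5)


class TestFitTrajectory:
    def test_noiseless_linear_truth(self, ages57, sex57):
        fit = fit_trajectory(ages57, 2 + 0.05 * ages57, sex57)
        assert abs(fit.edf - 1.0) < 0.05
        assert abs(fit.sex_coefficient) < 1e-6
        assert fit.selected_model == "linear"

    def test_noiseless_quadratic_peak_location(self, ages57, sex57):
        y = 10 - 0.01 * (ages57 - 40.0) ** 2
        fit = fit_trajectory(ages57, y, sex57)
        assert fit.edf > 1
        curve = fit.fitted_curve
        argmax = curve.loc[curve.fit.idxmax(), "age_months"]
        assert abs(argmax - 40.0) <= 1.0
        assert fit.selected_model == "smooth"

    def test_edf_within_admissible_range(self, ages57, sex57):
        rng = np.random.default_rng(2)
        for _ in range(5):
            fit = fit_trajectory(ages57, rng.normal(0, 1, 57), sex57)
            assert 1.0 <= fit.edf <= 5.0 + 1e-6  # [1, k-1] for k=6

    def test_sex_offset_shifts_coefficient_not_smooth(self, ages57, sex57):
        rng = np.random.default_rng(3)
        y = 3 + 0.02 * ages57 + rng.normal(0, 0.3, 57)
        fit0 = fit_trajectory(ages57, y, sex57)
        y2 = y + 1.5 * (sex57 == "male")
        fit1 = fit_trajectory(ages57, y2, sex57)
        assert fit1.sex_coefficient - fit0.sex_coefficient == pytest.approx(1.5, abs=0.05)
        assert abs(fit1.edf - fit0.edf) < 0.2

    def test_small_sample_refused(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_trajectory([20] * 5 + [30] * 4, np.arange(9.0), ["male"] * 9)

    def test_trend_sign_recovery_under_noise(self, ages57, sex57):
        """Standardized slope 0.5: the fitted linear trend sign matches the
        generating sign in >=95% of replicates."""
        age_sd = ages57.std()
        slope = 0.5 / age_sd  # unit-variance noise
        ok = 0
        n_rep = 40
        for r in range(n_rep):
            rng = np.random.default_rng(900 + r)
            y = slope * ages57 + rng.normal(0, 1, 57)
            fit = fit_trajectory(ages57, y, sex57)
            c = fit.fitted_curve
            ok += np.polyfit(c.age_months, c.fit, 1)[0] > 0
        assert ok / n_rep >= 0.95


class TestModelSelection:
    def test_bic_tie_breaks_to_simpler(self):
        assert select_by_bic({"intercept": 1.0, "linear": 1.0, "smooth": 1.0}) == "intercept"
        assert select_by_bic({"intercept": 2.0, "linear": 1.0, "smooth": 1.0}) == "linear"

    def test_linear_truth_selects_linear(self, ages57, sex57):
        hits = 0
        for r in range(10):
            rng = np.random.default_rng(100 + r)
            y = 1 + 0.05 * ages57 + rng.normal(0, 0.3, 57)
            hits += fit_trajectory(ages57, y, sex57).selected_model == "linear"
        assert hits >= 8

    def test_curved_truth_selects_smooth(self, ages57, sex57):
        hits = 0
        for r in range(10):
            rng = np.random.default_rng(200 + r)
            y = np.sin(ages57 / 8.0) + rng.normal(0, 0.15, 57)
            hits += fit_trajectory(ages57, y, sex57).selected_model == "smooth"
        assert hits >= 8


class TestFdrAdjust:
    def test_worked_vector(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_constant_vectors(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(fdr_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_matches_brute_force_on_permutations(self):
        rng = np.random.default_rng(11)
        base = rng.uniform(0.001, 1.0, 6)
        for perm in itertools.permutations(range(6)):
            p = base[list(perm)]
            assert np.allclose(fdr_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            fdr_adjust([1.5])


class TestFitAllRegions:
    def test_bookkeeping_row_counts(self, default_cohort):
        cohort, _ = default_cohort
        fits, failures = fit_all_regions(cohort, "volume_mm3")
        assert len(fits) == 22 and not failures  # 11 regions x 2 hemispheres
        fits_t, _ = fit_all_regions(cohort, "thickness_mm")
        assert len(fits_t) == 16  # 8 cortical pairs x 2
        for f in fits:
            assert f.q_value >= f.p_value - 1e-12

    def test_planted_signal_attains_smallest_q(self):
        """One strongly age-dependent region among flat regions wins the family."""
        import dataclasses
        from frontolimbic.simulate import TrajectorySpec, default_region_specs

        specs = []
        for rs in default_region_specs():
            flat_v = TrajectorySpec("constant", c=rs.volume.c)
            if rs.name == "fusiform":
                strong = TrajectorySpec("linear", c=rs.volume.c * 0.7,
                                        b=rs.volume.c * 0.6 / 57.0)
                specs.append(dataclasses.replace(rs, volume=strong))
            else:
                specs.append(dataclasses.replace(rs, volume=flat_v))
        cfg = GeneratorConfig(region_specs=specs, subject_scale_sd=0.0, seed=21)
        cohort, _ = simulate_cohort(cfg)
        fits, _ = fit_all_regions(cohort, "volume_mm3", mode="absolute")
        for hemi in ("left", "right"):
            block = [f for f in fits if f.hemisphere == hemi]
            best = min(block, key=lambda f: f.q_value)
            assert best.region_name == "fusiform"


class TestAgainstMgcv:
    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_fit_close_to_mgcv_reml(self, tmp_path, ages57, sex57):
        """Independent GAM oracle: mgcv with a cubic regression spline and
        REML gives the same curve, sex effect and similar edf."""
        rng = np.random.default_rng(7)
        noise_sd = 0.4
        y = 5 + 0.08 * ages57 - 0.0012 * (ages57 - 45) ** 2 + rng.normal(0, noise_sd, 57)
        fit = fit_trajectory(ages57, y, sex57)
        male = (sex57 == "male").astype(float)
        data = tmp_path / "d.csv"
        np.savetxt(data, np.column_stack([ages57, y, male]), delimiter=",",
                   header="age,y,male", comments="")
        curve_out = tmp_path / "curve.csv"
        r_code = f"""
        d <- read.csv("{data}")
        m <- mgcv::gam(y ~ male + s(age, k=6, bs="cr"), data=d, method="REML")
        s <- summary(m)
        grid <- data.frame(age={int(ages57.min())}:{int(ages57.max())}, male=mean(d$male))
        pred <- predict(m, newdata=grid)
        cat(sprintf("%.6f %.6f\\n", s$edf[1], coef(m)["male"]))
        write.csv(data.frame(age_months=grid$age, fit_r=pred), "{curve_out}", row.names=FALSE)
        """
        res = subprocess.run(["Rscript", "-e", r_code], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        edf_r, sex_r = map(float, res.stdout.split()[-2:])
        assert fit.sex_coefficient == pytest.approx(sex_r, abs=0.05)
        assert abs(fit.edf - edf_r) < 0.75
        import pandas as pd

        merged = fit.fitted_curve.merge(pd.read_csv(curve_out), on="age_months")
        rms = float(np.sqrt(((merged.fit - merged.fit_r) ** 2).mean()))
        assert rms < 0.25 * noise_sd


class TestGroupAnovaLsd:
    def test_two_group_lsd_equals_pooled_t_test(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 9)
        values = np.concatenate([a, b])
        groups = np.array([1] * 12 + [2] * 9)
        F, p, pairwise = group_anova_lsd(values, groups)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert pairwise[(1, 2)]["p"] == pytest.approx(p_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)  # F test == t^2 for k=2

    def test_extreme_separation(self):
        rng = np.random.default_rng(14)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(10, 1, 10)])
        groups = np.array([1] * 10 + [2] * 10)
        _, p, _ = group_anova_lsd(values, groups)
        assert p < 1e-3

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(15)
        ps = []
        for _ in range(200):
            values = rng.normal(0, 1, 20)
            groups = np.array([1] * 10 + [2] * 10)
            ps.append(group_anova_lsd(values, groups)[1])
        assert 0.01 < np.mean(np.array(ps) < 0.05) < 0.12
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            group_anova_lsd([1.0, 2.0, 3.0], ["a", "a", "b"])
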