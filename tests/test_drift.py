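import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from md3f import (
    PairSet,
    StudyDesign,
    build_pairs,
    compare_group_drifts,
    distance_matrix,
    fit_md3f,
    fit_pairs_arrays,
    fit_per_subject,
    replicate_rng,
    simulate_prepost,
    simulate_trajectory,
    SimulationScenario,
)


def _dist_from_design(design: StudyDesign, positions: dict[str, np.ndarray]):
    ids = design.sample_ids
    pts = np.vstack([positions[s] for s in ids])
    return distance_matrix(squareform(pdist(pts)), ids)


def _line_design(times, subject="A"):
    frame = pd.DataFrame(
        {
            "sample": [f"{subject}{k}" for k in range(len(times))],
            "subject": subject,
            "time": times,
        }
    )
    positions = {f"{subject}{k}": np.array([float(t)]) for k, t in enumerate(times)}
    return StudyDesign(frame), positions


class TestBuildPairs:
    def test_baseline_mode_counts_and_intervals(self):
        design, pos = _line_design([0.0, 1.0, 2.0])
        pairs = build_pairs(_dist_from_design(design, pos), design, mode="baseline")
        assert sorted(pairs.delta_t) == [1.0, 2.0]
        assert sorted(pairs.distance) == [1.0, 2.0]

    def test_all_pairs_mode_counts(self):
        design, pos = _line_design([0.0, 1.0, 2.0])
        pairs = build_pairs(_dist_from_design(design, pos), design, mode="all_pairs")
        assert len(pairs) == 3

    def test_modes_coincide_for_two_timepoints(self):
        rows = []
        positions = {}
        rng = np.random.default_rng(0)
        for subj in ("A", "B"):
            for k, t in enumerate([0.0, 2.0]):
                sid = f"{subj}{k}"
                rows.append({"sample": sid, "subject": subj, "time": t})
                positions[sid] = rng.normal(size=3)
        design = StudyDesign(pd.DataFrame(rows))
        dist = _dist_from_design(design, positions)
        results = {
            mode: build_pairs(dist, design, mode=mode)
            for mode in ("baseline", "consecutive", "all_pairs")
        }
        for pairs in results.values():
            assert len(pairs) == 2
        ref = results["baseline"]
        for pairs in results.values():
            np.testing.assert_allclose(sorted(pairs.distance), sorted(ref.distance))

    def test_single_timepoint_subject_skipped_with_warning(self):
        design, pos = _line_design([0.0, 1.0, 2.0])
        lone = pd.DataFrame({"sample": ["L0"], "subject": ["L"], "time": [0.0]})
        merged = StudyDesign(pd.concat([design.frame, lone], ignore_index=True))
        pos["L0"] = np.array([9.0])
        with pytest.warns(UserWarning, match="fewer than 2"):
            pairs = build_pairs(_dist_from_design(merged, pos), merged)
        assert set(pairs.subject) == {"A"}

    def test_duplicate_time_errors_unless_deduped(self):
        frame = pd.DataFrame(
            {
                "sample": ["A0", "A1", "A2", "A3"],
                "subject": "A",
                "time": [0.0, 1.0, 1.0, 2.0],
            }
        )
        design = StudyDesign(frame)
        pos = {s: np.array([float(i)]) for i, s in enumerate(frame["sample"])}
        dist = _dist_from_design(design, pos)
        with pytest.raises(ValueError, match="duplicate"):
            build_pairs(dist, design)
        pairs = build_pairs(dist, design, dedupe="first")
        assert len(pairs) == 2  # times 1 and 2 vs baseline 0, first A1 kept

    def test_missing_sample_in_distances_rejected(self):
        design, pos = _line_design([0.0, 1.0, 2.0])
        short = StudyDesign(design.frame.iloc[:2])
        dist = _dist_from_design(short, pos)
        with pytest.raises(ValueError, match="absent"):
            build_pairs(dist, design)

    def test_pairset_validation(self):
        with pytest.raises(ValueError, match="positive"):
            PairSet(np.array([0.0]), np.array([1.0]), np.array(["a"]), "baseline")


class TestFitMD3F:
    def test_exact_linear2_recovery(self):
        """Noiseless d^2 = t*(3 + 4t) is recovered exactly by the default model."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.sqrt(t * (3.0 + 4.0 * t))
        fit = fit_pairs_arrays(t, d, model="linear2", scaling="time_scaled")
        assert fit.slope == pytest.approx(4.0, abs=1e-9)
        assert fit.intercept == pytest.approx(3.0, abs=1e-9)
        assert fit.alpha_hat == pytest.approx(2.0, abs=1e-9)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-9)

    def test_constant_distance_gives_zero_drift(self):
        t = np.array([1.0, 2.0, 3.0])
        d = np.full(3, 5.0)
        fit = fit_pairs_arrays(t, d, model="linear", scaling="literal")
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.alpha_hat == 0.0

    @pytest.mark.parametrize(
        "model,scaling,xfun,yfun",
        [
            ("linear2", "time_scaled", lambda t: t, lambda d, t: d**2 / t),
            ("linear2", "literal", lambda t: t**2, lambda d, t: d**2),
            ("linear", "time_scaled", lambda t: np.sqrt(t), lambda d, t: d / np.sqrt(t)),
            ("linear", "literal", lambda t: t, lambda d, t: d),
        ],
    )
    def test_each_variant_matches_direct_ols(self, model, scaling, xfun, yfun):
        rng = np.random.default_rng(1)
        t = rng.exponential(size=25) + 0.05
        d = np.abs(rng.normal(size=25)) * np.sqrt(t)
        fit = fit_pairs_arrays(t, d, model=model, scaling=scaling)
        ref = stats.linregress(xfun(t), yfun(d, t))
        assert fit.slope == pytest.approx(ref.slope, rel=1e-12)
        assert fit.intercept == pytest.approx(ref.intercept, rel=1e-12)
        assert fit.slope_p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_negative_slope_clipped_to_zero_drift(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.sqrt(np.maximum(10.0 - 2.0 * t, 0.1) * t)
        fit = fit_pairs_arrays(t, d)
        assert fit.slope < 0
        assert fit.alpha_hat == 0.0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(size=30) + 0.01
        d = rng.exponential(size=30)
        base = fit_pairs_arrays(t, d)
        scaled = fit_pairs_arrays(t, 3.0 * d)
        assert scaled.slope == pytest.approx(9.0 * base.slope, rel=1e-9)
        assert scaled.alpha_hat == pytest.approx(3.0 * base.alpha_hat, rel=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_pairs_arrays(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_zero_regressor_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_pairs_arrays(np.ones(5), np.arange(5.0))

    def test_fit_md3f_on_pairset_matches_array_path(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.array([1.1, 2.0, 2.9, 4.2])
        pairs = PairSet(t, d, np.array(["a"] * 4, dtype=object), "baseline")
        assert fit_md3f(pairs).slope == pytest.approx(fit_pairs_arrays(t, d).slope)

    def test_null_pvalues_approximately_uniform(self):
        """Under pure diffusion the slope-test p-values are ~Uniform(0,1)."""
        sc = SimulationScenario(n=50, d=10, alpha=0.0)
        pvals = np.empty(2000)
        for r in range(2000):
            s = simulate_prepost(sc, rng=replicate_rng(17, r))
            pvals[r] = fit_pairs_arrays(s.times, s.distances()).slope_p
        assert stats.kstest(pvals, "uniform").pvalue > 0.001


class TestFitPerSubject:
    def _multi_subject(self, n_subjects=5, n_times=5, rng=None):
        rng = rng or np.random.default_rng(4)
        rows, positions = [], {}
        for i in range(n_subjects):
            subj = f"S{i}"
            for k in range(n_times):
                sid = f"{subj}t{k}"
                rows.append({"sample": sid, "subject": subj, "time": float(k)})
                positions[sid] = rng.normal(size=4) + k
        design = StudyDesign(pd.DataFrame(rows))
        return design, _dist_from_design(design, positions)

    def test_all_subjects_fitted(self):
        design, dist = self._multi_subject()
        fits = fit_per_subject(dist, design)
        assert len(fits.fits) == 5
        assert fits.skipped == {}

    def test_three_timepoints_baseline_mode_skipped(self):
        design, dist = self._multi_subject(n_subjects=1, n_times=3)
        with pytest.raises(ValueError, match="no subject"):
            fit_per_subject(dist, design, mode="baseline")

    def test_short_subject_reported_as_skipped(self):
        rng = np.random.default_rng(5)
        design, dist = self._multi_subject(rng=rng)
        short_rows = [
            {"sample": f"Zt{k}", "subject": "Z", "time": float(k)} for k in range(3)
        ]
        frame = pd.concat([design.frame, pd.DataFrame(short_rows)], ignore_index=True)
        merged = StudyDesign(frame)
        positions = {s: rng.normal(size=4) for s in merged.sample_ids}
        dist = _dist_from_design(merged, positions)
        fits = fit_per_subject(dist, merged, mode="baseline")
        assert fits.skipped == {"Z": "insufficient pairs"}
        assert len(fits.fits) == 5

    def test_drift_magnitude_recovered_across_subjects(self):
        """Mean per-subject alpha-hat over 200 simulated walks recovers alpha=1."""
        sc = SimulationScenario(n=2, d=10, alpha=1.0)
        alpha_hats = np.empty(200)
        for r in range(200):
            tr = simulate_trajectory(sc, n_steps=20, dt=1.0, rng=replicate_rng(7, r))
            dt, d = tr.baseline_pairs()
            alpha_hats[r] = fit_pairs_arrays(dt, d).alpha_hat
        se = alpha_hats.std(ddof=1) / np.sqrt(200)
        assert abs(alpha_hats.mean() - 1.0) < 3 * se


class TestCompareGroupDrifts:
    def _fits_for(self, alpha_hats_by_group):
        from md3f.drift import MD3FFit, PerSubjectFits

        fits, rows = {}, []
        i = 0
        for group, values in alpha_hats_by_group.items():
            for v in values:
                subj = f"s{i}"
                fits[subj] = MD3FFit(
                    "linear2", "time_scaled", v**2, 1.0, 0.1, 0.1, 0.5, v, 5
                )
                rows.append(
                    {"sample": f"{subj}x", "subject": subj, "time": 0.0, "group": group}
                )
                i += 1
        return PerSubjectFits(fits, {}), StudyDesign(pd.DataFrame(rows))

    def test_identical_groups_give_t_zero_p_one(self):
        fits, design = self._fits_for({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0]})
        cmp = compare_group_drifts(fits, design)
        assert cmp.t_statistic == 0.0
        assert cmp.p_value == 1.0

    def test_separated_groups_are_significant(self):
        fits, design = self._fits_for({"a": [0.0, 0.0, 0.0], "b": [10.0, 10.0, 10.1]})
        cmp = compare_group_drifts(fits, design)
        assert cmp.p_value < 0.01
        assert cmp.group_means[0] == pytest.approx(0.0)

    def test_matches_pooled_variance_t_test(self):
        g1, g2 = [0.4, 0.9, 1.3, 0.7], [1.1, 1.5, 0.8]
        fits, design = self._fits_for({"a": g1, "b": g2})
        cmp = compare_group_drifts(fits, design)
        ref = stats.ttest_ind(g1, g2, equal_var=True)
        assert cmp.t_statistic == pytest.approx(ref.statistic)
        assert cmp.p_value == pytest.approx(ref.pvalue)

    def test_wrong_group_count_rejected(self):
        fits, design = self._fits_for({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="exactly 2"):
            compare_group_drifts(fits, design)

    def test_equal_alpha_groups_calibrated(self, two_group_design):
        """Rejection rate of the group test is near nominal when groups share alpha."""
        rej = 0
        n_rep = 400
        sc = SimulationScenario(n=2, d=5, alpha=1.0)
        for r in range(n_rep):
            rng = replicate_rng(23, r)
            alpha_hats = {"ctrl": [], "case": []}
            for g in ("ctrl", "case"):
                for _ in range(8):
                    tr = simulate_trajectory(sc, n_steps=10, dt=1.0, rng=rng)
                    dt, d = tr.baseline_pairs()
                    alpha_hats[g].append(fit_pairs_arrays(dt, d).alpha_hat)
            p = stats.ttest_ind(
                alpha_hats["ctrl"], alpha_hats["case"], equal_var=True
            ).pvalue
            rej += p < 0.05
        frac = rej / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(frac - 0.05) < 3.5 * se
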