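"""Generator contracts: reproducibility, planted structure, trends."""

import numpy as np
import pytest

from cesep.chemometrics import cluster_profiles
from cesep.design import build_candidate_set
from cesep.efficiency import efficiency_index
from cesep.errors import DomainError
from cesep.peaks import HYPOGYMNIA_ANALYTES, detect_peaks, resolution_set
from cesep.rsm import backward_eliminate, fit_quadratic, fit_statistics
from cesep.synthetic import (
    RS_NAMES,
    make_truth,
    simulate_doe_responses,
    simulate_electropherogram,
    simulate_species_profiles,
    true_peak_table,
)

CENTER = {"boric_acid": 40.0, "doc": 65.0, "meoh": 12.5, "ph": 9.3}


class TestMakeTruth:
    def test_same_seed_identical(self, fs):
        t1, t2 = make_truth(5, fs), make_truth(5, fs)
        for name in t1.coef:
            assert np.array_equal(t1.coef[name], t2.coef[name])
        assert t1.noise_sd == t2.noise_sd

    def test_null_preset_zero_effects(self, fs):
        truth = make_truth(6, fs, "null")
        for name, beta in truth.coef.items():
            assert np.allclose(beta[1:], 0.0)

    def test_unknown_preset(self, fs):
        with pytest.raises(DomainError):
            make_truth(0, fs, "impossible")

    def test_easy_preset_resolutions_stay_in_safe_band(self, fs):
        """All Rs surfaces remain inside (1, 1.5): cap and penalty inactive."""
        truth = make_truth(7, fs)
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.uniform(-1, 1, size=(500, 4)), build_candidate_set(fs, 3)])
        for name in RS_NAMES:
            vals = truth.surface(name, pts)
            assert np.all(vals > 1.0) and np.all(vals < 1.5)

    def test_easy_preset_e_is_mean_of_rs(self, fs, design25):
        truth = make_truth(8, fs)
        resp = simulate_doe_responses(truth, design25, seed=1, noise_scale=0.0)
        assert np.allclose(resp["E"], resp[list(RS_NAMES)].mean(axis=1), atol=1e-12)

    def test_analytic_argmax_interior(self, fs):
        for s in range(10):
            x = make_truth(100 + s, fs).analytic_argmax()
            assert np.all(np.abs(x) < 1.0)

    def test_mt_increases_in_mobile_phase_factors(self, fs):
        """dMT/dx > 0 for boric acid, DOC and MeOH over the whole box."""
        truth = make_truth(9, fs)
        rng = np.random.default_rng(1)
        pts = rng.uniform(-1, 1, size=(200, 4))
        eps = 1e-6
        for axis in range(3):
            shifted = pts.copy()
            shifted[:, axis] = np.clip(shifted[:, axis] + eps, -1, 1)
            diff = truth.surface("MT", shifted) - truth.surface("MT", pts)
            assert np.all(diff >= 0)

    def test_zero_factor_terms(self, fs):
        truth = make_truth(10, fs, zero_factors=("doc",))
        for name in RS_NAMES:
            for j, term in enumerate(truth.spec.terms):
                if "doc" in term:
                    assert truth.coef[name][j] == 0.0


class TestSimulateDoeResponses:
    def test_zero_noise_exact_polynomial(self, fs, design25):
        truth = make_truth(11, fs)
        resp = simulate_doe_responses(truth, design25, seed=2, noise_scale=0.0)
        for name in RS_NAMES:
            assert np.allclose(resp[name], truth.surface(name, design25.coded), atol=1e-14)

    def test_fit_recovers_truth(self, fs, quad_spec, design25):
        truth = make_truth(12, fs)
        resp = simulate_doe_responses(truth, design25, seed=3, noise_scale=0.0)
        model = fit_quadratic(design25, resp["Rs4"], quad_spec)
        assert np.allclose(model.coef, truth.coef["Rs4"], atol=1e-8)

    def test_residual_sd_matches_noise(self, fs, quad_spec):
        """Residual SD of the fit approaches the planted noise SD at large n."""
        truth = make_truth(13, fs)
        rng = np.random.default_rng(4)
        coded = rng.uniform(-1, 1, size=(400, 4))
        from cesep.design import DesignMatrix

        dm = DesignMatrix(coded=coded)
        resp = simulate_doe_responses(truth, dm, seed=5)
        y = resp["Rs1"].to_numpy()
        model = fit_quadratic(dm, y, quad_spec)
        resid = y - model.predict_coded(coded)
        sd = resid.std(ddof=quad_spec.n_params)
        assert sd == pytest.approx(truth.noise_sd["Rs1"], rel=0.15)

    def test_replicates_get_independent_noise(self, fs, design25):
        truth = make_truth(14, fs)
        resp = simulate_doe_responses(truth, design25, seed=6)
        reps = resp.loc[design25.replicate_flags, "Rs1"]
        assert reps.nunique() == len(reps)

    def test_realistic_refined_r2_in_reported_span(self, fs, quad_spec, design25):
        """Median refined-model R² over seeds falls in the mid panel span."""
        r2s = []
        for s in range(30):
            truth = make_truth(3000 + s, fs, "realistic")
            resp = simulate_doe_responses(truth, design25, seed=4000 + s)
            y = resp["Rs1"].to_numpy()
            refined = backward_eliminate(fit_quadratic(design25, y, quad_spec), design25, y)
            r2s.append(fit_statistics(refined, design25, y).r2)
        assert 0.5 <= np.median(r2s) <= 0.95


class TestElectropherogramGenerator:
    def test_round_trip_recovers_all_analytes(self, fs):
        truth = make_truth(15, fs)
        eg, table = simulate_electropherogram(truth, CENTER, seed=7, noise_sd=0.0)
        det = detect_peaks(eg, min_snr=10)
        assert len(det) == len(HYPOGYMNIA_ANALYTES)
        for p in table:
            assert any(abs(q.mt - p.mt) < 0.02 for q in det)

    def test_meoh_strictly_prolongs_migration(self, fs):
        truth = make_truth(16, fs)
        low = true_peak_table(truth, {**CENTER, "meoh": 5.0})
        high = true_peak_table(truth, {**CENTER, "meoh": 20.0})
        for analyte in HYPOGYMNIA_ANALYTES:
            assert high[analyte].mt > low[analyte].mt

    def test_coelution_engages_penalty(self, fs):
        truth = make_truth(17, fs)
        table = true_peak_table(truth, {"boric_acid": 60.0, "doc": 65.0, "meoh": 25.0, "ph": 9.3})
        rs = resolution_set(table)
        assert np.any(rs.values < 1.0)
        res = efficiency_index(rs)
        assert res.e < np.mean(rs.values)

    def test_same_seed_identical_trace(self, fs):
        truth = make_truth(18, fs)
        eg1, _ = simulate_electropherogram(truth, CENTER, seed=8)
        eg2, _ = simulate_electropherogram(truth, CENTER, seed=8)
        assert np.array_equal(eg1.signal, eg2.signal)


class TestSpeciesProfiles:
    def test_two_blocks_recovered(self):
        m = simulate_species_profiles(16, 10, groups=(8, 8), seed=9)
        groups = cluster_profiles(m).cut(2)
        by_group = {}
        for label, g in groups.items():
            by_group.setdefault(g, set()).add(label.split("_")[0])
        assert all(len(prefixes) == 1 for prefixes in by_group.values())

    def test_single_group_has_no_stable_split(self):
        """Merge-height gap at k=2 is much larger for true 2-block data."""
        gaps_one, gaps_two = [], []
        for s in range(10):
            one = cluster_profiles(simulate_species_profiles(12, 8, groups=(12,), seed=s))
            two = cluster_profiles(simulate_species_profiles(12, 8, groups=(6, 6), seed=s))
            gaps_one.append(one.heights[-1] - one.heights[-2])
            gaps_two.append(two.heights[-1] - two.heights[-2])
        assert np.median(gaps_two) > 5 * np.median(gaps_one)

    def test_same_seed_identical(self):
        a = simulate_species_profiles(9, 7, groups=(4, 5), seed=10)
        b = simulate_species_profiles(9, 7, groups=(4, 5), seed=10)
        assert a.equals(b)

    def test_bad_group_sizes(self):
        with pytest.raises(DomainError):
            simulate_species_profiles(10, 8, groups=(4, 4), seed=0)
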