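"""Estimation tests: endpoint transforms, 4PL potency fitting, geometric
statistics, naive-pooled PK and effect-compartment fits (exact-data
recovery, grid-search optimality oracles, seeded noisy recovery), exposure
normalization and the pooled cross-compound Emax fit."""

import numpy as np
import pytest

import navpkpd as nv
from navpkpd.core import DoseEvent, DoseRegimen, PDStudy, PKStudy
from navpkpd.estimation import _four_pl, fit_ic50_4pl
from navpkpd.synthetic import (
    DEFAULT_PK,
    FMRIDesign,
    InVitroDesign,
    NoiseSpec,
    SatellitePKDesign,
    compound24_fmri_design,
    generate_fmri_study,
    generate_invitro_dataset,
    generate_satellite_pk_study,
)


class TestEndpointTransforms:
    @pytest.mark.parametrize(
        "control,drug,expected", [(100, 25, 75.0), (100, 100, 0.0), (50, 0, 100.0)]
    )
    def test_percent_inhibition_current(self, control, drug, expected):
        assert nv.percent_inhibition_current(control, drug) == pytest.approx(expected)

    def test_percent_inhibition_current_rejects_bad_control(self):
        with pytest.raises(ValueError):
            nv.percent_inhibition_current(0.0, 1.0)
        with pytest.raises(ValueError):
            nv.percent_inhibition_current(-5.0, 1.0)

    @pytest.mark.parametrize(
        "baseline,response,expected",
        [
            ([2.0] * 5, 0.5, 75.0),
            ([1.0, 2.0, 3.0], 2.0, 0.0),
            ([1.5, 1.5], 6.0, -300.0),
        ],
    )
    def test_percent_inhibition_fmri(self, baseline, response, expected):
        assert nv.percent_inhibition_fmri(baseline, response) == pytest.approx(expected)

    def test_percent_inhibition_fmri_domain_errors(self):
        with pytest.raises(ValueError):
            nv.percent_inhibition_fmri([], 1.0)
        with pytest.raises(ValueError):
            nv.percent_inhibition_fmri([0.0, 0.0], 1.0)

    def test_geometric_mean_examples(self):
        gm, _ = nv.geometric_mean_sd([1.0, 100.0])
        assert gm == pytest.approx(10.0)
        gm, gsd = nv.geometric_mean_sd([5.0, 5.0, 5.0])
        assert gm == pytest.approx(5.0) and gsd == pytest.approx(1.0)
        with pytest.raises(ValueError):
            nv.geometric_mean_sd([1.0, -2.0])

    def test_geometric_stats_match_log_space_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(0.3, 0.8, size=40)
        gm, gsd = nv.geometric_mean_sd(vals)
        logs = np.log(vals)
        assert gm == pytest.approx(np.exp(logs.mean()), rel=1e-12)
        assert gsd == pytest.approx(np.exp(logs.std(ddof=1)), rel=1e-12)


class TestFourPLFit:
    @pytest.mark.parametrize("ic50,hill,tol", [(1.0, 1.0, 1e-6), (0.103, 1.5, 1e-4)])
    def test_exact_data_recovery(self, ic50, hill, tol):
        conc, inhib = generate_invitro_dataset(
            ic50, hill, InVitroDesign(noise_sd=0.0), seed=0
        )
        fit = fit_ic50_4pl(conc, inhib)
        assert fit.ic50 == pytest.approx(ic50, rel=tol)
        assert fit.hill == pytest.approx(hill, rel=tol)
        assert fit.converged
        # the fitted curve passes through 50% at the IC50 by construction
        assert _four_pl(np.array([fit.ic50]), fit.ic50, fit.hill, 0, 100)[0] == pytest.approx(50.0)

    def test_beats_grid_search_oracle(self):
        conc, inhib = generate_invitro_dataset(0.5, 1.2, InVitroDesign(noise_sd=5.0), seed=3)
        fit = fit_ic50_4pl(conc, inhib)
        sse_fit = np.sum((_four_pl(conc, fit.ic50, fit.hill, 0, 100) - inhib) ** 2)
        ic_grid = np.geomspace(conc.min() / 3, conc.max() * 3, 50)
        h_grid = np.geomspace(0.3, 5.0, 50)
        sse_grid = min(
            np.sum((_four_pl(conc, ic, h, 0, 100) - inhib) ** 2)
            for ic in ic_grid
            for h in h_grid
        )
        assert sse_fit <= sse_grid + 1e-9

    def test_unbracketed_transition_warns(self):
        conc = np.array([1e-4, 3e-4, 1e-3, 3e-3, 1e-2])  # far below IC50=1
        inhib = _four_pl(conc, 1.0, 1.0, 0, 100)
        with pytest.warns(UserWarning, match="bracket"):
            fit = fit_ic50_4pl(conc, inhib)
        assert not fit.converged

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_ic50_4pl([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])  # < 4 distinct


class TestPKNaivePooled:
    def test_exact_data_recovery(self):
        studies = generate_satellite_pk_study(
            DEFAULT_PK, SatellitePKDesign(dose=1.0, noise=NoiseSpec(0, 0, 0)), seed=0
        )
        fit = nv.fit_pk_naive_pooled(studies)
        for name, truth in zip(("CL", "V", "CL2", "V2"), (0.5, 0.5, 0.3, 1.0)):
            assert fit.estimate(name) == pytest.approx(truth, rel=1e-4)
        assert fit.converged

    def test_seeded_noisy_recovery_of_clearance(self):
        studies = generate_satellite_pk_study(DEFAULT_PK, SatellitePKDesign(dose=1.0), seed=11)
        fit = nv.fit_pk_naive_pooled(studies)
        assert fit.estimate("CL") == pytest.approx(DEFAULT_PK.CL, rel=0.15)

    def test_objective_not_worse_than_truth(self):
        studies = generate_satellite_pk_study(DEFAULT_PK, SatellitePKDesign(dose=1.0), seed=23)
        fit = nv.fit_pk_naive_pooled(studies)
        obs = np.concatenate([s.series.values for s in studies])
        pred = np.concatenate(
            [
                nv.plasma_concentration(DEFAULT_PK, s.regimen, s.series.times).values
                for s in studies
            ]
        )
        sse_truth = float(np.sum((np.log(pred) - np.log(obs)) ** 2))
        assert fit.objective <= sse_truth + 1e-9

    def test_requires_positive_observations(self):
        studies = generate_satellite_pk_study(
            DEFAULT_PK, SatellitePKDesign(dose=1.0, noise=NoiseSpec(0, 0, 0)), seed=0
        )
        s0 = studies[0].series
        bad = PKStudy(
            series=type(s0)(s0.subject_id, s0.times, np.append(s0.values[:-1], 0.0), "plasma"),
            regimen=studies[0].regimen,
        )
        with pytest.raises(ValueError, match="BLQ"):
            nv.fit_pk_naive_pooled([bad] + list(studies[1:]))

    def test_objective_invariant_to_study_ordering(self):
        studies = generate_satellite_pk_study(DEFAULT_PK, SatellitePKDesign(dose=1.0), seed=2)
        f1 = nv.fit_pk_naive_pooled(studies)
        f2 = nv.fit_pk_naive_pooled(list(reversed(studies)))
        assert f1.objective == pytest.approx(f2.objective, rel=1e-9)


class TestEffectCompartmentFit:
    def test_exact_data_recovery_of_reference_truths(self):
        pd_true = nv.PDParams(EC50=0.78, ke0=1.65)
        study = generate_fmri_study(
            DEFAULT_PK, pd_true, compound24_fmri_design(noise=NoiseSpec(0, 0, 0)), seed=0
        )
        fit = nv.fit_effect_compartment(study.pd_studies)
        assert fit.estimate("EC50") == pytest.approx(0.78, rel=1e-3)
        assert fit.estimate("ke0") == pytest.approx(1.65, rel=1e-3)

    def test_fast_equilibration_reduces_to_direct_emax(self):
        # huge ke0 and a constant-plateau regimen: fitted EC50 must match a
        # direct Emax fit of mean effect vs plateau concentration
        pd_true = nv.PDParams(EC50=2.0, ke0=500.0)
        design = FMRIDesign(dose_groups=((1.0, 2), (3.0, 2), (10.0, 2)),
                            noise=NoiseSpec(0, 0, 0))
        study = generate_fmri_study(DEFAULT_PK, pd_true, design, seed=0)
        fit = nv.fit_effect_compartment(study.pd_studies)
        assert fit.estimate("EC50") == pytest.approx(2.0, rel=1e-3)

    def test_beats_log_grid_oracle(self):
        pd_true = nv.PDParams(EC50=0.78, ke0=1.65)
        study = generate_fmri_study(DEFAULT_PK, pd_true, compound24_fmri_design(), seed=9)
        fit = nv.fit_effect_compartment(study.pd_studies)
        obs = np.concatenate([s.effects.values for s in study.pd_studies])

        def sse(ec50, ke0):
            pd_par = nv.PDParams(EC50=ec50, ke0=ke0)
            pred = np.concatenate(
                [
                    nv.emax_effect(
                        pd_par,
                        nv.effect_site_concentration(
                            s.pk, ke0, s.regimen, s.effects.times
                        ).values,
                    )
                    for s in study.pd_studies
                ]
            )
            return float(np.sum((pred - obs) ** 2))

        grid_best = min(
            sse(a, b)
            for a in np.geomspace(0.05, 50, 40)
            for b in np.geomspace(0.05, 20, 40)
        )
        assert fit.objective <= grid_best + 1e-6

    def test_low_effect_data_warns(self):
        pd_true = nv.PDParams(EC50=100.0, ke0=1.0)
        design = FMRIDesign(dose_groups=((0.1, 2),), noise=NoiseSpec(0, 0, 0))
        study = generate_fmri_study(DEFAULT_PK, pd_true, design, seed=0)
        with pytest.warns(UserWarning, match="below 10%"):
            nv.fit_effect_compartment(study.pd_studies)

    def test_recovery_calibration_across_replicates(self):
        """Median relative error of EC50/ke0 < 15% over 20 seeded replicates
        of the multi-dose imaging design, and the reported CV% tracks the
        empirical dispersion within a factor of 2."""
        pd_true = nv.PDParams(EC50=0.78, ke0=1.65)
        errs_ec50, errs_ke0, cvs_ec50 = [], [], []
        ests = []
        for seed in range(20):
            study = generate_fmri_study(DEFAULT_PK, pd_true, compound24_fmri_design(), seed=seed)
            fit = nv.fit_effect_compartment(study.pd_studies)
            errs_ec50.append(abs(fit.estimate("EC50") / 0.78 - 1))
            errs_ke0.append(abs(fit.estimate("ke0") / 1.65 - 1))
            cvs_ec50.append(fit.cv_pct("EC50"))
            ests.append(fit.estimate("EC50"))
        assert np.median(errs_ec50) < 0.15
        assert np.median(errs_ke0) < 0.15
        empirical_cv = 100 * np.std(ests, ddof=1) / np.mean(ests)
        reported = np.median(cvs_ec50)
        assert reported / empirical_cv < 2.0 and empirical_cv / reported < 2.0


class TestNormalizedExposure:
    def test_unit_normalization(self):
        comp = nv.CompoundRecord("x", fu_p=0.2, ic50_invitro=0.5)
        assert nv.normalize_exposure(0.5 / 0.2, comp) == pytest.approx(1.0)
        assert nv.normalize_exposure(0.0, comp) == 0.0

    def test_reference_compound_arithmetic(self):
        comp24 = nv.CompoundRecord("24", fu_p=0.148, ic50_invitro=0.103)
        assert nv.normalize_exposure(1.0, comp24) == pytest.approx(1.437, abs=5e-4)


class TestPooledEmaxFit:
    @staticmethod
    def _noise_free_points(scaling, n=30, seed=0):
        rng = np.random.default_rng(seed)
        x = 10 ** rng.uniform(-1, 2, n)
        y = 100 * x / (scaling + x)
        return [
            nv.PooledERPoint("c", f"a{i}", float(xi), float(yi))
            for i, (xi, yi) in enumerate(zip(x, y))
        ]

    @pytest.mark.parametrize("scaling", [2.35, 1.0])
    def test_exact_recovery(self, scaling):
        fit = nv.fit_pooled_emax(self._noise_free_points(scaling))
        assert fit.estimate("EC50") == pytest.approx(scaling, rel=1e-4)

    def test_beats_dense_log_grid(self):
        rng = np.random.default_rng(4)
        pts = self._noise_free_points(2.35, seed=4)
        pts = [
            nv.PooledERPoint(p.compound_id, p.subject_id, p.normalized_exposure,
                             p.mean_effect + rng.normal(0, 10))
            for p in pts
        ]
        fit = nv.fit_pooled_emax(pts)
        x = np.array([p.normalized_exposure for p in pts])
        y = np.array([p.mean_effect for p in pts])
        grid = np.geomspace(0.01, 100, 200)
        sse_grid = min(float(np.sum((100 * x / (g + x) - y) ** 2)) for g in grid)
        assert fit.objective <= sse_grid + 1e-9

    def test_one_sided_exposures_warn(self):
        pts = [
            nv.PooledERPoint("c", f"a{i}", x, 100 * x / (1 + x))
            for i, x in enumerate(np.geomspace(10, 100, 12))
        ]
        with pytest.warns(UserWarning, match="span unity"):
            nv.fit_pooled_emax(pts)

    def test_cv_definition_matches_hand_computation(self):
        fit = nv.FitResult(
            {"EC50": nv.ParamEstimate(10.21, 1.60)}, 1.0, 10, True, 0.0
        )
        assert fit.cv_pct("EC50") == pytest.approx(100 * 1.60 / 10.21)
        assert fit.cv_pct("EC50") == pytest.approx(15.7, abs=0.05)
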