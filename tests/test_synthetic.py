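"""Synthetic-generator tests: determinism under seeds, zero-noise
exactness, design structure (sampling times, dose groups), panel
construction, and the full generate-fit-correlate recovery loop."""

import numpy as np
import pytest

import navpkpd as nv
from navpkpd.estimation import fit_effect_compartment, fit_pk_naive_pooled
from navpkpd.ivivc import IVIVCPair
from navpkpd.synthetic import (
    DEFAULT_PK,
    FMRIDesign,
    InVitroDesign,
    NoiseSpec,
    SatellitePKDesign,
    ThermodeDesign,
    compound24_fmri_design,
    generate_compound_panel,
    generate_fmri_study,
    generate_invitro_dataset,
    generate_pooled_er_dataset,
    generate_satellite_pk_study,
    generate_thermode_study,
)

PD24 = nv.PDParams(EC50=0.78, ke0=1.65)


class TestDeterminism:
    def test_same_seed_reproduces_every_generator(self):
        a1 = generate_invitro_dataset(1.0, 1.0, seed=5)
        a2 = generate_invitro_dataset(1.0, 1.0, seed=5)
        np.testing.assert_array_equal(a1[1], a2[1])

        b1 = generate_satellite_pk_study(DEFAULT_PK, seed=5)
        b2 = generate_satellite_pk_study(DEFAULT_PK, seed=5)
        np.testing.assert_array_equal(b1[0].series.values, b2[0].series.values)

        c1 = generate_fmri_study(DEFAULT_PK, PD24, compound24_fmri_design(), seed=5)
        c2 = generate_fmri_study(DEFAULT_PK, PD24, compound24_fmri_design(), seed=5)
        np.testing.assert_array_equal(
            c1.pd_studies[0].effects.values, c2.pd_studies[0].effects.values
        )

        d1 = generate_thermode_study(DEFAULT_PK, PD24, ThermodeDesign(doses=(1.0, 3.0)), seed=5)
        d2 = generate_thermode_study(DEFAULT_PK, PD24, ThermodeDesign(doses=(1.0, 3.0)), seed=5)
        assert [o.score for o in d1.observations] == [o.score for o in d2.observations]

    def test_different_seed_changes_values_not_structure(self):
        s1 = generate_satellite_pk_study(DEFAULT_PK, seed=1)
        s2 = generate_satellite_pk_study(DEFAULT_PK, seed=2)
        np.testing.assert_array_equal(s1[0].series.times, s2[0].series.times)
        assert not np.allclose(s1[0].series.values, s2[0].series.values)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            generate_invitro_dataset(1.0, 1.0, seed=None)


class TestInVitroGenerator:
    def test_zero_noise_points_lie_on_logistic_curve(self):
        conc, inhib = generate_invitro_dataset(0.5, 1.2, InVitroDesign(noise_sd=0.0), seed=0)
        expected = 100.0 / (1.0 + (0.5 / conc) ** 1.2)
        np.testing.assert_allclose(inhib, expected, rtol=1e-12)
        assert conc.size == 10
        assert conc.min() < 0.5 < conc.max()

    def test_end_to_end_ic50_recovery_calibration(self):
        errs = []
        for seed in range(20):
            conc, inhib = generate_invitro_dataset(0.5, 1.2, seed=seed)
            fit = nv.fit_ic50_4pl(conc, inhib)
            errs.append(abs(fit.ic50 / 0.5 - 1))
        assert np.median(errs) < 0.10


class TestSatellitePKGenerator:
    def test_zero_variability_equals_analytic_curve(self):
        studies = generate_satellite_pk_study(
            DEFAULT_PK, SatellitePKDesign(dose=2.0, noise=NoiseSpec(0, 0, 0)), seed=0
        )
        for st in studies:
            clean = nv.plasma_concentration(DEFAULT_PK, st.regimen, st.series.times).values
            np.testing.assert_allclose(st.series.values, clean, rtol=1e-12)

    def test_dose_doubling_doubles_concentrations(self):
        lo = generate_satellite_pk_study(
            DEFAULT_PK, SatellitePKDesign(dose=1.0, noise=NoiseSpec(0, 0, 0)), seed=0
        )
        hi = generate_satellite_pk_study(
            DEFAULT_PK, SatellitePKDesign(dose=2.0, noise=NoiseSpec(0, 0, 0)), seed=0
        )
        np.testing.assert_allclose(hi[0].series.values, 2 * lo[0].series.values, rtol=1e-12)

    def test_sampling_spans_two_minutes_to_24_hours(self):
        st = generate_satellite_pk_study(DEFAULT_PK, seed=0)[0]
        assert st.series.times[0] == pytest.approx(2 / 60)
        assert st.series.times[-1] == pytest.approx(24.0)
        assert st.series.times.size == 9


class TestFMRIGenerator:
    def test_multidose_reference_design_structure(self):
        design = compound24_fmri_design()
        assert [n for _, n in design.dose_groups] == [3, 6, 3, 3]
        assert [d for d, _ in design.dose_groups] == pytest.approx([0.12, 0.28, 0.6, 2.0])
        study = generate_fmri_study(DEFAULT_PK, PD24, design, seed=0)
        assert len(study.pd_studies) == 15
        # 0.2-h sampling over 4 h -> 20 observations per animal
        assert study.pd_studies[0].effects.times.size == 20
        # two plasma samples per animal
        assert len(study.plasma_samples) == 30

    def test_zero_noise_fast_ke0_matches_direct_emax_of_plasma(self):
        # no-hysteresis limit: effect equals the Emax response at the
        # concurrent plasma concentration
        pd_fast = nv.PDParams(EC50=2.0, ke0=800.0)
        design = FMRIDesign(dose_groups=((3.0, 1),), noise=NoiseSpec(0, 0, 0))
        study = generate_fmri_study(DEFAULT_PK, pd_fast, design, seed=0)
        st = study.pd_studies[0]
        mask = st.effects.times > 1.2  # past the short equilibration transient
        cp = nv.plasma_concentration(DEFAULT_PK, st.regimen, st.effects.times).values
        direct = nv.emax_effect(pd_fast, cp)
        np.testing.assert_allclose(st.effects.values[mask], direct[mask], rtol=0.02)

    def test_baseline_period_mean_inhibition_near_zero(self):
        means = []
        for seed in range(10):
            study = generate_fmri_study(DEFAULT_PK, PD24, compound24_fmri_design(), seed=seed)
            for st in study.pd_studies:
                base = st.effects.values[st.effects.times < 1.0]
                means.append(base.mean())
        assert abs(np.mean(means)) < 1.0  # % units

    def test_infusion_mean_effect_and_eoi_concentration_helpers(self):
        study = generate_fmri_study(
            DEFAULT_PK, PD24, compound24_fmri_design(noise=NoiseSpec(0, 0, 0)), seed=0
        )
        eff = study.mean_infusion_effect()
        conc = study.end_of_infusion_concentration()
        assert set(eff) == set(conc)
        # higher dose groups produce larger mean on-infusion effect
        by_dose = {}
        for st in study.pd_studies:
            dose = float(st.effects.subject_id.split("_")[0][1:])
            by_dose.setdefault(dose, eff[st.effects.subject_id])
        doses = sorted(by_dose)
        assert all(by_dose[a] < by_dose[b] for a, b in zip(doses, doses[1:]))


class TestPooledERGenerator:
    def test_zero_dispersion_ratio_one_lies_on_unity_curve(self):
        comps = nv.reference_compounds()
        pts = generate_pooled_er_dataset(comps, 1.0, seed=0, noise_sd=0.0)
        for p in pts:
            expected = 100 * p.normalized_exposure / (1.0 + p.normalized_exposure)
            assert p.mean_effect == pytest.approx(expected, rel=1e-9)

    def test_recovers_generating_scaling_factor(self):
        comps = nv.reference_compounds()
        pts = generate_pooled_er_dataset(comps, 2.35, seed=0, noise_sd=0.0)
        fit = nv.fit_pooled_emax(pts)
        assert fit.estimate("EC50") == pytest.approx(2.35, rel=1e-3)


class TestThermodeGenerator:
    def test_zero_noise_vehicle_scores_at_baseline(self):
        design = ThermodeDesign(doses=(1.0,), n_per_group=4, score_sd=0.0)
        study = generate_thermode_study(DEFAULT_PK, PD24, design, seed=0)
        assert study.vehicle_baseline_mean() == pytest.approx(1.5)
        veh = [o for o in study.observations if o.dose == 0]
        for o in veh:
            assert nv.thermode_percent_of_baseline(o.score, study.vehicle_baseline_mean()) == pytest.approx(100.0)

    def test_increasing_dose_lowers_percent_of_baseline(self):
        design = ThermodeDesign(doses=(0.3, 1.0, 3.0, 10.0), n_per_group=6, score_sd=0.0)
        study = generate_thermode_study(DEFAULT_PK, PD24, design, seed=0)
        base = study.vehicle_baseline_mean()
        pct = {}
        for o in study.observations:
            if o.dose > 0:
                pct.setdefault(o.dose, nv.thermode_percent_of_baseline(o.score, base))
        doses = sorted(pct)
        assert all(pct[a] >= pct[b] for a, b in zip(doses, doses[1:]))


class TestCompoundPanel:
    def test_zero_dispersion_unity_ratio_gives_perfect_regression(self):
        truth, _ = generate_compound_panel(6, ivivc_ratio=1.0, dispersion=0.0, seed=3)
        pairs = [
            IVIVCPair(c.compound_id, c.ic50_invitro,
                      truth.pd[c.compound_id].EC50, c.fu_p)
            for c in truth.compounds
        ]
        res = nv.ivivc_regression(pairs, "log10")
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_panel_potencies_span_decades(self):
        truth, _ = generate_compound_panel(30, seed=8)
        ic50s = np.array([c.ic50_invitro for c in truth.compounds])
        assert np.ptp(np.log10(ic50s)) > 1.5
        fu = np.array([c.fu_p for c in truth.compounds])
        assert np.all((fu > 0) & (fu <= 1))

    def test_normalization_collapses_exposure_response_spread(self):
        """Across a wide-potency panel, per-compound potency expressed on the
        normalized exposure scale is far less dispersed than on the raw
        total-plasma scale (the overlay-collapse phenomenon)."""
        truth, _ = generate_compound_panel(27, ivivc_ratio=1.0, dispersion=0.15, seed=12)
        raw = [np.log10(truth.pd[c.compound_id].EC50) for c in truth.compounds]
        normalized = [
            np.log10(truth.pd[c.compound_id].EC50 * c.fu_p / c.ic50_invitro)
            for c in truth.compounds
        ]
        assert np.var(normalized) < 0.25 * np.var(raw)

    def test_end_to_end_pipeline_recovers_unity_slope(self):
        """Generate panels with unbound EC50 = in vitro IC50, fit PK then the
        effect-compartment model, correct for binding and regress: the mean
        IVIVC slope across seeds must sit near unity."""
        slopes = []
        for seed in range(10):
            truth, studies = generate_compound_panel(
                7, ivivc_ratio=1.0, dispersion=0.1, seed=seed,
                fmri_n_per_group=2, satellite_n_animals=2,
            )
            pairs = []
            for comp in truth.compounds:
                cid = comp.compound_id
                pk_fit = fit_pk_naive_pooled(studies.satellite_pk[cid])
                pk_hat = nv.PKParams(
                    CL=pk_fit.estimate("CL"), V=pk_fit.estimate("V"),
                    CL2=pk_fit.estimate("CL2"), V2=pk_fit.estimate("V2"),
                )
                pd_studies = [
                    nv.PDStudy(effects=s.effects, regimen=s.regimen, pk=pk_hat)
                    for s in studies.fmri[cid].pd_studies
                ]
                pd_fit = fit_effect_compartment(pd_studies)
                pairs.append(
                    IVIVCPair(cid, comp.ic50_invitro, pd_fit.estimate("EC50"), comp.fu_p)
                )
            slopes.append(nv.ivivc_regression(pairs, "log10").slope)
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.2)
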