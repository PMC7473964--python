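"""Synthetic study generators.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes: 10-point in vitro
concentration-response curves, satellite IV PK studies with sparse
sampling out to 24 h, olfaction-imaging PD studies (1 h baseline, 1 h
bolus-plus-infusion dosing, up to 2 h washout, percent inhibition sampled
every 0.2 h), single-timepoint SC thermode studies, and whole compound
panels with a configurable in vitro to in vivo potency ratio.

Noise magnitudes are assumptions (the source studies do not publish them)
and default to: additive PD noise SD 8 %, multiplicative PK residual CV
20 %, between-animal PK variability CV 30 %.  All generators are
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import (
    CompoundRecord,
    ConcentrationSeries,
    DoseEvent,
    DoseRegimen,
    EffectSeries,
    PDParams,
    PDStudy,
    PKParams,
    PKStudy,
    effect_site_concentration,
    emax_effect,
    loading_infusion_regimen,
    mg_per_kg_to_umol_per_kg,
    plasma_concentration,
)
from .estimation import PooledERPoint

__all__ = [
    "DEFAULT_PK",
    "NoiseSpec",
    "InVitroDesign",
    "SatellitePKDesign",
    "FMRIDesign",
    "ThermodeDesign",
    "FMRIStudyData",
    "ThermodeStudyData",
    "CompoundPanelTruth",
    "generate_invitro_dataset",
    "generate_satellite_pk_study",
    "generate_fmri_study",
    "generate_thermode_study",
    "generate_pooled_er_dataset",
    "generate_compound_panel",
    "compound24_fmri_design",
]

#: default rhesus small-molecule disposition used wherever a study design
#: does not specify PK truth (central volume 0.5 L/kg, steady-state volume
#: 1.5 L/kg, moderate clearance); terminal half-life ~2.7 h
DEFAULT_PK = PKParams(CL=0.5, V=0.5, CL2=0.3, V2=1.0)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is mandatory for reproducibility")
    return np.random.default_rng(seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes: PD additive SD in % units, PK residual CV, and
    between-animal PK variability CV (all dimensionless fractions except
    ``pd_sd``)."""

    pd_sd: float = 8.0
    pk_cv: float = 0.20
    between_animal_cv: float = 0.30

    def __post_init__(self) -> None:
        if self.pd_sd < 0 or self.pk_cv < 0 or self.between_animal_cv < 0:
            raise ValueError("noise magnitudes must be >= 0")


# ---------------------------------------------------------------------------
# in vitro concentration-response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InVitroDesign:
    """10-point calibration curve, log-spaced around the expected IC50."""

    n_concentrations: int = 10
    span_decades: float = 3.6
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.n_concentrations < 4:
            raise ValueError("need at least 4 concentrations")


def generate_invitro_dataset(
    ic50: float,
    hill: float,
    design: InVitroDesign = InVitroDesign(),
    seed=None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Concentration / percent-inhibition points from a 4PL truth with
    additive Gaussian noise (asymptotes 0 and 100)."""
    if ic50 <= 0 or hill <= 0:
        raise ValueError("ic50 and hill must be positive")
    rng = _rng(seed)
    half = design.span_decades / 2
    conc = ic50 * np.logspace(-half, half, design.n_concentrations)
    truth = 100.0 / (1.0 + (ic50 / conc) ** hill)
    obs = truth + rng.normal(0.0, design.noise_sd, size=conc.size)
    return conc, obs


# ---------------------------------------------------------------------------
# satellite IV PK study
# ---------------------------------------------------------------------------

#: nine sparse sampling times from 2 min to 24 h post dose
DEFAULT_PK_SAMPLE_TIMES = (2 / 60, 5 / 60, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0)


@dataclass(frozen=True)
class SatellitePKDesign:
    """Single IV-bolus dose group with sparse sampling to 24 h."""

    dose: float = 1.0  # umol/kg
    n_animals: int = 3
    sample_times: Tuple[float, ...] = DEFAULT_PK_SAMPLE_TIMES
    noise: NoiseSpec = NoiseSpec()

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


def _perturb_pk(pk: PKParams, rng: np.random.Generator, cv: float) -> PKParams:
    if cv <= 0:
        return pk
    f = _lognormal_factor(rng, cv, size=4)
    return PKParams(CL=pk.CL * f[0], V=pk.V * f[1], CL2=pk.CL2 * f[2], V2=pk.V2 * f[3])


def generate_satellite_pk_study(
    true_pk: PKParams,
    design: SatellitePKDesign = SatellitePKDesign(),
    seed=None,
) -> List[PKStudy]:
    """Per-animal IV-bolus concentration series: animal-level parameters
    drawn lognormally around the population truth, multiplicative residual
    noise on each sample."""
    rng = _rng(seed)
    times = np.asarray(design.sample_times, dtype=float)
    out: List[PKStudy] = []
    for i in range(design.n_animals):
        animal_pk = _perturb_pk(true_pk, rng, design.noise.between_animal_cv)
        regimen = DoseRegimen([DoseEvent(0.0, "iv_bolus", design.dose)])
        clean = plasma_concentration(animal_pk, regimen, times, subject_id=f"pk{i+1}")
        noisy = clean.values * _lognormal_factor(rng, design.noise.pk_cv, size=times.size)
        series = ConcentrationSeries(f"pk{i+1}", times, noisy, "plasma")
        out.append(PKStudy(series=series, regimen=regimen))
    return out


# ---------------------------------------------------------------------------
# olfaction-imaging PD study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FMRIDesign:
    """Bolus-plus-1-h-infusion olfaction imaging design.

    ``dose_groups`` maps total dose (umol/kg) to number of animals.  Each
    animal yields percent-inhibition readouts every 0.2 h (triple-averaged
    4-min measurements): 5 during the 1-h baseline, 5 during the infusion
    hour, and 5 per washout hour.  Two plasma samples per animal are taken
    at the end of infusion and the end of the session.
    """

    dose_groups: Tuple[Tuple[float, int], ...]
    washout_h: float = 2.0
    baseline_h: float = 1.0
    infusion_h: float = 1.0
    noise: NoiseSpec = NoiseSpec()

    def __post_init__(self) -> None:
        if not self.dose_groups:
            raise ValueError("at least one dose group is required")
        if any(n < 1 for _, n in self.dose_groups):
            raise ValueError("every dose group needs >= 1 animal")

    def observation_times(self) -> np.ndarray:
        total = self.baseline_h + self.infusion_h + self.washout_h
        # centers of 0.2-h averaging blocks: 0.1, 0.3, ...
        return np.arange(0.1, total, 0.2)

    def end_of_infusion(self) -> float:
        return self.baseline_h + self.infusion_h

    def end_of_study(self) -> float:
        return self.baseline_h + self.infusion_h + self.washout_h


def compound24_fmri_design(
    mol_weight: float = 500.0, noise: NoiseSpec = NoiseSpec()
) -> FMRIDesign:
    """The reference multi-dose imaging design: 0.06, 0.14, 0.3 and 1 mg/kg
    groups with 3, 6, 3 and 3 animals."""
    groups = tuple(
        (mg_per_kg_to_umol_per_kg(mg, mol_weight), n)
        for mg, n in ((0.06, 3), (0.14, 6), (0.3, 3), (1.0, 3))
    )
    return FMRIDesign(dose_groups=groups, noise=noise)


@dataclass(frozen=True)
class PlasmaSample:
    subject_id: str
    dose: float
    time: float
    value: float


@dataclass(frozen=True)
class FMRIStudyData:
    """Generated imaging study: per-animal PD series (with regimen and the
    population PK used to build it) plus sparse plasma samples."""

    pd_studies: Tuple[PDStudy, ...]
    plasma_samples: Tuple[PlasmaSample, ...]
    design: FMRIDesign

    def mean_infusion_effect(self) -> Dict[str, float]:
        """Per-animal arithmetic mean percent inhibition over the infusion
        hour (the pooled exposure-response PD endpoint)."""
        out = {}
        lo = self.design.baseline_h
        hi = self.design.end_of_infusion()
        for st in self.pd_studies:
            mask = (st.effects.times > lo) & (st.effects.times <= hi)
            out[st.effects.subject_id] = float(st.effects.values[mask].mean())
        return out

    def end_of_infusion_concentration(self) -> Dict[str, float]:
        out = {}
        t_eoi = self.design.end_of_infusion()
        for s in self.plasma_samples:
            if abs(s.time - t_eoi) < 1e-9:
                out[s.subject_id] = s.value
        return out


def generate_fmri_study(
    true_pk: PKParams,
    true_pd: PDParams,
    design: FMRIDesign,
    seed=None,
) -> FMRIStudyData:
    """Simulate an olfaction-imaging study under the loading bolus + 1 h
    infusion paradigm (dosing starts after the baseline hour).

    The effect time course follows the effect-compartment Emax model at the
    population PK (plus additive Gaussian noise); plasma samples at end of
    infusion and end of study carry multiplicative lognormal noise.
    Baseline-period observations are pure noise around zero, mirroring the
    baseline-normalized percent-inhibition endpoint.
    """
    rng = _rng(seed)
    times = design.observation_times()
    t_samples = (design.end_of_infusion(), design.end_of_study())
    studies: List[PDStudy] = []
    samples: List[PlasmaSample] = []
    for dose, n in design.dose_groups:
        regimen = loading_infusion_regimen(
            dose, true_pk, infusion_duration=design.infusion_h, start_time=design.baseline_h
        )
        ce = effect_site_concentration(true_pk, true_pd.ke0, regimen, times).values
        clean_effect = emax_effect(true_pd, ce)
        cp_at_samples = plasma_concentration(
            true_pk, regimen, np.asarray(t_samples)
        ).values
        for j in range(n):
            sid = f"d{dose:g}_a{j+1}"
            noisy = clean_effect + rng.normal(0.0, design.noise.pd_sd, size=times.size)
            studies.append(
                PDStudy(
                    effects=EffectSeries(sid, times, noisy),
                    regimen=regimen,
                    pk=true_pk,
                )
            )
            for t, cp in zip(t_samples, cp_at_samples):
                samples.append(
                    PlasmaSample(
                        sid, dose, t, float(cp * _lognormal_factor(rng, design.noise.pk_cv))
                    )
                )
    return FMRIStudyData(tuple(studies), tuple(samples), design)


# ---------------------------------------------------------------------------
# pooled cross-compound exposure-response dataset
# ---------------------------------------------------------------------------


def generate_pooled_er_dataset(
    compounds: Sequence[CompoundRecord],
    true_scaling_ec50: float,
    seed=None,
    n_animals: int = 3,
    doses_per_compound: Tuple[int, int] = (1, 3),
    exposure_decades: Tuple[float, float] = (-1.0, 2.0),
    noise_sd: float = 10.0,
    compound_dispersion: float = 0.0,
) -> List[PooledERPoint]:
    """Individual-animal pooled exposure-response points.

    For each compound, 1-3 dose groups (uniformly drawn) are placed
    log-uniformly over normalized exposures 0.1-100, each with ``n_animals``
    animals whose exposures scatter around the group target.  The mean
    infusion-hour effect follows the dimensionless Emax model with scaling
    factor ``true_scaling_ec50`` (optionally with per-compound lognormal
    dispersion) plus additive Gaussian noise.
    """
    if true_scaling_ec50 <= 0:
        raise ValueError("true_scaling_ec50 must be positive")
    rng = _rng(seed)
    lo, hi = doses_per_compound
    points: List[PooledERPoint] = []
    for comp in compounds:
        comp_ec50 = true_scaling_ec50 * _lognormal_factor(rng, compound_dispersion)
        n_doses = int(rng.integers(lo, hi + 1))
        targets = 10.0 ** rng.uniform(exposure_decades[0], exposure_decades[1], size=n_doses)
        for g, target in enumerate(targets):
            # modest between-animal exposure scatter within a dose group
            exposures = target * _lognormal_factor(rng, 0.25, size=n_animals)
            effects = 100.0 * exposures / (comp_ec50 + exposures) + rng.normal(
                0.0, noise_sd, size=n_animals
            )
            for j, (x, e) in enumerate(zip(exposures, effects)):
                points.append(
                    PooledERPoint(comp.compound_id, f"{comp.compound_id}_g{g+1}a{j+1}", float(x), float(e))
                )
    return points


# ---------------------------------------------------------------------------
# thermode study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThermodeDesign:
    """SC dose groups (plus vehicle) with a single post-dose readout taken
    at the projected effect-site tmax."""

    doses: Tuple[float, ...]
    n_per_group: int = 6
    baseline_score: float = 1.5
    score_sd: float = 0.25
    ka: float = 1.0
    F: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive (vehicle is implicit)")


@dataclass(frozen=True)
class ThermodeObservation:
    subject_id: str
    dose: float  # 0 for vehicle
    score: float
    sample_time: float
    plasma_conc: float


@dataclass(frozen=True)
class ThermodeStudyData:
    observations: Tuple[ThermodeObservation, ...]
    design: ThermodeDesign

    def vehicle_baseline_mean(self) -> float:
        scores = [o.score for o in self.observations if o.dose == 0]
        return float(np.mean(scores))


def generate_thermode_study(
    true_pk: PKParams,
    true_pd: PDParams,
    design: ThermodeDesign,
    seed=None,
    noise: NoiseSpec = NoiseSpec(),
) -> ThermodeStudyData:
    """Single-timepoint SC thermode study.

    Withdrawal scores scale down from the baseline score in proportion to
    the model-predicted percent effect at the effect-site peak (the inverse
    of the percent-of-baseline conversion), truncated at zero, with
    additive Gaussian score noise.  A vehicle group is always included.
    """
    from .simulation import project_sc_study  # local import to avoid a cycle

    rng = _rng(seed)
    obs: List[ThermodeObservation] = []
    for j in range(design.n_per_group):
        score = max(float(rng.normal(design.baseline_score, design.score_sd)), 0.0)
        obs.append(ThermodeObservation(f"veh_a{j+1}", 0.0, score, 0.0, 0.0))
    projections = {
        p.dose: p
        for p in project_sc_study(
            true_pk, true_pd, design.doses, ka=design.ka, F=design.F, grid_step=0.01
        )
    }
    for dose in design.doses:
        proj = projections[dose]
        regimen = DoseRegimen(
            [DoseEvent(0.0, "extravascular", dose, ka=design.ka, F=design.F)]
        )
        cp = plasma_concentration(true_pk, regimen, np.array([proj.sampling_time])).values[0]
        for j in range(design.n_per_group):
            clean = design.baseline_score * (1.0 - proj.peak_effect / 100.0)
            score = max(float(clean + rng.normal(0.0, design.score_sd)), 0.0)
            conc = float(cp * _lognormal_factor(rng, noise.pk_cv))
            obs.append(
                ThermodeObservation(
                    f"d{dose:g}_a{j+1}", dose, score, proj.sampling_time, conc
                )
            )
    return ThermodeStudyData(tuple(obs), design)


# ---------------------------------------------------------------------------
# compound panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundPanelTruth:
    """Generative truth for a compound panel: records, per-compound PK and
    PD truths, and the in vitro to in vivo potency ratio that links the
    true unbound EC50 to the in vitro IC50."""

    compounds: Tuple[CompoundRecord, ...]
    pk: Dict[str, PKParams]
    pd: Dict[str, PDParams]
    ivivc_ratio: float


@dataclass(frozen=True)
class PanelStudies:
    """Per-compound generated satellite PK and imaging studies."""

    satellite_pk: Dict[str, List[PKStudy]]
    fmri: Dict[str, FMRIStudyData]


def generate_compound_panel(
    n_compounds: int,
    ivivc_ratio: float = 1.0,
    dispersion: float = 0.0,
    seed=None,
    base_pk: PKParams = DEFAULT_PK,
    pk_spread_cv: float = 0.30,
    fmri_dose_groups: int = 3,
    fmri_n_per_group: int = 3,
    satellite_n_animals: int = 3,
    noise: NoiseSpec = NoiseSpec(),
    mol_weight: float = 500.0,
) -> Tuple[CompoundPanelTruth, PanelStudies]:
    """Generate a compound panel and every study the pipeline consumes.

    In vitro IC50s are lognormal across roughly two decades (0.1-20 uM
    scale) and fu_p is logit-normal around ~0.08.  The true total-plasma
    EC50 of each compound is ``ivivc_ratio * IC50 / fu_p`` times a
    lognormal dispersion factor, so ``dispersion=0, ratio=1`` puts every
    compound exactly on the unity IVIVC line.  ke0 values are lognormal
    around 1.3 1/h (the scale seen in vivo).  Imaging dose groups are
    placed around each compound's expected plateau EC50 so the study spans
    the informative part of the response.
    """
    if n_compounds < 3:
        raise ValueError("a panel needs at least 3 compounds")
    if ivivc_ratio <= 0:
        raise ValueError("ivivc_ratio must be positive")
    rng = _rng(seed)

    compounds: List[CompoundRecord] = []
    pk_truth: Dict[str, PKParams] = {}
    pd_truth: Dict[str, PDParams] = {}
    sat: Dict[str, List[PKStudy]] = {}
    fmri: Dict[str, FMRIStudyData] = {}

    for i in range(n_compounds):
        cid = f"syn{i+1:02d}"
        ic50 = float(np.exp(rng.normal(np.log(1.4), 1.15)))  # ~0.1-20 uM
        fu = float(1.0 / (1.0 + np.exp(-rng.normal(-2.45, 0.9))))
        comp = CompoundRecord(cid, fu, ic50, mol_weight=mol_weight)
        compounds.append(comp)

        pk = _perturb_pk(base_pk, rng, pk_spread_cv)
        pk_truth[cid] = pk
        ec50_total = ivivc_ratio * ic50 / fu * _lognormal_factor(rng, dispersion)
        ke0 = float(np.exp(rng.normal(np.log(1.3), 0.5)))
        pd = PDParams(EC50=ec50_total, ke0=ke0)
        pd_truth[cid] = pd

        sat_design = SatellitePKDesign(
            dose=ec50_total * (base_pk.V + base_pk.CL),  # plateau near EC50
            n_animals=satellite_n_animals,
            noise=noise,
        )
        sat[cid] = generate_satellite_pk_study(pk, sat_design, seed=rng)

        # dose groups bracketing the dose whose 1-h plateau hits the EC50
        ref_dose = ec50_total * (pk.V + pk.CL)
        factors = np.logspace(-0.7, 0.7, fmri_dose_groups)
        groups = tuple((float(ref_dose * f), fmri_n_per_group) for f in factors)
        design = FMRIDesign(dose_groups=groups, noise=noise)
        fmri[cid] = generate_fmri_study(pk, pd, design, seed=rng)

    truth = CompoundPanelTruth(tuple(compounds), pk_truth, pd_truth, ivivc_ratio)
    return truth, PanelStudies(satellite_pk=sat, fmri=fmri)
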