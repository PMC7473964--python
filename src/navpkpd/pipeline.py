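"""Staged analysis pipeline.

Stages run in the order the discovery workflow used them:

1. in vitro potency fits (4PL per compound)
2. satellite PK fits (naive-pooled two-compartment)
3. PK-prediction qualification against the sparse imaging plasma samples
   (2-fold rule; failures drop out of the effect-compartment stage)
4. pooled normalized exposure-response Emax fit (in vitro to in vivo
   scaling factor)
5. effect-compartment PD fits with fixed PK
6. CV-filtered IVIVC regression
7. prospective SC dose projection for the retained compounds

Each stage writes its artifact before the next begins, and every exclusion
(2-fold rule, CV filter) is logged with its reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as nio
from .core import DoseRegimen, PDStudy, PKParams, PKStudy
from .estimation import (
    FitResult,
    PooledERPoint,
    fit_effect_compartment,
    fit_ic50_4pl,
    fit_pk_naive_pooled,
    fit_pooled_emax,
)
from .core import PDParams
from .ivivc import IVIVCPair, filter_by_cv, ivivc_regression
from .simulation import plasma_concentration, project_sc_study, qualify_pk_prediction

__all__ = ["PipelineResult", "run_pipeline", "generate_pipeline_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    invitro_fits: pd.DataFrame
    pk_fits: pd.DataFrame
    qualification: pd.DataFrame
    pooled_er: Optional[FitResult]
    pd_fits: pd.DataFrame
    ivivc: Optional[dict]
    sc_projection: pd.DataFrame
    exclusions: List[dict]


def _is_satellite(dose_group: str) -> bool:
    return dose_group.startswith("satellite")


def _fmri_windows(regimen: DoseRegimen):
    """(infusion start, infusion end, study end guess) from a loading
    regimen."""
    inf = [e for e in regimen.events if e.route == "iv_infusion"]
    if not inf:
        start = regimen.events[0].time
        return start, start, start
    return inf[0].time, inf[0].time + inf[0].duration, inf[0].time + inf[0].duration


def run_pipeline(config: nio.PipelineConfig) -> PipelineResult:
    """Execute the staged analysis on long-format input files and write
    per-stage artifacts under ``config.output_dir``."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logging.getLogger("navpkpd").addHandler(handler)
    logging.getLogger("navpkpd").setLevel(logging.INFO)
    exclusions: List[dict] = []

    try:
        compounds = {c.compound_id: c for c in nio.read_compound_table(config.compound_table)}
        obs = nio.read_observations(config.observations)
        regimens = nio.read_regimen_table(config.regimens)

        # ---- stage 1: in vitro potency -----------------------------------
        invitro_rows = []
        invitro_ic50: Dict[str, float] = {}
        for cid, (conc, inhib) in sorted(obs.invitro.items()):
            fit = fit_ic50_4pl(conc, inhib)
            invitro_ic50[cid] = fit.ic50
            invitro_rows.append(
                {
                    "compound_id": cid,
                    "ic50_uM": fit.ic50,
                    "ic50_se": fit.ic50_se,
                    "hill": fit.hill,
                    "residual_sd": fit.residual_sd,
                    "converged": fit.converged,
                    "n_obs": fit.n_obs,
                }
            )
        invitro_fits = pd.DataFrame(invitro_rows)
        invitro_fits.to_csv(outdir / "invitro_fits.csv", index=False)
        logger.info("stage invitro: fitted %d compounds", len(invitro_rows))

        # ---- stage 2: satellite PK ---------------------------------------
        pk_rows = []
        pk_params: Dict[str, PKParams] = {}
        by_compound_sat: Dict[str, List[PKStudy]] = {}
        for sid, series in obs.concentrations.items():
            if not _is_satellite(obs.dose_group_of[sid]):
                continue
            keep = series.values > config.lloq
            if keep.sum() < 2:
                continue
            series = type(series)(sid, series.times[keep], series.values[keep], "plasma")
            by_compound_sat.setdefault(obs.compound_of[sid], []).append(
                PKStudy(series=series, regimen=regimens[sid])
            )
        for cid, studies in sorted(by_compound_sat.items()):
            fit = fit_pk_naive_pooled(studies)
            row = {"compound_id": cid, **fit.to_dict()}
            pk_rows.append(row)
            if fit.converged:
                pk_params[cid] = PKParams(
                    CL=fit.estimate("CL"), V=fit.estimate("V"),
                    CL2=fit.estimate("CL2"), V2=fit.estimate("V2"),
                )
            else:
                exclusions.append({"stage": "satellite_pk", "compound_id": cid,
                                   "reason": "PK fit did not converge"})
                logger.info("stage pk: compound %s excluded (non-convergence)", cid)
        pk_fits = pd.DataFrame(pk_rows)
        pk_fits.to_csv(outdir / "pk_fits.csv", index=False)
        logger.info("stage pk: fitted %d compounds", len(pk_params))

        # ---- stage 3: PK-prediction qualification ------------------------
        qual_rows = []
        qualified: Dict[str, bool] = {}
        fmri_conc_by_group: Dict[str, Dict[str, list]] = {}
        for sid, series in obs.concentrations.items():
            dg = obs.dose_group_of[sid]
            if _is_satellite(dg):
                continue
            cid = obs.compound_of[sid]
            fmri_conc_by_group.setdefault(cid, {}).setdefault(dg, []).append(sid)
        for cid, groups in sorted(fmri_conc_by_group.items()):
            if cid not in pk_params:
                continue
            all_pass = True
            for dg, sids in sorted(groups.items()):
                regimen = regimens[sids[0]]
                # mean observed concentration per sampling time
                pooled: Dict[float, list] = {}
                for sid in sids:
                    s = obs.concentrations[sid]
                    for t, v in zip(s.times, s.values):
                        pooled.setdefault(round(float(t), 6), []).append(float(v))
                observed = [(t, float(np.mean(v))) for t, v in sorted(pooled.items())]
                t_end = max(t for t, _ in observed) + 1e-6
                sim = plasma_concentration(
                    pk_params[cid], regimen, np.linspace(0.0, t_end, 2001)
                )
                report = qualify_pk_prediction(sim, observed, config.fold_limit)
                qual_rows.append(
                    {
                        "compound_id": cid,
                        "dose_group": dg,
                        "max_fold_error": report.max_fold_error,
                        "passed": report.passed,
                    }
                )
                all_pass &= report.passed
            qualified[cid] = all_pass
            if not all_pass:
                exclusions.append({"stage": "pk_qualification", "compound_id": cid,
                                   "reason": f"simulated plasma not within {config.fold_limit}-fold of observed"})
                logger.info("stage qualification: compound %s excluded (%g-fold rule)",
                            cid, config.fold_limit)
        qualification = pd.DataFrame(qual_rows)
        qualification.to_csv(outdir / "qualification.csv", index=False)

        # ---- stage 4: pooled normalized exposure-response ----------------
        er_points: List[PooledERPoint] = []
        for cid, groups in sorted(fmri_conc_by_group.items()):
            comp = compounds.get(cid)
            ic50 = invitro_ic50.get(cid, comp.ic50_invitro if comp else None)
            if comp is None or ic50 is None:
                continue
            for dg, sids in groups.items():
                for sid in sids:
                    if sid not in obs.effects:
                        continue
                    regimen = regimens[sid]
                    t0, t1, _ = _fmri_windows(regimen)
                    s = obs.concentrations[sid]
                    i_eoi = int(np.argmin(np.abs(s.times - t1)))
                    cp_eoi = float(s.values[i_eoi])
                    eff = obs.effects[sid]
                    mask = (eff.times > t0) & (eff.times <= t1)
                    if not mask.any():
                        continue
                    er_points.append(
                        PooledERPoint(
                            cid, sid, cp_eoi * comp.fu_p / ic50,
                            float(eff.values[mask].mean()),
                        )
                    )
        pooled_er = fit_pooled_emax(er_points) if len(er_points) >= 10 else None
        if pooled_er is not None:
            (outdir / "pooled_er.json").write_text(json.dumps(pooled_er.to_dict(), indent=2))
            logger.info("stage pooled-er: scaling factor %.3g (n=%d)",
                        pooled_er.estimate("EC50"), pooled_er.n_obs)

        # ---- stage 5: effect-compartment PD fits -------------------------
        pd_rows = []
        pd_estimates: Dict[str, FitResult] = {}
        by_compound_pd: Dict[str, List[PDStudy]] = {}
        for sid, eff in obs.effects.items():
            cid = obs.compound_of[sid]
            if cid not in pk_params or not qualified.get(cid, False):
                continue
            by_compound_pd.setdefault(cid, []).append(
                PDStudy(effects=eff, regimen=regimens[sid], pk=pk_params[cid])
            )
        for cid, studies in sorted(by_compound_pd.items()):
            fit = fit_effect_compartment(studies)
            pd_rows.append({"compound_id": cid, **fit.to_dict()})
            if fit.converged:
                pd_estimates[cid] = fit
        pd_fits = pd.DataFrame(pd_rows)
        if not pd_fits.empty:
            pd_fits = pd_fits.rename(
                columns={"EC50": "ec50_uM", "EC50_se": "ec50_se", "EC50_cv_pct": "ec50_cv_pct",
                         "ke0": "ke0_per_h", "ke0_se": "ke0_se", "ke0_cv_pct": "ke0_cv_pct"}
            )
        pd_fits.to_csv(outdir / "pd_fits.csv", index=False)
        logger.info("stage effect-compartment: fitted %d compounds", len(pd_estimates))

        # ---- stage 6: CV filter + IVIVC ----------------------------------
        ivivc_out = None
        if pd_estimates:
            cv_table = pd.DataFrame(
                [
                    {
                        "compound_id": cid,
                        "ec50_cv_pct": fit.cv_pct("EC50"),
                        "ke0_cv_pct": fit.cv_pct("ke0"),
                    }
                    for cid, fit in pd_estimates.items()
                ]
            )
            included = filter_by_cv(cv_table, config.cv_threshold)
            for cid in pd_estimates:
                if cid not in included:
                    exclusions.append({"stage": "cv_filter", "compound_id": cid,
                                       "reason": f"EC50 or ke0 CV% exceeds {config.cv_threshold}"})
            pairs = [
                IVIVCPair(
                    compound_id=cid,
                    invitro_ic50=invitro_ic50.get(cid, compounds[cid].ic50_invitro),
                    invivo_ec50_total=pd_estimates[cid].estimate("EC50"),
                    fu_p=compounds[cid].fu_p,
                    ec50_cv=pd_estimates[cid].cv_pct("EC50"),
                    ke0_cv=pd_estimates[cid].cv_pct("ke0"),
                )
                for cid in included
            ]
            if len(pairs) >= 3:
                ivivc_out = ivivc_regression(pairs, config.regression_space).to_dict()
                (outdir / "ivivc.json").write_text(json.dumps(ivivc_out, indent=2))
                logger.info("stage ivivc: slope %.3g, R^2 %.3g, n=%d",
                            ivivc_out["slope"], ivivc_out["r_squared"], ivivc_out["n"])

        # ---- stage 7: SC projection --------------------------------------
        proj_rows = []
        retained = ivivc_out["included_ids"] if ivivc_out else list(pd_estimates)
        for cid in retained:
            fit = pd_estimates[cid]
            pdp = PDParams(EC50=fit.estimate("EC50"), ke0=fit.estimate("ke0"))
            for proj in project_sc_study(pk_params[cid], pdp, config.sc_doses,
                                         grid_step=0.005):
                proj_rows.append(
                    {
                        "compound_id": cid,
                        "dose_umol_per_kg": proj.dose,
                        "peak_effect_pct": proj.peak_effect,
                        "tmax_effect_h": proj.tmax_effect,
                        "sampling_time_h": proj.sampling_time,
                        "peak_plasma_uM": proj.peak_plasma,
                    }
                )
        sc_projection = pd.DataFrame(proj_rows)
        sc_projection.to_csv(outdir / "sc_projection.csv", index=False)

        (outdir / "exclusions.json").write_text(json.dumps(exclusions, indent=2))
        return PipelineResult(
            invitro_fits=invitro_fits,
            pk_fits=pk_fits,
            qualification=qualification,
            pooled_er=pooled_er,
            pd_fits=pd_fits,
            ivivc=ivivc_out,
            sc_projection=sc_projection,
            exclusions=exclusions,
        )
    finally:
        logging.getLogger("navpkpd").removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# input generation
# ---------------------------------------------------------------------------


def generate_pipeline_inputs(
    outdir,
    seed: int,
    n_compounds: int = 7,
    ivivc_ratio: float = 1.0,
    dispersion: float = 0.0,
    **panel_kwargs,
) -> dict:
    """Generate a synthetic compound panel and write the three long-format
    input files the pipeline consumes.  Returns the file paths plus the
    generating truth (also written to ``truth.json``)."""
    from .synthetic import generate_compound_panel, generate_invitro_dataset, InVitroDesign

    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, studies = generate_compound_panel(
        n_compounds, ivivc_ratio=ivivc_ratio, dispersion=dispersion, seed=rng, **panel_kwargs
    )

    obs_rows: List[dict] = []
    regimens: Dict[str, DoseRegimen] = {}
    for comp in truth.compounds:
        cid = comp.compound_id
        conc, inhib = generate_invitro_dataset(
            comp.ic50_invitro, comp.hill or 1.0, InVitroDesign(), seed=rng
        )
        for k, (c, y) in enumerate(zip(conc, inhib)):
            obs_rows.append(
                {"subject_id": f"{cid}_well{k+1}", "compound_id": cid, "time_h": c,
                 "obs_type": "invitro_pct", "value": y, "dose_group": "invitro"}
            )
        for st in studies.satellite_pk[cid]:
            sid = f"{cid}_{st.series.subject_id}"
            regimens[sid] = st.regimen
            for t, v in zip(st.series.times, st.series.values):
                obs_rows.append(
                    {"subject_id": sid, "compound_id": cid, "time_h": t,
                     "obs_type": "conc_uM", "value": v, "dose_group": "satellite"}
                )
        fmri = studies.fmri[cid]
        for st in fmri.pd_studies:
            sid = f"{cid}_{st.effects.subject_id}"
            regimens[sid] = st.regimen
            dg = f"fmri_{st.effects.subject_id.split('_')[0]}"
            for t, v in zip(st.effects.times, st.effects.values):
                obs_rows.append(
                    {"subject_id": sid, "compound_id": cid, "time_h": t,
                     "obs_type": "effect_pct", "value": v, "dose_group": dg}
                )
        for s in fmri.plasma_samples:
            sid = f"{cid}_{s.subject_id}"
            dg = f"fmri_{s.subject_id.split('_')[0]}"
            obs_rows.append(
                {"subject_id": sid, "compound_id": cid, "time_h": s.time,
                 "obs_type": "conc_uM", "value": s.value, "dose_group": dg}
            )

    paths = {
        "compound_table": str(outdir / "compound_table.csv"),
        "observations": str(outdir / "observations.csv"),
        "regimens": str(outdir / "regimens.csv"),
    }
    nio.write_compound_table(truth.compounds, paths["compound_table"])
    nio.write_observations(obs_rows, paths["observations"])
    nio.write_regimen_table(regimens, paths["regimens"])
    truth_dict = {
        "ivivc_ratio": truth.ivivc_ratio,
        "compounds": {
            c.compound_id: {
                "fu_p": c.fu_p,
                "ic50_uM": c.ic50_invitro,
                "pk": vars(truth.pk[c.compound_id]),
                "pd": vars(truth.pd[c.compound_id]),
            }
            for c in truth.compounds
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth_dict, indent=2))
    return {**paths, "truth": truth_dict}
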