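"""CSV file formats and pipeline configuration.

Long-format (NONMEM-style) tables are used throughout:

* compound table: ``compound_id, fu_p, ic50_uM[, hill, mol_weight]``
* regimen table: ``subject_id, time_h, route, amount, amount_unit,
  duration_h, ka_per_h, F`` (one row per dose event; ``amount_unit`` is
  ``umol_per_kg`` or ``mg_per_kg``, the latter converted via molecular
  weight on read)
* observation table: ``subject_id, compound_id, time_h, obs_type, value,
  dose_group`` with ``obs_type`` one of ``conc_uM``, ``effect_pct`` or
  ``invitro_pct``.  For ``invitro_pct`` rows the ``time_h`` column carries
  the test concentration in uM (there is no time axis in vitro).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    CompoundRecord,
    ConcentrationSeries,
    DoseEvent,
    DoseRegimen,
    EffectSeries,
    mg_per_kg_to_umol_per_kg,
)

__all__ = [
    "OBS_TYPES",
    "ObservationData",
    "PipelineConfig",
    "read_compound_table",
    "write_compound_table",
    "read_regimen_table",
    "write_regimen_table",
    "read_observations",
    "write_observations",
    "load_config",
]

OBS_TYPES = ("conc_uM", "effect_pct", "invitro_pct")


def _exact_floats(df: pd.DataFrame) -> pd.DataFrame:
    """Render float columns as shortest round-trip reprs so written CSVs
    read back bit-identical."""
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda x: repr(float(x)))
        elif df[col].dtype == object:
            df[col] = df[col].map(
                lambda x: repr(float(x)) if isinstance(x, float) else x
            )
    return df


# ---------------------------------------------------------------------------
# compound table
# ---------------------------------------------------------------------------


def read_compound_table(path) -> List[CompoundRecord]:
    """Read and validate a compound property table."""
    df = pd.read_csv(path, dtype={"compound_id": str}, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: compound table is empty")
    required = {"compound_id", "fu_p", "ic50_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dupes = df["compound_id"].astype(str).duplicated()
    if dupes.any():
        raise ValueError(
            f"{path}: duplicate compound ids {sorted(df['compound_id'][dupes].astype(str))}"
        )
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                CompoundRecord(
                    compound_id=str(row["compound_id"]),
                    fu_p=float(row["fu_p"]),
                    ic50_invitro=float(row["ic50_uM"]),
                    hill=float(row["hill"]) if "hill" in df.columns and pd.notna(row.get("hill")) else None,
                    mol_weight=float(row["mol_weight"]) if "mol_weight" in df.columns and pd.notna(row.get("mol_weight")) else 500.0,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from exc
    return records


def write_compound_table(records: Sequence[CompoundRecord], path) -> None:
    _exact_floats(pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "fu_p": r.fu_p,
                "ic50_uM": r.ic50_invitro,
                "hill": r.hill if r.hill is not None else "",
                "mol_weight": r.mol_weight,
            }
            for r in records
        ]
    )).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# regimen table
# ---------------------------------------------------------------------------


def read_regimen_table(
    path, mol_weight: Union[float, Mapping[str, float]] = 500.0
) -> Dict[str, DoseRegimen]:
    """Read per-subject dose regimens; mg/kg amounts are converted to
    umol/kg via ``mol_weight`` (a scalar, or a mapping by subject id)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: regimen table is empty")
    out: Dict[str, List[DoseEvent]] = {}
    for idx, row in df.iterrows():
        sid = str(row["subject_id"])
        amount = float(row["amount"])
        unit = str(row["amount_unit"])
        if unit == "mg_per_kg":
            mw = mol_weight[sid] if isinstance(mol_weight, Mapping) else mol_weight
            amount = mg_per_kg_to_umol_per_kg(amount, mw)
        elif unit != "umol_per_kg":
            raise ValueError(f"{path}: row {idx}: unknown amount_unit {unit!r}")

        def _opt(col):
            v = row.get(col)
            return float(v) if v is not None and pd.notna(v) and v != "" else None

        try:
            ev = DoseEvent(
                time=float(row["time_h"]),
                route=str(row["route"]),
                amount=amount,
                duration=_opt("duration_h"),
                ka=_opt("ka_per_h"),
                F=_opt("F"),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from exc
        out.setdefault(sid, []).append(ev)
    return {sid: DoseRegimen(events) for sid, events in out.items()}


def write_regimen_table(regimens: Mapping[str, DoseRegimen], path) -> None:
    rows = []
    for sid, regimen in regimens.items():
        for e in regimen.events:
            rows.append(
                {
                    "subject_id": sid,
                    "time_h": e.time,
                    "route": e.route,
                    "amount": e.amount,
                    "amount_unit": "umol_per_kg",
                    "duration_h": e.duration if e.duration is not None else "",
                    "ka_per_h": e.ka if e.ka is not None else "",
                    "F": e.F if e.F is not None else "",
                }
            )
    _exact_floats(pd.DataFrame(rows)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# observation table
# ---------------------------------------------------------------------------


@dataclass
class ObservationData:
    """Observations grouped by subject and type.

    ``concentrations`` and ``effects`` map subject id to series;
    ``invitro`` maps compound id to (concentration, percent inhibition)
    arrays; ``compound_of`` and ``dose_group_of`` record each subject's
    compound and dose-group labels.
    """

    concentrations: Dict[str, ConcentrationSeries]
    effects: Dict[str, EffectSeries]
    invitro: Dict[str, Tuple[np.ndarray, np.ndarray]]
    compound_of: Dict[str, str]
    dose_group_of: Dict[str, str]


def read_observations(path) -> ObservationData:
    df = pd.read_csv(path, dtype={"subject_id": str, "compound_id": str, "dose_group": str},
                     float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: observation table is empty")
    bad = set(df["obs_type"].unique()) - set(OBS_TYPES)
    if bad:
        raise ValueError(f"{path}: unknown obs_type value(s) {sorted(bad)}")

    conc: Dict[str, ConcentrationSeries] = {}
    eff: Dict[str, EffectSeries] = {}
    invitro: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    compound_of: Dict[str, str] = {}
    dose_group_of: Dict[str, str] = {}

    for (sid, otype), g in df.groupby(["subject_id", "obs_type"], sort=False):
        compound_of[sid] = str(g["compound_id"].iloc[0])
        dose_group_of[sid] = str(g["dose_group"].iloc[0])
        if otype == "invitro_pct":
            cid = str(g["compound_id"].iloc[0])
            x = g["time_h"].to_numpy(float)  # concentration, uM
            y = g["value"].to_numpy(float)
            if cid in invitro:
                x = np.concatenate([invitro[cid][0], x])
                y = np.concatenate([invitro[cid][1], y])
            invitro[cid] = (x, y)
            continue
        g = g.sort_values("time_h")
        t = g["time_h"].to_numpy(float)
        v = g["value"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"{path}: subject {sid}: {otype} times must be strictly increasing"
            )
        if otype == "conc_uM":
            conc[sid] = ConcentrationSeries(sid, t, v, "plasma")
        else:
            eff[sid] = EffectSeries(sid, t, v)
    return ObservationData(conc, eff, invitro, compound_of, dose_group_of)


def write_observations(rows: Sequence[dict], path) -> None:
    """Write long-format observation rows (dicts with the table's columns)."""
    df = pd.DataFrame(rows, columns=["subject_id", "compound_id", "time_h", "obs_type", "value", "dose_group"])
    bad = set(df["obs_type"].unique()) - set(OBS_TYPES)
    if bad:
        raise ValueError(f"unknown obs_type value(s) {sorted(bad)}")
    _exact_floats(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Paths and stage options for a full staged analysis run."""

    output_dir: str
    compound_table: str
    observations: str
    regimens: str
    seed: int = 0
    cv_threshold: float = 50.0
    fold_limit: float = 2.0
    lloq: float = 1e-4
    regression_space: str = "log10"
    sc_doses: Tuple[float, ...] = (0.3, 1.0, 3.0)

    def __post_init__(self) -> None:
        if self.cv_threshold <= 0 or self.fold_limit < 1 or self.lloq < 0:
            raise ValueError("thresholds must be positive (fold_limit >= 1)")
        self.sc_doses = tuple(float(d) for d in self.sc_doses)

    def validate_paths(self) -> None:
        for name in ("compound_table", "observations", "regimens"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return PipelineConfig(**data)
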