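"""Reference rhesus NaV1.7 compound panel.

Two published summary tables are shipped as package data because the
analysis consumes them directly: (a) the in vitro panel of 27 inhibitors
with fraction unbound in rhesus plasma and intrinsic patch-clamp IC50, and
(b) the effect-compartment fit summary for the 10 compounds with full PK-PD
datasets (EC50 and ke0 with standard errors and CV%).

Molecular weights of the panel compounds are not public; a default of
500 g/mol is attached for mass <-> molar dose conversion.
"""

from __future__ import annotations

from typing import List

import pandas as pd

from .core import CompoundRecord

__all__ = [
    "reference_compound_table",
    "reference_compounds",
    "reference_effect_compartment_table",
]

# compound_id, fu_p, ic50_uM
_COMPOUND_PANEL = [
    ("1", 0.118, 18.2),
    ("2", 0.001, 6.25),
    ("3", 0.106, 3.04),
    ("4", 0.069, 20.9),
    ("5", 0.066, 2.56),
    ("6", 0.074, 0.348),
    ("7", 0.138, 1.30),
    ("8", 0.078, 2.05),
    ("9", 0.080, 3.55),
    ("10", 0.019, 5.10),
    ("11", 0.053, 0.806),
    ("12", 0.048, 0.851),
    ("13", 0.097, 0.667),
    ("14", 0.049, 0.328),
    ("15", 0.051, 0.387),
    ("16", 0.042, 0.162),
    ("17", 0.082, 2.10),
    ("18", 0.106, 0.334),
    ("19", 0.178, 1.83),
    ("20", 0.008, 1.59),
    ("21", 0.251, 0.377),
    ("22", 0.341, 1.39),
    ("23", 0.173, 1.12),
    ("24", 0.148, 0.103),
    ("25", 0.146, 0.484),
    ("26", 0.048, 0.994),
    ("27", 0.070, 0.479),
]

# compound_id, ec50_uM, ec50_se, ec50_cv_pct, ke0_per_h, ke0_se, ke0_cv_pct
_EFFECT_COMPARTMENT_FITS = [
    ("6", 10.21, 1.60, 16.0, 2.20, 0.68, 31.0),
    ("13", 13.66, 2.97, 22.0, 3.22, 1.02, 32.0),
    ("14", 11.79, 2.55, 22.0, 1.14, 0.25, 22.0),
    ("16", 1.62, 1.33, 82.0, 0.66, 0.25, 38.0),
    ("18", 5.97, 0.86, 14.0, 1.39, 0.36, 26.0),
    ("21", 1.25, 0.45, 36.0, 0.62, 0.42, 67.0),
    ("22", 3.11, 0.66, 21.0, 3.74, 1.87, 50.0),
    ("24", 0.78, 0.18, 23.0, 1.65, 0.32, 20.0),
    ("25", 1.40, 0.33, 23.0, 0.74, 0.34, 46.0),
    ("27", 1.24, 1.19, 95.0, 0.55, 0.51, 93.0),
]


def reference_compound_table() -> pd.DataFrame:
    """The 27-compound in vitro panel: fu_p and intrinsic IC50 (uM)."""
    return pd.DataFrame(_COMPOUND_PANEL, columns=["compound_id", "fu_p", "ic50_uM"])


def reference_compounds(mol_weight: float = 500.0) -> List[CompoundRecord]:
    """The in vitro panel as validated :class:`CompoundRecord` objects."""
    return [
        CompoundRecord(cid, fu, ic50, mol_weight=mol_weight)
        for cid, fu, ic50 in _COMPOUND_PANEL
    ]


def reference_effect_compartment_table() -> pd.DataFrame:
    """Published effect-compartment fits (total-plasma EC50 in uM, ke0 in
    1/h) with SE and CV% for the 10 fully characterized compounds."""
    return pd.DataFrame(
        _EFFECT_COMPARTMENT_FITS,
        columns=[
            "compound_id",
            "ec50_uM",
            "ec50_se",
            "ec50_cv_pct",
            "ke0_per_h",
            "ke0_se",
            "ke0_cv_pct",
        ],
    )
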