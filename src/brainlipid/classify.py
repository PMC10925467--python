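"""Neuropathology + cognition case classification (Control / AAD / SAD).

Rules operate on the standard CERAD neuritic-plaque scale (0 none .. 3
frequent) and Braak stage (0..6):

* Control: CERAD 0-1 and Braak 0-3, not demented; if Braak = 3 then CERAD
  must equal 0.
* AAD (asymptomatic AD): CERAD 1-3 and Braak 3-6, not demented.
* SAD (symptomatic AD): CERAD 2-3 and Braak 3-6, demented.

Dementia is any of MMSE < 24, CASI < 81, CDR >= 1 (an explicit override flag
wins when set). ROSMAP records CERAD on an inverted 1-4 scale; classification
refuses to run unless the scale is declared, and an explicit converter maps
the inverted recording onto the standard scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import pandas as pd


class Diagnosis(str, Enum):
    CONTROL = "Control"
    AAD = "AAD"
    SAD = "SAD"
    UNCLASSIFIED = "Unclassified"


@dataclass(frozen=True)
class NeuropathRecord:
    cerad: int  # on the scale declared by cerad_scale
    braak: int
    cerad_scale: str = "standard"  # "standard" (0-3) or "rosmap" (inverted 1-4)
    mmse: Optional[float] = None
    casi: Optional[float] = None
    cdr: Optional[float] = None
    dementia_at_last_eval: Optional[bool] = None


@dataclass(frozen=True)
class DiagnosisCall:
    call: Diagnosis
    rule_fired: str


def convert_cerad_from_rosmap(cerad_rosmap: int) -> int:
    """Map the inverted ROSMAP CERAD recording (1 definite .. 4 no AD) to 0-3."""
    mapping = {4: 0, 3: 1, 2: 2, 1: 3}
    if cerad_rosmap not in mapping:
        raise ValueError(f"ROSMAP CERAD must be 1-4, got {cerad_rosmap}")
    return mapping[cerad_rosmap]


def is_demented(record: NeuropathRecord) -> bool:
    """Dementia: MMSE < 24, CASI < 81, or CDR >= 1 (logical OR); override wins."""
    if record.dementia_at_last_eval is not None:
        return bool(record.dementia_at_last_eval)
    if record.mmse is None and record.casi is None and record.cdr is None:
        raise ValueError("no cognitive inputs to determine dementia status")
    if record.mmse is not None and record.mmse < 24:
        return True
    if record.casi is not None and record.casi < 81:
        return True
    if record.cdr is not None and record.cdr >= 1:
        return True
    return False


def classify_case(record: NeuropathRecord) -> DiagnosisCall:
    """Apply the diagnosis rules in order Control -> AAD -> SAD."""
    if record.cerad_scale == "rosmap":
        cerad = convert_cerad_from_rosmap(record.cerad)
    elif record.cerad_scale == "standard":
        cerad = record.cerad
    else:
        raise ValueError(
            f"CERAD scale must be declared 'standard' or 'rosmap', got {record.cerad_scale!r}"
        )
    if not 0 <= cerad <= 3:
        raise ValueError(f"CERAD out of range: {cerad}")
    if not 0 <= record.braak <= 6:
        raise ValueError(f"Braak out of range: {record.braak}")
    demented = is_demented(record)
    braak = record.braak

    if (
        cerad in (0, 1)
        and 0 <= braak <= 3
        and not demented
        and (braak != 3 or cerad == 0)
    ):
        return DiagnosisCall(Diagnosis.CONTROL, "control: CERAD 0-1, Braak 0-3, no dementia")
    if cerad in (1, 2, 3) and 3 <= braak <= 6 and not demented:
        return DiagnosisCall(Diagnosis.AAD, "aad: CERAD 1-3, Braak 3-6, no dementia")
    if cerad in (2, 3) and 3 <= braak <= 6 and demented:
        return DiagnosisCall(Diagnosis.SAD, "sad: CERAD 2-3, Braak 3-6, dementia")
    return DiagnosisCall(Diagnosis.UNCLASSIFIED, "no rule fired")


def classify_traits_table(traits: pd.DataFrame, cerad_scale: str = "standard") -> pd.DataFrame:
    """Append diagnosis and rule-fired columns to a traits table.

    Expects columns ``cerad``, ``braak`` and either ``dementia`` or the
    cognitive scores ``mmse``/``casi``/``cdr``.
    """
    out = traits.copy()
    calls = []
    for _, row in traits.iterrows():
        rec = NeuropathRecord(
            cerad=int(row["cerad"]),
            braak=int(row["braak"]),
            cerad_scale=cerad_scale,
            mmse=row.get("mmse"),
            casi=row.get("casi"),
            cdr=row.get("cdr"),
            dementia_at_last_eval=(
                bool(row["dementia"]) if "dementia" in row and pd.notna(row["dementia"]) else None
            ),
        )
        calls.append(classify_case(rec))
    out["diagnosis"] = [c.call.value for c in calls]
    out["rule_fired"] = [c.rule_fired for c in calls]
    return out
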