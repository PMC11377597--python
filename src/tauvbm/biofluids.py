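"""Biofluid Alzheimer-biomarker gate.

Athletes are screened for Alzheimer-type pathology from plasma p-tau181 and/or
a CSF triplet (Aβ42, p-tau181, total tau) before any imaging analysis; anyone
positive on any available modality at any visit — or flagged for an AD-like
tau-PET retention pattern — is excluded from the cohort.

Thresholds (all strict '>'):

* plasma p-tau181, in-house Simoa assay: > 10.5 pg/mL if age < 60,
  > 13.3 pg/mL if age >= 60;
* plasma p-tau181, commercial Simoa Advantage V2 kit: > 2.2 pg/mL;
* CSF: p-tau181 > 68 pg/mL AND Aβ42/t-tau index < 0.8.

The Aβ42/t-tau index has no single canonical formula; the default is the
Hulstaert discriminant ratio Aβ42 / (240 + 1.18 * t-tau), but any callable
(abeta42, ttau) -> float can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "PLASMA_INHOUSE_YOUNG",
    "PLASMA_INHOUSE_OLD",
    "PLASMA_V2",
    "CSF_PTAU",
    "CSF_INDEX",
    "default_ab42_ttau_index",
    "classify_plasma",
    "classify_csf",
    "GateResult",
    "apply_gate",
]

PLASMA_INHOUSE_YOUNG = 10.5  # pg/mL, age < 60
PLASMA_INHOUSE_OLD = 13.3  # pg/mL, age >= 60
PLASMA_V2 = 2.2  # pg/mL
CSF_PTAU = 68.0  # pg/mL
CSF_INDEX = 0.8
AGE_CUT = 60.0

PLASMA_ASSAYS = ("in_house", "commercial_v2")


def default_ab42_ttau_index(abeta42: float, ttau: float) -> float:
    """Hulstaert discriminant ratio: Aβ42 / (240 + 1.18 * t-tau)."""
    return abeta42 / (240.0 + 1.18 * ttau)


def classify_plasma(value: float, assay: str, age: float | None = None) -> bool:
    """True iff the plasma p-tau181 value is AD-biomarker positive."""
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"plasma p-tau181 must be positive, got {value}")
    if assay == "in_house":
        if age is None:
            raise ValueError("in-house assay threshold is age-dependent; age is required")
        return value > (PLASMA_INHOUSE_YOUNG if age < AGE_CUT else PLASMA_INHOUSE_OLD)
    if assay == "commercial_v2":
        return value > PLASMA_V2
    raise ValueError(f"unknown plasma assay {assay!r}; expected one of {PLASMA_ASSAYS}")


def classify_csf(
    ptau: float,
    abeta42: float,
    ttau: float,
    index_fn: Callable[[float, float], float] = default_ab42_ttau_index,
) -> bool:
    """True iff CSF indicates AD pathology: p-tau > 68 AND index < 0.8."""
    for name, v in (("ptau", ptau), ("abeta42", abeta42), ("ttau", ttau)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"CSF {name} must be positive, got {v}")
    return (ptau > CSF_PTAU) and (index_fn(abeta42, ttau) < CSF_INDEX)


@dataclass
class GateResult:
    included: list[str]
    excluded: list[str]
    reasons: dict[str, str] = field(default_factory=dict)
    report: pd.DataFrame | None = None

    @property
    def n_screened(self) -> int:
        return len(self.included) + len(self.excluded)


def apply_gate(
    panels: pd.DataFrame,
    ages: dict[str, float] | pd.Series | None = None,
    pet_ad_flags: dict[str, bool] | pd.Series | None = None,
    index_fn: Callable[[float, float], float] = default_ab42_ttau_index,
) -> GateResult:
    """Apply the cohort exclusion gate.

    ``panels`` has one row per subject *visit* with columns ``subject_id`` and
    any of ``plasma_ptau181``, ``plasma_assay``, ``csf_ptau181``,
    ``csf_abeta42``, ``csf_ttau`` (missing values NaN/empty). A subject is
    excluded iff ANY available modality at ANY visit classifies positive, or
    their tau-PET retention pattern was flagged as AD-like. A subject with
    neither a gateable panel (plasma value+assay, or complete CSF triplet)
    nor a PET flag is an error.
    """
    panels = panels.copy()
    if "subject_id" not in panels.columns:
        raise ValueError("panels must have a subject_id column")
    ages = dict(ages) if ages is not None else {}
    flags = dict(pet_ad_flags) if pet_ad_flags is not None else {}

    decisions: dict[str, str | None] = {}
    gateable: dict[str, bool] = {}
    rows = []
    for sid, grp in panels.groupby("subject_id", sort=True):
        sid = str(sid)
        decisions.setdefault(sid, None)
        gateable.setdefault(sid, False)
        for _, row in grp.iterrows():
            plasma = row.get("plasma_ptau181")
            if plasma is not None and np.isfinite(plasma):
                assay = row.get("plasma_assay")
                if not isinstance(assay, str):
                    raise ValueError(f"subject {sid}: plasma value without assay name")
                pos = classify_plasma(float(plasma), assay, ages.get(sid))
                gateable[sid] = True
                rows.append((sid, "plasma", f"{assay}:{plasma}", pos))
                if pos and decisions[sid] is None:
                    thr = (
                        PLASMA_V2
                        if assay == "commercial_v2"
                        else (
                            PLASMA_INHOUSE_YOUNG
                            if ages.get(sid, 0) < AGE_CUT
                            else PLASMA_INHOUSE_OLD
                        )
                    )
                    decisions[sid] = f"plasma p-tau181 {plasma} pg/mL > {thr} ({assay})"
            csf_vals = [row.get(c) for c in ("csf_ptau181", "csf_abeta42", "csf_ttau")]
            if all(v is not None and np.isfinite(v) for v in csf_vals):
                ptau, abeta, ttau = (float(v) for v in csf_vals)
                pos = classify_csf(ptau, abeta, ttau, index_fn)
                gateable[sid] = True
                rows.append((sid, "csf", f"ptau:{ptau},abeta42:{abeta},ttau:{ttau}", pos))
                if pos and decisions[sid] is None:
                    decisions[sid] = (
                        f"CSF p-tau181 {ptau} > {CSF_PTAU} and index "
                        f"{index_fn(abeta, ttau):.3f} < {CSF_INDEX}"
                    )

    for sid, flagged in flags.items():
        sid = str(sid)
        decisions.setdefault(sid, None)
        gateable.setdefault(sid, False)
        if flagged:
            gateable[sid] = True
            if decisions[sid] is None:
                decisions[sid] = "tau-PET retention pattern suggestive of AD"
            rows.append((sid, "pet_pattern", "flagged", True))

    ungateable = sorted(s for s, ok in gateable.items() if not ok)
    if ungateable:
        raise ValueError(f"subjects without a gateable biofluid panel or PET flag: {ungateable}")

    included = sorted(s for s, why in decisions.items() if why is None)
    excluded = sorted(s for s, why in decisions.items() if why is not None)
    report = pd.DataFrame(rows, columns=["subject_id", "modality", "values", "positive"])
    return GateResult(
        included=included,
        excluded=excluded,
        reasons={s: w for s, w in decisions.items() if w is not None},
        report=report,
    )
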