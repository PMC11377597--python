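"""Neuropsychological composite scores.

Three domain composites are built from normed test scores (higher = better
performance on every measure):

* memory (z scale): RAVLT trials 1-5, RAVLT long-delay recall, RVDLT trials
  1-5 — arithmetic mean of the available z-scores;
* attention / speed of processing (z scale): TMT-A, digit span forward,
  Stroop colour naming, Stroop word reading, SDMT written, SDMT oral;
* executive function (t scale): the four WCST t-scores are averaged first,
  then that average, digit span backwards and TMT-B are averaged — so the
  WCST block carries the weight of a single element (1/3 of the composite).

Minimum-availability rules (>= 2/3 memory inputs, >= 4/6 speed inputs, all
three executive elements) keep a composite stable under sparse batteries;
when unmet the composite is missing (NaN), never an exception. z- and
t-scales are never mixed within a composite.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "MEMORY_INPUTS",
    "MEMORY_INPUTS_2TEST",
    "SPEED_INPUTS",
    "WCST_INPUTS",
    "memory_composite",
    "speed_composite",
    "executive_composite",
    "compute_composites",
]

MEMORY_INPUTS = ("ravlt_trials_z", "ravlt_delay_z", "rvdlt_trials_z")
#: abstract-style 2-test variant (RAVLT + RVDLT learning only)
MEMORY_INPUTS_2TEST = ("ravlt_trials_z", "rvdlt_trials_z")
SPEED_INPUTS = (
    "tmt_a_z",
    "digit_fwd_z",
    "stroop_color_z",
    "stroop_word_z",
    "sdmt_written_z",
    "sdmt_oral_z",
)
WCST_INPUTS = (
    "wcst_err_t",
    "wcst_persev_err_t",
    "wcst_nonpersev_err_t",
    "wcst_conceptual_t",
)


def _mean_if(values: list[float], min_present: int) -> float:
    present = [v for v in values if v is not None and np.isfinite(v)]
    if len(present) < min_present:
        return math.nan
    return float(np.mean(present))


def _get(scores, names) -> list[float]:
    if isinstance(scores, pd.Series):
        return [scores.get(n, math.nan) for n in names]
    return [scores.get(n, math.nan) for n in names]


def memory_composite(scores, min_present: int = 2, two_test: bool = False) -> float:
    """Mean of the available memory z-scores (NaN if fewer than min_present)."""
    inputs = MEMORY_INPUTS_2TEST if two_test else MEMORY_INPUTS
    if two_test:
        min_present = min(min_present, len(inputs))
    return _mean_if(_get(scores, inputs), min_present)


def speed_composite(scores, min_present: int = 4) -> float:
    """Mean of the available attention/speed z-scores (NaN if < min_present)."""
    return _mean_if(_get(scores, SPEED_INPUTS), min_present)


def executive_composite(scores, min_wcst: int = 3) -> float:
    """Mean of digit-span-backwards t, WCST t average, and TMT-B t.

    Requires all three elements; the WCST element itself needs at least
    ``min_wcst`` of its four scores. Missing element -> NaN composite.
    """
    wcst = _mean_if(_get(scores, WCST_INPUTS), min_wcst)
    digit = _get(scores, ("digit_bwd_t",))[0]
    tmt_b = _get(scores, ("tmt_b_t",))[0]
    vals = [digit, wcst, tmt_b]
    if any(v is None or not np.isfinite(v) for v in vals):
        return math.nan
    return float(np.mean(vals))


def compute_composites(
    df: pd.DataFrame,
    two_test_memory: bool = False,
    min_memory: int = 2,
    min_speed: int = 4,
    min_wcst: int = 3,
) -> pd.DataFrame:
    """Per-subject composite table from a neuropsych score table.

    ``df`` has one row per subject with a ``subject_id`` column plus the
    normed score columns; unknown columns are ignored. Returns subject_id,
    the three composites and the count of inputs behind each.
    """
    out = []
    for _, row in df.iterrows():
        mem_inputs = MEMORY_INPUTS_2TEST if two_test_memory else MEMORY_INPUTS
        out.append(
            {
                "subject_id": row["subject_id"],
                "memory": memory_composite(row, min_present=min_memory, two_test=two_test_memory),
                "speed": speed_composite(row, min_present=min_speed),
                "executive": executive_composite(row, min_wcst=min_wcst),
                "n_memory": int(np.sum([np.isfinite(row.get(c, np.nan)) for c in mem_inputs])),
                "n_speed": int(np.sum([np.isfinite(row.get(c, np.nan)) for c in SPEED_INPUTS])),
                "n_wcst": int(np.sum([np.isfinite(row.get(c, np.nan)) for c in WCST_INPUTS])),
            }
        )
    return pd.DataFrame(out)
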