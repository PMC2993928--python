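"""Packaged reference dataset: per-subject VTA/SN cluster-mean FA values.

The published 22-subject MDD cohort reports, for each patient, the mean FA
over the right VTA/SN difference cluster together with antidepressant
history and current-use flags, sectioned into a "normal" (below-gap) and an
"abnormal" (above-gap) subgroup.  These values drive the gapping re-analysis
and the medication tallies.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_vta_sn_table", "reference_vta_sn_values"]

# (FA value, history of antidepressant treatment, on antidepressants at scan,
#  published subgroup section)
_ROWS = [
    (0.263588, "No", "No", "normal"),
    (0.332777, "Yes", "Yes", "normal"),
    (0.353066, "Yes", "Yes", "normal"),
    (0.362028, "Yes", "No", "normal"),
    (0.390219, "No", "No", "normal"),
    (0.391810, "Yes", "No", "normal"),
    (0.410209, "Yes", "Yes", "normal"),
    (0.417723, "No", "No", "normal"),
    (0.434277, "No", "No", "normal"),
    (0.435750, "No", "No", "normal"),
    (0.448794, "Yes", "Yes", "normal"),
    (0.455736, "Yes", "No", "normal"),
    (0.544226, "Yes", "No", "abnormal"),
    (0.546144, "No", "No", "abnormal"),
    (0.548690, "Yes", "No", "abnormal"),
    (0.602679, "Yes", "Yes", "abnormal"),
    (0.603839, "No", "No", "abnormal"),
    (0.612006, "Yes", "No", "abnormal"),
    (0.646446, "Yes", "Yes", "abnormal"),
    (0.658727, "Yes", "Yes", "abnormal"),
    (0.677050, "No", "No", "abnormal"),
    (0.745329, "Yes", "No", "abnormal"),
]


def reference_vta_sn_table() -> pd.DataFrame:
    """The 22 published VTA/SN cluster-mean FA values with medication flags.

    Columns: ``fa`` (float), ``history_antidepressant`` and
    ``on_antidepressant`` ("Yes"/"No"), ``subgroup`` ("normal"/"abnormal"
    per the published sectioning).
    """
    return pd.DataFrame(
        _ROWS,
        columns=["fa", "history_antidepressant", "on_antidepressant", "subgroup"],
    )


def reference_vta_sn_values() -> list[float]:
    """Just the 22 FA values, in published order (ascending within section)."""
    return [r[0] for r in _ROWS]
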