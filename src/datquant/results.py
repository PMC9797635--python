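"""Common result container for all semi-quantification methods."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["QuantResult", "INDEX_TYPE_BY_METHOD", "results_to_frame"]

#: the index each method reports (fixed per method)
INDEX_TYPE_BY_METHOD = {
    "manual": "BPI",
    "twobox": "SBR",
    "threebox": "TBPI",
    "voi_mri_like": "BPI",
    "voi_ct_like": "BPI",
}


@dataclass
class QuantResult:
    """One semi-quantitative index for one acquisition and compartment."""

    method: str
    compartment: str  # CA, PU, ST or per-side variants (CA_R, ...)
    index_type: str   # BPI, SBR or TBPI
    value: float
    acquisition_id: str

    def __post_init__(self) -> None:
        expected = INDEX_TYPE_BY_METHOD.get(self.method)
        if expected is not None and self.index_type != expected:
            raise ValueError(
                f"method {self.method} reports {expected}, not {self.index_type}"
            )


def results_to_frame(results, fills=None) -> pd.DataFrame:
    """Tabulate results; if ``fills`` maps acquisition_id -> FillRecord, the
    matching ground truth (achieved SBR for SBR indices, achieved BPI
    otherwise) and the activity level are attached."""
    rows = []
    for r in results:
        row = {
            "acquisition_id": r.acquisition_id,
            "method": r.method,
            "compartment": r.compartment,
            "index_type": r.index_type,
            "value": r.value,
        }
        if fills is not None:
            fill = fills[r.acquisition_id]
            row["truth"] = fill.achieved_sbr if r.index_type == "SBR" else fill.achieved_bpi
            row["activity_level"] = fill.activity_level
            row["nominal_ratio"] = fill.nominal_ratio
        rows.append(row)
    return pd.DataFrame(rows)
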