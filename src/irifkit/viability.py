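"""Clonogenic-assay arithmetic: plating efficiency and surviving fraction.

Definitions (percentages):

    PE = colonies / seeded * 100
    SF = colonies_irradiated / (seeded * PE / 100) * 100

so the unirradiated reference — whose colony count defines PE — has
SF = 100% by construction. MTT-style readouts reduce to normalization
against the untreated control plus replicate aggregation and reuse
:func:`aggregate_replicates`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def plating_efficiency(colonies: float, seeded: float) -> float:
    """PE in percent from the mean unirradiated colony count."""
    if seeded <= 0:
        raise ValueError("seeded cell count must be > 0")
    if colonies > seeded:
        logger.warning(
            "colony count %.1f exceeds seeded count %.0f (merged-colony miscount?)",
            colonies, seeded,
        )
    return colonies / seeded * 100.0


def surviving_fraction(colonies_ir: float, seeded: float, pe: float) -> float:
    """SF in percent: irradiated colonies relative to the PE-expected yield."""
    if seeded <= 0:
        raise ValueError("seeded cell count must be > 0")
    if pe <= 0:
        raise ValueError("surviving fraction is undefined for PE <= 0")
    return colonies_ir / (seeded * pe / 100.0) * 100.0


def aggregate_replicates(
    records: pd.DataFrame,
    value: str,
    by: list[str],
) -> pd.DataFrame:
    """Mean ± sample SD (n-1 denominator) of *value* per condition.

    A condition with a single replicate reports its SD as missing.
    """
    def _agg(x: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "n": len(x),
                "mean": x.mean(),
                "sd": x.std(ddof=1) if len(x) > 1 else np.nan,
            }
        )

    out = records.groupby(by)[value].apply(_agg).unstack().reset_index()
    out["n"] = out["n"].astype(int)
    return out


def survival_table(counts: pd.DataFrame) -> pd.DataFrame:
    """PE/SF per condition from a colony-count table.

    Expects columns ``dose_Gy, gnp, seeded, colonies`` (one row per well /
    replicate). The reference for PE is the ``dose_Gy == 0, gnp == False``
    condition; SF is computed per (dose, gnp) from mean colony counts.
    """
    required = {"dose_Gy", "gnp", "seeded", "colonies"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    ref = counts[(counts["dose_Gy"] == 0) & (~counts["gnp"].astype(bool))]
    if ref.empty:
        raise ValueError("no unirradiated GNP(-) reference wells to define PE")
    seeded_ref = float(ref["seeded"].mean())
    pe = plating_efficiency(float(ref["colonies"].mean()), seeded_ref)
    rows = []
    for (dose, gnp), sub in counts.groupby(["dose_Gy", "gnp"]):
        colonies = float(sub["colonies"].mean())
        seeded = float(sub["seeded"].mean())
        rows.append(
            {
                "dose_Gy": dose,
                "gnp": gnp,
                "seeded": seeded,
                "colonies_mean": colonies,
                "PE_pct": pe,
                "SF_pct": surviving_fraction(colonies, seeded, pe),
            }
        )
    return pd.DataFrame(rows)
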