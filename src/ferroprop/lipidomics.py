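"""Lipidomics peak-area normalisation and illuminated/control fold changes.

Raw MRM peak areas are normalised to the matched internal-standard area
(and optionally to protein content, for the oxidized-glycerophospholipid
workflow; fatty-acid panels omit the protein step). Fold changes divide the
illuminated normalised ratio by the replicate-paired non-illuminated
control and are averaged arithmetically across replicates (geometric mean
available as an option).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["normalize_areas", "fold_changes"]

REQUIRED = ["species", "condition", "replicate", "area", "is_area"]


def normalize_areas(table: pd.DataFrame, per_protein: bool = True) -> pd.DataFrame:
    """Append a ``normalized`` column: area / IS area (/ protein µg).

    ``table`` needs columns species, condition, replicate, area, is_area,
    and protein_ug when ``per_protein``. Zero or negative IS areas or
    protein content raise with the offending row named.
    """
    missing = [c for c in REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if per_protein and "protein_ug" not in table.columns:
        raise ValueError("per_protein=True requires a protein_ug column")
    bad = table.index[table["is_area"] <= 0]
    if len(bad):
        raise ValueError(f"non-positive internal-standard area in row(s) {list(bad[:5])}")
    out = table.copy()
    out["normalized"] = out["area"] / out["is_area"]
    if per_protein:
        bad = out.index[out["protein_ug"] <= 0]
        if len(bad):
            raise ValueError(f"non-positive protein content in row(s) {list(bad[:5])}")
        out["normalized"] = out["normalized"] / out["protein_ug"]
    return out


def fold_changes(
    normalized: pd.DataFrame,
    treated: str = "illuminated",
    control: str = "control",
    mean: str = "arithmetic",
) -> pd.DataFrame:
    """Per-replicate and replicate-mean fold changes per species.

    Each species must have a matched (treated, control) pair in every
    replicate; fold change = normalized(treated) / normalized(control) per
    replicate, summarised by the arithmetic mean (or geometric with
    ``mean="geometric"``). Returns a frame with columns species, replicate,
    fold_change plus one ``mean_fold_change`` per species.
    """
    if mean not in ("arithmetic", "geometric"):
        raise ValueError("mean must be 'arithmetic' or 'geometric'")
    if "normalized" not in normalized.columns:
        raise ValueError("run normalize_areas first (no 'normalized' column)")
    piv = normalized.pivot_table(
        index=["species", "replicate"], columns="condition", values="normalized",
        aggfunc="first",
    )
    for cond in (treated, control):
        if cond not in piv.columns:
            raise ValueError(f"condition {cond!r} missing from table")
    if piv[[treated, control]].isna().any().any():
        bad = piv.index[piv[[treated, control]].isna().any(axis=1)]
        raise ValueError(f"unmatched replicate pairing for {list(bad[:5])}")
    if (piv[control] <= 0).any():
        bad = piv.index[piv[control] <= 0]
        raise ValueError(f"zero/negative control ratio for {list(bad[:5])}")
    fc = (piv[treated] / piv[control]).rename("fold_change").reset_index()
    if mean == "arithmetic":
        m = fc.groupby("species")["fold_change"].mean()
    else:
        m = fc.groupby("species")["fold_change"].apply(lambda v: float(np.exp(np.log(v).mean())))
    fc["mean_fold_change"] = fc["species"].map(m)
    return fc
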