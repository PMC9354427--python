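"""Long-to-paired reshaping shared by the model-fitting modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["to_pairs"]


def to_pairs(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Reshape a one-row-per-twin frame into one row per family.

    Returns a frame with ``zygosity``, ``sex`` and, for each requested
    column ``c``, ``c_1`` and ``c_2`` for the two co-twins.  Families
    without exactly two members, or with inconsistent zygosity/sex, are
    dropped.
    """
    required = {"family_id", "twin_index", "zygosity", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    counts = df.groupby("family_id")["twin_index"].agg(["size", "nunique"])
    good = counts[(counts["size"] == 2) & (counts["nunique"] == 2)].index
    sub = df[df["family_id"].isin(good)].sort_values(["family_id", "twin_index"])

    fam = sub.groupby("family_id", sort=True)
    consistent = fam["zygosity"].nunique().eq(1) & fam["sex"].nunique().eq(1)
    sub = sub[sub["family_id"].isin(consistent[consistent].index)]

    wide = sub.pivot(index="family_id", columns="twin_index", values=columns)
    out = pd.DataFrame(index=wide.index)
    for c in columns:
        out[f"{c}_1"] = wide[(c, 1)]
        out[f"{c}_2"] = wide[(c, 2)]
    meta = sub[sub["twin_index"] == 1].set_index("family_id")[["zygosity", "sex"]]
    out = out.join(meta)
    return out.reset_index()


def pair_array(pairs: pd.DataFrame, column: str) -> np.ndarray:
    """(n, 2) float array of a paired column."""
    return pairs[[f"{column}_1", f"{column}_2"]].to_numpy(float)
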