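"""Between-individual and within-pair outcome differences by pillar count.

Descriptive counterparts of the model-based analyses: how much does the
raw outcome (BMI in kg/m^2, PHQ-2 total) differ between individuals, and
between co-twins, who meet ``d`` more pillars?

* **Between-individual**: for a difference ``d``, average the contrasts
  mean(outcome | k + d) - mean(outcome | k) over every eligible ``k``
  (unweighted by default); the standard error treats the category means
  as independent and accounts for categories shared between contrasts.
* **Within-pair**: among complete pairs whose members differ in pillar
  count, the difference "twin meeting more pillars minus co-twin",
  grouped by the absolute count difference and (optionally) zygosity.
  Strata with no pairs are simply absent from the output.

These descriptives use complete cases and the raw outcome scale; the
structural models use transformed scales and FIML.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._data import pair_array, to_pairs

__all__ = ["DifferenceSummary", "between_individual_diffs", "within_pair_diffs"]


@dataclass
class DifferenceSummary:
    d: int
    zygosity: str  # "MZ", "DZ" or "pooled"
    mean_diff: float
    se: float | None
    n: int

    def to_row(self) -> dict:
        return {
            "d": self.d, "zygosity": self.zygosity,
            "mean_diff": self.mean_diff, "se": self.se, "n": self.n,
        }


def between_individual_diffs(
    df: pd.DataFrame, outcome: str, d: int, count_col: str = "n_pillars",
    weighted: bool = False, max_count: int = 5,
) -> DifferenceSummary | None:
    """Average between-individual outcome contrast for a count difference d.

    Averages mean(outcome | k + d) - mean(outcome | k) over eligible k;
    contrasts with an empty contributing category are skipped.  Returns
    None when no contrast is computable.  ``n`` is the number of
    individuals in the contributing categories.
    """
    if not 1 <= d <= max_count:
        raise ValueError(f"d must be in 1..{max_count}")
    sub = df[[outcome, count_col]].dropna()
    stats = sub.groupby(count_col)[outcome].agg(["mean", "var", "count"])

    coeffs: dict[int, float] = {}
    m = 0
    for k in range(0, max_count - d + 1):
        if k in stats.index and k + d in stats.index and stats.loc[k, "count"] >= 1 \
                and stats.loc[k + d, "count"] >= 1:
            coeffs[k + d] = coeffs.get(k + d, 0.0) + 1.0
            coeffs[k] = coeffs.get(k, 0.0) - 1.0
            m += 1
    if m == 0:
        return None
    if weighted:
        # weight contrasts by the harmonic pair size; recompute coefficients
        coeffs = {}
        wsum = 0.0
        for k in range(0, max_count - d + 1):
            if k in stats.index and k + d in stats.index:
                n1, n2 = stats.loc[k, "count"], stats.loc[k + d, "count"]
                if n1 < 1 or n2 < 1:
                    continue
                w = 2.0 / (1.0 / n1 + 1.0 / n2)
                coeffs[k + d] = coeffs.get(k + d, 0.0) + w
                coeffs[k] = coeffs.get(k, 0.0) - w
                wsum += w
        coeffs = {k: v / wsum for k, v in coeffs.items()}
        mean = sum(c * stats.loc[k, "mean"] for k, c in coeffs.items())
    else:
        mean = sum(c * stats.loc[k, "mean"] for k, c in coeffs.items()) / m
        coeffs = {k: c / m for k, c in coeffs.items()}

    var = 0.0
    valid = True
    for k, c in coeffs.items():
        nk = stats.loc[k, "count"]
        vk = stats.loc[k, "var"]
        if nk < 2 or not np.isfinite(vk):
            valid = False
            break
        var += c**2 * vk / nk
    se = float(np.sqrt(var)) if valid else None
    n_total = int(sum(stats.loc[k, "count"] for k in coeffs))
    return DifferenceSummary(d=d, zygosity="pooled", mean_diff=float(mean),
                             se=se, n=n_total)


def within_pair_diffs(
    df: pd.DataFrame, outcome: str, count_col: str = "n_pillars",
    by_zygosity: bool = True,
) -> list[DifferenceSummary]:
    """Within-pair outcome differences by absolute pillar-count difference.

    Uses complete pairs (both outcomes and both counts observed); pairs
    with equal counts are excluded.  The signed difference is
    outcome(more-pillars twin) - outcome(co-twin).  SEs (sd / sqrt(n))
    are reported for strata with n >= 2; empty strata are absent.
    """
    pairs = to_pairs(df, [outcome, count_col])
    y = pair_array(pairs, outcome)
    c = pair_array(pairs, count_col)
    ok = ~np.isnan(y).any(axis=1) & ~np.isnan(c).any(axis=1)
    y, c = y[ok], c[ok]
    zyg = pairs.loc[ok, "zygosity"].to_numpy()
    dcount = c[:, 0] - c[:, 1]
    discordant = dcount != 0
    y, c, zyg, dcount = y[discordant], c[discordant], zyg[discordant], dcount[discordant]
    sign = np.sign(dcount)
    diff = sign * (y[:, 0] - y[:, 1])
    absd = np.abs(dcount).astype(int)

    out = []
    strata = (
        [(d, z) for d in sorted(set(absd)) for z in ("MZ", "DZ")]
        if by_zygosity
        else [(d, "pooled") for d in sorted(set(absd))]
    )
    for d, z in strata:
        mask = absd == d if z == "pooled" else (absd == d) & (zyg == z)
        n = int(mask.sum())
        if n == 0:
            continue
        vals = diff[mask]
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else None
        out.append(DifferenceSummary(d=d, zygosity=z, mean_diff=float(vals.mean()),
                                     se=se, n=n))
    return out


def difference_table(df: pd.DataFrame, outcome: str, max_count: int = 5,
                     count_col: str = "n_pillars") -> pd.DataFrame:
    """Combined descriptive table behind the difference figures."""
    rows = []
    for d in range(1, max_count + 1):
        s = between_individual_diffs(df, outcome, d, count_col=count_col,
                                     max_count=max_count)
        if s is not None:
            rows.append({"kind": "between_individual", **s.to_row()})
    for s in within_pair_diffs(df, outcome, count_col=count_col):
        rows.append({"kind": "within_pair", **s.to_row()})
    return pd.DataFrame(rows)
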