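"""Deviation statistics against experimental solubility and polymer ranking.

Sign convention: Δw = w_calc − w_exp, so a positive average deviation (AD)
means the model overestimates the solubility.  AAD/AD/AARD are reported in
percent.  AARD is reported for completeness but never used for ranking
because of its bias toward small experimental weight fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DeviationReport", "deviations", "rank_polymers", "RankEntry"]


@dataclass
class DeviationReport:
    """Per-point, per-system and aggregate deviation metrics (percent)."""

    points: pd.DataFrame            # system, T_K, w_exp, w_calc, delta_w
    per_system: pd.DataFrame        # system, N, AAD, AD, AARD, aard_defined
    aad: float
    ad: float
    aard: float | None
    n: int
    aard_defined: bool = True
    median_system_aad: float | None = None

    def __post_init__(self) -> None:
        if self.n > 0 and self.aad + 1e-12 < abs(self.ad):
            raise ValueError("AAD must be >= |AD|")


def deviations(exp_table: pd.DataFrame, predictions: pd.DataFrame) -> DeviationReport:
    """Compare predicted with experimental weight-fraction solubilities.

    Both tables need columns ``system``, ``T_K`` and a weight fraction
    column (``w_exp`` / ``w_calc``; a plain ``w_API`` is accepted too).
    Rows are matched on the (system, T_K) key; unmatched experimental keys
    raise an error listing them.
    """
    exp = exp_table.rename(columns={"w_API": "w_exp"}).copy()
    calc = predictions.rename(columns={"w_API": "w_calc"}).copy()
    for frame, col in ((exp, "w_exp"), (calc, "w_calc")):
        missing = {"system", "T_K", col} - set(frame.columns)
        if missing:
            raise ValueError(f"table lacks columns {sorted(missing)}")
    merged = exp.merge(calc[["system", "T_K", "w_calc"]], on=["system", "T_K"], how="left")
    unmatched = merged[merged["w_calc"].isna()]
    if len(unmatched):
        keys = [f"({r.system}, {r.T_K} K)" for r in unmatched.itertuples()]
        raise ValueError(f"no prediction for experimental keys: {', '.join(keys)}")

    merged["delta_w"] = merged["w_calc"] - merged["w_exp"]

    def _metrics(group: pd.DataFrame) -> pd.Series:
        delta = group["delta_w"].to_numpy()
        w_exp = group["w_exp"].to_numpy()
        defined = bool(np.all(w_exp != 0.0))
        aard = float(np.mean(np.abs(delta / w_exp)) * 100.0) if defined else np.nan
        return pd.Series({
            "N": len(group),
            "AAD": float(np.mean(np.abs(delta)) * 100.0),
            "AD": float(np.mean(delta) * 100.0),
            "AARD": aard,
            "aard_defined": defined,
        })

    per_system = (
        merged.groupby("system", sort=True).apply(_metrics, include_groups=False)
        .reset_index()
    )
    per_system["N"] = per_system["N"].astype(int)

    delta = merged["delta_w"].to_numpy()
    w_exp = merged["w_exp"].to_numpy()
    aard_defined = bool(np.all(w_exp != 0.0))
    return DeviationReport(
        points=merged,
        per_system=per_system,
        aad=float(np.mean(np.abs(delta)) * 100.0),
        ad=float(np.mean(delta) * 100.0),
        aard=float(np.mean(np.abs(delta / w_exp)) * 100.0) if aard_defined else None,
        n=len(merged),
        aard_defined=aard_defined,
        median_system_aad=float(per_system["AAD"].median()),
    )


@dataclass(frozen=True)
class RankEntry:
    """One row of a polymer compatibility ranking."""

    rank: int
    polymer: str
    w_api: float
    aaps: bool
    members: tuple[str, ...] = ()


def rank_polymers(
    per_polymer: dict[str, tuple[float, bool]],
    t_ref: float = 298.15,
    aaps_tie_band: float = 0.0,
    grouping: dict[str, str] | None = None,
) -> list[RankEntry]:
    """Order polymers by predicted API solubility at the reference T.

    ``per_polymer`` maps polymer name to (predicted w_API at ``t_ref``,
    AAPS flag).  Polymers are sorted by descending solubility; when two
    candidates tie within ``aaps_tie_band`` the AAPS-free one ranks higher;
    remaining ties break deterministically by name.  ``grouping`` collapses
    grades of one polymer family to a single entry (mean solubility,
    AAPS if any member shows it).  The combination rule approximates the
    originally unpublished procedure and is configurable.
    """
    if len(per_polymer) < 2:
        raise ValueError("ranking needs at least two polymers")
    grouping = grouping or {}
    grouped: dict[str, list[tuple[str, float, bool]]] = {}
    for name, (w, aaps) in per_polymer.items():
        grouped.setdefault(grouping.get(name, name), []).append((name, w, aaps))

    rows = []
    for label, members in grouped.items():
        w_mean = float(np.mean([m[1] for m in members]))
        aaps_any = any(m[2] for m in members)
        rows.append((label, w_mean, aaps_any, tuple(sorted(m[0] for m in members))))

    rows.sort(key=lambda r: (-r[1], r[0]))
    # demote AAPS-positive entries past AAPS-free ones within the tie band
    changed = True
    while changed:
        changed = False
        for i in range(len(rows) - 1):
            upper, lower = rows[i], rows[i + 1]
            tie = abs(upper[1] - lower[1]) <= aaps_tie_band
            if tie and upper[2] and not lower[2]:
                rows[i], rows[i + 1] = lower, upper
                changed = True
    return [
        RankEntry(rank=i + 1, polymer=r[0], w_api=r[1], aaps=r[2], members=r[3])
        for i, r in enumerate(rows)
    ]
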