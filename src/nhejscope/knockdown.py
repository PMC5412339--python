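"""Expression knockdown from qPCR Ct tables and Western-blot densitometry.

The qPCR side implements comparative-threshold (2^-ddCt) relative
quantification: per group, dCt = mean Ct(target) - mean Ct(reference gene);
ddCt = dCt(group) - dCt(control); fold change = 2^-ddCt; percent reduction
= (1 - fold) x 100. Per-replicate folds (replicate-wise dCt against the
control's mean dCt) are retained for dispersion estimates and for the
group-comparison statistics.

The densitometry side consumes optical-density numbers (target band vs
loading control) — never images — normalizes the per-replicate ratio to the
control-group mean, and runs the same group statistics.

Group statistics are one-way ANOVA (F = MS_between / MS_within, computed
from the standard sums of squares; p from the F distribution) followed by
Tukey's honestly-significant-difference pairwise comparisons (delegated to
scipy's studentized-range implementation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticsError, TableError

CT_COLUMNS = ("group", "sample", "gene_role", "replicate", "ct")
DENSITOMETRY_COLUMNS = ("group", "replicate", "od_target", "od_loading")


@dataclass(frozen=True)
class FoldChangeResult:
    group: str
    delta_ct: float
    delta_delta_ct: float
    fold: float
    percent_reduction: float
    sem_fold: float | None
    sem_ddct: float | None
    replicate_folds: tuple[float, ...]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class TukeyPair:
    group_i: str
    group_j: str
    p_adj: float


@dataclass(frozen=True)
class GroupStats:
    anova: AnovaResult
    tukey: tuple[TukeyPair, ...]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a Ct table (columns group, sample, gene_role,
    replicate, ct; every (group, sample) needs >= 1 target and >= 1
    reference row; Ct in (0, 45])."""
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise TableError(f"Ct table missing columns: {sorted(missing)}")
    bad_roles = set(table["gene_role"]) - {"target", "reference"}
    if bad_roles:
        raise TableError(f"unknown gene_role values: {sorted(bad_roles)}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    if ct.isna().any() or (ct <= 0).any() or (ct > 45).any():
        raise TableError("every Ct must be a number in (0, 45]")
    for (group, sample), sub in table.groupby(["group", "sample"]):
        roles = set(sub["gene_role"])
        if "target" not in roles or "reference" not in roles:
            raise TableError(
                f"sample {sample!r} in group {group!r} lacks "
                f"{'target' if 'target' not in roles else 'reference'}-gene rows"
            )
    out = table.copy()
    out["ct"] = ct
    return out


def _sem(values: np.ndarray) -> float | None:
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def ddct_fold(
    table: pd.DataFrame,
    control_group: str,
    per_replicate_pairing: bool = False,
) -> list[FoldChangeResult]:
    """2^-ddCt fold change per group, against ``control_group``.

    Group-level dCt uses replicate-mean Ct per gene role (default); with
    ``per_replicate_pairing`` the replicate-i target Ct is paired with the
    replicate-i reference Ct and dCt is the mean of those differences.
    Replicate-level folds (for SEM and downstream ANOVA) are always
    computed replicate-wise against the control group's mean dCt.
    """
    table = validate_ct_table(table)
    groups = list(dict.fromkeys(table["group"]))
    if control_group not in groups:
        raise TableError(f"control group {control_group!r} not in table")

    def group_dct(g: str) -> tuple[float, np.ndarray]:
        sub = table[table["group"] == g]
        tgt = sub[sub["gene_role"] == "target"]
        ref = sub[sub["gene_role"] == "reference"]
        if per_replicate_pairing:
            merged = tgt.merge(
                ref, on=["group", "sample", "replicate"], suffixes=("_t", "_r")
            )
            if merged.empty:
                raise TableError(
                    f"group {g!r}: no replicate-paired target/reference rows"
                )
            per_rep = (merged["ct_t"] - merged["ct_r"]).to_numpy(float)
            return float(per_rep.mean()), per_rep
        dct = float(tgt["ct"].mean() - ref["ct"].mean())
        ref_mean = float(ref["ct"].mean())
        per_rep = tgt["ct"].to_numpy(float) - ref_mean
        return dct, per_rep

    control_dct, _ = group_dct(control_group)
    results = []
    for g in groups:
        dct, per_rep_dct = group_dct(g)
        ddct = dct - control_dct
        fold = 2.0 ** (-ddct)
        rep_ddct = per_rep_dct - control_dct
        rep_folds = 2.0 ** (-rep_ddct)
        results.append(
            FoldChangeResult(
                group=g,
                delta_ct=dct,
                delta_delta_ct=ddct,
                fold=fold,
                percent_reduction=(1.0 - fold) * 100.0,
                sem_fold=_sem(rep_folds),
                sem_ddct=_sem(rep_ddct),
                replicate_folds=tuple(float(x) for x in rep_folds),
            )
        )
    return results


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the standard sums of squares."""
    if len(groups) < 2:
        raise StatisticsError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise StatisticsError("every group needs at least 2 values")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = len(all_vals) - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            raise StatisticsError(
                "F undefined: zero variance both within and between groups"
            )
        return AnovaResult(f=math.inf, df_between=df_b, df_within=df_w, p=0.0)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f=float(f), df_between=df_b, df_within=df_w, p=p)


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
) -> tuple[TukeyPair, ...]:
    """Tukey HSD adjusted p per group pair (studentized-range based)."""
    if len(groups) < 2:
        raise StatisticsError("Tukey HSD needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise StatisticsError("every group needs at least 2 values")
    if names is None:
        names = [f"group{i}" for i in range(len(groups))]
    res = stats.tukey_hsd(*[np.asarray(g, dtype=float) for g in groups])
    pairs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pairs.append(
                TukeyPair(
                    group_i=str(names[i]),
                    group_j=str(names[j]),
                    p_adj=float(res.pvalue[i, j]),
                )
            )
    return tuple(pairs)


def group_stats(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
) -> GroupStats:
    return GroupStats(
        anova=one_way_anova(groups), tukey=tukey_hsd(groups, names)
    )


def validate_densitometry_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(DENSITOMETRY_COLUMNS) - set(table.columns)
    if missing:
        raise TableError(f"densitometry table missing columns: {sorted(missing)}")
    out = table.copy()
    for col in ("od_target", "od_loading"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
        if out[col].isna().any():
            raise TableError(f"non-numeric values in {col}")
    if (out["od_loading"] <= 0).any():
        raise TableError("od_loading must be positive")
    return out


def densitometry_ratio(
    table: pd.DataFrame, control_group: str
) -> tuple[pd.DataFrame, GroupStats | None]:
    """Loading-normalized band ratios per replicate, scaled to the control
    mean, with ANOVA/Tukey across groups.

    Returns the table with added ``ratio`` (od_target / od_loading) and
    ``normalized`` (ratio / control-group mean ratio) columns. Group
    statistics are None when any group has fewer than 2 replicates or
    fewer than 2 groups are present (the ratios are still reported).
    """
    table = validate_densitometry_table(table)
    groups = list(dict.fromkeys(table["group"]))
    if control_group not in groups:
        raise TableError(f"control group {control_group!r} not in table")
    out = table.copy()
    out["ratio"] = out["od_target"] / out["od_loading"]
    control_mean = out.loc[out["group"] == control_group, "ratio"].mean()
    out["normalized"] = out["ratio"] / control_mean
    per_group = [
        out.loc[out["group"] == g, "normalized"].to_numpy(float) for g in groups
    ]
    if len(per_group) < 2 or any(len(g) < 2 for g in per_group):
        return out, None
    try:
        return out, group_stats(per_group, groups)
    except StatisticsError:
        # degenerate (zero-variance) tables still report their ratios
        return out, None
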