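"""Differential expression across the six stage comparisons.

Fold changes are computed on FPKM stage means with a pseudocount. The
significance test is a count-based negative-binomial Wald test: per-feature
dispersion by method of moments pooled across the two groups, strengthened
by sharing information across features (each feature uses at least the
across-feature median dispersion), with the statistic referred to the
standard normal. It reproduces the thresholding logic of an NB-based DE
caller, not any particular tool's numbers. Benjamini-Hochberg q-values are
computed per comparison group.

Two DE grades are kept: ``is_de`` (|FC| >= 1.7, q < 0.05) for the DE lists,
and the stricter ``is_cerna_grade`` (|log2FC| >= 1, q < 0.05) used when
assembling ceRNA networks.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import COMPARISON_LABELS, COMPARISONS, ExpressionMatrix, comparison_label

_GROUPS = {comparison_label(a, b): (a, b) for a, b in COMPARISONS}


def resolve_group(group: str | tuple[str, str]) -> tuple[str, str, str]:
    """Return (label, numerator, denominator) for a comparison label or pair."""
    if isinstance(group, str):
        if group not in _GROUPS:
            raise KeyError(f"unknown comparison group {group!r}; expected one of {COMPARISON_LABELS}")
        num, den = _GROUPS[group]
        return group, num, den
    num, den = group
    return comparison_label(num, den), num, den


def fold_change(
    expr: ExpressionMatrix,
    group: str | tuple[str, str],
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-feature linear fold change and log2 fold change for one comparison.

    FC = (mean FPKM numerator + pseudocount) / (mean FPKM denominator +
    pseudocount).
    """
    _label, num, den = resolve_group(group)
    a = expr.fpkm[expr.samples_for_stage(num)].mean(axis=1)
    b = expr.fpkm[expr.samples_for_stage(den)].mean(axis=1)
    fc = (a + pseudocount) / (b + pseudocount)
    return pd.DataFrame({"fold_change": fc, "log2fc": np.log2(fc)})


def nb_test(
    counts: ExpressionMatrix | pd.DataFrame,
    group: str | tuple[str, str],
    design: Mapping[str, tuple[str, int]] | None = None,
    dispersion_floor: float = 1e-8,
    share_dispersion: bool = True,
) -> pd.Series:
    """Two-sided NB Wald p-values for one stage comparison.

    The variance of each group's log mean is approximated by
    ``(1/mean + dispersion) / n`` with a method-of-moments dispersion pooled
    across the two groups; with ``share_dispersion`` each feature's
    dispersion is floored at the across-feature median, which keeps the test
    calibrated with few replicates. Identical count vectors give p = 1.
    """
    if isinstance(counts, ExpressionMatrix):
        if counts.counts is None:
            raise ValueError("ExpressionMatrix has no counts table")
        table, design = counts.counts, counts.design
    else:
        if design is None:
            raise ValueError("design required when passing a bare counts table")
        table = counts
    arr = table.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")

    _label, num, den = resolve_group(group)
    cols_a = [s for s, (st, _r) in design.items() if st == num]
    cols_b = [s for s, (st, _r) in design.items() if st == den]
    x = table[cols_a].to_numpy(dtype=float)
    y = table[cols_b].to_numpy(dtype=float)

    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    den_d = mx**2 + my**2
    disp = np.maximum(
        ((vx - mx) + (vy - my)) / np.where(den_d > 0, den_d, np.inf), dispersion_floor
    )
    if share_dispersion and len(disp) > 1:
        disp = np.maximum(disp, float(np.median(disp)))

    pc = 0.5  # guards log and 1/mean at zero counts
    se2 = ((1.0 / np.maximum(mx, pc) + disp) + (1.0 / np.maximum(my, pc) + disp)) / x.shape[1]
    z = (np.log(mx + pc) - np.log(my + pc)) / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.Series(np.clip(p, 0.0, 1.0), index=table.index, name="p")


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input."""
    arr = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame,
    fc_threshold: float = 1.7,
    q_threshold: float = 0.05,
    cerna_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Attach the two DE flags to a results table with fold_change and q.

    ``is_de``: fold change >= threshold or <= 1/threshold (direction-
    symmetric, boundary inclusive) and q strictly below ``q_threshold``.
    ``is_cerna_grade``: |log2FC| >= ``cerna_log2fc`` and the same q rule.
    If ``fc_threshold`` is None only the q rule applies (as used for miRNAs).
    """
    out = results.copy()
    sig = out["q"] < q_threshold
    if fc_threshold is None:
        out["is_de"] = sig
    else:
        fc = out["fold_change"]
        out["is_de"] = ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)) & sig
    out["is_cerna_grade"] = (out["log2fc"].abs() >= cerna_log2fc) & sig
    return out


def de_table(
    expr: ExpressionMatrix,
    group: str | tuple[str, str],
    pseudocount: float = 0.01,
    fc_threshold: float | None = 1.7,
    q_threshold: float = 0.05,
    cerna_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Full DE results for one comparison: FC, p, BH q and both flags."""
    label, _num, _den = resolve_group(group)
    res = fold_change(expr, group, pseudocount=pseudocount)
    res["p"] = nb_test(expr, group)
    res["q"] = bh_adjust(res["p"].to_numpy())
    res = call_de(res, fc_threshold=fc_threshold, q_threshold=q_threshold,
                  cerna_log2fc=cerna_log2fc)
    res.insert(0, "group", label)
    res.index.name = "feature_id"
    return res


def run_all_comparisons(expr: ExpressionMatrix, **kwargs) -> pd.DataFrame:
    """Concatenated :func:`de_table` over the six comparison groups."""
    return pd.concat([de_table(expr, label, **kwargs) for label in COMPARISON_LABELS])


def venn_membership(
    de_sets: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, dict[frozenset[str], int]]:
    """Membership table and non-empty Venn region counts over the six groups.

    Returns a boolean feature x group table and a mapping from each
    non-empty region (the exact set of groups a feature belongs to) to its
    feature count.
    """
    unknown = [g for g in de_sets if g not in COMPARISON_LABELS]
    if unknown:
        raise KeyError(f"unknown comparison groups {unknown}; expected {COMPARISON_LABELS}")
    missing = [g for g in COMPARISON_LABELS if g not in de_sets]
    if missing:
        raise KeyError(f"missing comparison groups {missing}")
    sets = {g: set(de_sets[g]) for g in COMPARISON_LABELS}
    features = sorted(set().union(*sets.values()))
    table = pd.DataFrame(
        {g: [f in sets[g] for f in features] for g in COMPARISON_LABELS},
        index=pd.Index(features, name="feature_id"),
    )
    regions: dict[frozenset[str], int] = {}
    for f in features:
        key = frozenset(g for g in COMPARISON_LABELS if f in sets[g])
        regions[key] = regions.get(key, 0) + 1
    return table, regions
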