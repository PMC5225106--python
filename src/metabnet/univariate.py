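"""Per-feature two-group statistics with a signed fold-change convention.

A ratio r of group means is reported as the signed fold change f = r
when r >= 1 and f = -1/r when r < 1, so |f| >= 1 always and the sign
gives the direction; its log2 form L = sign(f) * log2|f| = log2 r.
Features are screened by a Student t-test with Benjamini-Hochberg FDR,
and "discriminating" features are those with VIP > 1 from a PLS-DA
model and t-test p < 0.05 (both thresholds strict).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import NormalizedTable

logger = logging.getLogger(__name__)

__all__ = [
    "signed_fold_change",
    "fold_to_log2",
    "log2_to_fold",
    "two_group_test",
    "bh_fdr",
    "select_discriminant",
    "differential_table",
]


def signed_fold_change(mean_a: float, mean_b: float) -> tuple[float, float]:
    """Signed fold change f and its log2 form L for two positive means.

    r = mean_a/mean_b; f = r if r >= 1 else -1/r; L = log2 r.  The
    round trip f -> L -> f is the identity for all |f| >= 1.
    """
    if not mean_a > 0:
        raise ValueError(f"group A mean must be strictly positive, got {mean_a}")
    if not mean_b > 0:
        raise ValueError(f"group B mean must be strictly positive, got {mean_b}")
    r = mean_a / mean_b
    f = r if r >= 1.0 else -1.0 / r
    return f, float(np.log2(r))


def fold_to_log2(f: float) -> float:
    """log2 form of a signed fold change: L = sign(f) * log2|f|."""
    if abs(f) < 1.0:
        raise ValueError(f"signed fold change must satisfy |f| >= 1, got {f}")
    return float(np.sign(f) * np.log2(abs(f)))


def log2_to_fold(L: float) -> float:
    """Signed fold change from its log2 form; inverse of fold_to_log2."""
    r = 2.0**L
    return float(r if r >= 1.0 else -1.0 / r)


def two_group_test(
    values_a: Sequence[float], values_b: Sequence[float], variant: str = "student"
) -> tuple[float, float]:
    """Two-sample t-test; pooled-variance Student by default, Welch optional.

    A zero pooled variance with unequal means would give p = 0, which is
    forbidden; the smallest positive float is reported with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 finite values")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means; "
                      "reporting smallest positive p", RuntimeWarning)
        return float(np.sign(a.mean() - b.mean()) * np.inf), float(np.nextafter(0, 1))
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p)


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_discriminant(
    table: pd.DataFrame, vip_threshold: float = 1.0, p_threshold: float = 0.05
) -> pd.Index:
    """Features with VIP strictly above 1 and p strictly below 0.05.

    ``table`` needs columns ``vip`` and ``p`` indexed by feature.
    """
    if table["vip"].isna().any():
        raise ValueError("VIP must be available for every feature")
    mask = (table["vip"] > vip_threshold) & (table["p"] < p_threshold)
    return table.index[mask]


def differential_table(
    table: NormalizedTable,
    compare: str,
    within: Sequence[str] = (),
    level_a: str | None = None,
    level_b: str | None = None,
    vip: pd.Series | None = None,
    variant: str = "student",
) -> pd.DataFrame:
    """Per-feature two-group statistics over a metadata-driven grid.

    ``compare`` names the metadata axis whose two levels are contrasted
    (A vs B gives fold = mean_A/mean_B signed); ``within`` lists axes
    whose level combinations each yield one comparison stratum, e.g.
    genotype contrasts within every (condition, timepoint) cell.  BH
    q-values are computed per stratum across features.  A VIP series
    (from a PLS-DA fit) adds the discriminant flag VIP > 1 and p < 0.05.
    """
    meta = table.metadata
    if compare not in meta.columns:
        raise ValueError(f"unknown metadata axis {compare!r}")
    levels = list(pd.unique(meta[compare].astype(str)))
    if level_a is None or level_b is None:
        if len(levels) != 2:
            raise ValueError(
                f"axis {compare!r} has {len(levels)} levels; pass level_a/level_b"
            )
        level_a, level_b = levels

    strata: list[tuple[tuple, pd.Index]]
    if within:
        strata = [(labels if isinstance(labels, tuple) else (labels,), idx)
                  for labels, idx in table.groups(*within)]
    else:
        strata = [((), meta.index)]

    rows = []
    for labels, idx in strata:
        sub_meta = meta.loc[idx]
        ia = idx[sub_meta[compare].astype(str) == level_a]
        ib = idx[sub_meta[compare].astype(str) == level_b]
        if len(ia) < 2 or len(ib) < 2:
            logger.warning("stratum %s skipped: fewer than 2 samples per group", labels)
            continue
        tag = "/".join(str(v) for v in labels) if labels else "all"
        comparison = f"{level_a}_vs_{level_b}" + (f"@{tag}" if labels else "")
        stats_rows = []
        for feat in table.features:
            va = table.values.loc[ia, feat].to_numpy()
            vb = table.values.loc[ib, feat].to_numpy()
            ma, mb = float(np.nanmean(va)), float(np.nanmean(vb))
            f, L = signed_fold_change(ma, mb)
            t, p = two_group_test(va, vb, variant=variant)
            stats_rows.append((feat, comparison, ma, mb, f, L, t, p))
        sub = pd.DataFrame(
            stats_rows,
            columns=["feature", "comparison", "mean_a", "mean_b",
                     "fold", "log2fc", "t", "p"],
        )
        sub["q"] = bh_fdr(sub["p"])
        rows.append(sub)
    if not rows:
        raise ValueError("no stratum had enough samples in both groups")
    out = pd.concat(rows, ignore_index=True)
    if vip is not None:
        out["vip"] = out["feature"].map(vip).to_numpy()
        out["selected"] = (out["vip"] > 1.0) & (out["p"] < 0.05)
    else:
        out["vip"] = np.nan
        out["selected"] = False
    return out
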