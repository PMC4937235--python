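"""Step 1 — per-probe two-group differential expression.

Classic array-era class comparison: per-probe two-sample t-tests on log2
intensities (pooled variance by default, Welch optional), with selection
gated jointly on fold change (>2 by default), raw p-value (<0.001) and a
presence filter (probe measured in >=80% of the contrast's samples).  No
multiple-testing correction is applied at this step by design — the raw
p-gate plus the fold-change gate is the screening rule; FDR control
enters later, at count-based validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DiffExpThresholds:
    """Selection gates for step-1 differential expression."""

    fc_min: float = 2.0
    p_max: float = 0.001
    present_frac_min: float = 0.80

    def validate(self) -> None:
        if not self.fc_min > 1:
            raise ValueError(f"fc_min must be > 1, got {self.fc_min}")
        if not 0 < self.p_max < 1:
            raise ValueError(f"p_max must be in (0, 1), got {self.p_max}")
        if not 0 < self.present_frac_min <= 1:
            raise ValueError(f"present_frac_min must be in (0, 1], got {self.present_frac_min}")


def two_group_ttest(
    matrix: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    variance_mode: Literal["pooled", "welch"] = "pooled",
    probe_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-probe two-sample t-test of group A versus group B.

    Parameters
    ----------
    matrix : DataFrame, probes x samples, log2 scale
    group_a, group_b : sample-id collections; must be disjoint and present
        in the matrix.
    variance_mode : "pooled" (classic equal-variance t) or "welch".
    probe_map : optional probe -> gene map; adds a gene_symbol column.

    Returns
    -------
    DataFrame indexed by probe with columns gene_symbol (optional),
    mean_a, mean_b, log2fc (= mean_a - mean_b), fold_change (signed,
    magnitude >= 1), t_stat, p_value, n_a, n_b, present_frac, testable.
    Probes with fewer than two usable samples in either group are flagged
    ``testable=False`` (t/p = NaN) rather than dropped.  Degenerate
    zero-variance probes get the limiting values (t=0, p=1 for equal
    means; p=0 otherwise).
    """
    group_a = list(group_a)
    group_b = list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if variance_mode not in ("pooled", "welch"):
        raise ValueError(f"variance_mode must be 'pooled' or 'welch', got {variance_mode!r}")
    missing = [s for s in [*group_a, *group_b] if s not in matrix.columns]
    if missing:
        raise ValueError(f"samples not in matrix: {missing[:5]}")

    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    present_frac = (n_a + n_b) / (a.shape[1] + b.shape[1])
    testable = (n_a >= 2) & (n_b >= 2)

    mean_a = np.full(len(matrix), np.nan)
    mean_b = np.full(len(matrix), np.nan)
    with np.errstate(invalid="ignore"):
        mean_a[n_a > 0] = np.nanmean(a[n_a > 0], axis=1)
        mean_b[n_b > 0] = np.nanmean(b[n_b > 0], axis=1)

    t_stat = np.full(len(matrix), np.nan)
    p_value = np.full(len(matrix), np.nan)
    if testable.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(
                a[testable],
                b[testable],
                axis=1,
                equal_var=(variance_mode == "pooled"),
                nan_policy="omit",
            )
        t_sub = np.asarray(res.statistic, dtype=float)
        p_sub = np.asarray(res.pvalue, dtype=float)
        # zero-variance limits: equal means -> t=0, p=1; unequal -> p=0
        var_a = np.nanvar(a[testable], axis=1, ddof=1)
        var_b = np.nanvar(b[testable], axis=1, ddof=1)
        diff = mean_a[testable] - mean_b[testable]
        degenerate = (var_a == 0) & (var_b == 0)
        t_sub[degenerate & (diff == 0)] = 0.0
        p_sub[degenerate & (diff == 0)] = 1.0
        t_sub[degenerate & (diff != 0)] = np.sign(diff[degenerate & (diff != 0)]) * np.inf
        p_sub[degenerate & (diff != 0)] = 0.0
        t_stat[testable] = t_sub
        p_value[testable] = p_sub

    log2fc = mean_a - mean_b
    with np.errstate(invalid="ignore"):
        fold_change = np.where(log2fc >= 0, 2.0 ** log2fc, -(2.0 ** (-log2fc)))
    fold_change = np.where(np.isnan(log2fc), np.nan, fold_change)

    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "fold_change": fold_change,
            "t_stat": t_stat,
            "p_value": p_value,
            "n_a": n_a,
            "n_b": n_b,
            "present_frac": present_frac,
            "testable": testable,
        },
        index=matrix.index,
    )
    if probe_map is not None:
        out.insert(0, "gene_symbol", probe_map.reindex(out.index))
    return out


def select_de(
    records: pd.DataFrame, thresholds: DiffExpThresholds | None = None
) -> tuple[set[str], set[str]]:
    """Apply the fold-change / p-value / presence gates.

    Returns disjoint (up, down) probe-id sets: up requires
    ``log2fc > log2(fc_min)``, down ``log2fc < -log2(fc_min)``; both
    require ``p <= p_max``, ``present_frac >= present_frac_min`` and
    testability.
    """
    thresholds = thresholds or DiffExpThresholds()
    thresholds.validate()
    lfc = np.log2(thresholds.fc_min)
    ok = (
        records["testable"]
        & (records["p_value"] <= thresholds.p_max)
        & (records["present_frac"] >= thresholds.present_frac_min)
    )
    up = set(records.index[ok & (records["log2fc"] > lfc)])
    down = set(records.index[ok & (records["log2fc"] < -lfc)])
    return up, down
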