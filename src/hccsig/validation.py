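"""Count-based validation of a signature on a paired tumor/normal cohort.

The array-derived signature is checked on an independent sequencing
cohort: counts are log-transformed and full-quantile normalized across
libraries, each gene gets a paired test of within-patient tumor-minus-
normal differences, p-values are Benjamini–Hochberg adjusted, and a gene
is *confirmed* when its q-value clears the FDR gate with the same
direction as on the array.  Cross-platform agreement is summarized by
the squared Pearson correlation (and regression slope) between array and
sequencing log2 fold changes.

The paired test is a one-sample t-test on per-patient log-ratio
differences — a deliberate, clearly-labelled methodological simplification
of a negative-binomial GLM: it preserves the paired structure and the
FDR gate while staying fully transparent (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import log2_transform, quantile_normalize


def filter_low_counts(counts: pd.DataFrame, min_mean: float = 5.0) -> pd.DataFrame:
    """Keep genes with mean count >= min_mean across libraries."""
    return counts.loc[counts.mean(axis=1) >= min_mean]


def normalize_counts_fullquantile(
    counts: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count + pseudocount) followed by full-quantile normalization."""
    if pseudocount <= 0 and (counts.to_numpy() == 0).any():
        raise ValueError(
            "normalize_counts_fullquantile: pseudocount must be > 0 when zero counts are present"
        )
    return quantile_normalize(log2_transform(counts.astype(float), pseudocount))


def paired_de(norm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene paired differential expression on normalized log2 values.

    For each gene, d_i = tumor_i - normal_i over patients; log2fc_seq is
    mean(d) and the p-value comes from a two-sided one-sample t-test of d
    against 0 (df = n_pairs - 1).  Zero-variance differences are handled
    as limits: p=1 for d == 0, p=0 (flagged ``degenerate``) for constant
    nonzero d.

    ``design`` maps patient_id -> (tumor_sample_id, normal_sample_id);
    both members of every pair must be columns of ``norm``.
    """
    if len(design) < 2:
        raise ValueError(f"paired_de: need >= 2 pairs, got {len(design)}")
    for col in ("tumor_sample_id", "normal_sample_id"):
        absent = [s for s in design[col] if s not in norm.columns]
        if absent:
            raise ValueError(f"paired_de: sample {absent[0]!r} not in matrix")
    tumor = norm[list(design["tumor_sample_id"])].to_numpy()
    normal = norm[list(design["normal_sample_id"])].to_numpy()
    d = tumor - normal
    mean_d = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    n = d.shape[1]

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_1samp(d, 0.0, axis=1)
    t_stat = np.asarray(res.statistic, dtype=float)
    p_value = np.asarray(res.pvalue, dtype=float)
    zero_var = sd == 0
    t_stat[zero_var & (mean_d == 0)] = 0.0
    p_value[zero_var & (mean_d == 0)] = 1.0
    t_stat[zero_var & (mean_d != 0)] = np.sign(mean_d[zero_var & (mean_d != 0)]) * np.inf
    p_value[zero_var & (mean_d != 0)] = 0.0

    return pd.DataFrame(
        {
            "log2fc_seq": mean_d,
            "t_stat": t_stat,
            "p_value": p_value,
            "n_pairs": n,
            "degenerate": zero_var & (mean_d != 0),
        },
        index=norm.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1, in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    if len(p) == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ConcordanceSummary:
    """Cross-platform agreement summary for one gene universe."""

    n_signature: int
    n_tested: int
    n_confirmed_up: int
    n_confirmed_down: int
    r_squared: float | None
    slope: float | None

    def to_dict(self) -> dict:
        return {
            "n_signature": self.n_signature,
            "n_tested": self.n_tested,
            "n_confirmed_up": self.n_confirmed_up,
            "n_confirmed_down": self.n_confirmed_down,
            "r_squared": self.r_squared,
            "slope": self.slope,
        }


def concordance(
    records: pd.DataFrame, signature: Iterable[str], fdr_max: float = 0.05
) -> ConcordanceSummary:
    """Confirmation counts and fold-change concordance over a gene set.

    ``records`` must carry log2fc_seq, q_value and log2fc_array.  A gene
    is confirmed when q < fdr_max and the two platforms agree in sign;
    counts are split by array direction.  r_squared is the squared
    Pearson correlation between the two log2FC vectors over signature
    genes with both values (requires >= 3 such genes; otherwise the
    regression fields are None, counts are still reported).
    """
    signature = set(signature)
    sub = records.loc[records.index.isin(signature)].dropna(
        subset=["log2fc_seq", "log2fc_array", "q_value"]
    )
    confirmed = (sub["q_value"] < fdr_max) & (
        np.sign(sub["log2fc_seq"]) == np.sign(sub["log2fc_array"])
    )
    n_up = int((confirmed & (sub["log2fc_array"] > 0)).sum())
    n_down = int((confirmed & (sub["log2fc_array"] < 0)).sum())
    if len(sub) >= 3 and sub["log2fc_array"].nunique() > 1:
        fit = stats.linregress(sub["log2fc_array"], sub["log2fc_seq"])
        r_squared: float | None = float(fit.rvalue**2)
        slope: float | None = float(fit.slope)
    else:
        r_squared = slope = None
    return ConcordanceSummary(
        n_signature=len(signature),
        n_tested=len(sub),
        n_confirmed_up=n_up,
        n_confirmed_down=n_down,
        r_squared=r_squared,
        slope=slope,
    )


def validate_signature(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    array_log2fc: pd.Series,
    signature: Iterable[str],
    fdr_max: float = 0.05,
    min_mean_count: float = 5.0,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, ConcordanceSummary]:
    """Full count-based validation of an array-derived signature.

    Filters low-count genes, normalizes, runs the paired test, adjusts
    with BH, merges the array log2FCs and summarizes concordance over
    ``signature``.  Returns (records, summary); records carry
    log2fc_seq, p_value, q_value, log2fc_array and confirmed.
    """
    filtered = filter_low_counts(counts, min_mean_count)
    norm = normalize_counts_fullquantile(filtered, pseudocount)
    records = paired_de(norm, design)
    records["q_value"] = bh_adjust(records["p_value"].to_numpy())
    records["log2fc_array"] = array_log2fc.reindex(records.index)
    records["confirmed"] = (
        (records["q_value"] < fdr_max)
        & (np.sign(records["log2fc_seq"]) == np.sign(records["log2fc_array"]))
        & records["log2fc_array"].notna()
    )
    summary = concordance(records, signature, fdr_max)
    return records, summary
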