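"""Model-style interfaces: build a screen from data, ``fit()``, inspect results.

`SignatureScreen` wraps the two-step strategy (class comparison, then
multi-tissue screening) the way statistical modelling packages wrap an
estimator: the model holds the data and design, ``fit`` applies the
thresholds and returns a results object carrying the differential-
expression table, the tissue profile, the three signatures, the filter
funnel and a ``summary()``.  `PairedValidation` does the same for the
count-based confirmation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as hio
from .diffexp import DiffExpThresholds, select_de, two_group_ttest
from .preprocess import drop_missing_probes, quantile_normalize
from .signature import (
    SignatureSet,
    SignatureThresholds,
    TissueProfile,
    build_tissue_profile,
    classify_liver_specific,
    classify_tumor_associated,
    classify_tumor_specific,
    signature_overlap,
    tissue_elevated_fraction,
    tumor_up_fraction,
)
from .validation import ConcordanceSummary, validate_signature

CATEGORIES = ("liver_specific", "tumor_associated", "tumor_specific")


@dataclass
class SignatureScreenResults:
    """Fitted output of one analysis setting of the two-step screen."""

    setting: str
    de_table: pd.DataFrame
    up_probes: set[str]
    down_probes: set[str]
    profile: TissueProfile
    signature_set: SignatureSet
    funnel: dict[str, int]
    diff_thresholds: DiffExpThresholds
    sig_thresholds: SignatureThresholds
    probe_map: pd.Series

    @property
    def gene_log2fc(self) -> pd.Series:
        """Gene-level mean tumor log2FC versus the panel reference.

        Redundant probes of a gene are averaged.
        """
        per_probe = self.profile.tumor_mean_log2fc
        return per_probe.groupby(self.probe_map.reindex(per_probe.index)).mean()

    def to_frame(self) -> pd.DataFrame:
        """Per-gene signature table: category, fold change and rule fractions."""
        agg = pd.DataFrame(
            {
                "mean_log2fc": self.gene_log2fc,
                "tumor_frac": tumor_up_fraction(
                    self.profile, self.probe_map, self.sig_thresholds
                ),
                "tissue_frac": tissue_elevated_fraction(
                    self.profile, self.probe_map, self.sig_thresholds
                ),
            }
        )
        rows = []
        for category in CATEGORIES:
            for gene in sorted(self.signature_set.category(category)):
                rows.append(
                    {
                        "gene": gene,
                        "setting": self.setting,
                        "category": category,
                        "mean_log2fc": agg.loc[gene, "mean_log2fc"],
                        "tumor_frac": agg.loc[gene, "tumor_frac"],
                        "tissue_frac": agg.loc[gene, "tissue_frac"],
                    }
                )
        return pd.DataFrame(
            rows, columns=["gene", "setting", "category", "mean_log2fc", "tumor_frac", "tissue_frac"]
        )

    def summary(self) -> str:
        s = self.signature_set
        f = self.funnel
        lines = [
            f"Two-step signature screen — setting: {self.setting}",
            "=" * 56,
            "Step 1: tumor vs normal liver (per-probe t-test)",
            f"  probes in                     {f['n_probes']:>6d}",
            f"  dropped (missing values)      {f['n_dropped_missing']:>6d}",
            f"  untestable                    {f['n_untestable']:>6d}",
            f"  upregulated (FC>{self.diff_thresholds.fc_min:g}, "
            f"p<={self.diff_thresholds.p_max:g})  {f['n_up_probes']:>6d}",
            f"  downregulated                 {f['n_down_probes']:>6d}",
            f"  failing gates                 {f['n_fail']:>6d}",
            "Step 2: multi-tissue screening",
            f"  unique genes in up set        {f['n_up_genes']:>6d}",
            f"  liver_specific genes          {len(s.liver_specific):>6d}",
            f"  tumor_associated genes        {len(s.tumor_associated):>6d}",
            f"  tumor_specific genes          {len(s.tumor_specific):>6d}",
            "Thresholds: "
            f"log2FC>{self.sig_thresholds.log2fc_up:g} in >{self.sig_thresholds.tumor_frac_min:.0%} "
            f"of tumors; elevated in <{self.sig_thresholds.tissue_frac_max:.0%} of tissue types "
            f"(tissue log2FC>{self.sig_thresholds.tissue_log2fc_up:g})",
        ]
        return "\n".join(lines)


@dataclass
class StratifiedScreenResults:
    """Results of the pooled and per-etiology settings, plus set algebra."""

    results: dict[str, SignatureScreenResults]

    def overlap(self, category: str = "tumor_specific") -> pd.DataFrame:
        return signature_overlap(
            [r.signature_set for r in self.results.values()], category
        )

    def common_genes(self, category: str = "tumor_specific") -> set[str]:
        sets = [set(r.signature_set.category(category)) for r in self.results.values()]
        return set.intersection(*sets) if sets else set()

    def summary(self) -> str:
        parts = [r.summary() for r in self.results.values()]
        common = sorted(self.common_genes())
        parts.append(
            f"tumor_specific genes common to all {len(self.results)} settings: "
            f"{len(common)} ({', '.join(common) if common else '-'})"
        )
        return "\n\n".join(parts)


class SignatureScreen:
    """Two-step tumor-specific signature screen over an expression cohort.

    Parameters
    ----------
    expression : DataFrame, probes x samples, log2 scale.
    sample_sheet : DataFrame indexed by sample_id with group / etiology /
        tissue_type columns (see :func:`hccsig.io.read_sample_sheet`).
    probe_map : Series, probe_id -> gene symbol.
    normalized : set True if the matrix is already quantile-normalized;
        otherwise ``fit`` normalizes first (dropping probes with missing
        values).
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        probe_map: pd.Series,
        normalized: bool = False,
    ) -> None:
        absent = [s for s in expression.columns if s not in sample_sheet.index]
        if absent:
            raise ValueError(f"sample {absent[0]!r} missing from sample sheet")
        unmapped = [p for p in expression.index if p not in probe_map.index]
        if unmapped:
            raise ValueError(f"{len(unmapped)} probes unmapped (first: {unmapped[0]!r})")
        self.expression = expression
        self.sample_sheet = sample_sheet.loc[expression.columns]
        self.probe_map = probe_map
        self.normalized = normalized

    @classmethod
    def from_files(cls, expression_path, sample_sheet_path, probe_map_path,
                   normalized: bool = False) -> "SignatureScreen":
        matrix = hio.read_expression(expression_path)
        sheet = hio.read_sample_sheet(sample_sheet_path, matrix)
        pm = hio.read_probe_map(probe_map_path, matrix)
        return cls(matrix, sheet, pm, normalized=normalized)

    def _tumor_ids(self, etiology: str | None) -> list[str]:
        sheet = self.sample_sheet
        mask = sheet["group"] == "tumor"
        if etiology is not None:
            mask &= sheet["etiology"] == etiology
        ids = list(sheet.index[mask])
        if not ids:
            raise ValueError(f"no tumor samples for etiology {etiology!r}")
        return ids

    def fit(
        self,
        diff_thresholds: DiffExpThresholds | None = None,
        sig_thresholds: SignatureThresholds | None = None,
        etiology: str | None = None,
        setting: str | None = None,
        variance_mode: str = "pooled",
    ) -> SignatureScreenResults:
        """Run both steps for one analysis setting.

        ``etiology`` restricts the tumor group (e.g. "HBV"); the normal
        panels are always shared across settings.
        """
        diff_thresholds = diff_thresholds or DiffExpThresholds()
        sig_thresholds = sig_thresholds or SignatureThresholds()
        diff_thresholds.validate()
        sig_thresholds.validate()
        setting = setting or (f"{etiology}-HCC" if etiology else "HCC")

        matrix = self.expression
        n_probes_in = len(matrix)
        if self.normalized:
            matrix, n_dropped = matrix, 0
        else:
            matrix, n_dropped = drop_missing_probes(matrix)
            matrix = quantile_normalize(matrix)

        tumor_ids = self._tumor_ids(etiology)
        liver_ids = list(self.sample_sheet.index[self.sample_sheet["group"] == "normal_liver"])
        de = two_group_ttest(matrix, tumor_ids, liver_ids, variance_mode, self.probe_map)
        up, down = select_de(de, diff_thresholds)

        profile = build_tissue_profile(matrix, self.sample_sheet, tumor_ids)
        liver = classify_liver_specific(profile, self.probe_map, thresholds=sig_thresholds)
        assoc = classify_tumor_associated(
            profile, up, self.probe_map, thresholds=sig_thresholds
        )
        specific = classify_tumor_specific(profile, assoc, self.probe_map, sig_thresholds)
        sig_set = SignatureSet(
            setting=setting,
            liver_specific=frozenset(liver),
            tumor_associated=frozenset(assoc),
            tumor_specific=frozenset(specific),
        )

        n_untestable = int((~de["testable"]).sum())
        funnel = {
            "n_probes": n_probes_in,
            "n_dropped_missing": n_dropped,
            "n_tested": len(de),
            "n_untestable": n_untestable,
            "n_up_probes": len(up),
            "n_down_probes": len(down),
            "n_fail": len(de) - n_untestable - len(up) - len(down),
            "n_up_genes": len(set(self.probe_map.reindex(sorted(up)).dropna())),
            "n_liver_specific": len(liver),
            "n_tumor_associated": len(assoc),
            "n_tumor_specific": len(specific),
        }
        return SignatureScreenResults(
            setting=setting,
            de_table=de,
            up_probes=up,
            down_probes=down,
            profile=profile,
            signature_set=sig_set,
            funnel=funnel,
            diff_thresholds=diff_thresholds,
            sig_thresholds=sig_thresholds,
            probe_map=self.probe_map,
        )

    def fit_stratified(
        self,
        diff_thresholds: DiffExpThresholds | None = None,
        sig_thresholds: SignatureThresholds | None = None,
        etiologies: tuple[str, ...] = ("HBV", "HCV"),
    ) -> StratifiedScreenResults:
        """Fit the pooled setting plus one setting per viral etiology."""
        results = {"HCC": self.fit(diff_thresholds, sig_thresholds)}
        for et in etiologies:
            results[f"{et}-HCC"] = self.fit(diff_thresholds, sig_thresholds, etiology=et)
        return StratifiedScreenResults(results=results)


@dataclass
class PairedValidationResults:
    """Fitted output of the count-based confirmation step."""

    records: pd.DataFrame
    concordance: ConcordanceSummary
    signature: frozenset[str]
    fdr_max: float

    def confirmed_genes(self) -> set[str]:
        sub = self.records.loc[self.records.index.isin(self.signature)]
        return set(sub.index[sub["confirmed"]])

    def summary(self) -> str:
        c = self.concordance
        r2 = "n/a" if c.r_squared is None else f"{c.r_squared:.4f}"
        slope = "n/a" if c.slope is None else f"{c.slope:.4f}"
        return "\n".join(
            [
                "Paired count-based validation",
                "=" * 40,
                f"  signature genes               {c.n_signature:>6d}",
                f"  tested (both platforms)       {c.n_tested:>6d}",
                f"  confirmed up (q<{self.fdr_max:g})        {c.n_confirmed_up:>6d}",
                f"  confirmed down                {c.n_confirmed_down:>6d}",
                f"  fold-change concordance R^2   {r2:>8s}",
                f"  regression slope              {slope:>8s}",
            ]
        )

    def plot_concordance(self, path=None, ax=None):
        """Scatter of array vs sequencing log2FC over signature genes."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        sub = self.records.loc[self.records.index.isin(self.signature)].dropna(
            subset=["log2fc_array", "log2fc_seq"]
        )
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(sub["log2fc_array"], sub["log2fc_seq"],
                   c=np.where(sub["confirmed"], "tab:red", "tab:gray"), s=18)
        lim = max(1.0, float(np.nanmax(np.abs(sub[["log2fc_array", "log2fc_seq"]].to_numpy()))))
        ax.plot([-lim, lim], [-lim, lim], lw=0.8, color="k", ls="--")
        ax.set_xlabel("array log2FC")
        ax.set_ylabel("RNA-seq log2FC")
        if self.concordance.r_squared is not None:
            ax.set_title(f"R² = {self.concordance.r_squared:.4f}")
        if path is not None:
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


class PairedValidation:
    """Count-based validation model over a paired tumor/normal cohort."""

    def __init__(self, counts: pd.DataFrame, design: pd.DataFrame) -> None:
        for col in ("tumor_sample_id", "normal_sample_id"):
            absent = [s for s in design[col] if s not in counts.columns]
            if absent:
                raise ValueError(f"design sample {absent[0]!r} not in count matrix")
        self.counts = counts
        self.design = design

    @classmethod
    def from_files(cls, counts_path, design_path) -> "PairedValidation":
        return cls(hio.read_counts(counts_path), hio.read_design(design_path))

    def fit(
        self,
        array_log2fc: pd.Series,
        signature,
        fdr_max: float = 0.05,
        min_mean_count: float = 5.0,
        pseudocount: float = 1.0,
    ) -> PairedValidationResults:
        records, summary = validate_signature(
            self.counts, self.design, array_log2fc, signature,
            fdr_max=fdr_max, min_mean_count=min_mean_count, pseudocount=pseudocount,
        )
        return PairedValidationResults(
            records=records,
            concordance=summary,
            signature=frozenset(signature),
            fdr_max=fdr_max,
        )
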