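"""Step 2 — multi-tissue screening and signature classification.

Genes surviving the tumor-vs-liver class comparison are profiled against
a panel of normal tissue types and partitioned into three signatures:

liver-specific
    elevated in both tumor and normal liver relative to the non-liver
    tissue panel — organ identity rather than tumor biology.
tumor-associated
    elevated in tumor relative to the averaged normal panel.
tumor-specific
    the tumor-associated subset upregulated (log2FC > 1) in more than 80%
    of individual tumor samples *and* elevated in fewer than 10% of
    normal tissue types — the candidate immunotherapy targets.

The elevated-in-a-tissue predicate is deliberately a single configurable
function (:func:`tissue_elevated_fraction`): a tissue type counts as
elevated when its gene-level log2FC, recentered on the across-tissue
median, exceeds ``tissue_log2fc_up`` (default 0.5, half the tumor
up-threshold).  Median recentering makes the call robust to the panel
reference being dragged by the very tissues under test; see
docs/methods.md for the rationale and alternatives.

Liver-specific and tumor-associated membership is computed per probe and
collapsed to unique gene symbols (a gene passes if any of its redundant
probes passes — mirroring how unique-gene counts shrink relative to
probe counts on arrays).  The tumor-specific sample/tissue fractions are
computed on gene-level profiles (redundant probes averaged) so the
boundary thresholds act on the least noisy estimate available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SignatureThresholds:
    """Rule thresholds for signature classification.

    log2fc_up : minimum log2 fold change to call a probe/sample/tissue
        upregulated (default 1, i.e. 2-fold).
    tumor_frac_min : a tumor-specific gene must be upregulated in strictly
        more than this fraction of tumor samples (default 0.80).
    tissue_frac_max : ... and elevated in strictly fewer than this
        fraction of normal tissue types (default 0.10).
    tissue_log2fc_up : log2FC above which a tissue type counts as
        elevated (default 0.5).
    majority_frac : fraction of tissue types a gene must exceed
        individually under the 'majority' tumor-associated variant
        (default 0.50; the default variant compares against the panel
        mean instead).
    """

    log2fc_up: float = 1.0
    tumor_frac_min: float = 0.80
    tissue_frac_max: float = 0.10
    tissue_log2fc_up: float = 0.5
    majority_frac: float = 0.50

    def validate(self) -> None:
        if not 0 < self.tumor_frac_min <= 1:
            raise ValueError(f"tumor_frac_min must be in (0, 1], got {self.tumor_frac_min}")
        if not 0 <= self.tissue_frac_max < 1:
            raise ValueError(f"tissue_frac_max must be in [0, 1), got {self.tissue_frac_max}")
        if not 0 < self.majority_frac <= 1:
            raise ValueError(f"majority_frac must be in (0, 1], got {self.majority_frac}")


@dataclass
class TissueProfile:
    """Per-probe fold-change profile against the normal panel.

    reference : per-probe mean over the reference samples (all non-tumor
        samples by default: tissue panel plus normal liver).
    panel_reference : per-probe mean over non-liver tissue samples only.
    tumor_log2fc : probe x tumor-sample log2FC versus ``reference``.
    tissue_log2fc : probe x tissue-type log2FC (tissue mean - reference).
    liver_log2fc : normal-liver mean minus ``panel_reference``.
    tumor_mean_log2fc : mean tumor log2FC versus ``reference``.
    tumor_mean_log2fc_vs_panel : mean tumor log2FC versus
        ``panel_reference`` (used by the liver-specific rule, whose
        reference must exclude liver to avoid being self-defeating).
    """

    reference: pd.Series
    panel_reference: pd.Series
    tumor_log2fc: pd.DataFrame
    tissue_log2fc: pd.DataFrame
    liver_log2fc: pd.Series
    tumor_mean_log2fc: pd.Series
    tumor_mean_log2fc_vs_panel: pd.Series
    tissue_types: list[str] = field(default_factory=list)

    @property
    def probes(self) -> pd.Index:
        return self.reference.index


def build_tissue_profile(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    tumor_ids: Sequence[str] | None = None,
    include_liver_in_reference: bool = True,
) -> TissueProfile:
    """Profile every probe against the normal-tissue panel.

    The reference is the per-probe mean over all non-tumor samples
    (tissue panel plus normal liver; set ``include_liver_in_reference``
    False to exclude liver).  Requires at least two tissue types and at
    least one sample per annotated tissue type.
    """
    sheet = sheet.loc[matrix.columns]
    groups = sheet["group"]
    tumor_ids = list(tumor_ids) if tumor_ids is not None else list(sheet.index[groups == "tumor"])
    liver_ids = list(sheet.index[groups == "normal_liver"])
    tissue_ids = list(sheet.index[groups == "normal_tissue"])
    if not tumor_ids:
        raise ValueError("build_tissue_profile: no tumor samples")
    if not liver_ids:
        raise ValueError("build_tissue_profile: no normal_liver samples")

    tissue_of = sheet.loc[tissue_ids, "tissue_type"]
    tissue_types = sorted(tissue_of.unique())
    if len(tissue_types) < 2:
        raise ValueError(f"build_tissue_profile: need >= 2 tissue types, got {len(tissue_types)}")
    empty = [t for t in tissue_types if (tissue_of == t).sum() == 0]
    if empty:
        raise ValueError(f"build_tissue_profile: tissue type without samples: {empty[0]!r}")

    ref_ids = tissue_ids + (liver_ids if include_liver_in_reference else [])
    reference = matrix[ref_ids].mean(axis=1)
    panel_reference = matrix[tissue_ids].mean(axis=1)

    tumor_log2fc = matrix[tumor_ids].sub(reference, axis=0)
    tissue_means = {
        t: matrix[list(tissue_of.index[tissue_of == t])].mean(axis=1) for t in tissue_types
    }
    tissue_log2fc = pd.DataFrame(tissue_means).sub(reference, axis=0)
    liver_log2fc = matrix[liver_ids].mean(axis=1) - panel_reference

    return TissueProfile(
        reference=reference,
        panel_reference=panel_reference,
        tumor_log2fc=tumor_log2fc,
        tissue_log2fc=tissue_log2fc,
        liver_log2fc=liver_log2fc,
        tumor_mean_log2fc=tumor_log2fc.mean(axis=1),
        tumor_mean_log2fc_vs_panel=matrix[tumor_ids].mean(axis=1) - panel_reference,
        tissue_types=tissue_types,
    )


def collapse_to_genes(
    probe_set: Iterable[str],
    probe_map: pd.Series,
    mode: Literal["any", "all"] = "any",
) -> set[str]:
    """Collapse a probe set to unique gene symbols.

    mode="any" (default): a gene is included if at least one of its
    probes is in the set.  mode="all": every probe of the gene must be in
    the set.  Unmapped probes raise :class:`KeyError` listing them.
    """
    probe_set = set(probe_set)
    unmapped = sorted(p for p in probe_set if p not in probe_map.index)
    if unmapped:
        raise KeyError(f"collapse_to_genes: unmapped probes {unmapped[:10]}")
    if mode == "any":
        return set(probe_map.loc[sorted(probe_set)])
    if mode == "all":
        by_gene = probe_map.groupby(probe_map).groups
        return {g for g, probes in by_gene.items() if set(probes) <= probe_set}
    raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")


def _liver_specific_mask(profile: TissueProfile, thresholds: SignatureThresholds) -> pd.Series:
    return (profile.tumor_mean_log2fc_vs_panel > thresholds.log2fc_up) & (
        profile.liver_log2fc > thresholds.log2fc_up
    )


def classify_liver_specific(
    profile: TissueProfile,
    probe_map: pd.Series,
    candidate_probes: Iterable[str] | None = None,
    thresholds: SignatureThresholds | None = None,
) -> set[str]:
    """Genes elevated in both tumor and normal liver versus the non-liver panel.

    Evaluated over the full probe universe by default (liver-specific
    genes need not differ between tumor and liver, so the step-1 contrast
    cannot be a prerequisite); pass ``candidate_probes`` to restrict.
    """
    thresholds = thresholds or SignatureThresholds()
    thresholds.validate()
    mask = _liver_specific_mask(profile, thresholds)
    probes = set(profile.probes[mask])
    if candidate_probes is not None:
        probes &= set(candidate_probes)
    return collapse_to_genes(probes, probe_map)


def classify_tumor_associated(
    profile: TissueProfile,
    up_probes: Iterable[str],
    probe_map: pd.Series,
    thresholds: SignatureThresholds | None = None,
    mode: Literal["mean", "majority"] = "mean",
    exclude_liver_specific: bool = True,
) -> set[str]:
    """Genes from the step-1 up set elevated over the normal panel.

    mode="mean": mean tumor log2FC versus the panel reference must exceed
    ``log2fc_up``.  mode="majority": the tumor mean must exceed
    ``log2fc_up`` against more than ``majority_frac`` of tissue types
    individually.  Genes meeting the liver-specific rule are excluded by
    default, keeping the two signatures disjoint.
    """
    thresholds = thresholds or SignatureThresholds()
    thresholds.validate()
    up_probes = set(up_probes)
    in_up = profile.probes.isin(up_probes)
    if mode == "mean":
        mask = profile.tumor_mean_log2fc > thresholds.log2fc_up
    elif mode == "majority":
        tumor_mean = profile.tumor_mean_log2fc + profile.reference
        over = tumor_mean.to_numpy()[:, None] - (
            profile.tissue_log2fc.to_numpy() + profile.reference.to_numpy()[:, None]
        )
        frac = (over > thresholds.log2fc_up).mean(axis=1)
        mask = pd.Series(frac > thresholds.majority_frac, index=profile.probes)
    else:
        raise ValueError(f"mode must be 'mean' or 'majority', got {mode!r}")
    probes = set(profile.probes[mask & in_up])
    genes = collapse_to_genes(probes, probe_map)
    if exclude_liver_specific:
        genes -= collapse_to_genes(
            set(profile.probes[_liver_specific_mask(profile, thresholds)]), probe_map
        )
    return genes


def gene_tumor_log2fc(profile: TissueProfile, probe_map: pd.Series) -> pd.DataFrame:
    """Gene x tumor-sample log2FC, averaging each gene's redundant probes."""
    genes = probe_map.reindex(profile.probes)
    return profile.tumor_log2fc.groupby(genes.to_numpy()).mean()


def gene_tissue_log2fc(profile: TissueProfile, probe_map: pd.Series) -> pd.DataFrame:
    """Gene x tissue-type log2FC, averaging each gene's redundant probes."""
    genes = probe_map.reindex(profile.probes)
    return profile.tissue_log2fc.groupby(genes.to_numpy()).mean()


def tissue_elevated_fraction(
    profile: TissueProfile,
    probe_map: pd.Series,
    thresholds: SignatureThresholds | None = None,
    recenter: bool = True,
) -> pd.Series:
    """Fraction of normal tissue types in which each gene is elevated.

    The single configurable specificity predicate of the tumor-specific
    rule.  Tissue type *t* counts as elevated for a gene when its
    gene-level log2FC exceeds ``tissue_log2fc_up`` after subtracting the
    gene's median across tissue types (``recenter=True``, the default).
    Recentering keeps the call honest when a minority of elevated
    tissues drags the shared panel reference upward; with
    ``recenter=False`` the raw log2FC versus the reference is
    thresholded.
    """
    thresholds = thresholds or SignatureThresholds()
    fc = gene_tissue_log2fc(profile, probe_map)
    if recenter:
        fc = fc.sub(fc.median(axis=1), axis=0)
    return (fc > thresholds.tissue_log2fc_up).mean(axis=1)


def tumor_up_fraction(
    profile: TissueProfile,
    probe_map: pd.Series,
    thresholds: SignatureThresholds | None = None,
) -> pd.Series:
    """Fraction of tumor samples in which each gene is upregulated (> log2fc_up)."""
    thresholds = thresholds or SignatureThresholds()
    return (gene_tumor_log2fc(profile, probe_map) > thresholds.log2fc_up).mean(axis=1)


def classify_tumor_specific(
    profile: TissueProfile,
    tumor_associated: Iterable[str],
    probe_map: pd.Series,
    thresholds: SignatureThresholds | None = None,
) -> set[str]:
    """Tumor-associated genes that are strictly tumor-restricted.

    A gene is retained iff, on its gene-level profile (redundant probes
    averaged), it is (a) upregulated (log2FC > ``log2fc_up``) in strictly
    more than ``tumor_frac_min`` of tumor samples and (b) elevated in
    strictly fewer than ``tissue_frac_max`` of normal tissue types
    (:func:`tissue_elevated_fraction`).  Always a subset of
    ``tumor_associated``.
    """
    thresholds = thresholds or SignatureThresholds()
    thresholds.validate()
    tumor_associated = set(tumor_associated)
    tumor_frac = tumor_up_fraction(profile, probe_map, thresholds)
    tissue_frac = tissue_elevated_fraction(profile, probe_map, thresholds)
    passing = set(
        tumor_frac.index[
            (tumor_frac > thresholds.tumor_frac_min)
            & (tissue_frac < thresholds.tissue_frac_max)
        ]
    )
    return passing & tumor_associated


@dataclass(frozen=True)
class SignatureSet:
    """The three gene signatures produced by one analysis setting."""

    setting: str
    liver_specific: frozenset[str]
    tumor_associated: frozenset[str]
    tumor_specific: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tumor_specific <= self.tumor_associated:
            raise ValueError(
                f"SignatureSet({self.setting}): tumor_specific must be a subset of tumor_associated"
            )
        if self.liver_specific & self.tumor_associated:
            raise ValueError(
                f"SignatureSet({self.setting}): liver_specific and tumor_associated overlap"
            )

    def category(self, name: str) -> frozenset[str]:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown signature category {name!r}") from None


def venn_partition(sets: Mapping[str, Iterable[str]]) -> dict[tuple[bool, ...], list[str]]:
    """Partition the union of the input sets into all Venn cells.

    Keys are membership tuples aligned with the mapping's key order
    (all-False cell omitted — it is the complement of the union); values
    are sorted member lists.  Cells are disjoint and union to the union
    of the inputs.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("venn_partition needs >= 2 sets")
    as_sets = {k: set(v) for k, v in sets.items()}
    universe = set().union(*as_sets.values())
    cells: dict[tuple[bool, ...], list[str]] = {
        mask: [] for mask in product([False, True], repeat=len(names)) if any(mask)
    }
    for member in sorted(universe):
        mask = tuple(member in as_sets[n] for n in names)
        cells[mask].append(member)
    return cells


def signature_overlap(
    sets: Sequence[SignatureSet], category: str = "tumor_specific"
) -> pd.DataFrame:
    """Venn-partition one signature category across analysis settings.

    Returns a DataFrame with one row per Venn cell: a boolean membership
    column per setting, the cell size ``n``, and the comma-joined sorted
    ``members``.
    """
    if len(sets) < 2:
        raise ValueError("signature_overlap needs >= 2 signature sets")
    named = {s.setting: s.category(category) for s in sets}
    cells = venn_partition(named)
    rows = []
    for mask, members in cells.items():
        row = dict(zip(named.keys(), mask))
        row["n"] = len(members)
        row["members"] = ",".join(members)
        rows.append(row)
    return pd.DataFrame(rows)
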