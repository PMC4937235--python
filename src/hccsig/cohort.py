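"""Synthetic expression and count cohorts with planted signature genes.

The generator emulates the structure of a multi-series HCC meta-analysis
cohort — 55 tumors (13 HBV-, 42 HCV-associated), 14 normal livers and a
panel of 41 normal tissue types with 2 samples each — plus a paired
9-patient tumor/adjacent-normal count cohort for cross-platform
validation.  Genes are planted in one of four classes whose log2-scale
signal mirrors the categories the screening pipeline must recover:

``tumor_specific``
    elevated by ``delta`` in tumor samples only.
``tumor_associated``
    elevated by ``delta`` in tumors and by ``delta/4`` in a random 20% of
    normal tissue types (partial off-target expression, making the
    tumor_associated/tumor_specific boundary non-trivial).
``liver_specific``
    elevated by ``delta`` in tumors *and* normal liver (organ identity).
``down_in_tumor``
    reduced by ``delta`` in tumor samples.

All remaining genes are ``background``.  Signals are additive on the log2
scale so planted fold changes are exact in the zero-noise limit, and all
draws are taken from one :func:`numpy.random.default_rng` stream so a
(config, seed) pair reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL_LIVER = "normal_liver"
NORMAL_TISSUE = "normal_tissue"

PLANTED_CLASSES = ("tumor_specific", "tumor_associated", "liver_specific", "down_in_tumor")
BACKGROUND = "background"

#: Fraction of tissue types in which a planted tumor_associated gene is
#: partially elevated (by delta/4).  Kept above the default 10%
#: tissue-fraction gate so these genes exercise the tumor_specific boundary.
TUMOR_ASSOCIATED_TISSUE_FRAC = 0.20


def _default_planted() -> dict[str, int]:
    return {cls: 25 for cls in PLANTED_CLASSES}


@dataclass(frozen=True)
class CohortConfig:
    """Shape and signal parameters of a synthetic cohort.

    Defaults reproduce the study-scale design: 55 tumors split 13 HBV /
    42 HCV, 14 normal livers, 41 tissue types with 2 samples each, and a
    planted log2 effect of 3 (an 8-fold change) against noise_sd = 0.3.
    """

    n_tumor: int = 55
    n_hbv: int = 13
    n_hcv: int = 42
    n_normal_liver: int = 14
    n_tissue_types: int = 41
    samples_per_tissue: int = 2
    n_genes: int = 1000
    probes_per_gene_range: tuple[int, int] = (2, 4)
    n_planted_per_class: Mapping[str, int] = field(default_factory=_default_planted)
    delta: float = 3.0
    baseline_mu: float = 7.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ValueError` naming the first invalid field."""
        for name in ("n_tumor", "n_hbv", "n_hcv", "n_normal_liver",
                     "n_tissue_types", "samples_per_tissue", "n_genes"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"CohortConfig.{name} must be >= 1, got {getattr(self, name)}")
        if self.n_hbv + self.n_hcv != self.n_tumor:
            raise ValueError(
                f"CohortConfig.n_hbv + n_hcv must equal n_tumor "
                f"({self.n_hbv} + {self.n_hcv} != {self.n_tumor})"
            )
        lo, hi = self.probes_per_gene_range
        if lo < 1 or hi < lo:
            raise ValueError(
                f"CohortConfig.probes_per_gene_range must satisfy 1 <= min <= max, got {(lo, hi)}"
            )
        if self.delta <= 0:
            raise ValueError(f"CohortConfig.delta must be > 0, got {self.delta}")
        if self.noise_sd < 0:
            raise ValueError(f"CohortConfig.noise_sd must be >= 0, got {self.noise_sd}")
        if self.baseline_sd < 0:
            raise ValueError(f"CohortConfig.baseline_sd must be >= 0, got {self.baseline_sd}")
        unknown = set(self.n_planted_per_class) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"CohortConfig.n_planted_per_class has unknown classes {sorted(unknown)}")
        n_planted = sum(int(v) for v in self.n_planted_per_class.values())
        if any(int(v) < 0 for v in self.n_planted_per_class.values()):
            raise ValueError("CohortConfig.n_planted_per_class counts must be >= 0")
        if n_planted > self.n_genes:
            raise ValueError(
                f"CohortConfig.n_planted_per_class sums to {n_planted} > n_genes = {self.n_genes}"
            )


def _sample_sheet(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_tumor):
        etiology = "HBV" if i < config.n_hbv else "HCV"
        rows.append((f"tumor_{i + 1:02d}", TUMOR, etiology, ""))
    for i in range(config.n_normal_liver):
        rows.append((f"liver_{i + 1:02d}", NORMAL_LIVER, "NA", ""))
    for t in range(config.n_tissue_types):
        for r in range(config.samples_per_tissue):
            rows.append(
                (f"tissue{t + 1:02d}_{r + 1}", NORMAL_TISSUE, "NA", f"tissue_{t + 1:02d}")
            )
    sheet = pd.DataFrame(rows, columns=["sample_id", "group", "etiology", "tissue_type"])
    return sheet.set_index("sample_id")


def simulate_expression(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Simulate a probe-level log2 expression cohort with planted classes.

    Returns
    -------
    expression : DataFrame, probes x samples
        Log2 intensities.
    sample_sheet : DataFrame indexed by sample_id
        Columns ``group`` (tumor / normal_liver / normal_tissue),
        ``etiology`` (HBV / HCV / NA) and ``tissue_type``.
    probe_map : Series, probe_id -> gene symbol
        Many-to-one; every gene carries 1..k redundant probes.
    truth : Series, gene -> class
        Planted class per gene (``background`` for unplanted genes) — the
        oracle for recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sheet = _sample_sheet(config)
    samples = sheet.index.to_numpy()

    genes = np.array([f"G{i + 1:05d}" for i in range(config.n_genes)])
    # planted-class assignment: one shuffled draw, then contiguous slices
    shuffled = rng.permutation(genes)
    truth = pd.Series(BACKGROUND, index=genes, name="class")
    pos = 0
    for cls in PLANTED_CLASSES:
        k = int(config.n_planted_per_class.get(cls, 0))
        truth.loc[shuffled[pos:pos + k]] = cls
        pos += k

    lo, hi = config.probes_per_gene_range
    n_probes_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    probe_gene = np.repeat(genes, n_probes_per_gene)
    within = np.concatenate([np.arange(k) + 1 for k in n_probes_per_gene])
    probes = np.array([f"{g}_p{j}" for g, j in zip(probe_gene, within)])
    probe_map = pd.Series(probe_gene, index=probes, name="gene_symbol")
    probe_map.index.name = "probe_id"

    gene_offset = rng.normal(0.0, config.baseline_sd, size=config.n_genes)
    offset_by_gene = pd.Series(gene_offset, index=genes)

    base = config.baseline_mu + offset_by_gene.loc[probe_gene].to_numpy()
    values = base[:, None] + rng.normal(0.0, config.noise_sd, size=(len(probes), len(samples)))

    group = sheet["group"].to_numpy()
    is_tumor = group == TUMOR
    is_liver = group == NORMAL_LIVER
    tissue_of_sample = sheet["tissue_type"].to_numpy()
    tissue_types = [f"tissue_{t + 1:02d}" for t in range(config.n_tissue_types)]

    cls_by_probe = truth.loc[probe_gene].to_numpy()
    values[np.ix_(cls_by_probe == "tumor_specific", is_tumor)] += config.delta
    values[np.ix_(cls_by_probe == "tumor_associated", is_tumor)] += config.delta
    values[np.ix_(cls_by_probe == "liver_specific", is_tumor | is_liver)] += config.delta
    values[np.ix_(cls_by_probe == "down_in_tumor", is_tumor)] -= config.delta

    # partial off-target expression of tumor_associated genes: delta/4 in a
    # random fixed-size subset (20%) of tissue types, drawn per gene
    n_elev = int(np.floor(TUMOR_ASSOCIATED_TISSUE_FRAC * config.n_tissue_types))
    ta_genes = truth.index[truth == "tumor_associated"]
    for g in ta_genes:
        chosen = rng.choice(tissue_types, size=n_elev, replace=False)
        col_mask = np.isin(tissue_of_sample, chosen)
        row_mask = probe_gene == g
        values[np.ix_(row_mask, col_mask)] += config.delta / 4.0

    expr = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples)
    expr.columns.name = "sample_id"
    return expr, sheet, probe_map, truth


def simulate_counts(
    config: CohortConfig,
    truth: pd.Series,
    n_patients: int = 9,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a paired tumor/adjacent-normal count cohort.

    For each patient one tumor and one non-tumor library is drawn.  The
    natural-scale mean of gene *g* in library *l* is::

        mu = 2 ** (baseline_mu + gene_offset_g + effect_g(library)) * b_p * s_l

    where ``b_p`` is a log-normal per-patient baseline shared by the pair,
    ``s_l`` a log-normal per-library size factor, and ``effect_g`` the
    planted log2 signal of the gene's class in a tumor-vs-adjacent-liver
    contrast (+delta for tumor_specific / tumor_associated tumors, -delta
    for down_in_tumor tumors; liver_specific genes are elevated in both
    members of the pair and therefore null for the paired ratio).  Counts
    are negative binomial with ``variance = mu + dispersion * mu**2``;
    ``dispersion = 0`` gives the Poisson limit.

    Returns the gene x sample count matrix and the paired design
    (patient_id -> tumor/normal sample ids).
    """
    config.validate()
    if n_patients < 2:
        raise ValueError(f"n_patients must be >= 2 for a paired test, got {n_patients}")
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")

    rng = np.random.default_rng(seed)
    genes = truth.index.to_numpy()
    n_genes = len(genes)

    gene_offset = rng.normal(0.0, config.baseline_sd, size=n_genes)
    cls = truth.to_numpy()
    tumor_effect = np.zeros(n_genes)
    both_effect = np.zeros(n_genes)
    tumor_effect[np.isin(cls, ["tumor_specific", "tumor_associated"])] = config.delta
    tumor_effect[cls == "down_in_tumor"] = -config.delta
    both_effect[cls == "liver_specific"] = config.delta

    design_rows = []
    columns = {}
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        b_p = np.exp(rng.normal(0.0, 0.5))
        for kind, effect in (("T", tumor_effect + both_effect), ("N", both_effect)):
            s_l = np.exp(rng.normal(0.0, 0.25))
            mu = np.power(2.0, config.baseline_mu + gene_offset + effect) * b_p * s_l
            if dispersion == 0:
                counts = rng.poisson(mu)
            else:
                n_param = 1.0 / dispersion
                p_param = n_param / (n_param + mu)
                counts = rng.negative_binomial(n_param, p_param)
            columns[f"{pid}_{kind}"] = counts
        design_rows.append((pid, f"{pid}_T", f"{pid}_N"))

    count_matrix = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    count_matrix.columns.name = "sample_id"
    design = pd.DataFrame(
        design_rows, columns=["patient_id", "tumor_sample_id", "normal_sample_id"]
    ).set_index("patient_id")
    return count_matrix, design
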