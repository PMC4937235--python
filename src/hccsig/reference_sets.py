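"""Published tumor-specific signature gene lists for HCC.

Reference gene sets from a published two-step meta-analysis of
HBV/HCV-associated hepatocellular carcinoma — the tumor-specific
signatures reported for the pooled-HCC, HBV-HCC and HCV-HCC analysis
settings.  They serve as fixed inputs for set-arithmetic checks (signature
sizes, cross-etiology overlaps) and as a reference vocabulary when
comparing new runs against the published result.
"""

from __future__ import annotations

from .signature import venn_partition

HCC_SPECIFIC: tuple[str, ...] = (
    "ABL2", "ACSL4", "AKR1B10", "ATP6V1C1", "BUB3", "CASK", "CCT3",
    "CDKN2A", "EIF3H", "ENAH", "FAM122B", "FLVCR1", "GBAP1", "GPC3",
    "HKDC1", "HNRNPU", "ICK", "IGF2BP3", "IRS1", "LARS", "LOC344887",
    "LOC389834", "MIB1", "MRPL9", "MTR", "OTUD6B", "PHF20L1", "PRCC",
    "PRKDC", "PSMD4", "PSPH", "RAD21", "RBM12B", "ROBO1", "RRM2B",
    "SMARCC1", "SMYD2", "SMYD3", "SRXN1", "TCERG1", "TERF1", "TMEM106C",
    "TMEM68", "TSHZ2", "TTC13", "UBE2Q1", "UBR5", "UTP14A", "VASH2",
    "ZKSCAN3", "ZNF260", "ZNF623",
)

HBV_HCC_SPECIFIC: tuple[str, ...] = ("CDKN2A", "IGF2BP3", "ZNF623")

HCV_HCC_SPECIFIC: tuple[str, ...] = (
    "ABL2", "ACSL4", "AKR1B10", "CCT3", "CDKN2A", "EIF3H", "FLVCR1",
    "GBAP1", "GPC3", "HKDC1", "HNRNPU", "IGF2BP3", "LOC344887", "MRPL9",
    "MTR", "PRCC", "PRKDC", "PSPH", "RAD21", "SMYD3", "SQSTM1", "SRXN1",
    "TBC1D31", "TBCE", "TERF1", "TMEM106C", "TRIM31", "TXNRD1", "UBR5",
    "VASH2", "ZNF623",
)

SETTINGS: dict[str, tuple[str, ...]] = {
    "HCC": HCC_SPECIFIC,
    "HBV-HCC": HBV_HCC_SPECIFIC,
    "HCV-HCC": HCV_HCC_SPECIFIC,
}


def reference_overlap() -> dict[tuple[bool, ...], list[str]]:
    """Venn partition of the three published tumor-specific signatures.

    Cell keys follow the (HCC, HBV-HCC, HCV-HCC) setting order.
    """
    return venn_partition({k: set(v) for k, v in SETTINGS.items()})


def common_to_all_settings() -> set[str]:
    """Genes shared by all three published tumor-specific signatures."""
    return set(HCC_SPECIFIC) & set(HBV_HCC_SPECIFIC) & set(HCV_HCC_SPECIFIC)
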