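"""Tabular I/O for expression matrices, sample sheets, probe maps and counts.

All files are UTF-8 TSV with a header row; lines starting with ``#`` are
ignored.  Missing expression values are written as empty cells and read
back as NaN.  Round-tripping write -> read is the identity (floats are
written at full precision).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VALID_GROUPS = frozenset({"tumor", "normal_liver", "normal_tissue"})
VALID_ETIOLOGIES = frozenset({"HBV", "HCV", "NA"})


class ParseError(ValueError):
    """Raised for malformed tabular inputs."""


def _line_of(path, token: str) -> int | None:
    """1-based line number of the first data line starting with token."""
    try:
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if line.split("\t", 1)[0] == token:
                    return i
    except OSError:
        return None
    return None


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows etc.: pandas reports the line
        raise ParseError(f"{path}: {exc}") from exc
    return df


def read_expression(path) -> pd.DataFrame:
    """Read a probe x sample log2-intensity matrix.

    First column = probe id, header = sample ids.  Empty cells and "NA"
    become NaN.  Duplicate ids, ragged rows and non-numeric cells raise
    :class:`ParseError` identifying the offender.
    """
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected a probe-id column plus >=1 sample column")
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "probe_id"
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        line = _line_of(path, str(dup[0]))
        raise ParseError(f"{path}: duplicated probe id {dup[0]!r}"
                         + (f" (line {line})" if line else ""))
    if raw.columns.duplicated().any():
        bad = raw.columns[raw.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicated sample id {bad!r}")
    values = raw.replace({"": np.nan, "NA": np.nan, "nan": np.nan})
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad_mask = numeric.isna() & values.notna()
    if bad_mask.to_numpy().any():
        probe = bad_mask.index[bad_mask.any(axis=1)][0]
        col = bad_mask.columns[bad_mask.loc[probe]][0]
        line = _line_of(path, str(probe))
        raise ParseError(
            f"{path}: non-numeric value {values.loc[probe, col]!r} at probe {probe!r}, "
            f"sample {col!r}" + (f" (line {line})" if line else "")
        )
    numeric.columns.name = "sample_id"
    return numeric


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="", index_label="probe_id")


def read_sample_sheet(path, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate a sample sheet.

    Columns: sample_id, group, etiology, tissue_type.  Group values are
    case-folded (``Tumor`` -> ``tumor``); etiology is upper-cased with
    blank -> ``NA``.  When ``matrix`` is given, every matrix sample must
    appear exactly once.
    """
    sheet = _read_table(path)
    required = {"sample_id", "group", "etiology", "tissue_type"}
    missing = required - set(sheet.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet lacks columns {sorted(missing)}")
    sheet = sheet.set_index("sample_id")
    dup = sheet.index[sheet.index.duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated sample id {dup[0]!r}")
    sheet["group"] = sheet["group"].str.strip().str.lower()
    bad = sheet.index[~sheet["group"].isin(VALID_GROUPS)]
    if len(bad):
        raise ParseError(
            f"{path}: sample {bad[0]!r} has unknown group {sheet.loc[bad[0], 'group']!r} "
            f"(expected one of {sorted(VALID_GROUPS)})"
        )
    sheet["etiology"] = sheet["etiology"].str.strip().str.upper().replace({"": "NA"})
    bad = sheet.index[~sheet["etiology"].isin(VALID_ETIOLOGIES)]
    if len(bad):
        raise ParseError(f"{path}: sample {bad[0]!r} has unknown etiology")
    sheet["tissue_type"] = sheet["tissue_type"].str.strip()
    lacking = sheet.index[(sheet["group"] == "normal_tissue") & (sheet["tissue_type"] == "")]
    if len(lacking):
        raise ParseError(f"{path}: normal_tissue sample {lacking[0]!r} lacks tissue_type")
    if matrix is not None:
        absent = [s for s in matrix.columns if s not in sheet.index]
        if absent:
            raise ParseError(f"{path}: matrix sample {absent[0]!r} missing from sample sheet")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index_label="sample_id")


def read_probe_map(path, matrix: pd.DataFrame | None = None) -> pd.Series:
    """Read a probe_id -> gene_symbol map; symbols are upper-cased."""
    df = _read_table(path)
    if not {"probe_id", "gene_symbol"} <= set(df.columns):
        raise ParseError(f"{path}: probe map needs columns probe_id, gene_symbol")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated probe id {dup.iloc[0]!r}")
    pm = df.set_index("probe_id")["gene_symbol"].str.strip().str.upper()
    if (pm == "").any():
        bad = pm.index[pm == ""][0]
        raise ParseError(f"{path}: probe {bad!r} has empty gene symbol")
    if matrix is not None:
        unmapped = [p for p in matrix.index if p not in pm.index]
        if unmapped:
            raise ParseError(
                f"{path}: {len(unmapped)} matrix probes unmapped (first: {unmapped[0]!r})"
            )
    return pm


def write_probe_map(probe_map: pd.Series, path) -> None:
    probe_map.rename("gene_symbol").to_csv(path, sep="\t", index_label="probe_id")


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample matrix of non-negative integer counts."""
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected a gene-id column plus >=1 sample column")
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "gene_id"
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated gene id {dup[0]!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        raise ParseError(f"{path}: non-numeric count at gene {gene!r}")
    arr = numeric.to_numpy()
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        gene = numeric.index[((numeric < 0) | (numeric != numeric.round())).any(axis=1)][0]
        raise ParseError(f"{path}: counts must be non-negative integers (gene {gene!r})")
    out = numeric.astype(np.int64)
    out.columns.name = "sample_id"
    return out


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> pd.DataFrame:
    """Read a paired design: patient_id, tumor_sample_id, normal_sample_id."""
    df = _read_table(path)
    need = {"patient_id", "tumor_sample_id", "normal_sample_id"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: paired design needs columns {sorted(need)}")
    design = df.set_index("patient_id")[["tumor_sample_id", "normal_sample_id"]]
    ids = pd.concat([design["tumor_sample_id"], design["normal_sample_id"]])
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ParseError(f"{path}: sample {dup.iloc[0]!r} appears in more than one pair slot")
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="patient_id")


def write_truth(truth: pd.Series, path) -> None:
    truth.rename("class").to_csv(path, sep="\t", index_label="gene_id")


def read_truth(path) -> pd.Series:
    df = _read_table(path)
    if not {"gene_id", "class"} <= set(df.columns):
        raise ParseError(f"{path}: truth labels need columns gene_id, class")
    return df.set_index("gene_id")["class"]
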