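"""Table readers/writers for the pipeline's plain-text formats.

All output tables carry a ``#``-prefixed comment header recording the tool
version, config hash and seed, so any artifact can be traced back to the run
that produced it.
"""

from __future__ import annotations

import pandas as pd

from . import __version__

PHENOTYPE_COLUMNS = ["line_id", "trait", "condition", "replicate", "value"]
SAMPLE_SHEET_COLUMNS = ["sample_id", "role", "condition", "replicate"]
ROLES = {"maternal", "paternal", "hybrid"}


class SchemaError(ValueError):
    """An input file does not match the expected schema."""


def _header_lines(meta: dict | None) -> str:
    lines = [f"# heterosim {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, sep=",", meta: dict | None = None, index=True):
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep=sep, index=index)


def read_table(path, sep=",", index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


def read_phenotypes(path) -> pd.DataFrame:
    table = read_table(path, sep=",")
    missing = set(PHENOTYPE_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing phenotype columns {sorted(missing)}")
    if (table["value"] < 0).any():
        raise SchemaError(f"{path}: negative trait values")
    return table[PHENOTYPE_COLUMNS]


def read_counts(path) -> pd.DataFrame:
    counts = read_table(path, sep="\t", index_col=0)
    if counts.empty:
        raise SchemaError(f"{path}: empty count matrix")
    non_numeric = counts.columns[
        [not pd.api.types.is_numeric_dtype(counts[c]) for c in counts.columns]
    ]
    if len(non_numeric):
        raise SchemaError(f"{path}: non-numeric count columns {list(non_numeric)}")
    if (counts.to_numpy() < 0).any():
        raise SchemaError(f"{path}: negative counts")
    counts.index.name = "gene"
    return counts


def read_sample_sheet(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    sheet = read_table(path, sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise SchemaError(f"{path}: missing sample-sheet columns {sorted(missing)}")
    bad_roles = set(sheet["role"]) - ROLES
    if bad_roles:
        raise SchemaError(f"{path}: unknown roles {sorted(bad_roles)}")
    if counts is not None:
        uncovered = set(counts.columns) - set(sheet["sample_id"])
        if uncovered:
            raise SchemaError(
                f"{path}: sample sheet does not cover count columns {sorted(uncovered)}"
            )
    return sheet
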