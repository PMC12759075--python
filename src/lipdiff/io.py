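"""Readers and writers for the tabular formats the pipeline consumes.

Dialects
--------
Ion table (TSV): key columns ``protein_id, peptide, charge, mod_key,
start, end`` followed by one intensity column per sample.  Missing
intensities are encoded as empty cells; on read, zeros are also treated
as missing (an intensity of 0 carries no quantitative information).

Design table (TSV): ``sample_id, condition, treatment, replicate`` with
treatment in {LiP, trypsin_only}.

Annotation table (TSV): ``protein_id, gene, pI, n_domains, ecod_xgroups,
cofactors, mw_kda, oligomeric_state``; set-valued fields are
semicolon-delimited.

All writers emit a stable column order and a fixed float format so that
identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .differential import (
    ABUNDANCE_COLUMNS,
    CUTSITE_COLUMNS,
    StudyDesign,
    TREATMENT_CONTROL,
    TREATMENT_LIP,
)
from .peptide_map import ProteinSeq
from .structure_calls import CALL_COLUMNS

__all__ = [
    "ION_KEY_COLUMNS",
    "read_ion_table",
    "write_ion_table",
    "read_design",
    "write_design",
    "read_annotations",
    "write_annotations",
    "write_fasta",
    "read_cutsites",
    "write_cutsites",
    "read_calls",
    "write_calls",
    "write_abundance",
    "read_abundance",
    "split_set_field",
]

ION_KEY_COLUMNS = ["protein_id", "peptide", "charge", "mod_key", "start", "end"]

FLOAT_FORMAT = "%.10g"


class TableFormatError(ValueError):
    """Raised when a TSV does not match the documented dialect."""


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")


def read_ion_table(path) -> pd.DataFrame:
    """Read an ion quantification TSV; sample columns are everything after
    the six key columns.  Empty cells and zeros become NaN (missing)."""
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "peptide": str,
                                               "mod_key": str})
    _require_columns(frame, ION_KEY_COLUMNS, path)
    sample_cols = [c for c in frame.columns if c not in ION_KEY_COLUMNS]
    if not sample_cols:
        raise TableFormatError(f"{path}: ion table has no sample columns")
    for c in sample_cols:
        frame[c] = pd.to_numeric(frame[c], errors="raise").astype(float)
        frame.loc[frame[c] <= 0, c] = np.nan
    frame["start"] = frame["start"].astype(int)
    frame["end"] = frame["end"].astype(int)
    frame["charge"] = frame["charge"].astype(int)
    frame["ion_key"] = (
        frame["peptide"] + "/" + frame["charge"].astype(str) + "/" + frame["mod_key"]
    )
    if frame[sample_cols].notna().sum(axis=1).eq(0).any():
        raise TableFormatError(
            f"{path}: ion rows with no observed intensity are not allowed"
        )
    return frame


def write_ion_table(frame: pd.DataFrame, path) -> None:
    cols = ION_KEY_COLUMNS + [
        c for c in frame.columns if c not in ION_KEY_COLUMNS and c != "ion_key"
    ]
    frame[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_design(path, comparison: tuple[str, str] | None = None) -> StudyDesign:
    """Read a design TSV.  When ``comparison`` is omitted the first two
    distinct conditions (file order) form (test, reference)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str,
                                               "treatment": str})
    _require_columns(frame, ["sample_id", "condition", "treatment", "replicate"], path)
    bad = set(frame["treatment"]) - {TREATMENT_LIP, TREATMENT_CONTROL}
    if bad:
        raise TableFormatError(
            f"{path}: unknown treatments {sorted(bad)}; "
            f"expected {TREATMENT_LIP!r} or {TREATMENT_CONTROL!r}"
        )
    if comparison is None:
        conditions = list(dict.fromkeys(frame["condition"]))
        if len(conditions) < 2:
            raise TableFormatError(f"{path}: need >= 2 conditions for a comparison")
        comparison = (conditions[0], conditions[1])
    return StudyDesign.from_frame(frame, comparison)


def write_design(design: StudyDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


ANNOTATION_COLUMNS = [
    "protein_id", "gene", "pI", "n_domains", "ecod_xgroups", "cofactors",
    "mw_kda", "oligomeric_state",
]


def read_annotations(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t",
        dtype={"protein_id": str, "gene": str, "ecod_xgroups": str,
               "cofactors": str, "oligomeric_state": str},
        keep_default_na=True,
    )
    _require_columns(frame, ["protein_id"], path)
    for col in ("ecod_xgroups", "cofactors"):
        if col in frame.columns:
            frame[col] = frame[col].fillna("")
    return frame


def write_annotations(frame: pd.DataFrame, path) -> None:
    cols = [c for c in ANNOTATION_COLUMNS if c in frame.columns] + [
        c for c in frame.columns if c not in ANNOTATION_COLUMNS
    ]
    frame[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def split_set_field(value: str) -> frozenset[str]:
    """Parse a semicolon-delimited set-valued annotation field."""
    if not value or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    return frozenset(v for v in str(value).split(";") if v)


def write_fasta(proteome: Iterable[ProteinSeq], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for protein in proteome:
            fh.write(f">{protein.id}\n")
            for i in range(0, len(protein.sequence), width):
                fh.write(protein.sequence[i : i + width] + "\n")


def write_cutsites(frame: pd.DataFrame, path) -> None:
    frame[CUTSITE_COLUMNS].to_csv(path, sep="\t", index=False,
                                  float_format=FLOAT_FORMAT)


def read_cutsites(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "site_id": str})
    _require_columns(frame, CUTSITE_COLUMNS, path)
    frame["significant"] = frame["significant"].astype(bool)
    return frame


def write_calls(frame: pd.DataFrame, path) -> None:
    frame[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "status": str,
                                               "context": str})
    _require_columns(frame, CALL_COLUMNS, path)
    return frame


def write_abundance(frame: pd.DataFrame, path) -> None:
    frame[ABUNDANCE_COLUMNS].to_csv(path, sep="\t", index=False,
                                    float_format=FLOAT_FORMAT)


def read_abundance(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    _require_columns(frame, ABUNDANCE_COLUMNS, path)
    return frame
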