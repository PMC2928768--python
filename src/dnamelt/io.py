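"""Readers and writers: FASTA (plain or gzip), dataset CSV/TSV, JSON summaries.

Dataset schema (CSV or TSV, header required):

    id,sequence,na_molar,strand_conc,strand_conc_units,exp_tm

``strand_conc_units`` is "molar" or "g_per_ml"; ``exp_tm`` may be blank
for prediction-only records.  Evaluation output appends ``pred_tm`` and
``residual`` columns.  Malformed rows are errors naming the row, never
silent skips.
"""

from __future__ import annotations

import gzip
import io as _stdio
import json
import math
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd
from Bio import SeqIO

from .model import MeltingConditions, TmDatasetRecord
from .profile import GenomeTmSummary

__all__ = [
    "read_fasta",
    "read_dataset",
    "write_dataset",
    "summary_to_json",
]

REQUIRED_COLUMNS = ["id", "sequence", "na_molar", "strand_conc", "strand_conc_units", "exp_tm"]


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return _stdio.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file as ordered (id, sequence) pairs.

    Sequences are returned raw (case preserved); validation and
    uppercasing happen at the point of scoring.
    """
    with _open_text(path) as fh:
        first = fh.read(1)
        if not first:
            raise ValueError(f"{path}: empty FASTA input")
        if first != ">":
            raise ValueError(f"{path}: line 1: sequence data before any '>' header")
        fh.seek(0)
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_dataset(path: str | Path, sep: str | None = None) -> list[TmDatasetRecord]:
    """Read a Tm dataset table into typed records; every bad row is a hard error."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tsv.gz")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "sequence": str, "strand_conc_units": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header must be {REQUIRED_COLUMNS}")
    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        try:
            exp = row["exp_tm"]
            exp_tm = None if pd.isna(exp) else float(exp)
            records.append(
                TmDatasetRecord(
                    id=str(row["id"]),
                    sequence=str(row["sequence"]).strip(),
                    conditions=MeltingConditions(
                        na_molar=float(row["na_molar"]),
                        strand_conc=float(row["strand_conc"]),
                        strand_conc_units=str(row["strand_conc_units"]),
                    ),
                    exp_tm=exp_tm,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {rownum}: {exc}") from exc
    return records


def write_dataset(
    records: Iterable[TmDatasetRecord],
    path: str | Path,
    include_predictions: bool = False,
) -> None:
    """Write records back to the canonical CSV schema (optionally with pred_tm, residual)."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "sequence": r.sequence,
            "na_molar": r.conditions.na_molar,
            "strand_conc": r.conditions.strand_conc,
            "strand_conc_units": r.conditions.strand_conc_units,
            "exp_tm": "" if r.exp_tm is None else r.exp_tm,
        }
        if include_predictions:
            row["pred_tm"] = "" if r.pred_tm is None else r.pred_tm
            row["residual"] = "" if r.residual is None else r.residual
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def summary_to_json(
    summary: GenomeTmSummary, coefficients_dict: dict, out: TextIO
) -> None:
    """Serialize a genome Tm summary (per-record and overall Tm, window bookkeeping)."""
    json.dump(
        {
            "overall_tm_c": summary.overall_tm,
            "per_record_tm_c": summary.per_record_tm,
            "records_used": summary.records_used,
            "window_size": summary.window_size,
            "n_windows": summary.n_windows,
            "skipped_windows": summary.skipped_windows,
            "conditions": {
                "na_molar": summary.conditions.na_molar,
                "strand_conc": summary.conditions.strand_conc,
                "strand_conc_units": summary.conditions.strand_conc_units,
            },
            "coefficients": coefficients_dict,
        },
        out,
        indent=2,
    )
    out.write("\n")
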