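"""Tab-delimited readers and writers for every pipeline table.

Dialect: UTF-8, tab-delimited, '.' decimal separator, first column the row
identifier. Expression column headers encode ``cell_line:condition:replicate``.
Missing values are an empty cell or ``NA``. A loader for the GEO Series
Matrix text format is included so deposited experiments can be fed through
the same pipeline without any binary tooling.
"""
from __future__ import annotations

import io as _io
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CONDITIONS, ExpressionExperiment, ReceptorDesign

_NA_VALUES = ["", "NA", "null"]


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def _parse_header_field(field: str) -> tuple[str, str, str]:
    parts = field.split(":")
    if len(parts) != 3 or not all(parts):
        raise ValueError(
            f"malformed expression column header {field!r}; "
            "expected 'cell_line:condition:replicate'"
        )
    line, cond, rep = parts
    if cond not in CONDITIONS:
        raise ValueError(f"unknown condition {cond!r} in header {field!r}")
    return line, cond, rep


def read_expression_table(path: str | Path,
                          log2_scale: bool = False) -> ExpressionExperiment:
    """Read a replicate-level expression table.

    The header row names the probe-set column first, then one column per
    array as ``cell_line:condition:replicate``. Duplicate probe-set rows,
    negative linear fluorescence and malformed headers raise ``ValueError``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=_NA_VALUES,
                     keep_default_na=False)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    df = df.set_index(df.columns[0])
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate probe-set rows: {dup}")
    cols = [_parse_header_field(c) for c in df.columns]
    df.columns = pd.MultiIndex.from_tuples(
        cols, names=["cell_line", "condition", "replicate"])
    df = df.astype(float)
    exp = ExpressionExperiment(df, log2_scale=log2_scale,
                               metadata={"source": str(path)})
    return exp


def write_expression_table(exp: ExpressionExperiment, path: str | Path) -> None:
    out = exp.values.copy()
    out.columns = [f"{l}:{c}:{r}" for l, c, r in out.columns]
    out.to_csv(path, sep="\t", index_label="probe_set", na_rep="NA")


# ---------------------------------------------------------------------------
# probe-set -> gene annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> dict[str, str]:
    """Read a two-column (probe_set, gene) map.

    Probe sets absent from the file are treated as unannotated downstream.
    A probe set listed twice with conflicting gene symbols is an error;
    duplicate consistent rows are tolerated. An empty file yields an empty
    map (every probe set unannotated).
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in {"probe_set", "probeset", "id"}:
                continue
            if len(parts) < 2 or not parts[0]:
                raise ValueError(f"{path}:{lineno}: expected 'probe_set<TAB>gene'")
            ps, gene = parts[0], parts[1]
            if not gene:
                continue  # explicit blank gene == unannotated
            if ps in mapping and mapping[ps] != gene:
                raise ValueError(
                    f"{path}: probe set {ps!r} maps to both "
                    f"{mapping[ps]!r} and {gene!r}")
            mapping[ps] = gene
    return mapping


def write_annotation(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_set\tgene\n")
        for ps, gene in mapping.items():
            fh.write(f"{ps}\t{gene}\n")


# ---------------------------------------------------------------------------
# receptor design matrix
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> ReceptorDesign:
    """Read a receptor x cell-line 0/1 presence matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ReceptorDesign(df, metadata={"source": str(path)})


def write_design(design: ReceptorDesign, path: str | Path) -> None:
    design.presence.astype(int).to_csv(path, sep="\t", index_label="receptor")


# ---------------------------------------------------------------------------
# cohort / intervention tables
# ---------------------------------------------------------------------------

def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a sample-level cohort table.

    Requires ``sample_id``, ``marker_a`` and ``marker_b`` columns
    (normalized expression ratios); raw target/housekeeping columns are
    carried through when present.
    """
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    for col in ("sample_id", "marker_a", "marker_b"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df.set_index("sample_id")


def write_cohort_table(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index_label="sample_id")


def read_intervention_table(path: str | Path) -> pd.DataFrame:
    """Read an animal-level table with ``animal_id``, ``group``, ``measurement``."""
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    for col in ("animal_id", "group", "measurement"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def write_intervention_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GEO Series Matrix
# ---------------------------------------------------------------------------

_LOG2_PAT = re.compile(r"log[ _-]?2|log2", re.IGNORECASE)


def read_geo_series_matrix(path: str | Path,
                           sample_map: dict[str, tuple[str, str, str]],
                           log2_scale: bool | None = None,
                           ) -> ExpressionExperiment:
    """Load a GEO Series Matrix text file as an :class:`ExpressionExperiment`.

    Parameters
    ----------
    path : path
        A local ``*_series_matrix.txt`` file (uncompressed).
    sample_map : dict
        Maps each ``!Sample_title`` string to a
        ``(cell_line, condition, replicate)`` triple; every sample in the
        file must be mapped, otherwise the offending title is reported.
    log2_scale : bool, optional
        Manual override of the scale flag. When omitted, the loader scans
        the ``!Sample_data_processing`` / ``!Series_summary`` metadata for
        a log2 mention and records what it decided in the metadata.
    """
    path = Path(path)
    meta_lines: list[str] = []
    table_lines: list[str] = []
    in_table = False
    saw_end = False
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                saw_end = True
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                meta_lines.append(line)
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix_table block found")
    if not saw_end:
        raise ValueError(f"{path}: missing series_matrix_table_end marker")

    titles = _geo_meta_row(meta_lines, "!Sample_title")
    if titles is None:
        raise ValueError(f"{path}: no !Sample_title metadata line")

    df = pd.read_csv(_io.StringIO("\n".join(table_lines)), sep="\t",
                     index_col=0, na_values=_NA_VALUES, keep_default_na=False)
    if df.shape[1] != len(titles):
        raise ValueError(
            f"{path}: table has {df.shape[1]} sample columns but metadata "
            f"names {len(titles)} samples")
    columns = []
    for title in titles:
        if title not in sample_map:
            raise ValueError(f"{path}: sample title {title!r} absent from "
                             "the supplied sample map")
        columns.append(sample_map[title])
    df.columns = pd.MultiIndex.from_tuples(
        columns, names=["cell_line", "condition", "replicate"])
    df = df.astype(float)

    if log2_scale is None:
        blob = " ".join(m for m in meta_lines
                        if m.startswith(("!Sample_data_processing",
                                         "!Series_summary")))
        log2_scale = bool(_LOG2_PAT.search(blob))
        scale_note = "auto-detected from metadata"
    else:
        scale_note = "manual override"
    return ExpressionExperiment(
        df, log2_scale=log2_scale,
        metadata={"source": str(path), "scale_note": scale_note,
                  "sample_titles": titles})


def _geo_meta_row(meta_lines: list[str], key: str) -> list[str] | None:
    for line in meta_lines:
        if line.startswith(key + "\t") or line == key:
            fields = line.split("\t")[1:]
            return [f.strip().strip('"') for f in fields]
    return None
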