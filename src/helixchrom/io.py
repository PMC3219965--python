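"""Readers and writers for the pipeline's tabular formats.

All tables are tab-separated UTF-8 with a header row and ``.`` for missing
values; nested reports are JSON.  Separations are stored in kb with
3-decimal precision, genomic positions as integer bp.  Coordinates are
normalized to 0-based half-open on read; a ``chr`` prefix is tolerated both
ways and preserved as given.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import GenomicFixture

__all__ = [
    "read_contact_table",
    "write_contact_table",
    "read_bed",
    "write_bed",
    "read_cytoband",
    "write_cytoband",
    "read_gene_table",
    "write_gene_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_fragment_table",
    "write_fragment_table",
    "read_tag_pairs",
    "write_tag_pairs",
    "read_genomic_inputs",
    "write_genomic_fixture",
    "load_config",
    "resolved_config",
    "sha256_of",
]

_NA = "."

CONTACT_COLUMNS = ["locus", "anchor_id", "site_id", "separation_kb", "frequency"]
CONTACT_OPTIONAL = ["sem", "n_assays", "expression_class"]


class TableFormatError(ValueError):
    """A file violates its declared format (missing columns, bad layout)."""


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=True,
                       comment="#")


def read_contact_table(path) -> pd.DataFrame:
    """Contact-profile TSV -> validated DataFrame.

    Mandatory columns: locus, anchor_id, site_id, separation_kb, frequency.
    Malformed rows (non-numeric or negative separation, non-numeric or
    negative frequency) are dropped; their line numbers are collected in
    ``attrs["row_errors"]``.
    """
    df = pd.read_csv(path, sep="\t", na_values=[_NA], dtype=str, comment="#")
    missing = [c for c in CONTACT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing mandatory column(s) {missing}")

    row_errors = []
    sep = pd.to_numeric(df["separation_kb"], errors="coerce")
    freq = pd.to_numeric(df["frequency"], errors="coerce")
    for i in df.index:
        problems = []
        if not np.isfinite(sep[i]):
            problems.append("non-numeric separation_kb")
        elif sep[i] < 0:
            problems.append("negative separation_kb")
        if not np.isfinite(freq[i]):
            problems.append("non-numeric frequency")
        elif freq[i] < 0:
            problems.append("negative frequency")
        if problems:
            # +2: header line plus 1-based numbering
            row_errors.append({"line": int(i) + 2, "error": "; ".join(problems)})
    bad = {e["line"] - 2 for e in row_errors}
    keep = [i for i in df.index if i not in bad]
    out = df.loc[keep].copy()
    out["separation_kb"] = sep[keep]
    out["frequency"] = freq[keep]
    if "sem" in out.columns:
        out["sem"] = pd.to_numeric(out["sem"], errors="coerce")
    if "n_assays" in out.columns:
        out["n_assays"] = pd.to_numeric(out["n_assays"], errors="coerce").astype("Int64")
    if "expression_class" not in out.columns:
        out["expression_class"] = "unknown"
    else:
        out["expression_class"] = out["expression_class"].fillna("unknown")
    out = out.reset_index(drop=True)
    out.attrs["row_errors"] = row_errors
    return out


def write_contact_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["separation_kb"] = out["separation_kb"].map(lambda v: f"{v:.3f}")
    if "sem" in out.columns:
        out["sem"] = out["sem"].map(lambda v: _NA if pd.isna(v) else f"{v:.6g}")
    if "frequency" in out.columns:
        out["frequency"] = out["frequency"].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False, na_rep=_NA)


# ---------------------------------------------------------------------------
# genomic formats
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """BED3+ (0-based half-open natively).  Rows with end <= start are dropped
    and reported in ``attrs["row_errors"]``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], usecols=[0, 1, 2])
    bad = df.index[df["end"] <= df["start"]].tolist()
    out = df.drop(index=bad).reset_index(drop=True)
    out.attrs["row_errors"] = [
        {"line": int(i) + 1, "error": "end <= start"} for i in bad
    ]
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    return out


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def read_cytoband(path) -> pd.DataFrame:
    """UCSC cytoBand TSV: chrom, start, end, name, gieStain (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "gieStain"])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_cytoband(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "name", "gieStain"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gene_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"gene_id", "chrom", "tss", "strand", "housekeeping"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing)}")
    df["tss"] = df["tss"].astype(int)
    df["housekeeping"] = df["housekeeping"].astype(int)
    return df


def write_gene_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_expression_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA])
    df.index.name = "gene_id"
    return df


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep=_NA)


def read_fragment_table(path) -> pd.DataFrame:
    """Restriction fragments; per chromosome they must tile without overlap."""
    df = _read_tsv(path)
    required = {"fragment_id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing)}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    for chrom, group in df.groupby("chrom"):
        g = group.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise TableFormatError(f"{path}: overlapping fragments on {chrom}")
    return df


def write_fragment_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tag_pairs(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"chrom", "fragment_1", "direction_1", "fragment_2", "direction_2"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("fragment_1", "direction_1", "fragment_2", "direction_2"):
        df[col] = df[col].astype(int)
    return df


def write_tag_pairs(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genomic_inputs(paths: dict) -> GenomicFixture:
    """Assemble a GenomicFixture from a dict of file paths.

    Recognized keys: genes, expression, conserved_elements,
    transcription_units (BED), bands (cytoBand), fragments, tag_pairs.
    """
    readers = {
        "genes": read_gene_table,
        "expression": read_expression_matrix,
        "conserved_elements": read_bed,
        "bands": read_cytoband,
        "fragments": read_fragment_table,
        "tag_pairs": read_tag_pairs,
    }
    fixture = GenomicFixture()
    for key, path in paths.items():
        if key == "transcription_units":
            bed = read_bed(path)
            tu = pd.read_csv(path, sep="\t", header=None, comment="#")
            bed["gene_id"] = tu[3] if tu.shape[1] > 3 else [
                f"tu{i}" for i in range(len(tu))
            ]
            fixture.transcription_units = bed
        elif key in readers:
            setattr(fixture, key, readers[key](path))
        else:
            raise ValueError(f"unknown genomic input key {key!r}")
    return fixture


def write_genomic_fixture(fixture: GenomicFixture, outdir) -> dict:
    """Write every populated table of a fixture; returns {key: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    if fixture.genes is not None:
        written["genes"] = outdir / "genes.tsv"
        write_gene_table(fixture.genes, written["genes"])
    if fixture.expression is not None:
        written["expression"] = outdir / "expression.tsv"
        write_expression_matrix(fixture.expression, written["expression"])
    if fixture.conserved_elements is not None:
        written["conserved_elements"] = outdir / "conserved_elements.bed"
        write_bed(fixture.conserved_elements, written["conserved_elements"])
    if fixture.transcription_units is not None:
        written["transcription_units"] = outdir / "transcription_units.bed"
        fixture.transcription_units[["chrom", "start", "end", "gene_id"]].to_csv(
            written["transcription_units"], sep="\t", index=False, header=False
        )
    if fixture.bands is not None:
        written["bands"] = outdir / "cytoband.tsv"
        write_cytoband(fixture.bands, written["bands"])
    if fixture.fragments is not None:
        written["fragments"] = outdir / "fragments.tsv"
        write_fragment_table(fixture.fragments, written["fragments"])
    if fixture.tag_pairs is not None:
        written["tag_pairs"] = outdir / "tag_pairs.tsv"
        write_tag_pairs(fixture.tag_pairs, written["tag_pairs"])
    if fixture.truth:
        truth_path = outdir / "truth.json"
        with open(truth_path, "w") as fh:
            json.dump(_jsonable(fixture.truth), fh, indent=2)
        written["truth"] = truth_path
    return {k: str(v) for k, v in written.items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# configuration and provenance
# ---------------------------------------------------------------------------

def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path, known_keys: set[str]) -> dict:
    """YAML config; unknown keys are rejected outright."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise TableFormatError(f"{path}: config must be a mapping")
    unknown = set(cfg) - set(known_keys)
    if unknown:
        raise TableFormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return cfg


def resolved_config(params: dict, inputs: dict | None = None) -> dict:
    """Fully-resolved run configuration with a provenance block."""
    from datetime import datetime, timezone

    from . import __version__

    return {
        "params": _jsonable(params),
        "provenance": {
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "python": sys.version.split()[0],
            "input_checksums": {
                name: sha256_of(path) for name, path in (inputs or {}).items()
            },
        },
    }
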