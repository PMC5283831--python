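"""Readers and writers for the pipeline's file formats.

Peaks: BED6 and ENCODE narrowPeak, 0-based half-open, as written by common
peak callers.  Annotation: plain TSV TSS tables (gene_id, chrom, tss,
strand, expression) and DE tables (gene_id, log2FC, padj; column names
configurable to match common DE output headers).  Sequences: FASTA through
Biopython.  Plate data: long-format TSV.

TSS tables are 0-based by default; pass ``one_based=True`` for 1-based
annotation exports (converted on read, and the conversion is recorded in the
returned frame's ``attrs``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NARROWPEAK_COLS = ["chrom", "start", "end", "name", "score", "strand",
                   "signalValue", "pValue", "qValue", "summit_offset"]
BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


class InputError(ValueError):
    """Malformed or inconsistent input file."""


def _read_table(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except Exception as exc:  # pragma: no cover - message formatting
        raise InputError(f"cannot parse {path}: {exc}") from exc


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read a BED6 or narrowPeak file (auto-detected by column count).

    Returns a frame with at least ``chrom, start, end`` and, for narrowPeak,
    ``summit_offset`` (-1 in the file means 'no summit' and becomes NaN).
    """
    path = Path(path)
    df = _read_table(path, header=None, comment="#")
    ncol = df.shape[1]
    if ncol == 10:
        df.columns = NARROWPEAK_COLS
        df.loc[df["summit_offset"] < 0, "summit_offset"] = np.nan
    elif ncol >= 3:
        df.columns = BED6_COLS[:ncol]
    else:
        raise InputError(f"{path}: expected >= 3 BED columns, found {ncol}")
    if (df["start"] >= df["end"]).any():
        bad = int((df["start"] >= df["end"]).sum())
        raise InputError(f"{path}: {bad} intervals with start >= end")
    return df


def write_peaks(peaks: pd.DataFrame, path: str | Path,
                narrowpeak: bool | None = None) -> None:
    """Write peaks as BED6 or narrowPeak (0-based half-open).

    Format defaults to narrowPeak when a ``summit_offset`` column is
    present.
    """
    path = Path(path)
    if narrowpeak is None:
        narrowpeak = "summit_offset" in peaks.columns
    df = peaks.copy()
    n = len(df)
    df["name"] = df.get("name", pd.Series([f"peak{i}" for i in range(n)]))
    df["score"] = df.get("score", 0)
    df["strand"] = df.get("strand", ".")
    if narrowpeak:
        df["signalValue"] = df.get("signalValue", 0.0)
        df["pValue"] = df.get("pValue", -1)
        df["qValue"] = df.get("qValue", -1)
        so = df.get("summit_offset")
        df["summit_offset"] = (-1 if so is None
                               else so.fillna(-1).astype(int))
        cols = NARROWPEAK_COLS
    else:
        cols = BED6_COLS
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read a TSS table TSV: gene_id, chrom, tss, strand, expression."""
    df = _read_table(path)
    missing = {"gene_id", "chrom", "tss", "strand", "expression"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing TSS columns {sorted(missing)}")
    if one_based:
        df["tss"] = df["tss"] - 1
    df.attrs["coordinate_convention"] = "0-based (converted from 1-based)" \
        if one_based else "0-based"
    return df


def write_tss_table(tss: pd.DataFrame, path: str | Path) -> None:
    tss.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path, gene_col: str = "gene_id",
                  lfc_col: str = "log2FoldChange",
                  padj_col: str = "padj") -> pd.DataFrame:
    """Read a DE results TSV, renaming columns to gene_id/log2fc/padj.

    Defaults match common DE output headers; our own synthetic tables use
    ``log2fc``, which is accepted automatically.
    """
    df = _read_table(path)
    if lfc_col not in df.columns and "log2fc" in df.columns:
        lfc_col = "log2fc"
    missing = {gene_col, lfc_col, padj_col} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing DE columns {sorted(missing)}")
    out = df.rename(columns={gene_col: "gene_id", lfc_col: "log2fc",
                             padj_col: "padj"})
    if out["padj"].isna().any():
        out = out.dropna(subset=["padj"])  # NA padj = untested gene
    return out


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (name, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(sequences, path: str | Path) -> None:
    """Write (name, sequence) pairs to FASTA."""
    recs = (SeqRecord(Seq(s), id=name, description="") for name, s in sequences)
    SeqIO.write(recs, str(path), "fasta")


def read_plate_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format plate TSV.

    Columns: ``pair_id, condition, dilution_or_conc, replicate, signal``.
    Conditions used by the pipeline: ``titration`` (serial dilution),
    ``vehicle``/``compound`` (single-concentration disruption) and ``dose``
    (dose-response, concentration in ``dilution_or_conc``).
    """
    df = _read_table(path)
    need = {"pair_id", "condition", "dilution_or_conc", "replicate", "signal"}
    missing = need - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing plate columns {sorted(missing)}")
    if (df["signal"] < 0).any():
        raise InputError(f"{path}: negative signals")
    return df


def write_plate_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def titration_to_long(series, pair_id: str) -> pd.DataFrame:
    rows = []
    for i, step in enumerate(series.dilution_steps):
        for rep in range(series.signals.shape[1]):
            rows.append((pair_id, "titration", float(step), rep,
                         float(series.signals[i, rep])))
    return pd.DataFrame(rows, columns=["pair_id", "condition",
                                       "dilution_or_conc", "replicate", "signal"])


def dose_response_to_long(data, pair_id: str) -> pd.DataFrame:
    rows = []
    for i, conc in enumerate(data.concentrations):
        for rep in range(data.responses.shape[1]):
            rows.append((pair_id, "dose", float(conc), rep,
                         float(data.responses[i, rep])))
    return pd.DataFrame(rows, columns=["pair_id", "condition",
                                       "dilution_or_conc", "replicate", "signal"])


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
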