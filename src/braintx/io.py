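"""Readers and writers for the pipeline's plain-text interchange formats.

Counts travel as TSV (genes x samples, header row) or MatrixMarket ``.mtx``
with ``<stem>.rows.txt`` / ``<stem>.cols.txt`` name sidecars; cell labels
and sample metadata as TSV; gene sets as GMT (set name, description, then
tab-separated genes); volumes as long-format TSV (x, y, z, region, gene,
energy).  Every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionVolume

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "read_metadata",
    "write_metadata",
    "read_volume",
    "write_volume",
]


# -- gene sets (GMT) -----------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: gene list} (duplicates dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning(
                    "%s:%d: set %r contains duplicate genes; de-duplicated",
                    path, lineno, name,
                )
            sets[name] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "braintx") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            unique = list(dict.fromkeys(genes))
            if not unique:
                logger.warning("set %r is empty; omitted from GMT", name)
                continue
            fh.write("\t".join([name, description, *unique]) + "\n")


# -- count matrices ------------------------------------------------------

def write_counts(counts: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write a genes x samples (or cells x genes) integer matrix.

    ``fmt='tsv'`` writes a header TSV; ``fmt='mtx'`` writes MatrixMarket
    plus ``<stem>.rows.txt`` and ``<stem>.cols.txt`` name sidecars.
    """
    path = Path(path)
    if fmt == "tsv":
        out = counts.copy()
        out.index.name = out.index.name or "gene"
        out.to_csv(path, sep="\t")
    elif fmt == "mtx":
        spio.mmwrite(str(path), sparse.csr_matrix(counts.to_numpy()))
        path.with_suffix(".rows.txt").write_text(
            "\n".join(map(str, counts.index)) + "\n"
        )
        path.with_suffix(".cols.txt").write_text(
            "\n".join(map(str, counts.columns)) + "\n"
        )
    else:
        raise ValueError("fmt must be 'tsv' or 'mtx'")


def read_counts(path) -> pd.DataFrame:
    """Read a count matrix written by :func:`write_counts` (TSV or MTX)."""
    path = Path(path)
    if path.suffix == ".mtx":
        rows_path = path.with_suffix(".rows.txt")
        cols_path = path.with_suffix(".cols.txt")
        for sidecar in (rows_path, cols_path):
            if not sidecar.exists():
                raise FileNotFoundError(
                    f"MTX sidecar name file missing: expected {sidecar}"
                )
        matrix = spio.mmread(str(path)).toarray()
        rows = rows_path.read_text().splitlines()
        cols = cols_path.read_text().splitlines()
        frame = pd.DataFrame(matrix, index=rows, columns=cols)
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row identifiers: {dups[:5]}")
    if frame.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate column identifiers")
    values = frame.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: matrix contains non-integer values")
    return frame.astype(np.int64)


# -- labels and metadata -------------------------------------------------

def write_labels(labels: pd.DataFrame, path) -> None:
    """Write per-cell labels (index cell_id; columns class[, subclass])."""
    out = labels.copy()
    out.index.name = "cell_id"
    out.to_csv(path, sep="\t")


def read_labels(path) -> pd.DataFrame:
    labels = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "class" not in labels.columns:
        raise ValueError(f"{path}: labels file needs a 'class' column")
    if labels.index.duplicated().any():
        raise ValueError(f"{path}: duplicate cell identifiers")
    return labels


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    required = {"condition", "sex", "batch"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    if meta.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample identifiers")
    return meta


# -- volumes -------------------------------------------------------------

def write_volume(volume: ExpressionVolume, path) -> None:
    """Long-format TSV: x, y, z, region, gene, energy (one row per pair)."""
    volume.to_long_frame().to_csv(path, sep="\t", index=False)


def read_volume(path, section_axis: str = "z") -> ExpressionVolume:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return ExpressionVolume.from_long_frame(frame, section_axis=section_axis)
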