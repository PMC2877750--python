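"""Readers and writers for the pipeline's tab-separated interchange formats.

All tabular files are UTF-8 TSV with ``#``-prefixed header comments that
carry the package version and a hash of the run configuration; writes are
atomic (temp file in the target directory, then rename). FASTA goes
through Biopython.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import InputError

__all__ = [
    "config_hash",
    "write_tsv",
    "read_tsv",
    "read_manifest",
    "read_beads",
    "read_annotation",
    "read_beta_matrix",
    "write_beta_matrix",
    "write_json",
    "read_fasta",
    "write_fasta",
]

MANIFEST_COLUMNS = ["sample_id", "tissue", "age_group", "sun", "sex", "sampling"]
BEAD_COLUMNS = ["sample_id", "probe_id", "channel", "allele", "intensity"]
ANNOTATION_COLUMNS = ["probe_id", "chromosome", "cpg_island", "gene_symbol"]


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(meta: Mapping | None) -> list[str]:
    from . import __version__

    lines = [f"# methylskin {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    return lines


def _atomic_write(path: Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(df: pd.DataFrame, path, meta: Mapping | None = None,
              index: bool = False) -> None:
    body = df.to_csv(sep="\t", index=index)
    _atomic_write(Path(path), "\n".join(_header_lines(meta)) + "\n" + body)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str,
                     path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(
            f"{what} {path} is missing column(s): {', '.join(missing)}"
        )


def read_manifest(path) -> pd.DataFrame:
    from .synthetic import validate_design

    design = read_tsv(path, dtype=str)
    _require_columns(design, MANIFEST_COLUMNS, "manifest", path)
    if design.empty:
        raise InputError(f"manifest {path} contains no samples")
    validate_design(design)
    return design.set_index("sample_id", drop=False)


def read_beads(path) -> pd.DataFrame:
    beads = read_tsv(
        path,
        dtype={"sample_id": "category", "probe_id": "category",
               "channel": "category", "allele": "category"},
    )
    _require_columns(beads, BEAD_COLUMNS, "bead table", path)
    if beads.empty:
        raise InputError(f"bead table {path} contains no beads")
    if (beads["intensity"] < 0).any():
        bad = int((beads["intensity"] < 0).idxmax())
        raise InputError(f"bead table {path}: negative intensity at row {bad}")
    return beads


def read_annotation(path) -> pd.DataFrame:
    ann = read_tsv(path)
    _require_columns(ann, ANNOTATION_COLUMNS[:3], "annotation", path)
    if "gene_symbol" not in ann.columns:
        ann["gene_symbol"] = ""
    if ann["probe_id"].duplicated().any():
        raise InputError(f"annotation {path}: duplicated probe_id values")
    ann["cpg_island"] = ann["cpg_island"].astype(bool)
    ann["chromosome"] = ann["chromosome"].astype(str)
    return ann.set_index("probe_id", drop=False)


def write_beta_matrix(beta: pd.DataFrame, path,
                      meta: Mapping | None = None) -> None:
    out = beta.copy()
    out.index.name = "probe_id"
    write_tsv(out, path, meta=meta, index=True)


def read_beta_matrix(path) -> pd.DataFrame:
    beta = read_tsv(path, index_col="probe_id")
    return beta.astype(float)


def write_json(obj, path, meta: Mapping | None = None) -> None:
    payload = dict(obj)
    if meta:
        payload["_meta"] = dict(meta)
    _atomic_write(Path(path), json.dumps(payload, indent=2, sort_keys=True,
                                         default=float) + "\n")


def read_fasta(path) -> list:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")
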