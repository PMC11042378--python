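"""Local-filesystem repository client: query -> manifest -> assemble.

A repository is a directory containing ``index.json`` (a list of file
records) plus one two-column TSV per sample file.  This reproduces the
query/download/assemble contract of a remote genomic data repository with a
local backend, so analyses and tests need no network access.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ASSAYS, AssayMatrix, SampleMeta

logger = logging.getLogger(__name__)

INDEX_NAME = "index.json"

#: metadata fields a Query may filter on
QUERY_FIELDS = ("file_id", "assay", "sample_id", "patient_id", "tissue")


@dataclass(frozen=True)
class FileRecord:
    """One downloadable per-sample file in the repository index."""

    file_id: str
    assay: str
    sample_id: str
    patient_id: str
    tissue: str
    relative_path: str


@dataclass
class Query:
    """Conjunctive filters over sample metadata fields.

    ``filters`` maps a field name to the set of allowed values; a record
    matches when every filtered field's value is allowed.
    """

    filters: Mapping[str, Sequence[str] | str]

    def normalized(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for field, allowed in self.filters.items():
            if field not in QUERY_FIELDS:
                raise ValidationError(
                    f"unknown query field {field!r}; valid fields: {', '.join(QUERY_FIELDS)}"
                )
            if isinstance(allowed, str):
                allowed = [allowed]
            out[field] = {str(v) for v in allowed}
        return out


def load_index(repo_dir: str | Path) -> list[FileRecord]:
    """Load and validate ``index.json`` from the repository root."""
    repo_dir = Path(repo_dir)
    index_path = repo_dir / INDEX_NAME
    if not index_path.exists():
        raise ValidationError(f"repository {repo_dir} has no {INDEX_NAME}")
    records = [FileRecord(**rec) for rec in json.loads(index_path.read_text())]
    seen: set[str] = set()
    for r in records:
        if r.file_id in seen:
            raise ValidationError(f"{index_path}: duplicate file_id {r.file_id!r}")
        seen.add(r.file_id)
        if r.assay not in ASSAYS:
            raise ValidationError(f"{index_path}: unknown assay {r.assay!r} for file {r.file_id!r}")
    return records


def query(index: Sequence[FileRecord], q: Query | Mapping[str, Sequence[str] | str]) -> list[FileRecord]:
    """Return records matching every filter, sorted by file_id."""
    if not isinstance(q, Query):
        q = Query(q)
    filters = q.normalized()
    hits = [
        r for r in index if all(str(getattr(r, field)) in allowed for field, allowed in filters.items())
    ]
    return sorted(hits, key=lambda r: r.file_id)


def sample_metadata(index: Sequence[FileRecord]) -> list[SampleMeta]:
    """Project the repository index onto per-sample metadata rows."""
    return [SampleMeta(r.sample_id, r.patient_id, r.tissue, r.assay) for r in index]


def _read_sample_file(path: Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "value"], dtype={0: str})
    dup = df["feature_id"][df["feature_id"].duplicated()].unique()
    if len(dup):
        raise ValidationError(f"{path}: duplicate feature id(s): {', '.join(dup[:5])}")
    return pd.Series(pd.to_numeric(df["value"], errors="coerce").to_numpy(), index=df["feature_id"])


def fetch_and_assemble(
    repo_dir: str | Path, records: Sequence[FileRecord], assay: str
) -> AssayMatrix:
    """Assemble per-sample files into one features x samples matrix.

    The feature set is the union over files; a feature absent from a given
    file is missing in that sample's column.  Columns are sorted by
    sample_id and features sorted lexicographically, so the result does not
    depend on the order of ``records``.
    """
    repo_dir = Path(repo_dir)
    records = [r for r in records if r.assay == assay]
    if not records:
        raise ValidationError(f"no records with assay {assay!r} to assemble")
    seen: set[str] = set()
    for r in records:
        if r.sample_id in seen:
            raise ValidationError(f"sample {r.sample_id!r} appears in more than one {assay} record")
        seen.add(r.sample_id)
    columns = {
        r.sample_id: _read_sample_file(repo_dir / r.relative_path)
        for r in sorted(records, key=lambda r: r.sample_id)
    }
    df = pd.DataFrame(columns).sort_index()
    df = df[sorted(df.columns)]
    df.index.name = None
    logger.info("assembled %s matrix: %d features x %d samples", assay, *df.shape)
    return AssayMatrix(df, assay)
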