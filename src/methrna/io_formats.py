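"""Readers and writers for every external file format the package touches.

Formats
-------
* Assay matrices: TSV, features x samples, header row of sample ids, first
  column of feature ids.  Empty cells, ``NA`` and ``NaN`` (any case) denote
  missing values on read; missing cells are written back as ``NA``.
* Locus manifests: CSV in the style of an Illumina 450K manifest, with named
  columns for locus id, chromosome and 1-based CpG position (extra columns
  are ignored; a gene-hint column is picked up when present).
* Gene models: GTF, using only lines whose feature field is ``gene``.
* Sample metadata: TSV with columns sample_id, patient_id, tissue, assay, or
  the equivalent JSON list of objects.
* Promoter windows: BED6 export (0-based half-open).

Chromosome names are stored without the ``chr`` prefix internally; both
dialects are accepted on input so manifests and GTFs join cleanly.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

ASSAYS = ("methylation", "expression")

#: markers accepted as missing on read (matched case-insensitively)
_NA_MARKERS = {"", "na", "nan"}


def _is_missing_marker(s: str) -> bool:
    return s.strip().lower() in _NA_MARKERS


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix; one convention internally."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AssayMatrix:
    """A features x samples numeric matrix for one assay.

    ``data`` is a float DataFrame whose NaN cells are the missing-value mask.
    ``scale`` records the value scale: ``beta`` (methylation fractions in
    [0, 1]), ``counts`` (non-negative), ``log`` (natural-log counts) or
    ``mvalue`` (logit-scale methylation); range validation is keyed on it.
    """

    data: pd.DataFrame
    assay: str
    scale: str = ""

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if not self.scale:
            self.scale = "beta" if self.assay == "methylation" else "counts"
        self.validate()

    # -- properties ---------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the value is missing."""
        return self.data.isna()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        dup_f = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_f):
            raise ValidationError(f"duplicate feature id(s): {', '.join(map(str, dup_f[:5]))}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_s):
            raise ValidationError(f"duplicate sample id(s): {', '.join(map(str, dup_s[:5]))}")
        vals = self.data.to_numpy(dtype=float)
        if self.scale == "beta":
            bad = (vals < 0) | (vals > 1)
        elif self.scale == "counts":
            bad = vals < 0
        else:
            bad = np.zeros(vals.shape, dtype=bool)
        bad &= ~np.isnan(vals)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"{self.assay} value {vals[i, j]!r} out of range for scale "
                f"{self.scale!r} at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )

    def replace(self, data: pd.DataFrame, scale: str | None = None) -> "AssayMatrix":
        return AssayMatrix(data=data, assay=self.assay, scale=self.scale if scale is None else scale)


@dataclass(frozen=True)
class SampleMeta:
    """One physical sample: (sample_id, assay) pairs are unique in a study."""

    sample_id: str
    patient_id: str
    tissue: str
    assay: str


@dataclass(frozen=True)
class ManifestRow:
    """One CpG locus from the array manifest (position is 1-based)."""

    locus_id: str
    chrom: str
    pos: int
    gene_hint: str | None = None


@dataclass(frozen=True)
class GeneModel:
    """A gene feature from a GTF; coordinates 1-based inclusive.

    The TSS is the gene's 5' end: ``start`` on the + strand, ``end`` on -.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}")
        if self.end < self.start:
            raise ValidationError(f"gene {self.gene_id!r}: end {self.end} < start {self.start}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


# ---------------------------------------------------------------------------
# Assay matrices
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, assay: str, scale: str | None = None) -> AssayMatrix:
    """Read a features x samples TSV into a validated :class:`AssayMatrix`.

    Row and column order are preserved from the file.  Empty cells, ``NA``
    and ``NaN`` become missing values.  Raises :class:`ValidationError` for
    duplicate ids or out-of-range values, naming the offender.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dup = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()].unique()
    if len(dup):
        raise ValidationError(f"{path}: duplicate sample id(s) in header: {', '.join(dup[:5])}")

    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        keep_default_na=False,
        na_values=[],
        dtype=str,
        skip_blank_lines=False,
    )
    df.columns = sample_ids
    df.index = df.index.astype(str)
    df.index.name = None
    vals = df.to_numpy()
    out = np.empty(vals.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(vals):
        s = str(cell)
        if _is_missing_marker(s):
            out[i, j] = np.nan
        else:
            try:
                out[i, j] = float(s)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric value {s!r} at feature "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}"
                ) from None
    try:
        return AssayMatrix(pd.DataFrame(out, index=df.index, columns=df.columns), assay, scale or "")
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from None


def write_matrix(m: AssayMatrix, path: str | Path) -> None:
    """Write the matrix back as TSV; missing cells become ``NA``.

    The default float formatting is the shortest round-tripping repr, so
    ``read_matrix(write_matrix(m))`` reproduces values and mask exactly.
    """
    m.data.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


# ---------------------------------------------------------------------------
# Locus manifest
# ---------------------------------------------------------------------------

_MANIFEST_ALIASES = {
    "locus_id": {"locus_id", "ilmnid", "name", "probe_id"},
    "chrom": {"chrom", "chromosome", "chr"},
    "pos": {"pos", "position", "mapinfo"},
    "gene_hint": {"gene_hint", "gene", "ucsc_refgene_name"},
}


def read_manifest(path: str | Path) -> list[ManifestRow]:
    """Read an Illumina-manifest-like CSV into :class:`ManifestRow` list.

    Columns are matched case-insensitively against common aliases; extra
    columns are ignored.  Chromosomes are normalized (no ``chr`` prefix).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap: dict[str, str] = {}
    lower = {c.lower().strip(): c for c in df.columns}
    for canon, aliases in _MANIFEST_ALIASES.items():
        for a in aliases:
            if a in lower:
                colmap[canon] = lower[a]
                break
    for required in ("locus_id", "chrom", "pos"):
        if required not in colmap:
            raise ValidationError(f"{path}: manifest is missing a {required!r} column")
    rows: list[ManifestRow] = []
    seen: set[str] = set()
    for idx, rec in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec = rec._asdict()
        locus = str(rec[colmap["locus_id"]]).strip()
        if locus in seen:
            raise ValidationError(f"{path}: duplicate locus id {locus!r} (line {idx})")
        seen.add(locus)
        raw_pos = str(rec[colmap["pos"]]).strip()
        try:
            pos = int(raw_pos)
        except ValueError:
            raise ValidationError(f"{path}: non-integer position {raw_pos!r} on line {idx}") from None
        if pos < 1:
            raise ValidationError(f"{path}: position {pos} < 1 on line {idx}")
        hint = None
        if "gene_hint" in colmap:
            h = str(rec[colmap["gene_hint"]]).strip()
            hint = h or None
        rows.append(ManifestRow(locus, normalize_chrom(rec[colmap["chrom"]]), pos, hint))
    return rows


def write_manifest(rows: Sequence[ManifestRow], path: str | Path) -> None:
    pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in rows],
            "chrom": [r.chrom for r in rows],
            "pos": [r.pos for r in rows],
            "gene_hint": [r.gene_hint or "" for r in rows],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gene annotation (GTF)
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Parse gene features from a GTF file.

    Only lines whose third field is ``gene`` are consumed; coordinates stay
    1-based inclusive as in the file.  An empty result (e.g. a GTF with only
    exon lines) logs a warning.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    with path.open() as fh:
        for n, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValidationError(f"{path}: line {n} has {len(fields)} fields, expected 9")
            if fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            if "gene_id" not in attrs:
                raise ValidationError(f"{path}: gene line {n} lacks a gene_id attribute")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValidationError(f"{path}: non-integer coordinates on line {n}") from None
            try:
                genes.append(
                    GeneModel(
                        gene_id=attrs["gene_id"],
                        chrom=normalize_chrom(fields[0]),
                        start=start,
                        end=end,
                        strand=fields[6],
                        gene_name=attrs.get("gene_name"),
                    )
                )
            except ValidationError as e:
                raise ValidationError(f"{path}: line {n}: {e}") from None
    if not genes:
        logger.warning("no gene features found in %s", path)
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GTF gene lines."""
    with Path(path).open("w") as fh:
        for g in genes:
            name = f' gene_name "{g.gene_name}";' if g.gene_name else ""
            fh.write(
                f"{g.chrom}\tmethrna\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";{name}\n'
            )


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_META_COLS = ("sample_id", "patient_id", "tissue", "assay")


def _validate_meta(rows: list[SampleMeta], source: str) -> list[SampleMeta]:
    seen: set[tuple[str, str]] = set()
    for r in rows:
        if r.assay not in ASSAYS:
            raise ValidationError(f"{source}: unknown assay {r.assay!r} for sample {r.sample_id!r}")
        key = (r.sample_id, r.assay)
        if key in seen:
            raise ValidationError(f"{source}: duplicate (sample_id, assay) pair {key}")
        seen.add(key)
    return rows


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata from TSV or JSON (detected by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in _META_COLS if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: metadata is missing column(s): {', '.join(missing)}")
        records = df.to_dict("records")
    rows = []
    for rec in records:
        try:
            rows.append(
                SampleMeta(
                    str(rec["sample_id"]), str(rec["patient_id"]), str(rec["tissue"]), str(rec["assay"])
                )
            )
        except KeyError as e:
            raise ValidationError(f"{path}: metadata record lacks key {e}") from None
    return _validate_meta(rows, str(path))


def write_sample_metadata(rows: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in rows], columns=list(_META_COLS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------


def write_promoter_bed(genes: Iterable[GeneModel], path: str | Path, window: int = 1500) -> None:
    """Write strand-aware promoter windows as BED6 (0-based half-open).

    The promoter covers the ``window`` bases strictly upstream of the TSS in
    the gene's reading direction (the TSS base itself is excluded).
    """
    with Path(path).open("w") as fh:
        for g in genes:
            if g.strand == "+":
                start0, end0 = max(0, g.tss - 1 - window), g.tss - 1
            else:
                start0, end0 = g.tss, g.tss + window
            if end0 <= start0:
                continue
            fh.write(f"{g.chrom}\t{start0}\t{end0}\t{g.gene_id}\t0\t{g.strand}\n")
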