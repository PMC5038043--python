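"""Shared data model and file I/O.

The pipeline's universal input is a taxon-by-sample table of raw read
counts plus a per-sample table of clinical and technical covariates
(bleeding-on-probing sextant count, periodontitis status, study site,
nutritional intervention arm, HIV status, sequencing run, demographics).
Count tables are read and written as wide TSV or BIOM 1.0 JSON;
representative 16S sequences travel as FASTA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CountMatrix",
    "SequenceSet",
    "FormatError",
    "ValidationError",
    "SITE_LEVELS",
    "INTERVENTION_LEVELS",
    "SEQRUN_LEVELS",
    "REQUIRED_METADATA_COLUMNS",
    "OPTIONAL_METADATA_COLUMNS",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "read_fasta",
    "write_fasta",
    "align_samples",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """In-memory data violates a domain invariant."""


# Category vocabularies (four enrollment sites, three supplement arms,
# four MiSeq runs).
SITE_LEVELS = ("lungwena", "malindi", "namwera", "mangochi")
INTERVENTION_LEVELS = ("IFA", "MMN", "LNS")
SEQRUN_LEVELS = ("run1", "run2", "run3", "run4")

REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "bop",
    "periodontitis",
    "site",
    "intervention",
    "hiv",
    "seqrun",
)
OPTIONAL_METADATA_COLUMNS = ("age", "bmi", "education", "ses", "anemia", "malaria")

_BOOL_COLUMNS = ("periodontitis", "hiv", "anemia", "malaria")
_TRUE_TOKENS = {"yes", "true", "1"}
_FALSE_TOKENS = {"no", "false", "0"}


@dataclass
class CountMatrix:
    """Non-negative integer taxon x sample read counts.

    ``counts[i, j]`` is the number of reads assigned to ``taxon_ids[i]``
    in ``sample_ids[j]``.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicate {name} ids: {dupes}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def select_taxa(self, taxa: Sequence[str]) -> "CountMatrix":
        index = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise ValidationError(f"unknown taxa: {missing}")
        rows = [index[t] for t in taxa]
        return CountMatrix(list(taxa), list(self.sample_ids), self.counts[rows])

    def select_samples(self, samples: Sequence[str]) -> "CountMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise ValidationError(f"unknown samples: {missing}")
        cols = [index[s] for s in samples]
        return CountMatrix(list(self.taxon_ids), list(samples), self.counts[:, cols])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SequenceSet:
    """Uppercase DNA sequences (A/C/G/T/N) keyed by unique record ids."""

    record_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.record_ids) != len(self.sequences):
            raise ValidationError("record_ids and sequences must align")
        if len(set(self.record_ids)) != len(self.record_ids):
            raise ValidationError("duplicate record ids")
        cleaned = []
        for rid, seq in zip(self.record_ids, self.sequences):
            seq = seq.upper()
            if not seq:
                raise ValidationError(f"empty sequence for record {rid!r}")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValidationError(
                    f"record {rid!r} contains non-DNA characters {sorted(bad)}"
                )
            cleaned.append(seq)
        self.sequences = cleaned

    def __len__(self) -> int:
        return len(self.record_ids)

    def __iter__(self):
        return iter(zip(self.record_ids, self.sequences))


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a taxon x sample count table.

    TSV layout: taxa as rows, first column the taxon id (header cell
    ``taxon_id``), remaining header cells the sample ids.  BIOM layout:
    version 1.0 JSON (sparse or dense).
    """
    path = Path(path)
    if format == "tsv":
        return _read_counts_tsv(path)
    if format in ("biom", "biom-json"):
        return _read_counts_biom(path)
    raise ValueError(f"unknown count-table format {format!r}")


def _read_counts_tsv(path: Path) -> CountMatrix:
    frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    taxa = [str(t) for t in frame.index]
    samples = [str(s) for s in frame.columns]
    counts = np.zeros((len(taxa), len(samples)), dtype=np.int64)
    for i, taxon in enumerate(taxa):
        for j, sample in enumerate(samples):
            cell = frame.iat[i, j]
            try:
                value = int(cell)
                if value < 0:
                    raise ValueError
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: cell ({taxon!r}, {sample!r}) = {cell!r} "
                    "is not a non-negative integer"
                ) from None
            counts[i, j] = value
    try:
        return CountMatrix(taxa, samples, counts)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_counts_biom(path: Path) -> CountMatrix:
    with open(path) as handle:
        doc = json.load(handle)
    taxa = [row["id"] for row in doc["rows"]]
    samples = [col["id"] for col in doc["columns"]]
    counts = np.zeros((len(taxa), len(samples)), dtype=np.int64)
    data = doc["data"]
    if doc.get("matrix_type") == "sparse":
        for i, j, v in data:
            if v != int(v) or v < 0:
                raise FormatError(
                    f"{path}: cell ({taxa[i]!r}, {samples[j]!r}) = {v!r} "
                    "is not a non-negative integer"
                )
            counts[i, j] = int(v)
    else:
        arr = np.asarray(data)
        if np.any(arr < 0) or not np.all(np.mod(arr, 1) == 0):
            raise FormatError(f"{path}: dense data contains non-integer or negative cells")
        counts = arr.astype(np.int64)
    try:
        return CountMatrix(taxa, samples, counts)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_count_table(matrix: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as handle:
            handle.write("taxon_id\t" + "\t".join(matrix.sample_ids) + "\n")
            for taxon, row in zip(matrix.taxon_ids, matrix.counts):
                handle.write(taxon + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
        return
    if format in ("biom", "biom-json"):
        rows_nz, cols_nz = np.nonzero(matrix.counts)
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "plaque-signals",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [matrix.n_taxa, matrix.n_samples],
            "rows": [{"id": t, "metadata": None} for t in matrix.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in matrix.sample_ids],
            "data": [
                [int(i), int(j), int(matrix.counts[i, j])]
                for i, j in zip(rows_nz, cols_nz)
            ],
        }
        with open(path, "w") as handle:
            json.dump(doc, handle)
        return
    raise ValueError(f"unknown count-table format {format!r}")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def _parse_bool(token: str, column: str, sample: str):
    low = str(token).strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise ValidationError(
        f"sample {sample!r}: cannot parse {column}={token!r} as yes/no"
    )


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate (and coerce) a metadata frame against the domain invariants."""
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"missing required metadata columns: {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"duplicate sample ids: {dupes}")

    bop = pd.to_numeric(meta["bop"], errors="coerce")
    bad = meta.loc[bop.isna() | (bop % 1 != 0) | (bop < 0) | (bop > 6), "sample_id"]
    if len(bad):
        raise ValidationError(
            f"bop must be an integer in 0..6; offending samples: {list(bad)[:5]}"
        )
    meta["bop"] = bop.astype(int)

    for col in _BOOL_COLUMNS:
        if col not in meta.columns:
            continue
        parsed = []
        for sid, value in zip(meta["sample_id"], meta[col]):
            if pd.isna(value) or (isinstance(value, str) and value.strip() == ""):
                parsed.append(pd.NA)
            elif isinstance(value, (bool, np.bool_)):
                parsed.append(bool(value))
            else:
                parsed.append(_parse_bool(value, col, sid))
        meta[col] = pd.array(parsed, dtype="boolean")
    if meta["periodontitis"].isna().any():
        bad = list(meta.loc[meta["periodontitis"].isna(), "sample_id"])[:5]
        raise ValidationError(f"periodontitis is required; missing for {bad}")

    for col, levels in (
        ("site", SITE_LEVELS),
        ("intervention", INTERVENTION_LEVELS),
        ("seqrun", SEQRUN_LEVELS),
    ):
        values = meta[col].astype(str)
        unknown = sorted(set(values) - set(levels))
        if unknown:
            raise ValidationError(f"unknown {col} labels: {unknown}")
        meta[col] = pd.Categorical(values, categories=levels)

    for col in ("age", "bmi", "education", "ses"):
        if col in meta.columns:
            meta[col] = pd.to_numeric(meta[col], errors="coerce")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata TSV.

    Missing optional fields are kept as NA (never imputed); modeling
    code is responsible for explicitly dropping incomplete records.
    """
    meta = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    meta = meta.replace({"": pd.NA})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map({True: "yes", False: "no"}, na_action="ignore")
    out.to_csv(Path(path), sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceSet:
    records = list(SeqIO.parse(str(path), "fasta"))
    return SequenceSet([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in seqs
    ]
    with open(path, "w") as handle:
        # 80-column wrapping is SeqIO's fasta default (60) overridden below
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=80)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Alignment of counts and metadata
# ---------------------------------------------------------------------------

def align_samples(
    counts: CountMatrix, meta: pd.DataFrame
) -> tuple[CountMatrix, pd.DataFrame, dict[str, list[str]]]:
    """Restrict counts and metadata to their shared samples, in count order.

    Returns the aligned pair plus a report of the ids dropped from each
    side.  Raises ``ValidationError`` if the intersection is empty.
    """
    meta_ids = set(meta["sample_id"])
    shared = [s for s in counts.sample_ids if s in meta_ids]
    if not shared:
        raise ValidationError("counts and metadata share no sample ids")
    dropped = {
        "counts": [s for s in counts.sample_ids if s not in meta_ids],
        "metadata": sorted(meta_ids - set(counts.sample_ids)),
    }
    aligned_counts = counts.select_samples(shared)
    aligned_meta = (
        meta.set_index("sample_id").loc[shared].reset_index()
    )
    return aligned_counts, aligned_meta, dropped
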