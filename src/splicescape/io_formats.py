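"""Readers and writers for the standard formats the pipeline touches.

Supported formats, all UTF-8 tab-separated text with LF line endings:

* Salmon ``quant.sf`` (Name, Length, EffectiveLength, TPM, NumReads),
* transcript-to-gene maps (2-3 column TSV, optional biotype),
* sample design tables (sample_id, phenotype),
* GMT gene-set collections,
* GCT "#1.2" expression matrices with companion CLS class files,
* plain result TSVs with explicit headers.

Extra ``quant.sf`` columns beyond the canonical five are ignored with a
logged warning. Transcript version suffixes (".N") are stripped before
tx2gene joins by default, since annotation-dialect drift between Gencode
and Ensembl identifiers is the most common join failure.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import (
    AbundanceTable,
    CountTable,
    FormatError,
    GeneSetCollection,
    SampleDesign,
    ValidationError,
)

logger = logging.getLogger(__name__)

QUANT_SF_COLUMNS = ("Name", "Length", "EffectiveLength", "TPM", "NumReads")

_VERSION_SUFFIX = re.compile(r"\.\d+$")


@dataclass(frozen=True)
class QuantRecord:
    """One transcript's quantification as emitted by Salmon."""

    transcript_id: str
    length: int
    effective_length: float
    tpm: float
    num_reads: float

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValidationError("empty transcript id")
        if self.length <= 0:
            raise ValidationError(f"{self.transcript_id}: length must be positive")
        if self.effective_length <= 0:
            raise ValidationError(
                f"{self.transcript_id}: effective length must be positive"
            )
        if self.tpm < 0:
            raise ValidationError(f"{self.transcript_id}: negative TPM")
        if self.num_reads < 0:
            raise ValidationError(f"{self.transcript_id}: negative read count")


def strip_version(transcript_id: str) -> str:
    """Drop a trailing Ensembl/Gencode ``.N`` version suffix."""
    return _VERSION_SUFFIX.sub("", transcript_id)


def read_quant_sf(path: str | Path) -> list[QuantRecord]:
    """Parse a Salmon ``quant.sf`` file into validated records.

    Raises :class:`FormatError` when a required column is missing and
    :class:`ValidationError` (with the line number) on invalid values.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a quant.sf header")
        header = header_line.rstrip("\n").split("\t")
        for col in QUANT_SF_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        extra = [c for c in header if c not in QUANT_SF_COLUMNS]
        if extra:
            logger.warning("%s: ignoring extra columns %s", path, extra)
        idx = {c: header.index(c) for c in QUANT_SF_COLUMNS}

        records: list[QuantRecord] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                rec = QuantRecord(
                    transcript_id=fields[idx["Name"]],
                    length=int(float(fields[idx["Length"]])),
                    effective_length=float(fields[idx["EffectiveLength"]]),
                    tpm=float(fields[idx["TPM"]]),
                    num_reads=float(fields[idx["NumReads"]]),
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if rec.transcript_id in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate transcript id {rec.transcript_id!r}"
                )
            seen.add(rec.transcript_id)
            records.append(rec)
    return records


def write_quant_sf(records: Iterable[QuantRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(QUANT_SF_COLUMNS) + "\n")
        # repr round-trips doubles exactly; fixtures must survive re-reading
        for r in records:
            fh.write(
                f"{r.transcript_id}\t{r.length}\t{r.effective_length!r}\t"
                f"{r.tpm!r}\t{r.num_reads!r}\n"
            )


def read_tx2gene(path: str | Path, strip_versions: bool = True) -> pd.DataFrame:
    """Read a 2-3 column transcript->gene TSV (optional third biotype column).

    Returns a DataFrame indexed by transcript id with columns ``gene_id`` and
    (possibly all-NA) ``biotype``.
    """
    path = Path(path)
    rows = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
            tx = strip_version(fields[0]) if strip_versions else fields[0]
            rows.append((tx, fields[1], fields[2] if len(fields) > 2 else None))
    if not rows:
        raise FormatError(f"{path}: empty tx2gene map")
    df = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "biotype"])
    dup = df["transcript_id"].duplicated()
    if dup.any():
        conflicting = df[df["transcript_id"].isin(df.loc[dup, "transcript_id"])]
        if conflicting.groupby("transcript_id")["gene_id"].nunique().gt(1).any():
            raise ValidationError(
                f"{path}: transcripts mapped to more than one gene"
            )
        df = df.drop_duplicates("transcript_id")
    return df.set_index("transcript_id")


def write_tx2gene(tx2gene: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        has_biotype = "biotype" in tx2gene.columns and tx2gene["biotype"].notna().any()
        for tx, row in tx2gene.iterrows():
            if has_biotype:
                fh.write(f"{tx}\t{row['gene_id']}\t{row['biotype']}\n")
            else:
                fh.write(f"{tx}\t{row['gene_id']}\n")


def read_design(path: str | Path) -> SampleDesign:
    """Read a two-column sample design TSV (sample_id, phenotype).

    A header line reading ``sample_id<TAB>phenotype`` is tolerated.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            if lineno == 1 and fields == ["sample_id", "phenotype"]:
                continue
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise FormatError(f"{path}: empty design table")
    return SampleDesign.from_pairs(pairs)


def write_design(design: SampleDesign, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tphenotype\n")
        for s, p in zip(design.samples, design.phenotypes):
            fh.write(f"{s}\t{p}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set collection (name, description, members...)."""
    path = Path(path)
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT lines need >= 3 fields (name, "
                    f"description, members...)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for name in collection:
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{collection.description(name)}\t{members}\n")


def write_gct_cls(
    matrix: pd.DataFrame,
    design: SampleDesign,
    gct_path: str | Path,
    cls_path: str | Path,
) -> None:
    """Write a features x samples matrix as GCT "#1.2" plus a CLS class file.

    Sample columns must match the design's samples exactly (order included).
    """
    if matrix.shape[0] == 0:
        raise ValidationError("refusing to write an empty GCT matrix")
    if tuple(matrix.columns) != design.samples:
        raise ValidationError("matrix columns do not match the design's samples")
    gct_path, cls_path = Path(gct_path), Path(cls_path)
    with gct_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(matrix.columns) + "\n")
        for name, row in matrix.iterrows():
            fh.write(f"{name}\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    classes = design.phenotype_names
    class_index = {p: i for i, p in enumerate(classes)}
    with cls_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{len(design)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(str(class_index[p]) for p in design.phenotypes) + "\n")


def read_gct(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected GCT version line '#1.2'")
        dims = fh.readline().split("\t")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"])
    if df.shape != (n_rows, n_cols):
        raise FormatError(f"{path}: dimension line does not match the matrix")
    return df


def assemble_abundance_table(
    per_sample: Mapping[str, list[QuantRecord]],
    tx2gene: pd.DataFrame,
    design: SampleDesign,
    biotype_filter: str | None = None,
    detection_threshold: float = 0.0,
    strip_versions: bool = True,
) -> AbundanceTable:
    """Join per-sample quantifications into one transcripts x samples table.

    Rows are restricted to transcripts that (a) match ``biotype_filter`` when
    one is given and (b) exceed ``detection_threshold`` TPM in at least one
    sample. A transcript absent from a sample's file gets TPM 0 in that
    column. Columns follow design order.
    """
    missing_samples = [s for s in design.samples if s not in per_sample]
    if missing_samples:
        raise ValidationError(f"samples in design but not provided: {missing_samples}")

    columns = {}
    for sample in design.samples:
        recs = per_sample[sample]
        ids = [
            strip_version(r.transcript_id) if strip_versions else r.transcript_id
            for r in recs
        ]
        columns[sample] = pd.Series([r.tpm for r in recs], index=ids, dtype=float)
    tpm = pd.DataFrame(columns).fillna(0.0)
    tpm = tpm[list(design.samples)]

    unmapped = tpm.index.difference(tx2gene.index)
    if len(unmapped):
        raise ValidationError(
            f"transcripts not present in the tx2gene map: {sorted(unmapped)[:10]}"
            + ("..." if len(unmapped) > 10 else "")
        )

    if biotype_filter is not None:
        biotypes = tx2gene["biotype"].reindex(tpm.index)
        tpm = tpm.loc[biotypes == biotype_filter]

    expressed = (tpm > detection_threshold).any(axis=1)
    tpm = tpm.loc[expressed]
    return AbundanceTable(tpm=tpm, tx2gene=tx2gene["gene_id"])


def read_counts_tsv(path: str | Path) -> CountTable:
    """Read a counts TSV: transcript_id, effective_length, then sample columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "effective_length" not in df.columns:
        raise FormatError(f"{path}: missing 'effective_length' column")
    eff = df["effective_length"].astype(float)
    counts = df.drop(columns=["effective_length"]).astype(np.int64)
    return CountTable(counts=counts, effective_length=eff)


def write_counts_tsv(table: CountTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(0, "effective_length", table.effective_length.reindex(out.index))
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t", lineterminator="\n")
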