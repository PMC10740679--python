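"""Detection and the degree-of-alternative-splicing (DAS) matrix.

The DAS of a gene in a sample is the number of its splice variants detected
in that sample — a per-gene summary of splicing complexity that is robust to
which particular isoform carries the expression. Detection means TPM
strictly above a threshold (default 0: any positive abundance counts, the
weakest assumption). The stable-expression filter keeps genes with at least
one detected transcript in *every* sample of a stated group; a stricter
per-transcript reading (one transcript detected throughout) is available via
``mode="transcript"``.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .containers import AbundanceTable, ValidationError


def detect(table: AbundanceTable, threshold: float = 0.0) -> pd.DataFrame:
    """Boolean transcripts x samples matrix: TPM strictly above ``threshold``."""
    if threshold < 0:
        raise ValidationError("detection threshold must be non-negative")
    return table.tpm > threshold


def das_matrix(detection: pd.DataFrame, tx2gene: pd.Series) -> pd.DataFrame:
    """Genes x samples integer matrix of detected splice variants per gene.

    Genes with no detected transcript in a sample get DAS 0 and stay as rows.
    """
    genes = tx2gene.reindex(detection.index)
    if genes.isna().any():
        missing = sorted(detection.index[genes.isna()])[:10]
        raise ValidationError(f"unmapped transcripts: {missing}")
    das = detection.astype(int).groupby(genes).sum()
    das.index.name = "gene_id"
    return das.astype(int)


def stable_genes(
    detection: pd.DataFrame,
    tx2gene: pd.Series,
    samples: Iterable[str] | None = None,
    mode: str = "gene",
) -> set[str]:
    """Genes stably expressed across ``samples`` (default: all samples).

    ``mode="gene"``: the gene counts as stable when at least one of its
    transcripts is detected in every listed sample (different transcripts may
    cover different samples). ``mode="transcript"``: some single transcript
    must be detected in every listed sample.
    """
    samples = list(samples) if samples is not None else list(detection.columns)
    if not samples:
        raise ValidationError("sample subset must be non-empty")
    unknown = [s for s in samples if s not in detection.columns]
    if unknown:
        raise ValidationError(f"unknown samples: {unknown}")
    sub = detection[samples]
    genes = tx2gene.reindex(detection.index)
    if genes.isna().any():
        missing = sorted(detection.index[genes.isna()])[:10]
        raise ValidationError(f"unmapped transcripts: {missing}")
    if mode == "gene":
        per_gene = sub.groupby(genes).any()  # gene detected in sample via any tx
        stable = per_gene.all(axis=1)
        return set(stable.index[stable])
    if mode == "transcript":
        tx_stable = sub.all(axis=1)
        return set(genes[tx_stable.to_numpy()].unique())
    raise ValueError(f"unknown stability mode: {mode!r}")
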