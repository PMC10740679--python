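"""Core in-memory containers shared by every pipeline stage.

The pipeline's central objects are thin, validated wrappers around pandas
structures: an :class:`AbundanceTable` (transcripts x samples TPM plus the
transcript-to-gene map), a :class:`CountTable` (integer read counts with
effective lengths, the substrate for rarefaction), a :class:`SampleDesign`
(ordered sample -> phenotype assignment) and a :class:`GeneSetCollection`
(named gene sets, GMT-shaped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Well-formed input violates a semantic invariant."""


@dataclass(frozen=True)
class SampleDesign:
    """Ordered assignment of samples to phenotypes.

    Column order of every downstream matrix follows ``samples``. At least two
    distinct phenotypes are required and sample ids must be unique.
    """

    samples: tuple[str, ...]
    phenotypes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.phenotypes):
            raise ValidationError("samples and phenotypes differ in length")
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if list(self.samples).count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if len(set(self.phenotypes)) < 2:
            raise ValidationError("a design needs >= 2 distinct phenotypes")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SampleDesign":
        pairs = list(pairs)
        return cls(tuple(s for s, _ in pairs), tuple(p for _, p in pairs))

    @property
    def phenotype_names(self) -> tuple[str, ...]:
        """Distinct phenotypes in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.phenotypes:
            seen.setdefault(p)
        return tuple(seen)

    def samples_of(self, phenotype: str) -> tuple[str, ...]:
        if phenotype not in self.phenotypes:
            raise KeyError(f"unknown phenotype: {phenotype!r}")
        return tuple(s for s, p in zip(self.samples, self.phenotypes) if p == phenotype)

    def phenotype_of(self, sample: str) -> str:
        try:
            return self.phenotypes[self.samples.index(sample)]
        except ValueError:
            raise KeyError(f"unknown sample: {sample!r}") from None

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class AbundanceTable:
    """Transcripts x samples TPM matrix joined to a transcript->gene map.

    ``tpm`` is indexed by transcript id with one column per sample in design
    order; ``tx2gene`` maps every row's transcript id to a gene id.
    """

    tpm: pd.DataFrame
    tx2gene: pd.Series

    def __post_init__(self) -> None:
        missing = self.tpm.index.difference(self.tx2gene.index)
        if len(missing):
            raise ValidationError(
                f"transcripts missing from tx2gene map: {sorted(missing)[:10]}"
            )
        if (self.tpm.to_numpy() < 0).any():
            raise ValidationError("negative TPM value in abundance table")

    @property
    def transcripts(self) -> pd.Index:
        return self.tpm.index

    @property
    def samples(self) -> pd.Index:
        return self.tpm.columns

    def gene_of(self) -> pd.Series:
        """Gene id for each transcript row, aligned to the table's index."""
        return self.tx2gene.reindex(self.tpm.index)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(sorted(self.gene_of().unique()))


@dataclass
class CountTable:
    """Transcripts x samples integer read counts with effective lengths."""

    counts: pd.DataFrame
    effective_length: pd.Series

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not pd.api.types.is_integer_dtype(self.counts.dtypes.iloc[0]) or any(
            not pd.api.types.is_integer_dtype(dt) for dt in self.counts.dtypes
        ):
            raise ValidationError("counts must be an integer matrix")
        if (arr < 0).any():
            raise ValidationError("negative count")
        eff = self.effective_length.reindex(self.counts.index)
        if eff.isna().any():
            missing = sorted(self.counts.index[eff.isna()])[:10]
            raise ValidationError(f"missing effective length for: {missing}")
        if (eff <= 0).any():
            raise ValidationError("effective lengths must be positive")

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class GeneSetCollection(Mapping[str, frozenset]):
    """Named gene sets with optional per-set descriptions (GMT semantics)."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def description(self, name: str) -> str:
        return self.descriptions.get(name, "")

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping emptied sets."""
        uni = frozenset(universe)
        kept = {n: m & uni for n, m in self.sets.items() if m & uni}
        return GeneSetCollection(
            dict(kept), {n: self.descriptions.get(n, "") for n in kept}
        )
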