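"""The tau graded specificity index over phenotype-mean abundances.

For a feature (a splice variant or a gene) with expression profile
components c_1..c_N, one per phenotype,

    tau = sum_i (1 - X_i) / (N - 1),    X_i = c_i / max_j c_j,

so tau = 0 for a perfectly uniform profile and tau = 1 for expression
confined to a single phenotype. Components are phenotype means of TPM;
gene-level components are the sums of the gene's splice-variant components
(for arithmetic means, sum-of-means equals mean-of-sums, so the order does
not matter).

tau = 1 is tested exactly: a component either is 0.0 or it is not, and X_i
is taken as 0 whenever the component is 0, so no float tolerance enters the
strict criterion. All-zero profiles have no defined normalization; their tau
is NaN and they are excluded from reports.

Classes: ubiquitous (tau < 0.15), specific (tau > 0.85), strict (tau = 1,
a subclass of specific reported separately), intermediate otherwise.
Strictly phenotype-specific selection additionally requires detection in
every sample of the feature's argmax phenotype.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import AbundanceTable, SampleDesign, ValidationError

TAU_UBIQUITOUS = 0.15
TAU_SPECIFIC = 0.85


def phenotype_means(table: AbundanceTable, design: SampleDesign) -> pd.DataFrame:
    """Features x phenotypes matrix of arithmetic-mean TPM per phenotype."""
    unknown = [s for s in design.samples if s not in table.tpm.columns]
    if unknown:
        raise ValidationError(f"design samples absent from table: {unknown}")
    cols = {}
    for pheno in design.phenotype_names:
        samples = list(design.samples_of(pheno))
        if not samples:
            raise ValidationError(f"phenotype {pheno!r} has no samples")
        cols[pheno] = table.tpm[samples].mean(axis=1)
    return pd.DataFrame(cols)


def gene_profiles(transcript_profiles: pd.DataFrame, tx2gene: pd.Series) -> pd.DataFrame:
    """Component-wise sum of a gene's splice-variant profiles."""
    genes = tx2gene.reindex(transcript_profiles.index)
    if genes.isna().any():
        missing = sorted(transcript_profiles.index[genes.isna()])[:10]
        raise ValidationError(f"unmapped transcripts: {missing}")
    out = transcript_profiles.groupby(genes).sum()
    out.index.name = "gene_id"
    return out


def tau(components) -> float:
    """Evaluate tau for one profile; NaN when all components are zero."""
    c = np.asarray(components, dtype=float)
    if c.ndim != 1 or c.size < 2:
        raise ValidationError("a profile needs >= 2 phenotype components")
    if (c < 0).any():
        raise ValidationError("negative profile component")
    m = c.max()
    if m == 0:
        return math.nan
    x = np.where(c == 0, 0.0, c / m)
    return float((1.0 - x).sum() / (c.size - 1))


def classify(tau_value: float) -> str:
    """Map a defined tau value to its specificity class."""
    if math.isnan(tau_value):
        raise ValidationError("tau is undefined for this profile")
    if tau_value == 1.0:
        return "strict"
    if tau_value > TAU_SPECIFIC:
        return "specific"
    if tau_value < TAU_UBIQUITOUS:
        return "ubiquitous"
    return "intermediate"


def tau_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-feature tau, argmax phenotype and class for a profile matrix.

    Features whose max component is shared by two or more phenotypes get a
    null ``argmax_phenotype`` (such features have tau < 1 and can never be
    strict). All-zero features get NaN tau and no class.
    """
    c = profiles.to_numpy(dtype=float)
    if (c < 0).any():
        raise ValidationError("negative profile component")
    m = c.max(axis=1)
    defined = m > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(c == 0, 0.0, c / m[:, None])
    taus = np.where(defined, (1.0 - x).sum(axis=1) / (c.shape[1] - 1), np.nan)

    is_max = c == m[:, None]
    unique_max = is_max.sum(axis=1) == 1
    argmax = np.where(
        defined & unique_max,
        np.asarray(profiles.columns)[c.argmax(axis=1)],
        None,
    )
    classes = [classify(t) if defined[i] else None for i, t in enumerate(taus)]
    return pd.DataFrame(
        {
            "tau": taus,
            "argmax_phenotype": argmax,
            "class": classes,
        },
        index=profiles.index,
    )


def strict_specific_features(
    records: pd.DataFrame,
    detection: pd.DataFrame,
    design: SampleDesign,
    level: str = "transcript",
    tx2gene: pd.Series | None = None,
) -> dict[str, set[str]]:
    """Strictly phenotype-specific features: tau = 1 plus stable detection.

    A feature is kept iff its tau is exactly 1 and it is detected in every
    sample of its argmax phenotype; at gene level "detected" means at least
    one of the gene's transcripts per sample (``tx2gene`` required).
    """
    if level == "gene":
        if tx2gene is None:
            raise ValidationError("gene-level selection needs a tx2gene map")
        genes = tx2gene.reindex(detection.index)
        det = detection.groupby(genes).any()
    elif level == "transcript":
        det = detection
    else:
        raise ValueError(f"unknown level: {level!r}")

    out: dict[str, set[str]] = {p: set() for p in design.phenotype_names}
    strict = records[records["tau"] == 1.0]
    for feature, row in strict.iterrows():
        pheno = row["argmax_phenotype"]
        if pheno is None or feature not in det.index:
            continue
        samples = list(design.samples_of(pheno))
        if det.loc[feature, samples].all():
            out[pheno].add(feature)
    return out


def venn_and_combined(
    gene_level_strict: Mapping[str, set[str]],
    transcript_level_strict: Mapping[str, set[str]],
    tx2gene: pd.Series,
) -> dict[str, dict]:
    """Per-phenotype comparison of the two strict gene subsets.

    For each phenotype: A = genes whose *integral* expression is strictly
    specific; B = genes owning at least one strictly specific splice variant.
    Reports the Venn regions |A\\B|, |B\\A|, |A∩B|, the combined set A∪B, the
    B\\A genes expressing exactly two strict splice variants, and the count
    of B\\A genes with three or more.
    """
    report: dict[str, dict] = {}
    for pheno, gene_set in gene_level_strict.items():
        tx_set = set(transcript_level_strict.get(pheno, set()))
        tx_counts: dict[str, int] = {}
        for tx in tx_set:
            g = tx2gene.get(tx)
            if g is None:
                raise ValidationError(f"unmapped strict transcript: {tx!r}")
            tx_counts[g] = tx_counts.get(g, 0) + 1
        b = set(tx_counts)
        a = set(gene_set)
        only_b = b - a
        two_variant = sorted(g for g in only_b if tx_counts[g] == 2)
        report[pheno] = {
            "gene_only": len(a - b),
            "transcript_only": len(only_b),
            "both": len(a & b),
            "combined": sorted(a | b),
            "combined_size": len(a | b),
            "two_variant_genes": two_variant,
            "three_or_more": sum(1 for g in only_b if tx_counts[g] >= 3),
        }
    return report
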