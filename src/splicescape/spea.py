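"""Splicing-based pathway enrichment analysis (SPEA).

SPEA is two-class gene-set enrichment run on the DAS matrix in place of an
expression matrix: genes are ranked by the signal-to-noise ratio of their
per-sample splice-variant counts between two phenotypes, a weighted
Kolmogorov-Smirnov running sum yields each set's enrichment score (ES), and
a gene-set permutation null (random member sets of the same size drawn from
the ranked list) yields the normalized score (NES), nominal p and FDR q. A
positive NES means the set's genes carry, on average, a higher degree of
alternative splicing in phenotype 1 than in phenotype 2.

Significance filter: |NES| > 1.5, nominal p < 0.05 and FDR q < 0.25.

Ranking metric
--------------
score(g) = (mu1 - mu2) / (sigma1' + sigma2') on DAS values, where each
sigma' is the sample standard deviation floored at 0.2*|mu| (0.2 when
mu = 0) — the floor used by two-class GSEA rankings to keep near-constant
genes from dominating. Groups of a single sample have no standard
deviation; ``metric="diff"`` (plain difference of means) covers that case.
Ties in score break lexicographically on gene id so runs are reproducible
bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import GeneSetCollection, SampleDesign, ValidationError

logger = logging.getLogger(__name__)

NES_MIN = 1.5
P_MAX = 0.05
FDR_MAX = 0.25


def snr_ranking(
    das: pd.DataFrame,
    design: SampleDesign,
    phenotype_1: str,
    phenotype_2: str,
    gene_filter: Iterable[str] | None = None,
    metric: str = "snr",
) -> pd.Series:
    """Rank genes by the two-class signal-to-noise ratio of their DAS values.

    Returns a Series of scores indexed by gene id, sorted descending with
    lexicographic tie-breaks. ``gene_filter`` (e.g. the stable-gene set)
    restricts the ranked universe.
    """
    for pheno in (phenotype_1, phenotype_2):
        if pheno not in design.phenotype_names:
            raise ValidationError(f"phenotype {pheno!r} not in design")
    s1 = list(design.samples_of(phenotype_1))
    s2 = list(design.samples_of(phenotype_2))

    sub = das
    if gene_filter is not None:
        keep = [g for g in das.index if g in set(gene_filter)]
        sub = das.loc[keep]

    a = sub[s1].to_numpy(dtype=float)
    b = sub[s2].to_numpy(dtype=float)
    mu1, mu2 = a.mean(axis=1), b.mean(axis=1)

    if metric == "snr":
        if len(s1) < 2 or len(s2) < 2:
            raise ValidationError(
                "signal-to-noise needs >= 2 samples per phenotype; "
                "use metric='diff' for single-sample groups"
            )
        sd1, sd2 = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
        sd1 = np.maximum(sd1, np.where(mu1 == 0, 0.2, 0.2 * np.abs(mu1)))
        sd2 = np.maximum(sd2, np.where(mu2 == 0, 0.2, 0.2 * np.abs(mu2)))
        scores = (mu1 - mu2) / (sd1 + sd2)
    elif metric == "diff":
        scores = mu1 - mu2
    else:
        raise ValueError(f"unknown metric: {metric!r}")

    ranked = pd.Series(scores, index=sub.index, name="score")
    order = sorted(ranked.index, key=lambda g: (-ranked[g], g))
    return ranked.loc[order]


@dataclass(frozen=True)
class EsResult:
    es: float
    running_sum: np.ndarray
    peak_index: int


def enrichment_score(
    ranked: pd.Series, members: Iterable[str], weight: float = 1.0
) -> EsResult:
    """Weighted KS enrichment score of ``members`` along a ranked list.

    Hits add |score|^weight normalized by the total hit weight; misses
    subtract 1/(n - n_hits). The ES is the running sum's maximum signed
    deviation from zero (positive branch wins exact ties).
    """
    members = set(members)
    is_member = np.asarray([g in members for g in ranked.index])
    n_hits = int(is_member.sum())
    if n_hits == 0:
        raise ValidationError("no gene-set member present in the ranked list")
    n = len(ranked)

    w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    # single-row batch keeps the observed ES bit-identical to the null's
    positions = np.flatnonzero(is_member)
    es = float(_es_batch(w, positions[None, :])[0])

    hit_total = w[is_member].sum()
    if hit_total == 0:
        increments = np.where(is_member, 1.0 / n_hits, 0.0)
    else:
        increments = np.where(is_member, w / hit_total, 0.0)
    decrement = 0.0 if n == n_hits else 1.0 / (n - n_hits)
    running = np.cumsum(np.where(is_member, increments, -decrement))
    peak = int(np.argmax(running)) if es >= 0 else int(np.argmin(running))
    return EsResult(es=es, running_sum=running, peak_index=peak)


def _es_batch(abs_w: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Vectorized ES for many same-size member sets given as sorted positions.

    The running sum is piecewise linear between hits, so its extremes occur
    just before or at hit positions; only those candidates are evaluated.
    """
    n = abs_w.shape[0]
    n_perm, k = positions.shape
    d = 0.0 if n == k else 1.0 / (n - k)

    hit_w = abs_w[positions]
    totals = hit_w.sum(axis=1, keepdims=True)
    zero_total = totals[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        inc = hit_w / totals
    if zero_total.any():
        inc[zero_total] = 1.0 / k

    h_after = np.cumsum(inc, axis=1)
    h_before = h_after - inc
    misses = positions - np.arange(k)  # misses preceding each hit
    after = h_after - misses * d
    before = h_before - misses * d

    pos_peak = after.max(axis=1)
    neg_peak = before.min(axis=1)
    return np.clip(np.where(pos_peak >= -neg_peak, pos_peak, neg_peak), -1.0, 1.0)


def gene_set_null(
    ranked: pd.Series,
    set_size: int,
    n_perm: int,
    seed: int | np.random.Generator = 0,
    weight: float = 1.0,
) -> np.ndarray:
    """ES null sample from ``n_perm`` uniformly drawn member sets of a size.

    This is the gene-set permutation null: membership is randomized, the
    ranking stays fixed. Deterministic under ``seed``.
    """
    n = len(ranked)
    if not 1 <= set_size <= n:
        raise ValidationError(f"set_size must be in [1, {n}]")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    abs_w = np.abs(ranked.to_numpy(dtype=float)) ** weight

    draws = rng.random((n_perm, n)).argpartition(set_size - 1, axis=1)[:, :set_size]
    draws.sort(axis=1)
    return _es_batch(abs_w, draws)


def nes_p_fdr(
    observed: Mapping[str, float],
    nulls: Mapping[str, np.ndarray],
    sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Normalize ES to NES and attach nominal p and FDR q per gene set.

    NES = ES / mean(|null ES of the same sign|); p is the same-sign null
    tail fraction with an add-one correction, (b+1)/(m+1). The q value
    compares the observed NES distribution against the pooled normalized
    null NES distribution, separately for each sign, and is clipped to
    [0, 1].
    """
    rows = {}
    pooled_pos: list[np.ndarray] = []
    pooled_neg: list[np.ndarray] = []
    for name, es in observed.items():
        null = np.asarray(nulls[name], dtype=float)
        pos = null[null >= 0]
        neg = null[null < 0]
        mean_pos = np.abs(pos).mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        if pos.size:
            pooled_pos.append(pos / mean_pos)
        if neg.size:
            pooled_neg.append(neg / mean_neg)

        side = pos if es >= 0 else neg
        side_mean = mean_pos if es >= 0 else mean_neg
        if side.size == 0 or not np.isfinite(side_mean) or side_mean == 0:
            nes, p = np.nan, np.nan
        else:
            nes = es / side_mean
            b = int((np.abs(side) >= abs(es)).sum())
            p = (b + 1) / (side.size + 1)
        rows[name] = {"es": es, "nes": nes, "p_nominal": p}

    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "set_name"
    if sizes is not None:
        df.insert(0, "size", [sizes[n] for n in df.index])

    null_pos = np.concatenate(pooled_pos) if pooled_pos else np.empty(0)
    null_neg = np.concatenate(pooled_neg) if pooled_neg else np.empty(0)
    obs = df["nes"].to_numpy()
    obs_pos = obs[np.isfinite(obs) & (obs >= 0)]
    obs_neg = obs[np.isfinite(obs) & (obs < 0)]

    qs = []
    for nes in df["nes"]:
        if not np.isfinite(nes):
            qs.append(np.nan)
            continue
        if nes >= 0:
            num = (null_pos >= nes).mean() if null_pos.size else np.nan
            den = (obs_pos >= nes).sum() / obs_pos.size if obs_pos.size else np.nan
        else:
            num = (null_neg <= nes).mean() if null_neg.size else np.nan
            den = (obs_neg <= nes).sum() / obs_neg.size if obs_neg.size else np.nan
        q = num / den if den and np.isfinite(den) else np.nan
        qs.append(float(min(max(q, 0.0), 1.0)) if np.isfinite(q) else np.nan)
    df["fdr_q"] = qs
    df["direction"] = np.where(df["es"] >= 0, "positive", "negative")
    df["significant"] = (
        (df["nes"].abs() > NES_MIN) & (df["p_nominal"] < P_MAX) & (df["fdr_q"] < FDR_MAX)
    ).fillna(False)
    return df


def spea(
    das: pd.DataFrame,
    design: SampleDesign,
    phenotype_1: str,
    phenotype_2: str,
    collection: GeneSetCollection,
    gene_filter: Iterable[str] | None = None,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    metric: str = "snr",
) -> pd.DataFrame:
    """Full SPEA for one phenotype pair against a gene-set collection.

    Null ES samples are shared between sets of equal size (the gene-set
    permutation null depends only on the set size), drawn deterministically
    from ``seed``.
    """
    ranked = snr_ranking(das, design, phenotype_1, phenotype_2, gene_filter, metric)
    universe = set(ranked.index)

    observed: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for name in collection:
        members = collection[name] & universe
        if not members:
            logger.warning("gene set %r has no member in the ranked list; skipped", name)
            continue
        observed[name] = enrichment_score(ranked, members, weight).es
        sizes[name] = len(members)

    rng = np.random.default_rng(seed)
    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted(set(sizes.values())):
        null_by_size[size] = gene_set_null(ranked, size, n_perm, rng, weight)
    nulls = {name: null_by_size[sizes[name]] for name in observed}

    records = nes_p_fdr(observed, nulls, sizes)
    records.attrs["pair"] = (phenotype_1, phenotype_2)
    return records


def spea_report(records: pd.DataFrame, pair_label: str) -> pd.DataFrame:
    """Signed pathway table for one phenotype pair, sorted by NES descending."""
    if records.empty:
        out = records.copy()
        out["pair"] = pd.Series(dtype=str)
        return out
    out = records.sort_values("nes", ascending=False, kind="mergesort").copy()
    out["pair"] = pair_label
    return out
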