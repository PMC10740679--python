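"""Sequencing-depth equalization by exact rarefaction of transcript counts.

Samples sequenced to different depths detect different numbers of splice
variants for purely technical reasons, which would bias any per-sample
isoform count. Depth is therefore equalized by subsampling every sample's
transcript counts *without replacement* down to a common target (the
smallest per-sample total by default), i.e. a multivariate hypergeometric
draw per sample. Unlike binomial thinning, this conserves the target total
exactly. TPM is then recomputed from the rarefied counts using Salmon's
effective-length convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AbundanceTable, CountTable, ValidationError


def downsample_counts(
    table: CountTable,
    target: int | str = "min",
    seed: int = 0,
    tx2gene: pd.Series | None = None,
) -> CountTable:
    """Rarefy every sample to exactly ``target`` total counts.

    ``target`` may be a positive integer or ``"min"`` (the smallest
    per-sample total). Each sample's counts are drawn without replacement
    from its original reads (multivariate hypergeometric), so the output
    totals equal the target exactly and no cell exceeds its original value.
    Deterministic under ``seed``.
    """
    totals = table.sample_totals
    if target == "min":
        target_n = int(totals.min())
    else:
        target_n = int(target)
        if target_n <= 0:
            raise ValidationError("target must be a positive integer or 'min'")
        too_small = totals[totals < target_n]
        if len(too_small):
            raise ValidationError(
                "target exceeds the total counts of sample(s): "
                + ", ".join(f"{s} ({int(t)})" for s, t in too_small.items())
            )
    rng = np.random.default_rng(seed)
    out = {}
    for sample in table.counts.columns:
        colors = table.counts[sample].to_numpy(dtype=np.int64)
        out[sample] = rng.multivariate_hypergeometric(colors, target_n)
    downsampled = pd.DataFrame(out, index=table.counts.index, dtype=np.int64)
    return CountTable(counts=downsampled, effective_length=table.effective_length)


def counts_to_tpm(table: CountTable, tx2gene: pd.Series | None = None) -> AbundanceTable:
    """Convert counts to TPM: rate_t = count_t / eff_len_t, scaled to 1e6.

    Every column with at least one positive count sums to 1e6. An all-zero
    sample has no defined normalization and raises.
    """
    eff = table.effective_length.reindex(table.counts.index).to_numpy(dtype=float)
    counts = table.counts.to_numpy(dtype=float)
    col_sums = counts.sum(axis=0)
    zero_cols = table.counts.columns[col_sums == 0]
    if len(zero_cols):
        raise ValidationError(
            f"cannot normalize all-zero sample(s): {list(zero_cols)}"
        )
    rates = counts / eff[:, None]
    tpm = rates / rates.sum(axis=0, keepdims=True) * 1e6
    tpm_df = pd.DataFrame(tpm, index=table.counts.index, columns=table.counts.columns)
    if tx2gene is None:
        # identity map lets the table stand alone when no annotation is given
        tx2gene = pd.Series(tpm_df.index, index=tpm_df.index, name="gene_id")
    return AbundanceTable(tpm=tpm_df, tx2gene=tx2gene)
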