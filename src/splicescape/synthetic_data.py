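"""Synthetic post-quantification fixtures with planted ground truth.

The generator emulates the layer a long-read quantification pipeline hands
to downstream analysis: per-sample ``quant.sf`` tables over an annotation of
genes with 1..K isoforms, a three-phenotype design with unequal replicate
counts (5/3/3 by default, mirroring a HepG2 / Huh7 / liver-tissue study
layout), log-normal abundance with per-sample multiplicative noise and a
hard detection-dropout threshold, plus two kinds of planted signal:

* strictly phenotype-specific isoforms — expressed above the dropout level
  in every sample of one phenotype and exactly zero elsewhere, the ground
  truth for tau = 1 recovery;
* DAS-shift gene sets — member genes gain a configured number of extra
  detected isoforms only in a target phenotype, the ground truth for SPEA.

Dropout is a hard threshold on the pre-normalization expression level (not
probabilistic), so the planted truth is exact by construction. Counts are
derived from abundances by inverting the TPM formula at a per-sample
library size with stochastic rounding (expressed cells floored at one read
so the detection pattern survives the count round-trip), and TPM is then
recomputed from the counts, keeping the two tables mutually consistent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .containers import (
    AbundanceTable,
    CountTable,
    GeneSetCollection,
    SampleDesign,
    ValidationError,
)
from .depth_norm import counts_to_tpm


@dataclass(frozen=True)
class DasShiftSpec:
    """A planted gene set whose members gain isoforms in one phenotype."""

    name: str
    n_genes: int
    extra_isoforms: int
    phenotype: str


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2500
    max_isoforms: int = 6
    phenotypes: tuple[tuple[str, int], ...] = (
        ("HepG2", 5),
        ("Huh7", 3),
        ("liver", 3),
    )
    log_mean: float = 1.5
    log_sd: float = 1.5
    noise_sd: float = 0.4
    dropout_tpm: float = 1.0
    n_specific_isoforms: int = 15
    das_shift_sets: tuple[DasShiftSpec, ...] = (
        DasShiftSpec("PLANTED_HEPG2_SHIFT", 20, 2, "HepG2"),
        DasShiftSpec("PLANTED_LIVER_SHIFT", 20, 2, "liver"),
    )
    n_null_sets: int = 20
    null_set_size: int = 20
    library_size: int = 120_000
    isoform_probs: tuple[float, ...] = (0.30, 0.25, 0.18, 0.12, 0.09, 0.06)
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.max_isoforms < 1:
            raise ValidationError("n_genes and max_isoforms must be positive")
        if self.log_sd <= 0 or self.noise_sd < 0:
            raise ValidationError("log_sd must be positive, noise_sd non-negative")
        if self.dropout_tpm < 0 or self.n_specific_isoforms < 0:
            raise ValidationError("dropout_tpm and n_specific_isoforms must be >= 0")
        names = {p for p, _ in self.phenotypes}
        for spec in self.das_shift_sets:
            if spec.phenotype not in names:
                raise ValidationError(
                    f"shift set {spec.name!r} targets unknown phenotype"
                )
            if spec.n_genes > self.n_genes:
                raise ValidationError(f"shift set {spec.name!r} larger than n_genes")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "phenotypes" in d:
            d["phenotypes"] = tuple((p["name"], p["n_samples"]) for p in d["phenotypes"])
        if "das_shift_sets" in d:
            d["das_shift_sets"] = tuple(
                DasShiftSpec(**s) for s in d["das_shift_sets"]
            )
        if "isoform_probs" in d:
            d["isoform_probs"] = tuple(d["isoform_probs"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted signals, exact by construction of the simulator.

    ``specific_transcripts`` covers every transcript expressed in exactly one
    phenotype — both the directly planted specific isoforms and the extra
    isoforms of DAS-shift genes (which satisfy the same invariant).
    """

    specific_transcripts: dict[str, str]
    shifted_sets: dict[str, tuple[str, str]]
    baseline_isoform_count: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "specific_transcripts": self.specific_transcripts,
            "shifted_sets": {k: list(v) for k, v in self.shifted_sets.items()},
            "baseline_isoform_count": self.baseline_isoform_count,
        }
        Path(path).write_text(
            json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            specific_transcripts=payload["specific_transcripts"],
            shifted_sets={k: tuple(v) for k, v in payload["shifted_sets"].items()},
            baseline_isoform_count=payload["baseline_isoform_count"],
        )


@dataclass
class SimulationOutput:
    annotation: pd.DataFrame
    counts: CountTable
    abundance: AbundanceTable
    design: SampleDesign
    truth: GroundTruth
    sets: GeneSetCollection
    config: SimulationConfig = field(repr=False, default=None)


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Draw a gene/isoform annotation: per-gene isoform counts are categorical.

    Returns a tx2gene DataFrame (index transcript_id; columns gene_id,
    biotype) with every biotype ``protein_coding``.
    """
    rng = np.random.default_rng([config.seed, 0])
    probs = np.asarray(config.isoform_probs[: config.max_isoforms], dtype=float)
    if probs.size < config.max_isoforms:
        probs = np.pad(probs, (0, config.max_isoforms - probs.size), constant_values=probs.min())
    probs = probs / probs.sum()
    n_iso = rng.choice(np.arange(1, config.max_isoforms + 1), size=config.n_genes, p=probs)
    rows = []
    for g in range(config.n_genes):
        gene = f"G{g:05d}"
        for i in range(n_iso[g]):
            rows.append((f"{gene}-{i + 1:03d}", gene, "protein_coding"))
    df = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "biotype"])
    return df.set_index("transcript_id")


def _build_design(config: SimulationConfig) -> SampleDesign:
    pairs = []
    for pheno, n in config.phenotypes:
        for k in range(1, n + 1):
            pairs.append((f"{pheno}_{k}", pheno))
    return SampleDesign.from_pairs(pairs)


def simulate_abundances(
    annotation: pd.DataFrame, config: SimulationConfig
) -> tuple[CountTable, AbundanceTable, SampleDesign, GroundTruth, GeneSetCollection]:
    """Generate the expression layer over an annotation with planted signal."""
    rng = np.random.default_rng([config.seed, 1])
    design = _build_design(config)
    transcripts = annotation.index.to_numpy()
    gene_of = annotation["gene_id"]
    n_tx, n_samples = len(transcripts), len(design)
    tx_pos = {t: i for i, t in enumerate(transcripts)}
    pheno_names = [p for p, _ in config.phenotypes]

    iso_count = gene_of.groupby(gene_of).size()

    # --- assign roles: shift-set members first, then specific isoforms
    shifted_sets: dict[str, tuple[str, str]] = {}
    set_members: dict[str, frozenset] = {}
    specific: dict[str, str] = {}  # transcript -> phenotype (only expressed there)
    used_genes: set[str] = set()
    for spec in config.das_shift_sets:
        eligible = sorted(
            g
            for g in iso_count.index
            if iso_count[g] >= spec.extra_isoforms + 1 and g not in used_genes
        )
        if len(eligible) < spec.n_genes:
            raise ValidationError(
                f"not enough genes with >= {spec.extra_isoforms + 1} isoforms "
                f"for shift set {spec.name!r}"
            )
        members = rng.choice(eligible, size=spec.n_genes, replace=False)
        used_genes.update(members)
        set_members[spec.name] = frozenset(members)
        shifted_sets[spec.name] = (spec.phenotype, "positive")
        for gene in members:
            gene_txs = sorted(annotation.index[gene_of == gene])
            for tx in gene_txs[-spec.extra_isoforms:]:  # last isoforms become extras
                specific[tx] = spec.phenotype

    free_txs = sorted(
        t for t in transcripts if t not in specific and gene_of[t] not in used_genes
    )
    for pheno in pheno_names:
        if config.n_specific_isoforms > len(free_txs):
            raise ValidationError(
                "not enough free transcripts to plant specific isoforms"
            )
        picked = rng.choice(free_txs, size=config.n_specific_isoforms, replace=False)
        for tx in picked:
            specific[tx] = pheno
        free_txs = [t for t in free_txs if t not in specific]

    baseline_isoform_count = {
        g: int(iso_count[g]) - sum(1 for t, _ in specific.items() if gene_of[t] == g)
        for g in iso_count.index
    }

    # --- expression levels: log-normal base, per-sample multiplicative noise
    base = rng.lognormal(config.log_mean, config.log_sd, size=n_tx)
    noise = rng.lognormal(0.0, config.noise_sd, size=(n_tx, n_samples)) if config.noise_sd > 0 else np.ones((n_tx, n_samples))
    expr = base[:, None] * noise
    expr[expr < config.dropout_tpm] = 0.0  # hard detection dropout

    pheno_cols = {
        p: [design.samples.index(s) for s in design.samples_of(p)] for p in pheno_names
    }
    # planted specifics are solidly expressed, like the stably detected
    # variants a strict-specificity screen would actually select
    specific_floor = float(np.exp(config.log_mean + config.log_sd))
    for tx, pheno in specific.items():
        i = tx_pos[tx]
        expr[i, :] = 0.0
        cols = pheno_cols[pheno]
        level = max(base[i], specific_floor)
        draw = level * (rng.lognormal(0.0, config.noise_sd, size=len(cols)) if config.noise_sd > 0 else 1.0)
        # strictly above the dropout level in every sample of the phenotype
        expr[i, cols] = np.maximum(draw, config.dropout_tpm * 1.5 + 1e-9)

    # --- transcript lengths and counts (invert TPM at a library size)
    lengths = rng.integers(500, 5001, size=n_tx)
    eff_len = (lengths - 150).astype(float)
    lib_sizes = rng.integers(
        int(0.85 * config.library_size), int(1.15 * config.library_size) + 1, size=n_samples
    )
    read_rates = expr * eff_len[:, None]  # reads proportional to level x length
    with np.errstate(invalid="ignore"):
        scaled = read_rates / read_rates.sum(axis=0, keepdims=True) * lib_sizes
    floors = np.floor(scaled)
    counts = (floors + (rng.random(scaled.shape) < (scaled - floors))).astype(np.int64)
    counts[(expr > 0) & (counts == 0)] = 1  # expressed cells keep >= 1 read

    # transcripts dropped out of every sample carry no information; keep the
    # tables free of all-zero rows (matching what quant.sf assembly retains)
    kept = counts.sum(axis=1) > 0
    count_table = CountTable(
        counts=pd.DataFrame(
            counts[kept], index=transcripts[kept], columns=list(design.samples)
        ),
        effective_length=pd.Series(
            eff_len[kept], index=transcripts[kept], name="effective_length"
        ),
    )
    abundance = counts_to_tpm(count_table, tx2gene=gene_of)

    # --- gene sets: planted shift sets plus random null sets
    descriptions = {name: "planted DAS shift" for name in set_members}
    all_genes = sorted(iso_count.index)
    for j in range(config.n_null_sets):
        name = f"NULL_{j:02d}"
        members = rng.choice(all_genes, size=min(config.null_set_size, len(all_genes)), replace=False)
        set_members[name] = frozenset(members)
        descriptions[name] = "random null set"
    collection = GeneSetCollection(dict(set_members), descriptions)

    truth = GroundTruth(
        specific_transcripts=dict(sorted(specific.items())),
        shifted_sets=shifted_sets,
        baseline_isoform_count=baseline_isoform_count,
    )
    return count_table, abundance, design, truth, collection


def simulate(config: SimulationConfig | None = None) -> SimulationOutput:
    """Annotation plus expression layer in one call."""
    config = config or SimulationConfig()
    annotation = simulate_annotation(config)
    counts, abundance, design, truth, sets = simulate_abundances(annotation, config)
    return SimulationOutput(annotation, counts, abundance, design, truth, sets, config)


def write_fixture_tree(
    output: SimulationOutput, directory: str | Path, force: bool = False
) -> None:
    """Materialize a simulation as files: one quant.sf per sample, tx2gene.tsv,
    design.tsv, truth.json, sets.gmt, counts.tsv and config.json.

    Floats are written with round-trippable precision, so re-reading through
    io_formats reproduces the in-memory tables exactly.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise ValidationError(
            f"{directory} exists and is not empty (pass force=True to overwrite)"
        )
    directory.mkdir(parents=True, exist_ok=True)

    lengths = output.counts.effective_length + 150
    for sample in output.design.samples:
        records = [
            io_formats.QuantRecord(
                transcript_id=tx,
                length=int(lengths[tx]),
                effective_length=float(output.counts.effective_length[tx]),
                tpm=float(output.abundance.tpm.loc[tx, sample]),
                num_reads=float(output.counts.counts.loc[tx, sample]),
            )
            for tx in output.abundance.tpm.index
        ]
        io_formats.write_quant_sf(records, directory / f"{sample}.quant.sf")

    io_formats.write_tx2gene(output.annotation, directory / "tx2gene.tsv")
    io_formats.write_design(output.design, directory / "design.tsv")
    io_formats.write_gmt(output.sets, directory / "sets.gmt")
    io_formats.write_counts_tsv(output.counts, directory / "counts.tsv")
    output.truth.to_json(directory / "truth.json")
    cfg = dataclasses.asdict(output.config) if output.config else {}
    (directory / "config.json").write_text(
        json.dumps(cfg, indent=1, sort_keys=True, default=list) + "\n", encoding="utf-8"
    )
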