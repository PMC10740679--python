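"""End-to-end orchestration: rarefy, profile, classify, enrich, report.

``run_all`` sequences the stages over a directory of per-sample ``quant.sf``
files plus ``tx2gene.tsv``, ``design.tsv`` and ``sets.gmt``:

1. downsample — rarefy counts to the minimal (or configured) depth,
2. das — detection matrix and genes x samples DAS matrix (+ GCT/CLS export),
3. tau — per-transcript and per-gene specificity index and classes,
4. spea — all pairwise phenotype comparisons over the gene-set collection,
5. combine — strict-specific selection, Venn regions, combined per-phenotype
   gene sets and the two-splice-variant gene list,
6. ora — over-representation of each combined set against the collection.

Every stage logs to stderr with a stage-scoped prefix and the run ends with
a JSON manifest (parameters, seeds, sha256 of every output) from which the
run can be replayed byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import das_profile, depth_norm, io_formats, tau_specificity
from .ora import ora as run_ora
from .spea import spea as run_spea, spea_report
from .containers import CountTable, SampleDesign, ValidationError

logger = logging.getLogger("splicescape.pipeline")


@dataclass
class PipelineConfig:
    input_dir: str
    out_dir: str
    detection_threshold: float = 0.0
    biotype_filter: str | None = "protein_coding"
    downsample_target: int | str = "min"
    stable_mode: str = "gene"
    n_perm: int = 1000
    nes_min: float = 1.5
    p_max: float = 0.05
    fdr_max: float = 0.25
    es_weight: float = 1.0
    metric: str = "snr"
    seed_downsample: int = 17
    seed_spea: int = 7

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if not 0 <= self.p_max <= 1:
            raise ValidationError("p_max must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_inputs(
    input_dir: str | Path, design: SampleDesign | None = None
) -> tuple[CountTable, pd.DataFrame, SampleDesign, "io_formats.GeneSetCollection"]:
    """Read a fixture/quantification tree into counts, tx2gene, design, sets."""
    input_dir = Path(input_dir)
    design = design or io_formats.read_design(input_dir / "design.tsv")
    tx2gene = io_formats.read_tx2gene(input_dir / "tx2gene.tsv")
    sets = io_formats.read_gmt(input_dir / "sets.gmt")

    counts_cols: dict[str, pd.Series] = {}
    eff: dict[str, float] = {}
    for sample in design.samples:
        path = input_dir / f"{sample}.quant.sf"
        if not path.exists():
            raise ValidationError(f"missing quantification file for sample {sample!r}")
        records = io_formats.read_quant_sf(path)
        ids = [io_formats.strip_version(r.transcript_id) for r in records]
        counts_cols[sample] = pd.Series(
            [round(r.num_reads) for r in records], index=ids, dtype="int64"
        )
        for tx, record in zip(ids, records):
            eff.setdefault(tx, record.effective_length)
    counts = pd.DataFrame(counts_cols).fillna(0).astype("int64")
    counts = counts[list(design.samples)]
    table = CountTable(
        counts=counts,
        effective_length=pd.Series(eff, name="effective_length").reindex(counts.index),
    )
    return table, tx2gene, design, sets


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }

    def finish_stage(name: str, outputs: list[Path], seed: int | None = None) -> None:
        for p in outputs:
            if not p.exists() or p.stat().st_size == 0:
                raise RuntimeError(f"stage {name}: output {p} missing or empty")
        manifest["stages"].append(
            {
                "name": name,
                "seed": seed,
                "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
            }
        )
        logger.info("[%s] done (%d outputs)", name, len(outputs))

    counts, tx2gene, design, sets = load_inputs(config.input_dir)

    # --- stage 1: depth equalization
    stage = "downsample"
    try:
        rarefied = depth_norm.downsample_counts(
            counts, target=config.downsample_target, seed=config.seed_downsample
        )
        counts_path = out_dir / "counts_downsampled.tsv"
        io_formats.write_counts_tsv(rarefied, counts_path)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed on {config.input_dir}: {exc}") from exc
    finish_stage(stage, [counts_path], config.seed_downsample)

    abundance = depth_norm.counts_to_tpm(rarefied, tx2gene=tx2gene["gene_id"])
    if config.biotype_filter is not None and tx2gene["biotype"].notna().any():
        keep = tx2gene["biotype"].reindex(abundance.tpm.index) == config.biotype_filter
        abundance.tpm = abundance.tpm.loc[keep.to_numpy()]
    abundance.tpm = abundance.tpm.loc[
        (abundance.tpm > config.detection_threshold).any(axis=1)
    ]

    # --- stage 2: detection and DAS
    stage = "das"
    detection = das_profile.detect(abundance, config.detection_threshold)
    das = das_profile.das_matrix(detection, abundance.tx2gene)
    das_path = out_dir / "das_matrix.tsv"
    das.to_csv(das_path, sep="\t", lineterminator="\n")
    gct_path, cls_path = out_dir / "das_matrix.gct", out_dir / "das_matrix.cls"
    io_formats.write_gct_cls(das, design, gct_path, cls_path)
    finish_stage(stage, [das_path, gct_path, cls_path])

    # --- stage 3: tau specificity
    stage = "tau"
    tx_profiles = tau_specificity.phenotype_means(abundance, design)
    gene_profiles = tau_specificity.gene_profiles(tx_profiles, abundance.tx2gene)
    tau_tx = tau_specificity.tau_table(tx_profiles)
    tau_genes = tau_specificity.tau_table(gene_profiles)
    tau_outputs = []
    for label, profiles, table in (
        ("transcripts", tx_profiles, tau_tx),
        ("genes", gene_profiles, tau_genes),
    ):
        path = out_dir / f"tau_{label}.tsv"
        pd.concat([profiles, table], axis=1).to_csv(
            path, sep="\t", lineterminator="\n"
        )
        tau_outputs.append(path)
    finish_stage(stage, tau_outputs)

    # --- stage 4: SPEA over all phenotype pairs
    stage = "spea"
    spea_outputs = []
    for p1, p2 in itertools.combinations(design.phenotype_names, 2):
        union_samples = list(design.samples_of(p1)) + list(design.samples_of(p2))
        stable = das_profile.stable_genes(
            detection, abundance.tx2gene, union_samples, mode=config.stable_mode
        )
        try:
            records = run_spea(
                das,
                design,
                p1,
                p2,
                sets,
                gene_filter=stable,
                n_perm=config.n_perm,
                weight=config.es_weight,
                seed=config.seed_spea,
                metric=config.metric,
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed on pair {p1}/{p2}: {exc}") from exc
        records["significant"] = (
            (records["nes"].abs() > config.nes_min)
            & (records["p_nominal"] < config.p_max)
            & (records["fdr_q"] < config.fdr_max)
        ).fillna(False)
        report = spea_report(records, f"{p1}_vs_{p2}")
        path = out_dir / f"spea_{p1}_vs_{p2}.tsv"
        report.to_csv(path, sep="\t", lineterminator="\n")
        spea_outputs.append(path)
    finish_stage(stage, spea_outputs, config.seed_spea)

    # --- stage 5: strict-specific selection, Venn regions, combined sets
    stage = "combine"
    strict_tx = tau_specificity.strict_specific_features(
        tau_tx, detection, design, level="transcript"
    )
    strict_genes = tau_specificity.strict_specific_features(
        tau_genes, detection, design, level="gene", tx2gene=abundance.tx2gene
    )
    venn = tau_specificity.venn_and_combined(strict_genes, strict_tx, abundance.tx2gene)
    venn_path = out_dir / "venn_report.json"
    venn_path.write_text(
        json.dumps(venn, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    combined_dir = out_dir / "combined_sets"
    combined_dir.mkdir(exist_ok=True)
    combine_outputs = [venn_path]
    for pheno, report in venn.items():
        path = combined_dir / f"{pheno}.txt"
        path.write_text("\n".join(report["combined"]) + "\n", encoding="utf-8")
        if report["combined"]:
            combine_outputs.append(path)
    two_var_path = out_dir / "two_variant_genes.tsv"
    with two_var_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("phenotype\tgene_id\n")
        for pheno, report in venn.items():
            for gene in report["two_variant_genes"]:
                fh.write(f"{pheno}\t{gene}\n")
    combine_outputs.append(two_var_path)
    finish_stage(stage, combine_outputs)

    # --- stage 6: over-representation of the combined sets
    stage = "ora"
    universe = set(abundance.gene_of().unique())
    ora_outputs = []
    for pheno, report in venn.items():
        query = set(report["combined"]) & universe
        path = out_dir / f"ora_{pheno}.tsv"
        if not query:
            logger.warning("[ora] phenotype %s has an empty combined set", pheno)
            continue
        records, _top = run_ora(query, sets, universe)
        records.to_csv(path, sep="\t", index=False, lineterminator="\n")
        ora_outputs.append(path)
    finish_stage(stage, ora_outputs)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
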