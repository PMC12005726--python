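"""Run orchestration: count → score → synergy, with manifests.

Each stage writes delimited-text tables plus a ``manifest.json`` recording
the parameters, seed, input checksums, and package version — enough to
reproduce the run byte for byte.  Configuration comes from a YAML file
and/or keyword overrides; CLI flags take precedence over the config file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .counting import (
    AnchorConfig,
    PairCountMatrix,
    count_pairs,
    representation_qc,
)
from .errors import InputError
from .interaction import HitCriteria, InteractionConfig, score_interactions
from .library import load_library
from .phenotype import PhenotypeConfig, score_phenotypes
from .simulate import SimConfig, simulate_counts, simulate_fastq
from .synergy import (
    TumorSeries,
    bliss_excess_matrix,
    bliss_expected_tumor,
    knockout_validation_table,
    read_dose_matrix,
    write_bliss_report,
)


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputError("config file must contain a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, stage: str, params: dict, inputs: dict[str, Path]) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "parameters": params,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))} for name, p in inputs.items()
        },
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_counts(matrix: PairCountMatrix, counts_path: Path, samples_path: Path) -> None:
    matrix.counts.reset_index().to_csv(counts_path, sep="\t", index=False)
    matrix.samples.reset_index().to_csv(samples_path, sep="\t", index=False)


def read_counts(counts_path: str | Path, samples_path: str | Path) -> PairCountMatrix:
    counts_path, samples_path = Path(counts_path), Path(samples_path)
    for p in (counts_path, samples_path):
        if not p.exists():
            raise InputError(f"file not found: {p}")
    counts = pd.read_csv(counts_path, sep="\t").set_index(["sgrna_1", "sgrna_2"])
    samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
    return PairCountMatrix(counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# stages


def run_count(
    library: str | Path,
    sample_sheet: str | Path,
    out_dir: str | Path,
    anchor: AnchorConfig | None = None,
    min_sgrna_pairs: int = 6,
    log10_rpm_threshold: float = 0.5,
) -> dict[str, Path]:
    """Count every sample's FASTQ pair and write counts + representation QC.

    The sample sheet needs columns sample_id, timepoint, replicate,
    fastq_1, fastq_2.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    anchor = anchor or AnchorConfig()
    design = load_library(library)
    sheet = pd.read_csv(Path(sample_sheet), sep=None, engine="python")
    required = {"sample_id", "timepoint", "replicate", "fastq_1", "fastq_2"}
    missing = required - set(sheet.columns)
    if missing:
        raise InputError(f"sample sheet missing columns: {sorted(missing)}")

    cols = {}
    unmatched = {}
    inputs = {"library": Path(library), "sample_sheet": Path(sample_sheet)}
    for row in sheet.itertuples(index=False):
        for fq in (row.fastq_1, row.fastq_2):
            if not Path(fq).exists():
                raise InputError(f"FASTQ file not found: {fq}")
        col, stats = count_pairs(row.fastq_1, row.fastq_2, anchor, design)
        cols[row.sample_id] = col
        unmatched[row.sample_id] = stats
        inputs[f"fastq_1:{row.sample_id}"] = Path(row.fastq_1)
        inputs[f"fastq_2:{row.sample_id}"] = Path(row.fastq_2)

    matrix = PairCountMatrix(
        counts=pd.DataFrame(cols),
        samples=sheet.set_index("sample_id")[["timepoint", "replicate"]],
        unmatched=unmatched,
    )
    counts_path = out_dir / "counts.tsv"
    samples_path = out_dir / "samples.tsv"
    write_counts(matrix, counts_path, samples_path)

    qc = representation_qc(
        matrix, design, min_sgrna_pairs=min_sgrna_pairs,
        log10_rpm_threshold=log10_rpm_threshold,
    )
    qc_path = out_dir / "representation_qc.tsv"
    qc.per_gene_pair.rename("n_sgrna_pairs_passing").reset_index().to_csv(
        qc_path, sep="\t", index=False
    )
    (out_dir / "qc_summary.txt").write_text(
        qc.summary()
        + "\n"
        + "\n".join(
            f"{s}: {st['matched']}/{st['total_reads']} matched "
            f"({st['anchor_not_found']} anchor misses, {st['spacer_unknown']} unknown spacers)"
            for s, st in unmatched.items()
        )
        + "\n"
    )
    manifest = _write_manifest(
        out_dir,
        "count",
        {
            "anchor": dataclasses.asdict(anchor),
            "min_sgrna_pairs": min_sgrna_pairs,
            "log10_rpm_threshold": log10_rpm_threshold,
        },
        inputs,
    )
    return {
        "counts": counts_path,
        "samples": samples_path,
        "qc": qc_path,
        "manifest": manifest,
    }


def run_score(
    library: str | Path,
    counts: str | Path,
    samples: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    n_perm: int = 999,
    k_neighbors: int = 200,
    pseudocount: float = 1.0,
    min_d0_log10_rpm: float = 0.5,
    null_scale: str = "mad",
    gi_cutoff: float = -2.0,
    p_cutoff: float = 0.01,
    z_cutoff: float = -5.0,
) -> dict[str, Path]:
    """Phenotype + GI scoring from a count matrix; writes all tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if n_perm > 0 and seed is None:
        raise InputError("a seed is required when permutation testing is enabled")
    design = load_library(library)
    matrix = read_counts(counts, samples)

    pheno = score_phenotypes(
        matrix,
        design,
        PhenotypeConfig(
            pseudocount=pseudocount,
            min_d0_log10_rpm=min_d0_log10_rpm,
            null_scale=null_scale,
        ),
    )
    gi = score_interactions(
        pheno,
        design,
        InteractionConfig(
            k_neighbors=k_neighbors,
            n_perm=n_perm,
            seed=seed,
            criteria=HitCriteria(gi_cutoff=gi_cutoff, p_cutoff=p_cutoff, z_cutoff=z_cutoff),
        ),
    )

    paths = {}
    paths["phenotype_sgrna"] = out_dir / "phenotype_sgrna_pairs.tsv"
    pheno.z_sym.rename("z_sym").reset_index().to_csv(
        paths["phenotype_sgrna"], sep="\t", index=False
    )
    paths["phenotype_gene"] = out_dir / "phenotype_gene_pairs.tsv"
    pheno.gene.reset_index().to_csv(paths["phenotype_gene"], sep="\t", index=False)
    paths["gi_sgrna"] = out_dir / "gi_sgrna_pairs.tsv"
    gi.sgrna.reset_index().to_csv(paths["gi_sgrna"], sep="\t", index=False)
    paths["gi_gene"] = out_dir / "gi_gene_pairs.tsv"
    gi.gene.reset_index().to_csv(paths["gi_gene"], sep="\t", index=False)
    paths["hits"] = out_dir / "hits.tsv"
    gi.hits.reset_index().to_csv(paths["hits"], sep="\t", index=False)

    paths["manifest"] = _write_manifest(
        out_dir,
        "score",
        {
            "seed": seed,
            "n_perm": n_perm,
            "k_neighbors": k_neighbors,
            "pseudocount": pseudocount,
            "min_d0_log10_rpm": min_d0_log10_rpm,
            "null_scale": null_scale,
            "cutoffs": {"gi": gi_cutoff, "p": p_cutoff, "z": z_cutoff},
            "quadratic_fit_gene": gi.fit_gene.coefficients,
            "quadratic_fit_sgrna": gi.fit_sgrna.coefficients,
            "null_stats": pheno.null_stats.to_dict(orient="index"),
        },
        {"library": Path(library), "counts": Path(counts), "samples": Path(samples)},
    )
    return paths


def run_synergy(
    out_dir: str | Path,
    dose_matrix: str | Path | None = None,
    knockout_fc: str | Path | None = None,
    tumor_series: str | Path | None = None,
) -> dict[str, Path]:
    """Bliss analyses for whichever validation inputs are provided."""
    if dose_matrix is None and knockout_fc is None and tumor_series is None:
        raise InputError("provide at least one synergy input")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    inputs: dict[str, Path] = {}

    if dose_matrix is not None:
        m = read_dose_matrix(dose_matrix)
        res = bliss_excess_matrix(m)
        paths["dose_report"] = out_dir / "bliss_dose_report.tsv"
        write_bliss_report(res, paths["dose_report"])
        (out_dir / "bliss_dose_summary.txt").write_text(
            f"mean Bliss excess: {res.mean_synergy_pct:.2f} percentage points\n"
        )
        inputs["dose_matrix"] = Path(dose_matrix)

    if knockout_fc is not None:
        df = pd.read_csv(Path(knockout_fc), sep=None, engine="python")
        out = knockout_validation_table(df)
        paths["knockout_report"] = out_dir / "knockout_synergy.tsv"
        out.to_csv(paths["knockout_report"], sep="\t", index=False)
        inputs["knockout_fc"] = Path(knockout_fc)

    if tumor_series is not None:
        df = pd.read_csv(Path(tumor_series), sep=None, engine="python")
        series = TumorSeries(data=df)
        out = bliss_expected_tumor(series)
        paths["tumor_report"] = out_dir / "tumor_bliss.tsv"
        out.reset_index().to_csv(paths["tumor_report"], sep="\t", index=False)
        inputs["tumor_series"] = Path(tumor_series)

    paths["manifest"] = _write_manifest(out_dir, "synergy", {}, inputs)
    return paths


def run_simulate(
    out_dir: str | Path,
    seed: int,
    sim: SimConfig | None = None,
    emit_fastq: bool = False,
    anchor: AnchorConfig | None = None,
    read_len: int = 60,
    error_rate: float = 0.0,
) -> dict[str, Path]:
    """Simulate a screen; write counts, truth tables, and optionally FASTQ."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = sim or SimConfig(seed=seed)
    if sim is not None and sim.seed != seed:
        cfg = dataclasses.replace(sim, seed=seed)
    matrix, truth = simulate_counts(cfg)

    from .library import write_library

    paths: dict[str, Path] = {}
    paths["counts"] = out_dir / "counts.tsv"
    paths["samples"] = out_dir / "samples.tsv"
    write_counts(matrix, paths["counts"], paths["samples"])
    paths["truth_pairs"] = out_dir / "truth_pairs.tsv"
    truth.pairs.reset_index().to_csv(paths["truth_pairs"], sep="\t", index=False)
    paths["truth_genes"] = out_dir / "truth_gene_fitness.tsv"
    truth.gene_fitness.rename_axis("gene").rename("fitness").reset_index().to_csv(
        paths["truth_genes"], sep="\t", index=False
    )

    design = truth.design
    write_library(design, out_dir / "library.tsv")
    paths["library"] = out_dir / "library.tsv"

    if emit_fastq:
        a = anchor or AnchorConfig()
        for sample in matrix.counts.columns:
            fq1 = out_dir / f"{sample}_1.fastq.gz"
            fq2 = out_dir / f"{sample}_2.fastq.gz"
            simulate_fastq(
                matrix.counts[sample], design, a, fq1, fq2,
                read_len=read_len, error_rate=error_rate, seed=seed,
            )
            paths[f"fastq:{sample}"] = fq1

    params = dataclasses.asdict(cfg)
    params["interactions"] = {f"{a}|{b}": v for (a, b), v in (cfg.interactions or {}).items()}
    paths["manifest"] = _write_manifest(out_dir, "simulate", params, {})
    return paths
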