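"""Command-line pipeline: simulate → score → associate.

Thin orchestration over the library: each subcommand reads/writes TSV (and
VCF for genotypes), records a JSON run manifest with input digests, seeds
and per-stage in/out counts, and exits non-zero with the failing stage named
on error.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import click
import pandas as pd
import yaml

from . import __version__
from .association import CohortTable, VitaminDGrsModel, genotype_distribution_test
from .qc import DosageMatrix, apply_qc, read_genotypes, sample_qc, variant_qc
from .score import score_cohort
from .simulate import SimConfig, simulate_cohort, study_preset, ukb_preset
from .weights import WeightTable, load_weight_table, packaged_weight_table

logger = logging.getLogger("vdgrs")

PRESETS = {"study": study_preset, "ukb": ukb_preset}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, stage: str, *, inputs=(), seed=None, counts=None, config=None) -> Path:
    manifest = {
        "stage": stage,
        "vdgrs_version": __version__,
        "seed": seed,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "counts": counts or {},
        "config": config,
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def write_vcf(matrix: DosageMatrix, path) -> None:
    """Write hard-call genotypes as a minimal VCF 4.2 (GT only).

    ALT is the stored effect-allele orientation; pseudo-positions are
    assigned sequentially on chromosome 1 (rsid matching is by ID).
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.sample_ids),
    ]
    for i, rid in enumerate(matrix.variant_ids):
        meta = matrix.variant_meta.loc[rid]
        dosages = matrix.dosages[rid].to_numpy()
        gts = []
        for d in dosages:
            if pd.isna(d):
                gts.append("./.")
            else:
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(round(d))])
        lines.append(
            f"1\t{1000 * (i + 1)}\t{rid}\t{meta['ref']}\t{meta['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_sim_config(path) -> SimConfig:
    """Build a SimConfig from YAML: optional ``preset`` key plus overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    preset_name = raw.pop("preset", None)
    preset_kwargs = raw.pop("preset_args", {})
    if preset_name is not None:
        if preset_name not in PRESETS:
            raise click.ClickException(f"unknown preset {preset_name!r}; choose from {sorted(PRESETS)}")
        cfg = PRESETS[preset_name](**preset_kwargs)
    else:
        cfg = SimConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise click.ClickException(f"unknown config key {key!r}")
        setattr(cfg, key, value)
    try:
        cfg.validate()
    except ValueError as exc:
        raise click.ClickException(f"invalid config: {exc}") from exc
    return cfg


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=[logging.StreamHandler(), logging.FileHandler(out_dir / "vdgrs.log")],
        force=True,
    )


@click.group()
@click.version_option(__version__)
def main() -> None:
    """6-SNP vitamin D genetic risk score pipeline."""


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML config (preset + overrides); defaults to the study preset.")
@click.option("--seed", type=int, default=None, help="Override the config seed.")
@click.option("--out", "out_dir", type=click.Path(), required=True)
def simulate(config_path, seed, out_dir) -> None:
    """Generate a synthetic cohort: genotypes.vcf + phenotypes.tsv."""
    out = Path(out_dir)
    _setup_logging(out)
    cfg = load_sim_config(config_path) if config_path else study_preset()
    if seed is not None:
        cfg.seed = seed
    matrix, cohort = simulate_cohort(cfg)
    write_vcf(matrix, out / "genotypes.vcf")
    cohort.frame.drop(columns=["log_dose"]).to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    write_manifest(out, "simulate", seed=cfg.seed, config=asdict(cfg),
                   counts={"samples": matrix.n_samples, "variants": matrix.n_variants})
    click.echo(f"wrote {matrix.n_samples} samples x {matrix.n_variants} variants to {out}")


@main.command()
@click.option("--vcf", "vcf_path", type=click.Path(exists=True), required=True)
@click.option("--weights", "weights_path", type=click.Path(exists=True), default=None,
              help="Weight TSV; defaults to the packaged 6-SNP panel.")
@click.option("--allow-palindromic", multiple=True, default=("rs8018720",), show_default=True,
              help="rsids whose A/T–C/G strand ambiguity is accepted.")
@click.option("--missing-policy", type=click.Choice(["mean_impute", "skip_variant", "drop_sample"]),
              default="mean_impute", show_default=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def score(vcf_path, weights_path, allow_palindromic, missing_policy, out_dir) -> None:
    """QC genotypes and compute Z-scored GRS per sample."""
    out = Path(out_dir)
    _setup_logging(out)
    try:
        weights = load_weight_table(weights_path) if weights_path else packaged_weight_table()
        matrix = read_genotypes(vcf_path, weights, allow_palindromic=allow_palindromic)
        vrep = variant_qc(matrix)
        srep = sample_qc(matrix)
        vrep.to_tsv(out / "variant_qc.tsv")
        srep.to_tsv(out / "sample_qc.tsv")
        filtered = apply_qc(matrix, vrep, srep)
        kept = WeightTable(tuple(w for w in weights if w.rsid in filtered.variant_ids))
        result = score_cohort(filtered, kept, missing_policy)
        result.to_tsv(out / "scores.tsv")
    except Exception as exc:
        logger.error("stage score failed: %s", exc)
        raise click.ClickException(f"stage score failed: {exc}") from exc
    write_manifest(
        out, "score", inputs=[vcf_path],
        counts={
            "variants_in": matrix.n_variants, "variants_out": filtered.n_variants,
            "samples_in": matrix.n_samples, "samples_out": filtered.n_samples,
        },
    )
    click.echo(f"scored {filtered.n_samples} samples on {filtered.n_variants} variants")


@main.command()
@click.option("--scores", "scores_path", type=click.Path(exists=True), required=True)
@click.option("--phenotypes", "pheno_path", type=click.Path(exists=True), required=True)
@click.option("--min-n", type=int, default=30, show_default=True)
@click.option("--plot/--no-plot", default=True, show_default=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def assoc(scores_path, pheno_path, min_n, plot, out_dir) -> None:
    """Predictor screen, multivariable + stratified GRS models, R² delta."""
    out = Path(out_dir)
    _setup_logging(out)
    try:
        scores = pd.read_csv(scores_path, sep="\t", index_col=0)
        cohort = CohortTable.from_tsv(pheno_path).with_scores(scores["grs_z"])
        usable = cohort.frame.dropna(subset=["grs_z", "vd_z"])
        if len(usable) < min_n:
            raise click.ClickException(
                f"stage assoc failed: only {len(usable)} joinable samples (< {min_n})"
            )
        results = VitaminDGrsModel(CohortTable(usable)).fit()
        results.to_tsv(out / "associations.tsv")
        results.screen.to_csv(out / "screen.tsv", sep="\t", index=False)
        (out / "r2.json").write_text(json.dumps(results.r2._asdict(), indent=2) + "\n")
        if plot:
            fig = results.plot_stratified()
            fig.savefig(out / "stratified_grs.png", dpi=150)
        click.echo(results.summary())
    except click.ClickException:
        raise
    except Exception as exc:
        logger.error("stage assoc failed: %s", exc)
        raise click.ClickException(f"stage assoc failed: {exc}") from exc
    write_manifest(out, "assoc", inputs=[scores_path, pheno_path],
                   counts={"samples": len(usable)})


@main.command(name="all")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.pass_context
def run_all(ctx, config_path, seed, out_dir) -> None:
    """simulate → score → assoc on the synthetic cohort, end to end."""
    out = Path(out_dir)
    ctx.invoke(simulate, config_path=config_path, seed=seed, out_dir=str(out))
    ctx.invoke(score, vcf_path=str(out / "genotypes.vcf"), weights_path=None,
               allow_palindromic=("rs8018720",), missing_policy="mean_impute", out_dir=str(out))
    ctx.invoke(assoc, scores_path=str(out / "scores.tsv"), pheno_path=str(out / "phenotypes.tsv"),
               min_n=30, plot=True, out_dir=str(out))


if __name__ == "__main__":
    sys.exit(main())
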