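"""End-to-end pipeline: simulate/load -> filter -> popgen -> LD -> H2 -> GWAS
-> overlap -> effects, with per-stage artifacts, logs and a checksummed
manifest.  Fully deterministic given the master seed: each stage derives its
own seed from the master seed and the stage name, so stages can be re-run in
isolation and reproduce the same output."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotypes as gio
from . import simulate as sim
from .gwas import run_gwas
from .heritability import among_line_ftest, broad_sense_h2, line_means, trait_correlation
from .ld import decay_landscape, distance_at_r2, fit_decay, pairwise_r2
from .overlap import overlap_permutation, overlap_to_frame
from .popgen import (
    pairwise_fst,
    site_counts_from_genotypes,
    structure_check,
    subsample_coverage,
    window_diversity,
    windows_to_frame,
)

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "vcf", "broods", "metadata", "gff3", "fasta", "out_dir", "seed",
    "simulate", "min_called_lines", "maf_min", "window_bp", "window_step_bp",
    "pool_size", "target_coverage", "min_count", "min_covered_fraction",
    "ld_max_dist", "ld_min_complete", "ld_max_pairs", "q", "n_perm",
    "overlap_window_sizes", "overlap_n_perm", "flank_bp", "pileup_depth",
    "gwas_traits",
}


@dataclass
class PipelineConfig:
    """All pipeline settings; unknown keys are rejected at load time."""

    out_dir: str
    seed: int = 0
    vcf: str | None = None
    broods: str | None = None
    metadata: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    simulate: dict | None = None          # SimulationConfig overrides, or None
    min_called_lines: int = gio.DEFAULT_MIN_CALLED_LINES
    maf_min: float = gio.DEFAULT_MAF_MIN
    window_bp: int = 400_000
    window_step_bp: int | None = None
    pool_size: int = 60
    target_coverage: int = 20
    min_count: int = 5
    min_covered_fraction: float = 0.0     # site lists are SNP-only, not pileups
    pileup_depth: int = 40
    ld_max_dist: int = 1_000_000
    ld_min_complete: int = 10
    ld_max_pairs: int | None = 200_000
    q: float = 0.1
    n_perm: int = 100
    overlap_window_sizes: tuple[int, ...] = (25_000, 50_000, 100_000, 200_000, 400_000)
    overlap_n_perm: int = 100
    flank_bp: int = 5_000
    gwas_traits: tuple[str, ...] = ("sex_ratio", "clutch")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "overlap_window_sizes" in d:
            d["overlap_window_sizes"] = tuple(d["overlap_window_sizes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    return (zlib.crc32(stage.encode()) ^ (master_seed * 0x9E3779B1)) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest.

    Inputs are validated before any stage runs.  On stage failure the
    manifest records the partial state and the exception is re-raised.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_stages = ["simulate", "filter", "popgen", "ld", "h2", "gwas", "overlap", "effects"]
    stages = stages or all_stages
    manifest: dict = {"seed": cfg.seed, "stages": {}, "artifacts": {}}
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1, sort_keys=True, default=str)
    )
    manifest["artifacts"]["config"] = "config.json"

    # -- input validation up front --------------------------------------
    if "simulate" not in stages or cfg.simulate is None:
        for key in ("vcf", "broods", "metadata"):
            p = getattr(cfg, key)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input '{key}' missing: {p}")

    def record(stage: str, **info):
        manifest["stages"][stage] = info
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    try:
        # -- simulate ----------------------------------------------------
        if "simulate" in stages and cfg.simulate is not None:
            scfg = sim.SimulationConfig(**cfg.simulate).replace(
                seed=stage_seed(cfg.seed, "simulate")
            )
            panel = sim.simulate_panel(scfg)
            genome = ann = None
            if cfg.fasta is None and panel.genotypes.n_snps and \
                    scfg.chromosome_length_bp <= 20_000_000:
                genome = sim.synthesize_reference(
                    panel.genotypes, scfg.chromosome_length_bp, scfg.seed
                )
                ann = sim.toy_annotation_gff3(
                    sorted(panel.genotypes.sites["chrom"].unique()),
                    scfg.chromosome_length_bp, seed=scfg.seed,
                )
            paths = sim.write_fixture(
                out / "fixture", panel.genotypes, panel.broods, panel.metadata,
                truth=panel.truth, genome=genome, annotation_gff3=ann,
            )
            cfg.vcf = str(paths["vcf"])
            cfg.broods = str(paths["broods"])
            cfg.metadata = str(paths["metadata"])
            if "fasta" in paths:
                cfg.fasta = str(paths["fasta"])
                cfg.gff3 = str(paths["gff3"])
            record("simulate", n_lines=panel.genotypes.n_lines,
                   n_snps=panel.genotypes.n_snps, n_broods=len(panel.broods))

        G_raw = gio.read_genotype_matrix(cfg.vcf)
        broods = gio.read_brood_table(cfg.broods)
        meta = gio.read_line_metadata(cfg.metadata)

        # -- filter ------------------------------------------------------
        G, flog = gio.apply_gwas_filters(
            G_raw, meta, min_called_lines=cfg.min_called_lines, maf_min=cfg.maf_min
        )
        flog.write_tsv(out / "filter_log.tsv")
        manifest["artifacts"]["filter_log"] = "filter_log.tsv"
        record("filter", n_lines=G.n_lines, n_snps=G.n_snps,
               steps=flog.steps)
        kept = set(G.line_ids)
        broods_kept = [b for b in broods if b.line_id in kept]

        # -- popgen ------------------------------------------------------
        if "popgen" in stages:
            rng_seed = stage_seed(cfg.seed, "popgen")
            sites = site_counts_from_genotypes(G_raw, depth=cfg.pileup_depth, seed=rng_seed)
            rng = np.random.default_rng(rng_seed + 1)
            sub = [subsample_coverage(s, target=cfg.target_coverage, seed=rng) for s in sites]
            wins = window_diversity(
                sub, pool_size=cfg.pool_size, window=cfg.window_bp,
                step=cfg.window_step_bp, min_count=cfg.min_count,
                min_covered_fraction=cfg.min_covered_fraction,
            )
            windows_to_frame(wins).to_csv(out / "diversity_windows.tsv", sep="\t", index=False)
            F = pairwise_fst(G_raw)
            F.to_frame().to_csv(out / "fst_matrix.tsv", sep="\t")
            sr_means = line_means(broods, "sex_ratio")
            Fk = pairwise_fst(G_raw.subset(
                line_mask=[l in kept and l in sr_means for l in G_raw.line_ids]))
            chk = structure_check(Fk, sr_means)
            off = F.values[np.triu_indices(len(F.line_ids), k=1)]
            record("popgen", n_windows=len(wins),
                   mean_fst=float(np.nanmean(off)),
                   structure_spearman_r=chk.spearman_r, structure_p=chk.p_value)
            manifest["artifacts"]["diversity_windows"] = "diversity_windows.tsv"
            manifest["artifacts"]["fst_matrix"] = "fst_matrix.tsv"

        # -- ld ----------------------------------------------------------
        if "ld" in stages:
            pairs = pairwise_r2(
                G, max_dist=cfg.ld_max_dist, min_complete=cfg.ld_min_complete,
                max_pairs=cfg.ld_max_pairs, seed=stage_seed(cfg.seed, "ld"),
            )
            pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
            fit = fit_decay(pairs)
            land = decay_landscape(G, max_dist=cfg.ld_max_dist, pairs=pairs)
            land.to_csv(out / "ld_landscape.tsv", sep="\t", index=False)
            record("ld", p_per_bp=fit.p, half_decay_bp=fit.half_decay_bp,
                   dist_r2_10pct_bp=distance_at_r2(fit, 0.1),
                   dist_r2_20pct_bp=distance_at_r2(fit, 0.2),
                   n_pairs=fit.n_pairs)
            manifest["artifacts"]["ld_pairs"] = "ld_pairs.tsv"
            manifest["artifacts"]["ld_landscape"] = "ld_landscape.tsv"

        # -- h2 ----------------------------------------------------------
        if "h2" in stages:
            df = gio.broods_to_frame(broods_kept)
            alt = among_line_ftest(broods_kept)
            h2_sr = broad_sense_h2(df["sex_ratio"], df["line_id"],
                                   trait="sex_ratio", transform="arcsine-sqrt")
            h2_cl = broad_sense_h2(df["clutch_size"], df["line_id"],
                                   trait="clutch_size", transform="identity")
            sr = line_means(broods_kept, "sex_ratio")
            cl = line_means(broods_kept, "clutch_size")
            order = sorted(sr)
            corr = trait_correlation([cl[l] for l in order], [sr[l] for l in order])
            pd.DataFrame(
                [
                    ("sex_ratio", h2_sr.transform, h2_sr.v_line, h2_sr.v_residual,
                     h2_sr.h2, h2_sr.likelihood_ratio, h2_sr.p_value),
                    ("clutch_size", h2_cl.transform, h2_cl.v_line, h2_cl.v_residual,
                     h2_cl.h2, h2_cl.likelihood_ratio, h2_cl.p_value),
                ],
                columns=["trait", "transform", "v_line", "v_residual", "h2", "lr", "p"],
            ).to_csv(out / "heritability.tsv", sep="\t", index=False)
            record("h2", f_statistic=alt.f_statistic, f_p=alt.p_value,
                   h2_sex_ratio=h2_sr.h2, h2_clutch=h2_cl.h2,
                   trait_corr_slope=corr.slope, trait_corr_p=corr.p_value)
            manifest["artifacts"]["heritability"] = "heritability.tsv"

        # -- gwas --------------------------------------------------------
        gwas = None
        if "gwas" in stages or "overlap" in stages:
            traits = tuple(cfg.gwas_traits)
            if "overlap" in stages:
                traits = ("sex_ratio", "clutch")     # overlap needs both scans
            gwas = run_gwas(G, broods_kept, traits=traits, q=cfg.q,
                            n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "gwas"))
            for trait, res in gwas.results.items():
                res.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
                manifest["artifacts"][f"gwas_{trait}"] = f"gwas_{trait}.tsv"
            thr_info = {
                t: {
                    "p_threshold": th.p_threshold,
                    "neg_log10_threshold": th.neg_log10_threshold,
                    "q_min": th.q_min,
                    "n_significant": int(len(gwas.significant(t))),
                }
                for t, th in gwas.thresholds.items()
            }
            (out / "gwas_thresholds.json").write_text(json.dumps(thr_info, indent=1))
            manifest["artifacts"]["gwas_thresholds"] = "gwas_thresholds.json"
            record("gwas", **{f"{t}_{k}": v for t, d in thr_info.items()
                              for k, v in d.items()})

        # -- overlap -----------------------------------------------------
        if "overlap" in stages and gwas is not None and \
                {"sex_ratio", "clutch"} <= set(gwas.results):
            tests = overlap_permutation(
                gwas.results["sex_ratio"], gwas.results["clutch"],
                window_sizes=cfg.overlap_window_sizes,
                n_perm=cfg.overlap_n_perm,
                seed=stage_seed(cfg.seed, "overlap"),
            )
            df = overlap_to_frame(tests)
            df.to_csv(out / "overlap_windows.tsv", sep="\t", index=False)
            record("overlap", n_windows=int(len(df)),
                   n_significant=int(df["significant"].sum()))
            manifest["artifacts"]["overlap_windows"] = "overlap_windows.tsv"

        # -- effects -----------------------------------------------------
        if "effects" in stages and cfg.gff3 and cfg.fasta:
            from .effects import AnnotationModel, classify_matrix, effect_summary

            ann = AnnotationModel.from_gff3(cfg.gff3)
            calls = classify_matrix(G_raw, ann, cfg.fasta, flank_bp=cfg.flank_bp)
            summ = effect_summary(calls)
            rows = []
            for cl in calls:
                primary = min(cl, key=lambda c: c.severity_rank)
                rows.append((primary.snp.chromosome, primary.snp.position,
                             primary.gene_id, primary.so_string, primary.aa_change))
            pd.DataFrame(rows, columns=["chrom", "pos", "gene", "so_term", "aa_change"]) \
                .to_csv(out / "effects.tsv", sep="\t", index=False)
            (out / "effects_summary.json").write_text(json.dumps({
                "counts": summ.counts, "n_synonymous": summ.n_synonymous,
                "n_missense": summ.n_missense, "n_nonsense": summ.n_nonsense,
                "n_nonsynonymous": summ.n_nonsynonymous, "pn_ps": summ.pn_ps,
            }, indent=1))
            record("effects", pn_ps=summ.pn_ps, n_classified=len(calls))
            manifest["artifacts"]["effects"] = "effects.tsv"
            manifest["artifacts"]["effects_summary"] = "effects_summary.json"
    except Exception as exc:
        manifest["failed"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise

    checksums = {}
    for name, rel in manifest["artifacts"].items():
        if name == "config":       # embeds absolute paths; provenance only
            continue
        p = out / rel
        if p.exists():
            checksums[rel] = _sha256(p)
    manifest["checksums"] = checksums
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
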