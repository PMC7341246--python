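"""Stage orchestration: config-driven runs with a consolidated report.

Routing follows the study design for small-herd SNP analyses: the QC-passed
(unpruned) marker set feeds LD/Ne and GWAS, while ROH detection runs on the
LD-pruned subset.  Every stage writes its table under the output directory
and the run report records counts, parameters and a config echo so a rerun
with the same config and seed reproduces the report byte-for-byte
(timestamps excluded — none are embedded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from herdgen import genio, gwas, ldne, roh, simulate
from herdgen.animal_model import PedigreeTable, deregress_ebv
from herdgen.genio import GenotypeDataset, QCParams
from herdgen.ldne import NeOptions
from herdgen.roh import ROHParams
from herdgen.gwas import GwasOptions

log = logging.getLogger("herdgen")


@dataclass
class PipelineConfig:
    """Inputs and per-stage options; defaults mirror the standard protocol."""

    genotypes: str | None = None          # PLINK prefix
    pedigree: str | None = None           # TSV animal/sire/dam
    ebv_tables: dict[str, str] = field(default_factory=dict)  # trait -> TSV
    gff3: str | None = None
    out_dir: str = "herdgen_out"
    seed: int = 0
    deregression_c: float = 0.10
    qc: QCParams = field(default_factory=QCParams)
    roh: ROHParams = field(default_factory=ROHParams)
    ne: NeOptions | None = None
    gwas: GwasOptions = field(default_factory=GwasOptions)
    ld_max_distance: int | None = 10_000_000
    ld_bin_width: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "qc" in kwargs:
            kwargs["qc"] = QCParams(**{
                k: tuple(v) if k == "autosomes" else v
                for k, v in kwargs["qc"].items()
            })
        if "roh" in kwargs:
            kwargs["roh"] = ROHParams(**kwargs["roh"])
        if "ne" in kwargs and kwargs["ne"] is not None:
            kwargs["ne"] = NeOptions(**kwargs["ne"])
        if "gwas" in kwargs:
            kwargs["gwas"] = GwasOptions(**kwargs["gwas"])
        cfg = cls(**kwargs)
        for p in (cfg.genotypes and Path(cfg.genotypes).with_suffix(".bed"),
                  cfg.pedigree, cfg.gff3, *cfg.ebv_tables.values()):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        return cfg


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run qc -> [prune -> roh], [ld -> ne], [deregress -> gwas]; return report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config": _config_echo(config)}
    stage = "load"
    try:
        if config.genotypes is None:
            raise ValueError("no genotype input configured")
        ds = genio.read_plink(config.genotypes)
        log.info("stage=load event=read n_samples=%d n_snps=%d", ds.n_samples, ds.n_snps)

        stage = "qc"
        ds_qc, qc_report = genio.qc_filter(ds, config.qc)
        qc_report.to_json(out / "qc_report.json")
        log.info("stage=qc event=done snps=%d samples=%d",
                 qc_report.n_snps_retained, qc_report.n_samples_retained)

        stage = "prune"
        kept = genio.ld_prune(
            ds_qc, config.qc.prune_window, config.qc.prune_step, config.qc.prune_r2
        )
        ds_pruned = genio.apply_snp_selection(ds_qc, kept)
        qc_report.n_snps_after_prune = ds_pruned.n_snps
        qc_report.to_json(out / "qc_report.json")
        report["qc"] = json.loads(qc_report.to_json())

        stage = "roh"
        segments = roh.detect_roh(ds_pruned, config.roh)
        seg_df = roh.segments_frame(segments)
        _write_tsv(seg_df, out / "roh_segments.tsv")
        genome = roh.covered_genome(ds_pruned)
        summary = roh.roh_summary(
            segments, ds_pruned.n_samples, genome=genome, samples=ds_pruned.samples,
            froh_min_length=config.roh.min_length,
        )
        class_table = roh.length_class_table(segments)
        _write_tsv(class_table, out / "roh_length_classes.tsv")
        froh8 = roh.compute_froh(segments, genome, 8_000_000, samples=ds_pruned.samples)
        report["roh"] = {
            "n_segments": summary["n_segments"],
            "mn_roh": summary["mn_roh"],
            "l_roh_mb": summary["l_roh_mb"],
            "snps_per_segment": summary["snps_per_segment"],
            "froh_4mb": summary.get("froh"),
            "froh_8mb_mean": float(froh8.mean()) if len(froh8) else 0.0,
            "length_classes": class_table.to_dict(orient="records"),
        }
        summary["per_individual"].reset_index().pipe(_write_tsv, out / "roh_per_individual.tsv")

        stage = "ld"
        pairs = ldne.pairwise_r2(ds_qc, max_distance=config.ld_max_distance)
        bins = ldne.bin_ld_decay(pairs, config.ld_bin_width)
        _write_tsv(bins, out / "ld_decay.tsv")

        stage = "ne"
        ne_opts = config.ne or NeOptions(sample_size=ds_qc.n_samples)
        traj = ldne.estimate_ne_trajectory(bins, ne_opts)
        _write_tsv(traj, out / "ne_trajectory.tsv")
        report["ne"] = {
            "n_points": int(len(traj)),
            "median_ne": float(traj["ne"].median()) if len(traj) else None,
        }

        stage = "gwas"
        if config.ebv_tables:
            report["gwas"] = {}
            axes = gwas.stratification_axes(ds_qc, config.gwas.n_axes)
            for trait, path in config.ebv_tables.items():
                ebv = pd.read_csv(path, sep="\t")
                debv = deregress_ebv(ebv, c=config.deregression_c)
                _write_tsv(debv, out / f"debv_{trait}.tsv")
                pheno = debv.set_index("animal")["debv"]
                opts = GwasOptions(**{**asdict(config.gwas), "trait": trait})
                raw = gwas.egscore_scan(pheno, ds_qc, axes, opts)
                lam, adj = gwas.genomic_control(raw, opts)
                if config.gff3 is not None:
                    adj = gwas.annotate_snp_feature(adj, config.gff3)
                _write_tsv(adj, out / f"gwas_{trait}.tsv")
                _write_tsv(lam.qq, out / f"gwas_{trait}_qq.tsv")
                hits = adj[adj["tier"] != "none"]
                report["gwas"][trait] = {
                    "lambda": lam.lambda_,
                    "n_snps": int(len(adj)),
                    "n_genome_wide": int((adj["tier"] == "genome-wide").sum()),
                    "n_suggestive": int((adj["tier"] == "suggestive").sum()),
                    "hits": hits.to_dict(orient="records"),
                    "debv_mean": float(pheno.mean()),
                    "debv_var": float(pheno.var(ddof=1)),
                }
        else:
            report["gwas"] = "skipped (no EBV inputs configured)"
    except Exception as err:
        (out / "FAILED").write_text(f"stage={stage}\nerror={err}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    (out / "run_report.json").write_text(
        json.dumps(report, indent=2, default=_jsonable, sort_keys=True) + "\n"
    )
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    return echo


def make_fixture(scale: str, seed: int, out_dir: str | Path) -> Path:
    """Emit a ready-to-run simulated dataset (PLINK + pedigree + EBV tables).

    'small' is a seconds-scale smoke fixture; 'full' is a 42-sample,
    29-autosome cohort with close-kin mating at 50K-chip marker density.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if scale == "small":
        cfg = simulate.SimConfig(
            seed=seed, n_founders=12, n_generations=3, mating="close_kin",
            close_kin_prob=0.4,
            chrom=simulate.ChromosomeSpec(n_chrom=3, length_bp=20_000_000),
        )
        n_keep = 10
    elif scale == "full":
        cfg = simulate.SimConfig(
            seed=seed, n_founders=44, n_generations=3, mating="close_kin",
            close_kin_prob=0.25,
            chrom=simulate.ChromosomeSpec(n_chrom=29, length_bp=90_000_000),
        )
        n_keep = 42
    else:
        raise ValueError(f"unknown scale {scale!r}")

    ped = simulate.sim_pedigree(cfg)
    ds, truth = simulate.gene_drop_genotypes(ped, cfg)
    last_gen = ped.df[ped.df["generation"] == ped.df["generation"].max()]["animal"]
    keep = list(last_gen)[:n_keep]
    idx = [ds.samples.index(a) for a in keep]
    ds_out = ds.subset(sample_idx=idx)
    genio.write_plink(ds_out, out / "genotypes")
    ped.df[["animal", "sire", "dam"]].to_csv(out / "pedigree.tsv", sep="\t", index=False)

    records, ebv, tbv = simulate.sim_phenotypes_and_ebv(ped, cfg)
    records.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    if ebv is not None:
        ebv[ebv["animal"].isin(keep)].to_csv(out / "ebv.tsv", sep="\t", index=False)

    truth_json = {
        "autozygosity": truth.autozygosity.loc[keep].to_dict(),
        "pedigree_f": truth.pedigree_f.loc[keep].to_dict(),
        "genome_length_bp": truth.genome_length_bp,
        "ibd_segments": {a: truth.ibd_segments[a] for a in keep},
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1, default=_jsonable))
    return out
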