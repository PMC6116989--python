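"""End-to-end orchestration: simulate/read -> QC -> GWAS -> ROH -> consensus report.

Coordinates are 1-based inclusive internally (the MAP convention); BED
exports are 0-based half-open via :mod:`polledgwas.plinkio`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import plinkio
from .genotypes import GenotypeMatrix
from .gqc import QcReport, QcThresholds, qc_filter
from .relmat import VarianceComponents
from .roh import (
    RohIsland,
    RohParams,
    call_islands,
    detect_roh,
    intersect_regions,
    islands_frame,
    segments_frame,
    snp_incidence,
)
from .simdata import SimConfig, simulate_dataset, write_dataset, read_dataset
from .tgibbs import GibbsConfig
from .wssgwas import (
    CandidateRegion,
    WssgwasConfig,
    regions_frame,
    run_iterations,
    select_regions,
    window_variances,
    windows_frame,
)

log = logging.getLogger("polledgwas")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: Path = Path("polledgwas_out")
    seed: int = 1
    sim: SimConfig | None = None
    input_dir: Path | None = None  # pedigree.csv, genotypes.ped/.map, phenotypes.tsv
    qc: QcThresholds = field(default_factory=QcThresholds)
    wss: WssgwasConfig = field(default_factory=WssgwasConfig)
    roh_params: RohParams = field(default_factory=RohParams)
    roh_subset: str = "polled"  # which animals enter the ROH scan
    region_threshold_pct: float = 1.0
    genes_bed: Path | None = None

    def __post_init__(self) -> None:
        if self.sim is None and self.input_dir is None:
            self.sim = SimConfig(seed=self.seed)
        if self.roh_subset not in ("all", "polled", "horned"):
            raise ValueError("roh_subset must be all, polled or horned")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "founder_maf_range" in sim:
                sim["founder_maf_range"] = tuple(sim["founder_maf_range"])
            kwargs["sim"] = SimConfig(**sim)
        if "qc" in raw:
            kwargs["qc"] = QcThresholds(**raw["qc"])
        if "roh_params" in raw:
            kwargs["roh_params"] = RohParams(**raw["roh_params"])
        wss_raw = raw.get("wss", {})
        gibbs = GibbsConfig(**{k: v for k, v in wss_raw.pop("gibbs", {}).items() if k != "h2"})
        if "h2" in wss_raw:
            gibbs.var = VarianceComponents.from_h2(wss_raw.pop("h2"))
        kwargs["wss"] = WssgwasConfig(gibbs=gibbs, **wss_raw)
        for key in ("out_dir", "seed", "input_dir", "roh_subset", "region_threshold_pct", "genes_bed"):
            if key in raw:
                kwargs[key] = raw[key]
        kwargs.update(overrides)
        for key in ("out_dir", "input_dir", "genes_bed"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        return cls(**kwargs)


@dataclass
class RegionReport:
    windows: pd.DataFrame
    gwas_regions: list[CandidateRegion]
    islands: list[RohIsland]
    consensus: list[CandidateRegion]
    gene_overlaps: pd.DataFrame | None = None
    qc_report: QcReport | None = None


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if not any(isinstance(h, logging.FileHandler) for h in log.handlers):
        fh = logging.FileHandler(out_dir / "pipeline.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    log.setLevel(logging.INFO)


def plot_window_shares(windows: pd.DataFrame, path: str | Path, threshold_pct: float = 1.0) -> None:
    """Manhattan-style plot of window variance shares along the genome."""
    fig, ax = plt.subplots(figsize=(9, 3.2))
    offset = 0
    ticks, labels = [], []
    for k, (c, grp) in enumerate(windows.groupby("chrom", sort=False)):
        x = grp["start_bp"].values + offset
        ax.scatter(x, grp["var_share_pct"].values, s=6, color=f"C{k % 10}")
        ticks.append(offset + grp["start_bp"].values.mean())
        labels.append(str(c))
        offset += grp["end_bp"].max() + 1
    ax.axhline(threshold_pct, color="grey", ls="--", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("% additive variance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def annotate_regions(
    regions: list[CandidateRegion], genes: pd.DataFrame | str | Path
) -> pd.DataFrame:
    """Genes (user BED) overlapping each region by at least 1 bp.

    ``genes`` may be a BED path or a frame with 1-based inclusive
    chrom/start/end/name columns.  Returns one row per (region, gene) pair
    plus per-region gene counts; regions pass through unchanged.
    """
    if not isinstance(genes, pd.DataFrame):
        genes = plinkio.read_bed(genes)
    rows = []
    for r in regions:
        hit = genes[
            (genes["chrom"].astype(str) == str(r.chrom))
            & (genes["start"] <= r.end_bp)
            & (genes["end"] >= r.start_bp)
        ]
        for _, g in hit.iterrows():
            rows.append((r.chrom, r.start_bp, r.end_bp, r.source, g["name"], g["start"], g["end"]))
    return pd.DataFrame(
        rows,
        columns=["chrom", "region_start", "region_end", "source", "gene", "gene_start", "gene_end"],
    )


def run_pipeline(cfg: PipelineConfig) -> RegionReport:
    """Run every stage, persisting each stage's artifacts under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    _setup_logging(out)
    log.info("pipeline start: %s", cfg)

    # --- stage: data -------------------------------------------------------
    try:
        if cfg.input_dir is not None:
            ped, geno, pheno = read_dataset(cfg.input_dir)
            log.info("loaded dataset from %s", cfg.input_dir)
        else:
            sim = cfg.sim
            ds = simulate_dataset(sim)
            ped, geno, pheno = ds.pedigree, ds.genotypes, ds.phenotypes
            write_dataset(ped, geno, pheno, out / "dataset", config=sim)
            log.info(
                "simulated %d animals (%d genotyped, %d SNPs), prevalence %.3f",
                len(ped),
                geno.n_animals,
                geno.n_snps,
                (pheno["category"] == 2).mean(),
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("data", exc) from exc

    # --- stage: qc ---------------------------------------------------------
    try:
        geno_qc, qc_report = qc_filter(geno, cfg.qc)
        qc_report.write_tsv(out / "qc_report.tsv")
        log.info("QC: %d/%d SNPs, %d/%d samples retained",
                 qc_report.n_snps_out, qc_report.n_snps_in,
                 qc_report.n_samples_out, qc_report.n_samples_in)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("qc", exc) from exc

    # --- stage: gwas -------------------------------------------------------
    try:
        if geno_qc.n_animals == 0:
            raise ValueError("no genotyped animals survive QC: SNP effects cannot be backsolved")
        wss = cfg.wss
        wss.gibbs.seed = cfg.seed + 1000
        effect_sets = run_iterations(ped, geno_qc, pheno, wss)
        final = effect_sets[-1]
        for es in effect_sets:
            es.to_frame().to_csv(out / f"snp_effects_iter{es.iteration}.tsv", sep="\t", index=False)
        final.gebv.to_csv(out / "gebv.tsv", sep="\t", index=False)

        sigma2_a = wss.gibbs.var.sigma2_a
        p = geno_qc.allele_freqs()
        Z = geno_qc.centered(np.clip(p, 1e-8, 1 - 1e-8))
        windows = window_variances(
            final.u_hat, Z, geno_qc.snp_map, sigma2_a, mode=wss.window_mode
        )
        wframe = windows_frame(windows)
        wframe.to_csv(out / "windows.tsv", sep="\t", index=False)
        gwas_regions = select_regions(windows, cfg.region_threshold_pct)
        regions_frame(gwas_regions).to_csv(out / "gwas_regions.tsv", sep="\t", index=False)
        if gwas_regions:
            plinkio.write_bed(
                regions_frame(gwas_regions), out / "gwas_regions.bed", name_col="total_var_share_pct"
            )
        plot_window_shares(wframe, out / "window_shares.png", cfg.region_threshold_pct)
        log.info("GWAS: %d windows, %d candidate regions", len(windows), len(gwas_regions))
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("gwas", exc) from exc

    # --- stage: roh --------------------------------------------------------
    try:
        roh_geno = geno_qc
        if cfg.roh_subset != "all":
            want = 2 if cfg.roh_subset == "polled" else 1
            cat_of = dict(zip(pheno["animal"], pheno["category"]))
            keep = np.array([cat_of.get(int(a)) == want for a in geno_qc.animal_ids])
            roh_geno = geno_qc.subset(animals=keep)
        segments = detect_roh(roh_geno, cfg.roh_params)
        segments_frame(segments).to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        incidence = snp_incidence(segments, roh_geno.snp_map, roh_geno.n_animals)
        inc = roh_geno.snp_map.copy()
        inc["incidence"] = incidence
        inc.to_csv(out / "roh_incidence.tsv", sep="\t", index=False)
        islands = call_islands(incidence, roh_geno.snp_map)
        islands_frame(islands).to_csv(out / "roh_islands.tsv", sep="\t", index=False)
        if islands:
            plinkio.write_bed(islands_frame(islands), out / "roh_islands.bed")
        log.info("ROH: %d segments (%d animals scanned), %d islands",
                 len(segments), roh_geno.n_animals, len(islands))
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("roh", exc) from exc

    # --- stage: consensus / report ----------------------------------------
    try:
        consensus = intersect_regions(gwas_regions, islands)
        regions_frame(consensus).to_csv(out / "consensus_regions.tsv", sep="\t", index=False)
        if consensus:
            plinkio.write_bed(regions_frame(consensus), out / "consensus_regions.bed")
        gene_overlaps = None
        if cfg.genes_bed is not None:
            gene_overlaps = annotate_regions(gwas_regions + consensus, cfg.genes_bed)
            gene_overlaps.to_csv(out / "gene_overlaps.tsv", sep="\t", index=False)
        log.info("consensus: %d regions", len(consensus))
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("report", exc) from exc

    return RegionReport(
        windows=wframe,
        gwas_regions=gwas_regions,
        islands=islands,
        consensus=consensus,
        gene_overlaps=gene_overlaps,
        qc_report=qc_report,
    )
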