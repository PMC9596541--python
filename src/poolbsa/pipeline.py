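"""One-command pipeline: simulate -> filter -> test -> intersect -> annotate.

`RunConfig` gathers every knob (design sizes, trait model, depth model,
filter thresholds, test calibration, window sizes) and round-trips through
YAML.  `run_pipeline` executes all stages deterministically for a given
seed, writing every intermediate table to the run directory for audit, and
returns a JSON-serialisable summary.  `pca_check` is the sanity check that
replicate pools of the same phenotype group resemble each other more than
pools of the contrasting group.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import io as pio
from .annotate import cluster_markers, flanking_genes, windows_to_bed
from .diff import (
    DEFAULT_P_GRID,
    PoolContrast,
    export_bayescan,
    import_bayescan,
    intersect_methods,
)
from .filtering import filter_htp_table, filter_raf_table, maf_matrix
from .pools import EARLY, LATE
from .sim import (
    FounderPanel,
    TraitModel,
    make_pools,
    select_extremes,
    sequence_pools,
    simulate_annotation,
    simulate_population,
)


@dataclass
class RunConfig:
    """Configuration of a full simulated analysis run."""

    seed: int = 0
    # experimental design
    n_sown: int = 672
    n_select: int = 52
    n_pools: int = 3
    # marker panel
    n_markers: int = 5000
    n_chrom: int = 7
    chrom_length: int = 30_000_000
    unplaced_fraction: float = 0.0
    haplotype_k: int = 2
    # trait model
    qtl_markers: list = field(default_factory=list)
    qtl_effects: list = field(default_factory=list)
    baseline_dte: float = 82.0
    noise_sd: float = 10.0
    censor_day: float = 94.0
    # depth model
    depth_mean: float = 100.0
    depth_dispersion: float = 5.0
    min_depth: int = 0
    error_rate: float = 0.001
    # SNP / haplotype filters
    min_allele_sum: int = 30
    posterior_cut: float = 0.95
    min_depth_after: int = 27
    raf_lo: float = 0.05
    raf_hi: float = 0.95
    min_locus_reads: int = 30
    min_variant_freq: float = 0.05
    # differentiation tests
    fdr: float = 0.05
    p_grid_lo: float = 1e-8
    p_grid_hi: float = 1e-1
    p_grid_points: int = 50
    # annotation
    flank: int = 50_000
    join_distance: int = 100_000
    genes_per_window: int = 2
    # optional externally produced BayeScan result file
    bayescan_results: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if self.n_select * 2 > self.n_sown:
            raise ValueError("cannot select more extremes than individuals sown")
        if not (0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must lie in [0, 0.1]")

    @property
    def p_grid(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.p_grid_lo), np.log10(self.p_grid_hi), self.p_grid_points
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage; write tables and a summary to ``outdir``.

    Stages: simulate the population and pools, sequence them, filter SNP
    and haplotype tables, run both replicate-pool tests at the configured
    FDR, optionally fold in a BayeScan result file, intersect the methods,
    cluster consensus markers into loci and pull flanking genes from the
    simulated annotation.  Deterministic for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_panel, s_pop, s_pool_e, s_pool_l, s_seq, s_annot = ss.spawn(6)

    # --- simulate -----------------------------------------------------
    panel = FounderPanel.random(
        config.n_markers,
        n_chrom=config.n_chrom,
        chrom_length=config.chrom_length,
        unplaced_fraction=config.unplaced_fraction,
        seed=np.random.default_rng(s_panel),
    )
    trait = TraitModel(
        qtl_markers=list(config.qtl_markers),
        qtl_effects=list(config.qtl_effects),
        baseline_dte=config.baseline_dte,
        noise_sd=config.noise_sd,
        censor_day=config.censor_day,
    )
    pop = simulate_population(panel, config.n_sown, trait, seed=np.random.default_rng(s_pop))
    early_idx, late_idx = select_extremes(pop, config.n_select)
    pools = make_pools(early_idx, EARLY, config.n_pools, seed=np.random.default_rng(s_pool_e))
    pools += make_pools(late_idx, LATE, config.n_pools, seed=np.random.default_rng(s_pool_l))
    specs = [spec for spec, _ in pools]

    raf, htp, truth = sequence_pools(
        pop,
        pools,
        panel,
        depth_mean=config.depth_mean,
        depth_dispersion=config.depth_dispersion,
        min_depth=config.min_depth,
        error_rate=config.error_rate,
        haplotype_k=config.haplotype_k,
        trait=trait,
        seed=np.random.default_rng(s_seq),
    )
    pio.write_table(raf, outdir / "raf.tsv")
    pio.write_table(htp, outdir / "htp.tsv")
    pio.write_table(truth, outdir / "truth.tsv")
    pio.write_pools(specs, outdir / "pools.tsv")

    qtl_positions = [
        (truth.loc[i, "chrom"], int(truth.loc[i, "pos"]))
        for i in np.flatnonzero(truth["is_qtl"].to_numpy())
    ]
    gff_path = outdir / "annotation.gff3"
    gene_truth = simulate_annotation(
        qtl_positions or [(str(panel.chroms[0]), int(panel.positions[0]))],
        gff_path,
        genes_per_window=config.genes_per_window,
        flank=config.flank,
        seed=np.random.default_rng(s_annot),
    )
    gene_truth.to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)

    # --- filter -------------------------------------------------------
    raf_f, raf_report = filter_raf_table(
        raf,
        specs,
        min_allele_sum=config.min_allele_sum,
        posterior_cut=config.posterior_cut,
        min_depth_after=config.min_depth_after,
        raf_lo=config.raf_lo,
        raf_hi=config.raf_hi,
    )
    htp_f, htp_report = filter_htp_table(
        htp,
        specs,
        min_locus_reads=config.min_locus_reads,
        min_variant_freq=config.min_variant_freq,
    )
    pio.write_table(raf_f, outdir / "raf.filtered.tsv")
    pio.write_table(htp_f, outdir / "htp.filtered.tsv")
    pio.write_vcf(raf_f, outdir / "snps.filtered.vcf")
    raf_report.to_frame().to_csv(outdir / "filter_report_snps.tsv", sep="\t", index=False)
    htp_report.to_frame().to_csv(outdir / "filter_report_htps.tsv", sep="\t", index=False)

    # --- test ---------------------------------------------------------
    frames = []
    if len(raf_f):
        frames.append(PoolContrast.from_raf_table(raf_f, specs).freqs)
    if len(htp_f):
        frames.append(PoolContrast.from_htp_table(htp_f, specs).freqs)
    if not frames:
        raise RuntimeError("test stage: no markers survived filtering")
    freqs = pd.concat(frames)
    model = PoolContrast(freqs, specs)
    res1 = model.fit(method="fst_replicate", fdr=config.fdr, p_grid=config.p_grid,
                     n_ind=config.n_select, n_rep=config.n_pools)
    res2 = model.fit(method="error_variance", fdr=config.fdr, p_grid=config.p_grid,
                     n_ind=config.n_select, n_rep=config.n_pools)
    res1.table.to_csv(outdir / "method1.tsv", sep="\t")
    res2.table.to_csv(outdir / "method2.tsv", sep="\t")

    manifest = export_bayescan(
        freqs.to_numpy(), specs, outdir / "bayescan_input.txt",
        marker_ids=list(freqs.index),
    )
    method_sets = {
        "fst_replicate": res1.significant,
        "error_variance": res2.significant,
    }
    if config.bayescan_results:
        method_sets["bayescan"] = import_bayescan(
            config.bayescan_results, q_threshold=config.fdr, manifest=manifest
        )

    inter = intersect_methods(method_sets)
    consensus = sorted(inter["consensus"], key=str)

    # --- annotate -----------------------------------------------------
    marker_rows = []
    for mid in consensus:
        chrom, pos = _marker_position(str(mid))
        marker_rows.append({"marker_id": mid, "chrom": chrom, "pos": pos})
    reports = []
    loci = []
    if marker_rows:
        loci = cluster_markers(pd.DataFrame(marker_rows), join_distance=config.join_distance)
        for locus in loci:
            reports.append(flanking_genes(locus, gff_path, flank=config.flank))
        pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
            outdir / "candidate_genes.tsv", sep="\t", index=False
        )
        pio.write_bed(windows_to_bed(loci, config.flank), outdir / "locus_windows.bed")

    # --- summarise ----------------------------------------------------
    maf = maf_matrix(raf_f, specs, chromosomal_only=config.unplaced_fraction > 0)
    pca = pca_check(maf, specs) if len(maf) >= 2 else {
        "variance_ratio": [], "separated": None, "degenerate": True}

    summary = {
        "config_seed": config.seed,
        "n_sown": config.n_sown,
        "n_elongating": int(pop.elongating.sum()),
        "n_censored": int((~pop.elongating).sum()),
        "markers_simulated": int(config.n_markers),
        "snps_filtered": int(len(raf_f)),
        "htp_variants_filtered": int(len(htp_f)),
        "filter_report_snps": raf_report.stages,
        "filter_report_htps": htp_report.stages,
        "method1": {"p_level": _num(res1.p_level), "fdr": _num(res1.fdr_estimate),
                    "l": res1.n_tested, "d": res1.n_significant},
        "method2": {"p_level": _num(res2.p_level), "fdr": _num(res2.fdr_estimate),
                    "l": res2.n_tested, "d": res2.n_significant},
        "per_method_significant": inter["per_method"],
        "consensus_markers": [str(m) for m in consensus],
        "consensus_loci": [loc.name for loc in loci],
        "pca": {"variance_ratio": [float(v) for v in pca["variance_ratio"]],
                "pc1_separates_groups": pca["separated"]},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _num(x):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)


def _marker_position(marker_id: str) -> tuple[str, int]:
    """Chromosome and anchor position from a marker id.

    SNP ids are ``chrom:pos``; haplotype-variant ids are
    ``htp_<chrom>_<start>|<haplotype>``.
    """
    if marker_id.startswith("htp_"):
        locus = marker_id.split("|", 1)[0]
        _, chrom, start = locus.split("_", 2)
        return chrom, int(start)
    chrom, pos = marker_id.rsplit(":", 1)
    return chrom, int(pos)


def pca_check(maf: pd.DataFrame, pools) -> dict:
    """Centered PCA of the pools x markers MAF matrix.

    Returns per-component variance fractions and whether the PC1 scores of
    early and late pools are linearly separable (disjoint score ranges).
    Degenerate input (zero total variance) yields a warning and no flag.
    """
    if maf.shape[0] < 2 or maf.shape[1] < 2:
        raise ValueError("PCA needs at least 2 markers and 2 pools")
    X = maf.to_numpy(dtype=float).T  # pools x markers
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        warnings.warn("all pools identical; PCA variance undefined")
        return {"variance_ratio": [], "scores": None, "separated": None, "degenerate": True}
    pca = PCA()
    scores = pca.fit_transform(X)
    pc1 = scores[:, 0]
    groups = [p.group for p in pools]
    e = pc1[[i for i, g in enumerate(groups) if g == EARLY]]
    l = pc1[[i for i, g in enumerate(groups) if g == LATE]]
    separated = None
    if len(e) and len(l):
        separated = bool(e.max() < l.min() or l.max() < e.min())
    return {
        "variance_ratio": pca.explained_variance_ratio_.tolist(),
        "scores": pc1,
        "separated": separated,
        "degenerate": False,
    }
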