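"""Replicated simulation studies of the differentiation tests.

These drive the package's self-validation: null calibration (no QTLs; how
many markers does each FDR-calibrated test declare, all of which are false
discoveries), power/recovery (how often are planted markers with a large
true between-group frequency difference detected), and the stringency
ordering between the two replicate-pool tests.  Each replicate simulates
the full experiment: 672 individuals sown, the 52 earliest and 52 latest
elongating selected, three replicate pools per group, depth-limited
sequencing, then both tests calibrated to a target FDR.
"""

from __future__ import annotations

import warnings

import numpy as np

from .diff import PoolContrast
from .pools import EARLY, LATE
from .sim import (
    FounderPanel,
    TraitModel,
    make_pools,
    select_extremes,
    sequence_pools,
    simulate_population,
)


def simulate_experiment(
    n_markers: int,
    trait: TraitModel,
    seed,
    n_sown: int = 672,
    n_select: int = 52,
    n_pools: int = 3,
    depth_mean: float = 100.0,
    depth_dispersion: float = 5.0,
    error_rate: float = 0.001,
):
    """One full design replicate; returns (model, truth, specs)."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_panel, s_pop, s_pe, s_pl, s_seq = ss.spawn(5)
    panel = FounderPanel.random(n_markers, seed=np.random.default_rng(s_panel))
    pop = simulate_population(panel, n_sown, trait, seed=np.random.default_rng(s_pop))
    early, late = select_extremes(pop, n_select)
    pools = make_pools(early, EARLY, n_pools, np.random.default_rng(s_pe))
    pools += make_pools(late, LATE, n_pools, np.random.default_rng(s_pl))
    raf, _, truth = sequence_pools(
        pop, pools, panel,
        depth_mean=depth_mean, depth_dispersion=depth_dispersion,
        error_rate=error_rate, haplotype_k=0, trait=trait,
        seed=np.random.default_rng(s_seq),
    )
    specs = [s for s, _ in pools]
    return PoolContrast.from_raf_table(raf, specs), truth, specs


def null_calibration_study(
    n_markers: int = 20_000,
    n_seeds: int = 20,
    seed: int = 0,
    target_fdr: float = 0.05,
) -> dict:
    """No planted QTLs: every declared marker is a false discovery.

    Returns per-method totals and the empirical FDR
    (total false / max(total declared, 1); 0 when nothing is declared),
    plus its Monte-Carlo standard error over seeds.
    """
    trait = TraitModel()  # no QTLs
    per_seed = {"fst_replicate": [], "error_variance": []}
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_seeds):
        model, _, _ = simulate_experiment(n_markers, trait, child)
        for method in per_seed:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(method=method, fdr=target_fdr)
            per_seed[method].append(res.n_significant)
    out = {}
    for method, counts in per_seed.items():
        counts = np.array(counts)
        total = int(counts.sum())
        # all discoveries under the null are false
        fdr_by_seed = np.where(counts > 0, 1.0, 0.0)
        out[method] = {
            "false_discoveries": total,
            "empirical_fdr": total / max(total, 1) if total else 0.0,
            "fdr_by_seed_mean": float(fdr_by_seed.mean()),
            "fdr_mc_se": float(fdr_by_seed.std(ddof=1) / np.sqrt(len(counts))),
            "d_by_seed": counts.tolist(),
        }
    return out


def power_study(
    n_markers: int = 2_000,
    n_seeds: int = 20,
    seed: int = 0,
    target_fdr: float = 0.05,
    min_true_diff: float = 0.5,
    qtl_effects: tuple = (-15.0, -15.0, 15.0),
) -> dict:
    """Planted strong QTLs; power conditional on realised true group
    frequency difference >= ``min_true_diff``, plus the per-replicate
    significant-set sizes used for the stringency comparison.

    QTL effects are ~1.5x the environmental SD per allele copy, which under
    10%-tail truncation selection typically shifts the between-group true
    frequency difference past 0.5.  Censoring is disabled so both extreme
    groups stay full.
    """
    rng = np.random.default_rng(seed)
    qtl_idx = np.sort(rng.choice(n_markers, size=len(qtl_effects), replace=False))
    trait = TraitModel(
        qtl_markers=qtl_idx.tolist(),
        qtl_effects=list(qtl_effects),
        baseline_dte=150.0,
        noise_sd=10.0,
        censor_day=1e6,
    )
    hits = {"fst_replicate": 0, "error_variance": 0}
    eligible = 0
    d_counts = {"fst_replicate": [], "error_variance": []}
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_seeds):
        model, truth, _ = simulate_experiment(n_markers, trait, child)
        diff = (truth["early_true_freq"] - truth["late_true_freq"]).abs()
        strong = [i for i in qtl_idx if diff.iloc[i] >= min_true_diff]
        strong_ids = [model.marker_ids[i] for i in strong]
        eligible += len(strong)
        for method in hits:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(method=method, fdr=target_fdr)
            d_counts[method].append(res.n_significant)
            hits[method] += sum(m in res.significant for m in strong_ids)
    d1 = np.array(d_counts["fst_replicate"])
    d2 = np.array(d_counts["error_variance"])
    return {
        "eligible_markers": eligible,
        "power": {m: hits[m] / eligible if eligible else np.nan for m in hits},
        "d_by_seed": d_counts,
        "stringency_fraction": float((d2 <= d1).mean()),
    }
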