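"""Forward simulator: trait model, selection, pooling, sequencing, GFF3."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolbsa.pools import EARLY, LATE
from poolbsa.sim import (
    FounderPanel,
    Population,
    TraitModel,
    make_pools,
    select_extremes,
    sequence_pools,
    simulate_annotation,
    simulate_population,
)

from conftest import POOL_IDS


def small_panel(n=50, seed=0, freq=None):
    panel = FounderPanel.random(n, n_chrom=2, seed=seed)
    if freq is not None:
        panel.alt_freqs[:] = freq
    return panel


def fixed_population(dosage_value, n_ind, n_markers, dte=None):
    dosages = np.full((n_ind, n_markers), dosage_value, dtype=np.uint8)
    dte = np.zeros(n_ind) if dte is None else np.asarray(dte, dtype=float)
    return Population(dosages=dosages, dte=dte, elongating=np.ones(n_ind, bool))


class TestTraitModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            TraitModel(qtl_markers=[1], qtl_effects=[])
        with pytest.raises(ValueError):
            TraitModel(qtl_markers=[1, 1], qtl_effects=[2.0, 3.0])
        with pytest.raises(ValueError):
            TraitModel(noise_sd=-1)
        with pytest.raises(ValueError):
            TraitModel(baseline_dte=100, censor_day=90)

    def test_qtl_index_out_of_range(self):
        panel = small_panel(10)
        trait = TraitModel(qtl_markers=[99], qtl_effects=[1.0])
        with pytest.raises(ValueError):
            simulate_population(panel, 5, trait)


class TestSimulatePopulation:
    def test_degenerate_noise_gives_constant_dte(self):
        panel = small_panel()
        trait = TraitModel(baseline_dte=60.0, noise_sd=0.0, censor_day=94.0)
        pop = simulate_population(panel, 20, trait, seed=1)
        assert (pop.dte == 60.0).all()
        assert pop.elongating.all()

    def test_censoring_rate_matches_design(self):
        # censor day placed at the 146/672 upper tail of the DTE distribution
        frac = 146 / 672
        sd = 10.0
        censor = 82.0 + stats.norm.ppf(1 - frac) * sd
        trait = TraitModel(baseline_dte=82.0, noise_sd=sd, censor_day=censor)
        pop = simulate_population(small_panel(), 672, trait, seed=5)
        n_censored = int((~pop.elongating).sum())
        # binomial 3-sigma band around 146
        assert abs(n_censored - 146) < 3 * np.sqrt(672 * frac * (1 - frac))

    def test_additive_effect_recovered_by_dosage_group_means(self):
        panel = small_panel(20, freq=0.5)
        trait = TraitModel(qtl_markers=[3], qtl_effects=[-10.0],
                           baseline_dte=80.0, noise_sd=5.0, censor_day=1e6)
        pop = simulate_population(panel, 5000, trait, seed=11)
        dos = pop.dosages[:, 3]
        diff = pop.dte[dos == 2].mean() - pop.dte[dos == 0].mean()
        assert diff == pytest.approx(-20.0, abs=0.8)

    def test_hwe_dosage_frequencies(self):
        panel = small_panel(30, freq=0.3)
        pop = simulate_population(panel, 20_000, TraitModel(), seed=3)
        assert pop.dosages.mean() / 2 == pytest.approx(0.3, abs=0.01)

    def test_determinism(self):
        panel = small_panel()
        a = simulate_population(panel, 100, TraitModel(), seed=42)
        b = simulate_population(panel, 100, TraitModel(), seed=42)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.dte, b.dte)

    def test_ld_blocks_induce_within_block_correlation(self):
        panel = small_panel(40, freq=0.5)
        pop = simulate_population(panel, 4000, TraitModel(), seed=9, ld_block_size=20)
        d = pop.dosages.astype(float)
        within = np.corrcoef(d[:, 0], d[:, 1])[0, 1]
        assert within > 0.9


class TestSelectExtremes:
    def test_simple_case(self):
        pop = fixed_population(0, 3, 2, dte=[5, 9, 7])
        early, late = select_extremes(pop, 1)
        assert list(early) == [0] and list(late) == [1]

    def test_design_sized_selection(self):
        trait = TraitModel()
        pop = simulate_population(small_panel(), 672, trait, seed=5)
        early, late = select_extremes(pop, 52)
        assert len(early) == len(late) == 52
        assert not set(early) & set(late)
        assert pop.dte[early].max() <= pop.dte[late].min()
        assert pop.elongating[early].all() and pop.elongating[late].all()

    def test_ties_broken_by_index_groups_disjoint(self):
        pop = fixed_population(0, 5, 2, dte=[7, 7, 7, 7, 7])
        early, late = select_extremes(pop, 2)
        assert list(early) == [0, 1]
        assert list(late) == [3, 4]

    def test_too_few_elongating_rejected(self):
        pop = fixed_population(0, 5, 2, dte=[1, 2, 3, 4, 5])
        pop.elongating[:] = [True, True, False, False, False]
        with pytest.raises(ValueError):
            select_extremes(pop, 2)


class TestMakePools:
    def test_default_split_sizes(self):
        members = np.arange(52)
        pools = make_pools(members, EARLY, 3, seed=0)
        sizes = sorted(spec.n_individuals for spec, _ in pools)
        assert sizes == [17, 17, 18]
        assert sorted(spec.n_gametes for spec, _ in pools) == [34, 34, 36]
        all_members = np.concatenate([m for _, m in pools])
        assert sorted(all_members) == list(members)

    def test_single_pool(self):
        pools = make_pools(np.arange(52), LATE, 1, seed=0)
        assert len(pools) == 1 and pools[0][0].n_individuals == 52

    def test_determinism(self):
        a = make_pools(np.arange(52), EARLY, 3, seed=7)
        b = make_pools(np.arange(52), EARLY, 3, seed=7)
        for (_, ma), (_, mb) in zip(a, b):
            assert np.array_equal(ma, mb)

    def test_too_many_pools_rejected(self):
        with pytest.raises(ValueError):
            make_pools(np.arange(3), EARLY, 4, seed=0)


def default_pools_for(pop, seed=0):
    early, late = select_extremes(pop, 52)
    return (make_pools(early, EARLY, 3, seed) + make_pools(late, LATE, 3, seed + 1))


class TestSequencePools:
    def test_fixed_reference_gives_raf_one(self):
        panel = small_panel(20)
        pop = fixed_population(0, 120, 20)  # alt dosage 0 -> reference fixed
        pools = make_pools(np.arange(52), EARLY, 3, 0) + make_pools(
            np.arange(52, 104), LATE, 3, 1
        )
        raf, _, _ = sequence_pools(pop, pools, panel, error_rate=0.0, seed=2)
        for pid in POOL_IDS:
            assert (raf[f"{pid}_raf"].dropna() == 1.0).all()

    def test_raf_concentrates_at_high_depth(self):
        # all-heterozygote pools: true frequency exactly 0.5 per pool
        panel = small_panel(400, seed=1)
        pop = fixed_population(1, 120, 400)
        pools = make_pools(np.arange(52), EARLY, 3, 0) + make_pools(
            np.arange(52, 104), LATE, 3, 1
        )
        raf, _, _ = sequence_pools(pop, pools, panel, depth_mean=500,
                                   depth_dispersion=1e9, error_rate=0.0, seed=3)
        inside = ((raf["E1_raf"] - 0.5).abs() <= 0.07).mean()
        assert inside >= 0.95

    def test_counts_and_raf_consistent(self):
        panel = small_panel(100, seed=2)
        pop = simulate_population(panel, 672, TraitModel(), seed=4)
        pools = default_pools_for(pop)
        raf, htp, truth = sequence_pools(pop, pools, panel, trait=TraitModel(), seed=5)
        for pid in POOL_IDS:
            depth = raf[f"{pid}_ref_count"] + raf[f"{pid}_alt_count"]
            ok = depth > 0
            np.testing.assert_allclose(
                raf.loc[ok, f"{pid}_raf"],
                raf.loc[ok, f"{pid}_ref_count"] / depth[ok],
            )
            assert (raf[f"{pid}_raf"] >= 0).where(ok, True).all()
            assert (raf[f"{pid}_raf"] <= 1).where(ok, True).all()

    def test_haplotype_conservation(self):
        panel = small_panel(100, seed=2)
        pop = simulate_population(panel, 200, TraitModel(), seed=4)
        pools = make_pools(np.arange(52), EARLY, 3, 0) + make_pools(
            np.arange(52, 104), LATE, 3, 1
        )
        _, htp, _ = sequence_pools(pop, pools, panel, haplotype_k=2, seed=6)
        assert htp["haplotype"].str.len().eq(2).all()
        for locus, sub in htp.groupby("locus_id"):
            assert len(sub) <= 4
            for pid in POOL_IDS:
                tot = sub[f"{pid}_count"].sum()
                if tot > 0:
                    assert sub[f"{pid}_freq"].sum() == pytest.approx(1.0)

    def test_truth_table_matches_dosage_means(self):
        panel = small_panel(30, seed=3)
        pop = simulate_population(panel, 672, TraitModel(), seed=7)
        pools = default_pools_for(pop)
        _, _, truth = sequence_pools(pop, pools, panel, seed=8)
        spec0, members0 = pools[0]
        np.testing.assert_allclose(
            truth[f"{spec0.pool_id}_true_freq"],
            pop.dosages[members0].mean(axis=0) / 2.0,
        )
        early_members = np.concatenate([m for s, m in pools if s.group == EARLY])
        np.testing.assert_allclose(
            truth["early_true_freq"], pop.dosages[early_members].mean(axis=0) / 2.0
        )

    def test_null_frequency_difference_centered_at_zero(self):
        panel = FounderPanel.random(12_000, seed=10)
        pop = simulate_population(panel, 672, TraitModel(), seed=11)
        pools = default_pools_for(pop)
        _, _, truth = sequence_pools(pop, pools, panel, haplotype_k=0, seed=12)
        diff = truth["early_true_freq"] - truth["late_true_freq"]
        se = diff.std() / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se

    def test_planted_qtl_outranks_null_markers(self):
        panel = FounderPanel.random(10_000, seed=13)
        panel.alt_freqs[500] = 0.5
        trait = TraitModel(qtl_markers=[500], qtl_effects=[-25.0],
                           baseline_dte=110.0, noise_sd=10.0, censor_day=1e6)
        pop = simulate_population(panel, 672, trait, seed=14)
        pools = default_pools_for(pop)
        _, _, truth = sequence_pools(pop, pools, panel, haplotype_k=0,
                                      trait=trait, seed=15)
        diff = (truth["early_true_freq"] - truth["late_true_freq"]).abs()
        null_diff = diff.drop(index=500)
        assert diff[500] > np.quantile(null_diff, 0.99)

    def test_byte_identical_tables_for_fixed_seed(self, tmp_path):
        panel = small_panel(60, seed=4)
        pop = simulate_population(panel, 200, TraitModel(), seed=16)
        pools = make_pools(np.arange(52), EARLY, 3, 0) + make_pools(
            np.arange(52, 104), LATE, 3, 1
        )
        out = []
        for run in range(2):
            raf, htp, truth = sequence_pools(pop, pools, panel, seed=17)
            paths = []
            for name, df in (("raf", raf), ("htp", htp), ("truth", truth)):
                p = tmp_path / f"{name}{run}.tsv"
                df.to_csv(p, sep="\t", index=False)
                paths.append(p.read_bytes())
            out.append(paths)
        assert out[0] == out[1]

    def test_error_rate_bounds(self):
        panel = small_panel(10)
        pop = fixed_population(0, 10, 10)
        pools = make_pools(np.arange(5), EARLY, 3, 0) + make_pools(
            np.arange(5, 10), LATE, 3, 1
        )
        with pytest.raises(ValueError):
            sequence_pools(pop, pools, panel, error_rate=0.5)


class TestSimulateAnnotation:
    def test_truth_list_and_boundaries(self, tmp_path):
        path = tmp_path / "toy.gff3"
        truth = simulate_annotation([("1", 1_000_000)], path, genes_per_window=3,
                                    genes_outside=2, seed=1)
        text = path.read_text()
        assert text.startswith("##gff-version 3")
        assert text.count("\tgene\t") == 5
        assert truth["in_window"].sum() >= 3

    def test_zero_genes_per_window(self, tmp_path):
        path = tmp_path / "toy.gff3"
        truth = simulate_annotation([("2", 500_000)], path, genes_per_window=0,
                                    genes_outside=3, seed=2)
        assert not truth["in_window"].any()

    def test_unwritable_path_is_io_error(self, tmp_path):
        with pytest.raises(OSError):
            simulate_annotation([("1", 100)], tmp_path / "no" / "dir.gff3", seed=0)
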