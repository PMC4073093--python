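"""Simulator statistics: Mendelian ratios, linkage, bulks, counts, depths."""

import filecmp

import numpy as np
import pytest

from bulkmap import synthetic_data as sd
from bulkmap.genetics import BulkComposition, expected_bulk_freq, haldane_cm_to_r
from bulkmap.io_formats import CaptureTarget, ConfigurationError


def _se(p, n):
    return np.sqrt(p * (1 - p) / n)


class TestSimulateF2:
    def test_mendelian_causal_dosage_fractions(self, tiny_map):
        pop = sd.simulate_f2(tiny_map, n_individuals=10_000, causal=("1H", 5.0), seed=7)
        dos = pop.dosages[:, pop.marker_map.causal_index]
        for k, p in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            frac = np.mean(dos == k)
            assert abs(frac - p) <= 3 * _se(p, 10_000)
        assert set(pop.phenotypes) == {"mutant", "wildtype"}
        assert np.all((pop.phenotypes == "mutant") == (dos == 2))

    def test_colocated_markers_identical(self):
        config = sd.GeneticMapConfig(
            chromosomes=(("1H", 10.0),), markers_per_cm=1.0,
            contigs_per_chromosome=1, unanchored_fraction=0.0, seed=0,
        )
        # all 10 markers sit on one contig at the same cM
        pop = sd.simulate_f2(config, n_individuals=200, causal=("1H", 5.0), seed=3)
        marker_cols = np.delete(pop.dosages, pop.marker_map.causal_index, axis=1)
        assert np.all(marker_cols == marker_cols[:, :1])

    def test_recombination_fraction_matches_haldane(self, tiny_map):
        # anchors at 5 and 15 cM: expect r = 0.0906 over 10 cM
        pop = sd.simulate_f2(tiny_map, n_individuals=5_000, causal=("1H", 5.0), seed=11)
        gametes = sd._simulate_gametes(pop.marker_map, 10_000, np.random.default_rng(5))
        table = pop.marker_map.table
        cols = [
            int(np.flatnonzero((table["cm"] == cm).to_numpy())[0])
            for cm in (5.0, 15.0)
        ]
        rec = np.mean(gametes[:, cols[0]] != gametes[:, cols[1]])
        r_expected = haldane_cm_to_r(10.0)
        assert abs(rec - r_expected) <= 3 * _se(r_expected, 10_000)

    def test_causal_off_map_rejected(self, tiny_map):
        with pytest.raises(ConfigurationError):
            sd.simulate_f2(tiny_map, 10, causal=("1H", 25.0))
        with pytest.raises(ConfigurationError):
            sd.simulate_f2(tiny_map, 10, causal=("9H", 5.0))


class TestComposeBulks:
    def test_study_design_composition(self, scenario1):
        mut, wt = scenario1.mutant_bulk, scenario1.wildtype_bulk
        assert mut.composition == BulkComposition(17, 1, 0)
        assert wt.composition.n_hom_mutant == 0
        assert wt.n_plants == 30
        assert set(mut.member_indices).isdisjoint(wt.member_indices)

    def test_no_contaminant_means_all_homozygous(self, tiny_map):
        pop = sd.simulate_f2(tiny_map, n_individuals=400, causal=("1H", 5.0), seed=2)
        mut, _ = sd.compose_bulks(pop, 18, 30, n_misphenotyped_het=0, seed=1)
        assert mut.composition.n_het == 0
        assert mut.composition.n_hom_mutant == 18

    def test_wildtype_bulk_het_hom_near_two_to_one(self, tiny_map):
        # over many draws from a large population the ratio approaches 2:1
        pop = sd.simulate_f2(tiny_map, n_individuals=3_000, causal=("1H", 5.0), seed=4)
        hets = homs = 0
        for k in range(40):
            _, wt = sd.compose_bulks(pop, 18, 30, 1, seed=k)
            hets += wt.composition.n_het
            homs += wt.composition.n_hom_wildtype
        ratio = hets / homs
        assert 1.7 <= ratio <= 2.3

    def test_insufficient_individuals_error_states_shortfall(self, tiny_map):
        pop = sd.simulate_f2(tiny_map, n_individuals=12, causal=("1H", 5.0), seed=9)
        with pytest.raises(ValueError, match="need"):
            sd.compose_bulks(pop, 18, 30, 1, seed=0)


class TestSimulatePoolCounts:
    def test_pure_bulk_no_error_is_degenerate(self, tiny_map):
        pop = sd.simulate_f2(tiny_map, n_individuals=400, causal=("1H", 5.0), seed=2)
        mut, wt = sd.compose_bulks(pop, 18, 30, 0, seed=1)
        model = sd.DepthModel(mean_depth=40.0, dispersion=np.inf, error_rate=0.0)
        sites = sd.simulate_pool_counts(pop, mut, wt, model, seed=5)
        causal = pop.marker_map.table.iloc[pop.marker_map.causal_index]
        at_causal = [
            s for s in sites
            if s.contig_id == causal["contig_id"] and s.position == causal["position"]
        ][0]
        assert at_causal.ref_depth_mut == 0  # f_true = 1, error 0

    def test_mean_frequency_converges_to_expectation(self):
        # >= 1,000 sites at the same true frequency: mean within 3 SE of 35/36
        config = sd.GeneticMapConfig(
            chromosomes=(("1H", 10.0),), markers_per_cm=120.0,
            contigs_per_chromosome=1, unanchored_fraction=0.0, seed=0,
        )
        pop = sd.simulate_f2(config, n_individuals=300, causal=("1H", 5.0), seed=6)
        mut, wt = sd.compose_bulks(pop, 18, 30, 1, seed=2)
        model = sd.DepthModel(mean_depth=30.0, dispersion=np.inf, error_rate=0.0)
        sites = sd.simulate_pool_counts(pop, mut, wt, model, seed=8)
        assert len(sites) >= 1_000  # all markers fully linked to the causal locus
        freqs = np.array(
            [s.alt_depth_mut / s.total_mut for s in sites if s.total_mut > 0]
        )
        f_exp = float(expected_bulk_freq(0.0, mut.composition))
        se = np.sqrt(f_exp * (1 - f_exp) / 30) / np.sqrt(len(freqs))
        assert abs(freqs.mean() - f_exp) <= 3 * se

    def test_error_floor(self, tiny_map):
        pop = sd.simulate_f2(tiny_map, n_individuals=400, causal=("1H", 5.0), seed=2)
        mut, wt = sd.compose_bulks(pop, 18, 30, 0, seed=1)
        model = sd.DepthModel(mean_depth=10_000.0, dispersion=np.inf, error_rate=0.002)
        sites = sd.simulate_pool_counts(pop, mut, wt, model, seed=5)
        causal = pop.marker_map.table.iloc[pop.marker_map.causal_index]
        at_causal = [
            s for s in sites
            if s.contig_id == causal["contig_id"] and s.position == causal["position"]
        ][0]
        # mutant bulk is pure: ref reads only arise from sequencing error
        rate = at_causal.ref_depth_mut / at_causal.total_mut
        assert rate == pytest.approx(0.002, abs=3 * _se(0.002, 10_000))


class TestSimulateDepthTracks:
    def test_expected_depths_by_zygosity(self, scenario1):
        """Deleted exons keep ~1/36 of mutant-pool depth; intact targets keep all."""
        sc = scenario1
        mean = sc.config.target_depth.mean_depth
        del_contig = sc.deletion.contig_id
        # average over target factors: compare against the wildtype pool,
        # which shares each target's capture factor
        for start, end in sc.deletion.exons:
            mut = sc.depth_mut.depth_array(del_contig, start, end).mean()
            wt = sc.depth_wt.depth_array(del_contig, start, end).mean()
            # mutant bulk (17 hom + 1 het) retains 1/36, wildtype ~2/3
            assert mut / max(wt, 1e-9) < 0.15
        # an intact contig has comparable depth in both pools
        other = next(
            t.contig_id for t in sc.targets if t.contig_id != del_contig
        )
        t0 = [t for t in sc.targets if t.contig_id == other][0]
        mut = sc.depth_mut.depth_array(other, t0.start, t0.end).mean()
        wt = sc.depth_wt.depth_array(other, t0.start, t0.end).mean()
        assert 0.5 < mut / wt < 2.0
        # off-target positions carry no reads
        assert sc.depth_mut.depth_at(other, 1) == 0

    def test_fully_deleted_bulk_gives_zero_depth(self, tiny_map):
        pop = sd.simulate_f2(tiny_map, n_individuals=400, causal=("1H", 5.0), seed=2)
        mut, wt = sd.compose_bulks(pop, 18, 30, 0, seed=1)  # no het: all deleted
        contig = pop.marker_map.causal_contig
        targets = [CaptureTarget(contig, 1201, 1549)]
        deletion = sd.DeletionSpec(contig, ((1201, 1549),))
        track_mut, _ = sd.simulate_depth_tracks(
            pop, mut, wt, targets, deletion, sd.DepthModel(25.0), seed=3
        )
        assert track_mut.depth_array(contig, 1201, 1549).sum() == 0

    def test_deletion_outside_targets_rejected(self, tiny_map):
        pop = sd.simulate_f2(tiny_map, n_individuals=400, causal=("1H", 5.0), seed=2)
        mut, wt = sd.compose_bulks(pop, 18, 30, 1, seed=1)
        contig = pop.marker_map.causal_contig
        with pytest.raises(ConfigurationError, match="no capture target"):
            sd.simulate_depth_tracks(
                pop, mut, wt, [CaptureTarget(contig, 1, 100)],
                sd.DeletionSpec(contig, ((500, 900),)), sd.DepthModel(25.0), seed=3,
            )


class TestDeterminism:
    def test_fixed_seed_byte_identical_files(self, tmp_path):
        a = sd.simulate_scenario(seed=42)
        b = sd.simulate_scenario(seed=42)
        pa = sd.write_scenario(a, tmp_path / "a")
        pb = sd.write_scenario(b, tmp_path / "b")
        for name in pa:
            assert filecmp.cmp(pa[name], pb[name], shallow=False), name

    def test_different_seeds_different_genotypes(self):
        a = sd.simulate_scenario(seed=1, with_depth_tracks=False)
        b = sd.simulate_scenario(seed=2, with_depth_tracks=False)
        assert not np.array_equal(a.population.dosages, b.population.dosages)


class TestTheoryCrossValidation:
    def test_causal_marker_frequency_matches_closed_form(self, scenario1):
        """Simulated mutant-bulk frequency at the causal SNP tracks 35/36."""
        sc = scenario1
        mm = sc.population.marker_map
        idx = np.array(sc.mutant_bulk.member_indices)
        f_true = sc.population.dosages[idx, mm.causal_index].sum() / (2 * len(idx))
        f_theory = expected_bulk_freq(0.0, sc.mutant_bulk.composition)
        assert f_true == pytest.approx(f_theory, abs=1e-12)

    def test_unlinked_chromosome_frequencies_near_half(self, scenario1):
        sc = scenario1
        mm = sc.population.marker_map
        other = (mm.table["chromosome"] == "2H").to_numpy()
        for bulk in (sc.mutant_bulk, sc.wildtype_bulk):
            idx = np.array(bulk.member_indices)
            f = sc.population.dosages[idx][:, other].sum(axis=0) / (2 * len(idx))
            # one seed's bulk-sampling drift: chromosome-wide mean has
            # sd ~0.05 (few effectively independent loci per 150 cM)
            assert abs(f.mean() - 0.5) < 0.15
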