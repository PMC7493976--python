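"""The planted-scenario generator: determinism, construction, margins."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctcfrep import io as cio
from ctcfrep.config import PipelineConfig
from ctcfrep.mutation import motif_disruption_table
from ctcfrep.pwm import PWM
from ctcfrep.synthetic import (ScenarioConfig, generate_contact_map_pair,
                               generate_methylation_tables, generate_mutations,
                               generate_scenario, write_scenario)

SMALL = dict(n_sites=100, chrom_length=1_000_000, n_chromosomes=1,
             n_background_genes_per_chrom=10)


class TestDeterminism:
    def test_same_seed_reproduces_everything(self):
        s1 = generate_scenario(ScenarioConfig(seed=5, **SMALL))
        s2 = generate_scenario(ScenarioConfig(seed=5, **SMALL))
        pd.testing.assert_frame_equal(s1.sites, s2.sites)
        pd.testing.assert_frame_equal(s1.counts, s2.counts)
        assert s1.genome == s2.genome
        assert s1.truth.site_class == s2.truth.site_class
        for d1, d2 in zip(s1.peak_datasets, s2.peak_datasets):
            assert d1.peaks == d2.peaks
        m1, _ = generate_methylation_tables(s1)
        m2, _ = generate_methylation_tables(s2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_different_seeds_differ_but_share_schema(self):
        s1 = generate_scenario(ScenarioConfig(seed=5, **SMALL))
        s2 = generate_scenario(ScenarioConfig(seed=6, **SMALL))
        assert not s1.counts.equals(s2.counts)
        assert list(s1.counts.columns) == list(s2.counts.columns)
        assert list(s1.sites.columns) == list(s2.sites.columns)


class TestConstruction:
    def test_exact_class_counts(self):
        cfg = ScenarioConfig(seed=0, n_sites=1000, chrom_length=5_000_000)
        scen = generate_scenario(cfg)
        counts = scen.sites["site_class"].value_counts()
        assert counts["cancer_lost"] == 25
        assert counts["cancer_gained"] == 25
        assert counts.sum() == 1000
        cfg2 = ScenarioConfig(seed=0, n_sites=1000, chrom_length=5_000_000,
                              class_fractions={"constitutive": 0.10,
                                               "common": 0.50,
                                               "cancer_lost": 0.05,
                                               "cancer_gained": 0.05,
                                               "sample_specific": 0.30})
        counts2 = generate_scenario(cfg2).sites["site_class"].value_counts()
        assert counts2["cancer_lost"] == 50

    def test_site_spacing_at_least_one_kb(self):
        scen = generate_scenario(ScenarioConfig(seed=3, **SMALL))
        for _, grp in scen.sites.groupby("chrom"):
            gaps = np.diff(np.sort(grp["center"].to_numpy()))
            assert (gaps >= 1000).all()

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_scenario(ScenarioConfig(seed=0, n_sites=2000,
                                             chrom_length=1_000_000,
                                             n_chromosomes=1))

    def test_truth_covers_every_site_exactly_once(self):
        scen = generate_scenario(ScenarioConfig(seed=4, **SMALL))
        assert sorted(scen.truth.site_class) == sorted(scen.sites["site_id"])

    def test_consensus_planted_at_constitutive_and_gained_sites(self):
        scen = generate_scenario(ScenarioConfig(seed=4, **SMALL))
        pwm = PWM.from_counts(scen.pfm_counts)
        from ctcfrep.pwm import reverse_complement
        for row in scen.sites.itertuples(index=False):
            if row.site_class not in ("constitutive", "cancer_gained"):
                continue
            w = pwm.width
            window = scen.genome[row.chrom][row.center - w // 2:
                                            row.center - w // 2 + w]
            if row.motif_strand == "-":
                window = reverse_complement(window)
            assert window == pwm.consensus

    def test_matched_normal_never_has_gained_peaks(self):
        scen = generate_scenario(ScenarioConfig(seed=2, **SMALL))
        gained_centers = set(
            scen.sites.loc[scen.sites["site_class"] == "cancer_gained",
                           "center"])
        normal_ids = set(scen.design.loc[
            scen.design["matched_normal_for"] != "", "dataset_id"])
        for ds in scen.peak_datasets:
            if ds.dataset_id not in normal_ids:
                continue
            for p in ds.peaks:
                assert not any(abs(p.summit - c) < 500 for c in gained_centers)


class TestSignalMargins:
    def test_gained_cancer_signal_exceeds_common(self, scenario):
        """Planted gained sites out-signal common sites in cancer columns."""
        cancer_cols = scenario.design.loc[
            scenario.design["cancer_type"] != "", "dataset_id"]
        rpkm = scenario.rpkm[cancer_cols].mean(axis=1)
        cls = scenario.sites.set_index("site_id")["site_class"]
        gained = rpkm[cls == "cancer_gained"]
        common = rpkm[cls == "common"]
        t, p = stats.ttest_ind(gained, common, alternative="greater")
        assert t > 0 and p < 0.01
        lost = rpkm[cls == "cancer_lost"]
        t, p = stats.ttest_ind(common, lost, alternative="greater")
        assert t > 0 and p < 0.01

    def test_class_margins_recoverable_from_occupancy(self, called_scenario):
        """A naive per-class occupancy-mean oracle separates the classes."""
        atlas = called_scenario["atlas"]
        truth = called_scenario["truth_class"]
        freq = pd.Series({s.site_id: s.occupancy_frequency
                          for s in atlas.sites})
        by_class = freq.groupby(truth).mean()
        assert by_class["constitutive"] > by_class["common"] \
            > by_class["sample_specific"]
        assert by_class["cancer_lost"] > 0.7
        assert by_class["cancer_gained"] < 0.25


class TestContactMaps:
    def test_maps_symmetric(self):
        scen = generate_scenario(ScenarioConfig(seed=1, **SMALL))
        mc, mn = generate_contact_map_pair(scen)
        for store in (mc, mn):
            for cm in store.values():
                np.testing.assert_array_equal(cm.matrix, cm.matrix.T)

    def test_boost_one_draws_are_exchangeable_in_expectation(self):
        scen = generate_scenario(ScenarioConfig(seed=1, **SMALL))
        mc, mn = generate_contact_map_pair(scen, boost=1.0)
        a = next(iter(mc.values())).matrix
        b = next(iter(mn.values())).matrix
        # same Poisson intensity: overall means agree within sampling noise
        assert abs(a.mean() - b.mean()) / a.mean() < 0.05

    def test_planted_boost_raises_anchor_rows(self):
        scen = generate_scenario(ScenarioConfig(seed=1, **SMALL))
        mc, mn = generate_contact_map_pair(scen, boost=3.0)
        gained = scen.sites[scen.sites["site_class"] == "cancer_gained"]
        assert len(gained)
        for row in gained.itertuples(index=False):
            cm_c, cm_n = mc[row.chrom], mn[row.chrom]
            anchor = row.center // cm_c.bin_size
            ratio = (cm_c.matrix[anchor].sum() + 1) / (cm_n.matrix[anchor].sum() + 1)
            assert ratio > 1.5


class TestMethylationTables:
    def test_low_coverage_sites_end_up_insufficient(self, cfg):
        from ctcfrep.methylation import region_methylation_table
        scen = generate_scenario(ScenarioConfig(seed=8, **SMALL))
        meth_c, meth_n = generate_methylation_tables(scen)
        tab = region_methylation_table(scen.binding_sites(), meth_c, meth_n, cfg)
        frac_insufficient = (tab["status"] == "insufficient").mean()
        # matches the configured low-coverage fraction within sampling slack
        assert 0.02 < frac_insufficient < 0.3

    def test_zero_shift_rarely_calls_planted_sites(self, cfg):
        from ctcfrep.methylation import region_methylation_table
        scen = generate_scenario(ScenarioConfig(seed=8, **SMALL))
        meth_c, meth_n = generate_methylation_tables(scen, meth_shift=0.0)
        planted = (scen.truth.sites_of_class("cancer_lost")
                   + scen.truth.sites_of_class("cancer_gained"))
        tab = region_methylation_table(
            [s for s in scen.binding_sites() if s.site_id in planted],
            meth_c, meth_n, cfg)
        called = tab[tab["status"].isin(["hyper", "hypo"])]
        sufficient = tab[tab["status"] != "insufficient"]
        assert len(called) <= max(1, 0.1 * len(sufficient))


class TestMutations:
    def test_zero_background_single_planted_variant(self):
        cfg = ScenarioConfig(seed=9, mutation_rate=0.0,
                             n_planted_disruptions=1, **SMALL)
        scen = generate_scenario(cfg)
        muts = generate_mutations(scen)
        assert len(muts) == 1
        gained = scen.sites[scen.sites["site_class"] == "cancer_gained"]
        assert muts.iloc[0]["pos"] in set(
            gained["center"] - scen.pfm_counts.shape[1] // 2
            + scen.pfm_counts.shape[1] // 2)

    def test_background_count_matches_poisson_expectation(self):
        cfg = ScenarioConfig(seed=10, n_planted_disruptions=0, **SMALL)
        scen = generate_scenario(cfg)
        muts = generate_mutations(scen)
        expected = 1e-4 * 400 * 10 * 100  # rate x window x samples x sites
        assert abs(len(muts) - expected) <= 3 * np.sqrt(expected)

    def test_planted_disruption_scores_negative_downstream(self, cfg):
        scen = generate_scenario(ScenarioConfig(seed=11, mutation_rate=0.0,
                                                **SMALL))
        muts = generate_mutations(scen)
        pwm = PWM.from_counts(scen.pfm_counts)
        gained = [s for s in scen.binding_sites()
                  if scen.truth.site_class[s.site_id] == "cancer_gained"]
        tab = motif_disruption_table(gained, muts, scen.genome, pwm, cfg)
        scored = tab[tab["status"] == "ok"]
        assert len(scored) == len(muts)
        assert (scored["delta_score"] < 0).all()


class TestSerialization:
    def test_written_files_parse_with_the_readers(self, tmp_path):
        scen = generate_scenario(ScenarioConfig(seed=12, **SMALL))
        manifest = write_scenario(scen, tmp_path)
        files = cio.read_json(manifest)["files"]
        pcfg = PipelineConfig(min_peaks_per_dataset=1)
        for ds_id, rel in files["peaks"].items():
            ds = cio.read_peak_dataset(tmp_path / rel, pcfg, dataset_id=ds_id)
            assert len(ds.peaks) == ds.n_raw  # every emitted peak passes filters
        counts = cio.read_matrix_tsv(tmp_path / files["counts"])
        pd.testing.assert_frame_equal(counts, scen.counts)
        genome = cio.read_fasta(tmp_path / files["genome"])
        assert genome == scen.genome
        name, pfm = cio.read_pfm_jaspar(tmp_path / files["pfm"])
        np.testing.assert_array_equal(pfm, scen.pfm_counts)
        maps = cio.read_contact_tsv(tmp_path / files["hic_cancer"])
        assert set(maps) == {f"chr{i+1}" for i in range(scen.config.n_chromosomes)}
        meth = cio.read_cpg_table(tmp_path / files["methylation_cancer"])
        assert (meth["coverage"] >= 0).all()
        muts = cio.read_mutations(tmp_path / files["mutations"])
        assert set(muts.columns) >= {"chrom", "pos", "ref", "alt", "sample"}
        design = cio.read_design_table(tmp_path / files["design"])
        assert len(design) == scen.config.n_datasets
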