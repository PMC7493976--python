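"""Chromatin domain boundaries, gene association and DE enrichment."""

import numpy as np
import pandas as pd
import pytest

from ctcfrep.atlas import BindingSite, MotifHit, UnionAtlas
from ctcfrep.config import PipelineConfig
from ctcfrep.domains import (ChromatinDomain, ConstitutiveBoundaries,
                             assign_candidate_targets, build_domain,
                             candidate_target_set, correlate_ctcf_gene,
                             de_enrichment)
from ctcfrep.stattests import fisher_two_tailed


def constitutive_atlas(entries):
    """[(center, strand)] -> UnionAtlas of 150-bp constitutive sites on chr1."""
    sites = []
    for center, strand in entries:
        s, e = center - 75, center + 75
        sites.append(BindingSite(f"chr1:{s}-{e}", "chr1", s, e,
                                 motif=MotifHit(center - 9, strand, 1.0, 1e-5)))
    return UnionAtlas(sites, [])


def anchor_at(center):
    return BindingSite(f"chr1:{center - 75}-{center + 75}", "chr1",
                       center - 75, center + 75)


class TestBuildDomain:
    def test_divergent_boundaries_at_stated_distances(self, cfg):
        b = ConstitutiveBoundaries(constitutive_atlas(
            [(850_000, "-"), (1_200_000, "+")]))
        d = build_domain(anchor_at(1_000_000), b, cfg)
        assert d is not None
        assert (d.left_pos, d.right_pos) == (850_000, 1_200_000)
        assert d.interval == (850_000, 1_200_000)

    def test_too_close_boundary_skipped_not_blocking(self, cfg):
        b = ConstitutiveBoundaries(constitutive_atlas(
            [(950_000, "-"), (850_000, "-"), (1_200_000, "+")]))
        d = build_domain(anchor_at(1_000_000), b, cfg)
        assert d.left_pos == 850_000  # 50 kb neighbor is below the minimum side

    def test_wrong_orientation_skipped(self, cfg):
        b = ConstitutiveBoundaries(constitutive_atlas(
            [(870_000, "+"), (850_000, "-"), (1_200_000, "+")]))
        d = build_domain(anchor_at(1_000_000), b, cfg)
        assert d.left_pos == 850_000

    def test_absent_when_no_boundary_within_max_side(self, cfg):
        b = ConstitutiveBoundaries(constitutive_atlas(
            [(850_000, "-"), (2_100_000, "+")]))
        assert build_domain(anchor_at(1_000_000), b, cfg) is None

    def test_convergent_mode(self):
        cfg = PipelineConfig(domain_orientation="convergent")
        b = ConstitutiveBoundaries(constitutive_atlas(
            [(850_000, "+"), (1_200_000, "-")]))
        d = build_domain(anchor_at(1_000_000), b, cfg)
        assert (d.left_pos, d.right_pos) == (850_000, 1_200_000)

    def test_brute_force_oracle_agreement(self, cfg):
        """Nearest qualifying boundary per side matches exhaustive search."""
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            centers = np.sort(rng.choice(np.arange(100, 3000) * 1000,
                                         size=n, replace=False))
            strands = rng.choice(["-", "+"], size=n)
            anchor_c = int(rng.integers(100_000, 2_900_000))
            b = ConstitutiveBoundaries(constitutive_atlas(
                list(zip(centers.tolist(), strands.tolist()))))
            got = build_domain(anchor_at(anchor_c), b, cfg)

            lefts = [c for c, s in zip(centers, strands)
                     if s == "-" and cfg.domain_min_side <= anchor_c - c
                     <= cfg.domain_max_side]
            rights = [c for c, s in zip(centers, strands)
                      if s == "+" and cfg.domain_min_side <= c - anchor_c
                      <= cfg.domain_max_side]
            if lefts and rights:
                assert got is not None
                assert got.left_pos == max(lefts)
                assert got.right_pos == min(rights)
            else:
                assert got is None


class TestCorrelation:
    def test_perfect_linearity(self):
        p = correlate_ctcf_gene([1, 2, 3, 4], [2, 4, 6, 8])
        assert p.r == pytest.approx(1.0)
        assert p.highly_correlated

    def test_r2_exactly_at_threshold_is_not_highly_correlated(self):
        p = correlate_ctcf_gene([1, 2, 3], [1, 3, 2])
        assert p.r == pytest.approx(0.5)
        assert p.r_squared == pytest.approx(0.25)
        assert not p.highly_correlated  # strict inequality

    def test_constant_vector_flagged_undefined(self):
        p = correlate_ctcf_gene([1, 2, 3], [5, 5, 5])
        assert p.undefined and not p.highly_correlated

    def test_fraction_highly_correlated_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        pairs = [(rng.normal(size=8), rng.normal(size=8)) for _ in range(200)]
        fracs = []
        for thr in (0.1, 0.25, 0.5, 0.8):
            n = sum(correlate_ctcf_gene(x, y, r2_threshold=thr).highly_correlated
                    for x, y in pairs)
            fracs.append(n / len(pairs))
        assert fracs == sorted(fracs, reverse=True)


class TestTargets:
    def _genes(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g2", "g3", "g4"],
            "chrom": ["chr1"] * 4,
            "strand": ["+", "-", "+", "-"],
            "tss": [101_000, 150_000, 250_000, 900_000],
        })

    def test_promoter_overlap_takes_precedence(self, cfg):
        site = anchor_at(100_000)  # within 2 kb of g1's TSS
        dom = ChromatinDomain(site.site_id, "chr1", "l", "r", 50_000, 500_000)
        cat = assign_candidate_targets(site, self._genes(), dom, cfg)
        assert cat.set_index("gene_id")["category"].to_dict() == {
            "g1": "promoter", "g2": "intra_domain", "g3": "intra_domain",
            "g4": "inter_domain"}
        targets = candidate_target_set(site, self._genes(), dom, cfg)
        assert targets["gene_id"].tolist() == ["g1"]

    def test_intra_domain_targets_without_promoter_overlap(self, cfg):
        site = anchor_at(200_000)
        dom = ChromatinDomain(site.site_id, "chr1", "l", "r", 120_000, 400_000)
        targets = candidate_target_set(site, self._genes(), dom, cfg)
        assert targets["gene_id"].tolist() == ["g2", "g3"]

    def test_no_domain_and_no_promoter_gives_empty_set(self, cfg):
        site = anchor_at(600_000)
        targets = candidate_target_set(site, self._genes(), None, cfg)
        assert targets.empty

    def test_categories_partition_all_genes(self, cfg):
        rng = np.random.default_rng(13)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(50)],
            "chrom": ["chr1"] * 50,
            "strand": ["+"] * 50,
            "tss": rng.integers(0, 2_000_000, size=50),
        })
        site = anchor_at(int(rng.integers(100_000, 1_900_000)))
        dom = ChromatinDomain(site.site_id, "chr1", "l", "r",
                              site.center - 300_000, site.center + 200_000)
        cat = assign_candidate_targets(site, genes, dom, cfg)
        assert len(cat) == 50
        assert set(cat["category"]) <= {"promoter", "intra_domain", "inter_domain"}


class TestDeEnrichment:
    def test_two_tailed_fisher_hand_example(self):
        odds, p = fisher_two_tailed([[3, 1], [1, 3]])
        assert p == pytest.approx(34 / 70, abs=1e-12)
        assert odds == pytest.approx(9.0)

    def test_de_thresholds_and_table(self, cfg):
        de = pd.DataFrame({"log2fc": [2.0, -1.5, 0.2, 1.01, 2.0],
                           "fdr": [1e-8, 1e-9, 1e-9, 1e-8, 0.5]},
                          index=["g1", "g2", "g3", "g4", "g5"])
        # DE genes: g1, g2, g4 (|lfc| > 1 AND fdr < 1e-5)
        odds, p, table = de_enrichment(["g1", "g2"], de,
                                       ["g1", "g2", "g3", "g4", "g5"], cfg)
        assert table.loc["target", "de"] == 2
        assert table.loc["non_target", "de"] == 1
        assert table.loc["non_target", "not_de"] == 2

    def test_target_equals_universe_degenerate(self, cfg):
        de = pd.DataFrame({"log2fc": [2.0], "fdr": [1e-9]}, index=["g1"])
        odds, p, _ = de_enrichment(["g1"], de, ["g1"], cfg)
        assert odds == 1.0 and p == 1.0

    def test_empty_universe_raises(self, cfg):
        with pytest.raises(ValueError):
            de_enrichment([], pd.DataFrame(columns=["log2fc", "fdr"]), [], cfg)
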