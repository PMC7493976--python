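"""Mutation-rate profiles and motif disruption deltas."""

import numpy as np
import pandas as pd
import pytest

from ctcfrep.atlas import BindingSite, MotifHit
from ctcfrep.config import PipelineConfig
from ctcfrep.mutation import (differential_motif_score, motif_disruption_table,
                              motif_llr_score, mutation_rate_profile)
from ctcfrep.pwm import ALPHABET, DEFAULT_BACKGROUND, PWM, reverse_complement
from ctcfrep.synthetic import synthetic_ctcf_pfm


def mut_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample"])


def site_at(center, chrom="chr1"):
    return BindingSite(f"{chrom}:{center - 75}-{center + 75}", chrom,
                       center - 75, center + 75)


class TestProfile:
    def test_center_events_concentrate_at_offset_zero(self, cfg):
        sites = [site_at(1000), site_at(5000)]
        muts = mut_frame([("chr1", 1000, "A", "G", "S1"),
                          ("chr1", 5000, "C", "T", "S1")])
        prof = mutation_rate_profile(sites, muts, cfg)
        assert prof.loc[0] == 1.0
        assert prof.drop(index=0).sum() == 0.0

    def test_no_mutations_all_zero(self, cfg):
        prof = mutation_rate_profile([site_at(1000)], mut_frame([]), cfg)
        assert prof.sum() == 0.0 and len(prof) == 400

    def test_conservation_of_in_window_events(self, cfg):
        rng = np.random.default_rng(3)
        sites = [site_at(c) for c in (1000, 5000, 9000)]
        rows = []
        for _ in range(60):
            c = int(rng.choice([1000, 5000, 9000]))
            rows.append(("chr1", c + int(rng.integers(-300, 300)), "A", "G",
                         f"S{rng.integers(1, 4)}"))
        muts = mut_frame(rows)
        prof = mutation_rate_profile(sites, muts, cfg)
        in_window = sum(any(abs(p - c) <= 200 and p - c < 200 and p - c >= -200
                            for c in (1000, 5000, 9000))
                        for p in muts["pos"])
        assert prof.sum() * len(sites) == pytest.approx(in_window)

    def test_site_and_sample_order_invariance(self, cfg):
        sites = [site_at(1000), site_at(5000)]
        rows = [("chr1", 990, "A", "G", "S2"), ("chr1", 5020, "C", "T", "S1")]
        p1 = mutation_rate_profile(sites, mut_frame(rows), cfg)
        p2 = mutation_rate_profile(sites[::-1], mut_frame(rows[::-1]), cfg)
        pd.testing.assert_series_equal(p1, p2)

    def test_empty_site_set_raises(self, cfg):
        with pytest.raises(ValueError):
            mutation_rate_profile([], mut_frame([]), cfg)


class TestMotifScore:
    def test_background_matched_pwm_scores_zero(self):
        probs = np.tile(np.asarray(DEFAULT_BACKGROUND)[:, None], (1, 19))
        pwm = PWM(probs)
        rng = np.random.default_rng(1)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=19))
            assert motif_llr_score(seq, pwm) == 0.0

    def test_minus_strand_scores_reverse_complement(self):
        pwm = PWM.from_counts(synthetic_ctcf_pfm())
        seq = reverse_complement(pwm.consensus)
        assert motif_llr_score(seq, pwm, strand="-") == pytest.approx(pwm.max_score)

    def test_consensus_is_maximal_over_exhaustive_per_position_choice(self):
        pwm = PWM.from_counts(synthetic_ctcf_pfm())
        best = pwm.score(pwm.consensus)
        rng = np.random.default_rng(2)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=19))
            assert pwm.score(seq) <= best + 1e-12


class _DisruptionSetup:
    def __init__(self, strand="+"):
        self.pwm = PWM.from_counts(synthetic_ctcf_pfm())
        w = self.pwm.width
        self.center = 1000
        motif_start = self.center - w // 2
        planted = (self.pwm.consensus if strand == "+"
                   else reverse_complement(self.pwm.consensus))
        rng = np.random.default_rng(4)
        seq = list(rng.choice(list("ACGT"), size=2000))
        seq[motif_start:motif_start + w] = list(planted)
        self.genome = {"chr1": "".join(seq)}
        self.site = BindingSite("s", "chr1", self.center - 75, self.center + 75,
                                motif=MotifHit(motif_start, strand, 0.0, 1e-6))
        self.motif_start = motif_start
        self.w = w


class TestDisruption:
    def test_antisymmetry_over_all_single_base_changes(self, cfg):
        """delta(ref->alt) == -delta(alt->ref) exactly, every position/base."""
        s = _DisruptionSetup()
        for pos in range(s.motif_start, s.motif_start + s.w):
            ref = s.genome["chr1"][pos]
            for alt in "ACGT":
                if alt == ref:
                    continue
                fwd, st = differential_motif_score(
                    s.site, {"pos": pos, "ref": ref, "alt": alt}, s.genome,
                    s.pwm, cfg)
                assert st == "ok"
                mutated = dict(s.genome)
                seq = list(mutated["chr1"])
                seq[pos] = alt
                mutated["chr1"] = "".join(seq)
                rev, _ = differential_motif_score(
                    s.site, {"pos": pos, "ref": alt, "alt": ref}, mutated,
                    s.pwm, cfg)
                assert fwd == -rev

    def test_consensus_disruption_is_negative_and_extreme_at_best_column(self, cfg):
        s = _DisruptionSetup()
        # exhaustive single-base enumeration oracle for the most negative delta
        best_delta = 0.0
        for pos in range(s.motif_start, s.motif_start + s.w):
            ref = s.genome["chr1"][pos]
            for alt in "ACGT":
                if alt == ref:
                    continue
                d, _ = differential_motif_score(
                    s.site, {"pos": pos, "ref": ref, "alt": alt}, s.genome,
                    s.pwm, cfg)
                assert d < 0  # any change off the consensus weakens the motif
                best_delta = min(best_delta, d)
        j = int(np.argmax(s.pwm.probs.max(axis=0)))  # most informative column
        col = s.pwm.log_odds[:, j]
        expected = float(col.min() - col.max())
        assert best_delta == pytest.approx(expected)

    def test_minus_strand_motif_uses_reverse_complement(self, cfg):
        s = _DisruptionSetup(strand="-")
        pos = s.motif_start + 3
        ref = s.genome["chr1"][pos]
        alt = "A" if ref != "A" else "C"
        d, st = differential_motif_score(
            s.site, {"pos": pos, "ref": ref, "alt": alt}, s.genome, s.pwm, cfg)
        assert st == "ok" and d < 0

    def test_variant_outside_window_scores_zero(self, cfg):
        s = _DisruptionSetup()
        d, st = differential_motif_score(
            s.site, {"pos": s.center + 30, "ref": "A", "alt": "G"}, s.genome,
            s.pwm, cfg)
        assert (d, st) == (0.0, "out_of_window")

    def test_reference_mismatch_raises(self, cfg):
        s = _DisruptionSetup()
        pos = s.motif_start
        wrong = "A" if s.genome["chr1"][pos] != "A" else "C"
        with pytest.raises(ValueError, match="disagrees"):
            differential_motif_score(
                s.site, {"pos": pos, "ref": wrong, "alt": "G"}, s.genome,
                s.pwm, cfg)

    def test_indels_and_motifless_sites_flagged(self, cfg):
        s = _DisruptionSetup()
        d, st = differential_motif_score(
            s.site, {"pos": s.motif_start, "ref": "AT", "alt": "A"}, s.genome,
            s.pwm, cfg)
        assert (d, st) == (0.0, "indel")
        bare = BindingSite("b", "chr1", 900, 1100)
        d, st = differential_motif_score(
            bare, {"pos": 1000, "ref": "A", "alt": "G"}, s.genome, s.pwm, cfg)
        assert (d, st) == (0.0, "no_motif")

    def test_table_driver_scores_in_site_variants(self, cfg):
        s = _DisruptionSetup()
        pos = s.motif_start + 2
        ref = s.genome["chr1"][pos]
        alt = "G" if ref != "G" else "T"
        muts = mut_frame([("chr1", pos, ref, alt, "S1"),
                          ("chr1", 500_000, "A", "G", "S1")])
        tab = motif_disruption_table([s.site], muts, s.genome, s.pwm, cfg)
        assert len(tab) == 1
        assert tab.iloc[0]["status"] == "ok" and tab.iloc[0]["delta_score"] < 0
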