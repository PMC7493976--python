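"""Mutation-rate profiles around sites and PWM motif-disruption scores.

The per-bp mutation rate profile counts mutation events from all samples at
each offset of the 400-bp window centered on each site, averaged over sites.
Motif disruption scores a variant by the change in the PWM log-likelihood
ratio between the reference and mutated window (negative = disruption);
only single-nucleotide variants inside the motif window are scored, indels
and out-of-window variants contribute to the profile only.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import BindingSite
from .config import PipelineConfig
from .pwm import PWM, reverse_complement

logger = logging.getLogger(__name__)


def mutation_rate_profile(sites: Sequence[BindingSite], mutations: pd.DataFrame,
                          cfg: PipelineConfig) -> pd.Series:
    """Mean mutation count per site at each offset of the centered window.

    Offsets run -w/2 .. w/2-1 relative to the site center
    (w = cfg.mutation_window); every (sample, position) event counts once.
    """
    if not len(sites):
        raise ValueError("empty site set")
    w = cfg.mutation_window
    half = w // 2
    offsets = np.arange(-half, w - half)
    counts = np.zeros(w)
    by_chrom = {}
    for chrom, grp in mutations.groupby("chrom"):
        by_chrom[chrom] = np.sort(grp["pos"].to_numpy(int))
    for s in sites:
        pos = by_chrom.get(s.chrom)
        if pos is None:
            continue
        center = s.center
        i = np.searchsorted(pos, center - half, side="left")
        j = np.searchsorted(pos, center + (w - half), side="left")
        if j > i:
            off = pos[i:j] - center + half
            np.add.at(counts, off, 1)
    return pd.Series(counts / len(sites), index=offsets, name="mutation_rate")


def motif_llr_score(seq: str, pwm: PWM, strand: str = "+") -> float:
    """PWM log-likelihood-ratio score of a window, on the annotated strand.

    ``seq`` is the forward-strand window of exactly PWM width; for '-' strand
    motifs the reverse complement is scored.  Non-ACGT positions are skipped
    with a warning.
    """
    if strand == "-":
        seq = reverse_complement(seq)
    return pwm.score(seq, skip_invalid=True)


def differential_motif_score(site: BindingSite, variant, genome, pwm: PWM,
                             cfg: PipelineConfig) -> tuple[float, str]:
    """Delta motif score (alt - ref) for one single-nucleotide variant.

    The scored window is the PWM-width window at the site's motif hit (the
    19-bp motif window for the canonical CTCF matrix); variants outside it
    score 0 with status ``out_of_window``.  The variant's reference allele
    must match the genome.  Returns (delta, status); negative delta means
    the mutation weakens the motif.
    """
    if site.motif is None:
        return 0.0, "no_motif"
    ref = str(variant["ref"]).upper()
    alt = str(variant["alt"]).upper()
    if len(ref) != 1 or len(alt) != 1:
        return 0.0, "indel"
    pos = int(variant["pos"])
    w = pwm.width
    win_start = site.motif.start
    win_end = win_start + w
    if not (win_start <= pos < win_end):
        return 0.0, "out_of_window"
    ref_window = str(genome[site.chrom][win_start:win_end]).upper()
    if ref_window[pos - win_start] != ref:
        raise ValueError(
            f"variant ref {ref!r} at {site.chrom}:{pos} disagrees with genome "
            f"base {ref_window[pos - win_start]!r}")
    alt_window = ref_window[:pos - win_start] + alt + ref_window[pos - win_start + 1:]
    strand = site.motif.strand
    delta = motif_llr_score(alt_window, pwm, strand) - motif_llr_score(ref_window, pwm, strand)
    return float(delta), "ok"


def motif_disruption_table(sites: Sequence[BindingSite], mutations: pd.DataFrame,
                           genome, pwm: PWM, cfg: PipelineConfig) -> pd.DataFrame:
    """Score every mutation falling in a site's motif window.

    One row per (site, variant) combination where the variant lies within
    the site interval; the status column distinguishes scored variants from
    indels, motif-less sites and out-of-window positions.
    """
    rows = []
    by_chrom = {c: g.sort_values("pos") for c, g in mutations.groupby("chrom")}
    for s in sites:
        grp = by_chrom.get(s.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy(int)
        i = np.searchsorted(pos, s.start, side="left")
        j = np.searchsorted(pos, s.end, side="left")
        for _, var in grp.iloc[i:j].iterrows():
            delta, status = differential_motif_score(s, var, genome, pwm, cfg)
            rows.append((s.site_id, var["chrom"], int(var["pos"]), var["ref"],
                         var["alt"], var["sample"], delta, status))
    return pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "ref", "alt",
                                       "sample", "delta_score", "status"])
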