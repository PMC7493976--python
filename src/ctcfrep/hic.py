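"""Contact-map distance normalization and differential site interaction.

Contact probability decays with genomic distance, so each bin pair is
divided by the chromosome-wide mean count at its distance (expected-by-
distance normalization; no matrix balancing is applied).  Differential
interaction around a site compares the normalized interaction vectors of
the site's bin against its flanking bins (both sides, up to L) between two
conditions with a paired two-tailed Student's t test.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import BindingSite
from .config import PipelineConfig
from .domains import ChromatinDomain

logger = logging.getLogger(__name__)


class ContactMap:
    """Symmetric binned contact matrix for one chromosome.

    Stored dense (desk-scale chromosomes); ``sbar`` holds the per-distance
    mean profile after normalization (None for raw maps).
    """

    def __init__(self, chrom: str, bin_size: int, matrix: np.ndarray,
                 normalized: bool = False, sbar: np.ndarray | None = None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if np.any(matrix < 0):
            raise ValueError("contact counts must be >= 0")
        if not np.allclose(matrix, matrix.T):
            raise ValueError("contact matrix must be symmetric")
        self.chrom = chrom
        self.bin_size = int(bin_size)
        self.matrix = matrix
        self.normalized = normalized
        self.sbar = sbar

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_sparse(cls, chrom: str, bin_size: int, n_bins: int,
                    bin_i, bin_j, counts) -> "ContactMap":
        bin_i = np.asarray(bin_i, dtype=int)
        bin_j = np.asarray(bin_j, dtype=int)
        counts = np.asarray(counts, dtype=float)
        if np.any(bin_i < 0) or np.any(bin_j < 0) \
                or np.any(bin_i >= n_bins) or np.any(bin_j >= n_bins):
            raise ValueError("bin indices outside [0, n_bins)")
        m = np.zeros((n_bins, n_bins))
        m[bin_i, bin_j] = counts
        m[bin_j, bin_i] = counts
        return cls(chrom, bin_size, m)

    def to_sparse(self):
        """Upper-triangle (i <= j) nonzero entries as (i, j, value) arrays."""
        iu = np.triu_indices(self.n_bins)
        vals = self.matrix[iu]
        nz = vals != 0
        return iu[0][nz], iu[1][nz], vals[nz]

    def bin_of(self, pos: int) -> int:
        return int(pos // self.bin_size)


def normalize_by_distance(cm: ContactMap) -> ContactMap:
    """Divide every pair at distance k by the mean count at that distance.

    The mean at distance k averages over *all* n_bins - k pairs (zeros
    included).  Distances whose mean is zero are left at zero and recorded;
    the diagonal (k = 0) is excluded from normalization and carried through
    unchanged but ignored downstream.
    """
    n = cm.n_bins
    out = cm.matrix.copy()
    sbar = np.zeros(n)
    for k in range(1, n):
        diag = np.diagonal(cm.matrix, offset=k)
        s = diag.mean()
        sbar[k] = s
        if s > 0:
            idx = np.arange(n - k)
            out[idx, idx + k] = diag / s
            out[idx + k, idx] = out[idx, idx + k]
        elif np.any(diag):
            raise AssertionError("zero mean with nonzero entries is impossible")
    return ContactMap(cm.chrom, cm.bin_size, out, normalized=True, sbar=sbar)


def site_flank_vector(site: BindingSite, cm: ContactMap, cfg: PipelineConfig
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized interactions between the site's bin and its flanking bins.

    The anchor bin is ``floor(center / bin_size)``; flank bins lie within
    ``hic_flank_L`` on both sides, excluding the anchor itself and any
    distance whose chromosome-wide mean was zero.  Returns (signed bin
    offsets, values) ordered by offset; truncated at chromosome edges.
    """
    if not cm.normalized:
        raise ValueError("flank vectors are defined on normalized maps")
    anchor = cm.bin_of(site.center)
    if not (0 <= anchor < cm.n_bins):
        raise ValueError(f"anchor bin {anchor} outside map (n_bins={cm.n_bins})")
    span = cfg.hic_flank_L // cm.bin_size
    offsets = np.arange(-span, span + 1)
    offsets = offsets[offsets != 0]
    bins = anchor + offsets
    ok = (bins >= 0) & (bins < cm.n_bins)
    if cm.sbar is not None:
        ok &= cm.sbar[np.abs(offsets).clip(0, cm.n_bins - 1)] > 0
    offsets, bins = offsets[ok], bins[ok]
    return offsets, cm.matrix[anchor, bins]


@dataclasses.dataclass
class DifferentialInteractionResult:
    site_id: str
    n_flank_bins: int
    mean_log2_fc: float
    t_statistic: float
    p_value: float
    status: str = "ok"  # ok / insufficient_data


def differential_interaction(site: BindingSite, map_a: ContactMap,
                             map_b: ContactMap, cfg: PipelineConfig
                             ) -> DifferentialInteractionResult:
    """Paired two-tailed t test of site-flank interactions, condition a vs b.

    Flank bins common to both maps form the pairs (IA_b, IB_b); the mean
    log2 fold change uses a pseudocount on normalized values.  Requires at
    least 3 usable bins with a nonzero value in either condition, else the
    result is flagged ``insufficient_data``.
    """
    if map_a.chrom != map_b.chrom or map_a.bin_size != map_b.bin_size:
        raise ValueError("maps must share chromosome and bin size")
    off_a, ia = site_flank_vector(site, map_a, cfg)
    off_b, ib = site_flank_vector(site, map_b, cfg)
    common, idx_a, idx_b = np.intersect1d(off_a, off_b, return_indices=True)
    ia, ib = ia[idx_a], ib[idx_b]
    usable = (ia != 0) | (ib != 0)
    if usable.sum() < 3:
        return DifferentialInteractionResult(site.site_id, int(common.size),
                                             np.nan, np.nan, np.nan,
                                             status="insufficient_data")
    eps = cfg.hic_log2fc_pseudocount
    lfc = float(np.mean(np.log2((ia + eps) / (ib + eps))))
    diffs = ia - ib
    if np.all(diffs == 0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(ia, ib)
        t, p = float(t), float(p)
    return DifferentialInteractionResult(site.site_id, int(common.size), lfc, t, p)


def differential_interaction_table(sites: Sequence[BindingSite], map_a: dict,
                                   map_b: dict, cfg: PipelineConfig
                                   ) -> pd.DataFrame:
    """Run :func:`differential_interaction` for many sites over per-chrom maps."""
    rows = []
    for s in sites:
        if s.chrom not in map_a or s.chrom not in map_b:
            rows.append((s.site_id, 0, np.nan, np.nan, np.nan, "no_map"))
            continue
        r = differential_interaction(s, map_a[s.chrom], map_b[s.chrom], cfg)
        rows.append((r.site_id, r.n_flank_bins, r.mean_log2_fc,
                     r.t_statistic, r.p_value, r.status))
    return pd.DataFrame(rows, columns=["site_id", "n_flank_bins", "mean_log2_fc",
                                       "t_statistic", "p_value", "status"]
                        ).set_index("site_id")


def find_differential_regions(sites: Sequence[BindingSite], map_a: dict,
                              map_b: dict, domains: dict, cfg: PipelineConfig,
                              direction: str = "increased") -> pd.DataFrame:
    """Intra-domain bins whose interaction with the site changed, a vs b.

    For every site with a domain, reports bins inside the domain whose
    log2 fold change (with pseudocount) exceeds +hic_region_log2fc
    (direction 'increased') or falls below -hic_region_log2fc ('decreased')
    AND whose mean log2 interaction across the two conditions is positive.
    Sites without a domain are skipped with a logged status.  Output columns
    are BED-ready (chrom, start, end) plus the statistics.
    """
    if direction not in ("increased", "decreased"):
        raise ValueError("direction must be 'increased' or 'decreased'")
    eps = cfg.hic_log2fc_pseudocount
    thr = cfg.hic_region_log2fc
    rows = []
    for s in sites:
        dom: Optional[ChromatinDomain] = domains.get(s.site_id)
        if dom is None:
            logger.info("site %s has no domain; skipped", s.site_id)
            continue
        if s.chrom not in map_a or s.chrom not in map_b:
            continue
        ca, cb = map_a[s.chrom], map_b[s.chrom]
        anchor = ca.bin_of(s.center)
        b_lo = max(dom.left_pos // ca.bin_size, 0)
        b_hi = min((dom.right_pos - 1) // ca.bin_size, ca.n_bins - 1)
        bins = np.arange(b_lo, b_hi + 1)
        bins = bins[bins != anchor]
        ia = ca.matrix[anchor, bins]
        ib = cb.matrix[anchor, bins]
        lfc = np.log2((ia + eps) / (ib + eps))
        mean_log2 = 0.5 * (np.log2(ia + eps) + np.log2(ib + eps))
        if direction == "increased":
            hit = (lfc > thr) & (mean_log2 > 0)
        else:
            hit = (lfc < -thr) & (mean_log2 > 0)
        for b, f, m in zip(bins[hit], lfc[hit], mean_log2[hit]):
            rows.append((s.chrom, int(b) * ca.bin_size, (int(b) + 1) * ca.bin_size,
                         s.site_id, int(b), float(f), float(m)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "site_id",
                                       "bin", "log2_fc", "mean_log2_interaction"])
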