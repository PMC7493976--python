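"""Differential DNA methylation around binding sites.

Each site is scored over the 300-bp window centered on it: CpGs covered by
at least ``meth_min_coverage`` reads in *both* conditions at the same
position are paired, at least ``meth_min_cpgs`` such CpGs are required, and
the mean per-CpG difference (cancer - normal, percentage points) is
thresholded at ``meth_delta_threshold`` into hyper / hypo / unchanged.
The genome-wide association profile ranks sites by their differential
binding t statistic into equal-count bins and stacks the per-bin status
fractions (the binding-vs-methylation association view).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import BindingSite
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STATUSES = ("hypo", "unchanged", "hyper")


@dataclasses.dataclass
class RegionMethylation:
    site_id: str
    n_cpgs_used: int
    mean_delta: float  # percentage points, cancer - normal
    status: str        # hyper / hypo / unchanged / insufficient


class _CpGIndex:
    """Per-chromosome sorted position index over a CpG table."""

    def __init__(self, table: pd.DataFrame):
        self.by_chrom = {}
        for chrom, grp in table.groupby("chrom"):
            grp = grp.sort_values("start")
            self.by_chrom[chrom] = (
                grp["start"].to_numpy(int),
                grp["percent"].to_numpy(float),
                grp["coverage"].to_numpy(int),
            )

    def window(self, chrom: str, lo: int, hi: int):
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return (np.empty(0, int), np.empty(0), np.empty(0, int))
        pos, pct, cov = entry
        i = np.searchsorted(pos, lo, side="left")
        j = np.searchsorted(pos, hi, side="left")
        return pos[i:j], pct[i:j], cov[i:j]


def region_differential_methylation(site: BindingSite, cancer: "_CpGIndex | pd.DataFrame",
                                    normal: "_CpGIndex | pd.DataFrame",
                                    cfg: PipelineConfig) -> RegionMethylation:
    """Differential methylation of one site's 300-bp centered window.

    CpGs are paired across conditions by exact position; insufficiency
    (< meth_min_cpgs qualifying CpGs) is a status, not an error.
    """
    if isinstance(cancer, pd.DataFrame):
        cancer = _CpGIndex(cancer)
    if isinstance(normal, pd.DataFrame):
        normal = _CpGIndex(normal)
    half = cfg.meth_window // 2
    center = site.center
    lo, hi = center - half, center + half
    pos_c, pct_c, cov_c = cancer.window(site.chrom, lo, hi)
    pos_n, pct_n, cov_n = normal.window(site.chrom, lo, hi)
    common, ic, in_ = np.intersect1d(pos_c, pos_n, return_indices=True)
    ok = (cov_c[ic] >= cfg.meth_min_coverage) & (cov_n[in_] >= cfg.meth_min_coverage)
    n_used = int(ok.sum())
    if n_used < cfg.meth_min_cpgs:
        return RegionMethylation(site.site_id, n_used, np.nan, "insufficient")
    delta = float(np.mean(pct_c[ic][ok] - pct_n[in_][ok]))
    if delta > cfg.meth_delta_threshold:
        status = "hyper"
    elif delta < -cfg.meth_delta_threshold:
        status = "hypo"
    else:
        status = "unchanged"
    return RegionMethylation(site.site_id, n_used, delta, status)


def region_methylation_table(sites: Sequence[BindingSite], cancer: pd.DataFrame,
                             normal: pd.DataFrame, cfg: PipelineConfig
                             ) -> pd.DataFrame:
    """:func:`region_differential_methylation` over many sites."""
    ci, ni = _CpGIndex(cancer), _CpGIndex(normal)
    rows = []
    for s in sites:
        r = region_differential_methylation(s, ci, ni, cfg)
        rows.append((r.site_id, r.n_cpgs_used, r.mean_delta, r.status))
    return pd.DataFrame(rows, columns=["site_id", "n_cpgs_used", "mean_delta",
                                       "status"]).set_index("site_id")


def binding_methylation_association(table: pd.DataFrame, n_bins: int = 100
                                    ) -> pd.DataFrame:
    """Stacked-fraction profile of methylation status along the binding-change axis.

    ``table`` must carry a ``t_statistic`` column (differential binding,
    cancer vs others) and a methylation ``status`` column.  Sites with
    status ``insufficient`` are dropped; the rest are ranked by t statistic
    (ascending) and split into ``n_bins`` equal-count bins, any remainder
    going to the first bins.  Per bin: the fractions of hypo / unchanged /
    hyper (summing to 1) and the median t.
    """
    use = table[table["status"] != "insufficient"].copy()
    use = use[np.isfinite(use["t_statistic"])]
    if len(use) == 0:
        raise ValueError("no sites with sufficient methylation coverage")
    if len(use) < n_bins:
        logger.warning("only %d sites for %d bins; reducing bin count",
                       len(use), n_bins)
        n_bins = len(use)
    use = use.sort_values("t_statistic", kind="mergesort")
    chunks = np.array_split(np.arange(len(use)), n_bins)
    rows = []
    for k, idx in enumerate(chunks):
        grp = use.iloc[idx]
        n = len(grp)
        fr = {st: float((grp["status"] == st).sum()) / n for st in STATUSES}
        rows.append((k, n, float(grp["t_statistic"].median()),
                     fr["hypo"], fr["unchanged"], fr["hyper"]))
    return pd.DataFrame(rows, columns=["bin", "n_sites", "median_t",
                                       "frac_hypo", "frac_unchanged", "frac_hyper"])
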