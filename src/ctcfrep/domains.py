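"""Constitutive-CTCF-bounded chromatin domains and CTCF-gene association.

A site's chromatin domain is the interval between the nearest qualifying
constitutive site on each side: the boundary must lie between
``domain_min_side`` and ``domain_max_side`` from the anchor and its motif
must satisfy the orientation rule (default *divergent*: left boundary on the
'-' strand, right boundary on '+').  Constitutive sites failing either test
are skipped, not treated as blockers.  CTCF-gene association is Pearson
correlation across cell types between normalized binding (sqrt RPKM,
quantile normalized) and expression (sqrt TPM); pairs with R^2 strictly
above the threshold are "highly correlated".
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import BindingSite, UnionAtlas
from .config import PipelineConfig
from .stattests import fisher_two_tailed  # noqa: F401  (re-exported for callers)

logger = logging.getLogger(__name__)

_ORIENTATION_RULES = {
    # (left strand requirement, right strand requirement); None = either, but
    # opposite_any additionally requires the two boundaries to differ.
    "divergent": ("-", "+"),
    "convergent": ("+", "-"),
    "opposite_any": (None, None),
}


@dataclasses.dataclass
class ChromatinDomain:
    anchor_site_id: str
    chrom: str
    left_site_id: str
    right_site_id: str
    left_pos: int    # boundary site centers
    right_pos: int

    @property
    def interval(self) -> tuple:
        return (self.left_pos, self.right_pos)

    def contains(self, pos: int) -> bool:
        return self.left_pos <= pos < self.right_pos


@dataclasses.dataclass
class CtcfGenePair:
    site_id: str
    gene_id: str
    r: float
    r_squared: float
    category: str  # promoter / intra_domain / inter_domain
    highly_correlated: bool
    undefined: bool = False


class ConstitutiveBoundaries:
    """Per-chromosome sorted constitutive site centers with motif strands."""

    def __init__(self, constitutive: UnionAtlas):
        self.by_chrom: dict = {}
        for s in constitutive.sites:
            strand = s.motif.strand if s.motif else None
            self.by_chrom.setdefault(s.chrom, []).append((s.center, strand, s.site_id))
        for chrom in self.by_chrom:
            self.by_chrom[chrom].sort()

    def arrays(self, chrom: str):
        entries = self.by_chrom.get(chrom, [])
        pos = np.array([e[0] for e in entries], dtype=np.int64)
        strands = [e[1] for e in entries]
        ids = [e[2] for e in entries]
        return pos, strands, ids


def build_domain(anchor: BindingSite, boundaries: ConstitutiveBoundaries,
                 cfg: PipelineConfig) -> Optional[ChromatinDomain]:
    """Nearest qualifying constitutive boundary on each side of the anchor.

    Qualifying: distance from the anchor center within
    [domain_min_side, domain_max_side] and motif strand matching the
    orientation rule.  Absent if either side has no qualifying site.  The
    anchor itself need not be constitutive; a constitutive site at the
    anchor's own position is not a boundary.
    """
    pos, strands, ids = boundaries.arrays(anchor.chrom)
    if pos.size == 0:
        return None
    want_left, want_right = _ORIENTATION_RULES[cfg.domain_orientation]
    center = anchor.center
    lo, hi = cfg.domain_min_side, cfg.domain_max_side

    def pick(side: str):
        if side == "left":
            sel = np.nonzero((pos < center) & (center - pos >= lo)
                             & (center - pos <= hi))[0][::-1]  # nearest first
            want = want_left
        else:
            sel = np.nonzero((pos > center) & (pos - center >= lo)
                             & (pos - center <= hi))[0]
            want = want_right
        for i in sel:
            st = strands[i]
            if st is None:
                continue  # boundaries require an oriented motif
            if want is not None and st != want:
                continue
            yield i

    for li in pick("left"):
        for ri in pick("right"):
            if cfg.domain_orientation == "opposite_any" and strands[li] == strands[ri]:
                continue
            return ChromatinDomain(anchor.site_id, anchor.chrom,
                                   ids[li], ids[ri], int(pos[li]), int(pos[ri]))
        # divergent/convergent: left choice does not constrain the right, so
        # only opposite_any needs to try further combinations
        if cfg.domain_orientation != "opposite_any":
            return None
    return None


def build_domains(sites: Sequence[BindingSite], constitutive: UnionAtlas,
                  cfg: PipelineConfig) -> dict:
    """site_id -> ChromatinDomain (sites without a domain are absent)."""
    boundaries = ConstitutiveBoundaries(constitutive)
    out = {}
    for s in sites:
        d = build_domain(s, boundaries, cfg)
        if d is not None:
            out[s.site_id] = d
    return out


# ----------------------------------------------------------------------
# expression association
# ----------------------------------------------------------------------
def correlate_ctcf_gene(site_signal: Sequence[float], gene_expression: Sequence[float],
                        site_id: str = "", gene_id: str = "", category: str = "",
                        r2_threshold: float = 0.25) -> CtcfGenePair:
    """Pearson correlation of binding vs expression across shared cell types.

    Inputs are the already-normalized per-cell-type vectors (sqrt RPKM
    quantile normalized for the site; sqrt TPM for the gene).  Zero variance
    in either vector flags the pair undefined and excludes it from the
    highly-correlated set.
    """
    x = np.asarray(site_signal, dtype=float)
    y = np.asarray(gene_expression, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 shared cell types")
    if np.std(x) == 0 or np.std(y) == 0:
        return CtcfGenePair(site_id, gene_id, np.nan, np.nan, category,
                            highly_correlated=False, undefined=True)
    r = float(stats.pearsonr(x, y)[0])
    r2 = r * r
    return CtcfGenePair(site_id, gene_id, r, r2, category,
                        highly_correlated=bool(r2 > r2_threshold))


def assign_candidate_targets(site: BindingSite, genes: pd.DataFrame,
                             domain: Optional[ChromatinDomain],
                             cfg: PipelineConfig) -> pd.DataFrame:
    """Categorize genes of the site's chromosome for this site.

    Promoter targets: genes whose TSS +/- promoter_halfwidth window overlaps
    the site.  If any exist they are THE candidate targets; otherwise genes
    with a TSS inside the site's domain are intra_domain targets.  All
    remaining same-chromosome genes are inter_domain (pair classification
    only).  Categories are mutually exclusive with precedence
    promoter > intra_domain > inter_domain.
    """
    g = genes.loc[genes["chrom"] == site.chrom,
                  ["gene_id", "chrom", "strand", "tss"]].copy()
    h = cfg.promoter_halfwidth
    promoter = (site.start <= g["tss"] + h) & (g["tss"] - h < site.end)
    if domain is not None:
        intra = (~promoter) & (g["tss"] >= domain.left_pos) & (g["tss"] < domain.right_pos)
    else:
        intra = pd.Series(False, index=g.index)
    g["category"] = np.where(promoter, "promoter",
                             np.where(intra, "intra_domain", "inter_domain"))
    return g


def candidate_target_set(site: BindingSite, genes: pd.DataFrame,
                         domain: Optional[ChromatinDomain],
                         cfg: PipelineConfig) -> pd.DataFrame:
    """The candidate targets proper: promoter genes if any, else intra-domain."""
    cat = assign_candidate_targets(site, genes, domain, cfg)
    prom = cat[cat["category"] == "promoter"]
    if len(prom):
        return prom
    return cat[cat["category"] == "intra_domain"]


# ----------------------------------------------------------------------
# DE enrichment
# ----------------------------------------------------------------------
def de_enrichment(target_genes: Sequence[str], de_table: pd.DataFrame,
                  universe: Sequence[str], cfg: PipelineConfig
                  ) -> tuple[float, float, pd.DataFrame]:
    """Enrichment of differentially expressed genes in a target set.

    ``de_table`` is indexed by gene with columns ``log2fc`` and ``fdr``; a
    gene is DE when |log2fc| > de_log2fc and fdr < de_fdr.  Genes absent
    from the table count as not DE.  Returns (odds ratio, two-tailed Fisher
    p, the 2x2 table as a DataFrame).
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    targets = set(target_genes)
    if not targets <= set(universe):
        raise ValueError("target set must be a subset of the universe")
    de = set()
    for gene in universe:
        if gene in de_table.index:
            row = de_table.loc[gene]
            if abs(float(row["log2fc"])) > cfg.de_log2fc and float(row["fdr"]) < cfg.de_fdr:
                de.add(gene)
    a = len(targets & de)
    b = len(targets - de)
    c = len(de - targets)
    d = len(universe) - a - b - c
    table = pd.DataFrame([[a, b], [c, d]],
                         index=["target", "non_target"], columns=["de", "not_de"])
    odds, p = fisher_two_tailed(table.to_numpy())
    return odds, p, table
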