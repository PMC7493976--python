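"""Cancer-specific lost/gained site calling from occupancy and binding level.

Binding level is an RPKM read-count matrix over union sites, quantile
normalized across datasets.  A site is called *lost* in a cancer type when
its occupancy collapses in the cancer cohort while staying high overall and
in the matched normal tissue, and its binding level drops against both
comparison groups; *gained* is the mirrored set of criteria with an FDR
requirement on the binding-level increase.  Each call carries a per-criterion
ledger so the decision is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import PeakDataset, UnionAtlas, occupancy_by_stratum
from .config import PipelineConfig

logger = logging.getLogger(__name__)

LOST_CRITERIA = ["lost_cancer_freq", "lost_overall_freq", "lost_normal_freq",
                 "lost_t_vs_others", "lost_t_vs_normal", "lost_cancer_rpkm"]
GAINED_CRITERIA = ["gained_cancer_freq", "gained_overall_freq", "gained_normal_zero",
                   "gained_fdr_vs_others", "gained_fdr_vs_normal", "gained_cancer_rpkm"]


class CohortDesign:
    """Dataset-to-cohort assignment.

    Backed by a table with columns ``dataset_id``, ``cohort`` (free label),
    ``cancer_type`` (empty for non-cancer datasets) and ``matched_normal_for``
    (the cancer type a normal cohort serves as matched tissue for, else empty).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"dataset_id", "cohort", "cancer_type", "matched_normal_for"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"design table missing columns {sorted(missing)}")
        self.table = table.reset_index(drop=True).fillna("")
        if self.table["dataset_id"].duplicated().any():
            raise ValueError("duplicate dataset ids in design")

    @property
    def dataset_ids(self) -> list:
        return self.table["dataset_id"].tolist()

    def cancer_datasets(self, cancer_type: str) -> list:
        t = self.table
        return t.loc[t["cancer_type"] == cancer_type, "dataset_id"].tolist()

    def matched_normal_datasets(self, cancer_type: str) -> list:
        t = self.table
        return t.loc[t["matched_normal_for"] == cancer_type, "dataset_id"].tolist()

    def other_datasets(self, cancer_type: str) -> list:
        """All datasets except the cancer type's own (matched normal included)."""
        t = self.table
        return t.loc[t["cancer_type"] != cancer_type, "dataset_id"].tolist()

    def cancer_types(self) -> list:
        return sorted(x for x in self.table["cancer_type"].unique() if x)


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------
def compute_rpkm(counts: pd.DataFrame, site_lengths: Sequence[float],
                 library_sizes: Sequence[float]) -> pd.DataFrame:
    """RPKM = count / (site length in kb x library size in millions)."""
    lengths = np.asarray(site_lengths, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("site lengths must be positive")
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    if lengths.shape[0] != counts.shape[0] or libs.shape[0] != counts.shape[1]:
        raise ValueError("length/library-size dimensions do not match counts")
    vals = counts.to_numpy(float) / (lengths[:, None] / 1e3) / (libs[None, :] / 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean of the column-sorted values.

    The reference distribution is the vector of row means of the sorted
    columns; ties within a column receive the mean of the reference values
    at the tied ranks.  After normalization the sorted values of every
    column are identical.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    vals = matrix.to_numpy(float)
    ref = np.mean(np.sort(vals, axis=0), axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average the reference values over tied input values
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ----------------------------------------------------------------------
# differential binding
# ----------------------------------------------------------------------
@dataclasses.dataclass
class DifferentialBindingResult:
    site_id: str
    t_statistic: float
    p_value: float
    fdr: float
    effect_size: float  # Cohen's d, pooled sd
    log2_fold_change: float
    degenerate: bool = False


def differential_binding(matrix: pd.DataFrame, cols_a: Sequence[str],
                         cols_b: Sequence[str], pseudocount: float = 0.01,
                         welch: bool = False) -> pd.DataFrame:
    """Row-wise unpaired two-tailed Student's t test of group a vs group b.

    Pooled-variance t by default (Welch behind a flag); Cohen's d uses the
    pooled sd.  Benjamini-Hochberg FDR is computed across all rows of the
    call, which defines the comparison family.  Degenerate rows (zero pooled
    variance) get t = 0, p = 1 when the means agree and are flagged with
    p = 0 when they differ.
    """
    a = matrix[list(cols_a)].to_numpy(float)
    b = matrix[list(cols_b)].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 datasets")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    diff = ma - mb
    if welch:
        se = np.sqrt(va / na + vb / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df_w = se ** 4 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        dof = df_w
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    else:
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        se = sp * np.sqrt(1.0 / na + 1.0 / nb)
        dof = np.full(diff.shape, na + nb - 2, dtype=float)
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        d = diff / sp
    zero_same = degenerate & (diff == 0)
    zero_diff = degenerate & (diff != 0)
    t[zero_same], p[zero_same], d[zero_same] = 0.0, 1.0, 0.0
    t[zero_diff] = np.sign(diff[zero_diff]) * np.inf
    p[zero_diff] = 0.0
    d[zero_diff] = np.sign(diff[zero_diff]) * np.inf
    fdr = multipletests(p, method="fdr_bh")[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2((ma + pseudocount) / (mb + pseudocount))
    return pd.DataFrame({
        "t_statistic": t, "p_value": p, "fdr": fdr, "effect_size": d,
        "log2_fold_change": lfc, "mean_a": ma, "mean_b": mb,
        "degenerate": degenerate,
    }, index=matrix.index)


# ----------------------------------------------------------------------
# the caller
# ----------------------------------------------------------------------
def call_cancer_specific_sites(atlas: UnionAtlas,
                               peak_datasets: Sequence[PeakDataset],
                               matrix: pd.DataFrame,
                               design: CohortDesign,
                               cancer_type: str,
                               cfg: PipelineConfig) -> pd.DataFrame:
    """Call lost/gained/none per site for one cancer type.

    ``matrix`` must be the quantile-normalized RPKM matrix indexed by site id
    with one column per included dataset.  Occupancy is recomputed per
    stratum (cancer cohort, all datasets, matched normal).  The returned
    table carries one boolean column per criterion (the ledger), the two
    differential-binding summaries, and the final ``call``.

    Lost requires ALL of: cancer occupancy frequency <= 0.2; overall
    frequency >= 0.7; matched-normal frequency >= 0.5 with score >= 2;
    t < 0 vs all other datasets; t < 0 vs matched normal; mean cancer
    binding < 5.  Gained requires ALL of: cancer frequency >= 0.5 with
    score >= 2; overall frequency <= 0.2; matched-normal score = 0;
    t > 0 with BH FDR <= 0.01 vs all others and vs matched normal; mean
    cancer binding > 2.
    """
    cancer = [d for d in design.cancer_datasets(cancer_type) if d in matrix.columns]
    normal = [d for d in design.matched_normal_datasets(cancer_type)
              if d in matrix.columns]
    others = [d for d in design.other_datasets(cancer_type) if d in matrix.columns]
    site_ids = [s.site_id for s in atlas.sites]
    out = pd.DataFrame(index=pd.Index(site_ids, name="site_id"))
    if not normal:
        logger.warning("no matched normal datasets for %s: calls disabled", cancer_type)
        out["call"] = "none"
        out.attrs["status"] = "disabled_no_matched_normal"
        out.attrs["cancer_type"] = cancer_type
        return out
    if len(cancer) < 2:
        raise ValueError(f"cancer type {cancer_type!r} needs >= 2 datasets")

    occ = occupancy_by_stratum(
        atlas, peak_datasets,
        {"cancer": cancer, "overall": list(matrix.columns), "normal": normal}, cfg)
    occ = occ.loc[site_ids]

    sub = matrix.loc[site_ids]
    vs_others = differential_binding(sub, cancer, others)
    vs_normal = differential_binding(sub, cancer, normal)
    mean_cancer = sub[cancer].to_numpy(float).mean(axis=1)

    out["cancer_score"] = occ["cancer"]
    out["cancer_freq"] = occ["cancer_freq"]
    out["overall_freq"] = occ["overall_freq"]
    out["normal_score"] = occ["normal"]
    out["normal_freq"] = occ["normal_freq"]
    out["mean_cancer_signal"] = mean_cancer
    out["t_vs_others"] = vs_others["t_statistic"]
    out["fdr_vs_others"] = vs_others["fdr"]
    out["t_vs_normal"] = vs_normal["t_statistic"]
    out["fdr_vs_normal"] = vs_normal["fdr"]
    out["effect_size_vs_others"] = vs_others["effect_size"]
    out["log2fc_vs_others"] = vs_others["log2_fold_change"]

    out["lost_cancer_freq"] = out["cancer_freq"] <= cfg.lost_cancer_max_freq
    out["lost_overall_freq"] = out["overall_freq"] >= cfg.lost_overall_min_freq
    out["lost_normal_freq"] = ((out["normal_freq"] >= cfg.lost_normal_min_freq)
                               & (out["normal_score"] >= cfg.matched_normal_min_score))
    out["lost_t_vs_others"] = out["t_vs_others"] < 0
    out["lost_t_vs_normal"] = out["t_vs_normal"] < 0
    out["lost_cancer_rpkm"] = out["mean_cancer_signal"] < cfg.lost_cancer_max_rpkm

    out["gained_cancer_freq"] = ((out["cancer_freq"] >= cfg.gained_cancer_min_freq)
                                 & (out["cancer_score"] >= cfg.matched_normal_min_score))
    out["gained_overall_freq"] = out["overall_freq"] <= cfg.gained_overall_max_freq
    out["gained_normal_zero"] = out["normal_score"] == 0
    out["gained_fdr_vs_others"] = ((out["t_vs_others"] > 0)
                                   & (out["fdr_vs_others"] <= cfg.specificity_fdr))
    out["gained_fdr_vs_normal"] = ((out["t_vs_normal"] > 0)
                                   & (out["fdr_vs_normal"] <= cfg.specificity_fdr))
    out["gained_cancer_rpkm"] = out["mean_cancer_signal"] > cfg.gained_cancer_min_rpkm

    lost = out[LOST_CRITERIA].all(axis=1)
    gained = out[GAINED_CRITERIA].all(axis=1)
    both = lost & gained
    if both.any():  # impossible by construction (0.7 vs 0.2 overall frequency)
        raise AssertionError("site called both lost and gained")
    out["call"] = np.where(lost, "lost", np.where(gained, "gained", "none"))
    out.attrs["status"] = "ok"
    out.attrs["cancer_type"] = cancer_type
    for sid, row in out[out["call"] != "none"].iterrows():
        logger.info("%s %s: %s", cancer_type, row["call"], sid)
    return out


# ----------------------------------------------------------------------
# chromatin accessibility
# ----------------------------------------------------------------------
def prepare_accessibility(raw_counts: pd.DataFrame, pseudocount: float = 5.0
                          ) -> pd.DataFrame:
    """log2(x + pseudocount) then quantile normalization of raw insertion counts."""
    return quantile_normalize(np.log2(raw_counts + pseudocount))


def differential_accessibility_score(matrix: pd.DataFrame,
                                     cancer_cols: Sequence[str],
                                     other_cols: Sequence[str],
                                     prepared: bool = True) -> pd.Series:
    """Per-site fold change of mean normalized accessibility, cancer vs others.

    ``matrix`` is a normalized insertion-count matrix (set ``prepared=False``
    to apply the log2(x+5) + quantile-normalization preparation here).
    """
    if not prepared:
        matrix = prepare_accessibility(matrix)
    if not list(cancer_cols) or not list(other_cols):
        raise ValueError("empty stratum")
    num = matrix[list(cancer_cols)].mean(axis=1)
    den = matrix[list(other_cols)].mean(axis=1)
    return num / den
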