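"""Transcription-factor binding enrichment over a regulatory-element repertoire.

Given a repertoire of candidate cis-regulatory elements (a stand-in for the
union DNase I hypersensitive sites) and a binary binding profile per TF over
those elements, query regions select the subset of elements they overlap and
each TF is scored by a two-tailed Fisher's exact test of binding inside vs
outside the selection.  TFs are ranked by ascending p value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stattests import fisher_two_tailed

logger = logging.getLogger(__name__)


class RegulatoryRepertoire:
    """Ordered, non-overlapping candidate elements (chrom, start, end)."""

    def __init__(self, elements: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required <= set(elements.columns):
            raise ValueError(f"repertoire needs columns {sorted(required)}")
        el = elements.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, grp in el.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(starts >= ends):
                raise ValueError("elements must have start < end")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping elements on {chrom}")
        self.elements = el

    @property
    def n_elements(self) -> int:
        return len(self.elements)


def overlap_repertoire(regions: pd.DataFrame,
                       repertoire: RegulatoryRepertoire) -> np.ndarray:
    """Boolean selection vector: element overlaps >= 1 bp with any query region."""
    sel = np.zeros(repertoire.n_elements, dtype=bool)
    el = repertoire.elements
    for chrom, grp in regions.groupby("chrom"):
        sub = el.index[el["chrom"] == chrom]
        if len(sub) == 0:
            continue
        starts = el.loc[sub, "start"].to_numpy()
        ends = el.loc[sub, "end"].to_numpy()
        for s, e in grp[["start", "end"]].itertuples(index=False):
            # elements with start < e and end > s overlap [s, e)
            i = np.searchsorted(ends, s, side="right")
            j = np.searchsorted(starts, e, side="left")
            if j > i:
                sel[sub[i:j]] = True
    return sel


def tf_rank_enrichment(selection: np.ndarray, profiles: pd.DataFrame) -> pd.DataFrame:
    """Rank TFs by binding enrichment inside the selected elements.

    ``profiles`` is an elements x TFs 0/1 matrix aligned to the repertoire
    order.  For each TF a 2x2 table {bound, unbound} x {selected, unselected}
    is tested with the two-tailed Fisher's exact test; output is sorted by
    ascending p, ties broken by descending odds ratio then TF name.  An
    all-zero profile records p = 1 and odds ratio 0.
    """
    selection = np.asarray(selection, dtype=bool)
    if selection.size != profiles.shape[0]:
        raise ValueError("selection length must match number of elements")
    if not selection.any():
        raise ValueError("empty selection")
    n_sel = int(selection.sum())
    n = selection.size
    rows = []
    for tf in profiles.columns:
        bound = profiles[tf].to_numpy() != 0
        if not bound.any():
            rows.append((tf, 0.0, 1.0, 0, n_sel))
            continue
        a = int((bound & selection).sum())
        b = int(bound.sum()) - a
        c = n_sel - a
        d = n - a - b - c
        odds, p = fisher_two_tailed([[a, b], [c, d]])
        rows.append((tf, odds, p, a, n_sel))
    out = pd.DataFrame(rows, columns=["tf", "odds_ratio", "p_value",
                                      "n_bound_selected", "n_selected"])
    out = out.sort_values(["p_value", "odds_ratio", "tf"],
                          ascending=[True, False, True], kind="mergesort")
    return out.reset_index(drop=True)
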