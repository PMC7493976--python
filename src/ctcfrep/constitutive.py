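"""Constitutive-site model: power-law fit of the occupancy distribution.

The number of sites observed at occupancy score ``i`` falls off roughly as a
power law, ``E_i = a * (i - b)^(-c)``, except for an excess of sites bound in
nearly every dataset.  The constitutive cutoff ``A`` is the smallest score at
which the observed tail exceeds the expected tail by more than
``excess_factor`` (i.e. observed > (1 + excess_factor) x expected);
constitutive sites are those with occupancy score >= A + 1.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .atlas import UnionAtlas
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    pass


@dataclasses.dataclass
class OccupancyDistribution:
    """Observed site counts O_i per occupancy score i = 1..n_datasets."""
    n_datasets: int
    counts: dict  # score -> count

    def __post_init__(self):
        clean = {}
        for i, o in self.counts.items():
            i = int(i)
            if not (1 <= i <= self.n_datasets):
                raise ValueError(f"score {i} outside 1..{self.n_datasets}")
            if o < 0:
                raise ValueError("counts must be >= 0")
            clean[i] = float(o)
        self.counts = clean

    @classmethod
    def from_atlas(cls, atlas: UnionAtlas) -> "OccupancyDistribution":
        counts: dict = {}
        for s in atlas.sites:
            if s.occupancy_score >= 1:
                counts[s.occupancy_score] = counts.get(s.occupancy_score, 0) + 1
        return cls(atlas.n_datasets, counts)

    @classmethod
    def from_array(cls, o: Sequence[float], n_datasets: int | None = None
                   ) -> "OccupancyDistribution":
        """Dense vector o[0] = O_1, o[1] = O_2, ..."""
        o = np.asarray(o, dtype=float)
        n = n_datasets if n_datasets is not None else o.size
        return cls(n, {i + 1: v for i, v in enumerate(o) if v > 0})

    def dense(self) -> np.ndarray:
        out = np.zeros(self.n_datasets)
        for i, o in self.counts.items():
            out[i - 1] = o
        return out


@dataclasses.dataclass
class PowerLawFit:
    """E_i = a * (i - b)^(-c), fitted on ``fit_range`` (inclusive scores)."""
    a: float
    b: float
    c: float
    fit_range: tuple
    residual: float  # sum of squared log-residuals over the fitted scores

    def expected(self, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        base = scores - self.b
        with np.errstate(invalid="ignore"):
            out = self.a * np.power(base, -self.c)
        out[~np.isfinite(out)] = np.inf
        return out


def fit_power_law(dist: OccupancyDistribution,
                  fit_range: tuple | None = None) -> PowerLawFit:
    """Least squares of log(O_i) on log(i - b), with b found by bounded search.

    Only scores with O_i > 0 inside ``fit_range`` enter the fit; at least 5
    are required.  b is optimized over [0, min(fit_range) - 0.01] so the
    shifted scores stay positive; the inner (a, c) solve is ordinary linear
    regression in log space, which is robust on heavy-tailed counts.
    """
    lo, hi = fit_range if fit_range is not None else (1, dist.n_datasets)
    pts = sorted((i, o) for i, o in dist.counts.items() if lo <= i <= hi and o > 0)
    if len(pts) < 5:
        raise FitError(f"need >= 5 nonzero counts in fit range, got {len(pts)}")
    i_arr = np.array([p[0] for p in pts], dtype=float)
    log_o = np.log([p[1] for p in pts])

    def sse(b: float) -> float:
        x = np.log(i_arr - b)
        slope, intercept, *_ = stats.linregress(x, log_o)
        return float(np.sum((log_o - (intercept + slope * x)) ** 2))

    b_hi = lo - 0.01
    if b_hi <= 0:
        b_opt = 0.0
    else:
        res = optimize.minimize_scalar(sse, bounds=(0.0, b_hi), method="bounded",
                                       options={"xatol": 1e-8})
        b_opt = float(res.x)
        # the boundary b=0 is a legitimate optimum the bounded search can miss
        if sse(0.0) <= res.fun:
            b_opt = 0.0
    x = np.log(i_arr - b_opt)
    slope, intercept, *_ = stats.linregress(x, log_o)
    c = -float(slope)
    a = float(np.exp(intercept))
    if c <= 0:
        raise FitError(f"fitted exponent must be positive, got c={c:.3g}")
    return PowerLawFit(a=a, b=b_opt, c=c, fit_range=(lo, hi), residual=sse(b_opt))


def determine_cutoff(dist: OccupancyDistribution, fit: "PowerLawFit | Sequence[float]",
                     excess_factor: float = 5.0) -> Optional[int]:
    """Smallest score i whose observed-over-expected tail excess exceeds the factor.

    A = min{ i : sum_{j>=i}(O_j - E_j) / sum_{j>=i} E_j > excess_factor }.
    Returns None when no score qualifies (a valid outcome: no excess tail).
    ``fit`` may also be a dense vector of expected counts E_1..E_N.
    """
    n = dist.n_datasets
    scores = np.arange(1, n + 1)
    o = dist.dense()
    if isinstance(fit, PowerLawFit):
        e = fit.expected(scores)
    else:
        e = np.asarray(fit, dtype=float)
        if e.shape != (n,):
            raise ValueError(f"expected-count vector must have length {n}")
    if not np.all(np.isfinite(e)):
        # scores at or below b have undefined expectation; exclude them
        bad = ~np.isfinite(e)
        e = e.copy()
        o = o.copy()
        e[bad] = 0.0
        o[bad] = 0.0
    tail_o = np.cumsum(o[::-1])[::-1]
    tail_e = np.cumsum(e[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (tail_o - tail_e) / tail_e
    qualifies = (tail_e > 0) & (ratio > excess_factor)
    idx = np.nonzero(qualifies)[0]
    if idx.size == 0:
        return None
    return int(scores[idx[0]])


def select_constitutive(atlas: UnionAtlas, A: Optional[int],
                        cfg: PipelineConfig) -> UnionAtlas:
    """Sites with occupancy score >= A + 1 (strictly above the cutoff).

    When the excess-tail cutoff is absent, falls back to the frequency rule
    ``score >= ceil(constitutive_frequency * n_datasets)``; which rule fired
    is logged.
    """
    if A is not None:
        cut = A + 1
        logger.info("constitutive cutoff from excess-tail model: score >= %d", cut)
    else:
        cut = int(np.ceil(cfg.constitutive_frequency * atlas.n_datasets))
        logger.info("excess-tail cutoff absent; frequency fallback: score >= %d", cut)
    keep = [s.site_id for s in atlas.sites if s.occupancy_score >= cut]
    return atlas.subset(keep)
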