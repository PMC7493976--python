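"""Position weight matrix scoring with exact background p-values.

A PWM is stored as per-position log-likelihood ratios against a background
nucleotide distribution.  Scores are quantized to a fixed grid (default
1e-3 log-units) so that the null score distribution — the distribution of
the score of a random background sequence — can be computed *exactly* by
dynamic programming over the per-position score lattice.  Every sequence
score is then an exact multiple of the grid step, and tail probabilities
agree with brute-force enumeration up to floating point.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: background nucleotide frequencies for A, C, G, T used throughout
DEFAULT_BACKGROUND = (0.275, 0.225, 0.225, 0.275)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


class PWM:
    """Log-likelihood-ratio position weight matrix.

    Parameters
    ----------
    probs : (4, w) array
        Per-position base probabilities (rows A, C, G, T).
    background : length-4 sequence
        Background frequencies for A, C, G, T; must sum to 1.
    step : float
        Quantization step for log-odds scores, in log-units.
    name : str
        Optional motif name.
    """

    def __init__(self, probs, background=DEFAULT_BACKGROUND, step: float = 1e-3,
                 name: str = "pwm"):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError(f"probs must be (4, w), got {probs.shape}")
        if probs.shape[1] < 1:
            raise ValueError("PWM must have at least one column")
        if np.any(probs <= 0):
            raise ValueError("probabilities must be strictly positive "
                             "(apply a pseudocount to the counts first)")
        self.background = np.asarray(background, dtype=float)
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be 4 frequencies summing to 1")
        self.step = float(step)
        self.name = name
        probs = probs / probs.sum(axis=0, keepdims=True)
        self.probs = probs
        raw = np.log(probs) - np.log(self.background)[:, None]
        # integer lattice representation; all downstream scores are k * step
        self._lattice = np.round(raw / self.step).astype(np.int64)
        self.log_odds = self._lattice * self.step
        self._dist_cache: tuple | None = None

    # ------------------------------------------------------------------
    @classmethod
    def from_counts(cls, counts, background=DEFAULT_BACKGROUND,
                    pseudocount: float = 0.5, **kw) -> "PWM":
        """Build a PWM from a 4 x w count matrix with a +pseudocount per cell."""
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        return cls(counts + pseudocount, background=background, **kw)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=0))

    @property
    def max_score(self) -> float:
        return float(np.max(self.log_odds, axis=0).sum())

    def reverse_complemented(self) -> "PWM":
        """PWM scoring the reverse-complement strand of the same motif."""
        rc = PWM.__new__(PWM)
        rc.background = self.background
        rc.step = self.step
        rc.name = self.name + "_rc"
        rc.probs = self.probs[::-1, ::-1].copy()
        rc._lattice = self._lattice[::-1, ::-1].copy()
        rc.log_odds = rc._lattice * rc.step
        rc._dist_cache = None
        return rc

    # ------------------------------------------------------------------
    def encode(self, seq: str) -> np.ndarray:
        """Sequence -> base indices; non-ACGT becomes -1."""
        return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=np.int64)

    def score(self, seq: str, skip_invalid: bool = False) -> float:
        """Log-likelihood-ratio score of a sequence of exactly PWM width.

        Non-ACGT positions raise unless ``skip_invalid``, in which case they
        contribute zero (logged).
        """
        idx = self.encode(seq)
        if idx.size != self.width:
            raise ValueError(f"sequence length {idx.size} != PWM width {self.width}")
        bad = idx < 0
        if bad.any():
            if not skip_invalid:
                raise ValueError("sequence contains non-ACGT bases")
            logger.warning("skipping %d non-ACGT position(s) in %r", bad.sum(), seq)
        cols = np.nonzero(~bad)[0]
        return float(self.log_odds[idx[cols], cols].sum())

    def score_windows(self, seq: str) -> np.ndarray:
        """Scores of every width-w window of ``seq`` (NaN where non-ACGT)."""
        idx = self.encode(seq)
        w = self.width
        n = idx.size - w + 1
        if n <= 0:
            return np.empty(0)
        valid = idx >= 0
        safe = np.where(valid, idx, 0)
        per_pos = np.empty((4, idx.size))
        out = np.zeros(n)
        ok = np.ones(n, dtype=bool)
        for j in range(w):
            sl = slice(j, j + n)
            out += self.log_odds[safe[sl], j]
            ok &= valid[sl]
        out[~ok] = np.nan
        return out

    # ------------------------------------------------------------------
    def score_distribution(self) -> tuple[int, np.ndarray, np.ndarray]:
        """Exact null score distribution on the integer lattice.

        Returns ``(kmin, pmf, tail)`` where the achievable lattice scores are
        ``(kmin + j) * step`` for ``j`` in ``range(len(pmf))`` and
        ``tail[j] = P(score >= (kmin + j) * step)`` for a random sequence
        drawn from the background.
        """
        if self._dist_cache is not None:
            return self._dist_cache
        kmin = int(self._lattice.min(axis=0).sum())
        kmax = int(self._lattice.max(axis=0).sum())
        size = kmax - kmin + 1
        pmf = np.zeros(size)
        pmf[0] = 1.0
        lo = 0  # current distribution occupies offsets [0, hi) relative to running kmin
        run_min = 0
        run_max = 0
        for j in range(self.width):
            ks = self._lattice[:, j]
            new_min = run_min + int(ks.min())
            new_max = run_max + int(ks.max())
            new = np.zeros(new_max - new_min + 1)
            width_old = run_max - run_min + 1
            for b in range(4):
                off = (run_min + int(ks[b])) - new_min
                new[off:off + width_old] += self.background[b] * pmf[:width_old]
            pmf = new
            run_min, run_max = new_min, new_max
        assert run_min == kmin and run_max == kmax
        tail = np.cumsum(pmf[::-1])[::-1]
        self._dist_cache = (kmin, pmf, tail)
        return self._dist_cache

    def exact_pvalue(self, score: float) -> float:
        """P(background-sequence score >= ``score``), exact on the lattice.

        Monotone non-increasing in ``score``; ``-inf`` maps to 1.
        """
        if not np.isfinite(score):
            return 1.0 if score < 0 else 0.0
        kmin, _, tail = self.score_distribution()
        # smallest lattice point >= score, with slack for float error so an
        # achievable score includes its own lattice mass
        k = int(np.ceil(score / self.step - 1e-6))
        j = k - kmin
        if j <= 0:
            return 1.0
        if j >= tail.size:
            return 0.0
        return float(tail[j])
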