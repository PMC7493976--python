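"""Pipeline configuration: every tunable threshold in one validated, flat namespace.

All genomic quantities are in base pairs with 0-based half-open coordinates.
Each stage receives the whole :class:`PipelineConfig` so that thresholds stay
auditable in one place rather than being scattered across call sites.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a configuration file is malformed or violates an invariant."""


@dataclasses.dataclass
class PipelineConfig:
    """Flat namespace of all pipeline thresholds.

    Defaults correspond to the published CTCF-repertoire analysis: peaks are
    represented as 150-bp summit-centered windows (the inflection point of the
    adjacent-summit gap distribution), occupancy-based site classes use the
    0.2 / 0.5 / 0.7 frequency bounds, and so on.  See ``docs/methods.md``.
    """

    # --- atlas construction ---
    merge_halfwidth: int = 75          # bp each side of a summit
    merge_gap_cutoff: int = 150        # summit-gap cutoff implied by the halfwidth
    min_peaks_per_dataset: int = 2000  # datasets below this are excluded
    min_fold_enrichment: float = 4.0   # per-peak fold-enrichment filter
    high_confidence_min_occupancy: int = 3

    # --- constitutive-site model ---
    excess_factor: float = 5.0           # observed tail must exceed expected by this ratio
    constitutive_frequency: float = 0.8  # fallback frequency cutoff

    # --- cancer-specific site calling ---
    lost_cancer_max_freq: float = 0.2
    lost_overall_min_freq: float = 0.7
    lost_normal_min_freq: float = 0.5
    matched_normal_min_score: int = 2
    lost_cancer_max_rpkm: float = 5.0
    gained_cancer_min_freq: float = 0.5
    gained_overall_max_freq: float = 0.2
    gained_cancer_min_rpkm: float = 2.0
    specificity_fdr: float = 0.01

    # --- domains & expression ---
    promoter_halfwidth: int = 2000
    domain_min_side: int = 100_000
    domain_max_side: int = 1_000_000
    domain_orientation: str = "divergent"  # {divergent, convergent, opposite_any}
    r2_threshold: float = 0.25

    # --- Hi-C ---
    hic_bin_size: int = 5000
    hic_flank_L: int = 500_000
    hic_log2fc_pseudocount: float = 0.01
    hic_region_log2fc: float = 1.0

    # --- methylation ---
    meth_window: int = 300
    meth_min_cpgs: int = 3
    meth_min_coverage: int = 5
    meth_delta_threshold: float = 20.0  # percentage points

    # --- mutations & motif ---
    mutation_window: int = 400
    motif_window: int = 19
    pwm_background: tuple = (0.275, 0.225, 0.225, 0.275)  # A, C, G, T
    pwm_pvalue_threshold: float = 1e-4
    pwm_pseudocount: float = 0.5

    # --- differential expression thresholds (consumed, not fitted) ---
    de_log2fc: float = 1.0
    de_fdr: float = 1e-5

    random_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bp_fields = (
            "merge_halfwidth", "merge_gap_cutoff", "promoter_halfwidth",
            "domain_min_side", "domain_max_side", "hic_bin_size", "hic_flank_L",
            "meth_window", "mutation_window", "motif_window",
        )
        for name in bp_fields:
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        frac_fields = (
            "constitutive_frequency", "lost_cancer_max_freq", "lost_overall_min_freq",
            "lost_normal_min_freq", "gained_cancer_min_freq", "gained_overall_max_freq",
            "specificity_fdr", "r2_threshold", "pwm_pvalue_threshold", "de_fdr",
        )
        for name in frac_fields:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        bg = tuple(float(x) for x in self.pwm_background)
        if len(bg) != 4 or any(x < 0 for x in bg):
            raise ConfigError("pwm_background must be 4 non-negative frequencies")
        if not math.isclose(sum(bg), 1.0, abs_tol=1e-12):
            raise ConfigError(f"pwm_background must sum to 1, got {sum(bg)}")
        self.pwm_background = bg
        if self.domain_orientation not in ("divergent", "convergent", "opposite_any"):
            raise ConfigError(
                f"domain_orientation must be divergent/convergent/opposite_any, "
                f"got {self.domain_orientation!r}"
            )
        if self.merge_gap_cutoff != 2 * self.merge_halfwidth:
            logger.warning(
                "merge_gap_cutoff (%d) != 2 x merge_halfwidth (%d); summit windows "
                "no longer tile the gap cutoff", self.merge_gap_cutoff, self.merge_halfwidth,
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pwm_background"] = list(self.pwm_background)
        return d


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML or JSON mapping.

    Omitted keys take their defaults; an empty file yields all defaults.
    Unknown keys and invariant violations raise :class:`ConfigError`.
    """
    if path is None:
        return PipelineConfig()
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix == ".json":
            data = json.loads(text) if text.strip() else {}
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "pwm_background" in data:
        data["pwm_background"] = tuple(data["pwm_background"])
    return PipelineConfig(**data)
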