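"""Self-consistent synthetic multi-omics scenario with planted ground truth.

The generator emulates a cross-cohort CTCF ChIP-seq compendium at desk
scale: a panel of peak-call datasets over one set of genomic sites whose
per-dataset presence depends on a planted site class, an RPKM-like read
count matrix tied to the same presence draws, distance-decaying Hi-C
contact maps with interaction boosts planted at gained/lost sites, CpG
methylation shifted against binding change, an expression panel correlated
with planted site-gene pairs, mutations, and a regulatory-element
repertoire with one TF concentrated in gained-site domains.

Site classes and their per-cohort presence probabilities are the study
conditions: *constitutive* sites are bound nearly everywhere, *common*
sites broadly, *cancer_lost* sites everywhere except the cancer cohort,
*cancer_gained* sites in the cancer cohort only (never in the matched
normal, by construction), and *sample_specific* sites sporadically.

Each modality draws from its own seeded substream, so adding one modality
never perturbs another; everything is byte-reproducible given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .atlas import BindingSite, MotifHit, PeakCall, PeakDataset
from .config import PipelineConfig
from .domains import ConstitutiveBoundaries, build_domain
from .hic import ContactMap
from .pwm import ALPHABET, PWM, reverse_complement

logger = logging.getLogger(__name__)

CLASSES = ("constitutive", "common", "cancer_lost", "cancer_gained", "sample_specific")
COHORTS = ("cancer", "normal", "other")

# a deliberately synthetic, information-rich 19-bp consensus (not a database motif)
SYNTHETIC_CTCF_CONSENSUS = "CCACTAGGTGGCAGCTAGG"

_STREAMS = {"sites": 0, "peaks": 1, "signal": 2, "genome": 3, "hic": 4,
            "methylation": 5, "mutations": 6, "expression": 7, "repertoire": 8}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def synthetic_ctcf_pfm(n_observations: int = 100, dominant: int = 85) -> np.ndarray:
    """A synthetic CTCF-like position frequency matrix (4 x 19 counts)."""
    w = len(SYNTHETIC_CTCF_CONSENSUS)
    minor = (n_observations - dominant) // 3
    counts = np.full((4, w), minor, dtype=float)
    for j, base in enumerate(SYNTHETIC_CTCF_CONSENSUS):
        counts[ALPHABET.index(base), j] = n_observations - 3 * minor
    return counts


@dataclasses.dataclass
class ScenarioConfig:
    """Study conditions of the synthetic scenario (see module docstring)."""
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_sites: int = 2000
    n_datasets_cancer: int = 8
    n_datasets_normal_matched: int = 8
    n_datasets_other: int = 24
    cancer_type: str = "TALL"
    normal_cohort: str = "CD4T"
    class_fractions: dict = dataclasses.field(default_factory=lambda: {
        "constitutive": 0.10, "common": 0.55, "cancer_lost": 0.025,
        "cancer_gained": 0.025, "sample_specific": 0.30})
    presence: dict = dataclasses.field(default_factory=lambda: {
        "constitutive":    {"cancer": 0.95, "normal": 0.95, "other": 0.95},
        "common":          {"cancer": 0.80, "normal": 0.80, "other": 0.80},
        "cancer_lost":     {"cancer": 0.02, "normal": 0.97, "other": 0.97},
        "cancer_gained":   {"cancer": 0.85, "normal": 0.00, "other": 0.003},
        "sample_specific": {"cancer": 0.05, "normal": 0.05, "other": 0.05}})
    site_halfwidth: int = 75
    min_site_spacing: int = 1000
    summit_jitter_sd: float = 10.0
    background_rpkm: float = 0.5
    signal_effect_log2fc: float = 4.0   # bound level = background * 2^effect
    signal_noise_sd: float = 0.15       # lognormal sd (natural-log units)
    library_size: int = 40_000_000
    hic_decay_exponent: float = 1.0
    hic_base_count: float = 60.0
    hic_interaction_boost: float = 2.0
    meth_shift: float = 30.0            # percentage points at planted sites
    meth_baseline: float = 25.0
    meth_cpg_noise_sd: float = 6.0
    meth_coverage_mean: float = 25.0
    meth_low_coverage_mean: float = 1.5
    meth_low_coverage_fraction: float = 0.1
    mutation_rate: float = 1e-4         # per bp per sample
    n_mutation_samples: int = 10
    n_planted_disruptions: int = 5
    n_cell_types: int = 12
    expression_r: float = 0.7
    n_background_genes_per_chrom: int = 60
    n_tfs: int = 20
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if set(self.class_fractions) != set(CLASSES):
            raise ValueError(f"class fractions must cover {CLASSES}")
        for cls, probs in self.presence.items():
            for cohort, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"presence[{cls}][{cohort}]={p} outside [0,1]")

    @property
    def n_datasets(self) -> int:
        return (self.n_datasets_cancer + self.n_datasets_normal_matched
                + self.n_datasets_other)

    @property
    def bound_rpkm(self) -> float:
        return self.background_rpkm * 2.0 ** self.signal_effect_log2fc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class GroundTruth:
    """Planted per-site truth emitted alongside the scenario data."""
    site_class: dict                 # site_id -> class
    planted_domains: dict            # site_id -> (left_pos, right_pos)
    planted_diff_interactions: dict  # site_id -> true log2 interaction change
    planted_meth_delta: dict         # site_id -> true percentage-point shift
    planted_pairs: list              # (site_id, gene_id, true correlation)

    def sites_of_class(self, cls: str) -> list:
        return [s for s, c in self.site_class.items() if c == cls]


@dataclasses.dataclass
class Scenario:
    config: ScenarioConfig
    sites: pd.DataFrame              # site_id, chrom, start, end, center, site_class, motif_strand
    peak_datasets: list              # PeakDataset per dataset
    design: pd.DataFrame
    counts: pd.DataFrame             # sites x datasets read counts
    site_lengths: pd.Series
    library_sizes: pd.Series
    genome: dict                     # chrom -> sequence
    chrom_sizes: dict
    pfm_name: str
    pfm_counts: np.ndarray
    gene_models: pd.DataFrame
    site_panel: pd.DataFrame         # sites x cell types, sqrt(RPKM)-scale
    expression: pd.DataFrame         # genes x cell types, sqrt(TPM)-scale
    de_table: pd.DataFrame           # gene -> log2fc, fdr
    repertoire: pd.DataFrame
    tf_profiles: pd.DataFrame
    truth: GroundTruth

    @property
    def rpkm(self) -> pd.DataFrame:
        lengths = self.site_lengths.to_numpy(float)
        libs = self.library_sizes.to_numpy(float)
        return self.counts / (lengths[:, None] / 1e3) / (libs[None, :] / 1e6)

    def binding_sites(self) -> list:
        """Truth sites as BindingSite objects (motif hit where planted)."""
        out = []
        w = len(SYNTHETIC_CTCF_CONSENSUS)
        for row in self.sites.itertuples(index=False):
            motif = None
            if row.motif_strand in ("+", "-"):
                motif = MotifHit(start=row.center - w // 2, strand=row.motif_strand,
                                 llr_score=np.nan, p_value=np.nan)
            out.append(BindingSite(row.site_id, row.chrom, row.start, row.end,
                                   motif=motif))
        return out


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------
def _class_counts(cfg: ScenarioConfig) -> dict:
    """Exact per-class counts by largest remainder, summing to n_sites."""
    raw = {c: cfg.class_fractions[c] * cfg.n_sites for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = cfg.n_sites - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _site_positions(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = [cfg.n_sites // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_sites % cfg.n_chromosomes):
        per_chrom[i] += 1
    rows = []
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n = per_chrom[ci]
        grid = cfg.chrom_length // (n + 1)
        jitter_max = (grid - cfg.min_site_spacing) // 2
        if jitter_max < 0:
            raise ValueError(
                f"cannot place {n} sites with {cfg.min_site_spacing} bp spacing "
                f"on a {cfg.chrom_length} bp chromosome")
        centers = (np.arange(1, n + 1) * grid
                   + rng.integers(-jitter_max, jitter_max + 1, size=n))
        for c in np.sort(centers):
            rows.append((chrom, int(c)))
    df = pd.DataFrame(rows, columns=["chrom", "center"])
    df["start"] = df["center"] - cfg.site_halfwidth
    df["end"] = df["center"] + cfg.site_halfwidth
    df["site_id"] = [f"{r.chrom}:{r.start}-{r.end}" for r in df.itertuples()]
    return df[["site_id", "chrom", "start", "end", "center"]]


def _assign_classes(cfg: ScenarioConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    counts = _class_counts(cfg)
    labels = np.concatenate([np.full(counts[c], c, dtype=object) for c in CLASSES])
    return rng.permutation(labels)


def _dataset_table(cfg: ScenarioConfig) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_datasets_cancer):
        rows.append((f"{cfg.cancer_type}_c{i + 1}", cfg.cancer_type,
                     cfg.cancer_type, "", "cancer"))
    for i in range(cfg.n_datasets_normal_matched):
        rows.append((f"{cfg.normal_cohort}_n{i + 1}", cfg.normal_cohort,
                     "", cfg.cancer_type, "normal"))
    for i in range(cfg.n_datasets_other):
        rows.append((f"other_{i + 1}", f"tissue_{i % 6 + 1}", "", "", "other"))
    return pd.DataFrame(rows, columns=["dataset_id", "cohort", "cancer_type",
                                       "matched_normal_for", "_group"])


# ----------------------------------------------------------------------
# core generator
# ----------------------------------------------------------------------
def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate the full scenario (peaks, signal, genome, expression, truth).

    Deterministic given ``cfg.seed``.  Contact maps, methylation tables and
    mutations are generated by their dedicated functions so that each
    modality can be (re)drawn independently.
    """
    rng_sites = _rng(cfg.seed, "sites")
    sites = _site_positions(cfg, rng_sites)
    sites["site_class"] = _assign_classes(cfg, len(sites), rng_sites)
    n_sites = len(sites)

    # motif strands: constitutive sites alternate '-'/'+' along each
    # chromosome (so divergent boundary pairs exist); gained sites get '+'.
    strand = np.full(n_sites, ".", dtype=object)
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index[grp["site_class"] == "constitutive"]
        strand[idx] = np.where(np.arange(len(idx)) % 2 == 0, "-", "+")
    strand[sites.index[sites["site_class"] == "cancer_gained"]] = "+"
    sites["motif_strand"] = strand

    datasets = _dataset_table(cfg)
    groups = datasets["_group"].to_numpy()
    class_arr = sites["site_class"].to_numpy()

    # presence draws shared between peaks and signal (one experiment per cell)
    rng_peaks = _rng(cfg.seed, "peaks")
    presence_p = np.empty((n_sites, len(datasets)))
    for j, grp in enumerate(groups):
        col = np.array([cfg.presence[c][grp] for c in class_arr])
        presence_p[:, j] = col
    present = rng_peaks.random((n_sites, len(datasets))) < presence_p

    centers = sites["center"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    peak_datasets = []
    for j, ds_id in enumerate(datasets["dataset_id"]):
        rows = np.nonzero(present[:, j])[0]
        jitter = np.rint(rng_peaks.normal(0.0, cfg.summit_jitter_sd,
                                          size=rows.size)).astype(int)
        folds = 4.0 + rng_peaks.exponential(4.0, size=rows.size)
        peaks = [PeakCall(ds_id, chroms[i], int(centers[i] + dj), float(f))
                 for i, dj, f in zip(rows, jitter, folds)]
        peak_datasets.append(PeakDataset(ds_id, peaks, included=True,
                                         n_raw=len(peaks)))

    # signal follows peak presence (a bound cell signals at the elevated
    # level), except in cancer columns where the planted class rules: gained
    # sites are elevated in *every* cancer column and lost sites sit at
    # background there — the class effect, not the per-dataset peak draw,
    # defines the cancer binding level of planted sites.
    rng_sig = _rng(cfg.seed, "signal")
    bound = present.copy()
    cancer_cols = groups == "cancer"
    bound[np.ix_(class_arr == "cancer_gained", cancer_cols)] = True
    bound[np.ix_(class_arr == "cancer_lost", cancer_cols)] = False
    level = np.where(bound, cfg.bound_rpkm, cfg.background_rpkm)
    level = level * np.exp(rng_sig.normal(0.0, cfg.signal_noise_sd, size=level.shape))
    length_kb = (2 * cfg.site_halfwidth) / 1e3
    lib_m = cfg.library_size / 1e6
    counts = rng_sig.poisson(level * length_kb * lib_m).astype(float)
    counts = pd.DataFrame(counts, index=sites["site_id"].to_numpy(),
                          columns=datasets["dataset_id"].to_numpy())
    site_lengths = pd.Series(2 * cfg.site_halfwidth, index=counts.index,
                             name="length", dtype=float)
    library_sizes = pd.Series(float(cfg.library_size), index=counts.columns,
                              name="library_size")

    # genome with the synthetic consensus planted at constitutive/gained sites
    rng_gen = _rng(cfg.seed, "genome")
    genome = {}
    chrom_sizes = {}
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = rng_gen.integers(0, 4, size=cfg.chrom_length).astype(np.uint8)
        genome[chrom] = seq
        chrom_sizes[chrom] = cfg.chrom_length
    consensus = SYNTHETIC_CTCF_CONSENSUS
    w = len(consensus)
    base_idx = {b: i for i, b in enumerate(ALPHABET)}
    for row in sites.itertuples(index=False):
        if row.motif_strand not in ("+", "-"):
            continue
        motif = consensus if row.motif_strand == "+" else reverse_complement(consensus)
        start = row.center - w // 2
        genome[row.chrom][start:start + w] = [base_idx[b] for b in motif]
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    genome = {c: lut[a].tobytes().decode() for c, a in genome.items()}

    truth = GroundTruth(
        site_class=dict(zip(sites["site_id"], sites["site_class"])),
        planted_domains={}, planted_diff_interactions={},
        planted_meth_delta={}, planted_pairs=[])

    # planted domains: the orientation-and-size rule applied to the truth
    # constitutive sites (these are the boundaries the generator planted)
    dom_cfg = PipelineConfig()
    constit = [BindingSite(r.site_id, r.chrom, r.start, r.end,
                           motif=MotifHit(r.center - w // 2, r.motif_strand,
                                          np.nan, np.nan))
               for r in sites.itertuples(index=False)
               if r.site_class == "constitutive"]
    from .atlas import UnionAtlas
    boundaries = ConstitutiveBoundaries(UnionAtlas(constit, []))
    site_objs = {r.site_id: BindingSite(r.site_id, r.chrom, r.start, r.end)
                 for r in sites.itertuples(index=False)}
    for sid, cls in truth.site_class.items():
        if cls in ("cancer_lost", "cancer_gained"):
            d = build_domain(site_objs[sid], boundaries, dom_cfg)
            if d is not None:
                truth.planted_domains[sid] = (d.left_pos, d.right_pos)
            truth.planted_diff_interactions[sid] = (
                np.log2(cfg.hic_interaction_boost) if cls == "cancer_gained"
                else -np.log2(cfg.hic_interaction_boost))

    # expression panel + planted site-gene pairs
    rng_expr = _rng(cfg.seed, "expression")
    cell_types = [f"celltype_{k + 1}" for k in range(cfg.n_cell_types)]
    panel_p = np.array([[cfg.presence[c]["other"]] for c in class_arr])
    panel_present = rng_expr.random((n_sites, cfg.n_cell_types)) < panel_p
    panel_level = np.where(panel_present, cfg.bound_rpkm, cfg.background_rpkm)
    panel_level = panel_level * np.exp(
        rng_expr.normal(0.0, cfg.signal_noise_sd, size=panel_level.shape))
    site_panel = pd.DataFrame(np.sqrt(panel_level),
                              index=sites["site_id"].to_numpy(), columns=cell_types)

    gene_rows = []
    expr_rows = {}
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        tss = rng_expr.integers(0, cfg.chrom_length,
                                size=cfg.n_background_genes_per_chrom)
        for k, t in enumerate(sorted(tss)):
            gid = f"{chrom}_gene_{k + 1}"
            gene_rows.append((gid, chrom, "+" if k % 2 == 0 else "-", int(t)))
            expr_rows[gid] = np.clip(3.0 + rng_expr.normal(0, 1, cfg.n_cell_types),
                                     0, None)
    r = cfg.expression_r
    for row in sites.itertuples(index=False):
        if row.site_class not in ("cancer_lost", "cancer_gained"):
            continue
        gid = f"target_of_{row.site_id}"
        offset = int(rng_expr.integers(5_000, 50_000)) * int(rng_expr.choice([-1, 1]))
        tss = int(np.clip(row.center + offset, 0, cfg.chrom_length - 1))
        gene_rows.append((gid, row.chrom, "+", tss))
        x = site_panel.loc[row.site_id].to_numpy()
        z = (x - x.mean()) / (x.std() or 1.0)
        y = r * z + np.sqrt(max(1 - r * r, 0.0)) * rng_expr.normal(0, 1, x.size)
        expr_rows[gid] = np.clip(3.0 + y, 0, None)
        truth.planted_pairs.append((row.site_id, gid, r))
    gene_models = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "tss"])
    expression = pd.DataFrame.from_dict(expr_rows, orient="index", columns=cell_types)
    expression.index.name = "gene_id"

    # differential expression table: genes inside planted gained domains are
    # upregulated, inside lost domains downregulated, the rest null
    de_rows = {}
    domain_of = {cls: [] for cls in ("cancer_lost", "cancer_gained")}
    for sid, (lo, hi) in truth.planted_domains.items():
        cls = truth.site_class[sid]
        chrom = sid.split(":")[0]
        domain_of[cls].append((chrom, lo, hi))
    for g in gene_models.itertuples(index=False):
        lfc, fdr = float(rng_expr.normal(0, 0.2)), float(rng_expr.uniform(0.2, 1.0))
        for chrom, lo, hi in domain_of["cancer_gained"]:
            if g.chrom == chrom and lo <= g.tss < hi:
                lfc, fdr = 2.0 + float(rng_expr.normal(0, 0.3)), 1e-8
                break
        else:
            for chrom, lo, hi in domain_of["cancer_lost"]:
                if g.chrom == chrom and lo <= g.tss < hi:
                    lfc, fdr = -2.0 + float(rng_expr.normal(0, 0.3)), 1e-8
                    break
        de_rows[g.gene_id] = (lfc, fdr)
    de_table = pd.DataFrame.from_dict(de_rows, orient="index",
                                      columns=["log2fc", "fdr"])
    de_table.index.name = "gene_id"

    # regulatory repertoire: one element per site plus inter-site elements
    rng_rep = _rng(cfg.seed, "repertoire")
    rep_rows = []
    half = 150
    for chrom, grp in sites.groupby("chrom", sort=False):
        cs = grp["center"].to_numpy()
        for c in cs:
            rep_rows.append((chrom, int(c) - half, int(c) + half))
        mids = (cs[:-1] + cs[1:]) // 2
        for m in mids:
            rep_rows.append((chrom, int(m) - half, int(m) + half))
    repertoire = (pd.DataFrame(rep_rows, columns=["chrom", "start", "end"])
                  .sort_values(["chrom", "start"]).reset_index(drop=True))
    in_gained_domain = np.zeros(len(repertoire), dtype=bool)
    for chrom, lo, hi in domain_of["cancer_gained"]:
        in_gained_domain |= ((repertoire["chrom"] == chrom)
                             & (repertoire["start"] < hi)
                             & (repertoire["end"] > lo)).to_numpy()
    profiles = {}
    p_notch = np.where(in_gained_domain, 0.8, 0.02)
    profiles["NOTCH1_like"] = (rng_rep.random(len(repertoire)) < p_notch).astype(int)
    for k in range(cfg.n_tfs - 1):
        rate = rng_rep.uniform(0.05, 0.3)
        profiles[f"TF_{k + 1:02d}"] = (rng_rep.random(len(repertoire)) < rate).astype(int)
    tf_profiles = pd.DataFrame(profiles)

    return Scenario(
        config=cfg, sites=sites, peak_datasets=peak_datasets,
        design=datasets.drop(columns="_group"), counts=counts,
        site_lengths=site_lengths, library_sizes=library_sizes,
        genome=genome, chrom_sizes=chrom_sizes,
        pfm_name="synthetic_CTCF", pfm_counts=synthetic_ctcf_pfm(),
        gene_models=gene_models, site_panel=site_panel, expression=expression,
        de_table=de_table, repertoire=repertoire, tf_profiles=tf_profiles,
        truth=truth)


# ----------------------------------------------------------------------
# contact maps
# ----------------------------------------------------------------------
def generate_contact_map_pair(scenario: Scenario, boost: float | None = None,
                              bin_size: int = 5000, flank_L: int = 500_000,
                              stream_offset: int = 0) -> tuple[dict, dict]:
    """Poisson contact maps for cancer and normal, with planted boosts.

    Expected count at bin distance k is ``hic_base_count * k^(-decay)``;
    interactions between a planted gained site's bin and its flanking bins
    within ``flank_L`` are multiplied by ``boost`` in the cancer map (lost
    sites: in the normal map).  ``boost=1`` yields exchangeable maps.
    Returns two dicts chrom -> :class:`ContactMap` (raw counts, symmetric).
    ``stream_offset`` shifts the random substream for replicate draws.
    """
    cfg = scenario.config
    if boost is None:
        boost = cfg.hic_interaction_boost
    rng = np.random.default_rng([cfg.seed, _STREAMS["hic"], stream_offset])
    n_bins = cfg.chrom_length // bin_size
    k = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    mu_base = cfg.hic_base_count * np.maximum(k, 1) ** (-cfg.hic_decay_exponent)
    span = flank_L // bin_size
    maps_c, maps_n = {}, {}
    sites = scenario.sites
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        mu_c = mu_base.copy()
        mu_n = mu_base.copy()
        chrom_sites = sites[sites["chrom"] == chrom]
        for row in chrom_sites.itertuples(index=False):
            cls = row.site_class
            if cls not in ("cancer_gained", "cancer_lost") or boost == 1.0:
                continue
            anchor = row.center // bin_size
            lo = max(anchor - span, 0)
            hi = min(anchor + span, n_bins - 1)
            target = mu_c if cls == "cancer_gained" else mu_n
            cols = np.r_[lo:anchor, anchor + 1:hi + 1]
            target[anchor, cols] *= boost
            target[cols, anchor] *= boost
        for mu, store in ((mu_c, maps_c), (mu_n, maps_n)):
            draw = rng.poisson(mu).astype(float)
            m = np.triu(draw)
            m = m + m.T - np.diag(np.diag(m))
            store[chrom] = ContactMap(chrom, bin_size, m)
    return maps_c, maps_n


# ----------------------------------------------------------------------
# methylation
# ----------------------------------------------------------------------
def generate_methylation_tables(scenario: Scenario, meth_shift: float | None = None
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CpG tables (cancer, normal) with methylation shifted against binding.

    Planted lost sites gain ``meth_shift`` percentage points of methylation
    in cancer, gained sites lose the same; all other sites receive a shift
    proportional to (minus) their realized standardized binding difference,
    scaled by 2/3 of ``meth_shift`` per standard unit — the genome-wide
    anti-correlation between binding change and methylation change.  A
    fraction of sites is emitted at low coverage to exercise the
    insufficiency filter.  CpGs are placed every 20-60 bp within +/-150 bp
    of each site center.  With ``meth_shift=0`` every shift vanishes.
    """
    cfg = scenario.config
    if meth_shift is None:
        meth_shift = cfg.meth_shift
    rng = _rng(cfg.seed, "methylation")
    design = scenario.design
    cancer_cols = design.loc[design["cancer_type"] == cfg.cancer_type,
                             "dataset_id"].tolist()
    other_cols = [d for d in scenario.counts.columns if d not in cancer_cols]
    log_rpkm = np.log2(scenario.rpkm + 0.5)
    diff = (log_rpkm[cancer_cols].mean(axis=1)
            - log_rpkm[other_cols].mean(axis=1)).to_numpy()
    classes = scenario.sites["site_class"].to_numpy()
    null_mask = ~np.isin(classes, ["cancer_lost", "cancer_gained"])
    scale = diff[null_mask].std() or 1.0
    z = diff / scale

    true_delta = np.where(
        classes == "cancer_lost", meth_shift,
        np.where(classes == "cancer_gained", -meth_shift,
                 -(2.0 * meth_shift / 3.0) * np.clip(z, -3, 3)))
    scenario.truth.planted_meth_delta = dict(
        zip(scenario.sites["site_id"], true_delta.tolist()))

    low_cov = rng.random(len(scenario.sites)) < cfg.meth_low_coverage_fraction
    rows_c, rows_n = [], []
    for i, row in enumerate(scenario.sites.itertuples(index=False)):
        pos = row.center - 150
        cpg_pos = []
        while pos < row.center + 150:
            cpg_pos.append(pos)
            pos += int(rng.integers(20, 61))
        cov_mean = cfg.meth_low_coverage_mean if low_cov[i] else cfg.meth_coverage_mean
        level_n = cfg.meth_baseline
        level_c = float(np.clip(level_n + true_delta[i], 0.0, 100.0))
        for p in cpg_pos:
            for level, rows in ((level_c, rows_c), (level_n, rows_n)):
                cov = int(rng.poisson(cov_mean))
                lev = float(np.clip(level + rng.normal(0, cfg.meth_cpg_noise_sd),
                                    0.0, 100.0))
                meth = int(rng.binomial(cov, lev / 100.0)) if cov else 0
                pct = 100.0 * meth / cov if cov else 0.0
                rows.append((row.chrom, p, p + 1, pct, meth, cov - meth))
    cols = ["chrom", "start", "end", "percent", "meth_count", "unmeth_count"]
    out = []
    for rows in (rows_c, rows_n):
        df = pd.DataFrame(rows, columns=cols)
        df["coverage"] = df["meth_count"] + df["unmeth_count"]
        out.append(df)
    return out[0], out[1]


# ----------------------------------------------------------------------
# mutations
# ----------------------------------------------------------------------
def generate_mutations(scenario: Scenario, mutation_rate: float | None = None,
                       window: int = 400) -> pd.DataFrame:
    """Uniform background mutations in site windows plus planted disruptions.

    Background events are Poisson with ``mutation_rate`` per bp per sample
    over the ``window`` centered on each site.  Planted motif-disrupting
    variants replace the consensus base at the motif's central column with
    its least-favored base, at the first ``n_planted_disruptions`` gained
    sites.  Positions are 0-based in the returned frame.
    """
    cfg = scenario.config
    if mutation_rate is None:
        mutation_rate = cfg.mutation_rate
    rng = _rng(cfg.seed, "mutations")
    samples = [f"S{k + 1}" for k in range(cfg.n_mutation_samples)]
    half = window // 2
    rows = []
    bases = list(ALPHABET)
    for row in scenario.sites.itertuples(index=False):
        n_events = rng.poisson(mutation_rate * window * len(samples))
        for _ in range(n_events):
            pos = int(row.center - half + rng.integers(0, window))
            ref = scenario.genome[row.chrom][pos]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4] \
                if ref in bases else "A"
            if ref not in bases:
                ref = "N"
            rows.append((row.chrom, pos, ref, alt, samples[int(rng.integers(0, len(samples)))]))

    pfm = scenario.pfm_counts
    w = pfm.shape[1]
    center_col = w // 2
    worst = ALPHABET[int(np.argmin(pfm[:, center_col]))]
    gained = scenario.sites[scenario.sites["site_class"] == "cancer_gained"]
    for row in gained.head(cfg.n_planted_disruptions).itertuples(index=False):
        motif_start = row.center - w // 2
        pos = motif_start + center_col
        ref = scenario.genome[row.chrom][pos]
        alt = worst if worst != ref else ALPHABET[(ALPHABET.index(ref) + 1) % 4]
        rows.append((row.chrom, pos, ref, alt, samples[0]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample"])


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------
def desk_scale_pipeline_config(cfg: ScenarioConfig) -> dict:
    """Pipeline-config overrides matching the scenario's scale."""
    return {"min_peaks_per_dataset": 100, "random_seed": int(cfg.seed)}


def write_scenario(scenario: Scenario, outdir: str | Path,
                   include_hic: bool = True, include_methylation: bool = True,
                   include_mutations: bool = True) -> Path:
    """Write the scenario in exactly the formats the readers consume.

    Returns the path of ``scenario.json`` (config + file manifest).
    """
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    cfg = scenario.config
    manifest: dict = {"files": {}}

    def record(key, path):
        manifest["files"][key] = str(Path(path).relative_to(out))

    peaks_dir = out / "peaks"
    peak_files = {}
    for ds in scenario.peak_datasets:
        p = peaks_dir / f"{ds.dataset_id}.narrowPeak"
        cio.write_peak_dataset(ds, p, halfwidth=cfg.site_halfwidth)
        peak_files[ds.dataset_id] = str(p.relative_to(out))
    manifest["files"]["peaks"] = peak_files

    scenario.design.to_csv(out / "design.tsv", sep="\t", index=False)
    record("design", out / "design.tsv")
    cio.write_matrix_tsv(scenario.counts, out / "counts.tsv")
    record("counts", out / "counts.tsv")
    scenario.site_lengths.to_frame().to_csv(out / "site_lengths.tsv", sep="\t")
    record("site_lengths", out / "site_lengths.tsv")
    scenario.library_sizes.to_frame().to_csv(out / "library_sizes.tsv", sep="\t")
    record("library_sizes", out / "library_sizes.tsv")
    site_bed = scenario.sites[["chrom", "start", "end", "site_id"]].rename(
        columns={"site_id": "name"})
    cio.write_bed(site_bed, out / "sites.bed")
    record("site_regions", out / "sites.bed")
    cio.write_fasta(scenario.genome, out / "genome.fa")
    record("genome", out / "genome.fa")
    cio.write_chrom_sizes(scenario.chrom_sizes, out / "chrom.sizes")
    record("chrom_sizes", out / "chrom.sizes")
    cio.write_pfm_jaspar(scenario.pfm_name, scenario.pfm_counts, out / "motif.pfm")
    record("pfm", out / "motif.pfm")
    scenario.gene_models.to_csv(out / "genes.tsv", sep="\t", index=False)
    record("genes", out / "genes.tsv")
    cio.write_matrix_tsv(scenario.site_panel, out / "site_panel.tsv")
    record("site_panel", out / "site_panel.tsv")
    cio.write_matrix_tsv(scenario.expression, out / "expression.tsv")
    record("expression", out / "expression.tsv")
    cio.write_matrix_tsv(scenario.de_table, out / "de_table.tsv")
    record("de_table", out / "de_table.tsv")
    cio.write_bed(scenario.repertoire, out / "repertoire.bed")
    record("repertoire", out / "repertoire.bed")
    cio.write_matrix_tsv(scenario.tf_profiles, out / "tf_profiles.tsv")
    record("tf_profiles", out / "tf_profiles.tsv")

    if include_hic:
        maps_c, maps_n = generate_contact_map_pair(scenario)
        cio.write_contact_tsv(maps_c, out / "hic_cancer.tsv")
        cio.write_contact_tsv(maps_n, out / "hic_normal.tsv")
        record("hic_cancer", out / "hic_cancer.tsv")
        record("hic_normal", out / "hic_normal.tsv")
    if include_methylation:
        meth_c, meth_n = generate_methylation_tables(scenario)
        cio.write_cpg_table(meth_c, out / "meth_cancer.cov.tsv")
        cio.write_cpg_table(meth_n, out / "meth_normal.cov.tsv")
        record("methylation_cancer", out / "meth_cancer.cov.tsv")
        record("methylation_normal", out / "meth_normal.cov.tsv")
    if include_mutations:
        muts = generate_mutations(scenario)
        cio.write_mutations(muts, out / "mutations.tsv")
        record("mutations", out / "mutations.tsv")

    truth = scenario.truth
    pd.DataFrame(sorted(truth.site_class.items()),
                 columns=["site_id", "site_class"]).to_csv(
        out / "truth" / "site_class.tsv", sep="\t", index=False)
    pd.DataFrame([(s, lo, hi) for s, (lo, hi) in sorted(truth.planted_domains.items())],
                 columns=["site_id", "left_pos", "right_pos"]).to_csv(
        out / "truth" / "planted_domains.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.planted_diff_interactions.items()),
                 columns=["site_id", "log2_change"]).to_csv(
        out / "truth" / "planted_diff_interactions.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.planted_meth_delta.items()),
                 columns=["site_id", "true_delta"]).to_csv(
        out / "truth" / "planted_meth_delta.tsv", sep="\t", index=False)
    pd.DataFrame(truth.planted_pairs,
                 columns=["site_id", "gene_id", "true_r"]).to_csv(
        out / "truth" / "planted_pairs.tsv", sep="\t", index=False)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(desk_scale_pipeline_config(cfg), fh)
    record("pipeline_config", out / "config.yaml")
    manifest["scenario_config"] = cfg.to_dict()
    cio.write_json(manifest, out / "scenario.json")
    return out / "scenario.json"
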