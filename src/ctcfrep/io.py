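"""Readers and writers for every external format the pipeline touches.

Coordinates are 0-based half-open (BED convention) everywhere internally;
the only 1-based ingestion point is the VCF-like mutation table, converted
on read.  All tabular output is plain TSV so results round-trip through
:func:`pandas.read_csv` field-for-field.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import BindingSite, MotifHit, PeakCall, PeakDataset, UnionAtlas
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


# ----------------------------------------------------------------------
# peak calls
# ----------------------------------------------------------------------
def read_peak_dataset(path: str | Path, cfg: PipelineConfig,
                      dataset_id: str | None = None) -> PeakDataset:
    """Read one peak-call dataset (narrowPeak or BED6+summit).

    narrowPeak (10 columns): summit = start + column-10 offset; an offset of
    −1 (summit unknown) falls back to the interval midpoint with a warning.
    Fold enrichment is the signalValue column.

    BED6+summit (7 columns): chrom, start, end, name, fold_enrichment,
    strand, absolute 0-based summit.

    Peaks with fold enrichment below ``cfg.min_fold_enrichment`` are dropped;
    if fewer than ``cfg.min_peaks_per_dataset`` survive, the dataset is
    flagged excluded (not an error).
    """
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.stem.split(".")[0]
    peaks = []
    n_raw = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 10:   # narrowPeak
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                fold = float(fields[6])
                offset = int(fields[9])
                if offset == -1:
                    summit = (start + end) // 2
                    logger.warning("%s:%d summit offset -1; using interval midpoint",
                                   path.name, lineno)
                else:
                    summit = start + offset
            elif len(fields) == 7:  # BED6 + absolute summit
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                fold = float(fields[4])
                summit = int(fields[6])
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 (narrowPeak) or 7 "
                    f"(BED6+summit) columns, got {len(fields)}")
            if not (start <= summit < end):
                raise FormatError(
                    f"{path}:{lineno}: summit {summit} outside peak [{start},{end})")
            n_raw += 1
            if fold < cfg.min_fold_enrichment:
                continue
            peaks.append(PeakCall(dataset_id, chrom, summit, fold))
    ds = PeakDataset(dataset_id, peaks, included=True, n_raw=n_raw)
    if len(peaks) < cfg.min_peaks_per_dataset:
        ds.included = False
        ds.exclusion_reason = (f"{len(peaks)} peaks after fold filter "
                               f"< {cfg.min_peaks_per_dataset}")
    return ds


def write_peak_dataset(ds: PeakDataset, path: str | Path,
                       halfwidth: int = 75) -> None:
    """Write peaks as narrowPeak, one 2*halfwidth window per summit."""
    with open(path, "w") as fh:
        for i, p in enumerate(ds.peaks):
            start = max(p.summit - halfwidth, 0)
            end = p.summit + halfwidth
            fh.write(f"{p.chrom}\t{start}\t{end}\t{ds.dataset_id}_peak{i}\t0\t.\t"
                     f"{p.fold_enrichment:g}\t-1\t-1\t{p.summit - start}\n")


# ----------------------------------------------------------------------
# site sets (BED6) and atlas tables
# ----------------------------------------------------------------------
def write_sites_bed(atlas: UnionAtlas, path: str | Path) -> None:
    """BED6: name = site id, score = occupancy score, strand = motif strand."""
    with open(path, "w") as fh:
        for s in atlas.sites:
            strand = s.motif.strand if s.motif else "."
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.site_id}\t"
                     f"{s.occupancy_score}\t{strand}\n")


def read_sites_bed(path: str | Path, dataset_ids=()) -> UnionAtlas:
    sites = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}: BED needs >= 4 columns")
            score = int(f[4]) if len(f) > 4 else 0
            sites.append(BindingSite(f[3], f[0], int(f[1]), int(f[2]),
                                     occupancy_score=score))
    return UnionAtlas(sites, dataset_ids)


def write_atlas_table(atlas: UnionAtlas, path: str | Path) -> None:
    atlas.to_dataframe().to_csv(path, sep="\t", index=False)


def read_atlas_table(path: str | Path, dataset_ids) -> UnionAtlas:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return UnionAtlas.from_dataframe(df, dataset_ids)


# ----------------------------------------------------------------------
# FASTA / chrom sizes
# ----------------------------------------------------------------------
def write_fasta(seqs: dict, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict:
    """Whole-genome dict chrom -> sequence (desk-scale genomes only).

    Any mapping chrom -> sequence (e.g. an indexed FASTA handle) satisfies
    the interface the scanners expect; this reader materializes the dict.
    """
    seqs: dict = {}
    name = None
    chunks: list = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_chrom_sizes(sizes: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: str | Path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            chrom, size = line.split()[:2]
            out[chrom] = int(size)
    return out


# ----------------------------------------------------------------------
# JASPAR PFM (4-row counts)
# ----------------------------------------------------------------------
def read_pfm_jaspar(path: str | Path) -> tuple[str, np.ndarray]:
    """Read a JASPAR-style PFM: a '>' header then 4 rows A/C/G/T of counts.

    Accepts both the bracketed ``A [ 1 2 3 ]`` and plain whitespace dialects.
    Returns (name, counts) with counts shaped (4, width).
    """
    rows = {}
    name = Path(str(path)).stem
    order = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].strip() or name
                continue
            base = line[0].upper()
            if base not in "ACGT":
                raise FormatError(f"{path}: unexpected PFM row {line[:20]!r}")
            body = line[1:].replace("[", " ").replace("]", " ")
            rows[base] = [float(x) for x in body.split()]
            order.append(base)
    if sorted(rows) != ["A", "C", "G", "T"]:
        raise FormatError(f"{path}: PFM must have exactly rows A, C, G, T")
    counts = np.array([rows[b] for b in "ACGT"])
    if counts.shape[1] < 1 or np.any(counts < 0):
        raise FormatError(f"{path}: PFM counts must be non-negative, width >= 1")
    return name, counts


def write_pfm_jaspar(name: str, counts: np.ndarray, path: str | Path) -> None:
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip("ACGT", counts):
            vals = " ".join(f"{v:g}" for v in row)
            fh.write(f"{base} [ {vals} ]\n")


# ----------------------------------------------------------------------
# TSV matrices / design / gene models
# ----------------------------------------------------------------------
def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Matrix with a header row of dataset/sample ids; first column = row ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_design_table(path: str | Path) -> pd.DataFrame:
    """Cohort design: dataset_id, cohort, cancer_type, matched_normal_for."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"dataset_id", "cohort", "cancer_type", "matched_normal_for"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: design table missing columns {sorted(missing)}")
    return df


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Gene models: gene_id, chrom, strand, tss (0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: gene models missing columns {sorted(missing)}")
    return df


# ----------------------------------------------------------------------
# sparse contact maps
# ----------------------------------------------------------------------
def read_contact_tsv(path: str | Path):
    """Sparse upper-triangle contact TSV (chrom, bin_i, bin_j, count).

    Returns a dict chrom -> ContactMap (symmetrized).
    """
    from .hic import ContactMap  # deferred: hic imports nothing from io
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "bin_i", "bin_j", "count", "bin_size", "n_bins"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: contact table missing columns {sorted(missing)}")
    out = {}
    for chrom, grp in df.groupby("chrom"):
        bin_size = int(grp["bin_size"].iloc[0])
        n_bins = int(grp["n_bins"].iloc[0])
        out[chrom] = ContactMap.from_sparse(
            chrom, bin_size, n_bins,
            grp["bin_i"].to_numpy(), grp["bin_j"].to_numpy(),
            grp["count"].to_numpy(float))
    return out


def write_contact_tsv(maps: dict, path: str | Path) -> None:
    frames = []
    for chrom, cm in maps.items():
        i, j, v = cm.to_sparse()
        frames.append(pd.DataFrame({
            "chrom": chrom, "bin_i": i, "bin_j": j, "count": v,
            "bin_size": cm.bin_size, "n_bins": cm.n_bins}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# CpG methylation tables (Bismark-coverage-like, 0-based here)
# ----------------------------------------------------------------------
CPG_COLUMNS = ["chrom", "start", "end", "percent", "meth_count", "unmeth_count"]


def read_cpg_table(path: str | Path) -> pd.DataFrame:
    """CpG table: chrom, start, end, percent, meth_count, unmeth_count.

    Bismark-coverage column layout, except coordinates are 0-based half-open
    like every other interval in this package (the CpG position is ``start``).
    Adds a ``coverage`` column = meth + unmeth.
    """
    df = pd.read_csv(path, sep="\t", names=CPG_COLUMNS, header=None,
                     dtype={"chrom": str})
    if df["start"].lt(0).any():
        raise FormatError(f"{path}: negative CpG positions")
    df["coverage"] = df["meth_count"] + df["unmeth_count"]
    return df


def write_cpg_table(df: pd.DataFrame, path: str | Path) -> None:
    df[CPG_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


# ----------------------------------------------------------------------
# VCF-like mutation tables
# ----------------------------------------------------------------------
def read_mutations(path: str | Path) -> pd.DataFrame:
    """Mutation TSV: chrom, pos (1-based), ref, alt, sample.

    Positions are converted to 0-based on read; multi-allelic alt fields
    (comma-separated) are split into one record each.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str,
                                            "sample": str})
    required = {"chrom", "pos", "ref", "alt", "sample"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: mutation table missing columns {sorted(missing)}")
    df = df.assign(alt=df["alt"].str.split(",")).explode("alt", ignore_index=True)
    if (df["ref"] == df["alt"]).any():
        raise FormatError(f"{path}: ref == alt in some records")
    df["pos"] = df["pos"].astype(int) - 1
    if df["pos"].lt(0).any():
        raise FormatError(f"{path}: positions must be 1-based and positive")
    return df


def write_mutations(df: pd.DataFrame, path: str | Path) -> None:
    """Inverse of :func:`read_mutations` (re-emits 1-based positions)."""
    out = df[["chrom", "pos", "ref", "alt", "sample"]].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# BED intervals / JSON metadata
# ----------------------------------------------------------------------
def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ -> DataFrame(chrom, start, end[, name])."""
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}: BED needs >= 3 columns")
            rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
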