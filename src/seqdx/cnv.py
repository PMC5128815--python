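"""Copy-number ratio profiles from low-pass binned read counts.

Tumor and baseline read counts on a shared bin grid are library-size
normalized and compared bin-by-bin:

    ratio = (tumor_count / tumor_total) / (baseline_count / baseline_total)

Gene-level calls average the ratio over bins overlapping the gene region
(overlap-length weighted) and categorize with half-open thresholds:
ratio < 0.6 deep deletion, [0.6, 1.8) neutral, [1.8, 3.0) low-grade
amplification ("ratio close to two"), >= 3.0 high-grade amplification.
Bins with zero baseline count are flagged and excluded from gene calls.
No segmentation or tumor-purity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DataFormatError

DEEP_DELETION_MAX = 0.6
LOW_AMP_MIN = 1.8
HIGH_AMP_MIN = 3.0

BIN_COLUMNS = ["chrom", "start", "end", "count"]


def validate_bins(bins: pd.DataFrame, name: str = "bins") -> pd.DataFrame:
    """Check BED-like (chrom, start, end, count) records: 0-based
    half-open, sorted by (chrom, start), non-overlapping, counts >= 0."""
    missing = [c for c in BIN_COLUMNS if c not in bins.columns]
    if missing:
        raise DataFormatError(f"{name}: missing columns {missing}")
    if (bins["count"] < 0).any():
        raise DataFormatError(f"{name}: negative counts")
    if (bins["end"] <= bins["start"]).any():
        bad = bins[bins["end"] <= bins["start"]].iloc[0]
        raise DataFormatError(
            f"{name}: empty or inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    for chrom, grp in bins.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (np.diff(starts) < 0).any():
            raise DataFormatError(f"{name}: bins not sorted by start on {chrom}")
        if (starts[1:] < ends[:-1]).any():
            i = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
            raise DataFormatError(
                f"{name}: overlapping bins on {chrom} at {starts[i + 1]} < {ends[i]}"
            )
    return bins


def read_bins(path) -> pd.DataFrame:
    """Read a BED-like bins TSV (chrom, start, end, count)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["chrom", "start", "end"]:
        df = pd.read_csv(path, sep="\t", header=None, names=BIN_COLUMNS)
    return validate_bins(df[BIN_COLUMNS].copy())


@dataclass
class RatioProfile:
    """Per-bin tumor/baseline copy-number ratios.

    ``table`` has columns chrom, start, end, tumor_count, baseline_count,
    ratio, log2_ratio, flagged; flagged bins (zero baseline) are excluded
    from gene calls.
    """

    table: pd.DataFrame

    @property
    def usable(self) -> pd.DataFrame:
        return self.table[~self.table["flagged"]]


@dataclass
class GeneCnvCall:
    gene: str
    chrom: str
    start: int
    end: int
    mean_ratio: Optional[float]
    category: Optional[str]  # deep_deletion | neutral | low_amp | high_amp
    n_bins: int
    warning: Optional[str] = None


def bin_log_ratio(tumor: pd.DataFrame, baseline: pd.DataFrame) -> RatioProfile:
    """Library-size-normalized per-bin ratios of tumor vs baseline counts.

    Both inputs must share an identical bin grid.  Ratios are invariant to
    scaling either library's counts by a constant.
    """
    tumor = validate_bins(tumor, "tumor")
    baseline = validate_bins(baseline, "baseline")
    grid_cols = ["chrom", "start", "end"]
    if len(tumor) != len(baseline) or not tumor[grid_cols].reset_index(drop=True).equals(
            baseline[grid_cols].reset_index(drop=True)):
        merged = tumor[grid_cols].reset_index(drop=True).compare(
            baseline[grid_cols].reset_index(drop=True)
        ) if len(tumor) == len(baseline) else None
        if merged is not None and len(merged):
            row = tumor[grid_cols].reset_index(drop=True).iloc[merged.index[0]]
            raise DataFormatError(
                f"bin grids differ; first offending interval "
                f"{row['chrom']}:{row['start']}-{row['end']}"
            )
        raise DataFormatError("bin grids differ in length")
    t = tumor["count"].to_numpy(dtype=float)
    b = baseline["count"].to_numpy(dtype=float)
    t_tot, b_tot = t.sum(), b.sum()
    if t_tot <= 0 or b_tot <= 0:
        raise DataFormatError("tumor and baseline must each have positive total counts")
    flagged = b == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (t / t_tot) / (b / b_tot)
        log2r = np.log2(ratio)
    table = tumor[grid_cols].copy().reset_index(drop=True)
    table["tumor_count"] = tumor["count"].to_numpy()
    table["baseline_count"] = baseline["count"].to_numpy()
    table["ratio"] = np.where(flagged, np.nan, ratio)
    table["log2_ratio"] = np.where(flagged, np.nan, log2r)
    table["flagged"] = flagged
    return RatioProfile(table=table)


def categorize_ratio(ratio: float) -> str:
    """Half-open category thresholds (1.8 -> low_amp, 3.0 -> high_amp)."""
    if ratio < DEEP_DELETION_MAX:
        return "deep_deletion"
    if ratio < LOW_AMP_MIN:
        return "neutral"
    if ratio < HIGH_AMP_MIN:
        return "low_amp"
    return "high_amp"


def gene_cnv_call(profile: RatioProfile, gene_regions) -> list[GeneCnvCall]:
    """Overlap-length-weighted mean ratio and category per gene region.

    ``gene_regions`` is an iterable of (gene, chrom, start, end) or a
    DataFrame with those columns.  A region with no usable (unflagged)
    overlapping bin yields a call with no category and a warning flag.
    """
    if isinstance(gene_regions, pd.DataFrame):
        regions = list(gene_regions[["gene", "chrom", "start", "end"]].itertuples(index=False))
    else:
        regions = list(gene_regions)
    usable = profile.usable
    calls = []
    for gene, chrom, start, end in regions:
        sub = usable[usable["chrom"] == chrom]
        overlap = np.minimum(sub["end"].to_numpy(), end) - np.maximum(sub["start"].to_numpy(), start)
        sel = overlap > 0
        if not sel.any():
            calls.append(GeneCnvCall(gene=gene, chrom=chrom, start=int(start), end=int(end),
                                     mean_ratio=None, category=None, n_bins=0,
                                     warning="no usable bins overlap the region"))
            continue
        w = overlap[sel].astype(float)
        r = sub["ratio"].to_numpy()[sel]
        mean_ratio = float(np.average(r, weights=w))
        calls.append(GeneCnvCall(gene=gene, chrom=chrom, start=int(start), end=int(end),
                                 mean_ratio=mean_ratio, category=categorize_ratio(mean_ratio),
                                 n_bins=int(sel.sum())))
    return calls


def calls_to_frame(calls: list[GeneCnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": c.gene, "chrom": c.chrom, "start": c.start, "end": c.end,
             "mean_ratio": c.mean_ratio, "category": c.category, "n_bins": c.n_bins,
             "warning": c.warning}
            for c in calls
        ]
    )


def write_seg(profile: RatioProfile, sample_id: str, path) -> None:
    """Optional SEG export of per-bin log2 ratios."""
    t = profile.usable
    with open(path, "w") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
        for row in t.itertuples(index=False):
            fh.write(f"{sample_id}\t{row.chrom}\t{row.start}\t{row.end}\t1\t{row.log2_ratio:.6f}\n")
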