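"""Shallow-WGS copy-number profiling: counts to log2 ratio profiles.

The processing chain mirrors the standard low-coverage CNV workflow:

1. count read starts per fixed-width autosomal bin (BED half-open intervals);
2. exclude blacklisted bins and bins with reference mappability below 0.2;
3. correct local GC effects with a loess fit (tricube weights, degree 2) of
   counts on GC, trained on the high-confidence subset with mappability
   above 0.8;
4. fit a line through the origin to the density-weighted centers of GC
   corrected counts per mappability interval; its slope scales mappability
   to an expected reference count per bin;
5. the profile is the per-bin log2 ratio of corrected count over that scaled
   reference count.

The whole chain is invariant to sequencing depth: multiplying all raw
counts by a constant leaves the log2 profile unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import is_autosome, normalize_chrom

MAPPABILITY_MIN = 0.2      # bins below this reference mappability are excluded
LOESS_MAPPABILITY_MIN = 0.8  # loess GC fit uses only bins above this
DEFAULT_SPAN = 0.3


@dataclass
class GenomicProfile:
    """Per-bin log2 copy-number ratios with an inclusion mask.

    `log2_ratio` is NaN wherever `included` is False; `provenance` records
    the thresholds, loess span and reference slope that produced it.
    """

    bins: pd.DataFrame
    log2_ratio: np.ndarray
    included: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.log2_ratio) != len(self.bins) or len(self.included) != len(self.bins):
            raise ValueError("profile arrays must be index-aligned with bins")
        if not np.all(np.isfinite(self.log2_ratio[self.included])):
            raise ValueError("log2_ratio must be finite wherever included")

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.loc[:, ["chrom", "start", "end"]].copy()
        out["log2_ratio"] = self.log2_ratio
        out["included"] = self.included
        return out


def validate_bins(bins: pd.DataFrame) -> None:
    """Check the bin-grid invariants: sorted, non-overlapping, valid fractions."""
    for col in ("chrom", "start", "end", "gc", "mappability", "blacklist"):
        if col not in bins.columns:
            raise ValueError(f"bin grid missing column {col!r}")
    if (bins["start"] >= bins["end"]).any():
        raise ValueError("bin start must be < end")
    for col in ("gc", "mappability"):
        v = bins[col]
        if ((v < 0) | (v > 1)).any():
            raise ValueError(f"{col} must lie in [0, 1]")
    for _, sub in bins.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if not (np.all(np.diff(starts) > 0) and np.all(starts[1:] >= ends[:-1])):
            raise ValueError("bins within a chromosome must be sorted and non-overlapping")


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_reads(read_starts, bins: pd.DataFrame):
    """Assign read start positions to bins; returns (counts, report).

    A read lands in the unique bin whose half-open [start, end) interval
    contains its 5' start.  Reads on non-autosomes or outside the grid are
    dropped and tallied; malformed records are skipped and counted.  The
    report satisfies assigned + dropped + skipped == input.
    """
    if isinstance(read_starts, pd.DataFrame):
        records = list(zip(read_starts["chrom"], read_starts["pos"]))
    else:
        records = list(read_starts)

    counts = np.zeros(len(bins), dtype=np.int64)
    by_chrom = {}
    for chrom, sub in bins.groupby("chrom", sort=False):
        by_chrom[str(chrom)] = (
            sub["start"].to_numpy(), sub["end"].to_numpy(), sub.index.to_numpy()
        )

    report = {"input": len(records), "assigned": 0, "dropped_non_autosome": 0,
              "dropped_outside_grid": 0, "skipped_malformed": 0}
    for rec in records:
        try:
            chrom, pos = rec[0], int(rec[1])
            if pos < 0:
                raise ValueError
        except (TypeError, ValueError, IndexError):
            report["skipped_malformed"] += 1
            continue
        if not is_autosome(chrom):
            report["dropped_non_autosome"] += 1
            continue
        key = normalize_chrom(chrom)
        if key not in by_chrom:
            report["dropped_outside_grid"] += 1
            continue
        starts, ends, idx = by_chrom[key]
        j = np.searchsorted(starts, pos, side="right") - 1
        if j < 0 or pos >= ends[j]:
            report["dropped_outside_grid"] += 1
            continue
        counts[idx[j]] += 1
        report["assigned"] += 1
    return counts, report


def apply_blacklist(bins: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Flag bins overlapping any blacklist interval (BED-style frame).

    Any overlap, however small, marks the bin blacklisted; existing flags
    are kept.  Returns a copy of the grid.
    """
    out = bins.copy()
    flagged = out["blacklist"].to_numpy().astype(bool).copy()
    chrom = out["chrom"].to_numpy()
    start = out["start"].to_numpy()
    end = out["end"].to_numpy()
    for bc, bs, be in zip(blacklist["chrom"], blacklist["start"], blacklist["end"]):
        if not is_autosome(bc):
            continue
        flagged |= (chrom == normalize_chrom(bc)) & (start < be) & (end > bs)
    out["blacklist"] = flagged
    return out


def filter_bins(bins: pd.DataFrame, mappability_min: float = MAPPABILITY_MIN) -> np.ndarray:
    """Inclusion mask: not blacklisted and mappability >= threshold.

    The threshold is inclusive — a bin at exactly the minimum is kept; only
    bins strictly below it are excluded.
    """
    return (~bins["blacklist"].to_numpy().astype(bool)) & (
        bins["mappability"].to_numpy() >= mappability_min
    )


# ---------------------------------------------------------------------------
# loess GC correction
# ---------------------------------------------------------------------------

def _loess_pass(xs, ys, grid, k, degree, extra_w=None):
    fitted = np.empty(len(grid))
    for gi, g in enumerate(grid):
        d = np.abs(xs - g)
        h = np.partition(d, k - 1)[k - 1]
        if h <= 0:
            h = max(d.max() * 1e-9, 1e-12)
        w = np.clip(1.0 - (d / (h * (1 + 1e-9))) ** 3, 0.0, None) ** 3
        if extra_w is not None:
            w = w * extra_w
        use = w > 0
        if use.sum() <= degree:
            use = d <= np.partition(d, min(degree + 1, len(d) - 1))[min(degree + 1, len(d) - 1)]
            w = np.where(use, 1.0, 0.0)
        xc = xs[use] - g  # center for conditioning
        coeffs = np.polyfit(xc, ys[use], deg=min(degree, use.sum() - 1), w=np.sqrt(w[use]))
        fitted[gi] = coeffs[-1]
    return fitted


def _loess_curve(x: np.ndarray, y: np.ndarray, span: float, degree: int = 2,
                 n_grid: int = 200, robust_iter: int = 2):
    """Fit a robust loess curve y~x and return (grid, fitted-at-grid).

    Tricube distance weights, local polynomial of `degree`, followed by
    `robust_iter` bisquare reweighting passes so that bins carrying genuine
    copy-number signal do not drag the bias estimate (robustness weights are
    scale-free, keeping the fit exactly equivariant in y).
    """
    n = len(x)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    k = min(max(degree + 2, int(np.ceil(span * n))), n)
    grid = np.unique(np.quantile(xs, np.linspace(0.0, 1.0, min(n_grid, n))))
    fitted = _loess_pass(xs, ys, grid, k, degree)
    for _ in range(robust_iter):
        resid = ys - np.interp(xs, grid, fitted)
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        rw = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
        fitted = _loess_pass(xs, ys, grid, k, degree, extra_w=rw)
    return grid, fitted


def loess_gc_correct(counts, bins: pd.DataFrame, mask: np.ndarray,
                     span: float = DEFAULT_SPAN) -> np.ndarray:
    """Remove the local GC effect from bin counts, preserving overall scale.

    The loess curve count~GC is trained only on masked-in bins with
    mappability above 0.8; every masked-in bin's count is divided by the
    fitted value at its GC and multiplied by the mean fitted level, so the
    corrected counts keep the scale of the input.  GC values outside the
    fitted range use the nearest fitted value.  Bins outside the mask come
    back as NaN.
    """
    counts = np.asarray(counts, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    mapp = bins["mappability"].to_numpy()
    gc = bins["gc"].to_numpy()
    train = mask & (mapp > LOESS_MAPPABILITY_MIN)
    if train.sum() < 50:
        raise ValueError(
            f"only {int(train.sum())} masked-in bins with mappability > "
            f"{LOESS_MAPPABILITY_MIN}; need at least 50 — provide a larger input"
        )
    grid, fitted_grid = _loess_curve(gc[train], counts[train], span=span)
    def predict(x):
        return np.interp(np.clip(x, grid[0], grid[-1]), grid, fitted_grid)

    mean_level = float(np.mean(predict(gc[train])))
    corrected = np.full(len(bins), np.nan)
    fit_at = predict(gc[mask])
    corrected[mask] = counts[mask] / fit_at * mean_level
    return corrected


# ---------------------------------------------------------------------------
# reference slope and log2 profile
# ---------------------------------------------------------------------------

def fit_reference_slope(corrected, bins: pd.DataFrame, mask: np.ndarray,
                        n_groups: int = 20) -> float:
    """Slope of the through-origin line over mappability-density centers.

    Masked-in bins are grouped into `n_groups` equal-width mappability
    intervals on [0.2, 1]; each non-empty interval contributes its center
    (median mappability, median corrected count) with weight equal to its
    occupancy; the slope is the weighted least-squares line through the
    origin over these centers.  It converts a mappability into an expected
    reference count.
    """
    corrected = np.asarray(corrected, dtype=float)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(corrected)
    mapp = bins["mappability"].to_numpy()[mask]
    vals = corrected[mask]
    if len(vals) == 0:
        raise ValueError("no masked-in bins with finite corrected counts")
    deciles = np.unique(np.clip(np.floor(mapp * 10).astype(int), 0, 9))
    if len(deciles) < 3:
        raise ValueError(
            f"masked-in bins span only {len(deciles)} mappability decile(s); need >= 3"
        )
    edges = np.linspace(MAPPABILITY_MIN, 1.0, n_groups + 1)
    group = np.clip(np.digitize(mapp, edges) - 1, 0, n_groups - 1)
    num = den = 0.0
    for g in np.unique(group):
        sel = group == g
        w = float(sel.sum())
        mx = float(np.median(mapp[sel]))
        my = float(np.median(vals[sel]))
        num += w * mx * my
        den += w * mx * mx
    slope = num / den
    if slope <= 0:
        raise ValueError(f"non-positive reference slope ({slope:.4g}); pathological input")
    return slope


def log2_profile(corrected, bins: pd.DataFrame, mask: np.ndarray, slope: float,
                 provenance: dict | None = None) -> GenomicProfile:
    """log2 ratio of corrected counts over slope-scaled reference counts.

    The expected count of a masked-in bin is slope * mappability; bins whose
    corrected count is not positive are removed from the mask rather than
    given an infinite ratio.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    corrected = np.asarray(corrected, dtype=float)
    mask = np.asarray(mask, dtype=bool).copy()
    mask &= np.isfinite(corrected) & (corrected > 0)
    expected = slope * bins["mappability"].to_numpy()
    ratio = np.full(len(bins), np.nan)
    ratio[mask] = np.log2(corrected[mask] / expected[mask])
    prov = dict(provenance or {})
    prov.setdefault("slope", float(slope))
    return GenomicProfile(bins=bins, log2_ratio=ratio, included=mask, provenance=prov)


def run_pipeline(
    bins: pd.DataFrame,
    counts=None,
    read_starts=None,
    span: float = DEFAULT_SPAN,
    mappability_min: float = MAPPABILITY_MIN,
) -> GenomicProfile:
    """Full deterministic chain: count -> filter -> GC-correct -> slope -> log2.

    Provide either per-bin `counts` or raw `read_starts` (counted here).
    """
    validate_bins(bins)
    report = None
    if counts is None:
        if read_starts is None:
            raise ValueError("provide counts or read_starts")
        counts, report = count_reads(read_starts, bins)
    counts = np.asarray(counts)
    if len(counts) != len(bins):
        raise ValueError("counts must be index-aligned with bins")
    if (np.asarray(counts) < 0).any():
        raise ValueError("counts must be non-negative")

    mask = filter_bins(bins, mappability_min)
    corrected = loess_gc_correct(counts, bins, mask, span=span)
    slope = fit_reference_slope(corrected, bins, mask)
    provenance = {
        "mappability_min": mappability_min,
        "loess_mappability_min": LOESS_MAPPABILITY_MIN,
        "span": span,
        "slope": slope,
        "n_bins": int(len(bins)),
        "n_filtered_in": int(mask.sum()),
    }
    if report is not None:
        provenance["count_report"] = report
    return log2_profile(corrected, bins, mask, slope, provenance=provenance)
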