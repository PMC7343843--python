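"""Pool-seq Watterson diversity in windows, and hysteresis segmentation of
per-window rate tracks.

In pooled sequencing only read counts are observed, not genotypes, and a
site segregating in the pool may look monomorphic in the reads.  The
Watterson estimator is therefore corrected per site: the usual harmonic
denominator a(n) is replaced by the expected harmonic factor of the number
of pool haplotypes actually sampled by the reads, restricted to allele
configurations detectable at the chosen minor-read threshold.  Summing this
factor over analyzed sites gives the window denominator, and
theta_hat = S / denom, with S the number of called segregating sites.

The per-site factor is computed from the neutral frequency spectrum:

    f(r, n, b) = sum_{i=1}^{n-1} (1/i) * P(b <= Bin(r, i/n) <= r - b)

where r is read depth, n pool size and b the minor-read detection
threshold.  At b = 1 this equals E[a(K)] with K the number of distinct
pool lineages among r reads drawn with replacement (the occupancy
formulation), which tests verify by independent enumeration.

Region segmentation follows a two-threshold hysteresis rule: a region opens
on a run of at least ``run`` windows above ``open_thresh`` and closes on a
run of at least ``run`` windows below ``close_thresh``; intermediate rates
neither open nor close.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "RateRegion",
    "site_filter",
    "watterson_factor",
    "theta_windows",
    "summarize_by_class",
    "hysteresis_segment",
]


@dataclass
class RateRegion:
    """A contiguous run of windows called as a high-rate region."""

    contig: str
    start: int
    end: int  # bp, half-open
    n_windows: int
    mean_rate: float
    kind: str = "generic"


def site_filter(
    ref_count: np.ndarray | int,
    alt_count: np.ndarray | int,
    min_cov: int = 4,
    max_cov: int = 250,
    min_minor: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Coverage and minor-allele filters for pooled sites (vectorized).

    A site is *analyzed* iff min_cov <= depth < max_cov (the upper bound is
    strict), and *segregating* iff analyzed and its minor allele is
    supported by at least ``min_minor`` reads.  Base quality filtering is
    assumed applied upstream, when the count table was produced.
    Returns (analyzed, segregating) boolean arrays.
    """
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    depth = ref + alt
    analyzed = (depth >= min_cov) & (depth < max_cov)
    minor = np.minimum(ref, alt)
    segregating = analyzed & (minor >= min_minor)
    return analyzed, segregating


@lru_cache(maxsize=100_000)
def _watterson_factor_scalar(r: int, n: int, min_minor: int) -> float:
    if r < 1:
        raise ValueError("read depth must be >= 1")
    if r > 10_000:
        raise ValueError("read depth > 1e4 not supported")
    if n < 2:
        raise ValueError("pool size must be >= 2")
    b = min_minor
    if r < 2 * b:  # cannot see both alleles b times
        return 0.0
    i = np.arange(1, n)
    p = i / n
    detect = binom.cdf(r - b, r, p) - binom.cdf(b - 1, r, p)
    return float(np.sum(detect / i))


def watterson_factor(
    r: int | np.ndarray, n: int, min_minor: int = 2
) -> float | np.ndarray:
    """Per-site Pool-seq Watterson denominator factor.

    Expected harmonic factor of the number of distinct pool lineages among
    ``r`` reads from a pool of ``n`` haploids, restricted to allele
    configurations detectable with at least ``min_minor`` reads of the
    minor allele.  Scalar or vectorized over ``r``.
    """
    if np.isscalar(r):
        return _watterson_factor_scalar(int(r), int(n), int(min_minor))
    r = np.asarray(r)
    uniq = np.unique(r)
    lookup = {int(u): _watterson_factor_scalar(int(u), int(n), int(min_minor)) for u in uniq}
    return np.array([lookup[int(v)] for v in r])


def theta_windows(
    sites: pd.DataFrame,
    pool_size: int = 50,
    window: int = 10_000,
    min_analyzed: int = 9000,
    min_cov: int = 4,
    max_cov: int = 250,
    min_minor: int = 2,
) -> pd.DataFrame:
    """Per-window Watterson theta over a sorted pooled-count table.

    ``sites`` columns: contig, pos (0-based), ref_count, alt_count.
    Windows are fixed-width, anchored at coordinate 0 of each contig.
    Output columns: contig, start, end, n_analyzed, S, denom, theta_hat,
    dropped — windows with fewer than ``min_analyzed`` analyzed positions
    are flagged dropped (excluded from summaries but still reported).
    Raises on input not sorted by (contig, pos).
    """
    for contig, grp in sites.groupby("contig", sort=False):
        if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
            raise ValueError(f"{contig}: positions not strictly increasing")

    analyzed, segregating = site_filter(
        sites["ref_count"].to_numpy(), sites["alt_count"].to_numpy(),
        min_cov=min_cov, max_cov=max_cov, min_minor=min_minor,
    )
    depth = sites["ref_count"].to_numpy() + sites["alt_count"].to_numpy()
    factors = np.zeros(len(sites))
    if analyzed.any():
        factors[analyzed] = watterson_factor(depth[analyzed], pool_size, min_minor)

    df = pd.DataFrame(
        {
            "contig": sites["contig"].to_numpy(),
            "win": sites["pos"].to_numpy() // window,
            "analyzed": analyzed.astype(np.int64),
            "S": segregating.astype(np.int64),
            "denom": factors,
        }
    )
    agg = df.groupby(["contig", "win"], sort=True).sum().reset_index()
    agg["start"] = agg["win"] * window
    agg["end"] = agg["start"] + window
    agg = agg.rename(columns={"analyzed": "n_analyzed"})
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["theta_hat"] = np.where(agg["denom"] > 0, agg["S"] / agg["denom"], 0.0)
    agg["dropped"] = agg["n_analyzed"] < min_analyzed
    return agg[["contig", "start", "end", "n_analyzed", "S", "denom", "theta_hat", "dropped"]]


def summarize_by_class(
    windows: pd.DataFrame, contig_classes: Mapping[str, str]
) -> pd.DataFrame:
    """Mean and SEM of per-window theta_hat grouped by chromosome class.

    Dropped windows are excluded.  Contigs absent from ``contig_classes``
    are grouped under "Unknown"; a class with a single retained window gets
    SEM = NaN.
    """
    retained = windows.loc[~windows["dropped"]].copy()
    retained["class"] = [contig_classes.get(c, "Unknown") for c in retained["contig"]]
    rows = []
    for cls, grp in retained.groupby("class", sort=True):
        vals = grp["theta_hat"].to_numpy()
        mean = float(np.mean(vals))
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append((cls, len(vals), mean, sem))
    return pd.DataFrame(rows, columns=["class", "n_windows", "mean_theta", "sem_theta"])


def hysteresis_segment(
    rates: Sequence[float],
    contig: str = "contig",
    open_thresh: float = 0.005,
    close_thresh: float = 0.001,
    run: int = 5,
    window: int = 10_000,
    kind: str = "generic",
) -> list[RateRegion]:
    """Two-threshold hysteresis segmentation of an ordered window rate track.

    A region opens at the first window of a run of >= ``run`` consecutive
    windows with rate strictly above ``open_thresh``; once open, it closes
    at the window preceding the first window of a run of >= ``run``
    consecutive windows strictly below ``close_thresh`` (the closing run is
    excluded).  An open region is closed at the contig end.  Rates between
    the thresholds neither open nor close.  Coordinates are bp, half-open,
    window-aligned.
    """
    if close_thresh > open_thresh:
        raise ValueError("close_thresh must not exceed open_thresh")
    x = np.asarray(rates, dtype=float)
    n = len(x)
    above = x > open_thresh
    below = x < close_thresh
    regions: list[RateRegion] = []
    i = 0
    open_start: int | None = None
    while i < n:
        if open_start is None:
            if above[i] and np.all(above[i : i + run]) and i + run <= n:
                open_start = i
                i += run
            else:
                i += 1
        else:
            if below[i] and i + run <= n and np.all(below[i : i + run]):
                regions.append(_make_region(x, contig, open_start, i, window, kind))
                open_start = None
                i += 1  # closing-run windows cannot re-open (close < open thresh)
            else:
                i += 1
    if open_start is not None:
        regions.append(_make_region(x, contig, open_start, n, window, kind))
    return regions


def _make_region(
    x: np.ndarray, contig: str, start_win: int, end_win: int, window: int, kind: str
) -> RateRegion:
    return RateRegion(
        contig=contig,
        start=start_win * window,
        end=end_win * window,
        n_windows=end_win - start_win,
        mean_rate=float(np.mean(x[start_win:end_win])),
        kind=kind,
    )
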