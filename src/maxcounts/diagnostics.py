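"""Evaluation battery for count summarization methods.

Covers the properties a good expression measure should have: no
dependence on exon length or GC content (binned bias curves), no
over-representation of highly expressed exons (count-concentration
summaries), accuracy against spike-ins of known concentration,
low technical variance (variance and CV curves across replicates), and
robustness to alignment filtering (relative-variation statistic).

Curves follow the binned-spline convention: points are sorted by the
x covariate, averaged in fixed-size bins (default 5000 exons), and a
natural cubic spline is drawn through the bin means. Log transforms use
log2(x + 1) so zero counts stay representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import linregress, pearsonr, spearmanr

from .counting import CountMatrix

__all__ = [
    "BinnedCurve",
    "DistributionSummary",
    "SpikeinReport",
    "log_counts",
    "binned_bias_curve",
    "distribution_summary",
    "variance_cv_curves",
    "spikein_accuracy",
    "delta_stat",
    "relative_variation",
    "load_concentrations",
]

DEFAULT_BIN_SIZE = 5000


def log_counts(x) -> np.ndarray:
    """log2(x + 1), the log scale used for all curves."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


@dataclass
class BinnedCurve:
    """Bin means of (x, y) plus a natural cubic spline through them."""

    bin_bounds: np.ndarray  # (n_bins + 1,) bounds on x
    mean_x: np.ndarray
    mean_y: np.ndarray
    spearman: float = np.nan

    def __post_init__(self) -> None:
        ux, idx = np.unique(self.mean_x, return_index=True)
        if ux.size >= 2:
            self._spline = CubicSpline(ux, self.mean_y[idx], bc_type="natural")
        else:
            const = float(self.mean_y[0])
            self._spline = lambda x: np.full_like(np.asarray(x, dtype=float), const)

    def __call__(self, x) -> np.ndarray:
        return np.asarray(self._spline(np.asarray(x, dtype=float)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean_x": self.mean_x, "mean_y": self.mean_y})


def _binned(x: np.ndarray, y: np.ndarray, bin_size: int,
            spearman_score: float = np.nan) -> BinnedCurve:
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = xs.size
    edges = list(range(0, n, bin_size)) + [n]
    mean_x, mean_y, bounds = [], [], [xs[0]]
    for lo, hi in zip(edges[:-1], edges[1:]):
        mean_x.append(xs[lo:hi].mean())
        mean_y.append(ys[lo:hi].mean())
        bounds.append(xs[hi - 1])
    return BinnedCurve(
        bin_bounds=np.asarray(bounds),
        mean_x=np.asarray(mean_x),
        mean_y=np.asarray(mean_y),
        spearman=spearman_score,
    )


def binned_bias_curve(x, y, bin_size: int = DEFAULT_BIN_SIZE) -> BinnedCurve:
    """Bias of mean log-counts ``y`` against a per-exon covariate ``x``.

    Exons are sorted by the covariate and averaged in consecutive bins of
    ``bin_size`` (the last bin may be smaller); a natural cubic spline
    runs through the bin means. The Spearman correlation of (x, y) is
    attached as a scalar bias score.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be aligned")
    if x.size < 2:
        raise ValueError("need at least 2 points for a bias curve")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        rho = 0.0
    else:
        rho = float(spearmanr(x, y).statistic)
    return _binned(x, y, bin_size, spearman_score=rho)


@dataclass
class DistributionSummary:
    """Concentration of a library's counts on few exons.

    ``curve`` maps the fraction of nonzero-count exons (sorted by
    decreasing count) to the fraction of total counts they hold;
    ``pct_exons_at_50``/``90`` are the x-values where the curve reaches
    50% and 90% of the total.
    """

    curve: pd.DataFrame  # columns: pct_exons, pct_counts
    pct_exons_at_50: float
    pct_exons_at_90: float
    n_nonzero: int


def distribution_summary(counts) -> DistributionSummary:
    """Cumulative count-share curve over nonzero-count exons."""
    values = np.asarray(counts, dtype=float)
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("all counts are zero")
    desc = np.sort(values)[::-1]
    cum = np.cumsum(desc)
    total = cum[-1]
    n = desc.size
    pct_exons = 100.0 * np.arange(1, n + 1) / n
    pct_counts = 100.0 * cum / total

    def pct_at(q: float) -> float:
        k = int(np.searchsorted(cum, q * total, side="left")) + 1
        return 100.0 * k / n

    return DistributionSummary(
        curve=pd.DataFrame({"pct_exons": pct_exons, "pct_counts": pct_counts}),
        pct_exons_at_50=pct_at(0.50),
        pct_exons_at_90=pct_at(0.90),
        n_nonzero=n,
    )


def _rescale_01(x: np.ndarray) -> np.ndarray:
    span = np.ptp(x)
    return (x - x.min()) / span if span > 0 else np.zeros_like(x)


def variance_cv_curves(matrix: CountMatrix, bin_size: int = DEFAULT_BIN_SIZE
                       ) -> tuple[BinnedCurve, BinnedCurve]:
    """Technical variance and CV across the replicates of one group.

    The variance curve plots the unbiased variance of log-counts against
    their mean; the CV curve plots sd/mean of raw counts against the log
    of the raw mean. The x-axes are affinely rescaled to [0, 1] so curves
    of differently scaled measures are comparable.
    """
    if len(set(matrix.groups.values())) > 1:
        raise ValueError("restrict the matrix to one replicate group first")
    if matrix.data.shape[1] < 2:
        raise ValueError("variance needs at least two replicates")
    raw = matrix.data.to_numpy(dtype=float)
    logs = log_counts(raw)
    mean_log = logs.mean(axis=1)
    var_log = logs.var(axis=1, ddof=1)
    mean_raw = raw.mean(axis=1)
    sd_raw = raw.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean_raw > 0, sd_raw / mean_raw, 0.0)
    var_curve = _binned(_rescale_01(mean_log), var_log, bin_size)
    cv_curve = _binned(_rescale_01(log_counts(mean_raw)), cv, bin_size)
    return var_curve, cv_curve


@dataclass
class SpikeinReport:
    """Log-log agreement between counts and true concentrations."""

    r: float
    p_value: float
    slope: float
    intercept: float
    residuals: pd.Series
    n: int


def spikein_accuracy(counts: pd.Series, truth: pd.Series) -> SpikeinReport:
    """Regress log counts on log true concentrations.

    Spike-ins with zero counts are excluded; at least 3 nonzero points
    are required. Pearson's r is computed on the log-log scale with the
    standard two-sided t-transform p-value; residuals are per spike-in.
    """
    counts = pd.Series(counts, dtype=float)
    missing = counts.index.difference(truth.index)
    if len(missing):
        raise KeyError(f"no true concentration for: {list(missing)[:5]}")
    if (truth.loc[counts.index] <= 0).any():
        raise ValueError("true concentrations must be positive")
    keep = counts > 0
    counts = counts[keep]
    if len(counts) < 3:
        raise ValueError("need at least 3 spike-ins with nonzero counts")
    x = np.log10(truth.loc[counts.index].to_numpy(dtype=float))
    y = np.log10(counts.to_numpy(dtype=float))
    fit = linregress(x, y)
    r, p = pearsonr(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    return SpikeinReport(
        r=float(r), p_value=float(p), slope=float(fit.slope),
        intercept=float(fit.intercept),
        residuals=pd.Series(resid, index=counts.index), n=len(counts),
    )


def delta_stat(xa: float, xb: float) -> float:
    """Percent discrepancy between two estimates of equal true abundance:
    ``(xa - xb) / (xa + xb) * 100``, in [-100, 100]."""
    if xa < 0 or xb < 0:
        raise ValueError("counts must be non-negative")
    if xa + xb == 0:
        raise ValueError("delta undefined for two zero estimates")
    return (xa - xb) / (xa + xb) * 100.0


def relative_variation(orig: CountMatrix, filt: CountMatrix
                       ) -> tuple[pd.DataFrame, float]:
    """Per-entry sensitivity of raw counts to alignment filtering.

    ``(X_orig - X_filt) / (X_orig + 1) * 100``; the +1 in the denominator
    avoids division by zero. Returns the percent matrix and the fraction
    of entries that are exactly 0%.
    """
    if not orig.data.index.equals(filt.data.index) or \
            not orig.data.columns.equals(filt.data.columns):
        raise ValueError("matrices must share exon and library indexes")
    rv = (orig.data - filt.data) / (orig.data + 1) * 100.0
    frac_zero = float((rv.to_numpy() == 0).mean())
    return rv, frac_zero


def load_concentrations(path) -> pd.Series:
    """Read a spike-in concentration table (TSV: id, concentration)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["id", "concentration"])
    if df["id"].duplicated().any():
        raise ValueError("duplicate spike-in ids in concentration table")
    conc = df.set_index("id")["concentration"].astype(float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    return conc
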