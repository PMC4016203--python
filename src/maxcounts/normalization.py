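"""Between- and within-library normalization of count matrices.

Implements the trimmed mean of M-values (TMM) between-library scaling,
RPKM (reads per kilobase of exon model per million mapped reads),
between-lane full-quantile normalization, and within-lane full-quantile
normalization over a per-exon covariate (exon length by default).

TMM follows its original formulation: the reference library is the one
whose scaled upper quartile is closest to the mean upper quartile; for
each library, log-ratios M and log-abundances A are computed over exons
expressed in both the library and the reference, doubly trimmed (30% on
M, 5% on A), and averaged with inverse asymptotic-variance weights; the
factors are rescaled to geometric mean 1.

Full-quantile normalization maps each group's values onto the average
empirical quantile profile of all groups. Each group's quantile function
is linear interpolation through its order statistics at mid-probabilities
(i + 0.5)/n, so for equal-size groups the procedure reduces exactly to
averaging order statistics; ties receive the mean of the values they
span (mid-rank).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .counting import CountMatrix

__all__ = [
    "SizeFactors",
    "tmm_factors",
    "apply_size_factors",
    "rpkm",
    "fq_between_lane",
    "fq_within_lane",
]


@dataclass
class SizeFactors:
    """Per-library positive scaling factors from TMM."""

    factors: pd.Series
    ref_library: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Log2 TMM factor of one library against the reference."""
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask].astype(float), ref[mask].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M under binomial sampling
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))


def tmm_factors(matrix: CountMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05) -> SizeFactors:
    """Trimmed-mean-of-M-values scaling factors for a raw count matrix."""
    data = matrix.data
    if data.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    lib_sizes = data.sum(axis=0)
    if (lib_sizes == 0).any():
        empty = lib_sizes.index[lib_sizes == 0].tolist()
        raise ValueError(f"libraries with all-zero counts: {empty}")
    uq = (data / lib_sizes).quantile(0.75, axis=0)
    ref_lib = (uq - uq.mean()).abs().idxmin()
    ref = data[ref_lib].to_numpy()
    n_ref = float(lib_sizes[ref_lib])
    logf = {}
    for lib in data.columns:
        if lib == ref_lib:
            logf[lib] = 0.0
        else:
            logf[lib] = _tmm_pair(data[lib].to_numpy(), ref, float(lib_sizes[lib]),
                                  n_ref, trim_m, trim_a)
    factors = pd.Series({lib: 2.0 ** f for lib, f in logf.items()})[data.columns]
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return SizeFactors(factors=factors, ref_library=str(ref_lib))


def apply_size_factors(matrix: CountMatrix, factors: SizeFactors) -> CountMatrix:
    """Scale each library by its effective size (factor × library size).

    Values become counts per scaled library, multiplied by the geometric
    mean of the effective sizes so they remain on the raw-count scale.
    """
    missing = set(matrix.libraries) - set(factors.factors.index)
    if missing:
        raise KeyError(f"no size factor for libraries: {sorted(missing)}")
    eff = factors.factors[matrix.libraries] * matrix.library_sizes()
    scale = np.exp(np.mean(np.log(eff)))
    return matrix.with_data(matrix.data / eff * scale)


def rpkm(matrix: CountMatrix, lengths: pd.Series) -> CountMatrix:
    """Reads per kilobase of exon per million mapped reads.

    ``RPKM_ij = N_ij / (L_i/10^3 × N·j/10^6)`` with L_i the exon length in
    bp and N·j the library's total raw counts (not TMM-corrected).
    """
    lengths = lengths.reindex(matrix.exon_ids)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every exon needs a positive length")
    totals = matrix.library_sizes()
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"libraries with zero total counts: {empty}")
    denom = np.outer(lengths / 1e3, totals / 1e6)
    return matrix.with_data(matrix.data / denom)


def _quantile_normalize_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    """Map each group onto the mean empirical quantile profile."""
    sorted_vals = [np.sort(g.astype(float)) for g in groups]
    mid_p = [(np.arange(s.size) + 0.5) / s.size for s in sorted_vals]

    def target(p: np.ndarray) -> np.ndarray:
        acc = np.zeros_like(p, dtype=float)
        for mp, sv in zip(mid_p, sorted_vals):
            acc += np.interp(p, mp, sv)
        return acc / len(sorted_vals)

    out = []
    for g in groups:
        p = (rankdata(g) - 0.5) / g.size
        out.append(target(p))
    return out


def fq_between_lane(matrix: CountMatrix) -> CountMatrix:
    """Full-quantile normalization across libraries.

    Each library's sorted values are replaced by the across-library mean
    of order statistics, mapped back through the library's ranks;
    afterwards every column has the same sorted vector (up to ties).
    """
    if matrix.data.shape[1] < 2:
        raise ValueError("between-lane normalization needs at least two libraries")
    cols = [matrix.data[c].to_numpy() for c in matrix.libraries]
    normed = _quantile_normalize_groups(cols)
    data = pd.DataFrame(
        {c: v for c, v in zip(matrix.libraries, normed)}, index=matrix.exon_ids
    )
    return matrix.with_data(data)


def fq_within_lane(matrix: CountMatrix, covariate: pd.Series,
                   n_strata: int = 10) -> CountMatrix:
    """Full-quantile normalization across covariate strata, per library.

    Exons are stratified into ``n_strata`` near-equal-size groups by
    covariate rank (the stratification is shared by all libraries); each
    stratum's values are mapped to the mean quantile profile over strata,
    removing the dependence of the count distribution on the covariate.
    """
    covariate = covariate.reindex(matrix.exon_ids)
    if covariate.isna().any():
        raise ValueError("covariate undefined for some exons")
    n = len(matrix.exon_ids)
    if n_strata > n:
        raise ValueError(f"n_strata ({n_strata}) exceeds number of exons ({n})")
    order = np.argsort(covariate.to_numpy(), kind="stable")
    strata = np.array_split(order, n_strata)
    out = matrix.data.astype(float).copy()
    for lib in matrix.libraries:
        col = matrix.data[lib].to_numpy()
        groups = [col[idx] for idx in strata]
        normed = _quantile_normalize_groups(groups)
        new_col = np.empty(n, dtype=float)
        for idx, vals in zip(strata, normed):
            new_col[idx] = vals
        out[lib] = new_col
    return matrix.with_data(out)
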