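"""Two-channel expression normalization and SAM-style differential
expression.

Each array is already a mutant-vs-wild-type log2 ratio, so the design is
one-class: the question per gene is whether the mean log-ratio differs
from zero. The moderated statistic is

    d = mean(log-ratios) / (se(log-ratios) + s0)

with the fudge constant s0 stabilizing genes with tiny standard errors;
by default s0 is the 5th percentile of gene-wise standard errors. The
false-discovery rate is estimated by permutation: the signs of whole
replicate arrays are flipped (the one-class exchangeability argument for
symmetric ratio noise), d is recomputed, and a gene's q-value is the
median count of null |d| at or above its own |d| across permutations,
divided by the observed count, capped at 1.

Arrays with an intensity-dependent dye bias are normalized with Loess
(locally weighted regression of log-ratio on mean spot intensity,
subtracted per array); ratio tables for stability analyses are
median-centred instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from pombechip.matrix import EnrichmentMatrix, require_min_finite

DEFAULT_FDR = 0.005
DEFAULT_LOESS_SPAN = 0.3
_MIN_LOESS_POINTS = 10


@dataclass
class DEResult:
    gene_id: str
    mean_log2fc: float
    d_stat: float
    q_value: float
    called: bool

    @property
    def fold_change(self) -> float:
        return float(2.0 ** self.mean_log2fc)

    @property
    def direction(self) -> str:
        if not self.called:
            return "unchanged"
        return "up" if self.mean_log2fc > 0 else "down"


def loess_normalize(
    matrix: EnrichmentMatrix,
    intensities: pd.DataFrame,
    span: float = DEFAULT_LOESS_SPAN,
) -> EnrichmentMatrix:
    """Per array, subtract the Loess fit of log-ratio on mean intensity.

    Removes smooth intensity-dependent dye bias (including any constant
    offset, which is a flat trend). ``intensities`` must be aligned to
    the matrix (same genes x samples).
    """
    if not matrix.values.index.equals(intensities.index) or not matrix.values.columns.equals(
        intensities.columns
    ):
        intensities = intensities.reindex(
            index=matrix.values.index, columns=matrix.values.columns
        )
    out = matrix.values.copy()
    for col in out.columns:
        m = out[col].to_numpy(float)
        a = intensities[col].to_numpy(float)
        ok = np.isfinite(m) & np.isfinite(a)
        if ok.sum() < _MIN_LOESS_POINTS:
            raise ValueError(
                f"array {col!r}: only {int(ok.sum())} finite (ratio, intensity) "
                f"points; need >= {_MIN_LOESS_POINTS} to fit Loess"
            )
        fitted = lowess(m[ok], a[ok], frac=span, return_sorted=False)
        m[ok] = m[ok] - fitted
        out[col] = m
    return matrix.with_values(out)


def trend_amplitude(
    matrix: EnrichmentMatrix, intensities: pd.DataFrame, span: float = DEFAULT_LOESS_SPAN
) -> pd.Series:
    """Max |Loess-fitted trend| per array — the residual-bias diagnostic."""
    amps = {}
    for col in matrix.values.columns:
        m = matrix.values[col].to_numpy(float)
        a = intensities[col].to_numpy(float)
        ok = np.isfinite(m) & np.isfinite(a)
        fitted = lowess(m[ok], a[ok], frac=span, return_sorted=False)
        amps[col] = float(np.max(np.abs(fitted)))
    return pd.Series(amps)


def median_centre(matrix: EnrichmentMatrix) -> EnrichmentMatrix:
    """Subtract each column's median (used for RNA-stability ratio tables)."""
    require_min_finite(matrix.values, 1)
    return matrix.with_values(matrix.values - matrix.values.median(axis=0, skipna=True))


def _row_mean_se(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise NaN-aware mean and standard error of the mean.

    Mean is NaN with no finite cells; se is NaN with fewer than 2.
    """
    finite = np.isfinite(values)
    n = finite.sum(axis=1)
    filled = np.where(finite, values, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=1) / n
        dev = np.where(finite, values - mean[:, None], 0.0)
        var = (dev**2).sum(axis=1) / (n - 1)
        se = np.sqrt(var) / np.sqrt(n)
    mean[n == 0] = np.nan
    se[n < 2] = np.nan
    return mean, se


def _se(values: np.ndarray) -> np.ndarray:
    return _row_mean_se(values)[1]


def percentile_s0(matrix: EnrichmentMatrix, percentile: float = 5.0) -> float:
    """s0 as a fixed percentile of the gene-wise standard errors.

    A cheap alternative to :func:`tune_s0`; with few replicates the
    standard-error distribution is heavy-tailed and a low percentile
    under-damps the statistic, so the tuned value is the default.
    """
    se = _se(matrix.values.to_numpy(float))
    se = se[np.isfinite(se)]
    if se.size == 0:
        raise ValueError("no gene has >= 2 finite replicates; cannot derive s0")
    return float(np.percentile(se, percentile))


def tune_s0(matrix: EnrichmentMatrix, n_bins: int = 20) -> float:
    """The SAM fudge-factor search: choose s0 to decouple d from se.

    Candidate s0 values are the 0th-100th percentiles (in steps of 5) of
    the gene-wise standard errors. For each candidate, genes are binned
    by standard error, the median absolute deviation of d is computed
    within each bin, and the candidate minimizing the coefficient of
    variation of these spreads is selected — the d-statistic's scale
    should not depend on where a gene sits in the variance spectrum.
    """
    vals = matrix.values.to_numpy(float)
    mean, se = _row_mean_se(vals)
    ok = np.isfinite(se) & np.isfinite(mean)
    se, mean = se[ok], mean[ok]
    if se.size < 2 * n_bins:
        return float(np.median(se)) if se.size else 0.0
    edges = np.quantile(se, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, se, side="right") - 1, 0, n_bins - 1)
    best_s0, best_cv = 0.0, np.inf
    for alpha in np.linspace(0, 100, 21):
        s0 = float(np.percentile(se, alpha))
        with np.errstate(invalid="ignore", divide="ignore"):
            d = mean / (se + s0)
        spreads = []
        for b in range(n_bins):
            db = d[(bins == b) & np.isfinite(d)]
            if db.size:
                spreads.append(1.4826 * np.median(np.abs(db - np.median(db))))
        spreads = np.asarray(spreads)
        m = spreads.mean() if spreads.size else 0.0
        cv = spreads.std(ddof=1) / m if m > 0 and spreads.size > 1 else np.inf
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return best_s0


def default_s0(matrix: EnrichmentMatrix) -> float:
    """Default fudge factor: the tuned SAM value."""
    return tune_s0(matrix)


def sam_statistic(matrix: EnrichmentMatrix, s0: float | None = None) -> pd.Series:
    """Per-gene moderated one-class statistic d = mean / (se + s0).

    Genes with fewer than 2 finite replicates get NaN.
    """
    if s0 is None:
        s0 = default_s0(matrix)
    if s0 < 0:
        raise ValueError(f"s0 must be >= 0, got {s0}")
    vals = matrix.values.to_numpy(float)
    mean, se = _row_mean_se(vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = mean / (se + s0)
    return pd.Series(d, index=matrix.values.index, name="d_stat")


def sam_fdr(
    matrix: EnrichmentMatrix,
    n_permutations: int = 100,
    seed: int | None = None,
    fdr_threshold: float = DEFAULT_FDR,
    s0: float | None = None,
) -> list[DEResult]:
    """One-class SAM with sign-flip permutation FDR.

    Null d-statistics come from flipping the sign of whole replicate
    columns (one random ±1 per array per permutation, shared by all
    genes). For each gene, q = median over permutations of the number of
    null |d| >= |d_gene|, divided by the observed number of |d| >=
    |d_gene|, capped at 1. Genes with q < ``fdr_threshold`` are called.

    Fully reproducible given ``seed``; omitting the seed is an error
    because the permutation draw is the only stochastic element.
    """
    if n_permutations < 50:
        raise ValueError(f"need >= 50 permutations, got {n_permutations}")
    if seed is None:
        raise ValueError("sam_fdr requires an explicit seed for reproducibility")
    rng = np.random.default_rng(seed)

    if s0 is None:
        s0 = default_s0(matrix)
    d_obs = sam_statistic(matrix, s0=s0).to_numpy(float)
    vals = matrix.values.to_numpy(float)
    n_rep = vals.shape[1]

    finite = np.isfinite(d_obs)
    abs_obs = np.abs(d_obs[finite])
    # observed count of |d| >= each gene's |d| (rank from the top, ties included)
    order = np.sort(abs_obs)
    n_obs_ge = abs_obs.size - np.searchsorted(order, abs_obs, side="left")

    null_counts = np.empty((n_permutations, abs_obs.size), dtype=np.int64)
    for b in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n_rep)
        vperm = vals * signs[np.newaxis, :]
        pmean, pse = _row_mean_se(vperm)
        with np.errstate(invalid="ignore", divide="ignore"):
            d_null = pmean / (pse + s0)
        abs_null = np.sort(np.abs(d_null[np.isfinite(d_null)]))
        null_counts[b] = abs_null.size - np.searchsorted(abs_null, abs_obs, side="left")
    med_null = np.median(null_counts, axis=0)

    q = np.minimum(med_null / n_obs_ge, 1.0)
    q_full = np.full(d_obs.shape, np.nan)
    q_full[finite] = q

    mean_fc, _ = _row_mean_se(vals)
    results = []
    for i, gid in enumerate(matrix.values.index):
        qi = q_full[i]
        results.append(
            DEResult(
                gene_id=str(gid),
                mean_log2fc=float(mean_fc[i]) if np.isfinite(mean_fc[i]) else float("nan"),
                d_stat=float(d_obs[i]),
                q_value=float(qi) if np.isfinite(qi) else 1.0,
                called=bool(np.isfinite(qi) and qi < fdr_threshold),
            )
        )
    return results


def called_sets(results: list[DEResult]) -> tuple[set[str], set[str]]:
    """Split the called genes into (up-regulated, down-regulated) id sets."""
    up = {r.gene_id for r in results if r.called and r.mean_log2fc > 0}
    down = {r.gene_id for r in results if r.called and r.mean_log2fc < 0}
    return up, down


def fold_change(matrix: EnrichmentMatrix, gene_id: str) -> float:
    """Linear fold-change: 2^(mean log2 ratio across replicates)."""
    if gene_id not in matrix.values.index:
        raise KeyError(f"gene {gene_id!r} not in matrix")
    row = matrix.values.loc[gene_id].to_numpy(float)
    if not np.any(np.isfinite(row)):
        raise ValueError(f"gene {gene_id!r}: all replicates missing")
    return float(2.0 ** np.nanmean(row))


def write_de_results(results: list[DEResult], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\tmean_log2fc\tfold_change\td_stat\tq_value\tdirection\n")
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.mean_log2fc:.4f}\t{r.fold_change:.4f}\t"
                f"{r.d_stat:.4f}\t{r.q_value:.6g}\t{r.direction}\n"
            )
    return path
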