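"""Expression/methylation preprocessing and SVD-based quality control.

The expression path replaces zeros by the dataset-wide minimal positive
value and log2-transforms.  The methylation path converts array intensities
to beta values, drops probes with excessive missingness and imputes the
rest probe-wise by k-nearest neighbours.  ``svd_qc`` counts significant
components of variation against a random-matrix (Marchenko-Pastur) null
and associates them with sample factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, MethylationMatrix, SampleSheet

__all__ = [
    "beta_from_intensities",
    "preprocess_expression",
    "filter_and_impute",
    "svd_qc",
    "SVDQCReport",
    "bmiq_hook",
]


def beta_from_intensities(M, U):
    """Beta value from methylated/unmethylated intensities:
    ``Max(M,0) / (Max(M,0) + Max(U,0) + 100)``.

    Accepts scalars or arrays; negative intensities are clamped to zero by
    the formula, so the result always lies in [0, 1).
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.isfinite(M).all() and np.isfinite(U).all()):
        raise ValueError("intensities must be finite")
    m = np.maximum(M, 0.0)
    u = np.maximum(U, 0.0)
    beta = m / (m + u + 100.0)
    return float(beta) if beta.ndim == 0 else beta


def preprocess_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace zeros by the dataset-wide minimal positive value, then log2.

    Requires a raw-scale matrix with at least one positive entry.
    """
    if expr.scale != "raw":
        raise ValueError("preprocess_expression expects a raw-scale matrix")
    vals = expr.values.copy()
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("all-zero expression matrix")
    vals[vals == 0] = pos.min()
    out = pd.DataFrame(np.log2(vals), index=expr.data.index, columns=expr.data.columns)
    return ExpressionMatrix(out, scale="log2", cohort_id=expr.cohort_id)


def _masked_sq_distances(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise squared Euclidean distances over shared non-missing samples.

    Returns (D2, n_shared).  Pairs with no shared samples get D2 = inf.
    """
    W = (~np.isnan(X)).astype(float)
    A = np.nan_to_num(X)
    sq = (A * A) * W
    G = A @ A.T
    D2 = sq @ W.T + W @ sq.T - 2.0 * (A * W) @ (A * W).T
    # A*W == A since missing entries are zeroed; kept explicit for clarity
    n_shared = W @ W.T
    D2 = np.where(n_shared > 0, np.maximum(D2, 0.0), np.inf)
    return D2, n_shared


def filter_and_impute(
    meth: MethylationMatrix, max_na_fraction: float = 0.70, k: int = 10
) -> MethylationMatrix:
    """Drop probes missing in more than ``max_na_fraction`` of samples and
    impute remaining gaps probe-wise by k-nearest-neighbour averaging.

    Neighbour distance is plain Euclidean over the samples both probes
    observe; a probe's missing value is the mean of its k nearest probes'
    values in that sample (clipped to [0, 1]).  When no neighbour observes
    the sample, the probe's own mean is used and a warning issued.
    Observed values are never altered.
    """
    df = meth.data
    na_frac = df.isna().mean(axis=1)
    kept = df.loc[na_frac <= max_na_fraction]
    if kept.empty:
        raise ValueError("no probe passes the NA-fraction threshold")
    X = kept.to_numpy(dtype=float)
    miss = np.isnan(X)
    if not miss.any():
        return MethylationMatrix(kept.copy(), cohort_id=meth.cohort_id)

    D2, _ = _masked_sq_distances(X)
    np.fill_diagonal(D2, np.inf)
    out = X.copy()
    observed = ~miss
    probe_means = np.nanmean(X, axis=1)
    for i in np.nonzero(miss.any(axis=1))[0]:
        order = np.argsort(D2[i], kind="stable")
        order = order[np.isfinite(D2[i][order])]
        for j in np.nonzero(miss[i])[0]:
            cand = order[observed[order, j]]
            if cand.size == 0:
                warnings.warn(
                    f"probe {kept.index[i]!r}: no neighbour observes sample "
                    f"{kept.columns[j]!r}; falling back to the probe mean"
                )
                out[i, j] = probe_means[i]
            else:
                out[i, j] = X[cand[:k], j].mean()
    out = np.clip(out, 0.0, 1.0)
    return MethylationMatrix(
        pd.DataFrame(out, index=kept.index, columns=kept.columns),
        cohort_id=meth.cohort_id,
    )


# Tracy-Widom (GOE) 95th percentile, used to calibrate the Marchenko-Pastur
# edge for finite matrices (Johnstone's largest-eigenvalue test at the 5%
# level); without this allowance the top noise eigenvalue crosses the
# asymptotic edge in a sizeable fraction of draws.
_TW1_Q95 = 0.9793


@dataclass
class SVDQCReport:
    """Significant components of variation and their factor associations."""

    n_significant: int
    variance_fractions: np.ndarray  # per retained component
    pvalues: pd.DataFrame  # components x factors
    eigenvalues: np.ndarray
    threshold: float


def _component_factor_pvalue(score: np.ndarray, factor: pd.Series) -> float:
    """Associate one component's sample scores with one factor: rank-sum for
    2-level factors, Kruskal-Wallis for >2 levels, Spearman for numeric."""
    if pd.api.types.is_numeric_dtype(factor):
        if factor.nunique() < 2:
            return np.nan
        return float(stats.spearmanr(score, factor.to_numpy()).pvalue)
    levels = factor.astype(str)
    uniq = levels.unique()
    groups = [score[(levels == u).to_numpy()] for u in uniq]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        return np.nan
    if len(groups) == 2:
        return float(stats.mannwhitneyu(groups[0], groups[1]).pvalue)
    return float(stats.kruskal(*groups).pvalue)


def svd_qc(
    data: pd.DataFrame, sheet: SampleSheet, factors: list[str] | None = None
) -> SVDQCReport:
    """SVD quality control of a genes/probes x samples matrix.

    Rows are centred; the number of significant components is the count of
    eigenvalues of the (row-standardised) sample correlation structure
    exceeding the Marchenko-Pastur upper edge with a Tracy-Widom
    finite-sample allowance at the 5% level.  Retained components are
    tested for association with each sample-sheet factor.
    """
    factors = factors if factors is not None else ["status", "group"]
    X = data.to_numpy(dtype=float)
    p, n = X.shape
    if n < 5:
        raise ValueError("svd_qc requires at least 5 samples")
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        return SVDQCReport(0, np.array([]), pd.DataFrame(columns=factors), np.array([]), np.nan)
    Xs = X[keep] / sd[keep, None]
    p_eff = Xs.shape[0]

    # eigenvalues of the n x n sample correlation structure (rows as
    # observations), compared with the MP edge for ratio n / p_eff
    U, svals, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = svals**2 / p_eff
    edge = (1.0 + np.sqrt(n / p_eff)) ** 2
    mu = (np.sqrt(p_eff - 1) + np.sqrt(n)) ** 2
    sigma = (np.sqrt(p_eff - 1) + np.sqrt(n)) * (
        1.0 / np.sqrt(p_eff - 1) + 1.0 / np.sqrt(n)
    ) ** (1.0 / 3.0)
    threshold = max(edge, (mu + _TW1_Q95 * sigma) / p_eff)
    n_sig = int(np.sum(eig > threshold))

    var_frac = (svals**2 / np.sum(svals**2))[:n_sig]
    pvals = {}
    for f in factors:
        if f not in sheet.table.columns:
            continue
        col = sheet.table.loc[data.columns, f]
        pvals[f] = [
            _component_factor_pvalue(Vt[c], col) for c in range(n_sig)
        ]
    pv = pd.DataFrame(pvals, index=[f"PC{c + 1}" for c in range(n_sig)])
    return SVDQCReport(n_sig, var_frac, pv, eig, threshold)


def bmiq_hook(meth: MethylationMatrix) -> MethylationMatrix:
    """No-op placeholder where a real-data adapter would insert Infinium
    type-II probe normalisation; synthetic data has no probe-type bias."""
    return meth
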