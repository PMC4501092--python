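"""Partial-correlation causal filtering of gene-index associations.

A marginal correlation between an epigenetic-enzyme gene's expression and
a global methylation-instability index can be confounded by the gene's own
promoter methylation (which the global shift drags along) or mediated by
another gene's expression.  Partialling those covariates out of both the
gene and the index discriminates direct influences: only directly coupled
genes retain a significant partial correlation.  Per-cohort records are
summarised into a consensus network of edges significant with consistent
sign in at least m of T cohorts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meta import fisher_z

__all__ = [
    "partial_correlation",
    "single_gene_causal_test",
    "full_model_causal_test",
    "build_consensus",
    "ConsensusNetwork",
]

logger = logging.getLogger(__name__)


def _independent_columns(Z: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a maximal linearly independent subset of columns,
    found by rank-revealing pivoted QR."""
    if Z.shape[1] == 0:
        return np.array([], dtype=int)
    from scipy.linalg import qr

    _, R, piv = qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        return np.array([], dtype=int)
    rank = int(np.sum(diag > tol * diag[0]))
    return np.sort(piv[:rank])


def partial_correlation(y, x, covariates=None) -> dict:
    """Partial Pearson correlation of ``y`` and ``x`` given covariates.

    Both variables are residualised by least squares on the covariates
    (standardised, plus intercept); the partial r is the Pearson
    correlation of the residuals, with a Fisher-Z P value of variance
    1/(n - k - 3) for k retained covariates.  Collinear covariates are
    dropped to an independent subset (logged).  With no covariates this
    is exactly the plain Pearson correlation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        Z = np.empty((n, 0))
    else:
        Z = np.column_stack([np.asarray(c, dtype=float) for c in covariates])
    if Z.shape[0] != n or x.size != n:
        raise ValueError("inputs must share the sample dimension")
    if n <= Z.shape[1] + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={Z.shape[1]})")

    # standardise covariates for numerical stability (result invariant)
    if Z.shape[1]:
        mu = Z.mean(axis=0)
        sd = Z.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Zs = (Z - mu) / sd
        keep = _independent_columns(Zs)
        if keep.size < Z.shape[1]:
            logger.info("dropped %d collinear covariates", Z.shape[1] - keep.size)
        Zs = Zs[:, keep]
    else:
        Zs = Z
    k = Zs.shape[1]
    design = np.column_stack([np.ones(n), Zs])
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    ry = y - design @ coef_y
    rx = x - design @ coef_x
    sy, sx = np.linalg.norm(ry), np.linalg.norm(rx)
    if sy == 0 or sx == 0:
        return {"r": np.nan, "pvalue": np.nan, "n": n, "k": k, "undefined": True}
    r = float(np.clip(ry @ rx / (sy * sx), -1.0, 1.0))
    if n - k - 3 <= 0:
        p = np.nan
    elif abs(r) == 1.0:
        p = 0.0
    else:
        z = float(fisher_z(r)) * math.sqrt(n - k - 3)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return {"r": r, "pvalue": p, "n": n, "k": k, "undefined": False}


def _records_for_gene(
    gene: str,
    x: np.ndarray,
    indices: pd.DataFrame,
    covariates,
    cohort: str,
    mode: str,
    covariate_desc: str,
    index_cols: dict[str, str],
) -> list[dict]:
    rows = []
    for label, col in index_cols.items():
        y = indices[col].to_numpy(dtype=float)
        res = partial_correlation(y, x, covariates)
        marg = partial_correlation(y, x, None)
        rows.append(
            {
                "gene": gene,
                "cohort": cohort,
                "index": label,
                "mode": mode,
                "partial_r": res["r"],
                "pvalue": res["pvalue"],
                "marginal_r": marg["r"],
                "marginal_pvalue": marg["pvalue"],
                "n": res["n"],
                "k": res["k"],
                "covariates": covariate_desc,
                "survives": bool(
                    not res["undefined"]
                    and res["pvalue"] < 0.05
                    and np.sign(res["r"]) == np.sign(marg["r"])
                ),
            }
        )
    return rows


_INDEX_COLS = {"HyperZ": "HyperZ_sig", "HypoZ": "HypoZ_sig"}


def single_gene_causal_test(
    gene: str,
    expr_values: pd.Series,
    promoter_meth: pd.Series | None,
    indices: pd.DataFrame,
    cohort: str = "",
    index_cols: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Partial correlation of one gene's expression with each index,
    controlling the gene's own promoter DNAm level.

    A gene "survives" when the partial P is < 0.05 with the same sign as
    the marginal correlation.  Genes without an annotated promoter
    cluster are flagged untestable.
    """
    index_cols = index_cols or _INDEX_COLS
    samples = [s for s in indices.index if s in expr_values.index]
    idx = indices.loc[samples]
    x = expr_values.loc[samples].to_numpy(dtype=float)
    if promoter_meth is None:
        logger.warning("gene %s has no promoter cluster; untestable", gene)
        rows = [
            {"gene": gene, "cohort": cohort, "index": label, "mode": "single_gene",
             "partial_r": np.nan, "pvalue": np.nan, "marginal_r": np.nan,
             "marginal_pvalue": np.nan, "n": len(samples), "k": 0,
             "covariates": "untestable", "survives": False}
            for label in index_cols
        ]
        return pd.DataFrame(rows)
    cov = [promoter_meth.loc[samples].to_numpy(dtype=float)]
    return pd.DataFrame(
        _records_for_gene(gene, x, idx, cov, cohort, "single_gene", "own promoter DNAm", index_cols)
    )


def full_model_causal_test(
    genes: list[str],
    expr: pd.DataFrame,
    promoter_meth: pd.DataFrame,
    indices: pd.DataFrame,
    cohort: str = "",
    index_cols: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Partial correlations in the joint model over K selected genes.

    For each gene the covariates are the other K-1 genes' expression plus
    the promoter DNAm of all K genes.  Requires n > 2K + 3 matched cancer
    samples.  With K = 1 this reduces to the single-gene test.
    """
    index_cols = index_cols or _INDEX_COLS
    K = len(genes)
    samples = [s for s in indices.index if s in expr.columns]
    n = len(samples)
    if n <= 2 * K + 3:
        raise ValueError(f"need more than {2 * K + 3} matched cancer samples, have {n}")
    idx = indices.loc[samples]
    prom_genes = [g for g in genes if g in promoter_meth.index]
    rows = []
    for g in genes:
        x = expr.loc[g, samples].to_numpy(dtype=float)
        cov = [expr.loc[o, samples].to_numpy(dtype=float) for o in genes if o != g]
        cov += [promoter_meth.loc[o, samples].to_numpy(dtype=float) for o in prom_genes]
        desc = f"{K - 1} other genes' expression + {len(prom_genes)} promoter DNAm"
        rows.extend(
            _records_for_gene(g, x, idx, cov, cohort, "full_model", desc, index_cols)
        )
    return pd.DataFrame(rows)


@dataclass
class ConsensusNetwork:
    """Gene-index edges significant with consistent sign in >= m cohorts."""

    edges: pd.DataFrame  # gene, index, sign, n_support
    m: int
    n_cohorts: int

    def edge_set(self) -> set[tuple[str, str, int]]:
        return {
            (r.gene, r.index, int(r.sign)) for r in self.edges.itertuples()
        }


def build_consensus(
    records: pd.DataFrame, alpha: float = 0.05, m: int = 6
) -> ConsensusNetwork:
    """Count, per (gene, index), cohorts whose partial correlation is
    significant with each sign; keep an edge when either sign reaches m."""
    T = int(records["cohort"].nunique())
    m_eff = min(m, T)
    if m_eff < m:
        logger.warning("consensus threshold clamped from %d to %d cohorts", m, m_eff)
    rows = []
    for (gene, index), sub in records.groupby(["gene", "index"], sort=True):
        sig = sub[(sub["pvalue"] < alpha) & sub["partial_r"].notna()]
        n_pos = int((sig["partial_r"] > 0).sum())
        n_neg = int((sig["partial_r"] < 0).sum())
        if n_pos >= m_eff:
            rows.append({"gene": gene, "index": index, "sign": 1, "n_support": n_pos})
        elif n_neg >= m_eff:
            rows.append({"gene": gene, "index": index, "sign": -1, "n_support": n_neg})
    edges = pd.DataFrame(rows, columns=["gene", "index", "sign", "n_support"])
    return ConsensusNetwork(edges=edges, m=m_eff, n_cohorts=T)
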