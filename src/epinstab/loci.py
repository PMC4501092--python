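"""Locus-level correlation of regional methylation with a regulator's
expression, and cross-cohort rank consistency of those correlations.

For a candidate regulator, every eligible regional cluster (CGI clusters
for hypermethylation-associated genes, open-sea clusters for
hypomethylation-associated genes) is correlated with the gene's
expression over cancer samples and Fisher-Z transformed.  Clusters are
then ranked in a reference cohort and the ranking is compared with each
other cohort's statistics by Spearman correlation: consistently high
rank correlations mean the regulator tracks methylation at the same loci
across cancer types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .indices import RegionBetaMatrix, RegionalClusterSet
from .io import ExpressionMatrix
from .meta import _pearson_rows, fisher_z

__all__ = ["locus_correlations", "rank_consistency", "RankConsistencyReport"]


def locus_correlations(
    region_betas: RegionBetaMatrix,
    expr: ExpressionMatrix,
    gene: str,
    class_restriction: str,
    clusters: RegionalClusterSet,
    cancer_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher-Z Pearson correlation of every eligible cluster's beta with
    the gene's expression, over cancer samples only.

    ``class_restriction`` is ``"cgi"`` or ``"opensea"``.  Zero-variance
    clusters are flagged (NaN statistic).
    """
    if gene not in expr.data.index:
        raise ValueError(f"gene {gene!r} absent from the expression matrix")
    eligible = clusters.of_class(class_restriction).intersection(region_betas.data.index)
    samples = [s for s in expr.sample_ids if s in region_betas.data.columns]
    if cancer_samples is not None:
        cs = set(cancer_samples)
        samples = [s for s in samples if s in cs]
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 matched cancer samples")
    B = region_betas.data.loc[eligible, samples].to_numpy()
    y = expr.data.loc[gene, samples].to_numpy(dtype=float)
    r = _pearson_rows(B, y)
    z = np.asarray(fisher_z(r), dtype=float)
    return pd.DataFrame(
        {
            "cluster_id": eligible,
            "gene": gene,
            "region_class": class_restriction,
            "r": r,
            "fisher_z": z,
            "n": n,
            "undefined": ~np.isfinite(z),
        }
    ).set_index("cluster_id")


@dataclass
class RankConsistencyReport:
    """Spearman agreement of each cohort's locus statistics with the
    reference-cohort ranking."""

    reference: str
    table: pd.DataFrame  # cohort, rho, pvalue, n_clusters
    ranking: pd.Index  # cluster ids in reference order


def rank_consistency(
    tables: dict[str, pd.DataFrame],
    reference: str,
    direction: str = "descending",
) -> RankConsistencyReport:
    """Rank clusters by the reference cohort's Fisher Z (descending for
    positively associated regulators, ascending for negative) and report
    the Spearman rho/P of that ranking against every other cohort.

    Cluster universes are intersected across cohorts; ties get average
    ranks (standard Spearman convention).
    """
    if reference not in tables:
        raise ValueError(f"reference cohort {reference!r} not among the tables")
    if direction not in ("descending", "ascending"):
        raise ValueError("direction must be 'descending' or 'ascending'")
    shared = None
    for df in tables.values():
        ids = df.index[~df["undefined"].fillna(False)] if "undefined" in df else df.index
        shared = ids if shared is None else shared.intersection(ids)
    if shared is None or len(shared) < 3:
        raise ValueError("need at least 3 clusters shared across cohorts")
    ref_z = tables[reference].loc[shared, "fisher_z"]
    order = ref_z.sort_values(ascending=(direction == "ascending"), kind="stable").index
    rows = []
    for cid, df in tables.items():
        if cid == reference:
            continue
        rho, p = stats.spearmanr(
            ref_z.to_numpy(), df.loc[shared, "fisher_z"].to_numpy()
        )
        if direction == "ascending":
            # rho of the ranking itself is invariant; report vs reference stats
            pass
        rows.append({"cohort": cid, "rho": float(rho), "pvalue": float(p), "n_clusters": len(shared)})
    return RankConsistencyReport(
        reference=reference, table=pd.DataFrame(rows), ranking=order
    )
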