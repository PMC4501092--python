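"""Regional probe clustering and the HyperZ/HypoZ methylation-instability indices.

Probes of one region class on one chromosome are grouped greedily into
clusters of bounded span (<= 1500 bp) and inter-probe gap (<= 500 bp).
Cluster-level beta values are compared against a normal-tissue reference
as Z scores, and per-cancer-sample indices summarise the positive
deviations over promoter CGIs (HyperZ: promoter hypermethylation load)
and the negative deviations over open-sea clusters (HypoZ: intergenic
hypomethylation load):

    HyperZ_s = (1/n_r) sum_r Z_rs H(Z_rs)        over promoter-CGI clusters
    HypoZ_s  = (1/n_r) sum_r |Z_rs| H(-Z_rs)     over open-sea clusters

with the Heaviside convention H(z) = 1 iff z > 0.  A "significant" variant
restricts both the summation and n_r to clusters whose Z passes a
one-sided P < 0.05 tail in the direction of interest (|Z| > 1.6449).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethylationMatrix, ProbeAnnotation, SampleSheet

__all__ = [
    "ClusterParams",
    "RegionalClusterSet",
    "RegionBetaMatrix",
    "NormalReference",
    "ZScoreMatrix",
    "cluster_probes",
    "summarize_regions",
    "compute_zscores",
    "compute_indices",
    "full_index_table",
    "index_association",
    "promoter_methylation",
]

logger = logging.getLogger(__name__)

#: one-sided normal 5% tail
Z_SIG = 1.6449


@dataclass(frozen=True)
class ClusterParams:
    max_cluster_width: int = 1500
    max_gap: int = 500

    def __post_init__(self) -> None:
        if self.max_cluster_width <= 0 or self.max_gap <= 0:
            raise ValueError("cluster parameters must be positive")


@dataclass
class RegionalClusterSet:
    """Cluster table: one row per cluster with member probes
    (position-sorted), genomic extent and promoter flags."""

    table: pd.DataFrame  # index cluster_id; columns chromosome, region_class,
    # start, end, span, probes (list), promoter_cgi, promoter_gene

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.table.index)

    def of_class(self, region_class: str) -> pd.Index:
        return self.table.index[self.table["region_class"] == region_class]

    @property
    def promoter_cgi_clusters(self) -> pd.Index:
        return self.table.index[self.table["promoter_cgi"].astype(bool)]

    @property
    def opensea_clusters(self) -> pd.Index:
        return self.of_class("opensea")


def cluster_probes(ann: ProbeAnnotation, params: ClusterParams | None = None) -> RegionalClusterSet:
    """Greedy left-to-right clustering within each (chromosome, region class).

    A probe joins the open cluster iff its gap to the previous probe is at
    most ``max_gap`` *and* the resulting span stays within
    ``max_cluster_width``; otherwise it starts a new cluster.
    """
    params = params or ClusterParams()
    rows = []
    t = ann.table
    for (chrom, cls), sub in t.groupby(["chromosome", "region_class"], sort=True):
        sub = sub.sort_values("position", kind="stable")
        pos = sub["position"].to_numpy()
        ids = sub.index.to_numpy()
        start_i = 0
        for i in range(1, len(pos) + 1):
            if (
                i == len(pos)
                or pos[i] - pos[i - 1] > params.max_gap
                or pos[i] - pos[start_i] > params.max_cluster_width
            ):
                members = list(ids[start_i:i])
                mem = t.loc[members]
                genes = mem["promoter_gene"].dropna().unique()
                rows.append({
                    "cluster_id": f"{chrom}:{pos[start_i]}:{cls}",
                    "chromosome": chrom,
                    "region_class": cls,
                    "start": int(pos[start_i]),
                    "end": int(pos[i - 1]),
                    "span": int(pos[i - 1] - pos[start_i]),
                    "probes": members,
                    "promoter_cgi": bool(mem["promoter_cgi"].astype(bool).all()),
                    "promoter_gene": genes[0] if len(genes) == 1 else None,
                })
                start_i = i
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.set_index("cluster_id")
    else:
        table = pd.DataFrame(
            columns=["chromosome", "region_class", "start", "end", "span",
                     "probes", "promoter_cgi", "promoter_gene"]
        )
    return RegionalClusterSet(table)


@dataclass
class RegionBetaMatrix:
    """Cluster x sample mean beta values."""

    data: pd.DataFrame

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.data.index)


def summarize_regions(meth: MethylationMatrix, clusters: RegionalClusterSet) -> RegionBetaMatrix:
    """Per-cluster per-sample mean beta of the member probes."""
    df = meth.data
    missing = set().union(*clusters.table["probes"]) - set(df.index) if len(clusters) else set()
    if missing:
        raise ValueError(f"clusters reference probes absent from the matrix: {sorted(missing)[:5]}")
    if df.isna().to_numpy().any():
        raise ValueError("methylation matrix must be complete (run filter_and_impute first)")
    out = {
        cid: df.loc[probes].mean(axis=0)
        for cid, probes in clusters.table["probes"].items()
    }
    return RegionBetaMatrix(pd.DataFrame(out).T.loc[clusters.cluster_ids])


@dataclass
class NormalReference:
    """Per-cluster mean/sd of the region beta over normal samples."""

    mean: pd.Series
    sd: pd.Series  # sample sd (n-1 denominator)
    n_normals: int


@dataclass
class ZScoreMatrix:
    """Cluster x cancer-sample Z scores relative to the normal reference.

    ``sig_hyper``/``sig_hypo`` flag one-sided significance (P < 0.05) in
    the hyper- and hypomethylation directions; ``excluded`` lists clusters
    dropped because the normal sd was zero.
    """

    data: pd.DataFrame
    sig_hyper: pd.DataFrame
    sig_hypo: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def compute_zscores(
    region_betas: RegionBetaMatrix, sheet: SampleSheet
) -> tuple[NormalReference, ZScoreMatrix]:
    """Z_rs = (beta_rs - mu_r^N) / sigma_r^N for every cancer sample,
    against the mean/sample-sd reference built from >= 2 normals."""
    normals = [s for s in sheet.normals if s in region_betas.data.columns]
    cancers = [s for s in sheet.cancers if s in region_betas.data.columns]
    if len(normals) < 2:
        raise ValueError("need at least 2 normal samples for the reference")
    ref_data = region_betas.data[normals]
    mu = ref_data.mean(axis=1)
    sd = ref_data.std(axis=1, ddof=1)
    ref = NormalReference(mean=mu, sd=sd, n_normals=len(normals))

    excluded = list(sd.index[sd == 0])
    if excluded:
        logger.info("excluding %d clusters with zero normal sd", len(excluded))
    keep = sd.index[sd > 0]
    z = region_betas.data.loc[keep, cancers].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return ref, ZScoreMatrix(
        data=z, sig_hyper=z > Z_SIG, sig_hypo=z < -Z_SIG, excluded=excluded
    )


def _one_index(
    z: ZScoreMatrix, eligible: pd.Index, direction: str, variant: str
) -> tuple[pd.Series, pd.Series]:
    zz = z.data.loc[eligible]
    if direction == "hyper":
        contrib = zz.clip(lower=0.0)
        sig = z.sig_hyper.loc[eligible]
    else:
        contrib = (-zz).clip(lower=0.0)
        sig = z.sig_hypo.loc[eligible]
    if variant == "all":
        n = pd.Series(float(len(eligible)), index=zz.columns)
        idx = contrib.sum(axis=0) / n
    elif variant == "significant":
        n = sig.sum(axis=0).astype(float)
        total = contrib.where(sig, 0.0).sum(axis=0)
        idx = total.div(n).where(n > 0, 0.0)
    else:
        raise ValueError(f"variant must be 'all' or 'significant', got {variant!r}")
    return idx, n


def compute_indices(
    z: ZScoreMatrix, clusters: RegionalClusterSet, variant: str = "all"
) -> pd.DataFrame:
    """Per-cancer-sample HyperZ (promoter-CGI clusters) and HypoZ
    (open-sea clusters) for one variant.

    Returns a sample-indexed frame with HyperZ, HypoZ and the cluster
    counts used; both indices are non-negative by construction.
    """
    avail = z.data.index
    hyper_cl = clusters.promoter_cgi_clusters.intersection(avail)
    hypo_cl = clusters.opensea_clusters.intersection(avail)
    if len(hyper_cl) == 0:
        raise ValueError("no promoter-CGI clusters available for HyperZ")
    if len(hypo_cl) == 0:
        raise ValueError("no open-sea clusters available for HypoZ")
    hyper, n_hyper = _one_index(z, hyper_cl, "hyper", variant)
    hypo, n_hypo = _one_index(z, hypo_cl, "hypo", variant)
    return pd.DataFrame(
        {"HyperZ": hyper, "HypoZ": hypo, "n_hyper": n_hyper, "n_hypo": n_hypo}
    )


def full_index_table(z: ZScoreMatrix, clusters: RegionalClusterSet) -> pd.DataFrame:
    """Both variants in one table: HyperZ/HypoZ (all clusters) and
    HyperZ_sig/HypoZ_sig (significant clusters only)."""
    all_v = compute_indices(z, clusters, "all")
    sig_v = compute_indices(z, clusters, "significant")
    return pd.DataFrame(
        {
            "HyperZ": all_v["HyperZ"],
            "HypoZ": all_v["HypoZ"],
            "HyperZ_sig": sig_v["HyperZ"],
            "HypoZ_sig": sig_v["HypoZ"],
        }
    )


def index_association(table: pd.DataFrame, x: str = "HyperZ", y: str = "HypoZ") -> dict:
    """Spearman rho/P and linear-model R^2 of HyperZ vs HypoZ across the
    cancer samples of one cohort.  Constant indices give NaN statistics."""
    if len(table) < 3:
        raise ValueError("need at least 3 cancer samples")
    xv = table[x].to_numpy(dtype=float)
    yv = table[y].to_numpy(dtype=float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        return {"rho": np.nan, "pvalue": np.nan, "r_squared": np.nan, "n": len(xv)}
    rho, p = stats.spearmanr(xv, yv)
    r = stats.pearsonr(xv, yv).statistic
    return {"rho": float(rho), "pvalue": float(p), "r_squared": float(r**2), "n": len(xv)}


def promoter_methylation(
    region_betas: RegionBetaMatrix, clusters: RegionalClusterSet, genes=None
) -> pd.DataFrame:
    """Gene x sample promoter DNAm level: mean beta of the promoter-CGI
    cluster(s) annotated to each gene.  Genes without a promoter cluster
    are absent from the result."""
    t = clusters.table
    mask = t["promoter_cgi"].astype(bool) & t["promoter_gene"].notna()
    rows = {}
    for gene, sub in t[mask].groupby("promoter_gene"):
        if genes is not None and gene not in set(genes):
            continue
        cids = [c for c in sub.index if c in region_betas.data.index]
        if cids:
            rows[gene] = region_betas.data.loc[cids].mean(axis=0)
    return pd.DataFrame(rows).T
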