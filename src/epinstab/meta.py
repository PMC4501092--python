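"""Cross-cohort differential-expression and correlation meta-analysis.

Per cohort, genes are tested for normal-vs-cancer differential expression
with an empirical-Bayes moderated t-test, and for Pearson correlation with
the HyperZ/HypoZ instability indices over matched cancer samples (Fisher-Z
P values).  Cohort-level calls at a relaxed nominal alpha are then counted
across cohorts, and the counts are judged against an analytic binomial
null: the probability that a random gene is significant in one cohort is
estimated from *all* genes of that cohort, averaged across cohorts, and
the tail probability of being called in >= m of T cohorts follows the
binomial formula.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, gammaln, polygamma

from .io import ExpressionMatrix, SampleSheet

__all__ = [
    "EBayesParams",
    "estimate_ebayes_params",
    "moderated_t",
    "consistency_count",
    "binomial_tail",
    "expected_random_count",
    "meta_significance",
    "fisher_z",
    "inverse_fisher_z",
    "correlate_expr_index",
    "correlation_consistency",
    "de_null_probabilities",
    "correlation_null_probabilities",
    "expr_expr_meta_network",
]

logger = logging.getLogger(__name__)

_MAX_D0 = 1e6  # prior df treated as infinite beyond this


@dataclass(frozen=True)
class EBayesParams:
    """Variance-shrinkage hyperparameters: prior df ``d0`` and prior
    variance ``s0_sq``.  ``d0 = 0`` reduces to the ordinary pooled t."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or not np.isfinite(self.s0_sq) or self.s0_sq <= 0:
            raise ValueError("need d0 >= 0 and finite s0_sq > 0")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_ebayes_params(sg_sq: np.ndarray, dg: int) -> EBayesParams:
    """Moment-match a scaled inverse-chi-square prior to the observed
    gene-variance distribution, on the log scale (digamma/trigamma
    moments of log sg^2)."""
    s = np.asarray(sg_sq, dtype=float)
    s = s[s > 0]
    if s.size < 2:
        return EBayesParams(0.0, 1.0)
    e = np.log(s) - digamma(dg / 2.0) + math.log(dg / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, dg / 2.0))
    if evar <= 0:
        d0 = _MAX_D0
    else:
        d0 = min(2.0 * _trigamma_inverse(evar), _MAX_D0)
    s0_sq = math.exp(float(np.mean(e)) + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return EBayesParams(d0, s0_sq)


def moderated_t(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    params: EBayesParams | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene cancer-vs-normal moderated t-test on a log2 matrix.

    Gene variances are shrunk toward the prior:
    ``s~^2 = (d0 s0^2 + dg sg^2) / (d0 + dg)`` with ``df = dg + d0``;
    hyperparameters are estimated from the data unless supplied.  All
    cancer samples are used, not only those with matched methylation.
    """
    if expr.scale != "log2":
        raise ValueError("moderated_t expects a log2-scale matrix")
    normals = [s for s in sheet.normals if s in expr.data.columns]
    cancers = [s for s in sheet.cancers if s in expr.data.columns]
    n1, n2 = len(normals), len(cancers)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    dg = n1 + n2 - 2
    if dg <= 0:
        raise ValueError("zero residual degrees of freedom")

    X1 = expr.data[normals].to_numpy()
    X2 = expr.data[cancers].to_numpy()
    diff = X2.mean(axis=1) - X1.mean(axis=1)
    ss = ((X1 - X1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (X2 - X2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    sg_sq = ss / dg

    if params is None:
        params = estimate_ebayes_params(sg_sq, dg)
    d0, s0_sq = params.d0, params.s0_sq
    if d0 >= _MAX_D0:
        s_tilde_sq = np.full_like(sg_sq, s0_sq)
        df = _MAX_D0
    else:
        s_tilde_sq = (d0 * s0_sq + dg * sg_sq) / (d0 + dg)
        df = dg + d0
    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = 2.0 * stats.t.sf(np.abs(t), df=min(df, _MAX_D0))
    return pd.DataFrame(
        {
            "cohort": expr.cohort_id,
            "diff": diff,
            "t": t,
            "pvalue": p,
            "direction": np.where(diff >= 0, "up", "down"),
        },
        index=pd.Index(expr.data.index, name="gene"),
    )


def consistency_count(
    records: dict[str, pd.DataFrame], alpha: float = 0.05, m: int = 8
) -> pd.DataFrame:
    """Count, per gene, the cohorts significantly up/down at ``alpha`` and
    call a gene consistent when >= m cohorts agree in direction.

    ``records`` maps cohort id to a per-gene test table (columns
    ``pvalue``, ``direction``).  Genes absent from a cohort count as not
    significant there.
    """
    T = len(records)
    m_eff = min(m, T)
    if m_eff < m:
        logger.warning("consistency threshold clamped from %d to %d cohorts", m, m_eff)
    genes = sorted(set().union(*(set(df.index) for df in records.values())))
    n_up = pd.Series(0, index=genes)
    n_down = pd.Series(0, index=genes)
    for cid, df in records.items():
        absent = set(genes) - set(df.index)
        if absent:
            logger.info("cohort %s: %d genes absent, counted not significant", cid, len(absent))
        sig = df[df["pvalue"] < alpha]
        up = sig.index[sig["direction"].isin(["up", "positive"])]
        down = sig.index[sig["direction"].isin(["down", "negative"])]
        n_up[n_up.index.isin(up)] += 1
        n_down[n_down.index.isin(down)] += 1
    call = np.where(n_up >= m_eff, "up", np.where(n_down >= m_eff, "down", "none"))
    return pd.DataFrame(
        {"n_up": n_up, "n_down": n_down, "call": call},
        index=pd.Index(genes, name="gene"),
    )


def binomial_tail(T: int, m: int, p: float) -> float:
    """Exact upper-tail binomial probability sum_{k=m}^{T} C(T,k) p^k (1-p)^(T-k)."""
    if not (0 <= m <= T):
        raise ValueError("need 0 <= m <= T")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be a probability")
    if m == 0:
        return 1.0
    total = math.fsum(
        math.comb(T, k) * p**k * (1.0 - p) ** (T - k) for k in range(m, T + 1)
    )
    return float(min(max(total, 0.0), 1.0))


def expected_random_count(pool: int, tail_p: float) -> tuple[float, float]:
    """Mean and sd of the number of genes from a random pool called
    consistent under the binomial null: (pool*p, sqrt(pool*p*(1-p)))."""
    mean = pool * tail_p
    sd = math.sqrt(pool * tail_p * (1.0 - tail_p))
    return mean, sd


def meta_significance(observed: int, pool: int, tail_p: float) -> float:
    """Exact P(X >= observed) for X ~ Binomial(pool, tail_p), computed in
    log space so extreme tails keep precision."""
    if not (0 <= observed <= pool):
        raise ValueError("need 0 <= observed <= pool")
    if observed == 0:
        return 1.0
    if tail_p <= 0.0:
        return 0.0
    if tail_p >= 1.0:
        return 1.0
    k = np.arange(observed, pool + 1)
    logterms = (
        gammaln(pool + 1)
        - gammaln(k + 1)
        - gammaln(pool - k + 1)
        + k * math.log(tail_p)
        + (pool - k) * math.log1p(-tail_p)
    )
    from scipy.special import logsumexp

    return float(np.exp(logsumexp(logterms)))


def fisher_z(r):
    """Variance-stabilising transform Z = 0.5 log((1+r)/(1-r))."""
    with np.errstate(divide="ignore"):
        return np.arctanh(r)


def inverse_fisher_z(z):
    return np.tanh(z)


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X with y; rows/targets of zero variance
    give NaN."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xs = np.sqrt((Xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (xs * ys)
    r[(xs == 0)] = np.nan
    if ys == 0:
        r[:] = np.nan
    return r


def correlate_expr_index(
    expr: ExpressionMatrix,
    index_table: pd.DataFrame,
    variant: str = "significant",
) -> pd.DataFrame:
    """Pearson correlation of every gene with HyperZ and HypoZ over the
    matched cancer samples, with Fisher-Z normal-approximation P values
    (variance 1/(n-3)).

    ``variant`` selects the index columns: "significant" uses
    HyperZ_sig/HypoZ_sig, "all" the all-regions columns.
    """
    if expr.scale != "log2":
        raise ValueError("correlate_expr_index expects a log2-scale matrix")
    cols = {"significant": ("HyperZ_sig", "HypoZ_sig"), "all": ("HyperZ", "HypoZ")}[variant]
    samples = [s for s in expr.sample_ids if s in index_table.index]
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 matched cancer samples")
    X = expr.data[samples].to_numpy()
    frames = []
    for label, col in zip(("HyperZ", "HypoZ"), cols):
        y = index_table.loc[samples, col].to_numpy(dtype=float)
        r = _pearson_rows(X, y)
        z = fisher_z(r)
        with np.errstate(invalid="ignore"):
            degenerate = ~np.isfinite(z) | (np.abs(r) > 1.0 - 1e-12)
        p = 2.0 * stats.norm.sf(np.abs(z) * math.sqrt(n - 3))
        frames.append(
            pd.DataFrame(
                {
                    "gene": expr.data.index,
                    "cohort": expr.cohort_id,
                    "index": label,
                    "r": r,
                    "fisher_z": z,
                    "pvalue": p,
                    "n": n,
                    "undefined": degenerate,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def correlation_consistency(
    records: pd.DataFrame, alpha: float = 0.05, m: int = 6
) -> pd.DataFrame:
    """Per gene x index: count cohorts with significant positive/negative
    correlation and call a consistent sign at >= m of T cohorts."""
    T = records.groupby("index")["cohort"].nunique().max()
    m_eff = min(m, int(T))
    if m_eff < m:
        logger.warning("consistency threshold clamped from %d to %d cohorts", m, m_eff)
    rec = records[~records["undefined"].fillna(False)] if "undefined" in records else records
    sig = rec["pvalue"] < alpha
    rows = []
    for (gene, index), sub in rec.groupby(["gene", "index"], sort=True):
        s = sub[sig.loc[sub.index]]
        n_pos = int((s["r"] > 0).sum())
        n_neg = int((s["r"] < 0).sum())
        call = "positive" if n_pos >= m_eff else ("negative" if n_neg >= m_eff else "none")
        rows.append({"gene": gene, "index": index, "n_pos": n_pos, "n_neg": n_neg, "call": call})
    return pd.DataFrame(rows)


def de_null_probabilities(records: dict[str, pd.DataFrame], alpha: float = 0.05) -> dict:
    """Per-cohort fractions of ALL genes significantly up/down, and their
    cross-cohort averages (p_bar_u, p_bar_d)."""
    per = {}
    for cid, df in records.items():
        sig = df["pvalue"] < alpha
        per[cid] = {
            "p_u": float((sig & (df["direction"] == "up")).mean()),
            "p_d": float((sig & (df["direction"] == "down")).mean()),
        }
    return {
        "per_cohort": per,
        "p_bar_u": float(np.mean([v["p_u"] for v in per.values()])),
        "p_bar_d": float(np.mean([v["p_d"] for v in per.values()])),
    }


def correlation_null_probabilities(records: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Average fractions of all genes significantly positively/negatively
    correlated with each index: p_bar_uu, p_bar_du (HyperZ +/-) and
    p_bar_ud, p_bar_dd (HypoZ +/-)."""
    out = {}
    key = {("HyperZ", "pos"): "p_bar_uu", ("HyperZ", "neg"): "p_bar_du",
           ("HypoZ", "pos"): "p_bar_ud", ("HypoZ", "neg"): "p_bar_dd"}
    per = {}
    for (index, cid), sub in records.groupby(["index", "cohort"]):
        sig = sub["pvalue"] < alpha
        per.setdefault(index, {})[cid] = {
            "pos": float((sig & (sub["r"] > 0)).mean()),
            "neg": float((sig & (sub["r"] < 0)).mean()),
        }
    for index, cohorts in per.items():
        for sign in ("pos", "neg"):
            out[key[(index, sign)]] = float(np.mean([v[sign] for v in cohorts.values()]))
    out["per_cohort"] = per
    return out


def expr_expr_meta_network(
    exprs: dict[str, ExpressionMatrix],
    sheets: dict[str, SampleSheet],
    genes: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Signed gene-gene meta-correlation network over cancer samples.

    Per cohort and gene pair, the Pearson correlation is Fisher-Z
    transformed; cohorts are combined by a sqrt(n-3)-weighted Stouffer
    statistic.  An edge is retained when the combined two-sided P passes a
    Bonferroni threshold over all pairs *and* the per-cohort sign agrees
    with the combined sign in more than half the contributing cohorts.
    """
    if len(exprs) < 1:
        raise ValueError("need at least one cohort")
    pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
    per_cohort: dict[str, dict] = {}
    for cid, expr in exprs.items():
        cancers = [s for s in sheets[cid].cancers if s in expr.data.columns]
        n = len(cancers)
        if n < 4:
            continue
        present = [g for g in genes if g in expr.data.index]
        X = expr.data.loc[present, cancers].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.corrcoef(X)
        per_cohort[cid] = {"genes": present, "R": R, "n": n}

    rows = []
    n_pairs = len(pairs)
    for a, b in pairs:
        zs, ws, signs = [], [], []
        for cid, d in per_cohort.items():
            if a not in d["genes"] or b not in d["genes"]:
                continue
            ia, ib = d["genes"].index(a), d["genes"].index(b)
            r = d["R"][ia, ib]
            if not np.isfinite(r):
                continue
            z = float(fisher_z(np.clip(r, -1 + 1e-15, 1 - 1e-15)))
            w = math.sqrt(d["n"] - 3)
            zs.append(z * w)  # standard normal under the null
            ws.append(w)
            signs.append(np.sign(r))
        if not zs:
            continue
        ws = np.asarray(ws)
        stat = float(np.sum(ws * np.asarray(zs)) / math.sqrt(float(np.sum(ws**2))))
        p = 2.0 * stats.norm.sf(abs(stat))
        sign = int(np.sign(stat)) if stat != 0 else 0
        agree = int(np.sum(np.asarray(signs) == sign))
        keep = (p < alpha / max(n_pairs, 1)) and (agree > len(signs) / 2) and sign != 0
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "combined_z": stat,
                "pvalue": p,
                "sign": sign,
                "n_cohorts": len(signs),
                "n_agreeing": agree,
                "edge": keep,
            }
        )
    return pd.DataFrame(rows)
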