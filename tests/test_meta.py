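import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epinstab.meta import (
    EBayesParams,
    binomial_tail,
    consistency_count,
    correlate_expr_index,
    correlation_consistency,
    de_null_probabilities,
    expected_random_count,
    expr_expr_meta_network,
    fisher_z,
    inverse_fisher_z,
    meta_significance,
    moderated_t,
)
from epinstab.simulate import DriverSpec, SimulationConfig, simulate_pan_cancer
from epinstab.preprocess import preprocess_expression

from conftest import make_expr, make_sheet


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _two_group(rng, p=50, n1=6, n2=8, shift_first=0):
    X = rng.normal(5, 1, size=(p, n1 + n2))
    if shift_first:
        X[:shift_first, n1:] += 1.0
    genes = [f"g{i}" for i in range(p)]
    samples = [f"N{i}" for i in range(n1)] + [f"T{i}" for i in range(n2)]
    expr = make_expr(X, genes, samples)
    return expr, make_sheet(samples[:n1], samples[n1:])


def test_moderated_t_equal_means_scores_zero():
    expr = make_expr([[1.0, 1, 2, 2], [3.0, 4, 3, 4]], ["g1", "g2"], list("abcd"))
    sheet = make_sheet(["a", "b"], ["c", "d"])
    res = moderated_t(expr, sheet)
    assert res.loc["g2", "t"] == pytest.approx(0.0)
    assert res.loc["g2", "pvalue"] == pytest.approx(1.0)


def test_moderated_t_with_zero_prior_df_equals_pooled_t():
    rng = np.random.default_rng(0)
    expr, sheet = _two_group(rng)
    res = moderated_t(expr, sheet, params=EBayesParams(0.0, 1.0))
    ref_t, ref_p = stats.ttest_ind(
        expr.values[:, 6:], expr.values[:, :6], axis=1, equal_var=True
    )
    assert np.allclose(res["t"], ref_t, atol=1e-10)
    assert np.allclose(res["pvalue"], ref_p, atol=1e-10)


def test_moderated_t_matches_limma_oracle(tmp_path):
    """The empirical-Bayes shrinkage agrees with the reference R
    implementation on a shared fixture."""
    rng = np.random.default_rng(42)
    X = rng.normal(8, 1, size=(60, 20)) * np.sqrt(rng.chisquare(4, size=(60, 1)) / 4)
    X[:5, 8:] += 1.5
    genes = [f"g{i}" for i in range(60)]
    samples = [f"N{i}" for i in range(8)] + [f"T{i}" for i in range(12)]
    expr = make_expr(X, genes, samples)
    res = moderated_t(expr, make_sheet(samples[:8], samples[8:]))

    expr.data.to_csv(tmp_path / "expr.tsv", sep="\t")
    script = tmp_path / "oracle.R"
    script.write_text(
        'suppressMessages(library(limma))\n'
        f'x <- as.matrix(read.table("{tmp_path}/expr.tsv", header=TRUE, row.names=1, sep="\\t"))\n'
        'design <- cbind(1, c(rep(0,8), rep(1,12)))\n'
        'fit <- eBayes(lmFit(x, design))\n'
        f'write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]), "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)\n'
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    lim = pd.read_csv(tmp_path / "out.tsv", sep="\t")
    assert np.allclose(res["t"].to_numpy(), lim["t"].to_numpy(), atol=1e-8)
    assert np.allclose(res["pvalue"].to_numpy(), lim["p"].to_numpy(), atol=1e-8)


def test_moderated_t_null_false_positive_rate():
    """On simulated genes with no planted effect, the rejection rate at
    P < 0.05 stays near nominal."""
    drivers = [DriverSpec("UHRF1", "C_hyper", "up", 0.0)]
    cfg = SimulationConfig(n_cohorts=1, n_genes=1200, n_ee_genes=5, drivers=drivers, seed=3)
    cohort = next(iter(simulate_pan_cancer(cfg).cohorts.values()))
    res = moderated_t(preprocess_expression(cohort.expr), cohort.sheet)
    fpr = float((res["pvalue"] < 0.05).mean())
    assert 0.03 <= fpr <= 0.07


# ---------------------------------------------------------------------------
# consistency counting and the binomial null
# ---------------------------------------------------------------------------

def _records(sig_patterns):
    """Build per-cohort DE tables for one gene from (pvalue, direction)."""
    out = {}
    for i, (p, d) in enumerate(sig_patterns):
        out[f"c{i}"] = pd.DataFrame(
            {"pvalue": [p], "direction": [d]}, index=pd.Index(["g"], name="gene")
        )
    return out


def test_consistency_call_thresholds():
    up8 = _records([(0.01, "up")] * 8 + [(0.5, "up")] * 2)
    assert consistency_count(up8)["call"].iloc[0] == "up"
    mixed = _records([(0.01, "up")] * 7 + [(0.01, "down")] + [(0.5, "up")] * 2)
    res = consistency_count(mixed)
    assert res["n_up"].iloc[0] == 7 and res["n_down"].iloc[0] == 1
    assert res["call"].iloc[0] == "none"


def test_consistency_handles_absent_genes():
    recs = _records([(0.01, "up")] * 9 + [(0.01, "up")])
    recs["c9"] = pd.DataFrame(
        {"pvalue": [0.01], "direction": ["up"]}, index=pd.Index(["other"], name="gene")
    )
    res = consistency_count(recs)
    assert res.loc["g", "n_up"] == 9
    assert res.loc["other", "n_up"] == 1


@pytest.mark.parametrize(
    "T,m,p,printed",
    [
        (10, 8, 0.32, 0.003),
        (10, 8, 0.34, 0.004),
        (10, 6, 0.12, 0.0004),
        (10, 6, 0.16, 0.002),
        (10, 6, 0.25, 0.02),
    ],
)
def test_binomial_tail_reproduces_printed_null_values(T, m, p, printed):
    """The analytic null tail probabilities round to the published values."""
    val = binomial_tail(T, m, p)
    digits = -int(math.floor(math.log10(printed)))
    assert round(val, digits) == pytest.approx(printed)


def test_binomial_tail_boundaries():
    assert binomial_tail(7, 0, 0.3) == 1.0
    assert binomial_tail(10, 8, 0.0) == 0.0
    assert binomial_tail(10, 10, 1.0) == 1.0


@given(
    T=st.integers(1, 20),
    p=st.floats(0.0, 1.0),
    data=st.data(),
)
@settings(deadline=None, max_examples=200)
def test_binomial_tail_matches_independent_cdf(T, p, data):
    m = data.draw(st.integers(0, T))
    ours = binomial_tail(T, m, p)
    ref = float(stats.binom.sf(m - 1, T, p))
    assert ours == pytest.approx(ref, abs=1e-12)


def test_expected_random_count_printed_operating_point():
    mean, sd = expected_random_count(212, binomial_tail(10, 8, 0.32))
    assert round(mean, 2) == pytest.approx(0.54)
    assert round(sd, 2) == pytest.approx(0.73)
    assert expected_random_count(100, 0.0) == (0.0, 0.0)
    m1, _ = expected_random_count(100, 0.01)
    m2, _ = expected_random_count(200, 0.01)
    assert m2 == pytest.approx(2 * m1)


def test_meta_significance_exact_tail():
    p = binomial_tail(10, 8, 0.32)
    assert meta_significance(0, 212, p) == 1.0
    assert meta_significance(1, 212, p) == pytest.approx(1 - (1 - p) ** 212, rel=1e-9)
    assert 0 < meta_significance(35, 212, p) < 1e-40


# ---------------------------------------------------------------------------
# Fisher Z and correlations
# ---------------------------------------------------------------------------

def test_fisher_z_known_value_and_antisymmetry():
    assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3), abs=1e-10)
    assert round(float(fisher_z(0.5)), 4) == 0.5493
    assert fisher_z(-0.3) == pytest.approx(-fisher_z(0.3))


@given(r=st.floats(-0.999999, 0.999999))
@settings(deadline=None, max_examples=200)
def test_fisher_z_roundtrip_and_monotone(r):
    assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-12)
    assert fisher_z(r) < fisher_z(min(r + 1e-6, 0.9999995))


def _index_table(rng, samples):
    vals = rng.random((len(samples), 2)) * 3
    return pd.DataFrame(vals, index=samples, columns=["HyperZ_sig", "HypoZ_sig"])


def test_correlate_expr_index_degenerate_and_antisymmetry():
    rng = np.random.default_rng(5)
    samples = [f"t{i}" for i in range(20)]
    idx = _index_table(rng, samples)
    g_noise = rng.normal(size=20)
    expr = make_expr(
        [idx["HyperZ_sig"].to_numpy(), g_noise, -g_noise],
        ["same_as_index", "g", "neg_g"],
        samples,
    )
    rec = correlate_expr_index(expr, idx)
    same = rec[(rec.gene == "same_as_index") & (rec["index"] == "HyperZ")].iloc[0]
    assert same["r"] == pytest.approx(1.0)
    assert same["undefined"]  # infinite Fisher Z flagged
    g = rec[(rec.gene == "g") & (rec["index"] == "HypoZ")].iloc[0]
    ng = rec[(rec.gene == "neg_g") & (rec["index"] == "HypoZ")].iloc[0]
    assert ng["r"] == pytest.approx(-g["r"])
    assert ng["fisher_z"] == pytest.approx(-g["fisher_z"])
    assert ng["pvalue"] == pytest.approx(g["pvalue"])


def test_constant_gene_flagged_undefined():
    rng = np.random.default_rng(6)
    samples = [f"t{i}" for i in range(10)]
    expr = make_expr([[1.0] * 10], ["flat"], samples)
    rec = correlate_expr_index(expr, _index_table(rng, samples))
    assert rec["undefined"].all()


def test_correlation_consistency_thresholds():
    rows = []
    for i in range(10):
        rows.append({"gene": "g", "cohort": f"c{i}", "index": "HyperZ",
                     "r": 0.5, "pvalue": 0.01 if i < 6 else 0.5, "undefined": False})
        rows.append({"gene": "g", "cohort": f"c{i}", "index": "HypoZ",
                     "r": -0.5, "pvalue": 0.01 if i < 5 else 0.5, "undefined": False})
    res = correlation_consistency(pd.DataFrame(rows))
    hyper = res[res["index"] == "HyperZ"].iloc[0]
    hypo = res[res["index"] == "HypoZ"].iloc[0]
    assert hyper["call"] == "positive" and hyper["n_pos"] == 6
    assert hypo["call"] == "none" and hypo["n_neg"] == 5


def test_de_null_probabilities_are_cohort_averages():
    recs = {
        "a": pd.DataFrame({"pvalue": [0.01, 0.5], "direction": ["up", "down"]}),
        "b": pd.DataFrame({"pvalue": [0.01, 0.01], "direction": ["down", "down"]}),
    }
    nulls = de_null_probabilities(recs)
    assert nulls["p_bar_u"] == pytest.approx((0.5 + 0.0) / 2)
    assert nulls["p_bar_d"] == pytest.approx((0.0 + 1.0) / 2)


# ---------------------------------------------------------------------------
# expression-expression meta network
# ---------------------------------------------------------------------------

def _cohort_exprs(rng, n_cohorts, genes_builder, n=40):
    exprs, sheets = {}, {}
    for c in range(n_cohorts):
        cid = f"c{c}"
        samples = [f"{cid}_t{i}" for i in range(n)]
        exprs[cid] = make_expr(genes_builder(rng, n), ["gA", "gB", "gC"], samples, cohort=cid)
        sheets[cid] = make_sheet([], samples)
    return exprs, sheets


def test_meta_network_finds_duplicated_gene_edge():
    rng = np.random.default_rng(9)

    def builder(rng, n):
        base = rng.normal(size=n)
        return [base, base + 0.45 * rng.normal(size=n), rng.normal(size=n)]

    exprs, sheets = _cohort_exprs(rng, 4, builder)
    net = expr_expr_meta_network(exprs, sheets, ["gA", "gB", "gC"])
    ab = net[(net.gene_a == "gA") & (net.gene_b == "gB")].iloc[0]
    assert ab["edge"] and ab["sign"] == 1
    null_edges = net[(net.gene_b == "gC") | (net.gene_a == "gC")]
    assert not null_edges["edge"].any()


def test_meta_network_null_genes_rarely_edge():
    rng = np.random.default_rng(10)

    def builder(rng, n):
        return [rng.normal(size=n) for _ in range(3)]

    fp = 0
    for _ in range(30):
        exprs, sheets = _cohort_exprs(rng, 3, builder)
        net = expr_expr_meta_network(exprs, sheets, ["gA", "gB", "gC"])
        fp += int(net["edge"].sum())
    assert fp / (30 * 3) <= 0.05


def test_meta_network_single_cohort_zero_correlation_no_edge():
    samples = [f"t{i}" for i in range(8)]
    rng = np.random.default_rng(2)
    x = np.arange(8, dtype=float)
    v = rng.normal(size=8)
    xc = x - x.mean()
    y = v - (v @ xc) / (xc @ xc) * xc  # exactly uncorrelated with x
    expr = make_expr([x, y], ["gA", "gB"], samples)
    net = expr_expr_meta_network({"c": expr}, {"c": make_sheet([], samples)}, ["gA", "gB"])
    assert not net["edge"].iloc[0]
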