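import numpy as np
import pandas as pd
import pytest

from epinstab.indices import (
    cluster_probes,
    compute_indices,
    compute_zscores,
    full_index_table,
    index_association,
    summarize_regions,
)
from epinstab.io import MethylationMatrix, ProbeAnnotation
from epinstab.simulate import SimulationConfig, simulate_pan_cancer, worked_fixture
from epinstab.preprocess import filter_and_impute

from conftest import make_sheet


def _ann(positions, region_class="cgi", chrom="chr1"):
    n = len(positions)
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": chrom,
                "position": positions,
                "region_class": region_class,
                "promoter_gene": None,
                "promoter_cgi": region_class == "cgi",
            },
            index=pd.Index([f"p{i}" for i in range(n)], name="probe_id"),
        )
    )


def _memberships(clusters):
    return [tuple(p) for p in clusters.table["probes"]]


@pytest.mark.parametrize(
    "positions,expected",
    [
        # gaps (200, 600, 1700): 600 and 1700 exceed max_gap
        ([100, 300, 900, 2600], [("p0", "p1"), ("p2",), ("p3",)]),
        # all gaps 400 but adding 1700 would give span 1600 > 1500
        ([100, 500, 900, 1300, 1700], [("p0", "p1", "p2", "p3"), ("p4",)]),
        ([42], [("p0",)]),
    ],
)
def test_greedy_clustering_hand_traces(positions, expected):
    cl = cluster_probes(_ann(positions))
    assert _memberships(cl) == expected
    assert (cl.table["span"] <= 1500).all()


def _brute_force_greedy(positions, max_gap=500, max_width=1500):
    """Independent re-implementation of the greedy partition."""
    clusters, current = [], []
    for pos in sorted(positions):
        if not current:
            current = [pos]
        elif pos - current[-1] <= max_gap and pos - current[0] <= max_width:
            current.append(pos)
        else:
            clusters.append(current)
            current = [pos]
    if current:
        clusters.append(current)
    return [tuple(c) for c in clusters]


def test_clustering_matches_brute_force_on_random_layouts():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = rng.integers(1, 50)
        positions = np.unique(rng.integers(1, 20_000, size=n))
        cl = cluster_probes(_ann(list(positions)))
        label_to_pos = {f"p{i}": int(positions[i]) for i in range(len(positions))}
        got_pos = [
            tuple(label_to_pos[p] for p in probes) for probes in cl.table["probes"]
        ]
        assert got_pos == _brute_force_greedy(positions)


def test_clusters_never_mix_classes_or_chromosomes():
    ann = pd.concat(
        [
            _ann([100, 200], "cgi").table,
            _ann([150, 250], "opensea").table.set_index(pd.Index(["q0", "q1"])),
        ]
    )
    ann.index.name = "probe_id"
    cl = cluster_probes(ProbeAnnotation(ann))
    assert len(cl) == 2
    assert set(cl.table["region_class"]) == {"cgi", "opensea"}


def test_summarize_regions_means():
    fx = worked_fixture()
    cl = cluster_probes(fx.annotation)
    rb = summarize_regions(fx.meth, cl)
    # singleton clusters: region beta equals the probe beta
    assert np.allclose(
        rb.data.to_numpy(), fx.meth.data.loc[[p[0] for p in cl.table["probes"]]].to_numpy()
    )
    # a two-probe cluster averages its members
    two = MethylationMatrix(
        pd.DataFrame({"s": [0.2, 0.4]}, index=["p0", "p1"])
    )
    cl2 = cluster_probes(_ann([100, 200]))
    rb2 = summarize_regions(two, cl2)
    assert rb2.data.iloc[0, 0] == pytest.approx(0.3)


def test_summarize_regions_missing_probe_errors():
    cl = cluster_probes(_ann([100, 200]))
    m = MethylationMatrix(pd.DataFrame({"s": [0.2]}, index=["p0"]))
    with pytest.raises(ValueError, match="absent"):
        summarize_regions(m, cl)


class TestWorkedFixtureIndices:
    @pytest.fixture(autouse=True)
    def _setup(self):
        fx = worked_fixture()
        self.clusters = cluster_probes(fx.annotation)
        rb = summarize_regions(fx.meth, self.clusters)
        self.ref, self.z = compute_zscores(rb, fx.sheet)
        self.expected = fx.expected

    def test_normal_reference_and_zscores(self):
        assert self.ref.mean.iloc[0] == pytest.approx(0.10)
        assert self.ref.sd.iloc[0] == pytest.approx(0.016330, abs=1e-6)
        assert self.z.data.loc["chrA:1000:cgi", "T1"] == pytest.approx(12.25, abs=0.01)
        # cancer at the normal mean scores zero
        assert (self.z.data["T2"] == 0).all()

    def test_index_values(self):
        table = full_index_table(self.z, self.clusters)
        assert table.loc["T1", "HyperZ"] == pytest.approx(6.125, abs=0.01)
        assert table.loc["T1", "HypoZ"] == pytest.approx(2.0, abs=1e-9)
        assert table.loc["T1", "HyperZ_sig"] == pytest.approx(self.expected["hyperz_sig_T1"])
        assert table.loc["T1", "HypoZ_sig"] == pytest.approx(4.0)
        # H(0) = 0: a cancer identical to the normal means has zero indices
        assert table.loc["T2"].tolist() == [0.0, 0.0, 0.0, 0.0]
        assert (table >= 0).all().all()


def test_compute_zscores_requires_two_normals():
    fx = worked_fixture()
    cl = cluster_probes(fx.annotation)
    rb = summarize_regions(fx.meth, cl)
    sheet = make_sheet(["N1"], ["T1", "T2"])
    with pytest.raises(ValueError, match="normal"):
        compute_zscores(rb, sheet)


def test_zero_sd_clusters_are_excluded():
    m = MethylationMatrix(
        pd.DataFrame(
            {"n1": [0.5, 0.1], "n2": [0.5, 0.2], "t1": [0.9, 0.9]},
            index=["p0", "p9"],
        )
    )
    ann = _ann([100, 5000])
    cl = cluster_probes(ProbeAnnotation(ann.table.set_index(pd.Index(["p0", "p9"], name="probe_id"))))
    rb = summarize_regions(m, cl)
    _, z = compute_zscores(rb, make_sheet(["n1", "n2"], ["t1"]))
    assert len(z.excluded) == 1
    assert len(z.data) == 1


def test_empty_eligible_cluster_set_errors():
    fx = worked_fixture()
    ann = fx.annotation.table.copy()
    ann["promoter_cgi"] = False  # no promoter CGIs anywhere
    cl = cluster_probes(ProbeAnnotation(ann))
    rb = summarize_regions(fx.meth, cl)
    _, z = compute_zscores(rb, fx.sheet)
    with pytest.raises(ValueError, match="promoter-CGI"):
        compute_indices(z, cl)


def test_hyperz_strictly_increases_with_added_cancer_methylation():
    fx = worked_fixture()
    cl = cluster_probes(fx.annotation)
    cgi_probes = ["cg000001", "cg000002"]

    def hyperz(delta):
        data = fx.meth.data.copy()
        data.loc[cgi_probes, ["T1", "T2"]] += delta
        rb = summarize_regions(MethylationMatrix(data), cl)
        _, z = compute_zscores(rb, fx.sheet)
        return compute_indices(z, cl)["HyperZ"]

    h0, h1, h2 = hyperz(0.0), hyperz(0.05), hyperz(0.10)
    assert (h1 > h0).all() and (h2 > h1).all()


def test_normal_samples_have_small_leave_one_out_indices():
    """Indices of normals (scored against the remaining normals) are small
    relative to planted cancers."""
    cfg = SimulationConfig(n_cohorts=1, seed=21)
    study = simulate_pan_cancer(cfg)
    cohort = next(iter(study.cohorts.values()))
    clusters = cluster_probes(study.annotation)
    meth = filter_and_impute(cohort.meth)
    rb = summarize_regions(meth, clusters)
    _, z = compute_zscores(rb, cohort.sheet)
    cancer_med = float(full_index_table(z, clusters)["HyperZ"].median())

    normals = cohort.sheet.normals
    loo_vals = []
    for s in normals:
        sheet = make_sheet([n for n in normals if n != s], [s])
        _, z_loo = compute_zscores(rb, sheet)
        loo_vals.append(full_index_table(z_loo, clusters).loc[s, "HyperZ"])
    assert np.median(loo_vals) < 0.2 * cancer_med


class TestIndexAssociation:
    def test_identical_indices(self):
        t = pd.DataFrame({"HyperZ": [1.0, 2, 3, 4], "HypoZ": [1.0, 2, 3, 4]})
        res = index_association(t)
        assert res["rho"] == pytest.approx(1.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_anti_monotone(self):
        t = pd.DataFrame({"HyperZ": [1.0, 2, 3], "HypoZ": [9.0, 5, 1]})
        assert index_association(t)["rho"] == pytest.approx(-1.0)

    def test_constant_index_reported_undefined(self):
        t = pd.DataFrame({"HyperZ": [1.0, 1, 1], "HypoZ": [1.0, 2, 3]})
        assert np.isnan(index_association(t)["rho"])

    def test_requires_three_samples(self):
        t = pd.DataFrame({"HyperZ": [1.0, 2], "HypoZ": [1.0, 2]})
        with pytest.raises(ValueError):
            index_association(t)
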