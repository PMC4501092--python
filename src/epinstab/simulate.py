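"""Synthetic multi-cohort matched expression/methylation data with planted truth.

The generator emulates the statistical structure the pipeline assumes:

* promoter-CGI regions are nearly unmethylated in normal tissue (beta ~ 0.10)
  while open-sea regions are highly methylated (beta ~ 0.80);
* each cancer sample carries two independent latent magnitudes — a
  hypermethylation magnitude ``h_s`` acting on a fixed set of affected
  promoter-CGI regions and a hypomethylation magnitude ``l_s`` acting on a
  fixed set of affected open-sea regions (half-normal draws, so both are
  non-negative and independent by construction);
* planted "driver" genes realize the three causal archetypes that the
  partial-correlation stage is designed to discriminate:

  - model C (direct): expression tracks ``h_s`` (or ``l_s``) directly;
  - model A (confounded): expression is driven by the gene's *own promoter*
    methylation, which itself tracks the global shift — a spurious
    expression-index correlation;
  - model B (mediated): expression tracks another driver's expression with
    no direct link to the latent magnitudes.

Affected-region sets, region weights and gene baselines are shared across
cohorts, so locus-level correlation rankings are comparable between cohorts
(as they are on a fixed array platform).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    EEGeneList,
    ExpressionMatrix,
    MethylationMatrix,
    ProbeAnnotation,
    SampleSheet,
)

__all__ = [
    "DriverSpec",
    "SimulationConfig",
    "GroundTruth",
    "CohortData",
    "SimulatedStudy",
    "WorkedFixture",
    "default_drivers",
    "simulate_pan_cancer",
    "worked_fixture",
]


@dataclass(frozen=True)
class DriverSpec:
    """One planted gene and the causal model it realizes.

    ``effect_size`` is the slope linking the gene's log2-expression
    deviation to the per-sample latent methylation-shift magnitude
    (model C), to its own promoter beta (model A, beta scale), or to the
    partner driver's expression (model B).
    """

    gene: str
    model: str  # C_hyper | C_hypo | A_confounded | B_correlated | null
    direction: str = "up"  # up | down
    effect_size: float = 3.0
    target_fraction: float = 0.5
    partner: str | None = None  # model B: the driver gene mediating the link

    def __post_init__(self) -> None:
        if self.model not in ("C_hyper", "C_hypo", "A_confounded", "B_correlated", "null"):
            raise ValueError(f"unknown driver model {self.model!r}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if self.model == "B_correlated" and self.partner is None:
            raise ValueError("B_correlated driver needs a partner gene")


def default_drivers() -> list[DriverSpec]:
    """The default planted-gene panel (two hyper drivers, one hypo
    tumor-suppressor, one confounded and one mediated gene)."""
    return [
        DriverSpec("UHRF1", "C_hyper", "up", 5.0),
        DriverSpec("WHSC1", "C_hyper", "up", 5.0),
        DriverSpec("CBX7", "C_hypo", "down", 5.0),
        DriverSpec("EYA4", "A_confounded", "down", 6.0),
        DriverSpec("PCNA", "B_correlated", "up", 0.5, partner="UHRF1"),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the pan-cancer simulation.

    Defaults mirror the real study's shape (10 cohorts) at desk scale:
    20 normals + 80 cancers per cohort, 300 genes of which 40 are
    epigenetic-enzyme genes, 200 promoter-CGI and 200 open-sea regions of
    3 probes each.  ``sigma_hyper``/``sigma_hypo`` are the half-normal
    scales of the latent magnitudes; with region weights uniform on
    ``region_weight_range`` the mean affected-region beta shift is
    sigma * sqrt(2/pi) * E[w] ~ 0.15.
    """

    n_cohorts: int = 10
    n_normal: int = 20
    n_cancer: int = 80
    n_genes: int = 300
    n_ee_genes: int = 40
    n_cgi_regions: int = 200
    n_opensea_regions: int = 200
    probes_per_region: int = 3
    cgi_baseline: float = 0.10
    opensea_baseline: float = 0.80
    beta_noise_sd: float = 0.03
    drivers: list[DriverSpec] = field(default_factory=default_drivers)
    expr_noise_sd: float = 0.5
    na_rate: float = 0.01
    sigma_hyper: float = 0.25
    sigma_hypo: float = 0.25
    region_response_sd: float = 1.0
    region_weight_range: tuple[float, float] = (0.5, 1.0)
    expr_baseline_range: tuple[float, float] = (4.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cohorts", "n_normal", "n_cancer", "n_genes", "n_ee_genes",
                     "n_cgi_regions", "n_opensea_regions", "probes_per_region"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.cgi_baseline < 1 and 0 < self.opensea_baseline < 1):
            raise ValueError("beta baselines must lie in (0, 1)")
        if len(self.drivers) > self.n_ee_genes:
            raise ValueError("more drivers requested than EE genes")
        if self.drivers and not any(d.model.startswith("C_") for d in self.drivers):
            raise ValueError("driver panel must contain at least one model-C driver")
        genes = [d.gene for d in self.drivers]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate driver genes")
        for d in self.drivers:
            if d.model == "B_correlated" and d.partner not in genes:
                raise ValueError(f"B_correlated driver {d.gene} partner {d.partner!r} not in panel")
        if self.n_ee_genes > self.n_cgi_regions:
            raise ValueError("need at least one promoter-CGI region per EE gene")


@dataclass
class GroundTruth:
    """Planted truth stored alongside the generated data.

    ``latents[cohort]`` holds the per-cancer-sample ``h`` and ``l``
    magnitudes; ``gene_models`` maps every gene to its causal archetype;
    ``regions`` records per region whether it is affected by hyper- or
    hypomethylation and with what weight.
    """

    latents: dict[str, pd.DataFrame]
    gene_models: dict[str, str]
    regions: pd.DataFrame
    seed: int

    def driver_genes(self, models=("C_hyper", "C_hypo")) -> list[str]:
        return [g for g, m in self.gene_models.items() if m in models]


@dataclass
class CohortData:
    cohort_id: str
    expr: ExpressionMatrix
    meth: MethylationMatrix
    sheet: SampleSheet


@dataclass
class SimulatedStudy:
    cohorts: dict[str, CohortData]
    annotation: ProbeAnnotation
    truth: GroundTruth
    config: SimulationConfig

    @property
    def cohort_ids(self) -> list[str]:
        return list(self.cohorts)


def _build_annotation(cfg: SimulationConfig, ee_genes: list[str]) -> tuple[ProbeAnnotation, pd.DataFrame]:
    """Shared probe manifest: one pseudo-chromosome per region class,
    regions 10 kb apart, probes 100 bp apart within a region.

    Returns the annotation and the region table (region_id -> class,
    member probes, promoter gene).  The first ``n_ee_genes`` CGI regions
    are the promoter-CGI regions of the EE genes, in order.
    """
    rows = []
    regions = []
    probe_i = 0
    for cls, chrom, n_regions, base in (
        ("cgi", "chrA", cfg.n_cgi_regions, cfg.cgi_baseline),
        ("opensea", "chrB", cfg.n_opensea_regions, cfg.opensea_baseline),
    ):
        for r in range(n_regions):
            start = 1000 + r * 10_000
            region_id = f"{cls}_{r:04d}"
            gene = ee_genes[r] if cls == "cgi" and r < len(ee_genes) else None
            probes = []
            for j in range(cfg.probes_per_region):
                pid = f"cg{probe_i:06d}"
                probe_i += 1
                probes.append(pid)
                rows.append({
                    "probe_id": pid,
                    "chromosome": chrom,
                    "position": start + 100 * j,
                    "region_class": cls,
                    "promoter_gene": gene,
                    "promoter_cgi": cls == "cgi",
                })
            regions.append({
                "region_id": region_id,
                "region_class": cls,
                "chromosome": chrom,
                "start": start,
                "baseline": base,
                "promoter_gene": gene,
                "probes": probes,
            })
    ann = pd.DataFrame(rows).set_index("probe_id")
    return ProbeAnnotation(ann), pd.DataFrame(regions).set_index("region_id")


def _choose_affected(cfg: SimulationConfig, region_table: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Mark affected regions.  Model-A genes' promoter regions are forced
    into the hyper-affected set; model-B/C drivers' promoters are kept
    unaffected so that their own promoter methylation carries no signal."""
    out = region_table.copy()
    frac_hyper = max([d.target_fraction for d in cfg.drivers if d.model == "C_hyper"] or [0.5])
    frac_hypo = max([d.target_fraction for d in cfg.drivers if d.model == "C_hypo"] or [0.5])
    a_genes = {d.gene for d in cfg.drivers if d.model == "A_confounded"}
    cb_genes = {d.gene for d in cfg.drivers if d.model in ("C_hyper", "C_hypo", "B_correlated")}

    cgi = out.index[out["region_class"] == "cgi"]
    forced_in = [r for r in cgi if out.loc[r, "promoter_gene"] in a_genes]
    forced_out = [r for r in cgi if out.loc[r, "promoter_gene"] in cb_genes]
    free = [r for r in cgi if r not in set(forced_in) | set(forced_out)]
    n_target = int(round(frac_hyper * len(cgi)))
    n_extra = max(0, min(len(free), n_target - len(forced_in)))
    chosen = set(forced_in) | set(rng.choice(free, size=n_extra, replace=False))
    out["affected_hyper"] = [r in chosen for r in out.index]

    osea = out.index[out["region_class"] == "opensea"]
    n_osea = int(round(frac_hypo * len(osea)))
    chosen_o = set(rng.choice(osea, size=n_osea, replace=False))
    out["affected_hypo"] = [r in chosen_o for r in out.index]

    lo, hi = cfg.region_weight_range
    out["weight"] = rng.uniform(lo, hi, size=len(out))
    return out


def _ee_gene_names(cfg: SimulationConfig) -> list[str]:
    """EE gene symbols: planted drivers first, then filled from the bundled
    list, then generic symbols if the bundled list runs out."""
    names = [d.gene for d in cfg.drivers]
    for sym in EEGeneList.bundled().symbols:
        if len(names) >= cfg.n_ee_genes:
            break
        if sym not in names:
            names.append(sym)
    i = 0
    while len(names) < cfg.n_ee_genes:
        cand = f"EE{i:03d}"
        if cand not in names:
            names.append(cand)
        i += 1
    return names[: cfg.n_ee_genes]


def simulate_pan_cancer(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate the full multi-cohort study.  Deterministic in ``config.seed``."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    ee_genes = _ee_gene_names(cfg)
    genes = ee_genes + [f"GENE{i:04d}" for i in range(cfg.n_genes - cfg.n_ee_genes)]
    annotation, region_table = _build_annotation(cfg, ee_genes)
    regions = _choose_affected(cfg, region_table, rng)
    baselines = pd.Series(
        rng.uniform(*cfg.expr_baseline_range, size=len(genes)), index=genes
    )

    gene_models = {g: "null" for g in genes}
    for d in cfg.drivers:
        gene_models[d.gene] = d.model

    probe_region = np.repeat(regions.index.to_numpy(), cfg.probes_per_region)
    region_base = regions["baseline"].to_numpy()
    w = regions["weight"].to_numpy()
    aff_h = regions["affected_hyper"].to_numpy()
    aff_l = regions["affected_hypo"].to_numpy()
    n_regions = len(regions)
    ppr = cfg.probes_per_region

    cohorts: dict[str, CohortData] = {}
    latents: dict[str, pd.DataFrame] = {}
    for c in range(cfg.n_cohorts):
        cid = f"cohort{c + 1:02d}"
        normals = [f"{cid}_N{i + 1:03d}" for i in range(cfg.n_normal)]
        cancers = [f"{cid}_T{i + 1:03d}" for i in range(cfg.n_cancer)]
        samples = normals + cancers
        n_s = len(samples)

        h = np.abs(rng.normal(0.0, cfg.sigma_hyper, size=cfg.n_cancer))
        l = np.abs(rng.normal(0.0, cfg.sigma_hypo, size=cfg.n_cancer))
        hs = np.concatenate([np.zeros(cfg.n_normal), h])  # per sample
        ls = np.concatenate([np.zeros(cfg.n_normal), l])

        # region x sample true methylation level, then probe-level noise.
        # Affected regions respond to the sample's latent magnitude with a
        # region-by-sample multiplicative response (truncated at zero):
        # tumor heterogeneity makes any single region a noisy readout of
        # the genome-wide load.
        resp_h = np.maximum(rng.normal(1.0, cfg.region_response_sd, size=(n_regions, n_s)), 0.0)
        resp_l = np.maximum(rng.normal(1.0, cfg.region_response_sd, size=(n_regions, n_s)), 0.0)
        shift = (
            (aff_h * w)[:, None] * hs[None, :] * resp_h
            - (aff_l * w)[:, None] * ls[None, :] * resp_l
        )
        region_true = np.clip(region_base[:, None] + shift, 0.0, 1.0)
        betas = np.repeat(region_true, ppr, axis=0)
        betas = np.clip(betas + rng.normal(0.0, cfg.beta_noise_sd, size=betas.shape), 0.0, 1.0)

        # observed per-region mean beta (pre-NA), used for model-A coupling
        region_obs = betas.reshape(n_regions, ppr, n_s).mean(axis=1)
        region_obs = pd.DataFrame(region_obs, index=regions.index, columns=samples)

        log2expr = (
            baselines.to_numpy()[:, None]
            + rng.normal(0.0, cfg.expr_noise_sd, size=(len(genes), n_s))
        )
        expr = pd.DataFrame(log2expr, index=genes, columns=samples)

        order = {"C_hyper": 0, "C_hypo": 0, "A_confounded": 1, "B_correlated": 2, "null": 3}
        for d in sorted(cfg.drivers, key=lambda d: order[d.model]):
            sign = 1.0 if d.direction == "up" else -1.0
            noise = expr.loc[d.gene].to_numpy() - baselines[d.gene]
            if d.model == "C_hyper":
                dev = d.effect_size * hs
            elif d.model == "C_hypo":
                dev = d.effect_size * ls
            elif d.model == "A_confounded":
                prom = regions.index[regions["promoter_gene"] == d.gene][0]
                pb = region_obs.loc[prom].to_numpy()
                dev = d.effect_size * (pb - pb[: cfg.n_normal].mean())
            elif d.model == "B_correlated":
                partner_dev = expr.loc[d.partner].to_numpy() - baselines[d.partner]
                dev = d.effect_size * partner_dev
            else:
                dev = 0.0
            expr.loc[d.gene] = baselines[d.gene] + sign * dev + noise

        # raw (RSEM-like) scale output; the preprocessing step recovers log2
        raw = pd.DataFrame(
            np.exp2(expr.to_numpy()), index=genes, columns=samples
        )

        if cfg.na_rate > 0:
            mask = rng.random(size=betas.shape) < cfg.na_rate
            betas = np.where(mask, np.nan, betas)
        meth = pd.DataFrame(betas, index=annotation.probe_ids, columns=samples)

        sheet = pd.DataFrame(
            {
                "status": ["normal"] * cfg.n_normal + ["cancer"] * cfg.n_cancer,
                "cohort_id": cid,
                "group": "",
            },
            index=pd.Index(samples, name="sample_id"),
        )
        cohorts[cid] = CohortData(
            cohort_id=cid,
            expr=ExpressionMatrix(raw, scale="raw", cohort_id=cid),
            meth=MethylationMatrix(meth, cohort_id=cid),
            sheet=SampleSheet(sheet),
        )
        latents[cid] = pd.DataFrame({"h": h, "l": l}, index=cancers)

    truth = GroundTruth(
        latents=latents,
        gene_models=gene_models,
        regions=regions.drop(columns="probes"),
        seed=cfg.seed,
    )
    return SimulatedStudy(cohorts=cohorts, annotation=annotation, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Worked single-cohort fixture with hand-computable index values
# ---------------------------------------------------------------------------

#: sample standard deviation of {0.10, 0.12, 0.08, 0.10}
_FIX_SD = float(np.sqrt(8e-4 / 3))  # 0.016329931618...


@dataclass
class WorkedFixture:
    expr: ExpressionMatrix
    meth: MethylationMatrix
    sheet: SampleSheet
    annotation: ProbeAnnotation
    expected: dict[str, float]


def worked_fixture() -> WorkedFixture:
    """Tiny deterministic cohort (4 normals, 2 cancers, 2 promoter-CGI and
    2 open-sea single-probe regions, 1 gene) whose HyperZ/HypoZ values are
    hand arithmetic.

    Region normals are {0.10, 0.12, 0.08, 0.10} (CGI; mean 0.10, sample sd
    0.016330) and {0.80, 0.82, 0.78, 0.80} (open sea).  Cancer sample T1 has
    region Z scores {+12.247, -1} on the CGI side and {-4, +2} on the open
    sea side, giving HyperZ = 6.124 and HypoZ = 2; cancer T2 sits exactly at
    the normal means, giving zero indices.
    """
    sd = _FIX_SD
    normals = ["N1", "N2", "N3", "N4"]
    cancers = ["T1", "T2"]
    samples = normals + cancers
    rows = {
        "cg000001": [0.10, 0.12, 0.08, 0.10, 0.30, 0.10],
        "cg000002": [0.10, 0.12, 0.08, 0.10, 0.10 - 1.0 * sd, 0.10],
        "cg000003": [0.80, 0.82, 0.78, 0.80, 0.80 - 4.0 * sd, 0.80],
        "cg000004": [0.80, 0.82, 0.78, 0.80, 0.80 + 2.0 * sd, 0.80],
    }
    meth = pd.DataFrame(rows, index=samples).T
    ann = pd.DataFrame(
        {
            "chromosome": ["chrA", "chrA", "chrB", "chrB"],
            "position": [1000, 11000, 1000, 11000],
            "region_class": ["cgi", "cgi", "opensea", "opensea"],
            "promoter_gene": ["EZH2", None, None, None],
            "promoter_cgi": [True, True, False, False],
        },
        index=pd.Index(list(rows), name="probe_id"),
    )
    expr = pd.DataFrame(
        {s: [v] for s, v in zip(samples, [8.0, 8.1, 7.9, 8.0, 9.0, 8.5])},
        index=["EZH2"],
    )
    sheet = pd.DataFrame(
        {
            "status": ["normal"] * 4 + ["cancer"] * 2,
            "cohort_id": "fixture",
            "group": "",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    z1 = 0.20 / sd  # 12.2474...
    expected = {
        "normal_mean_cgi": 0.10,
        "normal_sd": sd,
        "z_T1_region1": z1,
        "z_T1_region2": -1.0,
        "hyperz_T1": z1 / 2.0,
        "hypoz_T1": 2.0,
        "hyperz_sig_T1": z1,
        "hypoz_sig_T1": 4.0,
        "hyperz_T2": 0.0,
        "hypoz_T2": 0.0,
    }
    return WorkedFixture(
        expr=ExpressionMatrix(expr, scale="log2", cohort_id="fixture"),
        meth=MethylationMatrix(meth, cohort_id="fixture"),
        sheet=SampleSheet(sheet),
        annotation=ProbeAnnotation(ann),
        expected=expected,
    )
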