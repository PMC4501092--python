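"""Data model and TSV readers/writers shared by all pipeline stages.

Matrices are tab-separated text files: first column holds row identifiers
(genes or 450k-style probe ids), the header row holds sample identifiers and
``NA`` is the only missing-value token (the TCGA level-3 dialect).  Gene
identity is by symbol string, case-sensitive; no alias resolution is
attempted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MethylationMatrix",
    "ProbeAnnotation",
    "SampleSheet",
    "EEGeneList",
    "MatchedCohort",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
    "align_cohort",
]

REGION_CLASSES = ("cgi", "shore_shelf", "opensea")

#: float format preserving >= 10 significant digits for lossless round trips
_FLOAT_FMT = "%.12g"


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene expression for one cohort: genes x samples.

    ``scale`` records whether values are raw (RSEM-like, non-negative) or
    log2-transformed.
    """

    data: pd.DataFrame
    scale: str = "raw"
    cohort_id: str = ""

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("expression matrix must not contain missing values")
        if self.scale == "raw" and (vals < 0).any():
            bad = self.data.index[(vals < 0).any(axis=1)][0]
            raise ValueError(f"negative raw expression value (gene {bad!r})")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class MethylationMatrix:
    """Beta-value methylation matrix for one cohort: probes x samples.

    Non-missing entries lie in [0, 1]; NaN marks missing measurements.
    """

    data: pd.DataFrame
    cohort_id: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values outside [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def betas(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())


@dataclass
class ProbeAnnotation:
    """Probe genomic annotation.

    One row per probe: chromosome, 1-based position, region class
    (cgi / shore_shelf / opensea), optional promoter gene assignment and a
    promoter-CGI flag.  The promoter mapping is carried by the annotation
    itself (filled by the data generator or a real-data adapter); the
    pipeline never computes TSS windows.
    """

    table: pd.DataFrame  # index: probe_id; columns: chromosome, position, region_class, promoter_gene, promoter_cgi

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "probe ids")
        required = {"chromosome", "position", "region_class", "promoter_gene", "promoter_cgi"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if (t["position"].to_numpy() < 1).any():
            raise ValueError("probe positions must be >= 1")
        bad = set(t["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"unknown region classes: {sorted(bad)}")
        pc = t["promoter_cgi"].astype(bool)
        if (pc & (t["region_class"] != "cgi")).any():
            raise ValueError("promoter_cgi probes must have region_class 'cgi'")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class SampleSheet:
    """Sample metadata: status (normal/cancer), cohort and optional group."""

    table: pd.DataFrame  # index: sample_id; columns: status, cohort_id, group

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        if "group" not in self.table.columns:
            self.table = self.table.assign(group="")
        bad = set(self.table["status"]) - {"normal", "cancer"}
        if bad:
            raise ValueError(f"unknown sample status values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples(self, status: str) -> list[str]:
        return list(self.table.index[self.table["status"] == status])

    @property
    def normals(self) -> list[str]:
        return self.samples("normal")

    @property
    def cancers(self) -> list[str]:
        return self.samples("cancer")


@dataclass
class EEGeneList:
    """List of epigenetic-enzyme (chromatin writer/reader/eraser/editor) genes."""

    symbols: list[str]
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.symbols, "gene symbols")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)

    @classmethod
    def from_file(cls, path) -> "EEGeneList":
        symbols, families = [], {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                symbols.append(parts[0])
                if len(parts) > 1:
                    families[parts[0]] = parts[1]
        return cls(symbols, families)

    @classmethod
    def bundled(cls) -> "EEGeneList":
        """The gene list shipped with the package."""
        ref = importlib.resources.files("epinstab") / "data" / "ee_genes.txt"
        with importlib.resources.as_file(ref) as path:
            return cls.from_file(path)


def read_matrix(path, kind: str):
    """Read a genes/probes x samples TSV into a typed matrix.

    ``kind`` is ``"expression"`` or ``"methylation"``; missing values
    (``NA``) are legal only for methylation.
    """
    if kind not in ("expression", "methylation"):
        raise ValueError(f"kind must be 'expression' or 'methylation', got {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.astype(float)
    if kind == "expression":
        if df.isna().to_numpy().any():
            raise ValueError("expression matrix contains NA values")
        return ExpressionMatrix(df, scale="raw")
    return MethylationMatrix(df)


def write_matrix(matrix, path) -> None:
    """Write a matrix as TSV with ``NA`` for missing, 12 significant digits."""
    matrix.data.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)


def read_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df["promoter_gene"] = df["promoter_gene"].where(df["promoter_gene"].notna(), None)
    df["promoter_cgi"] = df["promoter_cgi"].astype(bool) if df["promoter_cgi"].dtype != bool else df["promoter_cgi"]
    return ProbeAnnotation(df)


def write_annotation(ann: ProbeAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", na_rep="NA")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    if "group" in df.columns:
        df["group"] = df["group"].fillna("")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class MatchedCohort:
    """Samples present in expression, methylation and the sample sheet.

    Sample order follows the expression matrix.  ``n_dropped_*`` report how
    many samples of each input were absent from the intersection.
    """

    expr: ExpressionMatrix
    meth: MethylationMatrix
    sheet: SampleSheet
    n_dropped_expr: int
    n_dropped_meth: int
    n_dropped_sheet: int

    @property
    def sample_ids(self) -> list[str]:
        return self.expr.sample_ids


def align_cohort(expr: ExpressionMatrix, meth: MethylationMatrix, sheet: SampleSheet) -> MatchedCohort:
    """Intersect the samples of the three inputs, preserving expression order."""
    common = set(expr.sample_ids) & set(meth.sample_ids) & set(sheet.sample_ids)
    if not common:
        raise ValueError("no samples shared between expression, methylation and sample sheet")
    keep = [s for s in expr.sample_ids if s in common]
    return MatchedCohort(
        expr=ExpressionMatrix(expr.data[keep], scale=expr.scale, cohort_id=expr.cohort_id),
        meth=MethylationMatrix(meth.data[keep], cohort_id=meth.cohort_id),
        sheet=SampleSheet(sheet.table.loc[keep].copy()),
        n_dropped_expr=len(expr.sample_ids) - len(keep),
        n_dropped_meth=len(meth.sample_ids) - len(keep),
        n_dropped_sheet=len(sheet.sample_ids) - len(keep),
    )
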