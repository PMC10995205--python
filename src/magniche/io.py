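"""Readers, writers and configuration for the tabular interchange formats.

All interchange files are UTF-8 tab-separated with a single header row.
Readers validate the documented schema and the type invariants; they reject
malformed tables rather than silently coercing. Missing environmental values
are encoded as the literal string ``NA`` and surface as NaN.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("magniche")

SAMPLE_TYPES = ("coral", "seawater")
WQ_CATEGORIES = ("NorthMarine", "NorthPlume", "SouthMarine", "SouthPlume", "Coastal")

MAG_COLUMNS = [
    "mag_id", "site", "completeness", "contamination", "genome_size",
    "gc", "n_genes", "coding_density", "taxonomy",
]
SAMPLE_COLUMNS = ["sample_id", "sample_type", "site", "wq_category", "library_size_gbp"]
COVERAGE_COLUMNS = ["mag_id", "sample_id", "mean_coverage", "covered_fraction"]
MODULE_COLUMNS = ["module_id", "name", "definition"]


class SchemaError(ValueError):
    """A table does not conform to its documented schema or invariants."""


@dataclass(frozen=True)
class MAGRecord:
    """One genome bin: quality estimates, genomic features, taxonomy, origin site."""

    mag_id: str
    site: str
    completeness: float
    contamination: float
    genome_size: int
    gc: float
    n_genes: int
    coding_density: float
    taxonomy: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise SchemaError(
                f"{self.mag_id}: completeness {self.completeness} outside [0, 100]"
            )
        if self.contamination < 0.0:
            raise SchemaError(f"{self.mag_id}: contamination {self.contamination} < 0")
        if self.genome_size <= 0:
            raise SchemaError(f"{self.mag_id}: genome_size must be positive")


@dataclass(frozen=True)
class SampleRecord:
    """One metagenome sample: type, site, water-quality category, library size, environment."""

    sample_id: str
    sample_type: str
    site: str
    wq_category: str | None
    library_size_gbp: float
    env: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise SchemaError(
                f"{self.sample_id}: sample_type {self.sample_type!r} not in {SAMPLE_TYPES}"
            )
        if not self.library_size_gbp > 0:
            raise SchemaError(f"{self.sample_id}: library_size_gbp must be > 0")


@dataclass(frozen=True)
class ModuleRow:
    module_id: str
    name: str
    definition: str


@dataclass
class FeatureMatrix:
    """MAG x feature-id non-negative integer count matrix with a namespace tag.

    ``counts`` is indexed by mag_id with one column per feature identifier
    (KO / Pfam / CAZy accessions, or orthologous-cluster ids).
    """

    counts: pd.DataFrame
    namespace: str

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise SchemaError(f"duplicate feature id {dup!r} in namespace {self.namespace}")
        if (self.counts.to_numpy() < 0).any():
            raise SchemaError(f"negative count in {self.namespace} feature matrix")

    @property
    def mag_ids(self) -> list[str]:
        return list(self.counts.index)

    def binarize(self) -> pd.DataFrame:
        """Presence/absence at count >= 1."""
        return (self.counts > 0).astype(int)


@dataclass
class RunConfig:
    """Analysis thresholds and permutation settings.

    Defaults are the published values of every threshold this pipeline applies:
    quality score >= 50 (completeness - 3 x contamination), completeness >= 75 %,
    strain dereplication at ANI >= 99 %, detection at covered fraction >= 0.10,
    seawater prevalence < 0.50, seawater relative abundance < 0.1 %, collinearity
    pruning at |r| > 0.7, environmental-vector selection at R^2 > 0.65, and
    module reporting at completeness > 75 %.
    """

    seed: int = 0
    n_permutations: int = 999
    fdr_method: str = "bh"
    quality_min: float = 50.0
    completeness_min: float = 75.0
    ani_threshold: float = 99.0
    covered_fraction_min: float = 0.10
    prevalence_max: float = 0.50
    seawater_abund_max: float = 0.1
    collinearity_r: float = 0.7
    envfit_r2_min: float = 0.65
    module_report_min: float = 75.0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise SchemaError("n_permutations must be >= 1")
        for name in (
            "quality_min", "completeness_min", "ani_threshold", "covered_fraction_min",
            "prevalence_max", "seawater_abund_max", "collinearity_r",
            "envfit_r2_min", "module_report_min",
        ):
            if not getattr(self, name) > 0:
                raise SchemaError(f"threshold {name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or flat ``key=value`` lines."""
        text = Path(path).read_text()
        if "=" in text.splitlines()[0] and ":" not in text.splitlines()[0]:
            pairs = dict(
                line.split("=", 1)
                for line in text.splitlines()
                if line.strip() and not line.startswith("#")
            )
            data = {k.strip(): yaml.safe_load(v) for k, v in pairs.items()}
        else:
            data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _read_tsv(path: str | Path, required: list[str], kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table {path.name}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, kind: str) -> pd.Series:
    try:
        return pd.to_numeric(df[col])
    except (ValueError, TypeError):
        bad = pd.to_numeric(df[col], errors="coerce")
        row = int(bad[bad.isna() & df[col].notna()].index[0])
        raise SchemaError(
            f"{kind}: unparseable numeric in column {col!r} at data row {row + 1} "
            f"(value {df[col].iloc[row]!r})"
        ) from None


def read_mags(path: str | Path) -> list[MAGRecord]:
    df = _read_tsv(path, MAG_COLUMNS, "MAG")
    if df["mag_id"].duplicated().any():
        dup = df.loc[df["mag_id"].duplicated(), "mag_id"].iloc[0]
        raise SchemaError(f"duplicate mag_id {dup!r}")
    for col in ("completeness", "contamination", "gc", "coding_density"):
        df[col] = _numeric(df, col, "MAG")
    for col in ("genome_size", "n_genes"):
        df[col] = _numeric(df, col, "MAG").astype(int)
    return [
        MAGRecord(
            mag_id=r.mag_id, site=r.site, completeness=r.completeness,
            contamination=r.contamination, genome_size=int(r.genome_size),
            gc=r.gc, n_genes=int(r.n_genes), coding_density=r.coding_density,
            taxonomy=r.taxonomy,
        )
        for r in df.itertuples()
    ]


def read_samples(path: str | Path) -> list[SampleRecord]:
    df = _read_tsv(path, SAMPLE_COLUMNS, "sample")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicate sample_id {dup!r}")
    df["library_size_gbp"] = _numeric(df, "library_size_gbp", "sample")
    env_cols = [c for c in df.columns if c not in SAMPLE_COLUMNS]
    for col in env_cols:
        df[col] = _numeric(df, col, "sample")
    records = []
    for r in df.itertuples():
        wq = getattr(r, "wq_category")
        wq = None if (wq is None or (isinstance(wq, float) and np.isnan(wq)) or wq == "") else wq
        env = {c: float(getattr(r, c)) for c in env_cols}
        records.append(
            SampleRecord(
                sample_id=r.sample_id, sample_type=r.sample_type, site=r.site,
                wq_category=wq, library_size_gbp=float(r.library_size_gbp), env=env,
            )
        )
    return records


def read_coverage(path: str | Path) -> pd.DataFrame:
    """Long-format coverage table; enforces the detection invariant
    mean_coverage = 0 implies covered_fraction = 0."""
    df = _read_tsv(path, COVERAGE_COLUMNS, "coverage")
    df["mean_coverage"] = _numeric(df, "mean_coverage", "coverage")
    df["covered_fraction"] = _numeric(df, "covered_fraction", "coverage")
    return validate_coverage(df)


def validate_coverage(df: pd.DataFrame) -> pd.DataFrame:
    if df.duplicated(subset=["mag_id", "sample_id"]).any():
        pair = df.loc[df.duplicated(subset=["mag_id", "sample_id"]), ["mag_id", "sample_id"]]
        raise SchemaError(f"duplicate (mag, sample) entry: {tuple(pair.iloc[0])}")
    if (df["mean_coverage"] < 0).any():
        raise SchemaError("mean_coverage must be >= 0")
    if ((df["covered_fraction"] < 0) | (df["covered_fraction"] > 1)).any():
        raise SchemaError("covered_fraction must lie in [0, 1]")
    bad = (df["mean_coverage"] == 0) & (df["covered_fraction"] > 0)
    if bad.any():
        row = df[bad].iloc[0]
        raise SchemaError(
            f"invariant violation for ({row.mag_id}, {row.sample_id}): "
            "mean_coverage = 0 requires covered_fraction = 0"
        )
    return df.reset_index(drop=True)


def read_annotations(path: str | Path, namespace: str) -> FeatureMatrix:
    """Wide annotation table: mag_id then one integer column per feature id."""
    df = _read_tsv(path, ["mag_id"], f"{namespace} annotation")
    if df["mag_id"].duplicated().any():
        raise SchemaError("duplicate mag_id in annotation table")
    counts = df.set_index("mag_id")
    for col in counts.columns:
        counts[col] = _numeric(counts, col, f"{namespace} annotation").astype(int)
    return FeatureMatrix(counts=counts, namespace=namespace)


def read_ani(path: str | Path) -> pd.DataFrame:
    """Square ANI matrix with mag_id row/column labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError("ANI matrix row and column labels differ")
    return df.astype(float)


def read_modules(path: str | Path) -> list[ModuleRow]:
    df = _read_tsv(path, MODULE_COLUMNS, "module")
    if df["module_id"].duplicated().any():
        raise SchemaError("duplicate module_id")
    return [ModuleRow(r.module_id, r.name, r.definition) for r in df.itertuples()]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV with deterministic column order and >= 10 significant digits."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=index, float_format="%.12g", na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df, path, index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)


def mags_to_frame(mags: Iterable[MAGRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(m) for m in mags], columns=MAG_COLUMNS)


def samples_to_frame(samples: Iterable[SampleRecord]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id, "sample_type": s.sample_type, "site": s.site,
            "wq_category": s.wq_category if s.wq_category is not None else "NA",
            "library_size_gbp": s.library_size_gbp,
        }
        row.update(s.env)
        rows.append(row)
    return pd.DataFrame(rows)


def write_manifest(outdir: str | Path, config: RunConfig, inputs: Mapping[str, str | Path],
                   seed: int | None = None) -> Path:
    """JSON run manifest (config hash, seed, input checksums) for reproducibility."""
    outdir = Path(outdir)
    cfg = dataclasses.asdict(config)
    checksums = {}
    for name, p in inputs.items():
        p = Path(p)
        if p.exists():
            checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed if seed is None else seed,
        "input_sha256": checksums,
    }
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def configure_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.WARNING if quiet else (logging.DEBUG if verbose else logging.INFO)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
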