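"""File dialects, run configuration, and domain containers.

Variant tables are held as :class:`pandas.DataFrame` objects with the fixed
column schema in :data:`VARIANT_COLUMNS`; nullable pandas dtypes keep a
missing annotation distinct from any numeric default (a blank MAX_AF cell is
*not* 0, and a blank DP cell is *not* a passing depth). Coverage histograms
from ``bedtools genomecov`` are reduced to a depth -> positions mapping per
sample. Run configuration carries the preset thresholds for the three study
designs: placental RNA-seq, circulating (cell-free) RNA, and WGS cell lines.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, FormatError

logger = logging.getLogger("pgin")

# ---------------------------------------------------------------------------
# Variant table schema
# ---------------------------------------------------------------------------

#: canonical column -> pandas dtype for the MAF-like variant table
VARIANT_COLUMNS: dict[str, str] = {
    "sample_id": "string",
    "chrom": "string",
    "pos": "Int64",
    "ref": "string",
    "alt": "string",
    "gene": "string",
    "classification": "string",
    "variant_type": "string",
    "dp": "Int64",
    "gq": "Float64",
    "qd": "Float64",
    "mq": "Float64",
    "read_pos_rank_sum": "Float64",
    "mq_rank_sum": "Float64",
    "fs": "Float64",
    "qual": "Float64",
    "max_af": "Float64",
    "polyphen": "string",
    "sift": "string",
    "clinvar_sig": "string",
    "alt_count": "Int64",
    "ref_count": "Int64",
    "context5": "string",
    "context3": "string",
    "rna_editing_site": "boolean",
    "low_complexity": "boolean",
    "common_variant": "boolean",
}

_NUMERIC_COLS = [c for c, t in VARIANT_COLUMNS.items() if t in ("Int64", "Float64")]
_BOOL_COLS = [c for c, t in VARIANT_COLUMNS.items() if t == "boolean"]
_REQUIRED_COLS = list(VARIANT_COLUMNS)

CLASSIFICATIONS = ("missense", "nonsense", "nonstop", "frameshift", "splice", "silent", "other")
VARIANT_TYPES = ("SNV", "INS", "DEL")


@dataclass
class VariantRecord:
    """One annotated somatic call; scalar view of a variant-table row.

    Missing annotations are ``None``. ``pos`` is 1-based inclusive.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    classification: str = "other"
    variant_type: str = "SNV"
    dp: int | None = None
    gq: float | None = None
    qd: float | None = None
    mq: float | None = None
    read_pos_rank_sum: float | None = None
    mq_rank_sum: float | None = None
    fs: float | None = None
    qual: float | None = None
    max_af: float | None = None
    polyphen: str | None = None
    sift: str | None = None
    clinvar_sig: str | None = None
    alt_count: int | None = None
    ref_count: int | None = None
    context5: str | None = None
    context3: str | None = None
    rna_editing_site: bool = False
    low_complexity: bool = False
    common_variant: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.max_af is not None and not (0.0 <= self.max_af <= 1.0):
            raise ValueError(f"max_af must be in [0,1], got {self.max_af}")
        if (
            self.dp is not None
            and self.alt_count is not None
            and self.ref_count is not None
            and self.alt_count + self.ref_count > self.dp
        ):
            raise ValueError("alt_count + ref_count exceeds dp")
        is_snv = len(self.ref) == 1 and len(self.alt) == 1
        if (self.variant_type == "SNV") != is_snv:
            raise ValueError(
                f"variant_type {self.variant_type} inconsistent with alleles {self.ref}>{self.alt}"
            )


def records_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Assemble VariantRecord objects into a schema-typed DataFrame."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))
    return _coerce_schema(df)


def frame_to_records(df: pd.DataFrame) -> list[VariantRecord]:
    out = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for col in VARIANT_COLUMNS:
            v = getattr(row, col)
            if pd.isna(v):
                v = False if col in _BOOL_COLS else None
            elif VARIANT_COLUMNS[col] == "Int64":
                v = int(v)
            kwargs[col] = v
        out.append(VariantRecord(**kwargs))
    return out


def _coerce_schema(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col, dtype in VARIANT_COLUMNS.items():
        if col not in df.columns:
            df[col] = pd.NA
        df[col] = df[col].astype(dtype)
    for col in _BOOL_COLS:
        df[col] = df[col].fillna(False).astype("boolean")
    return df[list(VARIANT_COLUMNS)]


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def read_variant_table(
    path: str | Path,
    dialect: str = "maf_like",
    column_map: Mapping[str, str] | str | Path | None = None,
) -> pd.DataFrame:
    """Read an annotated somatic variant table.

    Parameters
    ----------
    path
        TSV (``maf_like``) or single-sample VCF 4.2 (``minimal_vcf``).
    dialect
        ``maf_like`` or ``minimal_vcf``.
    column_map
        Optional mapping from the file's header names to the canonical
        schema names (or a YAML file containing one); lets real MAF exports
        with divergent headers be consumed without rewriting them.

    Returns
    -------
    DataFrame with one row per (sample, site, alt) and the
    :data:`VARIANT_COLUMNS` schema. Blank annotation cells become pandas
    missing values — never silently a default.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"variant table not found: {path}")
    if dialect == "maf_like":
        return _read_maf_like(path, column_map)
    if dialect == "minimal_vcf":
        return _read_minimal_vcf(path)
    raise FormatError(f"unknown variant-table dialect: {dialect!r}")


def _read_maf_like(path: Path, column_map) -> pd.DataFrame:
    if isinstance(column_map, (str, Path)):
        with open(column_map) as fh:
            column_map = yaml.safe_load(fh) or {}
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in _REQUIRED_COLS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: malformed header, missing column(s): {', '.join(missing)}")
    df = raw[_REQUIRED_COLS].copy()
    df = df.replace({"": pd.NA, ".": pd.NA, "NA": pd.NA, "missing": pd.NA})
    for col in _NUMERIC_COLS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise FormatError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} at line {line}"
            )
        df[col] = converted
    for col in _BOOL_COLS:
        vals = df[col].astype("string").str.lower()
        unknown = ~(vals.isin(_TRUE | _FALSE) | vals.isna())
        if unknown.any():
            line = int(np.flatnonzero(unknown.to_numpy())[0]) + 2
            raise FormatError(f"{path}: non-boolean value in column {col!r} at line {line}")
        df[col] = vals.isin(_TRUE)
    out = _coerce_schema(df)
    logger.info("read %d variant records from %s", len(out), path)
    return out


# INFO keys used by the minimal single-sample VCF dialect
_VCF_INFO_KEYS = {
    "GENE": "gene",
    "CLASS": "classification",
    "VTYPE": "variant_type",
    "QD": "qd",
    "MQ": "mq",
    "ReadPosRankSum": "read_pos_rank_sum",
    "MQRankSum": "mq_rank_sum",
    "FS": "fs",
    "MAX_AF": "max_af",
    "PolyPhen": "polyphen",
    "SIFT": "sift",
    "CLIN_SIG": "clinvar_sig",
    "C5": "context5",
    "C3": "context3",
}
_VCF_FLAG_KEYS = {
    "RNA_EDIT": "rna_editing_site",
    "LOWCOMPLEX": "low_complexity",
    "COMMON": "common_variant",
}


def _read_minimal_vcf(path: Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise FormatError(f"{path}: minimal_vcf dialect expects exactly one sample")
        sample = samples[0]
        for rec in vcf:
            for alt in rec.alts or ():
                row: dict[str, object] = {
                    "sample_id": sample,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "qual": rec.qual,
                }
                info = dict(rec.info)
                for key, col in _VCF_INFO_KEYS.items():
                    if key in info:
                        v = info[key]
                        if isinstance(v, tuple):
                            v = v[0]
                        row[col] = v
                for key, col in _VCF_FLAG_KEYS.items():
                    row[col] = key in info
                fmt = rec.samples[sample]
                if fmt.get("DP") is not None:
                    row["dp"] = fmt["DP"]
                if fmt.get("GQ") is not None:
                    row["gq"] = fmt["GQ"]
                ad = fmt.get("AD")
                if ad is not None and len(ad) >= 2 and ad[0] is not None:
                    row["ref_count"], row["alt_count"] = int(ad[0]), int(ad[1])
                if "variant_type" not in row:
                    row["variant_type"] = (
                        "SNV"
                        if len(rec.ref) == len(alt) == 1
                        else ("INS" if len(alt) > len(rec.ref) else "DEL")
                    )
                rows.append(row)
    df = pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))
    return _coerce_schema(df)


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a schema DataFrame as MAF-like TSV; missing cells stay blank."""
    out = df.copy()
    for col in _BOOL_COLS:
        out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Coverage histograms
# ---------------------------------------------------------------------------


@dataclass
class CoverageProfile:
    """Per-sample genome coverage as an exact depth -> positions histogram."""

    sample_id: str
    depth_hist: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d, c in self.depth_hist.items():
            if d < 0 or c < 0:
                raise FormatError(f"negative depth or count in histogram: ({d}, {c})")

    def total_positions(self) -> int:
        return int(sum(self.depth_hist.values()))


def read_coverage(path: str | Path, sample_id: str | None = None) -> CoverageProfile:
    """Parse a ``bedtools genomecov`` histogram.

    Accepts either the default 5-column output (feature, depth, count,
    feature_size, fraction) or a bare 2-column (depth, count) table.
    When genome-wide rows (feature ``genome``) are present they are used;
    otherwise per-contig rows are summed per depth. Duplicate depth rows
    are summed.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if raw.shape[1] >= 4:
        sub = raw[raw[0] == "genome"]
        if sub.empty:
            sub = raw
        depths = pd.to_numeric(sub[1], errors="raise").astype(int)
        counts = pd.to_numeric(sub[2], errors="raise").astype(int)
    elif raw.shape[1] == 2:
        depths = pd.to_numeric(raw[0], errors="raise").astype(int)
        counts = pd.to_numeric(raw[1], errors="raise").astype(int)
    else:
        raise FormatError(f"{path}: unrecognized coverage dialect ({raw.shape[1]} columns)")
    if (depths < 0).any() or (counts < 0).any():
        raise FormatError(f"{path}: negative depth or count")
    hist: dict[int, int] = {}
    for d, c in zip(depths.tolist(), counts.tolist()):
        hist[d] = hist.get(d, 0) + c
    return CoverageProfile(sample_id=sample_id or path.stem, depth_hist=hist)


def write_coverage(profile: CoverageProfile, path: str | Path) -> None:
    """Write a genomecov-style histogram (genome-wide rows only)."""
    total = profile.total_positions()
    with open(path, "w") as fh:
        for depth in sorted(profile.depth_hist):
            count = profile.depth_hist[depth]
            frac = count / total if total else 0.0
            fh.write(f"genome\t{depth}\t{count}\t{total}\t{frac:.7g}\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: preset -> threshold overrides for the three study designs
PRESETS: dict[str, dict[str, object]] = {
    # placental villous RNA-seq: burden denominator at 50x capture
    "placental_rna": {"burden_depth_threshold": 50},
    # circulating cell-free RNA: shallower, burden at 10x
    "circulating_rna": {"burden_depth_threshold": 10},
    # WGS trophoblast cell lines: depth > 30 and a tighter 33% recurrence
    # cut; the gene-level recurrence filter is not part of this design,
    # so its threshold is set to 1.0 (never triggered).
    "wgs_cell_line": {
        "burden_depth_threshold": 30,
        "variant_recurrence_max": 0.33,
        "gene_recurrence_max": 1.0,
    },
}


@dataclass
class RunConfig:
    """Thresholds and switches for one pipeline run.

    Defaults are the placental RNA-seq design; presets override the fields
    they own and any explicitly configured field wins over the preset.
    """

    preset: str = "placental_rna"
    burden_depth_threshold: int = 50
    rare_af_threshold: float = 0.01
    variant_recurrence_max: float = 0.70
    gene_recurrence_max: float = 0.50
    damaging_rule: str = "union"  # or "intersection"
    missing_af_is_rare: bool = True
    strict_missing_quality: bool = False
    include_indels_in_burden: bool = True
    hypoxia_tie_score: int = -1  # score at exact median ties; 0 also allowed
    seed: int = 0
    signature_rank: int = 3
    nmf_restarts: int = 10
    knn_neighbors: int = 5
    standardize_features: bool = False
    hypoxia_signature_paths: list[str] = field(default_factory=list)
    reference_signature_path: str | None = None

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ConfigError(
                f"unknown preset {self.preset!r}; expected one of {sorted(PRESETS)}"
            )
        if self.burden_depth_threshold <= 0:
            raise ConfigError("burden_depth_threshold must be positive")
        for name in ("rare_af_threshold", "variant_recurrence_max", "gene_recurrence_max"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.damaging_rule not in ("union", "intersection"):
            raise ConfigError(f"damaging_rule must be union or intersection, got {self.damaging_rule!r}")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML key/value file plus keyword overrides.

    Precedence: explicit file/keyword values > preset values > defaults.
    """
    data: dict[str, object] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update(overrides)
    preset = str(data.get("preset", "placental_rna"))
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}")
    merged = dict(PRESETS[preset])
    merged.update(data)
    merged["preset"] = preset
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(merged) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**merged)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Expression / metadata / gene-set files
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV, first column gene symbol (unique)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene symbol {dup!r}")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Cohort metadata CSV indexed by sample_id."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata must have a sample_id column")
    return df.set_index("sample_id")


def read_gene_signatures(path: str | Path) -> "list":
    """Two-column TSV (signature name, gene symbol) -> GeneSignature list."""
    from .hypoxia import GeneSignature

    df = pd.read_csv(path, sep="\t", header=None, names=["signature", "gene"], comment="#")
    out = []
    for name, sub in df.groupby("signature", sort=False):
        out.append(GeneSignature(name=str(name), genes=list(dict.fromkeys(sub["gene"]))))
    return out


def setup_logging(verbose: bool = True) -> None:
    """Route pipeline logs to stderr with per-stage record counts."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[pgin] %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
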