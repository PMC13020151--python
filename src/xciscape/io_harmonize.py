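"""Input tables, allelic-expression arithmetic, and single-cell harmonization.

Allelic expression (AE) is defined from read counts at heterozygous sites as

    AE = |0.5 - ref_reads / total_reads|

so AE = 0 means perfectly biallelic expression and AE = 0.5 fully monoallelic
expression. Downstream analyses visualize and model the complementary scale
1 - AE in [0.5, 1], where values >= 0.6 indicate biallelic expression, i.e.
escape from X chromosome inactivation in a skewed-XCI female.

Single-cell allelic measures arrive on three different scales (Xi/total,
Xa/total, Xi/Xa); :func:`harmonize_xi_fraction` maps them all onto the
common Xi/total fraction.

Coordinate convention: every interval is stored internally as 0-based
half-open. BED input is read as-is; 1-based inclusive annotation input
(biomaRt-style start/end) is shifted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ParBoundaries

_AE_TOL = 1e-9

VALID_SOURCE_SCALES = ("ae", "xi_over_total", "xa_over_total", "xi_over_xa")
VALID_REGIONS = ("PAR1", "PAR2", "NPX")


class TableSchemaError(ValueError):
    """A required column is missing or the file layout is unusable."""


class RowValidationError(ValueError):
    """One or more data rows violated a domain constraint.

    Collects every offending row (1-based line numbers counting the header)
    instead of stopping at the first, so a malformed file is reported once.
    """

    def __init__(self, path: str, errors: Sequence[tuple[int, str]]):
        self.path = str(path)
        self.errors = list(errors)
        preview = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{self.path}: {len(self.errors)} invalid row(s): {preview}{more}")


# ---------------------------------------------------------------------------
# Allelic-expression arithmetic
# ---------------------------------------------------------------------------

def compute_ae(ref_reads, total_reads):
    """Allelic expression |0.5 - ref_reads/total_reads|.

    Accepts scalars or array-likes (broadcast together). Values are validated:
    total_reads must be >= 1 and 0 <= ref_reads <= total_reads.
    """
    ref = np.asarray(ref_reads, dtype=float)
    tot = np.asarray(total_reads, dtype=float)
    if np.any(tot < 1):
        raise ValueError("total_reads must be >= 1")
    if np.any(ref < 0):
        raise ValueError("ref_reads must be non-negative")
    if np.any(ref > tot):
        raise ValueError("ref_reads may not exceed total_reads")
    ae = np.abs(0.5 - ref / tot)
    if ae.ndim == 0:
        return float(ae)
    return ae


def to_escape_scale(ae):
    """Map AE in [0, 0.5] to the 1-AE escape scale in [0.5, 1]."""
    a = np.asarray(ae, dtype=float)
    if np.any((a < -_AE_TOL) | (a > 0.5 + _AE_TOL)):
        raise ValueError("ae must lie in [0, 0.5]")
    out = 1.0 - a
    if out.ndim == 0:
        return float(out)
    return out


def harmonize_xi_fraction(value: float, source_scale: str) -> float:
    """Convert a single-cell allelic measure to the Xi/total fraction.

    xi_over_total values pass through; xa_over_total maps to 1 - value;
    an Xi/Xa ratio r maps to r / (1 + r). Result lies in [0, 1].
    """
    if source_scale not in ("xi_over_total", "xa_over_total", "xi_over_xa"):
        raise ValueError(f"unknown source scale {source_scale!r}")
    v = float(value)
    if source_scale == "xi_over_xa":
        if v < 0:
            raise ValueError(f"Xi/Xa ratio must be non-negative, got {v}")
        if math.isinf(v):
            return 1.0
        return v / (1.0 + v)
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{source_scale} fraction must lie in [0, 1], got {v}")
    if source_scale == "xa_over_total":
        return 1.0 - v
    return v


def xi_fraction_to_ae(xi_fraction: float) -> float:
    """AE implied by an Xi/total fraction: |0.5 - xi_fraction|, capped at 0.5.

    Xi/total can exceed 0.5 in noisy single-cell estimates (apparent
    over-expression from the inactive X); the AE scale folds such values.
    """
    f = float(xi_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"Xi/total fraction must lie in [0, 1], got {f}")
    return abs(0.5 - f)


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass
class AllelicObservation:
    """One gene x tissue x individual (x sample) allelic-expression measurement."""

    gene_id: str
    tissue: str
    individual: str
    ae: float
    sample_id: str | None = None
    ref_reads: int | None = None
    total_reads: int | None = None
    source_scale: str = "ae"

    def __post_init__(self) -> None:
        if self.source_scale not in VALID_SOURCE_SCALES:
            raise ValueError(f"unknown source_scale {self.source_scale!r}")
        if not 0.0 - _AE_TOL <= self.ae <= 0.5 + _AE_TOL:
            raise ValueError(f"ae must lie in [0, 0.5], got {self.ae}")
        if (self.ref_reads is None) != (self.total_reads is None):
            raise ValueError("ref_reads and total_reads must be given together")
        if self.ref_reads is not None:
            expected = compute_ae(self.ref_reads, self.total_reads)
            if abs(expected - self.ae) > _AE_TOL:
                raise ValueError(
                    f"ae={self.ae} inconsistent with counts "
                    f"{self.ref_reads}/{self.total_reads} (expect {expected})"
                )

    @property
    def one_minus_ae(self) -> float:
        return 1.0 - self.ae


@dataclass
class GeneAnnotation:
    """Gene interval (0-based half-open) with its region class."""

    gene_id: str
    start: int
    end: int
    region: str
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.region not in VALID_REGIONS:
            raise ValueError(f"{self.gene_id}: unknown region {self.region!r}")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SexBiasRecord:
    """Per gene x tissue shrunken sex effect (beta_mash) with its LFSR."""

    gene_id: str
    tissue: str
    beta_mash: float
    lfsr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lfsr <= 1.0:
            raise ValueError(f"lfsr must lie in [0, 1], got {self.lfsr}")


@dataclass
class TADInterval:
    """A topologically associating domain with its genomic-order rank."""

    tad_id: str
    start: int
    end: int
    rank: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.tad_id}: start {self.start} >= end {self.end}")
        if self.rank < 1:
            raise ValueError(f"{self.tad_id}: rank must be positive")


@dataclass
class ARERecord:
    """A sex-biased active regulatory element with its nearest gene."""

    element_id: str
    start: int
    end: int
    tissue: str
    sex_effect: float
    p_adj: float
    nearest_gene: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.element_id}: start {self.start} >= end {self.end}")
        if not 0.0 <= self.p_adj <= 1.0:
            raise ValueError(f"p_adj must lie in [0, 1], got {self.p_adj}")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_observations(
    records: pd.DataFrame | Iterable[AllelicObservation],
    level: str = "mean_per_gene_tissue",
) -> pd.DataFrame:
    """Collapse allelic observations to the requested analysis level.

    level='sample' is the identity; level='mean_per_gene_tissue' returns one
    row per (gene_id, tissue) with ae equal to the arithmetic mean over all
    individuals/samples. A 'level' provenance column records which was used.
    """
    df = _as_ae_frame(records)
    if level == "sample":
        out = df.copy()
    elif level == "mean_per_gene_tissue":
        if df.empty:
            out = pd.DataFrame(columns=["gene_id", "tissue", "ae", "n_obs"])
        else:
            out = (
                df.groupby(["gene_id", "tissue"], sort=True)["ae"]
                .agg(["mean", "size"])
                .reset_index()
                .rename(columns={"mean": "ae", "size": "n_obs"})
            )
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    out = out.copy()
    out["level"] = level
    return out


def _as_ae_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        {
            "gene_id": r.gene_id,
            "tissue": r.tissue,
            "individual": r.individual,
            "sample_id": r.sample_id,
            "ae": r.ae,
        }
        for r in records
    ]
    if not rows:
        return pd.DataFrame(columns=["gene_id", "tissue", "individual", "sample_id", "ae"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

#: Default column layouts; override any entry via the ``columns`` argument or a
#: YAML schema config mapping canonical names to the file's actual headers.
DEFAULT_COLUMNS = {
    "ae": {
        "gene_id": "gene_id",
        "tissue": "tissue",
        "individual": "individual",
        "sample_id": "sample_id",
        "ae": "ae",
        "ref_reads": "ref_reads",
        "total_reads": "total_reads",
    },
    "sexbias": {
        "gene_id": "gene_id",
        "tissue": "tissue",
        "beta_mash": "beta_mash",
        "lfsr": "lfsr",
        "mean_expression": "mean_expression",
    },
    "are": {
        "element_id": "element_id",
        "start": "start",
        "end": "end",
        "tissue": "tissue",
        "sex_effect": "sex_effect",
        "p_adj": "p_adj",
        "nearest_gene": "nearest_gene",
    },
    "annotation": {
        "gene_id": "gene_id",
        "start": "start",
        "end": "end",
        "region": "region",
        "strand": "strand",
    },
}


def _read_tsv(path, required: Sequence[str], columns: dict[str, str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {v: k for k, v in columns.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableSchemaError(
            f"{path}: missing required column(s) {missing}; present: {list(df.columns)}"
        )
    return df


def _coerce_float(df, col, errors, optional=False):
    out = np.full(len(df), np.nan)
    if col not in df.columns:
        return out
    for i, raw in enumerate(df[col]):
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
            if not optional:
                errors.append((i + 2, f"missing value in column {col!r}"))
            continue
        try:
            out[i] = float(raw)
        except (TypeError, ValueError):
            errors.append((i + 2, f"unparseable numeric {raw!r} in column {col!r}"))
    return out


def read_ae_table(path, columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a gene x tissue x individual allelic-expression TSV.

    Each row must carry an AE value and/or a ref/total read-count pair; when
    both are present they must agree. Rows violating the AE domain [0, 0.5]
    are collected into a :class:`RowValidationError` with line numbers.
    """
    cols = {**DEFAULT_COLUMNS["ae"], **(columns or {})}
    df = _read_tsv(path, ["gene_id", "tissue", "individual"], cols)
    errors: list[tuple[int, str]] = []
    ae = _coerce_float(df, "ae", errors, optional=True)
    ref = _coerce_float(df, "ref_reads", errors, optional=True)
    tot = _coerce_float(df, "total_reads", errors, optional=True)
    for i in range(len(df)):
        line = i + 2
        has_ae = not math.isnan(ae[i])
        has_counts = not math.isnan(ref[i]) and not math.isnan(tot[i])
        if not has_ae and not has_counts:
            errors.append((line, "row has neither an ae value nor read counts"))
            continue
        if has_counts:
            if tot[i] < 1:
                errors.append((line, f"total_reads must be >= 1, got {tot[i]:g}"))
                continue
            if not 0 <= ref[i] <= tot[i]:
                errors.append((line, f"ref_reads {ref[i]:g} outside [0, total_reads]"))
                continue
            derived = abs(0.5 - ref[i] / tot[i])
            if has_ae and abs(derived - ae[i]) > 1e-6:
                errors.append(
                    (line, f"ae={ae[i]:g} inconsistent with counts {ref[i]:g}/{tot[i]:g}")
                )
                continue
            ae[i] = derived
        if not -_AE_TOL <= ae[i] <= 0.5 + _AE_TOL:
            errors.append((line, f"ae={ae[i]:g} outside [0, 0.5]"))
    if errors:
        raise RowValidationError(path, errors)
    out = df[["gene_id", "tissue", "individual"]].copy()
    out["sample_id"] = df["sample_id"] if "sample_id" in df.columns else None
    out["ae"] = ae
    out["one_minus_ae"] = 1.0 - out["ae"]
    return out


def read_sexbias_table(path, columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a gene x tissue sex-bias TSV (beta_mash, lfsr, optional mean expression)."""
    cols = {**DEFAULT_COLUMNS["sexbias"], **(columns or {})}
    df = _read_tsv(path, ["gene_id", "tissue", "beta_mash", "lfsr"], cols)
    errors: list[tuple[int, str]] = []
    beta = _coerce_float(df, "beta_mash", errors)
    lfsr = _coerce_float(df, "lfsr", errors)
    expr = _coerce_float(df, "mean_expression", errors, optional=True)
    for i in range(len(df)):
        if not math.isnan(lfsr[i]) and not 0.0 <= lfsr[i] <= 1.0:
            errors.append((i + 2, f"lfsr={lfsr[i]:g} outside [0, 1]"))
    if errors:
        raise RowValidationError(path, errors)
    out = df[["gene_id", "tissue"]].copy()
    out["beta_mash"] = beta
    out["lfsr"] = lfsr
    if "mean_expression" in df.columns:
        out["mean_expression"] = expr
    return out


def read_are_table(path, columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an active-regulatory-element TSV with nearest-gene annotation."""
    cols = {**DEFAULT_COLUMNS["are"], **(columns or {})}
    df = _read_tsv(
        path, ["element_id", "start", "end", "tissue", "sex_effect", "p_adj", "nearest_gene"], cols
    )
    errors: list[tuple[int, str]] = []
    start = _coerce_float(df, "start", errors)
    end = _coerce_float(df, "end", errors)
    effect = _coerce_float(df, "sex_effect", errors)
    p_adj = _coerce_float(df, "p_adj", errors)
    for i in range(len(df)):
        line = i + 2
        if not math.isnan(start[i]) and not math.isnan(end[i]) and start[i] >= end[i]:
            errors.append((line, f"start {start[i]:g} >= end {end[i]:g}"))
        if not math.isnan(p_adj[i]) and not 0.0 <= p_adj[i] <= 1.0:
            errors.append((line, f"p_adj={p_adj[i]:g} outside [0, 1]"))
    if errors:
        raise RowValidationError(path, errors)
    out = df[["element_id", "tissue", "nearest_gene"]].copy()
    out["start"] = start.astype(int)
    out["end"] = end.astype(int)
    out["sex_effect"] = effect
    out["p_adj"] = p_adj
    return out


def read_tad_bed(path) -> pd.DataFrame:
    """Read a 3-column BED of TAD intervals (0-based half-open, as in BED).

    Returns a frame with tad_id, start, end and a genomic-order rank
    (1..N by start position).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    errors: list[tuple[int, str]] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableSchemaError(f"{path}: line {ln}: expected >= 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                errors.append((ln, f"unparseable coordinates {parts[1]!r}/{parts[2]!r}"))
                continue
            if start >= end:
                raise TableSchemaError(f"{path}: line {ln}: start {start} >= end {end}")
            rows.append({"chrom": chrom, "start": start, "end": end})
    if errors:
        raise RowValidationError(path, errors)
    df = pd.DataFrame(rows)
    if df.empty:
        raise TableSchemaError(f"{path}: no TAD intervals found")
    df = df.sort_values(["start", "end"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["tad_id"] = [f"TAD{r:03d}" for r in df["rank"]]
    return df[["tad_id", "chrom", "start", "end", "rank"]]


def read_gene_annotation(
    path,
    columns: dict[str, str] | None = None,
    boundaries: ParBoundaries | None = None,
    one_based: bool = True,
) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, start, end[, region, strand]).

    Input coordinates are 1-based inclusive by default (biomaRt convention)
    and shifted to the internal 0-based half-open convention on read. When no
    region column is present, the region class is computed from the interval
    midpoint and the PAR boundary configuration.
    """
    cols = {**DEFAULT_COLUMNS["annotation"], **(columns or {})}
    df = _read_tsv(path, ["gene_id", "start", "end"], cols)
    errors: list[tuple[int, str]] = []
    start = _coerce_float(df, "start", errors)
    end = _coerce_float(df, "end", errors)
    if errors:
        raise RowValidationError(path, errors)
    start = start.astype(int)
    end = end.astype(int)
    if one_based:
        start = start - 1
    bad = np.nonzero(start >= end)[0]
    if bad.size:
        raise RowValidationError(
            path, [(int(i) + 2, f"start >= end after convention shift") for i in bad]
        )
    out = df[["gene_id"]].copy()
    out["start"] = start
    out["end"] = end
    if "region" in df.columns:
        out["region"] = df["region"]
        unknown = set(out["region"]) - set(VALID_REGIONS)
        if unknown:
            raise RowValidationError(
                path,
                [
                    (int(i) + 2, f"unknown region {r!r}")
                    for i, r in out["region"].items()
                    if r in unknown
                ],
            )
    else:
        b = boundaries or ParBoundaries()
        out["region"] = [b.region_of(s, e) for s, e in zip(out["start"], out["end"])]
    out["strand"] = df["strand"] if "strand" in df.columns else "unknown"
    return out
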