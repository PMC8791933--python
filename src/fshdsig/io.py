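"""Domain types and text-format readers/writers.

The pipeline's shared vocabulary: a gene-by-sample :class:`CountMatrix` with an
explicit scale tag, per-biopsy clinical/imaging metadata records
(:class:`BiopsyMetadata`), and the signature gene lists
(:class:`SignatureGeneSets`).

All on-disk formats are plain text: counts and metadata are tab-separated
tables with ``NA`` marking missing values, gene sets are GMT lines or
one-symbol-per-line files.  Gene identity is an exact, case-sensitive symbol
match; no alias resolution is attempted.  Matrices are always genes-in-rows —
a transposed input is rejected rather than auto-detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "BiopsyMetadata",
    "SignatureGeneSets",
    "SignatureScores",
    "ValidationError",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "metadata_frame",
    "read_gene_sets",
    "write_gene_sets",
    "read_gene_list",
]

#: Recognised scales for a count matrix.
SCALES = ("raw", "size_factor_normalized", "log10p1", "quantile_normalized")

#: Scales on which values must be non-negative counts/intensities.
_NONNEG_SCALES = ("raw", "size_factor_normalized")


class ValidationError(ValueError):
    """An input violates a documented invariant."""


@dataclass
class CountMatrix:
    """Gene-by-sample expression table with an explicit scale tag.

    Parameters
    ----------
    values
        DataFrame with gene symbols as the index and biopsy/sample
        identifiers as columns.
    scale
        One of ``raw``, ``size_factor_normalized``, ``log10p1``,
        ``quantile_normalized``.
    """

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate gene symbols: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("count matrix body must be numeric")
        if np.isnan(arr).any():
            raise ValidationError("count matrix contains missing values")
        if self.scale in _NONNEG_SCALES and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at gene {idx[g]!r}, sample {cols[s]!r} on scale {self.scale!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: str) -> "CountMatrix":
        """Return a new matrix with the same validation applied."""
        return CountMatrix(values=values, scale=scale)


# ---------------------------------------------------------------------------
# Biopsy metadata
# ---------------------------------------------------------------------------

#: Canonical metadata column order for the tab-separated representation.
METADATA_COLUMNS = [
    "biopsy_id",
    "participant_id",
    "group",
    "muscle",
    "tirm",
    "fat_fraction",
    "histology_sum",
    "inflammation",
    "mrc",
    "age",
    "sex",
    "bmi",
    "css",
    "disease_duration",
    "age_at_onset",
    "d4z4_units",
    "six_mwt",
    "mfm",
    "replicate_pair",
]

_FLOAT_FIELDS = {"fat_fraction", "mrc", "age", "bmi", "disease_duration", "age_at_onset", "six_mwt", "mfm"}
_INT_FIELDS = {"histology_sum", "inflammation", "css", "d4z4_units"}


@dataclass
class BiopsyMetadata:
    """Clinical, imaging and histology fields for one muscle biopsy.

    ``None`` marks a missing value (written as ``NA`` on disk); missing is
    distinct from zero throughout.  Fields ending in a unit note: fat_fraction
    is a percentage (0-100), mrc is the 0-5 Medical Research Council strength
    grade in 0.5 steps, css the 10-grade Ricci clinical severity score,
    six_mwt the six-minute walking distance in meters and mfm the Motor
    Function Measure as a fraction of the maximum score.
    """

    biopsy_id: str
    participant_id: str
    group: str
    muscle: str
    tirm: str | None = None
    fat_fraction: float | None = None
    histology_sum: int | None = None
    inflammation: int | None = None
    mrc: float | None = None
    age: float | None = None
    sex: str | None = None
    bmi: float | None = None
    css: int | None = None
    disease_duration: float | None = None
    age_at_onset: float | None = None
    d4z4_units: int | None = None
    six_mwt: float | None = None
    mfm: float | None = None
    replicate_pair: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("CTRL", "FSHD"):
            raise ValidationError(f"{self.biopsy_id}: group must be CTRL or FSHD, got {self.group!r}")
        if self.muscle not in ("VL", "TA"):
            raise ValidationError(f"{self.biopsy_id}: muscle must be VL or TA, got {self.muscle!r}")
        if self.tirm is not None and self.tirm not in ("POS", "NEG"):
            raise ValidationError(f"{self.biopsy_id}: tirm must be POS/NEG/missing, got {self.tirm!r}")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValidationError(f"{self.biopsy_id}: sex must be M or F, got {self.sex!r}")
        if self.fat_fraction is not None and not (0 <= self.fat_fraction <= 100):
            raise ValidationError(f"{self.biopsy_id}: fat_fraction {self.fat_fraction} outside [0, 100]")
        if self.histology_sum is not None and not (0 <= self.histology_sum <= 12):
            raise ValidationError(f"{self.biopsy_id}: histology_sum {self.histology_sum} outside [0, 12]")
        if self.css is not None and not (0 <= self.css <= 10):
            raise ValidationError(f"{self.biopsy_id}: css {self.css} outside [0, 10]")
        if self.inflammation is not None and self.inflammation < 0:
            raise ValidationError(f"{self.biopsy_id}: inflammation must be >= 0")
        if self.mrc is not None:
            if not (0 <= self.mrc <= 5) or round(self.mrc * 2) != self.mrc * 2:
                raise ValidationError(f"{self.biopsy_id}: mrc {self.mrc} not a 0-5 grade in 0.5 steps")
        if self.mfm is not None and not (0 <= self.mfm <= 1):
            raise ValidationError(f"{self.biopsy_id}: mfm {self.mfm} outside [0, 1]")


def _validate_metadata_collection(records: Sequence[BiopsyMetadata]) -> None:
    ids = [r.biopsy_id for r in records]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate biopsy ids: {dups}")
    seen: dict[tuple[str, str], BiopsyMetadata] = {}
    for r in records:
        key = (r.participant_id, r.muscle)
        if key in seen and not (r.replicate_pair and seen[key].replicate_pair):
            raise ValidationError(
                f"participant {r.participant_id} has two {r.muscle} biopsies not flagged as a replicate pair"
            )
        seen[key] = r


@dataclass
class SignatureGeneSets:
    """The DUX4 target list and the PAX7 induced/repressed target lists."""

    dux4_targets: frozenset[str]
    pax7_induced: frozenset[str]
    pax7_repressed: frozenset[str]

    def __post_init__(self) -> None:
        self.dux4_targets = frozenset(self.dux4_targets)
        self.pax7_induced = frozenset(self.pax7_induced)
        self.pax7_repressed = frozenset(self.pax7_repressed)
        for name, s in (
            ("dux4_targets", self.dux4_targets),
            ("pax7_induced", self.pax7_induced),
            ("pax7_repressed", self.pax7_repressed),
        ):
            if not s:
                raise ValidationError(f"gene set {name} is empty")
        overlap = self.pax7_induced & self.pax7_repressed
        if overlap:
            raise ValidationError(
                f"genes present in both PAX7 induced and repressed lists: {sorted(overlap)}"
            )


@dataclass
class SignatureScores:
    """Per-biopsy signature scores and class labels."""

    biopsy_id: str
    dux4_score: float
    dux4_log: float
    dux4_class: str
    pax7_score: float | None = None
    pax7_class: str | None = None

    def __post_init__(self) -> None:
        if self.dux4_score < 0:
            raise ValidationError(f"{self.biopsy_id}: dux4_score must be >= 0")
        if not np.isclose(self.dux4_log, np.log10(self.dux4_score + 1)):
            raise ValidationError(f"{self.biopsy_id}: dux4_log is not log10(dux4_score + 1)")
        if self.dux4_class not in ("POS", "NEG"):
            raise ValidationError(f"{self.biopsy_id}: dux4_class must be POS or NEG")
        if self.pax7_class is not None and self.pax7_class not in ("HIGH", "LOW", "UNCLASSIFIED"):
            raise ValidationError(f"{self.biopsy_id}: bad pax7_class {self.pax7_class!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, delimiter: str = "\t") -> CountMatrix:
    """Read a raw gene-by-sample count table from a delimited text file.

    The first column holds gene symbols, the header row sample identifiers.
    Malformed numeric cells are reported with their gene and sample; duplicate
    identifiers and negative counts are rejected.
    """
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    raw.columns.name = None
    body = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad][0]
            raise ValidationError(
                f"{path}: malformed numeric cell at gene {gene!r}, sample {col!r}: {raw.loc[gene, col]!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna()][0]
            raise ValidationError(f"{path}: empty cell at gene {gene!r}, sample {col!r}")
        body[col] = converted
    return CountMatrix(values=body, scale="raw")


def write_counts(cm: CountMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a count matrix as delimited text (genes in rows)."""
    cm.values.to_csv(path, sep=delimiter, index_label="gene")


def _parse_field(name: str, text: str, biopsy_id: str):
    if text == "NA" or text == "":
        return None
    if name in _FLOAT_FIELDS:
        try:
            return float(text)
        except ValueError:
            raise ValidationError(f"{biopsy_id}: field {name} not numeric: {text!r}") from None
    if name in _INT_FIELDS:
        try:
            f = float(text)
        except ValueError:
            raise ValidationError(f"{biopsy_id}: field {name} not numeric: {text!r}") from None
        if f != int(f):
            raise ValidationError(f"{biopsy_id}: field {name} must be an integer: {text!r}")
        return int(f)
    if name == "replicate_pair":
        return text.lower() in ("1", "true", "yes")
    return text


def read_metadata(path: str | Path, delimiter: str = "\t") -> list[BiopsyMetadata]:
    """Read per-biopsy metadata records from a tab-separated table.

    Columns outside the documented schema are preserved in ``extras``.
    ``NA`` marks a missing value.
    """
    table = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    known = set(METADATA_COLUMNS)
    for required in ("biopsy_id", "participant_id", "group", "muscle"):
        if required not in table.columns:
            raise ValidationError(f"{path}: missing required column {required!r}")
    records = []
    for _, row in table.iterrows():
        biopsy_id = row["biopsy_id"]
        kwargs = {}
        extras = {}
        for col in table.columns:
            if col in known:
                kwargs[col] = _parse_field(col, row[col], biopsy_id)
            else:
                extras[col] = row[col] if row[col] != "NA" else None
        if kwargs.get("replicate_pair") is None:
            kwargs["replicate_pair"] = False
        records.append(BiopsyMetadata(extras=extras, **kwargs))
    _validate_metadata_collection(records)
    return records


def _format_field(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and float(value).is_integer():
        # keep integers clean but preserve float fields' round-trip
        return repr(value)
    return str(value)


def write_metadata(records: Sequence[BiopsyMetadata], path: str | Path, delimiter: str = "\t") -> None:
    """Write metadata records as a tab-separated table with NA for missing."""
    extra_cols: list[str] = []
    for r in records:
        for k in r.extras:
            if k not in extra_cols:
                extra_cols.append(k)
    cols = METADATA_COLUMNS + extra_cols
    with open(path, "w") as fh:
        fh.write(delimiter.join(cols) + "\n")
        for r in records:
            row = [_format_field(getattr(r, c)) for c in METADATA_COLUMNS]
            row += [_format_field(r.extras.get(c)) for c in extra_cols]
            fh.write(delimiter.join(row) + "\n")


def metadata_frame(records: Sequence[BiopsyMetadata]) -> pd.DataFrame:
    """Convert metadata records to a DataFrame indexed by biopsy_id.

    Missing values become NaN (numeric fields) or None (categorical fields);
    convenient for the statistics layer.
    """
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(r) if f.name != "extras"}
        d.update(r.extras)
        rows.append(d)
    df = pd.DataFrame(rows).set_index("biopsy_id")
    return df


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

GMT_SET_NAMES = {"DUX4_TARGETS": "dux4_targets", "PAX7_INDUCED": "pax7_induced", "PAX7_REPRESSED": "pax7_repressed"}


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a one-symbol-per-line gene list; duplicates collapse with a warning."""
    symbols = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if len(set(symbols)) != len(symbols):
        warnings.warn(f"{path}: duplicate symbols collapsed", stacklevel=2)
    return frozenset(symbols)


def read_gene_sets(
    gmt_path: str | Path | None = None,
    *,
    dux4_path: str | Path | None = None,
    pax7_induced_path: str | Path | None = None,
    pax7_repressed_path: str | Path | None = None,
) -> SignatureGeneSets:
    """Load the signature gene sets from a GMT file or three plain lists.

    The GMT file must contain sets named ``DUX4_TARGETS``, ``PAX7_INDUCED``
    and ``PAX7_REPRESSED`` (one per line: name, description, symbols...).
    """
    if gmt_path is not None:
        sets: dict[str, frozenset[str]] = {}
        for line in Path(gmt_path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{gmt_path}: GMT line needs name, description and >=1 symbol: {line!r}")
            name, _desc, *symbols = parts
            symbols = [s for s in symbols if s]
            if name not in GMT_SET_NAMES:
                continue
            if len(set(symbols)) != len(symbols):
                warnings.warn(f"{gmt_path}: duplicate symbols in {name} collapsed", stacklevel=2)
            sets[GMT_SET_NAMES[name]] = frozenset(symbols)
        missing = set(GMT_SET_NAMES.values()) - set(sets)
        if missing:
            raise ValidationError(f"{gmt_path}: missing gene sets: {sorted(missing)}")
        return SignatureGeneSets(**sets)
    if dux4_path is None or pax7_induced_path is None or pax7_repressed_path is None:
        raise ValueError("provide a GMT path or all three plain-list paths")
    return SignatureGeneSets(
        dux4_targets=read_gene_list(dux4_path),
        pax7_induced=read_gene_list(pax7_induced_path),
        pax7_repressed=read_gene_list(pax7_repressed_path),
    )


def write_gene_sets(gene_sets: SignatureGeneSets, path: str | Path) -> None:
    """Write the three signature sets as a GMT file (sorted symbols)."""
    with open(path, "w") as fh:
        for gmt_name, attr in GMT_SET_NAMES.items():
            symbols = sorted(getattr(gene_sets, attr))
            fh.write("\t".join([gmt_name, "na", *symbols]) + "\n")
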