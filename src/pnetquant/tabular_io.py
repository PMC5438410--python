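"""Readers, writers and validated in-memory containers for every table in the pipeline.

All on-disk formats are plain text: TSV for numeric matrices (spectral
counts, densitometry, result tables), CSV for the clinical cohort table.
Missing values are empty cells on disk and ``None``/``NaN`` in memory;
the literal category ``unknown`` is legal data, not a missing value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    """A required column is absent or the header does not match the schema."""


class ValidationError(ValueError):
    """A parsed value violates a data-model invariant."""


class ParseError(ValueError):
    """A cell could not be parsed as the declared type."""


CONDITIONS = ("tumor", "para_tumor")
STATUSES = ("DFS", "AWD", "DOD", "DUC", "alive_unknown", "lost")
GRADES = ("G1", "G2", "G3", "unknown")
STAGES = ("I", "IIa", "IIb", "III", "IV", "unknown")
KI67_CLASSES = ("<=2%", ">2%", "unknown")
LOCATIONS = ("head", "body_tail", "non_pancreas", "unknown")
SUBTYPES = ("insulinoma", "non_insulinoma")
FUNCTIONAL = ("functional", "nonfunctional")
DENSITOMETRY_GROUPS = ("tumor", "para_tumor", "normal")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SpectralCountMatrix:
    """Proteins x samples spectral counts plus protein metadata.

    ``counts`` is an integer DataFrame indexed by protein accession with one
    column per sample.  ``lengths`` (amino-acid residues) and
    ``unique_peptides`` are Series on the same index.  ``sample_meta`` maps
    each sample to its condition (tumor / para_tumor) and pair identifier.
    ``truth`` optionally records planted regulation labels when the matrix
    was simulated.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    unique_peptides: pd.Series
    sample_meta: pd.DataFrame
    truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        idx = self.counts.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein_ids: {dups}")
        for name, series in (("lengths", self.lengths),
                             ("unique_peptides", self.unique_peptides)):
            if not series.index.equals(idx):
                raise ValidationError(f"{name} index does not match counts index")
        bad_len = self.lengths[self.lengths <= 0]
        if len(bad_len):
            raise ValidationError(
                f"non-positive protein length for: {bad_len.index.tolist()}")
        if (self.unique_peptides < 0).any():
            raise ValidationError("negative unique_peptides")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("spectral counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).to_numpy().any():
            raise ValidationError("negative spectral counts")
        missing_meta = [s for s in self.counts.columns
                        if s not in self.sample_meta.index]
        if missing_meta:
            raise ValidationError(f"samples without metadata: {missing_meta}")
        bad_cond = self.sample_meta.loc[
            ~self.sample_meta["condition"].isin(CONDITIONS)]
        if len(bad_cond):
            raise ValidationError(
                f"unknown condition for samples: {bad_cond.index.tolist()}")

    # -- convenience ---------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.counts)

    def pairing(self) -> dict:
        """Map pair_id -> (tumor_sample, para_tumor_sample).

        Raises :class:`ValidationError` unless every pair id maps to exactly
        one tumor and one para-tumor sample.
        """
        pairs: dict = {}
        meta = self.sample_meta.loc[self.samples]
        for pair_id, grp in meta.groupby("pair_id"):
            tum = grp.index[grp["condition"] == "tumor"].tolist()
            par = grp.index[grp["condition"] == "para_tumor"].tolist()
            if len(tum) != 1 or len(par) != 1:
                raise ValidationError(
                    f"pair {pair_id!r} must have exactly one tumor and one "
                    f"para_tumor sample (got {len(tum)} / {len(par)})")
            pairs[pair_id] = (tum[0], par[0])
        return pairs


@dataclass
class SubjectRecord:
    """One patient of the clinical cohort (one row of the cohort CSV)."""

    subject_id: str
    cohort: str = "I"
    age: Optional[float] = None
    sex: Optional[str] = None
    subtype: Optional[str] = None
    functional: Optional[str] = None
    grade: str = "unknown"
    stage: str = "unknown"
    size_cm: Optional[float] = None
    ki67_class: str = "unknown"
    metastasis: Optional[bool] = None
    location: str = "unknown"
    uchl1_percent: Optional[float] = None
    inx_percent: Optional[float] = None
    followup_months: Optional[float] = None
    status: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status is not None and self.status not in STATUSES:
            raise ValidationError(
                f"subject {self.subject_id}: status {self.status!r} not one "
                f"of {STATUSES}")
        if self.followup_months is not None and self.followup_months < 0:
            raise ValidationError(
                f"subject {self.subject_id}: negative followup_months")
        for name in ("uchl1_percent", "inx_percent"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise ValidationError(
                    f"subject {self.subject_id}: {name}={v} outside [0, 100]")


@dataclass
class DensitometryRecord:
    """Western-blot band intensities for one lane/sample."""

    sample_id: str
    group: str
    band_intensity: dict = field(default_factory=dict)
    ihc_call: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in DENSITOMETRY_GROUPS:
            raise ValidationError(
                f"sample {self.sample_id}: group {self.group!r} not one of "
                f"{DENSITOMETRY_GROUPS}")
        for protein, v in self.band_intensity.items():
            if v < 0:
                raise ValidationError(
                    f"sample {self.sample_id}: negative intensity for {protein}")


@dataclass
class MarkerCallRecord:
    """Methylation-specific PCR result paired with the protein expression call.

    A valid MSP result shows at least one band; both bands together indicate
    hemi- or heterogeneous methylation.
    """

    sample_id: str
    methylated_band: bool
    unmethylated_band: bool
    expression: str

    def __post_init__(self) -> None:
        if not (self.methylated_band or self.unmethylated_band):
            raise ValidationError(
                f"sample {self.sample_id}: no MSP band detected (invalid result)")
        if self.expression not in ("positive", "negative"):
            raise ValidationError(
                f"sample {self.sample_id}: expression must be positive/negative")


# ---------------------------------------------------------------------------
# spectral-count table I/O
# ---------------------------------------------------------------------------

DEFAULT_COUNT_SCHEMA = {
    "protein_id": "protein_id",
    "length": "length_aa",
    "unique_peptides": "unique_peptides",
}


def read_count_table(path, sample_sheet=None, schema: Optional[dict] = None,
                     delimiter: str = "\t") -> SpectralCountMatrix:
    """Read a spectral-count TSV plus its sample sheet into a validated matrix.

    The table carries one row per protein: accession, length in residues,
    unique-peptide count, then one integer column per sample.  ``schema``
    maps the logical names ``protein_id``/``length``/``unique_peptides`` to
    the column names actually present.  The sample sheet (TSV:
    ``sample  condition  pair_id``) supplies the condition labels; if omitted,
    sample metadata must be attached later before paired analysis.
    """
    schema = {**DEFAULT_COUNT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    for logical, col in schema.items():
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r} "
                              f"(maps to {logical})")
    id_col = schema["protein_id"]
    len_col = schema["length"]
    up_col = schema["unique_peptides"]
    sample_cols = [c for c in df.columns if c not in {id_col, len_col, up_col}]

    dup = df[id_col][df[id_col].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate protein_ids {dup.tolist()}")

    def _int_col(col: str) -> np.ndarray:
        out = np.empty(len(df), dtype=np.int64)
        for i, raw in enumerate(df[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: row {i + 2}, column {col!r}: {raw!r} is not an "
                    f"integer") from None
            if v < 0:
                raise ParseError(
                    f"{path}: row {i + 2}, column {col!r}: negative count {v}")
            out[i] = v
        return out

    counts = pd.DataFrame(
        {c: _int_col(c) for c in sample_cols},
        index=pd.Index(df[id_col], name="protein_id"))
    lengths = pd.Series(pd.to_numeric(df[len_col]).to_numpy(),
                        index=counts.index, name="length_aa")
    bad = lengths[lengths <= 0]
    if len(bad):
        raise ValidationError(
            f"{path}: non-positive length for protein(s) {bad.index.tolist()}")
    unique_peptides = pd.Series(_int_col(up_col), index=counts.index,
                                name="unique_peptides")

    if sample_sheet is not None:
        meta = read_sample_sheet(sample_sheet)
    else:
        meta = pd.DataFrame({"condition": "tumor", "pair_id": sample_cols},
                            index=pd.Index(sample_cols, name="sample"))
    return SpectralCountMatrix(counts=counts, lengths=lengths,
                               unique_peptides=unique_peptides,
                               sample_meta=meta)


def read_sample_sheet(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "condition", "pair_id"):
        if col not in meta.columns:
            raise SchemaError(f"{path}: sample sheet missing column {col!r}")
    meta = meta.set_index("sample")
    bad = meta.loc[~meta["condition"].isin(CONDITIONS)]
    if len(bad):
        raise ValidationError(
            f"{path}: unknown condition for samples {bad.index.tolist()}")
    return meta


def write_count_table(matrix: SpectralCountMatrix, path,
                      sample_sheet_path=None) -> None:
    df = pd.DataFrame({
        "protein_id": matrix.protein_ids,
        "length_aa": matrix.lengths.to_numpy(),
        "unique_peptides": matrix.unique_peptides.to_numpy(),
    })
    for s in matrix.samples:
        df[s] = matrix.counts[s].to_numpy()
    df.to_csv(path, sep="\t", index=False)
    if sample_sheet_path is not None:
        matrix.sample_meta.rename_axis("sample").reset_index().to_csv(
            sample_sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort CSV I/O
# ---------------------------------------------------------------------------

_SUBJECT_FIELDS = [f.name for f in fields(SubjectRecord)]
_SUBJECT_FLOATS = {"age", "size_cm", "uchl1_percent", "inx_percent",
                   "followup_months"}


def read_cohort_table(path, delimiter: str = ",") -> list:
    """Read the clinical cohort CSV into a list of :class:`SubjectRecord`.

    Empty cells become ``None`` (explicit missing); rows are never silently
    dropped.  A status outside the enumeration or a negative follow-up raises
    :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    missing = [c for c in _SUBJECT_FIELDS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: cohort table missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        kwargs = {}
        for name in _SUBJECT_FIELDS:
            raw = row[name]
            if pd.isna(raw) or raw == "":
                kwargs[name] = None
            elif name in _SUBJECT_FLOATS:
                try:
                    kwargs[name] = float(raw)
                except ValueError:
                    raise ParseError(
                        f"{path}: row {i + 2}, column {name!r}: {raw!r} is "
                        f"not numeric") from None
            elif name == "metastasis":
                kwargs[name] = raw.strip().lower() in ("true", "1", "yes")
            else:
                kwargs[name] = raw
        # dataclass defaults for category fields expect strings, not None
        for name in ("grade", "stage", "ki67_class", "location", "cohort"):
            if kwargs[name] is None:
                kwargs[name] = "unknown" if name != "cohort" else "I"
        try:
            records.append(SubjectRecord(**kwargs))
        except ValidationError as e:
            raise ValidationError(f"{path}: row {i + 2}: {e}") from None
    return records


def write_cohort_table(subjects: Sequence[SubjectRecord], path) -> None:
    rows = [dataclasses.asdict(s) for s in subjects]
    pd.DataFrame(rows, columns=_SUBJECT_FIELDS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# densitometry / MSP tables
# ---------------------------------------------------------------------------

def read_densitometry_table(path, delimiter: str = "\t") -> list:
    """Read a densitometry TSV: ``sample_id  group  <protein columns...>``."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise SchemaError(f"{path}: densitometry table missing {col!r}")
    protein_cols = [c for c in df.columns
                    if c not in ("sample_id", "group", "ihc_call")]
    records = []
    for i, row in df.iterrows():
        intensities = {}
        for c in protein_cols:
            raw = row[c]
            if pd.isna(raw) or raw == "":
                continue
            try:
                intensities[c] = float(raw)
            except ValueError:
                raise ParseError(f"{path}: row {i + 2}, column {c!r}: {raw!r} "
                                 f"is not numeric") from None
        ihc = row.get("ihc_call")
        records.append(DensitometryRecord(
            sample_id=row["sample_id"], group=row["group"],
            band_intensity=intensities,
            ihc_call=None if pd.isna(ihc) else ihc))
    return records


def write_densitometry_table(records: Sequence[DensitometryRecord], path) -> None:
    proteins = sorted({p for r in records for p in r.band_intensity})
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "group": r.group,
               "ihc_call": r.ihc_call or ""}
        row.update({p: r.band_intensity.get(p, "") for p in proteins})
        rows.append(row)
    cols = ["sample_id", "group"] + proteins + ["ihc_call"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_marker_call_table(path, delimiter: str = "\t") -> list:
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    needed = ("sample_id", "methylated_band", "unmethylated_band", "expression")
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"{path}: marker-call table missing {col!r}")
    to_bool = lambda v: str(v).strip().lower() in ("true", "1", "yes", "m", "u")
    return [MarkerCallRecord(sample_id=row["sample_id"],
                             methylated_band=to_bool(row["methylated_band"]),
                             unmethylated_band=to_bool(row["unmethylated_band"]),
                             expression=row["expression"])
            for _, row in df.iterrows()]


def write_marker_call_table(records: Sequence[MarkerCallRecord], path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------

def write_results_table(records: Iterable, path) -> None:
    """Write a homogeneous sequence of result dataclasses (or dicts) as TSV.

    Values round-trip at full stored precision (floats via repr).  An empty
    sequence still emits the header row when the element type is known;
    otherwise an empty file.
    """
    records = list(records)
    if records and dataclasses.is_dataclass(records[0]):
        cols = [f.name for f in fields(records[0])]
        rows = [dataclasses.asdict(r) for r in records]
    elif records:
        cols = list(records[0].keys())
        rows = records
    else:
        Path(path).write_text("")
        return
    types = {type(r) for r in records}
    if len(types) > 1:
        raise ValidationError(f"heterogeneous record sequence: {types}")
    # repr keeps floats at full round-trippable precision
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def read_results_table(path, record_type=None) -> list:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if record_type is None:
        return df.to_dict("records")
    out = []
    for _, row in df.iterrows():
        kwargs = {f.name: row[f.name] for f in fields(record_type)
                  if f.name in df.columns}
        for k, v in kwargs.items():
            if isinstance(v, float) and np.isnan(v):
                kwargs[k] = None
        out.append(record_type(**kwargs))
    return out


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    """Read the single plain-text key-value (YAML) analysis config.

    Returns a flat dict; the verbatim text is kept under ``_raw`` so a run
    log can reproduce exactly what was read.
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a key-value mapping")
    cfg["_raw"] = text
    return cfg
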