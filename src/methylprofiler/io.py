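"""Reading, validating, orienting and writing the delimited-text inputs.

The canonical on-disk format for every table is CSV with a header row; the
missing-value tokens are an empty cell or the literal ``NA`` (case
sensitive).  Methylation matrices are accepted in either orientation and
canonicalized to samples-as-rows using the CpG identifier pattern on axis
labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousOrientationError,
    FormatError,
    ScaleDetectionError,
    SchemaError,
    ValidationError,
)
from .qc import QCReport

CPG_PATTERN = re.compile(r"^cg\d+$")

#: fraction of axis labels that must look like CpG ids for the axis to be
#: treated as the CpG axis
CPG_AXIS_VOTE = 0.9

MISSING_TOKENS = ["", "NA"]

SEX_TOKENS = {"Male", "Female", "NA"}

BETA = "beta"
M_VALUE = "m_value"


def _read_csv(path, **kwargs):
    # case-sensitive missing tokens: disable pandas' default NA list
    return pd.read_csv(path, keep_default_na=False, na_values=MISSING_TOKENS, **kwargs)


def _cpg_fraction(labels) -> float:
    labels = list(labels)
    if not labels:
        return 0.0
    hits = sum(1 for x in labels if CPG_PATTERN.match(str(x)))
    return hits / len(labels)


@dataclass
class MethylationMatrix:
    """A samples x CpGs grid of beta or M values.

    ``values`` is a dense DataFrame indexed by sample id with CpG ids as
    columns (canonical orientation).  ``scale`` declares whether entries are
    beta values (in [0, 1]) or M values (unbounded).
    """

    values: pd.DataFrame
    scale: str = BETA
    orientation_log: str = ""

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dups)}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicate CpG ids: {list(dups)}")
        if self.scale not in (BETA, M_VALUE):
            raise ValidationError(f"unknown scale {self.scale!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(self.values.copy(), self.scale, self.orientation_log)


def orient_matrix(m: MethylationMatrix, qc: QCReport | None = None) -> MethylationMatrix:
    """Canonicalize orientation so that CpG-pattern labels are the columns.

    Idempotent.  Raises :class:`AmbiguousOrientationError` when both axes or
    neither axis carry a >=90% majority of ``cg``-style labels.
    """
    row_frac = _cpg_fraction(m.values.index)
    col_frac = _cpg_fraction(m.values.columns)
    rows_cpg = row_frac >= CPG_AXIS_VOTE
    cols_cpg = col_frac >= CPG_AXIS_VOTE
    if rows_cpg and cols_cpg:
        raise AmbiguousOrientationError(
            "both axes look like CpG identifiers "
            f"(rows {row_frac:.0%}, columns {col_frac:.0%})"
        )
    if not rows_cpg and not cols_cpg:
        raise AmbiguousOrientationError(
            "neither axis looks like CpG identifiers "
            f"(rows {row_frac:.0%}, columns {col_frac:.0%})"
        )
    if rows_cpg:
        out = MethylationMatrix(
            m.values.T.copy(),
            m.scale,
            (m.orientation_log + " " if m.orientation_log else "")
            + "transposed: CpG sites were rows, samples are now rows",
        )
        if qc is not None:
            qc.add("orientation", "matrix transposed (CpG sites were rows)", 1)
        return out
    if qc is not None:
        qc.add("orientation", "no transposition required", 0)
    return m


def detect_value_scale(m: MethylationMatrix) -> str:
    """``m_value`` iff any non-missing entry lies outside [0, 1], else ``beta``."""
    vals = m.values.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size == 0:
        raise ScaleDetectionError("all values missing; value scale undecidable")
    if ((finite < 0.0) | (finite > 1.0)).any():
        return M_VALUE
    return BETA


def read_methylation_matrix(
    path, dialect: str = "csv", qc: QCReport | None = None
) -> MethylationMatrix:
    """Read a labelled numeric grid, canonicalize orientation, detect scale."""
    if dialect == "rds":
        try:
            import pyreadr  # optional dependency
        except ImportError as exc:  # pragma: no cover - optional path
            raise FormatError(
                "reading .rds files requires the optional 'pyreadr' package; "
                "convert the object to CSV instead"
            ) from exc
        result = pyreadr.read_r(str(path))  # pragma: no cover
        df = next(iter(result.values()))  # pragma: no cover
    elif dialect == "csv":
        try:
            df = _read_csv(path, index_col=0)
        except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
            raise FormatError(f"could not parse {path} as a labelled CSV grid: {exc}") from exc
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric cells in {path}: {exc}") from exc

    m = MethylationMatrix(df.astype(float))
    m = orient_matrix(m, qc=qc)
    scale = detect_value_scale(m)
    m.scale = scale
    if qc is not None:
        qc.add("scale", f"detected {scale.replace('_', ' ')}s")
    return m


@dataclass
class SampleAnnotations:
    """ID / Sex / Age records accompanying an upload."""

    data: pd.DataFrame  # index: ID (str); columns: Sex (str), Age (float)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate annotation ids: {list(dups)}")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)


def read_sample_annotations(path) -> SampleAnnotations:
    df = _read_csv(path, dtype=str)
    for col in ("ID", "Sex", "Age"):
        if col not in df.columns:
            raise SchemaError(f"annotation file {path} lacks required column {col!r}")
    df = df.set_index("ID")
    df.index = df.index.astype(str)
    sex = df["Sex"].fillna("NA")
    bad = sorted(set(sex) - SEX_TOKENS)
    if bad:
        raise ValidationError(
            f"invalid Sex tokens {bad}; expected one of 'Male', 'Female', 'NA'"
        )
    try:
        age = pd.to_numeric(df["Age"])
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric Age values in {path}: {exc}") from exc
    if (age.dropna() < 0).any():
        raise ValidationError("negative Age values are not allowed")
    out = pd.DataFrame({"Sex": sex, "Age": age.astype(float)}, index=df.index)
    return SampleAnnotations(out)


@dataclass
class PhenotypeTable:
    """Binary case/control statuses: 0=control, 1=case, NaN=missing."""

    data: pd.DataFrame  # index: ID; one float column per phenotype

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate phenotype ids: {list(dups)}")

    @property
    def phenotypes(self) -> list[str]:
        return list(self.data.columns)


def read_phenotype_table(path) -> PhenotypeTable:
    df = _read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(
            f"phenotype file {path} needs an ID column plus at least one status column"
        )
    id_col = df.columns[0]
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric status values in {path}: {exc}") from exc
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
    if not ok.all():
        bad = sorted(set(vals[~ok].tolist()))
        raise ValidationError(
            f"status values must be 0 (control), 1 (case) or missing; found {bad}"
        )
    return PhenotypeTable(df.astype(float))


def truncate_to_required_cpgs(
    m: MethylationMatrix, required, qc: QCReport | None = None
) -> MethylationMatrix:
    """Keep only columns listed in ``required``, preserving the matrix order.

    An empty intersection yields a 0-column matrix (the reference-fill step
    handles fully absent CpGs), not an error.
    """
    required = list(required)
    if not required:
        raise ValidationError("required CpG list is empty")
    wanted = set(required)
    keep = [c for c in m.cpg_ids if c in wanted]
    out = MethylationMatrix(m.values[keep].copy(), m.scale, m.orientation_log)
    if qc is not None:
        qc.add("truncate", "CpG sites retained after truncation", len(keep))
        if not keep:
            qc.add("truncate", "warning: no uploaded CpG sites match the required list", 0)
    return out


def read_cpg_list(path) -> list[str]:
    """One-column CSV of CpG identifiers (header ``CpG`` or none)."""
    df = _read_csv(path, dtype=str)
    col = "CpG" if "CpG" in df.columns else df.columns[0]
    ids = [str(x) for x in df[col].dropna()]
    # headerless single-column files: the first id lands in the header
    if col != "CpG" and CPG_PATTERN.match(str(col)):
        ids = [str(col)] + ids
    return ids


# ---------------------------------------------------------------------------
# Score tables


#: paper-facing trait listing order for non-age traits
TRAIT_ORDER = [
    "Alcohol",
    "Body Fat %",
    "BMI",
    "HDL cholesterol",
    "Smoking",
    "Waist-to-hip ratio",
]

ANNOTATION_COLUMNS = ("Sex", "Age")


@dataclass
class ScoreTable:
    """Per-sample predicted values for each trait plus optional annotations.

    ``data`` is indexed by sample ID; optional ``Sex``/``Age`` columns hold
    the uploaded annotations (``Age`` is true chronological age), followed by
    one numeric column per trait.  ``age_trait`` names the trait reported in
    years (the epigenetic age predictor), if configured.
    """

    data: pd.DataFrame
    traits: list[str] = field(default_factory=list)
    age_trait: str | None = None

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids in score table: {list(dups)}")
        missing = [t for t in self.traits if t not in self.data.columns]
        if missing:
            raise ValidationError(f"trait columns absent from score table: {missing}")
        if self.age_trait is not None and self.age_trait not in self.traits:
            raise ValidationError(f"age trait {self.age_trait!r} not among traits")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def has_annotations(self) -> bool:
        return "Age" in self.data.columns or "Sex" in self.data.columns

    def effective_age(self) -> pd.Series:
        """True age where uploaded, otherwise the epigenetic-age score."""
        if "Age" in self.data.columns:
            age = self.data["Age"].copy()
        else:
            age = pd.Series(np.nan, index=self.data.index, name="Age")
        if self.age_trait is not None:
            age = age.fillna(self.data[self.age_trait])
        return age

    def age_source(self) -> pd.Series:
        """Per-sample provenance of the effective age: 'true' or 'epigenetic'."""
        if "Age" in self.data.columns:
            true_known = self.data["Age"].notna()
        else:
            true_known = pd.Series(False, index=self.data.index)
        return true_known.map({True: "true", False: "epigenetic"})

    def subset(self, ids) -> "ScoreTable":
        return ScoreTable(self.data.loc[list(ids)].copy(), list(self.traits), self.age_trait)


#: default name for the years-scale age trait in score tables
AGE_TRAIT_DEFAULT = "Epigenetic Age"


def write_score_table(t: ScoreTable, path) -> None:
    df = t.data.copy()
    df.index.name = "ID"
    df.to_csv(path, na_rep="NA")


def read_score_table(path, age_trait: str | None = AGE_TRAIT_DEFAULT) -> ScoreTable:
    df = _read_csv(path)
    if "ID" not in df.columns:
        raise SchemaError(
            f"score table {path} lacks an ID column; expected header "
            "ID[,Sex,Age],<trait columns>"
        )
    df = df.set_index("ID")
    df.index = df.index.astype(str)
    if "Sex" in df.columns:
        # 'NA' is a legitimate sex token, not a missing value
        df["Sex"] = df["Sex"].fillna("NA")
    traits = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    if not traits:
        raise SchemaError(f"score table {path} has no trait columns")
    for c in traits + (["Age"] if "Age" in df.columns else []):
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric values in column {c!r}: {exc}") from exc
    if age_trait is not None and age_trait not in traits:
        age_trait = None
    return ScoreTable(df, traits, age_trait)
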