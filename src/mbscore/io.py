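"""Data model and file I/O for expression matrices, clinical tables and cohorts.

The pipeline's universal input is a :class:`Cohort`: a genes × samples matrix of
log-scale normalized expression intensities aligned one-to-one with a clinical
table carrying overall-survival follow-up and the confounders used during
screening (age, gender, IPSS-R category).  Expression values are assumed
already normalized upstream (array summarization is out of scope here); the
readers only parse, validate and collapse duplicate probes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, ParseError, ValidationError

logger = logging.getLogger(__name__)

IPSSR_LEVELS = ("very-low", "low", "intermediate", "high", "very-high")

_IPSSR_ALIASES = {
    "very-low": "very-low",
    "very low": "very-low",
    "verylow": "very-low",
    "vl": "very-low",
    "low": "low",
    "l": "low",
    "intermediate": "intermediate",
    "int": "intermediate",
    "i": "intermediate",
    "high": "high",
    "h": "high",
    "very-high": "very-high",
    "very high": "very-high",
    "veryhigh": "very-high",
    "vh": "very-high",
}

_GENDER_ALIASES = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
}


class ExpressionMatrix:
    """Genes × samples matrix of log-scale expression values.

    Parameters
    ----------
    frame : pandas.DataFrame
        Rows indexed by gene symbol, columns by sample identifier, numeric
        values.  Gene and sample identifiers must be unique and the matrix
        must contain no missing values.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.shape[0] == 0 or frame.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        if frame.index.duplicated().any():
            dups = sorted(set(frame.index[frame.index.duplicated()]))
            raise ValidationError(f"duplicate gene ids after collapsing: {dups}")
        if frame.columns.duplicated().any():
            dups = sorted(set(frame.columns[frame.columns.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = frame.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("expression matrix contains missing values")
        self._frame = frame.astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def gene_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def gene_values(self, gene: str) -> np.ndarray:
        """Expression of one gene across samples, in sample order."""
        if gene not in self._frame.index:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self._frame.loc[gene].to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self._frame.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self._frame.loc[:, list(sample_ids)])

    def to_tsv(self, path) -> None:
        self._frame.to_csv(path, sep="\t", index_label="gene")

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self._frame.equals(other._frame)

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


@dataclass
class ClinicalRecord:
    """One patient's survival follow-up and covariates.

    ``os_time`` is overall survival in months from diagnosis; ``os_event`` is
    1 when death was observed and 0 when follow-up was right-censored.
    Optional fields are ``None`` when unknown; unparseable optional inputs
    become missing rather than errors.
    """

    patient_id: str
    os_time: float
    os_event: int
    age: float | None = None
    gender: str | None = None
    ipssr: str | None = None
    group_label: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.patient_id = str(self.patient_id).strip()
        if not (isinstance(self.os_time, (int, float)) and math.isfinite(self.os_time)):
            raise ValidationError(
                f"patient {self.patient_id!r}: os_time must be finite, got {self.os_time!r}"
            )
        if self.os_time <= 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: os_time must be > 0, got {self.os_time!r}"
            )
        if self.os_event not in (0, 1):
            raise ValidationError(
                f"patient {self.patient_id!r}: os_event must be 0 or 1, got {self.os_event!r}"
            )
        if self.gender is not None and self.gender not in ("female", "male"):
            raise ValidationError(
                f"patient {self.patient_id!r}: gender must be female/male, got {self.gender!r}"
            )
        if self.ipssr is not None and self.ipssr not in IPSSR_LEVELS:
            raise ValidationError(
                f"patient {self.patient_id!r}: ipssr must be one of {IPSSR_LEVELS}, "
                f"got {self.ipssr!r}"
            )


@dataclass
class Cohort:
    """Aligned expression matrix + clinical records (same order, same ids)."""

    expression: ExpressionMatrix
    clinical: list[ClinicalRecord]

    def __post_init__(self):
        ids = [r.patient_id for r in self.clinical]
        if ids != self.expression.sample_ids:
            raise ValidationError(
                "cohort expression samples and clinical patients are not aligned"
            )

    @property
    def n(self) -> int:
        return len(self.clinical)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.clinical]

    @property
    def times(self) -> np.ndarray:
        return np.array([r.os_time for r in self.clinical], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.os_event for r in self.clinical], dtype=int)

    def clinical_frame(self) -> pd.DataFrame:
        """Clinical table as a DataFrame (one row per patient, cohort order)."""
        rows = []
        for r in self.clinical:
            row = {
                "patient_id": r.patient_id,
                "os_time": r.os_time,
                "os_event": r.os_event,
                "age": r.age,
                "gender": r.gender,
                "ipssr": r.ipssr,
                "group_label": r.group_label,
            }
            row.update(r.extras)
            rows.append(row)
        return pd.DataFrame(rows)

    def subset(self, patient_ids: Sequence[str]) -> "Cohort":
        wanted = list(patient_ids)
        by_id = {r.patient_id: r for r in self.clinical}
        missing = [p for p in wanted if p not in by_id]
        if missing:
            raise KeyError(f"patients not in cohort: {missing}")
        return Cohort(
            expression=self.expression.subset_samples(wanted),
            clinical=[by_id[p] for p in wanted],
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _infer_sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(
    path,
    collapse: str = "median",
    sep: str | None = None,
    on_missing: str = "drop",
) -> ExpressionMatrix:
    """Read a genes × samples expression table from delimited text.

    The first column holds gene (or probe) symbols, the header row sample
    identifiers.  Rows sharing a symbol are collapsed element-wise by the
    median when ``collapse="median"`` (the standard multi-probe rule), or
    left untouched with ``collapse="none"`` (which then fails validation if
    duplicates exist).

    Parameters
    ----------
    on_missing : {"drop", "impute", "error"}
        Genes with missing values are dropped with a warning (default),
        median-imputed per gene, or rejected.
    """
    if collapse not in ("median", "none"):
        raise ConfigError(f"unknown collapse strategy {collapse!r}")
    if on_missing not in ("drop", "impute", "error"):
        raise ConfigError(f"unknown missing-value policy {on_missing!r}")
    sep = sep or _infer_sep(path)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"cannot read expression table {path}: {exc}") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ParseError(f"expression table {path} is empty")
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    # A cell that was non-empty text but failed numeric conversion is a parse
    # error; a genuinely empty cell is missing data handled by `on_missing`.
    blank = raw.isna() | raw.apply(lambda c: c.astype(str).str.strip().isin(["", "NA", "nan", "NaN"]))
    bad = numeric.isna() & ~blank
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise ParseError(
            f"non-numeric expression value at gene {gene!r}, sample {col!r}: "
            f"{raw.loc[gene, col]!r}"
        )

    if collapse == "median" and numeric.index.duplicated().any():
        n_before = numeric.shape[0]
        numeric = numeric.groupby(level=0, sort=False).median()
        logger.info(
            "collapsed %d probe rows to %d genes by median", n_before, numeric.shape[0]
        )

    has_missing = numeric.isna().any(axis=1)
    if has_missing.any():
        genes = list(numeric.index[has_missing])
        if on_missing == "error":
            raise ValidationError(f"missing expression values for genes: {genes}")
        if on_missing == "drop":
            logger.warning("dropping %d genes with missing values: %s", len(genes), genes)
            numeric = numeric.loc[~has_missing]
        else:  # impute
            med = numeric.median(axis=1)
            numeric = numeric.apply(lambda row: row.fillna(med[row.name]), axis=1)
            logger.warning("median-imputed missing values for genes: %s", genes)
    if numeric.shape[0] == 0:
        raise ValidationError("no genes left after handling missing values")
    return ExpressionMatrix(numeric)


_MANDATORY = ("patient_id", "os_time", "os_event")


def read_clinical(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[ClinicalRecord]:
    """Read the clinical table into validated :class:`ClinicalRecord` rows.

    ``column_map`` maps canonical field names (``patient_id``, ``os_time``,
    ``os_event``, ``age``, ``gender``, ``ipssr``, ``group_label``) to the
    file's column names; identity is assumed for unmapped fields.  Columns not
    claimed by the map are kept verbatim in ``extras``.
    """
    sep = sep or _infer_sep(path)
    try:
        table = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot read clinical table {path}: {exc}") from exc
    table.columns = table.columns.astype(str).str.strip()
    cmap = dict(column_map or {})
    optional = ("age", "gender", "ipssr", "group_label")
    for name in _MANDATORY + optional:
        cmap.setdefault(name, name)
    for name in _MANDATORY:
        if cmap[name] not in table.columns:
            raise ConfigError(
                f"clinical table {path} lacks mandatory column "
                f"{cmap[name]!r} (for field {name!r})"
            )
    claimed = {cmap[n] for n in _MANDATORY + optional if cmap[n] in table.columns}
    extra_cols = [c for c in table.columns if c not in claimed]

    records: list[ClinicalRecord] = []
    for _, row in table.iterrows():
        pid = str(row[cmap["patient_id"]]).strip()
        try:
            os_time = float(row[cmap["os_time"]])
        except (TypeError, ValueError):
            raise ValidationError(
                f"patient {pid!r}: unparseable os_time {row[cmap['os_time']]!r}"
            ) from None
        try:
            os_event = int(float(row[cmap["os_event"]]))
        except (TypeError, ValueError):
            raise ValidationError(
                f"patient {pid!r}: unparseable os_event {row[cmap['os_event']]!r}"
            ) from None
        records.append(
            ClinicalRecord(
                patient_id=pid,
                os_time=os_time,
                os_event=os_event,
                age=_parse_optional_float(row, cmap["age"]),
                gender=_parse_alias(row, cmap["gender"], _GENDER_ALIASES),
                ipssr=_parse_alias(row, cmap["ipssr"], _IPSSR_ALIASES),
                group_label=_parse_optional_str(row, cmap["group_label"]),
                extras={c: row[c] for c in extra_cols},
            )
        )
    if not records:
        raise ValidationError(f"clinical table {path} has no rows")
    return records


def _parse_optional_float(row, col):
    if col not in row.index or pd.isna(row[col]):
        return None
    try:
        v = float(row[col])
    except (TypeError, ValueError):
        return None
    return v if math.isfinite(v) else None


def _parse_optional_str(row, col):
    if col not in row.index or pd.isna(row[col]):
        return None
    s = str(row[col]).strip()
    return s or None


def _parse_alias(row, col, aliases):
    s = _parse_optional_str(row, col)
    if s is None:
        return None
    return aliases.get(s.lower().replace("_", "-"))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_cohort(
    expr: ExpressionMatrix,
    clinical: Iterable[ClinicalRecord],
    policy: str = "intersect",
) -> Cohort:
    """Match expression samples with clinical patients by exact identifier.

    Under ``policy="intersect"`` only shared identifiers are kept (dropped
    counts are logged); under ``policy="strict"`` any mismatch raises.  The
    output ordering follows the clinical table.
    """
    if policy not in ("intersect", "strict"):
        raise ConfigError(f"unknown alignment policy {policy!r}")
    clinical = list(clinical)
    clin_ids = [r.patient_id.strip() for r in clinical]
    if len(set(clin_ids)) != len(clin_ids):
        dups = sorted({i for i in clin_ids if clin_ids.count(i) > 1})
        raise AlignmentError(f"duplicated patient ids in clinical table: {dups}")
    expr_ids = [s.strip() for s in expr.sample_ids]
    shared = set(clin_ids) & set(expr_ids)
    if not shared:
        raise AlignmentError("no shared identifiers between expression and clinical")
    if policy == "strict":
        unmatched = sorted((set(clin_ids) ^ set(expr_ids)))
        if unmatched:
            raise AlignmentError(f"strict alignment failed; unmatched ids: {unmatched}")
    kept = [r for r, pid in zip(clinical, clin_ids) if pid in shared]
    dropped_clin = len(clinical) - len(kept)
    dropped_expr = len(expr_ids) - len(shared)
    if dropped_clin or dropped_expr:
        logger.info(
            "alignment dropped %d clinical rows and %d expression samples",
            dropped_clin,
            dropped_expr,
        )
    order = [r.patient_id.strip() for r in kept]
    frame = expr.frame.copy()
    frame.columns = expr_ids
    return Cohort(expression=ExpressionMatrix(frame.loc[:, order]), clinical=kept)
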