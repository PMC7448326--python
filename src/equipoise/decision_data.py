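"""Domain types, validation and CSV I/O for decision matrices, rater rosters
and case portfolios.

The central object is the :class:`DecisionMatrix`: X raters each choose one
of Y management options for each of Z standardized patient cases, possibly
in two sessions and for several questions.  It is stored long-format (one
row per individual decision) with derived ordered sets of raters, cases and
categories, and count tables n_ij (raters choosing option j on case i) from
which all agreement statistics are computed.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from equipoise.errors import (
    DuplicateRecordError,
    EmptyInputError,
    MissingColumnError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: canonical long-format column order
COLUMNS = [
    "rater_id",
    "case_id",
    "session",
    "question_id",
    "choice",
    "confidence",
    "trial_proposal",
]

REQUIRED_COLUMNS = ["rater_id", "case_id", "session", "question_id", "choice"]

CONTROL_CLASSES = ("positive", "grey", "negative")


@dataclass(frozen=True)
class DecisionRecord:
    """One clinician's answer to one question about one case in one session."""

    rater_id: str
    case_id: str
    session: int
    question_id: str
    choice: str
    confidence: Optional[int] = None
    trial_proposal: Optional[bool] = None

    def __post_init__(self):
        if self.session not in (1, 2):
            raise ValidationError(
                f"session must be 1 or 2, got {self.session!r} "
                f"(rater={self.rater_id!r}, case={self.case_id!r})"
            )
        if not str(self.choice):
            raise ValidationError(
                f"empty choice label (rater={self.rater_id!r}, case={self.case_id!r})"
            )


@dataclass(frozen=True)
class RaterProfile:
    """Roster entry: who the rater is (specialty, experience, center)."""

    rater_id: str
    specialty: str
    experience: Optional[str] = None
    center: Optional[str] = None


@dataclass(frozen=True)
class CaseVignette:
    """Portfolio entry: one standardized case with its control class.

    ``control_class`` is one of ``positive`` (prior-trial-eligible, expected
    near-unanimous decisions for the intervention), ``negative`` (expected
    near-unanimous against) or ``grey`` (excluded from prior trials; the
    equipoise-rich stratum).
    """

    case_id: str
    control_class: str
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.control_class not in CONTROL_CLASSES:
            raise ValidationError(
                f"control_class must be one of {CONTROL_CLASSES}, "
                f"got {self.control_class!r} (case={self.case_id!r})"
            )


@dataclass(frozen=True)
class Portfolio:
    """Ordered collection of case vignettes with class composition counts."""

    vignettes: tuple
    composition: Mapping[str, int]

    @classmethod
    def from_vignettes(cls, vignettes: Iterable[CaseVignette]) -> "Portfolio":
        vignettes = tuple(vignettes)
        ids = [v.case_id for v in vignettes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate case_id in portfolio")
        comp = {c: 0 for c in CONTROL_CLASSES}
        for v in vignettes:
            comp[v.control_class] += 1
        return cls(vignettes=vignettes, composition=comp)

    @property
    def case_ids(self) -> list:
        return [v.case_id for v in self.vignettes]

    def __len__(self) -> int:
        return len(self.vignettes)


class DecisionMatrix:
    """Validated rater x case x session decision table.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format table with canonical columns (one row per record).
    categories : sequence of str, optional
        Declared option list Y.  If omitted, inferred from the observed
        choices (sorted).  Declared-but-unobserved categories are retained:
        the questionnaire's option list, not the observed answers, defines
        the category space entering chance agreement.
    """

    def __init__(self, data: pd.DataFrame, categories: Optional[Sequence[str]] = None):
        self._data = data.reset_index(drop=True)
        observed = set(data["choice"].unique())
        if categories is None:
            self.categories: tuple = tuple(sorted(observed))
        else:
            categories = tuple(dict.fromkeys(str(c) for c in categories))
            extra = observed - set(categories)
            if extra:
                raise ValidationError(
                    f"observed choices {sorted(extra)} not in declared categories {list(categories)}"
                )
            self.categories = categories
        self.raters: tuple = tuple(sorted(data["rater_id"].unique()))
        self.cases: tuple = tuple(sorted(data["case_id"].unique()))

    # -- basic accessors -------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def questions(self) -> tuple:
        return tuple(sorted(self._data["question_id"].unique()))

    @property
    def sessions(self) -> tuple:
        return tuple(sorted(self._data["session"].unique()))

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DecisionMatrix):
            return NotImplemented
        if self.categories != other.categories:
            return False
        a = _canonical_sort(self._data)
        b = _canonical_sort(other._data)
        return a.equals(b)

    def __repr__(self) -> str:
        return (
            f"DecisionMatrix(X={self.n_raters} raters, Z={self.n_cases} cases, "
            f"Y={len(self.categories)} categories, {len(self._data)} records)"
        )

    # -- slicing and counting --------------------------------------------

    def slice(self, question: str, session: Optional[int] = None) -> pd.DataFrame:
        """Rows for one question (and optionally one session)."""
        mask = self._data["question_id"] == question
        if session is not None:
            mask &= self._data["session"] == session
        out = self._data[mask]
        if out.empty:
            raise EmptyInputError(
                f"no records for question={question!r}"
                + (f", session={session}" if session is not None else "")
            )
        return out

    def count_table(self, question: str, session: int = 1) -> pd.DataFrame:
        """Per-case per-category counts n_ij (cases x categories).

        Rows are cases observed for this (question, session) slice; columns
        follow ``self.categories`` so declared-but-unobserved options appear
        as zero-count columns.
        """
        sl = self.slice(question, session)
        tab = (
            sl.groupby(["case_id", "choice"], sort=True)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=list(self.categories), fill_value=0)
        )
        tab.columns.name = None
        return tab

    def records(self) -> list:
        """Materialize the rows as :class:`DecisionRecord` objects."""
        out = []
        for row in self._data.itertuples(index=False):
            out.append(
                DecisionRecord(
                    rater_id=row.rater_id,
                    case_id=row.case_id,
                    session=int(row.session),
                    question_id=row.question_id,
                    choice=row.choice,
                    confidence=None if pd.isna(row.confidence) else int(row.confidence),
                    trial_proposal=None
                    if pd.isna(row.trial_proposal)
                    else bool(row.trial_proposal),
                )
            )
        return out


def _canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    return (
        df.sort_values(["case_id", "rater_id", "session", "question_id"])
        .reset_index(drop=True)
        .astype({"session": "int64"})
    )


def _records_to_frame(records: Iterable[DecisionRecord]) -> pd.DataFrame:
    rows = [
        (
            r.rater_id,
            r.case_id,
            int(r.session),
            r.question_id,
            r.choice,
            r.confidence,
            r.trial_proposal,
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=COLUMNS)
    df["confidence"] = df["confidence"].astype("Int64")
    df["trial_proposal"] = df["trial_proposal"].astype("boolean")
    return df


def validate_matrix(
    records: Union[Iterable[DecisionRecord], pd.DataFrame],
    categories: Optional[Sequence[str]] = None,
) -> DecisionMatrix:
    """Validate raw records and assemble a :class:`DecisionMatrix`.

    Checks: non-empty input, sessions in {1, 2}, non-empty choice labels,
    and at most one record per (rater, case, session, question) tuple.

    Raises
    ------
    EmptyInputError, DuplicateRecordError, ValidationError
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        for col in ("confidence", "trial_proposal"):
            if col not in df.columns:
                df[col] = pd.NA
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise MissingColumnError(f"missing required columns: {missing}")
        df = df[COLUMNS]
    else:
        records = list(records)
        if not records:
            raise EmptyInputError("no decision records supplied")
        df = _records_to_frame(records)
    if df.empty:
        raise EmptyInputError("no decision records supplied")

    for col in ("rater_id", "case_id", "question_id", "choice"):
        df[col] = df[col].astype(str)
    try:
        df["session"] = df["session"].astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable session value: {exc}") from exc
    bad_session = ~df["session"].isin([1, 2])
    if bad_session.any():
        raise ValidationError(
            f"session must be 1 or 2; offending values: "
            f"{sorted(df.loc[bad_session, 'session'].unique().tolist())}"
        )
    if (df["choice"].str.len() == 0).any():
        raise ValidationError("empty choice label in records")
    df["confidence"] = df["confidence"].astype("Int64")
    df["trial_proposal"] = _coerce_boolean(df["trial_proposal"])

    key = ["rater_id", "case_id", "session", "question_id"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0]
        raise DuplicateRecordError(tuple(first))

    return DecisionMatrix(_canonical_sort(df), categories=categories)


def _coerce_boolean(s: pd.Series) -> pd.Series:
    if s.dtype == "boolean":
        return s
    mapping = {
        "true": True, "false": False, "True": True, "False": False,
        "1": True, "0": False, True: True, False: False, 1: True, 0: False,
        1.0: True, 0.0: False,
    }
    return s.map(lambda v: pd.NA if pd.isna(v) else mapping.get(v, v)).astype("boolean")


# ---------------------------------------------------------------------------
# File I/O


def read_decisions(
    path: Union[str, Path, io.TextIOBase],
    dialect: Optional[Mapping[str, str]] = None,
    categories: Optional[Sequence[str]] = None,
) -> DecisionMatrix:
    """Read a long-format decisions CSV and return a validated matrix.

    Parameters
    ----------
    path : path or open text file
    dialect : mapping, optional
        Maps canonical column names to the file's column names, e.g.
        ``{"rater_id": "clinician"}``.  Unmapped names are used as-is.
    categories : sequence, optional
        Declared option list (see :class:`DecisionMatrix`).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    dialect = dict(dialect or {})
    rename = {file_col: canon for canon, file_col in dialect.items()}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"decisions file is missing required columns: {missing} "
            f"(found: {list(df.columns)})"
        )
    for col in ("confidence", "trial_proposal"):
        if col not in df.columns:
            df[col] = pd.NA
    df["confidence"] = pd.to_numeric(df["confidence"], errors="raise").astype("Int64")
    return validate_matrix(df[COLUMNS], categories=categories)


def write_decisions(matrix: DecisionMatrix, path: Union[str, Path]) -> Path:
    """Write the matrix as a long-format CSV with deterministic row order
    (case, rater, session, question).  Booleans are written as true/false,
    missing optional fields as empty cells; a write-read-write cycle is
    byte-identical."""
    if len(matrix) == 0:
        raise EmptyInputError("refusing to write an empty decision matrix")
    df = _canonical_sort(matrix.data).copy()
    df["confidence"] = df["confidence"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df["trial_proposal"] = df["trial_proposal"].map(
        lambda v: "" if pd.isna(v) else ("true" if v else "false")
    )
    path = Path(path)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def read_roster(path: Union[str, Path, io.TextIOBase]) -> list:
    """Read roster.csv (rater_id, specialty, experience, center)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if "rater_id" not in df.columns or "specialty" not in df.columns:
        raise MissingColumnError(
            f"roster needs rater_id and specialty columns (found {list(df.columns)})"
        )
    if df["rater_id"].duplicated().any():
        raise ValidationError("duplicate rater_id in roster")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            RaterProfile(
                rater_id=row.rater_id,
                specialty=row.specialty,
                experience=getattr(row, "experience", None) if "experience" in df.columns else None,
                center=getattr(row, "center", None) if "center" in df.columns else None,
            )
        )
    return out


def write_roster(roster: Sequence[RaterProfile], path: Union[str, Path]) -> Path:
    df = pd.DataFrame(
        [(r.rater_id, r.specialty, r.experience or "", r.center or "") for r in roster],
        columns=["rater_id", "specialty", "experience", "center"],
    )
    path = Path(path)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def read_portfolio(path: Union[str, Path, io.TextIOBase]) -> Portfolio:
    """Read portfolio.csv (case_id, control_class, free covariate columns)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if "case_id" not in df.columns or "control_class" not in df.columns:
        raise MissingColumnError(
            f"portfolio needs case_id and control_class columns (found {list(df.columns)})"
        )
    covar_cols = [c for c in df.columns if c not in ("case_id", "control_class")]
    vignettes = [
        CaseVignette(
            case_id=row["case_id"],
            control_class=row["control_class"],
            covariates={c: row[c] for c in covar_cols if pd.notna(row[c])},
        )
        for _, row in df.iterrows()
    ]
    return Portfolio.from_vignettes(vignettes)


def write_portfolio(portfolio: Portfolio, path: Union[str, Path]) -> Path:
    covar_cols = sorted({k for v in portfolio.vignettes for k in v.covariates})
    rows = []
    for v in portfolio.vignettes:
        row = {"case_id": v.case_id, "control_class": v.control_class}
        row.update({c: v.covariates.get(c, "") for c in covar_cols})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["case_id", "control_class", *covar_cols])
    path = Path(path)
    df.to_csv(path, index=False, lineterminator="\n")
    return path
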