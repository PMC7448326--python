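"""Two-session intra-rater reliability.

When the same clinician rates the same case portfolio twice (typically weeks
apart, cases re-presented in a different order), their self-consistency is a
second, humbling window on clinical uncertainty: a clinician who recommends
opposite options to the same patient demonstrates the uncertainty directly.

This module pairs the two sessions, computes per-rater decision-change
proportions and self-kappas (Cohen's kappa of a rater against their own
second session), per-case change fractions, and renders the case-level
summary sentence of the form "at least k/n clinicians (p%) changed their own
decision in q% (m/Z) of cases".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from equipoise.agreement import cohen_kappa_from_pairs
from equipoise.decision_data import DecisionMatrix
from equipoise.errors import DegenerateChanceError, EmptyInputError, ValidationError

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding, halves away from zero (so 17.05 -> 17.1)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(x: float) -> str:
    """One-decimal percent, trailing '.0' trimmed (25.0 -> '25', 17.07 -> '17.1')."""
    r = round_half_up(x, 1)
    return str(int(r)) if r == int(r) else f"{r:.1f}"


@dataclass(frozen=True)
class PairedSessions:
    """One row per (rater, case) with both session choices."""

    pairs: pd.DataFrame          # columns: rater_id, case_id, choice_1, choice_2
    n_unpaired: int              # observations present in only one session
    categories: tuple

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class IntraRaterSummary:
    """Rendered fields of the case-level decision-change sentence."""

    threshold: float
    k_raters: int
    n_raters: int
    pct_raters: float
    m_cases: int
    Z_cases: int
    pct_cases: float
    sentence: str


@dataclass(frozen=True)
class IntraRaterResult:
    """Per-rater and per-case decision-change metrics across two sessions."""

    per_rater: pd.DataFrame      # rater_id, n_cases, n_changed, change_proportion, self_kappa
    per_case: pd.DataFrame       # case_id, n_paired, n_changed, change_fraction
    n_unpaired: int
    qualifying_cases: tuple = ()
    summary: Optional[IntraRaterSummary] = None


def pair_sessions(matrix: DecisionMatrix, question: str) -> PairedSessions:
    """Join session-1 and session-2 choices per (rater, case).

    Unpaired observations (a rater/case seen in only one session) are
    excluded and counted.
    """
    s1 = matrix.slice(question, 1).set_index(["rater_id", "case_id"])["choice"]
    try:
        s2 = matrix.slice(question, 2).set_index(["rater_id", "case_id"])["choice"]
    except EmptyInputError:
        raise EmptyInputError(
            f"question {question!r} has no session-2 records; intra-rater "
            "analysis needs both sessions"
        )
    pairs = pd.concat([s1.rename("choice_1"), s2.rename("choice_2")], axis=1)
    n_unpaired = int(pairs.isna().any(axis=1).sum())
    pairs = pairs.dropna().reset_index()
    if pairs.empty:
        raise EmptyInputError(f"no paired observations for question {question!r}")
    if n_unpaired:
        logger.info("%d unpaired session observations excluded", n_unpaired)
    return PairedSessions(
        pairs=pairs.sort_values(["rater_id", "case_id"]).reset_index(drop=True),
        n_unpaired=n_unpaired,
        categories=matrix.categories,
    )


def rater_change_metrics(paired: PairedSessions) -> IntraRaterResult:
    """Per-rater change proportions and self-kappas; per-case change fractions.

    A "change" is a (rater, case) pair whose session-2 choice differs from
    session 1.  The self-kappa is Cohen's kappa between a rater's two
    sessions; it is NaN when undefined (rater constant on one category in
    both sessions, so chance agreement is 1).
    """
    df = paired.pairs
    if df.empty:
        raise EmptyInputError("empty paired table")
    changed = df["choice_1"] != df["choice_2"]

    per_rater_rows = []
    for rater, grp in df.assign(changed=changed).groupby("rater_id", sort=True):
        try:
            kappa, _, _, _ = cohen_kappa_from_pairs(
                grp["choice_1"], grp["choice_2"], paired.categories
            )
        except DegenerateChanceError:
            kappa = float("nan")
        per_rater_rows.append(
            {
                "rater_id": rater,
                "n_cases": len(grp),
                "n_changed": int(grp["changed"].sum()),
                "change_proportion": float(grp["changed"].mean()),
                "self_kappa": kappa,
            }
        )
    per_rater = pd.DataFrame(per_rater_rows)

    per_case = (
        df.assign(changed=changed)
        .groupby("case_id", sort=True)
        .agg(n_paired=("changed", "size"), n_changed=("changed", "sum"))
        .reset_index()
    )
    per_case["change_fraction"] = per_case["n_changed"] / per_case["n_paired"]
    return IntraRaterResult(
        per_rater=per_rater, per_case=per_case, n_unpaired=paired.n_unpaired
    )


def intrarater_case_summary(
    result: IntraRaterResult,
    rater_change_threshold: float = 0.25,
    min_paired_raters: int = 2,
) -> IntraRaterResult:
    """Count cases where at least a threshold fraction of raters changed
    their decision, and render the plain-language summary sentence.

    ``k`` in the sentence is the minimum rater count implied by the
    threshold (ceiling of threshold x n raters), matching "at least k/n"
    phrasing.  Percentages are rounded to one decimal, halves away from
    zero.  Cases with fewer than ``min_paired_raters`` paired raters are
    excluded from the case-level count (logged).
    """
    if not (0 < rater_change_threshold <= 1):
        raise ValidationError(
            f"rater_change_threshold must be in (0, 1], got {rater_change_threshold}"
        )
    per_case = result.per_case
    usable = per_case[per_case["n_paired"] >= min_paired_raters]
    n_excluded = len(per_case) - len(usable)
    if n_excluded:
        logger.warning(
            "%d case(s) with fewer than %d paired raters excluded from the "
            "intra-rater case summary", n_excluded, min_paired_raters,
        )
    qualifying = usable[usable["change_fraction"] >= rater_change_threshold - 1e-12]
    m = len(qualifying)
    Z = len(usable)
    n_raters = int(result.per_rater["rater_id"].nunique())
    k = math.ceil(rater_change_threshold * n_raters)
    pct_raters = 100.0 * k / n_raters if n_raters else float("nan")
    pct_cases = round_half_up(100.0 * m / Z, 1) if Z else float("nan")
    sentence = (
        f"at least {k}/{n_raters} clinicians ({format_percent(pct_raters)}%) "
        f"changed their own decision in {pct_cases:.1f}% ({m}/{Z}) of cases"
    )
    summary = IntraRaterSummary(
        threshold=rater_change_threshold,
        k_raters=k,
        n_raters=n_raters,
        pct_raters=pct_raters,
        m_cases=m,
        Z_cases=Z,
        pct_cases=pct_cases,
        sentence=sentence,
    )
    return IntraRaterResult(
        per_rater=result.per_rater,
        per_case=result.per_case,
        n_unpaired=result.n_unpaired,
        qualifying_cases=tuple(qualifying["case_id"]),
        summary=summary,
    )
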