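"""Per-case disagreement analytics and equipoise-candidate identification.

Where the kappa family summarizes agreement across a whole portfolio, this
module looks one case at a time: how did the votes split, which cases show
real disagreement (the equipoise-rich cases a randomized trial could
recruit), and does clinicians' willingness to propose a trial track the
disagreement?

The per-case disagreement measure is the *minority share*: the fraction of
raters outside the modal decision category (0 = unanimous; 0.5 = an even
binary split, maximal disagreement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from equipoise.decision_data import DecisionMatrix
from equipoise.errors import EmptyInputError, ValidationError
from equipoise.intrarater import round_half_up

logger = logging.getLogger(__name__)

#: disagreement threshold used in the standard summary ("at least 1/3 of
#: physicians disagreed"); chosen so an even binary split always qualifies
DEFAULT_MINORITY_THRESHOLD = 1.0 / 3.0


@dataclass(frozen=True)
class CaseVoteProfile:
    """Vote breakdown for one case on one question."""

    case_id: str
    counts: dict                 # category -> n_ij
    proportions: dict            # category -> n_ij / n_i
    n_raters: int
    majority_category: Optional[str]   # None when tied
    is_tie: bool
    minority_share: float        # 1 - max_j n_ij / n_i
    disagreement_flag: bool
    trial_vote_proportion: Optional[float] = None


def case_vote_profiles(
    matrix: DecisionMatrix,
    question: str,
    session: int = 1,
    minority_threshold: float = DEFAULT_MINORITY_THRESHOLD,
    trial_question: Optional[str] = None,
    trial_positive: str = "yes",
) -> list:
    """One vote profile per case (cases with fewer than 2 raters excluded).

    An exact tie for the modal category is marked explicitly
    (``majority_category=None``, ``is_tie=True``) — maximal disagreement.
    ``trial_question`` optionally attaches the per-case proportion of
    ``trial_positive`` answers to a companion trial-proposal question.
    """
    tab = matrix.count_table(question, session)
    tab = tab[tab.sum(axis=1) >= 2]
    if tab.empty:
        raise EmptyInputError(
            f"no cases with >=2 raters for question {question!r}, session {session}"
        )
    trial_props = (
        _trial_proportions(matrix, trial_question, session, trial_positive)
        if trial_question is not None
        else {}
    )
    profiles = []
    for case_id, row in tab.iterrows():
        counts = row.to_dict()
        n = int(row.sum())
        top = row.max()
        winners = [c for c, v in counts.items() if v == top]
        minority_share = 1.0 - top / n
        profiles.append(
            CaseVoteProfile(
                case_id=case_id,
                counts={c: int(v) for c, v in counts.items()},
                proportions={c: v / n for c, v in counts.items()},
                n_raters=n,
                majority_category=winners[0] if len(winners) == 1 else None,
                is_tie=len(winners) > 1,
                minority_share=float(minority_share),
                disagreement_flag=minority_share >= minority_threshold - 1e-12,
                trial_vote_proportion=trial_props.get(case_id),
            )
        )
    return profiles


def _trial_proportions(matrix, trial_question, session, trial_positive):
    sl = matrix.slice(trial_question, session)
    observed = set(sl["choice"].unique())
    if trial_positive not in observed and trial_positive not in matrix.categories:
        raise ValidationError(
            f"trial_positive {trial_positive!r} not among the trial question's "
            f"choices {sorted(observed)}"
        )
    grp = sl.groupby("case_id")["choice"]
    return (grp.apply(lambda s: float((s == trial_positive).mean()))).to_dict()


@dataclass(frozen=True)
class RaterRates:
    """Per-rater proportion of decisions in a target category, with spread."""

    rates: pd.DataFrame          # rater_id, n_cases, n_target, proportion
    target_category: str
    min: float
    max: float
    range: float


def rater_decision_rates(
    matrix: DecisionMatrix,
    question: str,
    target_category: str,
    session: int = 1,
) -> RaterRates:
    """For each rater, the fraction of their cases assigned the target
    category, plus the min/max/range across raters (the spread signal:
    identical overall rates can hide wide per-rater discrepancies)."""
    if target_category not in matrix.categories:
        raise ValidationError(
            f"unknown category {target_category!r}; categories are {list(matrix.categories)}"
        )
    sl = matrix.slice(question, session)
    grp = sl.assign(hit=sl["choice"] == target_category).groupby("rater_id", sort=True)
    rates = grp.agg(n_cases=("hit", "size"), n_target=("hit", "sum")).reset_index()
    rates["proportion"] = rates["n_target"] / rates["n_cases"]
    lo = float(rates["proportion"].min())
    hi = float(rates["proportion"].max())
    return RaterRates(
        rates=rates, target_category=target_category, min=lo, max=hi, range=hi - lo
    )


@dataclass(frozen=True)
class DisagreementSummary:
    """How many cases show at least a threshold level of disagreement."""

    minority_threshold: float
    threshold_pct: float
    m_cases: int
    Z_cases: int
    pct_cases: float
    more_than_third: Optional[bool]
    sentence: str


def disagreement_summary(
    profiles: Sequence[CaseVoteProfile],
    minority_threshold: float = DEFAULT_MINORITY_THRESHOLD,
) -> DisagreementSummary:
    """Count cases whose minority share reaches the threshold.

    At the default threshold of 1/3 the summary also reports whether the
    qualifying cases themselves exceed 1/3 of the portfolio ("at least 1/3
    of physicians disagreed in more than 1/3 of cases").
    """
    if not profiles:
        raise EmptyInputError("no case profiles")
    n_cat = len(profiles[0].counts)
    upper = (n_cat - 1) / n_cat
    if not (0 < minority_threshold <= upper + 1e-12):
        raise ValidationError(
            f"minority_threshold must be in (0, {upper:.4g}] for {n_cat} "
            f"categories, got {minority_threshold}"
        )
    m = sum(p.minority_share >= minority_threshold - 1e-12 for p in profiles)
    Z = len(profiles)
    pct = round_half_up(100.0 * m / Z, 1)
    at_third = abs(minority_threshold - 1.0 / 3.0) < 1e-9
    more_than_third = (m / Z > 1.0 / 3.0) if at_third else None
    thr_pct = round_half_up(100.0 * minority_threshold, 1)
    sentence = (
        f"at least {thr_pct:.1f}% of physicians disagreed in "
        f"{pct:.1f}% ({m}/{Z}) of cases"
    )
    return DisagreementSummary(
        minority_threshold=minority_threshold,
        threshold_pct=thr_pct,
        m_cases=m,
        Z_cases=Z,
        pct_cases=pct,
        more_than_third=more_than_third,
        sentence=sentence,
    )


def equipoise_candidates(
    profiles: Sequence[CaseVoteProfile],
    minority_threshold: float = DEFAULT_MINORITY_THRESHOLD,
    trial_threshold: Optional[float] = None,
) -> list:
    """Case ids where disagreement (and, optionally, willingness to propose
    a trial) is high enough to consider the case a randomization candidate.

    Sorted by descending minority share, ties broken by case id.
    """
    if trial_threshold is not None and all(
        p.trial_vote_proportion is None for p in profiles
    ):
        raise ValidationError(
            "trial_threshold given but no trial votes are attached to the profiles"
        )
    selected = [
        p
        for p in profiles
        if p.minority_share >= minority_threshold - 1e-12
        and (
            trial_threshold is None
            or (
                p.trial_vote_proportion is not None
                and p.trial_vote_proportion >= trial_threshold - 1e-12
            )
        )
    ]
    selected.sort(key=lambda p: (-p.minority_share, p.case_id))
    return [p.case_id for p in selected]


def sort_for_votebar(
    profiles: Sequence[CaseVoteProfile], target_category: str
) -> list:
    """Order profiles for a stacked vote-bar display: descending proportion
    of the target category (near-unanimous 'for' at the top, near-unanimous
    'against' at the bottom, contested cases in between); ties by case id."""
    if profiles and target_category not in profiles[0].counts:
        raise ValidationError(f"unknown category {target_category!r}")
    return sorted(
        profiles,
        key=lambda p: (-p.proportions.get(target_category, 0.0), p.case_id),
    )


def votebar_table(profiles: Sequence[CaseVoteProfile], target_category: str) -> pd.DataFrame:
    """Export-ready stacked-bar table: case_id, one proportion column per
    category, order index (0 = top of the bar chart)."""
    ordered = sort_for_votebar(profiles, target_category)
    cats = list(ordered[0].counts) if ordered else []
    rows = [
        {"case_id": p.case_id, **{c: p.proportions[c] for c in cats}, "order": i}
        for i, p in enumerate(ordered)
    ]
    return pd.DataFrame(rows, columns=["case_id", *cats, "order"])


@dataclass(frozen=True)
class TrialConcordance:
    """Association between per-case disagreement and trial-vote support."""

    table: pd.DataFrame          # case_id, minority_share, trial_vote_proportion
    spearman_rho: float          # NaN when undefined (zero variance)
    p_value: Optional[float]
    n_permutations: int
    defined: bool


def trial_concordance(
    matrix: DecisionMatrix,
    decision_question: str,
    trial_question: str,
    session: int = 1,
    n_permutations: int = 999,
    seed: int = 0,
    trial_positive: str = "yes",
) -> TrialConcordance:
    """Spearman rank correlation between per-case minority share on the
    decision question and per-case trial-vote proportion, with a seeded
    permutation p-value (two-sided, on |rho|).

    A positive correlation indicates that clinicians propose randomization
    precisely where they disagree — the operational signature of equipoise.
    Reported as undefined when either variable has zero variance.
    """
    profiles = case_vote_profiles(
        matrix,
        decision_question,
        session=session,
        trial_question=trial_question,
        trial_positive=trial_positive,
    )
    tab = pd.DataFrame(
        {
            "case_id": [p.case_id for p in profiles],
            "minority_share": [p.minority_share for p in profiles],
            "trial_vote_proportion": [p.trial_vote_proportion for p in profiles],
        }
    ).dropna(subset=["trial_vote_proportion"])
    if tab.empty:
        raise EmptyInputError(f"no per-case trial votes for {trial_question!r}")
    x = tab["minority_share"].to_numpy()
    y = tab["trial_vote_proportion"].to_numpy()
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.warning("trial concordance undefined: zero variance in an input")
        return TrialConcordance(
            table=tab, spearman_rho=float("nan"), p_value=None,
            n_permutations=0, defined=False,
        )
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm_rho = stats.spearmanr(x, rng.permutation(y)).statistic
        if abs(perm_rho) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return TrialConcordance(
        table=tab, spearman_rho=rho, p_value=float(p),
        n_permutations=n_permutations, defined=True,
    )
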