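"""Inter-rater agreement statistics for categorical management decisions.

Implements the kappa family used to summarize how reliably clinicians make
the same management decision on the same case:

* raw percent (pairwise) agreement, no chance correction;
* Fleiss' kappa generalized to a variable number of raters per case
  (real surveys have missing responses): per-case pairwise agreement
  P_i = (sum_j n_ij^2 - n_i) / (n_i (n_i - 1)), mean observed agreement
  P-bar, pooled category proportions p_j = sum_i n_ij / sum_i n_i, chance
  agreement P-bar_e = sum_j p_j^2, and kappa = (P-bar - P-bar_e) / (1 - P-bar_e);
* Cohen's kappa for two raters over their shared cases;
* PABAK (prevalence- and bias-adjusted kappa, 2 p_o - 1) for binary
  questions, insensitive to decision prevalence;
* percentile bootstrap confidence intervals by case resampling;
* the Landis-Koch verbal interpretation scale, with 0.6 as the lower bound
  of "substantial" agreement;
* subgroup analyses by rater (roster field) or case (portfolio field).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from equipoise.decision_data import DecisionMatrix, Portfolio, RaterProfile
from equipoise.errors import (
    AnalysisError,
    DegenerateChanceError,
    InsufficientCasesError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: tolerance below which 1 - chance agreement is treated as zero
DEGENERACY_TOL = 1e-12

#: Landis-Koch bands: (upper bound, label); intervals closed on the upper end
_LANDIS_KOCH = [
    (0.0, "poor"),       # kappa < 0
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
]

#: threshold below-or-at which agreement is not yet "substantial"
SUBSTANTIAL_THRESHOLD = 0.60


@dataclass(frozen=True)
class KappaBand:
    band: str
    below_substantial: bool


@dataclass(frozen=True)
class AgreementResult:
    """A kappa (or agreement proportion) with its chance components and CI."""

    method: str
    kappa: float
    observed_agreement: float
    chance_agreement: Optional[float]
    category_proportions: Mapping[str, float]
    n_raters: int
    n_cases: int
    band: Optional[str] = None
    below_substantial: Optional[bool] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    ci_method: Optional[str] = None
    ci_level: Optional[float] = None
    n_bootstrap: Optional[int] = None
    n_dropped_replicates: int = 0
    subgroup: Optional[str] = None
    status: str = "ok"
    caution_wide_ci: bool = False
    n_excluded_cases: int = 0

    def to_record(self) -> dict:
        """Flat record for CSV/JSON serialization."""
        return {
            "method": self.method,
            "subgroup": self.subgroup,
            "status": self.status,
            "kappa": self.kappa,
            "observed_agreement": self.observed_agreement,
            "chance_agreement": self.chance_agreement,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "ci_method": self.ci_method,
            "n_raters": self.n_raters,
            "n_cases": self.n_cases,
            "band": self.band,
            "caution_wide_ci": self.caution_wide_ci,
        }


def interpret_kappa(kappa: float) -> KappaBand:
    """Landis-Koch verbal band for a kappa value.

    Bands (upper ends closed): below 0 "poor"; [0, 0.20] "slight";
    (0.20, 0.40] "fair"; (0.40, 0.60] "moderate"; (0.60, 0.80]
    "substantial"; (0.80, 1] "almost perfect".  ``below_substantial`` is
    True whenever kappa <= 0.6, i.e. agreement has not reached the
    conventional "substantial" level.
    """
    if kappa > 1:
        raise ValidationError(f"kappa cannot exceed 1, got {kappa}")
    if kappa < 0:
        band = "poor"
    else:
        band = next(label for ub, label in _LANDIS_KOCH[1:] if kappa <= ub + 1e-15)
    return KappaBand(band=band, below_substantial=kappa <= SUBSTANTIAL_THRESHOLD)


# ---------------------------------------------------------------------------
# count-table primitives (shared with bootstrap and the power simulator)


def _usable_counts(matrix: DecisionMatrix, question: str, session: int):
    """Count table restricted to cases with n_i >= 2; returns
    (counts ndarray Z x J, case ids, number excluded)."""
    tab = matrix.count_table(question, session)
    n_i = tab.sum(axis=1)
    keep = n_i >= 2
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning(
            "%d case(s) with fewer than 2 raters excluded from agreement "
            "estimation (question=%r, session=%d)", n_excluded, question, session
        )
    tab = tab[keep]
    return tab.to_numpy(dtype=float), list(tab.index), n_excluded


def pairwise_agreement_per_case(counts: np.ndarray) -> np.ndarray:
    """P_i = (sum_j n_ij^2 - n_i) / (n_i (n_i - 1)) for each row."""
    n_i = counts.sum(axis=1)
    return (np.square(counts).sum(axis=1) - n_i) / (n_i * (n_i - 1))


def fleiss_from_counts(counts: np.ndarray) -> tuple:
    """(kappa, P-bar, P-bar_e, p_j) from a cases x categories count table.

    Supports unequal numbers of raters per case; p_j pools all assignments.
    Raises :class:`DegenerateChanceError` when all assignments fall in one
    category (chance agreement 1, kappa undefined).
    """
    if counts.shape[0] < 2:
        raise InsufficientCasesError(
            f"need at least 2 cases with >=2 raters, got {counts.shape[0]}"
        )
    p_i = pairwise_agreement_per_case(counts)
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / counts.sum()
    p_e = float(np.square(p_j).sum())
    if 1.0 - p_e < DEGENERACY_TOL:
        raise DegenerateChanceError(
            "all assignments fall in a single category; kappa is undefined"
        )
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return float(kappa), p_bar, p_e, p_j


# ---------------------------------------------------------------------------
# public estimators


def percent_agreement(
    matrix: DecisionMatrix, question: str, session: int = 1
) -> AgreementResult:
    """Mean over cases of pairwise percent agreement; no chance correction."""
    counts, _, n_excl = _usable_counts(matrix, question, session)
    if counts.shape[0] == 0:
        raise InsufficientCasesError("all cases have fewer than 2 raters")
    p_i = pairwise_agreement_per_case(counts)
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / counts.sum()
    return AgreementResult(
        method="percent",
        kappa=p_bar,
        observed_agreement=p_bar,
        chance_agreement=None,
        category_proportions=dict(zip(matrix.categories, p_j)),
        n_raters=matrix.n_raters,
        n_cases=counts.shape[0],
        n_excluded_cases=n_excl,
    )


def fleiss_kappa(
    matrix: DecisionMatrix, question: str, session: int = 1
) -> AgreementResult:
    """Fleiss' kappa (generalized to unequal raters per case) for one
    question/session slice."""
    counts, _, n_excl = _usable_counts(matrix, question, session)
    kappa, p_bar, p_e, p_j = fleiss_from_counts(counts)
    band = interpret_kappa(kappa)
    return AgreementResult(
        method="fleiss",
        kappa=kappa,
        observed_agreement=p_bar,
        chance_agreement=p_e,
        category_proportions=dict(zip(matrix.categories, p_j)),
        n_raters=matrix.n_raters,
        n_cases=counts.shape[0],
        band=band.band,
        below_substantial=band.below_substantial,
        n_excluded_cases=n_excl,
    )


def cohen_kappa_from_pairs(
    a: Sequence[str], b: Sequence[str], categories: Sequence[str]
) -> tuple:
    """(kappa, p_o, p_e, cross-table) for two aligned rating vectors.

    p_e comes from the product of the two raters' marginal category
    proportions.  Raises :class:`DegenerateChanceError` if p_e = 1 (both
    raters constant on the same category).
    """
    a = pd.Categorical(a, categories=list(categories))
    b = pd.Categorical(b, categories=list(categories))
    table = pd.crosstab(a, b, dropna=False).reindex(
        index=list(categories), columns=list(categories), fill_value=0
    )
    n = table.to_numpy().sum()
    if n == 0:
        raise InsufficientCasesError("no shared cases between the two raters")
    p_o = float(np.diag(table).sum() / n)
    ma = table.sum(axis=1).to_numpy() / n
    mb = table.sum(axis=0).to_numpy() / n
    p_e = float((ma * mb).sum())
    if 1.0 - p_e < DEGENERACY_TOL:
        raise DegenerateChanceError(
            "both raters constant on the same category; kappa is undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    return float(kappa), p_o, p_e, table


def _shared_ratings(
    matrix: DecisionMatrix, question: str, rater_a: str, rater_b: str, session: int
):
    sl = matrix.slice(question, session)
    a = sl[sl["rater_id"] == rater_a].set_index("case_id")["choice"]
    b = sl[sl["rater_id"] == rater_b].set_index("case_id")["choice"]
    shared = sorted(set(a.index) & set(b.index))
    if not shared:
        raise InsufficientCasesError(
            f"raters {rater_a!r} and {rater_b!r} share no cases"
        )
    return a.loc[shared], b.loc[shared]


def cohen_kappa(
    matrix: DecisionMatrix,
    question: str,
    rater_a: str,
    rater_b: str,
    session: int = 1,
) -> AgreementResult:
    """Cohen's kappa between two raters over the intersection of their cases."""
    a, b = _shared_ratings(matrix, question, rater_a, rater_b, session)
    kappa, p_o, p_e, table = cohen_kappa_from_pairs(a, b, matrix.categories)
    band = interpret_kappa(kappa)
    marg = (table.sum(axis=1) + table.sum(axis=0)) / (2 * len(a))
    return AgreementResult(
        method="cohen",
        kappa=kappa,
        observed_agreement=p_o,
        chance_agreement=p_e,
        category_proportions=dict(marg),
        n_raters=2,
        n_cases=len(a),
        band=band.band,
        below_substantial=band.below_substantial,
        subgroup=f"{rater_a}|{rater_b}",
    )


def pabak(
    matrix: DecisionMatrix,
    question: str,
    rater_a: str,
    rater_b: str,
    session: int = 1,
) -> AgreementResult:
    """Prevalence- and bias-adjusted kappa, 2 p_o - 1, for a binary question."""
    if len(matrix.categories) != 2:
        raise ValidationError(
            f"PABAK requires a binary question; got {len(matrix.categories)} categories"
        )
    a, b = _shared_ratings(matrix, question, rater_a, rater_b, session)
    p_o = float((a.to_numpy() == b.to_numpy()).mean())
    kappa = 2.0 * p_o - 1.0
    band = interpret_kappa(kappa)
    return AgreementResult(
        method="pabak",
        kappa=kappa,
        observed_agreement=p_o,
        chance_agreement=0.5,
        category_proportions={},
        n_raters=2,
        n_cases=len(a),
        band=band.band,
        below_substantial=band.below_substantial,
        subgroup=f"{rater_a}|{rater_b}",
    )


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_replicates(
    counts: np.ndarray,
    method: str,
    B: int,
    rng: np.random.Generator,
) -> tuple:
    """Vectorized case-resampling bootstrap of the agreement statistic.

    Returns (replicate values, number of degenerate replicates dropped).
    """
    z = counts.shape[0]
    p_i = pairwise_agreement_per_case(counts)
    n_i = counts.sum(axis=1)
    idx = rng.integers(0, z, size=(B, z))
    p_bar = p_i[idx].mean(axis=1)
    if method == "percent":
        return p_bar, 0
    boot_counts = counts[idx]                       # B x Z x J
    p_j = boot_counts.sum(axis=1) / n_i[idx].sum(axis=1, keepdims=True)
    p_e = np.square(p_j).sum(axis=1)
    ok = (1.0 - p_e) >= DEGENERACY_TOL
    kappas = (p_bar[ok] - p_e[ok]) / (1.0 - p_e[ok])
    return kappas, int((~ok).sum())


def bootstrap_ci(
    matrix: DecisionMatrix,
    question: str,
    method: str = "fleiss",
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    session: int = 1,
) -> AgreementResult:
    """Percentile bootstrap CI for Fleiss' kappa or percent agreement.

    Cases are resampled with replacement (all raters kept); replicates with
    degenerate chance agreement are dropped and counted, with a warning when
    more than 1% are dropped.  Deterministic for a fixed seed.
    """
    if B < 100:
        raise ValidationError(f"B must be at least 100, got {B}")
    if method not in ("fleiss", "percent"):
        raise ValidationError(f"bootstrap supports methods fleiss|percent, got {method!r}")
    point = (
        fleiss_kappa(matrix, question, session)
        if method == "fleiss"
        else percent_agreement(matrix, question, session)
    )
    counts, _, _ = _usable_counts(matrix, question, session)
    rng = np.random.default_rng(seed)
    reps, n_dropped = bootstrap_replicates(counts, method, B, rng)
    if n_dropped > 0.01 * B:
        logger.warning(
            "%d of %d bootstrap replicates dropped for degenerate chance agreement",
            n_dropped, B,
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return replace(
        point,
        ci_lower=float(lo),
        ci_upper=float(hi),
        ci_method="percentile-bootstrap",
        ci_level=level,
        n_bootstrap=B,
        n_dropped_replicates=n_dropped,
    )


# ---------------------------------------------------------------------------
# subgroups

#: fewer analyzed cases than this triggers the wide-CI caution flag; set at
#: the design rule-of-thumb minimum portfolio size
WIDE_CI_MIN_CASES = 30

_ROSTER_FIELDS = ("specialty", "experience", "center")


def subgroup_agreement(
    matrix: DecisionMatrix,
    roster: Optional[Sequence[RaterProfile]],
    portfolio: Optional[Portfolio],
    question: str,
    by: str,
    session: int = 1,
    method: str = "fleiss",
) -> list:
    """One agreement result per subgroup level.

    ``by`` names either a roster field (rater subgroups: specialty,
    experience, center) or a portfolio field (case subgroups: control_class
    or any covariate).  Subgroups too small to estimate are returned with
    ``status='insufficient'`` rather than silently omitted; estimable
    subgroups with fewer than 30 analyzed cases carry a wide-CI caution
    flag (subgrouping reduces the observations and confidence intervals at
    such sizes are irremediably wide).
    """
    groups = _partition(matrix, roster, portfolio, by)
    estimator = fleiss_kappa if method == "fleiss" else percent_agreement
    results = []
    for level_label, sub_df in groups:
        try:
            sub = DecisionMatrix(sub_df, categories=matrix.categories)
            res = estimator(sub, question, session)
            res = replace(
                res,
                subgroup=f"{by}={level_label}",
                caution_wide_ci=res.n_cases < WIDE_CI_MIN_CASES,
            )
        except AnalysisError as exc:
            logger.warning("subgroup %s=%s not estimable: %s", by, level_label, exc)
            res = AgreementResult(
                method=method,
                kappa=float("nan"),
                observed_agreement=float("nan"),
                chance_agreement=None,
                category_proportions={},
                n_raters=int(sub_df["rater_id"].nunique()),
                n_cases=int(sub_df["case_id"].nunique()),
                subgroup=f"{by}={level_label}",
                status="insufficient",
            )
        results.append(res)
    return results


def _partition(matrix, roster, portfolio, by):
    """Yield (level label, sub-DataFrame) pairs for a partition spec."""
    df = matrix.data
    if roster is not None and by in _ROSTER_FIELDS:
        levels: dict = {}
        for r in roster:
            levels.setdefault(getattr(r, by), []).append(r.rater_id)
        return [
            (lvl, df[df["rater_id"].isin(ids)])
            for lvl, ids in sorted(levels.items(), key=lambda kv: str(kv[0]))
        ]
    if portfolio is not None:
        if by == "control_class":
            getter = lambda v: v.control_class
        elif any(by in v.covariates for v in portfolio.vignettes):
            getter = lambda v: v.covariates.get(by)
        else:
            raise ValidationError(f"unknown partition field {by!r}")
        levels = {}
        for v in portfolio.vignettes:
            levels.setdefault(getter(v), []).append(v.case_id)
        return [
            (lvl, df[df["case_id"].isin(ids)])
            for lvl, ids in sorted(levels.items(), key=lambda kv: str(kv[0]))
        ]
    raise ValidationError(
        f"unknown partition field {by!r} (no roster/portfolio field matches)"
    )
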