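"""Generative model for decision matrices, the thrombectomy-like standard
fixture, and simulation-based design of agreement studies.

The generative model is deliberately minimal: each case z carries a latent
intervention propensity theta_z drawn from a per-control-class Beta
distribution (positive controls high, negative controls low, grey-zone
cases spread around 1/2), each rater x carries an additive bias b_x ~
Normal(0, sigma^2) on the log-odds scale, and a binary decision is a
Bernoulli draw with probability inverse-logit(logit(theta_z) + b_x).
Session-2 decisions copy session 1 with probability 1 - rho and are
redrawn otherwise, so rho is the per-decision instability.  Trial-proposal
votes are Bernoulli with probability increasing in the case's intrinsic
uncertainty u_z = 4 theta_z (1 - theta_z), which peaks at theta_z = 1/2.

This is enough structure to reproduce the qualitative phenomena an
agreement study of management decisions exhibits: wide per-rater decision
rates, a case spectrum from near-unanimous to evenly split, and overall
kappa below the "substantial" level — without modeling any real clinical
covariate process.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from equipoise.agreement import (
    SUBSTANTIAL_THRESHOLD,
    bootstrap_replicates,
    fleiss_from_counts,
)
from equipoise.decision_data import (
    CaseVignette,
    DecisionMatrix,
    Portfolio,
    RaterProfile,
    validate_matrix,
)
from equipoise.errors import ValidationError

logger = logging.getLogger(__name__)

#: control classes in quota tie-break priority order
CLASS_ORDER = ("positive", "grey", "negative")

#: per-class Beta parameters of the case propensity theta_z; a float means a
#: point mass.  Positive controls near-unanimous for, negatives against,
#: grey zone spread around 1/2.
DEFAULT_THETA = {
    "positive": (14.0, 2.0),
    "grey": (2.0, 2.0),
    "negative": (2.0, 14.0),
}

ThetaSpec = Union[float, tuple]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the decision-generating process.

    Attributes
    ----------
    n_raters, n_cases : int
        Study size (X raters, Z cases).
    composition : tuple of three floats
        Portfolio fractions (positive, grey, negative); must sum to 1.
    theta_params : mapping class -> Beta(a, b) or point mass
        Case-propensity distribution per control class.
    rater_sigma : float
        SD of the per-rater bias on the log-odds scale (0 = homogeneous
        raters).
    stability_rho : float
        Probability a session-2 decision is redrawn rather than copied
        (0 = perfectly stable raters, 1 = fresh independent draw).
    n_session2_raters : int
        Size of the intra-rater subset (first raters in id order) that
        rates the portfolio a second time; 0 disables session 2.
    trial_link : float or None
        Slope linking trial-vote propensity to case uncertainty
        u_z = 4 theta_z (1 - theta_z) on the log-odds scale; None disables
        the trial question.
    trial_base : float
        Trial-vote probability at zero case uncertainty.
    question_id, trial_question_id : str
        Question labels used in the generated records.
    specialties : mapping label -> count, optional
        Rater blocks for the roster (counts must sum to n_raters).
    seed : int
    """

    n_raters: int = 10
    n_cases: int = 40
    composition: tuple = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    theta_params: Mapping[str, ThetaSpec] = field(
        default_factory=lambda: dict(DEFAULT_THETA)
    )
    rater_sigma: float = 0.6
    stability_rho: float = 0.0
    n_session2_raters: int = 0
    trial_link: Optional[float] = None
    trial_base: float = 0.1
    question_id: str = "decision"
    trial_question_id: str = "trial"
    specialties: Optional[Mapping[str, int]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_raters < 1 or self.n_cases < 1:
            raise ValidationError("n_raters and n_cases must be positive")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValidationError(
                f"composition fractions must sum to 1, got {self.composition}"
            )
        if any(f < 0 for f in self.composition):
            raise ValidationError("composition fractions must be non-negative")
        if not (0.0 <= self.stability_rho <= 1.0):
            raise ValidationError(f"stability_rho must be in [0,1], got {self.stability_rho}")
        if self.rater_sigma < 0:
            raise ValidationError(f"rater_sigma must be >= 0, got {self.rater_sigma}")
        for cls, spec in self.theta_params.items():
            if isinstance(spec, tuple):
                if spec[0] <= 0 or spec[1] <= 0:
                    raise ValidationError(
                        f"Beta parameters for class {cls!r} must be positive, got {spec}"
                    )
            elif not (0.0 <= float(spec) <= 1.0):
                raise ValidationError(
                    f"point-mass theta for class {cls!r} must be in [0,1], got {spec}"
                )
        if self.specialties is not None and sum(self.specialties.values()) != self.n_raters:
            raise ValidationError("specialty counts must sum to n_raters")


@dataclass(frozen=True)
class DesignVerdict:
    """Rule-of-thumb check of a planned study size."""

    n_raters: int
    n_cases: int
    raters_ok: bool          # at least 10 raters
    cases_ok: bool           # at least 30 cases
    burden_warning: bool     # more than 50 cases: respondent burden
    informative: bool
    messages: tuple


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo precision summary over a (raters x cases) design grid."""

    grid: dict               # (n_raters, n_cases) -> summary dict
    n_replicates: int
    n_bootstrap: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"n_raters": r, "n_cases": z, **summary}
            for (r, z), summary in sorted(self.grid.items())
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# portfolio composition


def compose_portfolio(n_cases: int, fractions: Sequence[float]) -> Portfolio:
    """Integer class counts by the largest-remainder method.

    ``fractions`` are (positive, grey, negative) and must sum to 1; quota
    ties are broken in the fixed order positive > grey > negative so the
    result is deterministic.  Returns a Portfolio skeleton (vignettes carry
    ids and classes, no covariates).
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3:
        raise ValidationError("fractions must be (positive, grey, negative)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1, got {fractions}")
    n_nonzero = sum(f > 0 for f in fractions)
    if n_cases < n_nonzero:
        raise ValidationError(
            f"cannot split {n_cases} case(s) across {n_nonzero} nonzero classes"
        )
    counts = _largest_remainder(n_cases, fractions)
    width = len(str(n_cases))
    vignettes = []
    i = 1
    for cls, k in zip(CLASS_ORDER, counts):
        for _ in range(k):
            vignettes.append(CaseVignette(case_id=f"case{i:0{width}d}", control_class=cls))
            i += 1
    return Portfolio.from_vignettes(vignettes)


def _largest_remainder(n: int, fractions: Sequence[float]) -> list:
    quotas = [n * f for f in fractions]
    counts = [math.floor(q) for q in quotas]
    remainder = n - sum(counts)
    # tie-break: larger fractional part first, then class priority order
    order = sorted(range(len(fractions)), key=lambda j: (-(quotas[j] - counts[j]), j))
    for j in order[:remainder]:
        counts[j] += 1
    return counts


# ---------------------------------------------------------------------------
# decision simulation


def _draw_theta(rng: np.random.Generator, spec: ThetaSpec, size: int) -> np.ndarray:
    if isinstance(spec, tuple):
        return rng.beta(spec[0], spec[1], size=size)
    return np.full(size, float(spec))


def _decision_probs(config: SimulationConfig, rng: np.random.Generator):
    """Latent structure: per-case theta_z, per-rater bias b_x, and the
    (cases x raters) matrix of yes-probabilities."""
    portfolio = compose_portfolio(config.n_cases, config.composition)
    classes = [v.control_class for v in portfolio.vignettes]
    theta = np.empty(config.n_cases)
    for cls in CLASS_ORDER:
        mask = np.array([c == cls for c in classes])
        if mask.any():
            theta[mask] = _draw_theta(rng, config.theta_params[cls], int(mask.sum()))
    bias = (
        rng.normal(0.0, config.rater_sigma, size=config.n_raters)
        if config.rater_sigma > 0
        else np.zeros(config.n_raters)
    )
    # point-mass 0/1 propensities stay exactly deterministic under zero bias
    eps = 1e-12
    logit_theta = logit(np.clip(theta, eps, 1 - eps))
    probs = expit(logit_theta[:, None] + bias[None, :])
    exact = (theta == 0.0) | (theta == 1.0)
    if exact.any() and config.rater_sigma == 0:
        probs[exact, :] = theta[exact, None]
    return portfolio, theta, bias, probs


def simulate_counts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Fast path: session-1 per-case count table (Z x 2, columns [no, yes])
    for a binary question, without building a record-level matrix."""
    _, _, _, probs = _decision_probs(config, rng)
    yes = (rng.random(probs.shape) < probs).sum(axis=1)
    return np.column_stack([config.n_raters - yes, yes]).astype(float)


def simulate_decisions(config: SimulationConfig) -> DecisionMatrix:
    """Draw a full record-level decision matrix from the generative model.

    Binary decisions (categories ``no``/``yes``); optional second session
    for the first ``n_session2_raters`` raters; optional trial-proposal
    question for all raters in session 1.  Fully reproducible given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    portfolio, theta, _, probs = _decision_probs(config, rng)
    rater_ids = [f"r{i + 1:02d}" for i in range(config.n_raters)]
    case_ids = portfolio.case_ids

    session1 = rng.random(probs.shape) < probs          # Z x X booleans
    rows = []
    for zi, case in enumerate(case_ids):
        for xi, rater in enumerate(rater_ids):
            rows.append(
                (rater, case, 1, config.question_id,
                 "yes" if session1[zi, xi] else "no")
            )

    k2 = min(config.n_session2_raters, config.n_raters)
    if k2 > 0:
        redraw = rng.random((len(case_ids), k2)) < config.stability_rho
        fresh = rng.random((len(case_ids), k2)) < probs[:, :k2]
        session2 = np.where(redraw, fresh, session1[:, :k2])
        for zi, case in enumerate(case_ids):
            for xi in range(k2):
                rows.append(
                    (rater_ids[xi], case, 2, config.question_id,
                     "yes" if session2[zi, xi] else "no")
                )

    if config.trial_link is not None:
        uncertainty = 4.0 * theta * (1.0 - theta)
        eps = 1e-12
        p_trial = expit(
            logit(np.clip(config.trial_base, eps, 1 - eps))
            + config.trial_link * uncertainty
        )
        trial = rng.random(probs.shape) < p_trial[:, None]
        for zi, case in enumerate(case_ids):
            for xi, rater in enumerate(rater_ids):
                rows.append(
                    (rater, case, 1, config.trial_question_id,
                     "yes" if trial[zi, xi] else "no")
                )

    df = pd.DataFrame(
        rows, columns=["rater_id", "case_id", "session", "question_id", "choice"]
    )
    return validate_matrix(df, categories=("no", "yes"))


def make_roster(config: SimulationConfig) -> list:
    """Roster matching the simulated rater ids, split into specialty blocks."""
    rater_ids = [f"r{i + 1:02d}" for i in range(config.n_raters)]
    if config.specialties is None:
        return [RaterProfile(rater_id=r, specialty="clinician") for r in rater_ids]
    roster = []
    it = iter(rater_ids)
    for specialty, count in config.specialties.items():
        for _ in range(count):
            roster.append(RaterProfile(rater_id=next(it), specialty=specialty))
    return roster


# ---------------------------------------------------------------------------
# the standard thrombectomy-like fixture


#: fixture study shape: 41-case portfolio in three control classes, 60 + 26
#: raters in two specialties, 20-rater intra-rater subset
FIXTURE_CONFIG = SimulationConfig(
    n_raters=86,
    n_cases=41,
    composition=(1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),
    rater_sigma=0.6,
    stability_rho=0.35,
    n_session2_raters=20,
    trial_link=4.5,
    trial_base=0.1,
    question_id="thrombectomy",
    trial_question_id="trial",
    specialties={"neurology": 60, "interventional": 26},
)

_MAX_FIXTURE_ATTEMPTS = 10


def make_thrombectomy_fixture(seed: int = 0):
    """The standard synthetic test study: 41 cases (14 positive, 14 grey,
    13 negative), 86 raters (60 neurology, 26 interventional), a binary
    intervention question plus a trial-proposal question, and a 20-rater
    intra-rater subset with session-2 ratings.

    The fixture is required to exhibit overall uncertainty: if a draw's
    global Fleiss kappa reaches the substantial level (0.6) it is discarded
    with a warning and regenerated from a derived seed.

    Returns (DecisionMatrix, Portfolio, roster).
    """
    for attempt in range(_MAX_FIXTURE_ATTEMPTS):
        child_seed = int(
            np.random.SeedSequence([seed, attempt]).generate_state(1)[0] % (2**31)
        ) if attempt else seed
        config = replace(FIXTURE_CONFIG, seed=child_seed)
        rng = np.random.default_rng(child_seed)
        portfolio, covars = _fixture_portfolio(config, rng)
        matrix = simulate_decisions(config)
        counts = matrix.count_table(config.question_id, session=1).to_numpy(dtype=float)
        kappa, _, _, _ = fleiss_from_counts(counts)
        if kappa < SUBSTANTIAL_THRESHOLD:
            return matrix, portfolio, make_roster(config)
        logger.warning(
            "fixture draw %d gave kappa=%.3f >= %.1f; regenerating",
            attempt, kappa, SUBSTANTIAL_THRESHOLD,
        )
    raise RuntimeError("could not generate a below-substantial fixture")


def _fixture_portfolio(config: SimulationConfig, rng: np.random.Generator):
    """Portfolio with simple stroke-like covariates (age, severity score)."""
    skeleton = compose_portfolio(config.n_cases, config.composition)
    vignettes = []
    for v in skeleton.vignettes:
        if v.control_class == "positive":
            age = int(rng.integers(45, 80))
            nihss = int(rng.integers(8, 25))
        elif v.control_class == "grey":
            age = int(rng.integers(75, 95))
            nihss = int(rng.integers(2, 28))
        else:
            age = int(rng.integers(55, 95))
            nihss = int(rng.integers(0, 6))
        vignettes.append(
            CaseVignette(
                case_id=v.case_id,
                control_class=v.control_class,
                covariates={"age": age, "nihss": nihss},
            )
        )
    portfolio = Portfolio.from_vignettes(vignettes)
    return portfolio, None


# ---------------------------------------------------------------------------
# design rules and power


def design_check(n_raters: int, n_cases: int) -> DesignVerdict:
    """Rule-of-thumb informativeness check for a planned agreement study:
    at least 10 raters reviewing 30-50 cases.  More than 50 cases passes
    with a respondent-burden warning (the larger the portfolio, the fewer
    clinicians willing to complete it)."""
    if n_raters < 1 or n_cases < 1:
        raise ValidationError("n_raters and n_cases must be positive integers")
    raters_ok = n_raters >= 10
    cases_ok = n_cases >= 30
    burden = n_cases > 50
    messages = []
    if not raters_ok:
        messages.append(f"fewer than 10 raters ({n_raters}): study unlikely to be informative")
    if not cases_ok:
        messages.append(f"fewer than 30 cases ({n_cases}): study unlikely to be informative")
    if burden:
        messages.append(
            f"more than 50 cases ({n_cases}): respondent burden may reduce participation"
        )
    return DesignVerdict(
        n_raters=n_raters,
        n_cases=n_cases,
        raters_ok=raters_ok,
        cases_ok=cases_ok,
        burden_warning=burden,
        informative=raters_ok and cases_ok,
        messages=tuple(messages),
    )


def power_curve(
    base_config: SimulationConfig,
    rater_grid: Sequence[int],
    case_grid: Sequence[int],
    n_replicates: int = 200,
    n_bootstrap: int = 200,
    level: float = 0.95,
) -> PowerResult:
    """Monte-Carlo precision of the Fleiss kappa estimate over a design grid.

    For each (n_raters, n_cases) point, ``n_replicates`` studies are drawn
    from the base generative truth; each yields a kappa estimate and a
    percentile-bootstrap CI (reduced ``n_bootstrap``, recorded in the
    result).  Reported per grid point: mean and SD of kappa-hat, its
    empirical 2.5%/97.5% quantiles, the mean CI half-width, and the
    probability that the CI upper bound stays below the substantial
    threshold 0.6 (the power to demonstrate uncertainty).  Raw Monte-Carlo
    values are reported; no smoothing across the grid.
    """
    if n_replicates < 50:
        raise ValidationError(f"n_replicates must be >= 50, got {n_replicates}")
    if any(r < 2 for r in rater_grid) or any(z < 2 for z in case_grid):
        raise ValidationError("grid values must be at least 2 raters and 2 cases")
    alpha = (1.0 - level) / 2.0
    grid = {}
    for gi, n_raters in enumerate(rater_grid):
        for gj, n_cases in enumerate(case_grid):
            config = replace(base_config, n_raters=n_raters, n_cases=n_cases)
            kappas = np.full(n_replicates, np.nan)
            halfwidths = np.full(n_replicates, np.nan)
            upper_below = np.zeros(n_replicates, dtype=bool)
            for rep in range(n_replicates):
                ss = np.random.SeedSequence([base_config.seed, gi, gj, rep])
                rng = np.random.default_rng(ss)
                counts = simulate_counts(config, rng)
                try:
                    kappas[rep], _, _, _ = fleiss_from_counts(counts)
                except Exception:
                    continue
                reps, _ = bootstrap_replicates(counts, "fleiss", n_bootstrap, rng)
                lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
                halfwidths[rep] = (hi - lo) / 2.0
                upper_below[rep] = hi < SUBSTANTIAL_THRESHOLD
            ok = ~np.isnan(kappas)
            grid[(n_raters, n_cases)] = {
                "mean_kappa": float(np.mean(kappas[ok])),
                "sd_kappa": float(np.std(kappas[ok], ddof=1)),
                "q025": float(np.quantile(kappas[ok], 0.025)),
                "q975": float(np.quantile(kappas[ok], 0.975)),
                "mean_ci_halfwidth": float(np.nanmean(halfwidths)),
                "prob_upper_ci_below_substantial": float(upper_below[ok].mean()),
                "n_failed": int((~ok).sum()),
            }
    return PowerResult(
        grid=grid,
        n_replicates=n_replicates,
        n_bootstrap=n_bootstrap,
        seed=base_config.seed,
    )
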