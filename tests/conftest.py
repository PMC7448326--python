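"""Shared fixtures: small hand-built decision matrices and the standard
synthetic thrombectomy-like study."""

import numpy as np
import pandas as pd
import pytest

from equipoise import make_thrombectomy_fixture, validate_matrix
from equipoise.decision_data import DecisionRecord


def records_from_counts(yes_counts, n_raters, question="q1", session=1):
    """Binary records where case i receives ``yes_counts[i]`` yes votes out
    of ``n_raters``; raters in id order vote yes first."""
    recs = []
    for ci, k in enumerate(yes_counts):
        for ri in range(n_raters):
            recs.append(
                DecisionRecord(
                    rater_id=f"r{ri + 1}",
                    case_id=f"c{ci + 1}",
                    session=session,
                    question_id=question,
                    choice="yes" if ri < k else "no",
                )
            )
    return recs


def matrix_from_counts(yes_counts, n_raters, **kw):
    return validate_matrix(records_from_counts(yes_counts, n_raters, **kw),
                           categories=("no", "yes"))


def random_matrix(rng, n_raters=None, n_cases=None, n_categories=None):
    """Complete random matrix for oracle comparisons."""
    n_raters = n_raters or int(rng.integers(2, 7))
    n_cases = n_cases or int(rng.integers(2, 8))
    n_categories = n_categories or int(rng.integers(2, 4))
    cats = [f"opt{j}" for j in range(n_categories)]
    recs = [
        DecisionRecord(
            rater_id=f"r{x}", case_id=f"c{z}", session=1, question_id="q1",
            choice=cats[int(rng.integers(0, n_categories))],
        )
        for x in range(n_raters)
        for z in range(n_cases)
    ]
    return validate_matrix(recs, categories=cats)


def paired_frame(rows):
    """Build a pair_sessions-shaped matrix from (rater, case, choice1, choice2)."""
    recs = []
    for rater, case, c1, c2 in rows:
        recs.append(DecisionRecord(rater, case, 1, "q1", c1))
        recs.append(DecisionRecord(rater, case, 2, "q1", c2))
    return validate_matrix(recs)


@pytest.fixture(scope="session")
def fixture_study():
    """The standard 86-rater x 41-case synthetic study (seed 0)."""
    return make_thrombectomy_fixture(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
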