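"""Independent, deliberately naive reference implementations used only to
cross-check the package's agreement statistics.  Everything here is written
as direct loop-based formula evaluation over the count table, sharing no
code with the implementation under test."""

from __future__ import annotations

import itertools


def fleiss_kappa_oracle(count_rows):
    """Fleiss' kappa by direct formula evaluation.

    ``count_rows``: list of per-case category-count lists (possibly unequal
    row sums).  Per-case agreement is counted by enumerating ordered rater
    pairs within the case.
    """
    p_is = []
    for row in count_rows:
        n = sum(row)
        agree_pairs = sum(c * (c - 1) for c in row)
        p_is.append(agree_pairs / (n * (n - 1)))
    p_bar = sum(p_is) / len(p_is)
    total = sum(sum(row) for row in count_rows)
    n_cat = len(count_rows[0])
    p_j = [sum(row[j] for row in count_rows) / total for j in range(n_cat)]
    p_e = sum(p * p for p in p_j)
    return (p_bar - p_e) / (1 - p_e)


def scott_pi_oracle(a, b, categories):
    """Scott's pi for two complete rating vectors: chance agreement from the
    pooled marginal distribution."""
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    pooled = {c: (list(a) + list(b)).count(c) / (2 * n) for c in categories}
    p_e = sum(p * p for p in pooled.values())
    return (p_o - p_e) / (1 - p_e)


def cohen_kappa_oracle(a, b, categories):
    """Cohen's kappa by explicit cross-tabulation."""
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    pa = {c: list(a).count(c) / n for c in categories}
    pb = {c: list(b).count(c) / n for c in categories}
    p_e = sum(pa[c] * pb[c] for c in categories)
    return (p_o - p_e) / (1 - p_e)


def percent_agreement_oracle(count_rows):
    """Mean pairwise agreement by enumerating unordered rater pairs."""
    p_is = []
    for row in count_rows:
        raters = list(
            itertools.chain.from_iterable([j] * c for j, c in enumerate(row))
        )
        pairs = list(itertools.combinations(range(len(raters)), 2))
        agree = sum(raters[i] == raters[j] for i, j in pairs)
        p_is.append(agree / len(pairs))
    return sum(p_is) / len(p_is)
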