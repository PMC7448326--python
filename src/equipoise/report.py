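"""Structured study reports: GRRAS-adapted checklist, uncertainty index,
plain-language summary sentences and figure-ready data exports.

A :class:`StudyReport` bundles the full analysis of one agreement study —
global and subgroup kappas with bootstrap CIs, per-case disagreement
profiles, the intra-rater change summary when a second session exists, the
trial-concordance analysis when a trial-proposal question exists — together
with a 13-item reporting checklist adapted from the Guidelines for
Reporting Reliability and Agreement Studies (GRRAS) and an uncertainty
index that maps the kappa band to a trial-recruitment-potential label.

The report serializes to JSON (the machine contract) and Markdown (for
humans); figure-ready tables are exported as tidy CSVs rather than rendered
images.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from equipoise.agreement import (
    AgreementResult,
    bootstrap_ci,
    interpret_kappa,
    percent_agreement,
    subgroup_agreement,
)
from equipoise.decision_data import DecisionMatrix, Portfolio, RaterProfile
from equipoise.disagreement import (
    case_vote_profiles,
    disagreement_summary,
    equipoise_candidates,
    rater_decision_rates,
    trial_concordance,
    votebar_table,
)
from equipoise.errors import AnalysisError, EmptyInputError, ValidationError
from equipoise.intrarater import (
    intrarater_case_summary,
    pair_sessions,
    rater_change_metrics,
)

logger = logging.getLogger(__name__)

#: 13-item reporting checklist adapted from GRRAS to management-decision
#: agreement studies, with the config key that fills each fillable item
CHECKLIST_ITEMS = [
    (1, "Clinical dilemma identified in title/abstract", "dilemma"),
    (2, "Subject of interest: disease, management options, dilemma", "subject"),
    (3, "Patients confronted with the uncertainty", "patients"),
    (4, "Clinicians involved in the decisions", "clinicians"),
    (5, "Known reliability/agreement and study rationale", "rationale"),
    (6, "How the numbers of patients and clinicians were chosen", "sample_size_rationale"),
    (7, "How patients and clinicians were selected", "selection"),
    (8, "Experimental setting (session interval, information, blinding)", "setting"),
    (9, "Whether judgments were made independently", "independence"),
    (10, "Statistical analyses", None),          # filled from the analyses run
    (11, "Actual numbers of raters, cases, replicated judgments", None),
    (12, "Characteristics of clinicians and patients", None),
    (13, "Reliability/agreement estimates with statistical uncertainty", None),
]

#: default Landis-Koch band -> trial-recruitment-potential mapping; lower
#: agreement means higher uncertainty, hence higher recruitment potential
DEFAULT_RECRUITMENT_MAP = {
    "poor": "high",
    "slight": "high",
    "fair": "intermediate",
    "moderate": "intermediate",
    "substantial": "low",
    "almost perfect": "low",
}


@dataclass(frozen=True)
class UncertaintyIndex:
    kappa: float
    band: str
    below_substantial: bool
    recruitment_potential: str


def uncertainty_index(
    kappa: float, mapping: Optional[Mapping[str, str]] = None
) -> UncertaintyIndex:
    """Map a kappa value to its Landis-Koch band and a trial-recruitment-
    potential label by inverted ordering (the less clinicians agree, the
    more patients are in genuine equipoise, the easier recruitment).

    The band -> label mapping is an explicit, configurable convention of
    this package (default: poor/slight -> high, fair/moderate ->
    intermediate, substantial/almost perfect -> low).
    """
    band = interpret_kappa(kappa)
    table = dict(DEFAULT_RECRUITMENT_MAP)
    if mapping:
        table.update(mapping)
    return UncertaintyIndex(
        kappa=kappa,
        band=band.band,
        below_substantial=band.below_substantial,
        recruitment_potential=table[band.band],
    )


@dataclass
class StudyReport:
    """Full structured report of one agreement study."""

    checklist: list                  # 13 dicts: item, title, status, content
    results_block: dict              # JSON-safe analysis results
    uncertainty: UncertaintyIndex
    sentences: list
    provenance: dict
    tables: dict = field(default_factory=dict, repr=False)   # figure-ready DataFrames

    def to_json_dict(self) -> dict:
        return {
            "checklist": self.checklist,
            "results": self.results_block,
            "uncertainty_index": asdict(self.uncertainty),
            "sentences": self.sentences,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), indent=2, default=_json_default, **kwargs)

    def to_markdown(self) -> str:
        return render_markdown(self)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _nan_to_none(x):
    if x is None:
        return None
    x = float(x)
    return None if np.isnan(x) else x


def _agreement_record(res: AgreementResult) -> dict:
    rec = res.to_record()
    rec["kappa"] = _nan_to_none(rec["kappa"])
    rec["observed_agreement"] = _nan_to_none(rec["observed_agreement"])
    return rec


def build_report(
    matrix: DecisionMatrix,
    roster: Optional[Sequence[RaterProfile]] = None,
    portfolio: Optional[Portfolio] = None,
    config: Optional[Mapping] = None,
) -> StudyReport:
    """Run the full analysis stack on one study and assemble the report.

    ``config`` keys (all optional except that the primary question must be
    resolvable): ``question`` (primary decision question; defaults to the
    matrix's only question), ``trial_question``, ``target_category``
    (default "yes"), ``minority_threshold`` (default 1/3),
    ``rater_change_threshold`` (default 0.25), ``trial_threshold``,
    ``bootstrap_B`` (default 2000), ``ci_level`` (default 0.95), ``seed``
    (default 0), ``recruitment_map``, and the checklist metadata keys
    (dilemma, subject, patients, clinicians, rationale,
    sample_size_rationale, selection, setting, independence).

    Checklist items that cannot be filled from metadata or results are
    marked ``missing`` rather than omitted.
    """
    config = dict(config or {})
    question = config.get("question")
    if question is None:
        non_trial = [q for q in matrix.questions if q != config.get("trial_question")]
        if len(non_trial) != 1:
            raise ValidationError(
                f"config must name the primary question; matrix has {matrix.questions}"
            )
        question = non_trial[0]
    if question not in matrix.questions:
        raise ValidationError(f"primary question {question!r} not in {matrix.questions}")
    trial_question = config.get("trial_question")
    if trial_question is not None and trial_question not in matrix.questions:
        trial_question = None
    target = config.get("target_category", "yes")
    minority_threshold = float(config.get("minority_threshold", 1.0 / 3.0))
    change_threshold = float(config.get("rater_change_threshold", 0.25))
    seed = int(config.get("seed", 0))
    B = int(config.get("bootstrap_B", 2000))
    level = float(config.get("ci_level", 0.95))

    results: dict = {}
    tables: dict = {}

    # --- global agreement -------------------------------------------------
    global_res = bootstrap_ci(
        matrix, question, method="fleiss", B=B, seed=seed, level=level
    )
    results["fleiss_kappa"] = _agreement_record(global_res)
    results["percent_agreement"] = _agreement_record(
        percent_agreement(matrix, question)
    )

    # --- subgroups --------------------------------------------------------
    kappa_bar_rows = [{"group": "all raters", **_agreement_record(global_res)}]
    subgroup_records = []
    if roster is not None:
        for res in subgroup_agreement(matrix, roster, None, question, by="specialty"):
            subgroup_records.append(_agreement_record(res))
            kappa_bar_rows.append({"group": res.subgroup, **_agreement_record(res)})
    if portfolio is not None:
        for res in subgroup_agreement(
            matrix, None, portfolio, question, by="control_class"
        ):
            subgroup_records.append(_agreement_record(res))
    results["subgroups"] = subgroup_records
    tables["kappa_bars"] = pd.DataFrame(kappa_bar_rows)

    # --- per-case disagreement -------------------------------------------
    profiles = case_vote_profiles(
        matrix,
        question,
        minority_threshold=minority_threshold,
        trial_question=trial_question,
    )
    dis = disagreement_summary(profiles, minority_threshold)
    results["disagreement"] = {
        "minority_threshold": dis.minority_threshold,
        "m_cases": dis.m_cases,
        "Z_cases": dis.Z_cases,
        "pct_cases": dis.pct_cases,
        "more_than_third": dis.more_than_third,
        "sentence": dis.sentence,
    }
    candidates = equipoise_candidates(
        profiles,
        minority_threshold=minority_threshold,
        trial_threshold=config.get("trial_threshold") if trial_question else None,
    )
    results["equipoise_candidates"] = candidates
    tables["votebar"] = votebar_table(profiles, target)
    tables["candidates"] = pd.DataFrame(
        [
            {
                "case_id": p.case_id,
                "minority_share": p.minority_share,
                "trial_vote_proportion": p.trial_vote_proportion,
            }
            for p in sorted(profiles, key=lambda p: (-p.minority_share, p.case_id))
            if p.case_id in set(candidates)
        ]
    )

    # --- per-rater decision rates ----------------------------------------
    rates = rater_decision_rates(matrix, question, target)
    rates_df = rates.rates.copy()
    if roster is not None:
        spec_map = {r.rater_id: r.specialty for r in roster}
        rates_df["specialty"] = rates_df["rater_id"].map(spec_map)
    tables["rater_rates"] = rates_df
    results["rater_rates"] = {
        "target_category": target,
        "min": rates.min,
        "max": rates.max,
        "range": rates.range,
    }

    # --- intra-rater ------------------------------------------------------
    if 2 in matrix.sessions:
        paired = pair_sessions(matrix, question)
        intra = intrarater_case_summary(
            rater_change_metrics(paired), rater_change_threshold=change_threshold
        )
        s = intra.summary
        results["intrarater"] = {
            "status": "computed",
            "n_raters": s.n_raters,
            "k_raters": s.k_raters,
            "pct_raters": s.pct_raters,
            "m_cases": s.m_cases,
            "Z_cases": s.Z_cases,
            "pct_cases": s.pct_cases,
            "threshold": s.threshold,
            "qualifying_cases": list(intra.qualifying_cases),
            "mean_self_kappa": _nan_to_none(
                np.nanmean(intra.per_rater["self_kappa"].to_numpy(dtype=float))
            ),
            "sentence": s.sentence,
        }
        tables["intrarater_per_rater"] = intra.per_rater
        tables["intrarater_per_case"] = intra.per_case
        intra_sentence = s.sentence
    else:
        results["intrarater"] = {"status": "not applicable (single session)"}
        intra_sentence = None

    # --- trial concordance ------------------------------------------------
    if trial_question is not None:
        conc = trial_concordance(
            matrix, question, trial_question, seed=seed,
            n_permutations=int(config.get("n_permutations", 999)),
        )
        results["trial_concordance"] = {
            "spearman_rho": _nan_to_none(conc.spearman_rho),
            "p_value": conc.p_value,
            "n_permutations": conc.n_permutations,
            "defined": conc.defined,
            "note": (
                "exploratory operationalization of the trial-proposal question; "
                "association of per-case disagreement with trial-vote support"
            ),
        }
        tables["trial_concordance"] = conc.table

    # --- uncertainty index ------------------------------------------------
    uindex = uncertainty_index(global_res.kappa, config.get("recruitment_map"))
    results["uncertainty_index_note"] = (
        "band-to-recruitment mapping is a configurable convention of this package"
    )

    # --- sentences --------------------------------------------------------
    sentences = [dis.sentence]
    if intra_sentence:
        sentences.append(intra_sentence)
    sentences.append(
        f"overall agreement was {global_res.kappa:.2f} ({uindex.band}; "
        f"95% CI {global_res.ci_lower:.2f} to {global_res.ci_upper:.2f}), "
        f"indicating {'high or intermediate' if uindex.below_substantial else 'low'} "
        f"clinical uncertainty and {uindex.recruitment_potential} potential "
        f"for trial recruitment"
    )

    checklist = _fill_checklist(config, matrix, roster, portfolio, results)
    provenance = {
        "package": "equipoise",
        "version": _package_version(),
        "seed": seed,
        "question": question,
        "trial_question": trial_question,
        "config": {
            k: v for k, v in config.items() if isinstance(v, (str, int, float, bool))
        },
    }
    return StudyReport(
        checklist=checklist,
        results_block=results,
        uncertainty=uindex,
        sentences=sentences,
        provenance=provenance,
        tables=tables,
    )


def _package_version() -> str:
    import equipoise

    return getattr(equipoise, "__version__", "unknown")


def _fill_checklist(config, matrix, roster, portfolio, results) -> list:
    items = []
    for number, title, key in CHECKLIST_ITEMS:
        content = None
        if key is not None:
            content = config.get(key)
        elif number == 10:
            content = (
                "Fleiss kappa (variable raters per case) with percentile-bootstrap "
                "CI; percent agreement; subgroup kappas; per-case minority-share "
                "disagreement profiles; two-session intra-rater change metrics "
                "where available"
            )
        elif number == 11:
            n_rep = int((matrix.data["session"] == 2).sum())
            content = (
                f"{matrix.n_raters} raters, {matrix.n_cases} cases, "
                f"{len(matrix.data)} recorded judgments "
                f"({n_rep} replicated in a second session)"
            )
        elif number == 12:
            parts = []
            if roster is not None:
                spec_counts = pd.Series([r.specialty for r in roster]).value_counts()
                parts.append(
                    "clinicians: " + ", ".join(f"{v} {k}" for k, v in spec_counts.items())
                )
            if portfolio is not None:
                parts.append(
                    "cases: " + ", ".join(
                        f"{v} {k}" for k, v in portfolio.composition.items()
                    )
                )
            content = "; ".join(parts) if parts else None
        elif number == 13:
            rec = results["fleiss_kappa"]
            content = (
                f"Fleiss kappa {rec['kappa']:.3f} "
                f"(95% CI {rec['ci_lower']:.3f} to {rec['ci_upper']:.3f}), "
                f"band: {rec['band']}"
            )
        items.append(
            {
                "item": number,
                "title": title,
                "status": "provided" if content else "missing",
                "content": content,
            }
        )
    return items


def render_sentences(report: StudyReport) -> str:
    """Deterministic plain-language summary block."""
    return "\n".join(report.sentences)


def render_markdown(report: StudyReport) -> str:
    lines = ["# Agreement study report", ""]
    lines += ["## Summary", ""]
    for s in report.sentences:
        lines.append(f"- {s.capitalize()}.")
    u = report.uncertainty
    lines += [
        "",
        "## Uncertainty index",
        "",
        f"- kappa = {u.kappa:.3f} ({u.band}); "
        f"recruitment potential: **{u.recruitment_potential}**",
        "",
        "## Checklist (GRRAS-adapted)",
        "",
        "| # | Item | Status | Content |",
        "|---|------|--------|---------|",
    ]
    for item in report.checklist:
        content = item["content"] or ""
        lines.append(
            f"| {item['item']} | {item['title']} | {item['status']} | {content} |"
        )
    lines += ["", "## Results", "", "```json", json.dumps(
        report.results_block, indent=2, default=_json_default
    ), "```", ""]
    return "\n".join(lines)


#: figure-data panels exportable from a report
FIGURE_PANELS = ("rater_rates", "votebar", "kappa_bars")


def export_figure_data(
    report: StudyReport,
    which: str,
    path: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Tidy CSV data behind one display panel.

    ``rater_rates``: per-rater target-decision proportions (with specialty
    when a roster was supplied); ``votebar``: per-case stacked category
    proportions in display order; ``kappa_bars``: kappa + CI for all raters
    and each rater subgroup.
    """
    if which not in FIGURE_PANELS:
        raise ValidationError(
            f"unknown panel {which!r}; available: {FIGURE_PANELS}"
        )
    if which not in report.tables:
        raise AnalysisError(f"panel {which!r} was not computed for this report")
    df = report.tables[which]
    if path is not None:
        df.to_csv(path, index=False, lineterminator="\n")
    return df
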