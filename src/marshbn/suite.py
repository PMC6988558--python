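"""The 38-model suite: covariate-set variants x two responses.

Nineteen covariate-set combinations define the model variants; each is fit
with the binary RERA-presence response (model ids 1-19) and with the
nine-species response (ids 20-38).  Models are ranked by a Pareto frontier
over accuracy and complexity, with an advisory "selected" pick among the
frontier (best-model choice is acknowledged to be partly subjective; the
frontier is the objective output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bn import BNModel, complexity, learn_cpts, learn_tan_structure
from .case_data import CaseFile, ResponseSpec, to_model_cases
from .discretize import discretize_cases
from .evaluate import ModelEvaluation, evaluate

#: Post-screening covariate membership of the seven sets.  C6solo is the
#: single-covariate distance variant used by models 6/25, whose published
#: form used distance-to-roads alone.
DEFAULT_SET_DEFINITIONS = {
    "C1": ["site", "year", "session", "layout", "trap_position"],
    "C2": ["latitude", "longitude"],
    "C3": ["P1_Species", "P1_V_PERC", "P1_V1_MAX", "P1_V1_AVG"],
    "C4": ["P1_Species", "P1_V_PERC", "P1_V1_MAX", "P1_V1_AVG",
           "P2_Species", "P2_V_PERC", "P2_V1_MAX", "P2_V1_AVG",
           "P3_Species", "P3_V_PERC", "P3_V1_MAX", "P3_V1_AVG"],
    "C5": ["Marsh_Elev", "MHW", "Elev_MHW", "Elev_MHHW"],
    "C6": ["Dist_Levee", "Dist_Water", "Dist_Bay", "Dist_Road"],
    "C6solo": ["Dist_Road"],
    "C7": ["Patch_Size", "Patch_Size_Expanded"],
}

#: The 19 variants: variant number -> covariate sets combined.
DEFAULT_VARIANTS = {
    1: ("C1",), 2: ("C2",), 3: ("C3",), 4: ("C4",), 5: ("C5",),
    6: ("C6solo",), 7: ("C7",),
    8: ("C5", "C6"), 9: ("C6", "C7"), 10: ("C5", "C7"),
    11: ("C3", "C5", "C6"), 12: ("C3", "C6", "C7"), 13: ("C3", "C5", "C7"),
    14: ("C3", "C5", "C6", "C7"),
    15: ("C1", "C3", "C5", "C6"), 16: ("C1", "C3", "C6", "C7"),
    17: ("C1", "C3", "C5", "C7"), 18: ("C1", "C3", "C5", "C6", "C7"),
    19: ("C4", "C5", "C6", "C7"),
}


@dataclass
class SuiteSpec:
    """Which variants to fit, over which covariate sets and responses."""

    variants: dict = field(default_factory=lambda: dict(DEFAULT_VARIANTS))
    set_definitions: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_SET_DEFINITIONS.items()})
    responses: tuple = (ResponseSpec.rera_presence(), ResponseSpec.all_species())
    smoothing_alpha: float = 1.0

    def covariates_for(self, variant: int) -> list:
        """Ordered union of the variant's covariate sets (duplicates dropped)."""
        out: list = []
        for set_name in self.variants[variant]:
            for name in self.set_definitions[set_name]:
                if name not in out:
                    out.append(name)
        if not out:
            raise ValueError(f"variant {variant} has an empty covariate union")
        return out

    def model_id(self, variant: int, resp: ResponseSpec) -> int:
        offset = 0 if resp.mode == "rera_presence" else len(self.variants)
        return variant + offset


@dataclass
class FittedModel:
    model_id: int
    variant: int
    response: ResponseSpec
    model: BNModel
    dcases: object  # DiscretizedCases the model was calibrated on


@dataclass
class SuiteResult:
    rows: pd.DataFrame  # one row per model id, Tables-6/7-style columns
    frontier: list
    selected: list
    evaluations: dict  # model id -> ModelEvaluation


def build_suite(spec: SuiteSpec, cf: CaseFile, schemes: dict) -> list:
    """Fit one TAN model per (variant, response) over the capture cases.

    ``schemes`` must cover every covariate referenced by the variants; a
    missing covariate is reported with the offending variant.  Models come
    back ordered by model id.
    """
    fitted = []
    frame_cols = set(cf.to_frame().columns)
    for resp in spec.responses:
        model_cf = to_model_cases(cf, resp)
        for variant in sorted(spec.variants):
            covs = spec.covariates_for(variant)
            missing = [c for c in covs if c not in frame_cols or c not in schemes]
            if missing:
                raise ValueError(f"variant {variant}: covariates missing from "
                                 f"case file or schemes: {missing}")
            dcases = discretize_cases(model_cf, {c: schemes[c] for c in covs}, resp)
            model = learn_tan_structure(dcases, covs)
            learn_cpts(model, dcases, alpha=spec.smoothing_alpha)
            model.metadata.update({"model_id": spec.model_id(variant, resp),
                                   "variant": variant, "response": resp.mode,
                                   "sets": list(spec.variants[variant])})
            fitted.append(FittedModel(spec.model_id(variant, resp), variant,
                                      resp, model, dcases))
    fitted.sort(key=lambda f: f.model_id)
    return fitted


def evaluate_suite(fitted: list, focal_state: str = "RERA") -> SuiteResult:
    """Calibration-evaluate every fitted model and rank the suite."""
    records, evaluations = [], {}
    for fm in fitted:
        ev = evaluate(fm.model, fm.dcases, focal_state=focal_state)
        evaluations[fm.model_id] = ev
        records.append({
            "model": fm.model_id, "variant": fm.variant,
            "response": fm.response.mode,
            "nodes": ev.complexity.n_nodes, "links": ev.complexity.n_links,
            "probabilities": ev.complexity.n_probabilities,
            "overall_error": ev.overall_error, "type1_error": ev.type1_error,
            "type2_error": ev.type2_error, "spherical_payoff": ev.spherical_payoff,
        })
    columns = ["model", "variant", "response", "nodes", "links", "probabilities",
               "overall_error", "type1_error", "type2_error", "spherical_payoff"]
    rows = pd.DataFrame.from_records(records, columns=columns).set_index("model")
    frontier = rank_models(rows)
    selected = _select(rows, frontier)
    return SuiteResult(rows=rows, frontier=frontier, selected=selected,
                       evaluations=evaluations)


def rank_models(rows: pd.DataFrame, epsilon: float = 0.01) -> list:
    """Pareto non-dominated model ids.

    Objectives: minimize Type I error, overall error and probability count;
    maximize spherical payoff.  Model a dominates b when a is no worse than
    b in every objective (raw values) and better by more than ``epsilon``
    in at least one fractional metric, or strictly smaller in probability
    count.  Within a multi-response table, only models sharing a response
    compete.
    """
    if rows.empty:
        return []
    ids = list(rows.index)
    frontier = []
    for b in ids:
        rb = rows.loc[b]
        dominated = False
        for a in ids:
            if a == b:
                continue
            ra = rows.loc[a]
            if "response" in rows.columns and ra["response"] != rb["response"]:
                continue
            no_worse = (ra["type1_error"] <= rb["type1_error"]
                        and ra["overall_error"] <= rb["overall_error"]
                        and ra["probabilities"] <= rb["probabilities"]
                        and ra["spherical_payoff"] >= rb["spherical_payoff"])
            better = (ra["type1_error"] < rb["type1_error"] - epsilon
                      or ra["overall_error"] < rb["overall_error"] - epsilon
                      or ra["spherical_payoff"] > rb["spherical_payoff"] + epsilon
                      or ra["probabilities"] < rb["probabilities"])
            if no_worse and better:
                dominated = True
                break
        if not dominated:
            frontier.append(b)
    return frontier


def _select(rows: pd.DataFrame, frontier: list) -> list:
    """Advisory pick per response: minimal (type1, overall, probabilities)."""
    if not frontier:
        return []
    sub = rows.loc[frontier]
    selected = []
    groups = sub.groupby("response") if "response" in sub.columns else [(None, sub)]
    for _, g in groups:
        ranked = g.sort_values(["type1_error", "overall_error", "probabilities"])
        best = ranked.iloc[0]
        ties = ranked[(ranked["type1_error"] == best["type1_error"])
                      & (ranked["overall_error"] == best["overall_error"])
                      & (ranked["probabilities"] == best["probabilities"])]
        selected.extend(ties.index.tolist())
    return sorted(selected)


def report(result: SuiteResult, path) -> pd.DataFrame:
    """Write the suite table (model, complexity, errors, payoff) as CSV."""
    cols = ["nodes", "links", "probabilities", "overall_error",
            "type1_error", "type2_error", "spherical_payoff"]
    out = result.rows[["variant", "response"] + cols] if not result.rows.empty \
        else pd.DataFrame(columns=["variant", "response"] + cols)
    out.to_csv(path, index_label="model")
    return out
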