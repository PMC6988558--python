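"""Per-trap-night case files: domain types, CSV I/O, and margin summaries.

The case unit of the analysis is the *trap night*: one trap set for one
night.  Each record carries the sampling-design fields, the trap outcome
(a species code, or ``TRAP`` for an empty trap), and the environmental
covariates measured at the trap location.  Model case files contain the
capture records only; for the binary response every non-RERA capture is
relabelled ``NOTRERA``.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

#: Token written (and accepted, alongside the empty string) for missing values.
MISSING_TOKEN = "*"

#: The 10-label trap-outcome vocabulary; TRAP = trap set, no capture.
OUTCOMES = ("TRAP", "MICA", "MUMU", "PEMA", "RANO", "RARA", "RE", "REME", "RERA", "SOOR")

#: The nine capture-outcome species codes (OUTCOMES without TRAP).
CAPTURE_SPECIES = tuple(o for o in OUTCOMES if o != "TRAP")

#: Pseudo-state of the binary response: any capture that is not RERA.
NOTRERA = "NOTRERA"

#: Columns with fixed meaning in every case-file CSV, in order.
STRUCTURAL_COLUMNS = ("site", "year", "session", "layout", "latitude", "longitude", "outcome")


@dataclass(frozen=True)
class CovariateDef:
    """Definition of one covariate: name, units, kind, and set membership."""

    name: str
    description: str = ""
    units: str = "unitless"
    kind: str = "continuous"  # "continuous" | "categorical"
    sets: frozenset = field(default_factory=frozenset)  # subset of {"C1".."C7"}
    labels: tuple | None = None  # finite label list for categorical covariates

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")


@dataclass
class TrapCase:
    """One trap-night record: design fields, outcome, covariate values."""

    site: str
    year: int
    session: str
    layout: str
    latitude: float
    longitude: float
    outcome: str
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        # NOTRERA only ever appears in model case files built by
        # to_model_cases, never in raw survey data.
        if self.outcome not in OUTCOMES and self.outcome != NOTRERA:
            raise ValueError(f"unknown outcome label {self.outcome!r}")

    def value(self, name):
        """Covariate or structural-field value by name; None when missing."""
        if name in STRUCTURAL_COLUMNS:
            return getattr(self, name)
        return self.covariates.get(name)


@dataclass(frozen=True)
class ResponseSpec:
    """Which response variable a model predicts, and its ordered states."""

    mode: str  # "rera_presence" | "all_species"
    states: tuple

    @classmethod
    def rera_presence(cls) -> "ResponseSpec":
        return cls("rera_presence", ("RERA", "NOTRERA"))

    @classmethod
    def all_species(cls) -> "ResponseSpec":
        return cls("all_species", CAPTURE_SPECIES)

    @property
    def focal_state(self) -> str:
        return "RERA"


@dataclass
class CaseFile:
    """Ordered collection of trap cases plus the covariate catalog."""

    cases: list
    catalog: list

    def __post_init__(self):
        names = [d.name for d in self.catalog]
        if len(names) != len(set(names)):
            raise ValueError("covariate names must be unique within a catalog")
        known = set(names) | set(STRUCTURAL_COLUMNS)
        for i, case in enumerate(self.cases):
            unknown = set(case.covariates) - known
            if unknown:
                raise ValueError(f"case {i} references covariates not in catalog: {sorted(unknown)}")

    def __len__(self):
        return len(self.cases)

    def covariate_names(self) -> list:
        return [d.name for d in self.catalog]

    def covariate_def(self, name: str) -> CovariateDef:
        for d in self.catalog:
            if d.name == name:
                return d
        raise KeyError(name)

    def outcome_margin(self) -> Counter:
        return Counter(c.outcome for c in self.cases)

    def to_frame(self) -> pd.DataFrame:
        """Flat table: structural columns then catalog covariates (in order).

        Missing covariate values become NaN/None.  Structural fields double
        as covariates (e.g. latitude/longitude in set C2), so a catalog
        entry whose name is structural is not duplicated as a column.
        """
        cov_cols = [n for n in self.covariate_names() if n not in STRUCTURAL_COLUMNS]
        rows = []
        for case in self.cases:
            row = {k: getattr(case, k) for k in STRUCTURAL_COLUMNS}
            for n in cov_cols:
                row[n] = case.covariates.get(n)
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(STRUCTURAL_COLUMNS) + cov_cols)
        return df


def _parse_cell(text: str, kind: str):
    """Parse one CSV cell given the covariate kind; None when missing."""
    text = text.strip()
    if text == "" or text == MISSING_TOKEN:
        return None
    if kind == "continuous":
        return float(text)
    return text


def read_case_file(path, catalog: list) -> CaseFile:
    """Read a per-trap-night case file CSV.

    The header row holds the structural columns plus covariate codes; every
    covariate column must exist in ``catalog``.  Missing values are encoded
    as an empty field or ``*`` and preserved as missing — never imputed.
    """
    known = {d.name: d for d in catalog}
    cases = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        for col in header:
            if col not in STRUCTURAL_COLUMNS and col not in known:
                raise ValueError(f"covariate column {col!r} absent from catalog")
        missing_struct = [c for c in STRUCTURAL_COLUMNS if c not in header]
        if missing_struct:
            raise ValueError(f"case file lacks structural columns {missing_struct}")
        idx = {col: i for i, col in enumerate(header)}
        for rownum, row in enumerate(reader, start=2):
            outcome = row[idx["outcome"]].strip()
            if outcome not in OUTCOMES and outcome != NOTRERA:
                raise ValueError(f"row {rownum}: unknown outcome label {outcome!r}")
            covs = {}
            for col in header:
                if col in STRUCTURAL_COLUMNS:
                    continue
                val = _parse_cell(row[idx[col]], known[col].kind)
                if val is not None:
                    covs[col] = val
            cases.append(TrapCase(
                site=row[idx["site"]].strip(),
                year=int(row[idx["year"]]),
                session=row[idx["session"]].strip(),
                layout=row[idx["layout"]].strip(),
                latitude=float(row[idx["latitude"]]),
                longitude=float(row[idx["longitude"]]),
                outcome=outcome,
                covariates=covs,
            ))
    return CaseFile(cases=cases, catalog=list(catalog))


def write_case_file(cf: CaseFile, path) -> None:
    """Write a case file CSV (missing values as ``*``); inverse of reading."""
    cov_cols = [n for n in cf.covariate_names() if n not in STRUCTURAL_COLUMNS]
    header = list(STRUCTURAL_COLUMNS) + cov_cols
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for case in cf.cases:
            row = [case.site, case.year, case.session, case.layout,
                   repr(case.latitude), repr(case.longitude), case.outcome]
            for n in cov_cols:
                v = case.covariates.get(n)
                if v is None:
                    row.append(MISSING_TOKEN)
                elif isinstance(v, float):
                    row.append(repr(v))
                else:
                    row.append(v)
            writer.writerow(row)


def to_model_cases(cf: CaseFile, resp: ResponseSpec) -> CaseFile:
    """Restrict to capture records and map outcomes onto the response states.

    Empty trap nights (``TRAP``) never enter a model case file.  Under the
    binary response, every capture of a species other than RERA is
    relabelled ``NOTRERA``; under the all-species response the nine capture
    codes pass through unchanged.
    """
    out_cases = []
    for case in cf.cases:
        if case.outcome == "TRAP":
            continue
        outcome = case.outcome
        if resp.mode == "rera_presence" and outcome != "RERA":
            outcome = NOTRERA
        out_cases.append(TrapCase(case.site, case.year, case.session, case.layout,
                                  case.latitude, case.longitude, outcome,
                                  dict(case.covariates)))
    return CaseFile(cases=out_cases, catalog=list(cf.catalog))


def summarize_margins(cf: CaseFile, by: list) -> pd.DataFrame:
    """Counts and rates per 100 trap nights for a grouping of the case file.

    ``by`` is a subset of {site, year, outcome, layout}.  The denominator of
    each rate is the number of trap nights in the group defined by the
    non-outcome keys (all trap nights when only ``outcome`` is given), so
    e.g. 546 RERA captures over a site's 7,560 trap nights print as 7.2.
    """
    allowed = {"site", "year", "outcome", "layout"}
    if not set(by) <= allowed:
        raise ValueError(f"grouping keys must be a subset of {sorted(allowed)}")
    df = pd.DataFrame({k: [getattr(c, k) for c in cf.cases] for k in by})
    if df.empty:
        return pd.DataFrame(columns=list(by) + ["count", "rate"])
    counts = df.groupby(list(by), sort=True, observed=True).size().rename("count").reset_index()
    effort_keys = [k for k in by if k != "outcome"]
    if effort_keys:
        effort = df.groupby(effort_keys, sort=True, observed=True).size().rename("effort").reset_index()
        counts = counts.merge(effort, on=effort_keys)
    else:
        counts["effort"] = len(cf.cases)
    counts["rate"] = (100.0 * counts["count"] / counts["effort"]).round(1)
    return counts.drop(columns="effort")


def margin_checks(cf: CaseFile) -> dict:
    """Headline margins of a survey case file.

    Returns total trap nights, capture count, the empty-trap fraction, and
    RERA's share of captures and of all trap nights.
    """
    margin = cf.outcome_margin()
    total = len(cf.cases)
    empty = margin.get("TRAP", 0)
    captures = total - empty
    rera = margin.get("RERA", 0)
    return {
        "trap_nights": total,
        "captures": captures,
        "empty_fraction": empty / total if total else math.nan,
        "rera_capture_share": rera / captures if captures else math.nan,
        "rera_trap_night_share": rera / total if total else math.nan,
    }
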