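"""Discretization of covariates into at most five well-supported states.

Continuous covariates are cut into ordered interval states so that the
conditional probability tables of the downstream network stay tractable:
no more than ``max_states`` states per variable, each state supported by
at least ``min_support`` training cases (roughly 20).  Bins are seeded at
equal-frequency quantiles; when some bin falls short of the support floor
the number of bins is reduced and the quantiles recomputed, so the final
states are as balanced as the data allow.  Interval states follow the
half-open ``[low, high)`` convention with terminal clamping.

Categorical covariates pass through with their native labels, capped at
``max_states`` by pooling infrequent labels into ``"other"``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .case_data import CaseFile, ResponseSpec, STRUCTURAL_COLUMNS


@dataclass(frozen=True)
class DiscretizationScheme:
    """Per-covariate mapping from raw values to ordered state labels."""

    variable: str
    kind: str  # "continuous" | "categorical"
    boundaries: tuple  # ascending cut values (continuous) or () for categorical
    states: tuple  # ordered state labels
    support: tuple  # per-state training counts

    def __post_init__(self):
        if len(self.states) < 1 or len(self.states) != len(set(self.states)):
            raise ValueError("states must be non-empty and unique")
        if self.kind == "continuous":
            if len(self.boundaries) != len(self.states) - 1:
                raise ValueError("need exactly |states|-1 boundaries")
            if any(a >= b for a, b in zip(self.boundaries, self.boundaries[1:])):
                raise ValueError("boundaries must be strictly increasing")

    def apply(self, value):
        """State label for one value; ``None`` stays ``None`` (missing)."""
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        if self.kind == "categorical":
            v = str(value)
            if v in self.states:
                return v
            return "other" if "other" in self.states else None
        # [low, high): a value equal to a boundary belongs to the upper bin.
        i = int(np.searchsorted(self.boundaries, value, side="right"))
        return self.states[i]

    def apply_series(self, values: pd.Series) -> pd.Series:
        return values.map(self.apply)

    def to_dict(self) -> dict:
        return {"variable": self.variable, "kind": self.kind,
                "boundaries": list(self.boundaries), "states": list(self.states),
                "support": list(self.support)}

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationScheme":
        return cls(d["variable"], d["kind"], tuple(d["boundaries"]),
                   tuple(d["states"]), tuple(d["support"]))


def _interval_labels(boundaries: np.ndarray) -> tuple:
    edges = [float("-inf"), *boundaries.tolist(), float("inf")]
    labels = tuple(f"[{lo:.6g}, {hi:.6g})" for lo, hi in zip(edges, edges[1:]))
    if len(labels) != len(set(labels)):  # pathological rounding collision
        labels = tuple(f"[{lo!r}, {hi!r})" for lo, hi in zip(edges, edges[1:]))
    return labels


def fit_scheme(values, variable: str = "x", max_states: int = 5,
               min_support: int = 20) -> DiscretizationScheme:
    """Fit an interval discretization for one continuous covariate.

    Seeds ``max_states`` equal-frequency bins at quantiles of the non-missing
    training values; boundaries are snapped to midpoints between adjacent
    distinct data values.  If any bin's support falls below ``min_support``
    the bin count is reduced by one and the quantiles recomputed, down to a
    single all-covering state for degenerate inputs.
    """
    x = np.asarray(pd.Series(values, dtype=float).dropna(), dtype=float)
    if x.size == 0:
        raise ValueError("need at least one non-missing training value")
    distinct = np.unique(x)

    for k in range(min(max_states, distinct.size), 0, -1):
        if k == 1:
            boundaries = np.array([])
        else:
            qs = np.quantile(x, np.linspace(0, 1, k + 1)[1:-1])
            # Snap each cut to the midpoint between the adjacent distinct values.
            snapped = []
            for q in qs:
                j = int(np.searchsorted(distinct, q, side="right"))
                if j <= 0 or j >= distinct.size:
                    continue
                lo, hi = distinct[j - 1], distinct[j]
                # A quantile exactly on a data value splits below it.
                if q == lo and j - 1 > 0:
                    lo, hi = distinct[j - 2], distinct[j - 1]
                snapped.append((lo + hi) / 2.0)
            boundaries = np.unique(snapped)
        counts = np.bincount(np.searchsorted(boundaries, x, side="right"),
                             minlength=boundaries.size + 1)
        if boundaries.size + 1 < k:
            continue  # duplicate-heavy data collapsed some cuts; try fewer bins
        if counts.min() >= min_support or k == 1:
            labels = _interval_labels(boundaries) if boundaries.size else ("all",)
            return DiscretizationScheme(variable, "continuous",
                                        tuple(float(b) for b in boundaries),
                                        labels, tuple(int(c) for c in counts))
    raise AssertionError("unreachable: k=1 always returns")


def fit_categorical_scheme(values, variable: str = "x",
                           max_states: int = 5) -> DiscretizationScheme:
    """Pass-through scheme for a categorical covariate.

    Keeps up to ``max_states`` native labels (most frequent first, ties by
    label); if more labels occur, the top ``max_states - 1`` are kept and
    the rest pool into ``"other"``.
    """
    ser = pd.Series(values).dropna().astype(str)
    if ser.empty:
        raise ValueError("need at least one non-missing training value")
    counts = Counter(ser)
    ranked = sorted(counts, key=lambda v: (-counts[v], v))
    if len(ranked) <= max_states:
        states = tuple(ranked)
        support = tuple(counts[s] for s in states)
    else:
        keep = ranked[:max_states - 1]
        states = tuple(keep) + ("other",)
        support = tuple(counts[s] for s in keep) + (
            sum(counts[v] for v in ranked[max_states - 1:]),)
    return DiscretizationScheme(variable, "categorical", (), states, support)


def fit_schemes(cf: CaseFile, covariates=None, max_states: int = 5,
                min_support: int = 20) -> dict:
    """Fit schemes for the named covariates of a case file.

    ``covariates`` defaults to every catalog covariate.  Continuous
    covariates get interval schemes, categorical ones pass-through schemes.
    """
    df = cf.to_frame()
    names = list(covariates) if covariates is not None else cf.covariate_names()
    schemes = {}
    for name in names:
        d = cf.covariate_def(name)
        if d.kind == "continuous":
            schemes[name] = fit_scheme(df[name], name, max_states, min_support)
        else:
            schemes[name] = fit_categorical_scheme(df[name], name, max_states)
    return schemes


def save_schemes(schemes: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in schemes.values()], fh, indent=1)


def load_schemes(path) -> dict:
    with open(path) as fh:
        items = json.load(fh)
    return {d["variable"]: DiscretizationScheme.from_dict(d) for d in items}


@dataclass
class DiscretizedCases:
    """Integer-coded case table shared by structure/CPT learning and scoring.

    ``codes`` holds one int16 column per variable (state index; -1 = missing)
    and ``states`` the ordered label tuple per variable.  The response
    column (named by ``response_col``) is always fully observed.
    """

    codes: pd.DataFrame
    states: dict
    response_col: str

    def __len__(self):
        return len(self.codes)

    def cards(self) -> dict:
        return {k: len(v) for k, v in self.states.items()}

    def column(self, name: str) -> np.ndarray:
        return self.codes[name].to_numpy()

    def subset(self, index) -> "DiscretizedCases":
        return DiscretizedCases(self.codes.iloc[index].reset_index(drop=True),
                                self.states, self.response_col)


def discretize_cases(cf: CaseFile, schemes: dict, resp: ResponseSpec,
                     response_col: str = "outcome") -> DiscretizedCases:
    """Encode a *model* case file (capture records) as state indices.

    Every case outcome must be one of the response states; covariates not
    covered by ``schemes`` are ignored.
    """
    df = cf.to_frame()
    cols = {}
    states = {}
    out_index = {s: i for i, s in enumerate(resp.states)}
    try:
        cols[response_col] = np.array([out_index[o] for o in df["outcome"]], dtype=np.int16)
    except KeyError as exc:
        raise ValueError(f"case outcome {exc} is not a response state") from exc
    states[response_col] = tuple(resp.states)
    for name, scheme in schemes.items():
        idx = {s: i for i, s in enumerate(scheme.states)}
        labels = scheme.apply_series(df[name])
        cols[name] = np.array([-1 if lab is None else idx[lab] for lab in labels],
                              dtype=np.int16)
        states[name] = tuple(scheme.states)
    return DiscretizedCases(pd.DataFrame(cols), states, response_col)
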