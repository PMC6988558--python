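"""Pre-model correlation screening and species habitat comparison.

Before network induction, the continuous covariates are screened with all
pairwise Pearson correlations; covariates involved in significantly strong
correlations (|r| above a threshold with p below alpha) are greedily
eliminated so the retained set carries low redundancy.  After modelling,
per-covariate habitat differences between two species are compared with
unpaired Welch t tests (plus variance-ratio F tests) under a Bonferroni
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .case_data import CaseFile


@dataclass
class CorrelationScreenResult:
    """All pairwise correlations plus the greedy elimination outcome."""

    pairs: list  # (name_a, name_b, r, p, n) for all C(k,2) unordered pairs
    flagged: list  # subset with p < alpha and |r| > r_thresh
    eliminated: list
    retained: list


@dataclass
class SpeciesComparisonRow:
    """One covariate's two-species comparison (Welch t, Bonferroni p)."""

    variable: str
    t: float
    df: float
    p: float
    p_adj: float
    F: float
    p_f: float
    higher_mean: str  # species label, or "nd" when not significant


def pearson_r(x, y):
    """Pearson correlation with pairwise deletion of missing values.

    Returns ``(r, p, n)`` where p comes from the t transform with n-2 df.
    Requires >= 3 pairwise-complete observations and nonzero variance.
    """
    xa = np.asarray(pd.Series(x, dtype=float))
    ya = np.asarray(pd.Series(y, dtype=float))
    mask = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[mask], ya[mask]
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 pairwise-complete observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined: zero variance")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue), int(n)


def screen(cf: CaseFile, covariates: list, r_thresh: float = 0.75,
           alpha: float = 0.05) -> CorrelationScreenResult:
    """Correlation screen over continuous covariates with greedy elimination.

    All C(k,2) unordered pairs are evaluated.  While any retained pair is
    flagged (significant and |r| beyond the threshold), the covariate in the
    most flagged pairs is removed; ties go to the larger mean |r| over its
    flagged pairs, then to the covariate later in the given list (so the
    first-listed, more primary variable survives).  Deterministic.
    """
    df = cf.to_frame()
    names = list(covariates)
    order = {n: i for i, n in enumerate(names)}
    pairs, flagged = [], []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r, p, n = pearson_r(df[a], df[b])
            pairs.append((a, b, r, p, n))
            if p < alpha and abs(r) > r_thresh:
                flagged.append((a, b, r, p, n))

    retained = list(names)
    eliminated = []
    active = list(flagged)
    while active:
        tally = {}
        for a, b, r, _, _ in active:
            for v in (a, b):
                tally.setdefault(v, []).append(abs(r))
        # Most flagged pairs; tie -> larger mean |r|; tie -> later in list.
        victim = max(tally, key=lambda v: (len(tally[v]), float(np.mean(tally[v])), order[v]))
        eliminated.append(victim)
        retained.remove(victim)
        active = [f for f in active if victim not in f[:2]]
    return CorrelationScreenResult(pairs, flagged, eliminated, retained)


def welch_t(a, b):
    """Unpaired Welch t test: ``(t, df, p)`` with Welch–Satterthwaite df.

    Sign convention: ``mean(a) < mean(b)`` gives a negative statistic.
    """
    aa = np.asarray(pd.Series(a, dtype=float).dropna())
    bb = np.asarray(pd.Series(b, dtype=float).dropna())
    if aa.size < 2 or bb.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(aa) == 0 and np.ptp(bb) == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    res = stats.ttest_ind(aa, bb, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def variance_f(a, b):
    """Two-sided variance-ratio F test with F = larger/smaller variance.

    Returns ``(F, df1, df2, p)``; F >= 1 by construction.
    """
    aa = np.asarray(pd.Series(a, dtype=float).dropna())
    bb = np.asarray(pd.Series(b, dtype=float).dropna())
    if aa.size < 2 or bb.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = aa.var(ddof=1), bb.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("variance-ratio test undefined: zero variance")
    if va >= vb:
        F, df1, df2 = va / vb, aa.size - 1, bb.size - 1
    else:
        F, df1, df2 = vb / va, bb.size - 1, aa.size - 1
    p = min(1.0, 2.0 * float(stats.f.sf(F, df1, df2)))
    return float(F), int(df1), int(df2), p


def compare_species(cf: CaseFile, species_a: str, species_b: str,
                    covariates: list, alpha: float = 0.05) -> list:
    """Per-covariate habitat comparison between two captured species.

    For each covariate, compares its values over the trap nights where each
    species was captured (Welch t; two-sided F for the variances).  The
    Bonferroni multiplier is the number of covariates compared; the species
    with the higher mean is reported only when the adjusted p stays below
    ``alpha``, otherwise ``"nd"`` (no significant difference).
    """
    df = cf.to_frame()
    in_a = df["outcome"] == species_a
    in_b = df["outcome"] == species_b
    if not in_a.any():
        raise ValueError(f"species {species_a!r} absent from case file")
    if not in_b.any():
        raise ValueError(f"species {species_b!r} absent from case file")
    m = len(covariates)
    rows = []
    for name in covariates:
        a = df.loc[in_a, name]
        b = df.loc[in_b, name]
        t, dfree, p = welch_t(a, b)
        F, _, _, p_f = variance_f(a, b)
        p_adj = min(1.0, m * p)
        if p_adj < alpha:
            higher = species_a if t > 0 else species_b
        else:
            higher = "nd"
        rows.append(SpeciesComparisonRow(name, t, dfree, p, p_adj, F, p_f, higher))
    return rows


def comparison_table(rows: list) -> pd.DataFrame:
    """Species-comparison rows as a flat table."""
    return pd.DataFrame([r.__dict__ for r in rows])
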