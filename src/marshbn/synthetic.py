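"""Synthetic trap-survey generator.

Emulates the statistical structure of a multi-site salt-marsh small-mammal
trapping study: ~73% of trap nights empty, a nine-species capture mix with
the salt marsh harvest mouse (RERA) at 20% of captures, strongly correlated
covariate pairs (tidal datums; distance-to-urban vs distance-to-agriculture),
and planted habitat effects (patch size, distance to road, longitude)
driving RERA presence.  Correlated continuous covariates are realized
through a latent-Gaussian copula; the RERA component of the capture mix is
tilted on the logistic scale by the planted effects, with the intercept
re-calibrated so the marginal RERA share stays at its configured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr  # standard normal CDF, vectorized

from .case_data import CAPTURE_SPECIES, CaseFile, TrapCase
from .catalog import COVER_CLASSES, LAYOUTS, default_catalog

#: Capture-outcome composition: counts per species over 3,339 capture
#: trap-nights (RERA = 669 = 20% of captures).
DEFAULT_CAPTURE_COUNTS = {
    "MICA": 1565, "MUMU": 555, "PEMA": 433, "RANO": 14, "RARA": 1,
    "RE": 3, "REME": 34, "RERA": 669, "SOOR": 65,
}


@dataclass(frozen=True)
class CovariateDist:
    """Marginal distribution of one continuous covariate.

    ``normal(mu, sigma)``, ``lognormal(mu, sigma)`` (log-scale parameters),
    or ``uniform(lo, hi)``.  ``lo``/``hi`` clip bounds are applied after the
    marginal transform (percent covers live in [0, 100], distances >= 0).
    """

    dist: str
    a: float
    b: float
    lo: float | None = None
    hi: float | None = None

    def transform(self, z: np.ndarray) -> np.ndarray:
        if self.dist == "normal":
            x = self.a + self.b * z
        elif self.dist == "lognormal":
            x = np.exp(self.a + self.b * z)
        elif self.dist == "uniform":
            x = self.a + (self.b - self.a) * ndtr(z)
        else:
            raise ValueError(f"unknown distribution {self.dist!r}")
        if self.lo is not None or self.hi is not None:
            x = np.clip(x, self.lo, self.hi)
        return x


def default_covariate_spec() -> dict:
    """Default marginals, loosely matching marsh-plain field ranges."""
    n, ln = "normal", "lognormal"
    return {
        "P1_V_PERC": CovariateDist(n, 86.0, 12.0, 0.0, 100.0),
        "P1_V1_MAX": CovariateDist(n, 55.0, 15.0, 0.0, None),
        "P1_V1_AVG": CovariateDist(n, 37.0, 10.0, 0.0, None),
        "P2_V_PERC": CovariateDist(n, 25.0, 10.0, 0.0, 100.0),
        "P2_V1_MAX": CovariateDist(n, 30.0, 10.0, 0.0, None),
        "P2_V1_AVG": CovariateDist(n, 18.0, 7.0, 0.0, None),
        "P3_V_PERC": CovariateDist(n, 8.0, 5.0, 0.0, 100.0),
        "P3_V1_MAX": CovariateDist(n, 20.0, 8.0, 0.0, None),
        "P3_V1_AVG": CovariateDist(n, 12.0, 5.0, 0.0, None),
        "Marsh_Elev": CovariateDist(n, 180.0, 25.0),
        "MHW": CovariateDist(n, 1.80, 0.12),
        "MHHW": CovariateDist(n, 1.95, 0.12),
        "Elev_MHW": CovariateDist(n, 0.10, 0.12),
        "Elev_MHHW": CovariateDist(n, -0.05, 0.12),
        "Dist_Levee": CovariateDist(ln, np.log(80.0), 0.8),
        "Dist_Water": CovariateDist(ln, np.log(60.0), 0.8),
        "Dist_Bay": CovariateDist(ln, np.log(400.0), 0.9),
        "Dist_Urban": CovariateDist(n, 2500.0, 800.0, 0.0, None),
        "Dist_Ag": CovariateDist(n, 1800.0, 600.0, 0.0, None),
        "Dist_Road": CovariateDist(ln, np.log(1000.0), 0.7),
        "Patch_Size": CovariateDist(ln, np.log(25.0), 0.8),
        "Patch_Size_Expanded": CovariateDist(ln, np.log(60.0), 0.9),
    }


#: Default latent correlations: near-duplicate tidal datums, the
#: urban/agriculture trade-off, and mildly related patch metrics.
DEFAULT_CORRELATION_BLOCKS = (
    ("MHW", "MHHW", 0.99),
    ("Elev_MHW", "Elev_MHHW", 0.97),
    ("Dist_Urban", "Dist_Ag", -0.85),
    ("Patch_Size", "Patch_Size_Expanded", 0.60),
)

#: Default planted drivers of RERA presence (log-odds per SD of covariate):
#: larger marsh patches, traps further from paved roads, more easterly sites.
DEFAULT_EFFECTS = {"Patch_Size": 1.0, "Dist_Road": 0.8, "longitude": 0.6}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated survey.

    Defaults give 5 sites x 827 traps x 3 nights = 12,405 trap nights with
    a 73.1% empty-trap rate and the nine-species capture composition above.
    """

    n_sites: int = 5
    traps_per_site: int = 827
    nights: int = 3
    seed: int = 0
    p_empty: float = 0.731
    capture_mix: dict = field(default_factory=lambda: dict(DEFAULT_CAPTURE_COUNTS))
    covariate_spec: dict = field(default_factory=default_covariate_spec)
    correlation_blocks: tuple = DEFAULT_CORRELATION_BLOCKS
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    missing_rate: float = 0.02

    def __post_init__(self):
        if not 0.0 <= self.p_empty <= 1.0:
            raise ValueError("p_empty must lie in [0, 1]")
        for a, b, r in self.correlation_blocks:
            if abs(r) > 1.0:
                raise ValueError(f"target correlation |r|>1 for pair ({a}, {b})")
        mix = self.capture_probabilities()
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise AssertionError("capture mix failed to normalize")

    def capture_probabilities(self) -> dict:
        """Capture mix as a probability vector over the nine species."""
        total = float(sum(self.capture_mix.values()))
        if total <= 0:
            raise ValueError("capture_mix must have positive mass")
        return {s: self.capture_mix.get(s, 0.0) / total for s in CAPTURE_SPECIES}

    @property
    def n_trap_nights(self) -> int:
        return self.n_sites * self.traps_per_site * self.nights

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def planted_truth(cfg: SimConfig) -> dict:
    """The ground-truth drivers planted by :func:`simulate`.

    Returns the effect coefficients and the driver names ordered by
    decreasing absolute effect size.  Invariant to the seed.
    """
    effects = {k: v for k, v in cfg.effects.items() if v != 0.0}
    drivers = sorted(effects, key=lambda k: (-abs(effects[k]), k))
    return {"effects": effects, "drivers": drivers}


def _latent_correlation(names: list, blocks) -> np.ndarray:
    m = len(names)
    idx = {n: i for i, n in enumerate(names)}
    corr = np.eye(m)
    for a, b, r in blocks:
        if a not in idx or b not in idx:
            raise ValueError(f"correlation block references unknown covariate ({a}, {b})")
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return corr


def _tilt(p_rera: float, eta: np.ndarray) -> np.ndarray:
    """Tilt the RERA probability by exp(eta) on the odds scale."""
    w = p_rera * np.exp(eta)
    return w / (w + (1.0 - p_rera))


def simulate(cfg: SimConfig) -> CaseFile:
    """Generate a synthetic trap-survey case file.

    Deterministic given ``cfg.seed``.  Continuous covariates are constant
    over the nights a trap is deployed (they describe the trap location);
    the latent Gaussian copula realizes the requested pairwise correlations.
    The outcome of each trap night is empty with ``p_empty``, otherwise a
    species draw from the capture mix whose RERA component is tilted by the
    planted log-odds effects evaluated on that trap's covariates; the
    tilt intercept is calibrated so the expected RERA share of captures
    equals the configured mix.
    """
    rng = np.random.default_rng(cfg.seed)
    catalog = default_catalog()
    n_traps = cfg.n_sites * cfg.traps_per_site
    cov_names = list(cfg.covariate_spec)

    corr = _latent_correlation(cov_names, cfg.correlation_blocks)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    latent = rng.standard_normal((n_traps, len(cov_names))) @ chol.T
    values = {name: cfg.covariate_spec[name].transform(latent[:, j])
              for j, name in enumerate(cov_names)}

    # Site geometry: centers strung west-to-east along the bay shore.
    site_names = [f"Site{i + 1:02d}" for i in range(cfg.n_sites)]
    site_lat = 38.08 + 0.04 * rng.standard_normal(cfg.n_sites)
    site_lon = -122.55 + 0.07 * np.arange(cfg.n_sites) + 0.01 * rng.standard_normal(cfg.n_sites)
    site_of_trap = np.repeat(np.arange(cfg.n_sites), cfg.traps_per_site)
    values["latitude"] = site_lat[site_of_trap] + 0.004 * rng.standard_normal(n_traps)
    values["longitude"] = site_lon[site_of_trap] + 0.006 * rng.standard_normal(n_traps)

    # Categorical microsite covariates: dominant-cover identities.
    cover_p = {
        1: np.array([0.54, 0.24, 0.09, 0.05, 0.08]),
        2: np.array([0.30, 0.35, 0.15, 0.08, 0.12]),
        3: np.array([0.15, 0.30, 0.20, 0.12, 0.23]),
    }
    species_cols = {f"P{k}_Species": rng.choice(COVER_CLASSES, size=n_traps, p=cover_p[k])
                    for k in (1, 2, 3)}

    layout_of_site = [LAYOUTS[i % len(LAYOUTS)] for i in range(cfg.n_sites)]
    year_of_site = [1998 + 2 * i for i in range(cfg.n_sites)]

    # Planted linear predictor on standardized covariate values.
    eta = np.zeros(n_traps)
    for name, beta in cfg.effects.items():
        if beta == 0.0:
            continue
        if name not in values:
            raise ValueError(f"effect on unknown covariate {name!r}")
        x = np.asarray(values[name], dtype=float)
        sd = x.std()
        eta += beta * ((x - x.mean()) / sd if sd > 0 else 0.0)

    mix = cfg.capture_probabilities()
    p_rera = mix["RERA"]
    delta = 0.0
    if np.any(eta != 0.0) and 0.0 < p_rera < 1.0:
        # Intercept calibration: keep the marginal RERA share at p_rera.
        delta = brentq(lambda d: _tilt(p_rera, eta + d).mean() - p_rera, -20.0, 20.0)
    q_rera = _tilt(p_rera, eta + delta) if 0.0 < p_rera < 1.0 else np.full(n_traps, p_rera)

    other_species = [s for s in CAPTURE_SPECIES if s != "RERA"]
    other_p = np.array([mix[s] for s in other_species])
    other_p = other_p / other_p.sum() if other_p.sum() > 0 else other_p

    cases = []
    sessions = ("spring", "summer", "fall")
    for t in range(n_traps):
        s = site_of_trap[t]
        trap_id = f"T{(t % cfg.traps_per_site) + 1:04d}"
        covs_base = {name: float(values[name][t]) for name in cov_names}
        for col, arr in species_cols.items():
            covs_base[col] = str(arr[t])
        covs_base["trap_position"] = trap_id
        for night in range(cfg.nights):
            if rng.random() < cfg.p_empty:
                outcome = "TRAP"
            elif rng.random() < q_rera[t]:
                outcome = "RERA"
            else:
                outcome = str(rng.choice(other_species, p=other_p))
            covs = dict(covs_base)
            if cfg.missing_rate > 0:
                for name in cov_names:
                    if rng.random() < cfg.missing_rate:
                        del covs[name]
            cases.append(TrapCase(
                site=site_names[s],
                year=year_of_site[s],
                session=sessions[night % len(sessions)],
                layout=layout_of_site[s],
                latitude=float(values["latitude"][t]),
                longitude=float(values["longitude"][t]),
                outcome=outcome,
                covariates=covs,
            ))
    return CaseFile(cases=cases, catalog=catalog)
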