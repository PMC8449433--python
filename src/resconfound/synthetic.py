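"""Latent-trait synthetic data emulating a three-trait survey triad.

The generator draws a population of subjects with three positively correlated
*true* scores — socioeconomic background (SEB), cognitive ability (CA) and
education (Edu) — and degrades each into an observed score through classical
measurement error: ``obs = rel * true + sqrt(1 - rel^2) * noise`` with
independent standard-normal noise, so ``rel`` is the true-observed
correlation (classical reliability is ``rel**2``).

Two worlds can be simulated:

``residual_confounding``
    True scores are jointly multivariate normal with the requested
    correlation matrix; any adjusted association among observed scores beyond
    what the true structure implies is an artifact of measurement error.

``discrimination``
    True education is built structurally as
    ``a*TrCA + direct_effect*TrSEB + noise`` (unit variance by construction),
    i.e. background has a direct causal path into educational attainment over
    and above ability.

On top of the latent triad, raw survey-style columns can be generated: a
12-subtest one-factor ability battery, two positively-skewed annual parental
incomes with zeros-as-missing, and a 7-category ordinal highest-degree
variable cut at normal quantiles of survey-like category frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bias import CorrelationTriad

__all__ = [
    "LatentSpec",
    "BatterySpec",
    "IncomeSpec",
    "TriadSample",
    "NLSY_DEGREE_COUNTS",
    "DEFAULT_DEGREE_PROBS",
    "generate_latent_triad",
    "generate_battery",
    "generate_income",
    "coarsen_degree",
    "calibrate_to_observed",
    "generate_dataset",
]

SCENARIOS = ("residual_confounding", "discrimination")

#: Highest-degree category counts (None, GED, high-school diploma,
#: associate, bachelor, master, professional/PhD) used for the default
#: ordinal coarsening thresholds.
NLSY_DEGREE_COUNTS = np.array([515, 862, 2692, 598, 1352, 540, 149])
DEFAULT_DEGREE_PROBS = NLSY_DEGREE_COUNTS / NLSY_DEGREE_COUNTS.sum()

# Availability fractions of the three raw measurements in the survey wave the
# generator emulates (battery 7008, income 7302, degree 6708 of 8984).
DEFAULT_MISSING = {"battery": 1 - 7008 / 8984, "income": 1 - 7302 / 8984, "degree": 1 - 6708 / 8984}

TRUTH_COLUMNS = ("seb_true", "ca_true", "edu_true")


def _as_rho(rho) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (3, 3):
        raise ValueError(f"rho_true must be 3x3, got shape {rho.shape}")
    if not np.allclose(rho, rho.T, atol=1e-12):
        raise ValueError("rho_true must be symmetric")
    if not np.allclose(np.diag(rho), 1.0, atol=1e-12):
        raise ValueError("rho_true must have unit diagonal")
    if np.linalg.eigvalsh(rho).min() < -1e-10:
        raise ValueError("rho_true must be positive semi-definite")
    return rho


@dataclass(frozen=True)
class LatentSpec:
    """Parameters of the true-score world.

    Parameters
    ----------
    n
        Number of subjects (>= 10).
    rho_true
        3x3 correlation matrix among true scores, ordered (SEB, CA, Edu).
        In the discrimination scenario the (CA, Edu) entry is read as the
        structural ability->education path and the (SEB, Edu) entry is
        implied by the structure.
    rel
        True-observed correlations per trait, each in [0, 1].
    scenario
        ``"residual_confounding"`` or ``"discrimination"``.
    direct_effect
        Structural TrSEB->TrEdu path; used only in the discrimination
        scenario.
    seed
        Seed for all randomness; identical specs give identical samples.
    """

    n: int
    rho_true: tuple = field(
        default=((1.0, 0.5, 0.35), (0.5, 1.0, 0.7), (0.35, 0.7, 1.0))
    )
    rel: tuple = (0.9, 0.9, 0.9)
    scenario: str = "residual_confounding"
    direct_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError(f"n must be at least 10, got {self.n}")
        rho = _as_rho(self.rho_true)
        object.__setattr__(self, "rho_true", tuple(map(tuple, rho)))
        rel = tuple(float(r) for r in self.rel)
        if len(rel) != 3 or any(not 0 <= r <= 1 for r in rel):
            raise ValueError(f"rel must be three values in [0, 1], got {self.rel}")
        object.__setattr__(self, "rel", rel)
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.direct_effect < 0:
            raise ValueError("direct_effect must be non-negative")
        if self.scenario == "discrimination":
            self.effective_rho_true()  # validates the structural variance budget

    def effective_rho_true(self) -> np.ndarray:
        """True-score correlation matrix actually realized by the scenario."""
        rho = np.asarray(self.rho_true)
        if self.scenario == "residual_confounding":
            return rho
        a, b, r_sc = rho[1, 2], self.direct_effect, rho[0, 1]
        explained = a * a + b * b + 2 * a * b * r_sc
        if explained > 1 + 1e-12:
            raise ValueError(
                "discrimination paths explain more than unit variance: "
                f"a={a}, direct_effect={b}, rho_sc={r_sc}"
            )
        out = np.array(
            [
                [1.0, r_sc, b + a * r_sc],
                [r_sc, 1.0, a + b * r_sc],
                [b + a * r_sc, a + b * r_sc, 1.0],
            ]
        )
        return _as_rho(out)

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "rho_true": [list(row) for row in self.rho_true],
            "rel": list(self.rel),
            "scenario": self.scenario,
            "direct_effect": float(self.direct_effect),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatentSpec":
        return cls(
            n=int(d["n"]),
            rho_true=tuple(map(tuple, d.get("rho_true", cls.rho_true))),
            rel=tuple(d.get("rel", cls.rel)),
            scenario=d.get("scenario", "residual_confounding"),
            direct_effect=float(d.get("direct_effect", 0.0)),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class BatterySpec:
    """One-factor subtest battery: ``subtest_j = loading_j*TrCA + noise``."""

    k: int = 12
    loadings: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        lam = np.asarray(self.loadings if len(self.loadings) else np.linspace(0.6, 0.8, self.k))
        if lam.size != self.k:
            raise ValueError(f"expected {self.k} loadings, got {lam.size}")
        if np.any(lam <= 0) or np.any(lam >= 1):
            raise ValueError("loadings must lie strictly in (0, 1)")
        object.__setattr__(self, "loadings", tuple(float(x) for x in lam))


@dataclass(frozen=True)
class IncomeSpec:
    """Two correlated log-normal annual incomes tracking true SEB.

    Calibration targets are the mean and SD of the two-year average, in
    thousands of currency units.  ``seb_loading`` is the correlation between
    each year's log income and true SEB; ``year_corr`` the log-scale
    correlation between the two years (must be >= seb_loading**2 so the
    shared component can absorb the SEB signal).  ``zero_fraction`` of each
    column is set to exact zero at random, emulating zeros-as-missing.
    """

    mean_target: float = 47.0
    sd_target: float = 45.4
    seb_loading: float = 0.75
    year_corr: float = 0.8
    zero_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_target <= 0 or self.sd_target <= 0:
            raise ValueError("calibration targets must be positive")
        if not 0 <= self.seb_loading < 1:
            raise ValueError("seb_loading must lie in [0, 1)")
        if not self.seb_loading**2 <= self.year_corr < 1:
            raise ValueError(
                "year_corr must lie in [seb_loading^2, 1) so the two years can "
                "share the SEB component"
            )
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must lie in [0, 1)")


@dataclass
class TriadSample:
    """Subject-level sample: measured scores plus hidden truth columns.

    ``data`` holds one row per subject.  Truth columns (``*_true``) exist for
    oracle checks only and are never consumed by analysis operations;
    :meth:`observed` and :meth:`derived` expose the analysis-facing views.
    """

    data: pd.DataFrame
    spec: LatentSpec | None = None

    def observed(self) -> pd.DataFrame:
        cols = [c for c in ("seb_obs", "ca_obs", "edu_obs") if c in self.data]
        return self.data[cols]

    def derived(self) -> pd.DataFrame:
        """Analysis-variable view with the derived-CSV column names."""
        out = pd.DataFrame({"id": np.arange(len(self.data))})
        for src, dst in (("seb_obs", "seb"), ("ca_obs", "ca"), ("edu_obs", "edu")):
            if src in self.data:
                out[dst] = self.data[src].to_numpy()
        return out

    def to_csv(self, path, keep_truth: bool = False) -> None:
        df = self.data if keep_truth else self.data.drop(columns=list(TRUTH_COLUMNS), errors="ignore")
        df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.data)


def generate_latent_triad(spec: LatentSpec) -> TriadSample:
    """Draw true scores and classically-degraded observed scores.

    True scores are multivariate normal with the scenario's effective
    correlation matrix; each observed score is ``rel*true`` plus independent
    Gaussian noise scaled to unit total variance.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.effective_rho_true()
    # Cholesky with a PSD-safe fallback for singular (e.g. identity-rank) cases
    try:
        chol = np.linalg.cholesky(rho)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(rho)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    true = rng.standard_normal((spec.n, 3)) @ chol.T
    rel = np.asarray(spec.rel)
    noise = rng.standard_normal((spec.n, 3))
    obs = true * rel + noise * np.sqrt(1 - rel**2)
    df = pd.DataFrame(
        {
            "seb_true": true[:, 0],
            "ca_true": true[:, 1],
            "edu_true": true[:, 2],
            "seb_obs": obs[:, 0],
            "ca_obs": obs[:, 1],
            "edu_obs": obs[:, 2],
        }
    )
    return TriadSample(data=df, spec=spec)


def generate_battery(true_ca: np.ndarray, spec: BatterySpec) -> np.ndarray:
    """n x k one-factor subtest matrix: ``loading_j*true_ca`` plus independent noise."""
    true_ca = np.asarray(true_ca, dtype=float)
    rng = np.random.default_rng(spec.seed)
    lam = np.asarray(spec.loadings)
    noise = rng.standard_normal((true_ca.size, spec.k))
    return true_ca[:, None] * lam + noise * np.sqrt(1 - lam**2)


def generate_income(true_seb: np.ndarray, spec: IncomeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two annual income columns (thousands), log-normal around true SEB.

    Each year's log income is ``mu + sigma*Z_t`` with
    ``Z_t = lambda*TrSEB + gamma*shared + delta*unique_t`` standardized so that
    corr(Z_t, TrSEB) = ``seb_loading`` and corr(Z_1, Z_2) = ``year_corr``.
    ``mu`` and ``sigma`` solve the two-moment calibration: the two-year
    average hits ``mean_target`` and ``sd_target`` exactly in population.
    A ``zero_fraction`` of each column is zeroed at random (MCAR).
    """
    true_seb = np.asarray(true_seb, dtype=float)
    n = true_seb.size
    rng = np.random.default_rng(spec.seed)
    lam, rho = spec.seb_loading, spec.year_corr
    gamma = math.sqrt(rho - lam * lam)
    delta = math.sqrt(1 - rho)

    # mean/SD of the average of two correlated log-normals:
    #   E = exp(mu + s2/2),  Var = E^2 * (exp(s2) + exp(rho*s2) - 2) / 2
    ratio = (spec.sd_target / spec.mean_target) ** 2

    def gap(s2: float) -> float:
        return (math.exp(s2) + math.exp(rho * s2) - 2) / 2 - ratio

    s2 = optimize.brentq(gap, 1e-12, 20.0)
    mu = math.log(spec.mean_target) - s2 / 2
    sigma = math.sqrt(s2)

    shared = rng.standard_normal(n)
    cols = []
    for _ in range(2):
        z = lam * true_seb + gamma * shared + delta * rng.standard_normal(n)
        cols.append(np.exp(mu + sigma * z))
    y1, y2 = cols
    n_zero = int(round(spec.zero_fraction * n))
    if n_zero:
        y1[rng.choice(n, size=n_zero, replace=False)] = 0.0
        y2[rng.choice(n, size=n_zero, replace=False)] = 0.0
    return y1, y2


def coarsen_degree(true_edu: np.ndarray, cut_probs=DEFAULT_DEGREE_PROBS) -> np.ndarray:
    """Ordinal 0-6 degree by thresholding at standard-normal quantiles.

    Thresholds sit at the normal quantiles of the cumulative category
    probabilities, so a standard-normal input reproduces ``cut_probs`` in
    expectation.  Monotone: larger input never yields a smaller category.
    """
    probs = np.asarray(cut_probs, dtype=float)
    if np.any(probs < 0):
        raise ValueError("category probabilities must be non-negative")
    if abs(probs.sum() - 1) > 1e-9:
        raise ValueError(f"category probabilities must sum to 1, got {probs.sum()}")
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
    return np.searchsorted(cuts, np.asarray(true_edu, dtype=float), side="left")


def calibrate_to_observed(
    triad: CorrelationTriad,
    rel_seb: float = 0.9,
    rel_edu: float = 0.9,
    n: int = 4654,
    seed: int = 0,
) -> LatentSpec:
    """Latent chain spec whose *observed* correlations match a target triad.

    Assumes the true scores form a chain SEB - CA - Edu with no direct
    SEB->Edu path, i.e. rho(SEB,Edu) = rho(SEB,CA)*rho(CA,Edu).  Under that
    structure the CA reliability is identified from the observed triad:
    ``rel_ca = sqrt(r_sc*r_cd / r_sd)``; the SEB and Edu reliabilities are
    free and trade off against the latent correlations.
    """
    r_sc, r_sd, r_cd = triad.r_sc, triad.r_sd, triad.r_cd
    if min(r_sc, r_sd, r_cd) <= 0:
        raise ValueError("calibration requires all-positive observed correlations")
    rel_ca = math.sqrt(r_sc * r_cd / r_sd)
    if rel_ca > 1:
        raise ValueError(
            f"observed triad inconsistent with a no-direct-path chain (implied rel_ca={rel_ca:.3f})"
        )
    rho_sc = r_sc / (rel_seb * rel_ca)
    rho_ce = r_cd / (rel_ca * rel_edu)
    if max(rho_sc, rho_ce) > 1:
        raise ValueError("requested reliabilities imply latent correlations above 1")
    rho_se = rho_sc * rho_ce
    return LatentSpec(
        n=n,
        rho_true=(
            (1.0, rho_sc, rho_se),
            (rho_sc, 1.0, rho_ce),
            (rho_se, rho_ce, 1.0),
        ),
        rel=(rel_seb, rel_ca, rel_edu),
        scenario="residual_confounding",
        seed=seed,
    )


def generate_dataset(
    spec: LatentSpec,
    battery: BatterySpec | None = None,
    income: IncomeSpec | None = None,
    degree_probs=DEFAULT_DEGREE_PROBS,
    missing: dict | None = None,
    keep_truth: bool = False,
) -> pd.DataFrame:
    """Full raw survey-style dataset from the latent triad.

    Columns: ``id``, ``subtest_1..k``, ``income_y1/income_y2`` (zeros as
    missing), ``degree`` (ordinal 0-6), plus truth columns when
    ``keep_truth``.  Each instrument is driven by the *observed*-score layer
    of its trait: the ``rel`` degradation represents the gap between the
    latent construct and the signal the instrument actually taps, and the
    instrument (subtest noise, income noise, coarsening) adds its own error
    on top.  ``missing`` maps ``battery``/``income``/``degree`` to MCAR
    missing fractions; defaults emulate the survey's per-measure
    availability.
    """
    battery = battery or BatterySpec(seed=spec.seed + 1)
    income = income or IncomeSpec(seed=spec.seed + 2)
    miss = dict(DEFAULT_MISSING)
    miss.update(missing or {})
    sample = generate_latent_triad(spec)
    d = sample.data
    rng = np.random.default_rng(spec.seed + 3)

    sub = generate_battery(d["ca_obs"].to_numpy(), battery)
    y1, y2 = generate_income(d["seb_obs"].to_numpy(), income)
    degree = coarsen_degree(d["edu_obs"].to_numpy(), degree_probs).astype(float)

    n = len(d)

    def _mask(frac: float) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        k = int(round(frac * n))
        if k:
            m[rng.choice(n, size=k, replace=False)] = True
        return m

    sub[_mask(miss["battery"]), :] = np.nan
    inc_missing = _mask(miss["income"])
    y1[inc_missing] = 0.0
    y2[inc_missing] = 0.0
    degree[_mask(miss["degree"])] = np.nan

    out = pd.DataFrame({"id": np.arange(n)})
    for j in range(battery.k):
        out[f"subtest_{j + 1}"] = sub[:, j]
    out["income_y1"] = y1
    out["income_y2"] = y2
    out["degree"] = degree
    if keep_truth:
        for c in TRUTH_COLUMNS + ("seb_obs", "ca_obs", "edu_obs"):
            out[c] = d[c].to_numpy()
    return out
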