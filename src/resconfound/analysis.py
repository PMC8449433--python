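"""Six-way adjusted effects among three traits, and the reversal diagnostic.

All six ordered (outcome, predictor, adjuster) standardized partial effects
among SEB, cognitive ability and education are estimated by OLS on a single
listwise complete-case sample, with percentile-bootstrap (or analytic
normal) confidence intervals.  Two auxiliary analyses support the
adjudication between a discrimination and a residual-confounding reading of
the data: residual-residual exports (the partial-correlation scatters) and
the regression of the education-minus-ability difference score on SEB.

Sign-pattern adjudication
-------------------------
A direct background->education path ("discrimination") predicts a *negative*
SEB-ability association once education is adjusted for, and a *positive*
association between SEB and the difference score.  Residual confounding of
imperfectly measured traits instead predicts that every pair stays positive
whichever third variable is adjusted, and implies no particular association
with the difference score.  The verdict is a pure function of which
confidence intervals exclude zero and in which direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bias import CorrelationTriad, partial_beta

__all__ = [
    "EFFECT_ORDER",
    "AdjustedEffect",
    "AdjustedEffects",
    "DiffScoreResult",
    "AdjudicationResult",
    "complete_cases",
    "correlation_triad",
    "adjusted_effects_all",
    "residual_scatter",
    "difference_score_regression",
    "adjudicate",
]

TRAITS = ("seb", "ca", "edu")

#: the six directed (outcome, predictor, adjuster) triples
EFFECT_ORDER = tuple(
    (y, x, z)
    for x in TRAITS
    for y in TRAITS
    if x != y
    for z in TRAITS
    if z not in (x, y)
)


@dataclass(frozen=True)
class AdjustedEffect:
    outcome: str
    predictor: str
    adjuster: str
    beta: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError(
                f"point estimate {self.beta} outside its CI ({self.ci_low}, {self.ci_high})"
            )

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


@dataclass(frozen=True)
class AdjustedEffects:
    """The six directed standardized partial coefficients with CIs."""

    effects: tuple
    n_analysis: int
    ci_method: str = "bootstrap"

    def __post_init__(self) -> None:
        keys = {(e.outcome, e.predictor, e.adjuster) for e in self.effects}
        if keys != set(EFFECT_ORDER):
            raise ValueError("effects must cover exactly the 6 ordered trait pairs")

    def get(self, outcome: str, predictor: str) -> AdjustedEffect:
        for e in self.effects:
            if e.outcome == outcome and e.predictor == predictor:
                return e
        raise KeyError((outcome, predictor))

    def to_records(self) -> list[dict]:
        return [vars(e).copy() for e in self.effects]


@dataclass(frozen=True)
class DiffScoreResult:
    beta: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class AdjudicationResult:
    verdict: str  # discrimination_consistent | residual_confounding_consistent | inconclusive
    evidence: list = field(default_factory=list)


def complete_cases(data: pd.DataFrame) -> pd.DataFrame:
    """Listwise deletion to the single analysis sample used by all regressions."""
    return data.dropna(subset=list(TRAITS))


def _check_columns(data: pd.DataFrame) -> None:
    missing = [c for c in TRAITS if c not in data.columns]
    if missing:
        raise ValueError(f"derived-variables table lacks columns {missing}")


def correlation_triad(data: pd.DataFrame, policy: str = "listwise") -> CorrelationTriad:
    """Pearson correlations among the three derived variables.

    ``listwise`` computes all three on the shared complete-case sample (the
    default, matching a single analysis sample); ``pairwise`` uses each
    pair's own available rows, recording the smallest pairwise n.
    """
    _check_columns(data)
    if policy not in ("listwise", "pairwise"):
        raise ValueError("policy must be 'listwise' or 'pairwise'")
    df = data[list(TRAITS)]
    if policy == "listwise":
        df = df.dropna()
        n = len(df)
        if n < 3:
            raise ValueError(f"need at least 3 complete cases, got {n}")
        arr = df.to_numpy()
        if np.any(arr.std(axis=0) == 0):
            raise ValueError("constant column in analysis sample")
        r = np.corrcoef(arr, rowvar=False)
        return CorrelationTriad(r_sc=r[0, 1], r_sd=r[0, 2], r_cd=r[1, 2], n=n)

    def pair_r(a: str, b: str) -> tuple[float, int]:
        sub = df[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"need at least 3 cases for pair ({a}, {b})")
        arr = sub.to_numpy()
        if np.any(arr.std(axis=0) == 0):
            raise ValueError(f"constant column in pair ({a}, {b})")
        return float(np.corrcoef(arr, rowvar=False)[0, 1]), len(sub)

    r_sc, n1 = pair_r("seb", "ca")
    r_sd, n2 = pair_r("seb", "edu")
    r_cd, n3 = pair_r("ca", "edu")
    return CorrelationTriad(r_sc=r_sc, r_sd=r_sd, r_cd=r_cd, n=min(n1, n2, n3))


def _standardize_cols(arr: np.ndarray) -> np.ndarray:
    return (arr - arr.mean(axis=0)) / arr.std(axis=0)


def _six_betas_from_corr(r: np.ndarray) -> np.ndarray:
    """Vector of the six standardized partial coefficients in EFFECT_ORDER,
    from a 3x3 correlation matrix (possibly batched: ... x 3 x 3)."""
    idx = {t: i for i, t in enumerate(TRAITS)}
    out = []
    for y, x, z in EFFECT_ORDER:
        rxy = r[..., idx[x], idx[y]]
        rxz = r[..., idx[x], idx[z]]
        ryz = r[..., idx[y], idx[z]]
        out.append((rxy - rxz * ryz) / (1.0 - rxz**2))
    return np.stack(out, axis=-1)


def _bootstrap_corrs(arr: np.ndarray, B: int, rng: np.random.Generator, chunk: int = 256):
    """Yield batched 3x3 correlation matrices of subject resamples."""
    n = arr.shape[0]
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(b, n))
        sample = arr[idx]  # b x n x 3
        centered = sample - sample.mean(axis=1, keepdims=True)
        cov = np.einsum("bni,bnj->bij", centered, centered) / n
        sd = np.sqrt(np.einsum("bii->bi", cov))
        yield cov / (sd[:, :, None] * sd[:, None, :])
        done += b


def adjusted_effects_all(
    data: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> AdjustedEffects:
    """All six adjusted standardized effects with confidence intervals.

    Variables are standardized on the listwise complete-case sample; each
    effect is the OLS coefficient of the standardized predictor with the
    adjuster in the model, identical to the closed-form partial coefficient
    from the sample correlations.  CIs are percentile bootstrap over subject
    resampling (``B`` replicates, restandardized within each resample);
    ``B = 0`` gives analytic normal-theory CIs instead.
    """
    _check_columns(data)
    df = complete_cases(data)
    n = len(df)
    if n < 10:
        raise ValueError(f"need at least 10 complete cases, got {n}")
    arr = df[list(TRAITS)].to_numpy(dtype=float)
    if np.any(arr.std(axis=0) == 0):
        raise ValueError("constant column in analysis sample")
    r = np.corrcoef(arr, rowvar=False)
    off = np.abs(r[np.triu_indices(3, 1)])
    if np.any(off >= 1 - 1e-12):
        raise ValueError("perfect collinearity between two analysis variables")
    betas = _six_betas_from_corr(r)

    alpha = 1 - ci_level
    if B >= 1:
        rng = np.random.default_rng(seed)
        boot = np.concatenate(
            [_six_betas_from_corr(rb) for rb in _bootstrap_corrs(arr, B, rng)], axis=0
        )
        lo = np.quantile(boot, alpha / 2, axis=0)
        hi = np.quantile(boot, 1 - alpha / 2, axis=0)
        ci_method = "bootstrap"
    else:
        # normal-theory SE of a standardized two-predictor OLS coefficient
        z = stats.norm.ppf(1 - alpha / 2)
        idx = {t: i for i, t in enumerate(TRAITS)}
        lo = np.empty(6)
        hi = np.empty(6)
        for j, (y, x, zadj) in enumerate(EFFECT_ORDER):
            sub = r[np.ix_([idx[x], idx[zadj]], [idx[x], idx[zadj]])]
            rxy = np.array([r[idx[x], idx[y]], r[idx[zadj], idx[y]]])
            r2 = float(rxy @ np.linalg.solve(sub, rxy))
            se = np.sqrt((1 - r2) / ((n - 3) * (1 - r[idx[x], idx[zadj]] ** 2)))
            lo[j] = betas[j] - z * se
            hi[j] = betas[j] + z * se
        ci_method = "normal"

    effects = tuple(
        AdjustedEffect(
            outcome=y,
            predictor=x,
            adjuster=zadj,
            beta=float(betas[j]),
            ci_low=float(min(lo[j], betas[j])),
            ci_high=float(max(hi[j], betas[j])),
        )
        for j, (y, x, zadj) in enumerate(EFFECT_ORDER)
    )
    return AdjustedEffects(effects=effects, n_analysis=n, ci_method=ci_method)


def residual_scatter(data: pd.DataFrame, pair: tuple[str, str], adjuster: str) -> pd.DataFrame:
    """Residuals of each trait in ``pair`` after regressing out ``adjuster``.

    The correlation of the two residual columns is the partial correlation of
    the pair given the adjuster; the table is meant for plotting/export.
    """
    _check_columns(data)
    a, b = pair
    for name in (a, b, adjuster):
        if name not in TRAITS:
            raise ValueError(f"unknown trait {name!r}")
    if adjuster in pair or a == b:
        raise ValueError("pair and adjuster must be three distinct traits")
    df = complete_cases(data)
    arr = _standardize_cols(df[list(TRAITS)].to_numpy(dtype=float))
    cols = {t: arr[:, i] for i, t in enumerate(TRAITS)}
    z = cols[adjuster]
    out = pd.DataFrame({"id": df["id"].to_numpy() if "id" in df else np.arange(len(df))})
    for name in (a, b):
        v = cols[name]
        slope = (v @ z) / (z @ z)
        out[f"residual_{name}"] = v - slope * z
    return out


def difference_score_regression(
    data: pd.DataFrame, B: int = 2000, seed: int = 0, ci_level: float = 0.95
) -> DiffScoreResult:
    """OLS of (edu_std - ca_std) on seb_std on the complete-case sample.

    With all three variables standardized on the same sample, the coefficient
    equals r(seb, edu) - r(seb, ca) exactly.  Percentile bootstrap CI over
    subject resampling; ``B = 0`` gives the analytic normal CI.
    """
    _check_columns(data)
    df = complete_cases(data)
    n = len(df)
    if n < 10:
        raise ValueError(f"need at least 10 complete cases, got {n}")
    arr = df[list(TRAITS)].to_numpy(dtype=float)
    if np.any(arr.std(axis=0) == 0):
        raise ValueError("constant column in analysis sample")
    r = np.corrcoef(arr, rowvar=False)
    beta = float(r[0, 2] - r[0, 1])

    alpha = 1 - ci_level
    if B >= 1:
        rng = np.random.default_rng(seed)
        boot = np.concatenate(
            [rb[:, 0, 2] - rb[:, 0, 1] for rb in _bootstrap_corrs(arr, B, rng)], axis=0
        )
        lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    else:
        z = stats.norm.ppf(1 - alpha / 2)
        s = _standardize_cols(arr)
        resid = (s[:, 2] - s[:, 1]) - beta * s[:, 0]
        se = np.sqrt((resid @ resid) / (n - 2) / n)
        lo, hi = beta - z * se, beta + z * se
    return DiffScoreResult(
        beta=beta, ci_low=float(min(lo, beta)), ci_high=float(max(hi, beta)), n=n
    )


def adjudicate(effects: AdjustedEffects, diff: DiffScoreResult) -> AdjudicationResult:
    """Sign-pattern verdict from the CI evidence.

    ``discrimination_consistent`` requires the CA-on-SEB effect adjusting for
    education to be credibly negative *and* the difference-score effect
    credibly positive.  ``residual_confounding_consistent`` requires all six
    adjusted effects credibly positive and the difference-score effect not
    credibly positive.  Anything else is ``inconclusive``.
    """
    ca_on_seb = effects.get(outcome="ca", predictor="seb")
    evidence = []
    for e in effects.effects:
        evidence.append(
            {
                "quantity": f"{e.predictor}->{e.outcome}|{e.adjuster}",
                "prediction": {
                    "discrimination": "negative" if (e.outcome, e.predictor) == ("ca", "seb") else "unspecified",
                    "residual_confounding": "positive",
                },
                "observed_sign": "+" if e.beta > 0 else ("-" if e.beta < 0 else "0"),
                "ci": [e.ci_low, e.ci_high],
            }
        )
    evidence.append(
        {
            "quantity": "seb->(edu-ca)",
            "prediction": {"discrimination": "positive", "residual_confounding": "none"},
            "observed_sign": "+" if diff.beta > 0 else ("-" if diff.beta < 0 else "0"),
            "ci": [diff.ci_low, diff.ci_high],
        }
    )

    if ca_on_seb.ci_high < 0 and diff.ci_low > 0:
        verdict = "discrimination_consistent"
    elif all(e.ci_low > 0 for e in effects.effects) and not diff.ci_low > 0:
        verdict = "residual_confounding_consistent"
    else:
        verdict = "inconclusive"
    return AdjudicationResult(verdict=verdict, evidence=evidence)
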