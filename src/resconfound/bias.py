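"""Closed-form bias algebra for covariate adjustment under classical measurement error.

The central quantity is the expected standardized partial regression
coefficient of an observed background variable on a *true* score when the
analysis adjusts for the *measured* version of that score.  Under the
classical error model (observed = r * true + independent noise, everything
standardized) the adjustment is incomplete whenever the measurement is not
perfectly reliable, and the leftover association has the closed form

    E[beta] = r_obs * (1 - r_true_obs**2) / (r_true_obs * (1 - r_obs**2))

where ``r_obs`` is the observed correlation between the background variable
and the measured score and ``r_true_obs`` is the true-observed correlation
of the measured score (its square is the classical reliability).  The
formula is zero exactly when ``r_obs == 0`` or ``r_true_obs == 1``: residual
confounding needs both a nonzero observed correlation and imperfect
measurement.

An exact population oracle (:func:`population_partial_oracle`) derives the
same quantity from the full latent/observed covariance matrix by matrix
algebra, with no sampling; the two routes agree to machine precision and the
agreement is the package's verification surface for the formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReliabilityPair",
    "CorrelationTriad",
    "expected_adjusted_effect",
    "partial_beta",
    "attenuated_corr",
    "population_covariance",
    "population_partial_oracle",
]

TRAITS = ("seb", "ca", "edu")

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class ReliabilityPair:
    """Inputs to the adjusted-effect bias formula.

    Parameters
    ----------
    r_obs
        Correlation between the two *observed* variables (background variable
        and measured score), in (-1, 1).
    r_true_obs
        True-observed correlation of the adjusted (measured) variable, in
        (0, 1].  Note this is the *unsquared* quantity; classical reliability
        is its square.
    """

    r_obs: float
    r_true_obs: float

    def __post_init__(self) -> None:
        if not abs(self.r_obs) < 1:
            raise ValueError(
                f"r_obs must satisfy |r_obs| < 1 (collinearity); got {self.r_obs}"
            )
        if not 0 < self.r_true_obs <= 1:
            raise ValueError(
                "r_true_obs must lie in (0, 1]; the adjusted variable must carry "
                f"some signal. Got {self.r_true_obs}"
            )


@dataclass(frozen=True)
class CorrelationTriad:
    """Pairwise correlations among (SEB, cognitive ability, degree) and the n used.

    ``r_sc`` = SEB-CA, ``r_sd`` = SEB-Degree, ``r_cd`` = CA-Degree.
    """

    r_sc: float
    r_sd: float
    r_cd: float
    n: int = 0

    def __post_init__(self) -> None:
        m = self.matrix()
        if np.linalg.eigvalsh(m).min() < -_PSD_TOL:
            raise ValueError(f"correlation triad is not positive semi-definite: {m}")

    def matrix(self) -> np.ndarray:
        """3x3 correlation matrix ordered (seb, ca, edu)."""
        return np.array(
            [
                [1.0, self.r_sc, self.r_sd],
                [self.r_sc, 1.0, self.r_cd],
                [self.r_sd, self.r_cd, 1.0],
            ]
        )

    def pair(self, a: str, b: str) -> float:
        i, j = TRAITS.index(a), TRAITS.index(b)
        return float(self.matrix()[i, j])


def expected_adjusted_effect(pair: ReliabilityPair) -> float:
    """Expected standardized effect of an observed variable on a true score,
    adjusting for the measured version of that score.

    Returns ``r_obs*(1 - r_true_obs^2) / (r_true_obs*(1 - r_obs^2))``.
    Zero iff the observed correlation is zero or the measurement is perfectly
    reliable — the two conditions under which covariate adjustment actually
    removes the confounder.
    """
    r, t = pair.r_obs, pair.r_true_obs
    return r * (1.0 - t * t) / (t * (1.0 - r * r))


def partial_beta(r_xy: float, r_xz: float, r_yz: float) -> float:
    """Standardized coefficient of predictor X for outcome Y, adjusting Z.

    For standardized variables the two-predictor OLS coefficient of X is
    ``(r_xy - r_xz*r_yz) / (1 - r_xz^2)``; ``r_xz`` is the
    predictor-adjuster correlation.
    """
    if abs(r_xz) >= 1:
        raise ValueError(f"predictor and adjuster are collinear (|r_xz| = {abs(r_xz)})")
    return (r_xy - r_xz * r_yz) / (1.0 - r_xz * r_xz)


def attenuated_corr(r_true: float, rel_x: float, rel_y: float) -> float:
    """Observed correlation implied by a true-score correlation and independent
    classical errors: ``r_true * rel_x * rel_y`` (rel = true-observed correlation)."""
    for name, v in (("rel_x", rel_x), ("rel_y", rel_y)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]; got {v}")
    if not -1 <= r_true <= 1:
        raise ValueError(f"r_true must lie in [-1, 1]; got {r_true}")
    return r_true * rel_x * rel_y


# ---------------------------------------------------------------------------
# population oracle

LABELS = ("seb_true", "ca_true", "edu_true", "seb_obs", "ca_obs", "edu_obs")


def population_covariance(spec) -> np.ndarray:
    """Exact 6x6 population covariance over (true, observed) scores.

    Variable order is :data:`LABELS`.  All variables have unit variance;
    observed = rel*true + sqrt(1-rel^2)*noise with independent noise, so
    cov(obs_i, obs_j) = rel_i*rel_j*rho_ij and cov(obs_i, true_j) = rel_i*rho_ij.

    ``spec`` is a :class:`~resconfound.synthetic.LatentSpec`; its effective
    true-score correlation matrix (structural in the discrimination scenario)
    is used.
    """
    rho = np.asarray(spec.effective_rho_true(), dtype=float)
    rel = np.asarray(spec.rel, dtype=float)
    cov = np.empty((6, 6))
    cov[:3, :3] = rho
    cov[:3, 3:] = rho * rel[None, :]
    cov[3:, :3] = cov[:3, 3:].T
    cov[3:, 3:] = rho * rel[:, None] * rel[None, :]
    np.fill_diagonal(cov, 1.0)
    if np.linalg.eigvalsh(cov).min() < -1e-8:
        raise ValueError("implied latent/observed covariance is not PSD")
    return cov


def population_partial_oracle(spec, outcome: str, predictor: str, adjuster: str) -> float:
    """Population standardized partial coefficient by covariance algebra.

    Regresses ``outcome`` on ``predictor`` + ``adjuster`` in the exact
    population covariance of the latent world — no sampling involved.  Any of
    the six latent/observed variables in :data:`LABELS` may be named.  This is
    the independent check of :func:`expected_adjusted_effect`: the oracle for
    (``seb_obs`` -> ``ca_true`` | ``ca_obs``) equals the formula to 1e-10.
    """
    cov = population_covariance(spec)
    idx = {name: i for i, name in enumerate(LABELS)}
    for name in (outcome, predictor, adjuster):
        if name not in idx:
            raise KeyError(f"unknown variable {name!r}; choose from {LABELS}")
    y, x, z = idx[outcome], idx[predictor], idx[adjuster]
    s_xx = cov[np.ix_([x, z], [x, z])]
    if abs(np.linalg.det(s_xx)) < 1e-12:
        raise ValueError("predictor/adjuster covariance is singular")
    s_xy = cov[np.ix_([x, z], [y])]
    beta = np.linalg.solve(s_xx, s_xy)
    # variables all have unit variance, so the coefficient is already standardized
    return float(beta[0, 0])
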