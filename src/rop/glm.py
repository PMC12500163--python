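"""Generalized linear model core: fitting, aliasing, and joint tests.

Gaussian (identity link) and binomial (logit link) families, fitted by
Fisher scoring (IRLS).  Rank-deficient designs are handled by a
rank-revealing pivoted QR: aliased columns are excluded from the fit and
recorded by name, because in phase models a dropped column silently
changes the hypothesis being tested.

Three asymptotically equivalent tests of a joint null on a coefficient
subset are provided: likelihood ratio, Wald, and Rao score.  For the
Gaussian family the default reference distribution is chi-square (matching
the GLM framing); an F small-sample option is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special, stats  # noqa: F401

_FAMILIES = ("gaussian", "binomial")

#: relative tolerance on deviance change declaring IRLS convergence
CONV_TOL = 1e-8
MAX_ITER = 100
#: |eta| beyond which binomial fitted probabilities are numerically 0/1
_ETA_CLIP = 30.0


class DegenerateDesignError(ValueError):
    """Raised when a design cannot support the requested test at all."""


@dataclass
class GlmFit:
    """Result of one maximum-likelihood GLM fit.

    ``params``/``cov`` are indexed by the *kept* (non-aliased) column
    names; ``aliased`` lists the excluded columns.
    """

    family: str
    columns: list[str]
    aliased: list[str]
    params: np.ndarray
    cov: np.ndarray
    deviance: float
    llf: float
    scale: float
    mu: np.ndarray
    nobs: int
    rank: int
    converged: bool
    separation: bool = False

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def param_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.columns)


def _validate_family(family: str) -> str:
    family = family.lower()
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}, got {family!r}")
    return family


def _rank_reveal(X: np.ndarray, columns: Sequence[str]) -> tuple[np.ndarray, list[int], list[str]]:
    """Pivoted-QR rank detection. Returns (X_kept, kept_idx, aliased_names)."""
    n, p = X.shape
    if p == 0:
        raise DegenerateDesignError("empty design")
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    kept = sorted(piv[:rank].tolist())
    aliased = [columns[i] for i in sorted(piv[rank:].tolist())]
    return X[:, kept], kept, aliased


def fit_glm(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    family: str = "gaussian",
    columns: Sequence[str] | None = None,
    max_iter: int = MAX_ITER,
    tol: float = CONV_TOL,
) -> GlmFit:
    """Fit a GLM by Fisher scoring with aliased-column exclusion.

    Binomial responses must be 0/1.  Perfect separation is flagged when
    fitted logits diverge while the deviance keeps falling toward zero.
    """
    family = _validate_family(family)
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        X = X.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(X, dtype=np.float64)
        if columns is None:
            columns = [f"x{i}" for i in range(X.shape[1])]
        columns = list(columns)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("response length does not match design rows")
    if family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial response must be 0/1")

    Xk, kept_idx, aliased = _rank_reveal(X, columns)
    kept_names = [columns[i] for i in kept_idx]
    rank = len(kept_idx)
    if n <= rank:
        raise DegenerateDesignError(
            f"{n} rows cannot identify {rank} estimable columns"
        )

    if family == "gaussian":
        beta, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
        resid = y - Xk @ beta
        rss = float(resid @ resid)
        scale = rss / (n - rank)
        XtX_inv = np.linalg.inv(Xk.T @ Xk)
        llf = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)
        return GlmFit(
            family=family, columns=kept_names, aliased=aliased,
            params=beta, cov=scale * XtX_inv, deviance=rss, llf=llf,
            scale=scale, mu=Xk @ beta, nobs=n, rank=rank, converged=True,
        )

    # binomial logit via Fisher scoring with step halving
    beta = np.zeros(rank)
    eta = Xk @ beta
    mu = special.expit(eta)
    dev = _binom_deviance(y, mu)
    converged = False
    for _ in range(max_iter):
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        WX = Xk * w[:, None]
        try:
            beta_new = np.linalg.solve(Xk.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(np.sqrt(w)[:, None] * Xk, np.sqrt(w) * z, rcond=None)[0]
        step = beta_new - beta
        # step halving if deviance increases
        for _ in range(20):
            eta_new = np.clip(Xk @ (beta + step), -_ETA_CLIP, _ETA_CLIP)
            mu_new = special.expit(eta_new)
            dev_new = _binom_deviance(y, mu_new)
            if dev_new <= dev + 1e-10:
                break
            step *= 0.5
        beta = beta + step
        eta, mu = eta_new, mu_new
        if abs(dev - dev_new) <= tol * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new

    separation = bool(
        converged
        and (np.abs(Xk @ beta) >= _ETA_CLIP - 1e-6).any()
        and dev < 1e-6 * n
    )
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = Xk.T @ (Xk * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    llf = float(np.sum(y * np.log(np.clip(mu, 1e-300, None))
                       + (1 - y) * np.log(np.clip(1 - mu, 1e-300, None))))
    return GlmFit(
        family=family, columns=kept_names, aliased=aliased, params=beta,
        cov=cov, deviance=dev, llf=llf, scale=1.0, mu=mu, nobs=n,
        rank=rank, converged=converged, separation=separation,
    )


def _binom_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = y * np.log(mu) + (1 - y) * np.log(1 - mu)
    return float(-2.0 * ll.sum())


# ---------------------------------------------------------------------------
# Test results
# ---------------------------------------------------------------------------

@dataclass
class PhaseTestResult:
    """Outcome of one (possibly joint) coefficient test.

    ``status`` is ``'ok'`` when the test ran; otherwise ``'inestimable'``
    (all tested columns aliased with the adjustment set),
    ``'not_converged'`` or ``'separation'``, in which case the statistic
    and p-value are None.
    """

    test_name: str
    statistic: float | None
    df: int | None
    p_value: float | None
    estimates: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    status: str = "ok"
    nobs: int = 0
    aliased: tuple[str, ...] = ()
    notes: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if not self.ok:
            return f"<PhaseTestResult {self.test_name}: {self.status}>"
        return (
            f"<PhaseTestResult {self.test_name}: stat={self.statistic:.4g}, "
            f"df={self.df}, p={self.p_value:.4g}>"
        )


def joint_test(
    X: pd.DataFrame,
    y: np.ndarray,
    test_cols: Sequence[str],
    family: str = "gaussian",
    test_type: str = "lrt",
    test_name: str | None = None,
    inference: str = "chisq",
) -> PhaseTestResult:
    """Joint test that all coefficients on ``test_cols`` are zero.

    The adjustment set is every other column of ``X``.  Tested columns
    lying in the span of the adjustment set are aliased: they reduce the
    degrees of freedom, and the whole test is reported inestimable if none
    of them add rank.  ``test_type`` is one of ``'lrt'``, ``'wald'``,
    ``'score'``; ``inference='f'`` (Gaussian only) uses the F reference
    instead of chi-square.
    """
    family = _validate_family(family)
    test_type = test_type.lower()
    if test_type not in ("lrt", "wald", "score"):
        raise ValueError(f"unknown test_type {test_type!r}")
    if inference not in ("chisq", "f"):
        raise ValueError("inference must be 'chisq' or 'f'")
    if inference == "f" and family != "gaussian":
        raise ValueError("F inference is only defined for the gaussian family")
    test_cols = list(test_cols)
    missing = [c for c in test_cols if c not in X.columns]
    if missing:
        raise ValueError(f"tested columns not in design: {missing}")
    if test_name is None:
        test_name = "+".join(test_cols)
    other = [c for c in X.columns if c not in test_cols]
    y = np.asarray(y, dtype=np.float64)

    full = fit_glm(X, y, family=family)
    reduced = fit_glm(X[other], y, family=family)
    df = full.rank - reduced.rank
    kept_tested = [c for c in test_cols if c in full.columns]
    aliased_tested = tuple(c for c in test_cols if c not in full.columns)
    if df <= 0:
        return PhaseTestResult(
            test_name=test_name, statistic=None, df=None, p_value=None,
            status="inestimable", nobs=full.nobs, aliased=aliased_tested,
            notes="tested columns lie in the span of the adjustment set",
        )
    for fit, which in ((full, "full"), (reduced, "reduced")):
        if fit.family == "binomial" and fit.separation:
            return PhaseTestResult(
                test_name=test_name, statistic=None, df=None, p_value=None,
                status="separation", nobs=fit.nobs, aliased=aliased_tested,
                notes=f"perfect separation in the {which} model",
            )
        if not fit.converged:
            return PhaseTestResult(
                test_name=test_name, statistic=None, df=None, p_value=None,
                status="not_converged", nobs=fit.nobs, aliased=aliased_tested,
                notes=f"{which} model did not converge",
            )

    estimates = {
        c: (float(full.params[full.columns.index(c)]),
            float(full.bse[full.columns.index(c)]))
        for c in kept_tested
    }

    if test_type == "lrt":
        if family == "gaussian":
            stat = full.nobs * math.log(reduced.deviance / full.deviance)
        else:
            stat = reduced.deviance - full.deviance
    elif test_type == "wald":
        idx = [full.columns.index(c) for c in kept_tested]
        b = full.params[idx]
        V = full.cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
    else:  # score
        stat = _score_statistic(X, y, other, reduced, family)
    stat = max(float(stat), 0.0)

    if inference == "f":
        # (RSS0 - RSS1)/q over RSS1/(n - p): exact under Gaussian errors
        fstat = ((reduced.deviance - full.deviance) / df) / (
            full.deviance / (full.nobs - full.rank)
        )
        p = float(stats.f.sf(fstat, df, full.nobs - full.rank))
        stat = float(fstat)
    else:
        p = float(stats.chi2.sf(stat, df))
    return PhaseTestResult(
        test_name=test_name, statistic=stat, df=df, p_value=p,
        estimates=estimates, status="ok", nobs=full.nobs,
        aliased=aliased_tested,
    )


def _score_statistic(
    X: pd.DataFrame,
    y: np.ndarray,
    other: Sequence[str],
    reduced: GlmFit,
    family: str,
) -> float:
    """Rao score statistic evaluated at the restricted MLE.

    Uses the expected information over the full (non-aliased) design; the
    score components of the adjustment set vanish at the restricted fit, so
    the quadratic form isolates the tested block.
    """
    cols = list(X.columns)
    Xf = X.to_numpy(dtype=np.float64)
    Xf, kept_idx, _ = _rank_reveal(Xf, cols)
    # linear predictor of the reduced fit, mapped onto all rows
    eta0 = X[list(reduced.columns)].to_numpy(dtype=np.float64) @ reduced.params
    if family == "gaussian":
        mu0 = eta0
        resid = y - mu0
        phi = float(resid @ resid) / len(y)
        W = np.ones_like(y)
    else:
        mu0 = special.expit(eta0)
        resid = y - mu0
        phi = 1.0
        W = np.maximum(mu0 * (1.0 - mu0), 1e-12)
    U = Xf.T @ resid / phi
    info = Xf.T @ (Xf * W[:, None]) / phi
    try:
        return float(U @ np.linalg.solve(info, U))
    except np.linalg.LinAlgError:
        return float(U @ np.linalg.pinv(info) @ U)


def estimability_report(
    X: pd.DataFrame,
    phase_terms: Sequence[str],
    tol: float = 1e-8,
) -> dict[str, dict]:
    """Aliasing diagnosis per phase term.

    A term is *aliased* when its column lies in the span of all the other
    columns (intercept, genotypes, dominance terms, covariates and the
    remaining phase terms it would be adjusted by).  For an aliased term,
    ``aliased_with`` names a minimal set of spanning columns recovered from
    the least-squares representation.
    """
    report: dict[str, dict] = {}
    for term in phase_terms:
        if term not in X.columns:
            raise ValueError(f"unknown design column {term!r}")
        others = [c for c in X.columns if c != term]
        A = X[others].to_numpy(dtype=np.float64)
        b = X[term].to_numpy(dtype=np.float64)
        coef, _, _, _ = np.linalg.lstsq(A, b, rcond=None)
        resid = b - A @ coef
        scale = max(1.0, float(np.abs(b).max()))
        if math.sqrt(float(resid @ resid)) <= tol * scale * math.sqrt(len(b)):
            support = [others[i] for i in np.nonzero(np.abs(coef) > tol)[0]]
            report[term] = {"estimable": False, "aliased_with": support}
        else:
            report[term] = {"estimable": True, "aliased_with": []}
    return report
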