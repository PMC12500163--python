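"""Regression on Phase (RoP) model and results.

RoP tests whether the phenotypic contribution of two variants is
coordinated through their chromosomal phase.  The model is a GLM

    g(E(Y)) = b0 + bGA*GA + bDA*DA + bGB*GB + bDB*DB
                 + bPcis*Pcis + bPtrans*Ptrans (+ covariates)

where GA, GB are additive genotypes, DA, DB dominance indicators, and
Pcis, Ptrans are the additive cis and trans phasetypes of the designated
reference allele pair (by default the alternative alleles: Pcis = Cis_AB,
Ptrans = Trans_AB).  The cis and trans effects are tested separately with
two 1-df tests, H0: bPcis = 0 and H0: bPtrans = 0, each adjusted for both
marginal effects and the other phase term.  Because of the linear
identities between genotypes and phasetypes, the test statistics are
invariant to the reference-allele choice; only the sign of the estimated
phase coefficient can flip under reference misspecification.

Usage follows the Model/Results convention::

    model = RoPModel(y, cohort, family="gaussian")
    res = model.fit()           # LRT by default; 'wald' and 'score' exposed
    res.cis, res.trans          # PhaseTestResult for each 1-df test
    print(res.summary())
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import coding
from .coding import (
    BiallelicDiplotype,
    MultiallelicPhasetypeCode,
    multiallelic_design,
    phasetype_table,
)
from .glm import (
    DegenerateDesignError,
    GlmFit,
    PhaseTestResult,
    estimability_report as _estimability_report,
    fit_glm,
    joint_test,
)

__all__ = [
    "RoPModel",
    "RoPResults",
    "rop_test",
    "rop_multiallelic_test",
    "recessive_cis_test",
    "estimability_report",
    "build_rop_design",
]


def _as_cohort(cohort) -> np.ndarray:
    if isinstance(cohort, np.ndarray):
        H = cohort
    else:
        H = coding.cohort_array(cohort)
    if H.ndim != 3 or H.shape[1:] != (2, 2):
        raise ValueError(f"expected (n, 2, 2) haplotype array, got {np.shape(cohort)}")
    return H


def n_distinct_diplotypes(cohort) -> int:
    """Number of distinct (unordered) diplotypes observed in a cohort."""
    H = _as_cohort(cohort)
    # canonicalise haplotype order within each individual
    key1 = H[:, 0, 0] * 2 + H[:, 0, 1]
    key2 = H[:, 1, 0] * 2 + H[:, 1, 1]
    lo = np.minimum(key1, key2)
    hi = np.maximum(key1, key2)
    return len(np.unique(lo * 4 + hi))


def build_rop_design(
    cohort,
    covariates: pd.DataFrame | None = None,
    ref: tuple[str, str] = ("A", "B"),
    dominance_phase: bool = False,
    include_trans: bool = True,
) -> pd.DataFrame:
    """Design matrix for the RoP model.

    ``ref`` selects the reference allele pair for the phase terms, e.g.
    ``('a', 'B')`` sets Pcis = Cis_aB and recodes GA to count the 'a'
    allele.  ``dominance_phase`` adds the dominance phase indicators
    Dcis = 1[Pcis == 1] and Dtrans = 1[Ptrans == 1] used by the
    recessive-cis strategies; ``include_trans=False`` drops the trans
    block (recessive-cis Model 2).
    """
    ra, rb = ref
    if ra not in ("A", "a") or rb not in ("B", "b"):
        raise ValueError("ref must be a pair from {'A','a'} x {'B','b'}")
    pt = phasetype_table(_as_cohort(cohort))
    ga = pt["GA"] if ra == "A" else 2 - pt["GA"]
    gb = pt["GB"] if rb == "B" else 2 - pt["GB"]
    pair = ra + rb
    design = pd.DataFrame(
        {
            "const": np.ones(len(pt)),
            "GA": ga.astype(float),
            "DA": pt["DA"].astype(float),
            "GB": gb.astype(float),
            "DB": pt["DB"].astype(float),
            "Pcis": pt[f"Cis_{pair}"].astype(float),
        }
    )
    if dominance_phase:
        design["Dcis"] = (design["Pcis"] == 1).astype(float)
    if include_trans:
        design["Ptrans"] = pt[f"Trans_{pair}"].astype(float)
        if dominance_phase:
            design["Dtrans"] = (design["Ptrans"] == 1).astype(float)
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        overlap = set(cov.columns) & set(design.columns)
        if overlap:
            raise ValueError(f"covariate names collide with model terms: {overlap}")
        design = pd.concat([design, cov.astype(float)], axis=1)
    return design


class RoPModel:
    """Regression on Phase model for one pair of phased biallelic variants.

    Parameters
    ----------
    endog
        Phenotype vector; continuous (``family='gaussian'``) or 0/1
        (``family='binomial'``).
    cohort
        (n, 2, 2) 0/1 haplotype array ``[sample, haplotype, locus]`` or a
        sequence of :class:`~rop.coding.BiallelicDiplotype`.
    covariates
        Optional DataFrame of additive covariates, row-aligned with endog.
    ref
        Reference allele pair for the phase terms (default the alternative
        alleles; the tests are invariant to this choice).
    """

    def __init__(
        self,
        endog,
        cohort,
        covariates: pd.DataFrame | None = None,
        family: str = "gaussian",
        ref: tuple[str, str] = ("A", "B"),
    ) -> None:
        self.endog = np.asarray(endog, dtype=np.float64)
        self.cohort = _as_cohort(cohort)
        if len(self.endog) != len(self.cohort):
            raise ValueError("endog and cohort lengths differ")
        if n_distinct_diplotypes(self.cohort) < 3:
            raise DegenerateDesignError(
                "fewer than 3 distinct diplotypes observed; "
                "phase terms cannot be separated from genotypes"
            )
        self.family = family
        self.ref = ref
        self.covariates = covariates
        self.exog = build_rop_design(self.cohort, covariates, ref=ref)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        hap_columns: Sequence[str] = ("hap1_A", "hap1_B", "hap2_A", "hap2_B"),
        covariates: Sequence[str] = (),
        family: str = "gaussian",
        ref: tuple[str, str] = ("A", "B"),
    ) -> "RoPModel":
        """Build from a tidy table with per-haplotype allele columns."""
        h = data[list(hap_columns)].to_numpy(dtype=np.int64)
        cohort = np.stack([h[:, :2], h[:, 2:]], axis=1)
        cov = data[list(covariates)] if covariates else None
        return cls(data[response].to_numpy(), cohort, cov, family=family, ref=ref)

    def fit(self, test_type: str = "lrt", inference: str = "chisq") -> "RoPResults":
        """Fit the full model and run the two 1-df phase tests."""
        full = fit_glm(self.exog, self.endog, family=self.family)
        cis = joint_test(
            self.exog, self.endog, ["Pcis"], family=self.family,
            test_type=test_type, test_name="RoP cis", inference=inference,
        )
        trans = joint_test(
            self.exog, self.endog, ["Ptrans"], family=self.family,
            test_type=test_type, test_name="RoP trans", inference=inference,
        )
        return RoPResults(self, full, cis, trans, test_type=test_type)


class RoPResults:
    """Fitted RoP model: coefficient estimates plus the cis/trans tests."""

    def __init__(
        self,
        model: RoPModel,
        fit: GlmFit,
        cis: PhaseTestResult,
        trans: PhaseTestResult,
        test_type: str,
    ) -> None:
        self.model = model
        self._fit = fit
        self.cis = cis
        self.trans = trans
        self.test_type = test_type

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._fit.params, index=self._fit.columns)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._fit.bse, index=self._fit.columns)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self._fit.mu

    @property
    def llf(self) -> float:
        return self._fit.llf

    @property
    def deviance(self) -> float:
        return self._fit.deviance

    @property
    def aliased(self) -> list[str]:
        return list(self._fit.aliased)

    @property
    def nobs(self) -> int:
        return self._fit.nobs

    def estimability(self) -> dict[str, dict]:
        return estimability_report(self.model.exog, ["Pcis", "Ptrans"])

    def to_frame(self) -> pd.DataFrame:
        """One row per phase test, serialisable to TSV/JSON."""
        rows = []
        for r in (self.cis, self.trans):
            est, se = r.estimates.get(
                "Pcis" if "cis" in r.test_name else "Ptrans", (np.nan, np.nan)
            )
            rows.append(
                {
                    "test": r.test_name, "statistic": r.statistic, "df": r.df,
                    "p_value": r.p_value, "estimate": est, "se": se,
                    "status": r.status, "n": r.nobs,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        fam = self.model.family
        lines = [
            "Regression on Phase (RoP) results",
            "=" * 58,
            f"family: {fam:<12} n: {self.nobs:<8} test: {self.test_type.upper()}",
            f"reference allele pair: {''.join(self.model.ref)}",
        ]
        if self._fit.aliased:
            lines.append(f"aliased columns: {', '.join(self._fit.aliased)}")
        lines.append("-" * 58)
        lines.append(f"{'term':<10}{'coef':>12}{'std err':>12}")
        for name, b, se in zip(self._fit.columns, self._fit.params, self._fit.bse):
            lines.append(f"{name:<10}{b:>12.4f}{se:>12.4f}")
        lines.append("-" * 58)
        lines.append(f"{'test':<12}{'stat':>10}{'df':>5}{'p-value':>12}  status")
        for r in (self.cis, self.trans):
            if r.ok:
                lines.append(
                    f"{r.test_name:<12}{r.statistic:>10.4f}{r.df:>5}"
                    f"{r.p_value:>12.4g}  {r.status}"
                )
            else:
                lines.append(f"{r.test_name:<12}{'--':>10}{'--':>5}{'--':>12}  {r.status}")
        lines.append("=" * 58)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional interfaces
# ---------------------------------------------------------------------------

def rop_test(
    response,
    cohort,
    covariates: pd.DataFrame | None = None,
    family: str = "gaussian",
    test_type: str = "lrt",
    ref: tuple[str, str] = ("A", "B"),
    inference: str = "chisq",
) -> tuple[PhaseTestResult, PhaseTestResult]:
    """The two 1-df RoP phase tests (cis, trans)."""
    res = RoPModel(
        response, cohort, covariates, family=family, ref=ref
    ).fit(test_type=test_type, inference=inference)
    return res.cis, res.trans


def recessive_cis_test(
    response,
    cohort,
    family: str = "gaussian",
    model_variant: int = 1,
    covariates: pd.DataFrame | None = None,
    test_type: str = "lrt",
) -> PhaseTestResult:
    """2-df joint test of the additive and dominance cis phase terms.

    H0: bPcis = bDcis = 0, with Dcis = 1[Pcis == 1].  Variant 1 keeps the
    trans phase terms (Ptrans, Dtrans) in the model; variant 2 omits them,
    which improves recessive-cis power at the cost of type-I-error
    inflation when the true effect is in trans.

    The four phase terms satisfy the exact identity
    ``Pcis - Dcis = Ptrans - Dtrans`` (both sides equal twice the AB/AB
    indicator), so variant 1's design is never full rank.  The model is
    identified by excluding the redundant ``Dtrans`` column — the column
    a sequential fitter would alias — leaving the same column space and a
    well-defined 2-df joint test.
    """
    if model_variant not in (1, 2):
        raise ValueError("model_variant must be 1 or 2")
    X = build_rop_design(
        cohort, covariates, dominance_phase=True,
        include_trans=(model_variant == 1),
    )
    if model_variant == 1 and "Dtrans" in X.columns:
        X = X.drop(columns="Dtrans")
    return joint_test(
        X, response, ["Pcis", "Dcis"], family=family, test_type=test_type,
        test_name=f"recessive cis (model {model_variant})",
    )


def rop_multiallelic_test(
    response,
    codes: Sequence[MultiallelicPhasetypeCode],
    covariates: pd.DataFrame | None = None,
    family: str = "gaussian",
    test_type: str = "lrt",
) -> tuple[PhaseTestResult, PhaseTestResult]:
    """Joint cis and trans tests for a multi-allelic marker pair.

    With m and n alleles the nominal df is (m-1)(n-1) per test; aliased
    phase columns reduce the df and are reported on the result.
    """
    D = multiallelic_design(codes)
    X = pd.concat(
        [pd.DataFrame({"const": np.ones(len(D))}), D], axis=1
    )
    if covariates is not None:
        X = pd.concat([X, pd.DataFrame(covariates).reset_index(drop=True)], axis=1)
    cis_cols = [c for c in D.columns if c.startswith("Cis[")]
    trans_cols = [c for c in D.columns if c.startswith("Trans[")]
    y = np.asarray(response, dtype=np.float64)
    cis = joint_test(
        X, y, cis_cols, family=family, test_type=test_type,
        test_name="RoP cis (multi-allelic)",
    )
    trans = joint_test(
        X, y, trans_cols, family=family, test_type=test_type,
        test_name="RoP trans (multi-allelic)",
    )
    return cis, trans


def estimability_report(
    design: pd.DataFrame, phase_terms: Sequence[str] | None = None
) -> dict[str, dict]:
    """Per-phase-term estimability status for a design matrix.

    A phase term is flagged when its column lies in the span of the other
    columns (a zero column aliases with the intercept; under strong LD a
    cis term can collapse onto the rare variant's genotype).
    """
    if phase_terms is None:
        phase_terms = [
            c for c in design.columns
            if c in ("Pcis", "Ptrans", "Dcis", "Dtrans")
            or c.startswith(("Cis[", "Trans["))
        ]
    return _estimability_report(design, phase_terms)
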