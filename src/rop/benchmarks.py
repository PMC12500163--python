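"""Benchmark tests for phase-effect detection.

Comparators for the RoP phase tests:

* 1-df genotype interaction test: H0: bGAGB = 0 in
  g(E(Y)) = b0 + bGA*GA + bGB*GB + bGAGB*GA*GB.
* 4-df genotype interaction test: joint null on the four products
  GA*GB, GA*DB, DA*GB, DA*DB over the main-effects model.
* Saturated 5-df test: the four products plus the phase indicator V,
  where V = 1 iff both loci are heterozygous with the alternative
  alleles in cis (GA = GB = Cis_AB = 1).
* Haplotype odds-ratio (OR) test: 1-df chi-square from the log
  cross-ratio of the four haplotype frequencies in cases vs controls.
* 3-df haplotype regression: joint test of Cis_AB, Cis_Ab, Cis_aB with
  Cis_ab as reference and no marginal-effect adjustment.

The interaction tests detect phase only indirectly and cannot say whether
a signal is cis or trans; the OR test approximates additive cis effects
and is blind to trans effects; haplotype regression is confounded by
marginal effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coding import phasetype_table
from .glm import PhaseTestResult, joint_test
from .model import _as_cohort

__all__ = [
    "HaplotypeFrequencies",
    "interaction_test_1df",
    "interaction_test_4df",
    "saturated_test_5df",
    "haplotype_or_test",
    "haplotype_regression_3df",
    "haplotype_frequencies_from_cohort",
]


def _base_frame(cohort) -> pd.DataFrame:
    pt = phasetype_table(_as_cohort(cohort))
    return pt.astype(float)


def interaction_test_1df(
    response, cohort, family: str = "gaussian", test_type: str = "lrt"
) -> PhaseTestResult:
    """1-df test of the additive-by-additive genotype interaction."""
    pt = _base_frame(cohort)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "GA": pt["GA"],
            "GB": pt["GB"],
            "GAGB": pt["GA"] * pt["GB"],
        }
    )
    return joint_test(
        X, response, ["GAGB"], family=family, test_type=test_type,
        test_name="1df interaction",
    )


def _interaction_design(pt: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "const": 1.0,
            "GA": pt["GA"],
            "DA": pt["DA"],
            "GB": pt["GB"],
            "DB": pt["DB"],
            "GAGB": pt["GA"] * pt["GB"],
            "GADB": pt["GA"] * pt["DB"],
            "DAGB": pt["DA"] * pt["GB"],
            "DADB": pt["DA"] * pt["DB"],
        }
    )


def interaction_test_4df(
    response, cohort, family: str = "gaussian", test_type: str = "lrt"
) -> PhaseTestResult:
    """4-df joint test of all additive/dominance genotype interactions."""
    X = _interaction_design(_base_frame(cohort))
    return joint_test(
        X, response, ["GAGB", "GADB", "DAGB", "DADB"], family=family,
        test_type=test_type, test_name="4df interaction",
    )


def phase_indicator_v(cohort) -> np.ndarray:
    """V = 1 iff both loci heterozygous with alternative alleles in cis."""
    pt = phasetype_table(_as_cohort(cohort))
    return (
        (pt["GA"] == 1) & (pt["GB"] == 1) & (pt["Cis_AB"] == 1)
    ).to_numpy(dtype=np.float64)


def saturated_test_5df(
    response, cohort, family: str = "gaussian", test_type: str = "lrt"
) -> PhaseTestResult:
    """5-df joint test of the four genotype interactions plus V.

    On the ten diplotypes this design is saturated: any phase-effect mean
    structure is captured, but the extra df cost power relative to the
    targeted RoP tests, and the sign of bV depends on both the reference
    alleles and the cis/trans mechanism, so it cannot distinguish them.
    If no double heterozygotes are present, V is aliased and the test
    falls back to the remaining interaction df (reported on the result).
    """
    pt = _base_frame(cohort)
    X = _interaction_design(pt)
    X["V"] = phase_indicator_v(cohort)
    return joint_test(
        X, response, ["GAGB", "GADB", "DAGB", "DADB", "V"], family=family,
        test_type=test_type, test_name="saturated",
    )


def haplotype_regression_3df(
    response, cohort, family: str = "gaussian", test_type: str = "lrt"
) -> PhaseTestResult:
    """3-df haplotype regression: H0: bAB = bAb = baB = 0.

    Each haplotype of the pair is treated as an allele of one multi-allelic
    marker and modelled additively (Cis_ab is the reference; no
    marginal-effect adjustment), so the test is sensitive to main effects
    as well as to phase.
    """
    pt = _base_frame(cohort)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "Cis_AB": pt["Cis_AB"],
            "Cis_Ab": pt["Cis_Ab"],
            "Cis_aB": pt["Cis_aB"],
        }
    )
    return joint_test(
        X, response, ["Cis_AB", "Cis_Ab", "Cis_aB"], family=family,
        test_type=test_type, test_name="haplotype regression",
    )


# ---------------------------------------------------------------------------
# Haplotype odds-ratio test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeFrequencies:
    """Observed haplotype frequencies per case/control group.

    ``cases``/``controls`` map the four haplotypes 'AB', 'aB', 'Ab', 'ab'
    to frequencies summing to one within each group; ``n_cases`` and
    ``n_controls`` are group sizes in individuals (2n haplotypes each).
    """

    cases: dict
    controls: dict
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        for name, f in (("cases", self.cases), ("controls", self.controls)):
            if set(f) != {"AB", "aB", "Ab", "ab"}:
                raise ValueError(f"{name} must have keys AB, aB, Ab, ab")
            tot = sum(f.values())
            if not math.isclose(tot, 1.0, rel_tol=0, abs_tol=1e-8):
                raise ValueError(f"{name} frequencies sum to {tot}, not 1")
            if any(v < 0 for v in f.values()):
                raise ValueError(f"{name} frequencies must be nonnegative")


def haplotype_frequencies_from_cohort(
    cohort, response, continuity: float = 0.0
) -> HaplotypeFrequencies:
    """Observed phased haplotype frequencies split by case status.

    ``continuity`` adds the given pseudo-count (e.g. 0.5) to every
    haplotype count in both groups before normalising.
    """
    H = _as_cohort(cohort)
    y = np.asarray(response)
    out = {}
    ns = {}
    for label, mask in (("cases", y == 1), ("controls", y == 0)):
        haps = H[mask].reshape(-1, 2)  # (2*n_g, 2)
        counts = {
            "AB": float(((haps[:, 0] == 1) & (haps[:, 1] == 1)).sum()),
            "aB": float(((haps[:, 0] == 0) & (haps[:, 1] == 1)).sum()),
            "Ab": float(((haps[:, 0] == 1) & (haps[:, 1] == 0)).sum()),
            "ab": float(((haps[:, 0] == 0) & (haps[:, 1] == 0)).sum()),
        }
        counts = {k: v + continuity for k, v in counts.items()}
        tot = sum(counts.values())
        out[label] = {k: v / tot for k, v in counts.items()}
        ns[label] = int(mask.sum())
    return HaplotypeFrequencies(
        cases=out["cases"], controls=out["controls"],
        n_cases=ns["cases"], n_controls=ns["controls"],
    )


def haplotype_or_test(freqs: HaplotypeFrequencies) -> PhaseTestResult:
    """1-df haplotype odds-ratio test from case/control frequencies.

    The statistic is log(OR)^2 / (v1 + v0) with

        log(OR) = log(fAB1*fab1 / (fAb1*faB1)) - log(fAB0*fab0 / (fAb0*faB0))
        v_i     = (1 / 2n_i) * sum over the four haplotypes of 1/f

    referred to chi-square with 1 df.  Under a rare outcome log(OR)
    approximates the additive cis effect and vanishes under pure trans
    effects.  All eight frequencies must be strictly positive; use a
    continuity correction upstream if a haplotype is unobserved.
    """
    for name, f in (("case", freqs.cases), ("control", freqs.controls)):
        zero = [k for k, v in f.items() if v <= 0]
        if zero:
            raise ValueError(
                f"zero {name} haplotype frequency for {zero}; "
                "apply a continuity correction to proceed"
            )
    f1, f0 = freqs.cases, freqs.controls
    log_or = math.log(f1["AB"] * f1["ab"] / (f1["Ab"] * f1["aB"])) - math.log(
        f0["AB"] * f0["ab"] / (f0["Ab"] * f0["aB"])
    )
    v1 = sum(1.0 / f1[k] for k in ("AB", "aB", "Ab", "ab")) / (2 * freqs.n_cases)
    v0 = sum(1.0 / f0[k] for k in ("AB", "aB", "Ab", "ab")) / (2 * freqs.n_controls)
    stat = log_or**2 / (v1 + v0)
    se = math.sqrt(v1 + v0)
    return PhaseTestResult(
        test_name="haplotype OR",
        statistic=float(stat),
        df=1,
        p_value=float(stats.chi2.sf(stat, 1)),
        estimates={"log_OR": (float(log_or), float(se))},
        status="ok",
        nobs=freqs.n_cases + freqs.n_controls,
    )
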