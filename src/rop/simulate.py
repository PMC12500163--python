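"""Simulation framework: cohorts, phenotype models, and rejection rates.

Haplotypes for two biallelic loci are generated under Hardy-Weinberg
equilibrium from the four haplotype frequencies implied by the allele
frequencies (pA, pB) and the normalised linkage-disequilibrium coefficient
D'.  Phenotypes follow a registry of generating models: continuous models
for the conditional-analysis experiments (allelic heterogeneity vs
additive cis/trans effects) and logistic models for the type-I-error and
power comparisons, with case/control cohorts built by rejection sampling
of fresh individuals until the target group sizes are reached.

Every source of randomness is seeded: per-iteration generators are derived
from the master seed and the iteration index through ``SeedSequence`` spawn
keys, so runs are reproducible and trivially parallelisable.

Switch errors — phasing mistakes that flip cis to trans and vice versa —
are injected only into double heterozygotes, the sole diplotypes in which
a switch is observable, after the phenotype has been generated from the
true phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from . import benchmarks
from .glm import PhaseTestResult
from .model import RoPModel, build_rop_design, recessive_cis_test

__all__ = [
    "SimulationScenario",
    "PowerSummary",
    "hap_freqs_from_ld",
    "sample_cohort",
    "simulate_phenotype",
    "inject_switch_errors",
    "estimate_rates",
    "conditional_power_experiment",
    "power_ratio_surface",
    "switch_error_experiment",
    "h2_to_effect",
    "exact_term_variance",
    "standard_tests",
    "MODEL_IDS",
]

HAPLOTYPES = np.array([[1, 1], [0, 1], [1, 0], [0, 0]], dtype=np.int64)
_HAP_KEYS = ("AB", "aB", "Ab", "ab")

#: guard for pathological binary scenarios during rejection sampling
MAX_REJECTION_DRAWS = 10_000_000


# ---------------------------------------------------------------------------
# Population haplotype frequencies and cohort sampling
# ---------------------------------------------------------------------------

def hap_freqs_from_ld(pA: float, pB: float, dprime: float) -> dict[str, float]:
    """Haplotype frequencies from allele frequencies and D'.

    ``f_AB = pA*pB + D`` with ``D = D' * Dmax``, where Dmax is the largest
    |D| compatible with the marginals: ``min(pA(1-pB), (1-pA)pB)`` for
    D' >= 0 and ``min(pA*pB, (1-pA)(1-pB))`` for D' < 0.  The remaining
    three frequencies follow from the marginal constraints.
    """
    if not (0.0 < pA < 1.0 and 0.0 < pB < 1.0):
        raise ValueError("allele frequencies must lie in (0, 1)")
    if not -1.0 <= dprime <= 1.0:
        raise ValueError("D' must lie in [-1, 1]")
    if dprime >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d = dprime * dmax
    f = {
        "AB": pA * pB + d,
        "aB": (1 - pA) * pB - d,
        "Ab": pA * (1 - pB) - d,
        "ab": (1 - pA) * (1 - pB) + d,
    }
    # exact nonnegativity up to roundoff by construction
    for k, v in f.items():
        if v < -1e-12:
            raise ValueError(f"negative haplotype frequency for {k}: {v}")
        f[k] = max(v, 0.0)
    return f


def dprime_from_freqs(freqs: Mapping[str, float]) -> float:
    """Recover D' from haplotype frequencies (round-trip check)."""
    pA = freqs["AB"] + freqs["Ab"]
    pB = freqs["AB"] + freqs["aB"]
    d = freqs["AB"] - pA * pB
    if abs(d) < 1e-15:
        return 0.0
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    return d / dmax


def _freq_vector(freqs: Mapping[str, float]) -> np.ndarray:
    v = np.array([freqs[k] for k in _HAP_KEYS], dtype=np.float64)
    return v / v.sum()


def sample_cohort(
    freqs: Mapping[str, float], n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw n individuals as two independent haplotypes each (HWE).

    Returns an (n, 2, 2) 0/1 array [sample, haplotype, locus].
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = _freq_vector(freqs)
    idx = rng.choice(4, size=(n, 2), p=p)
    return HAPLOTYPES[idx]


# ---------------------------------------------------------------------------
# Phenotype models (generating models for the simulation studies)
# ---------------------------------------------------------------------------

def _terms(H: np.ndarray) -> dict[str, np.ndarray]:
    a1, b1 = H[:, 0, 0], H[:, 0, 1]
    a2, b2 = H[:, 1, 0], H[:, 1, 1]
    return {
        "GA": a1 + a2,
        "GB": b1 + b2,
        "Pcis": a1 * b1 + a2 * b2,
        "Ptrans": a1 * b2 + a2 * b1,
    }


def _lp(model_id: str, t: Mapping[str, np.ndarray], beta0: float, beta: float):
    if model_id == "heterogeneity":
        return beta0 + beta * t["GA"] + beta * t["GB"]
    if model_id == "additive_cis":
        return beta0 + beta * t["Pcis"]
    if model_id == "additive_trans":
        return beta0 + beta * t["Ptrans"]
    if model_id == "t1e_additive_a":
        return beta0 + beta * t["GA"]
    if model_id == "t1e_dominant_a":
        return beta0 + beta * (t["GA"] >= 1)
    if model_id == "t1e_recessive_a":
        return beta0 + beta * (t["GA"] == 2)
    if model_id == "t1e_additive_both":
        return beta0 + beta * t["GA"] + beta * t["GB"]
    if model_id == "t1e_dominant_both":
        return beta0 + beta * (t["GA"] >= 1) + beta * (t["GB"] >= 1)
    if model_id == "t1e_recessive_both":
        return beta0 + beta * (t["GA"] == 2) + beta * (t["GB"] == 2)
    if model_id == "power_additive_cis":
        return beta0 + beta * t["Pcis"]
    if model_id == "power_dominant_cis":
        return beta0 + beta * (t["Pcis"] >= 1)
    if model_id == "power_recessive_cis":
        return beta0 + beta * (t["Pcis"] == 2)
    if model_id == "power_additive_trans":
        return beta0 + beta * t["Ptrans"]
    if model_id == "power_dominant_trans":
        return beta0 + beta * (t["Ptrans"] >= 1)
    raise ValueError(f"unknown model_id {model_id!r}")


#: model_id -> (outcome kind, default effect coefficient)
MODEL_IDS: dict[str, tuple[str, float]] = {
    # continuous (conditional-analysis experiments); residual sd 1
    "heterogeneity": ("continuous", 0.5),
    "additive_cis": ("continuous", 1.5),
    "additive_trans": ("continuous", 1.5),
    # logistic, type-I error: marginal effects only, coefficient 1
    "t1e_additive_a": ("binary", 1.0),
    "t1e_dominant_a": ("binary", 1.0),
    "t1e_recessive_a": ("binary", 1.0),
    "t1e_additive_both": ("binary", 1.0),
    "t1e_dominant_both": ("binary", 1.0),
    "t1e_recessive_both": ("binary", 1.0),
    # logistic, power: phase effects; 0.5 additive/dominant, 1.5 recessive
    "power_additive_cis": ("binary", 0.5),
    "power_dominant_cis": ("binary", 0.5),
    "power_recessive_cis": ("binary", 1.5),
    "power_additive_trans": ("binary", 0.5),
    "power_dominant_trans": ("binary", 0.5),
}

T1E_MODELS = tuple(m for m in MODEL_IDS if m.startswith("t1e_"))
POWER_MODELS = tuple(m for m in MODEL_IDS if m.startswith("power_"))


@dataclass
class SimulationScenario:
    """One simulation configuration.

    The baseline intercept is -2 throughout (for logistic models this is a
    baseline prevalence of 0.12); ``beta=None`` uses the model's default
    effect coefficient.  Binary scenarios use ``n_cases``/``n_controls``
    (1000 each by default); continuous scenarios use ``n``.
    ``switch_rate`` injects phasing errors into double heterozygotes after
    phenotype generation.
    """

    model_id: str
    pA: float = 0.2
    pB: float = 0.2
    dprime: float = 0.0
    n: int = 1000
    n_cases: int = 1000
    n_controls: int = 1000
    beta0: float = -2.0
    beta: float | None = None
    residual_sd: float = 1.0
    n_iter: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    switch_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(
                f"unknown model_id {self.model_id!r}; choose from {sorted(MODEL_IDS)}"
            )
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0.0 <= self.switch_rate <= 1.0:
            raise ValueError("switch_rate must lie in [0, 1]")
        hap_freqs_from_ld(self.pA, self.pB, self.dprime)  # validates

    @property
    def outcome(self) -> str:
        return MODEL_IDS[self.model_id][0]

    @property
    def effect(self) -> float:
        return MODEL_IDS[self.model_id][1] if self.beta is None else self.beta

    def freqs(self) -> dict[str, float]:
        return hap_freqs_from_ld(self.pA, self.pB, self.dprime)


def simulate_phenotype(
    scenario: SimulationScenario,
    cohort: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a response for a scenario.

    Continuous scenarios add Gaussian noise to the stated linear model for
    the supplied cohort (drawn fresh when ``cohort`` is None).  Binary
    scenarios ignore the supplied cohort and rejection-sample fresh
    individuals from the population until exactly ``n_cases`` cases and
    ``n_controls`` controls are collected.

    Returns ``(y, cohort_used)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if scenario.outcome == "continuous":
        if cohort is None:
            cohort = sample_cohort(scenario.freqs(), scenario.n, rng)
        eta = _lp(scenario.model_id, _terms(cohort), scenario.beta0, scenario.effect)
        y = eta + rng.normal(0.0, scenario.residual_sd, size=len(cohort))
        return y, cohort
    return _sample_case_control(scenario, rng)


def _sample_case_control(
    scenario: SimulationScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    p_hap = _freq_vector(scenario.freqs())
    need_cases, need_controls = scenario.n_cases, scenario.n_controls
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    got_cases = got_controls = 0
    drawn = 0
    batch = max(2 * (need_cases + need_controls), 1000)
    while got_cases < need_cases or got_controls < need_controls:
        if drawn >= MAX_REJECTION_DRAWS:
            raise RuntimeError(
                "rejection sampling exceeded the draw cap; the scenario's "
                "success probabilities are too extreme"
            )
        m = min(batch, MAX_REJECTION_DRAWS - drawn)
        H = HAPLOTYPES[rng.choice(4, size=(m, 2), p=p_hap)]
        drawn += m
        eta = _lp(scenario.model_id, _terms(H), scenario.beta0, scenario.effect)
        yy = rng.random(m) < special.expit(eta)
        if got_cases < need_cases:
            take = H[yy][: need_cases - got_cases]
            cases.append(take)
            got_cases += len(take)
        if got_controls < need_controls:
            take = H[~yy][: need_controls - got_controls]
            controls.append(take)
            got_controls += len(take)
    cohort = np.concatenate(cases + controls, axis=0)
    y = np.concatenate(
        [np.ones(need_cases), np.zeros(need_controls)]
    )
    return y, cohort


def inject_switch_errors(
    cohort: np.ndarray,
    rate: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Flip the phase of double heterozygotes with the given probability.

    A switch error swaps the haplotype assignment at one locus, turning
    AB/ab into Ab/aB and vice versa.  Only individuals heterozygous at
    both loci can express a switch; every other diplotype is invariant.
    Genotypes are never altered.  Returns a new array.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("switch-error rate must lie in [0, 1]")
    H = np.array(cohort, copy=True)
    if rate == 0.0:
        return H
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t = _terms(H)
    double_het = (t["GA"] == 1) & (t["GB"] == 1)
    flip = double_het & (rng.random(len(H)) < rate)
    # swap locus-B alleles between the two haplotypes
    idx = np.nonzero(flip)[0]
    tmp = H[idx, 0, 1].copy()
    H[idx, 0, 1] = H[idx, 1, 1]
    H[idx, 1, 1] = tmp
    return H


# ---------------------------------------------------------------------------
# Registered tests and rate estimation
# ---------------------------------------------------------------------------

TestRunner = Callable[[np.ndarray, np.ndarray], "PhaseTestResult | Mapping[str, PhaseTestResult]"]


def standard_tests(
    family: str,
    which: Sequence[str] = ("rop",),
    test_type: str = "lrt",
) -> dict[str, TestRunner]:
    """Named registry of test runners for :func:`estimate_rates`.

    Available names: ``rop`` (expands to ``rop_cis`` and ``rop_trans`` from
    a single model fit), ``interaction_1df``, ``interaction_4df``,
    ``saturated``, ``haplotype_3df``, ``or_test`` (binomial only),
    ``recessive_cis_m1``, ``recessive_cis_m2``.
    """
    reg: dict[str, TestRunner] = {}
    for name in which:
        if name == "rop":
            def _rop(y, H, fam=family, tt=test_type):
                res = RoPModel(y, H, family=fam).fit(test_type=tt)
                return {"rop_cis": res.cis, "rop_trans": res.trans}
            reg["rop"] = _rop
        elif name == "interaction_1df":
            reg[name] = lambda y, H, fam=family, tt=test_type: (
                benchmarks.interaction_test_1df(y, H, family=fam, test_type=tt))
        elif name == "interaction_4df":
            reg[name] = lambda y, H, fam=family, tt=test_type: (
                benchmarks.interaction_test_4df(y, H, family=fam, test_type=tt))
        elif name == "saturated":
            reg[name] = lambda y, H, fam=family, tt=test_type: (
                benchmarks.saturated_test_5df(y, H, family=fam, test_type=tt))
        elif name == "haplotype_3df":
            reg[name] = lambda y, H, fam=family, tt=test_type: (
                benchmarks.haplotype_regression_3df(y, H, family=fam, test_type=tt))
        elif name == "or_test":
            if family != "binomial":
                raise ValueError("the haplotype OR test requires a binary outcome")
            def _or(y, H):
                freqs = benchmarks.haplotype_frequencies_from_cohort(H, y)
                return benchmarks.haplotype_or_test(freqs)
            reg["or_test"] = _or
        elif name == "recessive_cis_m1":
            reg[name] = lambda y, H, fam=family, tt=test_type: (
                recessive_cis_test(y, H, family=fam, model_variant=1, test_type=tt))
        elif name == "recessive_cis_m2":
            reg[name] = lambda y, H, fam=family, tt=test_type: (
                recessive_cis_test(y, H, family=fam, model_variant=2, test_type=tt))
        else:
            raise ValueError(f"unknown test name {name!r}")
    return reg


@dataclass
class PowerSummary:
    """Per-test rejection rates for one scenario.

    ``rates[name]`` is (count of p <= alpha) / (iterations where the test
    ran); Monte-Carlo SE is sqrt(r(1-r)/n); iterations in which a test
    reported a non-ok status are tracked in ``failures`` and excluded from
    that test's denominator.
    """

    scenario: SimulationScenario
    n_iter: int
    rejections: dict[str, int]
    valid: dict[str, int]
    failures: dict[str, int]

    @property
    def rates(self) -> dict[str, float]:
        return {
            k: (self.rejections[k] / self.valid[k]) if self.valid[k] else math.nan
            for k in self.rejections
        }

    @property
    def mc_se(self) -> dict[str, float]:
        out = {}
        for k, r in self.rates.items():
            n = self.valid[k]
            out[k] = math.sqrt(r * (1 - r) / n) if n else math.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.rejections:
            rows.append(
                {
                    "model_id": self.scenario.model_id,
                    "pA": self.scenario.pA,
                    "pB": self.scenario.pB,
                    "dprime": self.scenario.dprime,
                    "switch_rate": self.scenario.switch_rate,
                    "test": k,
                    "rate": self.rates[k],
                    "mc_se": self.mc_se[k],
                    "n_iter": self.n_iter,
                    "n_valid": self.valid[k],
                    "n_failed": self.failures[k],
                    "alpha": self.scenario.alpha,
                    "seed": self.scenario.seed,
                }
            )
        return pd.DataFrame(rows)


def _iter_rng(seed: int | None, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed or 0, spawn_key=(i,)))


def estimate_rates(
    scenario: SimulationScenario,
    tests: Mapping[str, TestRunner] | Sequence[str],
    seed: int | None = None,
) -> PowerSummary:
    """Monte-Carlo rejection rates for a set of tests under one scenario.

    Each iteration draws a fresh cohort and phenotype (with per-iteration
    generators derived from the master seed), optionally corrupts the
    observed phase with switch errors, runs every registered test and
    records whether p <= alpha.
    """
    if seed is None:
        seed = scenario.seed
    family = "binomial" if scenario.outcome == "binary" else "gaussian"
    if not isinstance(tests, Mapping):
        tests = standard_tests(family, which=tests)
    rejections: dict[str, int] = {}
    valid: dict[str, int] = {}
    failures: dict[str, int] = {}

    def record(name: str, result: PhaseTestResult) -> None:
        rejections.setdefault(name, 0)
        valid.setdefault(name, 0)
        failures.setdefault(name, 0)
        if result.ok:
            valid[name] += 1
            if result.p_value <= scenario.alpha:
                rejections[name] += 1
        else:
            failures[name] += 1

    for i in range(scenario.n_iter):
        rng = _iter_rng(seed, i)
        y, H = simulate_phenotype(scenario, rng=rng)
        if scenario.switch_rate > 0:
            H = inject_switch_errors(H, scenario.switch_rate, rng)
        for name, runner in tests.items():
            out = runner(y, H)
            if isinstance(out, PhaseTestResult):
                record(name, out)
            else:
                for sub, r in out.items():
                    record(sub, r)
    return PowerSummary(
        scenario=replace(scenario, seed=seed), n_iter=scenario.n_iter,
        rejections=rejections, valid=valid, failures=failures,
    )


# ---------------------------------------------------------------------------
# Conditional-analysis experiment
# ---------------------------------------------------------------------------

def conditional_power_experiment(
    scenario: SimulationScenario, seed: int | None = None
) -> dict[str, float]:
    """Power of the secondary-variant test with and without conditioning.

    Per iteration, fits (i) Y ~ GB and (ii) Y ~ GA + GB and tests bGB
    (1 df) in each, alongside the RoP cis and trans tests.  Returns four
    rejection rates: ``snpB_unconditional``, ``snpB_conditional``,
    ``rop_cis``, ``rop_trans``.  Conditioning helps when the two variants
    are unlinked but can mask the secondary signal under LD, which is why
    it cannot separate allelic heterogeneity from phase effects.
    """
    from .glm import joint_test

    if scenario.outcome != "continuous":
        raise ValueError("the conditional-analysis experiment uses continuous outcomes")
    if seed is None:
        seed = scenario.seed
    counts = {"snpB_unconditional": 0, "snpB_conditional": 0, "rop_cis": 0, "rop_trans": 0}
    for i in range(scenario.n_iter):
        rng = _iter_rng(seed, i)
        y, H = simulate_phenotype(scenario, rng=rng)
        t = _terms(H)
        X1 = pd.DataFrame({"const": np.ones(len(y)), "GB": t["GB"].astype(float)})
        r1 = joint_test(X1, y, ["GB"], family="gaussian", test_name="snpB")
        X2 = X1.assign(GA=t["GA"].astype(float))
        r2 = joint_test(X2, y, ["GB"], family="gaussian", test_name="snpB|GA")
        res = RoPModel(y, H, family="gaussian").fit()
        for key, r in (
            ("snpB_unconditional", r1),
            ("snpB_conditional", r2),
            ("rop_cis", res.cis),
            ("rop_trans", res.trans),
        ):
            if r.ok and r.p_value <= scenario.alpha:
                counts[key] += 1
    return {k: v / scenario.n_iter for k, v in counts.items()}


# ---------------------------------------------------------------------------
# LD power-ratio surfaces
# ---------------------------------------------------------------------------

def _population_moments(freqs: Mapping[str, float]) -> tuple[np.ndarray, list[str]]:
    """Exact E[x x'] of the RoP design over the diplotype distribution."""
    p = _freq_vector(freqs)
    cols = ["const", "GA", "DA", "GB", "DB", "Pcis", "Ptrans"]
    M = np.zeros((7, 7))
    for i in range(4):
        for j in range(4):
            H = np.array([[HAPLOTYPES[i], HAPLOTYPES[j]]])
            t = _terms(H)
            x = np.array(
                [1.0, t["GA"][0], float(t["GA"][0] == 1), t["GB"][0],
                 float(t["GB"][0] == 1), t["Pcis"][0], t["Ptrans"][0]]
            )
            M += p[i] * p[j] * np.outer(x, x)
    return M, cols


def analytic_power(
    freqs: Mapping[str, float],
    effect: str,
    beta: float,
    n: int,
    sigma: float,
    alpha: float = 0.05,
) -> float:
    """Noncentral-chi-square power of the 1-df RoP test, Gaussian outcome.

    The noncentrality is n * beta^2 * s^2 / sigma^2 where s^2 is the
    population residual variance of the tested phase term after projecting
    on the adjustment columns.  Returns NaN when the term is aliased at
    the population level (s^2 = 0).
    """
    M, cols = _population_moments(freqs)
    term = {"cis": "Pcis", "trans": "Ptrans"}[effect]
    k = cols.index(term)
    other = [i for i in range(len(cols)) if i != k]
    Mzz = M[np.ix_(other, other)]
    Mzk = M[other, k]
    s2 = M[k, k] - Mzk @ np.linalg.lstsq(Mzz, Mzk, rcond=None)[0]
    if s2 < 1e-12:
        return float("nan")
    ncp = n * beta**2 * s2 / sigma**2
    crit = stats.chi2.ppf(1 - alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp))


def power_ratio_surface(
    pa_values: Sequence[float],
    pb_values: Sequence[float],
    effect: str = "cis",
    dprimes: tuple[float, float] = (0.0, 0.8),
    n: int = 1000,
    sigma: float = 2.0,
    beta: float = 1.0,
    alpha: float = 0.05,
    method: str = "simulation",
    n_iter: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ratio of RoP power under LD to power without LD over a frequency grid.

    For each (pA, pB) cell a quantitative outcome is modelled with an
    additive phase effect (defaults: n=1000, sigma=2, beta=1); power is
    estimated at each D' in ``dprimes`` and the ratio power(D'[1]) /
    power(D'[0]) is reported.  ``method='analytic'`` uses the noncentral
    chi-square route from exact population design moments instead of
    simulation.
    """
    if effect not in ("cis", "trans"):
        raise ValueError("effect must be 'cis' or 'trans'")
    model_id = "additive_cis" if effect == "cis" else "additive_trans"
    rows = []
    for ia, pa in enumerate(pa_values):
        for ib, pb in enumerate(pb_values):
            powers = {}
            for dp in dprimes:
                freqs = hap_freqs_from_ld(pa, pb, dp)
                if method == "analytic":
                    powers[dp] = analytic_power(freqs, effect, beta, n, sigma, alpha)
                else:
                    scen = SimulationScenario(
                        model_id=model_id, pA=pa, pB=pb, dprime=dp, n=n,
                        beta=beta, residual_sd=sigma, n_iter=n_iter,
                        alpha=alpha,
                        seed=(seed or 0) + 1000 * ia + 10 * ib + int(dp * 10),
                    )
                    key = "rop_cis" if effect == "cis" else "rop_trans"
                    powers[dp] = estimate_rates(scen, ("rop",)).rates[key]
            p0, p1 = powers[dprimes[0]], powers[dprimes[1]]
            rows.append(
                {
                    "pA": pa, "pB": pb, "effect": effect,
                    f"power_d{dprimes[0]}": p0, f"power_d{dprimes[1]}": p1,
                    "ratio": p1 / p0 if p0 and not math.isnan(p0) else math.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Heritability calibration and the switch-error experiment
# ---------------------------------------------------------------------------

def exact_term_variance(freqs: Mapping[str, float], term: str = "Pcis") -> float:
    """Population variance of a model term from the diplotype distribution."""
    p = _freq_vector(freqs)
    vals = []
    probs = []
    for i in range(4):
        for j in range(4):
            H = np.array([[HAPLOTYPES[i], HAPLOTYPES[j]]])
            t = _terms(H)
            if term not in t:
                raise ValueError(f"unknown term {term!r}")
            vals.append(float(t[term][0]))
            probs.append(p[i] * p[j])
    vals = np.array(vals)
    probs = np.array(probs)
    mean = float(probs @ vals)
    return float(probs @ (vals - mean) ** 2)


def h2_to_effect(
    h2: float,
    freqs: Mapping[str, float],
    term: str = "Pcis",
    sigma: float = 1.0,
) -> float:
    """Effect coefficient giving a target heritability for one term.

    Solves h2 = beta^2 Var(term) / (beta^2 Var(term) + sigma^2) with the
    term variance computed exactly from the population diplotype
    probabilities.  The residual standard deviation is held fixed
    (sigma=1 by default) and beta is solved for.
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must lie in [0, 1)")
    if h2 == 0.0:
        return 0.0
    var = exact_term_variance(freqs, term)
    if var <= 0:
        raise ValueError(f"term {term!r} has zero population variance")
    return math.sqrt(h2 / (1.0 - h2) * sigma**2 / var)


def switch_error_experiment(
    maf_scenarios: Sequence[tuple[float, float]] = ((0.05, 0.05), (0.05, 0.2), (0.2, 0.2)),
    switch_rates: Sequence[float] = (0.0, 0.05, 0.10, 0.20),
    h2: float = 0.003,
    n: int = 5000,
    n_iter: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Robustness of RoP to phasing (switch) errors.

    For each MAF scenario, haplotypes for n individuals are simulated with
    the two variants independent (D' = 0) and a continuous outcome is
    generated under an additive cis effect whose coefficient is calibrated
    to the target heritability (sigma fixed at 1).  Switch errors are then
    injected into double heterozygotes at each rate and the RoP cis power
    and trans type-I error are estimated.  The rates share each
    iteration's cohort and phenotype (a paired, common-random-numbers
    design), so the per-scenario retention ratios are estimated much more
    precisely than with independent runs.  Returns one tidy row per
    scenario x rate.
    """
    rows = []
    for k, (pa, pb) in enumerate(maf_scenarios):
        freqs = hap_freqs_from_ld(pa, pb, 0.0)
        beta = h2_to_effect(h2, freqs, term="Pcis", sigma=1.0)
        scen = SimulationScenario(
            model_id="additive_cis", pA=pa, pB=pb, dprime=0.0, n=n,
            beta=beta, residual_sd=1.0, n_iter=n_iter, alpha=alpha,
            seed=(seed or 0) + 100 * k,
        )
        rej = {rate: {"cis": 0, "trans": 0} for rate in switch_rates}
        for i in range(n_iter):
            rng = _iter_rng(scen.seed, i)
            y, H = simulate_phenotype(scen, rng=rng)
            for rate in switch_rates:
                Hc = inject_switch_errors(H, rate, rng) if rate > 0 else H
                res = RoPModel(y, Hc, family="gaussian").fit()
                if res.cis.ok and res.cis.p_value <= alpha:
                    rej[rate]["cis"] += 1
                if res.trans.ok and res.trans.p_value <= alpha:
                    rej[rate]["trans"] += 1
        for rate in switch_rates:
            rows.append(
                {
                    "pA": pa, "pB": pb, "h2": h2, "beta": beta,
                    "switch_rate": rate,
                    "cis_power": rej[rate]["cis"] / n_iter,
                    "trans_t1e": rej[rate]["trans"] / n_iter,
                    "n": n, "n_iter": n_iter,
                }
            )
    return pd.DataFrame(rows)
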