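"""Bias-corrected prevalence estimation from multiplex panel tests.

A multiplex panel runs many component tests (one per disease subtype, e.g.
one per pneumococcal serotype) on each subject and reports the panel
positive if *any* component is positive.  Even very small component false
positive rates compound across the panel: with 20 components at 99.75%
specificity the panel false positive rate is 1 - 0.9975**20 ~ 4.9%, so raw
panel test positivity is usually a biased over-estimate of the true
prevalence of the combined condition.

This module implements, in the order the method runs:

1.  The forward misclassification model for a single component test
    (apparent prevalence as a function of true prevalence, expected false
    positive / false negative counts, and the crossover prevalence at which
    the two balance).
2.  Panel-level operating characteristics: panel specificity is the product
    of component specificities; panel sensitivity is a prevalence-dependent
    quantity derived from component test positivities.
3.  The Rogan-Gladen misclassification correction for single tests and its
    panel-level extension, giving bias-corrected true-prevalence estimates.
4.  A cohort simulator (independent subtype carriage, independent component
    test errors) with a packaged pneumococcal-serotype-like scenario and
    PCV7/13/15/20 vaccine-group aggregation.
5.  Uncertainty propagation for unknown sensitivity/specificity: beta priors
    from control-group counts, a resampling procedure around the
    Rogan-Gladen estimators, Lang-Reiczigel-style frequentist intervals, and
    a Bayesian latent-prevalence model sampled with emcee.
6.  CSV / YAML input-output used by the command line interface.

Throughout, subtypes are assumed independent (co-carriage allowed, no
competition) and test errors independent of each other and of carriage.
Correlated errors (e.g. antigenic cross-reactivity between serotypes) are
out of scope.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger("panelprev")

__all__ = [
    # exceptions
    "PanelTestError",
    "UninformativeTestError",
    "EstimateUndefinedError",
    "InfeasibleScenarioError",
    "ConvergenceError",
    # domain types
    "ComponentProfile",
    "PanelDefinition",
    "PrevalenceVector",
    "ApparentPrevalence",
    "PanelPerformance",
    "PrevalenceEstimate",
    "ControlData",
    "BetaPrior",
    "PerformancePrior",
    "ScenarioConfig",
    "SimulatedCohort",
    # forward model
    "apparent_from_true",
    "expected_errors",
    "single_crossover_prevalence",
    # panel operating characteristics and inversion
    "panel_specificity",
    "panel_sensitivity",
    "rogan_gladen",
    "panel_prevalence_estimate",
    "expected_panel_ap",
    "panel_crossover_prevalence",
    "bias_surface",
    # simulator
    "scale_distribution",
    "default_ipd_like_weights",
    "pcv_group_definitions",
    "simulate_cohort",
    "aggregate_groups",
    "true_vs_apparent_curves",
    # uncertainty
    "resampling_interval",
    "frequentist_interval",
    "bayesian_estimate",
    # io
    "read_result_matrix",
    "read_controls",
    "read_scenario_config",
    "write_cohort",
    "write_estimates",
    "config_hash",
    # packaged scenario constants
    "IPD_LIKE_WEIGHTS",
    "PCV_GROUPS",
    "DEFAULT_SENS",
    "DEFAULT_SPEC",
    "DEFAULT_N_SUBJECTS",
    "DEFAULT_PANEL_PREV",
]

# --------------------------------------------------------------------------
# Defaults and packaged scenario constants
# --------------------------------------------------------------------------

#: Denominators smaller than this are treated as "estimator undefined"
#: rather than produce an enormous point estimate.
DENOMINATOR_TOL = 1e-12

#: Youden index (sens + spec - 1) in (0, this] triggers a conditioning
#: warning; <= 0 is a hard error in any inversion operation.
YOUDEN_WARN_TOL = 1e-9

#: Default component operating characteristics of the packaged scenario:
#: moderately sensitive (80%), highly specific (99.75%) serotype tests.
DEFAULT_SENS = 0.80
DEFAULT_SPEC = 0.9975

#: Default cohort size and overall panel prevalence of the packaged scenario.
DEFAULT_N_SUBJECTS = 4000
DEFAULT_PANEL_PREV = 0.10

#: Resampling and MCMC defaults.
DEFAULT_RESAMPLE_REPS = 1000
DEFAULT_N_WALKERS = 32
DEFAULT_N_WARMUP = 1000
DEFAULT_N_STEPS = 1000
RHAT_MAX = 1.05
ESS_MIN = 400.0

# Relative serotype frequencies emulating an invasive pneumococcal disease
# (IPD) case series: each entry is the serotype's share of ALL IPD cases, so
# the 20 PCV20 serotypes sum to ~0.70 (the remainder being non-PCV20
# disease).  SYNTHETIC stand-in, constructed so that the dominant serotype
# (8) makes up 25.6% of the total, at least one serotype (5) has no observed
# cases, and scaling to a 10% overall carriage prevalence puts the largest
# component at ~3.8% with only serotypes 3 and 8 above the 1.23% single-test
# crossover.  Only the relative shape matters to every operation here.
IPD_LIKE_WEIGHTS: dict[str, float] = {
    "8": 0.256,
    "3": 0.090,
    "19A": 0.060,
    "22F": 0.050,
    "12F": 0.040,
    "15B": 0.035,
    "10A": 0.030,
    "11A": 0.028,
    "33F": 0.025,
    "7F": 0.020,
    "1": 0.012,
    "4": 0.012,
    "14": 0.010,
    "6A": 0.010,
    "19F": 0.008,
    "23F": 0.007,
    "6B": 0.005,
    "9V": 0.003,
    "18C": 0.002,
    "5": 0.000,
}

#: Nested pneumococcal conjugate vaccine serotype groups.
PCV_GROUPS: dict[str, tuple[str, ...]] = {
    "PCV7": ("4", "6B", "9V", "14", "18C", "19F", "23F"),
    "PCV13": ("4", "6B", "9V", "14", "18C", "19F", "23F",
              "1", "3", "5", "6A", "7F", "19A"),
    "PCV15": ("4", "6B", "9V", "14", "18C", "19F", "23F",
              "1", "3", "5", "6A", "7F", "19A", "22F", "33F"),
    "PCV20": tuple(IPD_LIKE_WEIGHTS),
}


# --------------------------------------------------------------------------
# Exceptions
# --------------------------------------------------------------------------

class PanelTestError(Exception):
    """Base class for panel-test estimation errors."""


class UninformativeTestError(PanelTestError, ValueError):
    """sens + spec <= 1: the test carries no information about prevalence."""


class EstimateUndefinedError(PanelTestError, ArithmeticError):
    """An estimator's denominator vanished at these operating points."""


class InfeasibleScenarioError(PanelTestError, ValueError):
    """A simulation scenario cannot be realised (e.g. unreachable target)."""


class ConvergenceError(PanelTestError, RuntimeError):
    """MCMC failed its convergence diagnostics; details in ``diagnostics``."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class ComponentProfile:
    """Operating characteristics of one component test.

    ``sens`` is P(test+ | subtype present), ``spec`` is
    P(test- | subtype absent).  Construction only requires both to be
    probabilities; inversion operations additionally require an informative
    test (``sens + spec > 1``, positive Youden index) and enforce it via
    :meth:`require_informative`.
    """

    component_id: str
    sens: float
    spec: float

    def __post_init__(self):
        _check_prob(self.sens, "sens")
        _check_prob(self.spec, "spec")

    @property
    def youden(self) -> float:
        """Youden index ``sens + spec - 1``; the Rogan-Gladen denominator."""
        return self.sens + self.spec - 1.0

    def require_informative(self) -> None:
        if self.youden <= 0.0:
            raise UninformativeTestError(
                f"component {self.component_id!r}: sens + spec = "
                f"{self.sens + self.spec:.6g} <= 1 (uninformative test)"
            )
        if self.youden <= YOUDEN_WARN_TOL:
            warnings.warn(
                f"component {self.component_id!r}: Youden index "
                f"{self.youden:.3g} is barely positive; estimates will be "
                "ill-conditioned",
                RuntimeWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class PanelDefinition:
    """A named panel or group: an ordered set of component ids."""

    panel_id: str
    component_ids: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "component_ids", tuple(self.component_ids))
        if not self.component_ids:
            raise ValueError(f"panel {self.panel_id!r} has no components")
        if len(set(self.component_ids)) != len(self.component_ids):
            raise ValueError(f"panel {self.panel_id!r} has duplicate component ids")


@dataclass(frozen=True)
class PrevalenceVector:
    """True per-component prevalences and the implied panel prevalence.

    Under independent subtypes the panel (any-subtype) prevalence is
    ``1 - prod(1 - p_n)``.
    """

    component_ids: tuple[str, ...]
    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or len(p) != len(self.component_ids):
            raise ValueError("p must be 1-d and match component_ids")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("component prevalences must be in [0, 1]")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "component_ids", tuple(self.component_ids))

    @property
    def panel_prev(self) -> float:
        """1 - prod(1 - p_n): prevalence of carrying any subtype."""
        return float(1.0 - _prod(1.0 - self.p))

    def as_series(self) -> pd.Series:
        return pd.Series(self.p, index=list(self.component_ids), name="prevalence")


@dataclass(frozen=True)
class ApparentPrevalence:
    """Observed (or expected) test positivity for components and panel.

    ``k`` holds per-component positive counts out of ``m`` subjects;
    ``k_panel`` the count of subjects with at least one positive component.
    Counts are stored as floats so that exact *expected* counts (generally
    non-integral) flow through the same type; counts derived from a result
    matrix are integral.  Fractions are always derived, never stored.

    When ``k_panel`` is None the panel positivity is derived under
    independence as ``1 - prod(1 - AP_n)``; when a subject-level result
    matrix is available the directly counted panel positives are preferred.
    """

    component_ids: tuple[str, ...]
    k: np.ndarray
    m: int
    k_panel: float | None = None

    def __post_init__(self):
        k = np.asarray(self.k, dtype=float)
        if k.ndim != 1 or len(k) != len(self.component_ids):
            raise ValueError("k must be 1-d and match component_ids")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if np.any(k < 0) or np.any(k > self.m):
            raise ValueError("component counts must satisfy 0 <= k <= m")
        if self.k_panel is not None:
            kp = float(self.k_panel)
            if not 0 <= kp <= self.m:
                raise ValueError("panel count must satisfy 0 <= k_panel <= m")
            if kp > float(k.sum()) + 1e-9 or kp < float(k.max(initial=0.0)) - 1e-9:
                raise ValueError(
                    "panel count inconsistent with component counts: "
                    "max(k_n) <= k_panel <= sum(k_n) must hold"
                )
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "component_ids", tuple(self.component_ids))

    @property
    def ap(self) -> np.ndarray:
        """Per-component test positivity fractions k_n / m."""
        return self.k / self.m

    @property
    def ap_panel(self) -> float:
        """Panel positivity: counted directly if available, else 1-prod(1-AP_n)."""
        if self.k_panel is not None:
            return float(self.k_panel) / self.m
        return float(1.0 - _prod(1.0 - self.ap))

    @classmethod
    def from_matrix(cls, results: pd.DataFrame) -> "ApparentPrevalence":
        """Count positives from a subject x component 0/1 result matrix."""
        values = results.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("result matrix cells must be 0 or 1")
        return cls(
            component_ids=tuple(str(c) for c in results.columns),
            k=values.sum(axis=0).astype(float),
            m=len(results),
            k_panel=float(values.any(axis=1).sum()),
        )

    @classmethod
    def expected(
        cls,
        prev: PrevalenceVector,
        profiles: Sequence[ComponentProfile],
        m: int,
    ) -> "ApparentPrevalence":
        """Exact expected counts under the forward model (non-integral)."""
        sens, spec = _profile_arrays(profiles, prev.component_ids)
        ap = prev.p * sens + (1.0 - prev.p) * (1.0 - spec)
        ap_panel = 1.0 - _prod(1.0 - ap)
        return cls(prev.component_ids, ap * m, m, k_panel=ap_panel * m)

    def subset(self, component_ids: Sequence[str]) -> "ApparentPrevalence":
        """Component counts for a sub-panel; the panel count is dropped
        because any-positive counts cannot be recovered from marginals."""
        idx = [self.component_ids.index(c) for c in component_ids]
        return ApparentPrevalence(tuple(component_ids), self.k[idx], self.m)


@dataclass(frozen=True)
class PanelPerformance:
    """Derived panel operating characteristics (prevalence-dependent).

    ``spec_panel`` is the product of component specificities; ``sens_panel``
    is clamped to [0, 1] with the raw value kept in ``diagnostics``.
    """

    spec_panel: float
    sens_panel: float
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A prevalence point estimate with interval and provenance.

    ``method`` is one of ``rogan_gladen | resampling | frequentist |
    bayesian``.  Point-only estimators set ``lower == point == upper`` and
    ``level`` to None.  ``diagnostics`` carries unclamped values, denominator
    magnitudes, dropped-replicate counts, MCMC convergence metrics etc.
    """

    point: float
    lower: float
    upper: float
    level: float | None
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("point", "lower", "upper"):
            _check_prob(getattr(self, name), name)
        if not self.lower - 1e-12 <= self.point <= self.upper + 1e-12:
            raise ValueError("interval must satisfy lower <= point <= upper")


# --------------------------------------------------------------------------
# Small numeric helpers
# --------------------------------------------------------------------------

def _prod(factors: np.ndarray | Iterable[float]) -> float:
    """Product of probabilities via sum of logs when all factors are
    positive (stable for panels of dozens of components), direct product
    otherwise (a zero factor makes the answer exactly zero)."""
    arr = np.asarray(list(factors) if not isinstance(factors, np.ndarray) else factors,
                     dtype=float)
    if arr.size == 0:
        return 1.0
    if np.all(arr > 0.0):
        return float(np.exp(np.log(arr).sum()))
    return float(np.prod(arr))


def _profile_arrays(
    profiles: Sequence[ComponentProfile],
    component_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(sens, spec) arrays, aligned to ``component_ids`` when given."""
    if not profiles:
        raise ValueError("at least one component profile is required")
    if component_ids is not None:
        by_id = {p.component_id: p for p in profiles}
        missing = [c for c in component_ids if c not in by_id]
        if missing:
            raise ValueError(f"no profile for component(s) {missing}")
        profiles = [by_id[c] for c in component_ids]
    sens = np.array([p.sens for p in profiles])
    spec = np.array([p.spec for p in profiles])
    return sens, spec


def _uniform_profiles(n: int, sens: float, spec: float) -> list[ComponentProfile]:
    return [ComponentProfile(f"c{i + 1}", sens, spec) for i in range(n)]


def _as_weight_series(weights) -> pd.Series:
    if isinstance(weights, pd.Series):
        w = weights.astype(float)
    elif isinstance(weights, Mapping):
        w = pd.Series(weights, dtype=float)
    else:
        arr = np.asarray(weights, dtype=float)
        w = pd.Series(arr, index=[f"c{i + 1}" for i in range(len(arr))])
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if not (w > 0).any():
        raise ValueError("at least one weight must be positive")
    return w


# --------------------------------------------------------------------------
# Forward misclassification model (single component)
# --------------------------------------------------------------------------

def apparent_from_true(p: float, profile: ComponentProfile) -> float:
    """Expected test positivity at true prevalence ``p``.

    AP = p * sens + (1 - p) * (1 - spec).  Linear and strictly increasing in
    p for an informative test.
    """
    p = _check_prob(p, "p")
    return p * profile.sens + (1.0 - p) * (1.0 - profile.spec)


def expected_errors(
    p: float, profile: ComponentProfile, m: int
) -> tuple[float, float]:
    """Expected (false positive, false negative) counts among ``m`` tests.

    E[FP] = m (1-p)(1-spec);  E[FN] = m p (1-sens).  At low prevalence the
    false positives dominate; the two balance exactly at the crossover
    prevalence of :func:`single_crossover_prevalence`.
    """
    p = _check_prob(p, "p")
    if m < 1:
        raise ValueError("m must be >= 1")
    e_fp = m * (1.0 - p) * (1.0 - profile.spec)
    e_fn = m * p * (1.0 - profile.sens)
    return e_fp, e_fn


def single_crossover_prevalence(profile: ComponentProfile) -> float:
    """Prevalence p* at which expected positivity equals true prevalence.

    Solves AP(p) = p, giving p* = (1-spec) / ((1-spec) + (1-sens)).  Below
    p* test positivity over-estimates prevalence (false positives dominate);
    above it, under-estimates.  A perfect test (sens = spec = 1) has AP == p
    everywhere and no crossover.
    """
    profile.require_informative()
    fp_rate = 1.0 - profile.spec
    fn_rate = 1.0 - profile.sens
    if fp_rate == 0.0 and fn_rate == 0.0:
        raise EstimateUndefinedError(
            "no crossover: a perfect test has apparent prevalence equal to "
            "true prevalence at every prevalence"
        )
    if fp_rate + fn_rate == 0.0:  # pragma: no cover - caught above
        raise EstimateUndefinedError("degenerate operating point")
    return fp_rate / (fp_rate + fn_rate)


# --------------------------------------------------------------------------
# Panel operating characteristics and bias-corrected estimators
# --------------------------------------------------------------------------

def panel_specificity(profiles: Sequence[ComponentProfile]) -> float:
    """Panel specificity: the product of component specificities.

    A true-negative panel result requires every component to be a true
    negative, so spec_panel = prod(spec_n) <= min(spec_n): adding components
    can only erode specificity.
    """
    if not profiles:
        raise ValueError("panel_specificity requires at least one component")
    return _prod(np.array([p.spec for p in profiles]))


def _rg_complement_factors(
    ap: np.ndarray, sens: np.ndarray, spec: np.ndarray
) -> tuple[np.ndarray, int]:
    """Per-component Rogan-Gladen estimates of (1 - prev_n).

    q_n = (sens_n - AP_n) / (sens_n + spec_n - 1), clamped into [0, 1].
    AP_n outside [1 - spec_n, sens_n] is sampling noise; each clamp is
    counted and logged.
    """
    q = (sens - ap) / (sens + spec - 1.0)
    n_clamped = int(np.count_nonzero((q < 0.0) | (q > 1.0)))
    if n_clamped:
        logger.info(
            "clamped %d component (1-prev) estimate(s) into [0, 1]; "
            "observed positivity outside the test's operating range "
            "(sampling noise)", n_clamped,
        )
    return np.clip(q, 0.0, 1.0), n_clamped


def panel_sensitivity(
    ap: ApparentPrevalence, profiles: Sequence[ComponentProfile]
) -> PanelPerformance:
    """Panel sensitivity and specificity from component positivities.

    sens_panel = 1 - [prod(1 - AP_n) - prod(spec_n) * prod(q_n)]
                     / (1 - prod(q_n)),
    where q_n is the component-level Rogan-Gladen estimate of (1 - prev_n).
    Unlike a single test's sensitivity, this depends on prevalence: false
    negatives in one component can be masked by (true or false) positives in
    another, so panels become more sensitive as prevalence rises.

    Raises :class:`EstimateUndefinedError` when the estimated panel
    prevalence is zero (prod(q_n) >= 1), where sensitivity has no meaning.
    """
    for profile in profiles:
        profile.require_informative()
    sens, spec = _profile_arrays(profiles, ap.component_ids)
    q, n_clamped = _rg_complement_factors(ap.ap, sens, spec)
    q_prod = _prod(q)
    spec_panel = _prod(spec)
    if q_prod >= 1.0 - DENOMINATOR_TOL:
        raise EstimateUndefinedError(
            "panel sensitivity undefined at zero estimated prevalence "
            "(every component positivity is at or below its false positive "
            "rate)"
        )
    sens_raw = 1.0 - (_prod(1.0 - ap.ap) - spec_panel * q_prod) / (1.0 - q_prod)
    return PanelPerformance(
        spec_panel=spec_panel,
        sens_panel=float(np.clip(sens_raw, 0.0, 1.0)),
        diagnostics={
            "sens_panel_unclamped": float(sens_raw),
            "q_prod": float(q_prod),
            "n_q_clamped": n_clamped,
            "estimated_panel_prev": float(1.0 - q_prod),
        },
    )


def rogan_gladen(ap: float, profile: ComponentProfile) -> PrevalenceEstimate:
    """Rogan-Gladen misclassification-corrected prevalence for one test.

    prev = (AP + spec - 1) / (sens + spec - 1), the exact inverse of
    :func:`apparent_from_true` on its range.  The point estimate is clamped
    to [0, 1]; the unclamped value is kept in ``diagnostics`` (sampling noise
    routinely pushes AP below the test's false positive rate).
    """
    ap = _check_prob(ap, "ap")
    profile.require_informative()
    raw = (ap + profile.spec - 1.0) / profile.youden
    point = float(np.clip(raw, 0.0, 1.0))
    return PrevalenceEstimate(
        point=point, lower=point, upper=point, level=None,
        method="rogan_gladen",
        diagnostics={"unclamped": float(raw), "denominator": profile.youden},
    )


def panel_prevalence_estimate(
    ap: ApparentPrevalence, profiles: Sequence[ComponentProfile]
) -> PrevalenceEstimate:
    """Bias-corrected true prevalence of the combined panel.

    prev_panel = [prod(spec_n) - (1 - AP_panel)] * (1 - prod(q_n))
                 / [prod(spec_n) - prod(1 - AP_n)],

    which is Rogan-Gladen applied at panel level with the panel sensitivity
    and specificity of :func:`panel_sensitivity`.  On exact expected
    positivities this recovers the true panel prevalence identically
    (q_n = 1 - p_n).  For a single component it reduces to
    :func:`rogan_gladen`.
    """
    for profile in profiles:
        profile.require_informative()
    sens, spec = _profile_arrays(profiles, ap.component_ids)
    q, n_clamped = _rg_complement_factors(ap.ap, sens, spec)
    q_prod = _prod(q)
    spec_panel = _prod(spec)
    ap_panel = ap.ap_panel
    diagnostics: dict = {
        "q_prod": float(q_prod),
        "n_q_clamped": n_clamped,
        "ap_panel": float(ap_panel),
        "spec_panel": float(spec_panel),
        "panel_count_observed": ap.k_panel is not None,
    }
    if q_prod >= 1.0 - DENOMINATOR_TOL:
        # Every component at or below its false positive rate: the
        # zero-prevalence fixed point of the estimator.
        diagnostics["zero_prevalence_limit"] = True
        return PrevalenceEstimate(0.0, 0.0, 0.0, None, "rogan_gladen", diagnostics)
    denominator = spec_panel - _prod(1.0 - ap.ap)
    diagnostics["denominator"] = float(denominator)
    if abs(denominator) < DENOMINATOR_TOL:
        raise EstimateUndefinedError(
            "estimate undefined: panel test uninformative at these operating "
            f"points (denominator {denominator:.3g})"
        )
    raw = (spec_panel - (1.0 - ap_panel)) * (1.0 - q_prod) / denominator
    diagnostics["unclamped"] = float(raw)
    point = float(np.clip(raw, 0.0, 1.0))
    return PrevalenceEstimate(point, point, point, None, "rogan_gladen", diagnostics)


def expected_panel_ap(
    prev: PrevalenceVector, profiles: Sequence[ComponentProfile]
) -> float:
    """Expected panel positivity 1 - prod(1 - AP_n) under independence."""
    sens, spec = _profile_arrays(profiles, prev.component_ids)
    ap = prev.p * sens + (1.0 - prev.p) * (1.0 - spec)
    return float(1.0 - _prod(1.0 - ap))


def panel_crossover_prevalence(
    weights, profiles: Sequence[ComponentProfile]
) -> float:
    """Panel prevalence at which expected panel positivity equals truth.

    Component prevalences are scaled as p_n = s * w_n; the scale s is swept
    by bisection until expected panel positivity and true panel prevalence
    agree to |difference| < 1e-10.  Below the returned prevalence the panel
    positivity over-estimates truth, above it under-estimates.
    """
    w = _as_weight_series(weights)
    for profile in profiles:
        profile.require_informative()
    sens, spec = _profile_arrays(profiles, list(w.index))
    wv = w.to_numpy()

    def bias(s: float) -> tuple[float, float]:
        p = s * wv
        ap = p * sens + (1.0 - p) * (1.0 - spec)
        prev_panel = 1.0 - _prod(1.0 - p)
        return (1.0 - _prod(1.0 - ap)) - prev_panel, prev_panel

    # Locate a sign change on a scan grid first: near the feasibility edge
    # both curves approach 1 and their difference underflows, so endpoint
    # signs alone cannot distinguish "no crossover" from a tiny residual.
    s_max = 0.999 / wv.max()
    grid = np.linspace(s_max / 512, s_max, 512)
    f_grid = np.array([bias(s)[0] for s in grid])
    sign0 = np.sign(f_grid[0])
    if sign0 == 0:
        return bias(grid[0])[1]
    flipped = np.nonzero(np.sign(f_grid) == -sign0)[0]
    if flipped.size == 0:
        raise EstimateUndefinedError(
            "no crossover in range: expected panel positivity is "
            f"{'above' if f_grid[0] > 0 else 'below'} true prevalence "
            "throughout"
        )
    idx = int(flipped[0])
    lo, hi = (grid[idx - 1] if idx else 0.0), grid[idx]
    f_lo = bias(lo)[0] if idx else sign0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid, prev_mid = bias(mid)
        if abs(f_mid) < 1e-10:
            return prev_mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return bias(0.5 * (lo + hi))[1]  # pragma: no cover - bisection converges


def bias_surface(
    weights,
    prev_target: float,
    sens_grid: Sequence[float],
    spec_grid: Sequence[float],
) -> pd.DataFrame:
    """Ratio of expected panel positivity to true prevalence over a
    sensitivity x specificity grid (uniform operating point across
    components).

    Rows are indexed by sensitivity, columns by specificity.  Cells > 1 mean
    positivity over-estimates prevalence (excess false positives), < 1
    under-estimates (excess false negatives); a perfect test gives exactly 1.
    """
    if not 0.0 < prev_target < 1.0:
        raise ValueError("prev_target must be in (0, 1)")
    w = _as_weight_series(weights)
    prev = scale_distribution(w, prev_target)
    sens_grid = np.asarray(sens_grid, dtype=float)
    spec_grid = np.asarray(spec_grid, dtype=float)
    if np.any(sens_grid <= 0) or np.any(sens_grid > 1):
        raise ValueError("sens_grid values must be in (0, 1]")
    if np.any(spec_grid <= 0) or np.any(spec_grid > 1):
        raise ValueError("spec_grid values must be in (0, 1]")
    p = prev.p[None, None, :]
    ap = p * sens_grid[:, None, None] + (1.0 - p) * (1.0 - spec_grid[None, :, None])
    ratio = (1.0 - np.prod(1.0 - ap, axis=2)) / prev_target
    return pd.DataFrame(ratio, index=pd.Index(sens_grid, name="sens"),
                        columns=pd.Index(spec_grid, name="spec"))


# --------------------------------------------------------------------------
# Simulator: scenario construction and cohort generation
# --------------------------------------------------------------------------

def scale_distribution(weights, target_panel_prev: float) -> PrevalenceVector:
    """Scale relative subtype frequencies to a target panel prevalence.

    Finds s such that 1 - prod(1 - s * w_n) = target (bisection to 1e-12)
    and returns p_n = s * w_n.  Only the relative shape of ``weights``
    matters.  Any target in [0, 1) is reachable because the dominant
    component's prevalence approaches 1 as s grows.
    """
    w = _as_weight_series(weights)
    target = _check_prob(target_panel_prev, "target_panel_prev")
    wv = w.to_numpy()
    ids = tuple(str(i) for i in w.index)
    if target == 0.0:
        return PrevalenceVector(ids, np.zeros_like(wv))
    if target >= 1.0:
        raise InfeasibleScenarioError(
            "target panel prevalence must be < 1 (maximum achievable "
            "approaches 1 only in the limit)"
        )

    def panel_prev(s: float) -> float:
        return 1.0 - _prod(1.0 - s * wv)

    lo, hi = 0.0, (1.0 - 1e-12) / wv.max()
    if panel_prev(hi) < target:
        raise InfeasibleScenarioError(
            f"target panel prevalence {target:.4g} unreachable; maximum "
            f"achievable with these weights is {panel_prev(hi):.4g}"
        )
    for _ in range(200):
        s = 0.5 * (lo + hi)
        if abs(panel_prev(s) - target) < 1e-12:
            break
        if panel_prev(s) < target:
            lo = s
        else:
            hi = s
    return PrevalenceVector(ids, s * wv)


def default_ipd_like_weights() -> pd.Series:
    """Packaged serotype frequency distribution (synthetic IPD-like).

    Shares of a hypothetical IPD case series for the 20 PCV20 serotypes
    (they sum to ~0.70 of all cases; the rest are non-PCV20 serotypes, which
    is irrelevant to scaling).  Dominant serotype 8 at 25.6% of the total,
    serotype 5 with no observed cases, long-tailed in between.  Scaled to a
    10% overall carriage prevalence the largest component sits at ~3.8%.
    """
    return pd.Series(IPD_LIKE_WEIGHTS, dtype=float)


def pcv_group_definitions() -> list[PanelDefinition]:
    """Nested PCV7 / PCV13 / PCV15 / PCV20 vaccine serotype groups."""
    return [PanelDefinition(name, ids) for name, ids in PCV_GROUPS.items()]


@dataclass(frozen=True)
class ScenarioConfig:
    """A simulation scenario: who is tested, with what, and how often
    each subtype occurs.

    ``weights`` are relative subtype frequencies scaled so the panel
    (any-subtype) prevalence equals ``target_panel_prev``; carriage is
    independent Bernoulli per subject per component (co-carriage allowed),
    and each component test errs independently with the profile's
    sensitivity/specificity.
    """

    seed: int
    n_subjects: int = DEFAULT_N_SUBJECTS
    weights: pd.Series = field(default_factory=default_ipd_like_weights)
    target_panel_prev: float = DEFAULT_PANEL_PREV
    profiles: tuple[ComponentProfile, ...] = ()
    groups: tuple[PanelDefinition, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "weights", _as_weight_series(self.weights))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        _check_prob(self.target_panel_prev, "target_panel_prev")
        if not self.profiles:
            object.__setattr__(
                self,
                "profiles",
                tuple(
                    ComponentProfile(str(c), DEFAULT_SENS, DEFAULT_SPEC)
                    for c in self.weights.index
                ),
            )
        profile_ids = {p.component_id for p in self.profiles}
        if profile_ids != set(map(str, self.weights.index)):
            raise ValueError("profiles must cover exactly the weighted components")
        if not self.groups and profile_ids == set(IPD_LIKE_WEIGHTS):
            object.__setattr__(self, "groups", tuple(pcv_group_definitions()))
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def prevalence(self) -> PrevalenceVector:
        return scale_distribution(self.weights, self.target_panel_prev)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "weights": {str(k): float(v) for k, v in self.weights.items()},
            "target_panel_prev": self.target_panel_prev,
            "profiles": {
                p.component_id: {"sens": p.sens, "spec": p.spec}
                for p in self.profiles
            },
            "groups": {g.panel_id: list(g.component_ids) for g in self.groups},
        }


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated cohort: latent carriage, observed results, provenance.

    ``truth`` and ``results`` are subject x component 0/1 DataFrames sharing
    index and columns; ``confusion`` tabulates TP/FP/TN/FN per component.
    """

    truth: pd.DataFrame
    results: pd.DataFrame
    confusion: pd.DataFrame
    config: ScenarioConfig

    def apparent_prevalence(self) -> ApparentPrevalence:
        return ApparentPrevalence.from_matrix(self.results)

    def true_prevalence(self) -> pd.Series:
        return self.truth.mean(axis=0)

    @property
    def panel_truth_prev(self) -> float:
        return float(self.truth.to_numpy().any(axis=1).mean())

    @property
    def panel_positivity(self) -> float:
        return float(self.results.to_numpy().any(axis=1).mean())


def simulate_cohort(config: ScenarioConfig) -> SimulatedCohort:
    """Simulate subject-level carriage and multiplex test results.

    Carriage: independent Bernoulli(p_n) per subject per component.
    Testing: Bernoulli(sens_n) given carriage, Bernoulli(1 - spec_n) given
    no carriage, independent across components and subjects.

    Two child RNG streams are derived from the root seed - one for carriage,
    one for test error - so sensitivity analyses can redraw errors while
    holding carriage fixed.  Identical config + seed reproduce the cohort
    bit-for-bit (NumPy PCG64 via ``default_rng``).
    """
    prev = config.prevalence
    sens, spec = _profile_arrays(config.profiles, prev.component_ids)
    n, k = config.n_subjects, len(prev.component_ids)
    carriage_seed, error_seed = np.random.SeedSequence(config.seed).spawn(2)
    carriage_rng = np.random.default_rng(carriage_seed)
    error_rng = np.random.default_rng(error_seed)

    truth = carriage_rng.random((n, k)) < prev.p
    u = error_rng.random((n, k))
    results = np.where(truth, u < sens, u < (1.0 - spec))

    index = pd.RangeIndex(n, name="subject")
    cols = list(prev.component_ids)
    truth_df = pd.DataFrame(truth.astype(np.int8), index=index, columns=cols)
    results_df = pd.DataFrame(results.astype(np.int8), index=index, columns=cols)
    confusion = pd.DataFrame(
        {
            "TP": (truth & results).sum(axis=0),
            "FP": (~truth & results).sum(axis=0),
            "FN": (truth & ~results).sum(axis=0),
            "TN": (~truth & ~results).sum(axis=0),
        },
        index=pd.Index(cols, name="component_id"),
    )
    return SimulatedCohort(truth_df, results_df, confusion, config)


def aggregate_groups(
    cohort: SimulatedCohort, groups: Sequence[PanelDefinition]
) -> pd.DataFrame:
    """Any-positive truth prevalence and test positivity per group.

    Nested groups (PCV7 < PCV13 < PCV15 < PCV20) necessarily have
    non-decreasing prevalence and positivity.
    """
    known = set(cohort.results.columns)
    rows = []
    for group in groups:
        unknown = [c for c in group.component_ids if c not in known]
        if unknown:
            raise ValueError(
                f"group {group.panel_id!r} references unknown component(s) "
                f"{unknown}"
            )
        cols = list(group.component_ids)
        rows.append(
            {
                "group": group.panel_id,
                "n_components": len(cols),
                "true_prev": float(cohort.truth[cols].to_numpy().any(axis=1).mean()),
                "positivity": float(
                    cohort.results[cols].to_numpy().any(axis=1).mean()
                ),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def true_vs_apparent_curves(
    weights,
    profiles: Sequence[ComponentProfile],
    prev_grid: Sequence[float],
) -> dict[str, pd.DataFrame]:
    """Analytic true-vs-apparent prevalence curves.

    For each target panel prevalence in ``prev_grid`` the weights are scaled
    to that prevalence; the component curves (linear in p_n) and the panel
    curve (non-linear: false positives compound while false negatives are
    masked) are returned as DataFrames.  The panel curve crosses the
    identity at :func:`panel_crossover_prevalence`.
    """
    w = _as_weight_series(weights)
    sens, spec = _profile_arrays(profiles, list(w.index))
    panel_rows, comp_rows = [], []
    for target in prev_grid:
        prev = scale_distribution(w, float(target))
        ap = prev.p * sens + (1.0 - prev.p) * (1.0 - spec)
        panel_rows.append(
            {
                "true_prev": prev.panel_prev,
                "apparent_prev": float(1.0 - _prod(1.0 - ap)),
            }
        )
        for cid, p_n, ap_n in zip(prev.component_ids, prev.p, ap):
            comp_rows.append(
                {"component_id": cid, "true_prev": float(p_n),
                 "apparent_prev": float(ap_n)}
            )
    return {
        "panel": pd.DataFrame(panel_rows),
        "components": pd.DataFrame(comp_rows),
    }


# --------------------------------------------------------------------------
# Uncertainty propagation: priors, resampling, frequentist, Bayesian
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ControlData:
    """Control-group counts informing test performance.

    Per component: disease-free (negative) controls inform specificity
    (``n_neg`` tested, ``k_neg`` correctly negative); disease-positive
    controls inform sensitivity (``n_pos`` tested, ``k_pos`` correctly
    positive).  Any side may be missing (NaN) for any component.
    """

    counts: pd.DataFrame  # index component_id; columns n_pos,k_pos,n_neg,k_neg

    COLUMNS = ("n_pos", "k_pos", "n_neg", "k_neg")

    def __post_init__(self):
        df = self.counts.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[list(self.COLUMNS)].astype(float)
        for side in ("pos", "neg"):
            n, k = df[f"n_{side}"], df[f"k_{side}"]
            bad = k > n
            if bad.any():
                raise ValueError(
                    f"n_correct exceeds n_tested for {side} controls of "
                    f"{list(df.index[bad])}"
                )
        object.__setattr__(self, "counts", df)

    @classmethod
    def empty(cls) -> "ControlData":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS),
                                index=pd.Index([], name="component_id")))

    def has(self, component_id: str, side: str) -> bool:
        if component_id not in self.counts.index:
            return False
        row = self.counts.loc[component_id]
        return bool(np.isfinite(row[f"n_{side}"]) and np.isfinite(row[f"k_{side}"]))


@dataclass(frozen=True)
class BetaPrior:
    """A beta prior Beta(a, b), or a point mass when ``point`` is set."""

    a: float | None = None
    b: float | None = None
    point: float | None = None

    def __post_init__(self):
        if self.point is not None:
            if self.a is not None or self.b is not None:
                raise ValueError("give either (a, b) shapes or a point, not both")
            _check_prob(self.point, "point")
        else:
            if self.a is None or self.b is None or self.a <= 0 or self.b <= 0:
                raise ValueError("beta shape parameters must be positive")

    @property
    def is_degenerate(self) -> bool:
        return self.point is not None

    @property
    def mean(self) -> float:
        if self.is_degenerate:
            return float(self.point)
        return self.a / (self.a + self.b)

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.is_degenerate:
            return np.full(size, self.point)
        return rng.beta(self.a, self.b, size)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        if self.is_degenerate:
            raise ValueError("point-mass prior has no density")
        return stats.beta.logpdf(x, self.a, self.b)


@dataclass(frozen=True)
class PerformancePrior:
    """Per-component beta priors on sensitivity and specificity.

    ``provenance`` records how the prior was built: ``from_controls``
    (posterior of control counts under a Beta(a0, b0) base prior), ``user``
    (explicit shapes) or ``fixed`` (point masses at assumed values; valid
    for resampling, rejected by the Bayesian sampler which needs proper
    densities).
    """

    sens: Mapping[str, BetaPrior]
    spec: Mapping[str, BetaPrior]
    provenance: str = "user"

    def component_ids(self) -> set[str]:
        return set(self.sens) & set(self.spec)

    def require_components(self, ids: Sequence[str]) -> None:
        missing = [c for c in ids if c not in self.sens or c not in self.spec]
        if missing:
            raise ValueError(f"no performance prior for component(s) {missing}")

    def sample_matrices(
        self, ids: Sequence[str], rng: np.random.Generator, reps: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """(reps, n_components) draws of sensitivity and specificity."""
        sens = np.column_stack([self.sens[c].sample(rng, reps) for c in ids])
        spec = np.column_stack([self.spec[c].sample(rng, reps) for c in ids])
        return sens, spec

    @classmethod
    def from_controls(
        cls, controls: ControlData, component_ids: Sequence[str],
        a0: float = 1.0, b0: float = 1.0,
    ) -> "PerformancePrior":
        """Beta posteriors of the control counts under a Beta(a0, b0) prior:
        sens ~ Beta(k_pos + a0, n_pos - k_pos + b0) and likewise for spec
        from negative controls.  Every requested component must have both
        control types."""
        sens, spec = {}, {}
        for cid in component_ids:
            for side, store in (("pos", sens), ("neg", spec)):
                if not controls.has(cid, side):
                    raise ValueError(
                        f"component {cid!r} lacks {side} control data; "
                        "provide controls or an explicit prior"
                    )
                row = controls.counts.loc[cid]
                n, k = row[f"n_{side}"], row[f"k_{side}"]
                store[cid] = BetaPrior(a=k + a0, b=n - k + b0)
        return cls(sens, spec, provenance="from_controls")

    @classmethod
    def fixed(
        cls, profiles: Sequence[ComponentProfile]
    ) -> "PerformancePrior":
        """Point-mass priors at assumed sensitivity/specificity values."""
        return cls(
            sens={p.component_id: BetaPrior(point=p.sens) for p in profiles},
            spec={p.component_id: BetaPrior(point=p.spec) for p in profiles},
            provenance="fixed",
        )

    @classmethod
    def from_mean_ess(
        cls, means: Mapping[str, tuple[float, float]], ess: float
    ) -> "PerformancePrior":
        """Beta priors with given (sens, spec) means and a common prior
        'effective sample size' a + b = ess."""
        sens, spec = {}, {}
        for cid, (s_mean, p_mean) in means.items():
            sens[cid] = BetaPrior(a=s_mean * ess, b=(1 - s_mean) * ess)
            spec[cid] = BetaPrior(a=p_mean * ess, b=(1 - p_mean) * ess)
        return cls(sens, spec, provenance="user")


def _estimate_bundle(
    component_ids: Sequence[str],
    comp_estimates: Mapping[str, PrevalenceEstimate],
    panel_estimate: PrevalenceEstimate,
) -> dict:
    return {"components": dict(comp_estimates), "panel": panel_estimate}


def _quantile_estimate(
    draws: np.ndarray, level: float, method: str, diagnostics: dict
) -> PrevalenceEstimate:
    alpha = (1.0 - level) / 2.0
    lower, point, upper = np.quantile(draws, [alpha, 0.5, 1.0 - alpha])
    return PrevalenceEstimate(
        point=float(np.clip(point, 0, 1)),
        lower=float(np.clip(lower, 0, 1)),
        upper=float(np.clip(upper, 0, 1)),
        level=level, method=method, diagnostics=diagnostics,
    )


def resampling_interval(
    ap: ApparentPrevalence,
    priors: PerformancePrior,
    reps: int = DEFAULT_RESAMPLE_REPS,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
) -> dict:
    """Resampling + Rogan-Gladen uncertainty propagation.

    Each replicate draws component sensitivities/specificities from their
    priors and positive counts from a binomial resample of the observed
    counts, then applies the Rogan-Gladen correction per component and the
    panel estimator for the combined panel.  Points are replicate medians;
    intervals central quantiles at ``level``.  Replicates where the panel
    estimator is undefined (vanishing denominator or non-positive Youden
    index) are dropped and counted in diagnostics; more than 50% undefined
    raises :class:`EstimateUndefinedError` (the panel is underpowered at
    these operating points).

    Returns ``{"components": {id: PrevalenceEstimate}, "panel":
    PrevalenceEstimate}``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    ids = list(ap.component_ids)
    priors.require_components(ids)
    rng = np.random.default_rng(seed)
    sens, spec = priors.sample_matrices(ids, rng, reps)  # (reps, K)
    k_star = rng.binomial(ap.m, ap.ap[None, :].repeat(reps, axis=0))
    ap_star = k_star / ap.m
    kp = ap.ap_panel
    ap_panel_star = rng.binomial(ap.m, kp, size=reps) / ap.m

    youden = sens + spec - 1.0
    informative = youden > 0.0

    # Component-level Rogan-Gladen per replicate (undefined draws dropped).
    with np.errstate(divide="ignore", invalid="ignore"):
        comp_raw = (ap_star + spec - 1.0) / youden
    comp_est = np.clip(comp_raw, 0.0, 1.0)
    comp_estimates = {}
    for j, cid in enumerate(ids):
        keep = informative[:, j]
        if keep.sum() < reps / 2:
            raise EstimateUndefinedError(
                f"component {cid!r}: prior mass on uninformative tests "
                "exceeds 50% of replicates"
            )
        comp_estimates[cid] = _quantile_estimate(
            comp_est[keep, j], level, "resampling",
            {"n_dropped": int(reps - keep.sum()), "reps": reps},
        )

    # Panel estimator per replicate.
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.clip((sens - ap_star) / youden, 0.0, 1.0)
    q_prod = np.prod(q, axis=1)
    spec_panel = np.prod(spec, axis=1)
    denominator = spec_panel - np.prod(1.0 - ap_star, axis=1)
    all_informative = informative.all(axis=1)
    zero_prev = q_prod >= 1.0 - DENOMINATOR_TOL
    defined = all_informative & (zero_prev | (np.abs(denominator) >= DENOMINATOR_TOL))
    with np.errstate(divide="ignore", invalid="ignore"):
        panel_raw = (spec_panel - (1.0 - ap_panel_star)) * (1.0 - q_prod) / denominator
    panel_raw = np.where(zero_prev, 0.0, panel_raw)
    panel_draws = np.clip(panel_raw[defined], 0.0, 1.0)
    n_dropped = int(reps - defined.sum())
    if n_dropped > reps / 2:
        raise EstimateUndefinedError(
            "panel test underpowered at these operating points: "
            f"{n_dropped}/{reps} resampling replicates undefined"
        )
    panel_estimate = _quantile_estimate(
        panel_draws, level, "resampling",
        {"n_dropped": n_dropped, "reps": reps,
         "n_zero_prevalence": int(zero_prev.sum())},
    )
    return _estimate_bundle(ids, comp_estimates, panel_estimate)


def _adjusted_positivity(k: float, n: float) -> tuple[float, float]:
    """Lang-Reiczigel "+2 successes, +4 trials" adjusted proportion and its
    variance, pulling boundary counts off 0 and 1."""
    n_adj = n + 4.0
    p_adj = (k + 2.0) / n_adj
    return p_adj, p_adj * (1.0 - p_adj) / n_adj


def _control_moments(row: pd.Series) -> tuple[float, float, float, float]:
    """(se, se_var, sp, sp_var): raw control proportions with their binomial
    variances (zero when the control group was error-free)."""
    se = row["k_pos"] / row["n_pos"]
    sp = row["k_neg"] / row["n_neg"]
    return (se, se * (1 - se) / row["n_pos"], sp, sp * (1 - sp) / row["n_neg"])


def _lang_reiczigel_single(
    k: float, m: int, controls_row: pd.Series, level: float
) -> PrevalenceEstimate:
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    se_hat, se_var, sp_hat, sp_var = _control_moments(controls_row)
    youden = se_hat + sp_hat - 1.0
    if youden <= 0:
        raise UninformativeTestError(
            "estimated sens + spec <= 1 from control data (uninformative test)"
        )
    ap_adj, ap_var = _adjusted_positivity(k, m)
    prev_raw = (ap_adj + sp_hat - 1.0) / youden
    prev_trunc = float(np.clip(prev_raw, 0.0, 1.0))
    var = (ap_var + se_var * prev_trunc**2 + sp_var * (1.0 - prev_trunc) ** 2) / youden**2
    half = z * math.sqrt(max(var, 0.0))
    return PrevalenceEstimate(
        point=prev_trunc,
        lower=float(np.clip(prev_trunc - half, 0.0, 1.0)),
        upper=float(np.clip(prev_trunc + half, 0.0, 1.0)),
        level=level, method="frequentist",
        diagnostics={
            "unclamped": float(prev_raw), "variance": float(var),
            "sens_hat": float(se_hat), "spec_hat": float(sp_hat),
        },
    )


def frequentist_interval(
    ap: ApparentPrevalence,
    controls: ControlData,
    level: float = 0.95,
) -> dict:
    """Adjusted frequentist prevalence intervals from control-group counts.

    Single tests use the Lang-Reiczigel construction: Agresti-Coull-adjusted
    positivity and control proportions, Rogan-Gladen point estimate
    truncated to [0, 1], and a Wald interval whose variance combines the
    binomial variance of positivity with the control-group variances of
    sensitivity and specificity, scaled by the squared Youden index.

    The panel estimate applies the same correction at panel level using the
    panel operating characteristics (product specificity, Eq-1 sensitivity);
    its variance adds, by the delta method, the panel-positivity binomial
    term, the log-product-propagated specificity variance, and a numerical
    gradient of panel sensitivity with respect to each component's estimated
    sensitivity and specificity.

    Requires both control types for every component; otherwise directs the
    caller to :func:`resampling_interval` with explicit priors.
    """
    ids = list(ap.component_ids)
    for cid in ids:
        if not (controls.has(cid, "pos") and controls.has(cid, "neg")):
            raise ValueError(
                f"component {cid!r} lacks control data; use "
                "resampling_interval with explicit priors instead"
            )
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    comp_estimates = {
        cid: _lang_reiczigel_single(ap.k[j], ap.m, controls.counts.loc[cid], level)
        for j, cid in enumerate(ids)
    }
    if len(ids) == 1:
        only = comp_estimates[ids[0]]
        return _estimate_bundle(ids, comp_estimates, replace(only))

    # Panel: point estimate from the raw (unshrunken) operating
    # characteristics and component positivities; Agresti-Coull shrinkage of
    # 20 near-boundary specificities would compound into a material bias at
    # panel level, so adjusted values enter only through the variances and
    # the panel positivity.
    se = np.empty(len(ids))
    sp = np.empty(len(ids))
    se_var = np.empty(len(ids))
    sp_var = np.empty(len(ids))
    for j, cid in enumerate(ids):
        se[j], se_var[j], sp[j], sp_var[j] = _control_moments(
            controls.counts.loc[cid]
        )
    if np.any(se + sp <= 1.0):
        raise UninformativeTestError(
            "estimated sens + spec <= 1 for at least one component"
        )
    ap_adj = ap.ap.copy()
    ap_var = np.array([_adjusted_positivity(kj, ap.m)[1] for kj in ap.k])
    ap_panel_adj, ap_panel_var = _adjusted_positivity(
        ap.ap_panel * ap.m if ap.k_panel is None else ap.k_panel, ap.m
    )

    def panel_point(se_v, sp_v, ap_v, ap_panel_v) -> float:
        q = np.clip((se_v - ap_v) / (se_v + sp_v - 1.0), 0.0, 1.0)
        q_prod = float(np.prod(q))
        spec_panel = float(np.prod(sp_v))
        denominator = spec_panel - float(np.prod(1.0 - ap_v))
        if q_prod >= 1.0 - DENOMINATOR_TOL:
            return 0.0
        if abs(denominator) < DENOMINATOR_TOL:
            raise EstimateUndefinedError(
                "panel estimator undefined at the control-estimated "
                "operating points"
            )
        return (spec_panel - (1.0 - ap_panel_v)) * (1.0 - q_prod) / denominator

    prev_raw = panel_point(se, sp, ap_adj, ap_panel_adj)
    prev_trunc = float(np.clip(prev_raw, 0.0, 1.0))

    # Delta-method variance: numerical gradient wrt every uncertain input.
    variance = 0.0
    grad_h = 1e-6
    g = (panel_point(se, sp, ap_adj, ap_panel_adj + grad_h)
         - panel_point(se, sp, ap_adj, ap_panel_adj - grad_h)) / (2 * grad_h)
    variance += g * g * ap_panel_var
    for j in range(len(ids)):
        for vec, var_vec in ((se, se_var), (sp, sp_var), (ap_adj, ap_var)):
            bumped_hi, bumped_lo = vec.copy(), vec.copy()
            bumped_hi[j] += grad_h
            bumped_lo[j] -= grad_h
            if vec is se:
                g = (panel_point(bumped_hi, sp, ap_adj, ap_panel_adj)
                     - panel_point(bumped_lo, sp, ap_adj, ap_panel_adj)) / (2 * grad_h)
            elif vec is sp:
                g = (panel_point(se, bumped_hi, ap_adj, ap_panel_adj)
                     - panel_point(se, bumped_lo, ap_adj, ap_panel_adj)) / (2 * grad_h)
            else:
                g = (panel_point(se, sp, bumped_hi, ap_panel_adj)
                     - panel_point(se, sp, bumped_lo, ap_panel_adj)) / (2 * grad_h)
            variance += g * g * var_vec[j]
    half = z * math.sqrt(max(variance, 0.0))
    panel_estimate = PrevalenceEstimate(
        point=prev_trunc,
        lower=float(np.clip(prev_trunc - half, 0.0, 1.0)),
        upper=float(np.clip(prev_trunc + half, 0.0, 1.0)),
        level=level, method="frequentist",
        diagnostics={"unclamped": float(prev_raw), "variance": float(variance)},
    )
    return _estimate_bundle(ids, comp_estimates, panel_estimate)


def _component_posterior(
    k: float,
    m: int,
    sens_prior: BetaPrior,
    spec_prior: BetaPrior,
    *,
    n_walkers: int,
    n_warmup: int,
    n_steps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Sample the 3-parameter component model (prev, sens, spec) with emcee.

    Uniform prior on prevalence; beta priors on sensitivity and specificity;
    likelihood k ~ Binomial(m, prev*sens + (1-prev)(1-spec)).  Returns
    posterior prevalence draws of shape (n_walkers, n_steps) plus
    convergence diagnostics (walkers treated as chains for split-Rhat/ESS).
    """
    import emcee

    if sens_prior.is_degenerate or spec_prior.is_degenerate:
        raise ValueError(
            "Bayesian estimation needs proper (non-degenerate) beta priors "
            "on sensitivity and specificity"
        )

    # Sampling runs on the logit scale: prevalence posteriors sit close to
    # zero for rare subtypes and the (prev, spec) ridge is easier for the
    # ensemble to traverse unbounded.  The log-Jacobian keeps the target
    # equal to the natural-scale posterior.
    def log_post(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        x = 1.0 / (1.0 + np.exp(-theta))
        prev, sens, spec = x[:, 0], x[:, 1], x[:, 2]
        theta_ap = np.clip(prev * sens + (1 - prev) * (1 - spec),
                           1e-12, 1 - 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = k * np.log(theta_ap) + (m - k) * np.log1p(-theta_ap)
            lp = sens_prior.logpdf(sens) + spec_prior.logpdf(spec)
            # logit^-1 saturates for extreme proposals; -inf is the correct
            # log-density there.
            jacobian = np.sum(np.log(x) + np.log1p(-x), axis=1)
        out = ll + lp + jacobian
        return np.where(np.isnan(out), -np.inf, out)

    def logit(v: np.ndarray) -> np.ndarray:
        v = np.clip(v, 1e-9, 1 - 1e-9)
        return np.log(v / (1.0 - v))

    # Initialise walkers near the prior means and the Rogan-Gladen point.
    se0, sp0 = sens_prior.mean, spec_prior.mean
    prev0 = (k / m + sp0 - 1.0) / max(se0 + sp0 - 1.0, 1e-6)
    prev0 = float(np.clip(prev0, 1e-4, 1 - 1e-4))
    p0 = np.column_stack(
        [
            logit(prev0 * np.exp(rng.normal(0, 0.2, n_walkers))),
            logit(se0 + rng.normal(0, 0.02, n_walkers)),
            logit(sp0 + rng.normal(0, 0.005, n_walkers)),
        ]
    )
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, 3, log_post, vectorize=True,
                                    moves=moves)
    # emcee's internal RandomState is entropy-seeded by default; pin it so
    # identical seeds reproduce chains bit-for-bit.
    sampler.random_state = np.random.RandomState(
        int(rng.integers(2**31))
    ).get_state()
    state = sampler.run_mcmc(p0, n_warmup, skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, n_steps, skip_initial_state_check=True)
    chain = sampler.get_chain()  # (steps, walkers, 3) on the logit scale
    prev_draws = (1.0 / (1.0 + np.exp(-chain[:, :, 0]))).T  # (walkers, steps)

    import arviz as az

    ds = az.convert_to_dataset({"prev": prev_draws})
    diagnostics = {
        "rhat": float(az.rhat(ds)["prev"]),
        "ess": float(az.ess(ds)["prev"]),
        "acceptance_fraction": float(sampler.acceptance_fraction.mean()),
    }
    return prev_draws, diagnostics


def bayesian_estimate(
    data: ApparentPrevalence | pd.DataFrame,
    priors: PerformancePrior,
    groups: Sequence[PanelDefinition] = (),
    *,
    level: float = 0.95,
    n_walkers: int = DEFAULT_N_WALKERS,
    n_warmup: int = DEFAULT_N_WARMUP,
    n_steps: int = DEFAULT_N_STEPS,
    seed: int | None = None,
    rhat_max: float = RHAT_MAX,
    ess_min: float = ESS_MIN,
) -> dict:
    """Bayesian latent-prevalence model for components and panel groups.

    Model per component n: latent prevalence prev_n ~ Uniform(0, 1)
    (uninformative), sens_n and spec_n with informed beta priors, observed
    positive counts k_n ~ Binomial(m, prev_n*sens_n + (1-prev_n)(1-spec_n)).
    Subtype independence makes the posterior factorise by component, so each
    component is sampled separately (emcee ensemble sampler, 3 dimensions);
    group prevalences are derived from the joint posterior draws as
    1 - prod(1 - prev_n) over group members.

    Outputs posterior medians with central credible intervals at ``level``.
    Convergence is enforced per component: split-chain Rhat < ``rhat_max``
    (walkers as chains) and effective sample size > ``ess_min``; failure
    raises :class:`ConvergenceError` carrying the diagnostics.

    Returns ``{"components": {...}, "groups": {...}, "panel":
    PrevalenceEstimate}``; "panel" covers all components.
    """
    if isinstance(data, pd.DataFrame):
        ap = ApparentPrevalence.from_matrix(data)
    else:
        ap = data
    ids = list(ap.component_ids)
    priors.require_components(ids)
    if seed is None:
        raise ValueError("a seed is required for MCMC")
    seed_seq = np.random.SeedSequence(seed)
    draws: dict[str, np.ndarray] = {}
    comp_estimates: dict[str, PrevalenceEstimate] = {}
    for child, (j, cid) in zip(seed_seq.spawn(len(ids)), enumerate(ids)):
        rng = np.random.default_rng(child)
        prev_draws, diag = _component_posterior(
            ap.k[j], ap.m, priors.sens[cid], priors.spec[cid],
            n_walkers=n_walkers, n_warmup=n_warmup, n_steps=n_steps, rng=rng,
        )
        if diag["rhat"] >= rhat_max or diag["ess"] <= ess_min:
            raise ConvergenceError(
                f"component {cid!r} failed convergence: rhat={diag['rhat']:.3f} "
                f"(limit {rhat_max}), ess={diag['ess']:.0f} (minimum {ess_min})",
                diagnostics=diag,
            )
        flat = prev_draws.reshape(-1)
        draws[cid] = flat
        comp_estimates[cid] = _quantile_estimate(flat, level, "bayesian", diag)

    def group_estimate(member_ids: Sequence[str]) -> PrevalenceEstimate:
        # Component posteriors are independent, so pairing draws index-wise
        # across components samples the joint posterior of the group.
        not_prev = np.ones_like(draws[member_ids[0]])
        for cid in member_ids:
            not_prev = not_prev * (1.0 - draws[cid])
        return _quantile_estimate(1.0 - not_prev, level, "bayesian", {})

    group_estimates = {g.panel_id: group_estimate(list(g.component_ids))
                       for g in groups}
    result = _estimate_bundle(ids, comp_estimates, group_estimate(ids))
    result["groups"] = group_estimates
    return result


# --------------------------------------------------------------------------
# Input / output: CSV result matrices, control counts, scenario configs
# --------------------------------------------------------------------------

def read_result_matrix(path) -> tuple[pd.DataFrame, ApparentPrevalence]:
    """Read a subject x component 0/1 result matrix CSV.

    Header row holds component ids; an optional first column named
    ``subject_id`` becomes the index.  Cells must be 0 or 1; non-binary
    cells, duplicate component ids and ragged rows raise ``ValueError`` with
    the offending line number.  Lines starting with ``#`` (provenance
    headers) are skipped.
    """
    import csv

    path = Path(path)
    with path.open(newline="") as fh:
        rows = [
            (lineno, row)
            for lineno, row in enumerate(csv.reader(fh), start=1)
            if row and not row[0].startswith("#")
        ]
    if not rows:
        raise ValueError(f"{path}: empty file")
    header_line, header = rows[0]
    data_rows = rows[1:]
    if not data_rows:
        raise ValueError(f"{path}: no data rows after the header")
    has_subject_col = header[0] == "subject_id"
    component_ids = header[1:] if has_subject_col else header
    if not component_ids:
        raise ValueError(f"{path}: header has no component ids")
    if len(set(component_ids)) != len(component_ids):
        raise ValueError(f"{path}: duplicate component ids in header "
                         f"(line {header_line})")
    matrix = np.empty((len(data_rows), len(component_ids)), dtype=np.int8)
    subjects = []
    for i, (lineno, row) in enumerate(data_rows):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(header)} fields, "
                f"got {len(row)} (ragged row)"
            )
        cells = row[1:] if has_subject_col else row
        subjects.append(row[0] if has_subject_col else str(i))
        for j, cell in enumerate(cells):
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path}: line {lineno}: non-binary cell {cell!r} in "
                    f"column {component_ids[j]!r}"
                )
            matrix[i, j] = int(cell)
    df = pd.DataFrame(matrix, columns=component_ids,
                      index=pd.Index(subjects, name="subject_id"))
    ap = ApparentPrevalence.from_matrix(df)
    logger.info(
        "read %d subjects x %d components from %s; panel positives %d",
        len(df), len(component_ids), path, int(ap.k_panel),
    )
    return df, ap


def read_controls(path) -> ControlData:
    """Read control-group counts CSV.

    Schema: ``component_id,control_type,n_tested,n_correct`` with
    control_type in {positive, negative}.  Duplicate (component, type) rows
    are summed with a warning; ``n_correct > n_tested`` is an error.  An
    empty data section yields empty :class:`ControlData`.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#",
                     dtype={"component_id": str, "control_type": str})
    if df.empty:
        return ControlData.empty()
    required = {"component_id", "control_type", "n_tested", "n_correct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bad_type = ~df["control_type"].isin(["positive", "negative"])
    if bad_type.any():
        raise ValueError(
            f"{path}: control_type must be 'positive' or 'negative', got "
            f"{sorted(df.loc[bad_type, 'control_type'].unique())}"
        )
    if (df["n_correct"] > df["n_tested"]).any():
        raise ValueError(f"{path}: n_correct exceeds n_tested")
    dupes = df.duplicated(subset=["component_id", "control_type"], keep=False)
    if dupes.any():
        warnings.warn(
            f"{path}: duplicate (component_id, control_type) rows summed",
            UserWarning, stacklevel=2,
        )
    grouped = (
        df.groupby(["component_id", "control_type"])[["n_tested", "n_correct"]]
        .sum()
        .unstack("control_type")
    )
    out = pd.DataFrame(index=grouped.index)
    for side, label in (("pos", "positive"), ("neg", "negative")):
        if ("n_tested", label) in grouped.columns:
            out[f"n_{side}"] = grouped[("n_tested", label)]
            out[f"k_{side}"] = grouped[("n_correct", label)]
    return ControlData(out)


def read_scenario_config(path) -> ScenarioConfig:
    """Read a simulation scenario from YAML.

    Recognised keys: seed (required), n_subjects, target_panel_prev,
    weights (mapping component id -> relative frequency; default the
    packaged IPD-like distribution), sens / spec (scalars applied to every
    component, or per-component mappings), groups (mapping group id -> list
    of component ids; defaults to the PCV groups for the packaged weights).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "seed" not in raw:
        raise ValueError(f"{path}: scenario config must be a mapping with a 'seed'")
    weights = raw.get("weights")
    weights = (default_ipd_like_weights() if weights is None
               else pd.Series(weights, dtype=float))
    sens = raw.get("sens", DEFAULT_SENS)
    spec = raw.get("spec", DEFAULT_SPEC)
    profiles = tuple(
        ComponentProfile(
            str(cid),
            float(sens[cid]) if isinstance(sens, Mapping) else float(sens),
            float(spec[cid]) if isinstance(spec, Mapping) else float(spec),
        )
        for cid in weights.index
    )
    groups = tuple(
        PanelDefinition(name, tuple(ids))
        for name, ids in raw.get("groups", {}).items()
    )
    return ScenarioConfig(
        seed=int(raw["seed"]),
        n_subjects=int(raw.get("n_subjects", DEFAULT_N_SUBJECTS)),
        weights=weights,
        target_panel_prev=float(raw.get("target_panel_prev", DEFAULT_PANEL_PREV)),
        profiles=profiles,
        groups=groups,
    )


def config_hash(config) -> str:
    """Short stable hash of a configuration for provenance lines."""
    if isinstance(config, ScenarioConfig):
        config = config.to_dict()
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance_header(config_digest: str, seed) -> str:
    return f"# panelprev provenance: config_hash={config_digest} seed={seed}\n"


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write results.csv and truth.csv (0/1 matrices with subject_id) plus a
    provenance header comment; both round-trip through
    :func:`read_result_matrix` bit-exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config_hash(cohort.config)
    paths = {}
    for name, frame in (("results", cohort.results), ("truth", cohort.truth)):
        path = outdir / f"{name}.csv"
        with path.open("w") as fh:
            fh.write(_provenance_header(digest, cohort.config.seed))
            frame.rename_axis("subject_id").to_csv(fh)
        paths[name] = path
    return paths


def write_estimates(
    estimates: dict, path, *, config_digest: str = "", seed=None
) -> Path:
    """Write an estimate bundle (components / panel / groups) to CSV with
    columns unit_id, method, point, lower, upper, level, flags."""
    rows = []

    def add(unit_id: str, est: PrevalenceEstimate):
        flags = ";".join(
            key for key in ("zero_prevalence_limit",)
            if est.diagnostics.get(key)
        )
        if est.diagnostics.get("n_dropped"):
            flags = (flags + ";" if flags else "") + \
                f"dropped={est.diagnostics['n_dropped']}"
        rows.append(
            {
                "unit_id": unit_id, "method": est.method,
                "point": est.point, "lower": est.lower, "upper": est.upper,
                "level": "" if est.level is None else est.level,
                "flags": flags,
            }
        )

    for cid, est in estimates.get("components", {}).items():
        add(cid, est)
    for gid, est in estimates.get("groups", {}).items():
        add(gid, est)
    if "panel" in estimates:
        add("panel", estimates["panel"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(_provenance_header(config_digest or "-", seed))
        pd.DataFrame(rows).to_csv(fh, index=False)
    return path
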