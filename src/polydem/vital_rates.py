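"""Vital-rate regressions with all-subsets AICc model selection.

The demographic model is built from 13 regression vital rates per genotype,
each a GLM of a transition on log size ``z``, soil moisture ``M`` (volumetric
water content, %) and herbivory ``H`` (% leaf area removed), with all two- and
three-way interactions as candidate terms:

====  =========================================  ==================  =============
key   response                                   family              rows
====  =========================================  ==================  =============
s     survival t -> t+1                          binomial (logit)    all plants
b0    bolting at t+1                             binomial (logit)    survivors, not bolting at t
b1    bolting at t+1                             binomial (logit)    survivors, bolting at t
gqq'  size at t+1 (mean growth)                  gaussian            survivors, state q -> q'
vqq'  squared growth residual (growth variance)  gaussian (HC1 cov)  survivors, state q -> q'
r     reproduced at t+1                          binomial (logit)    survivors bolting at t+1
f     seed count                                 gaussian            reproducers
====  =========================================  ==================  =============

State subscripts follow the bolting convention: a single subscript is the past
bolting state, double subscripts are past and present states (1 = bolting).
Growth (``g``) and reproduction (``r``, ``f``) use the size at which the
transition is expressed: ``g``/``v`` regress size at t+1 on size at t, while
``r`` and ``f`` use size at t+1, the size of the plant in the census at which
reproduction is scored.

Three recruitment rates (germination, seed-bank survival, germinant survival)
plus the recruit-size distribution are constants supplied externally rather
than regressions; see :class:`RecruitmentConstants`.

Model selection enumerates every subset of the 7-term global model that
respects marginality (an interaction enters only with all its lower-order
constituents) and picks the minimum AICc.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .exceptions import AICcUndefinedError, FitError, SchemaError

#: Canonical order of candidate terms in the global model (intercept implicit).
GLOBAL_TERMS = ("z", "M", "H", "z:M", "z:H", "M:H", "z:M:H")

#: Candidate terms for size-free rates (e.g. recruit size if fitted).
DRIVER_TERMS = ("M", "H", "M:H")

#: Floor applied to predicted growth variances (log-size^2 units).
VARIANCE_FLOOR = 1e-6

RATE_KEYS = (
    "s", "b0", "b1",
    "g00", "g01", "g10", "g11",
    "v00", "v01", "v10", "v11",
    "r", "f",
)

#: Growth/variance pairs: v rates are fitted on squared residuals of these.
GROWTH_FOR_VARIANCE = {"v00": "g00", "v01": "g01", "v10": "g10", "v11": "g11"}


def _term_factors(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


def respects_marginality(terms) -> bool:
    """True if every interaction in ``terms`` has all its lower-order
    constituents (mains and sub-interactions) also present."""
    present = set(terms)
    for term in terms:
        factors = _term_factors(term)
        if len(factors) == 1:
            continue
        for k in range(1, len(factors)):
            for sub in itertools.combinations(factors, k):
                if ":".join(sub) not in present:
                    return False
    return True


def hierarchical_term_sets(candidates=GLOBAL_TERMS) -> list[tuple[str, ...]]:
    """All marginality-respecting subsets of ``candidates``, in canonical
    order, smallest models first (intercept-only is ``()``)."""
    sets = []
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            if respects_marginality(combo):
                sets.append(combo)
    return sets


# ---------------------------------------------------------------------------
# Specs and fitted-model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VitalRateSpec:
    """Declarative description of one vital-rate regression."""

    key: str
    family: str                      # "binomial" | "gaussian"
    response: str                    # CensusTable column (or derived column)
    size_col: str | None             # which census size enters as z
    row_filter: str                  # pandas query string; "" = all rows
    candidate_terms: tuple[str, ...] = GLOBAL_TERMS
    size_free: bool = False
    robust_cov: bool = False         # HC1 covariance (variance rates)

    def filter_rows(self, data: pd.DataFrame) -> pd.DataFrame:
        sub = data.query(self.row_filter) if self.row_filter else data
        if len(sub) == 0:
            raise SchemaError(f"no rows left for vital rate '{self.key}' "
                              f"after filter '{self.row_filter}'")
        return sub


def _growth_spec(key: str) -> VitalRateSpec:
    q_from, q_to = key[-2], key[-1]
    return VitalRateSpec(
        key=key, family="gaussian", response="size_t1", size_col="size_t",
        row_filter=(f"survived_t1 == 1 and bolting_t == {q_from} "
                    f"and bolting_t1 == {q_to}"),
    )


def _variance_spec(key: str) -> VitalRateSpec:
    g = _growth_spec(GROWTH_FOR_VARIANCE[key])
    return replace(g, key=key, response="_sq_resid", robust_cov=True)


RATE_SPECS: dict[str, VitalRateSpec] = {
    "s": VitalRateSpec("s", "binomial", "survived_t1", "size_t", ""),
    "b0": VitalRateSpec("b0", "binomial", "bolting_t1", "size_t",
                        "survived_t1 == 1 and bolting_t == 0"),
    "b1": VitalRateSpec("b1", "binomial", "bolting_t1", "size_t",
                        "survived_t1 == 1 and bolting_t == 1"),
    **{k: _growth_spec(k) for k in ("g00", "g01", "g10", "g11")},
    **{k: _variance_spec(k) for k in ("v00", "v01", "v10", "v11")},
    "r": VitalRateSpec("r", "binomial", "reproduced_t1", "size_t1",
                       "survived_t1 == 1 and bolting_t1 == 1"),
    "f": VitalRateSpec("f", "gaussian", "seed_count_t1", "size_t1",
                       "survived_t1 == 1 and reproduced_t1 == 1"),
}


@dataclass
class FittedVitalRate:
    """One fitted (or truth-specified) vital-rate regression.

    ``params`` is on the link scale, ordered (intercept, then ``terms`` in
    canonical order). ``cov`` is the coefficient sampling covariance used for
    the parametric bootstrap. ``driver_overrides`` pins a driver at a fixed
    value during prediction; it is used by the driver-contribution analysis.
    """

    key: str
    family: str
    terms: tuple[str, ...]
    params: np.ndarray
    cov: np.ndarray
    n: int = 0
    loglik: float = np.nan
    aicc_value: float = np.nan
    selection_table: pd.DataFrame | None = None
    size_col: str | None = "size_t"
    driver_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        p = len(self.terms) + 1
        if self.params.shape != (p,):
            raise ValueError(f"{self.key}: expected {p} coefficients for "
                             f"terms {self.terms}, got {self.params.shape}")
        if self.cov.shape != (p, p):
            raise ValueError(f"{self.key}: covariance shape {self.cov.shape} "
                             f"does not match {p} coefficients")


@dataclass(frozen=True)
class RecruitmentConstants:
    """Recruitment rates taken as known constants (not refitted from census).

    germination:      probability a seed germinates the next spring (gamma)
    seedbank_survival: annual survival of an ungerminated seed (sigma_sb)
    germinant_survival: first-summer survival of a germinant (sigma_j)
    recruit_size_mean / recruit_size_sd: log-size distribution of surviving
        first-year recruits at their first census.
    """

    germination: float
    seedbank_survival: float
    germinant_survival: float
    recruit_size_mean: float
    recruit_size_sd: float

    def __post_init__(self):
        for name in ("germination", "seedbank_survival", "germinant_survival"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.recruit_size_sd > 0:
            raise ValueError("recruit_size_sd must be > 0")


@dataclass(frozen=True)
class SeedCalibration:
    """OLS calibration of seed number on fruit length (mm)."""

    slope: float
    intercept: float

    def predict(self, fruit_length):
        out = self.intercept + self.slope * np.asarray(fruit_length, float)
        return np.maximum(out, 0.0)


@dataclass
class GenotypeModelSet:
    """All 13 fitted vital rates plus recruitment constants for one genotype."""

    genotype: str
    fits: dict[str, FittedVitalRate]
    recruitment: RecruitmentConstants
    seed_calibration: SeedCalibration | None = None

    def __post_init__(self):
        missing = [k for k in RATE_KEYS if k not in self.fits]
        if missing:
            raise SchemaError(f"model set for {self.genotype} is missing "
                              f"vital rates {missing}", columns=missing)


# ---------------------------------------------------------------------------
# Design matrices and prediction
# ---------------------------------------------------------------------------

def term_values(term: str, z, M, H) -> np.ndarray:
    """Elementwise product of the main-effect columns named in ``term``."""
    mains = {"z": z, "M": M, "H": H}
    out = None
    for factor in _term_factors(term):
        col = np.asarray(mains[factor], dtype=float)
        out = col if out is None else out * col
    return out


def build_design(rows: pd.DataFrame, terms, *, size_col: str | None = "size_t",
                 response: str | None = None):
    """Predictor matrix (and response vector) for a census subset.

    Columns are ordered (intercept, z, M, H, z:M, z:H, M:H, z:M:H) restricted
    to ``terms``. Rows with missing predictor or response values are rejected
    with the offending row labels.
    """
    terms = tuple(t for t in GLOBAL_TERMS if t in set(terms))
    needs_z = any("z" in _term_factors(t) for t in terms)
    cols = ["moisture_t", "herbivory_t"]
    if needs_z:
        if size_col is None:
            raise SchemaError("terms include size but the rate is size-free")
        cols.append(size_col)
    if response is not None:
        cols.append(response)
    missing_cols = [c for c in cols if c not in rows.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}",
                          columns=missing_cols)
    bad = rows.index[rows[cols].isna().any(axis=1)]
    if len(bad):
        raise SchemaError(f"missing values in rows {list(bad[:10])}"
                          + ("..." if len(bad) > 10 else ""))
    z = rows[size_col].to_numpy(float) if needs_z else np.zeros(len(rows))
    M = rows["moisture_t"].to_numpy(float)
    H = rows["herbivory_t"].to_numpy(float)
    X = np.column_stack([np.ones(len(rows))]
                        + [term_values(t, z, M, H) for t in terms])
    if response is None:
        return X
    return X, rows[response].to_numpy(float)


def linear_predictor(fit: FittedVitalRate, z, E) -> np.ndarray:
    """Link-scale prediction at log-size ``z`` and environment ``E=(M, H)``."""
    M, H = E
    M = fit.driver_overrides.get("M", M)
    H = fit.driver_overrides.get("H", H)
    z, M, H = np.broadcast_arrays(np.asarray(z, float),
                                  np.asarray(M, float),
                                  np.asarray(H, float))
    eta = np.full(z.shape, fit.params[0])
    for coef, term in zip(fit.params[1:], fit.terms):
        eta = eta + coef * term_values(term, z, M, H)
    return eta


def predict_rate(fit: FittedVitalRate, z, E) -> np.ndarray:
    """Response-scale prediction: inverse logit for binomial rates, identity
    for gaussian ones. Variance rates are floored at ``VARIANCE_FLOOR``."""
    eta = linear_predictor(fit, z, E)
    if fit.family == "binomial":
        return expit(eta)
    if fit.key.startswith("v"):
        return np.maximum(eta, VARIANCE_FLOOR)
    return eta


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise AICcUndefinedError(
            f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _n_params(family: str, n_coef: int) -> int:
    # Gaussian fits also estimate the residual variance.
    return n_coef + (1 if family == "gaussian" else 0)


def fit_vital_rate(spec: VitalRateSpec, data: pd.DataFrame, terms,
                   *, response: np.ndarray | None = None) -> FittedVitalRate:
    """Maximum-likelihood fit of one candidate model for one vital rate.

    ``response`` overrides the response column (used for variance rates,
    whose response is derived from a paired mean-growth fit).
    """
    terms = tuple(t for t in GLOBAL_TERMS if t in set(terms))
    sub = spec.filter_rows(data)
    if response is None:
        X, y = build_design(sub, terms, size_col=spec.size_col,
                            response=spec.response)
    else:
        X = build_design(sub, terms, size_col=spec.size_col)
        y = np.asarray(response, dtype=float)
        if len(y) != len(X):
            raise SchemaError("response override length mismatch")
    n, p = X.shape
    k = _n_params(spec.family, p)
    if n < p + 1:
        raise FitError(f"{spec.key}: n={n} too small for {p} coefficients",
                       terms=terms)
    try:
        if spec.family == "binomial":
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        else:
            cov_type = "HC1" if spec.robust_cov else "nonrobust"
            res = sm.OLS(y, X).fit(cov_type=cov_type)
    except Exception as exc:  # separation, singular design, ...
        raise FitError(f"{spec.key}: fit failed for terms {terms}: {exc}",
                       terms=terms) from exc
    params = np.asarray(res.params, float)
    cov = np.asarray(res.cov_params(), float)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(cov))):
        raise FitError(f"{spec.key}: non-finite estimates for terms {terms} "
                       "(separation or singular design)", terms=terms)
    llf = float(res.llf)
    try:
        crit = aicc(llf, k, n) if np.isfinite(llf) else -np.inf
    except AICcUndefinedError:
        raise FitError(f"{spec.key}: AICc undefined at n={n}, k={k}",
                       terms=terms)
    return FittedVitalRate(
        key=spec.key, family=spec.family, terms=terms, params=params,
        cov=cov, n=n, loglik=llf, aicc_value=crit, size_col=spec.size_col,
    )


def select_model(spec: VitalRateSpec, data: pd.DataFrame,
                 *, response: np.ndarray | None = None,
                 parsimony_window: float = 2.0) -> FittedVitalRate:
    """All-subsets AICc selection over the marginality-respecting candidates.

    Every candidate is fitted and ranked by AICc. Candidates within
    ``parsimony_window`` AICc units of the minimum are treated as equally
    supported, and the most parsimonious of them (fewest parameters, ties
    broken by lower AICc then lexicographic term order) is returned; set
    ``parsimony_window=0`` for strict AICc minimisation. The full selection
    table travels with the winning fit.
    """
    candidates = DRIVER_TERMS if spec.size_free else spec.candidate_terms
    rows, fits, errors = [], {}, []
    for terms in hierarchical_term_sets(candidates):
        try:
            fit = fit_vital_rate(spec, data, terms, response=response)
            fits[terms] = fit
            rows.append({"terms": "+".join(terms) or "1",
                         "k": _n_params(spec.family, len(terms) + 1),
                         "loglik": fit.loglik, "aicc": fit.aicc_value,
                         "converged": True})
        except FitError as exc:
            errors.append(exc)
            rows.append({"terms": "+".join(terms) or "1",
                         "k": _n_params(spec.family, len(terms) + 1),
                         "loglik": np.nan, "aicc": np.inf,
                         "converged": False})
    if not fits:
        raise FitError(f"{spec.key}: every candidate model failed "
                       f"({len(errors)} errors; first: {errors[0]})")
    min_aicc = min(fit.aicc_value for fit in fits.values())
    supported = [t for t, fit in fits.items()
                 if fit.aicc_value <= min_aicc + parsimony_window]
    best_terms = min(supported,
                     key=lambda t: (len(t), fits[t].aicc_value, t))
    best = fits[best_terms]
    table = pd.DataFrame(rows).sort_values("aicc", kind="stable")
    table["delta_aicc"] = table["aicc"] - min_aicc
    table["selected"] = table["terms"].eq("+".join(best_terms) or "1")
    best.selection_table = table.reset_index(drop=True)
    return best


def fit_variance_rate(spec: VitalRateSpec, data: pd.DataFrame,
                      growth_fit: FittedVitalRate, *, terms=None) -> FittedVitalRate:
    """Fit a growth-variance rate on squared residuals of its growth fit."""
    sub = spec.filter_rows(data)
    M = sub["moisture_t"].to_numpy(float)
    H = sub["herbivory_t"].to_numpy(float)
    mu = predict_rate(growth_fit, sub[spec.size_col].to_numpy(float), (M, H))
    sq = (sub["size_t1"].to_numpy(float) - mu) ** 2
    if terms is None:
        return select_model(spec, data, response=sq)
    return fit_vital_rate(spec, data, terms, response=sq)


def fit_genotype_modelset(data: pd.DataFrame, genotype: str,
                          recruitment: RecruitmentConstants,
                          *, term_sets: dict[str, tuple] | None = None,
                          seed_calibration: SeedCalibration | None = None,
                          ) -> GenotypeModelSet:
    """Fit all 13 vital rates for one genotype.

    With ``term_sets`` given (a mapping key -> term tuple), each rate is fit
    at that fixed model form; otherwise all-subsets AICc selection runs per
    rate. Variance rates are always fitted on the squared residuals of the
    paired mean-growth fit.
    """
    sub = data[data["genotype"] == genotype]
    if len(sub) == 0:
        raise SchemaError(f"no census rows for genotype {genotype!r}")
    fits: dict[str, FittedVitalRate] = {}
    for key in RATE_KEYS:
        spec = RATE_SPECS[key]
        if key in GROWTH_FOR_VARIANCE:
            gfit = fits[GROWTH_FOR_VARIANCE[key]]
            terms = term_sets.get(key) if term_sets else None
            fits[key] = fit_variance_rate(spec, sub, gfit, terms=terms)
        elif term_sets is not None:
            fits[key] = fit_vital_rate(spec, sub, term_sets[key])
        else:
            fits[key] = select_model(spec, sub)
    return GenotypeModelSet(genotype=genotype, fits=fits,
                            recruitment=recruitment,
                            seed_calibration=seed_calibration)


def fit_seed_calibration(fruit_lengths, seed_counts) -> SeedCalibration:
    """OLS of seed number on total fruit length; needs >= 3 pairs."""
    x = np.asarray(fruit_lengths, float)
    y = np.asarray(seed_counts, float)
    if len(x) < 3:
        raise FitError("seed calibration needs at least 3 pairs")
    if np.ptp(x) == 0:
        raise FitError("seed calibration: fruit lengths have zero variance")
    X = np.column_stack([np.ones(len(x)), x])
    res = sm.OLS(y, X).fit()
    return SeedCalibration(slope=float(res.params[1]),
                           intercept=float(res.params[0]))


def modelset_from_coefficients(genotype: str, coefs: dict[str, dict[str, float]],
                               recruitment: RecruitmentConstants,
                               ) -> GenotypeModelSet:
    """Build a GenotypeModelSet from known (e.g. truth) coefficients.

    ``coefs`` maps each rate key to ``{"intercept": a, term: b, ...}``.
    Covariances are zero, so bootstrap draws reproduce the point estimate.
    """
    fits = {}
    for key in RATE_KEYS:
        spec = RATE_SPECS[key]
        cdict = dict(coefs[key])
        intercept = float(cdict.pop("intercept", 0.0))
        unknown = set(cdict) - set(GLOBAL_TERMS)
        if unknown:
            raise SchemaError(f"{key}: unknown terms {sorted(unknown)}")
        terms = tuple(t for t in GLOBAL_TERMS if t in cdict)
        params = np.array([intercept] + [float(cdict[t]) for t in terms])
        p = len(params)
        fits[key] = FittedVitalRate(
            key=key, family=spec.family, terms=terms, params=params,
            cov=np.zeros((p, p)), size_col=spec.size_col,
        )
    return GenotypeModelSet(genotype=genotype, fits=fits,
                            recruitment=recruitment)
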