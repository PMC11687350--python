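"""Synthetic census generator and individual-based validation oracle.

This module emulates the data-generating process the regression pipeline
assumes: a transplant cohort of two near-isogenic genotypes censused annually
for survival, size (log height), bolting state, reproduction and seed set,
under block-level soil moisture (volumetric water content, %) and per-plant
herbivory (% leaf area removed). Truth parameters are explicit, so parameter
recovery, model selection and kernel eigenvalues can all be validated against
known generating values.

It also provides an individual-based lineage simulator that applies the same
annual timing convention as the kernel module (reproduction by bolting plants,
seed fates split between immediate recruitment and the seed bank, then
survival / bolting / growth); its realised log growth rate is an independent
Monte-Carlo oracle for the kernel's dominant eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ExtinctionError, SchemaError
from .vital_rates import (GLOBAL_TERMS, RATE_KEYS, GenotypeModelSet,
                          RecruitmentConstants, modelset_from_coefficients,
                          predict_rate)

#: Mandatory CensusTable columns (one transition per row).
CENSUS_COLUMNS = (
    "individual", "genotype", "block", "year",
    "size_t", "bolting_t", "herbivory_t", "moisture_t",
    "survived_t1", "size_t1", "bolting_t1", "reproduced_t1", "seed_count_t1",
)


@dataclass(frozen=True)
class GenotypeTruth:
    """Known truth parameters for one genotype.

    ``coefs`` maps each regression vital rate (s, b0, b1, g00..g11, v00..v11,
    r, f) to ``{"intercept": value, term: value, ...}`` on the link scale
    (logit for probabilities, identity for growth means/variances and seed
    number). ``seed_sd`` is the SD of realised seed counts around f.
    """

    coefs: dict[str, dict[str, float]]
    recruitment: RecruitmentConstants
    seed_sd: float = 5.0

    def __post_init__(self):
        missing = [k for k in RATE_KEYS if k not in self.coefs]
        if missing:
            raise SchemaError(f"truth is missing vital rates {missing}")
        for key, cdict in self.coefs.items():
            unknown = set(cdict) - set(GLOBAL_TERMS) - {"intercept"}
            if unknown:
                raise SchemaError(f"truth {key}: unknown terms {sorted(unknown)}")
        if not self.seed_sd > 0:
            raise ValueError("seed_sd must be > 0")

    def modelset(self, genotype: str) -> GenotypeModelSet:
        """Zero-covariance model set evaluating the truth exactly."""
        return modelset_from_coefficients(genotype, self.coefs, self.recruitment)

    def term_sets(self) -> dict[str, tuple[str, ...]]:
        """The generating model form of each vital rate."""
        return {k: tuple(t for t in GLOBAL_TERMS if t in self.coefs[k])
                for k in RATE_KEYS}


#: Truth parameters per genotype.
TruthParams = dict[str, GenotypeTruth]


@dataclass
class EnvironmentSeries:
    """Block-level drivers per year plus the per-plant herbivory process.

    ``table`` has one row per (block, year) with columns block, year,
    moisture (VWC %), herbivory (block mean % leaf area removed).
    Individual plants draw zero-inflated herbivory around the block mean.
    """

    table: pd.DataFrame
    herbivory_dispersion: float = 8.0
    zero_inflation: float = 0.25

    @property
    def n_years(self) -> int:
        return self.table["year"].nunique()


def default_truth() -> TruthParams:
    """Bundled two-genotype truth for a size-structured perennial with a seed
    bank and bolting-gated reproduction.

    The BB genotype is the more drought-sensitive (stronger positive moisture
    slopes, so its fitness collapses faster as soils dry) and only weakly
    herbivory-sensitive; the MM genotype tolerates drought better but pays a
    larger herbivory cost on survival and bolting, partly offset at high
    moisture (a positive moisture x herbivory interaction: well-watered
    plants compensate for damage) and by small positive herbivory effects on
    vegetative growth and repeat bolting. The two fitness surfaces nearly
    coincide at moderate-to-high moisture and diverge as soils dry — MM ahead
    under low herbivory, BB ahead under high herbivory — so the genotype gap
    is confined to dry environments. Driver scales: moisture is volumetric
    water content in % (field range roughly 4-20), herbivory is % leaf area
    removed (zero-heavy, mean well below 20).
    """
    recruitment = RecruitmentConstants(
        germination=0.15, seedbank_survival=0.35, germinant_survival=0.30,
        recruit_size_mean=1.0, recruit_size_sd=0.35)
    shared = {
        # growth: mean-reverting around state-specific targets
        "g01": {"intercept": 1.10, "z": 0.62, "M": 0.010},
        "g10": {"intercept": 0.45, "z": 0.55},
        "g11": {"intercept": 0.90, "z": 0.58, "M": 0.006},
        # growth variances (identity scale, log-size^2)
        "v00": {"intercept": 0.10},
        "v01": {"intercept": 0.14},
        "v10": {"intercept": 0.12},
        "v11": {"intercept": 0.11},
    }
    bb = GenotypeTruth(coefs={
        "s": {"intercept": -1.7, "z": 0.9, "M": 0.16, "H": -0.005,
              "M:H": 0.0010},
        "b0": {"intercept": -4.5, "z": 1.8, "M": 0.06, "H": -0.004},
        "b1": {"intercept": -2.0, "z": 0.6, "M": 0.06},
        "g00": {"intercept": 0.55, "z": 0.72, "M": 0.008},
        "r": {"intercept": -1.0, "z": 1.0, "H": -0.006},
        "f": {"intercept": -10.0, "z": 14.0, "M": 0.5, "H": -0.05},
        **shared,
    }, recruitment=recruitment)
    mm = GenotypeTruth(coefs={
        "s": {"intercept": -1.0, "z": 0.9, "M": 0.115, "H": -0.022,
              "M:H": 0.0015},
        "b0": {"intercept": -4.5, "z": 1.8, "M": 0.055, "H": -0.010},
        "b1": {"intercept": -2.0, "z": 0.6, "M": 0.05, "H": 0.004},
        "g00": {"intercept": 0.55, "z": 0.72, "M": 0.008, "H": 0.002},
        "r": {"intercept": -1.0, "z": 1.0, "H": -0.008},
        "f": {"intercept": -10.0, "z": 14.0, "M": 0.5, "H": -0.05},
        **shared,
    }, recruitment=recruitment)
    return {"BB": bb, "MM": mm}


# ---------------------------------------------------------------------------
# Environment process
# ---------------------------------------------------------------------------

def simulate_environment(n_blocks: int, years: int,
                         moisture_range=(4.0, 20.0),
                         herbivory_dispersion: float = 8.0,
                         moisture_herbivory_corr: float = 0.0,
                         seed: int = 0,
                         herbivory_mean: float = 8.0,
                         zero_inflation: float = 0.25) -> EnvironmentSeries:
    """Block x year driver series with an optional moisture-herbivory link.

    Moisture is uniform on ``moisture_range`` per block-year; the block-mean
    herbivory marginal is a scaled beta centred on ``herbivory_mean`` %. The
    requested Pearson correlation between block moisture and block-mean
    herbivory is induced through a gaussian copula (marginals unchanged).
    """
    if n_blocks < 1 or years < 1:
        raise ValueError("n_blocks and years must be >= 1")
    lo, hi = float(moisture_range[0]), float(moisture_range[1])
    if not (0 <= lo < hi):
        raise ValueError(f"empty or negative moisture range ({lo}, {hi})")
    rho = float(moisture_herbivory_corr)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation must be in [-1, 1], got {rho}")
    if herbivory_dispersion <= 0:
        raise ValueError("herbivory_dispersion must be > 0")
    rng = np.random.default_rng(seed)
    n = n_blocks * years
    cov = np.array([[1.0, rho], [rho, 1.0]])
    latent = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="svd")
    u = stats.norm.cdf(latent)
    moisture = lo + (hi - lo) * u[:, 0]
    # beta marginal for the block-mean herbivory, mean herbivory_mean/100
    mean_h = herbivory_mean / 100.0
    a = 1.5
    b = a * (1.0 - mean_h) / mean_h
    herb = 100.0 * stats.beta.ppf(u[:, 1], a, b)
    blocks = np.repeat(np.arange(n_blocks), years)
    yrs = np.tile(np.arange(years), n_blocks)
    table = pd.DataFrame({"block": blocks, "year": yrs,
                          "moisture": moisture,
                          "herbivory": np.clip(herb, 0.0, 100.0)})
    return EnvironmentSeries(table=table,
                             herbivory_dispersion=float(herbivory_dispersion),
                             zero_inflation=float(zero_inflation))


def _plant_herbivory(rng: np.random.Generator, block_mean: np.ndarray,
                     dispersion: float, zero_inflation: float) -> np.ndarray:
    """Zero-inflated per-plant damage around the block mean (both in %)."""
    m = np.clip(block_mean / 100.0 / max(1.0 - zero_inflation, 1e-9),
                1e-4, 0.999)
    a = dispersion * m
    b = dispersion * (1.0 - m)
    damage = 100.0 * rng.beta(a, b)
    zero = rng.random(block_mean.shape) < zero_inflation
    return np.where(zero, 0.0, np.clip(damage, 0.0, 100.0))


# ---------------------------------------------------------------------------
# Census simulator
# ---------------------------------------------------------------------------

def simulate_census(truth: TruthParams, env: EnvironmentSeries,
                    n_plants: int, n_years: int, seed: int = 0) -> pd.DataFrame:
    """Simulate annual transition records for each genotype.

    ``n_plants`` individuals per genotype are followed for ``n_years``
    transitions; plants that die are replaced the following year by fresh
    recruits (new IDs), keeping the monitored cohort size constant, as in a
    maintained common-garden planting. Each transition row draws survival,
    bolting, growth, reproduction and seed set from the truth vital rates at
    the row's (size, moisture, herbivory).
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    if env.n_years < n_years:
        raise ValueError(f"environment series covers {env.n_years} years, "
                         f"needs {n_years}")
    rng = np.random.default_rng(seed)
    env_by_year = {y: g for y, g in env.table.groupby("year")}
    rows = []
    for genotype, gt in truth.items():
        ms = gt.modelset(genotype)
        rec = gt.recruitment
        n_blocks = env.table["block"].nunique()
        block_of = np.arange(n_plants) % n_blocks
        size = rng.uniform(0.6, 3.2, size=n_plants)
        bolting = (rng.random(n_plants)
                   < 1.0 / (1.0 + np.exp(-(size - 2.5)))).astype(int)
        ident = np.array([f"{genotype}_{i:05d}" for i in range(n_plants)])
        next_id = n_plants
        for year in range(n_years):
            eyr = env_by_year[sorted(env_by_year)[year]]
            moist = eyr.set_index("block")["moisture"].reindex(block_of).to_numpy()
            herb_block = eyr.set_index("block")["herbivory"].reindex(block_of).to_numpy()
            herb = _plant_herbivory(rng, herb_block, env.herbivory_dispersion,
                                    env.zero_inflation)
            E = (moist, herb)
            surv = rng.random(n_plants) < predict_rate(ms.fits["s"], size, E)
            b_prob = np.where(
                bolting == 1,
                predict_rate(ms.fits["b1"], size, E),
                predict_rate(ms.fits["b0"], size, E))
            bolt_next = (rng.random(n_plants) < b_prob).astype(int)
            mu = np.empty(n_plants)
            sd = np.empty(n_plants)
            for qf in (0, 1):
                for qt in (0, 1):
                    sel = (bolting == qf) & (bolt_next == qt)
                    if not sel.any():
                        continue
                    Ez = (moist[sel], herb[sel])
                    mu[sel] = predict_rate(ms.fits[f"g{qf}{qt}"], size[sel], Ez)
                    sd[sel] = np.sqrt(predict_rate(ms.fits[f"v{qf}{qt}"],
                                                   size[sel], Ez))
            size_next = rng.normal(mu, sd)
            r_prob = predict_rate(ms.fits["r"], size_next, E)
            repro = (bolt_next == 1) & (rng.random(n_plants) < r_prob)
            f_mean = predict_rate(ms.fits["f"], size_next, E)
            seeds = np.maximum(np.round(rng.normal(f_mean, gt.seed_sd)), 0.0)
            rows.append(pd.DataFrame({
                "individual": ident, "genotype": genotype,
                "block": block_of, "year": year,
                "size_t": size, "bolting_t": bolting,
                "herbivory_t": herb, "moisture_t": moist,
                "survived_t1": surv.astype(int),
                "size_t1": np.where(surv, size_next, np.nan),
                "bolting_t1": np.where(surv, bolt_next, np.nan),
                "reproduced_t1": np.where(surv, (surv & repro).astype(float),
                                          np.nan),
                "seed_count_t1": np.where(surv & repro, seeds, np.nan),
            }))
            # advance survivors; replace the dead with fresh recruits
            n_dead = int((~surv).sum())
            size = np.where(surv, size_next,
                            rng.normal(rec.recruit_size_mean,
                                       rec.recruit_size_sd, n_plants))
            bolting = np.where(surv, bolt_next, 0).astype(int)
            if n_dead:
                new_ids = [f"{genotype}_{next_id + j:05d}" for j in range(n_dead)]
                next_id += n_dead
                ident = ident.copy()
                ident[~surv] = new_ids
    out = pd.concat(rows, ignore_index=True)
    dup = out.duplicated(subset=["individual", "year"])
    if dup.any():
        raise SchemaError("duplicated (individual, year) keys in census")
    return out


# ---------------------------------------------------------------------------
# Individual-based lineage oracle
# ---------------------------------------------------------------------------

@dataclass
class LineageTrajectory:
    """IBM output: yearly totals (plants + bank seeds) and growth estimate."""

    pop_sizes: np.ndarray
    burn_in: int

    @property
    def log_growth(self) -> float:
        n = self.pop_sizes
        return float((np.log(n[-1]) - np.log(n[self.burn_in]))
                     / (len(n) - 1 - self.burn_in))

    @property
    def lam(self) -> float:
        return float(np.exp(self.log_growth))


def simulate_lineage_ibm(truth: GenotypeTruth, env_fixed, n0: int,
                         horizon: int, burn_in: int = 10, seed: int = 0,
                         genotype: str = "X",
                         initial_bolting: float = 0.0) -> LineageTrajectory:
    """Individual-based lineage simulation at a constant environment.

    Starts from ``n0`` recruits (a fraction ``initial_bolting`` of them in
    the bolting state) and an empty seed bank; each year
    bolting plants reproduce (Bernoulli(r) then Poisson(f) seeds), seeds
    either recruit next year (germination x germinant survival) or enter the
    bank, bank seeds germinate or persist, and plants survive / switch
    bolting state / grow, exactly mirroring the kernel's annual transition.
    Raises :class:`ExtinctionError` if the lineage dies out before the growth
    rate is estimable.
    """
    if not 0 <= burn_in < horizon:
        raise ValueError("need 0 <= burn_in < horizon")
    rng = np.random.default_rng(seed)
    ms = truth.modelset(genotype)
    rec = truth.recruitment
    gamma, sig_sb, sig_j = (rec.germination, rec.seedbank_survival,
                            rec.germinant_survival)
    E = (float(env_fixed[0]), float(env_fixed[1]))
    size = rng.normal(rec.recruit_size_mean, rec.recruit_size_sd, size=n0)
    bolting = (rng.random(n0) < initial_bolting).astype(int)
    bank = 0
    pop = [n0 + bank]
    for year in range(1, horizon + 1):
        n = size.size
        # reproduction by bolting plants at the current census
        seeds_total = 0
        if n:
            is_bolt = bolting == 1
            if is_bolt.any():
                zb = size[is_bolt]
                r = predict_rate(ms.fits["r"], zb, E)
                f = np.maximum(predict_rate(ms.fits["f"], zb, E), 0.0)
                reproducing = rng.random(zb.size) < r
                seeds_total = int(rng.poisson(f[reproducing]).sum())
        # fates of this year's seeds
        new_recruits = rng.binomial(seeds_total, gamma * sig_j)
        rest = seeds_total - new_recruits
        to_bank = rng.binomial(rest, (1.0 - gamma) * sig_sb
                               / max(1.0 - gamma * sig_j, 1e-12))
        # seed-bank dynamics
        germ = rng.binomial(bank, gamma)
        bank_recruits = rng.binomial(germ, sig_j)
        bank = rng.binomial(bank - germ, sig_sb) + to_bank
        # plant survival, bolting transition, growth
        if n:
            surv = rng.random(n) < predict_rate(ms.fits["s"], size, E)
            size, bolting = size[surv], bolting[surv]
        if size.size:
            b_prob = np.where(bolting == 1,
                              predict_rate(ms.fits["b1"], size, E),
                              predict_rate(ms.fits["b0"], size, E))
            bolt_next = (rng.random(size.size) < b_prob).astype(int)
            mu = np.empty(size.size)
            sd = np.empty(size.size)
            for qf in (0, 1):
                for qt in (0, 1):
                    sel = (bolting == qf) & (bolt_next == qt)
                    if sel.any():
                        mu[sel] = predict_rate(ms.fits[f"g{qf}{qt}"],
                                               size[sel], E)
                        sd[sel] = np.sqrt(predict_rate(ms.fits[f"v{qf}{qt}"],
                                                       size[sel], E))
            size = rng.normal(mu, sd)
            bolting = bolt_next
        n_recruit = new_recruits + bank_recruits
        if n_recruit:
            size = np.concatenate([size, rng.normal(rec.recruit_size_mean,
                                                    rec.recruit_size_sd,
                                                    n_recruit)])
            bolting = np.concatenate([bolting, np.zeros(n_recruit, dtype=int)])
        total = size.size + bank
        pop.append(total)
        if total == 0:
            if year <= burn_in:
                raise ExtinctionError(
                    f"lineage extinct in year {year}, before burn-in ended",
                    year=year)
            raise ExtinctionError(
                f"lineage extinct in year {year}; growth rate undefined",
                year=year)
    return LineageTrajectory(pop_sizes=np.asarray(pop, dtype=float),
                             burn_in=burn_in)


# ---------------------------------------------------------------------------
# Census I/O
# ---------------------------------------------------------------------------

def write_census(table: pd.DataFrame, path) -> None:
    """Write a census table as UTF-8 CSV, one transition per row.

    Floats are written at full precision (%.17g) so that reading the file
    back reproduces the in-memory table bit for bit.
    """
    missing = [c for c in CENSUS_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"census table missing columns {missing}",
                          columns=missing)
    table.to_csv(path, index=False, float_format="%.17g")


def read_census(path) -> pd.DataFrame:
    """Read a census CSV; unknown extra columns are preserved.

    Raises :class:`SchemaError` naming any missing mandatory column.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CENSUS_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"census file missing mandatory columns {missing}",
                          columns=missing)
    return table
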