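"""Bivariate driver grid, lambda surfaces, and parametric bootstrap.

The environment grid spans soil moisture (volumetric water content, %) from 0
to 1.25x the maximum observed value in 25 equal-width bins, and herbivory
(% leaf area removed) from 0 to 100% in 25 log-width bins (damage data are
heavily right-skewed, so log-width bins resolve the common low-damage range).
Lambda is evaluated at every cell for each genotype; parameter uncertainty is
propagated by drawing vital-rate coefficient vectors from their estimated
multivariate-normal sampling distributions (independently across the separate
regressions) and recomputing the whole surface per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import KernelError, PolydemError
from .kernel import SizeMesh, build_kernel, dominant_eigen
from .vital_rates import RATE_KEYS, GenotypeModelSet

DEFAULT_N_BINS = 25
DEFAULT_BOOTSTRAP_B = 1000


@dataclass(frozen=True)
class DriverGrid:
    """Cell-value axes of the moisture x herbivory grid.

    Cells are ordered moisture-major: ``cell = i_moisture * len(herbivory)
    + i_herbivory``.
    """

    moisture: np.ndarray     # strictly increasing, constant spacing
    herbivory: np.ndarray    # strictly increasing, widening spacing

    @property
    def n_cells(self) -> int:
        return len(self.moisture) * len(self.herbivory)

    def cells(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (moisture, herbivory) coordinates of every cell."""
        M, H = np.meshgrid(self.moisture, self.herbivory, indexing="ij")
        return M.ravel(), H.ravel()


def make_grid(max_obs_moisture: float, n_bins: int = DEFAULT_N_BINS,
              herbivory_floor: float = 0.5) -> DriverGrid:
    """Build the driver grid.

    Moisture cell values are centres of ``n_bins`` equal bins on
    ``[0, 1.25 * max_obs_moisture]``. Herbivory bin edges are {0} followed by
    a geometric sequence from ``herbivory_floor`` to 100; cell values are the
    geometric midpoints of their edges. The zero-edge cell continues the same
    geometric sequence (its value is ``herbivory_floor / sqrt(ratio)``), so
    cell values form an exact geometric progression and cell-to-cell spacing
    is strictly increasing.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if max_obs_moisture <= 0:
        raise ValueError("max_obs_moisture must be > 0")
    if not 0 < herbivory_floor < 100:
        raise ValueError("herbivory_floor must be in (0, 100)")
    upper = 1.25 * max_obs_moisture
    width = upper / n_bins
    moisture = (np.arange(n_bins) + 0.5) * width
    edges = np.concatenate([[0.0],
                            np.geomspace(herbivory_floor, 100.0, n_bins)])
    ratio = (100.0 / herbivory_floor) ** (1.0 / (n_bins - 1))
    herb = np.sqrt(edges[1:-1] * edges[2:])
    herbivory = np.concatenate([[herbivory_floor / np.sqrt(ratio)], herb])
    return DriverGrid(moisture=moisture, herbivory=herbivory)


@dataclass
class LambdaSurface:
    """Lambda per grid cell for one genotype (flat, moisture-major order)."""

    genotype: str
    grid: DriverGrid
    values: np.ndarray
    provenance: str = "point"

    def as_frame(self) -> pd.DataFrame:
        M, H = self.grid.cells()
        return pd.DataFrame({"genotype": self.genotype, "moisture": M,
                             "herbivory": H, "lam": self.values,
                             "provenance": self.provenance})


def evaluate_surface(modelset: GenotypeModelSet, grid: DriverGrid,
                     mesh: SizeMesh, provenance: str = "point") -> LambdaSurface:
    """Lambda at every grid cell (dominant eigenvalue of the cell's kernel)."""
    M, H = grid.cells()
    values = np.empty(grid.n_cells)
    for i, (mi, hi) in enumerate(zip(M, H)):
        try:
            values[i] = dominant_eigen(build_kernel(modelset, (mi, hi), mesh))
        except (KernelError, PolydemError) as exc:
            raise KernelError(
                f"lambda failed at cell (moisture={mi:.3g}, "
                f"herbivory={hi:.3g}): {exc}") from exc
    if not np.all(np.isfinite(values)) or values.min() < 0:
        raise KernelError("surface contains non-finite or negative lambda")
    return LambdaSurface(genotype=modelset.genotype, grid=grid,
                         values=values, provenance=provenance)


@dataclass
class BootstrapEnsemble:
    """B x n_cells lambda draws for one genotype, plus percentile summaries."""

    genotype: str
    grid: DriverGrid
    draws: np.ndarray            # (B, n_cells)
    seed: int

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[1] != self.grid.n_cells:
            raise ValueError("draws must be (B, n_cells)")

    @property
    def B(self) -> int:
        return self.draws.shape[0]

    def percentiles(self, q=(2.5, 50.0, 97.5)) -> np.ndarray:
        return np.percentile(self.draws, q, axis=0)

    def summary_frame(self) -> pd.DataFrame:
        lo, med, hi = self.percentiles()
        M, H = self.grid.cells()
        return pd.DataFrame({"genotype": self.genotype, "moisture": M,
                             "herbivory": H, "lam_lo": lo, "lam_median": med,
                             "lam_hi": hi})


def _coef_samplers(modelset: GenotypeModelSet):
    """Per-rate covariance factors for multivariate-normal coefficient draws."""
    samplers = {}
    for key in RATE_KEYS:
        fit = modelset.fits[key]
        cov = 0.5 * (fit.cov + fit.cov.T)
        if np.allclose(cov, 0.0):
            samplers[key] = (fit.params, None)
            continue
        w, V = np.linalg.eigh(cov)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise KernelError(
                f"coefficient covariance for vital rate '{key}' is not "
                f"positive semi-definite (min eigenvalue {w.min():.3g})")
        factor = V * np.sqrt(np.clip(w, 0.0, None))
        samplers[key] = (fit.params, factor)
    return samplers


def draw_modelset(modelset: GenotypeModelSet, rng: np.random.Generator,
                  samplers=None) -> GenotypeModelSet:
    """One parametric-bootstrap replicate of the model set.

    Coefficients are drawn from Normal(beta_hat, Sigma_hat) independently per
    vital rate; recruitment constants are held fixed.
    """
    samplers = samplers or _coef_samplers(modelset)
    fits = {}
    for key in RATE_KEYS:
        fit = modelset.fits[key]
        mean, factor = samplers[key]
        if factor is None:
            params = mean
        else:
            params = mean + factor @ rng.standard_normal(len(mean))
        fits[key] = replace(fit, params=params, selection_table=None)
    return GenotypeModelSet(genotype=modelset.genotype, fits=fits,
                            recruitment=modelset.recruitment,
                            seed_calibration=modelset.seed_calibration)


def bootstrap_ensemble(modelset: GenotypeModelSet, grid: DriverGrid,
                       mesh: SizeMesh, B: int = DEFAULT_BOOTSTRAP_B,
                       seed: int = 0, cells: np.ndarray | None = None,
                       ) -> BootstrapEnsemble:
    """Parametric-bootstrap lambda ensemble over the grid.

    ``cells`` optionally restricts evaluation to a subset of flat cell
    indices (other cells are reported as NaN); this keeps coverage
    simulations affordable without changing the estimator.
    """
    rng = np.random.default_rng(seed)
    samplers = _coef_samplers(modelset)
    M, H = grid.cells()
    idx = np.arange(grid.n_cells) if cells is None else np.asarray(cells)
    draws = np.full((B, grid.n_cells), np.nan)
    for b in range(B):
        ms_b = draw_modelset(modelset, rng, samplers)
        for i in idx:
            draws[b, i] = dominant_eigen(
                build_kernel(ms_b, (M[i], H[i]), mesh))
    return BootstrapEnsemble(genotype=modelset.genotype, grid=grid,
                             draws=draws, seed=seed)
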