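"""Driver contributions to lambda, genotype fitness differences, and the
polymorphism-maintenance criteria over environment space.

* **Driver contributions** quantify how much of a driver's effect on lambda
  flows through each vital rate: the driver is pinned at a reference value in
  one vital rate at a time and the proportional change in lambda, averaged
  over grid cells, is reported. Pairs where model selection did not retain
  the driver are structural zeros.
* **Fitness differences** pair bootstrap replicates by index across genotypes
  and flag cells where the 95% percentile interval of (lambda_MM - lambda_BB)
  excludes zero.
* **Polymorphism criteria**: Criterion I - both genotypes can persist at or
  above replacement (upper 95% bound of lambda >= 1); Criterion II - the
  genotype fitness difference is statistically indistinguishable from zero;
  Criterion III - both, marking putatively polymorphic environments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kernel import SizeMesh
from .surface import BootstrapEnsemble, DriverGrid, evaluate_surface
from .vital_rates import RATE_KEYS, GenotypeModelSet

DRIVERS = ("moisture", "herbivory")
_DRIVER_SYMBOL = {"moisture": "M", "herbivory": "H"}


def _uses_driver(fit, driver: str) -> bool:
    symbol = _DRIVER_SYMBOL[driver]
    return any(symbol in term.split(":") for term in fit.terms)


def _pin_driver(modelset: GenotypeModelSet, keys, driver: str,
                reference: float) -> GenotypeModelSet:
    symbol = _DRIVER_SYMBOL[driver]
    fits = dict(modelset.fits)
    for key in keys:
        fit = fits[key]
        overrides = dict(fit.driver_overrides)
        overrides[symbol] = float(reference)
        fits[key] = replace(fit, driver_overrides=overrides)
    return GenotypeModelSet(genotype=modelset.genotype, fits=fits,
                            recruitment=modelset.recruitment,
                            seed_calibration=modelset.seed_calibration)


def driver_contribution(modelset: GenotypeModelSet, grid: DriverGrid,
                        mesh: SizeMesh, driver: str, vital_rate: str,
                        reference: float,
                        full_surface: np.ndarray | None = None) -> float:
    """Proportional contribution c of ``driver`` to lambda via ``vital_rate``.

    c = mean over grid cells of (lambda_full - lambda_pinned) / lambda_full,
    where the pinned model set evaluates ``driver`` at ``reference`` in the
    named vital rate only. If the driver was not retained in that rate's
    selected model the contribution is exactly 0 (structural zero).
    """
    if vital_rate not in RATE_KEYS:
        raise ValueError(f"unknown vital rate key {vital_rate!r}")
    if driver not in DRIVERS:
        raise ValueError(f"unknown driver {driver!r}")
    if not _uses_driver(modelset.fits[vital_rate], driver):
        return 0.0
    if full_surface is None:
        full_surface = evaluate_surface(modelset, grid, mesh).values
    pinned = _pin_driver(modelset, [vital_rate], driver, reference)
    mod_surface = evaluate_surface(pinned, grid, mesh).values
    return float(np.mean((full_surface - mod_surface) / full_surface))


def contribution_table(modelsets: dict[str, GenotypeModelSet],
                       grid: DriverGrid, mesh: SizeMesh,
                       references: dict[str, float]) -> pd.DataFrame:
    """Per genotype x vital rate x driver contribution table.

    ``references`` maps driver name to the value at which its effects are
    removed (typically the observed mean).
    """
    rows = []
    for genotype, ms in modelsets.items():
        full = evaluate_surface(ms, grid, mesh).values
        for key in RATE_KEYS:
            row = {"genotype": genotype, "vital_rate": key}
            for driver in DRIVERS:
                row[f"c_{driver}"] = driver_contribution(
                    ms, grid, mesh, driver, key, references[driver],
                    full_surface=full)
                row[f"{driver}_retained"] = _uses_driver(ms.fits[key], driver)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class FitnessDifference:
    """Per-cell bootstrap summary of lambda_MM - lambda_BB."""

    grid: DriverGrid
    median: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    significant: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        M, H = self.grid.cells()
        return pd.DataFrame({"moisture": M, "herbivory": H,
                             "delta_median": self.median,
                             "delta_lo": self.lo, "delta_hi": self.hi,
                             "significant": self.significant})


def fitness_difference(ens_mm: BootstrapEnsemble,
                       ens_bb: BootstrapEnsemble) -> FitnessDifference:
    """Replicate-paired genotype fitness difference with 95% percentile CI."""
    if ens_mm.B != ens_bb.B:
        raise ValueError("ensembles have different bootstrap sizes")
    if (len(ens_mm.grid.moisture) != len(ens_bb.grid.moisture)
            or not np.allclose(ens_mm.grid.moisture, ens_bb.grid.moisture)
            or not np.allclose(ens_mm.grid.herbivory, ens_bb.grid.herbivory)):
        raise ValueError("ensembles were evaluated on different grids")
    delta = ens_mm.draws - ens_bb.draws
    lo, med, hi = np.percentile(delta, (2.5, 50.0, 97.5), axis=0)
    significant = (lo > 0) | (hi < 0)
    return FitnessDifference(grid=ens_mm.grid, median=med, lo=lo, hi=hi,
                             significant=significant)


@dataclass
class PolymorphismMap:
    """Per-cell persistence and polymorphism flags plus summary fractions."""

    grid: DriverGrid
    persist: dict[str, np.ndarray]   # genotype -> bool per cell
    criterion1: np.ndarray           # both genotypes persist
    criterion2: np.ndarray           # fitness difference not significant
    criterion3: np.ndarray           # criterion1 & criterion2
    fractions: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        M, H = self.grid.cells()
        out = pd.DataFrame({"moisture": M, "herbivory": H})
        for g, flags in self.persist.items():
            out[f"persist_{g}"] = flags
        out["criterion1"] = self.criterion1
        out["criterion2"] = self.criterion2
        out["criterion3"] = self.criterion3
        return out


def classify_cells(ens_mm: BootstrapEnsemble,
                   ens_bb: BootstrapEnsemble) -> PolymorphismMap:
    """Apply the polymorphism criteria cell by cell.

    A genotype persists in a cell when the upper bound of its bootstrap 95%
    interval of lambda reaches replacement (>= 1).
    """
    diff = fitness_difference(ens_mm, ens_bb)
    persist = {}
    for ens in (ens_bb, ens_mm):
        hi = np.percentile(ens.draws, 97.5, axis=0)
        persist[ens.genotype] = hi >= 1.0
    crit1 = persist[ens_bb.genotype] & persist[ens_mm.genotype]
    crit2 = ~diff.significant
    crit3 = crit1 & crit2
    n = ens_mm.grid.n_cells
    fractions = {
        f"persist_{ens_bb.genotype}": float(persist[ens_bb.genotype].mean()),
        f"persist_{ens_mm.genotype}": float(persist[ens_mm.genotype].mean()),
        "criterion1": float(crit1.sum() / n),
        "criterion2": float(crit2.sum() / n),
        "criterion3": float(crit3.sum() / n),
    }
    return PolymorphismMap(grid=ens_mm.grid, persist=persist, criterion1=crit1,
                           criterion2=crit2, criterion3=crit3,
                           fractions=fractions)


def overlay_ambient(pmap: PolymorphismMap, ambient) -> pd.DataFrame:
    """Locate ambient field conditions in polymorphism space.

    ``ambient`` is an iterable of mappings with keys ``year``,
    ``moisture_mean``, ``moisture_sd``, ``herbivory_mean``, ``herbivory_sd``.
    Each point is mapped to its nearest grid cell; the report flags whether
    that cell is putatively polymorphic (Criterion III) and gives the
    distance, in cells along each axis, to the nearest non-polymorphic cell
    (NaN if none in that row/column).
    """
    ambient = list(ambient)
    if not ambient:
        raise ValueError("ambient list is empty")
    grid = pmap.grid
    nm, nh = len(grid.moisture), len(grid.herbivory)
    crit3 = pmap.criterion3.reshape(nm, nh)
    rows = []
    for pt in ambient:
        mo, he = float(pt["moisture_mean"]), float(pt["herbivory_mean"])
        out_of_range = not (grid.moisture[0] <= mo <= grid.moisture[-1]
                            and grid.herbivory[0] <= he <= grid.herbivory[-1])
        i = int(np.argmin(np.abs(grid.moisture - mo)))
        j = int(np.argmin(np.abs(grid.herbivory - he)))
        inside = bool(crit3[i, j])
        non_poly_m = np.flatnonzero(~crit3[:, j])
        non_poly_h = np.flatnonzero(~crit3[i, :])
        dist_m = float(np.min(np.abs(non_poly_m - i))) if len(non_poly_m) else np.nan
        dist_h = float(np.min(np.abs(non_poly_h - j))) if len(non_poly_h) else np.nan
        rows.append({"year": pt.get("year"), "moisture_mean": mo,
                     "herbivory_mean": he,
                     "moisture_sd": float(pt.get("moisture_sd", np.nan)),
                     "herbivory_sd": float(pt.get("herbivory_sd", np.nan)),
                     "cell_moisture": float(grid.moisture[i]),
                     "cell_herbivory": float(grid.herbivory[j]),
                     "out_of_range": out_of_range, "inside_polymorphic": inside,
                     "dist_to_monomorphic_moisture_cells": dist_m,
                     "dist_to_monomorphic_herbivory_cells": dist_h})
    return pd.DataFrame(rows)
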