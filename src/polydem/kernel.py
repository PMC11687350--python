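"""Discretised integral projection model with a seed bank and bolting states.

The population state is {seed bank} U {log size x bolting state}. The kernel
is a square non-negative matrix of order ``2m + 1``:

* index 0: seed bank;
* indices 1..m: non-bolting plants in the m size bins;
* indices m+1..2m: bolting plants in the same bins.

Annual transitions (census to census, environment E = (moisture, herbivory)):

* bank -> bank: ``sigma_sb * (1 - gamma)`` (a seed neither germinates nor
  dies in the bank);
* bank -> non-bolting recruit: ``gamma * sigma_j * phi_R(z')`` where phi_R is
  the Normal(recruit_size_mean, recruit_size_sd^2) recruit-size density;
* plant (z, q) -> plant (z', q'): ``s(z,E) * P(q->q'|z,E) * G_qq'(z'|z,E)``
  with ``P(q->1) = b_q(z,E)`` and ``G`` the Normal growth density with mean
  ``g_qq'(z,E)`` and variance ``v_qq'(z,E)`` (floored);
* bolting plant (z, 1) -> seed bank: ``r(z,E) * f(z,E) * (1-gamma) * sigma_sb``;
* bolting plant (z, 1) -> recruit: ``r(z,E) * f(z,E) * gamma * sigma_j * phi_R``.

Only bolting plants reproduce; negative predicted seed numbers are truncated
to zero. Size densities are integrated over bins by normal-CDF differences,
and out-of-range tail mass is added to the boundary bins (eviction handling),
so the survival/growth block conserves survival mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .exceptions import KernelError
from .vital_rates import GenotypeModelSet, predict_rate

#: Default number of size bins.
DEFAULT_M = 100


@dataclass(frozen=True)
class SizeMesh:
    """Midpoint mesh over log size."""

    m: int
    lower: float
    upper: float

    def __post_init__(self):
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("mesh bounds must be finite")
        if not self.lower < self.upper:
            raise ValueError("mesh lower bound must be below upper bound")
        if self.m < 2:
            raise ValueError("mesh needs at least 2 bins")

    @property
    def dz(self) -> float:
        return (self.upper - self.lower) / self.m

    @property
    def midpoints(self) -> np.ndarray:
        return self.lower + (np.arange(self.m) + 0.5) * self.dz

    @property
    def edges(self) -> np.ndarray:
        return self.lower + np.arange(self.m + 1) * self.dz


def make_mesh(size_min: float, size_max: float, m: int = DEFAULT_M,
              pad: float = 1.0) -> SizeMesh:
    """Mesh spanning the data range extended by ``pad`` on each side."""
    if not (np.isfinite(size_min) and np.isfinite(size_max)):
        raise ValueError("size range must be finite")
    if not size_min < size_max:
        raise ValueError("size_min must be below size_max")
    return SizeMesh(m=int(m), lower=float(size_min - pad),
                    upper=float(size_max + pad))


@dataclass
class KernelMatrix:
    """Assembled kernel with its provenance stamp."""

    matrix: np.ndarray
    mesh: SizeMesh
    environment: tuple[float, float]
    genotype: str

    @property
    def order(self) -> int:
        return self.matrix.shape[0]


def growth_density(z_to, z_from, q_from: int, q_to: int,
                   modelset: GenotypeModelSet, E) -> np.ndarray:
    """Normal growth density in ``z_to`` for one state transition.

    Mean from ``g_{q_from q_to}``, variance from ``v_{q_from q_to}``
    (floored). Integrates to ~1 over an unbounded size domain.
    """
    key = f"{q_from}{q_to}"
    mu = predict_rate(modelset.fits["g" + key], z_from, E)
    var = predict_rate(modelset.fits["v" + key], z_from, E)
    sd = np.sqrt(var)
    z_to = np.asarray(z_to, dtype=float)
    return np.exp(-0.5 * ((z_to - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def _binned_normal(mesh: SizeMesh, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Column-stochastic bin masses of Normal(mu_j, sd_j) over the mesh.

    Returns an (m, n_col) matrix of CDF differences; tail mass outside the
    mesh is evicted to the corresponding boundary bin, so each column sums
    to 1 exactly.
    """
    mu = np.atleast_1d(np.asarray(mu, float))
    sd = np.atleast_1d(np.asarray(sd, float))
    zscores = (mesh.edges[:, None] - mu[None, :]) / sd[None, :]
    cdf = ndtr(zscores)                      # (m+1, n_col)
    mass = np.diff(cdf, axis=0)              # (m, n_col)
    mass[0, :] += cdf[0, :]                  # lower tail -> first bin
    mass[-1, :] += 1.0 - cdf[-1, :]          # upper tail -> last bin
    return mass


def build_kernel(modelset: GenotypeModelSet, E, mesh: SizeMesh) -> KernelMatrix:
    """Assemble the (2m+1)-order kernel for one genotype and environment."""
    m = mesh.m
    z = mesh.midpoints
    rec = modelset.recruitment
    gamma, sig_sb, sig_j = (rec.germination, rec.seedbank_survival,
                            rec.germinant_survival)

    def rate(key, zz):
        vals = predict_rate(modelset.fits[key], zz, E)
        if not np.all(np.isfinite(vals)):
            raise KernelError(f"non-finite prediction from vital rate '{key}' "
                              f"at E={tuple(E)}")
        return vals

    s = rate("s", z)
    b = {0: rate("b0", z), 1: rate("b1", z)}
    K = np.zeros((2 * m + 1, 2 * m + 1))

    # Seed-bank column: persist in the bank or emerge as a non-bolting recruit.
    phi_R = _binned_normal(mesh, np.array([rec.recruit_size_mean]),
                           np.array([rec.recruit_size_sd]))[:, 0]
    K[0, 0] = sig_sb * (1.0 - gamma)
    K[1:m + 1, 0] = gamma * sig_j * phi_R

    # Survival/growth/bolting block.
    for q_from in (0, 1):
        col = slice(1 + q_from * m, 1 + (q_from + 1) * m)
        for q_to in (0, 1):
            row = slice(1 + q_to * m, 1 + (q_to + 1) * m)
            key = f"{q_from}{q_to}"
            mu = rate("g" + key, z)
            sd = np.sqrt(rate("v" + key, z))
            G = _binned_normal(mesh, mu, sd)          # (m, m), columns sum 1
            p_state = b[q_from] if q_to == 1 else 1.0 - b[q_from]
            K[row, col] += G * (s * p_state)[None, :]

    # Fecundity from bolting plants: seeds either enter the bank or emerge
    # as next year's non-bolting recruits.
    seeds = np.maximum(rate("r", z) * np.maximum(rate("f", z), 0.0), 0.0)
    bolt_cols = slice(m + 1, 2 * m + 1)
    K[0, bolt_cols] = seeds * (1.0 - gamma) * sig_sb
    K[1:m + 1, bolt_cols] += np.outer(phi_R, seeds * gamma * sig_j)

    if not np.all(np.isfinite(K)):
        raise KernelError("kernel assembly produced non-finite entries")
    if K.min() < 0:
        raise KernelError("kernel assembly produced negative entries")
    return KernelMatrix(matrix=K, mesh=mesh, environment=(float(E[0]), float(E[1])),
                        genotype=modelset.genotype)


def export_kernel(K: KernelMatrix, path) -> None:
    """Write a kernel as a CSV matrix plus a JSON header sidecar.

    The sidecar (``<path>.json``) records the mesh, environment and genotype
    so an exported kernel can be interpreted without the run that made it.
    """
    import json
    from pathlib import Path

    path = Path(path)
    np.savetxt(path, K.matrix, delimiter=",", fmt="%.17g")
    header = {"genotype": K.genotype,
              "environment": {"moisture": K.environment[0],
                              "herbivory": K.environment[1]},
              "mesh": {"m": K.mesh.m, "lower": K.mesh.lower,
                       "upper": K.mesh.upper},
              "layout": "row/col 0 = seed bank; 1..m non-bolting size bins; "
                        "m+1..2m bolting size bins"}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(header, indent=1))


def dominant_eigen(K, tol: float = 1e-10, max_iter: int = 20000) -> float:
    """Dominant eigenvalue (spectral radius) of a non-negative matrix.

    Shifted power iteration (the shift breaks periodic cycling; for a
    non-negative matrix the spectral radius is the Perron root, so the shift
    just translates it). Falls back to a dense eigendecomposition if the
    iteration has not met ``tol`` (relative residual) within ``max_iter``.
    """
    A = K.matrix if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise KernelError("dominant_eigen expects a square matrix")
    if not np.all(np.isfinite(A)):
        raise KernelError("matrix has non-finite entries")
    if A.min() < 0:
        raise KernelError("matrix has negative entries")
    n = A.shape[0]
    scale = A.max()
    if scale == 0.0:
        return 0.0
    shift = 0.1 * scale
    v = np.full(n, 1.0 / n)
    lam_prev = np.inf
    for _ in range(max_iter):
        w = A @ v + shift * v
        norm = w.sum()                      # w >= 0, so this is the 1-norm
        if norm == 0.0:
            return 0.0
        lam = norm / v.sum()
        v = w / norm
        # cheap pre-check on the eigenvalue estimate before paying for the
        # residual of the unshifted problem
        if abs(lam - lam_prev) <= 0.01 * tol * lam:
            resid = np.max(np.abs(A @ v - (lam - shift) * v))
            if resid <= tol * max(lam - shift, tol):
                return float(lam - shift)
        lam_prev = lam
    # dense fallback; for non-negative matrices the spectral radius is an
    # eigenvalue (Perron-Frobenius), so report max |eigenvalue|
    eigvals = np.linalg.eigvals(A)
    return float(np.max(np.abs(eigvals)))
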