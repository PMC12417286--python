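"""Synthetic pinwheel orientation-preference maps and their diagnostics.

The generator superposes half-winding orientation singularities ("pinwheels")
at random positions: the preferred orientation at a site is

    phi(x) = ( sum_j s_j * arg(x - c_j) ) mod pi,    s_j = +-1/2 winding,

so that traversing a loop around a single center advances the orientation by
+-pi (half winding).  Elongation is assigned by a radial profile of the
distance d to the nearest center, with kappa(0) = 1 (isotropic at the center,
eccentricity 1) increasing outwards — the configuration in which orientation
tuning is broadest at the pinwheel centers and sharpens towards the periphery.

Per-site diagnostics mirror what an experimenter would tabulate from joint
measurements: distance to the nearest pinwheel center, receptive-field
eccentricity, local orientation homogeneity H (double-angle circular resultant
of neighbouring preferences), and the tuning-selectivity statistic |R| implied
by the site's elongation.  The module tests measurement logic, not map
development: no Kohonen/elastic-net dynamics are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedMeasureError
from .resultant import resultant_power

__all__ = [
    "CorticalMap",
    "generate_pinwheel_map",
    "orientation_homogeneity",
    "measure_map",
    "loop_winding",
]


@dataclass
class CorticalMap:
    """Lattice of sites with preferred orientation in [0, pi), elongation
    kappa >= 1 and eccentricity 1/kappa, plus the pinwheel centers with their
    winding signs (+-1/2)."""

    orientation: np.ndarray
    kappa: np.ndarray
    centers: np.ndarray
    signs: np.ndarray

    def __post_init__(self) -> None:
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.orientation.shape != self.kappa.shape:
            raise InvalidParameterError("orientation and kappa grids must match")
        if np.any(self.kappa <= 0):
            raise InvalidParameterError("kappa must be positive everywhere")

    @property
    def grid_size(self) -> int:
        return self.orientation.shape[0]

    @property
    def eccentricity(self) -> np.ndarray:
        return 1.0 / self.kappa


def _linear_profile(d: np.ndarray, d_max: float, kappa_max: float) -> np.ndarray:
    return 1.0 + (kappa_max - 1.0) * d / d_max


def generate_pinwheel_map(grid_size: int = 64,
                          n_pinwheels: int = 4,
                          kappa_profile: str | Callable = "linear",
                          seed: int | None = None,
                          kappa_max: float = 8.0,
                          centers: np.ndarray | None = None,
                          signs: np.ndarray | None = None,
                          min_separation: float = 2.0,
                          max_attempts: int = 200) -> CorticalMap:
    """Generate a synthetic pinwheel map on a ``grid_size x grid_size`` lattice.

    Centers (continuous positions, lattice units) and winding signs are drawn
    under the seed unless supplied explicitly; draws with centers closer than
    ``min_separation`` lattice steps are rejected and regenerated.
    ``kappa_profile`` maps distance to the nearest center to kappa >= 1 with
    kappa(0) = 1; the default linear profile reaches ``kappa_max`` at the
    farthest site.  Site coordinates are lattice indices (x, y) in
    ``{0, ..., grid_size - 1}``.
    """
    if grid_size < 16:
        raise InvalidParameterError("grid_size must be at least 16")
    rng = np.random.default_rng(seed)

    if centers is None:
        for _ in range(max_attempts):
            cand = rng.uniform(0.0, grid_size - 1.0, size=(n_pinwheels, 2))
            if n_pinwheels == 1:
                centers = cand
                break
            dists = np.linalg.norm(cand[:, None, :] - cand[None, :, :], axis=-1)
            np.fill_diagonal(dists, np.inf)
            if dists.min() >= min_separation:
                centers = cand
                break
        else:
            raise InvalidParameterError(
                "could not place pinwheel centers at the required separation"
            )
    else:
        centers = np.asarray(centers, dtype=float).reshape(-1, 2)
        if len(centers) > 1:
            dists = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
            np.fill_diagonal(dists, np.inf)
            if dists.min() < min_separation:
                raise InvalidParameterError("pinwheel centers too close together")
    if signs is None:
        signs = rng.choice([-0.5, 0.5], size=len(centers))
    else:
        signs = np.asarray(signs, dtype=float)
        if not np.all(np.isin(signs, [-0.5, 0.5])):
            raise InvalidParameterError("winding signs must be +-1/2")

    xs = np.arange(grid_size, dtype=float)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    phase = np.zeros_like(gx)
    for (cx, cy), s in zip(centers, signs):
        phase += s * np.arctan2(gy - cy, gx - cx)
    orientation = np.mod(phase, math.pi)

    d = np.full_like(gx, np.inf)
    for cx, cy in centers:
        d = np.minimum(d, np.hypot(gx - cx, gy - cy))
    d_max = float(d.max())
    if callable(kappa_profile):
        kappa = np.asarray(kappa_profile(d, d_max), dtype=float)
    elif kappa_profile == "linear":
        kappa = _linear_profile(d, d_max, kappa_max)
    else:
        raise InvalidParameterError(f"unknown kappa profile {kappa_profile!r}")
    if np.any(kappa < 1.0 - 1e-12):
        raise InvalidParameterError("kappa profile must stay >= 1")
    return CorticalMap(orientation=orientation, kappa=kappa,
                       centers=np.asarray(centers), signs=np.asarray(signs))


def _double_angle_resultant(phis: np.ndarray) -> float:
    return float(np.abs(np.mean(np.exp(2j * phis))))


def orientation_homogeneity(cmap: CorticalMap, site: tuple[int, int],
                            radius: float = 3.0) -> float:
    """Homogeneity H of orientation preference around a site.

    H is the modulus of the circular mean of the neighbours' unit phasors
    under the double-angle mapping ``phi -> 2 phi`` (which identifies opposite
    orientations): 1 for locally uniform preference, 0 for fully dispersed.
    The site itself is excluded.
    """
    if radius < 1:
        raise InvalidParameterError("radius must be at least one lattice step")
    i, j = site
    n = cmap.grid_size
    r = int(math.ceil(radius))
    i0, i1 = max(0, i - r), min(n, i + r + 1)
    j0, j1 = max(0, j - r), min(n, j + r + 1)
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    dist = np.hypot(ii - i, jj - j)
    mask = (dist <= radius) & (dist > 0)
    if not mask.any():
        raise UndefinedMeasureError("no neighbours within the given radius")
    return _double_angle_resultant(cmap.orientation[i0:i1, j0:j1][mask])


def measure_map(cmap: CorticalMap, lam: float = 2.0,
                radius: float = 3.0) -> pd.DataFrame:
    """Per-site joint measurement table.

    Columns: site id, lattice coordinates, distance ``d`` to the nearest
    pinwheel center, ``kappa``, ``eccentricity`` (1/kappa), orientation
    preference, homogeneity ``H`` within ``radius``, and ``selectivity`` (the
    resultant modulus |R| of the power-family tuning curve with exponent
    ``lam`` at the site's kappa).  Together with the map's 2-D grids this
    provides the scatter data for selectivity-vs-eccentricity,
    homogeneity-vs-eccentricity and eccentricity-vs-pinwheel-distance plots.
    """
    n = cmap.grid_size
    gx, gy = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float),
                         indexing="ij")
    d = np.full_like(gx, np.inf)
    for cx, cy in cmap.centers:
        d = np.minimum(d, np.hypot(gx - cx, gy - cy))

    hom = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            hom[i, j] = orientation_homogeneity(cmap, (i, j), radius)

    selectivity = resultant_power(lam, cmap.kappa.ravel()).reshape(n, n)

    return pd.DataFrame({
        "site": np.arange(n * n),
        "x": gx.ravel().astype(int),
        "y": gy.ravel().astype(int),
        "distance": d.ravel(),
        "kappa": cmap.kappa.ravel(),
        "eccentricity": cmap.eccentricity.ravel(),
        "orientation_rad": cmap.orientation.ravel(),
        "homogeneity": hom.ravel(),
        "selectivity": selectivity.ravel(),
    })


def loop_winding(cmap: CorticalMap, center: tuple[float, float],
                 radius: float = 5.0, n_points: int = 256) -> float:
    """Total orientation change around a closed loop (sum of increments
    wrapped to (-pi/2, pi/2]); +-pi when the loop encloses exactly one
    half-winding singularity."""
    cx, cy = center
    alphas = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    xi = np.clip(np.rint(cx + radius * np.cos(alphas)).astype(int), 0,
                 cmap.grid_size - 1)
    yi = np.clip(np.rint(cy + radius * np.sin(alphas)).astype(int), 0,
                 cmap.grid_size - 1)
    phis = cmap.orientation[xi, yi]
    phis = np.append(phis, phis[0])  # close the loop exactly
    incs = np.diff(phis)
    incs = (incs + math.pi / 2) % math.pi - math.pi / 2
    return float(incs.sum())
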