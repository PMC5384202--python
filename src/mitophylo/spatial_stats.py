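"""Population frequencies, gene diversity and kriged frequency surfaces.

Ordinary kriging interpolates haplogroup frequencies onto a geographic
grid: at every grid node the weights w solve

    [ Gamma  1 ] [ w ]   [ gamma_0 ]
    [ 1^T    0 ] [ m ] = [ 1       ]

with Gamma the semivariogram matrix between observations and gamma_0 the
semivariances to the target, so that sum(w) = 1 (unbiasedness) and the
interpolator is exact at the data points when the nugget is zero.
Distances are great-circle by default (degrees in, km out); planar
distance is available for synthetic tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

VARIOGRAM_MODELS = ("spherical", "exponential", "linear")


# ---------------------------------------------------------------------------
# frequency tables and diversity


def tabulate_frequencies(
    assignments: Mapping[str, str],
    metadata: pd.DataFrame,
    clade: str,
    include: set[str] | None = None,
    min_n: int = 5,
) -> pd.DataFrame:
    """Per-population carrier frequency (%) of ``clade``.

    ``assignments`` maps sample_id -> assigned clade name; a sample counts
    as a carrier when its assignment equals ``clade`` or is in ``include``
    (pass the clade's descendant names to count the whole subtree).
    Populations sampled below ``min_n`` are flagged, not dropped.
    """
    carriers = {clade} | (include or set())
    unknown = [s for s in assignments if s not in metadata.index]
    if unknown:
        raise ValueError(f"assignments reference unknown samples: {unknown[:5]}")
    rows = []
    for pop, sub in metadata.groupby("population", sort=True):
        ids = sub["sample_id"]
        n = len(ids)
        k = sum(1 for s in ids if assignments.get(s) in carriers)
        rows.append(
            {
                "population": pop,
                "latitude": float(sub["latitude"].iloc[0]),
                "longitude": float(sub["longitude"].iloc[0]),
                "n_sampled": n,
                "n_carrier": k,
                "frequency": 100.0 * k / n,
                "low_n": n < min_n,
            }
        )
    return pd.DataFrame(rows)


def gene_diversity(counts: Sequence[int]) -> float:
    """Nei's gene (haplotype) diversity H = n/(n-1) * (1 - sum p_i^2)."""
    arr = np.asarray(list(counts), dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative haplotype counts")
    n = arr.sum()
    if n < 2:
        raise ValueError("gene diversity needs n >= 2")
    p = arr / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


# ---------------------------------------------------------------------------
# distances and variograms


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def planar_distance(lat1, lon1, lat2, lon2) -> np.ndarray:
    return np.sqrt((lat1 - lat2) ** 2 + (lon1 - lon2) ** 2)


_DISTANCES = {"haversine": haversine_km, "planar": planar_distance}


@dataclass
class VariogramSpec:
    model: str = "spherical"
    range_: float = 1000.0
    sill: float = 1.0
    nugget: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in VARIOGRAM_MODELS:
            raise ValueError(
                f"variogram model must be one of {VARIOGRAM_MODELS}, got {self.model!r}"
            )
        if self.range_ <= 0 or self.sill <= 0 or self.nugget < 0:
            raise ValueError("variogram parameters must be positive (nugget >= 0)")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        g = np.where(h > 0, self.nugget, 0.0)
        if self.model == "linear":
            return g + self.sill / self.range_ * h
        if self.model == "exponential":
            return g + self.sill * (1.0 - np.exp(-3.0 * h / self.range_))
        # spherical
        hr = np.clip(h / self.range_, 0.0, 1.0)
        return g + self.sill * (1.5 * hr - 0.5 * hr**3)


def empirical_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    distance: str = "haversine",
    n_bins: int = 10,
    max_dist: float | None = None,
) -> pd.DataFrame:
    """Binned empirical semivariogram: columns (h, gamma, n_pairs)."""
    dist_fn = _DISTANCES[distance]
    lat, lon = coords[:, 0], coords[:, 1]
    d = dist_fn(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    iu = np.triu_indices(len(values), k=1)
    h = d[iu]
    sv = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    if max_dist is None:
        max_dist = float(h.max())
    edges = np.linspace(0, max_dist, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (h > lo) & (h <= hi)
        if mask.sum() == 0:
            continue
        rows.append({"h": h[mask].mean(), "gamma": sv[mask].mean(), "n_pairs": int(mask.sum())})
    return pd.DataFrame(rows)


def fit_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    model: str = "spherical",
    distance: str = "haversine",
    n_bins: int = 10,
) -> VariogramSpec:
    """Weighted least-squares fit of a variogram model to the empirical
    semivariogram (weights = pair counts per bin)."""
    emp = empirical_variogram(coords, values, distance, n_bins)
    if len(emp) < 3:
        raise ValueError("too few distance bins to fit a variogram")
    h = emp["h"].to_numpy()
    gamma = emp["gamma"].to_numpy()
    w = np.sqrt(emp["n_pairs"].to_numpy(dtype=float))
    g_max = max(gamma.max(), 1e-9)

    def resid(theta):
        rng, sill, nug = theta
        spec = VariogramSpec(model, rng, sill, nug)
        return w * (spec(h) - gamma)

    x0 = np.array([max(h.max() / 2, 1e-6), g_max, 0.0])
    lb = np.array([1e-9, 1e-9, 0.0])
    ub = np.array([10 * h.max(), 10 * g_max, g_max])
    sol = optimize.least_squares(resid, x0, bounds=(lb, ub))
    rng, sill, nug = sol.x
    spec = VariogramSpec(model, float(rng), float(sill), float(nug))
    logger.info(
        "fitted %s variogram: range=%.3g sill=%.3g nugget=%.3g", model, rng, sill, nug
    )
    return spec


# ---------------------------------------------------------------------------
# kriging


@dataclass
class GridSpec:
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    n_lat: int = 25
    n_lon: int = 25

    def nodes(self) -> tuple[np.ndarray, np.ndarray]:
        lats = np.linspace(self.lat_min, self.lat_max, self.n_lat)
        lons = np.linspace(self.lon_min, self.lon_max, self.n_lon)
        glat, glon = np.meshgrid(lats, lons, indexing="ij")
        return glat.ravel(), glon.ravel()


@dataclass
class FrequencySurface:
    grid: pd.DataFrame  # latitude, longitude, frequency
    variogram: VariogramSpec
    weights_sum: np.ndarray = field(repr=False, default=None)

    def to_tsv(self, path) -> None:
        self.grid.to_csv(path, sep="\t", index=False)


def kriging_weights(
    obs_coords: np.ndarray,
    target: tuple[float, float],
    variogram: VariogramSpec,
    distance: str = "haversine",
) -> tuple[np.ndarray, float]:
    """Solve the ordinary-kriging system for one target point; returns
    (weights, lagrange multiplier)."""
    A, dist_fn = _kriging_matrix(obs_coords, variogram, distance)
    n = len(obs_coords)
    b = np.empty(n + 1)
    b[:n] = variogram(
        dist_fn(obs_coords[:, 0], obs_coords[:, 1], target[0], target[1])
    )
    b[n] = 1.0
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular kriging system; consider adding a nugget"
        ) from exc
    return sol[:n], float(sol[n])


def _kriging_matrix(obs_coords, variogram, distance):
    dist_fn = _DISTANCES[distance]
    lat, lon = obs_coords[:, 0], obs_coords[:, 1]
    d = dist_fn(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    n = len(obs_coords)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = variogram(d)
    np.fill_diagonal(A[:n, :n], 0.0)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    return A, dist_fn


def krige(
    table: pd.DataFrame,
    grid_spec: GridSpec,
    variogram_spec: VariogramSpec | str = "fit",
    distance: str = "haversine",
    clip: tuple[float, float] = (0.0, 100.0),
) -> FrequencySurface:
    """Ordinary kriging of a frequency table onto a geographic grid.

    ``variogram_spec`` may be a fitted :class:`VariogramSpec` or a model
    name / ``"fit"`` to fit one from the data.  Predictions are clipped to
    the frequency range; clipping is logged.
    """
    coords = table[["latitude", "longitude"]].to_numpy(dtype=float)
    values = table["frequency"].to_numpy(dtype=float)
    if len(coords) < 2:
        raise ValueError("kriging needs at least 2 observation points")
    _check_duplicates(coords, values)
    if isinstance(variogram_spec, str):
        model = "spherical" if variogram_spec == "fit" else variogram_spec
        variogram = fit_variogram(coords, values, model=model, distance=distance)
    else:
        variogram = variogram_spec

    glat, glon = grid_spec.nodes()
    dist_fn = _DISTANCES[distance]
    A, _ = _kriging_matrix(coords, variogram, distance)
    n = len(coords)
    B = np.empty((n + 1, len(glat)))
    B[:n, :] = variogram(
        dist_fn(coords[:, 0][:, None], coords[:, 1][:, None], glat[None, :], glon[None, :])
    )
    # exact hits: semivariance to a coincident observation is zero
    for j in range(len(glat)):
        hit = (np.abs(coords[:, 0] - glat[j]) < 1e-12) & (
            np.abs(coords[:, 1] - glon[j]) < 1e-12
        )
        B[:n, j][hit] = 0.0
    B[n, :] = 1.0
    try:
        W = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular kriging system; consider adding a nugget") from exc
    pred = W[:n, :].T @ values
    wsum = W[:n, :].sum(axis=0)
    clipped = np.clip(pred, *clip)
    n_clip = int((clipped != pred).sum())
    if n_clip:
        logger.info("clipped %d kriging predictions to %s", n_clip, clip)
    grid = pd.DataFrame(
        {"latitude": glat, "longitude": glon, "frequency": clipped}
    )
    return FrequencySurface(grid=grid, variogram=variogram, weights_sum=wsum)


def _check_duplicates(coords: np.ndarray, values: np.ndarray) -> None:
    seen: dict[tuple[float, float], float] = {}
    for (la, lo), v in zip(coords, values):
        key = (round(float(la), 9), round(float(lo), 9))
        if key in seen and seen[key] != v:
            raise ValueError(
                f"duplicate coordinates {key} with conflicting values "
                f"({seen[key]} vs {v})"
            )
        seen[key] = v
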