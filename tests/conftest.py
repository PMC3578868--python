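"""Shared fixtures: analytic shape generators, brute-force geometry oracles,
and lightweight feature-matrix builders."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.affinity import rotate as shapely_rotate
from shapely.geometry import Polygon
from hypothesis import settings, HealthCheck

from osteomorph.feature_table import FeatureMatrix, column_name
from osteomorph.morphometrics import FEATURE_NAMES

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# analytic shapes and rasterization


def superellipse_polygon(a: float, b: float, m: float, angle_deg: float = 0.0,
                         n_theta: int = 1440) -> Polygon:
    """Continuous superellipse |x/a|^m + |y/b|^m = 1, rotated."""
    t = np.linspace(0, 2 * math.pi, n_theta, endpoint=False)
    ct, st = np.cos(t), np.sin(t)
    x = a * np.sign(ct) * np.abs(ct) ** (2 / m)
    y = b * np.sign(st) * np.abs(st) ** (2 / m)
    poly = Polygon(np.stack([x, y], axis=1))
    return shapely_rotate(poly, angle_deg) if angle_deg else poly


def rasterize_polygon(poly: Polygon, pad: int = 4) -> np.ndarray:
    """Pixel-center-in-polygon rasterization on a padded grid."""
    minx, miny, maxx, maxy = poly.bounds
    h = int(maxy - miny) + 2 * pad
    w = int(maxx - minx) + 2 * pad
    yy, xx = np.mgrid[0:h, 0:w]
    pts = shapely.points(xx.ravel() + minx - pad + 0.5, yy.ravel() + miny - pad + 0.5)
    return shapely.contains(poly, pts).reshape(h, w)


def polygon_calipers(poly: Polygon) -> tuple[float, float]:
    """(max, min) caliper diameters of a continuous polygon."""
    hull = np.array(poly.convex_hull.exterior.coords)[:-1]
    d = hull[:, None, :] - hull[None, :, :]
    fer_max = float(np.sqrt((d ** 2).sum(-1)).max())
    edges = np.roll(hull, -1, axis=0) - hull
    ln = np.hypot(edges[:, 0], edges[:, 1])
    ok = ln > 0
    nor = np.stack([-edges[ok, 1], edges[ok, 0]], axis=1) / ln[ok, None]
    rel = hull[None, :, :] - hull[ok][:, None, :]
    fer_min = float(np.abs((rel * nor[:, None, :]).sum(-1)).max(axis=1).min())
    return fer_max, fer_min


# ---------------------------------------------------------------------------
# brute-force raster oracles


def oracle_calipers(mask: np.ndarray, step_deg: float = 1.0) -> tuple[float, float]:
    """Feret diameters by exhaustive projection of pixel corners over rotations."""
    from scipy import ndimage as ndi

    boundary = mask & ~ndi.binary_erosion(mask, np.ones((3, 3), bool))
    rr, cc = np.nonzero(boundary)
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    pts = (np.stack([rr, cc], 1)[:, None, :] + offs[None]).reshape(-1, 2)
    best_max, best_min = 0.0, np.inf
    for deg in np.arange(0.0, 180.0, step_deg):
        th = math.radians(deg)
        proj = pts[:, 0] * math.cos(th) + pts[:, 1] * math.sin(th)
        width = proj.max() - proj.min()
        best_max = max(best_max, width)
        best_min = min(best_min, width)
    return best_max, best_min


def oracle_inner_radius(mask: np.ndarray) -> float:
    """Largest inscribed circle radius by exhaustive pixel distance search."""
    from scipy import ndimage as ndi

    filled = ndi.binary_fill_holes(mask)
    fy, fx = np.nonzero(filled)
    by, bx = np.nonzero(~filled)
    d2 = (fy[:, None] - by[None, :]) ** 2 + (fx[:, None] - bx[None, :]) ** 2
    return float(np.sqrt(d2.min(axis=1)).max())


# ---------------------------------------------------------------------------
# feature-matrix builders (no imaging)


def make_meta(n_lots=3, n_passages=3, wells=3, conditions=("induction", "control"),
              seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows, index = [], []
    for lot in range(1, n_lots + 1):
        for cond in conditions:
            for p in range(1, n_passages + 1):
                for w in range(1, wells + 1):
                    index.append(f"L{lot}_{cond}_P{p}_W{w}")
                    base = 0.8 if cond == "induction" else 0.3
                    rows.append({
                        "lot": lot, "passage": p, "condition": cond,
                        "alp_rate": base + 0.1 * rng.standard_normal(),
                        "ca_rate": 0.5 * base + 0.05 * rng.standard_normal(),
                    })
    return pd.DataFrame(rows, index=index)


def make_matrix(meta: pd.DataFrame, features=FEATURE_NAMES, timepoints=(1, 2, 3),
                seed=0, signal: str | None = "alp_rate",
                noise_features: tuple[str, ...] = ()) -> FeatureMatrix:
    """Synthetic feature matrix: informative columns track a marker plus
    noise; ``noise_features`` are pure noise at every timepoint."""
    rng = np.random.default_rng(seed)
    column_info = [(f, s, t) for f in features for s in ("mean", "sd")
                   for t in timepoints]
    cols = [column_name(f, s, t) for f, s, t in column_info]
    y = meta[signal].to_numpy(float) if signal else np.zeros(len(meta))
    data = np.empty((len(meta), len(cols)))
    for j, (f, s, t) in enumerate(column_info):
        if f in noise_features:
            data[:, j] = rng.standard_normal(len(meta))
        else:
            slope = rng.uniform(0.5, 2.0) * (1 if s == "mean" else 0.3)
            data[:, j] = slope * y * (t / max(timepoints)) \
                + 0.15 * rng.standard_normal(len(meta))
    X = pd.DataFrame(data, index=meta.index, columns=cols)
    missing = pd.DataFrame(False, index=meta.index, columns=cols)
    return FeatureMatrix(X=X, meta=meta.copy(), missing=missing,
                         column_info=column_info)


@pytest.fixture(scope="session")
def random_fixture_shapes():
    """~60 rasterized shapes with continuous truth, spanning spindles,
    spread blobs and ring (holed) shapes."""
    rng = np.random.default_rng(11)
    shapes = []
    for _ in range(60):
        a = rng.uniform(18, 40)
        aspect = rng.uniform(1.2, 5.0)
        m = rng.uniform(1.3, 4.0)
        ang = rng.uniform(0, 180)
        poly = superellipse_polygon(a, a / aspect, m, ang)
        shapes.append((rasterize_polygon(poly), poly))
    return shapes
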