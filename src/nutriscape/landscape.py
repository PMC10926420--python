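"""Nonparametric nutritional landscapes: thin-plate splines over (P, C) intake.

A trait's nutritional landscape is a smooth surface over per-day protein
and carbohydrate intake, fitted to the untransformed trait values by a
thin-plate smoothing spline. The smoothing parameter is chosen by
generalized cross-validation (GCV). Predictions are only reported inside
the convex hull of the observed intakes — the landscape is not
extrapolated beyond where flies actually ate. The optimum (the intake
that maximises the trait) is the argmax of the masked surface, refined by
continuous local optimization, and its sampling uncertainty is bounded by
a case-resampling bootstrap region of the argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import Delaunay
from scipy.spatial.distance import cdist

__all__ = ["ThinPlateSpline", "LandscapeModel", "LandscapeResults"]

_FLAT_TOL = 1e-12


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """Thin-plate radial basis r^2 log(r), with the removable 0 at r = 0."""
    out = np.zeros_like(r)
    mask = r > 0
    out[mask] = r[mask] ** 2 * np.log(r[mask])
    return out


class ThinPlateSpline:
    """Thin-plate smoothing spline on scattered 2-D data.

    Minimises sum (y_i - f(x_i))^2 + n*lambda*J(f) where J is the
    thin-plate bending energy. The null space of the penalty is the affine
    functions, so planes are reproduced exactly at any smoothing level.
    Coordinates are standardized internally for conditioning; ``lam`` is
    expressed on that standardized scale.

    The solver reduces the system to the penalty's range space with a QR
    decomposition and eigendecomposes it once, after which evaluating the
    fit, its GCV score and its roughness at any ``lam`` is cheap; ``lam
    = None`` selects the GCV minimiser over a log-spaced grid.
    """

    #: GCV search grid for the smoothing parameter (standardized coordinates)
    LAMBDA_GRID = np.logspace(-9, 3, 61)

    def __init__(self, lam: float | None = None):
        self.lam = lam
        self._fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ThinPlateSpline":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        if X.shape != (n, 2):
            raise ValueError("X must be (n, 2)")
        if n < 7:
            raise ValueError("need at least 7 points for a thin-plate spline")
        self._mean = X.mean(axis=0)
        self._scale = X.std(axis=0)
        if np.any(self._scale <= 0):
            raise ValueError("degenerate intake cloud: a coordinate is constant")
        Xs = (X - self._mean) / self._scale

        K = _tps_kernel(cdist(Xs, Xs))
        T = np.column_stack([np.ones(n), Xs])
        if np.linalg.matrix_rank(T) < 3:
            raise ValueError("degenerate 1-D intake cloud: points are collinear")
        Q, R = np.linalg.qr(T, mode="complete")
        Q1, Q2 = Q[:, :3], Q[:, 3:]
        self._R1 = R[:3, :]
        M = Q2.T @ K @ Q2
        M = (M + M.T) / 2
        d, U = np.linalg.eigh(M)
        d = np.clip(d, 0.0, None)  # kernel is conditionally PSD
        self._d = d
        self._z = U.T @ (Q2.T @ y)
        self._U, self._Q1, self._Q2, self._K = U, Q1, Q2, K
        self._Xs, self._y, self._n = Xs, y, n

        lam = self.lam
        if lam is None:
            scores = [self._gcv(l) for l in self.LAMBDA_GRID]
            lam = float(self.LAMBDA_GRID[int(np.argmin(scores))])
        self.lam_ = float(lam)
        self._solve(self.lam_)
        self._fitted = True
        return self

    # -- internals ----------------------------------------------------------

    def _gamma(self, lam: float) -> np.ndarray:
        return self._z / (self._d + self._n * lam)

    def _gcv(self, lam: float) -> float:
        nl = self._n * lam
        denom = self._d + nl
        rss = float(np.sum((nl * self._z / denom) ** 2))
        edf_resid = float(np.sum(nl / denom))  # trace(I - A)
        if edf_resid <= 0:
            return np.inf
        return self._n * rss / edf_resid**2

    def _solve(self, lam: float) -> None:
        gamma = self._gamma(lam)
        c = self._Q2 @ (self._U @ gamma)
        resid = self._y - (self._K @ c + self._n * lam * c)
        self.coef_ = c
        self.poly_coef_ = np.linalg.solve(self._R1, self._Q1.T @ resid)
        self._gamma_ = gamma

    # -- public surface -----------------------------------------------------

    def gcv_score(self, lam: float | None = None) -> float:
        return self._gcv(self.lam_ if lam is None else lam)

    def roughness(self) -> float:
        """Bending energy c' K c of the fitted surface (standardized scale)."""
        return float(np.sum(self._d * self._gamma_**2))

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("spline is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self._mean) / self._scale
        Knew = _tps_kernel(cdist(Xs, self._Xs))
        T = np.column_stack([np.ones(len(Xs)), Xs])
        return Knew @ self.coef_ + T @ self.poly_coef_


@dataclass
class LandscapeResults:
    """A fitted nutritional landscape on a hull-masked grid."""

    grid_P: np.ndarray            # (gx,) cell-center protein coordinates
    grid_C: np.ndarray            # (gy,)
    values: np.ndarray            # (gy, gx), NaN outside the convex hull
    lam: float
    spline: ThinPlateSpline
    hull: Delaunay
    X: np.ndarray                 # observed (P, C) intakes
    y: np.ndarray
    optimum: tuple[float, float, float] = field(init=False)
    flat: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.optimum = self._find_optimum()

    # -- optimum ------------------------------------------------------------

    def _grid_argmax(self, values: np.ndarray) -> tuple[int, int]:
        """Best (row, col) cell; ties broken toward lower P then lower C."""
        vmax = np.nanmax(values)
        tol = max(abs(vmax), 1.0) * 1e-12
        rows, cols = np.where(values >= vmax - tol)
        # lexicographic by (P, C) = (grid_P[col], grid_C[row])
        order = np.lexsort((self.grid_C[rows], self.grid_P[cols]))
        k = order[0]
        return int(rows[k]), int(cols[k])

    def _find_optimum(self) -> tuple[float, float, float]:
        vals = self.values
        finite = np.isfinite(vals)
        if not finite.any():
            raise ValueError("landscape has no grid cells inside the hull")
        vmax, vmin = np.nanmax(vals), np.nanmin(vals)
        if vmax - vmin <= _FLAT_TOL * max(1.0, abs(vmax)):
            warnings.warn("flat landscape: returning the centroid of observed intakes")
            self.flat = True
            cP, cC = self.X.mean(axis=0)
            return float(cP), float(cC), float(self.spline.predict([[cP, cC]])[0])
        i, j = self._grid_argmax(vals)
        x0 = np.array([self.grid_P[j], self.grid_C[i]])

        def neg(x):
            if self.hull.find_simplex(x[None, :])[0] < 0:
                return np.inf
            return -float(self.spline.predict(x[None, :])[0])

        res = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 500},
        )
        x = res.x if np.isfinite(res.fun) and -res.fun >= vals[i, j] else x0
        return float(x[0]), float(x[1]), float(self.spline.predict(x[None, :])[0])

    # -- bootstrap optimum region -------------------------------------------

    def optimum_region(
        self,
        B: int = 200,
        alpha: float = 0.05,
        seed: int | np.random.Generator | None = None,
        max_failure_fraction: float = 0.10,
    ) -> pd.DataFrame:
        """Bootstrap (1 - alpha) region for the landscape optimum.

        Cases (flies) are resampled with replacement B times; the spline is
        refitted at the original smoothing level and the grid argmax
        recorded. The region is the smallest set of grid cells (by
        bootstrap count rank) covering the central (1 - alpha) mass of
        argmaxes, always including the point optimum's cell.

        Returns a DataFrame with columns P, C, count — one row per cell in
        the region.
        """
        if B < 200:
            raise ValueError("B must be at least 200")
        if not 0 < alpha <= 0.5:
            raise ValueError("alpha must lie in (0, 0.5]")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n = len(self.y)
        gx, gy = np.meshgrid(self.grid_P, self.grid_C)
        inside = self.hull.find_simplex(np.column_stack([gx.ravel(), gy.ravel()])) >= 0
        grid_pts = np.column_stack([gx.ravel(), gy.ravel()])
        lam_boot = max(self.lam, 1e-7)  # floor guards resampled-duplicate ties

        counts = np.zeros(grid_pts.shape[0], dtype=int)
        failures = 0
        for _ in range(B):
            idx = rng.integers(0, n, n)
            try:
                sp = ThinPlateSpline(lam=lam_boot).fit(self.X[idx], self.y[idx])
                pred = np.where(inside, sp.predict(grid_pts), -np.inf)
                counts[int(np.argmax(pred))] += 1
            except (ValueError, np.linalg.LinAlgError):
                failures += 1
        if failures > max_failure_fraction * B:
            raise RuntimeError(
                f"{failures}/{B} bootstrap refits failed; "
                "data may be too degenerate for a stable landscape"
            )
        successes = B - failures
        order = np.argsort(-counts, kind="stable")
        cum = np.cumsum(counts[order])
        need = (1 - alpha) * successes
        ncells = int(np.searchsorted(cum, need - 1e-9) + 1)
        chosen = set(order[:ncells][counts[order[:ncells]] > 0].tolist())
        # the region always contains the point optimum's cell
        oi = int(np.argmin(np.abs(self.grid_P - self.optimum[0])))
        oj = int(np.argmin(np.abs(self.grid_C - self.optimum[1])))
        chosen.add(oj * len(self.grid_P) + oi)
        rows = [
            {"P": grid_pts[k, 0], "C": grid_pts[k, 1], "count": int(counts[k])}
            for k in sorted(chosen)
        ]
        return pd.DataFrame(rows)

    # -- convenience --------------------------------------------------------

    def summary(self) -> str:
        P, C, v = self.optimum
        return (
            f"Thin-plate-spline landscape: n = {len(self.y)}, "
            f"lambda = {self.lam:.3g}\n"
            f"optimum: protein = {P:.3f} mg/day, carbohydrate = {C:.3f} mg/day, "
            f"predicted value = {v:.3f}"
            + (" (flat landscape; centroid reported)" if self.flat else "")
        )

    def plot(self, ax=None, cmap: str = "viridis"):
        """Heat map of the masked landscape with the optimum marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mesh = ax.pcolormesh(self.grid_P, self.grid_C, self.values,
                             cmap=cmap, shading="auto")
        ax.plot(*self.optimum[:2], "r^", markersize=10)
        ax.set_xlabel("protein intake (mg/day)")
        ax.set_ylabel("carbohydrate intake (mg/day)")
        plt.colorbar(mesh, ax=ax)
        return ax


class LandscapeModel:
    """Fit a trait's nutritional landscape from fly-level records.

    Uses untransformed trait values and raw mg/day intakes (landscapes
    visualise the data scale; the response-surface models use standardized
    values — both intentional).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        trait: str,
        *,
        intake_cols: tuple[str, str] = ("P_mg_day", "C_mg_day"),
        smoothing: float | str = "auto",
        grid_size: int = 100,
    ):
        df = data[[*intake_cols, trait]].dropna()
        X = df[list(intake_cols)].to_numpy(float)
        y = df[trait].to_numpy(float)
        if len(y) < 20:
            raise ValueError(f"need >= 20 points, got {len(y)}")
        Xc = X - X.mean(axis=0)
        sv = np.linalg.svd(Xc, compute_uv=False)
        if sv[1] < 1e-9 * max(sv[0], 1.0):
            raise ValueError("degenerate 1-D intake cloud: points are collinear")
        ratios = np.unique(np.round(np.arctan2(X[:, 1], X[:, 0]), 6))
        if len(ratios) < 3:
            raise ValueError(f"need points spanning >= 3 rails, found {len(ratios)}")
        self.X, self.y = X, y
        self.trait = trait
        self.smoothing = smoothing
        self.grid_size = grid_size

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str, **kw) -> "LandscapeModel":
        return cls(data, trait, **kw)

    def fit(self) -> LandscapeResults:
        lam = None if self.smoothing == "auto" else float(self.smoothing)
        spline = ThinPlateSpline(lam=lam).fit(self.X, self.y)
        hull = Delaunay(self.X)
        g = self.grid_size
        grid_P = np.linspace(self.X[:, 0].min(), self.X[:, 0].max(), g)
        grid_C = np.linspace(self.X[:, 1].min(), self.X[:, 1].max(), g)
        gx, gy = np.meshgrid(grid_P, grid_C)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        vals = spline.predict(pts)
        vals[hull.find_simplex(pts) < 0] = np.nan
        return LandscapeResults(
            grid_P=grid_P, grid_C=grid_C, values=vals.reshape(g, g),
            lam=spline.lam_, spline=spline, hull=hull, X=self.X, y=self.y,
        )
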