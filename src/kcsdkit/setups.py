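"""Electrode setups, estimation spaces, noise models and on-disk artifacts.

Coordinates are unit-agnostic: electrode positions, basis radii ``R`` and
``h``, and estimation bounds must share one length unit, and the
conductivity ``sigma`` the matching unit (e.g. mm and S/mm).  Electrode
tables and potential matrices are plain delimited text (comma or tab,
auto-detected, header row required); maps are stored as self-describing
NumPy ``.npz`` archives holding the values, the point coordinates and the
grid descriptor so read-back round-trips bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeSetup",
    "PotentialRecord",
    "EstimationSpace",
    "NoiseModel",
    "read_setup",
    "read_potentials",
    "write_potentials",
    "write_setup",
    "default_estimation_space",
    "write_map",
    "read_map",
]

_COORD_COLUMNS = ("x", "y", "z")


@dataclass(frozen=True)
class ElectrodeSetup:
    """Electrode positions in 1, 2 or 3 dimensions plus tissue conductivity."""

    positions: np.ndarray  # N×k
    sigma: float = 1.0

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] not in (1, 2, 3):
            raise ValueError("positions must be N×k with k in {1, 2, 3}")
        if pos.shape[0] < 2:
            raise ValueError("at least 2 electrodes are required")
        if not np.all(np.isfinite(pos)):
            raise ValueError("electrode coordinates must be finite")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        dup = _duplicate_rows(pos)
        if dup:
            raise ValueError(f"duplicate electrode coordinates at row pairs {dup}")
        object.__setattr__(self, "positions", pos)

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def bounding_box(self) -> list[tuple[float, float]]:
        return [(float(lo), float(hi)) for lo, hi in
                zip(self.positions.min(axis=0), self.positions.max(axis=0))]

    def pairwise_distances(self) -> np.ndarray:
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        d = np.linalg.norm(diff, axis=2)
        return d[np.triu_indices(self.n_electrodes, k=1)]

    def subset(self, keep) -> "ElectrodeSetup":
        """Setup restricted to the electrodes indexed by ``keep``."""
        return ElectrodeSetup(self.positions[np.asarray(keep, dtype=int)], self.sigma)


def _duplicate_rows(pos: np.ndarray) -> list[tuple[int, int]]:
    pairs = []
    for i in range(pos.shape[0]):
        for j in range(i + 1, pos.shape[0]):
            if np.array_equal(pos[i], pos[j]):
                pairs.append((i, j))
    return pairs


@dataclass(frozen=True)
class PotentialRecord:
    """Measured potentials, N electrodes × T time samples."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
        if vals.ndim != 2:
            raise ValueError("potentials must be an N or N×T array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("potential values must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def check_against(self, setup: ElectrodeSetup) -> None:
        if self.n_electrodes != setup.n_electrodes:
            raise ValueError(
                f"potential rows ({self.n_electrodes}) do not match electrode "
                f"count ({setup.n_electrodes})")


@dataclass(frozen=True)
class EstimationSpace:
    """Points where CSD and interpolated potential are evaluated.

    ``grid`` is an optional regular-grid descriptor, a list of
    ``(min, max, count)`` per axis; when present, ``points`` is exactly its
    row-major expansion (last axis fastest).
    """

    points: np.ndarray  # P×k
    grid: tuple | None = None

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[0] < 1:
            raise ValueError("estimation space needs at least one point")
        object.__setattr__(self, "points", pts)
        if self.grid is not None:
            grid = tuple((float(lo), float(hi), int(n)) for lo, hi, n in self.grid)
            object.__setattr__(self, "grid", grid)
            expanded = _expand_grid(grid)
            if expanded.shape != pts.shape or not np.array_equal(expanded, pts):
                raise ValueError("grid descriptor does not expand to stored points")

    @classmethod
    def from_grid(cls, grid) -> "EstimationSpace":
        grid = tuple((float(lo), float(hi), int(n)) for lo, hi, n in grid)
        return cls(_expand_grid(grid), grid)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def shape(self) -> tuple:
        if self.grid is None:
            return (self.n_points,)
        return tuple(n for _, _, n in self.grid)


def _expand_grid(grid) -> np.ndarray:
    axes = [np.linspace(lo, hi, n) for lo, hi, n in grid]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


@dataclass(frozen=True)
class NoiseModel:
    """Multivariate-normal measurement noise, ``ε ~ N(0, Σ_V)``.

    Either a full N×N covariance or the scalar shorthand ``Σ_V = σ²·I``.
    """

    covariance: np.ndarray | None = None
    variance: float | None = None  # scalar shorthand σ²

    def __post_init__(self):
        if (self.covariance is None) == (self.variance is None):
            raise ValueError("give exactly one of covariance or variance")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
                raise ValueError("covariance must be square")
            scale = max(np.abs(cov).max(), 1.0)
            if np.abs(cov - cov.T).max() > 1e-12 * scale:
                raise ValueError("covariance must be symmetric")
            w = np.linalg.eigvalsh(0.5 * (cov + cov.T))
            if w.min() < -1e-10 * max(w.max(), 1.0):
                raise ValueError("covariance must be positive semi-definite")
            object.__setattr__(self, "covariance", 0.5 * (cov + cov.T))
        elif not self.variance >= 0:
            raise ValueError("variance must be non-negative")

    def full_covariance(self, n: int) -> np.ndarray:
        if self.covariance is not None:
            if self.covariance.shape[0] != n:
                raise ValueError("covariance size does not match electrode count")
            return self.covariance
        return self.variance * np.eye(n)


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise ValueError(f"could not parse table {path}: {exc}") from exc
    return df


def read_setup(path, sigma: float = 1.0) -> ElectrodeSetup:
    """Read an electrode-position table (columns ``x[,y[,z]]``)."""
    df = _read_table(path)
    cols = [c for c in _COORD_COLUMNS if c in df.columns]
    if not cols or cols != list(_COORD_COLUMNS[: len(cols)]):
        raise ValueError(
            f"{path}: expected coordinate columns x[,y[,z]], got {list(df.columns)}")
    data = df[cols]
    bad = data.apply(pd.to_numeric, errors="coerce")
    nan_rows = np.where(bad.isna().any(axis=1))[0]
    if nan_rows.size:
        raise ValueError(f"{path}: non-numeric coordinate in row {nan_rows[0]}")
    return ElectrodeSetup(bad.to_numpy(dtype=float), sigma=sigma)


def write_setup(setup: ElectrodeSetup, path) -> None:
    cols = _COORD_COLUMNS[: setup.dim]
    pd.DataFrame(setup.positions, columns=list(cols)).to_csv(path, index=False)


def read_potentials(path) -> PotentialRecord:
    """Read an electrodes × time potential matrix (any column names)."""
    df = _read_table(path)
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        row = int(np.where(vals.isna().any(axis=1))[0][0])
        raise ValueError(f"{path}: non-numeric potential value in row {row}")
    return PotentialRecord(vals.to_numpy(dtype=float))


def write_potentials(record: PotentialRecord, path) -> None:
    cols = [f"t{j}" for j in range(record.n_samples)]
    pd.DataFrame(record.values, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# estimation spaces and map archives
# ---------------------------------------------------------------------------

def default_estimation_space(setup: ElectrodeSetup,
                             points_per_axis: int) -> EstimationSpace:
    """Regular grid over the electrode bounding box (the default region of
    interest is the region spanned by the electrodes)."""
    if points_per_axis < 1:
        raise ValueError("points_per_axis must be >= 1")
    box = setup.bounding_box()
    for ax, (lo, hi) in enumerate(box):
        if lo == hi:
            raise ValueError(
                f"all electrodes share coordinate {lo} on axis {ax}; supply "
                "explicit estimation bounds for degenerate axes")
    return EstimationSpace.from_grid([(lo, hi, points_per_axis) for lo, hi in box])


def write_map(values, space: EstimationSpace, path) -> None:
    """Store a scalar field over an estimation space as an ``.npz`` archive."""
    vals = np.asarray(values, dtype=float)
    flat = vals.reshape(-1) if vals.ndim > 1 else vals
    if flat.shape[0] != space.n_points:
        raise ValueError(
            f"values length {flat.shape[0]} does not match space size "
            f"{space.n_points}")
    if space.grid is not None:
        grid = np.asarray(space.grid, dtype=float)
        np.savez(path, values=flat, points=space.points, grid=grid)
    else:
        np.savez(path, values=flat, points=space.points)


def read_map(path) -> tuple[np.ndarray, EstimationSpace]:
    with np.load(path) as npz:
        values = npz["values"]
        points = npz["points"]
        grid = None
        if "grid" in npz.files:
            grid = tuple((row[0], row[1], int(row[2])) for row in npz["grid"])
    return values, EstimationSpace(points, grid)
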