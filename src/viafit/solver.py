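"""Coupled cell-fraction / oxygen dynamics on a 2-D grid.

Cell motion is neglected, so the cell fraction obeys an independent
scalar ODE at every node, advanced with classical RK4 sub-stepping.
Oxygen is quasi-steady: after every cell step the nonlinear
diffusion–consumption balance

    ∇²C = Q·α·C / (1 + Q1·C)

is re-solved by Picard iteration on a 5-point finite-difference stencil.
Boundary conditions: C = 1 (Dirichlet) on "medium" nodes — nodes outside
the cell phase at t = 0, where oxygen is held at the far-field value —
and zero normal gradient on the outer walls.  The zero-flux condition on
the cell fraction is vacuous here because the transport term is dropped;
it is stated for completeness and generates no stencil.

The domain is the unit square; time is in hours with a default step of
1 h over 72 h.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import ModelParams, _dalpha_dt_raw

__all__ = [
    "SimGrid",
    "StateField",
    "SimConfig",
    "SolverError",
    "image_to_alpha0",
    "solve_oxygen",
    "step_alpha",
    "simulate",
    "viability_percent",
]


class SolverError(RuntimeError):
    """Raised when the oxygen solve or time stepping fails."""


@dataclass(frozen=True)
class SimGrid:
    """Uniform node grid on the unit square.

    ``medium_mask`` marks nodes outside the cell phase at t = 0; oxygen
    is pinned to the far-field value 1 there.  At least one medium node
    must exist so that oxygen has a source.
    """

    nx: int
    ny: int
    medium_mask: np.ndarray  # shape (ny, nx), bool

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 nodes per axis")
        mask = np.asarray(self.medium_mask, dtype=bool)
        if mask.shape != (self.ny, self.nx):
            raise ValueError(
                f"medium_mask shape {mask.shape} != (ny, nx) = {(self.ny, self.nx)}"
            )
        if not mask.any():
            raise ValueError("medium_mask must contain at least one True node "
                             "(oxygen source)")
        object.__setattr__(self, "medium_mask", mask)

    @property
    def hx(self) -> float:
        return 1.0 / (self.nx - 1)

    @property
    def hy(self) -> float:
        return 1.0 / (self.ny - 1)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    def node_weights(self) -> np.ndarray:
        """Trapezoidal quadrature weights, shape (ny, nx)."""
        wx = np.full(self.nx, self.hx)
        wx[[0, -1]] = self.hx / 2.0
        wy = np.full(self.ny, self.hy)
        wy[[0, -1]] = self.hy / 2.0
        return np.outer(wy, wx)


@dataclass
class StateField:
    """Nodal cell fraction and oxygen level at one time point."""

    t: float
    alpha: np.ndarray  # (ny, nx)
    c: np.ndarray      # (ny, nx)

    def validate(self, grid: SimGrid, atol: float = 1e-9) -> None:
        for name, f in (("alpha", self.alpha), ("c", self.c)):
            if f.shape != (grid.ny, grid.nx):
                raise ValueError(f"{name} shape {f.shape} does not match grid")
            if np.any(f < -atol) or np.any(f > 1 + atol):
                raise ValueError(f"{name} outside [0, 1]")
        if not np.allclose(self.c[grid.medium_mask], 1.0, atol=atol):
            raise ValueError("c must equal 1 on medium nodes")


@dataclass(frozen=True)
class SimConfig:
    """Time-stepping and oxygen-solve settings (time in hours)."""

    dt: float = 1.0
    t_end: float = 72.0
    ode_substeps: int = 10
    picard_tol: float = 1e-8
    picard_max_iter: int = 100
    record_every: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        n = self.t_end / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("t_end must be a multiple of dt")
        if self.ode_substeps < 1:
            raise ValueError("ode_substeps must be >= 1")
        if self.picard_tol <= 0:
            raise ValueError("picard_tol must be > 0")
        m = self.record_every / self.dt
        if abs(m - round(m)) > 1e-9 or self.record_every <= 0:
            raise ValueError("record_every must be a positive multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


# ---------------------------------------------------------------------------
# image-based initial condition

def image_to_alpha0(
    img: np.ndarray | str | Path,
    nx: int,
    ny: int,
    alpha_seed: float = 0.5,
    threshold: float | None = None,
) -> tuple[np.ndarray, SimGrid]:
    """Build the initial cell fraction and medium mask from a grayscale image.

    The image is normalized to [0, 1], resampled to the node grid, and
    segmented into cell/medium by Otsu's threshold (or a caller-supplied
    fixed ``threshold``).  Cell nodes receive ``alpha_seed``; medium
    nodes get alpha = 0 and enter the medium mask (oxygen pinned to 1).

    Returns ``(alpha0, grid)``.
    """
    if isinstance(img, (str, Path)):
        import imageio.v3 as iio

        img = iio.imread(img)
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:  # RGB(A): luminance
        img = img[..., :3].mean(axis=-1)
    if img.size == 0:
        raise ValueError("image is empty")
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        if threshold is None:
            raise ValueError(
                "constant-intensity image: Otsu threshold undefined; "
                "supply a fixed threshold"
            )
        img = np.zeros_like(img) if lo <= threshold else np.ones_like(img)

    from skimage.transform import resize

    sampled = resize(img, (ny, nx), order=1, mode="edge", anti_aliasing=False)
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(sampled))
    cells = sampled > threshold
    medium = ~cells
    if not medium.any():
        # fully confluent image: keep the outer wall as the oxygen source
        medium = np.zeros((ny, nx), dtype=bool)
        medium[0, :] = medium[-1, :] = True
        medium[:, 0] = medium[:, -1] = True
        cells = ~medium
    alpha0 = np.where(cells, float(alpha_seed), 0.0)
    return alpha0, SimGrid(nx=nx, ny=ny, medium_mask=medium)


# ---------------------------------------------------------------------------
# quasi-steady oxygen solve

def _laplacian_rows(grid: SimGrid):
    """5-point Laplacian with mirrored (zero-gradient) outer walls.

    Returns (rows, cols, vals) triplets for the full-grid operator in
    row-major node ordering.  Mirroring doubles the inward neighbour's
    weight at a wall.
    """
    nx, ny = grid.nx, grid.ny
    ix2, iy2 = 1.0 / grid.hx**2, 1.0 / grid.hy**2
    rows, cols, vals = [], [], []

    def idx(j, i):
        return j * nx + i

    for j in range(ny):
        for i in range(nx):
            k = idx(j, i)
            rows.append(k); cols.append(k); vals.append(-2.0 * (ix2 + iy2))
            # x neighbours (mirror at walls)
            for di in (-1, 1):
                ii = i + di
                if ii < 0 or ii >= nx:
                    ii = i - di
                rows.append(k); cols.append(idx(j, ii)); vals.append(ix2)
            for dj in (-1, 1):
                jj = j + dj
                if jj < 0 or jj >= ny:
                    jj = j - dj
                rows.append(k); cols.append(idx(jj, i)); vals.append(iy2)
    return np.array(rows), np.array(cols), np.array(vals)


class _OxygenOperator:
    """Caches the discrete Laplacian and the medium-node row replacement."""

    def __init__(self, grid: SimGrid):
        self.grid = grid
        n = grid.n_nodes
        rows, cols, vals = _laplacian_rows(grid)
        med = grid.medium_mask.ravel()
        keep = ~med[rows]  # drop Laplacian rows on Dirichlet nodes
        rows, cols, vals = rows[keep], cols[keep], vals[keep]
        # identity rows on medium nodes
        d = np.flatnonzero(med)
        rows = np.concatenate([rows, d])
        cols = np.concatenate([cols, d])
        vals = np.concatenate([vals, np.ones(d.size)])
        self._rows, self._cols, self._vals = rows, cols, vals
        self._med = med
        self._n = n

    def solve(self, alpha: np.ndarray, p: ModelParams, config: SimConfig,
              c0: np.ndarray | None = None) -> np.ndarray:
        grid = self.grid
        med = self._med
        a = alpha.ravel()
        c = np.ones(self._n) if c0 is None else c0.ravel().copy()
        rhs = np.where(med, 1.0, 0.0)
        interior = ~med
        for _ in range(config.picard_max_iter):
            # lag the saturation denominator: (L - diag(k)) c_new = rhs
            k = np.where(interior, p.Q * a / (1.0 + p.Q1 * c), 0.0)
            vals = self._vals.copy()
            diag_extra = -k
            rows = np.concatenate([self._rows, np.arange(self._n)])
            cols = np.concatenate([self._cols, np.arange(self._n)])
            vals = np.concatenate([vals, diag_extra])
            A = sp.csc_matrix((vals, (rows, cols)), shape=(self._n, self._n))
            c_new = spla.spsolve(A, rhs)
            c_new[med] = 1.0  # pin Dirichlet values exactly
            diff = float(np.max(np.abs(c_new - c)))
            c = c_new
            if diff < config.picard_tol:
                return np.clip(c, 0.0, 1.0).reshape(grid.ny, grid.nx)
        raise SolverError(
            f"oxygen Picard iteration did not converge in "
            f"{config.picard_max_iter} iterations (last residual {diff:.3e})"
        )


def solve_oxygen(
    alpha: np.ndarray,
    grid: SimGrid,
    p: ModelParams,
    config: SimConfig | None = None,
    c0: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the quasi-steady oxygen balance for a given cell field.

    Picard iteration on ∇²C = Q·α·C/(1+Q1·C), with C = 1 pinned on
    medium nodes and mirrored (zero-gradient) outer walls.  Returns the
    oxygen field in [0, 1].
    """
    if config is None:
        config = SimConfig()
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]")
    if p.Q == 0.0:
        return np.ones((grid.ny, grid.nx))
    return _OxygenOperator(grid).solve(alpha, p, config, c0=c0)


# ---------------------------------------------------------------------------
# cell-fraction stepping

_CLAMP_TOL = 1e-12


def step_alpha(
    alpha: np.ndarray,
    c: np.ndarray,
    p: ModelParams,
    config: SimConfig,
) -> np.ndarray:
    """Advance the cell fraction by dt with oxygen frozen.

    Every node is an independent scalar ODE, integrated with
    ``ode_substeps`` classical RK4 steps.  The result is clamped to
    [0, 1] only to absorb round-off; a clamp larger than 1e−12 means the
    step is under-resolved and raises ``SolverError``.
    """
    h = config.dt / config.ode_substeps
    a = np.asarray(alpha, dtype=float).copy()
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(config.ode_substeps):
            k1 = _dalpha_dt_raw(a, c, p)
            k2 = _dalpha_dt_raw(a + 0.5 * h * k1, c, p)
            k3 = _dalpha_dt_raw(a + 0.5 * h * k2, c, p)
            k4 = _dalpha_dt_raw(a + h * k3, c, p)
            a = a + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(a)):
        raise SolverError(
            "cell-fraction step diverged (non-finite values); "
            "increase ode_substeps"
        )
    overshoot = max(float(np.max(a - 1.0, initial=0.0)),
                    float(np.max(-a, initial=0.0)))
    if overshoot > _CLAMP_TOL:
        raise SolverError(
            f"cell-fraction step left [0,1] by {overshoot:.3e}; "
            f"increase ode_substeps"
        )
    return np.clip(a, 0.0, 1.0)


def viability_percent(
    alpha: np.ndarray,
    reference: np.ndarray,
    grid: SimGrid,
) -> float:
    """Percentage of viable cells relative to a reference field.

    100 × ∫α dA / ∫α_ref dA with trapezoidal nodal weights; the
    reference is the field at the normalization (treatment) time, so the
    reference itself reads 100%.
    """
    w = grid.node_weights()
    ref_mass = float(np.sum(reference * w))
    if ref_mass <= 0:
        raise ValueError("reference field has zero cell mass")
    return 100.0 * float(np.sum(alpha * w)) / ref_mass


@dataclass
class Trajectory:
    """Recorded fields and the viability curve of one simulation."""

    states: list[StateField]
    times: np.ndarray
    viability_pct: np.ndarray

    def viability_at(self, t: float) -> float:
        i = np.flatnonzero(np.isclose(self.times, t, atol=1e-9))
        if i.size == 0:
            raise KeyError(f"time {t} h was not recorded")
        return float(self.viability_pct[i[0]])


def simulate(
    alpha0: np.ndarray,
    grid: SimGrid,
    p: ModelParams,
    config: SimConfig | None = None,
) -> Trajectory:
    """Run the coupled dynamics from t = 0 (treatment time) to t_end.

    Alternates the quasi-steady oxygen solve with the RK4 cell step,
    recording fields every ``record_every`` hours and reducing each to a
    viability percentage against the t = 0 field.
    """
    if config is None:
        config = SimConfig()
    alpha = np.asarray(alpha0, dtype=float).copy()
    if alpha.shape != (grid.ny, grid.nx):
        raise ValueError("alpha0 shape does not match grid")
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha0 must lie in [0, 1]")

    op = _OxygenOperator(grid) if p.Q > 0 else None
    rec_stride = int(round(config.record_every / config.dt))

    def oxygen(a, warm):
        if op is None:
            return np.ones((grid.ny, grid.nx))
        return op.solve(a, p, config, c0=warm)

    try:
        c = oxygen(alpha, None)
    except SolverError as e:
        raise SolverError(f"t=0 h: {e}") from e

    states = [StateField(t=0.0, alpha=alpha.copy(), c=c.copy())]
    for step in range(1, config.n_steps + 1):
        t = step * config.dt
        try:
            alpha = step_alpha(alpha, c, p, config)
            c = oxygen(alpha, c)
        except SolverError as e:
            raise SolverError(f"t={t:g} h: {e}") from e
        if step % rec_stride == 0:
            states.append(StateField(t=t, alpha=alpha.copy(), c=c.copy()))

    ref = states[0].alpha
    times = np.array([s.t for s in states])
    viab = np.array([viability_percent(s.alpha, ref, grid) for s in states])
    return Trajectory(states=states, times=times, viability_pct=viab)
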