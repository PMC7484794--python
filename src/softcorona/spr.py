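"""Two-dimensional affinity-distribution analysis of SPR sensorgrams.

A sensorgram series recorded at several analyte concentrations is modelled
as a superposition of independent 1:1 Langmuir binding sites,

    R_total(t) = sum_j P_j * theta(K_D_j, k_off_j; C, t),

with the site weights P >= 0 living on a 21 x 21 logarithmic grid of
equilibrium dissociation constants K_D (default 1e-9 to 1e-3 M) and
off-rates k_off (default 1e-5 to 1e0 s^-1); the on-rate is k_a = k_off/K_D.
The weights are recovered by non-negative least squares with zeroth-order
Tikhonov regularization. The regularization strength is chosen by an
F-statistic parsimony rule: among a log-spaced scan of strengths, the
largest alpha is kept whose residual sum of squares S(alpha) still satisfies

    S(alpha) <= S_min * (1 + q * F^-1(p; q, n-q) / (n - q)),

with n retained data points, q grid nodes and confidence p (default 0.95) —
the most parsimonious distribution statistically consistent with the best
fit, showing only features the data demand.

Association and dissociation fit windows exclude the rinsing gap between
phases; a linear drift correction (mean of pre- and post-injection baseline
slopes) can be applied first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .errors import (
    ConfigurationError,
    EmptyDistributionError,
    InsufficientBaselineError,
    InvalidInputError,
    InvalidMeasurementError,
)

#: Grid-axis defaults: K_D in M, k_off in s^-1, 21 log-spaced points each.
KD_BOUNDS = (1e-9, 1e-3)
KOFF_BOUNDS = (1e-5, 1e0)
GRID_POINTS = 21

MODES = ("independent_cycles", "sequential_titration")


@dataclass(frozen=True)
class InjectionSchedule:
    """Sequential-injection layout shared by all cycles.

    Times are seconds from the start of each cycle; concentrations are the
    per-cycle analyte concentrations in nM, strictly increasing. The fit
    windows select the association and dissociation stretches retained for
    fitting (data around the rinse between them are omitted).
    """

    concentrations_nM: tuple = (20.0, 100.0, 300.0, 1000.0, 3000.0)
    t_inject_start: float = 0.0
    t_inject_end: float = 800.0
    t_dissoc_end: float = 2400.0
    assoc_window: tuple = (2.0, 798.0)
    dissoc_window: tuple = (1400.0, 2400.0)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_nM, dtype=float)
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ConfigurationError(
                "concentrations must be positive and strictly increasing"
            )
        a0, a1 = self.assoc_window
        d0, d1 = self.dissoc_window
        if not (self.t_inject_start <= a0 < a1 <= self.t_inject_end):
            raise ConfigurationError("association window outside injection phase")
        if not (self.t_inject_end < d0 < d1 <= self.t_dissoc_end):
            raise ConfigurationError("dissociation window outside dissociation phase")

    @property
    def concentrations_M(self) -> np.ndarray:
        return np.asarray(self.concentrations_nM, dtype=float) * 1e-9

    @property
    def n_cycles(self) -> int:
        return len(self.concentrations_nM)

    def retained_mask(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask of cycle-local times inside the fit windows."""
        t = np.asarray(times, dtype=float)
        a0, a1 = self.assoc_window
        d0, d1 = self.dissoc_window
        return ((t >= a0) & (t <= a1)) | ((t >= d0) & (t <= d1))


@dataclass
class Sensorgram:
    """Response-vs-time traces over injection cycles.

    ``time`` is cycle-local (seconds from each cycle start); ``cycle`` maps
    each point to its injection cycle (0-based, ordered as the schedule's
    concentrations).
    """

    time: np.ndarray
    response: np.ndarray
    cycle: np.ndarray
    drift_corrected: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.cycle = np.asarray(self.cycle, dtype=int)
        if not (len(self.time) == len(self.response) == len(self.cycle)):
            raise InvalidInputError("time/response/cycle lengths differ")
        if not np.all(np.isfinite(self.response)):
            raise InvalidInputError("non-finite responses")
        for c in np.unique(self.cycle):
            t = self.time[self.cycle == c]
            if np.any(np.diff(t) <= 0):
                raise InvalidInputError(f"time not strictly increasing in cycle {c}")

    @property
    def n_cycles(self) -> int:
        return int(self.cycle.max()) + 1

    def cycle_data(self, c: int) -> tuple[np.ndarray, np.ndarray]:
        sel = self.cycle == c
        return self.time[sel], self.response[sel]


@dataclass
class KineticGrid:
    """21 x 21 (K_D, k_off) grid with fitted non-negative weights (RU)."""

    kd_values: np.ndarray  # (n_kd,), M
    koff_values: np.ndarray  # (n_koff,), s^-1
    weights: np.ndarray  # (n_kd, n_koff), RU
    alpha: float = 0.0  # chosen regularization strength
    rss: float = np.nan  # residual sum of squares at alpha
    rss_min: float = np.nan  # best RSS over the scan
    rss_threshold: float = np.nan  # parsimony acceptance bound
    n_points: int = 0  # retained data points
    parsimony_ok: bool = True
    mode: str = "independent_cycles"

    @property
    def total_signal(self) -> float:
        return float(self.weights.sum())

    @property
    def ka_values(self) -> np.ndarray:
        """Derived on-rates k_a = k_off / K_D (M^-1 s^-1), grid-shaped."""
        return self.koff_values[None, :] / self.kd_values[:, None]

    def nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (kd, koff) node coordinates; K_D varies slowest."""
        kd, koff = np.meshgrid(self.kd_values, self.koff_values, indexing="ij")
        return kd.ravel(), koff.ravel()


def default_grid(
    kd_bounds: tuple = KD_BOUNDS,
    koff_bounds: tuple = KOFF_BOUNDS,
    n: int = GRID_POINTS,
) -> KineticGrid:
    """Empty grid with the published axis bounds and 21 points per axis."""
    kd = np.logspace(np.log10(kd_bounds[0]), np.log10(kd_bounds[1]), n)
    koff = np.logspace(np.log10(koff_bounds[0]), np.log10(koff_bounds[1]), n)
    return KineticGrid(kd_values=kd, koff_values=koff, weights=np.zeros((n, n)))


# ---------------------------------------------------------------------------
# Langmuir 1:1 basis traces
# ---------------------------------------------------------------------------

def _theta_cycles(
    kd: np.ndarray,
    koff: np.ndarray,
    schedule: InjectionSchedule,
    times_per_cycle: Sequence[np.ndarray],
    mode: str,
) -> list[np.ndarray]:
    """Occupancy traces theta(t) for arrays of nodes, one block per cycle.

    Returns a list of (n_nodes, n_times_c) arrays. Sequential mode carries
    the end-of-cycle occupancy into the next cycle; independent mode resets
    to zero.
    """
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}")
    kd = np.atleast_1d(np.asarray(kd, dtype=float))
    koff = np.atleast_1d(np.asarray(koff, dtype=float))
    if np.any(kd <= 0) or np.any(koff <= 0):
        raise InvalidMeasurementError("K_D and k_off must be > 0")
    ka = koff / kd
    t0 = schedule.t_inject_start
    t_off = schedule.t_inject_end
    theta0 = np.zeros_like(kd)
    out = []
    for conc, times in zip(schedule.concentrations_M, times_per_cycle):
        t = np.asarray(times, dtype=float)
        rate = ka * conc + koff  # (nodes,)
        theta_eq = conc / (conc + kd)
        assoc = theta_eq[:, None] + (theta0 - theta_eq)[:, None] * np.exp(
            -rate[:, None] * np.clip(t[None, :] - t0, 0.0, None)
        )
        theta_off = theta_eq + (theta0 - theta_eq) * np.exp(-rate * (t_off - t0))
        dissoc = theta_off[:, None] * np.exp(
            -koff[:, None] * np.clip(t[None, :] - t_off, 0.0, None)
        )
        theta = np.where(t[None, :] <= t_off, assoc, dissoc)
        theta = np.where(t[None, :] < t0, theta0[:, None], theta)
        out.append(theta)
        if mode == "sequential_titration":
            end = schedule.t_dissoc_end
            theta0 = theta_off * np.exp(-koff * (end - t_off))
        # independent mode: theta0 stays 0
    return out


def langmuir_basis(
    kd: float,
    koff: float,
    schedule: InjectionSchedule,
    times: np.ndarray,
    mode: str = "independent_cycles",
) -> np.ndarray:
    """Unit-amplitude occupancy trace of one site, (n_cycles, len(times)).

    ``times`` is a cycle-local grid reused for every cycle.
    """
    blocks = _theta_cycles(
        [kd], [koff], schedule, [times] * schedule.n_cycles, mode
    )
    return np.vstack([b[0] for b in blocks])


def build_design_matrix(
    grid: KineticGrid,
    schedule: InjectionSchedule,
    times_per_cycle: Sequence[np.ndarray],
    mode: str = "independent_cycles",
) -> np.ndarray:
    """Design matrix over retained time points: rows = (cycle, time) points
    inside the fit windows, columns = grid nodes (K_D slowest)."""
    kd, koff = grid.nodes()
    retained = [schedule.retained_mask(t) for t in times_per_cycle]
    if not any(m.any() for m in retained):
        raise ConfigurationError("no time points inside the fit windows")
    blocks = _theta_cycles(kd, koff, schedule, times_per_cycle, mode)
    cols = [b[:, m] for b, m in zip(blocks, retained)]
    return np.hstack(cols).T  # (n_points, n_nodes)


# ---------------------------------------------------------------------------
# Drift correction
# ---------------------------------------------------------------------------

def drift_correct(
    s: Sensorgram,
    pre_window: tuple,
    post_window: tuple,
) -> Sensorgram:
    """Remove a linear baseline drift from each cycle.

    The drift slope is the mean of the slopes fitted in the pre- and
    post-injection baseline windows (cycle-local seconds); the subtracted
    line is anchored so the pre-injection baseline averages zero.
    """
    time = s.time.copy()
    resp = s.response.copy()
    for c in np.unique(s.cycle):
        sel = s.cycle == c
        t, y = time[sel], resp[sel]
        slopes = []
        anchor = None
        for lo, hi in (pre_window, post_window):
            w = (t >= lo) & (t <= hi)
            if w.sum() < 2:
                raise InsufficientBaselineError(
                    f"cycle {c}: window [{lo}, {hi}] has < 2 points"
                )
            slope, intercept = np.polyfit(t[w], y[w], 1)
            slopes.append(slope)
            if anchor is None:
                anchor = (t[w].mean(), y[w].mean())
        slope = float(np.mean(slopes))
        t_ref, y_ref = anchor
        resp[sel] = y - (slope * (t - t_ref) + y_ref)
    return Sensorgram(time=time, response=resp, cycle=s.cycle.copy(),
                      drift_corrected=True)


# ---------------------------------------------------------------------------
# Regularized inversion
# ---------------------------------------------------------------------------

def _nnls_normal_equations(
    gram: np.ndarray, atb: np.ndarray, alpha: float, jitter: float
) -> np.ndarray:
    """argmin_{P>=0} ||A P - r||^2 + alpha ||P||^2 via the normal equations.

    Factorizes G + alpha*I = L L^T and solves the equivalent small NNLS
    problem min ||L^T P - L^-1 A^T r||^2; ``jitter`` keeps the factorization
    positive definite as alpha -> 0.
    """
    q = gram.shape[0]
    eps = jitter
    for _ in range(8):
        try:
            low = linalg.cholesky(
                gram + (alpha + eps) * np.eye(q), lower=True
            )
            break
        except linalg.LinAlgError:
            eps = max(eps * 100.0, 1e-14)
    else:  # pragma: no cover - pathological conditioning
        raise InvalidInputError("Gram matrix could not be factorized")
    y = linalg.solve_triangular(low, atb, lower=True)
    weights, _ = optimize.nnls(low.T, y)
    return weights


def fit_distribution(
    sensorgram: Sensorgram,
    schedule: InjectionSchedule,
    grid: Optional[KineticGrid] = None,
    mode: str = "independent_cycles",
    reg_confidence: float = 0.95,
    alphas: Optional[np.ndarray] = None,
    alpha: Optional[float] = None,
) -> KineticGrid:
    """Fit the non-negative (K_D, k_off) weight distribution to a sensorgram.

    Globally fits association and dissociation windows of all cycles. With
    ``alpha`` given, solves at that single regularization strength;
    otherwise scans ``alphas`` (default: 34 log-spaced multiples of the
    mean Gram-diagonal) and applies the F-statistic parsimony rule at
    ``reg_confidence``.
    """
    if grid is None:
        grid = default_grid()
    if sensorgram.n_cycles != schedule.n_cycles:
        raise ConfigurationError(
            f"sensorgram has {sensorgram.n_cycles} cycles, schedule "
            f"{schedule.n_cycles}"
        )
    times_per_cycle, data = [], []
    for c in range(schedule.n_cycles):
        t, y = sensorgram.cycle_data(c)
        times_per_cycle.append(t)
        data.append(y[schedule.retained_mask(t)])
    r = np.concatenate(data)
    a_mat = build_design_matrix(grid, schedule, times_per_cycle, mode)
    n, q = a_mat.shape

    gram = a_mat.T @ a_mat
    atb = a_mat.T @ r
    scale = np.trace(gram) / q
    jitter = 1e-12 * scale

    def solve(a: float) -> tuple[np.ndarray, float]:
        w = _nnls_normal_equations(gram, atb, a, jitter)
        resid = a_mat @ w - r
        return w, float(resid @ resid)

    if alpha is not None:
        weights, rss = solve(alpha)
        result_alpha, rss_min, threshold, ok = alpha, rss, np.nan, True
    else:
        if alphas is None:
            alphas = scale * np.logspace(-8, 3, 34)
        alphas = np.sort(np.asarray(alphas, dtype=float))
        solutions = [solve(a) for a in alphas]
        rss_all = np.array([s[1] for s in solutions])
        rss_min = float(rss_all.min())
        if n <= q:
            raise ConfigurationError(
                f"need more than {q} retained points, got {n}"
            )
        fcrit = stats.f.ppf(reg_confidence, q, n - q)
        threshold = rss_min * (1.0 + q * fcrit / (n - q))
        feasible = np.flatnonzero(rss_all <= threshold)
        ok = feasible.size > 0
        idx = int(feasible.max()) if ok else 0
        weights, rss = solutions[idx]
        result_alpha = float(alphas[idx])

    return KineticGrid(
        kd_values=grid.kd_values,
        koff_values=grid.koff_values,
        weights=weights.reshape(len(grid.kd_values), len(grid.koff_values)),
        alpha=result_alpha,
        rss=rss,
        rss_min=rss_min,
        rss_threshold=threshold,
        n_points=n,
        parsimony_ok=ok,
        mode=mode,
    )


def predict_response(
    grid: KineticGrid,
    schedule: InjectionSchedule,
    times: np.ndarray,
    mode: str = "independent_cycles",
) -> np.ndarray:
    """Model sensorgram R_total(t) = sum_j P_j theta_j(t), one row per cycle."""
    kd, koff = grid.nodes()
    blocks = _theta_cycles(kd, koff, schedule, [times] * schedule.n_cycles, mode)
    w = grid.weights.ravel()
    return np.vstack([w @ b for b in blocks])


def population_fractions(
    grid: KineticGrid,
    regions: Sequence[tuple],
) -> dict:
    """Signal fraction of each (K_D range, k_off range) region.

    ``regions`` is a sequence of ((kd_lo, kd_hi), (koff_lo, koff_hi))
    rectangles, pairwise disjoint at the node level; mass outside every
    region is reported under "unassigned".
    """
    total = grid.weights.sum()
    if total <= 0:
        raise EmptyDistributionError("distribution has zero total weight")
    kd, koff = np.meshgrid(grid.kd_values, grid.koff_values, indexing="ij")
    assigned = np.zeros(grid.weights.shape, dtype=bool)
    fractions = {}
    for i, ((kd_lo, kd_hi), (koff_lo, koff_hi)) in enumerate(regions):
        member = (
            (kd >= kd_lo) & (kd <= kd_hi) & (koff >= koff_lo) & (koff <= koff_hi)
        )
        if (member & assigned).any():
            raise ConfigurationError("regions overlap at grid nodes")
        assigned |= member
        fractions[f"region_{i}"] = float(grid.weights[member].sum() / total)
    fractions["unassigned"] = float(grid.weights[~assigned].sum() / total)
    return fractions


def mass_weighted_centroid(grid: KineticGrid) -> tuple[float, float]:
    """(log10 K_D, log10 k_off) centroid of the weight distribution."""
    total = grid.weights.sum()
    if total <= 0:
        raise EmptyDistributionError("distribution has zero total weight")
    lkd = np.log10(grid.kd_values)
    lko = np.log10(grid.koff_values)
    ckd = float((grid.weights.sum(axis=1) @ lkd) / total)
    cko = float((grid.weights.sum(axis=0) @ lko) / total)
    return ckd, cko
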