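"""Uniform sampling of the steady-state flux polytope.

The feasible set {v : Sv = 0, lb <= v <= ub} is a convex polytope inside the
null space of S.  :func:`achr_sample` walks it with an artificially-centered
hit-and-run (ACHR) chain: each step picks a direction from a randomly chosen
warmup point to the running center of all visited points, finds the feasible
segment along that direction, and jumps to a uniformly chosen point on it.
Warmup points are the 2n flux-variability vertices pulled toward their
centroid.  Numerical drift off the null space is cancelled by periodic
re-projection onto null(S).

:func:`rejection_sample` is an exact, brute-force uniform sampler for
low-dimensional polytopes (<= 4 free dimensions) used as an independent
oracle when validating the chain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from .model import StoichiometricSystem

logger = logging.getLogger(__name__)

_DIR_EPS = 1e-12  # direction components below this are treated as zero


class DegeneratePolytopeWarning(UserWarning):
    """The polytope has no free directions; the unique point is returned."""


@dataclass
class SamplerConfig:
    """ACHR sampler settings.

    ``max_steps`` is a hard ceiling on total chain steps.  ``steps_per_sample``
    (thinning) defaults to 100 x the number of free dimensions when None.
    ``projection_period`` is in recorded samples.  ``tolerance`` caps |Sv| for
    any returned sample.
    """

    n_samples: int = 10000
    max_steps: int = int(1e10)
    seed: int = 0
    steps_per_sample: int | None = None
    projection_period: int = 50
    tolerance: float = 1e-6
    warmup_pull: float = 0.33

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class SampleSet:
    """n_samples x n_reactions matrix of sampled flux vectors."""

    strain: str
    time_h: float
    samples: np.ndarray
    reaction_ids: list[str]
    config: SamplerConfig = field(default_factory=SamplerConfig)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def column(self, rid: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rid)]


@dataclass
class ValidityReport:
    max_abs_sv: float
    n_bound_violations: int
    empty: bool = False


# ---------------------------------------------------------------------------
# LP kernel


def solve_lp(
    system: StoichiometricSystem, objective: np.ndarray, sense: str = "max"
) -> tuple[str, float | None, np.ndarray | None]:
    """Optimise a linear objective over the flux polytope.

    Returns (status, objective value, flux vector); status is one of
    "optimal", "infeasible", "unbounded".
    """
    c = np.asarray(objective, dtype=float)
    if sense == "max":
        c = -c
    elif sense != "min":
        raise ValueError("sense must be 'max' or 'min'")
    res = linprog(
        c=c,
        A_eq=system.S,
        b_eq=np.zeros(system.n_metabolites),
        bounds=list(zip(system.lb, system.ub)),
        method="highs",
    )
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    if not res.success:
        raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")
    val = float(res.fun) if sense == "min" else -float(res.fun)
    return "optimal", val, np.asarray(res.x)


def flux_variability(system: StoichiometricSystem) -> np.ndarray:
    """Per-reaction (min, max) flux over the polytope; shape (n, 2)."""
    status, _, _ = solve_lp(system, np.zeros(system.n_reactions), "min")
    if status != "optimal":
        raise RuntimeError(f"system is {status}; cannot run flux variability")
    out = np.empty((system.n_reactions, 2))
    for j in range(system.n_reactions):
        c = np.zeros(system.n_reactions)
        c[j] = 1.0
        for k, sense in enumerate(("min", "max")):
            status, val, _ = solve_lp(system, c, sense)
            if status != "optimal":
                raise RuntimeError(f"FVA {sense} failed for reaction {j}: {status}")
            out[j, k] = val
    return out


def _fva_vertices(system: StoichiometricSystem) -> np.ndarray:
    """The 2n optimal vertices from per-reaction min/max LPs."""
    pts = []
    for j in range(system.n_reactions):
        c = np.zeros(system.n_reactions)
        c[j] = 1.0
        for sense in ("min", "max"):
            status, _, v = solve_lp(system, c, sense)
            if status != "optimal":
                raise RuntimeError(f"warmup LP {sense} failed for reaction {j}: {status}")
            pts.append(v)
    return np.array(pts)


def generate_warmup(
    system: StoichiometricSystem, config: SamplerConfig | None = None
) -> np.ndarray:
    """2n FVA vertices pulled ``warmup_pull`` of the way toward their mean.

    Pulling avoids starting the chain exactly on the boundary; by convexity
    the pulled points remain feasible.
    """
    config = config or SamplerConfig()
    verts = _fva_vertices(system)
    center = verts.mean(axis=0)
    return verts + config.warmup_pull * (center - verts)


def _null_projector(S: np.ndarray) -> np.ndarray:
    N = null_space(S)
    if N.size == 0:
        return np.zeros((S.shape[1], S.shape[1]))
    return N @ N.T


def n_free_dimensions(
    system: StoichiometricSystem, tol: float = 1e-9, fva: np.ndarray | None = None
) -> int:
    """Dimension of the flux polytope.

    Computed as the rank of the null-space basis of S restricted to the
    coordinates whose FVA range exceeds ``tol``: null-space directions that
    only move bound-pinned reactions do not extend the polytope.  This is
    what thinning and the rejection-oracle guard care about.
    """
    if fva is None:
        fva = flux_variability(system)
    pinned = fva[:, 1] - fva[:, 0] <= tol
    if np.all(pinned):
        return 0
    # equality-pin the FVA-fixed coordinates and take the remaining null space
    rows = np.eye(system.n_reactions)[pinned]
    aug = np.vstack([system.S, rows]) if rows.size else system.S
    N = null_space(aug)
    return int(N.shape[1]) if N.size else 0


def achr_sample(
    system: StoichiometricSystem,
    config: SamplerConfig,
    strain: str = "",
    time_h: float = float("nan"),
) -> SampleSet:
    """Run the ACHR chain and return ``config.n_samples`` flux vectors.

    Deterministic given (system, config.seed).  Raises on infeasible systems;
    warns and returns the unique point repeated when the polytope is a single
    point.
    """
    rng = np.random.default_rng(config.seed)
    lb, ub = system.lb, system.ub
    warmup = generate_warmup(system, config)
    fva = flux_variability(system)
    free_dims = n_free_dimensions(system, fva=fva)

    if free_dims == 0:
        warnings.warn(
            "polytope has no free dimensions; returning its unique point",
            DegeneratePolytopeWarning,
        )
        point = warmup.mean(axis=0)
        samples = np.tile(point, (config.n_samples, 1))
        return SampleSet(strain, time_h, samples, list(system.reaction_ids), config)

    thin = config.steps_per_sample or 100 * free_dims
    projector = _null_projector(system.S)
    pinned = fva[:, 1] - fva[:, 0] <= 1e-9

    center = warmup.mean(axis=0)
    x = projector @ center
    np.clip(x, lb, ub, out=x)
    n_visited = warmup.shape[0]
    samples = np.empty((config.n_samples, system.n_reactions))
    steps_done = 0
    consecutive_failures = 0

    for i in range(config.n_samples):
        k = 0
        while k < thin:
            if steps_done >= config.max_steps:
                raise RuntimeError(
                    f"step ceiling {config.max_steps} reached after {i} samples"
                )
            d = warmup[rng.integers(warmup.shape[0])] - center
            # re-project the direction so rounding drift cannot feed back
            # through the running center and compound over the chain; pinned
            # coordinates never move (projection noise could unpin them)
            d = projector @ d
            d[pinned] = 0.0
            nrm = np.linalg.norm(d)
            if nrm < _DIR_EPS:
                consecutive_failures += 1
                if consecutive_failures >= 100:
                    raise RuntimeError(
                        "100 consecutive zero-norm directions; polytope is degenerate"
                    )
                continue
            d = d / nrm
            mask = np.abs(d) > _DIR_EPS
            lo = (lb[mask] - x[mask]) / d[mask]
            hi = (ub[mask] - x[mask]) / d[mask]
            amin = np.minimum(lo, hi).max()
            amax = np.maximum(lo, hi).min()
            if amax - amin < _DIR_EPS:
                consecutive_failures += 1
                if consecutive_failures >= 100:
                    raise RuntimeError(
                        "100 consecutive blocked directions; polytope is degenerate"
                    )
                continue
            consecutive_failures = 0
            # keep strictly inside by a hair so ties at bounds resolve inward
            alpha = rng.uniform(amin + _DIR_EPS, amax - _DIR_EPS)
            x = x + alpha * d
            np.clip(x, lb, ub, out=x)  # shed sub-1e-11 rounding excursions
            n_visited += 1
            center = center + (x - center) / n_visited
            steps_done += 1
            k += 1
        if (i + 1) % config.projection_period == 0:
            x = projector @ x
            np.clip(x, lb, ub, out=x)
            resid = np.max(np.abs(system.S @ x))
            if resid > config.tolerance:
                raise RuntimeError(
                    f"mass-balance residual {resid:.2e} exceeds tolerance after projection"
                )
        samples[i] = x

    sample_set = SampleSet(strain, time_h, samples, list(system.reaction_ids), config)
    report = check_sample_validity(sample_set, system)
    if report.n_bound_violations or report.max_abs_sv > config.tolerance:
        raise RuntimeError(
            f"sampler produced invalid points: max|Sv|={report.max_abs_sv:.2e}, "
            f"{report.n_bound_violations} bound violations"
        )
    _geweke_diagnostic(samples, system.reaction_ids)
    return sample_set


def _geweke_diagnostic(samples: np.ndarray, reaction_ids, z_warn: float = 4.0) -> None:
    """Warning-only mean-split convergence check per reaction."""
    n = samples.shape[0]
    if n < 100:
        return
    a, b = samples[: n // 4], samples[-n // 2 :]
    pooled = np.sqrt(a.var(axis=0) / a.shape[0] + b.var(axis=0) / b.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(a.mean(axis=0) - b.mean(axis=0)) / pooled
    bad = [rid for rid, zi in zip(reaction_ids, z) if np.isfinite(zi) and zi > z_warn]
    if bad:
        logger.warning("possible non-convergence (|z|>%.1f) for reactions: %s", z_warn, bad)


def rejection_sample(
    system: StoichiometricSystem,
    n: int,
    seed: int = 0,
    max_free_dims: int = 4,
    strain: str = "",
    time_h: float = float("nan"),
) -> SampleSet:
    """Exactly uniform sampling by rejection in affine-hull coordinates.

    Parameterises v = v0 + M u, where v0 is a feasible anchor (the pulled-in
    warmup centroid) and M an orthonormal basis of the polytope's affine hull
    (the null space of S augmented with the FVA-pinned coordinates, so
    bound-pinned directions are excluded).  u is drawn uniformly in the
    bounding box of the hull coordinates and points violating any flux bound
    are discarded, which is exactly uniform on the polytope.  Cost is
    exponential in the free dimension, so systems with more than
    ``max_free_dims`` free dimensions are rejected.
    """
    fva = flux_variability(system)
    free = n_free_dimensions(system, fva=fva)
    if free == 0:
        _, _, v = solve_lp(system, np.zeros(system.n_reactions), "min")
        return SampleSet(strain, time_h, np.tile(v, (n, 1)), list(system.reaction_ids))
    if free > max_free_dims:
        raise ValueError(
            f"rejection sampling guarded to <= {max_free_dims} free dimensions, got {free}"
        )
    pinned = fva[:, 1] - fva[:, 0] <= 1e-9
    aug = np.vstack([system.S, np.eye(system.n_reactions)[pinned]])
    M = null_space(aug)
    v0 = generate_warmup(system).mean(axis=0)

    # bounding box of u = M^T (v - v0) over the polytope, via LPs
    box = np.empty((free, 2))
    for k in range(free):
        offset = float(M[:, k] @ v0)
        for s, sense in enumerate(("min", "max")):
            status, val, _ = solve_lp(system, M[:, k], sense)
            if status != "optimal":
                raise RuntimeError(f"bounding-box LP failed: {status}")
            box[k, s] = val - offset

    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    tried = 0
    got = 0
    tol = 1e-9
    batch = max(4 * n, 1000)
    while got < n:
        u = rng.uniform(box[:, 0], box[:, 1], size=(batch, free))
        v = v0 + u @ M.T
        ok = np.all(v >= system.lb - tol, axis=1) & np.all(v <= system.ub + tol, axis=1)
        accepted.append(v[ok])
        tried += batch
        got = sum(a.shape[0] for a in accepted)
        if tried > 1e6 and got / tried < 1e-6:
            raise RuntimeError(
                f"rejection acceptance rate {got/tried:.2e} below 1e-6; giving up"
            )
    samples = np.vstack(accepted)[:n]
    return SampleSet(strain, time_h, samples, list(system.reaction_ids))


def check_sample_validity(
    samples: SampleSet, system: StoichiometricSystem, tol: float | None = None
) -> ValidityReport:
    """Worst mass-balance residual and count of bound violations beyond tol."""
    tol = tol if tol is not None else samples.config.tolerance
    X = samples.samples
    if X.size == 0:
        return ValidityReport(0.0, 0, empty=True)
    max_sv = float(np.max(np.abs(system.S @ X.T)))
    viol = int(
        np.sum(np.any((X < system.lb - tol) | (X > system.ub + tol), axis=1))
    )
    return ValidityReport(max_sv, viol)


# ---------------------------------------------------------------------------
# persistence


def write_sample_csv(samples: SampleSet, path: str) -> None:
    import pandas as pd

    pd.DataFrame(samples.samples, columns=samples.reaction_ids).to_csv(path, index=False)


def read_sample_csv(path: str, strain: str = "", time_h: float = float("nan")) -> SampleSet:
    import pandas as pd

    df = pd.read_csv(path)
    return SampleSet(strain, time_h, df.to_numpy(), list(df.columns))
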