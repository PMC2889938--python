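"""Match NCA-reconstructed and simulated NF-κB profiles to infer IKK input.

The data-derived TF activity (log-ratio scale, relative units) and the
simulated nuclear NF-κB concentration live on different scales, so both
are mapped to relative activities: the simulated concentration is
divided by its resting (t = 0) value and logged — mirroring the
log-ratio convention of the expression data — and both series are then
scaled to a maximum of 1.  Candidate IKK inputs are ranked by the
Pearson correlation between the two normalized profiles on the shared
time grid; since Pearson correlation is invariant under positive affine
maps, the winner does not depend on the normalization convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import TimeGrid, ValidationError
from .ikk import IKKProfile
from .kinetics import KineticModel, equilibrate, nfkb_activity, simulate

__all__ = [
    "MatchResult",
    "normalize_max1",
    "sim_to_activity",
    "pearson",
    "match_profiles",
]


@dataclass
class MatchResult:
    """Winning IKK candidate for one condition, with the full score table."""

    best_profile: IKKProfile
    pcc: float
    per_candidate: list[tuple[str, float]]
    normalized_target: np.ndarray
    normalized_best: np.ndarray
    grid: TimeGrid


def normalize_max1(series) -> np.ndarray:
    """Scale a series so its maximum is exactly 1.0."""
    x = np.asarray(series, dtype=float)
    m = x.max()
    if not np.isfinite(m) or m <= 0:
        raise ValidationError(f"series maximum {m} is not positive")
    return x / m


def sim_to_activity(conc, total_moiety: float | None = None,
                    floor: float | None = None) -> np.ndarray:
    """Convert simulated nuclear NF-κB concentrations to relative activity.

    r_j = ln(max(c_j, eps) / max(c_0, eps)) with c_0 the resting (first)
    value, matching the log-ratio convention of the expression data;
    eps = 1e-6 x ``total_moiety`` (or an explicit ``floor``) guards the
    log against a near-zero resting concentration.  The log series is
    then scaled to maximum 1 when its maximum is positive; otherwise it
    is returned unscaled (flat response).
    """
    c = np.asarray(conc, dtype=float)
    if c.min() < 0:
        raise ValidationError("concentrations must be >= 0")
    if np.all(c == 0):
        raise ValidationError("all-zero concentration series")
    if floor is None:
        floor = 1e-6 * (total_moiety if total_moiety is not None else c.max())
    r = np.log(np.maximum(c, floor) / max(c[0], floor))
    if r.max() > 0:
        return normalize_max1(r)
    return r


def pearson(x, y) -> float:
    """Sample Pearson correlation; zero variance is an error, not NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"series shapes differ: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError(f"need >= 3 points, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise ValidationError("zero variance in a series")
    return float((xc * yc).sum() / (sx * sy))


def match_profiles(
    target,
    candidates: list[IKKProfile],
    model: KineticModel,
    grid: TimeGrid,
    *,
    drop_t0: bool = False,
    rtol: float = 1e-7,
    atol: float = 1e-10,
    refine: bool = False,
) -> MatchResult:
    """Select the candidate IKK input whose simulation best matches the target.

    Every candidate is simulated from the common pre-equilibrated
    resting state, its nuclear NF-κB is sampled on ``grid``, converted
    to relative activity, and scored by Pearson correlation against the
    max-1-normalized target.  Ties are broken by the smaller IKK time
    integral (parsimony), then by candidate order.  ``drop_t0`` excludes
    the t = 0 point from the correlation.  ``refine`` polishes the
    winner's knot heights with a derivative-free maximizer of r.
    """
    if not candidates:
        raise ValidationError("no candidates")
    target = np.asarray(target, dtype=float)
    times = grid.as_array()
    if target.shape != times.shape:
        raise ValidationError(
            f"target length {target.size} != grid length {times.size}")
    sel = slice(1, None) if drop_t0 else slice(None)

    basals = {c.basal for c in candidates}
    rest = {b: equilibrate(model, b) for b in basals}
    t_end = float(times[-1])
    norm_target = normalize_max1(target)
    total = None
    if "NFkB_total" in model.moieties:
        total = model.moiety_total("NFkB_total", rest[candidates[0].basal])

    def score(prof: IKKProfile) -> tuple[float, np.ndarray]:
        traj = simulate(model, prof, t_end, rtol=rtol, atol=atol,
                        equilibrate_first=False, y0=rest[prof.basal])
        act = sim_to_activity(nfkb_activity(traj, grid), total_moiety=total)
        return pearson(norm_target[sel], act[sel]), act

    table: list[tuple[str, float]] = []
    best_i, best_key, best_act = -1, None, None
    for i, prof in enumerate(candidates):
        r, act = score(prof)
        table.append((prof.label or f"candidate{i}", r))
        key = (-r, prof.integral(), i)
        if best_key is None or key < best_key:
            best_i, best_key, best_act = i, key, act
    best = candidates[best_i]
    best_r = table[best_i][1]

    if refine:
        from scipy.optimize import minimize

        v0 = np.array(best.knot_values)

        def neg_r(v):
            prof = IKKProfile(best.knot_times, tuple(np.maximum(v, 0.0)),
                              basal=best.basal, label=best.label + "_refined")
            try:
                return -score(prof)[0]
            except (ValidationError, RuntimeError):
                return 1.0

        opt = minimize(neg_r, v0, method="Nelder-Mead",
                       options={"maxiter": 200, "xatol": 1e-3, "fatol": 1e-5})
        if -opt.fun > best_r:
            best = IKKProfile(best.knot_times,
                              tuple(np.maximum(opt.x, 0.0)),
                              basal=best.basal, label=best.label + "_refined")
            best_r, best_act = score(best)

    return MatchResult(best, best_r, table, norm_target, best_act, grid)
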