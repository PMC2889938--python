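"""Piecewise-linear candidate IKK activity profiles.

The inverse problem searches over time-varying IKK kinase activities
represented by values at a fixed set of time knots with linear
interpolation in between.  Outside the knot range the activity sits at
a basal level (the resting kinase activity before stimulation).
The default knot set {0, 0.5, 1, 2, 4, 6, 12} h follows the kinase-assay
sampling times; the 1 h knot gives the search freedom at times the
expression grid does not sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .datamodel import ValidationError

__all__ = ["DEFAULT_KNOTS", "IKKProfile", "generate_candidates",
           "read_profile", "write_profile"]

DEFAULT_KNOTS: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 12.0)


@dataclass(frozen=True)
class IKKProfile:
    """Continuous piecewise-linear IKK activity curve.

    ``basal`` applies before the first and after the last knot.
    """

    knot_times: tuple[float, ...]
    knot_values: tuple[float, ...]
    basal: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.knot_times)
        v = tuple(float(x) for x in self.knot_values)
        if len(t) != len(v):
            raise ValidationError(
                f"{len(t)} knot times vs {len(v)} values")
        if len(t) < 1:
            raise ValidationError("profile needs >= 1 knot")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError(f"knot times not strictly increasing: {t}")
        if not all(np.isfinite(v)) or min(v) < 0:
            raise ValidationError(f"knot values must be finite and >= 0: {v}")
        if not np.isfinite(self.basal) or self.basal < 0:
            raise ValidationError(f"basal must be finite and >= 0: {self.basal}")
        object.__setattr__(self, "knot_times", t)
        object.__setattr__(self, "knot_values", v)

    def evaluate(self, t) -> float | np.ndarray:
        """Activity at time(s) t: linear between knots, basal outside."""
        tt = np.asarray(t, dtype=float)
        out = np.interp(tt, self.knot_times, self.knot_values,
                        left=self.basal, right=self.basal)
        return float(out) if np.isscalar(t) else out

    __call__ = evaluate

    @property
    def peak_time(self) -> float:
        """Knot time of maximum activity (earliest on ties)."""
        return self.knot_times[int(np.argmax(self.knot_values))]

    @property
    def peak_value(self) -> float:
        return max(self.knot_values)

    def integral(self) -> float:
        """Time integral of the activity over the knot span (trapezoid)."""
        return float(np.trapezoid(self.knot_values, self.knot_times))


def generate_candidates(
    *,
    peak_times,
    peak_heights,
    decay_fractions,
    knots=DEFAULT_KNOTS,
    basal: float = 0.0,
    second_wave=None,
) -> list[IKKProfile]:
    """Enumerate a pulse-decay family of candidate profiles.

    Each candidate rises linearly from ``basal`` at the first knot to a
    peak height at its peak time, then decays geometrically: each
    subsequent knot carries ``decay_fraction`` times the previous value
    (floored at basal).  ``second_wave``, when given, is an iterable of
    (time, added_height) pairs; each pair spawns an extra variant per
    base candidate with the height added at that knot (mimicking a late
    second activity wave), alongside the wave-free base candidates.

    The list is deduplicated and deterministically ordered (grid order).
    """
    knots = tuple(float(k) for k in knots)
    peak_times = list(peak_times)
    peak_heights = list(peak_heights)
    decay_fractions = list(decay_fractions)
    if not peak_times or not peak_heights or not decay_fractions:
        raise ValidationError("candidate grids must be non-empty")
    for pt in peak_times:
        if pt not in knots:
            raise ValidationError(f"peak time {pt} not in knot set {knots}")
    waves = [None] + [tuple(w) for w in (second_wave or [])]
    out: list[IKKProfile] = []
    seen: set[tuple] = set()
    for pt, h, d, wave in itertools.product(peak_times, peak_heights,
                                            decay_fractions, waves):
        vals = []
        for kt in knots:
            if kt < pt:
                v = basal + (h - basal) * (kt - knots[0]) / (pt - knots[0]) \
                    if pt > knots[0] else basal
            elif kt == pt:
                v = h
            else:
                prev = vals[-1]
                v = max(basal, prev * d)
            vals.append(v)
        label = f"peak{pt:g}h_h{h:g}_d{d:g}"
        if wave is not None:
            wt, wh = wave
            if wt not in knots:
                raise ValidationError(f"second-wave time {wt} not in knots")
            vals = [v + (wh if kt == wt else 0.0) for kt, v in zip(knots, vals)]
            label += f"_wave{wt:g}h_{wh:g}"
        key = tuple(round(v, 12) for v in vals)
        if key in seen:
            continue
        seen.add(key)
        out.append(IKKProfile(knots, tuple(vals), basal=basal, label=label))
    if not out:
        raise ValidationError("empty candidate set")
    return out


def read_profile(path) -> IKKProfile:
    """Read a two-column ``time_h  ikk_activity`` TSV (# comments allowed).

    A ``# basal: <x>`` comment sets the out-of-range activity; it
    defaults to the first knot's value.
    """
    times, vals = [], []
    basal = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "basal:" in line:
                    basal = float(line.split("basal:")[1])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}: expected 2 columns, got {len(parts)}")
            times.append(float(parts[0]))
            vals.append(float(parts[1]))
    if basal is None:
        basal = vals[0] if vals else 0.0
    return IKKProfile(tuple(times), tuple(vals), basal=basal)


def write_profile(profile: IKKProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# basal: {profile.basal:g}\n")
        fh.write("# time_h\tikk_activity\n")
        for t, v in zip(profile.knot_times, profile.knot_values):
            fh.write(f"{t:g}\t{v:.10g}\n")
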