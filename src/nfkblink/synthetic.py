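"""Synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates the layout of stimulus-response PBMC microarray
studies: ~50 target genes profiled at {0, 0.5, 2, 4, 6, 12} h under
three stimulus doses, on a log2-ratio scale, with regulatory strengths
shared across doses and dose-scaled TF activities.  Expression follows
the exact NCA forward model E = S_true · A_true plus i.i.d. Gaussian
noise, so ground-truth factors are available for recovery tests.

TF activities are gamma-shaped pulses (smooth rise and decay with the
peak placeable at any grid point); dose scaling of the amplitudes
defaults to (0.6, 0.8, 1.0), a sub-proportional spread across an
order-of-magnitude dose range as seen in innate-immune stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (ExpressionMatrix, RegulatoryNetwork, TimeGrid,
                        ValidationError)
from .ikk import IKKProfile
from .kinetics import KineticModel, nfkb_activity, simulate
from .linker import sim_to_activity
from .nca import check_identifiability

__all__ = ["SyntheticSpec", "gen_support", "pulse", "gen_nca_instance",
           "gen_end_to_end", "EndToEndBundle"]

DEFAULT_GRID = TimeGrid((0.0, 0.5, 2.0, 4.0, 6.0, 12.0))


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic NCA instance.

    ``peak_index`` places each TF's activity peak on the grid; TF k
    defaults to peaking at grid index 2 (2 h for the default grid), with
    later TFs shifted to keep activity rows linearly independent.
    """

    n_genes: int = 54
    n_tfs: int = 3
    n_edges: int = 77
    conditions: tuple[str, ...] = ("lps0.01", "lps0.1", "lps1")
    grid: TimeGrid = field(default_factory=lambda: DEFAULT_GRID)
    dose_scale: tuple[float, ...] = (0.6, 0.8, 1.0)
    strength_mu: float = 0.0      # log-normal magnitude location (ln scale)
    strength_sigma: float = 0.5   # log-normal magnitude spread
    sign_prob: float = 0.8        # P(activating edge)
    noise_sigma: float = 0.1      # additive Gaussian, log2-ratio units
    peak_index: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if any(a <= 0 for a in self.dose_scale):
            raise ValidationError("dose amplitudes must be > 0")
        if len(self.dose_scale) != len(self.conditions):
            raise ValidationError("one dose amplitude per condition required")
        if self.n_edges < self.n_genes or self.n_edges > self.n_genes * self.n_tfs:
            raise ValidationError(
                f"edge count {self.n_edges} infeasible for "
                f"{self.n_genes} genes x {self.n_tfs} TFs with full gene coverage")
        if not (0 <= self.peak_index < len(self.grid)):
            raise ValidationError("peak_index outside grid")


def pulse(times: np.ndarray, peak_time: float, shape: float = 2.0) -> np.ndarray:
    """Gamma-shaped activity pulse, maximum 1 at ``peak_time``.

    a(t) = (t/tp)^shape * exp(shape * (1 - t/tp)); a(0) = 0, smooth rise
    and decay.  Larger ``shape`` narrows the pulse.
    """
    t = np.asarray(times, dtype=float)
    if peak_time <= 0:
        raise ValidationError("peak_time must be > 0")
    u = t / peak_time
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = u[pos] ** shape * np.exp(shape * (1.0 - u[pos]))
    return out


def gen_support(n_genes: int, n_tfs: int, n_edges: int, rng: np.random.Generator,
                max_retries: int = 200) -> np.ndarray:
    """Random identifiable boolean support with an exact edge count.

    Every gene gets at least one regulator and every TF a non-empty
    regulon; patterns failing the NCA identifiability criteria are
    resampled (bounded retries).
    """
    J_proxy = max(n_tfs, 2)
    for _ in range(max_retries):
        mask = np.zeros((n_genes, n_tfs), dtype=bool)
        # one regulator per gene, round-robin TFs for guaranteed coverage
        first = rng.permutation(n_genes) % n_tfs
        mask[np.arange(n_genes), first] = True
        free = np.argwhere(~mask)
        extra = n_edges - n_genes
        pick = rng.choice(len(free), size=extra, replace=False)
        mask[free[pick, 0], free[pick, 1]] = True
        if check_identifiability(mask, J_proxy).identifiable:
            return mask
    raise ValidationError(
        f"no identifiable support found in {max_retries} tries "
        f"({n_genes} genes, {n_tfs} TFs, {n_edges} edges)")


def _activities(spec: SyntheticSpec, nfkb_row: np.ndarray | None = None
                ) -> np.ndarray:
    """Ground-truth K x (D*J) activity matrix; TF 1 is NF-κB."""
    t = spec.grid.as_array()
    J = len(t)
    rows = []
    for k in range(spec.n_tfs):
        if k == 0 and nfkb_row is not None:
            base = np.asarray(nfkb_row, dtype=float)
            if base.shape != t.shape:
                raise ValidationError("nfkb_row length must match grid")
        else:
            # stagger later TFs' peaks and widths for linear independence
            pk = t[min(spec.peak_index + k, J - 2)]
            base = pulse(t, pk if pk > 0 else t[1], shape=2.0 + k)
        rows.append(np.concatenate([amp * base for amp in spec.dose_scale]))
    return np.vstack(rows)


def gen_nca_instance(spec: SyntheticSpec, nfkb_row: np.ndarray | None = None
                     ) -> tuple[ExpressionMatrix, RegulatoryNetwork,
                                np.ndarray, np.ndarray]:
    """Draw (E, network, S_true, A_true) from the NCA forward model.

    E = S_true A_true + noise; S_true is zero off a random identifiable
    support, with log-normal magnitudes and Bernoulli signs.  ``nfkb_row``
    optionally fixes TF 1's per-condition activity shape (used by the
    end-to-end generator).  Deterministic for a fixed spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i + 1:03d}" for i in range(spec.n_genes)]
    tfs = ["NFKB"] + [f"TF{k + 1}" for k in range(1, spec.n_tfs)]
    mask = gen_support(spec.n_genes, spec.n_tfs, spec.n_edges, rng)
    mag = rng.lognormal(spec.strength_mu, spec.strength_sigma,
                        size=int(mask.sum()))
    sign = np.where(rng.random(int(mask.sum())) < spec.sign_prob, 1.0, -1.0)
    S = np.zeros((spec.n_genes, spec.n_tfs))
    S[mask] = mag * sign
    A = _activities(spec, nfkb_row=nfkb_row)
    E = S @ A + rng.normal(0.0, spec.noise_sigma, size=(spec.n_genes, A.shape[1]))
    edges = [(tfs[k], genes[i], int(np.sign(S[i, k])))
             for i, k in np.argwhere(mask)]
    net = RegulatoryNetwork(tfs, genes, edges)
    grids = {c: spec.grid for c in spec.conditions}
    expr = ExpressionMatrix(genes, list(spec.conditions), grids, E)
    return expr, net, S, A


@dataclass
class EndToEndBundle:
    """Closed-loop fixture: expression generated from a known IKK input."""

    expr: ExpressionMatrix
    net: RegulatoryNetwork
    ikk_truth: IKKProfile
    nfkb_activity_truth: np.ndarray  # relative activity on the grid
    S_true: np.ndarray
    A_true: np.ndarray


def gen_end_to_end(ikk_truth: IKKProfile, model: KineticModel,
                   spec: SyntheticSpec) -> EndToEndBundle:
    """Generate expression whose NF-κB activity row is simulated, not drawn.

    The ground-truth IKK profile drives the kinetic model; the sampled
    nuclear NF-κB is converted to relative activity and installed as
    TF 1's per-condition activity shape (dose-scaled), closing the loop
    forward-simulation -> expression -> NCA -> profile matching.
    """
    if spec.n_tfs < 1:
        raise ValidationError("need >= 1 TF")
    t_end = float(spec.grid.times[-1])
    traj = simulate(model, ikk_truth, t_end)
    conc = nfkb_activity(traj, spec.grid)
    total = (model.moiety_total("NFkB_total", traj.amounts[:, 0])
             if "NFkB_total" in model.moieties else None)
    act = sim_to_activity(conc, total_moiety=total)
    expr, net, S, A = gen_nca_instance(spec, nfkb_row=act)
    return EndToEndBundle(expr, net, ikk_truth, act, S, A)
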