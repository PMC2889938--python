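"""Mass-action kinetic simulator for the IKK–IκB–NF-κB signaling module.

The model is a reaction table over two well-mixed compartments
(cytoplasm and nucleus, volume ratio ``kv`` = V_nuc / V_cyt) with five
reaction types:

* association  A + B -> C          rate k·[A]·[B]
* dissociation C -> A + B          rate k·[C]
* transport    X_cyt <-> X_nuc     rate k·[X_src]; the receiving side is
  scaled by the volume ratio so volume-weighted totals are conserved
* synthesis    ∅ -> X              rate k, optionally multiplied by a
  template species (e.g. nuclear NF-κB driving IκBα transcription)
* degradation  X -> (partners)     rate k·[X], optionally multiplied by
  a catalyst; products, if any, are binding partners of the degraded
  moiety that survive (e.g. IKK·IκB·NF-κB -> IKK + NF-κB when the IκB
  inside the complex is destroyed)

IKK is a clamped species: its concentration is dictated by a
time-varying input profile and it obeys no mass balance.  The bundled
default configuration (``models/nfkb_ikk.yaml``) is an IκBα/β/ε,
two-compartment NF-κB module with 24 species and 72 reactions; NF-κB is
neither created nor destroyed, so its volume-weighted total is a
conserved moiety (checked at load time against the stoichiometry).

Amount units are μM-like arbitrary concentrations; time is in hours.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .datamodel import TimeGrid, ValidationError
from .ikk import IKKProfile

__all__ = [
    "Species",
    "Reaction",
    "KineticModel",
    "Trajectory",
    "ModelConfigError",
    "load_model",
    "default_model",
    "compile_rates",
    "equilibrate",
    "simulate",
    "nfkb_activity",
    "to_sbml",
]

COMPARTMENTS = ("cytoplasm", "nucleus")
REACTION_TYPES = ("association", "dissociation", "transport", "synthesis",
                  "degradation")


class ModelConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Species:
    name: str
    compartment: str
    init: float
    clamped: bool = False


@dataclass(frozen=True)
class Reaction:
    rtype: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k: float
    modifiers: tuple[str, ...] = ()
    label: str = ""


@dataclass
class KineticModel:
    """Validated reaction network over two compartments."""

    name: str
    species: list[Species]
    reactions: list[Reaction]
    kv: float
    moieties: dict[str, dict[str, float]] = field(default_factory=dict)
    readout: str = "NFkB_n"

    def __post_init__(self) -> None:
        self._validate()

    # -- bookkeeping --------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def compartment_volume(self, name: str) -> float:
        sp = self.species[self.index(name)]
        return self.kv if sp.compartment == "nucleus" else 1.0

    def initial_state(self) -> np.ndarray:
        return np.array([s.init for s in self.species], dtype=float)

    def moiety_total(self, moiety: str, state: np.ndarray) -> float:
        """Volume-weighted conserved total of one moiety for a state vector."""
        w = self.moieties[moiety]
        return float(sum(
            w[n] * self.compartment_volume(n) * state[self.index(n)] for n in w))

    # -- validation ---------------------------------------------------------

    _ARITIES = {  # (n_reactants, allowed product counts)
        "association": (2, (1,)),
        "dissociation": (1, (2,)),
        "transport": (1, (1,)),
        "synthesis": (0, (1,)),
        "degradation": (1, (0, 1, 2)),
    }

    def _validate(self) -> None:
        if self.kv <= 0:
            raise ModelConfigError(f"volume ratio kv must be > 0, got {self.kv}")
        names = self.species_names
        if len(set(names)) != len(names):
            raise ModelConfigError("duplicate species names")
        comp = {s.name: s.compartment for s in self.species}
        for s in self.species:
            if s.compartment not in COMPARTMENTS:
                raise ModelConfigError(
                    f"species {s.name}: unknown compartment {s.compartment!r}")
            if s.init < 0:
                raise ModelConfigError(f"species {s.name}: negative initial amount")
        participating: set[str] = set()
        for i, r in enumerate(self.reactions):
            where = f"reaction #{i + 1} ({r.label or r.rtype})"
            if r.rtype not in REACTION_TYPES:
                raise ModelConfigError(f"{where}: unknown type {r.rtype!r}")
            if r.k <= 0:
                raise ModelConfigError(f"{where}: non-positive rate constant {r.k}")
            for n in (*r.reactants, *r.products, *r.modifiers):
                if n not in comp:
                    raise ModelConfigError(f"{where}: unknown species {n!r}")
            n_req, prod_ok = self._ARITIES[r.rtype]
            if len(r.reactants) != n_req or len(r.products) not in prod_ok:
                raise ModelConfigError(
                    f"{where}: arity {len(r.reactants)}->{len(r.products)} "
                    f"invalid for type {r.rtype}")
            if r.rtype == "transport":
                if comp[r.reactants[0]] == comp[r.products[0]]:
                    raise ModelConfigError(f"{where}: transport within one compartment")
            elif r.rtype != "synthesis":
                cset = {comp[n] for n in (*r.reactants, *r.products)}
                if len(cset) > 1:
                    raise ModelConfigError(f"{where}: participants span compartments")
            participating.update(r.reactants)
            participating.update(r.products)
        orphans = [s.name for s in self.species
                   if s.name not in participating and not s.clamped]
        if orphans:
            raise ModelConfigError(f"species in no reaction and not clamped: {orphans}")
        # declared moieties must lie in the left null space of the
        # volume-weighted stoichiometry (clamped species excluded)
        N = self.stoichiometry()
        vol = np.array([self.compartment_volume(n) for n in names])
        for mname, members in self.moieties.items():
            for n in members:
                if n not in comp:
                    raise ModelConfigError(f"moiety {mname}: unknown species {n!r}")
            w = np.array([members.get(n, 0.0) for n in names])
            drift = (w * vol) @ N
            if np.max(np.abs(drift)) > 1e-12:
                bad = [self.reactions[j].label or str(j) for j in
                       np.where(np.abs(drift) > 1e-12)[0]]
                raise ModelConfigError(
                    f"moiety {mname} not conserved by reactions {bad}")

    def stoichiometry(self) -> np.ndarray:
        """Effective stoichiometry (species x reactions), volume-corrected.

        Entry (s, r) is the coefficient multiplying reaction r's rate in
        d[s]/dt; products in a different compartment than the reaction's
        source carry the volume-ratio factor.  Clamped species rows are
        zero (their balance is dictated by the input).
        """
        names = self.species_names
        idx = {n: i for i, n in enumerate(names)}
        clamped = {s.name for s in self.species if s.clamped}
        N = np.zeros((len(names), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            src = r.reactants[0] if r.reactants else r.products[0]
            v_src = self.compartment_volume(src)
            for n in r.reactants:
                if n not in clamped:
                    N[idx[n], j] -= 1.0
            for n in r.products:
                if n not in clamped:
                    N[idx[n], j] += v_src / self.compartment_volume(n)
        return N


@dataclass
class Trajectory:
    """Dense simulated time courses: ``amounts[s, t]`` for species s."""

    model: KineticModel
    times: np.ndarray
    amounts: np.ndarray

    def series(self, species: str) -> np.ndarray:
        return self.amounts[self.model.index(species)]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_model(path) -> KineticModel:
    """Load and validate a YAML kinetic-model configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _model_from_config(cfg, origin=str(path))


def default_model() -> KineticModel:
    """The bundled 24-species / 72-reaction NF-κB module."""
    ref = importlib.resources.files("nfkblink") / "models" / "nfkb_ikk.yaml"
    cfg = yaml.safe_load(ref.read_text())
    return _model_from_config(cfg, origin="bundled nfkb_ikk.yaml")


def _model_from_config(cfg: dict, origin: str) -> KineticModel:
    try:
        species = [
            Species(str(s["name"]), str(s["compartment"]), float(s["init"]),
                    bool(s.get("clamped", False)))
            for s in cfg["species"]
        ]
        reactions = [
            Reaction(
                str(r["type"]),
                tuple(r.get("reactants") or ()),
                tuple(r.get("products") or ()),
                float(r["k"]),
                tuple(r.get("modifiers") or ()),
                str(r.get("label", "")),
            )
            for r in cfg["reactions"]
        ]
        moieties = {
            str(m["name"]): {str(k): float(v) for k, v in m["members"].items()}
            for m in cfg.get("moieties", [])
        }
        return KineticModel(
            name=str(cfg.get("name", origin)),
            species=species,
            reactions=reactions,
            kv=float(cfg["kv"]),
            moieties=moieties,
            readout=str(cfg.get("readout", "NFkB_n")),
        )
    except (KeyError, TypeError) as exc:
        raise ModelConfigError(f"{origin}: malformed config ({exc})") from None


# ---------------------------------------------------------------------------
# rate compilation and integration
# ---------------------------------------------------------------------------

def compile_rates(model: KineticModel
                  ) -> Callable[[float, np.ndarray, Callable[[float], float]], np.ndarray]:
    """Build the ODE right-hand side d(state)/dt = f(t, state, input).

    ``input`` maps time to the clamped-species (IKK) concentration; the
    clamped species' derivative is forced to zero and its value in every
    rate law is taken from the input, not from the state vector.
    """
    names = model.species_names
    n = len(names)
    idx = {m: i for i, m in enumerate(names)}
    clamped_idx = np.array([i for i, s in enumerate(model.species) if s.clamped],
                           dtype=int)
    N = model.stoichiometry()
    # factor index n points at a constant 1.0 slot in the extended state
    one = n
    f1 = np.full(len(model.reactions), one, dtype=int)
    f2 = np.full(len(model.reactions), one, dtype=int)
    f3 = np.full(len(model.reactions), one, dtype=int)
    ks = np.array([r.k for r in model.reactions])
    for j, r in enumerate(model.reactions):
        facs = [idx[m] for m in (*r.reactants, *r.modifiers)]
        if len(facs) > 3:
            raise ModelConfigError("more than 3 concentration factors in a rate law")
        for slot, fi in zip((f1, f2, f3), facs):
            slot[j] = fi

    def rhs(t: float, y: np.ndarray, input_fn: Callable[[float], float]
            ) -> np.ndarray:
        y_ext = np.empty(n + 1)
        np.maximum(y, 0.0, out=y_ext[:n])  # guard tiny negative overshoot
        if clamped_idx.size:
            y_ext[clamped_idx] = input_fn(t)
        y_ext[one] = 1.0
        v = ks * y_ext[f1] * y_ext[f2] * y_ext[f3]
        return N @ v

    return rhs


def equilibrate(
    model: KineticModel,
    basal: float,
    *,
    y0: np.ndarray | None = None,
    dxdt_tol: float = 1e-9,
    chunk: float = 200.0,
    max_time: float = 20000.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> np.ndarray:
    """Relax the model to its resting state under constant basal input.

    Integrates in chunks until max |d state/dt| < ``dxdt_tol``; raises if
    the budget ``max_time`` (model hours) is exhausted first.
    """
    rhs = compile_rates(model)
    f = lambda t, y: rhs(t, y, lambda _t: basal)
    y = model.initial_state() if y0 is None else np.asarray(y0, float).copy()
    for i, s in enumerate(model.species):
        if s.clamped:
            y[i] = basal
    t = 0.0
    while t < max_time:
        sol = solve_ivp(f, (0.0, chunk), y, method="BDF", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"equilibration failed at t={t + sol.t[-1]:.3g} h: "
                               f"{sol.message}")
        y = sol.y[:, -1]
        t += chunk
        if np.max(np.abs(f(0.0, y))) < dxdt_tol:
            return np.maximum(y, 0.0)
    raise RuntimeError(
        f"no steady state within {max_time} h (max |dydt| = "
        f"{np.max(np.abs(f(0.0, y))):.3g})")


def simulate(
    model: KineticModel,
    input_profile: IKKProfile,
    t_end: float,
    *,
    rtol: float = 1e-7,
    atol: float = 1e-10,
    equilibrate_first: bool = True,
    y0: np.ndarray | None = None,
    n_points: int = 241,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the model under a time-varying clamped IKK input.

    By default the system is first relaxed to steady state at the
    profile's basal IKK, then the stimulus is applied at t = 0.  The
    integration proceeds segment-by-segment between the profile's knots
    (the input is piecewise linear, so its kinks are exact segment
    boundaries) and returns dense output on at least ``n_points`` times
    plus every knot.
    """
    if t_end <= 0:
        raise ValidationError(f"t_end must be > 0, got {t_end}")
    rhs = compile_rates(model)
    input_fn = input_profile.evaluate
    if y0 is not None:
        y = np.asarray(y0, float).copy()
    elif equilibrate_first:
        y = equilibrate(model, input_profile.basal)
    else:
        y = model.initial_state()

    t_eval = np.union1d(np.linspace(0.0, t_end, n_points),
                        [t for t in input_profile.knot_times if 0.0 <= t <= t_end])
    seg_bounds = np.union1d([0.0, t_end],
                            [t for t in input_profile.knot_times
                             if 0.0 < t < t_end])
    times = [np.array([0.0])]
    states = [y[:, None].copy()]
    f = lambda t, yy: rhs(t, yy, input_fn)
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        te = t_eval[(t_eval > a) & (t_eval <= b)]
        te = np.union1d(te, [b])
        sol = solve_ivp(f, (a, b), y, method=method, rtol=rtol, atol=atol,
                        t_eval=te)
        if not sol.success:
            raise RuntimeError(f"integration failed in [{a:.3g}, {b:.3g}] h: "
                               f"{sol.message}")
        y = sol.y[:, -1]
        times.append(sol.t)
        states.append(sol.y)
    t_all = np.concatenate(times)
    y_all = np.concatenate(states, axis=1)
    # clamped species: store the actual input values
    for i, s in enumerate(model.species):
        if s.clamped:
            y_all[i] = np.array([input_fn(t) for t in t_all])
    if np.min(y_all) < -10 * atol:
        raise RuntimeError(
            f"negative concentration {np.min(y_all):.3g} beyond tolerance")
    np.maximum(y_all, 0.0, out=y_all)
    return Trajectory(model, t_all, y_all)


def nfkb_activity(traj: Trajectory, grid: TimeGrid | Sequence[float],
                  species: str | None = None) -> np.ndarray:
    """Sample the nuclear free NF-κB concentration at the grid times."""
    times = grid.as_array() if isinstance(grid, TimeGrid) else np.asarray(grid, float)
    if times.max() > traj.times[-1] + 1e-12 or times.min() < traj.times[0] - 1e-12:
        raise ValidationError(
            f"grid [{times.min()}, {times.max()}] outside simulated horizon "
            f"[{traj.times[0]}, {traj.times[-1]}]")
    y = traj.series(species or traj.model.readout)
    return np.interp(times, traj.times, y)


# ---------------------------------------------------------------------------
# SBML export
# ---------------------------------------------------------------------------

def to_sbml(model: KineticModel) -> str:
    """Render the reaction network as SBML Level 3 with mass-action laws."""
    import xml.etree.ElementTree as ET

    ns = "http://www.sbml.org/sbml/level3/version2/core"
    ET.register_namespace("", ns)
    sbml = ET.Element(f"{{{ns}}}sbml", {"level": "3", "version": "2"})
    m = ET.SubElement(sbml, f"{{{ns}}}model", {"id": _sbml_id(model.name)})
    lc = ET.SubElement(m, f"{{{ns}}}listOfCompartments")
    ET.SubElement(lc, f"{{{ns}}}compartment",
                  {"id": "cytoplasm", "size": "1", "constant": "true"})
    ET.SubElement(lc, f"{{{ns}}}compartment",
                  {"id": "nucleus", "size": repr(model.kv), "constant": "true"})
    ls = ET.SubElement(m, f"{{{ns}}}listOfSpecies")
    for s in model.species:
        ET.SubElement(ls, f"{{{ns}}}species", {
            "id": _sbml_id(s.name), "compartment": s.compartment,
            "initialConcentration": repr(s.init),
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "true" if s.clamped else "false",
            "constant": "false",
        })
    lr = ET.SubElement(m, f"{{{ns}}}listOfReactions")
    mathns = "http://www.w3.org/1998/Math/MathML"
    for j, r in enumerate(model.reactions):
        rx = ET.SubElement(lr, f"{{{ns}}}reaction", {
            "id": f"r{j + 1}", "name": r.label or r.rtype, "reversible": "false"})
        if r.reactants:
            lrr = ET.SubElement(rx, f"{{{ns}}}listOfReactants")
            for n in r.reactants:
                ET.SubElement(lrr, f"{{{ns}}}speciesReference",
                              {"species": _sbml_id(n), "stoichiometry": "1",
                               "constant": "true"})
        if r.products:
            lrp = ET.SubElement(rx, f"{{{ns}}}listOfProducts")
            for n in r.products:
                ET.SubElement(lrp, f"{{{ns}}}speciesReference",
                              {"species": _sbml_id(n), "stoichiometry": "1",
                               "constant": "true"})
        if r.modifiers:
            lrm = ET.SubElement(rx, f"{{{ns}}}listOfModifiers")
            for n in r.modifiers:
                ET.SubElement(lrm, f"{{{ns}}}modifierSpeciesReference",
                              {"species": _sbml_id(n)})
        kl = ET.SubElement(rx, f"{{{ns}}}kineticLaw")
        math = ET.SubElement(kl, f"{{{mathns}}}math")
        apply_ = ET.SubElement(math, f"{{{mathns}}}apply")
        ET.SubElement(apply_, f"{{{mathns}}}times")
        cn = ET.SubElement(apply_, f"{{{mathns}}}cn")
        cn.text = repr(r.k)
        for n in (*r.reactants, *r.modifiers):
            ci = ET.SubElement(apply_, f"{{{mathns}}}ci")
            ci.text = _sbml_id(n)
    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True)


def _sbml_id(name: str) -> str:
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in name)
    return out if out and not out[0].isdigit() else f"s_{out}"
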