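"""Continuous logic-based ODE engine for intracellular signaling networks.

Each molecular species is a node with a normalized activation level
``y`` in ``[0, y_max]``.  Edges (reactions) drive a node toward
``y_max`` through normalized Hill-type transfer functions combined with
fuzzy AND/OR logic gates:

* terms within one reaction combine multiplicatively (AND),
* multiple reactions sharing a target combine by inclusive OR
  (``a ⊕ b = a + b − a·b``),
* each species relaxes as ``dy/dt = (drive · y_max − y) / τ``.

The transfer function is the normalized Hill curve
``f_act(x) = β x^n / (K^n + x^n)`` constrained so that
``f_act(EC50) = 1/2`` and ``f_act(1) = 1``; inhibition uses
``f_inhib = 1 − f_act``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "HillParams",
    "SpeciesNode",
    "Term",
    "Reaction",
    "NetworkModel",
    "SimulationResult",
    "NetworkSyntaxError",
    "ConvergenceError",
    "hill_constants",
    "transfer_act",
    "transfer_inhib",
    "reaction_activation",
    "node_drive",
    "or_fold",
    "rhs",
    "simulate",
    "steady_state",
    "parse_network",
    "serialize_network",
]

ROLES = ("input", "receptor", "intracellular", "output")

#: default Hill parameters used uniformly across the SMC model
DEFAULT_N = 1.4
DEFAULT_EC50 = 0.52


class NetworkSyntaxError(ValueError):
    """Raised for malformed network-definition text (carries a line number)."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class ConvergenceError(RuntimeError):
    """Raised when a steady-state solve does not reach the residual tolerance."""


def hill_constants(n: float, ec50: float) -> tuple[float, float]:
    """Return ``(beta, k)`` for the normalized Hill transfer function.

    The pair is the unique solution of ``f_act(ec50) = 1/2`` and
    ``f_act(1) = 1``:

    ``beta = (ec50^n − 1) / (2 ec50^n − 1)`` and ``k = (beta − 1)^(1/n)``
    (equivalently ``k^n = beta − 1``).

    Raises
    ------
    ValueError
        If ``n <= 0``, ``ec50`` is outside ``(0, 1)``, or ``ec50^n >= 1/2``
        (the transfer function cannot then be normalized with gain > 1).
    """
    if n <= 0:
        raise ValueError(f"Hill exponent must be positive, got n={n}")
    if not (0.0 < ec50 < 1.0):
        raise ValueError(f"ec50 must lie in (0, 1), got {ec50}")
    e = ec50**n
    if e >= 0.5:
        raise ValueError(
            f"ec50^n = {e:.6g} >= 1/2: normalized Hill gain undefined "
            f"for (n={n}, ec50={ec50})"
        )
    beta = (e - 1.0) / (2.0 * e - 1.0)
    k = (beta - 1.0) ** (1.0 / n)
    return beta, k


@dataclass(frozen=True)
class HillParams:
    """Normalized Hill transfer-function parameters.

    ``beta`` and ``k`` are derived from ``(n, ec50)`` so that
    ``f_act(ec50) = 0.5`` and ``f_act(1) = 1``.
    """

    n: float = DEFAULT_N
    ec50: float = DEFAULT_EC50
    beta: float = field(init=False)
    k: float = field(init=False)

    def __post_init__(self):
        beta, k = hill_constants(self.n, self.ec50)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "k", k)

    @property
    def kn(self) -> float:
        """``k^n = beta − 1``."""
        return self.beta - 1.0


def transfer_act(x, hill: HillParams):
    """Activating transfer ``f_act(x) = β x^n / (K^n + x^n)``.

    Accepts scalars or arrays; negative inputs (solver undershoot) are
    clipped to zero before the fractional power.
    """
    xn = np.clip(x, 0.0, None) ** hill.n
    return hill.beta * xn / (hill.kn + xn)


def transfer_inhib(x, hill: HillParams):
    """Inhibiting transfer ``f_inhib(x) = 1 − f_act(x)``."""
    return 1.0 - transfer_act(x, hill)


def or_fold(values: Iterable[float]) -> float:
    """Inclusive-OR fold ``a ⊕ b = a + b − a·b`` (associative, commutative)."""
    acc = 0.0
    for v in values:
        acc = acc + v - acc * v
    return acc


@dataclass(frozen=True)
class Term:
    """One upstream factor of a reaction: a source species and a polarity."""

    source: str
    inhibiting: bool = False


@dataclass(frozen=True)
class Reaction:
    """A logic reaction: AND of terms, scaled by weight ``W``, driving a target.

    An *input* reaction has no terms and contributes its weight directly,
    so an otherwise-unregulated input node settles at activation ``W``.
    """

    target: str
    terms: tuple[Term, ...] = ()
    weight: float = 1.0
    hill: HillParams | None = None  # None -> model default

    def __post_init__(self):
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"reaction weight must be in [0, 1], got {self.weight}")

    @property
    def is_input(self) -> bool:
        return len(self.terms) == 0


@dataclass(frozen=True)
class SpeciesNode:
    """A network node: normalized activation with first-order relaxation."""

    name: str
    role: str = "intracellular"
    y_max: float = 1.0
    tau: float = 1.0
    y0: float = 0.0

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for species {self.name}")
        if not (0.0 <= self.y_max <= 1.0):
            raise ValueError(f"{self.name}: y_max must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError(f"{self.name}: tau must be positive")
        if not (0.0 <= self.y0 <= self.y_max + 1e-9):
            raise ValueError(f"{self.name}: y0 must be in [0, y_max]")


@dataclass(frozen=True)
class NetworkModel:
    """Species + reactions + default Hill parameters; the simulatable object."""

    species: tuple[SpeciesNode, ...]
    reactions: tuple[Reaction, ...]
    defaults: HillParams = HillParams()

    def __post_init__(self):
        names = [s.name for s in self.species]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate species declarations: {sorted(dup)}")
        declared = set(names)
        for r in self.reactions:
            if r.target not in declared:
                raise ValueError(f"reaction targets undeclared species {r.target!r}")
            for t in r.terms:
                if t.source not in declared:
                    raise ValueError(
                        f"reaction on {r.target!r} references undeclared "
                        f"species {t.source!r}"
                    )

    # -- convenience accessors -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def species_by_name(self, name: str) -> SpeciesNode:
        return self.species[self.index(name)]

    def incoming(self, target: str) -> list[Reaction]:
        return [r for r in self.reactions if r.target == target]

    def reactions_by_role(self, role: str) -> list[int]:
        """Indices of reactions whose *target* species has the given role."""
        roles = {s.name: s.role for s in self.species}
        return [i for i, r in enumerate(self.reactions) if roles[r.target] == role]

    # -- modification helpers (return new models) ------------------------------
    def with_y_max(self, overrides: dict[str, float]) -> "NetworkModel":
        for name in overrides:
            self.index(name)  # raise KeyError for unknown names
        new_species = tuple(
            replace(
                s,
                y_max=overrides.get(s.name, s.y_max),
                y0=min(s.y0, overrides.get(s.name, s.y_max)),
            )
            for s in self.species
        )
        return replace(self, species=new_species)

    def with_weights(self, weights: dict[int, float]) -> "NetworkModel":
        """Return a model with reaction weights replaced by reaction index."""
        new_reactions = tuple(
            replace(r, weight=weights.get(i, r.weight))
            for i, r in enumerate(self.reactions)
        )
        return replace(self, reactions=new_reactions)

    def with_defaults(self, hill: HillParams) -> "NetworkModel":
        return replace(self, defaults=hill)

    def compile(self) -> "CompiledNetwork":
        return CompiledNetwork(self)


# ---------------------------------------------------------------------------
# scalar reference semantics (used directly by tests and small models)
# ---------------------------------------------------------------------------

def reaction_activation(r: Reaction, state: dict[str, float],
                        default_hill: HillParams) -> float:
    """AND gate: ``W ·  Π f(y_source)`` over terms; input reactions return W."""
    hill = r.hill or default_hill
    value = r.weight
    for t in r.terms:
        if t.source not in state:
            raise KeyError(f"state does not cover species {t.source!r}")
        f = transfer_inhib if t.inhibiting else transfer_act
        value *= float(f(state[t.source], hill))
    return value


def node_drive(reactions: Sequence[Reaction], state: dict[str, float],
               default_hill: HillParams) -> float:
    """OR fold of reaction activations for reactions sharing one target."""
    targets = {r.target for r in reactions}
    if len(targets) > 1:
        raise ValueError(f"node_drive given mixed targets {sorted(targets)}")
    return or_fold(reaction_activation(r, state, default_hill) for r in reactions)


# ---------------------------------------------------------------------------
# compiled (vectorized) form
# ---------------------------------------------------------------------------

class CompiledNetwork:
    """Array representation of a :class:`NetworkModel` for fast ODE evaluation.

    Supports batched evaluation: the state may be ``(n_species,)`` or
    ``(n_species, n_cells)``, and reaction weights may be overridden
    per-cell with a ``(n_reactions, n_cells)`` array (used by the
    population module).
    """

    def __init__(self, model: NetworkModel):
        self.model = model
        self.n_species = len(model.species)
        self.n_reactions = len(model.reactions)
        self.names = model.names
        self.y_max = np.array([s.y_max for s in model.species])
        self.tau = np.array([s.tau for s in model.species])
        self.y0 = np.array([s.y0 for s in model.species])

        index = {s.name: i for i, s in enumerate(model.species)}

        # order reactions grouped by target species so the OR fold is a
        # segmented product; within a target keep file order (OR commutes)
        order = sorted(range(self.n_reactions),
                       key=lambda i: (index[model.reactions[i].target], i))
        self.reaction_order = order
        rx = [model.reactions[i] for i in order]

        self.rx_weight = np.array([r.weight for r in rx])
        self.rx_target = np.array([index[r.target] for r in rx], dtype=np.intp)

        term_src, term_inhib, term_rx = [], [], []
        rx_starts = []
        pos = 0
        for j, r in enumerate(rx):
            rx_starts.append(pos)
            for t in r.terms:
                term_src.append(index[t.source])
                term_inhib.append(t.inhibiting)
                term_rx.append(j)
                pos += 1
        self.term_src = np.array(term_src, dtype=np.intp)
        self.term_inhib = np.array(term_inhib, dtype=bool)
        self.term_rx = np.array(term_rx, dtype=np.intp)
        self.rx_starts = np.array(rx_starts, dtype=np.intp)
        self.rx_n_terms = np.diff(np.append(self.rx_starts, pos))

        hills = [r.hill or model.defaults for r in rx]
        self.term_n = np.array([hills[j].n for j in term_rx])
        self.term_beta = np.array([hills[j].beta for j in term_rx])
        self.term_kn = np.array([hills[j].kn for j in term_rx])

        # segmented-OR bookkeeping per target species
        tgt = self.rx_target
        self.regulated = np.zeros(self.n_species, dtype=bool)
        self.regulated[tgt] = True
        # boundaries of equal-target runs in the sorted reaction list
        if self.n_reactions:
            run_starts = np.flatnonzero(np.r_[True, np.diff(tgt) != 0])
            self.or_starts = run_starts
            self.or_target = tgt[run_starts]
        else:
            self.or_starts = np.zeros(0, dtype=np.intp)
            self.or_target = np.zeros(0, dtype=np.intp)

    # -- core evaluation -------------------------------------------------------
    def drive(self, y: np.ndarray, rx_weight: np.ndarray | None = None
              ) -> np.ndarray:
        """OR-combined activation drive for every species (0 if unregulated)."""
        if self.n_reactions == 0:
            return np.zeros_like(y)
        w = self.rx_weight if rx_weight is None else rx_weight
        batched = y.ndim == 2
        if self.term_src.size:
            trail = (slice(None),) + (None,) * (y.ndim - 1)
            x = np.clip(y[self.term_src], 0.0, None)
            xn = x ** self.term_n[trail]
            f = self.term_beta[trail] * xn / (self.term_kn[trail] + xn)
            f[self.term_inhib] = 1.0 - f[self.term_inhib]
            # pad with a sentinel 1 so zero-term (input) reactions — whose
            # start index may equal len(f) — stay valid reduceat indices
            f = np.concatenate([f, np.ones((1,) + f.shape[1:])], axis=0)
            prod = np.multiply.reduceat(f, self.rx_starts, axis=0)
            # an empty segment returns the element at its start index;
            # input reactions must contribute a bare product of 1
            prod[self.rx_n_terms == 0] = 1.0
        else:
            shape = (self.n_reactions,) + y.shape[1:]
            prod = np.ones(shape)
        if w.ndim == 1 and batched:
            v = w[:, None] * prod
        else:
            v = w * prod
        one_minus = 1.0 - v
        seg = np.multiply.reduceat(one_minus, self.or_starts, axis=0)
        drive = np.zeros_like(y)
        drive[self.or_target] = 1.0 - seg
        return drive

    def rhs(self, y: np.ndarray, rx_weight: np.ndarray | None = None
            ) -> np.ndarray:
        drive = self.drive(y, rx_weight)
        tau = self.tau if y.ndim == 1 else self.tau[:, None]
        y_max = self.y_max if y.ndim == 1 else self.y_max[:, None]
        dy = (drive * y_max - y) / tau
        if not self.regulated.all():
            # unregulated non-input species stay constant at y0
            dy[~self.regulated] = 0.0
        return dy


def rhs(model: NetworkModel, state: np.ndarray) -> np.ndarray:
    """Derivative vector ``dy/dt = (drive · y_max − y)/τ`` for the full model."""
    state = np.asarray(state, dtype=float)
    if state.shape[0] != len(model.species):
        raise ValueError("state length does not match species count")
    return model.compile().rhs(state)


@dataclass
class SimulationResult:
    """Trajectory output: time grid, states, steady endpoint, transient peaks."""

    times: np.ndarray
    states: np.ndarray  # (n_species, n_times)
    names: list[str]
    converged: bool
    residual: float

    @property
    def steady(self) -> np.ndarray:
        return self.states[:, -1]

    @property
    def peaks(self) -> np.ndarray:
        return self.states.max(axis=1)

    def as_dict(self, which: str = "steady") -> dict[str, float]:
        vec = getattr(self, which)
        return dict(zip(self.names, vec))


DEFAULT_T_END = 40.0
DEFAULT_TOL = 1e-6
MIN_SAMPLES = 400


def simulate(model_or_compiled, y0: np.ndarray | None = None,
             t_end: float = DEFAULT_T_END, n_samples: int = MIN_SAMPLES,
             tol: float = DEFAULT_TOL, rtol: float = 1e-8,
             atol: float = 1e-10) -> SimulationResult:
    """Integrate the network ODEs and sample the trajectory densely.

    The trajectory is sampled at ``n_samples`` (>= 400) uniform points so
    transient peaks — which gate the bistable PI3K/AKT switch — are not
    missed by coarse solver output.
    """
    net = (model_or_compiled if isinstance(model_or_compiled, CompiledNetwork)
           else model_or_compiled.compile())
    if y0 is None:
        y0 = net.y0
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 < -1e-12) or np.any(y0 > net.y_max + 1e-12):
        raise ValueError("initial state outside [0, y_max]")
    n_samples = max(n_samples, MIN_SAMPLES)
    t_eval = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(lambda t, y: net.rhs(y), (0.0, t_end), y0,
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    residual = float(np.abs(net.rhs(sol.y[:, -1])).max())
    return SimulationResult(times=sol.t, states=sol.y, names=net.names,
                            converged=residual < tol, residual=residual)


def steady_state(model_or_compiled, y0: np.ndarray | None = None,
                 tol: float = DEFAULT_TOL, t_end: float = DEFAULT_T_END
                 ) -> np.ndarray:
    """Deterministic steady state: integrate to ``t_end``, check the residual.

    If ``max|dy/dt|`` at the endpoint exceeds ``tol`` the horizon is
    extended once (x10); persistent non-convergence raises
    :class:`ConvergenceError` rather than returning a state silently.
    """
    net = (model_or_compiled if isinstance(model_or_compiled, CompiledNetwork)
           else model_or_compiled.compile())
    res = simulate(net, y0=y0, t_end=t_end, tol=tol)
    if res.converged:
        return res.steady
    res = simulate(net, y0=res.steady, t_end=10.0 * t_end, tol=tol)
    if res.converged:
        return res.steady
    raise ConvergenceError(
        f"steady state not reached: residual {res.residual:.3g} > tol {tol:.3g} "
        f"after t = {11 * t_end}"
    )


# ---------------------------------------------------------------------------
# parser / serializer for the reaction-grammar network file
# ---------------------------------------------------------------------------

_SPECIES_RE = re.compile(r"^species\s+(?P<name>\w+)(?P<opts>(?:\s+\w+=\S+)*)\s*$")
_OPT_RE = re.compile(r"(\w+)=(\S+)")
_NAME_RE = re.compile(r"^\w+$")


def _parse_opts(opts: str, line_no: int) -> dict[str, str]:
    return {m.group(1): m.group(2) for m in _OPT_RE.finditer(opts)}


def parse_network(text: str) -> NetworkModel:
    """Parse a network-definition document into a :class:`NetworkModel`.

    Grammar (one statement per line, ``#`` comments)::

        species NAME [role=input|receptor|intracellular|output]
                     [ymax=..] [tau=..] [y0=..]
        A & !B => C [w=..] [n=..] [ec50=..]     # AND of terms, ! = inhibition
        => C [w=..]                             # input reaction (no terms)

    Rules sharing a target OR-combine in file order.
    """
    species: list[SpeciesNode] = []
    reactions: list[Reaction] = []
    declared: set[str] = set()
    model_n, model_ec50 = DEFAULT_N, DEFAULT_EC50

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("hill "):
            opts = _parse_opts(line[5:], line_no)
            model_n = float(opts.get("n", model_n))
            model_ec50 = float(opts.get("ec50", model_ec50))
            continue
        m = _SPECIES_RE.match(line)
        if m:
            name = m.group("name")
            if name in declared:
                raise NetworkSyntaxError(f"duplicate species {name!r}", line_no)
            opts = _parse_opts(m.group("opts"), line_no)
            try:
                node = SpeciesNode(
                    name=name,
                    role=opts.get("role", "intracellular"),
                    y_max=float(opts.get("ymax", 1.0)),
                    tau=float(opts.get("tau", 1.0)),
                    y0=float(opts.get("y0", 0.0)),
                )
            except ValueError as exc:
                raise NetworkSyntaxError(str(exc), line_no) from None
            species.append(node)
            declared.add(name)
            continue
        if "=>" in line:
            lhs, _, rest = line.partition("=>")
            rest = rest.strip()
            parts = rest.split()
            if not parts:
                raise NetworkSyntaxError("missing reaction target", line_no)
            target = parts[0]
            opts = _parse_opts(" ".join(parts[1:]), line_no)
            if not _NAME_RE.match(target):
                raise NetworkSyntaxError(f"bad target name {target!r}", line_no)
            if target not in declared:
                raise NetworkSyntaxError(
                    f"undeclared species {target!r}", line_no)
            terms = []
            lhs = lhs.strip()
            if lhs:
                for tok in (t.strip() for t in lhs.split("&")):
                    if not tok:
                        raise NetworkSyntaxError("empty AND term", line_no)
                    inhib = tok.startswith("!")
                    src = tok[1:].strip() if inhib else tok
                    if not _NAME_RE.match(src):
                        raise NetworkSyntaxError(f"bad term {tok!r}", line_no)
                    if src not in declared:
                        raise NetworkSyntaxError(
                            f"undeclared species {src!r}", line_no)
                    terms.append(Term(source=src, inhibiting=inhib))
            hill = None
            if "n" in opts or "ec50" in opts:
                hill = HillParams(n=float(opts.get("n", model_n)),
                                  ec50=float(opts.get("ec50", model_ec50)))
            try:
                reactions.append(Reaction(target=target, terms=tuple(terms),
                                          weight=float(opts.get("w", 1.0)),
                                          hill=hill))
            except ValueError as exc:
                raise NetworkSyntaxError(str(exc), line_no) from None
            continue
        raise NetworkSyntaxError(f"unrecognized statement: {line!r}", line_no)

    return NetworkModel(species=tuple(species), reactions=tuple(reactions),
                        defaults=HillParams(n=model_n, ec50=model_ec50))


def _fmt(x: float) -> str:
    return format(x, ".17g")


def serialize_network(model: NetworkModel) -> str:
    """Write a model back to the reaction-grammar text (parse round-trips)."""
    lines = [f"hill n={_fmt(model.defaults.n)} ec50={_fmt(model.defaults.ec50)}"]
    for s in model.species:
        opts = [f"role={s.role}"]
        if s.y_max != 1.0:
            opts.append(f"ymax={_fmt(s.y_max)}")
        if s.tau != 1.0:
            opts.append(f"tau={_fmt(s.tau)}")
        if s.y0 != 0.0:
            opts.append(f"y0={_fmt(s.y0)}")
        lines.append(f"species {s.name} " + " ".join(opts))
    for r in model.reactions:
        lhs = " & ".join(("!" if t.inhibiting else "") + t.source for t in r.terms)
        stmt = f"{lhs} => {r.target}".strip() if lhs else f"=> {r.target}"
        if r.weight != 1.0:
            stmt += f" w={_fmt(r.weight)}"
        if r.hill is not None:
            stmt += f" n={_fmt(r.hill.n)} ec50={_fmt(r.hill.ec50)}"
        lines.append(stmt)
    return "\n".join(lines) + "\n"


def states_to_tsv(names: Sequence[str], values: np.ndarray) -> str:
    """Export a state vector as a (species, activation) tab-separated table."""
    lines = ["species\tactivation"]
    for name, v in zip(names, values):
        lines.append(f"{name}\t{v:.10g}")
    return "\n".join(lines) + "\n"
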