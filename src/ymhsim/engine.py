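"""Fixed-step stock-flow simulation core.

A model is declared as a :class:`ModelGraph`: stocks (state variables),
flows (rates moving material between stocks or across the model boundary),
auxiliaries (intermediate algebra), scalar parameters, and piecewise-linear
lookup tables.  Rate expressions are written in a deliberately small
arithmetic language — ``+ - * / ^``, ``min``/``max``/``pow``/``abs``,
lookup calls, and the time symbol ``t`` — so that graphs remain
serializable and auditable; there is no general code execution.

Integration is explicit first-order (Euler) with a fixed step, the default
behaviour of mainstream system-dynamics tools, plus a convergence helper
(:func:`refine_until_converged`) that halves the step until reported series
stabilise.  Stocks flagged nonnegative are protected by proportional
outflow rescaling within the step: when a step would drive a stock below
zero, all of its outflows are scaled by a common factor so the stock lands
exactly at zero and downstream flow budgets stay consistent.

Time-dated parameter overrides (multiply / set / add, active from a start
time inclusive to a stop time exclusive) are the mechanism by which
scenarios and sensitivity draws modify a run without mutating the graph.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_right
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ModelGraph",
    "SimulationSettings",
    "Trajectory",
    "Override",
    "Diagnostic",
    "GraphValidationError",
    "SimulationError",
    "ConvergenceError",
    "ExpressionError",
    "parse_expression",
    "expression_symbols",
    "validate_graph",
    "simulate",
    "refine_until_converged",
    "compose",
]

# ---------------------------------------------------------------------------
# Expression language
# ---------------------------------------------------------------------------

#: callables usable in expressions, with (min arity, max arity)
_BUILTIN_FUNCS = {"min": (2, 8), "max": (2, 8), "pow": (2, 2), "abs": (1, 1)}

#: names that cannot be used for model symbols
RESERVED_NAMES = frozenset({"t"}) | frozenset(_BUILTIN_FUNCS)

_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")

_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<num>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?|\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>\*\*|[()+\-*/^,])"
    r")"
)


class ExpressionError(ValueError):
    """Raised when an expression does not parse."""


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ExpressionError(f"unexpected character {rest[0]!r} in {text!r}")
        if m.group("num") is not None:
            tokens.append(("num", m.group("num")))
        elif m.group("name") is not None:
            tokens.append(("name", m.group("name")))
        else:
            tokens.append(("op", m.group("op")))
        pos = m.end()
    tokens.append(("end", ""))
    return tokens


# AST node shapes:
#   ("num", float) | ("var", name) | ("call", name, [args])
#   ("bin", op, left, right) | ("neg", operand)

_BINARY_PRECEDENCE = {"+": 10, "-": 10, "*": 20, "/": 20, "^": 30, "**": 30}


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str]:
        return self.tokens[self.i]

    def next(self) -> tuple[str, str]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_op(self, op: str) -> None:
        kind, val = self.next()
        if kind != "op" or val != op:
            raise ExpressionError(f"expected {op!r} in {self.text!r}, got {val!r}")

    def parse(self):
        node = self.parse_binary(0)
        kind, val = self.peek()
        if kind != "end":
            raise ExpressionError(f"trailing input {val!r} in {self.text!r}")
        return node

    def parse_binary(self, min_prec: int):
        left = self.parse_unary()
        while True:
            kind, val = self.peek()
            if kind != "op" or val not in _BINARY_PRECEDENCE:
                return left
            prec = _BINARY_PRECEDENCE[val]
            if prec < min_prec:
                return left
            self.next()
            # '^'/'**' is right-associative, the rest left-associative
            next_min = prec if val in ("^", "**") else prec + 1
            right = self.parse_binary(next_min)
            op = "^" if val == "**" else val
            left = ("bin", op, left, right)

    def parse_unary(self):
        kind, val = self.peek()
        if kind == "op" and val == "-":
            self.next()
            return ("neg", self.parse_unary())
        if kind == "op" and val == "+":
            self.next()
            return self.parse_unary()
        return self.parse_atom()

    def parse_atom(self):
        kind, val = self.next()
        if kind == "num":
            return ("num", float(val))
        if kind == "name":
            nk, nv = self.peek()
            if nk == "op" and nv == "(":
                self.next()
                args = []
                if not (self.peek() == ("op", ")")):
                    args.append(self.parse_binary(0))
                    while self.peek() == ("op", ","):
                        self.next()
                        args.append(self.parse_binary(0))
                self.expect_op(")")
                return ("call", val, args)
            return ("var", val)
        if kind == "op" and val == "(":
            node = self.parse_binary(0)
            self.expect_op(")")
            return node
        raise ExpressionError(f"unexpected token {val!r} in {self.text!r}")


def parse_expression(text: str):
    """Parse an expression into its AST; raises :class:`ExpressionError`."""
    if not isinstance(text, str) or not text.strip():
        raise ExpressionError("empty expression")
    return _Parser(text).parse()


def expression_symbols(node) -> tuple[set[str], set[str]]:
    """Return ``(variables, functions)`` referenced by a parsed expression."""
    variables: set[str] = set()
    functions: set[str] = set()

    def walk(n):
        tag = n[0]
        if tag == "var":
            variables.add(n[1])
        elif tag == "call":
            functions.add(n[1])
            for a in n[2]:
                walk(a)
        elif tag == "bin":
            walk(n[2])
            walk(n[3])
        elif tag == "neg":
            walk(n[1])

    walk(node)
    return variables, functions


def _emit(node, rename: dict[str, str]) -> str:
    tag = node[0]
    if tag == "num":
        return repr(node[1])
    if tag == "var":
        return rename.get(node[1], node[1])
    if tag == "neg":
        return f"(-{_emit(node[1], rename)})"
    if tag == "bin":
        op = node[1]
        left = _emit(node[2], rename)
        right = _emit(node[3], rename)
        if op == "^":
            return f"({left})**({right})"
        return f"({left}{op}{right})"
    if tag == "call":
        name = node[1]
        args = ",".join(_emit(a, rename) for a in node[2])
        if name in _BUILTIN_FUNCS:
            return f"{name}({args})"
        return f"_lk_{name}({args})"
    raise AssertionError(f"unknown node {node!r}")


# ---------------------------------------------------------------------------
# Graph declaration
# ---------------------------------------------------------------------------


@dataclass
class Stock:
    initial: float
    unit: str = ""
    nonnegative: bool = True


@dataclass
class Flow:
    rate: str
    source: str | None = None  # None = model boundary
    sink: str | None = None
    unit: str = ""


@dataclass
class Parameter:
    value: float
    unit: str = ""


@dataclass
class Lookup:
    """Piecewise-linear table: sorted (x, y) breakpoints, clamped ends."""

    points: list[tuple[float, float]]


class ModelGraph:
    """Declarative stock/flow/auxiliary network — the simulable object."""

    def __init__(self) -> None:
        self.stocks: dict[str, Stock] = {}
        self.flows: dict[str, Flow] = {}
        self.aux: dict[str, str] = {}
        self.params: dict[str, Parameter] = {}
        self.lookups: dict[str, Lookup] = {}
        self._cache: "_Compiled | None" = None  # validated+compiled form

    # -- construction -------------------------------------------------------

    def add_stock(self, name: str, initial: float, unit: str = "", nonnegative: bool = True) -> "ModelGraph":
        self._claim(name)
        self.stocks[name] = Stock(float(initial), unit, nonnegative)
        return self

    def add_flow(self, name: str, rate: str, source: str | None = None, sink: str | None = None, unit: str = "") -> "ModelGraph":
        self._claim(name)
        self.flows[name] = Flow(rate, source, sink, unit)
        return self

    def add_aux(self, name: str, expr: str, unit: str = "") -> "ModelGraph":
        self._claim(name)
        self.aux[name] = expr
        return self

    def add_param(self, name: str, value: float, unit: str = "") -> "ModelGraph":
        self._claim(name)
        self.params[name] = Parameter(float(value), unit)
        return self

    def add_lookup(self, name: str, points) -> "ModelGraph":
        self._claim(name)
        self.lookups[name] = Lookup([(float(x), float(y)) for x, y in points])
        return self

    def _claim(self, name: str) -> None:
        if name in self.symbols():
            raise ValueError(f"symbol {name!r} already defined")
        self._cache = None  # structural change invalidates the compiled form

    def symbols(self) -> set[str]:
        return (
            set(self.stocks)
            | set(self.flows)
            | set(self.aux)
            | set(self.params)
            | set(self.lookups)
        )

    def merge(self, other: "ModelGraph") -> "ModelGraph":
        """Merge another fragment into this graph in place; collisions raise."""
        clash = self.symbols() & other.symbols()
        if clash:
            raise ValueError(f"symbol collision on merge: {sorted(clash)}")
        self._cache = None
        self.stocks.update(other.stocks)
        self.flows.update(other.flows)
        self.aux.update(other.aux)
        self.params.update(other.params)
        self.lookups.update(other.lookups)
        return self

    def copy(self) -> "ModelGraph":
        g = ModelGraph()
        g.stocks = {k: Stock(v.initial, v.unit, v.nonnegative) for k, v in self.stocks.items()}
        g.flows = {k: Flow(v.rate, v.source, v.sink, v.unit) for k, v in self.flows.items()}
        g.aux = dict(self.aux)
        g.params = {k: Parameter(v.value, v.unit) for k, v in self.params.items()}
        g.lookups = {k: Lookup(list(v.points)) for k, v in self.lookups.items()}
        return g


def compose(*fragments: ModelGraph) -> ModelGraph:
    """Compose model fragments into a single graph (collisions raise)."""
    g = ModelGraph()
    for frag in fragments:
        g.merge(frag)
    return g


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Diagnostic:
    symbol: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.symbol}: {self.message}"


class GraphValidationError(ValueError):
    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = diagnostics
        super().__init__("invalid model graph:\n" + "\n".join(str(d) for d in diagnostics))


def validate_graph(graph: ModelGraph) -> list[Diagnostic]:
    """Check every :class:`ModelGraph` invariant; returns diagnostics, not exceptions.

    An empty list means the graph is simulable: names are well formed and
    unique, every referenced symbol is defined, auxiliary dependencies are
    acyclic, flow endpoints are declared stocks or the boundary, and lookup
    breakpoints are strictly increasing.
    """
    diags: list[Diagnostic] = []

    for name in graph.symbols():
        if not _NAME_RE.match(name):
            diags.append(Diagnostic(name, "invalid-name", "symbol is not a valid identifier"))
        elif name in RESERVED_NAMES:
            diags.append(Diagnostic(name, "reserved-symbol", "name is reserved by the engine"))

    defined_vars = set(graph.stocks) | set(graph.aux) | set(graph.params)
    exprs = [(name, expr, "auxiliary") for name, expr in graph.aux.items()]
    exprs += [(name, flow.rate, "flow") for name, flow in graph.flows.items()]

    aux_deps = nx.DiGraph()
    aux_deps.add_nodes_from(graph.aux)

    for name, text, kind in exprs:
        try:
            node = parse_expression(text)
        except ExpressionError as exc:
            diags.append(Diagnostic(name, "parse-error", str(exc)))
            continue
        variables, functions = expression_symbols(node)
        for v in variables:
            if v == "t":
                continue
            if v not in defined_vars:
                diags.append(Diagnostic(name, "undefined-symbol", f"undefined symbol {v!r} in {kind} {name!r}"))
            if kind == "auxiliary" and v in graph.aux:
                aux_deps.add_edge(v, name)
        for f in functions:
            if f in _BUILTIN_FUNCS:
                continue
            if f not in graph.lookups:
                diags.append(Diagnostic(name, "undefined-symbol", f"undefined lookup or function {f!r} in {kind} {name!r}"))

    if not nx.is_directed_acyclic_graph(aux_deps):
        cycle = nx.find_cycle(aux_deps)
        members = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
        diags.append(Diagnostic(cycle[0][0], "cyclic-auxiliaries", f"auxiliary cycle: {members}"))

    for name, flow in graph.flows.items():
        for endpoint in (flow.source, flow.sink):
            if endpoint is not None and endpoint not in graph.stocks:
                diags.append(Diagnostic(name, "unknown-endpoint", f"flow endpoint {endpoint!r} is not a declared stock"))

    for name, lookup in graph.lookups.items():
        xs = [p[0] for p in lookup.points]
        if len(xs) == 0:
            diags.append(Diagnostic(name, "bad-lookup", "lookup has no breakpoints"))
        elif any(b <= a for a, b in zip(xs, xs[1:])):
            diags.append(Diagnostic(name, "bad-lookup", "lookup breakpoints must be strictly increasing"))

    return diags


# ---------------------------------------------------------------------------
# Settings, overrides, trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationSettings:
    """Fixed-step run settings on a decimal-calendar-year time axis."""

    start_time: float
    stop_time: float
    dt: float = 1.0 / 12.0

    def __post_init__(self) -> None:
        if not self.start_time < self.stop_time:
            raise ValueError("start_time must be < stop_time")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        span = self.stop_time - self.start_time
        n = round(span / self.dt)
        if n < 1 or abs(n * self.dt - span) > 1e-9 * max(1.0, span):
            raise ValueError("(stop_time - start_time) / dt must be a whole number of steps")

    @property
    def n_steps(self) -> int:
        return round((self.stop_time - self.start_time) / self.dt)


@dataclass(frozen=True)
class Override:
    """Time-dated parameter override, active on ``start <= t < stop``."""

    parameter: str
    action: str  # "multiply" | "set" | "add"
    value: float
    start: float = -math.inf
    stop: float = math.inf

    def __post_init__(self) -> None:
        if self.action not in ("multiply", "set", "add"):
            raise ValueError(f"unknown override action {self.action!r}")
        if not self.start < self.stop:
            raise ValueError("override start must be < stop")


@dataclass
class Trajectory:
    """Simulated series (stocks, auxiliaries, flow rates) on a shared grid."""

    time: np.ndarray
    series: dict[str, np.ndarray]
    dt: float
    stock_names: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def __contains__(self, name: str) -> bool:
        return name in self.series

    def at(self, name: str, t: float) -> float:
        """Value of a series at time ``t`` (linear interpolation on the grid)."""
        return float(np.interp(t, self.time, self.series[name]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.series, index=pd.Index(self.time, name="time"))
        return df

    def equals(self, other: "Trajectory") -> bool:
        """Bit-exact equality of grids and every shared-name series."""
        if self.series.keys() != other.series.keys():
            return False
        if not np.array_equal(self.time, other.time):
            return False
        return all(np.array_equal(self.series[k], other.series[k]) for k in self.series)


class SimulationError(RuntimeError):
    """Non-finite value or arithmetic failure during a run."""


class ConvergenceError(RuntimeError):
    """dt refinement hit the floor without the outcome series stabilising."""


# ---------------------------------------------------------------------------
# Compilation and stepping
# ---------------------------------------------------------------------------


def _make_lookup(points: list[tuple[float, float]]):
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    n = len(xs)

    def interp(x: float) -> float:
        if x <= xs[0]:
            return ys[0]
        if x >= xs[-1]:
            return ys[-1]
        i = bisect_right(xs, x)
        x0, x1 = xs[i - 1], xs[i]
        y0, y1 = ys[i - 1], ys[i]
        return y0 + (y1 - y0) * (x - x0) / (x1 - x0)

    return interp


class _Compiled:
    """A graph compiled to one generated step function."""

    def __init__(self, graph: ModelGraph):
        self.graph = graph
        self.stock_names = list(graph.stocks)
        self.param_names = list(graph.params)
        self.flow_names = list(graph.flows)

        # order auxiliaries by dependency
        deps = nx.DiGraph()
        deps.add_nodes_from(graph.aux)
        parsed_aux = {name: parse_expression(expr) for name, expr in graph.aux.items()}
        for name, node in parsed_aux.items():
            variables, _ = expression_symbols(node)
            for v in variables & set(graph.aux):
                deps.add_edge(v, name)
        self.aux_names = list(nx.topological_sort(deps))

        stock_idx = {n: i for i, n in enumerate(self.stock_names)}
        param_idx = {n: i for i, n in enumerate(self.param_names)}

        lines = ["def _rhs(t, _S, _P):"]
        for name, i in stock_idx.items():
            lines.append(f"    {name} = _S[{i}]")
        for name, i in param_idx.items():
            lines.append(f"    {name} = _P[{i}]")
        for name in self.aux_names:
            lines.append(f"    {name} = {_emit(parsed_aux[name], {})}")
        flow_vars = []
        for j, name in enumerate(self.flow_names):
            node = parse_expression(graph.flows[name].rate)
            lines.append(f"    _f{j} = {_emit(node, {})}")
            flow_vars.append(f"_f{j}")
        aux_tuple = "(" + ",".join(self.aux_names) + ("," if len(self.aux_names) == 1 else "") + ")"
        flow_tuple = "(" + ",".join(flow_vars) + ("," if len(flow_vars) == 1 else "") + ")"
        lines.append(f"    return {aux_tuple if self.aux_names else '()'}, {flow_tuple if flow_vars else '()'}")

        namespace: dict[str, object] = {"min": min, "max": max, "pow": pow, "abs": abs}
        for name, lookup in graph.lookups.items():
            namespace[f"_lk_{name}"] = _make_lookup(lookup.points)
        exec("\n".join(lines), namespace)  # noqa: S102 - generated from the audited mini-language
        self.rhs = namespace["_rhs"]

        # flow incidence per stock
        self.inflows: list[list[int]] = [[] for _ in self.stock_names]
        self.outflows: list[list[int]] = [[] for _ in self.stock_names]
        for j, name in enumerate(self.flow_names):
            flow = graph.flows[name]
            if flow.sink is not None:
                self.inflows[stock_idx[flow.sink]].append(j)
            if flow.source is not None:
                self.outflows[stock_idx[flow.source]].append(j)
        self.nonneg = [graph.stocks[n].nonnegative for n in self.stock_names]
        self.limited = [
            i for i, n in enumerate(self.stock_names)
            if graph.stocks[n].nonnegative and self.outflows[i]
        ]


def _parameter_segments(
    graph: ModelGraph, settings: SimulationSettings, overrides: tuple[Override, ...], param_names: list[str]
) -> list[tuple[float, list[float]]]:
    """Piecewise-constant parameter vectors over the run."""
    base = [graph.params[n].value for n in param_names]
    if not overrides:
        return [(settings.start_time, base)]
    bounds = {settings.start_time}
    for ov in overrides:
        for b in (ov.start, ov.stop):
            if settings.start_time < b < settings.stop_time:
                bounds.add(b)
    segments = []
    idx = {n: i for i, n in enumerate(param_names)}
    for t0 in sorted(bounds):
        vec = list(base)
        for ov in overrides:
            if ov.start <= t0 < ov.stop:
                i = idx[ov.parameter]
                if ov.action == "multiply":
                    vec[i] = vec[i] * ov.value
                elif ov.action == "set":
                    vec[i] = ov.value
                else:
                    vec[i] = vec[i] + ov.value
        segments.append((t0, vec))
    return segments


def _limit_outflows(comp: _Compiled, S: list[float], fl: list[float], dt: float) -> None:
    """Proportionally rescale outflows of nonnegative stocks that would cross zero."""
    for _ in range(4):
        changed = False
        for i in comp.limited:
            out = 0.0
            for j in comp.outflows[i]:
                out += fl[j]
            if out <= 0.0:
                continue
            inn = 0.0
            for j in comp.inflows[i]:
                inn += fl[j]
            projected = S[i] + dt * (inn - out)
            if projected < -1e-12 * max(1.0, abs(S[i])):
                scale = (S[i] + dt * inn) / (dt * out)
                if scale < 0.0:
                    scale = 0.0
                for j in comp.outflows[i]:
                    fl[j] *= scale
                changed = True
        if not changed:
            return


def simulate(
    graph: ModelGraph,
    settings: SimulationSettings,
    overrides: tuple[Override, ...] | list[Override] = (),
) -> Trajectory:
    """Run the graph with explicit first-order steps.

    Stocks advance as ``S(t + dt) = S(t) + dt * (inflows - outflows)``;
    outflows of nonnegative-flagged stocks are uniformly rescaled within a
    step so the stock never crosses zero.  Overrides replace parameter
    values from their start time (inclusive) to their stop time
    (exclusive).  A non-finite value aborts with the time and symbol named.
    """
    comp = getattr(graph, "_cache", None)
    if comp is None:
        diags = validate_graph(graph)
        if diags:
            raise GraphValidationError(diags)
        comp = _Compiled(graph)
        graph._cache = comp
    overrides = tuple(overrides)
    for ov in overrides:
        if ov.parameter not in graph.params:
            raise ValueError(f"override references undeclared parameter {ov.parameter!r}")
    segments = _parameter_segments(graph, settings, overrides, comp.param_names)
    seg_times = [s[0] for s in segments]

    n = settings.n_steps
    dt = settings.dt
    t0 = settings.start_time
    nS, nA, nF = len(comp.stock_names), len(comp.aux_names), len(comp.flow_names)

    S = [graph.stocks[name].initial for name in comp.stock_names]
    rec_S = np.empty((n + 1, nS))
    rec_A = np.empty((n + 1, nA))
    rec_F = np.empty((n + 1, nF))

    rhs = comp.rhs
    seg_ptr = 0
    P = segments[0][1]
    for k in range(n + 1):
        t = t0 + k * dt
        while seg_ptr + 1 < len(segments) and t >= seg_times[seg_ptr + 1] - 1e-12:
            seg_ptr += 1
            P = segments[seg_ptr][1]
        try:
            aux, flows = rhs(t, S, P)
        except (ZeroDivisionError, OverflowError, ValueError) as exc:
            raise SimulationError(f"arithmetic failure at t={t:.6f}: {exc}") from exc
        fl = list(flows)
        _limit_outflows(comp, S, fl, dt)
        rec_S[k] = S
        rec_A[k] = aux
        rec_F[k] = fl
        if k == n:
            break
        for i in range(nS):
            dS = 0.0
            for j in comp.inflows[i]:
                dS += fl[j]
            for j in comp.outflows[i]:
                dS -= fl[j]
            s_new = S[i] + dt * dS
            if comp.nonneg[i] and s_new < 0.0:
                s_new = 0.0
            if not math.isfinite(s_new):
                raise SimulationError(
                    f"non-finite value for stock {comp.stock_names[i]!r} at t={t + dt:.6f} "
                    f"(rate expression of one of: "
                    f"{[comp.flow_names[j] for j in comp.inflows[i] + comp.outflows[i]]})"
                )
            S[i] = s_new

    time = t0 + dt * np.arange(n + 1)
    series: dict[str, np.ndarray] = {}
    for i, name in enumerate(comp.stock_names):
        series[name] = rec_S[:, i].copy()
    for i, name in enumerate(comp.aux_names):
        series[name] = rec_A[:, i].copy()
    for i, name in enumerate(comp.flow_names):
        series[name] = rec_F[:, i].copy()
    return Trajectory(time=time, series=series, dt=dt, stock_names=tuple(comp.stock_names))


def refine_until_converged(
    graph: ModelGraph,
    settings: SimulationSettings,
    overrides: tuple[Override, ...] | list[Override] = (),
    watch: list[str] | None = None,
    rel_tol: float = 0.005,
    min_dt: float = 1.0 / 1024.0,
) -> tuple[Trajectory, float]:
    """Halve dt until watched series change by < ``rel_tol`` between refinements.

    Compares successive runs on the coarser grid; returns the converged
    (finer) trajectory and the dt it used.  Raises :class:`ConvergenceError`
    naming the worst series if dt reaches ``min_dt`` without converging.
    """
    names = watch if watch is not None else list(graph.stocks)
    dt = settings.dt
    traj = simulate(graph, settings, overrides)
    while True:
        dt2 = dt / 2.0
        fine = simulate(
            graph,
            SimulationSettings(settings.start_time, settings.stop_time, dt2),
            overrides,
        )
        worst_err, worst_name = 0.0, names[0]
        for name in names:
            a = traj.series[name]
            b = fine.series[name][::2]
            scale = max(float(np.max(np.abs(a))), float(np.max(np.abs(b))), 1e-12)
            err = float(np.max(np.abs(a - b))) / scale
            if err > worst_err:
                worst_err, worst_name = err, name
        if worst_err < rel_tol:
            return fine, dt2
        if dt2 <= min_dt:
            raise ConvergenceError(
                f"no convergence by dt={dt2:.6g} yr; worst series {worst_name!r} "
                f"still changing by {worst_err:.3%}"
            )
        traj, dt = fine, dt2
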