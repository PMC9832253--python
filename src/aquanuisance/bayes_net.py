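"""Discrete Bayesian network for macrophyte-management decision support.

The network links what drives people's perception of plant growth as a
nuisance (activity, respondent type, species, growth level) to a plant
management option (no / partial / full removal) and onwards to the
short-term ecological consequences of removal, with phytoplankton risk as
the endpoint.  Nodes are discrete; each carries a conditional probability
table (CPT) over its states for every combination of parent states.

Inference is exact: variable elimination with a min-fill ordering, checked
against full joint enumeration.  Evidence is hard (a node observed in one
state) and may sit anywhere in the graph, so the same engine answers both
forward ("set the user group, read off the recommended option") and
backward ("set a phytoplankton target, read back the management posterior")
queries.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NodeDef",
    "Cpt",
    "BayesNet",
    "ScenarioResult",
    "ImpossibleEvidenceError",
    "validate_network",
    "learn_cpt",
    "infer",
    "enumerate_joint",
    "map_decision",
    "run_scenario",
    "save_network",
    "load_network",
    "example_network",
    "random_network",
    "forward_sample",
]

ROW_SUM_TOL = 1e-9


class ImpossibleEvidenceError(ValueError):
    """The evidence configuration has zero probability under the network."""


@dataclass(frozen=True)
class NodeDef:
    name: str
    states: tuple[str, ...]

    def __post_init__(self):
        if len(self.states) < 2:
            raise ValueError(f"node {self.name!r} needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"node {self.name!r} has duplicate state labels")


@dataclass(frozen=True)
class Cpt:
    """P(child | parents): array shaped (*parent cardinalities, child states)."""

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def row(self, parent_states: tuple[int, ...]) -> np.ndarray:
        return self.table[parent_states]


@dataclass
class BayesNet:
    nodes: dict[str, NodeDef]
    edges: set[tuple[str, str]]
    cpts: dict[str, Cpt] = field(default_factory=dict)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, c in self.edges if c == node))

    def card(self, node: str) -> int:
        return len(self.nodes[node].states)

    def state_index(self, node: str, state: str) -> int:
        try:
            return self.nodes[node].states.index(state)
        except ValueError:
            raise KeyError(f"{state!r} is not a state of node {node!r}") from None


@dataclass(frozen=True)
class ScenarioResult:
    name: str
    evidence: Mapping[str, str]
    posteriors: Mapping[str, Mapping[str, float]]
    map_node: str
    map_state: str
    map_probability: float
    tie: bool


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_network(net: BayesNet) -> list[str]:
    """Structural and numerical checks; a valid network yields []."""
    issues: list[str] = []
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for p, c in net.edges:
        if p not in net.nodes or c not in net.nodes:
            issues.append(f"edge ({p} -> {c}) references unknown node")
        else:
            g.add_edge(p, c)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        issues.append("cycle: " + " -> ".join(str(e[0]) for e in cyc) + f" -> {cyc[-1][1]}")
        return issues
    for name in net.nodes:
        if name not in net.cpts:
            issues.append(f"missing CPT for node {name!r}")
            continue
        cpt = net.cpts[name]
        if tuple(sorted(cpt.parents)) != net.parents(name):
            issues.append(f"CPT parents {cpt.parents} of {name!r} do not match "
                          f"graph parents {net.parents(name)}")
            continue
        expected = tuple(net.card(p) for p in cpt.parents) + (net.card(name),)
        if cpt.table.shape != expected:
            issues.append(f"CPT of {name!r} has shape {cpt.table.shape}, expected {expected}")
            continue
        if np.any(cpt.table < -ROW_SUM_TOL) or np.any(cpt.table > 1 + ROW_SUM_TOL):
            issues.append(f"CPT of {name!r} has entries outside [0, 1]")
        sums = cpt.table.sum(axis=-1)
        bad = np.argwhere(np.abs(sums - 1.0) > ROW_SUM_TOL)
        for rowidx in bad[:10]:
            issues.append(f"CPT row of {name!r} at parent index {tuple(int(i) for i in rowidx)} "
                          f"sums to {float(sums[tuple(rowidx)]):.6g}")
    extra = set(net.cpts) - set(net.nodes)
    for name in sorted(extra):
        issues.append(f"CPT for unknown node {name!r}")
    return issues


def _require_valid(net: BayesNet) -> None:
    issues = validate_network(net)
    if issues:
        raise ValueError("invalid network: " + "; ".join(issues))


# ---------------------------------------------------------------------------
# CPT learning from cases
# ---------------------------------------------------------------------------

def learn_cpt(cases: pd.DataFrame, child: str, parents: Sequence[str],
              child_states: Optional[Sequence[str]] = None,
              parent_states: Optional[Mapping[str, Sequence[str]]] = None,
              pseudocount: float = 1.0) -> Cpt:
    """Estimate P(child | parents) from discrete case records.

    P(c | p) = (count(c, p) + a) / (count(p) + a * |child states|) with
    pseudocount a >= 0 (a = 1 is the uniform-prior default).  With a = 0,
    parent combinations absent from the data are an error; with a > 0 they
    fall back to the uniform distribution.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    for col in [child, *parents]:
        if col not in cases.columns:
            raise KeyError(f"cases lack column {col!r}")
    cs = list(child_states) if child_states is not None else sorted(cases[child].astype(str).unique())
    ps = {p: list(parent_states[p]) if parent_states and p in parent_states
          else sorted(cases[p].astype(str).unique()) for p in parents}
    shape = tuple(len(ps[p]) for p in parents) + (len(cs),)
    counts = np.zeros(shape)
    idx_of = {p: {s: i for i, s in enumerate(ps[p])} for p in parents}
    c_of = {s: i for i, s in enumerate(cs)}
    for _, row in cases.iterrows():
        key = tuple(idx_of[p][str(row[p])] for p in parents)
        counts[key + (c_of[str(row[child])],)] += 1.0
    row_tot = counts.sum(axis=-1, keepdims=True)
    if pseudocount == 0.0:
        unseen = np.argwhere(row_tot[..., 0] == 0)
        if len(unseen):
            combos = [tuple(ps[p][i] for p, i in zip(parents, u)) for u in unseen]
            raise ValueError(f"unseen parent combination(s) with pseudocount 0: {combos}")
        table = counts / row_tot
    else:
        table = (counts + pseudocount) / (row_tot + pseudocount * len(cs))
    return Cpt(child=child, parents=tuple(parents), table=table)


# ---------------------------------------------------------------------------
# exact inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Factor:
    vars: tuple[str, ...]
    values: np.ndarray

    def sum_out(self, var: str) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(self.vars[:ax] + self.vars[ax + 1:], self.values.sum(axis=ax))


def _factor_product(a: _Factor, b: _Factor) -> _Factor:
    out_vars = a.vars + tuple(v for v in b.vars if v not in a.vars)
    def expand(f: _Factor) -> np.ndarray:
        src_vars = [v for v in out_vars if v in f.vars]
        arr = np.transpose(f.values, [f.vars.index(v) for v in src_vars])
        shape = [arr.shape[src_vars.index(v)] if v in f.vars else 1 for v in out_vars]
        return arr.reshape(shape)
    return _Factor(out_vars, expand(a) * expand(b))


def _evidence_indices(net: BayesNet, evidence: Mapping[str, str]) -> dict[str, int]:
    return {n: net.state_index(n, s) for n, s in evidence.items()}


def _reduced_factors(net: BayesNet, ev_idx: Mapping[str, int]) -> list[_Factor]:
    factors = []
    for name, cpt in net.cpts.items():
        vars_ = cpt.parents + (name,)
        values = cpt.table
        keep_vars, slicer = [], []
        for v in vars_:
            if v in ev_idx:
                slicer.append(ev_idx[v])
            else:
                slicer.append(slice(None))
                keep_vars.append(v)
        factors.append(_Factor(tuple(keep_vars), values[tuple(slicer)]))
    return factors


def _min_fill_order(factors: list[_Factor], eliminate: set[str]) -> list[str]:
    """Min-fill elimination order with deterministic name tie-breaking."""
    neighbors: dict[str, set[str]] = {}
    for f in factors:
        for v in f.vars:
            neighbors.setdefault(v, set()).update(u for u in f.vars if u != v)
    order = []
    remaining = set(eliminate)
    while remaining:
        best, best_fill = None, None
        for v in sorted(remaining):
            nb = neighbors.get(v, set()) & (set(neighbors) - {v})
            fill = sum(1 for a, b in itertools.combinations(sorted(nb), 2)
                       if b not in neighbors.get(a, set()))
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        nb = neighbors.pop(best, set())
        for a in nb:
            neighbors[a].discard(best)
            neighbors[a].update(b for b in nb if b != a)
        order.append(best)
        remaining.discard(best)
    return order


def infer(net: BayesNet, evidence: Mapping[str, str], query: Iterable[str],
          ) -> dict[str, dict[str, float]]:
    """Exact posteriors P(query node | evidence) by variable elimination.

    Evidence may sit on any node, including descendants of the query
    (diagnostic inference); with empty evidence the priors are returned.
    """
    _require_valid(net)
    query = list(query)
    for q in query:
        if q not in net.nodes:
            raise KeyError(f"unknown query node {q!r}")
    ev_idx = _evidence_indices(net, evidence)

    out: dict[str, dict[str, float]] = {}
    for q in query:
        if q in ev_idx:
            post = np.zeros(net.card(q))
            post[ev_idx[q]] = 1.0
        else:
            factors = _reduced_factors(net, ev_idx)
            eliminate = set(net.nodes) - set(ev_idx) - {q}
            for v in _min_fill_order(factors, eliminate):
                involved = [f for f in factors if v in f.vars]
                rest = [f for f in factors if v not in f.vars]
                if not involved:
                    continue
                prod = involved[0]
                for f in involved[1:]:
                    prod = _factor_product(prod, f)
                factors = rest + [prod.sum_out(v)]
            result = _Factor((), np.array(1.0))
            for f in factors:
                result = _factor_product(result, f)
            if result.vars != (q,):
                result = _Factor((q,), np.transpose(result.values,
                                                    [result.vars.index(q)]))
            post = np.asarray(result.values, float)
            total = post.sum()
            if total <= 0.0:
                raise ImpossibleEvidenceError(
                    f"evidence {dict(evidence)} has zero probability")
            post = post / total
        out[q] = dict(zip(net.nodes[q].states, (float(v) for v in post)))
    return out


def enumerate_joint(net: BayesNet, evidence: Mapping[str, str], query: Iterable[str],
                    max_states: int = 10 ** 6) -> dict[str, dict[str, float]]:
    """Posteriors by summing the full joint; reference oracle for ``infer``."""
    _require_valid(net)
    names = list(net.nodes)
    cards = [net.card(n) for n in names]
    if int(np.prod(cards)) > max_states:
        raise ValueError("joint state space exceeds the enumeration limit")
    joint = np.ones(cards)
    for name, cpt in net.cpts.items():
        vars_ = cpt.parents + (name,)
        perm = [vars_.index(v) for v in names if v in vars_]
        arr = np.transpose(cpt.table, perm)
        shape = [net.card(v) if v in vars_ else 1 for v in names]
        joint = joint * arr.reshape(shape)
    for n, idx in _evidence_indices(net, evidence).items():
        ax = names.index(n)
        mask = np.zeros(cards[ax])
        mask[idx] = 1.0
        shape = [1] * len(names)
        shape[ax] = cards[ax]
        joint = joint * mask.reshape(shape)
    total = joint.sum()
    if total <= 0.0:
        raise ImpossibleEvidenceError(f"evidence {dict(evidence)} has zero probability")
    out = {}
    for q in query:
        ax = names.index(q)
        marg = joint.sum(axis=tuple(i for i in range(len(names)) if i != ax))
        out[q] = dict(zip(net.nodes[q].states, (float(v) for v in marg / total)))
    return out


def map_decision(net: BayesNet, evidence: Mapping[str, str], decision_node: str,
                 ) -> tuple[str, float, bool]:
    """MAP state of the decision node under evidence.

    Ties are broken by declared state order (first wins) and flagged.
    """
    if decision_node not in net.nodes:
        raise KeyError(f"unknown decision node {decision_node!r}")
    post = infer(net, evidence, [decision_node])[decision_node]
    states = net.nodes[decision_node].states
    probs = np.array([post[s] for s in states])
    best = int(np.argmax(probs))
    tie = bool(np.sum(np.isclose(probs, probs[best], rtol=0.0, atol=1e-12)) > 1)
    return states[best], float(probs[best]), tie


def run_scenario(net: BayesNet, name: str, evidence: Mapping[str, str],
                 query: Sequence[str] = ("Perception", "Plant management option", "Phytoplankton"),
                 decision_node: str = "Plant management option") -> ScenarioResult:
    """Apply a named evidence preset and collect the decision-relevant posteriors.

    Presets may also place evidence on the endpoint (e.g. a phytoplankton
    target) and read the management posterior back through the graph.
    """
    for n in evidence:
        if n not in net.nodes:
            raise KeyError(f"scenario {name!r}: unknown node {n!r}")
    query = [q for q in query if q in net.nodes]
    posteriors = infer(net, evidence, query)
    state, prob, tie = map_decision(net, evidence, decision_node)
    return ScenarioResult(name=name, evidence=dict(evidence), posteriors=posteriors,
                          map_node=decision_node, map_state=state,
                          map_probability=prob, tie=tie)


# ---------------------------------------------------------------------------
# file formats: JSON structure + one TSV per CPT
# ---------------------------------------------------------------------------

def _cpt_filename(node: str) -> str:
    return "cpt_" + node.lower().replace(" ", "_") + ".tsv"


def save_network(net: BayesNet, directory) -> None:
    """Write nodes/edges as JSON and one TSV per node CPT.

    TSV layout: one column per parent (state labels), then one probability
    column per child state named ``p_<state>``; rows iterate over parent
    state combinations in declared order.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    struct = {
        "nodes": [{"name": n.name, "states": list(n.states)} for n in net.nodes.values()],
        "edges": sorted([list(e) for e in net.edges]),
    }
    (d / "network.json").write_text(json.dumps(struct, indent=2))
    for name, cpt in net.cpts.items():
        rows = []
        parent_states = [net.nodes[p].states for p in cpt.parents]
        for combo in itertools.product(*[range(len(s)) for s in parent_states]):
            row = {p: parent_states[i][combo[i]] for i, p in enumerate(cpt.parents)}
            probs = cpt.table[combo]
            for j, s in enumerate(net.nodes[name].states):
                row[f"p_{s}"] = f"{probs[j]:.10g}"
            rows.append(row)
        pd.DataFrame(rows).to_csv(d / _cpt_filename(name), sep="\t", index=False)


def load_network(directory) -> BayesNet:
    """Load a network saved by :func:`save_network`; row sums are validated."""
    d = Path(directory)
    struct = json.loads((d / "network.json").read_text())
    nodes = {n["name"]: NodeDef(n["name"], tuple(n["states"])) for n in struct["nodes"]}
    edges = {tuple(e) for e in struct["edges"]}
    net = BayesNet(nodes=nodes, edges=edges)
    for name, node in nodes.items():
        path = d / _cpt_filename(name)
        if not path.exists():
            raise FileNotFoundError(f"missing CPT file {path}")
        df = pd.read_csv(path, sep="\t", dtype=str)
        parents = net.parents(name)
        parent_states = [nodes[p].states for p in parents]
        shape = tuple(len(s) for s in parent_states) + (len(node.states),)
        table = np.zeros(shape)
        expected_rows = int(np.prod([len(s) for s in parent_states])) if parents else 1
        if len(df) != expected_rows:
            raise ValueError(f"CPT file for {name!r} has {len(df)} rows, expected {expected_rows}")
        for _, row in df.iterrows():
            combo = tuple(parent_states[i].index(str(row[p])) for i, p in enumerate(parents))
            table[combo] = [float(row[f"p_{s}"]) for s in node.states]
        net.cpts[name] = Cpt(child=name, parents=parents, table=table)
    issues = validate_network(net)
    if issues:
        raise ValueError("invalid network on load: " + "; ".join(issues))
    return net


def example_network() -> BayesNet:
    """The synthetic example decision network shipped with the package.

    Topology follows the decision-support structure (perception drivers ->
    Perception -> Plant management option -> ecological consequences ->
    Phytoplankton); all CPTs are synthetic stand-ins, NOT the expert tables
    of the original tool.
    """
    from importlib import resources
    with resources.as_file(resources.files("aquanuisance") / "data" / "example_net_synthetic") as d:
        return load_network(d)


def random_network(rng: np.random.Generator, max_nodes: int = 8, max_states: int = 3,
                   edge_prob: float = 0.4) -> BayesNet:
    """A random DAG with random CPTs; used for inference equivalence checks.

    Nodes are named n0..nk with edges only from lower to higher index, so the
    graph is acyclic by construction.
    """
    n_nodes = int(rng.integers(2, max_nodes + 1))
    nodes = {}
    for i in range(n_nodes):
        card = int(rng.integers(2, max_states + 1))
        nodes[f"n{i}"] = NodeDef(f"n{i}", tuple(f"s{j}" for j in range(card)))
    edges = {(f"n{i}", f"n{j}") for i in range(n_nodes) for j in range(i + 1, n_nodes)
             if rng.random() < edge_prob}
    net = BayesNet(nodes=nodes, edges=edges)
    for name in nodes:
        parents = net.parents(name)
        shape = tuple(net.card(p) for p in parents) + (net.card(name),)
        raw = rng.gamma(1.0, 1.0, size=shape) + 1e-3
        net.cpts[name] = Cpt(name, parents, raw / raw.sum(axis=-1, keepdims=True))
    return net


def forward_sample(net: BayesNet, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Ancestral sampling; used to cross-check the factorisation."""
    _require_valid(net)
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges)
    order = list(nx.topological_sort(g))
    data: dict[str, np.ndarray] = {}
    for name in order:
        cpt = net.cpts[name]
        card = net.card(name)
        if not cpt.parents:
            probs = np.broadcast_to(cpt.table, (n, card))
        else:
            idx = tuple(data[p] for p in cpt.parents)
            probs = cpt.table[idx]
        u = rng.random(n)
        data[name] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    return pd.DataFrame({name: [net.nodes[name].states[i] for i in col]
                         for name, col in data.items()})
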