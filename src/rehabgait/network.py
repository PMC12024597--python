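"""Discrete Bayesian network for rehabilitation-training planning.

The default network models how observed joint motions (hip, knee, ankle, per
anatomical plane) inform per-plane recovery status, per-joint rehabilitation
goals, and an overall training-scenario node:

* 15 binary *observation* roots (B11..B82): one per measured joint motion,
  state 0 = good, state 1 = poor.
* 8 binary *intermediate* nodes (B1..B8): recovery status of each joint plane,
  each a child of its plane's motion pair (knee sagittal, B4, has the single
  parent B41), state 0 = recovered, 1 = injured.
* 3 ternary *goal* nodes (P1 hip, P2 knee, P3 ankle), each conditioned on its
  joint's motion roots through the packaged conditional probability tables.
* 1 ternary *target* node E (mild / moderate / severe repair scenario), child
  of all eight intermediates.

The goal-node tables ship verbatim as packaged fixtures; the intermediate and
target tables are not published for this network, so they default to explicit,
overridable parameterizations (leaky noisy-OR for intermediates, a weighted
injured-count kernel for E; see :func:`build_rehab_network`).

Inference is exact: :func:`query_posterior` runs variable elimination with a
deterministic min-fill ordering, and :func:`enumerate_posterior` is an
independent full-joint summation used as a cross-check oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import (
    CapacityError,
    ConfigError,
    FixtureError,
    InconsistentEvidenceError,
    StructuralError,
)

__all__ = [
    "NodeSpec",
    "ConditionalTable",
    "NetworkModel",
    "Evidence",
    "Posterior",
    "GoalScores",
    "ValidationReport",
    "build_rehab_network",
    "query_posterior",
    "enumerate_posterior",
    "weighted_goal_score",
    "validate_model",
    "DEFAULT_WEIGHTS",
    "DEFAULT_STAGE_PRIORITIES",
]

ROLE_OBSERVATION = "observation_motion"
ROLE_INTERMEDIATE = "intermediate"
ROLE_GOAL = "goal"
ROLE_TARGET = "target"

#: Functional impact weights (1-5). Core sagittal planes (hip B1, knee B4)
#: carry the maximum weight 5; the remaining plane nodes are secondary tier
#: (3, the published example being ankle coronal B7); motion-level observation
#: nodes are auxiliary (1, example: hip abduction B21).
DEFAULT_WEIGHTS: dict[str, int] = {
    "B1": 5, "B2": 3, "B3": 3, "B4": 5, "B5": 3, "B6": 3, "B7": 3, "B8": 3,
}

#: Rehabilitation-priority coefficients by recovery stage.
DEFAULT_STAGE_PRIORITIES: dict[str, float] = {
    "mild": 0.8,
    "moderate": 0.6,
    "severe": 0.4,
}

_MOTION_LABELS = {
    "B11": "hip flexion", "B12": "hip extension",
    "B21": "hip abduction", "B22": "hip adduction",
    "B31": "hip external rotation", "B32": "hip internal rotation",
    "B41": "knee flexion",
    "B51": "knee external rotation", "B52": "knee internal rotation",
    "B61": "ankle flexion", "B62": "ankle extension",
    "B71": "ankle abduction", "B72": "ankle adduction",
    "B81": "ankle external rotation", "B82": "ankle internal rotation",
}

_PLANE_LABELS = {
    "B1": "hip sagittal plane", "B2": "hip coronal plane",
    "B3": "hip horizontal plane", "B4": "knee sagittal plane",
    "B5": "knee horizontal plane", "B6": "ankle sagittal plane",
    "B7": "ankle coronal plane", "B8": "ankle horizontal plane",
}

#: Intermediate node -> its plane's observation roots.
PLANE_PARENTS = {
    "B1": ("B11", "B12"), "B2": ("B21", "B22"), "B3": ("B31", "B32"),
    "B4": ("B41",), "B5": ("B51", "B52"), "B6": ("B61", "B62"),
    "B7": ("B71", "B72"), "B8": ("B81", "B82"),
}

#: Goal node -> its joint's observation roots (table parent order).
GOAL_PARENTS = {
    "P1": ("B11", "B12", "B21", "B22", "B31", "B32"),
    "P2": ("B41", "B51", "B52"),
    "P3": ("B61", "B62", "B71", "B72", "B81", "B82"),
}

TARGET_STATES = ("mild_repair", "moderate_repair", "severe_repair")


@dataclass(frozen=True)
class NodeSpec:
    """A network node: identifier, display label, layer role, ordered states."""

    id: str
    label: str
    role: str
    states: tuple[str, ...]

    def __post_init__(self):
        if self.role not in (ROLE_OBSERVATION, ROLE_INTERMEDIATE, ROLE_GOAL,
                             ROLE_TARGET):
            raise ConfigError(f"unknown role {self.role!r} for node {self.id}")
        if self.role in (ROLE_OBSERVATION, ROLE_INTERMEDIATE) \
                and len(self.states) != 2:
            raise ConfigError(f"{self.id}: motion/intermediate nodes are binary")
        if self.role in (ROLE_GOAL, ROLE_TARGET) and len(self.states) != 3:
            raise ConfigError(f"{self.id}: goal/target nodes have 3 states")

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass
class ConditionalTable:
    """One child node's probability rows over ordered parent configurations.

    ``rows`` maps a parent-state tuple (ordered as ``parent_order``) to a
    probability vector over the child's states.  ``completion_rule`` declares
    how configurations absent from the source are filled when the table is
    expanded: ``"none"`` requires completeness, ``"uniform"`` fills missing
    rows with a uniform vector.
    """

    child: str
    parent_order: tuple[str, ...]
    rows: dict[tuple[int, ...], tuple[float, ...]]
    completion_rule: str = "none"
    child_states: tuple[str, ...] | None = None

    def __post_init__(self):
        self.parent_order = tuple(self.parent_order)
        self.rows = {tuple(k): tuple(float(p) for p in v)
                     for k, v in self.rows.items()}
        if self.completion_rule not in ("none", "uniform"):
            raise ConfigError(
                f"unknown completion_rule {self.completion_rule!r}")

    @property
    def n_child_states(self) -> int:
        return len(next(iter(self.rows.values())))

    def validate(self, parent_cards: Sequence[int] | None = None,
                 atol: float = 1e-6) -> list[str]:
        """Return a list of problems (empty when the table is valid)."""
        issues = []
        k = self.n_child_states
        for cfg, vec in self.rows.items():
            if len(cfg) != len(self.parent_order):
                issues.append(f"{self.child}{cfg}: wrong tuple length")
                continue
            if len(vec) != k:
                issues.append(f"{self.child}{cfg}: ragged probability vector")
            if any(p < 0 for p in vec):
                issues.append(f"{self.child}{cfg}: negative probability")
            dev = abs(sum(vec) - 1.0)
            if dev > atol:
                issues.append(
                    f"{self.child}{cfg}: row sums to {sum(vec):.6f}")
        if parent_cards is not None:
            full = int(np.prod(parent_cards)) if parent_cards else 1
            if len(self.rows) > full:
                issues.append(f"{self.child}: more rows than configurations")
            if self.completion_rule == "none" and len(self.rows) != full:
                issues.append(
                    f"{self.child}: {len(self.rows)}/{full} rows present "
                    "with completion_rule 'none'")
        return issues

    def max_row_sum_deviation(self) -> float:
        return max(abs(sum(v) - 1.0) for v in self.rows.values())

    def to_array(self, parent_cards: Sequence[int]) -> np.ndarray:
        """Expand to an ndarray of shape ``(*parent_cards, n_child_states)``."""
        k = self.n_child_states
        shape = tuple(parent_cards) + (k,)
        arr = np.empty(shape, dtype=float)
        missing = []
        for cfg in itertools.product(*(range(c) for c in parent_cards)):
            vec = self.rows.get(cfg)
            if vec is None:
                if self.completion_rule == "uniform":
                    vec = (1.0 / k,) * k
                    missing.append(cfg)
                else:
                    raise FixtureError(
                        f"table for {self.child}: configuration {cfg} missing "
                        "and completion_rule is 'none'")
            arr[cfg] = vec
        return arr


@dataclass
class Evidence:
    """Hard evidence: node id -> observed state index."""

    assignments: dict[str, int] = field(default_factory=dict)

    def validate(self, model: "NetworkModel") -> None:
        for node, state in self.assignments.items():
            if node not in model.nodes:
                raise ConfigError(f"evidence names unknown node {node!r}")
            if not 0 <= int(state) < model.nodes[node].n_states:
                raise ConfigError(
                    f"evidence state {state} out of range for {node}")


@dataclass
class Posterior:
    """Exact marginals per queried node, plus the inference provenance."""

    marginals: dict[str, np.ndarray]
    evidence: dict[str, int] = field(default_factory=dict)
    elimination_order: list[str] = field(default_factory=list)

    def __getitem__(self, node: str) -> np.ndarray:
        return self.marginals[node]

    def __contains__(self, node: str) -> bool:
        return node in self.marginals


class NetworkModel:
    """DAG + node specs + CPTs + weights/priorities for the rehab network."""

    def __init__(self, nodes: Iterable[NodeSpec],
                 edges: Iterable[tuple[str, str]],
                 tables: Mapping[str, ConditionalTable],
                 priors: Mapping[str, Sequence[float]],
                 weights: Mapping[str, float] | None = None,
                 stage_priorities: Mapping[str, float] | None = None):
        self.nodes: dict[str, NodeSpec] = {}
        for spec in nodes:
            if spec.id in self.nodes:
                raise StructuralError(f"duplicate node id {spec.id}")
            self.nodes[spec.id] = spec
        self.edges = [tuple(e) for e in edges]
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise StructuralError(f"edge ({u}, {v}) names unknown node")
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self.nodes)
        self.graph.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise StructuralError("edge list contains a cycle")
        self.tables = dict(tables)
        self.priors = {k: np.asarray(v, dtype=float) for k, v in priors.items()}
        self.weights = dict(weights or {})
        self.stage_priorities = dict(stage_priorities
                                     or DEFAULT_STAGE_PRIORITIES)
        for child, tab in self.tables.items():
            expected = tuple(tab.parent_order)
            actual = tuple(self.parents(child))
            if set(expected) != set(actual):
                raise StructuralError(
                    f"table for {child}: parent_order {expected} does not "
                    f"match graph parents {actual}")

    def parents(self, node: str) -> list[str]:
        return sorted(self.graph.predecessors(node))

    def children(self, node: str) -> list[str]:
        return sorted(self.graph.successors(node))

    def is_root(self, node: str) -> bool:
        return self.graph.in_degree(node) == 0

    def card(self, node: str) -> int:
        return self.nodes[node].n_states

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph))

    def weight(self, node: str) -> float:
        return float(self.weights.get(node, 1.0))

    def factors(self) -> list["_Factor"]:
        """One factor per node: prior for roots, expanded CPT otherwise."""
        out = []
        for node in self.nodes:
            if self.is_root(node):
                prior = self.priors.get(node)
                if prior is None:
                    raise FixtureError(f"root {node} has no prior")
                out.append(_Factor((node,), np.asarray(prior, dtype=float)))
            else:
                tab = self.tables.get(node)
                if tab is None:
                    raise FixtureError(f"non-root {node} has no table")
                cards = [self.card(p) for p in tab.parent_order]
                arr = tab.to_array(cards)
                out.append(_Factor(tuple(tab.parent_order) + (node,), arr))
        return out

    def subnetwork(self, node_ids: Iterable[str]) -> "NetworkModel":
        """Restrict to an ancestrally closed node subset (roots stay roots)."""
        keep = set(node_ids)
        for node in keep:
            missing = set(self.parents(node)) - keep
            if missing and node in self.tables:
                raise StructuralError(
                    f"subnetwork not ancestrally closed: {node} lacks "
                    f"parents {sorted(missing)}")
        nodes = [s for nid, s in self.nodes.items() if nid in keep]
        edges = [(u, v) for u, v in self.edges if u in keep and v in keep]
        tables = {c: t for c, t in self.tables.items() if c in keep}
        priors = {r: p for r, p in self.priors.items() if r in keep}
        return NetworkModel(nodes, edges, tables, priors, self.weights,
                            self.stage_priorities)


# ---------------------------------------------------------------------------
# Factor algebra (internal)


class _Factor:
    """Dense factor over named discrete variables."""

    __slots__ = ("vars", "values")

    def __init__(self, variables: tuple[str, ...], values: np.ndarray):
        self.vars = tuple(variables)
        self.values = np.asarray(values, dtype=float)
        assert self.values.ndim == len(self.vars)

    def multiply(self, other: "_Factor") -> "_Factor":
        merged = list(self.vars) + [v for v in other.vars
                                    if v not in self.vars]
        a = self._expand(merged)
        b = other._expand(merged)
        return _Factor(tuple(merged), a * b)

    def _expand(self, merged: list[str]) -> np.ndarray:
        # Move own axes into merged order, add broadcast axes for new vars.
        idx = [merged.index(v) for v in self.vars]
        arr = self.values
        shape = [1] * len(merged)
        for ax, pos in enumerate(idx):
            shape[pos] = arr.shape[ax]
        perm = np.argsort(idx)
        arr = np.transpose(arr, perm)
        return arr.reshape(shape)

    def sum_out(self, var: str) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(self.vars[:ax] + self.vars[ax + 1:],
                       self.values.sum(axis=ax))

    def reduce(self, var: str, state: int) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(self.vars[:ax] + self.vars[ax + 1:],
                       np.take(self.values, state, axis=ax))


def _reduce_all(factors: list[_Factor], evidence: Mapping[str, int]
                ) -> list[_Factor]:
    out = []
    for f in factors:
        for var, state in evidence.items():
            if var in f.vars:
                f = f.reduce(var, int(state))
        out.append(f)
    return out


def _min_fill_order(factors: list[_Factor], keep: set[str]) -> list[str]:
    """Min-fill elimination order, lexicographic tie-break (deterministic)."""
    adj: dict[str, set[str]] = {}
    for f in factors:
        for v in f.vars:
            adj.setdefault(v, set()).update(u for u in f.vars if u != v)
    order = []
    remaining = sorted(v for v in adj if v not in keep)
    while remaining:
        best, best_fill = None, None
        for v in remaining:
            nbrs = [u for u in adj[v] if u in adj]
            fill = sum(1 for a, b in itertools.combinations(nbrs, 2)
                       if b not in adj[a])
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        order.append(best)
        nbrs = [u for u in adj[best] if u in adj]
        for a, b in itertools.combinations(nbrs, 2):
            adj[a].add(b)
            adj[b].add(a)
        for u in nbrs:
            adj[u].discard(best)
        del adj[best]
        remaining.remove(best)
    return order


def _eliminate(factors: list[_Factor], order: list[str]) -> list[_Factor]:
    factors = list(factors)
    for var in order:
        bucket = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        if not bucket:
            continue
        prod = bucket[0]
        for f in bucket[1:]:
            prod = prod.multiply(f)
        factors.append(prod.sum_out(var))
    return factors


def query_posterior(model: NetworkModel, query: Sequence[str],
                    evidence: Evidence | None = None) -> Posterior:
    """Exact conditional marginals of ``query`` nodes by variable elimination.

    With empty evidence this returns prior marginals.  Evidence assigning
    zero joint probability raises :class:`InconsistentEvidenceError`.
    """
    if isinstance(query, str):
        query = [query]
    if not query:
        raise ConfigError("query must name at least one node")
    ev = evidence or Evidence()
    ev.validate(model)
    for node in query:
        if node not in model.nodes:
            raise ConfigError(f"query names unknown node {node!r}")
    base = _reduce_all(model.factors(), ev.assignments)
    marginals: dict[str, np.ndarray] = {}
    elim_log: list[str] = []
    for node in query:
        if node in ev.assignments:
            vec = np.zeros(model.card(node))
            vec[int(ev.assignments[node])] = 1.0
            marginals[node] = vec
            continue
        order = _min_fill_order(base, keep={node})
        elim_log.extend(order)
        remaining = _eliminate(base, order)
        prod = remaining[0]
        for f in remaining[1:]:
            prod = prod.multiply(f)
        # prod is now over {node} only (evidence vars already sliced out)
        if prod.vars != (node,):
            for v in prod.vars:
                if v != node:
                    prod = prod.sum_out(v)
        total = prod.values.sum()
        if not total > 0:
            raise InconsistentEvidenceError(
                "evidence has zero probability mass "
                f"(assignments {dict(ev.assignments)!r})")
        marginals[node] = prod.values / total
    return Posterior(marginals, dict(ev.assignments), elim_log)


#: Largest joint state space enumerate_posterior will materialize.
ENUMERATION_CAP = 10_000_000


def enumerate_posterior(model: NetworkModel, query: Sequence[str],
                        evidence: Evidence | None = None) -> Posterior:
    """Exact posterior by summing the full joint; test oracle for
    :func:`query_posterior`.

    Deterministic bit-for-bit: the joint is built by multiplying node factors
    in id order over the full state-space array, then marginalized.
    """
    if isinstance(query, str):
        query = [query]
    ev = evidence or Evidence()
    ev.validate(model)
    node_ids = list(model.nodes)
    cards = [model.card(n) for n in node_ids]
    if math.prod(cards) > ENUMERATION_CAP:
        raise CapacityError(
            f"joint state space has {math.prod(cards)} > {ENUMERATION_CAP} "
            "configurations")
    joint = _Factor((), np.array(1.0))
    for f in model.factors():
        joint = joint.multiply(f)
    # Expand to the full node order for a stable summation layout.
    joint = joint.multiply(
        _Factor(tuple(node_ids),
                np.ones(tuple(cards))))
    for var, state in ev.assignments.items():
        joint = joint.reduce(var, int(state))
    total = joint.values.sum()
    if not total > 0:
        raise InconsistentEvidenceError(
            f"evidence has zero probability mass ({dict(ev.assignments)!r})")
    marginals = {}
    for node in query:
        if node in ev.assignments:
            vec = np.zeros(model.card(node))
            vec[int(ev.assignments[node])] = 1.0
            marginals[node] = vec
            continue
        f = joint
        for v in joint.vars:
            if v != node:
                f = f.sum_out(v)
        marginals[node] = f.values / total
    return Posterior(marginals, dict(ev.assignments), ["<enumeration>"])


# ---------------------------------------------------------------------------
# Goal scoring


@dataclass
class GoalScores:
    """Stage-weighted goal scores and the resulting descending ranking."""

    stage: str
    scores: dict[str, float]
    ranking: list[str]


def weighted_goal_score(posteriors: Posterior, model: NetworkModel,
                        stage: str) -> GoalScores:
    """Score each goal node and rank them for the given recovery stage.

    Toolkit convention: ``score(g) = priority(stage) * sum over n in
    {g} + parents(g) of weight(n) * P(n = favourable state)``, where the
    favourable state is index 0 (good / recovered / first-listed goal state)
    and only nodes present in ``posteriors`` contribute.  Ranking is sorted
    descending, ties broken by node id.
    """
    if stage not in model.stage_priorities:
        raise ConfigError(
            f"unknown stage {stage!r}; expected one of "
            f"{sorted(model.stage_priorities)}")
    priority = float(model.stage_priorities[stage])
    goals = [n for n, s in model.nodes.items() if s.role == ROLE_GOAL]
    missing = [g for g in goals if g not in posteriors]
    if missing:
        raise ConfigError(f"posteriors missing goal nodes {missing}")
    scores = {}
    for g in goals:
        contributing = [g] + [p for p in model.parents(g) if p in posteriors]
        scores[g] = priority * sum(
            model.weight(n) * float(posteriors[n][0]) for n in contributing)
    ranking = sorted(goals, key=lambda g: (-scores[g], g))
    return GoalScores(stage, scores, ranking)


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    ok: bool
    issues: list[str]
    max_row_sum_deviation: float

    def __bool__(self) -> bool:
        return self.ok


def validate_model(model: NetworkModel, atol: float = 1e-6
                   ) -> ValidationReport:
    """Report-only structural and numerical validation of a network model."""
    issues: list[str] = []
    if not nx.is_directed_acyclic_graph(model.graph):
        issues.append("cycle/layer violation: graph is not acyclic")
    max_dev = 0.0
    for child, tab in model.tables.items():
        cards = [model.card(p) for p in tab.parent_order]
        issues.extend(tab.validate(cards, atol=atol))
        max_dev = max(max_dev, tab.max_row_sum_deviation())
    for root, prior in model.priors.items():
        dev = abs(float(np.sum(prior)) - 1.0)
        max_dev = max(max_dev, dev)
        if dev > atol:
            issues.append(f"prior of {root} sums to {np.sum(prior):.6f}")
        if np.any(np.asarray(prior) < 0):
            issues.append(f"prior of {root} has a negative entry")
    for nid, spec in model.nodes.items():
        if spec.role == ROLE_OBSERVATION and not model.is_root(nid):
            issues.append(f"cycle/layer violation: observation node {nid} "
                          "has parents")
    target = [n for n, s in model.nodes.items() if s.role == ROLE_TARGET]
    inter = [n for n, s in model.nodes.items()
             if s.role == ROLE_INTERMEDIATE]
    for t in target:
        if nx.is_directed_acyclic_graph(model.graph):
            ancestors = nx.ancestors(model.graph, t)
            for b in inter:
                if b not in ancestors:
                    issues.append(
                        f"{t} must descend from all intermediates ({b} is "
                        "not an ancestor)")
    return ValidationReport(not issues, issues, max_dev)


# ---------------------------------------------------------------------------
# Default network construction


def _noisy_or_table(child: str, parents: tuple[str, ...], leak: float,
                    activation: float) -> ConditionalTable:
    """Leaky noisy-OR: each 'poor' parent independently drives the child to
    'injured' with probability ``activation``; ``leak`` injures it anyway."""
    rows = {}
    for cfg in itertools.product((0, 1), repeat=len(parents)):
        p_healthy = (1.0 - leak)
        for state in cfg:
            if state == 1:
                p_healthy *= (1.0 - activation)
        rows[cfg] = (p_healthy, 1.0 - p_healthy)
    return ConditionalTable(child, parents, rows,
                            child_states=("recovered", "injured"))


def _target_table(parents: tuple[str, ...], weights: Mapping[str, float],
                  centers: tuple[float, float, float] | None = None,
                  temperature: float | None = None) -> ConditionalTable:
    """Weighted injured-count kernel for the scenario node E.

    With s = sum of weight(Bi) over injured intermediates and S the total
    weight, P(E = k) is a softmax of -((s - c_k)/tau)^2 with stage centers
    c = (0, S/2, S) and temperature tau = S/4 by default: an all-recovered
    cohort points to the mild scenario, an all-injured one to severe.
    """
    total = sum(float(weights.get(p, 1.0)) for p in parents)
    if centers is None:
        centers = (0.0, total / 2.0, total)
    if temperature is None:
        temperature = max(total / 4.0, 1e-9)
    rows = {}
    for cfg in itertools.product((0, 1), repeat=len(parents)):
        s = sum(float(weights.get(p, 1.0))
                for p, st in zip(parents, cfg) if st == 1)
        logits = [-(((s - c) / temperature) ** 2) for c in centers]
        mx = max(logits)
        exps = [math.exp(v - mx) for v in logits]
        z = sum(exps)
        rows[cfg] = tuple(e / z for e in exps)
    return ConditionalTable("E", parents, rows, child_states=TARGET_STATES)


def build_rehab_network(topology_config: Mapping | None = None
                        ) -> NetworkModel:
    """Build the default 27-node rehabilitation network.

    ``topology_config`` may override pieces of the default build::

        {"root_priors": {"B11": 0.2, ...},        # P(state 1) per root
         "noisy_or": {"leak": 0.05, "activation": 0.8},
         "target": {"centers": [...], "temperature": ...},
         "weights": {...}, "stage_priorities": {...},
         "add_edges": [["P1", "E"], ...],
         "remove_edges": [["B1", "E"], ...]}

    Edge overrides are validated structurally: the result must stay acyclic
    and the target must remain a descendant of every intermediate node.
    """
    cfg = dict(topology_config or {})
    weights = {**DEFAULT_WEIGHTS, **cfg.get("weights", {})}
    stage_priorities = {**DEFAULT_STAGE_PRIORITIES,
                        **cfg.get("stage_priorities", {})}
    nor = {"leak": 0.05, "activation": 0.8, **cfg.get("noisy_or", {})}
    tgt = dict(cfg.get("target", {}))

    nodes = [NodeSpec(i, _MOTION_LABELS[i], ROLE_OBSERVATION,
                      ("good", "poor")) for i in _MOTION_LABELS]
    nodes += [NodeSpec(i, _PLANE_LABELS[i], ROLE_INTERMEDIATE,
                       ("recovered", "injured")) for i in _PLANE_LABELS]

    from .fixtures import load_cpt_table  # deferred: fixtures imports types
    goal_tables = {g: load_cpt_table(b) for g, b in
                   (("P1", "hip_P1"), ("P2", "knee_P2"), ("P3", "ankle_P3"))}
    goal_labels = {"P1": "hip rehabilitation goal",
                   "P2": "knee rehabilitation goal",
                   "P3": "ankle rehabilitation goal"}
    nodes += [NodeSpec(g, goal_labels[g], ROLE_GOAL,
                       goal_tables[g].child_states or ("s0", "s1", "s2"))
              for g in ("P1", "P2", "P3")]
    nodes.append(NodeSpec("E", "rehabilitation training scenario",
                          ROLE_TARGET, TARGET_STATES))

    edges: list[tuple[str, str]] = []
    for b, parents in PLANE_PARENTS.items():
        edges += [(p, b) for p in parents]
    for g, parents in GOAL_PARENTS.items():
        edges += [(p, g) for p in parents]
    inter = tuple(sorted(_PLANE_LABELS))
    edges += [(b, "E") for b in inter]

    for e in cfg.get("add_edges", []):
        edges.append((e[0], e[1]))
    for e in cfg.get("remove_edges", []):
        edge = (e[0], e[1])
        if edge not in edges:
            raise StructuralError(f"cannot remove absent edge {edge}")
        edges.remove(edge)

    # Structural invariants before tables are built from the final edge set.
    g = nx.DiGraph(edges)
    g.add_nodes_from(s.id for s in nodes)
    if not nx.is_directed_acyclic_graph(g):
        raise StructuralError("override creates a cycle")
    ancestors = nx.ancestors(g, "E")
    for b in inter:
        if b not in ancestors:
            raise StructuralError("E must descend from all intermediates "
                                  f"({b} lost)")

    by_id = {s.id: s for s in nodes}
    tables: dict[str, ConditionalTable] = {}
    priors: dict[str, np.ndarray] = {}
    root_p1 = dict(cfg.get("root_priors", {}))
    for nid in by_id:
        parent_ids = tuple(sorted(g.predecessors(nid)))
        if not parent_ids:
            p1 = float(root_p1.get(nid, 0.5))
            if not 0.0 <= p1 <= 1.0:
                raise ConfigError(f"root prior for {nid} outside [0, 1]")
            if by_id[nid].n_states != 2:
                raise ConfigError(f"root {nid} must be binary")
            priors[nid] = np.array([1.0 - p1, p1])
        elif nid in goal_tables:
            tab = goal_tables[nid]
            if set(tab.parent_order) != set(parent_ids):
                raise StructuralError(
                    f"override changed parents of {nid}; its packaged table "
                    f"conditions on {tab.parent_order}")
            tables[nid] = tab
        elif by_id[nid].role == ROLE_INTERMEDIATE:
            tables[nid] = _noisy_or_table(nid, parent_ids, nor["leak"],
                                          nor["activation"])
        elif nid == "E":
            tables[nid] = _target_table(
                parent_ids, weights,
                centers=tuple(tgt["centers"]) if "centers" in tgt else None,
                temperature=tgt.get("temperature"))
        else:
            raise StructuralError(f"no table rule for non-root {nid}")

    return NetworkModel(nodes, edges, tables, priors, weights,
                        stage_priorities)
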