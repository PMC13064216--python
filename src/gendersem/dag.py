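"""Causal graph of sex, latent gender, and incident health outcomes.

The hypothesized causal structure is a directed acyclic graph in which sex
assigned at birth is exogenous and causes a latent gender construct; gender is
reflected by a set of observed gender-related indicator variables; and both
sex and gender (together with age, immigration history and pre-outcome risk
factors) act on binary incident outcomes (migraine, stroke).  The graph is
compiled deterministically into a structural-equation-model specification:
latent nodes become measurement blocks, covariate edges into indicators become
indicator regressions, and outcome parents become structural predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

__all__ = [
    "CausalGraph",
    "SemSpecification",
    "CycleError",
    "build_default_graph",
    "validate_acyclic",
    "parents",
    "to_sem_spec",
    "write_graph",
    "read_graph",
]

NODE_ROLES = {"exogenous", "endogenous", "latent", "indicator", "outcome"}

#: Gender indicators in their canonical (anchor-first) order.
DEFAULT_INDICATORS = [
    "housework",
    "childcare",
    "parental_leave",
    "wage",
    "income",
    "education",
    "employment",
    "risk_taking",
    "political_interest",
    "physician_visits",
]

#: Risk factors reported before the outcome, modeled as direct outcome
#: predictors (their own upstream equations are deliberately not modeled).
RISK_FACTORS = ["smoking", "hypertension", "diabetes"]

OUTCOMES = ["migraine", "stroke"]


class CycleError(ValueError):
    """Raised when a directed cycle is found; carries the offending nodes."""

    def __init__(self, nodes: set[str]):
        self.nodes = set(nodes)
        super().__init__(f"cycle detected: {sorted(self.nodes)}")


@dataclass(frozen=True)
class CausalGraph:
    """A directed acyclic graph with role-annotated nodes.

    Parameters
    ----------
    nodes
        Mapping node name -> role, role one of ``exogenous``, ``endogenous``,
        ``latent``, ``indicator``, ``outcome``.
    edges
        Directed (source, target) pairs.
    """

    nodes: dict[str, str]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for name, role in self.nodes.items():
            if role not in NODE_ROLES:
                raise ValueError(f"unknown role {role!r} for node {name!r}")
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
        # exogenous nodes must not have incoming edges
        for u, v in self.edges:
            if self.nodes[v] == "exogenous":
                raise ValueError(f"exogenous node {v!r} has incoming edge from {u!r}")
        # latent nodes need >= 2 indicator children
        for name, role in self.nodes.items():
            if role == "latent":
                kids = [v for u, v in self.edges if u == name and self.nodes[v] == "indicator"]
                if len(kids) < 2:
                    raise ValueError(
                        f"latent node {name!r} has {len(kids)} indicator children; need >= 2"
                    )
        validate_acyclic(self)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for name, role in self.nodes.items():
            g.add_node(name, role=role)
        g.add_edges_from(self.edges)
        return g

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in set(self.edges)


@dataclass
class SemSpecification:
    """Compiled SEM specification.

    ``latents`` maps each latent to its ordered indicator list; the paired
    value is the fixed loading (identification anchor) or ``None`` for a free
    loading.  ``exogenous`` lists observed exogenous covariates whose
    variances/covariances are held at their sample values during fitting.
    """

    latents: dict[str, list[tuple[str, float | None]]]
    indicator_regressions: list[tuple[str, tuple[str, ...]]]
    structural: list[tuple[str, tuple[str, ...]]]
    exogenous: tuple[str, ...]
    scaling_rule: str = "sex_anchored_0_1"
    mean_structure: bool = False
    dropped_edges: list[tuple[str, str]] = field(default_factory=list)

    def free_parameter_names(self) -> list[str]:
        names: list[str] = []
        for lat, inds in self.latents.items():
            for ind, fixed in inds:
                if fixed is None:
                    names.append(f"{lat}=~{ind}")
        for ind, covs in self.indicator_regressions:
            names.extend(f"{ind}~{c}" for c in covs)
        for y, preds in self.structural:
            names.extend(f"{y}~{x}" for x in preds)
        if len(names) != len(set(names)):
            raise ValueError("duplicate free parameter in specification")
        return names

    def to_text(self) -> str:
        """Serialize to a lavaan-style model-description dialect."""
        lines = []
        for lat, inds in self.latents.items():
            terms = [
                ind if fixed is None else f"{fixed:g}*{ind}" for ind, fixed in inds
            ]
            lines.append(f"{lat} =~ " + " + ".join(terms))
        for ind, covs in self.indicator_regressions:
            lines.append(f"{ind} ~ " + " + ".join(covs))
        for y, preds in self.structural:
            lines.append(f"{y} ~ " + " + ".join(preds))
        if self.dropped_edges:
            lines.append("# dropped (intermediate path): " + ", ".join(
                f"{u}->{v}" for u, v in self.dropped_edges))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, exogenous: Iterable[str] = ()) -> "SemSpecification":
        latents: dict[str, list[tuple[str, float | None]]] = {}
        ind_regs: list[tuple[str, tuple[str, ...]]] = []
        structural: list[tuple[str, tuple[str, ...]]] = []
        indicator_names: set[str] = set()
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=~" in line:
                lhs, rhs = line.split("=~")
                inds: list[tuple[str, float | None]] = []
                for term in rhs.split("+"):
                    term = term.strip()
                    if "*" in term:
                        val, name = term.split("*")
                        inds.append((name.strip(), float(val)))
                    else:
                        inds.append((term, None))
                latents[lhs.strip()] = inds
                indicator_names.update(name for name, _ in inds)
            elif "~" in line:
                lhs, rhs = line.split("~")
                lhs = lhs.strip()
                preds = tuple(t.strip() for t in rhs.split("+"))
                if lhs in indicator_names:
                    ind_regs.append((lhs, preds))
                else:
                    structural.append((lhs, preds))
        return cls(
            latents=latents,
            indicator_regressions=ind_regs,
            structural=structural,
            exogenous=tuple(exogenous),
        )


def build_default_graph(include_immigration: bool = True) -> CausalGraph:
    """Construct the default sex/gender/outcome causal graph.

    Exogenous: sex, age, immigration history, plus the indicator covariates
    (children, partner, east).  Sex causes latent gender; gender is reflected
    by ten indicators; housework/childcare additionally depend on children and
    partner, income/wage on age and east residence.  Sex, gender, age (and
    optionally immigration history) act on both incident outcomes, as do the
    three before-outcome risk factors.
    """
    nodes: dict[str, str] = {
        "sex": "exogenous",
        "age": "exogenous",
        "immigration": "exogenous",
        "children": "exogenous",
        "partner": "exogenous",
        "east": "exogenous",
        "sexual_orientation": "exogenous",
        "gender": "latent",
    }
    for ind in DEFAULT_INDICATORS:
        nodes[ind] = "indicator"
    for rf in RISK_FACTORS:
        nodes[rf] = "endogenous"
    for out in OUTCOMES:
        nodes[out] = "outcome"

    edges: list[tuple[str, str]] = [("sex", "gender")]
    edges += [("gender", ind) for ind in DEFAULT_INDICATORS]
    edges += [
        ("children", "housework"),
        ("partner", "housework"),
        ("children", "childcare"),
        ("partner", "childcare"),
        ("age", "income"),
        ("east", "income"),
        ("age", "wage"),
        ("east", "wage"),
    ]
    for out in OUTCOMES:
        edges += [
            ("sex", out),
            ("gender", out),
            ("sexual_orientation", out),
            ("partner", out),
            ("age", out),
        ]
        if include_immigration:
            edges.append(("immigration", out))
        edges += [(rf, out) for rf in RISK_FACTORS]
    return CausalGraph(nodes=nodes, edges=tuple(edges))


def validate_acyclic(graph: CausalGraph) -> bool:
    """True iff the graph has no directed cycle (topological ordering exists).

    Raises :class:`CycleError` with the offending node set otherwise.
    """
    if not graph.nodes:
        raise ValueError("graph has no nodes")
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    try:
        list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cyc = nx.find_cycle(g)
        raise CycleError({u for u, _ in cyc} | {v for _, v in cyc}) from None
    return True


def parents(graph: CausalGraph, node: str) -> list[str]:
    """Sources of edges into ``node``, in construction order."""
    if node not in graph.nodes:
        raise KeyError(f"unknown node {node!r}")
    return [u for u, v in graph.edges if v == node]


def to_sem_spec(
    graph: CausalGraph,
    include_intermediates: bool = False,
    anchor: str | None = None,
) -> SemSpecification:
    """Compile a causal graph into an SEM specification.

    Risk-factor nodes enter outcome equations as direct predictors; when
    ``include_intermediates`` is off (the default, matching a parsimonious
    direct-effects model) their own parent edges are dropped and reported in
    ``dropped_edges`` rather than becoming equations.  Identification fixes
    the first indicator loading (the anchor) to 1; the latent mean is 0.
    """
    validate_acyclic(graph)
    latents: dict[str, list[tuple[str, float | None]]] = {}
    for name, role in graph.nodes.items():
        if role != "latent":
            continue
        inds = [v for u, v in graph.edges if u == name and graph.nodes[v] == "indicator"]
        if len(inds) < 2:
            raise ValueError(f"latent {name!r} has fewer than 2 indicators")
        anchor_ind = anchor if anchor in inds else inds[0]
        latents[name] = [
            (ind, 1.0 if ind == anchor_ind else None) for ind in inds
        ]

    latent_names = set(latents)
    indicator_names = {ind for inds in latents.values() for ind, _ in inds}

    ind_regs: list[tuple[str, tuple[str, ...]]] = []
    for ind in sorted(indicator_names, key=list(graph.nodes).index):
        covs = tuple(
            u for u, v in graph.edges
            if v == ind and u not in latent_names
        )
        if covs:
            ind_regs.append((ind, covs))

    structural: list[tuple[str, tuple[str, ...]]] = []
    dropped: list[tuple[str, str]] = []
    # latent regressions (e.g. gender ~ sex)
    for lat in latents:
        preds = tuple(u for u, v in graph.edges if v == lat)
        if preds:
            structural.append((lat, preds))
    for name, role in graph.nodes.items():
        if role == "outcome":
            preds = tuple(u for u, v in graph.edges if v == name)
            structural.append((name, preds))

    exog = []
    for name, role in graph.nodes.items():
        if role == "exogenous":
            exog.append(name)
        elif role == "endogenous" and not include_intermediates:
            # risk factors kept as direct predictors only: drop their parents
            for u, v in graph.edges:
                if v == name:
                    dropped.append((u, v))
            exog.append(name)

    for y, preds in structural:
        if y in preds:
            raise ValueError(f"{y!r} predicts itself")

    return SemSpecification(
        latents=latents,
        indicator_regressions=ind_regs,
        structural=structural,
        exogenous=tuple(exog),
        dropped_edges=dropped,
    )


# ---------------------------------------------------------------------------
# plain-text serialization: node-role header block, then a TAB edge list

def write_graph(graph: CausalGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# nodes\n")
        for name, role in graph.nodes.items():
            fh.write(f"{name}\t{role}\n")
        fh.write("# edges\n")
        for u, v in graph.edges:
            fh.write(f"{u}\t{v}\n")


def read_graph(path) -> CausalGraph:
    nodes: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                section = line.lstrip("# ").strip()
                continue
            a, b = line.split("\t")
            if section == "nodes":
                nodes[a] = b
            else:
                edges.append((a, b))
    return CausalGraph(nodes=nodes, edges=tuple(edges))
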