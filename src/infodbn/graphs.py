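"""Two-slice DAGs and their folded cyclic representation.

The dynamic model lives on a bipartite graph over ``{condition@t0}`` and
``{condition@t1}`` whose arcs all point forward in time, so it is acyclic by
construction.  Folding collapses the two copies of each condition into one
node: an arc pair X0->Y1 and Y0->X1 becomes a feedback loop X<->Y, a lone
cross arc stays unidirectional, and X0->X1 becomes an autoloop expressing
week-to-week autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import ParameterError

Arc = tuple  # (source condition, target condition), meaning source@t0 -> target@t1


@dataclass(frozen=True)
class TwoSliceDAG:
    """Directed bipartite graph with arcs from slice t0 to slice t1 only."""

    conditions: tuple
    arcs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "arcs", frozenset(tuple(a) for a in self.arcs))
        known = set(self.conditions)
        for s, t in self.arcs:
            if s not in known or t not in known:
                raise ParameterError(f"arc ({s!r}, {t!r}) references unknown condition")

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def has_arc(self, source: str, target: str) -> bool:
        return (source, target) in self.arcs

    def parents(self, target: str) -> tuple:
        """Parents of target@t1, in condition order."""
        ps = {s for s, t in self.arcs if t == target}
        return tuple(c for c in self.conditions if c in ps)

    def self_arcs(self) -> tuple:
        return tuple(c for c in self.conditions if (c, c) in self.arcs)

    def cross_arcs(self) -> frozenset:
        return frozenset((s, t) for s, t in self.arcs if s != t)

    # -- serialization -----------------------------------------------------

    def to_edge_frame(self) -> pd.DataFrame:
        rows = sorted(self.arcs)
        return pd.DataFrame(rows, columns=["source", "target"]).assign(lag=1)

    def to_csv(self, path) -> None:
        self.to_edge_frame().to_csv(path, index=False)

    @classmethod
    def from_edge_frame(cls, frame: pd.DataFrame, conditions: Iterable[str] | None = None):
        arcs = frozenset(zip(frame["source"], frame["target"]))
        if conditions is None:
            conditions = sorted({c for a in arcs for c in a})
        return cls(tuple(conditions), arcs)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for c in self.conditions:
            g.add_node(f"{c}@t0", condition=c, slice="t0")
            g.add_node(f"{c}@t1", condition=c, slice="t1")
        for s, t in sorted(self.arcs):
            g.add_edge(f"{s}@t0", f"{t}@t1")
        return g

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


@dataclass(frozen=True)
class FoldedGraph:
    """Cyclic condition graph with arcs classed feedback / unidirectional / autoloop."""

    nodes: tuple
    feedback: frozenset = field(default_factory=frozenset)  # unordered pairs, stored sorted
    unidirectional: frozenset = field(default_factory=frozenset)  # ordered (source, target)
    autoloops: frozenset = field(default_factory=frozenset)  # condition names

    def arc_table(self) -> pd.DataFrame:
        rows = [(a, b, "feedback") for a, b in sorted(self.feedback)]
        rows += [(s, t, "unidirectional") for s, t in sorted(self.unidirectional)]
        rows += [(c, c, "autoloop") for c in sorted(self.autoloops)]
        return pd.DataFrame(rows, columns=["source", "target", "class"])

    def has_cross_arc(self, a: str, b: str) -> bool:
        """Any cross arc between a and b, in either direction or as feedback."""
        return (
            tuple(sorted((a, b))) in self.feedback
            or (a, b) in self.unidirectional
            or (b, a) in self.unidirectional
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for a, b in sorted(self.feedback):
            g.add_edge(a, b, arc_class="feedback")
            g.add_edge(b, a, arc_class="feedback")
        for s, t in sorted(self.unidirectional):
            g.add_edge(s, t, arc_class="unidirectional")
        for c in sorted(self.autoloops):
            g.add_edge(c, c, arc_class="autoloop")
        return g

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_dot(self) -> str:
        """DOT source; feedback pairs drawn as single bidirectional edges."""
        lines = ["digraph folded {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for a, b in sorted(self.feedback):
            lines.append(f'  "{a}" -> "{b}" [dir=both, class=feedback];')
        for s, t in sorted(self.unidirectional):
            lines.append(f'  "{s}" -> "{t}" [penwidth=2, class=unidirectional];')
        for c in sorted(self.autoloops):
            lines.append(f'  "{c}" -> "{c}" [class=autoloop];')
        lines.append("}")
        return "\n".join(lines)


def fold(dag: TwoSliceDAG) -> FoldedGraph:
    """Collapse the two slices of a two-slice DAG into a cyclic graph."""
    cross = dag.cross_arcs()
    feedback = set()
    unidirectional = set()
    for s, t in cross:
        if (t, s) in cross:
            feedback.add(tuple(sorted((s, t))))
        else:
            unidirectional.add((s, t))
    autoloops = frozenset(dag.self_arcs())
    return FoldedGraph(
        nodes=dag.conditions,
        feedback=frozenset(feedback),
        unidirectional=frozenset(unidirectional),
        autoloops=autoloops,
    )


def unfold(folded: FoldedGraph) -> TwoSliceDAG:
    """Inverse of :func:`fold` for graphs that came from a two-slice DAG."""
    arcs = set()
    for a, b in folded.feedback:
        arcs.add((a, b))
        arcs.add((b, a))
    arcs.update(folded.unidirectional)
    arcs.update((c, c) for c in folded.autoloops)
    return TwoSliceDAG(folded.nodes, frozenset(arcs))
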