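"""Gene-interaction diagrams: genotype trees of serial layers of single
alleles or parallel pairs.

A diagram stacks "layers" vertically.  Each layer is one gene (a circle)
or a parallel-acting pair (a bisected circle) and splits the incoming
transfer between a buffer compartment (a square holding what the layer
hides) and the transfer passed to the next layer.  Transfer fractions
multiply down the vertical path; at every horizontal level the buffer
compartments accumulated so far plus the running transfer sum to exactly 1.
Observed (epistatic) values can be attached in brackets beside the neutral
expectations without disturbing them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ValidationError
from .neutrality import expected_parallel
from .params import BufferingState, state_from_t_bar

__all__ = ["DiagramNode", "DiagramTree", "Compartment", "build_tree",
           "validate", "export", "tree_from_json"]

_TOL = 1e-9


@dataclass(frozen=True)
class DiagramNode:
    """One layer: a single allele or a parallel pair, with its split."""

    gene_labels: tuple[str, ...]
    functional_flags: tuple[bool, ...]
    mode: str  # "single" | "parallel_pair"
    t_bar_edge: float
    b_edge: float
    child: "DiagramNode | None" = None


@dataclass(frozen=True)
class Compartment:
    """A square in the diagram: what one level transfers or buffers."""

    level: int
    kind: str  # "transfer" | "buffer"
    expected: float
    observed: float | None = None


@dataclass(frozen=True)
class DiagramTree:
    root: DiagramNode
    expected_t_bar: float
    compartments: tuple[Compartment, ...]
    observed_t_bar: float | None = None

    @property
    def nodes(self) -> list[DiagramNode]:
        out, node = [], self.root
        while node is not None:
            out.append(node)
            node = node.child
        return out


def _layer_state(labels: Sequence[str],
                 states: Sequence[BufferingState]) -> BufferingState:
    if len(labels) != len(states) or len(labels) not in (1, 2):
        raise ValidationError(
            "each layer is one allele or a parallel pair; got "
            f"{len(labels)} labels and {len(states)} states")
    if len(states) == 1:
        return states[0]
    return expected_parallel(list(states)).state


def build_tree(layers: Sequence[tuple], observed_t_bar: float | None = None,
               observed_compartments: dict[int, float] | None = None
               ) -> DiagramTree:
    """Assemble a genotype tree from ordered serial layers.

    Each layer is ``(labels, states)`` or ``(labels, states, functional)``:
    one label and one :class:`BufferingState` for a single allele, two of
    each for a parallel pair (combined by summing B).  ``functional``
    flags default to False (mutant alleles draw as unfilled circles).
    Optional observed values attach in brackets: ``observed_t_bar`` for
    the final transfer compartment, ``observed_compartments`` mapping a
    level index to an observed buffer value.
    """
    if not layers:
        raise ValidationError("a diagram needs at least one layer")
    observed_compartments = observed_compartments or {}
    nodes: list[DiagramNode] = []
    compartments: list[Compartment] = []
    prefix_t = 1.0
    for level, layer in enumerate(layers, start=1):
        labels, states = layer[0], layer[1]
        functional = tuple(layer[2]) if len(layer) > 2 else (False,) * len(labels)
        state = _layer_state(labels, states)
        nodes.append(DiagramNode(
            gene_labels=tuple(labels), functional_flags=functional,
            mode="single" if len(labels) == 1 else "parallel_pair",
            t_bar_edge=state.t_bar, b_edge=state.b))
        compartments.append(Compartment(
            level=level, kind="buffer", expected=prefix_t * state.b,
            observed=observed_compartments.get(level)))
        prefix_t *= state.t_bar
    compartments.append(Compartment(level=len(nodes), kind="transfer",
                                    expected=prefix_t,
                                    observed=observed_t_bar))
    # Chain the nodes bottom-up into a serial path.
    root = nodes[-1]
    for node in reversed(nodes[:-1]):
        root = DiagramNode(gene_labels=node.gene_labels,
                           functional_flags=node.functional_flags,
                           mode=node.mode, t_bar_edge=node.t_bar_edge,
                           b_edge=node.b_edge, child=root)
    return DiagramTree(root=root, expected_t_bar=prefix_t,
                       compartments=tuple(compartments),
                       observed_t_bar=observed_t_bar)


def validate(tree: DiagramTree) -> list[dict]:
    """Check the diagram's conservation rules; report, never raise.

    Returns one entry per problem: ``level_sum`` when a horizontal level's
    expected values do not sum to 1, ``vertical_product`` when the stored
    expected transfer disagrees with the product of the edges, and
    ``observed_discrepancy`` (informational) wherever an attached observed
    value deviates from its neutral expectation.
    """
    problems: list[dict] = []
    nodes = tree.nodes
    buffers = [c for c in tree.compartments if c.kind == "buffer"]
    prefix_t = 1.0
    for level, (node, comp) in enumerate(zip(nodes, buffers), start=1):
        level_sum = prefix_t * node.t_bar_edge + prefix_t * node.b_edge
        level_sum += sum(c.expected for c in buffers[:level - 1])
        if abs(level_sum - 1.0) > _TOL:
            problems.append({"kind": "level_sum", "level": level,
                             "sum": level_sum})
        if abs(comp.expected - prefix_t * node.b_edge) > _TOL:
            problems.append({"kind": "level_sum", "level": level,
                             "sum": comp.expected / prefix_t + node.t_bar_edge
                             if prefix_t else comp.expected})
        prefix_t *= node.t_bar_edge
    if abs(prefix_t - tree.expected_t_bar) > _TOL:
        problems.append({"kind": "vertical_product",
                         "product": prefix_t,
                         "stored": tree.expected_t_bar})
    for comp in tree.compartments:
        if comp.observed is not None and abs(comp.observed - comp.expected) > _TOL:
            problems.append({"kind": "observed_discrepancy",
                             "level": comp.level, "compartment": comp.kind,
                             "expected": comp.expected,
                             "observed": comp.observed})
    return problems


def _tree_to_payload(tree: DiagramTree) -> dict:
    layers = []
    for node in tree.nodes:
        layers.append({
            "genes": list(node.gene_labels),
            "functional": list(node.functional_flags),
            "mode": node.mode,
            "t_bar": node.t_bar_edge,
            "b": node.b_edge,
        })
    return {
        "layers": layers,
        "expected_t_bar": tree.expected_t_bar,
        "observed_t_bar": tree.observed_t_bar,
        "compartments": [
            {"level": c.level, "kind": c.kind, "expected": c.expected,
             "observed": c.observed}
            for c in tree.compartments
        ],
    }


def tree_from_json(text: str) -> DiagramTree:
    """Rebuild a tree from its JSON export (inverse of ``export(..., "json")``).

    Parallel pairs are reconstructed from their per-layer combined split,
    so the rebuilt layer carries a single synthetic state with the same
    edge values; conservation and export are unchanged by the round trip.
    """
    payload = json.loads(text)
    observed_compartments = {
        c["level"]: c["observed"] for c in payload.get("compartments", [])
        if c["kind"] == "buffer" and c.get("observed") is not None
    }
    layers = []
    for layer in payload["layers"]:
        state = state_from_t_bar(layer["t_bar"])
        if layer["mode"] == "parallel_pair":
            # Split the combined B evenly to recover two placeholder states
            # whose parallel combination reproduces the stored edge.
            half = state_from_t_bar(2.0 / (1.0 + 1.0 / layer["t_bar"]))
            layers.append((layer["genes"], [half, half], layer["functional"]))
        else:
            layers.append((layer["genes"], [state], layer["functional"]))
    return build_tree(layers, observed_t_bar=payload.get("observed_t_bar"),
                      observed_compartments=observed_compartments or None)


def _dot(tree: DiagramTree) -> str:
    lines = ["digraph gene_interaction {", "  rankdir=TB;"]
    nodes = tree.nodes
    buffers = [c for c in tree.compartments if c.kind == "buffer"]
    transfer = next(c for c in tree.compartments if c.kind == "transfer")
    for i, (node, comp) in enumerate(zip(nodes, buffers)):
        label = "/".join(node.gene_labels)
        fill = "filled" if all(node.functional_flags) else "solid"
        lines.append(
            f'  gene{i} [shape=circle, style={fill}, label="{label}"];')
        obs = f" [{comp.observed:g}]" if comp.observed is not None else ""
        lines.append(
            f'  buffer{i} [shape=box, label="b={comp.expected:g}{obs}"];')
        lines.append(
            f'  gene{i} -> buffer{i} [label="{node.b_edge:g}", color=gray];')
        if i + 1 < len(nodes):
            lines.append(
                f'  gene{i} -> gene{i + 1} [label="{node.t_bar_edge:g}"];')
    obs = (f" [{transfer.observed:g}]"
           if transfer.observed is not None else "")
    color = ("red" if transfer.observed is not None
             and abs(transfer.observed - transfer.expected) > _TOL else "green")
    lines.append(f'  transfer [shape=box, '
                 f'label="t={transfer.expected:g}{obs}"];')
    lines.append(f'  gene{len(nodes) - 1} -> transfer '
                 f'[label="{nodes[-1].t_bar_edge:g}", color={color}];')
    lines.append("}")
    return "\n".join(lines)


def export(tree: DiagramTree, format: str = "json") -> str:
    """Serialize a diagram as DOT (Graphviz) or JSON text."""
    if format == "json":
        return json.dumps(_tree_to_payload(tree), indent=2)
    if format == "dot":
        return _dot(tree)
    raise ValidationError(f"unknown export format {format!r}; use 'dot' or 'json'")
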