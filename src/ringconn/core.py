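"""Connectome data model, tabular I/O, and input-fraction weight normalization.

Conventions used throughout the package:

* Edge direction is **pre -> post** (presynaptic neuron onto postsynaptic
  neuron) everywhere, including all files read and written.
* Neuron ids are opaque strings; no numbering scheme is assumed.
* A connectome holds at most one edge per ordered ``(pre, post)`` pair;
  duplicate raw edges are summed by :func:`aggregate`.
* Autapses (``pre == post``) are retained but reported, never silently
  dropped.

The normalization implemented by :func:`input_fractions` divides each
incoming synapse count by the receiving neuron's total input, so that a
neuron's incoming weights are fractions of its input ("synaptic load").
Two denominator policies exist: ``dataset_total`` uses the input synapses
present in the loaded connectome (columns then sum to exactly 1), while
``declared_total`` lets the caller supply per-neuron totals — useful when
the loaded network is a subnetwork of a larger reconstruction whose full
input counts are known but not exported.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import pandas as pd

CELL_CLASSES = ("sensory", "interneuron", "rpn", "endocrine_target", "other")
SIDES = ("left", "right", "unpaired")

NEURON_COLUMNS = ("id", "name", "cell_class", "cluster", "sensory_origin", "side")
EDGE_COLUMNS = ("pre", "post", "count")


class ValidationError(ValueError):
    """Raised when an input table or constructed object violates an invariant."""


@dataclass(frozen=True)
class Neuron:
    """An annotated node of the connectome.

    ``sensory_origin`` names the peripheral region a sensory neuron derives
    from (e.g. ``enteric``, ``pharyngeal``, ``olfactory``, ``somatosensory``,
    ``CO2``, ``TO_VO``) and is required exactly for sensory neurons.
    ``cluster`` carries the functional group label (for ring-gland
    projection neurons the peptide cluster, e.g. ``CRZ`` or ``DH44``).
    """

    id: str
    name: str = ""
    cell_class: str = "other"
    cluster: str | None = None
    sensory_origin: str | None = None
    side: str | None = None

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(
                f"unknown cell_class {self.cell_class!r} for neuron {self.id!r}; "
                f"expected one of {CELL_CLASSES}"
            )
        if self.side is not None and self.side not in SIDES:
            raise ValidationError(
                f"unknown side {self.side!r} for neuron {self.id!r}; "
                f"expected one of {SIDES}"
            )
        if self.cell_class == "sensory" and not self.sensory_origin:
            raise ValidationError(f"missing sensory_origin for sensory neuron {self.id!r}")
        if self.cell_class != "sensory" and self.sensory_origin:
            raise ValidationError(
                f"sensory_origin {self.sensory_origin!r} set on non-sensory neuron {self.id!r}"
            )


class SynapseEdge(NamedTuple):
    """A directed pre -> post connection with its synaptic contact count."""

    pre: str
    post: str
    count: int


class Connectome:
    """Directed graph of neurons with aggregated synapse-count edges.

    Construct via :func:`aggregate`; direct construction assumes edges are
    already unique per ordered pair and endpoint-validated.
    """

    def __init__(self, neurons: Iterable[Neuron], edges: Iterable[SynapseEdge] = ()):
        self.neurons: dict[str, Neuron] = {}
        for n in neurons:
            if n.id in self.neurons:
                raise ValidationError(f"duplicate neuron id {n.id!r}")
            self.neurons[n.id] = n
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self.neurons)
        for e in edges:
            if e.pre not in self.neurons:
                raise ValidationError(f"edge references unknown neuron id {e.pre!r}")
            if e.post not in self.neurons:
                raise ValidationError(f"edge references unknown neuron id {e.post!r}")
            if e.count < 1:
                raise ValidationError(f"edge ({e.pre!r}, {e.post!r}) has count {e.count} < 1")
            if self.graph.has_edge(e.pre, e.post):
                raise ValidationError(
                    f"duplicate edge ({e.pre!r}, {e.post!r}); aggregate raw edges first"
                )
            self.graph.add_edge(e.pre, e.post, count=int(e.count))

    # -- accessors ---------------------------------------------------------

    def ids(self) -> list[str]:
        return sorted(self.neurons)

    def count(self, pre: str, post: str) -> int:
        """Synapse count of the pre -> post edge, 0 if absent."""
        data = self.graph.get_edge_data(pre, post)
        return int(data["count"]) if data else 0

    def edges(self) -> list[SynapseEdge]:
        """All edges, sorted lexicographically by (pre, post)."""
        return sorted(
            SynapseEdge(u, v, int(d["count"])) for u, v, d in self.graph.edges(data=True)
        )

    def ids_of_class(self, cell_class: str) -> set[str]:
        return {i for i, n in self.neurons.items() if n.cell_class == cell_class}

    def ids_of_cluster(self, cluster: str) -> set[str]:
        return {i for i, n in self.neurons.items() if n.cluster == cluster}

    def autapses(self) -> list[SynapseEdge]:
        """Self-edges (pre == post); permitted but worth reporting."""
        return [e for e in self.edges() if e.pre == e.post]

    def total_input(self, post: str) -> int:
        """Observed input synapse count of ``post`` within this connectome."""
        return sum(int(d["count"]) for _, _, d in self.graph.in_edges(post, data=True))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Connectome):
            return NotImplemented
        return self.neurons == other.neurons and self.edges() == other.edges()

    def __repr__(self) -> str:
        return f"Connectome({len(self.neurons)} neurons, {self.graph.number_of_edges()} edges)"

    # -- frames / files ----------------------------------------------------

    def neurons_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": n.id,
                "name": n.name,
                "cell_class": n.cell_class,
                "cluster": n.cluster or "",
                "sensory_origin": n.sensory_origin or "",
                "side": n.side or "",
            }
            for n in sorted(self.neurons.values(), key=lambda n: n.id)
        ]
        return pd.DataFrame(rows, columns=list(NEURON_COLUMNS))

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges(), columns=list(EDGE_COLUMNS))

    def write(self, neurons_path: str | Path, edges_path: str | Path) -> None:
        """Write neurons.csv / edges.csv in the dialect :func:`load_neurons` /
        :func:`load_edges` read (header required, comma-separated, UTF-8)."""
        self.neurons_frame().to_csv(neurons_path, index=False)
        self.edges_frame().to_csv(edges_path, index=False)


def _read_table(source, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s) {missing}; found {list(df.columns)}")
    return df


def load_neurons(source: str | Path | io.IOBase) -> list[Neuron]:
    """Read a neuron annotation table (columns id,name,cell_class,cluster,
    sensory_origin,side; the last three may be empty).

    Raises :class:`ValidationError` on duplicate ids, unknown cell classes,
    or sensory neurons lacking a sensory origin.
    """
    df = _read_table(source, NEURON_COLUMNS[:3])
    neurons: list[Neuron] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        nid = str(row.id)
        if nid in seen:
            raise ValidationError(f"duplicate neuron id {nid!r}")
        seen.add(nid)
        neurons.append(
            Neuron(
                id=nid,
                name=str(getattr(row, "name", "") or ""),
                cell_class=str(row.cell_class),
                cluster=str(getattr(row, "cluster", "") or "") or None,
                sensory_origin=str(getattr(row, "sensory_origin", "") or "") or None,
                side=str(getattr(row, "side", "") or "") or None,
            )
        )
    return neurons


def load_edges(source: str | Path | io.IOBase) -> list[SynapseEdge]:
    """Read a raw synapse edge list (columns pre,post,count).

    Duplicate (pre, post) rows are kept as-is; aggregation is a separate,
    explicit step. Counts must be positive integers; violations raise
    :class:`ValidationError` naming the offending row.
    """
    df = _read_table(source, EDGE_COLUMNS)
    edges: list[SynapseEdge] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = str(row.count)
        try:
            count = int(raw)
        except ValueError:
            raise ValidationError(f"row {i + 1}: count {raw!r} is not an integer") from None
        if count < 1:
            raise ValidationError(f"row {i + 1}: count {count} must be >= 1")
        edges.append(SynapseEdge(str(row.pre), str(row.post), count))
    return edges


def aggregate(neurons: Iterable[Neuron], raw_edges: Iterable[SynapseEdge]) -> Connectome:
    """Build a connectome, summing duplicate (pre, post) pairs.

    Every edge endpoint must name a neuron in ``neurons``; a dangling
    endpoint raises :class:`ValidationError` with the missing id.
    Idempotent: aggregating an already-aggregated edge list is a no-op.
    """
    neurons = list(neurons)
    known = {n.id for n in neurons}
    sums: dict[tuple[str, str], int] = {}
    for e in raw_edges:
        for endpoint in (e.pre, e.post):
            if endpoint not in known:
                raise ValidationError(f"edge references unknown neuron id {endpoint!r}")
        if e.count < 1:
            raise ValidationError(f"edge ({e.pre!r}, {e.post!r}) has count {e.count} < 1")
        sums[(e.pre, e.post)] = sums.get((e.pre, e.post), 0) + int(e.count)
    return Connectome(neurons, (SynapseEdge(p, q, c) for (p, q), c in sorted(sums.items())))


@dataclass
class WeightedAdjacency:
    """Input-fraction-normalized synaptic weights.

    ``matrix`` is dense, rows = presynaptic ids, columns = postsynaptic ids
    (both sorted), ``matrix.loc[pre, post] = count(pre, post) /
    total_input(post)``. ``totals`` holds the denominator used per
    postsynaptic neuron. ``zero_input`` flags neurons with no incoming
    synapses (their columns are all zero).
    """

    matrix: pd.DataFrame
    denominator_policy: str
    totals: pd.Series
    zero_input: tuple[str, ...] = ()
    declared_totals: Mapping[str, int] | None = None

    def weight(self, pre: str, post: str) -> float:
        return float(self.matrix.at[pre, post])

    def incoming(self, post: str) -> pd.Series:
        """Nonzero incoming weights of ``post``, indexed by presynaptic id."""
        col = self.matrix[post]
        return col[col > 0]

    def write(self, csv_path: str | Path, sidecar_path: str | Path) -> None:
        """Dense CSV matrix (ids as first row/column) plus JSON metadata."""
        self.matrix.to_csv(csv_path, index_label="pre\\post")
        meta = {
            "denominator_policy": self.denominator_policy,
            "totals": {k: float(v) for k, v in self.totals.items()},
            "zero_input": list(self.zero_input),
            "direction": "rows presynaptic, columns postsynaptic",
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def input_fractions(
    c: Connectome,
    denominator_policy: str = "dataset_total",
    declared_totals: Mapping[str, int] | None = None,
) -> WeightedAdjacency:
    """Normalize each neuron's incoming synapse counts to fractions of its
    total input.

    Under ``dataset_total`` the denominator is the input sum observed in
    ``c`` (each non-isolated column then sums to exactly 1). Under
    ``declared_total`` the caller supplies totals, which must cover every
    neuron with observed input and be >= the observed sum (columns then
    sum to <= 1).
    """
    if denominator_policy not in ("dataset_total", "declared_total"):
        raise ValidationError(f"unknown denominator_policy {denominator_policy!r}")
    ids = c.ids()
    observed = pd.Series({i: c.total_input(i) for i in ids}, dtype=float)
    if denominator_policy == "declared_total":
        if declared_totals is None:
            raise ValidationError("declared_total policy requires declared_totals")
        totals = observed.copy()
        for i in ids:
            if observed[i] > 0 and i not in declared_totals:
                raise ValidationError(f"declared_totals missing neuron {i!r} which has input")
            if i in declared_totals:
                declared = float(declared_totals[i])
                if declared < observed[i]:
                    raise ValidationError(
                        f"declared total {declared:g} for {i!r} is below the "
                        f"observed input sum {observed[i]:g}"
                    )
                totals[i] = declared
    else:
        totals = observed
    matrix = pd.DataFrame(0.0, index=ids, columns=ids)
    for pre, post, count in c.edges():
        matrix.at[pre, post] = count / totals[post]
    zero_input = tuple(i for i in ids if observed[i] == 0)
    return WeightedAdjacency(
        matrix=matrix,
        denominator_policy=denominator_policy,
        totals=totals,
        zero_input=zero_input,
        declared_totals=dict(declared_totals) if declared_totals else None,
    )


def subnetwork(
    c: Connectome,
    keep: Callable[[Neuron], bool] | Iterable[str] | None = None,
    min_count: int = 1,
) -> Connectome:
    """Restrict a connectome to neurons satisfying ``keep`` and edges with
    count >= ``min_count``.

    ``keep`` may be a predicate over :class:`Neuron` or a collection of ids;
    ``None`` keeps every neuron. With ``min_count=1`` and an all-pass
    predicate this is the identity.
    """
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    if keep is None:
        pred: Callable[[Neuron], bool] = lambda n: True
    elif callable(keep):
        pred = keep
    else:
        kept_ids = set(keep)
        pred = lambda n: n.id in kept_ids
    neurons = [n for n in c.neurons.values() if pred(n)]
    remaining = {n.id for n in neurons}
    edges = [
        e
        for e in c.edges()
        if e.pre in remaining and e.post in remaining and e.count >= min_count
    ]
    return Connectome(neurons, edges)
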