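"""Feed-forward network (FFN) diffusion model.

A single forward sweep propagates sensory activation through
input-fraction synaptic weights. Sensory neurons are sources: when their
peripheral origin is stimulated they emit a fixed activity (the
*activation factor*, default 2) and bypass the activation function, which
is only defined on input fractions. Every downstream unit computes

    x = sum over inputs of (incoming weight x source activity)

and responds through a rectified linear ramp

    f(x) = 0            for x <= a
           (x-a)/(b-a)  for a < x < b
           1            for x >= b

with onset ``a`` (default 0.05: the unit starts responding when 5% of its
input is active) and saturation ``b`` (default 0.5). There is no
recurrence, no back-propagation and no signed (inhibitory) connection;
the network is layered strictly feed-forward — sensory neurons, their
direct targets, and the ring-gland projection neurons (RPNs) reached in a
second hop. Edges that would violate the layering (intra-layer,
backward, or RPN-to-RPN) are dropped and reported, never silently used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .core import Connectome, ValidationError, WeightedAdjacency


@dataclass(frozen=True)
class FFNParams:
    """Model constants: ramp onset ``a`` and saturation ``b`` (fractions of
    active input), source ``activation_factor``, and maximum hop depth."""

    a: float = 0.05
    b: float = 0.5
    activation_factor: float = 2.0
    max_hops: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.a < self.b):
            raise ValidationError(f"require 0 <= a < b, got a={self.a}, b={self.b}")
        if self.activation_factor < 0:
            # zero is allowed as a degenerate silent-source control
            raise ValidationError("activation_factor must be nonnegative")
        if self.max_hops not in (1, 2):
            raise ValidationError("max_hops must be 1 or 2")


def activation(x: float, p: FFNParams = FFNParams()) -> float:
    """Rectified linear ramp f(x); continuous with f(a)=0 and f(b)=1.

    The boundary values follow from continuity of the piecewise form.
    Negative x is rejected: weights and activities are nonnegative.
    """
    if x < 0:
        raise ValidationError(f"negative weighted input sum x={x}")
    if x <= p.a:
        return 0.0
    if x >= p.b:
        return 1.0
    return (x - p.a) / (p.b - p.a)


@dataclass
class LayeredFFN:
    """Layered feed-forward view of a connectome.

    ``layers`` are disjoint: sensory sources, their direct targets (hop 1,
    including directly contacted RPNs), and RPNs first reached at hop 2.
    ``forward_edges`` maps (pre, post) to the input-fraction weight; only
    layer-k -> layer-k+1 edges are kept, plus relay->RPN edges into RPNs
    that already sit in layer 1 (a neuron reachable at both hop depths is
    assigned the earlier layer but keeps its hop-2 inputs, preserving both
    path lengths). ``dropped_edges`` records everything the layering
    discarded.
    """

    layers: tuple[frozenset[str], frozenset[str], frozenset[str]]
    forward_edges: dict[tuple[str, str], float]
    rpns: frozenset[str]
    origin_of: dict[str, str]
    dropped_edges: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def sensory(self) -> frozenset[str]:
        return self.layers[0]

    def origins(self) -> list[str]:
        return sorted(set(self.origin_of.values()))

    def nodes(self) -> list[str]:
        return sorted(self.layers[0] | self.layers[1] | self.layers[2])

    def layer_of(self, node: str) -> int:
        for k, layer in enumerate(self.layers):
            if node in layer:
                return k
        raise KeyError(node)


@dataclass
class ActivityState:
    """Per-neuron activity after one propagation sweep. Sensory activities
    are 0 or the activation factor; all others lie in [0, 1]. ``x`` holds
    each non-sensory unit's weighted input sum."""

    activities: dict[str, float]
    x: dict[str, float]
    active_origin: str
    params: FFNParams


def build_ffn(
    c: Connectome,
    wa: WeightedAdjacency,
    sensory: Iterable[str],
    rpns: Iterable[str],
    p: FFNParams = FFNParams(),
) -> LayeredFFN:
    """Extract the layered feed-forward network from a connectome.

    Layer 0 is the sensory set; layer 1 everything directly postsynaptic to
    it (relay interneurons and directly contacted RPNs); layer 2 the RPNs
    first reached through layer-1 relays. With ``max_hops=1`` only the
    monosynaptic step is kept.
    """
    sensory, rpns = frozenset(sensory), frozenset(rpns)
    if sensory & rpns:
        raise ValidationError("sensory and rpn sets must be disjoint")
    origin_of = {
        s: c.neurons[s].sensory_origin or "" for s in sensory if s in c.neurons
    }

    forward: dict[tuple[str, str], float] = {}
    dropped: list[tuple[str, str, str]] = []

    layer1: set[str] = set()
    for s in sensory:
        for _, post in c.graph.out_edges(s):
            if post in sensory:
                dropped.append((s, post, "target is a sensory source"))
            else:
                layer1.add(post)
                forward[(s, post)] = wa.weight(s, post)
    if not layer1:
        raise ValidationError("empty network: no edges out of the sensory set")

    layer2: set[str] = set()
    if p.max_hops == 2:
        relays = layer1 - rpns
        for u in sorted(relays):
            for _, r in c.graph.out_edges(u):
                if r in rpns:
                    forward[(u, r)] = wa.weight(u, r)
                    if r not in layer1:
                        layer2.add(r)
                elif r in relays:
                    dropped.append((u, r, "intra-layer relay edge"))
        for u in sorted(layer1 & rpns):
            for _, r in c.graph.out_edges(u):
                if r in rpns or r in relays:
                    dropped.append((u, r, "edge out of an RPN"))
    return LayeredFFN(
        layers=(sensory, frozenset(layer1), frozenset(layer2)),
        forward_edges=forward,
        rpns=rpns,
        origin_of=origin_of,
        dropped_edges=dropped,
    )


def propagate(
    ffn: LayeredFFN, origin: str | Iterable[str], p: FFNParams = FFNParams()
) -> ActivityState:
    """One forward sweep with the sensory neurons of ``origin`` active.

    ``origin`` may also be a collection of origin labels to stimulate
    jointly. Active sources emit ``p.activation_factor``; all other
    sensory neurons are silent. Relay units respond to their sensory
    input; RPNs respond to their combined sensory (monosynaptic) and
    relay (disynaptic) forward inputs. No iteration, no back-propagation.
    """
    origins = {origin} if isinstance(origin, str) else set(origin)
    known = ffn.origins()
    unknown = origins - set(known)
    if unknown:
        raise ValidationError(
            f"unknown sensory origin(s) {sorted(unknown)}; known origins: {known}"
        )
    act: dict[str, float] = {}
    xs: dict[str, float] = {}
    for s in ffn.sensory:
        act[s] = p.activation_factor if ffn.origin_of.get(s) in origins else 0.0

    relays = ffn.layers[1] - ffn.rpns
    # in-edges per target, restricted to the feed-forward edge set
    incoming: dict[str, list[tuple[str, float]]] = {}
    for (u, v), w in ffn.forward_edges.items():
        incoming.setdefault(v, []).append((u, w))

    for u in sorted(relays):
        x = sum(w * act[pre] for pre, w in incoming.get(u, ()) if pre in ffn.sensory)
        xs[u] = x
        act[u] = activation(x, p)
    for r in sorted((ffn.layers[1] & ffn.rpns) | ffn.layers[2]):
        x = sum(w * act[pre] for pre, w in incoming.get(r, ()))
        xs[r] = x
        act[r] = activation(x, p)
    label = origin if isinstance(origin, str) else "+".join(sorted(origins))
    return ActivityState(activities=act, x=xs, active_origin=label, params=p)


def mean_group_activity(
    state: ActivityState, groups: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Unweighted mean activity per neuron group (e.g. RPN peptide cluster).

    Group members absent from the propagated network were never reached
    and count as activity 0, which keeps means comparable across groups.
    """
    rows = []
    for label in sorted(groups):
        members = sorted(set(groups[label]))
        if not members:
            raise ValidationError(f"empty group {label!r}")
        mean = sum(state.activities.get(m, 0.0) for m in members) / len(members)
        rows.append({"group": label, "origin": state.active_origin, "mean_activity": mean})
    return pd.DataFrame(rows, columns=["group", "origin", "mean_activity"])


def sweep(
    ffn: LayeredFFN,
    origins: Iterable[str],
    factors: Iterable[float],
    groups: Mapping[str, Iterable[str]],
    p: FFNParams = FFNParams(),
) -> pd.DataFrame:
    """Propagate once per (origin, activation factor) pair and tabulate the
    group means; rows sorted by (origin, factor, group)."""
    rows = []
    for origin in sorted(set(origins)):
        for factor in sorted(set(factors)):
            if factor < 0:
                raise ValidationError("activation factors must be nonnegative")
            state = propagate(ffn, origin, replace(p, activation_factor=factor))
            gm = mean_group_activity(state, groups)
            for rec in gm.itertuples(index=False):
                rows.append(
                    {
                        "origin": origin,
                        "factor": factor,
                        "group": rec.group,
                        "mean_activity": rec.mean_activity,
                    }
                )
    return pd.DataFrame(rows, columns=["origin", "factor", "group", "mean_activity"])


def activity_frame(ffn: LayeredFFN, state: ActivityState) -> pd.DataFrame:
    """Per-neuron activity table (ffn_activity.tsv layout)."""
    rows = [
        {
            "origin": state.active_origin,
            "neuron_id": n,
            "layer": ffn.layer_of(n),
            "x": state.x.get(n, math.nan),
            "activity": state.activities[n],
        }
        for n in ffn.nodes()
    ]
    return pd.DataFrame(rows, columns=["origin", "neuron_id", "layer", "x", "activity"])
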