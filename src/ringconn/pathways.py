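"""Thresholded connectivity analysis: upstream partners, sensory profiles,
1-/2-hop path enumeration, and hive-plot edge tables.

All synaptic thresholds are inclusive (a threshold of 3 keeps counts >= 3)
and apply per ordered neuron pair — never pooled over a target group, so a
neuron contacting two targets with 2 synapses each does not pass a
threshold of 3. Output tables are sorted lexicographically by id for
reproducible diffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import Connectome, Neuron, ValidationError, WeightedAdjacency, subnetwork


@dataclass(frozen=True)
class SensoryProfile:
    """Distribution of a neuron's (or pooled group's) input over sensory origins.

    ``basis="of_total_input"`` expresses each origin's synapses as a fraction
    of the subject's total input (fractions sum to <= 1, the remainder being
    non-sensory input). ``basis="of_sensory_input"`` renormalizes over
    sensory input only, ignoring other inputs, so nonempty fractions sum
    to 1 — the convention behind per-group sensory pie charts.
    """

    subject: str
    basis: str
    fractions: dict[str, float]
    zero_input: bool = False


@dataclass(frozen=True)
class Path:
    """A monosynaptic (2 nodes) or disynaptic (3 nodes) sensory -> RPN route,
    carrying the synapse count of each hop. No combined path strength is
    computed; scalarization is left to the caller."""

    nodes: tuple[str, ...]
    hop_counts: tuple[int, ...]
    origin: str

    def __post_init__(self) -> None:
        if len(self.nodes) not in (2, 3) or len(self.hop_counts) != len(self.nodes) - 1:
            raise ValidationError("a path has 2 or 3 nodes and one count per hop")

    @property
    def monosynaptic(self) -> bool:
        return len(self.nodes) == 2


def upstream_partners(
    c: Connectome, targets: Iterable[str], threshold: int = 3
) -> set[str]:
    """Neurons presynaptic to at least one target with count >= ``threshold``.

    Thresholding is per (partner, target) pair; counts are not summed over
    the target group. Target neurons themselves are excluded from the
    result.
    """
    targets = set(targets)
    if not targets:
        raise ValidationError("empty target set")
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    partners: set[str] = set()
    for t in targets:
        for pre, _, data in c.graph.in_edges(t, data=True):
            if pre not in targets and data["count"] >= threshold:
                partners.add(pre)
    return partners


def classify_interneurons(
    c: Connectome,
    interneurons: Iterable[str],
    sensory: Iterable[str],
    threshold: int = 2,
) -> dict[str, set[str]]:
    """Partition interneurons into those with and without direct sensory
    input at the given per-pair synaptic threshold (default 2)."""
    interneurons, sensory = set(interneurons), set(sensory)
    if interneurons & sensory:
        raise ValidationError("interneuron and sensory sets must be disjoint")
    with_sensory = {
        i
        for i in interneurons
        if any(
            pre in sensory and data["count"] >= threshold
            for pre, _, data in c.graph.in_edges(i, data=True)
        )
    }
    return {"with_sensory": with_sensory, "without_sensory": interneurons - with_sensory}


def sensory_profile(
    wa: WeightedAdjacency,
    neurons: Mapping[str, Neuron] | Iterable[Neuron],
    subject: str | Iterable[str],
    basis: str = "of_total_input",
) -> SensoryProfile:
    """Sensory-origin composition of a neuron's or group's synaptic input.

    Group profiles pool the members' input synapses (counts, reconstructed
    as weight x denominator) before normalizing, which is not the same as
    averaging per-member fractions. A subject with zero input yields an
    empty profile flagged ``zero_input``.
    """
    if basis not in ("of_total_input", "of_sensory_input"):
        raise ValidationError(f"unknown basis {basis!r}")
    if not isinstance(neurons, Mapping):
        neurons = {n.id: n for n in neurons}
    members = [subject] if isinstance(subject, str) else sorted(set(subject))
    label = members[0] if len(members) == 1 else "+".join(members)
    for m in members:
        if m not in wa.matrix.columns:
            raise ValidationError(f"unknown subject neuron {m!r}")

    # pooled input counts per presynaptic neuron
    counts = (wa.matrix[members] * wa.totals[members]).sum(axis=1)
    total = float(wa.totals[members].sum())
    if total == 0 or counts.sum() == 0:
        return SensoryProfile(subject=label, basis=basis, fractions={}, zero_input=True)

    by_origin: dict[str, float] = {}
    for pre, cnt in counts[counts > 0].items():
        n = neurons.get(pre)
        if n is not None and n.cell_class == "sensory":
            by_origin[n.sensory_origin] = by_origin.get(n.sensory_origin, 0.0) + float(cnt)
    if basis == "of_total_input":
        denom = total
    else:
        denom = sum(by_origin.values())
        if denom == 0:
            return SensoryProfile(subject=label, basis=basis, fractions={}, zero_input=False)
    fractions = {origin: by_origin[origin] / denom for origin in sorted(by_origin)}
    return SensoryProfile(subject=label, basis=basis, fractions=fractions)


def enumerate_paths(
    c: Connectome,
    sensory: Iterable[str],
    interneurons: Iterable[str],
    rpns: Iterable[str],
    mono_threshold: int = 3,
    sens_to_inter_threshold: int = 2,
    inter_to_rpn_threshold: int = 3,
) -> list[Path]:
    """All 1- and 2-hop sensory -> RPN routes meeting per-hop thresholds.

    Monosynaptic sensory->RPN edges (count >= ``mono_threshold``) and
    disynaptic sensory->interneuron->RPN routes (hops meeting
    ``sens_to_inter_threshold`` and ``inter_to_rpn_threshold`` respectively)
    are both returned; monosynaptic routes stay distinct records, never
    merged into 2-hop ones. Sorted by node ids.
    """
    for thr in (mono_threshold, sens_to_inter_threshold, inter_to_rpn_threshold):
        if thr < 1:
            raise ValidationError("thresholds must be >= 1")
    sensory, interneurons, rpns = set(sensory), set(interneurons), set(rpns)
    paths: list[Path] = []

    def origin_of(s: str) -> str:
        n = c.neurons[s]
        return n.sensory_origin or ""

    for s in sensory:
        strong_inters: list[tuple[str, int]] = []
        for _, post, data in c.graph.out_edges(s, data=True):
            cnt = int(data["count"])
            if post in rpns and cnt >= mono_threshold:
                paths.append(Path((s, post), (cnt,), origin_of(s)))
            if post in interneurons and cnt >= sens_to_inter_threshold:
                strong_inters.append((post, cnt))
        for i, c1 in strong_inters:
            for _, r, data in c.graph.out_edges(i, data=True):
                c2 = int(data["count"])
                if r in rpns and c2 >= inter_to_rpn_threshold:
                    paths.append(Path((s, i, r), (c1, c2), origin_of(s)))
    return sorted(paths, key=lambda p: (len(p.nodes), p.nodes))


def paths_frame(paths: Sequence[Path]) -> pd.DataFrame:
    """Flatten paths into the paths.tsv layout (interneuron empty for
    monosynaptic routes)."""
    rows = [
        {
            "origin": p.origin,
            "sensory_id": p.nodes[0],
            "interneuron_id": "" if p.monosynaptic else p.nodes[1],
            "rpn_id": p.nodes[-1],
            "hop1_count": p.hop_counts[0],
            "hop2_count": "" if p.monosynaptic else p.hop_counts[1],
        }
        for p in paths
    ]
    return pd.DataFrame(
        rows,
        columns=["origin", "sensory_id", "interneuron_id", "rpn_id", "hop1_count", "hop2_count"],
    )


def hive_edge_table(c: Connectome, threshold: int = 5) -> pd.DataFrame:
    """Edge table for hive-plot style summaries: edges below ``threshold``
    synapses dropped (default 5), sorted by (pre, post). Equivalent to the
    edge list of ``subnetwork(c, min_count=threshold)``."""
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    return subnetwork(c, min_count=threshold).edges_frame()
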