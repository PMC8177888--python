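"""Seeded synthetic-connectome generator.

Emulates the statistical structure of the larval sensory-to-neuroendocrine
network that the analysis modules assume: 56 ring-gland projection neurons
(RPNs) in 10 peptide clusters, ~200 upstream interneurons, sensory neurons
grouped by peripheral origin (with 26 CO2-responsive tracheal dendritic
neurons), right-skewed synapse counts per connection (minimum 1, capped
around 150), and optional planted pathways such as a strong
CO2 -> thoracic-interneuron -> {DH44, CRZ} motif over the diffuse
background.

Randomness is a single seeded stream per generation; per-stage sub-streams
are derived deterministically from it, so adding a planted motif never
perturbs the background edges drawn for the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import Connectome, Neuron, SynapseEdge, ValidationError, aggregate

#: RPN cluster census of the larval ring gland (10 clusters, 56 neurons).
DEFAULT_RPN_CENSUS: dict[str, int] = {
    "DMS": 4,
    "IPCs": 14,
    "DH44": 6,
    "CRZ": 6,
    "ITP": 8,
    "CA-LP": 6,
    "PTTH": 4,
    "HugRG": 4,
    "CAPA": 2,
    "EH": 2,
}

#: Sensory census by peripheral origin. Only the CO2 (tracheal dendritic)
#: count of 26 is anchored to the reconstruction; the remaining origins are
#: plausibility-level defaults summing to 160 sensory neurons.
DEFAULT_SENSORY_CENSUS: dict[str, int] = {
    "enteric": 40,
    "pharyngeal": 30,
    "olfactory": 21,
    "somatosensory": 30,
    "CO2": 26,
    "TO_VO": 13,
}


@dataclass(frozen=True)
class CountLaw:
    """Right-skewed positive-integer synapse-count law: a geometric
    distribution on {1, 2, ...} with the given mean, truncated at ``max``
    (the strongest observed connection is on the order of 150 synapses)."""

    mean: float = 6.0
    max: int = 150

    def __post_init__(self) -> None:
        if self.mean < 1 or self.max < 1:
            raise ValidationError("count law needs mean >= 1 and max >= 1")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        draws = rng.geometric(1.0 / self.mean, size=size)
        return np.minimum(draws, self.max)


@dataclass(frozen=True)
class PlantedMotif:
    """A strong 2-hop pathway to plant: all sensory neurons of ``origin``
    converge (sparsely) onto ``n_interneurons`` dedicated relay
    interneurons, which each strongly contact every RPN of the target
    clusters, with synapse counts drawn uniformly from ``count_range``."""

    origin: str = "CO2"
    n_interneurons: int = 4
    target_clusters: tuple[str, ...] = ("DH44", "CRZ")
    count_range: tuple[int, int] = (80, 150)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale defaults: 56 RPNs in 10 clusters, 209 interneurons,
    160 sensory neurons across six origins. ``edge_density`` is the
    probability per eligible sensory->interneuron or interneuron->RPN
    pair; direct sensory->RPN and interneuron->interneuron edges are drawn
    sparser (x0.1 and x0.25 respectively)."""

    rpn_census: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RPN_CENSUS)
    )
    n_interneurons: int = 209
    sensory_census: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SENSORY_CENSUS)
    )
    edge_density: float = 0.05
    count_law: CountLaw = CountLaw()
    planted_motifs: tuple[PlantedMotif, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.rpn_census.values()):
            raise ValidationError("rpn_census counts must be positive")
        if any(v < 1 for v in self.sensory_census.values()):
            raise ValidationError("sensory_census counts must be positive")
        if self.n_interneurons < 1:
            raise ValidationError("n_interneurons must be positive")
        if not (0.0 <= self.edge_density <= 1.0):
            raise ValidationError("edge_density must be in [0, 1]")


def _sides(n: int) -> list[str]:
    return ["left" if k % 2 == 0 else "right" for k in range(n)]


def _make_neurons(config: GeneratorConfig) -> list[Neuron]:
    neurons: list[Neuron] = []
    for cluster in config.rpn_census:
        n = config.rpn_census[cluster]
        for k, side in enumerate(_sides(n), start=1):
            nid = f"rpn_{cluster}_{k:02d}"
            neurons.append(
                Neuron(nid, name=f"{cluster}-{k}", cell_class="rpn", cluster=cluster, side=side)
            )
    for k, side in enumerate(_sides(config.n_interneurons), start=1):
        neurons.append(
            Neuron(f"int_{k:03d}", name=f"interneuron {k}", cell_class="interneuron", side=side)
        )
    for origin in config.sensory_census:
        n = config.sensory_census[origin]
        for k, side in enumerate(_sides(n), start=1):
            neurons.append(
                Neuron(
                    f"sens_{origin}_{k:02d}",
                    name=f"{origin} sensory {k}",
                    cell_class="sensory",
                    sensory_origin=origin,
                    side=side,
                )
            )
    return neurons


def _draw_edges(
    rng: np.random.Generator,
    pres: Sequence[str],
    posts: Sequence[str],
    p: float,
    law: CountLaw,
) -> list[SynapseEdge]:
    """Bernoulli(p) per ordered (pre, post) pair, synapse counts from the
    count law; self-pairs are never drawn."""
    if p <= 0 or not pres or not posts:
        return []
    mask = rng.random((len(pres), len(posts))) < p
    counts = law.sample(rng, int(mask.sum()))
    edges = []
    for (i, j), cnt in zip(np.argwhere(mask), counts):
        if pres[i] != posts[j]:
            edges.append(SynapseEdge(pres[i], posts[j], int(cnt)))
    return edges


def generate(config: GeneratorConfig = GeneratorConfig()) -> Connectome:
    """Generate a synthetic connectome; identical for identical seeds.

    Edge classes and their pair densities: sensory->interneuron and
    interneuron->RPN at ``edge_density``; sensory->RPN (monosynaptic
    shortcuts) at 0.1x; interneuron->interneuron at 0.25x. Planted motifs
    are applied last from their own random sub-stream.
    """
    neurons = _make_neurons(config)
    sens = sorted(n.id for n in neurons if n.cell_class == "sensory")
    inter = sorted(n.id for n in neurons if n.cell_class == "interneuron")
    rpns = sorted(n.id for n in neurons if n.cell_class == "rpn")

    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(child) for child in ss.spawn(5)]
    law, d = config.count_law, config.edge_density
    raw: list[SynapseEdge] = []
    raw += _draw_edges(streams[0], sens, inter, d, law)
    raw += _draw_edges(streams[1], inter, rpns, d, law)
    raw += _draw_edges(streams[2], sens, rpns, 0.1 * d, law)
    raw += _draw_edges(streams[3], inter, inter, 0.25 * d, law)
    c = aggregate(neurons, raw)
    for motif in config.planted_motifs:
        c = plant_pathway(c, motif, streams[4])
    return c


def plant_pathway(
    c: Connectome, motif: PlantedMotif, rng: np.random.Generator
) -> Connectome:
    """Return a new connectome with the motif's strong 2-hop pathway added.

    ``motif.n_interneurons`` relay interneurons are picked at random; each
    receives at least one strong edge from the origin's sensory neurons
    (each sensory neuron connects with probability 1/2) and one strong
    edge onto every RPN of each target cluster. Existing edges on those
    pairs are boosted (counts added); neurons are left unchanged.
    """
    origin_sens = sorted(
        n.id for n in c.neurons.values() if n.sensory_origin == motif.origin
    )
    if not origin_sens:
        raise ValidationError(f"no sensory neurons of origin {motif.origin!r}")
    targets: list[str] = []
    for cluster in motif.target_clusters:
        members = sorted(c.ids_of_cluster(cluster))
        if not members:
            raise ValidationError(f"unknown or empty target cluster {cluster!r}")
        targets.extend(members)
    inter = sorted(c.ids_of_class("interneuron"))
    if motif.n_interneurons > len(inter):
        raise ValidationError(
            f"motif needs {motif.n_interneurons} interneurons, only {len(inter)} exist"
        )
    relays = sorted(rng.choice(inter, size=motif.n_interneurons, replace=False))

    lo, hi = motif.count_range
    boosts: list[SynapseEdge] = []
    for relay in relays:
        chosen = [s for s in origin_sens if rng.random() < 0.5]
        if not chosen:
            chosen = [origin_sens[int(rng.integers(len(origin_sens)))]]
        for s in chosen:
            boosts.append(SynapseEdge(s, relay, int(rng.integers(lo, hi + 1))))
        for t in targets:
            boosts.append(SynapseEdge(relay, t, int(rng.integers(lo, hi + 1))))
    return aggregate(list(c.neurons.values()), c.edges() + boosts)


# -- packaged worked-example and census fixtures ---------------------------


def worked_example_fixture() -> tuple[Connectome, dict[str, int]]:
    """Minimal connectome encoding the printed hub-score worked example.

    The Munin-2-analog interneuron receives 3233 of its declared 10000
    input synapses from (pharyngeal) sensory neurons — sensory-input
    fraction exactly 0.3233 — and contributes 5652 of the CRZ-analog
    group's declared 10000 input synapses — output fraction exactly
    0.5652. Use with ``input_fractions(c, "declared_total", totals)``.
    """
    neurons = [
        Neuron("sens_ph_01", name="pharyngeal sensory 1", cell_class="sensory",
               sensory_origin="pharyngeal", side="left"),
        Neuron("sens_ph_02", name="pharyngeal sensory 2", cell_class="sensory",
               sensory_origin="pharyngeal", side="right"),
        Neuron("int_munin2", name="Munin 2", cell_class="interneuron", side="left"),
        Neuron("rpn_CRZ_01", name="CRZ-1", cell_class="rpn", cluster="CRZ", side="left"),
    ]
    edges = [
        SynapseEdge("sens_ph_01", "int_munin2", 2000),
        SynapseEdge("sens_ph_02", "int_munin2", 1233),
        SynapseEdge("int_munin2", "rpn_CRZ_01", 5652),
    ]
    declared_totals = {"int_munin2": 10000, "rpn_CRZ_01": 10000}
    return aggregate(neurons, edges), declared_totals


def load_rpn_census_fixture() -> dict[str, int]:
    """Packaged RPN cluster census table (data/rpn_census.csv)."""
    text = resources.files("ringconn.data").joinpath("rpn_census.csv").read_text()
    census: dict[str, int] = {}
    for line in text.strip().splitlines()[1:]:
        cluster, count = line.split(",")
        census[cluster] = int(count)
    return census


def load_worked_example() -> tuple[Connectome, dict[str, int]]:
    """Worked-example fixture read back from the packaged CSV/JSON files
    (same content as :func:`worked_example_fixture`)."""
    from .core import load_edges, load_neurons  # avoid cycle at import time

    data = resources.files("ringconn.data")
    with resources.as_file(data.joinpath("worked_example_neurons.csv")) as p:
        neurons = load_neurons(p)
    with resources.as_file(data.joinpath("worked_example_edges.csv")) as p:
        edges = load_edges(p)
    totals = json.loads(data.joinpath("worked_example_totals.json").read_text())
    return aggregate(neurons, edges), {k: int(v) for k, v in totals.items()}
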