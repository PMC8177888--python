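import numpy as np
import pytest
from hypothesis import settings

from ringconn import (
    Connectome,
    GeneratorConfig,
    Neuron,
    PlantedMotif,
    SynapseEdge,
    aggregate,
    input_fractions,
    worked_example_fixture,
)

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

RPN_CLUSTERS = ("DMS", "IPCs", "DH44", "CRZ", "ITP", "CA-LP", "PTTH", "HugRG", "CAPA", "EH")


def random_connectome(seed: int, n_sensory=10, n_inter=12, n_rpn=8, density=0.15, max_count=8):
    """Small random connectome for oracle-equivalence tests: edges drawn in
    every direction-eligible class (including sensory->RPN shortcuts and
    interneuron->interneuron noise)."""
    rng = np.random.default_rng(seed)
    origins = ("CO2", "enteric", "pharyngeal")
    neurons = (
        [Neuron(f"s{k}", cell_class="sensory", sensory_origin=origins[k % 3])
         for k in range(n_sensory)]
        + [Neuron(f"i{k}", cell_class="interneuron") for k in range(n_inter)]
        + [Neuron(f"r{k}", cell_class="rpn", cluster=RPN_CLUSTERS[k % len(RPN_CLUSTERS)])
           for k in range(n_rpn)]
    )
    ids = [n.id for n in neurons]
    edges = []
    for pre in ids:
        for post in ids:
            if pre == post or post.startswith("s"):
                continue
            if rng.random() < density:
                edges.append(SynapseEdge(pre, post, int(rng.integers(1, max_count + 1))))
    return aggregate(neurons, edges)


@pytest.fixture
def tiny():
    """Two sensory inputs onto one interneuron feeding one RPN, plus a
    direct sensory->RPN shortcut."""
    neurons = [
        Neuron("s1", cell_class="sensory", sensory_origin="CO2"),
        Neuron("s2", cell_class="sensory", sensory_origin="enteric"),
        Neuron("i1", cell_class="interneuron"),
        Neuron("r1", cell_class="rpn", cluster="CRZ"),
    ]
    edges = [
        SynapseEdge("s1", "i1", 10),
        SynapseEdge("s2", "i1", 30),
        SynapseEdge("i1", "r1", 5),
        SynapseEdge("s1", "r1", 4),
    ]
    return aggregate(neurons, edges)


@pytest.fixture
def worked_example():
    c, totals = worked_example_fixture()
    wa = input_fractions(c, "declared_total", totals)
    return c, totals, wa


@pytest.fixture
def planted_config():
    return GeneratorConfig(seed=7, planted_motifs=(PlantedMotif(),))


def cluster_groups(c: Connectome) -> dict[str, set[str]]:
    clusters = {n.cluster for n in c.neurons.values() if n.cell_class == "rpn" and n.cluster}
    return {cl: c.ids_of_cluster(cl) for cl in sorted(clusters)}
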