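# Methods

## Connectome model and normalization

A connectome is a directed graph of annotated neurons with at most one
edge per ordered (pre, post) pair, carrying the aggregated synaptic
contact count. Edge direction is presynaptic → postsynaptic everywhere.
Autapses are retained and reported rather than dropped; left/right side
labels are annotation only (no automatic mirroring); ids are opaque
strings.

Input-fraction normalization divides each incoming count by the
receiving neuron's total input, so incoming weights are fractions of a
neuron's synaptic load. Two denominator policies exist because a network
exported for analysis may be a subnetwork of a larger reconstruction:

- `dataset_total` (default): the denominator is the input sum observed in
  the loaded connectome. Every non-isolated column of the weight matrix
  then sums to 1 (enforced to 1e-12 in tests).
- `declared_total`: the caller supplies per-neuron totals (validated to
  cover every neuron with observed input and to be at least the observed
  sum); columns then sum to ≤ 1. This is how the worked-example fixture
  encodes printed fractions exactly: integer counts of 3233 and 5652
  against declared totals of 10000.

Fractions that combine several counts (sensory-input fraction of an
interneuron, an interneuron's contribution to a group's pooled input)
are computed as summed integer counts over the denominator — one
division — rather than as sums of per-edge floating weights, so
printed-precision decimal fractions reproduce bit-exactly.

## Thresholded connectivity analysis

All synaptic thresholds are inclusive (threshold 3 keeps counts ≥ 3) and
apply per ordered neuron pair, never pooled over a target group: a
neuron contacting two targets with 2 synapses each does not pass a
threshold of 3. Defaults: 3 synapses for upstream partners of RPNs and
for interneuron→RPN hops, 2 for sensory→interneuron hops, 5 for
hive-plot edge tables.

Path enumeration returns monosynaptic sensory→RPN edges and disynaptic
sensory→interneuron→RPN routes as separate records carrying per-hop
counts. No combined path strength is defined; any scalarization is left
to the caller. Output tables sort lexicographically by id so reruns
diff cleanly.

Sensory profiles express a subject's input composition over peripheral
origins on one of two bases: `of_total_input` (fractions of all input;
they sum to ≤ 1, the remainder being non-sensory) or `of_sensory_input`
(renormalized over sensory input only; nonempty fractions sum to 1).
Group profiles pool member input counts before normalizing, which is
deliberately not the mean of per-member fractions.

## FFN diffusion model

The model is a single-sweep feed-forward network without recurrence,
iteration, or back-propagation, and it ignores transmitter sign — all
connections act excitatory. Units are rectified linear ramps on their
weighted input sum x:

    f(x) = 0            x ≤ a
           (x−a)/(b−a)  a < x < b
           1            x ≥ b

Defaults a = 0.05 and b = 0.5: a unit starts responding when 5% of its
input is active and saturates at 50%, maximizing the usable response
range. The knot values f(a) = 0 and f(b) = 1 are forced by continuity.
Sensory neurons are sources, not units: when their origin is stimulated
they emit the activation factor (default 2) directly, because f is
defined on input fractions and sources have no modelled inputs. A zero
activation factor is accepted as a degenerate silent-source control.

Layering: layer 0 is the sensory set, layer 1 everything directly
postsynaptic to it (relay interneurons and directly contacted RPNs),
layer 2 the RPNs first reached through layer-1 relays. A neuron
reachable at both depths is assigned the earlier layer but keeps its
hop-2 inputs, so monosynaptic and disynaptic routes both contribute to
its single evaluation. Edges that violate the layering — intra-layer
relay→relay edges, edges out of RPNs (including RPN→RPN), edges into
sensory neurons — are dropped and logged. Keeping RPN→RPN edges would
make RPN activities depend on evaluation order within the sweep, which
is why they are excluded rather than ordered arbitrarily.

Propagation is deterministic; seeds only affect the synthetic generator.
Reported outputs are per-neuron activities and unweighted mean activity
per RPN cluster (members never reached count as 0). Properties held by
construction and verified in tests: non-sensory activities lie in
[0, 1]; activity is monotone in any weight and in the activation factor;
joint stimulation of two origins never yields less activity than either
alone; on a chain s→i→r with weights w₁, w₂ the output is
f(w₂ · f(2·w₁)).

## Hub score

For interneuron i and RPN group G:

    hub(i, G) = frac_sensory_in(i) × frac_to_rpn(i, G)

where `frac_sensory_in` is the fraction of i's total input contributed
by sensory neurons and `frac_to_rpn` is i's synapses onto members of G
divided by G's pooled total input. Pooling over the group is the
default; a `per_cell` variant scores single output neurons for
single-cell views. Scores are invariant under rescaling all counts by a
common positive factor (the fractions cancel), kept at full float
precision, and tabulated in descending order with ties broken by id.

## DCV fractions

Dense-core-vesicle fusion sites are typed by ring-gland tissue (CC+AO,
CA, PG; CNS fusion sites are out of model). Each group's counts are
normalized by its total across tissues, so per-group fractions sum to 1;
groups with zero total are omitted. Output is order-invariant in the
input records.

## Synthetic generator

The generator emulates the study-scale network the analysis assumes,
not any particular reconstructed adjacency:

- Census: 56 RPNs in 10 clusters (DMS 4, IPCs 14, DH44 6, CRZ 6, ITP 8,
  CA-LP 6, PTTH 4, HugRG 4, CAPA 2, EH 2), 209 interneurons, and 160
  sensory neurons over six origins. Only the 26 CO₂-responsive tracheal
  dendritic neurons are an anchored count; the other origin sizes
  (enteric 40, pharyngeal 30, olfactory 21, somatosensory 30, TO/VO 13)
  are plausibility-level defaults chosen once.
- Edges: independent Bernoulli draws per eligible ordered pair —
  sensory→interneuron and interneuron→RPN at `edge_density` (default
  0.05), sensory→RPN shortcuts at 0.1×, interneuron→interneuron noise at
  0.25× — with synapse counts from a geometric law on {1, 2, …} (mean 6,
  right-skewed) truncated at 150, matching the heavy skew and ~150-synapse
  maximum of real connection strengths. The law is configurable; real
  in/out-degree distributions at this granularity are not published, so
  these defaults are sanity-level, and passing tests on synthetic data
  show algorithmic correctness, not biological fidelity.
- Planted motifs: a configurable origin → n relay interneurons → target
  clusters pathway with counts drawn uniformly from a high range
  (default 80–150). Each relay receives strong edges from a random half
  of the origin's sensory neurons (at least one) and contacts every
  member of each target cluster, so path enumeration finds the motif by
  construction.
- Randomness: one seed per generation; per-stage sub-streams are spawned
  deterministically from it, so adding a motif leaves the background
  edges of the same seed untouched.

With the default planted CO₂ motif the FFN ranks DH44 and CRZ top-2 by
mean activity under CO₂ stimulation in 100 of 100 seeds (ties at
saturation counted in favour of neither side: both planted groups must
be ≥ every other group).

## Numerical and interface choices

- Validation failures raise a single `ValidationError` type naming the
  offending id/row; the CLI maps it to exit code 2 (unexpected errors
  exit 1).
- CLI tables carry a `#` header comment with the parameter values and
  package version and format floats with 9 significant digits, so reruns
  on identical inputs are byte-identical.
- Test problem sizes: oracle-equivalence suites use 30-node random
  connectomes against exhaustive brute-force scans (100 graphs);
  generator checks run at the full default census, which builds in
  tens of milliseconds.

## Known limitations

- No inhibitory or signed synapses, no recurrent dynamics, no learning;
  the FFN is a static one-pass prediction of relative modulation, not a
  simulation of firing.
- Whether input-fraction denominators should count all postsynapses of a
  neuron in a full volume or only those inside the analysed subnetwork
  is data-dependent; both policies are supported and the default
  (`dataset_total`) is stated everywhere it matters.
- The generator does not attempt to reproduce any real adjacency matrix,
  hemilateral pairing symmetry, or spatial structure; side labels are
  cosmetic.
- Empirical summary numbers that depend on a specific full
  reconstruction (e.g. counts of upstream partners or per-group synaptic
  loads) are functions of the input data, not constants of this package;
  only the packaged worked-example fixture pins exact values.
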