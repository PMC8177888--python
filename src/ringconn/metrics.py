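"""Sensory-to-endocrine hub scoring and dense-core-vesicle (DCV) fusion-site
target-tissue fractions.

The hub score ranks how strongly an interneuron relays sensory information
to a neuroendocrine output group: it is the product of (i) the fraction of
the interneuron's total synaptic input that comes from sensory neurons and
(ii) the fraction of the RPN group's pooled total input contributed by
that interneuron. Both factors are input fractions in [0, 1], so the score
is too, and it is invariant to rescaling all synapse counts by a common
factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import Connectome, ValidationError, WeightedAdjacency

RING_GLAND_TISSUES = ("CC_AO", "CA", "PG")


@dataclass(frozen=True)
class HubScore:
    """One (interneuron, RPN group) relay record; ``score`` is the exact
    product of the two input fractions."""

    interneuron: str
    rpn_group: str
    frac_sensory_in: float
    frac_to_rpn: float
    score: float


@dataclass(frozen=True)
class DCVRecord:
    """Count of membrane-fused DCVs of one RPN group in one ring-gland
    tissue (corpora cardiaca + aorta, corpus allatum, or prothoracic
    gland). Fusion sites within the CNS are out of model."""

    rpn_group: str
    tissue: str
    fused_count: int

    def __post_init__(self) -> None:
        if self.tissue not in RING_GLAND_TISSUES:
            raise ValidationError(
                f"unknown tissue {self.tissue!r}; expected one of {RING_GLAND_TISSUES}"
            )
        if self.fused_count < 0:
            raise ValidationError("fused_count must be >= 0")


def hub_score(frac_sensory_in: float, frac_to_rpn: float) -> float:
    """Product of the sensory-input fraction and the output-contribution
    fraction, at full floating precision. Both arguments must be in [0, 1]."""
    for name, v in (("frac_sensory_in", frac_sensory_in), ("frac_to_rpn", frac_to_rpn)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name}={v} outside [0, 1]")
    return frac_sensory_in * frac_to_rpn


def frac_sensory_input(
    c: Connectome, wa: WeightedAdjacency, neuron: str, sensory: Iterable[str]
) -> float:
    """Fraction of ``neuron``'s total input contributed by sensory neurons,
    under the adjacency's denominator policy.

    Computed as summed counts over the denominator (one division), not as a
    sum of per-edge weights, so printed-precision fractions reproduce
    exactly.
    """
    total = float(wa.totals[neuron])
    if total == 0:
        return 0.0
    return sum(c.count(s, neuron) for s in set(sensory)) / total


def frac_to_group(
    c: Connectome, wa: WeightedAdjacency, interneuron: str, members: Iterable[str]
) -> float:
    """Fraction of a group's pooled total input contributed by one
    interneuron: its synapses onto all members over the members' summed
    input denominators."""
    members = sorted(set(members))
    pooled_total = float(wa.totals[members].sum())
    if pooled_total == 0:
        return 0.0
    onto = sum(c.count(interneuron, m) for m in members)
    return onto / pooled_total


def hub_table(
    c: Connectome,
    wa: WeightedAdjacency,
    interneurons: Iterable[str],
    rpn_groups: Mapping[str, Iterable[str]],
    sensory: Iterable[str],
    per_cell: bool = False,
) -> list[HubScore]:
    """Hub scores for every (interneuron, RPN group) pair with a nonzero
    connection, sorted by score descending (ties broken by ids).

    The output-contribution denominator pools input over all group members
    by default; ``per_cell=True`` instead emits one record per single
    group member (labelled ``group:member``) for single-output views.
    """
    if not rpn_groups:
        raise ValidationError("rpn_groups must be nonempty")
    sensory = set(sensory)
    records: list[HubScore] = []
    for i in sorted(set(interneurons)):
        fs = frac_sensory_input(c, wa, i, sensory)
        for label in sorted(rpn_groups):
            members = sorted(set(rpn_groups[label]))
            if per_cell:
                targets = [(f"{label}:{m}", [m]) for m in members]
            else:
                targets = [(label, members)]
            for sub_label, sub_members in targets:
                if not any(c.count(i, m) > 0 for m in sub_members):
                    continue
                ft = frac_to_group(c, wa, i, sub_members)
                records.append(
                    HubScore(
                        interneuron=i,
                        rpn_group=sub_label,
                        frac_sensory_in=fs,
                        frac_to_rpn=ft,
                        score=hub_score(fs, ft),
                    )
                )
    return sorted(records, key=lambda r: (-r.score, r.interneuron, r.rpn_group))


def hub_frame(records: Sequence[HubScore]) -> pd.DataFrame:
    """Hub scores as the hub_scores.tsv layout."""
    return pd.DataFrame(
        [
            {
                "interneuron": r.interneuron,
                "rpn_group": r.rpn_group,
                "frac_sensory_in": r.frac_sensory_in,
                "frac_to_rpn": r.frac_to_rpn,
                "score": r.score,
            }
            for r in records
        ],
        columns=["interneuron", "rpn_group", "frac_sensory_in", "frac_to_rpn", "score"],
    )


def dcv_fractions(records: Iterable[DCVRecord]) -> pd.DataFrame:
    """Per-group tissue fractions of fused DCVs.

    Each group's counts are normalized by its total across tissues, so the
    fractions per group sum to 1. Groups with zero total are omitted (a
    warning row cannot be normalized); record order never affects output.
    Returns columns (rpn_group, tissue, fraction) sorted by group then
    tissue order CC_AO, CA, PG.
    """
    totals: dict[str, int] = {}
    counts: dict[tuple[str, str], int] = {}
    for r in records:
        totals[r.rpn_group] = totals.get(r.rpn_group, 0) + r.fused_count
        key = (r.rpn_group, r.tissue)
        counts[key] = counts.get(key, 0) + r.fused_count
    rows = []
    for group in sorted(totals):
        if totals[group] == 0:
            continue  # omitted: no fused DCVs to apportion
        for tissue in RING_GLAND_TISSUES:
            if (group, tissue) in counts:
                rows.append(
                    {
                        "rpn_group": group,
                        "tissue": tissue,
                        "fraction": counts[(group, tissue)] / totals[group],
                    }
                )
    return pd.DataFrame(rows, columns=["rpn_group", "tissue", "fraction"])


def load_dcv_records(source) -> list[DCVRecord]:
    """Read a dcv.csv table (columns rpn_group, tissue, fused_count)."""
    df = pd.read_csv(source, dtype={"rpn_group": str, "tissue": str})
    required = {"rpn_group", "tissue", "fused_count"}
    if not required.issubset(df.columns):
        raise ValidationError(f"dcv table needs columns {sorted(required)}")
    return [
        DCVRecord(str(r.rpn_group), str(r.tissue), int(r.fused_count))
        for r in df.itertuples(index=False)
    ]
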