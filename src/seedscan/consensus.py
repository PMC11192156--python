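"""Replicate-scan reconciliation.

Each physical seed batch is scanned twice (the seeds are rearranged and
flipped between passes).  Seeds are not individually matched across the two
scans, so agreement is defined on per-species count vectors: half the L1
distance counts seeds that changed class, and half the total-count
difference counts seeds present in only one scan.  The relative discrepancy
standardizes by the mean number of seeds per scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .scanio import ScanMetadata

__all__ = [
    "ConsensusReport",
    "pair_replicates",
    "species_counts",
    "consensus_and_discrepancy",
]


@dataclass
class ConsensusReport:
    batch_id: str
    counts_rep1: Dict[str, int]
    counts_rep2: Dict[str, int]
    consensus_counts: Dict[str, float]  # elementwise mean, may be half-integer
    consensus_integer: Dict[str, int]  # largest-remainder apportionment
    discrepancy_abs: float
    discrepancy_rel: float


def pair_replicates(
    metadata: Sequence[ScanMetadata],
) -> Tuple[List[Tuple[ScanMetadata, ScanMetadata]], List[ScanMetadata]]:
    """Group scans by batch (site+trap+date+fill) and pair rep1 with rep2.

    Returns (pairs, unpaired singletons).  More than two replicates of one
    batch is an error; extending to k scans is deliberately out of scope.
    """
    groups: Dict[str, List[ScanMetadata]] = {}
    for meta in metadata:
        groups.setdefault(meta.batch_id, []).append(meta)
    pairs = []
    unpaired = []
    for batch_id in sorted(groups):
        scans = sorted(groups[batch_id], key=lambda m: m.replicate_index)
        if len(scans) > 2:
            raise ValueError(
                f"batch {batch_id} has {len(scans)} replicate scans; only 2 supported"
            )
        if len(scans) == 1:
            unpaired.append(scans[0])
        else:
            pairs.append((scans[0], scans[1]))
    return pairs, unpaired


def species_counts(
    labels: Sequence[str], vocabulary: Sequence[str]
) -> Dict[str, int]:
    """Tally labels over the full species vocabulary (zeros included)."""
    counts = {s: 0 for s in vocabulary}
    for lab in labels:
        if lab not in counts:
            raise ValueError(f"label {lab!r} not in vocabulary {list(vocabulary)}")
        counts[lab] += 1
    return counts


def _round_half_up(x: float) -> int:
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def _largest_remainder(means: Mapping[str, float], target_total: int) -> Dict[str, int]:
    floors = {s: int(v) for s, v in means.items()}
    short = target_total - sum(floors.values())
    # distribute leftover units by largest fractional part, ties by name
    order = sorted(means, key=lambda s: (-(means[s] - floors[s]), s))
    out = dict(floors)
    for s in order[:short]:
        out[s] += 1
    return out


def consensus_and_discrepancy(
    c1: Mapping[str, int],
    c2: Mapping[str, int],
    batch_id: str = "",
) -> ConsensusReport:
    """Consensus mean counts and the between-scan discrepancy.

    discrepancy_abs = 0.5 * sum_s |c1[s] - c2[s]| + 0.5 * |total1 - total2|
    (relabelled seeds plus appear/disappear events); discrepancy_rel
    divides by the mean scan total.  Symmetric in its arguments; zero iff
    the count vectors are equal.
    """
    if set(c1) != set(c2):
        raise ValueError(
            f"species vocabularies differ: {sorted(c1)} vs {sorted(c2)}"
        )
    species = sorted(c1)
    t1 = sum(c1.values())
    t2 = sum(c2.values())
    l1 = sum(abs(c1[s] - c2[s]) for s in species)
    disc_abs = 0.5 * l1 + 0.5 * abs(t1 - t2)
    mean_total = 0.5 * (t1 + t2)
    disc_rel = disc_abs / mean_total if mean_total > 0 else 0.0
    means = {s: 0.5 * (c1[s] + c2[s]) for s in species}
    integer = _largest_remainder(means, _round_half_up(mean_total))
    return ConsensusReport(
        batch_id=batch_id,
        counts_rep1=dict(c1),
        counts_rep2=dict(c2),
        consensus_counts=means,
        consensus_integer=integer,
        discrepancy_abs=disc_abs,
        discrepancy_rel=disc_rel,
    )
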