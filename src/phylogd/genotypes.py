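"""Recursive top-down genotype propagation along a clone tree.

Per clone and genomic locus the genotype is the triplet (x, y, z): copies
of allele A, copies of allele B, and the mutation multiplicity (number of
copies of allele A bearing the SNV; by convention SNVs always sit on the
A allele, which is without loss of generality since allele labels are
independent across loci).  The germline root is (1, 1, 0) everywhere.

Event semantics:

* SNV: z <- z + 1 (skipped if allele A is absent, which cannot carry a new
  mutation).
* GAIN(magnitude m): the chosen allele gains m copies; if it is allele A
  and a mutation is present the duplicated copies are taken to be mutant
  copies (z <- z + m), keeping multiplicity proportional.
* LOSS: the chosen allele loses one copy; if allele A and every remaining
  copy was mutant (z = x), a mutant copy must be lost (z <- z - 1).  A loss
  on an allele already at zero copies is skipped: LOH is irreversible.
* WGD: doubles every allele present at one or more copies, including
  mutant copies: (x, y, z) <- (2x, 2y, 2z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EvolutionEvent
from .genome import GenomeLayout
from .topology import PhylogenyTopology


@dataclass
class CloneGenotypes:
    """Per-clone arm copy numbers and per-locus mutation multiplicities."""

    layout: GenomeLayout
    x: dict[int, np.ndarray] = field(default_factory=dict)  # clone -> [n_arms]
    y: dict[int, np.ndarray] = field(default_factory=dict)
    z: dict[int, np.ndarray] = field(default_factory=dict)  # clone -> [n_loci]
    skipped_events: list[EvolutionEvent] = field(default_factory=list)

    def triplet(self, clone: int, locus: int) -> tuple[int, int, int]:
        arm = int(self.layout.arm_of[locus])
        return int(self.x[clone][arm]), int(self.y[clone][arm]), int(self.z[clone][locus])

    def total_cn(self, clone: int) -> np.ndarray:
        return self.x[clone] + self.y[clone]


def apply_event(
    ev: EvolutionEvent,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    arm_of: np.ndarray,
) -> bool:
    """Apply one event in place; returns False if the event was skipped."""
    if ev.kind == "SNV":
        arm = int(arm_of[ev.locus])
        if x[arm] == 0:
            return False
        z[ev.locus] += 1
        return True
    if ev.kind == "WGD":
        x *= 2
        y *= 2
        z *= 2
        return True
    arm = int(ev.locus)
    target = x if ev.allele == "A" else y
    if target[arm] == 0:
        return False  # irreversible LOH
    if ev.kind == "GAIN":
        target[arm] += ev.magnitude
        if ev.allele == "A":
            on_arm = arm_of == arm
            z[on_arm & (z >= 1)] += ev.magnitude
        return True
    if ev.kind == "LOSS":
        if ev.allele == "A":
            on_arm = arm_of == arm
            z[on_arm & (z >= target[arm])] -= 1
        target[arm] -= 1
        return True
    raise ValueError(f"unknown event kind {ev.kind}")


def propagate_genotypes(
    topology: PhylogenyTopology,
    events: list[EvolutionEvent],
    layout: GenomeLayout,
) -> CloneGenotypes:
    """Determine every clone's genotype by recursive top-down application."""
    by_edge: dict[tuple[int, int], list[EvolutionEvent]] = {}
    for ev in events:
        by_edge.setdefault(ev.edge, []).append(ev)
    for evs in by_edge.values():
        evs.sort(key=lambda e: e.order_index)

    geno = CloneGenotypes(layout)
    root = topology.germline_root
    geno.x[root] = np.ones(layout.n_arms, dtype=np.int64)
    geno.y[root] = np.ones(layout.n_arms, dtype=np.int64)
    geno.z[root] = np.zeros(layout.n_loci, dtype=np.int64)

    stack = [root]
    while stack:
        node = stack.pop()
        for child in topology.children(node):
            x = geno.x[node].copy()
            y = geno.y[node].copy()
            z = geno.z[node].copy()
            for ev in by_edge.get((node, child), []):
                if not apply_event(ev, x, y, z, layout.arm_of):
                    geno.skipped_events.append(ev)
            geno.x[child], geno.y[child], geno.z[child] = x, y, z
            stack.append(child)
    return geno
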