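"""Somatic evolution events on clone-tree edges.

Events are SNVs (point mutations under the infinite-sites assumption),
allele-specific copy-number gains and losses at arm scale, and whole-genome
doublings.  Events on an edge are applied in a uniformly random order, so
SNVs can occur both before and after copy-number events on the same edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .topology import PhylogenyTopology

Kind = Literal["SNV", "GAIN", "LOSS", "WGD"]


@dataclass(frozen=True)
class EvolutionEvent:
    kind: Kind
    edge: tuple[int, int]
    locus: int | None = None  # SNV: locus id; GAIN/LOSS: arm id
    allele: Literal["A", "B"] | None = None
    magnitude: int = 1
    order_index: int = 0


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def assign_events(
    topology: PhylogenyTopology,
    n_snvs: int,
    truncal_fraction: float,
    rng: np.random.Generator,
    *,
    n_arms: int = 44,
    gains_per_edge: np.ndarray | dict[tuple[int, int], int] | None = None,
    losses_per_edge: np.ndarray | dict[tuple[int, int], int] | None = None,
    wgd_edges: list[tuple[int, int]] | None = None,
    gain_magnitudes: "np.random.Generator | None" = None,
) -> list[EvolutionEvent]:
    """Assign SNVs, SCNAs and WGDs to the edges of a clone tree.

    The trunk receives ``round(n_snvs * truncal_fraction)`` SNVs; the rest
    are spread uniformly at random over subclonal edges.  Each SNV uses a
    fresh locus id (infinite sites).  Gains/losses target a uniformly random
    arm and allele.  Within each edge the events are shuffled into a
    uniformly random order recorded in ``order_index``.
    """
    if not 0.0 <= truncal_fraction <= 1.0:
        raise ValueError("truncal_fraction must be in [0, 1]")
    trunk = (topology.germline_root, topology.mrca)
    sub_edges = topology.subclonal_edges()
    n_truncal = _round_half_even(n_snvs * truncal_fraction)
    n_sub = n_snvs - n_truncal
    if n_sub > 0 and not sub_edges:
        raise ValueError("subclonal SNVs requested but the tree has no subclonal edges")

    per_edge: dict[tuple[int, int], list[EvolutionEvent]] = {e: [] for e in topology.edges()}
    locus = 0
    for _ in range(n_truncal):
        per_edge[trunk].append(EvolutionEvent("SNV", trunk, locus=locus))
        locus += 1
    if n_sub:
        choices = rng.integers(0, len(sub_edges), size=n_sub)
        for idx in choices:
            e = sub_edges[int(idx)]
            per_edge[e].append(EvolutionEvent("SNV", e, locus=locus))
            locus += 1

    def _counts(spec, edges):
        if spec is None:
            return {}
        if isinstance(spec, dict):
            return spec
        return dict(zip(edges, spec))

    all_edges = topology.edges()
    for kind, spec in (("GAIN", gains_per_edge), ("LOSS", losses_per_edge)):
        for edge, k in _counts(spec, all_edges).items():
            for _ in range(int(k)):
                arm = int(rng.integers(n_arms))
                allele = "A" if rng.random() < 0.5 else "B"
                mag = 1
                if kind == "GAIN" and gain_magnitudes is not None:
                    mag = 1 + int(gain_magnitudes.poisson(0.3))
                per_edge[edge].append(EvolutionEvent(kind, edge, locus=arm, allele=allele, magnitude=mag))

    for edge in wgd_edges or []:
        per_edge[edge].append(EvolutionEvent("WGD", edge))

    out: list[EvolutionEvent] = []
    for edge in all_edges:
        evs = per_edge[edge]
        order = rng.permutation(len(evs))
        for rank, i in enumerate(order):
            e = evs[int(i)]
            out.append(EvolutionEvent(e.kind, e.edge, e.locus, e.allele, e.magnitude, order_index=rank))
    return out
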