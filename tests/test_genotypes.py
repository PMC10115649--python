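"""Event assignment and genotype propagation semantics."""

import itertools

import numpy as np
import pytest

from phylogd.events import EvolutionEvent, assign_events
from phylogd.genome import GenomeLayout
from phylogd.genotypes import apply_event, propagate_genotypes
from phylogd.topology import simulate_topology


def _chain3():
    """germline -> 1 -> 2 chain."""
    from phylogd.topology import PhylogenyTopology

    return PhylogenyTopology(parent_of={1: 0, 2: 1})


def _layout(n_loci=1, arm=0, n_arms=4):
    return GenomeLayout(n_arms=n_arms, arm_of=np.full(n_loci, arm), pos=np.zeros(n_loci, dtype=int))


class TestAssignEvents:
    def test_all_truncal(self, rng):
        topo = _chain3()
        events = assign_events(topo, 50, 1.0, rng)
        snvs = [e for e in events if e.kind == "SNV"]
        assert len(snvs) == 50
        assert all(e.edge == (0, 1) for e in snvs)

    def test_truncal_fraction_preserved(self, rng):
        topo = simulate_topology(6, rng)
        events = assign_events(topo, 100, 0.6, rng)
        trunk = (topo.germline_root, topo.mrca)
        snvs = [e for e in events if e.kind == "SNV"]
        assert sum(e.edge == trunk for e in snvs) == 60
        assert sum(e.edge != trunk for e in snvs) == 40

    def test_infinite_sites(self, rng):
        topo = simulate_topology(8, rng)
        events = assign_events(topo, 200, 0.5, rng)
        loci = [e.locus for e in events if e.kind == "SNV"]
        assert len(loci) == len(set(loci))

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            assign_events(_chain3(), 10, 1.5, rng)

    def test_subclonal_snvs_need_subclonal_edges(self, rng):
        from phylogd.topology import PhylogenyTopology

        trunk_only = PhylogenyTopology(parent_of={1: 0})
        with pytest.raises(ValueError):
            assign_events(trunk_only, 10, 0.5, rng)


class TestPropagation:
    def test_no_events_everything_diploid(self, rng):
        topo = _chain3()
        layout = _layout(n_loci=3)
        geno = propagate_genotypes(topo, [], layout)
        for clone in topo.nodes:
            assert geno.triplet(clone, 0) == (1, 1, 0)

    def test_snv_before_and_after_wgd(self):
        topo = _chain3()
        layout = _layout()
        # SNV then WGD on the same edge -> doubled mutant copies
        ev = [
            EvolutionEvent("SNV", (0, 1), locus=0, order_index=0),
            EvolutionEvent("WGD", (0, 1), order_index=1),
        ]
        geno = propagate_genotypes(topo, ev, layout)
        assert geno.triplet(1, 0) == (2, 2, 2)
        # WGD then SNV -> single mutant copy on a doubled genome
        ev = [
            EvolutionEvent("WGD", (0, 1), order_index=0),
            EvolutionEvent("SNV", (0, 1), locus=0, order_index=1),
        ]
        geno = propagate_genotypes(topo, ev, layout)
        assert geno.triplet(1, 0) == (2, 2, 1)

    def test_loh_is_irreversible(self):
        topo = _chain3()
        layout = _layout()
        events = [
            EvolutionEvent("SNV", (0, 1), locus=0, order_index=0),
            EvolutionEvent("LOSS", (0, 1), locus=0, allele="B", order_index=1),
            # clone 1 now (1, 0, 1); losing A reaches (0, 0, 0)
            EvolutionEvent("LOSS", (1, 2), locus=0, allele="A", order_index=0),
            EvolutionEvent("GAIN", (1, 2), locus=0, allele="A", order_index=1),
        ]
        geno = propagate_genotypes(topo, events, layout)
        assert geno.triplet(1, 0) == (1, 0, 1)
        assert geno.triplet(2, 0) == (0, 0, 0)  # gain on lost allele skipped
        assert len(geno.skipped_events) == 1

    def test_loss_removes_mutant_copy_only_when_forced(self):
        x = np.array([2])
        y = np.array([1])
        z = np.array([1])
        arm_of = np.array([0])
        apply_event(EvolutionEvent("LOSS", (0, 1), locus=0, allele="A"), x, y, z, arm_of)
        assert (x[0], z[0]) == (1, 1)  # non-mutant copy lost first
        apply_event(EvolutionEvent("LOSS", (0, 1), locus=0, allele="A"), x, y, z, arm_of)
        assert (x[0], z[0]) == (0, 0)  # z = x forces losing the mutant

    def test_wgd_doubles_any_genotype(self):
        for x0, y0, z0 in [(1, 1, 0), (2, 1, 2), (3, 0, 1), (0, 2, 0)]:
            x, y, z = np.array([x0]), np.array([y0]), np.array([z0])
            apply_event(EvolutionEvent("WGD", (0, 1)), x, y, z, np.array([0]))
            assert (x[0], y[0], z[0]) == (2 * x0, 2 * y0, 2 * z0)

    def test_reachable_copy_number_states(self):
        """<=1 WGD, <=2 gains, <=2 losses reach the common allele states."""
        base = [EvolutionEvent("GAIN", (0, 1), locus=0, allele="A"),
                EvolutionEvent("GAIN", (0, 1), locus=0, allele="A"),
                EvolutionEvent("LOSS", (0, 1), locus=0, allele="B"),
                EvolutionEvent("LOSS", (0, 1), locus=0, allele="B"),
                EvolutionEvent("WGD", (0, 1))]
        seen = set()
        arm_of = np.array([0])
        for r in range(len(base) + 1):
            for combo in itertools.permutations(base, r):
                x, y, z = np.array([1]), np.array([1]), np.array([0])
                for ev in combo:
                    apply_event(ev, x, y, z, arm_of)
                a, b = int(x[0]), int(y[0])
                seen.add((max(a, b), min(a, b)))
        for state in [(2, 1), (3, 1), (4, 1), (3, 2), (4, 2), (1, 0), (2, 0)]:
            assert state in seen
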