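"""Bulk sampling and the Poisson/binomial read model."""

import numpy as np
import pytest

from phylogd.events import EvolutionEvent
from phylogd.genome import GenomeLayout
from phylogd.genotypes import propagate_genotypes
from phylogd.sampling import (
    BulkSample,
    compute_sample_state,
    expected_vaf,
    generate_reads,
    inject_artefacts,
    sample_bulk,
)
from phylogd.topology import PhylogenyTopology, simulate_topology


def _one_clone_setup(n_loci=1, mutated=True):
    topo = PhylogenyTopology(parent_of={1: 0})
    layout = GenomeLayout(n_arms=2, arm_of=np.zeros(n_loci, dtype=int), pos=np.zeros(n_loci, dtype=int))
    events = [EvolutionEvent("SNV", (0, 1), locus=i) for i in range(n_loci if mutated else 0)]
    geno = propagate_genotypes(topo, events, layout)
    return topo, layout, geno


def test_proportions_on_simplex(rng):
    topo = simulate_topology(10, rng)
    samples = sample_bulk(topo, 20, np.full(20, 0.5), np.full(20, 100.0), rng)
    for s in samples:
        assert abs(s.proportions.sum() - 1.0) < 1e-12
        assert len(set(s.clone_ids)) == len(s.clone_ids)


def test_single_clone_gets_full_proportion(rng):
    topo = PhylogenyTopology(parent_of={1: 0})
    (s,) = sample_bulk(topo, 1, np.array([0.7]), np.array([100.0]), rng)
    assert s.clone_ids == [1]
    assert s.proportions[0] == pytest.approx(1.0)


def test_clones_per_sample_uniform_three_to_eight(rng):
    topo = simulate_topology(12, rng)
    samples = sample_bulk(topo, 10_000, np.full(10_000, 0.5), np.full(10_000, 100.0), rng)
    sizes = np.array([len(s.clone_ids) for s in samples])
    assert sizes.min() >= 3 and sizes.max() <= 8
    se = np.sqrt((1 / 6) * (5 / 6) / 10_000)
    for k in range(3, 9):
        assert abs((sizes == k).mean() - 1 / 6) < 3 * se


def test_fractional_copy_number_arithmetic():
    topo = PhylogenyTopology(parent_of={1: 0, 2: 1})
    layout = GenomeLayout(n_arms=2, arm_of=np.array([0, 1]), pos=np.zeros(2, dtype=int))
    # clone 2 gains both alleles on arm 0 -> total CN 4 there
    events = [
        EvolutionEvent("GAIN", (1, 2), locus=0, allele="A", order_index=0),
        EvolutionEvent("GAIN", (1, 2), locus=0, allele="B", order_index=1),
    ]
    geno = propagate_genotypes(topo, events, layout)
    s = BulkSample("R1", purity=1.0, clone_ids=[1, 2], proportions=np.array([0.5, 0.5]), coverage=100.0)
    f, rho = compute_sample_state(s, geno)
    assert f[0] == pytest.approx(3.0)  # mean of CN 2 and CN 4
    assert f[1] == pytest.approx(2.0)
    assert rho == pytest.approx(2.5)  # mean over the two arms


def test_read_totals_match_closed_form_mean(rng):
    topo, layout, geno = _one_clone_setup()
    s = BulkSample("R1", 1.0, [1], np.array([1.0]), coverage=400.0)
    compute_sample_state(s, geno)
    draws = rng.poisson(s.f_arm[0] / s.ploidy * s.coverage, size=100_000)
    assert abs(draws.mean() - 400.0) < 3 * draws.std() / np.sqrt(len(draws))


def test_expected_vaf_pure_heterozygous(rng):
    topo, layout, geno = _one_clone_setup()
    s = BulkSample("R1", 1.0, [1], np.array([1.0]), coverage=400.0)
    compute_sample_state(s, geno)
    psi = expected_vaf(s, geno)
    assert psi[0] == pytest.approx(0.5)
    reads = generate_reads([s], geno, rng)
    vaf = reads.v[0] / reads.t[0]
    # one locus; many independent tumours would be needed for tighter MC --
    # instead check the binomial mean over repeated draws
    vs = rng.binomial(reads.t[0], 0.5, size=100_000)
    assert abs((vs / reads.t[0]).mean() - 0.5) < 3 * (vs / reads.t[0]).std() / np.sqrt(len(vs))


def test_purity_dilutes_vaf():
    topo, layout, geno = _one_clone_setup()
    s = BulkSample("R1", 0.5, [1], np.array([1.0]), coverage=400.0)
    compute_sample_state(s, geno)
    # mu z / (mu (x+y) + 2(1-mu)) = 0.5 / (1 + 1) = 0.25
    assert expected_vaf(s, geno)[0] == pytest.approx(0.25)


def test_unmutated_loci_have_zero_vaf(rng):
    topo, layout, geno = _one_clone_setup(n_loci=5, mutated=False)
    s = BulkSample("R1", 0.8, [1], np.array([1.0]), coverage=400.0)
    compute_sample_state(s, geno)
    reads = generate_reads([s], geno, rng)
    assert np.all(reads.psi == 0)
    assert np.all(reads.v == 0)
    assert np.all(reads.v <= reads.t)


class TestArtefacts:
    def _setup(self, rng):
        topo = simulate_topology(6, rng)
        layout = GenomeLayout(n_arms=4, arm_of=np.zeros(3, dtype=int), pos=np.zeros(3, dtype=int))
        events = [EvolutionEvent("SNV", (0, 1), locus=i) for i in range(3)]
        geno = propagate_genotypes(topo, events, layout)
        samples = sample_bulk(topo, 3, np.full(3, 0.6), np.full(3, 200.0), rng)
        for s in samples:
            compute_sample_state(s, geno)
        reads = generate_reads(samples, geno, rng)
        return topo, geno, samples, reads

    def test_zero_artefacts_identity(self, rng):
        topo, geno, samples, reads = self._setup(rng)
        out, _ = inject_artefacts(reads, samples, geno, topo, 0, rng)
        assert out is reads

    def test_locus_count_extended_and_flagged(self, rng):
        topo, geno, samples, reads = self._setup(rng)
        out, arms = inject_artefacts(reads, samples, geno, topo, 4, rng)
        assert out.t.shape[0] == reads.t.shape[0] + 4
        assert out.is_artefact.sum() == 4
        assert np.all(out.v <= out.t)
        assert len(arms) == 4

    def test_artefact_vaf_has_no_shared_clone_structure(self, rng):
        # psi of an artefact is recomputed from fresh proportions per
        # sample; across many artefacts the per-sample values decorrelate
        topo, geno, samples, reads = self._setup(rng)
        out, _ = inject_artefacts(reads, samples, geno, topo, 200, rng)
        psi = out.psi[reads.t.shape[0]:]
        spread = np.abs(psi[:, 0] - psi[:, 1])
        assert np.quantile(spread, 0.9) > 0.05
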