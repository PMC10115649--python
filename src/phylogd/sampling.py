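"""Bulk tumour samples and the sequencing read-count model.

Each bulk sample mixes 1 - mu normal diploid cells with mu tumour cells
drawn from n-hat distinct clones whose proportions (over cancer cells) are
flat-Dirichlet distributed.  Per locus p and sample s the fractional copy
number is f_ps = sum_i u_i (x_ip + y_ip), the sample ploidy rho_s is the
genome-average of f, total reads are Poisson((f/rho) * gamma) and variant
reads are Binomial(t, psi), where psi is the expected variant allele
fraction.  With normal contamination,

    psi = mu * sum(u z) / (mu * sum(u (x + y)) + 2 (1 - mu)),

which reduces to the pure-tumour form sum(u z) / sum(u (x + y)) at mu = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import CloneGenotypes
from .topology import PhylogenyTopology

NHAT_RANGE = (3, 8)  # clones per bulk sample, uniform


@dataclass
class BulkSample:
    sample_id: str
    purity: float
    clone_ids: list[int]
    proportions: np.ndarray  # aligned with clone_ids, sums to 1
    coverage: float
    # filled by compute_sample_state
    f_arm: np.ndarray | None = None
    ploidy: float | None = None

    def clone_fraction(self, clones: set[int]) -> float:
        """Cancer-cell fraction of the sample made up by ``clones``."""
        return float(sum(u for c, u in zip(self.clone_ids, self.proportions) if c in clones))


@dataclass
class ReadCounts:
    """Per locus x sample total/variant read counts and expected VAF."""

    t: np.ndarray  # [n_loci, n_samples]
    v: np.ndarray
    psi: np.ndarray
    is_artefact: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.is_artefact is None:
            self.is_artefact = np.zeros(self.t.shape[0], dtype=bool)


def sample_bulk(
    topology: PhylogenyTopology,
    n_samples: int,
    purity_draws: np.ndarray,
    coverage_draws: np.ndarray,
    rng: np.random.Generator,
) -> list[BulkSample]:
    """Draw bulk samples: n-hat ~ U{3..8} distinct clones, Dirichlet(1) mix."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    clones = topology.clones
    samples = []
    for s in range(n_samples):
        nhat = int(rng.integers(NHAT_RANGE[0], NHAT_RANGE[1] + 1))
        nhat = min(nhat, len(clones))
        chosen = sorted(rng.choice(clones, size=nhat, replace=False).tolist())
        u = rng.dirichlet(np.ones(nhat))
        samples.append(
            BulkSample(
                sample_id=f"R{s + 1}",
                purity=float(purity_draws[s]),
                clone_ids=chosen,
                proportions=u,
                coverage=float(coverage_draws[s]),
            )
        )
    return samples


def compute_sample_state(sample: BulkSample, geno: CloneGenotypes) -> tuple[np.ndarray, float]:
    """Fractional copy number per arm and the sample ploidy (their mean)."""
    f = np.zeros(geno.layout.n_arms)
    for clone, u in zip(sample.clone_ids, sample.proportions):
        f += u * (geno.x[clone] + geno.y[clone])
    rho = float(f.mean())
    sample.f_arm = f
    sample.ploidy = rho
    return f, rho


def expected_vaf(sample: BulkSample, geno: CloneGenotypes) -> np.ndarray:
    """psi per locus, diluting both mutant and total copies by purity."""
    mu = sample.purity
    layout = geno.layout
    num = np.zeros(layout.n_loci)
    den = np.zeros(layout.n_loci)
    for clone, u in zip(sample.clone_ids, sample.proportions):
        num += u * geno.z[clone]
        den += u * (geno.x[clone] + geno.y[clone])[layout.arm_of]
    psi = (mu * num) / (mu * den + 2.0 * (1.0 - mu))
    if np.any((psi < 0) | (psi > 1)):
        raise AssertionError("expected VAF left [0, 1]; internal inconsistency")
    return psi


def generate_reads(
    samples: list[BulkSample],
    geno: CloneGenotypes,
    rng: np.random.Generator,
) -> ReadCounts:
    """Draw (t, v) for every locus in every sample."""
    layout = geno.layout
    t = np.zeros((layout.n_loci, len(samples)), dtype=np.int64)
    v = np.zeros_like(t)
    psi = np.zeros((layout.n_loci, len(samples)))
    for j, sample in enumerate(samples):
        if sample.f_arm is None:
            compute_sample_state(sample, geno)
        f_locus = sample.f_arm[layout.arm_of]
        mean_t = f_locus / sample.ploidy * sample.coverage
        psi[:, j] = expected_vaf(sample, geno)
        t[:, j] = rng.poisson(mean_t)
        v[:, j] = rng.binomial(t[:, j], psi[:, j])
    return ReadCounts(t=t, v=v, psi=psi)


def inject_artefacts(
    reads: ReadCounts,
    samples: list[BulkSample],
    geno: CloneGenotypes,
    topology: PhylogenyTopology,
    n_artefacts: int,
    rng: np.random.Generator,
) -> tuple[ReadCounts, np.ndarray]:
    """Append artefactual SNV loci that violate tree consistency.

    Each artefact is an SNV placed on a random clone subtree, but its psi in
    each sample is computed with freshly drawn, per-sample-independent clone
    proportions, so the per-sample signals share no clone structure.
    Returns the extended counts and the arm ids of the artefact loci.
    """
    if n_artefacts < 0:
        raise ValueError("n_artefacts must be >= 0")
    if n_artefacts == 0:
        return reads, np.zeros(0, dtype=int)
    layout = geno.layout
    arms = rng.integers(0, layout.n_arms, size=n_artefacts)
    carriers = [topology.subtree(c) for c in rng.choice(topology.clones, size=n_artefacts)]
    t = np.zeros((n_artefacts, len(samples)), dtype=np.int64)
    v = np.zeros_like(t)
    psi = np.zeros((n_artefacts, len(samples)))
    for j, sample in enumerate(samples):
        mu = sample.purity
        for k in range(n_artefacts):
            u = rng.dirichlet(np.ones(len(sample.clone_ids)))  # fresh, inconsistent
            arm = int(arms[k])
            num = den = 0.0
            for clone, uu in zip(sample.clone_ids, u):
                cx = geno.x[clone][arm]
                cy = geno.y[clone][arm]
                den += uu * (cx + cy)
                if clone in carriers[k]:
                    num += uu * min(1, cx)
            p = (mu * num) / (mu * den + 2.0 * (1.0 - mu))
            psi[k, j] = p
            mean_t = sample.f_arm[arm] / sample.ploidy * sample.coverage
            t[k, j] = rng.poisson(mean_t)
            v[k, j] = rng.binomial(t[k, j], p)
    flags = np.concatenate([reads.is_artefact, np.ones(n_artefacts, dtype=bool)])
    return (
        ReadCounts(
            t=np.vstack([reads.t, t]),
            v=np.vstack([reads.v, v]),
            psi=np.vstack([reads.psi, psi]),
            is_artefact=flags,
        ),
        arms,
    )
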