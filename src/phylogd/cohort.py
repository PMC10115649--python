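"""Cohort-scale tumour simulation with ground-truth records.

``simulate_cohort`` rejection-samples tumours until each satisfies the
cohort inclusion constraints (tumour purity > 20% in every sample, more
than 150 somatic SNVs, truncal mutation proportion below 90%), emitting
per-tumour ground truth (topology, events including WGD placements,
genotypes, clone proportions, per-region WGD truth) alongside read counts.

The default parameter distributions are parametric stand-ins shaped on
published multi-region NSCLC whole-exome cohorts: sequencing coverage
centred on 413x (truncated normal), purity uniform on (0.2, 0.9), and a
negative-binomial SNV burden with mean 400.  Every distribution can be
overridden through :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .events import EvolutionEvent, assign_events
from .genome import GenomeLayout
from .genotypes import CloneGenotypes, propagate_genotypes
from .sampling import BulkSample, ReadCounts, compute_sample_state, generate_reads, inject_artefacts, sample_bulk
from .topology import CLONE_RANGES, SAMPLE_RANGES, PhylogenyTopology, draw_n_clones, simulate_topology


@dataclass
class SimConfig:
    """Distributional configuration of the tumour simulator."""

    sample_group: str = "mixed"  # low | medium | high | mixed
    group_weights: tuple[float, float, float] = (0.45, 0.45, 0.10)
    n_clones_range: tuple[int, int] | None = None   # overrides the group range
    n_samples_range: tuple[int, int] | None = None
    n_arms: int = 44
    purity_range: tuple[float, float] = (0.2, 0.9)
    coverage_mean: float = 413.0
    coverage_sd: float = 60.0
    coverage_floor: float = 50.0
    snv_mean: float = 400.0
    snv_shape: float = 4.0  # negative-binomial r
    truncal_fraction_range: tuple[float, float] = (0.40, 0.95)
    trunk_gain_rate: float = 5.0
    trunk_loss_rate: float = 5.0
    edge_gain_rate: float = 0.5
    edge_loss_rate: float = 0.5
    p_truncal_wgd: float = 0.4
    subclonal_wgd_probs: tuple[float, ...] = (0.35, 0.25, 0.25, 0.15)  # P(0..3 events)
    max_wgd_per_lineage: int = 2
    n_artefacts: int = 10
    # cohort inclusion constraints
    min_purity: float = 0.20
    min_snvs: int = 150
    max_truncal_prop: float = 0.90

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class WGDTruthEvent:
    """A simulated WGD with its phylogenetic placement and regional CCFs."""

    event_id: int
    edge: tuple[int, int]
    truncal: bool
    ccf: np.ndarray  # per sample: cancer-cell fraction of doubled clones
    detectable_regions: np.ndarray = None  # bool per sample

    @property
    def detectable(self) -> bool:
        return bool(self.detectable_regions is not None and self.detectable_regions.any())


@dataclass
class SimulatedTumour:
    tumour_id: str
    config: SimConfig
    sample_group: str
    topology: PhylogenyTopology
    layout: GenomeLayout
    events: list[EvolutionEvent]
    genotypes: CloneGenotypes
    samples: list[BulkSample]
    reads: ReadCounts
    wgd_truth: list[WGDTruthEvent]
    truncal_fraction: float
    mutation_clone: np.ndarray = field(default=None)  # locus -> clone of origin (-1 artefact)

    # ---- truth helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def clone_ccf(self, clone: int) -> np.ndarray:
        """Per-sample fraction of cancer cells at or below ``clone``."""
        sub = self.topology.subtree(clone)
        return np.array([s.clone_fraction(sub) for s in self.samples])

    def region_wgd_counts(self, cap: int | None = None) -> np.ndarray:
        """Ground-truth-detectable WGD count per region.

        Counts the truth events detectable in each region (CCF above the
        detectability threshold there, alone or jointly with parallel
        events).  Uncapped by default; the cap of two subclonal events is
        applied to the detector's reported events, not to its inputs.
        """
        counts = np.zeros(self.n_samples, dtype=int)
        for ev in self.wgd_truth:
            if ev.detectable_regions is not None:
                counts += ev.detectable_regions.astype(int)
        return counts if cap is None else np.minimum(counts, cap)

    def region_wgd_state_counts(self, cap: int = 2) -> np.ndarray:
        """Majority-cell WGD count per region: what the major-allele
        >=2 / >=3 over >=50%-of-genome ploidy rule measures."""
        counts = np.zeros(self.n_samples, dtype=int)
        wgd_clones = [self.topology.subtree(ev.edge[1]) for ev in self.wgd_truth]
        for j, s in enumerate(self.samples):
            for k in range(1, cap + 1):
                frac = sum(
                    u for clone, u in zip(s.clone_ids, s.proportions)
                    if sum(clone in sub for sub in wgd_clones) >= k
                )
                if frac >= 0.5:
                    counts[j] = k
        return counts

    def exact_mutation_cn(self) -> np.ndarray:
        """Noiseless mutation copy number sum(u_i z_i) per locus x sample.

        Artefact loci (no true genotype) get zero.
        """
        out = np.zeros((self.layout.n_loci, self.n_samples))
        n_real = self.genotypes.layout.n_loci
        for j, s in enumerate(self.samples):
            for clone, u in zip(s.clone_ids, s.proportions):
                out[:n_real, j] += u * self.genotypes.z[clone]
        return out

    def bulk_major_cn(self) -> np.ndarray:
        """Rounded bulk allele-specific major copy number per arm x sample."""
        major = np.zeros((self.layout.n_arms, self.n_samples), dtype=int)
        for j, s in enumerate(self.samples):
            xb = np.zeros(self.layout.n_arms)
            yb = np.zeros(self.layout.n_arms)
            for clone, u in zip(s.clone_ids, s.proportions):
                xb += u * self.genotypes.x[clone]
                yb += u * self.genotypes.y[clone]
            major[:, j] = np.maximum(np.rint(xb), np.rint(yb)).astype(int)
        return major

    def n_detectable_subclonal(self) -> int:
        return sum(ev.detectable and not ev.truncal for ev in self.wgd_truth)


def mark_detectable(
    tumour: SimulatedTumour,
    threshold: float = 0.75,
    sum_floor: float = 0.25,
) -> None:
    """Mark, per region, the WGD truth events detectable there.

    An event is detectable in a region when its CCF exceeds the threshold
    there, or when the summed CCF of a set of pairwise parallel
    (non-nested) events containing it does, provided every contributing
    event (including itself) holds at least ``sum_floor`` of the region's
    cancer cells -- a joint sweep of the region by substantial parallel
    doublings.  Truncal events (CCF 1 everywhere) are detectable in every
    region.
    """
    evs = tumour.wgd_truth
    n = tumour.n_samples
    subtrees = {ev.event_id: tumour.topology.subtree(ev.edge[1]) for ev in evs}

    def nested(a: WGDTruthEvent, b: WGDTruthEvent) -> bool:
        return a.edge[1] in subtrees[b.event_id] or b.edge[1] in subtrees[a.event_id]

    sub = [ev for ev in evs if not ev.truncal]
    for ev in evs:
        if ev.truncal:
            ev.detectable_regions = np.ones(n, dtype=bool)
            continue
        det = ev.ccf > threshold
        others = [o for o in sub if o.event_id != ev.event_id and not nested(ev, o)]
        for mask in range(1, 1 << len(others)):
            group = [others[i] for i in range(len(others)) if mask >> i & 1]
            if any(nested(a, b) for i, a in enumerate(group) for b in group[i + 1:]):
                continue
            total = ev.ccf + sum(o.ccf for o in group)
            floors = (ev.ccf >= sum_floor) & np.all([o.ccf >= sum_floor for o in group], axis=0)
            det |= (total > threshold) & floors
        ev.detectable_regions = det


def _draw_truncated_normal(mean, sd, floor, rng):
    while True:
        x = rng.normal(mean, sd)
        if x > floor:
            return x


def simulate_tumour(config: SimConfig, tumour_id: str, rng: np.random.Generator) -> SimulatedTumour:
    """Simulate one tumour (no cohort constraints applied)."""
    group = config.sample_group
    if group == "mixed":
        group = rng.choice(["low", "medium", "high"], p=np.asarray(config.group_weights) / sum(config.group_weights))
    if config.n_clones_range is not None:
        lo, hi = config.n_clones_range
        n_clones = int(rng.integers(lo, hi + 1))
    else:
        n_clones = draw_n_clones(group, rng)
    topo = simulate_topology(n_clones, rng)

    n_snvs = int(rng.negative_binomial(config.snv_shape, config.snv_shape / (config.snv_shape + config.snv_mean)))
    truncal_fraction = float(rng.uniform(*config.truncal_fraction_range))

    edges = topo.edges()
    gains = {e: (rng.poisson(config.trunk_gain_rate) if e[1] == topo.mrca else rng.poisson(config.edge_gain_rate)) for e in edges}
    losses = {e: (rng.poisson(config.trunk_loss_rate) if e[1] == topo.mrca else rng.poisson(config.edge_loss_rate)) for e in edges}

    # WGD placement: random clones, but no lineage accumulates more than
    # two doublings (matching the 0/1/2 per-region WGD states that
    # major-copy-number ploidy logic can express)
    wgd_edges: list[tuple[int, int]] = []
    if rng.random() < config.p_truncal_wgd:
        wgd_edges.append((topo.germline_root, topo.mrca))
    probs = np.asarray(config.subclonal_wgd_probs) / sum(config.subclonal_wgd_probs)
    n_sub_wgd = int(rng.choice(len(probs), p=probs))

    def lineage_depth(clone: int, chosen: list[tuple[int, int]]) -> int:
        path = {clone, *topo.ancestors(clone)}
        return sum(e[1] in path for e in chosen)

    sub_edges = topo.subclonal_edges()
    for _ in range(n_sub_wgd):
        allowed = [
            e for e in sub_edges
            if e not in wgd_edges
            and max(lineage_depth(c, wgd_edges + [e]) for c in topo.subtree(e[1])) <= config.max_wgd_per_lineage
        ]
        if not allowed:
            break
        wgd_edges.append(allowed[int(rng.integers(len(allowed)))])

    events = assign_events(
        topo, n_snvs, truncal_fraction, rng,
        n_arms=config.n_arms, gains_per_edge=gains, losses_per_edge=losses,
        wgd_edges=wgd_edges, gain_magnitudes=rng,
    )
    layout = GenomeLayout.place_loci(n_snvs, rng, n_arms=config.n_arms)
    geno = propagate_genotypes(topo, events, layout)

    group_sr = config.n_samples_range or SAMPLE_RANGES[group]
    n_samples = int(rng.integers(group_sr[0], group_sr[1] + 1))
    purity = rng.uniform(*config.purity_range, size=n_samples)
    coverage = np.array([
        _draw_truncated_normal(config.coverage_mean, config.coverage_sd, config.coverage_floor, rng)
        for _ in range(n_samples)
    ])
    samples = sample_bulk(topo, n_samples, purity, coverage, rng)
    for s in samples:
        compute_sample_state(s, geno)
    reads = generate_reads(samples, geno, rng)
    reads, artefact_arms = inject_artefacts(reads, samples, geno, topo, config.n_artefacts, rng)
    if config.n_artefacts:
        layout = GenomeLayout(
            n_arms=layout.n_arms,
            arm_of=np.concatenate([layout.arm_of, artefact_arms]),
            pos=np.concatenate([layout.pos, rng.integers(0, 49_999_999, size=config.n_artefacts)]),
        )
        # genotypes keep z over the real loci only; artefacts have no true z

    mutation_clone = np.full(layout.n_loci, -1, dtype=int)
    for ev in events:
        if ev.kind == "SNV":
            mutation_clone[ev.locus] = ev.edge[1]

    tum = SimulatedTumour(
        tumour_id=tumour_id,
        config=config,
        sample_group=str(group),
        topology=topo,
        layout=layout,
        events=events,
        genotypes=geno,
        samples=samples,
        reads=reads,
        wgd_truth=[],
        truncal_fraction=truncal_fraction,
        mutation_clone=mutation_clone,
    )
    for i, edge in enumerate(wgd_edges):
        ccf = tum.clone_ccf(edge[1]) if edge[1] != topo.mrca else np.ones(n_samples)
        tum.wgd_truth.append(WGDTruthEvent(event_id=i, edge=edge, truncal=edge[1] == topo.mrca, ccf=ccf))
    mark_detectable(tum)
    return tum


def simulate_cohort(
    config: SimConfig,
    n_tumours: int,
    seed: int | np.random.Generator,
    max_attempts_factor: int = 100,
) -> list[SimulatedTumour]:
    """Simulate tumours satisfying the cohort inclusion constraints."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[SimulatedTumour] = []
    attempts = 0
    limit = max(10_000, max_attempts_factor * n_tumours)
    while len(out) < n_tumours:
        attempts += 1
        if attempts > limit and len(out) < 0.01 * attempts:
            raise RuntimeError("cohort acceptance rate below 1%; check the configuration")
        tum = simulate_tumour(config, f"SIM{len(out) + 1:04d}", rng)
        n_snvs = int((tum.mutation_clone >= 0).sum())
        if n_snvs <= config.min_snvs:
            continue
        if any(s.purity <= config.min_purity for s in tum.samples):
            continue
        n_truncal = int((tum.mutation_clone == tum.topology.mrca).sum())
        if n_truncal / n_snvs >= config.max_truncal_prop:
            continue
        out.append(tum)
    return out
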