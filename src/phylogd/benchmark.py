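"""Simulation benchmark of multiple-subclonal-WGD detection.

Simulates a cohort, derives ground-truth detectable WGD events (regional
CCF > 0.75, or parallel events whose regional CCF sum exceeds 0.75), and
scores three detectors on the task "does this tumour carry two or more
detectable subclonal WGD events":

* ``parallelgd`` -- the doubled-cluster detector of :mod:`phylogd.wgd`,
  fed the per-region ground-truth-detectable WGD counts, the true mutation
  cluster identities, per-mutation mutation copy numbers and major
  copy-number states (mirroring the published validation protocol);
* ``nejm`` -- subclonal WGD called when some but not all regions harbour
  a WGD; it can never call two events;
* ``nejm2`` -- number of subclonal events = number of distinct
  non-minimum per-region WGD-count levels (detects a second event only
  when 0, 1 and 2 WGD states co-occur).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clonality import estimate_mutation_copy_number
from .cohort import SimConfig, SimulatedTumour, simulate_cohort
from .wgd import QUADRUPLED_MUTCN, GDClusterFlag, doubled_fraction, flag_gd_clusters, infer_wgd_events

POSITIVE_MIN_EVENTS = 2


def baseline_nejm(region_counts: np.ndarray) -> bool:
    """Subclonal WGD iff some but not all regions harbour a WGD."""
    counts = np.asarray(region_counts)
    present = counts > 0
    return bool(present.any() and not present.all())


def baseline_nejm2(region_counts: np.ndarray) -> int:
    """Number of subclonal events = distinct non-minimum WGD-count levels."""
    counts = np.asarray(region_counts)
    levels = np.unique(counts)
    return int(len(levels) - 1)


@dataclass
class TumourCalls:
    tumour_id: str
    truth_positive: bool
    n_detectable_subclonal: int
    parallelgd: int
    nejm: int
    nejm2: int


def detector_inputs(tumour: SimulatedTumour, noiseless: bool = False):
    """Assemble the validation inputs for the doubled-cluster detector.

    Returns (cluster ids per mutation, mutCN [mutations x regions], major
    CN per mutation x region, per-region detectable WGD counts, trunk
    cluster id, ancestor map).  Mutation copy numbers are estimated from
    the simulated reads (true purity, rounded bulk copy numbers) unless
    ``noiseless``, in which case the exact sum(u z) is used.
    """
    topo = tumour.topology
    real = tumour.mutation_clone >= 0
    clusters = tumour.mutation_clone[real]
    arm_of = tumour.layout.arm_of[real]
    major_arm = tumour.bulk_major_cn()          # arms x regions
    major = major_arm[arm_of, :]                # mutations x regions
    if noiseless:
        mutcn = tumour.exact_mutation_cn()[real, :]
    else:
        mutcn = np.zeros((int(real.sum()), tumour.n_samples))
        v = tumour.reads.v[real, :]
        t = tumour.reads.t[real, :]
        for j, s in enumerate(tumour.samples):
            xb = np.zeros(tumour.layout.n_arms)
            yb = np.zeros(tumour.layout.n_arms)
            for clone, u in zip(s.clone_ids, s.proportions):
                xb += u * tumour.genotypes.x[clone]
                yb += u * tumour.genotypes.y[clone]
            local_cn = (np.rint(xb) + np.rint(yb))[arm_of]
            mutcn[:, j] = estimate_mutation_copy_number(v[:, j], t[:, j], s.purity, local_cn)
    counts = tumour.region_wgd_counts()
    ancestors = {c: set(topo.ancestors(c)) for c in topo.clones}
    return clusters, mutcn, major, counts, topo.mrca, ancestors


def run_parallelgd(tumour: SimulatedTumour, noiseless: bool = False) -> int:
    """Number of subclonal WGD events called for one tumour."""
    clusters, mutcn, major, counts, trunk, ancestors = detector_inputs(tumour, noiseless)
    fractions: dict[int, np.ndarray] = {}
    n_eligible: dict[int, np.ndarray] = {}
    quad: dict[int, np.ndarray] = {}
    for cid in np.unique(clusters):
        members = clusters == cid
        f = np.empty(tumour.n_samples)
        q = np.empty(tumour.n_samples)
        ne = np.empty(tumour.n_samples, dtype=int)
        for j in range(tumour.n_samples):
            f[j], ne[j] = doubled_fraction(mutcn[members, j], major[members, j], counts[j])
            q[j], _ = doubled_fraction(
                mutcn[members, j], major[members, j], counts[j],
                threshold=QUADRUPLED_MUTCN,
            )
        fractions[int(cid)] = f
        n_eligible[int(cid)] = ne
        quad[int(cid)] = q
    flags = flag_gd_clusters(fractions, n_eligible, quad)
    es = infer_wgd_events(flags, counts, trunk_cluster=trunk, ancestors_of=ancestors)
    return es.n_subclonal


def evaluate(calls: list[TumourCalls]) -> pd.DataFrame:
    """Sensitivity/specificity per method for the >= 2-event task."""
    rows = []
    for method in ("parallelgd", "nejm", "nejm2"):
        tp = fn = tn = fp = 0
        for c in calls:
            pred = getattr(c, method) >= POSITIVE_MIN_EVENTS
            if c.truth_positive:
                tp += pred
                fn += not pred
            else:
                fp += pred
                tn += not pred
        rows.append(
            dict(
                method=method,
                sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
                specificity=tn / (tn + fp) if tn + fp else float("nan"),
                tp=tp, fn=fn, tn=tn, fp=fp, n_tumours=len(calls),
            )
        )
    return pd.DataFrame(rows)


#: validation cohort: every tumour receives one to three subclonal WGD
#: events on random clones (the detection task is pointless on tumours
#: simulated without any)
BENCHMARK_WGD_PROBS = (0.0, 1 / 3, 1 / 3, 1 / 3)


def run_benchmark(
    config: SimConfig | None = None,
    n_tumours: int = 500,
    seed: int = 42,
    noiseless: bool = False,
) -> tuple[pd.DataFrame, list[TumourCalls]]:
    """End-to-end benchmark; returns (summary table, per-tumour audit)."""
    config = config or SimConfig(subclonal_wgd_probs=BENCHMARK_WGD_PROBS)
    cohort = simulate_cohort(config, n_tumours, seed)
    calls = []
    for tum in cohort:
        # the baselines consume per-region WGD states as a ploidy caller
        # would determine them from the major copy number
        counts = tum.region_wgd_state_counts()
        calls.append(
            TumourCalls(
                tumour_id=tum.tumour_id,
                truth_positive=tum.n_detectable_subclonal() >= POSITIVE_MIN_EVENTS,
                n_detectable_subclonal=tum.n_detectable_subclonal(),
                parallelgd=run_parallelgd(tum, noiseless),
                nejm=1 if baseline_nejm(counts) else 0,
                nejm2=baseline_nejm2(counts),
            )
        )
    return evaluate(calls), calls
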