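"""Simulation-based validation of clustering and tree reconstruction.

Generates tumours whose true clusters are mutually separated in PhyloCCF
space (a minimum max-norm gap between every pair of detectable clusters),
runs the full reconstruction pipeline on the simulated reads, and scores

* the adjusted Rand index between true and inferred mutation clusters;
* whether the true clone tree (restricted to detectable clones) appears
  among the enumerated candidate trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cohort import SimConfig, SimulatedTumour, simulate_tumour
from .pipeline import TumourReconstruction, reconstruct

#: conditions of the clustering/tree recovery study: 4-5 regions at 400x,
#: copy-number-quiet evolution (no WGD; doubling-induced multiplicity
#: scatter is the WGD detector's problem, validated separately), and
#: burdens that give every subclone a cluster of recoverable size
RECOVERY_CONFIG = SimConfig(
    sample_group="medium",
    n_clones_range=(5, 9),
    n_samples_range=(4, 5),
    coverage_sd=0.0,
    coverage_mean=400.0,
    purity_range=(0.5, 0.9),
    snv_mean=600.0,
    truncal_fraction_range=(0.35, 0.75),
    p_truncal_wgd=0.0,
    subclonal_wgd_probs=(1.0, 0.0, 0.0, 0.0),
    n_artefacts=0,
)

MIN_CLUSTER_MUTATIONS = 10  # smaller true clusters are not recoverable targets


def true_clusters(
    tumour: SimulatedTumour,
    min_ccf: float = 0.0,
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """True clusters (clone -> regional CCF) and per-mutation labels.

    Every clone carrying at least one mutation (and exceeding ``min_ccf``
    somewhere, when set) forms a cluster; other mutations (artefacts) get
    label -1.
    """
    ccf = {}
    for clone in tumour.topology.clones:
        if not np.any(tumour.mutation_clone == clone):
            continue
        vec = tumour.clone_ccf(clone)
        if vec.max() >= min_ccf:
            ccf[clone] = vec
    labels = np.array([
        c if c in ccf else -1 for c in tumour.mutation_clone
    ])
    return ccf, labels


def has_min_gap(ccf: dict[int, np.ndarray], gap: float) -> bool:
    keys = sorted(ccf)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            if np.max(np.abs(ccf[a] - ccf[b])) < gap:
                return False
    return True


def pipeline_inputs(tumour: SimulatedTumour):
    """Reconstruction inputs (var, tot, purity, local CN, major CN, segment ids)."""
    var = tumour.reads.v
    tot = tumour.reads.t
    purity = np.array([s.purity for s in tumour.samples])
    n_arms = tumour.layout.n_arms
    local = np.zeros((tumour.layout.n_loci, tumour.n_samples))
    major = np.zeros_like(local)
    for j, s in enumerate(tumour.samples):
        xb = np.zeros(n_arms)
        yb = np.zeros(n_arms)
        for clone, u in zip(s.clone_ids, s.proportions):
            xb += u * tumour.genotypes.x[clone]
            yb += u * tumour.genotypes.y[clone]
        a = np.rint(xb)[tumour.layout.arm_of[:tumour.layout.n_loci]]
        b = np.rint(yb)[tumour.layout.arm_of[:tumour.layout.n_loci]]
        local[:, j] = a + b
        major[:, j] = np.maximum(a, b)
    return var, tot, purity, local, major, np.asarray(tumour.layout.arm_of)


def project_true_tree(
    tumour: SimulatedTumour, detectable: set[int]
) -> dict[int, int]:
    """True parent map restricted to detectable clones.

    Each detectable clone's parent is its nearest detectable ancestor; the
    MRCA acts as the trunk (it is detectable by construction).
    """
    topo = tumour.topology
    parent = {}
    for clone in detectable:
        if clone == topo.mrca:
            continue
        for anc in topo.ancestors(clone):
            if anc in detectable:
                parent[clone] = anc
                break
    return parent


def match_clusters(
    rec: TumourReconstruction, true_labels: np.ndarray
) -> dict[int, int] | None:
    """Inferred-cluster -> true-clone map by majority membership.

    Several inferred clusters may map to the same clone (presence-pattern
    pre-grouping can split one subclone across groups); tree comparison
    contracts them.
    """
    mapping = {}
    for cid, cl in rec.clusters.items():
        if cl.removed:
            continue
        members = true_labels[cl.members]
        members = members[members >= 0]
        if len(members) == 0:
            return None
        vals, counts = np.unique(members, return_counts=True)
        mapping[cid] = int(vals[np.argmax(counts)])
    return mapping


def contract_tree(
    parent_of: dict[int, int], trunk: int, mapping: dict[int, int]
) -> dict[int, int] | None:
    """Collapse a cluster tree onto true-clone labels.

    Edges between clusters with the same mapped label contract away; the
    result is the parent map over labels, or None when two clusters with
    one label end up with conflicting parents (the tree does not collapse
    cleanly onto the true clones).
    """
    out: dict[int, int] = {}
    for node in parent_of:
        lab = mapping[node]
        anc = parent_of[node]
        while anc != trunk and mapping[anc] == lab:
            anc = parent_of[anc]
        if mapping[anc] == lab:
            continue
        plab = mapping[anc]
        if lab in out and out[lab] != plab:
            return None
        out[lab] = plab
    return out


def evaluate_tumour(tumour: SimulatedTumour, seed: int = 0) -> dict:
    """Run reconstruction on one tumour and score recovery."""
    ccf_true, true_labels = true_clusters(tumour)
    var, tot, purity, local, major, seg = pipeline_inputs(tumour)
    rec = reconstruct(var, tot, purity, local, major, segment_of_mutation=seg, seed=seed)

    both = (true_labels >= 0) & rec.retained
    ari = adjusted_rand_score(true_labels[both], rec.labels[both]) if both.sum() > 1 else np.nan

    true_tree_found = False
    mapping = match_clusters(rec, true_labels)
    if mapping is not None and set(mapping.values()) == set(ccf_true):
        true_parent = project_true_tree(tumour, set(ccf_true))
        for pm in [rec.tree.parent_of] + rec.tree.alternatives:
            translated = contract_tree(pm, rec.trunk, mapping)
            if translated == true_parent:
                true_tree_found = True
                break
    return {
        "tumour_id": tumour.tumour_id,
        "n_true_clusters": len(ccf_true),
        "n_inferred": sum(1 for c in rec.clusters.values() if not c.removed),
        "ari": ari,
        "true_tree_found": true_tree_found,
    }


def run_recovery(
    n_tumours: int = 50,
    seed: int = 0,
    config: SimConfig = RECOVERY_CONFIG,
    gap: float = 0.2,
    max_attempts: int = 10_000,
) -> pd.DataFrame:
    """Recovery study over gap-separated simulated tumours."""
    rng = np.random.default_rng(seed)
    rows = []
    attempts = 0
    while len(rows) < n_tumours and attempts < max_attempts:
        attempts += 1
        tum = simulate_tumour(config, f"REC{len(rows) + 1:03d}", rng)
        if tum.n_samples < 4:
            continue
        ccf_true, _ = true_clusters(tum)
        if len(ccf_true) < 2 or not has_min_gap(ccf_true, gap):
            continue
        sizes = {c: int((tum.mutation_clone == c).sum()) for c in ccf_true}
        if min(sizes.values()) < MIN_CLUSTER_MUTATIONS:
            continue
        rows.append(evaluate_tumour(tum, seed=seed))
    return pd.DataFrame(rows)
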