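"""Multi-region reconstruction pipeline.

From per-mutation read counts, purity and local copy number to: PhyloCCF
per mutation, presence-pattern pre-grouping, within-group clustering,
cluster clonality classification, spurious-cluster removal, and clone-tree
reconstruction with alternative-tree enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import clonality, clustering, tree as treemod


@dataclass
class TumourReconstruction:
    labels: np.ndarray                       # cluster id per retained mutation (-1 dropped)
    retained: np.ndarray                     # boolean mask over input mutations
    ccf_mutation: np.ndarray                 # mutations x regions PhyloCCF
    mutcn: np.ndarray                        # mutations x regions mutation copy number
    clusters: dict[int, clustering.MutationCluster] = field(default_factory=dict)
    trunk: int | None = None
    tree: treemod.CloneTree | None = None

    @property
    def cluster_ccf(self) -> dict[int, np.ndarray]:
        return {cid: cl.ccf for cid, cl in self.clusters.items() if not cl.removed}

    def counts(self) -> tuple[int, int]:
        """(n_truncal, n_subclonal) mutations on the reconstructed tree."""
        n_truncal = n_subclonal = 0
        for cid, cl in self.clusters.items():
            if cl.removed:
                continue
            size = int((self.labels == cid).sum())
            if cid == self.trunk:
                n_truncal += size
            else:
                n_subclonal += size
        return n_truncal, n_subclonal


def reconstruct(
    var: np.ndarray,
    tot: np.ndarray,
    purity: np.ndarray,
    local_cn: np.ndarray,
    major_cn: np.ndarray,
    segment_of_mutation: np.ndarray | None = None,
    seed: int = 0,
    tol: float = treemod.TOLERANCE,
    enum_cap: int = treemod.ENUM_CAP,
) -> TumourReconstruction:
    """Run the full reconstruction for one tumour.

    ``var``/``tot``/``local_cn``/``major_cn`` are mutations x regions;
    ``purity`` is per region.  Mutations with no variant read anywhere are
    dropped before clustering.
    """
    var = np.asarray(var)
    tot = np.asarray(tot)
    n_mut, n_reg = var.shape
    rng = np.random.default_rng(seed)

    ccf = np.zeros((n_mut, n_reg))
    mutcn = np.zeros((n_mut, n_reg))
    for j in range(n_reg):
        ccf[:, j], mutcn[:, j] = clonality.phyloccf_per_mutation(
            var[:, j], tot[:, j], float(purity[j]), local_cn[:, j], major_cn[:, j]
        )
    ccf = np.nan_to_num(ccf, nan=0.0)

    detected = (var >= 1).any(axis=1)
    labels = np.full(n_mut, -1, dtype=int)

    groups = clustering.precluster_by_presence(var[detected])
    det_idx = np.where(detected)[0]
    next_id = 0
    small: list[np.ndarray] = []
    for g in groups:
        idx = det_idx[g.members]
        if not g.clusterable:
            small.append(idx)
            continue
        sub = clustering.cluster_group(ccf[idx], seed=seed)
        labels[idx] = sub + next_id
        next_id += int(sub.max()) + 1
    if next_id == 0 and small:
        # nothing clusterable: pool everything into one cluster
        pooled = np.concatenate(small)
        labels[pooled] = 0
        next_id, small = 1, []

    centroids = {cid: ccf[labels == cid].mean(axis=0) for cid in range(next_id)}
    for idx in small:
        labels[idx] = clustering.assign_small_groups(ccf[idx], centroids)

    clusters: dict[int, clustering.MutationCluster] = {}
    for cid in range(next_id):
        members = np.where(labels == cid)[0]
        stats = [clonality.cluster_stat(ccf[members, j], rng=rng) for j in range(n_reg)]
        clusters[cid] = clustering.MutationCluster(
            cluster_id=cid,
            members=members,
            ccf=np.array([s.mean for s in stats]),
            ci=np.array([[s.ci_lo, s.ci_hi] for s in stats]),
        )

    # trunk: the dominant cluster (largest worst-region PhyloCCF)
    trunk = max(clusters, key=lambda c: (clusters[c].ccf.min(), clusters[c].ccf.sum()))

    def classify_all():
        for cid, cl in clusters.items():
            statuses = []
            for j in range(n_reg):
                statuses.append(
                    clonality.classify_region_clonality(
                        ccf[cl.members, j],
                        ccf[clusters[trunk].members, j],
                        cluster_ci=tuple(cl.ci[j]),
                        truncal_ci=tuple(clusters[trunk].ci[j]),
                    )
                )
            cl.region_status = statuses
            cl.tumour_status, cl.illusion = clonality.tumour_level_clonality(statuses)

    classify_all()

    # clusters clonal in every region sit at the trunk node by definition:
    # fold them into the truncal cluster (multiplicity rounding scatters
    # truncal mutations into satellites around PhyloCCF 1)
    satellites = [
        cid for cid, cl in clusters.items()
        if cid != trunk and cl.tumour_status == "truncal"
    ]
    if satellites:
        merged = np.concatenate([clusters[trunk].members] + [clusters[c].members for c in satellites])
        labels[merged] = trunk
        for c in satellites:
            del clusters[c]
        stats = [clonality.cluster_stat(ccf[merged, j], rng=rng) for j in range(n_reg)]
        clusters[trunk] = clustering.MutationCluster(
            cluster_id=trunk,
            members=np.sort(merged),
            ccf=np.array([s.mean for s in stats]),
            ci=np.array([[s.ci_lo, s.ci_hi] for s in stats]),
        )
        classify_all()

    if segment_of_mutation is not None:
        clustering.flag_colocalized(list(clusters.values()), segment_of_mutation, trunk_id=trunk)

    def active_ccf():
        return {cid: cl.ccf for cid, cl in clusters.items() if not cl.removed}

    ctree = treemod.build_clone_tree(active_ccf(), trunk, tol=tol, cap=enum_cap)
    if ctree is None:
        sizes = {cid: len(cl.members) for cid, cl in clusters.items() if not cl.removed}
        removed = treemod.remove_for_feasibility(active_ccf(), sizes, trunk, tol=tol)
        for cid in removed:
            clusters[cid].removed = True
            clusters[cid].removal_reason = "tree-infeasible"
        ctree = treemod.build_clone_tree(active_ccf(), trunk, tol=tol, cap=enum_cap)
        if ctree is None:
            raise RuntimeError("no clone tree satisfies the rules even after removals")

    for cid, cl in clusters.items():
        if cl.removed:
            labels[cl.members] = -1

    return TumourReconstruction(
        labels=labels,
        retained=labels >= 0,
        ccf_mutation=ccf,
        mutcn=mutcn,
        clusters=clusters,
        trunk=trunk,
        tree=ctree,
    )
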