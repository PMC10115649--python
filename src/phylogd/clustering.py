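"""Presence/absence pre-grouping and PhyloCCF clustering.

Mutations are first partitioned by their exact presence pattern across
regions (present = at least one mutant read).  Groups of fewer than five
mutations are not clustered; their members are assigned post hoc to the
nearest existing cluster by PhyloCCF distance.  Within each clusterable
group, mutations are clustered on their multi-region PhyloCCF vectors
with a Gaussian mixture (diagonal covariance) selected by BIC under the
cluster-count cap: 10 clusters for groups of >= 50 mutations, otherwise
floor(n / 5) (so a 23-mutation group is capped at 4 clusters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

MIN_GROUP_SIZE = 5
LARGE_GROUP = 50
LARGE_GROUP_CAP = 10
COLOC_FRACTION = 0.5


@dataclass
class PresenceGroup:
    pattern: tuple[bool, ...]
    members: np.ndarray  # mutation indices
    clusterable: bool


@dataclass
class MutationCluster:
    cluster_id: int
    members: np.ndarray
    ccf: np.ndarray | None = None          # per-region mean PhyloCCF
    ci: np.ndarray | None = None           # per-region (lo, hi)
    removed: bool = False
    removal_reason: str = "none"
    region_status: list[str] = field(default_factory=list)
    tumour_status: str = ""
    illusion: bool = False


def cluster_cap(n: int) -> int:
    """Maximum cluster count for a presence group of size ``n``."""
    return LARGE_GROUP_CAP if n >= LARGE_GROUP else n // MIN_GROUP_SIZE


def precluster_by_presence(var_counts: np.ndarray) -> list[PresenceGroup]:
    """Partition mutations by exact presence pattern over regions."""
    var_counts = np.asarray(var_counts)
    if var_counts.ndim != 2 or var_counts.shape[1] < 2:
        raise ValueError("need a mutations x regions matrix with >= 2 regions")
    present = var_counts >= 1
    groups: dict[tuple[bool, ...], list[int]] = {}
    for i, row in enumerate(present):
        groups.setdefault(tuple(bool(b) for b in row), []).append(i)
    return [
        PresenceGroup(pattern=pat, members=np.asarray(idx), clusterable=len(idx) >= MIN_GROUP_SIZE)
        for pat, idx in sorted(groups.items(), reverse=True)
    ]


def cluster_group(
    ccf: np.ndarray,
    seed: int = 0,
    cap: int | None = None,
) -> np.ndarray:
    """Cluster one group's PhyloCCF vectors; returns labels 0..k-1.

    Model selection minimises BIC over k = 1..cap.  This is a deterministic
    stand-in for a Dirichlet-process sampler; the pre-grouping and the
    cluster-count caps are applied unchanged.
    """
    X = np.nan_to_num(np.asarray(ccf, dtype=float), nan=0.0)
    n = len(X)
    if cap is None:
        cap = cluster_cap(n)
    cap = max(1, min(cap, n))
    if cap == 1 or np.allclose(X, X[0]):
        return np.zeros(n, dtype=int)
    best_labels, best_bic = np.zeros(n, dtype=int), np.inf
    for k in range(1, cap + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="diag", reg_covar=1e-4,
            random_state=seed, n_init=3, max_iter=300,
        )
        labels = gm.fit_predict(X)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best_bic, best_labels = bic, labels
    # relabel compactly in order of appearance
    _, labels = np.unique(best_labels, return_inverse=True)
    return labels


def assign_small_groups(
    small_ccf: np.ndarray,
    cluster_ccf: dict[int, np.ndarray],
) -> np.ndarray:
    """Assign unclustered mutations to the nearest cluster centroid."""
    ids = sorted(cluster_ccf)
    cents = np.vstack([np.nan_to_num(cluster_ccf[i], nan=0.0) for i in ids])
    X = np.nan_to_num(np.asarray(small_ccf, dtype=float), nan=0.0)
    d = np.linalg.norm(X[:, None, :] - cents[None, :, :], axis=2)
    return np.asarray(ids)[np.argmin(d, axis=1)]


def flag_colocalized(
    clusters: list[MutationCluster],
    segment_of_mutation: np.ndarray,
    trunk_id: int | None = None,
) -> None:
    """Flag clusters whose members pile onto a single copy-number segment.

    Mutations co-localised in the genome indicate clusters driven by
    errors in copy-number calling rather than real subclones: a cluster of
    >= 5 mutations with more than half its members on one segment is
    flagged (the trunk is never flagged).
    """
    for cl in clusters:
        if cl.cluster_id == trunk_id or len(cl.members) < MIN_GROUP_SIZE:
            continue
        segs = np.asarray(segment_of_mutation)[cl.members]
        _, counts = np.unique(segs, return_counts=True)
        if counts.max() > COLOC_FRACTION * len(cl.members):
            cl.removed = True
            cl.removal_reason = "colocalized"
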