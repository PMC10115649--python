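"""Tumour-level heterogeneity and expansion metrics.

* mutational ITH: subclonal / (truncal + subclonal) mutations after tree
  building (removed mutations excluded);
* SCNA ITH: length fraction of the aberrant genome whose aberrations are
  not shared by every region;
* wGII: per-chromosome-weighted fraction of the genome with copy number
  aberrant relative to sample ploidy;
* FLOH: length fraction of the genome with minor copy number 0;
* recent subclonal expansion score: max over regions of the largest
  leaf-cluster PhyloCCF (each leaf clipped to [0, 1] first), with a
  conservative minimum over alternative trees;
* SBS4 smoking-signature detection classifier on truncal signature weight
  and mutation count.
"""

from __future__ import annotations

import numpy as np

from .tree import CloneTree


def mutational_ith(n_subclonal: int, n_truncal: int) -> float:
    total = n_subclonal + n_truncal
    if total == 0:
        return float("nan")
    return n_subclonal / total


def scna_ith(aberrant: np.ndarray, heterogeneous: np.ndarray, lengths: np.ndarray) -> float:
    """Fraction of the aberrant genome with region-discordant SCNAs.

    ``aberrant`` marks segments aberrant in at least one region,
    ``heterogeneous`` those not aberrant identically in every region.
    """
    aberrant = np.asarray(aberrant, dtype=bool)
    heterogeneous = np.asarray(heterogeneous, dtype=bool)
    lengths = np.asarray(lengths, dtype=float)
    denom = lengths[aberrant].sum()
    if denom == 0:
        return float("nan")
    return float(lengths[heterogeneous & aberrant].sum() / denom)


def segment_states(total_cn: np.ndarray, ploidy: float) -> np.ndarray:
    """Call loss/neutral/gain/amp per segment relative to sample ploidy.

    Integer-copy-number analogues of the log-ratio thresholds
    log2(1.5/2) (loss) and log2(2.5/2) (gain) scaled by ploidy/2, with
    amplification beyond twice the ploidy.
    """
    cn = np.asarray(total_cn, dtype=float)
    states = np.full(cn.shape, "neutral", dtype=object)
    states[cn < 1.5 * ploidy / 2] = "loss"
    states[cn > 2.5 * ploidy / 2] = "gain"
    states[cn > 2 * ploidy] = "amp"
    return states


def wgii(total_cn: np.ndarray, lengths: np.ndarray, chroms: np.ndarray, ploidy: float) -> float:
    """Weighted genome instability index for one region."""
    states = segment_states(total_cn, ploidy)
    aberrant = states != "neutral"
    lengths = np.asarray(lengths, dtype=float)
    chroms = np.asarray(chroms)
    fracs = []
    for c in np.unique(chroms):
        on = chroms == c
        fracs.append(lengths[on & aberrant].sum() / lengths[on].sum())
    return float(np.mean(fracs))


def floh(minor_cn: np.ndarray, lengths: np.ndarray) -> float:
    """Length fraction of the genome subject to LOH (minor CN = 0)."""
    minor_cn = np.asarray(minor_cn)
    lengths = np.asarray(lengths, dtype=float)
    return float(lengths[minor_cn == 0].sum() / lengths.sum())


def recent_expansion_score(
    tree: CloneTree,
    ccf: dict[int, np.ndarray],
) -> tuple[float, float]:
    """(score on the default tree, minimum over alternative trees)."""

    def score_of(parent_of: dict[int, int]) -> float:
        t = CloneTree(parent_of=parent_of, trunk=tree.trunk)
        leaf_ccf = [np.clip(np.nan_to_num(ccf[leaf]), 0.0, 1.0) for leaf in t.leaves()]
        return float(np.max(np.vstack(leaf_ccf)))

    default = score_of(tree.parent_of)
    alt = min((score_of(pm) for pm in tree.alternatives), default=default)
    return default, min(default, alt)


def classify_sbs4(truncal_weight: float, truncal_count: int) -> str:
    """Three-tier smoking-signature (SBS4) detection status.

    Undetected: truncal weight < 0.1 and < 50 truncal assigned mutations;
    high confidence: weight > 0.3 and > 20 mutations; otherwise low
    confidence.
    """
    if not 0 <= truncal_weight <= 1:
        raise ValueError("truncal_weight must be in [0, 1]")
    if truncal_weight < 0.1 and truncal_count < 50:
        return "undetected"
    if truncal_weight > 0.3 and truncal_count > 20:
        return "high_confidence"
    return "low_confidence"
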