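"""Mutation copy number, PhyloCCF, and clonality classification.

The phylogenetic cancer cell fraction (PhyloCCF) of a mutation is the
fraction of cancer cells that carry it, or are estimated to have carried
it before a subclonal loss of the mutant allele.  It is obtained by
transforming the variant allele fraction (VAF) by tumour purity and local
copy number:

    mutCN = (VAF / mu) * (mu * CN_t + 2 * (1 - mu))
    PhyloCCF = mutCN / multiplicity,   multiplicity = round(mutCN) clipped
               to [1, major CN]

Cluster-level PhyloCCF is the mean over member mutations, with a
nonparametric bootstrap percentile interval.  A cluster is *clonal* in a
region when its members are statistically indistinguishable from the
truncal cluster there (one-sided Wilcoxon rank-sum, P = 0.05) or when the
95% CIs overlap (the truncal lower bound floored at 0.9); *subclonal* when
present but not clonal; *absent* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

CCF_CLIP = 1.5
PRESENT_EPS = 0.01  # "mean PhyloCCF > 0" with floating-point slack
TRUNCAL_CI_FLOOR = 0.9
WILCOXON_ALPHA = 0.05


def estimate_mutation_copy_number(
    var: np.ndarray,
    tot: np.ndarray,
    purity: float,
    local_cn: np.ndarray,
) -> np.ndarray:
    """Mutation copy number from read counts; NaN where coverage is zero."""
    var = np.asarray(var, dtype=float)
    tot = np.asarray(tot, dtype=float)
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(tot > 0, var / tot, np.nan)
    return (vaf / purity) * (purity * np.asarray(local_cn, dtype=float) + 2.0 * (1.0 - purity))


def multiplicity_estimate(mutcn: np.ndarray, major_cn: np.ndarray) -> np.ndarray:
    """Nearest positive integer multiplicity, capped at the major CN.

    Full ancestral-loss reconstruction is out of scope; capping at the
    regional major copy number absorbs the common subclonal-loss cases.
    """
    m = np.rint(np.asarray(mutcn, dtype=float))
    cap = np.maximum(np.asarray(major_cn, dtype=float), 1.0)
    return np.clip(m, 1.0, cap)


def phyloccf_per_mutation(
    var: np.ndarray,
    tot: np.ndarray,
    purity: float,
    local_cn: np.ndarray,
    major_cn: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(PhyloCCF, mutCN) per mutation for one region."""
    mutcn = estimate_mutation_copy_number(var, tot, purity, local_cn)
    mult = multiplicity_estimate(mutcn, major_cn)
    ccf = np.clip(mutcn / mult, 0.0, CCF_CLIP)
    return ccf, mutcn


@dataclass
class ClusterRegionStat:
    mean: float
    ci_lo: float
    ci_hi: float
    n: int


def cluster_stat(
    member_ccf: np.ndarray,
    rng: np.random.Generator | None = None,
    n_boot: int = 1000,
) -> ClusterRegionStat:
    """Mean PhyloCCF with a bootstrap percentile 95% CI over members."""
    vals = np.asarray(member_ccf, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return ClusterRegionStat(np.nan, np.nan, np.nan, 0)
    mean = float(vals.mean())
    if len(vals) == 1:
        return ClusterRegionStat(mean, mean, mean, 1)
    rng = rng or np.random.default_rng(0)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    boots = vals[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ClusterRegionStat(mean, float(lo), float(hi), len(vals))


def classify_region_clonality(
    cluster_ccf: np.ndarray,
    truncal_ccf: np.ndarray,
    cluster_ci: tuple[float, float] | None = None,
    truncal_ci: tuple[float, float] | None = None,
) -> str:
    """Classify one cluster in one region as clonal / subclonal / absent."""
    truncal_ccf = np.asarray(truncal_ccf, dtype=float)
    truncal_ccf = truncal_ccf[~np.isnan(truncal_ccf)]
    if len(truncal_ccf) == 0:
        raise ValueError("empty truncal cluster")
    vals = np.asarray(cluster_ccf, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return "absent"
    # clonal test 1: members not significantly below the truncal members
    if np.array_equal(vals, truncal_ccf):
        return "clonal"
    p = stats.mannwhitneyu(vals, truncal_ccf, alternative="less").pvalue
    if p > WILCOXON_ALPHA:
        return "clonal"
    # clonal test 2: CI overlap, truncal lower bound floored at 0.9
    if cluster_ci is not None and truncal_ci is not None:
        t_lo = min(truncal_ci[0], TRUNCAL_CI_FLOOR)
        if cluster_ci[1] >= t_lo and cluster_ci[0] <= truncal_ci[1]:
            return "clonal"
    if vals.mean() > PRESENT_EPS:
        return "subclonal"
    return "absent"


def tumour_level_clonality(region_statuses: list[str]) -> tuple[str, bool]:
    """Aggregate per-region statuses; returns (status, illusion flag).

    Truncal requires clonality in every region; a cluster that is clonal in
    some region yet subclonal at tumour level shows the illusion of
    clonality a single biopsy would suffer.
    """
    if not region_statuses:
        raise ValueError("no regions classified")
    if all(s == "clonal" for s in region_statuses):
        return "truncal", False
    if all(s == "absent" for s in region_statuses):
        return "absent", False
    illusion = any(s == "clonal" for s in region_statuses)
    return "subclonal", illusion
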