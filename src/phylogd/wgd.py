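"""Detection of truncal, subclonal and parallel whole-genome doublings.

A WGD doubles the mutant copy number of every mutation already present,
so mutation clusters that predate a subclonal WGD show an excess of
doubled mutations (mutation copy number > 1.5) in the regions the doubled
clone swept.  The detector

1. counts WGDs per region from allele-specific segments (major CN >= 2
   over >= 50% of the genome = one WGD; >= 3 over >= 50% = two);
2. computes each cluster's doubled-mutation fraction per region over
   mutations in copy-number-stable segments (major CN exactly equal to
   2^n_wgd, excluding amplification-contaminated loci);
3. flags genome-doubled clusters (fraction >= 0.25 in a first region,
   >= 0.1 in further regions once flagged somewhere);
4. merges doubled clusters with identical region sets into single events
   (clusters doubled in different, even overlapping, region sets indicate
   distinct, possibly parallel, WGDs), assigns events under the
   per-region WGD-count capacity, and falls back to maximum-parsimony
   region grouping when no cluster is flagged;
5. caps the subclonal event count at 2 (estimates beyond that were found
   unreliable), merging the most-overlapping events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PRIMARY_THRESHOLD = 0.25
SECONDARY_THRESHOLD = 0.10
DOUBLED_MUTCN = 1.5
MAX_SUBCLONAL_EVENTS = 2
MAX_WGD_PER_REGION = 2


def count_wgd_per_region(major_cn: np.ndarray, lengths: np.ndarray) -> int:
    """Region WGD count from length-weighted major-CN fractions."""
    major_cn = np.asarray(major_cn)
    lengths = np.asarray(lengths, dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("segments cover zero bases")
    frac2 = lengths[major_cn >= 2].sum() / total
    frac3 = lengths[major_cn >= 3].sum() / total
    if frac3 >= 0.5:
        return 2
    if frac2 >= 0.5:
        return 1
    return 0


QUADRUPLED_MUTCN = 3.0  # mutCN above this needs two doublings on one path


def doubled_fraction(
    mutcn: np.ndarray,
    major_cn: np.ndarray,
    n_wgd_region: int,
    threshold: float = DOUBLED_MUTCN,
) -> tuple[float, int]:
    """Fraction of doubled mutations among copy-number-stable loci.

    Eligible mutations lie in segments whose major copy number equals the
    expectation for a pure WGD history, 2^n_wgd; returns (fraction,
    n_eligible), with fraction NaN when nothing is eligible.  With
    ``threshold`` set to :data:`QUADRUPLED_MUTCN` the fraction instead
    counts doubly doubled mutations, which distinguishes a genuinely
    nested earlier WGD from an ancestor merely contaminated by its
    descendant's doubling (contamination is bounded by mutCN 2).
    """
    mutcn = np.asarray(mutcn, dtype=float)
    major_cn = np.asarray(major_cn)
    expected = 2 ** int(n_wgd_region)
    eligible = (major_cn == expected) & ~np.isnan(mutcn)
    n = int(eligible.sum())
    if n == 0:
        return float("nan"), 0
    frac = float((mutcn[eligible] > threshold).sum() / n)
    return frac, n


@dataclass
class GDClusterFlag:
    cluster_id: int
    fractions: np.ndarray      # per region, NaN where not assessable
    n_eligible: np.ndarray
    doubled_regions: list[int] = field(default_factory=list)
    quad_fractions: np.ndarray | None = None  # doubly doubled fraction

    @property
    def doubled(self) -> bool:
        return bool(self.doubled_regions)

    def quadrupled(self) -> bool:
        """Evidence that this cluster's mutations were doubled twice."""
        if self.quad_fractions is None:
            return False
        return bool(np.any(np.nan_to_num(self.quad_fractions, nan=-1.0) >= PRIMARY_THRESHOLD))


def flag_gd_clusters(
    fractions: dict[int, np.ndarray],
    n_eligible: dict[int, np.ndarray] | None = None,
    quad_fractions: dict[int, np.ndarray] | None = None,
) -> list[GDClusterFlag]:
    """Apply the 0.25 / 0.1 two-tier thresholds (inclusive boundaries)."""
    out = []
    for cid in sorted(fractions):
        f = np.asarray(fractions[cid], dtype=float)
        ne = np.asarray(n_eligible[cid]) if n_eligible is not None else np.zeros(len(f), dtype=int)
        fv = np.nan_to_num(f, nan=-1.0)
        regions: list[int] = []
        if np.any(fv >= PRIMARY_THRESHOLD):
            regions = sorted(np.where(fv >= SECONDARY_THRESHOLD)[0].tolist())
        out.append(
            GDClusterFlag(
                cluster_id=cid, fractions=f, n_eligible=ne, doubled_regions=regions,
                quad_fractions=None if quad_fractions is None else np.asarray(quad_fractions[cid], dtype=float),
            )
        )
    return out


@dataclass
class WGDEvent:
    event_id: int
    regions: frozenset[int]
    clonality: str              # truncal | subclonal
    source: str                 # doubled-cluster | parsimony
    clusters: tuple[int, ...] = ()


@dataclass
class WGDEventSet:
    events: list[WGDEvent]
    n_regions: int
    review_flag: bool = False

    @property
    def n_subclonal(self) -> int:
        return sum(e.clonality == "subclonal" for e in self.events)

    def per_region_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_regions, dtype=int)
        for e in self.events:
            for r in e.regions:
                counts[r] += 1
        return counts


def _parsimony_events(region_counts: np.ndarray, start_id: int = 0) -> list[WGDEvent]:
    """Level-set grouping: regions sharing the k-th WGD share one event."""
    events = []
    for k in range(1, int(region_counts.max(initial=0)) + 1):
        regions = frozenset(int(r) for r in np.where(region_counts >= k)[0])
        if not regions:
            continue
        clonality = "truncal" if len(regions) == len(region_counts) else "subclonal"
        events.append(WGDEvent(start_id + len(events), regions, clonality, "parsimony"))
    return events


def _chain_merge(
    sub_flags: list[GDClusterFlag],
    ancestors_of: dict[int, set[int]],
    effective_counts: np.ndarray,
) -> list[tuple[frozenset[int], tuple[int, ...]]]:
    """Collapse flagged clusters that lie on one ancestral path.

    Every mutation in a cluster ancestral to a genome-doubled clone is
    itself doubled in the swept regions, so a single subclonal WGD flags
    its whole ancestor chain.  Flagged clusters with no flagged descendant
    seed the events; each flagged ancestor is folded (region-set union)
    into the seed it overlaps most -- unless some seed region still has
    spare WGD-count capacity of >= 2, in which case the ancestor reflects a
    distinct, earlier (nested) WGD and stays its own event.
    """
    flagged = {fl.cluster_id: fl for fl in sub_flags}
    ids = set(flagged)

    def is_anc(a: int, b: int) -> bool:
        return a in ancestors_of.get(b, set())

    seeds = [cid for cid in ids if not any(is_anc(cid, o) for o in ids - {cid})]
    merged: dict[int, tuple[set[int], set[int]]] = {
        cid: (set(flagged[cid].doubled_regions), {cid}) for cid in sorted(seeds)
    }
    for cid in sorted(ids - set(seeds)):
        fl = flagged[cid]
        below = [s for s in merged if is_anc(cid, s)]
        capacity_for_two = any(
            any(effective_counts[r] >= 2 for r in flagged[s].doubled_regions) for s in below
        )
        # a genuinely earlier (nested) WGD leaves doubly doubled mutations
        # in the ancestor; contamination by a descendant's doubling cannot
        nested = capacity_for_two and (fl.quadrupled() if fl.quad_fractions is not None else True)
        if nested or not below:
            merged[cid] = (set(fl.doubled_regions), {cid})
            continue
        best = max(below, key=lambda s: (len(merged[s][0] & set(fl.doubled_regions)), -s))
        # regions flagged in other seeds belong to their events; an
        # ancestor of several doubled clones is doubled in all their sweeps
        foreign = set().union(
            *(flagged[s].doubled_regions for s in seeds if s != best), set()
        )
        merged[best][0].update(set(fl.doubled_regions) - foreign)
        merged[best][1].add(cid)
    return [(frozenset(r), tuple(sorted(c))) for r, c in merged.values()]


def infer_wgd_events(
    flags: list[GDClusterFlag],
    region_counts: np.ndarray,
    trunk_cluster: int | None = None,
    ancestors_of: dict[int, set[int]] | None = None,
) -> WGDEventSet:
    """Merge genome-doubled clusters into distinct WGD events.

    Subclonal doubled clusters with identical region sets collapse into one
    event; distinct region sets yield distinct (parallel) events.  When the
    clone tree is available (``ancestors_of`` maps each cluster to its
    ancestor clusters), flagged ancestor chains collapse onto their most
    derived flagged cluster first.  A flagged trunk marks a truncal
    (pre-MRCA) WGD over its flagged regions.  Events consume per-region
    capacity given by ``region_counts`` (cluster-supported events by
    mutation support first); with no doubled cluster at all, events are
    assigned by maximum parsimony over the region counts.
    """
    region_counts = np.asarray(region_counts, dtype=int)
    n_regions = len(region_counts)
    for fl in flags:
        if any(r >= n_regions for r in fl.doubled_regions):
            raise ValueError("flag references an unknown region")

    doubled = [fl for fl in flags if fl.doubled]
    if not doubled:
        events = _parsimony_events(region_counts)
        return _finalize(events, region_counts)

    capacity = region_counts.copy()
    events: list[WGDEvent] = []

    # A doubled trunk marks a truncal (pre-MRCA) WGD -- but only in the
    # regions where no genome-doubled subclonal cluster offers an
    # alternative explanation: a subclonal doubling doubles the truncal
    # mutations of its swept regions as a side effect.
    trunk_flag = next((fl for fl in doubled if fl.cluster_id == trunk_cluster), None)
    sub_doubled = [fl for fl in doubled if fl.cluster_id != trunk_cluster]
    explained = set().union(*(fl.doubled_regions for fl in sub_doubled), set())
    if trunk_flag is not None:
        kept = frozenset(
            r for r in trunk_flag.doubled_regions
            if r not in explained and capacity[r] > 0
        )
        if kept:
            for r in kept:
                capacity[r] -= 1
            events.append(
                WGDEvent(0, kept, "truncal", "doubled-cluster",
                         clusters=(trunk_flag.cluster_id,))
            )

    anc: dict[int, set[int]] = {k: set(v) for k, v in (ancestors_of or {}).items()}
    groups = _chain_merge(sub_doubled, anc, capacity.copy())

    # clusters doubled in the same regions may share one WGD event --
    # except across an ancestral relationship, where the chain merge has
    # already ruled the doublings distinct (nested events)
    def related(a: tuple[int, ...], b: tuple[int, ...]) -> bool:
        return any(x in anc.get(y, set()) or y in anc.get(x, set()) for x in a for y in b)

    merged: list[tuple[frozenset[int], tuple[int, ...]]] = []
    for regions, members in sorted(groups, key=lambda kv: (sorted(kv[0]), kv[1])):
        target = next(
            (i for i, (r, m) in enumerate(merged) if r == regions and not related(m, members)),
            None,
        )
        if target is None:
            merged.append((regions, members))
        else:
            r, m = merged[target]
            merged[target] = (r, tuple(sorted({*m, *members})))

    support = {fl.cluster_id: int(fl.n_eligible.sum()) for fl in doubled}
    candidates = sorted(
        merged, key=lambda kv: (-sum(support[c] for c in kv[1]), sorted(kv[0]))
    )
    for regions, members in candidates:
        kept = frozenset(r for r in regions if capacity[r] > 0)
        if not kept:
            continue
        for r in kept:
            capacity[r] -= 1
        events.append(
            WGDEvent(len(events), kept, "subclonal", "doubled-cluster", clusters=members)
        )

    # Regions whose WGD counts are not explained by any genome-doubled
    # cluster get events by maximum parsimony: regions harbouring
    # unexplained WGDs are presumed to share an event where possible
    # (level sets over the residual counts).  Where a flagged cluster
    # already claims the region, the remaining count is left unassigned:
    # there is no cluster evidence for a second, co-regional event.
    # When every region harbours a WGD, a level that completes a
    # partially flagged truncal event to full coverage is taken to be the
    # same tumour-wide doubling rather than a distinct subclonal one
    # (counts it would have consumed inside the truncal regions are
    # returned to the pool, since they belong to other events).
    all_regions = frozenset(range(n_regions))
    covered = set().union(*(e.regions for e in events if e.clonality == "subclonal"), set())
    eligible = np.array([r not in covered for r in range(n_regions)])
    wgd_everywhere = bool(np.all(region_counts >= 1))
    # a WGD in every region with no truncal event yet is most
    # parsimoniously one tumour-wide (truncal) doubling
    if wgd_everywhere and not any(e.clonality == "truncal" for e in events) and capacity.min() >= 1:
        capacity -= 1
        events.append(WGDEvent(len(events), all_regions, "truncal", "parsimony"))
    frac_of = {fl.cluster_id: fl.fractions for fl in doubled}
    trunk_completed = False
    while (capacity * eligible).max(initial=0) > 0:
        regions = frozenset(int(r) for r in np.where((capacity > 0) & eligible)[0])
        for r in regions:
            capacity[r] -= 1
        # a level completing the truncal event to full coverage (jointly
        # with the subclonal events) is the truncal WGD's missing regions
        ti = next((i for i, e in enumerate(events) if e.clonality == "truncal"), None)
        if (
            wgd_everywhere
            and not trunk_completed
            and ti is not None
            and events[ti].regions | regions | covered == all_regions
            and events[ti].regions | regions != events[ti].regions
        ):
            trunk_completed = True
            ev = events[ti]
            for r in regions & ev.regions:
                capacity[r] += 1
            events[ti] = WGDEvent(
                ev.event_id,
                frozenset(all_regions - covered),
                ev.clonality, ev.source, ev.clusters,
            )
            continue
        # a level confined to regions where an existing event's clusters
        # could not be assessed (no eligible mutations) extends that event
        extended = None
        for i, ev in enumerate(events):
            if ev.clonality != "subclonal" or ev.source != "doubled-cluster":
                continue
            if ev.regions & regions:
                continue
            if all(
                all(np.isnan(frac_of[c][r]) for c in ev.clusters if c in frac_of)
                for r in regions
            ):
                extended = i
                break
        if extended is not None:
            ev = events[extended]
            events[extended] = WGDEvent(
                ev.event_id, ev.regions | regions, ev.clonality, ev.source, ev.clusters
            )
            continue
        clonality = "truncal" if len(regions) == n_regions and not events else "subclonal"
        events.append(WGDEvent(len(events), regions, clonality, "parsimony"))
    return _finalize(events, region_counts)


def _finalize(events: list[WGDEvent], region_counts: np.ndarray) -> WGDEventSet:
    events = _cap_subclonal(events)
    es = WGDEventSet(events=events, n_regions=len(region_counts))
    es.review_flag = es.n_subclonal > 1
    assert np.all(es.per_region_counts() <= region_counts), "region WGD capacity exceeded"
    return es


def _cap_subclonal(events: list[WGDEvent]) -> list[WGDEvent]:
    """Merge subclonal events with largest region overlap until <= 2 remain."""
    sub = [e for e in events if e.clonality == "subclonal"]
    other = [e for e in events if e.clonality != "subclonal"]
    while len(sub) > MAX_SUBCLONAL_EVENTS:
        best, pair = -1, None
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                ov = len(sub[i].regions & sub[j].regions)
                if ov > best:
                    best, pair = ov, (i, j)
        i, j = pair
        merged = WGDEvent(
            sub[i].event_id,
            sub[i].regions | sub[j].regions,
            "subclonal",
            sub[i].source,
            clusters=tuple(sorted({*sub[i].clusters, *sub[j].clusters})),
        )
        sub = [e for k, e in enumerate(sub) if k not in (i, j)] + [merged]
    out = other + sub
    return [WGDEvent(k, e.regions, e.clonality, e.source, e.clusters) for k, e in enumerate(out)]


def tumour_wgd_status(event_set: WGDEventSet) -> str:
    """'no WGD' | 'truncal only' | 'subclonal'."""
    if event_set.n_subclonal > 0:
        return "subclonal"
    if event_set.events:
        return "truncal only"
    return "no WGD"
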