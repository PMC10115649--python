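"""Tabular and tree serialization.

Coordinates are 1-based inclusive throughout (SEG convention).  Readers
validate and reject malformed rows rather than coercing them.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import SimConfig, SimulatedTumour
from .tree import CloneTree

MUTATION_COLUMNS = ["tumour_id", "sample_id", "mutation_id", "chrom", "pos", "ref_count", "var_count"]
SEGMENT_COLUMNS = ["tumour_id", "sample_id", "chrom", "start", "end", "major_cn", "minor_cn"]


class TableFormatError(ValueError):
    pass


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"mutation table missing columns: {sorted(missing)}")
    if (df[["ref_count", "var_count"]] < 0).any().any():
        bad = df.index[(df[["ref_count", "var_count"]] < 0).any(axis=1)][0]
        raise TableFormatError(f"negative read count at row {bad}")
    dup = df.duplicated(subset=["tumour_id", "sample_id", "mutation_id"])
    if dup.any():
        raise TableFormatError(f"duplicate (tumour, sample, mutation) key at row {df.index[dup][0]}")
    return df


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"segment table missing columns: {sorted(missing)}")
    if (df["major_cn"] < df["minor_cn"]).any() or (df["minor_cn"] < 0).any():
        raise TableFormatError("segments require major_cn >= minor_cn >= 0")
    if (df["end"] < df["start"]).any():
        raise TableFormatError("segments require end >= start")
    for (tum, samp, chrom), grp in df.groupby(["tumour_id", "sample_id", "chrom"]):
        g = grp.sort_values("start")
        overlap = g["start"].values[1:] <= g["end"].values[:-1]
        if overlap.any():
            i = int(np.where(overlap)[0][0])
            a, b = g.iloc[i], g.iloc[i + 1]
            raise TableFormatError(
                f"overlapping segments in {tum}/{samp} chr{chrom}: "
                f"[{a.start},{a.end}] and [{b.start},{b.end}]"
            )
    return df


def mutation_table(tumour: SimulatedTumour) -> pd.DataFrame:
    rows = []
    for locus in range(tumour.layout.n_loci):
        chrom, pos = tumour.layout.locus_chrom_pos(locus)
        for j, s in enumerate(tumour.samples):
            t = int(tumour.reads.t[locus, j])
            v = int(tumour.reads.v[locus, j])
            rows.append((tumour.tumour_id, s.sample_id, f"M{locus}", chrom, pos, t - v, v))
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def segment_table(tumour: SimulatedTumour) -> pd.DataFrame:
    """Bulk rounded allele-specific copy number per arm and sample."""
    rows = []
    layout = tumour.layout
    for j, s in enumerate(tumour.samples):
        xb = np.zeros(layout.n_arms)
        yb = np.zeros(layout.n_arms)
        for clone, u in zip(s.clone_ids, s.proportions):
            xb += u * tumour.genotypes.x[clone]
            yb += u * tumour.genotypes.y[clone]
        for arm in range(layout.n_arms):
            start, end = layout.arm_span(arm)
            a, b = int(np.rint(xb[arm])), int(np.rint(yb[arm]))
            rows.append((tumour.tumour_id, s.sample_id, layout.arm_chrom(arm),
                         start, end, max(a, b), min(a, b)))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def truth_record(tumour: SimulatedTumour) -> dict:
    """JSON-serialisable ground truth for one simulated tumour."""
    return {
        "tumour_id": tumour.tumour_id,
        "sample_group": tumour.sample_group,
        "topology": {str(c): p for c, p in tumour.topology.parent_of.items()},
        "truncal_fraction": tumour.truncal_fraction,
        "samples": [
            {
                "sample_id": s.sample_id,
                "purity": s.purity,
                "coverage": s.coverage,
                "clones": list(map(int, s.clone_ids)),
                "proportions": [float(u) for u in s.proportions],
                "ploidy": s.ploidy,
            }
            for s in tumour.samples
        ],
        "mutation_clone": [int(c) for c in tumour.mutation_clone],
        "wgd_events": [
            {
                "event_id": ev.event_id,
                "edge": list(ev.edge),
                "truncal": ev.truncal,
                "ccf": [float(c) for c in ev.ccf],
                "detectable": ev.detectable,
            }
            for ev in tumour.wgd_truth
        ],
    }


def write_cohort(cohort: list[SimulatedTumour], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.concat([mutation_table(t) for t in cohort]).to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    pd.concat([segment_table(t) for t in cohort]).to_csv(outdir / "segments.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(t.tumour_id, s.sample_id, s.purity) for t in cohort for s in t.samples],
        columns=["tumour_id", "sample_id", "purity"],
    ).to_csv(outdir / "purity.tsv", sep="\t", index=False)
    truths = [truth_record(t) for t in cohort]
    (outdir / "truth.json").write_text(json.dumps(truths, indent=1))


def write_tree_json(tree: CloneTree, path: str | Path) -> None:
    payload = {
        "trunk": tree.trunk,
        "parent_of": {str(k): v for k, v in tree.parent_of.items()},
        "is_default": tree.is_default,
        "alternatives": [{str(k): v for k, v in pm.items()} for pm in tree.alternatives],
        "truncated": tree.truncated,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_tree_json(path: str | Path) -> CloneTree:
    payload = json.loads(Path(path).read_text())
    return CloneTree(
        parent_of={int(k): v for k, v in payload["parent_of"].items()},
        trunk=payload["trunk"],
        is_default=payload.get("is_default", True),
        alternatives=[{int(k): v for k, v in pm.items()} for pm in payload.get("alternatives", [])],
        truncated=payload.get("truncated", False),
    )


def load_config(path: str | Path | None) -> SimConfig:
    if path is None:
        return SimConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("purity_range", "truncal_fraction_range", "group_weights", "subclonal_wgd_probs"):
        if key in data:
            data[key] = tuple(data[key])
    return SimConfig(**data)


def dump_config(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config)))
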