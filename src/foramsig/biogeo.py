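"""Lineage biogeography: per-area abundance, endemism, habitat overlap.

Areas are sampling regions (CCFZ exploration areas, other deep-sea basins,
shallow-water sites); habitats collapse areas into the three-way
CCFZ / deep_sea / shallow contrast used for shared-OTU set intersections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from foramsig.classify import AssignmentRecord, UNASSIGNED
from foramsig.seqio import HABITATS, OtuRecord, SampleMeta


@dataclass
class AreaLineageMatrix:
    """Read counts per lineage (rows) per geographic area (columns)."""

    areas: list[str]
    lineages: list[str]
    reads: np.ndarray  # lineage x area, non-negative ints
    unassigned_reads: int = 0  # remainder outside any lineage

    def __post_init__(self) -> None:
        if self.reads.shape != (len(self.lineages), len(self.areas)):
            raise ValueError("matrix shape inconsistent with labels")
        if (self.reads < 0).any():
            raise ValueError("negative read counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.reads, index=self.lineages, columns=self.areas)


def lineage_by_area(
    assignments: Sequence[AssignmentRecord],
    records: Sequence[OtuRecord],
    meta: Sequence[SampleMeta],
) -> AreaLineageMatrix:
    """Sum reads of each lineage over the samples of each area.

    Unassigned OTUs are excluded from the matrix but their reads are
    reported as a remainder, so total reads are conserved.
    """
    area_of = {m.sample_id: m.area for m in meta}
    label_of = {a.otu_id: a.label for a in assignments}
    areas = sorted({m.area for m in meta})
    area_idx = {a: i for i, a in enumerate(areas)}
    lineages = sorted({
        lbl for lbl in (label_of.get(r.otu_id, UNASSIGNED) for r in records)
        if lbl != UNASSIGNED
    })
    lin_idx = {l: i for i, l in enumerate(lineages)}
    reads = np.zeros((len(lineages), len(areas)), dtype=np.int64)
    remainder = 0
    for rec in records:
        label = label_of.get(rec.otu_id, UNASSIGNED)
        for sample, count in rec.counts.items():
            if count == 0:
                continue
            if sample not in area_of:
                raise ValueError(f"sample {sample!r} has no metadata")
            if label == UNASSIGNED:
                remainder += count
            else:
                reads[lin_idx[label], area_idx[area_of[sample]]] += count
    return AreaLineageMatrix(areas, lineages, reads, remainder)


def relative_abundance(matrix: AreaLineageMatrix) -> pd.DataFrame:
    """Within-area relative abundance: each area column divided by its
    column total.  All-zero areas stay all-zero (with a warning)."""
    df = matrix.to_frame().astype(float)
    totals = df.sum(axis=0)
    zero_areas = totals[totals == 0].index.tolist()
    if zero_areas:
        warnings.warn(f"areas with zero lineage reads: {zero_areas}")
        totals = totals.replace(0, 1)
    return df / totals


def presence_absence(matrix: AreaLineageMatrix, min_reads: int = 1) -> pd.DataFrame:
    """Boolean lineage x area presence: reads >= min_reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return matrix.to_frame() >= min_reads


def endemic_lineages(presence: pd.DataFrame, focal_areas: Iterable[str]) -> list[str]:
    """Lineages present in at least one focal area and absent everywhere
    else — e.g. lineages endemic to the CCFZ exploration areas."""
    focal = set(focal_areas)
    unknown = focal - set(presence.columns)
    if unknown:
        raise ValueError(f"unknown areas: {sorted(unknown)}")
    if not focal:
        return []
    other = [c for c in presence.columns if c not in focal]
    in_focal = presence[sorted(focal)].any(axis=1)
    in_other = presence[other].any(axis=1) if other else pd.Series(False, index=presence.index)
    return presence.index[in_focal & ~in_other].tolist()


def habitat_powerset(habitats: Sequence[str] = HABITATS) -> list[frozenset[str]]:
    out = []
    for k in range(1, len(habitats) + 1):
        for combo in combinations(habitats, k):
            out.append(frozenset(combo))
    return out


def shared_otu_sets(
    assignments: Sequence[AssignmentRecord],
    records: Sequence[OtuRecord],
    meta: Sequence[SampleMeta],
    lineages: Sequence[str],
) -> tuple[dict[str, dict[str, set[str]]], dict[str, dict[frozenset[str], int]]]:
    """Habitat occupancy and exclusive-intersection counts per lineage.

    For each requested lineage, returns (a) the set of member OTU ids
    present in each habitat and (b) UpSet-style exclusive intersection
    counts over the habitat power set: each OTU is counted in exactly the
    cell matching its full habitat combination, so the cells partition the
    lineage's (deduplicated) OTU set.
    """
    habitat_of = {m.sample_id: m.habitat for m in meta}
    label_of = {a.otu_id: a.label for a in assignments}
    wanted = set(lineages)

    presence: dict[str, dict[str, set[str]]] = {
        l: {h: set() for h in HABITATS} for l in lineages
    }
    seen: set[str] = set()
    for rec in records:
        if rec.otu_id in seen:  # duplicates removed first
            continue
        seen.add(rec.otu_id)
        label = label_of.get(rec.otu_id)
        if label not in wanted:
            continue
        for sample, count in rec.counts.items():
            if count > 0:
                if sample not in habitat_of:
                    raise ValueError(f"sample {sample!r} has no metadata")
                presence[label][habitat_of[sample]].add(rec.otu_id)

    counts: dict[str, dict[frozenset[str], int]] = {}
    for lineage in lineages:
        cells = {combo: 0 for combo in habitat_powerset()}
        members = set().union(*presence[lineage].values())
        for otu in members:
            combo = frozenset(
                h for h in HABITATS if otu in presence[lineage][h]
            )
            cells[combo] += 1
        counts[lineage] = cells
    return presence, counts


def upset_table(counts: Mapping[str, Mapping[frozenset[str], int]]) -> pd.DataFrame:
    """Flatten intersection counts to a tidy table (lineage, combo, n_otus)."""
    rows = []
    for lineage, cells in counts.items():
        for combo, n in sorted(cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            rows.append({
                "lineage": lineage,
                "habitats": "&".join(sorted(combo)),
                "n_otus": n,
            })
    return pd.DataFrame(rows, columns=["lineage", "habitats", "n_otus"])
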