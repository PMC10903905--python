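"""Zero-mismatch signature classification and merging with prior taxonomy.

An OTU belongs to a lineage iff its sequence contains the lineage's
signature exactly (100% similarity, single strand): one base of difference
excludes it, by design — tolerating mismatches would erode signature
specificity.  When an OTU contains several signatures the longest pattern
wins (longer signatures define lower taxonomic levels) and all hits are
recorded.  Signature assignments are then combined with an optional prior
similarity-based taxonomy: priors that are well-defined taxa are kept,
while unassigned, ENFOR, Monothalamids X and undetermined-monothalamid
priors may be overridden by a lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from foramsig.discovery import Signature
from foramsig.matching import AhoCorasick
from foramsig.seqio import OtuRecord, PriorAssignment

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AssignmentRecord:
    """An OTU's label with provenance.

    ``source`` is "signature" or "prior" for labelled OTUs and absent for
    unassigned ones; signature assignments always carry the matched pattern.
    """

    otu_id: str
    label: str
    source: str | None = None
    matched_pattern: str | None = None
    conflict_note: str | None = None

    def __post_init__(self) -> None:
        if self.source == "signature" and self.label != UNASSIGNED \
                and not self.matched_pattern:
            raise ValueError(f"{self.otu_id}: signature assignment without pattern")


@dataclass(frozen=True)
class PrecedenceConfig:
    """Which prior statuses a signature assignment may override."""

    overridable_prior_statuses: frozenset[str] = frozenset(
        {"unassigned", "enfor", "monothalamids_X", "undetermined_monothalamid"}
    )


def match_signatures(
    signatures: Sequence[Signature],
    records: Iterable[OtuRecord],
) -> list[AssignmentRecord]:
    """Assign OTUs to lineages by exact (zero-mismatch) pattern containment.

    Matching is placement-blind: the pattern may occur anywhere on the
    forward strand.  Multiple hits resolve to the longest pattern, with a
    conflict note listing every matching lineage.
    """
    sigs = list(signatures)
    for s in sigs:
        if s.name is None:
            raise ValueError(f"signature {s.pattern!r} is unnamed; name_lineages first")
    out: list[AssignmentRecord] = []
    if not sigs:
        return [AssignmentRecord(r.otu_id, UNASSIGNED) for r in records]
    automaton = AhoCorasick([s.pattern for s in sigs])
    for rec in records:
        hit_idx = sorted(automaton.matching_patterns(rec.sequence))
        if not hit_idx:
            out.append(AssignmentRecord(rec.otu_id, UNASSIGNED))
            continue
        # longest pattern wins; ties broken by name for determinism
        best = min(hit_idx, key=lambda i: (-len(sigs[i].pattern), str(sigs[i].name)))
        note = None
        if len(hit_idx) > 1:
            note = "multiple signatures: " + ", ".join(
                f"{sigs[i].name}({sigs[i].pattern})" for i in hit_idx
            )
        out.append(AssignmentRecord(
            otu_id=rec.otu_id,
            label=str(sigs[best].name),
            source="signature",
            matched_pattern=sigs[best].pattern,
            conflict_note=note,
        ))
    return out


def merge_with_prior(
    prior: Sequence[PriorAssignment],
    sig_assign: Sequence[AssignmentRecord],
    config: PrecedenceConfig | None = None,
) -> list[AssignmentRecord]:
    """Combine prior taxonomy with signature assignments.

    Overridable priors (unassigned / ENFOR / Monothalamids X / undetermined
    monothalamids) yield to a signature hit; well-defined prior taxa are
    kept, with the signature hit recorded as a note.  OTUs absent from the
    prior table are treated as previously unassigned.
    """
    config = config or PrecedenceConfig()
    prior_by_id = {p.otu_id: p for p in prior}
    out: list[AssignmentRecord] = []
    for sig in sig_assign:
        p = prior_by_id.get(sig.otu_id)
        has_hit = sig.matched_pattern is not None
        if p is None or p.status in config.overridable_prior_statuses:
            if has_hit:
                out.append(sig)
            elif p is not None and p.status != "unassigned":
                # e.g. an ENFOR prior with no signature hit keeps its label
                out.append(AssignmentRecord(sig.otu_id, p.label, source="prior"))
            else:
                out.append(AssignmentRecord(sig.otu_id, UNASSIGNED))
        else:
            if sig.source == "prior" and sig.label == p.label:
                out.append(sig)  # already merged — idempotent pass-through
                continue
            note = None
            if has_hit:
                note = f"signature hit {sig.label}({sig.matched_pattern}) suppressed"
            out.append(AssignmentRecord(
                otu_id=sig.otu_id, label=p.label, source="prior", conflict_note=note
            ))
    return out


def composition_summary(
    combined: Sequence[AssignmentRecord],
    records: Sequence[OtuRecord],
    category_of=None,
) -> pd.DataFrame:
    """Per-category OTU and read composition of the combined assignment.

    ``category_of`` optionally maps labels to coarser groups (for example
    every L-lineage to "new_lineages"); by default each label is its own
    category.  Fractions are of total dataset reads and sum to 1.
    """
    by_id = {a.otu_id: a for a in combined}
    missing = [r.otu_id for r in records if r.otu_id not in by_id]
    if missing:
        raise ValueError(f"assignments missing for OTUs: {sorted(missing)[:5]}")
    rows: dict[str, dict[str, int]] = {}
    total_reads = 0
    for rec in records:
        label = by_id[rec.otu_id].label
        cat = category_of(label) if category_of else label
        slot = rows.setdefault(cat, {"n_otus": 0, "n_reads": 0})
        slot["n_otus"] += 1
        slot["n_reads"] += rec.total_reads
        total_reads += rec.total_reads
    df = pd.DataFrame(
        [
            {"category": cat, "n_otus": v["n_otus"], "n_reads": v["n_reads"]}
            for cat, v in rows.items()
        ]
    ).sort_values(["n_reads", "category"], ascending=[False, True], kind="stable")
    df["fraction_of_reads"] = (
        df["n_reads"] / total_reads if total_reads else 0.0
    )
    return df.reset_index(drop=True)


def new_lineage_category(label: str) -> str:
    """Default coarse-category mapping: L-numbered labels become
    "new_lineages", everything else keeps its own label."""
    import re

    return "new_lineages" if re.match(r"^L\d+[A-Z]?$", label) else label
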