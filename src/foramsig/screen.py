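"""Conserved-motif screening of 37F amplicons.

Foraminiferal amplicons obtained with the s14F1/s15 primer pair carry the
hypervariable 37F expansion segment bracketed by conserved helix-37
sequence: the pentamer ``GACAG`` immediately upstream of 37F and the
terminal nonamers ``TAGTCCTTT`` / ``TAGTCCCTT`` (a T>C substitution exists
in some species) at the 3' end of the conserved region.  Datasets produced
with the s14F1/s17 pair span two variable regions (37F and 41F); those are
screened instead for ``GACAG`` plus the helix-38 motif ``GGTGGT``.

Records failing the motif tests, the length filter (> 70 bp, strict) or the
abundance filter (> 100 reads, strict) are discarded with a per-record
verdict.  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import edlib

from foramsig.seqio import OtuRecord, ReferenceRecord

# s14F1 / s15 primer pair targeting 37F; each sample additionally carries an
# 8-nt multiplexing tag on both primers.
PRIMER_S14F1 = "AAGGGCACCACAAGAACGC"
PRIMER_S15 = "CCACCTATCACAYAATCATG"
TAG_LENGTH = 8
MIN_37F_LENGTH = 68
MAX_37F_LENGTH = 196

VERDICTS = (
    "kept",
    "no_anchor",
    "no_terminal",
    "too_short",
    "too_rare",
    "ambiguous_anchor",
    "failed_qc",
)

KEPT_VERDICTS = frozenset({"kept", "ambiguous_anchor"})


def shortest_amplicon_length(
    min_insert: int = MIN_37F_LENGTH,
    forward_primer: str = PRIMER_S14F1,
    reverse_primer: str = PRIMER_S15,
    tag_length: int = TAG_LENGTH,
) -> int:
    """Length of the shortest expected amplicon including primers and tags.

    Both primers are tagged with ``tag_length`` extra nucleotides, so the
    shortest product is forward + reverse + two tags + the minimum 37F
    insert.  Used to justify the size-selection cut-off applied before
    library preparation.
    """
    return len(forward_primer) + len(reverse_primer) + 2 * tag_length + min_insert


@dataclass(frozen=True)
class FilterConfig:
    """Retention rules for foraminiferal 37F amplicons.

    min_length and min_reads are strict (kept iff value > threshold).
    ``max_conserved_edits`` bounds the edits tolerated in the conserved
    segment upstream of the anchor during QC.
    """

    anchor_motif: str = "GACAG"
    terminal_motifs: frozenset[str] = frozenset({"TAGTCCTTT", "TAGTCCCTT"})
    alt_terminal_motif: str = "GGTGGT"
    min_length: int = 70
    min_reads: int = 100
    max_conserved_edits: int = 2
    length_on_core: bool = False  # apply min_length to the 37F core instead
    rescue_reverse_complement: bool = False

    def __post_init__(self) -> None:
        if self.min_length < 0 or self.min_reads < 0 or self.max_conserved_edits < 0:
            raise ValueError("thresholds must be non-negative")
        for motif in (self.anchor_motif, self.alt_terminal_motif, *self.terminal_motifs):
            if not motif or set(motif) - set("ACGTRYSWKMBDHVN"):
                raise ValueError(f"invalid motif {motif!r}")


@dataclass(frozen=True)
class RegionAnnotation:
    """Located conserved anchors and the 37F variable span.

    ``variable_span`` is the half-open interval [anchor_end, terminal_start)
    (or to the end of the sequence when no terminal is required).
    """

    anchor_start: int
    anchor_end: int
    terminal_motif: str | None
    terminal_start: int | None
    variable_span: tuple[int, int]
    ambiguous_anchor: bool = False

    def __post_init__(self) -> None:
        if not (self.anchor_start < self.anchor_end):
            raise ValueError("anchor interval empty")
        if self.terminal_start is not None and self.anchor_end > self.terminal_start:
            raise ValueError("anchor must precede terminal")
        if self.variable_span[1] < self.variable_span[0]:
            raise ValueError("negative variable span")


@dataclass(frozen=True)
class AnnotationFailure:
    verdict: str
    detail: str = ""


@dataclass(frozen=True)
class ScreenOutcome:
    otu_id: str
    verdict: str
    detail: str = ""


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def annotate_regions(
    sequence: str,
    config: FilterConfig | None = None,
    mode: str = "one_region",
) -> RegionAnnotation | AnnotationFailure:
    """Locate the GACAG anchor and the terminal motif delimiting 37F.

    In ``one_region`` mode the terminal is one of the TAGTCC(T/C)TT pair; in
    ``two_region`` mode (s14F1/s17 amplicons) it is GGTGGT in helix 38.  The
    leftmost terminal occurrence preceded by an anchor is used; when several
    anchor copies precede it, the last one — the copy actually abutting 37F —
    is taken and the annotation is flagged ambiguous.
    """
    if not sequence:
        raise ValueError("empty sequence")
    config = config or FilterConfig()
    if mode not in ("one_region", "two_region"):
        raise ValueError(f"unknown mode {mode!r}")

    anchors = _find_all(sequence, config.anchor_motif)
    if not anchors:
        return AnnotationFailure("no_anchor", f"missing {config.anchor_motif!r}")
    anchor_len = len(config.anchor_motif)

    terminals = (
        sorted(config.terminal_motifs) if mode == "one_region"
        else [config.alt_terminal_motif]
    )
    term_hits = sorted(
        (pos, motif) for motif in terminals for pos in _find_all(sequence, motif)
    )
    # leftmost terminal that still leaves room for an anchor before it
    chosen = None
    for pos, motif in term_hits:
        preceding = [a for a in anchors if a + anchor_len <= pos]
        if preceding:
            chosen = (pos, motif, preceding)
            break
    if chosen is None:
        wanted = " or ".join(repr(t) for t in terminals)
        return AnnotationFailure("no_terminal", f"missing terminal {wanted}")

    term_start, term_motif, preceding = chosen
    anchor_start = preceding[-1]
    return RegionAnnotation(
        anchor_start=anchor_start,
        anchor_end=anchor_start + anchor_len,
        terminal_motif=term_motif,
        terminal_start=term_start,
        variable_span=(anchor_start + anchor_len, term_start),
        ambiguous_anchor=len(preceding) > 1,
    )


def _reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
    return seq.translate(comp)[::-1]


def screen_dataset(
    records: Iterable[OtuRecord],
    config: FilterConfig | None = None,
    mode: str = "one_region",
    consensus: str | None = None,
) -> tuple[list[tuple[OtuRecord, RegionAnnotation]], list[ScreenOutcome]]:
    """Apply the foraminiferal retention filters to a dataset.

    Returns the kept records with their region annotations and a per-record
    outcome log.  Kept and discarded records partition the input; records
    kept despite multiple anchor copies are logged ``ambiguous_anchor``.
    When a conserved-region ``consensus`` is given, conserved-region QC runs
    as a final filter (verdict ``failed_qc``).
    """
    config = config or FilterConfig()
    kept: list[tuple[OtuRecord, RegionAnnotation]] = []
    log: list[ScreenOutcome] = []
    for rec in records:
        ann = annotate_regions(rec.sequence, config, mode)
        if isinstance(ann, AnnotationFailure) and config.rescue_reverse_complement:
            rc_ann = annotate_regions(_reverse_complement(rec.sequence), config, mode)
            if isinstance(rc_ann, RegionAnnotation):
                rec = OtuRecord(rec.otu_id, _reverse_complement(rec.sequence),
                                dict(rec.counts))
                ann = replace(rc_ann)
        if isinstance(ann, AnnotationFailure):
            log.append(ScreenOutcome(rec.otu_id, ann.verdict, ann.detail))
            continue
        measured = (
            ann.variable_span[1] - ann.variable_span[0]
            if config.length_on_core else len(rec.sequence)
        )
        if measured <= config.min_length:
            log.append(ScreenOutcome(
                rec.otu_id, "too_short",
                f"{measured} bp <= {config.min_length}"))
            continue
        if rec.total_reads <= config.min_reads:
            log.append(ScreenOutcome(
                rec.otu_id, "too_rare",
                f"{rec.total_reads} reads <= {config.min_reads}"))
            continue
        if consensus is not None:
            ok, edits = qc_conserved(rec, ann, consensus, config.max_conserved_edits)
            if not ok:
                log.append(ScreenOutcome(
                    rec.otu_id, "failed_qc",
                    f"{edits} edits > {config.max_conserved_edits}"))
                continue
        verdict = "ambiguous_anchor" if ann.ambiguous_anchor else "kept"
        log.append(ScreenOutcome(rec.otu_id, verdict))
        kept.append((rec, ann))
    return kept, log


def _upstream_segment(sequence: str, config: FilterConfig, mode: str) -> str | None:
    ann = annotate_regions(sequence, config, mode)
    if isinstance(ann, AnnotationFailure):
        return None
    return sequence[: ann.anchor_start]


def conserved_consensus(
    references: Sequence[ReferenceRecord],
    config: FilterConfig | None = None,
    mode: str = "one_region",
) -> str:
    """Majority-rule consensus of the conserved segment upstream of GACAG.

    Reference upstream segments are right-aligned at the anchor and
    truncated to the shortest one; each column takes its majority base,
    ties broken alphabetically (A < C < G < T).
    """
    config = config or FilterConfig()
    segments = []
    for ref in references:
        seg = _upstream_segment(ref.sequence, config, mode)
        if seg is not None:
            segments.append(seg)
    if not segments:
        raise ValueError("no reference with a locatable anchor")
    width = min(len(s) for s in segments)
    aligned = [s[len(s) - width:] for s in segments]
    out = []
    for col in zip(*aligned):
        counts: dict[str, int] = {}
        for base in col:
            counts[base] = counts.get(base, 0) + 1
        best = min(counts, key=lambda b: (-counts[b], b))
        out.append(best)
    return "".join(out) if width else ""


def qc_conserved(
    record: OtuRecord,
    annotation: RegionAnnotation,
    consensus: str,
    max_edits: int = 2,
) -> tuple[bool, int]:
    """Conserved-region quality control upstream of the anchor.

    The record's pre-anchor segment (trimmed leftward to the consensus
    length) is compared to the consensus by Levenshtein distance; every
    non-ACGT character in the segment adds one further edit (ambiguities
    count as errors).  Passes iff total edits <= max_edits.
    """
    if not consensus:
        raise ValueError("empty consensus")
    segment = record.sequence[: annotation.anchor_start]
    segment = segment[max(0, len(segment) - len(consensus)):]
    dist = edlib.align(segment, consensus, task="distance", mode="NW")["editDistance"]
    ambiguities = sum(1 for ch in segment if ch not in "ACGT")
    edits = int(dist) + ambiguities
    return edits <= max_edits, edits
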