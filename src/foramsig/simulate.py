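"""Synthetic 37F amplicon communities with planted lineage signatures.

The generator emulates the structure the signature method assumes: each
amplicon is a conserved upstream segment (helices 33-36), the ``GACAG``
anchor, a hypervariable 37F span of 68-196 nt, the conserved terminal
nonamer and a short downstream tail.  Planted lineages share an identical
signature window (anchor hexamer plus a drawn pattern of 12-53 nt) at the
start of their spans and are private elsewhere; noise OTUs carry unique
prefixes (half of them also sub-threshold read counts); contaminants lack
the anchor motif entirely.  Read totals are lognormal and spread over
samples multinomially through a per-area occupancy mask, producing
realistic presence patterns for the biogeography analytics.  Reference
sets include described clades, ENFOR and Monothalamids X sequences, with
optional decoys carrying a planted pattern to exercise the reference
exclusion rule.  All output is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from foramsig.screen import FilterConfig, annotate_regions, RegionAnnotation
from foramsig.seqio import OtuRecord, ReferenceRecord, SampleMeta

# conserved flank upstream of the anchor (helix 33-36-like segment) and the
# conserved tail after the terminal motif; fixed across the community
CONSERVED_UPSTREAM = "TTGTACACACCGCCCGTCGCTACTACCGATTGGA"
ANCHOR = "GACAG"
TERMINAL = "TAGTCCTTT"
CONSERVED_DOWNSTREAM = "AAGGAATTGACGGAAGG"

_FORBIDDEN_IN_SPAN = ("GACAG", "TAGTCCTTT", "TAGTCCCTT", "GGTGGT")

_DEFAULT_AREAS = (
    ("OMS", "CCFZ"),
    ("UK-1", "CCFZ"),
    ("BGR", "CCFZ"),
    ("IFREMER", "CCFZ"),
    ("North Atlantic", "deep_sea"),
    ("Svalbard", "shallow"),
)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic community.

    Defaults follow the study conditions of the target system: 37F spans of
    68-196 nt, signatures of 12-53 nt, lineages of a few OTUs each with
    clearly supra-threshold read support, and a CCFZ-dominated area layout
    with deep-sea and shallow outgroups.
    """

    n_lineages: int = 10
    otus_per_lineage: tuple[int, int] = (3, 6)
    core_length: tuple[int, int] = (68, 196)  # 37F span, excluding the anchor
    signature_length: tuple[int, int] = (12, 53)  # includes the anchor hexamer
    n_noise_otus: int = 50
    n_contaminants: int = 5
    reads_median: float = 2500.0
    reads_sigma: float = 1.0
    min_member_reads: int = 150
    guarantee_thresholds: bool = True
    min_lineage_reads: int = 5000  # planted lineages exceed this strictly
    sub_threshold_noise_fraction: float = 0.5
    samples_per_area: int = 2
    areas: tuple[tuple[str, str], ...] = _DEFAULT_AREAS
    occupancy: float = 0.5  # per-area presence probability for each OTU
    n_described_refs: int = 5
    n_enfor_refs: int = 3
    n_monoX_refs: int = 2
    decoy_categories: tuple[str, ...] = ()  # e.g. ("described_clade", "ENFOR")
    min_sig_len: int = 12  # prefix-uniqueness horizon for noise cores
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.signature_length
        if lo < 7 or lo > hi:
            raise ValueError("signature_length must satisfy 7 <= lo <= hi")
        if hi - 5 > self.core_length[0]:
            raise ValueError("signature longer than the shortest core")
        if self.core_length[0] > self.core_length[1]:
            raise ValueError("bad core_length range")
        if self.n_lineages > 4 ** (self.min_sig_len - 6):
            raise ValueError("too many lineages for distinct signature prefixes")


@dataclass
class GroundTruth:
    """Planted structure: which OTU belongs to which lineage, via which
    pattern, plus the decoy references exercising the exclusion rule."""

    lineage_members: dict[str, frozenset[str]]
    patterns: dict[str, str]
    otu_lineage: dict[str, str | None]
    decoys: list[tuple[str, str, str]] = field(default_factory=list)  # (ref_id, pattern, category)
    rejected_lineages: frozenset[str] = frozenset()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"otu_id": otu, "lineage": lin or "", "pattern": self.patterns.get(lin, "") if lin else ""}
            for otu, lin in sorted(self.otu_lineage.items())
        ]
        return pd.DataFrame(rows, columns=["otu_id", "lineage", "pattern"])


def _draw_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _draw_clean_span(rng: np.random.Generator, length: int, prefix: str = "") -> str:
    """A span of the given length starting with `prefix`, free of anchor and
    terminal motifs (real 37F spans carry a single adjacent anchor copy)."""
    for _ in range(200):
        span = prefix + _draw_bases(rng, length - len(prefix))
        if not any(m in span for m in _FORBIDDEN_IN_SPAN):
            return span
    raise RuntimeError("could not draw a motif-free span")


def _assemble(span: str) -> str:
    return CONSERVED_UPSTREAM + ANCHOR + span + TERMINAL + CONSERVED_DOWNSTREAM


def _verify_structure(sequence: str, span: str) -> bool:
    ann = annotate_regions(sequence, FilterConfig())
    if not isinstance(ann, RegionAnnotation):
        return False
    start, end = ann.variable_span
    return sequence[start:end] == span and not ann.ambiguous_anchor


def _lognormal_reads(rng: np.random.Generator, median: float, sigma: float) -> int:
    return max(1, int(round(float(rng.lognormal(np.log(median), sigma)))))


def plant_decoy_reference(
    params: SimulationParams,
    pattern: str,
    category: str,
    ref_id: str = "decoy",
    with_upstream_flank: bool | None = None,
) -> ReferenceRecord:
    """A reference sequence containing `pattern`, labelled `category`.

    Described-clade decoys embed the pattern together with the conserved
    upstream flank, so leftward extension of a conflicting candidate cannot
    escape the conflict; pass ``with_upstream_flank=False`` to build the
    escapable variant instead.
    """
    rng = np.random.default_rng((params.seed, hash(ref_id) & 0x7FFFFFFF))
    if with_upstream_flank is None:
        with_upstream_flank = category == "described_clade"
    left = CONSERVED_UPSTREAM if with_upstream_flank else _draw_bases(rng, 20)
    seq = left + pattern + _draw_bases(rng, 40)
    taxa = {
        "described_clade": "Clade Z (decoy)",
        "ENFOR": "ENFOR9 (decoy)",
        "monothalamids_X": "Monothalamids X9 (decoy)",
        "undetermined": "undetermined (decoy)",
    }
    return ReferenceRecord(ref_id=ref_id, sequence=seq,
                           taxon=taxa[category], category=category)


def _make_meta(params: SimulationParams) -> list[SampleMeta]:
    meta = []
    for area, habitat in params.areas:
        for k in range(params.samples_per_area):
            sid = f"{area.replace(' ', '_')}_s{k + 1}"
            meta.append(SampleMeta(sample_id=sid, area=area, habitat=habitat))
    return meta


def _spread_counts(
    rng: np.random.Generator,
    total: int,
    meta: Sequence[SampleMeta],
    occupancy: float,
) -> dict[str, int]:
    areas = sorted({m.area for m in meta})
    occupied = [a for a in areas if rng.random() < occupancy]
    if not occupied:
        occupied = [areas[int(rng.integers(0, len(areas)))]]
    samples = [m.sample_id for m in meta if m.area in set(occupied)]
    split = rng.multinomial(total, np.full(len(samples), 1.0 / len(samples)))
    counts = {m.sample_id: 0 for m in meta}
    for sid, c in zip(samples, split):
        counts[sid] = int(c)
    return counts


def simulate_dataset(
    params: SimulationParams,
) -> tuple[list[OtuRecord], list[SampleMeta], list[ReferenceRecord], GroundTruth]:
    """Generate a full synthetic dataset with ground truth.

    Returns OTU records (planted lineages, noise, contaminants), sample
    metadata, the reference database (optionally with decoys), and the
    planted ground truth.  Output is byte-identical for a fixed seed; every
    planted pattern is verified to occur in all of its members and in no
    other OTU before returning.
    """
    rng = np.random.default_rng(params.seed)
    meta = _make_meta(params)

    sig_lo, sig_hi = params.signature_length
    span_lo, span_hi = params.core_length
    horizon = params.min_sig_len - 5  # span prefix that must stay unique

    # distinct signature prefixes across lineages: the first `horizon` span
    # bases (G + tail start) must differ, or a union group would share a
    # >= min_sig_len core prefix and swallow both lineages
    used_prefixes: set[str] = set()
    patterns: dict[str, str] = {}
    lineage_tails: dict[str, str] = {}
    for li in range(params.n_lineages):
        name = f"planted_{li + 1}"
        for _ in range(500):
            sig_len = int(rng.integers(sig_lo, sig_hi + 1))
            tail = "G" + _draw_bases(rng, sig_len - 6)  # span part of the pattern
            if any(m in (ANCHOR + tail) for m in _FORBIDDEN_IN_SPAN[1:]) or \
               "GACAG" in tail:
                continue
            if tail[:horizon] in used_prefixes:
                continue
            used_prefixes.add(tail[:horizon])
            patterns[name] = ANCHOR + tail
            lineage_tails[name] = tail
            break
        else:
            raise RuntimeError("could not draw distinct lineage signatures")

    records: list[OtuRecord] = []
    otu_lineage: dict[str, str | None] = {}
    lineage_members: dict[str, set[str]] = {n: set() for n in patterns}

    # planted lineage members
    for name, tail in lineage_tails.items():
        n_members = int(rng.integers(params.otus_per_lineage[0],
                                     params.otus_per_lineage[1] + 1))
        member_reads = []
        for mi in range(n_members):
            otu_id = f"{name}_otu{mi + 1}"
            span_len = int(rng.integers(max(span_lo, len(tail)), span_hi + 1))
            for _ in range(200):
                span = _draw_clean_span(rng, span_len, prefix=tail)
                seq = _assemble(span)
                if _verify_structure(seq, span):
                    break
            else:
                raise RuntimeError("could not assemble a valid member sequence")
            reads = _lognormal_reads(rng, params.reads_median, params.reads_sigma)
            if params.guarantee_thresholds:
                reads = max(reads, params.min_member_reads)
            member_reads.append(reads)
            records.append(OtuRecord(otu_id, seq, {}))
            otu_lineage[otu_id] = name
            lineage_members[name].add(otu_id)
        if params.guarantee_thresholds:
            deficit = params.min_lineage_reads + 1 - sum(member_reads)
            if deficit > 0:
                member_reads[0] += deficit
        for rec, reads in zip(records[-n_members:], member_reads):
            rec.counts.update(_spread_counts(rng, reads, meta, params.occupancy))

    # noise OTUs: unique core prefixes (and suffix-window draws are random,
    # so no suffix group forms either); half are sub-threshold in reads
    for ni in range(params.n_noise_otus):
        otu_id = f"noise_{ni + 1}"
        span_len = int(rng.integers(span_lo, span_hi + 1))
        for _ in range(500):
            span = _draw_clean_span(rng, span_len)
            if span[:horizon] in used_prefixes:
                continue
            seq = _assemble(span)
            if _verify_structure(seq, span):
                used_prefixes.add(span[:horizon])
                break
        else:
            raise RuntimeError("could not draw a unique noise span")
        if rng.random() < params.sub_threshold_noise_fraction:
            reads = int(rng.integers(1, 101))  # fails the > 100 reads filter
        else:
            reads = _lognormal_reads(rng, params.reads_median, params.reads_sigma)
        records.append(OtuRecord(
            otu_id, seq, _spread_counts(rng, reads, meta, params.occupancy)))
        otu_lineage[otu_id] = None

    # contaminants: no anchor motif anywhere
    for ci in range(params.n_contaminants):
        otu_id = f"contam_{ci + 1}"
        for _ in range(200):
            seq = _draw_bases(rng, int(rng.integers(90, 220)))
            if "GACAG" not in seq:
                break
        else:
            raise RuntimeError("could not draw an anchor-free contaminant")
        reads = _lognormal_reads(rng, params.reads_median, params.reads_sigma)
        records.append(OtuRecord(
            otu_id, seq, _spread_counts(rng, reads, meta, params.occupancy)))
        otu_lineage[otu_id] = None

    # reference database; reference spans also avoid the planted prefixes
    references: list[ReferenceRecord] = []
    ref_specs = (
        [("described_clade", f"Clade {chr(ord('A') + i)}")
         for i in range(params.n_described_refs)]
        + [("ENFOR", f"ENFOR{i + 1}") for i in range(params.n_enfor_refs)]
        + [("monothalamids_X", f"Monothalamids X{i + 1}")
           for i in range(params.n_monoX_refs)]
    )
    for ri, (category, taxon) in enumerate(ref_specs):
        for _ in range(200):
            span = _draw_clean_span(rng, int(rng.integers(span_lo, span_hi + 1)))
            if span[:horizon] not in used_prefixes:
                break
        else:
            raise RuntimeError("could not draw a reference span")
        references.append(ReferenceRecord(
            ref_id=f"ref_{ri + 1}", sequence=_assemble(span),
            taxon=taxon, category=category))

    decoys: list[tuple[str, str, str]] = []
    rejected: set[str] = set()
    cores_by_otu = {
        r.otu_id: r.sequence[r.sequence.index(ANCHOR): r.sequence.index(TERMINAL)]
        for r in records if otu_lineage[r.otu_id] is not None
    }
    for di, category in enumerate(params.decoy_categories):
        target = f"planted_{di + 1}"
        if target not in patterns:
            raise ValueError("more decoys than planted lineages")
        ref_id = f"decoy_{di + 1}"
        if category in ("ENFOR", "monothalamids_X"):
            # exempt category: a simple embedding suffices, the candidate
            # survives regardless
            ref = plant_decoy_reference(params, patterns[target], category,
                                        ref_id=ref_id)
        else:
            # disallowed category: the decoy must contain every candidate a
            # subgroup of the target lineage could emit — each member's
            # core prefix, preceded by the conserved flank so that leftward
            # extension cannot escape the conflict either
            max_len = sig_hi
            segments = [
                CONSERVED_UPSTREAM + cores_by_otu[otu][:max_len]
                for otu in sorted(lineage_members[target])
            ]
            ref = ReferenceRecord(
                ref_id=ref_id, sequence="".join(segments),
                taxon="Clade Z (decoy)", category=category)
            rejected.add(target)
        references.append(ref)
        decoys.append((ref.ref_id, patterns[target], category))

    _check_feasibility(records, patterns, lineage_members)

    truth = GroundTruth(
        lineage_members={k: frozenset(v) for k, v in lineage_members.items()},
        patterns=patterns,
        otu_lineage=otu_lineage,
        decoys=decoys,
        rejected_lineages=frozenset(rejected),
    )
    return records, meta, references, truth


def _check_feasibility(
    records: Sequence[OtuRecord],
    patterns: dict[str, str],
    lineage_members: dict[str, set[str]],
) -> None:
    """Every planted pattern occurs in all of its members and nowhere else."""
    for name, pattern in patterns.items():
        matched = {r.otu_id for r in records if pattern in r.sequence}
        if matched != lineage_members[name]:
            raise RuntimeError(
                f"planted pattern for {name} is not diagnostic: "
                f"matched {sorted(matched)} vs members {sorted(lineage_members[name])}"
            )
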