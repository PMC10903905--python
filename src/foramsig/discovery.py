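"""Diagnostic-signature discovery in the 37F hypervariable region.

Unassigned OTU cores (the GACAG anchor plus the 37F variable span) are
grouped by shared sequence into candidate lineages, each defined by an
ultra-short exact pattern (12-53 nt by default).  Candidates fall into
three placement classes, mirroring where diagnostic variation accumulates
in the amplicon:

* ``prefix_anchored`` — the pattern starts at the conserved anchor hexamer
  (``GACAGG``) and runs into the start of 37F, where variability rises
  fastest; the bulk of signatures live here.
* ``upstream_extended`` — a prefix candidate whose pattern also occurs in a
  disallowed reference taxon is extended leftward into the conserved
  helix-35/36 segment until it no longer matches any such reference.
* ``suffix_anchored`` — OTU sets indistinguishable by prefix may instead
  share the end of 37F, immediately before the terminal motif.

A candidate is validated when its lineage has at least 2 member OTUs and
strictly more than 5000 supporting reads, and its pattern occurs in no
reference sequence outside the exempt categories (the environmental ENFOR
clades and Monothalamids X, which are themselves poorly characterised).
Validated lineages are named L1, L2, ... with sub-letters (L2A, L2B) for
near-identical signatures differing by roughly one substitution.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from foramsig.screen import RegionAnnotation
from foramsig.seqio import OtuRecord, ReferenceRecord

PLACEMENTS = ("prefix_anchored", "upstream_extended", "suffix_anchored")

_NAME_RE = re.compile(r"^L(\d+)([A-Z]?)$")


@dataclass(frozen=True)
class DiscoveryConfig:
    """Signature length bounds, validation thresholds, and exemptions.

    min_reads is strict (validated iff reads > min_reads).  Patterns whose
    diagnostic group shares a longer stretch are capped at ``max_sig_len``;
    longer shared stretches do not change membership.  ``minimal_patterns``
    switches from longest-common-prefix patterns to the shortest prefix
    that still yields the same member set.
    """

    min_sig_len: int = 12
    max_sig_len: int = 53
    min_otus: int = 2
    min_reads: int = 5000
    allowed_reference_categories: frozenset[str] = frozenset({"ENFOR", "monothalamids_X"})
    anchor_hexamer: str = "GACAGG"
    minimal_patterns: bool = False
    # sub-lineage grouping: same number when patterns are equal-length with
    # Hamming distance 1, or share an identical first min_sig_len-mer
    sublineage_hamming: int = 1

    def __post_init__(self) -> None:
        if self.min_sig_len > self.max_sig_len:
            raise ValueError("min_sig_len > max_sig_len")
        if min(self.min_sig_len, self.max_sig_len, self.min_otus, self.min_reads) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True, order=True)
class LineageName:
    """L-number naming with optional sub-lineage letter (L17, L2A)."""

    number: int
    sub_letter: str | None = None

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValueError("lineage number must be positive")
        if self.sub_letter is not None and (
            len(self.sub_letter) != 1 or not self.sub_letter.isupper()
        ):
            raise ValueError(f"bad sub-letter {self.sub_letter!r}")

    def __str__(self) -> str:
        return f"L{self.number}{self.sub_letter or ''}"

    @classmethod
    def parse(cls, text: str) -> "LineageName":
        m = _NAME_RE.match(text)
        if not m:
            raise ValueError(f"not a lineage name: {text!r}")
        return cls(int(m.group(1)), m.group(2) or None)


@dataclass(frozen=True)
class Signature:
    """A lineage-defining exact pattern with its member OTUs and support."""

    pattern: str
    placement: str
    member_otus: frozenset[str]
    total_reads: int
    name: LineageName | None = None

    def __post_init__(self) -> None:
        if set(self.pattern) - set("ACGT"):
            raise ValueError(f"pattern {self.pattern!r} is not A/C/G/T")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")

    @property
    def length(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class CoreRecord:
    """An OTU's 37F core plus the conserved segment upstream of the anchor."""

    otu_id: str
    core: str
    upstream: str
    total_reads: int


def extract_core(record: OtuRecord, annotation: RegionAnnotation) -> str:
    """Extract the 37F core: the anchor plus its following base (the anchor
    hexamer, ``GACAGG`` in most species) concatenated with the variable span
    up to but excluding the terminal motif."""
    span_start, span_end = annotation.variable_span
    if span_end <= span_start:
        raise ValueError(f"OTU {record.otu_id!r}: empty variable span")
    return record.sequence[annotation.anchor_start:span_end]


def make_core_records(
    kept: Iterable[tuple[OtuRecord, RegionAnnotation]],
) -> list[CoreRecord]:
    """Build discovery inputs from screened records."""
    out = []
    for rec, ann in kept:
        out.append(
            CoreRecord(
                otu_id=rec.otu_id,
                core=extract_core(rec, ann),
                upstream=rec.sequence[: ann.anchor_start],
                total_reads=rec.total_reads,
            )
        )
    return out


# -- candidate generation --------------------------------------------------


def _acgt_prefix(s: str) -> str:
    """Longest prefix of s containing only unambiguous bases."""
    for i, ch in enumerate(s):
        if ch not in "ACGT":
            return s[:i]
    return s


class _TrieNode:
    __slots__ = ("children", "otus")

    def __init__(self) -> None:
        self.children: dict[str, _TrieNode] = {}
        self.otus: list[int] = []  # records terminating exactly here


def _maximal_shared_prefixes(strings: Sequence[str]) -> dict[frozenset[int], int]:
    """Map every maximal index set sharing a common prefix to the length of
    that longest common prefix.  Built with a character trie; sets are the
    leaf sets of branching nodes."""
    root = _TrieNode()
    for idx, s in enumerate(strings):
        node = root
        for ch in s:
            node = node.children.setdefault(ch, _TrieNode())
        node.otus.append(idx)

    # each distinct leafset maps to its maximum recording depth = LCP length;
    # the set changes exactly at branching nodes and OTU-terminating nodes
    result: dict[frozenset[int], int] = {}

    def visit(node: _TrieNode, depth: int) -> set[int]:
        leafset: set[int] = set(node.otus)
        for child in node.children.values():
            leafset |= visit(child, depth + 1)
        if len(node.children) != 1 or node.otus:
            key = frozenset(leafset)
            result[key] = max(result.get(key, 0), depth)
        return leafset

    visit(root, 0)
    return result


def _pattern_in_disallowed_reference(
    pattern: str,
    references: Sequence[ReferenceRecord],
    allowed: frozenset[str],
) -> bool:
    return any(
        ref.category not in allowed and pattern in ref.sequence
        for ref in references
    )


def _minimal_prefix(cores: Sequence[str], members: frozenset[int],
                    full_pattern: str, min_len: int) -> str:
    """Shortest prefix of full_pattern whose member set is unchanged."""
    member_set = set(members)
    for length in range(min_len, len(full_pattern) + 1):
        pat = full_pattern[:length]
        matched = {i for i, c in enumerate(cores) if c.startswith(pat)}
        if matched == member_set:
            return pat
    return full_pattern


def discover_signatures(
    kept: Sequence[tuple[OtuRecord, RegionAnnotation]] | Sequence[CoreRecord],
    references: Sequence[ReferenceRecord],
    config: DiscoveryConfig | None = None,
) -> list[Signature]:
    """Discover unnamed diagnostic signatures among unassigned OTUs.

    Three tiers, in order: prefix-anchored candidates from a prefix trie
    over the cores; leftward upstream extension for prefix candidates
    rejected only by a reference conflict; and suffix-anchored candidates
    over the OTUs no surviving signature covers.  Every emitted signature
    satisfies the length, membership and read thresholds, the reference
    exclusion rule, and membership closure (its members are exactly the
    unassigned OTUs matching the pattern at its placement).
    """
    config = config or DiscoveryConfig()
    if not kept:
        return []
    if isinstance(kept[0], CoreRecord):
        cores: list[CoreRecord] = list(kept)  # type: ignore[arg-type]
    else:
        cores = make_core_records(kept)  # type: ignore[arg-type]

    core_strings = [_acgt_prefix(c.core) for c in cores]
    reads = [c.total_reads for c in cores]

    accepted: list[Signature] = []
    prefix_sets = _maximal_shared_prefixes(core_strings)
    for members, lcp in sorted(
        prefix_sets.items(), key=lambda kv: (sorted(kv[0]), kv[1])
    ):
        if len(members) < config.min_otus:
            continue
        if lcp < config.min_sig_len:
            continue
        any_member = next(iter(members))
        full_pattern = core_strings[any_member][: min(lcp, config.max_sig_len)]
        if config.minimal_patterns:
            pattern = _minimal_prefix(core_strings, members, full_pattern,
                                      config.min_sig_len)
        else:
            pattern = full_pattern
        total = sum(reads[i] for i in members)
        if total <= config.min_reads:
            continue
        if not _pattern_in_disallowed_reference(
            pattern, references, config.allowed_reference_categories
        ):
            accepted.append(Signature(
                pattern=pattern,
                placement="prefix_anchored",
                member_otus=frozenset(cores[i].otu_id for i in members),
                total_reads=total,
            ))
            continue
        # Tier 2: extend leftward into the conserved upstream segment
        rescued = _extend_upstream(pattern, members, cores, references, config)
        if rescued is not None:
            accepted.append(replace(
                rescued,
                member_otus=frozenset(cores[i].otu_id for i in members),
                total_reads=total,
            ))

    accepted = _resolve_overlaps(accepted)

    # Tier 3: suffix-anchored signatures for OTUs no prefix signature covers
    covered = set().union(*[s.member_otus for s in accepted]) if accepted else set()
    leftover_idx = [i for i, c in enumerate(cores) if c.otu_id not in covered]
    if leftover_idx:
        suffix_sigs = _suffix_candidates(
            cores, core_strings, leftover_idx, references, config
        )
        accepted.extend(_resolve_overlaps(suffix_sigs))

    accepted.sort(key=lambda s: (-s.total_reads, s.pattern))
    return accepted


def _extend_upstream(
    pattern: str,
    members: frozenset[int],
    cores: Sequence[CoreRecord],
    references: Sequence[ReferenceRecord],
    config: DiscoveryConfig,
) -> Signature | None:
    """Prepend conserved upstream bases one at a time until the pattern no
    longer occurs in any disallowed reference; bounded by max_sig_len and
    by the common upstream suffix of the members."""
    upstreams = [cores[i].upstream for i in members]
    common = _common_suffix(upstreams)
    common = _acgt_suffix(common)
    room = config.max_sig_len - len(pattern)
    for k in range(1, min(room, len(common)) + 1):
        extended = common[len(common) - k:] + pattern
        if not _pattern_in_disallowed_reference(
            extended, references, config.allowed_reference_categories
        ):
            return Signature(
                pattern=extended,
                placement="upstream_extended",
                member_otus=frozenset(),
                total_reads=0,
            )
    return None


def _common_suffix(strings: Sequence[str]) -> str:
    if not strings:
        return ""
    rev = [s[::-1] for s in strings]
    out = []
    for chars in zip(*rev):
        if len(set(chars)) != 1:
            break
        out.append(chars[0])
    return "".join(out)[::-1]


def _acgt_suffix(s: str) -> str:
    for i in range(len(s) - 1, -1, -1):
        if s[i] not in "ACGT":
            return s[i + 1:]
    return s


def _suffix_candidates(
    cores: Sequence[CoreRecord],
    core_strings: Sequence[str],
    leftover_idx: Sequence[int],
    references: Sequence[ReferenceRecord],
    config: DiscoveryConfig,
) -> list[Signature]:
    # suffix sharing = prefix sharing on reversed cores; the suffix of the
    # core ends right at the terminal motif, the other conserved boundary
    rev = {i: _acgt_prefix(core_strings[i][::-1]) for i in leftover_idx}
    order = sorted(leftover_idx)
    suffix_sets = _maximal_shared_prefixes([rev[i] for i in order])
    out = []
    for members_local, lcs in sorted(
        suffix_sets.items(), key=lambda kv: (sorted(kv[0]), kv[1])
    ):
        members = frozenset(order[j] for j in members_local)
        if len(members) < config.min_otus or lcs < config.min_sig_len:
            continue
        any_member = next(iter(members))
        length = min(lcs, config.max_sig_len)
        pattern = rev[any_member][:length][::-1]
        total = sum(cores[i].total_reads for i in members)
        if total <= config.min_reads:
            continue
        if _pattern_in_disallowed_reference(
            pattern, references, config.allowed_reference_categories
        ):
            continue
        # global closure: the suffix must not also occur in cores already
        # covered by prefix signatures, or membership would be ambiguous
        extra = [
            i for i in range(len(cores))
            if i not in members and core_strings[i].endswith(pattern)
        ]
        if extra:
            continue
        out.append(Signature(
            pattern=pattern,
            placement="suffix_anchored",
            member_otus=frozenset(cores[i].otu_id for i in members),
            total_reads=total,
        ))
    return out


def _resolve_overlaps(candidates: list[Signature]) -> list[Signature]:
    """Maximal-set semantics: drop any candidate whose member set is a
    proper subset of another's; among equal sets keep the longer pattern."""
    keep = []
    for i, sig in enumerate(candidates):
        dominated = False
        for j, other in enumerate(candidates):
            if i == j:
                continue
            if sig.member_otus < other.member_otus:
                dominated = True
                break
            if sig.member_otus == other.member_otus:
                if (len(other.pattern), other.pattern, -j) > (
                    len(sig.pattern), sig.pattern, -i
                ):
                    dominated = True
                    break
        if not dominated:
            keep.append(sig)
    return keep


# -- naming ----------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def name_lineages(
    candidates: Sequence[Signature],
    config: DiscoveryConfig | None = None,
) -> list[Signature]:
    """Assign deterministic L-numbers, with sub-letters for near-identical
    signatures.

    Two signatures share a number when their patterns have equal length and
    Hamming distance 1 (lineages deliberately split by an SNP rather than
    tolerating a mismatch) or share an identical first min_sig_len-mer.
    Numbers follow descending read support (ties broken by pattern);
    sub-letters follow the same order within a group.
    """
    config = config or DiscoveryConfig()
    sigs = sorted(candidates, key=lambda s: (-s.total_reads, s.pattern))
    n = len(sigs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(n):
        for j in range(i + 1, n):
            a, b = sigs[i].pattern, sigs[j].pattern
            same = False
            if len(a) == len(b) and _hamming(a, b) <= config.sublineage_hamming:
                same = True
            elif (len(a) >= config.min_sig_len and len(b) >= config.min_sig_len
                  and a[: config.min_sig_len] == b[: config.min_sig_len]):
                same = True
            if same:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    # groups ordered by their best (first-sorted) member
    ordered = sorted(groups.values(), key=lambda idxs: min(idxs))

    named = [None] * n
    for number, idxs in enumerate(ordered, start=1):
        if len(idxs) == 1:
            i = idxs[0]
            named[i] = replace(sigs[i], name=LineageName(number))
        else:
            for offset, i in enumerate(sorted(idxs)):
                letter = chr(ord("A") + offset)
                named[i] = replace(sigs[i], name=LineageName(number, letter))
    return list(named)  # in descending-reads order


# -- entropy profile -------------------------------------------------------


def positional_entropy(aligned_cores: Sequence[str]) -> np.ndarray:
    """Per-column Shannon entropy (bits) of an alignment of cores.

    Gap characters and ambiguities are excluded from the counts; a column
    with no usable character has entropy 0 (with a warning).
    """
    if not aligned_cores:
        raise ValueError("no sequences")
    lengths = {len(s) for s in aligned_cores}
    if len(lengths) != 1:
        raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
    width = lengths.pop()
    out = np.zeros(width)
    for col in range(width):
        counts: dict[str, int] = {}
        for s in aligned_cores:
            ch = s[col]
            if ch in "ACGT":
                counts[ch] = counts.get(ch, 0) + 1
        total = sum(counts.values())
        if total == 0:
            warnings.warn(f"column {col}: no usable characters, entropy set to 0")
            continue
        out[col] = -sum(
            (c / total) * math.log2(c / total) for c in counts.values()
        )
    return out
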