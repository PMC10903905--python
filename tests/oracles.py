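"""Independent brute-force oracles for discovery and matching.

These deliberately avoid the package's trie and automaton code paths: every
candidate group is found by enumerating all prefixes/suffixes of every core
and every match by a per-pattern text scan.
"""

from __future__ import annotations

from typing import Sequence

from foramsig.discovery import CoreRecord, DiscoveryConfig
from foramsig.seqio import ReferenceRecord


def _acgt_prefix(s: str) -> str:
    for i, ch in enumerate(s):
        if ch not in "ACGT":
            return s[:i]
    return s


def _acgt_suffix(s: str) -> str:
    for i in range(len(s) - 1, -1, -1):
        if s[i] not in "ACGT":
            return s[i + 1:]
    return s


def _common_suffix(strings):
    if not strings:
        return ""
    out = []
    for chars in zip(*[s[::-1] for s in strings]):
        if len(set(chars)) != 1:
            break
        out.append(chars[0])
    return "".join(out)[::-1]


def _resolve(cands):
    keep = []
    for i, (pat, plc, members, total) in enumerate(cands):
        dominated = False
        for j, (pat2, _, members2, _) in enumerate(cands):
            if i == j:
                continue
            if members < members2:
                dominated = True
                break
            if members == members2 and (len(pat2), pat2, -j) > (len(pat), pat, -i):
                dominated = True
                break
        if not dominated:
            keep.append((pat, plc, members, total))
    return keep


def brute_force_discover(
    cores: Sequence[CoreRecord],
    references: Sequence[ReferenceRecord],
    config: DiscoveryConfig | None = None,
) -> set[tuple[str, str, frozenset[str], int]]:
    """Exhaustive-search reference implementation of signature discovery."""
    config = config or DiscoveryConfig()
    strings = [_acgt_prefix(c.core) for c in cores]
    reads = [c.total_reads for c in cores]

    def in_disallowed(pat: str) -> bool:
        return any(
            ref.category not in config.allowed_reference_categories
            and pat in ref.sequence
            for ref in references
        )

    # every maximal prefix-sharing set, with its longest common prefix
    prefix_sets: dict[frozenset[int], int] = {}
    for s in strings:
        for L in range(1, len(s) + 1):
            pat = s[:L]
            members = frozenset(
                j for j, t in enumerate(strings) if t.startswith(pat)
            )
            prefix_sets[members] = max(prefix_sets.get(members, 0), L)

    accepted = []
    for members, lcp in prefix_sets.items():
        if len(members) < config.min_otus or lcp < config.min_sig_len:
            continue
        total = sum(reads[i] for i in members)
        if total <= config.min_reads:
            continue
        pattern = strings[min(members)][: min(lcp, config.max_sig_len)]
        if not in_disallowed(pattern):
            accepted.append((pattern, "prefix_anchored", members, total))
            continue
        common = _acgt_suffix(
            _common_suffix([cores[i].upstream for i in members])
        )
        room = config.max_sig_len - len(pattern)
        for k in range(1, min(room, len(common)) + 1):
            extended = common[len(common) - k:] + pattern
            if not in_disallowed(extended):
                accepted.append((extended, "upstream_extended", members, total))
                break

    accepted = _resolve(accepted)

    covered = set()
    for _, _, members, _ in accepted:
        covered |= members
    leftovers = [i for i in range(len(cores)) if i not in covered]
    rev = {i: _acgt_prefix(strings[i][::-1])[::-1] for i in leftovers}
    suffix_sets: dict[frozenset[int], int] = {}
    for i in leftovers:
        s = rev[i]
        for L in range(1, len(s) + 1):
            pat = s[len(s) - L:]
            members = frozenset(j for j in leftovers if rev[j].endswith(pat))
            suffix_sets[members] = max(suffix_sets.get(members, 0), L)

    suffix_accepted = []
    for members, lcs in suffix_sets.items():
        if len(members) < config.min_otus or lcs < config.min_sig_len:
            continue
        total = sum(reads[i] for i in members)
        if total <= config.min_reads:
            continue
        s = rev[min(members)]
        pattern = s[len(s) - min(lcs, config.max_sig_len):]
        if in_disallowed(pattern):
            continue
        if any(i not in members and strings[i].endswith(pattern)
               for i in range(len(cores))):
            continue
        suffix_accepted.append((pattern, "suffix_anchored", members, total))

    out = accepted + _resolve(suffix_accepted)
    return {
        (pat, plc, frozenset(cores[i].otu_id for i in members), total)
        for pat, plc, members, total in out
    }


def signature_set(signatures) -> set[tuple[str, str, frozenset[str], int]]:
    return {
        (s.pattern, s.placement, s.member_otus, s.total_reads)
        for s in signatures
    }
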