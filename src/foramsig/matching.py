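"""Exact multi-pattern substring search (Aho–Corasick automaton).

Signature classification is zero-mismatch by construction, so matching is
plain substring containment; the automaton makes one pass over each
sequence regardless of how many signature patterns are loaded.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Sequence


class AhoCorasick:
    """Classic goto/fail automaton over an arbitrary character alphabet."""

    def __init__(self, patterns: Iterable[str]) -> None:
        self._patterns: list[str] = []
        self._goto: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._output: list[list[int]] = [[]]
        for pat in patterns:
            self._insert(pat)
        self._build_failure_links()

    def _insert(self, pattern: str) -> None:
        if not pattern:
            raise ValueError("empty pattern")
        state = 0
        for ch in pattern:
            nxt = self._goto[state].get(ch)
            if nxt is None:
                nxt = len(self._goto)
                self._goto.append({})
                self._fail.append(0)
                self._output.append([])
                self._goto[state][ch] = nxt
            state = nxt
        self._output[state].append(len(self._patterns))
        self._patterns.append(pattern)

    def _build_failure_links(self) -> None:
        queue: deque[int] = deque()
        for child in self._goto[0].values():
            queue.append(child)
        while queue:
            state = queue.popleft()
            for ch, child in self._goto[state].items():
                queue.append(child)
                f = self._fail[state]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[child] = self._goto[f].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                self._output[child] = (
                    self._output[child] + self._output[self._fail[child]]
                )

    def find_all(self, text: str) -> list[tuple[int, int]]:
        """All (pattern_index, start_position) occurrences in text."""
        hits: list[tuple[int, int]] = []
        state = 0
        for pos, ch in enumerate(text):
            while state and ch not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(ch, 0)
            for pat_idx in self._output[state]:
                hits.append((pat_idx, pos - len(self._patterns[pat_idx]) + 1))
        return hits

    def matching_patterns(self, text: str) -> set[int]:
        """Indices of patterns occurring at least once in text."""
        return {idx for idx, _ in self.find_all(text)}


def naive_find_all(patterns: Sequence[str], text: str) -> list[tuple[int, int]]:
    """Per-pattern scan oracle: same output contract as AhoCorasick.find_all."""
    hits = []
    for idx, pat in enumerate(patterns):
        start = 0
        while True:
            pos = text.find(pat, start)
            if pos < 0:
                break
            hits.append((idx, pos))
            start = pos + 1
    return hits
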