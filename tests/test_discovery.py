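import numpy as np
import pytest

from conftest import make_amplicon, random_acgt
from oracles import brute_force_discover, signature_set
from foramsig.discovery import (
    CoreRecord,
    DiscoveryConfig,
    LineageName,
    Signature,
    discover_signatures,
    extract_core,
    make_core_records,
    name_lineages,
    positional_entropy,
)
from foramsig.screen import annotate_regions
from foramsig.seqio import OtuRecord, ReferenceRecord
from foramsig.simulate import CONSERVED_UPSTREAM


def core(otu_id, seq, reads, upstream=CONSERVED_UPSTREAM):
    return CoreRecord(otu_id=otu_id, core=seq, upstream=upstream, total_reads=reads)


def ref(rid, seq, category):
    return ReferenceRecord(rid, seq, rid, category)


class TestExtractCore:
    def test_core_is_anchor_hexamer_plus_variable_span(self):
        seq = "AAGACAGGTTTTCCCCTAGTCCTTT"
        rec = OtuRecord("x", seq, {"s": 10})
        ann = annotate_regions(seq)
        assert extract_core(rec, ann) == "GACAGGTTTTCCCC"

    def test_non_g_sixth_base_kept_as_observed(self):
        seq = "AAGACAGTTTTCCCCTAGTCCTTT"
        rec = OtuRecord("x", seq, {"s": 10})
        assert extract_core(rec, annotate_regions(seq)).startswith("GACAGT")

    def test_empty_span_raises(self):
        seq = "AAGACAGTAGTCCTTT"
        rec = OtuRecord("x", seq, {"s": 10})
        with pytest.raises(ValueError):
            extract_core(rec, annotate_regions(seq))

    def test_core_length_tracks_span_bounds(self):
        rng = np.random.default_rng(1)
        for span_len in (68, 120, 196):
            span = "G" + random_acgt(rng, span_len - 1)
            seq = make_amplicon(span)
            rec = OtuRecord("x", seq, {"s": 10})
            got = extract_core(rec, annotate_regions(seq))
            assert len(got) == 5 + span_len


class TestDiscoverSignatures:
    def test_shared_prefix_group_with_read_support(self):
        shared = "GACAGGTTTTCCCC"
        cores = [
            core("a", shared + "AATA" * 10, 3000),
            core("b", shared + "CGCC" * 10, 2000),
            core("c", shared + "GTAG" * 10, 1500),
            core("d", "GACAGGAAAA" + "TGCA" * 10, 1000),
            core("e", "GACAGGCCCC" + "ATGC" * 10, 1000),
        ]
        sigs = discover_signatures(cores, [])
        assert len(sigs) == 1
        sig = sigs[0]
        assert sig.pattern == shared
        assert sig.member_otus == frozenset({"a", "b", "c"})
        assert sig.total_reads == 6500
        assert sig.placement == "prefix_anchored"

    def test_4999_reads_is_below_threshold(self):
        shared = "GACAGGTTTTCCCC"
        cores = [
            core("a", shared + "AATA" * 10, 2999),
            core("b", shared + "CGCC" * 10, 2000),
        ]
        assert discover_signatures(cores, []) == []
        cores[0] = core("a", shared + "AATA" * 10, 3001)  # total 5001 > 5000
        assert len(discover_signatures(cores, [])) == 1

    def test_single_otu_group_is_not_a_lineage(self):
        cores = [core("a", "GACAGGTTTTCCCC" + "AATA" * 10, 9000)]
        assert discover_signatures(cores, []) == []

    def test_reference_exclusion_and_enfor_exemption(self):
        shared = "GACAGGTTTTCCCC"
        cores = [
            core("a", shared + "AATA" * 10, 3000),
            core("b", shared + "CGCC" * 10, 3000),
        ]
        # pattern present in a described clade (and its extensions too):
        # candidate rejected outright
        blocking = ref("clade_a", CONSERVED_UPSTREAM + shared + "AATA" * 10,
                       "described_clade")
        blocking2 = ref("clade_a2", CONSERVED_UPSTREAM + shared + "CGCC" * 10,
                        "described_clade")
        assert discover_signatures(cores, [blocking, blocking2]) == []
        # the same pattern occurring only in an ENFOR reference is exempt
        enfor = ref("enfor1", "TT" + shared + "GGAA", "ENFOR")
        sigs = discover_signatures(cores, [enfor])
        assert len(sigs) == 1 and sigs[0].placement == "prefix_anchored"

    def test_upstream_extension_escapes_reference_conflict(self):
        shared = "GACAGGTTTTCCCC"
        cores = [
            core("a", shared + "AATA" * 10, 3000),
            core("b", shared + "CGCC" * 10, 3000),
        ]
        # decoy carries the pattern but NOT the conserved upstream flank, so
        # one extra upstream base distinguishes the lineage from it
        decoy = ref("clade_a", "CCCCC" + shared + "GGGG", "described_clade")
        sigs = discover_signatures(cores, [decoy])
        assert len(sigs) == 1
        sig = sigs[0]
        assert sig.placement == "upstream_extended"
        assert sig.pattern.endswith(shared) and len(sig.pattern) == len(shared) + 1
        assert sig.pattern[0] == CONSERVED_UPSTREAM[-1]
        assert sig.member_otus == frozenset({"a", "b"})

    def test_suffix_signature_for_prefix_indistinguishable_otus(self):
        tail = "TTACGTACGTAC"
        cores = [
            core("a", "GACAGGAAAA" + "ATCG" * 8 + tail, 4000),
            core("b", "GACAGGCCCC" + "GCTA" * 8 + tail, 4000),
        ]
        sigs = discover_signatures(cores, [])
        assert len(sigs) == 1
        assert sigs[0].placement == "suffix_anchored"
        assert sigs[0].pattern.endswith(tail)
        assert sigs[0].member_otus == frozenset({"a", "b"})

    def test_empty_input(self):
        assert discover_signatures([], []) == []

    def test_pattern_capped_at_max_sig_len(self):
        shared = "GACAGG" + "A" * 80
        cores = [
            core("a", shared + "CT" * 10, 3000),
            core("b", shared + "GA" * 10, 3000),
        ]
        sigs = discover_signatures(cores, [])
        assert len(sigs[0].pattern) == DiscoveryConfig().max_sig_len

    def test_minimal_pattern_mode_keeps_membership(self):
        shared = "GACAGGTTTTCCCCAAAA"
        cores = [
            core("a", shared + "AATA" * 10, 3000),
            core("b", shared + "CGCC" * 10, 3000),
            core("c", "GACAGGAAAA" + "TGCA" * 10, 6000),
            core("d", "GACAGGACCA" + "GGAA" * 10, 6000),
        ]
        full = discover_signatures(cores, [])
        minimal = discover_signatures(
            cores, [], DiscoveryConfig(minimal_patterns=True))
        by_members_full = {s.member_otus: s.pattern for s in full}
        by_members_min = {s.member_otus: s.pattern for s in minimal}
        assert by_members_full.keys() == by_members_min.keys()
        for members, pat in by_members_min.items():
            assert len(pat) <= len(by_members_full[members])
            assert pat >= by_members_full[members][: len(pat)]

    def test_threshold_monotonicity(self, decoy_simulation):
        from foramsig.screen import screen_dataset

        _, (records, _, refs, _) = decoy_simulation
        kept, _ = screen_dataset(records)
        cores = make_core_records(kept)
        base = len(discover_signatures(cores, refs))
        for cfg in (DiscoveryConfig(min_reads=20000),
                    DiscoveryConfig(min_otus=4)):
            assert len(discover_signatures(cores, refs, cfg)) <= base

    def test_closure_and_exclusion_soundness(self, decoy_simulation):
        from foramsig.screen import screen_dataset

        _, (records, _, refs, _) = decoy_simulation
        kept, _ = screen_dataset(records)
        cores = make_core_records(kept)
        config = DiscoveryConfig()
        sigs = discover_signatures(cores, refs, config)
        assert sigs
        core_by_id = {c.otu_id: c for c in cores}
        for sig in sigs:
            # signature invariants
            assert config.min_sig_len <= sig.length <= config.max_sig_len
            assert len(sig.member_otus) >= config.min_otus
            assert sig.total_reads > config.min_reads
            # exclusion soundness by naive scan
            for r in refs:
                if r.category not in config.allowed_reference_categories:
                    assert sig.pattern not in r.sequence
            # membership closure at the declared placement
            if sig.placement == "prefix_anchored":
                matched = {c.otu_id for c in cores
                           if c.core.startswith(sig.pattern)}
                assert sig.pattern.startswith("GACAG")
            elif sig.placement == "suffix_anchored":
                matched = {c.otu_id for c in cores
                           if c.core.endswith(sig.pattern)}
            else:
                # pattern crosses the anchor boundary: starts k bases into
                # the upstream flank and continues as a core prefix
                matched = set()
                for c in cores:
                    joined = c.upstream + c.core
                    for k in range(1, len(sig.pattern)):
                        p = len(c.upstream) - k
                        if p >= 0 and joined.startswith(sig.pattern, p):
                            matched.add(c.otu_id)
                            break
            assert matched == set(sig.member_otus)

    def test_trie_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            cores, refs = _random_instance(rng)
            got = signature_set(discover_signatures(cores, refs))
            want = brute_force_discover(cores, refs)
            assert got == want


def _random_instance(rng, n_max=20):
    """Small random discovery instance with planted prefix structure."""
    prototypes = ["GACAGG" + random_acgt(rng, 54) for _ in range(3)]
    n = int(rng.integers(4, n_max))
    cores = []
    for i in range(n):
        proto = prototypes[int(rng.integers(0, len(prototypes)))]
        cut = int(rng.integers(6, len(proto)))
        s = proto[:cut] + random_acgt(rng, 60 - cut)
        cores.append(CoreRecord(f"o{i}", s, CONSERVED_UPSTREAM,
                                int(rng.integers(500, 8000))))
    refs = []
    if rng.random() < 0.6:
        proto = prototypes[int(rng.integers(0, len(prototypes)))]
        L = int(rng.integers(12, 30))
        cat = ["described_clade", "ENFOR"][int(rng.integers(0, 2))]
        flank = CONSERVED_UPSTREAM if rng.random() < 0.5 else random_acgt(rng, 10)
        refs.append(ReferenceRecord(
            "r1", flank + proto[:L] + random_acgt(rng, 20), "r1", cat))
    return cores, refs


class TestNameLineages:
    def _sig(self, pattern, reads):
        return Signature(pattern=pattern, placement="prefix_anchored",
                         member_otus=frozenset({"a", "b"}), total_reads=reads)

    def test_snp_pair_becomes_sublineages(self):
        a = self._sig("GACAGGTTTTCCCC", 9000)
        b = self._sig("GACAGGTTTTCCCG", 6000)  # Hamming distance 1
        named = name_lineages([a, b])
        assert [str(s.name) for s in named] == ["L1A", "L1B"]
        # higher read support gets the earlier letter
        assert named[0].total_reads == 9000

    def test_isolated_pattern_gets_plain_number(self):
        a = self._sig("GACAGGTTTTCCCC", 9000)
        b = self._sig("GACAGGTTTTCCCG", 6000)
        c = self._sig("GACAGGAAAAAAGG", 5500)
        named = name_lineages([a, b, c])
        assert sorted(str(s.name) for s in named) == ["L1A", "L1B", "L2"]

    def test_shared_first_12mer_groups(self):
        a = self._sig("GACAGGTTTTCCCCAAAA", 9000)
        b = self._sig("GACAGGTTTTCCGGGGGGGG", 6000)  # same first 12-mer
        named = name_lineages([a, b])
        assert [str(s.name) for s in named] == ["L1A", "L1B"]

    def test_numbering_follows_read_support(self):
        low = self._sig("GACAGGAAAAAAGG", 5200)
        high = self._sig("GACAGGTTTTCCCC", 9000)
        named = name_lineages([low, high])
        by_name = {str(s.name): s for s in named}
        assert by_name["L1"].total_reads == 9000
        assert by_name["L2"].total_reads == 5200

    def test_order_permutation_invariance(self):
        sigs = [
            self._sig("GACAGGTTTTCCCC", 9000),
            self._sig("GACAGGTTTTCCCG", 6000),
            self._sig("GACAGGAAAAAAGG", 5500),
            self._sig("GACAGGCCGGCCGG", 7000),
        ]
        ref_names = {s.pattern: str(s.name) for s in name_lineages(sigs)}
        rng = np.random.default_rng(5)
        for _ in range(10):
            perm = list(sigs)
            rng.shuffle(perm)
            got = {s.pattern: str(s.name) for s in name_lineages(perm)}
            assert got == ref_names


class TestPositionalEntropy:
    def test_closed_form_columns(self):
        cols = positional_entropy(["AAC", "AAC", "ACG", "ACT"])
        # col0 all A -> 0; col1 {A,A,C,C} -> 1 bit
        assert cols[0] == 0.0
        assert cols[1] == pytest.approx(1.0)

    def test_uniform_column_is_two_bits(self):
        assert positional_entropy(["A", "C", "G", "T"])[0] == pytest.approx(2.0)

    def test_gaps_excluded_and_empty_column_warns(self):
        with pytest.warns(UserWarning):
            cols = positional_entropy(["-A", "-C"])
        assert cols[0] == 0.0 and cols[1] == pytest.approx(1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            positional_entropy(["AA", "A"])
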