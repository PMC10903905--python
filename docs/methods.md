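# Methods

## Model and assumptions

`foramsig` treats a foraminiferal 37F amplicon as three parts: a conserved
segment upstream of the pentamer anchor `GACAG` (the 3' end of helix 37
and the helices before it), the hypervariable 37F expansion segment of
68–196 nt, and a conserved terminal nonamer `TAGTCCTTT` (or its `TAGTCCCTT`
T>C variant) closing the region. Datasets amplified with a two-region
primer pair additionally contain the helix-38 motif `GGTGGT`, which
replaces the terminal nonamer as the screening landmark. The method
assumes amplicons are primer-oriented (single strand); an optional
reverse-complement rescue flag exists but is off by default.

Diagnostic variability is assumed to rise steeply at the start of 37F,
immediately after the anchor hexamer `GACAGG`. Signatures are therefore
sought in three placement classes: anchored at the hexamer and extending
into 37F (the dominant class), extended leftward into the conserved
helix-35/36 segment when a prefix pattern collides with a reference taxon,
and anchored at the end of 37F for OTU sets that prefixes cannot separate.

## Screening rules

* Anchor and terminal motifs are both required; a record missing either is
  discarded with a named verdict. If several anchor copies precede the
  terminal, the last copy — the one abutting 37F — is used and the record
  is flagged `ambiguous_anchor` (still kept).
* Length and abundance thresholds are strict inequalities: kept iff
  length > 70 bp and reads > 100. The length filter applies to the full
  retained sequence by default; a `length_on_core` switch restricts it to
  the 37F span for pipelines that trim flanks upstream.
* Conserved-region QC compares each record's pre-anchor segment
  (right-aligned at the anchor, trimmed to the consensus length) against a
  majority-rule consensus of reference upstream segments, by Levenshtein
  distance plus one edit per ambiguous base; more than `max_conserved_edits`
  (default 2, a conservative reading of a stated 2–3 range) fails QC.
  Consensus ties break alphabetically (A < C < G < T) for determinism.

## Signature discovery

Cores (anchor + 37F span, up to but excluding the terminal) are inserted
into a character trie, truncated at the first non-ACGT base — patterns are
defined over unambiguous bases only. Every maximal OTU set sharing a common
prefix of at least `min_sig_len` (default 12) is a candidate; its pattern
is the longest common prefix capped at `max_sig_len` (default 53). Longer
patterns reduce the risk of misidentification, so the cap — not a minimal
discriminating prefix — is the default; a `minimal_patterns` switch yields
the shortest prefix with unchanged membership instead.

Validation requires at least `min_otus` members (default 2) and strictly
more than `min_reads` supporting reads (default 5000), and the exclusion
rule: the pattern must occur in no reference sequence whose category is
outside the exempt set (ENFOR and Monothalamids X, themselves environmental
groups). A candidate failing only the exclusion rule is retried with the
members' common upstream bases prepended one at a time (Tier 2,
`upstream_extended`), bounded by `max_sig_len`. OTUs covered by no
surviving candidate are regrouped by common core suffix (Tier 3,
`suffix_anchored`) under the same validation; a suffix candidate whose
pattern also terminates a covered OTU's core is dropped so that membership
closure — members are exactly the unassigned OTUs matching at the declared
placement — holds globally.

Overlapping candidates (member set a proper subset of another's) resolve
to the larger set; equal sets resolve to the longer pattern. This gives
maximal-set semantics: a group and its sub-groups yield one signature
unless the parent is itself invalid.

Naming is deterministic: signatures sort by descending read support (ties
by pattern), and two signatures share an L-number — becoming sub-lineages
A, B, … — when their patterns are equal-length with Hamming distance 1, or
share an identical first `min_sig_len`-mer. The Hamming-1 rule formalises
the policy of splitting lineages at an SNP rather than tolerating a
mismatch; it is a configurable approximation, not a published formula.

## Classification and merging

Matching is placement-blind, exact substring containment on the forward
strand, implemented as an Aho–Corasick automaton (one pass per sequence
regardless of the number of patterns); a naive per-pattern scan serves as
the independent oracle in tests. Multiple hits resolve to the longest
pattern, with every hit recorded in a conflict note. Merging with a prior
taxonomy keeps well-defined prior taxa (recording suppressed hits) and
lets lineages override unassigned, ENFOR, Monothalamids X and undetermined
monothalamid priors; the merge is idempotent.

## Biogeography

Relative abundance is computed within areas (each area column divided by
its column total over lineage-assigned reads); a flag-free remainder
records unassigned reads so totals are conserved. Presence defaults to
≥ 1 read (configurable; no published cut-off exists). Endemism to a focal
area set means presence in at least one focal area and absence elsewhere.
Habitat overlap uses UpSet semantics: each OTU (deduplicated by id) counts
in exactly the cell matching its full habitat combination, so cells
partition each lineage's OTU set.

## Synthetic communities

The generator emulates the study conditions: 37F spans of 68–196 nt,
signature lengths of 12–53 nt (including the anchor hexamer), lineages of
3–6 OTUs with read support guaranteed above the validation thresholds,
50 noise OTUs and a handful of anchor-free contaminants, lognormal read
totals (median 2500, σ = 1.0) spread multinomially over samples through a
per-area occupancy mask (presence probability 0.5), and a CCFZ-dominated
area layout (four CCFZ areas, one other deep-sea basin, one shallow site,
two samples each). Lineage signature prefixes are drawn to be distinct
within the first `min_sig_len` bases, and noise cores carry unique
prefixes — without this, coincidentally shared prefixes would merge
planted groups and recovery would not be identifiable. Spans are drawn
free of internal anchor/terminal motifs, matching the single-adjacent-
anchor structure real 37F amplicons show.

Decoy references exercise the exclusion rule. A described-clade decoy
embeds, for each member of its target lineage, the conserved upstream
flank plus that member's core prefix: this blocks the candidate, all of
its sub-group candidates, and every leftward extension, so the target
lineage is genuinely rejected. Exempt-category decoys (ENFOR,
Monothalamids X) embed the bare pattern; the candidate survives by the
exemption.

What the simulator does **not** emulate: sequencing error at read level,
chimeras, indel-rich length variation inside lineages, phylogenetic
correlation between lineages, or realistic taxon-abundance skew across
habitats. Passing the planted-recovery tests therefore demonstrates
algorithmic correctness under the stated structural assumptions, not
robustness to sequencing artefacts — those are handled upstream by
denoising/clustering tools whose outputs this package consumes.

## Numerical and design choices

* Coordinates are 0-based, half-open throughout.
* All randomness flows from a single `numpy` generator per seed; outputs
  are byte-identical across runs for a fixed seed.
* Entropy profiles use per-column Shannon entropy in bits over A/C/G/T,
  excluding gaps and ambiguities; an empty column is 0 with a warning.
* Edit distances use `edlib` (global alignment); ties and orderings
  everywhere break deterministically (reads first, then lexicographic).
* Problem sizes in the test and acceptance suites (10 lineages × 3–6
  OTUs, 50 noise OTUs, 100 seeded replicates, 1,000 oracle instances) were
  chosen as the smallest sizes at which the planted structure exercises
  every rule — groups, decoys, sub-threshold noise — while keeping the
  whole suite fast enough for routine use.

## Known limitations

* Signature discovery formalises with a trie what was originally a partly
  manual grouping; placement classes match, but the exact historical
  groupings of any given dataset may differ at the margin.
* Sub-lineage naming depends on the Hamming-1 / shared-12-mer rule and on
  read-support ordering; different thresholds yield different letterings
  (never different memberships).
* Exact matching is brittle to sequencing error by construction; an OTU
  one SNP away from a signature is deliberately excluded.
* Helix boundaries (35/36/37-II) are not modelled explicitly; upstream
  extension is bounded only by the maximum signature length.
* Phylogenetic placement of lineages into higher clades is out of scope;
  it requires external alignment and tree inference.
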