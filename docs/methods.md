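# Methods

## The store

The compiled database is a set of flat, dense, first-seen-order string
tables — names, accessions, sequences, descriptions — plus per-version
membership maps.  A membership record for `(version ordinal, accession
index)` holds integer indices into the string tables, an optional family
index, and, for precursors, product links `(mature index, arm, start, end)`
with 1-based inclusive hairpin coordinates.  Alias histories map an
accession index to the ordered list of name indices it has carried.

Two properties follow by construction and are enforced by
`validate_database` and the test suite:

* **dedup exactness** — each distinct string is stored exactly once; the
  stored counts equal what a linear scan of the raw releases finds;
* **losslessness** — `rebuild_release` reconstructs any registered release
  field-for-field from the indices, so the store is an equivalent, not a
  summary, of its inputs.

Version ordering is an explicit ordinal supplied at build time and never
parsed out of the label (real release labels include `7.1`, `9.2`).
Ties and orderings everywhere else are deterministic: entries sort by
accession, interning follows that order, so a build is a pure function of
the parsed release sequence.

Persistence is canonical JSON (sorted keys, no whitespace) behind a single
zlib stream, prefixed by a magic tag and a one-byte schema version.  No
timestamps are embedded, so `save` is deterministic and `save . load . save`
is byte-stable.  A foreign or truncated file fails loudly; no partial
database is ever returned.  zlib was chosen over heavier codecs because the
payload after dedup is small and the stdlib codec keeps the file
dependency-free.

## Parsing

`miRNA.dat` uses the legacy EMBL dialect (old-style `ID` lines, `FT miRNA`
features with `/accession` and `/product` qualifiers, `SQ` blocks).  The
reader is a dedicated line-based parser so that errors carry entry names and
line numbers; unknown line tags (citation lines and the like) are skipped
with a logged warning rather than an error.  FASTA goes through Bio.SeqIO.
Sequences are uppercased RNA with `T -> U` transliteration on input, and
anything outside `{A,C,G,U}` is a parse error.

**Arm inference** for a mature product, in precedence order: an explicit
`-5p`/`-3p` name suffix; otherwise the midpoint rule — a product wholly in
the first half of the hairpin (`2*end <= L`) is 5', wholly in the second
half (`2*start >= L`) is 3'; products straddling the midpoint are `unknown`.
This mirrors the naming semantics without requiring secondary-structure
files, which are ignored (as is `dead.txt`: death is inferred from absence
in later releases, which the alias files corroborate).

Alias merging: the observed cross-release name diffs build each accession's
history; a shipped `aliases.txt` is treated as the chronological spine when
present (it may know pre-era and intermediate names), with observed names it
lacks appended in observed order.  The invariant kept is that the last
element equals the current name whenever the accession is alive.

## Query semantics

Matching precedence is accession-exact, then name-exact (case-sensitive),
then case-folded.  Case matters in storage because miRBase encodes the
entity class in it (`mir` precursor vs `miR` mature); the case-folded
fallback exists for user convenience, and a folded hit that could be either
class is returned as `ambiguous` with both candidates listed rather than
silently picked.  The alive/dead dichotomy is refined to three statuses:
`dead` (known to an earlier version, gone from the target) is distinguished
from `not_found` (never seen), because the two call for different downstream
actions.  Unmatched inputs never raise — every batch operation returns one
ordered block of rows per input, mirroring the result-table contract of the
original web interface.

`check_version` pools precursor and mature names jointly (inputs in practice
mix both), counts a version's matched proportion over non-empty,
non-accession inputs, and breaks ties toward the highest ordinal.  When a
conversion has to infer its source version, the inferred label and its
matched proportion are emitted on the log channel for auditability.
`version_convert` is strict about its pipeline — resolve in the source
version, bridge by accession, name in the target version — so a name absent
from the declared source comes back `not_found` rather than being silently
matched elsewhere.

## The synthetic generator

The generator emulates the repository's documented evolution, not its
biology: sequences are uniform random RNA (hairpins 60–120 nt, matures
19–24 nt placed so the midpoint rule recovers the intended arm), and no
secondary structure or realistic sequence evolution is modeled.  What it
does model, per step and per entry:

| parameter                 | default | meaning                                   |
|---------------------------|---------|-------------------------------------------|
| `birth_rate`              | 0.08    | chance an existing entry spawns a new one |
| `kill_rate`               | 0.05    | chance an entry is removed (misannotation)|
| `rename_rate`             | 0.10    | chance of a fresh name (accession fixed)  |
| `arm_redesignation_rate`  | 0.05    | chance a star pair switches to `-5p`/`-3p`|
| `n_initial_precursors`    | 40      | founding population                       |
| `species_pool`            | hsa, mmu, dme, cel | name prefixes drawn uniformly  |

The four rates are per-entry-per-step probabilities of mutually exclusive
events (their sum is capped at 1).  Defaults are small because real
inter-release churn is modest relative to the standing population; tests
that need distinguishable versions raise `rename_rate` to 0.3, which is the
regime in which version inference is exercised.

The **rule schedule** drives the era transitions and defaults to the
documented history: `-as` retired at v16 (legacy names allowed in that
version, scrubbed by forced rename at the next release, no new ones after),
star retirement and forced arm suffixes at v17 for fly, v18 for
human/mouse/worm, v19 globally.  Renamed entries never reuse a retired name,
a rename revises the sequence with probability 0.5 (three point mutations —
exercising the dedup logic both ways), and each precursor joins a family
named after its base number with probability 0.8.

Every change is logged as an event `(version, kind, accession, old_name,
new_name)`.  Replaying the log reproduces each release's identity layer —
the per-version alive-accession set and accession-to-name map — exactly;
sequence payloads and coordinates live only in the releases themselves,
since the event vocabulary does not carry them.  The log is the oracle for
rename/kill/status tests, while content-level tests (sequences, tables,
families) check against brute-force scans of the raw parsed releases.

What passing these tests shows: the machinery is exact on inputs that follow
the documented grammar and evolution rules.  What it does not show:
robustness to the long tail of real-repository irregularities (multi-parent
matures are supported and tested, but e.g. species-code drift inside an
accession is treated as corruption and refused at build time).

## The demo fixture

`demo_history()` is hand-built, not generated: four releases labeled v16,
v17, v19 and v22 (release dates match the real calendar for those labels)
containing an `-as` rename chain, a mature killed before the final release,
and star pairs that transition to arm suffixes at the species-correct
stages.  All accessions sit in a reserved synthetic `09xxxxx` range so they
cannot collide with, or be mistaken for, real repository records.

## Problem sizes

The test suite and the acceptance script use twenty seeded histories of
15–35 founding precursors over 3–5 versions — small enough that exhaustive
dual-route checking of every entity against linear scans stays fast, large
enough that every event kind and rule transition occurs many times per run.
Version-inference recovery is measured over 100 trials of 20 sampled names.

## Known limitations

* Genomic-coordinate (GFF) annotation, secondary structure, and live
  download of real releases are out of scope; the builder consumes local
  release directories.
* Fuzzy or edit-distance name matching is deliberately absent: anything
  beyond case-folding risks silent misidentification in batch use.
* A name that maps to different accessions in different versions is resolved
  per version; cross-version name reuse inside one history is excluded by
  the generator and unhandled ambiguity in real data would surface as an
  `ambiguous` row, not a guess.
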