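# mirversions

Batch conversion and retrieval of miRNA annotation across repository
release versions.

## The problem

miRBase, the reference repository for miRNA annotation, renames,
re-annotates and retires entries between releases while each record's
**accession** (`MI0000001` for a precursor hairpin, `MIMAT0000001` for a
mature miRNA, `MIPF0000001` for a family) stays fixed for life.  The name
changes were substantial: the antisense "`-as`" suffix was abandoned at
version 16, and the guide/passenger `miR`/`miR*` convention was replaced by
explicit `-5p`/`-3p` arm suffixes in stages between versions 17 and 19.
Public target databases and published gene lists freeze whichever names were
current at their time of writing, so integrating two miRNA resources almost
always means reconciling identifiers minted under different releases.

`mirversions` compiles a set of miRBase-style release directories into a
single deduplicated, index-structured database (`.mirdb`) and answers batch
queries over it:

* **check** — alive/dead status, most probable source version of a name
  list, family membership;
* **convert** — name ↔ accession, name → name across versions (the
  accession is the bridge), precursor ↔ mature;
* **retrieve** — sequences, per-version name histories, complete
  per-version data tables, species and version statistics;
* **link** — stable URLs into the upstream website.

Every distinct name, accession and sequence string is stored once; dense
integer indices and per-version membership maps tie them together, so any
single release can be reconstructed losslessly while content shared between
releases costs nothing extra.

Because real release payloads are large and external, the package also ships
a **synthetic release generator** that emulates the documented nomenclature
evolution (births, kills, renames, the `-as` retirement, the staged
star-to-arm-suffix transition) and emits a ground-truth event log.  The
generator is first-class, tested code: it defines the study conditions for
every quantitative claim the test suite makes.

## The version-inference statistic

Given an input list of names *S* and a release *v* with name pool *N(v)*
(precursor and mature names pooled), the matched proportion is

    p(v) = |{s in S : s matches N(v)}| / |S|

with matching done exactly first, then case-folded.  Accession inputs are
excluded from the denominator — accessions are version-stable, so they carry
no version signal.  The most probable source version is `argmax p(v)`, ties
broken to the highest ordinal (the newest release maximizes downstream
compatibility).

## Worked example

The bundled demo fixture is a hand-built four-release history (v16, v17,
v19, v22) in the reserved synthetic accession range `09xxxxx`; its entries
exercise each documented transition.

```sh
$ mirversions fixture --db demo.mirdb
$ printf 'hsa-mir-103-1-as\nmmu-miR-1274a\nhsa-miR-224*\n' | \
    mirversions convert --from v16 --to v22 --db demo.mirdb
position,input,accession,name,status,version,source_version,source_name,target_name
0,hsa-mir-103-1-as,MI0900001,hsa-mir-103-1-as,alive,v22,v16,hsa-mir-103-1-as,hsa-mir-103b-1
1,mmu-miR-1274a,MIMAT0900001,mmu-miR-1274a,dead,v22,v16,mmu-miR-1274a,NA
2,hsa-miR-224*,MIMAT0900011,hsa-miR-224*,alive,v22,v16,hsa-miR-224*,hsa-miR-224-3p
```

Reading the rows: the v16 antisense precursor `hsa-mir-103-1-as` carries the
name `hsa-mir-103b-1` in v22 (same accession, renamed when `-as` was
retired); the mouse mature `mmu-miR-1274a` is **dead** — its accession left
the repository before v22, so there is no target name; and the passenger
`hsa-miR-224*` became `hsa-miR-224-3p` under the arm-suffix convention.
Rows always come back in input order, with `NA` for absent values.

When the source version is unknown, infer it first:

```sh
$ printf 'hsa-mir-103-1-as\nhsa-miR-224*\n' | mirversions check-version --db demo.mirdb
version,proportion,best
v16,1.0,yes
v17,0.5,no
v19,0.0,no
v22,0.0,no
```

Both names match v16's pool (proportion 1.0), only one survives into v17,
none later — the list is a v16 list.

The same operations are plain library calls:

```python
from mirversions import build_database, demo_history
from mirversions import query_engine as qe

db = build_database(demo_history())
row = qe.version_convert(db, ["hsa-mir-103-1-as"], "v16", "v22")[0]
assert row.extras["target_name"] == "hsa-mir-103b-1"
```

Other subcommands: `build` (compile real release directories), `simulate`
(synthetic histories + event log), `check-alive`, `check-family`, `pre2mat`,
`mat2pre`, `sequence`, `history`, `table`, `catalog`, `url`.  All accept
identifiers on stdin, one per line, or from a CSV column via `--column`;
`--links` adds upstream hyperlink columns.

## Layout

```
src/mirversions/
  core_model.py         # domain types, indexed store, save/load, rebuild
  mirbase_io.py         # flat-file/FASTA/miFam/sidecar parsers, builder
  synthetic_release.py  # history generator, event log, demo fixture, writer
  query_engine.py       # the fourteen batch check/convert/retrieve operations
  web_links.py          # upstream URL construction
  cli.py                # mirversions command-line front-end
docs/methods.md         # model, parameters, design choices, limitations
```
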