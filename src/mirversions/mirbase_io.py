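"""Parsers for miRBase-style release files and the multi-release database builder.

A release directory holds up to six plain-text (optionally gzipped) files:

* ``miRNA.dat``   — legacy-EMBL flat file; one precursor per ``//`` block with
  ``FT miRNA`` features for the mature products (1-based inclusive coordinates).
* ``hairpin.fa`` / ``mature.fa`` — FASTA, RNA alphabet, header ``>name ACC ...``.
* ``miFam.dat``   — family blocks (``AC``/``ID``/``MI`` lines, ``//`` terminated).
* ``organisms.txt`` — TSV species table (code, division, name, tree, taxon id).
* ``aliases.txt`` — TSV ``accession<TAB>name1;name2;...;`` name histories.

The flat-file dialect predates the modern EMBL grammar (old-style ID lines,
no mandatory SV/topology tokens), so the ``miRNA.dat`` reader is a dedicated
line-based parser that reports entry names and line numbers on failure; FASTA
goes through Bio.SeqIO.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

from Bio import SeqIO

from mirversions.core_model import (
    ACCESSION_RE,
    AccessionKind,
    Arm,
    BuildError,
    FamilyRecord,
    FamilyRef,
    MatureProduct,
    MembershipRecord,
    MirDatabase,
    ParseError,
    PrecursorEntry,
    ProductLink,
    SpeciesRecord,
    VersionInfo,
    VersionLabel,
    classify_accession,
    is_accession,
    validate_database,
)

logger = logging.getLogger(__name__)

_RNA_OK = set("ACGU")


@dataclass(frozen=True)
class ReleaseFiles:
    """Paths of one release's files. ``miRNA.dat`` and both FASTAs are required."""

    version: VersionLabel
    dat_path: Path
    hairpin_fasta_path: Path
    mature_fasta_path: Path
    mifam_path: Optional[Path] = None
    organisms_path: Optional[Path] = None
    aliases_path: Optional[Path] = None
    release_date: Optional[str] = None

    @classmethod
    def from_directory(
        cls,
        version: VersionLabel,
        directory: Union[str, Path],
        release_date: Optional[str] = None,
    ) -> "ReleaseFiles":
        """Locate the standard file names (plain or ``.gz``) in a release dir."""
        directory = Path(directory)

        def find(stem: str, required: bool) -> Optional[Path]:
            for candidate in (directory / stem, directory / f"{stem}.gz"):
                if candidate.exists():
                    return candidate
            if required:
                raise ParseError(f"release {version.label}: missing {stem} in {directory}")
            return None

        return cls(
            version=version,
            dat_path=find("miRNA.dat", required=True),
            hairpin_fasta_path=find("hairpin.fa", required=True),
            mature_fasta_path=find("mature.fa", required=True),
            mifam_path=find("miFam.dat", required=False),
            organisms_path=find("organisms.txt", required=False),
            aliases_path=find("aliases.txt", required=False),
            release_date=release_date,
        )


@dataclass(frozen=True)
class AliasRecord:
    """An accession's ordered name history, oldest first."""

    accession: str
    historical_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.historical_names:
            raise ValueError(f"alias record for {self.accession} has no names")


def _open_text(path: Union[str, Path]) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _clean_rna(raw: str, where: str) -> str:
    seq = re.sub(r"[\s\d]", "", raw).upper().replace("T", "U")
    bad = set(seq) - _RNA_OK
    if bad:
        raise ParseError(f"{where}: non-RNA characters {sorted(bad)} in sequence")
    return seq


def infer_arm(name: str, start: int, end: int, hairpin_length: int) -> Arm:
    """Arm of a mature product.

    Precedence: an explicit ``-5p``/``-3p`` name suffix wins; otherwise a
    product lying wholly in the first half of the hairpin is 5', wholly in the
    second half is 3'; products straddling the midpoint are unknown.
    """
    if name.endswith("-5p"):
        return Arm.FIVE_PRIME
    if name.endswith("-3p"):
        return Arm.THREE_PRIME
    if 2 * end <= hairpin_length:
        return Arm.FIVE_PRIME
    if 2 * start >= hairpin_length:
        return Arm.THREE_PRIME
    return Arm.UNKNOWN


# ---------------------------------------------------------------------------
# miRNA.dat
# ---------------------------------------------------------------------------

_LOCATION_RE = re.compile(r"(\d+)\.\.(\d+)\Z")
_QUALIFIER_RE = re.compile(r"/(\w+)=\"([^\"]*)\"")


def parse_mirna_dat(stream: Union[IO[str], str]) -> list[PrecursorEntry]:
    """Parse an EMBL-style ``miRNA.dat`` stream into precursor entries.

    One entry per ``//``-terminated block; mature features are read from
    ``FT miRNA`` lines with ``/accession`` and ``/product`` qualifiers.
    Sequences are stripped of whitespace/digits, uppercased and T->U
    transliterated.  Unknown line tags (citations etc.) are skipped with a
    logged warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    entries: list[PrecursorEntry] = []
    seen_acc: set[str] = set()
    skipped_tags: set[str] = set()

    name: Optional[str] = None
    accession: Optional[str] = None
    description = ""
    seq_parts: list[str] = []
    in_seq = False
    features: list[dict] = []
    current_feature: Optional[dict] = None
    entry_line = 0

    def finalize(lineno: int) -> None:
        nonlocal name, accession, description, seq_parts, in_seq, features, current_feature
        if name is None and accession is None and not features and not seq_parts:
            return  # stray terminator
        if name is None:
            raise ParseError(f"entry ending at line {lineno} has no ID line")
        if accession is None:
            raise ParseError(
                f"entry {name!r} (line {entry_line}) is missing its AC line"
            )
        if accession in seen_acc:
            raise ParseError(
                f"duplicate precursor accession {accession} at line {lineno}"
            )
        seen_acc.add(accession)
        sequence = _clean_rna("".join(seq_parts), f"entry {name!r}")
        products = []
        for feat in features:
            macc, mname = feat.get("accession"), feat.get("product")
            if macc is None or mname is None:
                raise ParseError(
                    f"entry {name!r}: miRNA feature at line {feat['line']} lacks "
                    f"/accession or /product"
                )
            start, end = feat["start"], feat["end"]
            if end > len(sequence):
                raise ParseError(
                    f"entry {name!r}: feature {mname} ends at {end} beyond "
                    f"hairpin length {len(sequence)}"
                )
            products.append(
                MatureProduct(
                    accession=macc,
                    name=mname,
                    arm=infer_arm(mname, start, end, len(sequence)),
                    start=start,
                    end=end,
                )
            )
        entries.append(
            PrecursorEntry(
                accession=accession,
                name=name,
                species_code=name.split("-", 1)[0],
                description=description,
                sequence=sequence,
                products=tuple(products),
            )
        )
        name = accession = None
        description = ""
        seq_parts = []
        in_seq = False
        features = []
        current_feature = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith("//"):
            finalize(lineno)
            continue
        if in_seq:
            seq_parts.append(line)
            continue
        tag, _, rest = line.partition("   ")
        tag = tag.strip()
        rest = rest.strip()
        if tag == "ID":
            name = rest.split()[0].rstrip(";") if rest else None
            if not name:
                raise ParseError(f"empty ID line at line {lineno}")
            entry_line = lineno
        elif tag == "AC":
            acc = rest.split()[0].rstrip(";") if rest else ""
            if not is_accession(acc) or classify_accession(acc) is not AccessionKind.PRECURSOR:
                raise ParseError(
                    f"entry {name!r}: AC line at line {lineno} holds no MI accession: {rest!r}"
                )
            accession = acc
        elif tag == "DE":
            description = rest if not description else description + " " + rest
        elif tag == "FT":
            if rest.startswith("miRNA"):
                loc = rest[len("miRNA"):].strip()
                m = _LOCATION_RE.match(loc)
                if not m:
                    raise ParseError(
                        f"entry {name!r}: malformed miRNA location {loc!r} at line {lineno}"
                    )
                start, end = int(m.group(1)), int(m.group(2))
                if start < 1 or end < start:
                    raise ParseError(
                        f"entry {name!r}: bad coordinates {start}..{end} at line {lineno}"
                    )
                current_feature = {"start": start, "end": end, "line": lineno}
                features.append(current_feature)
            elif rest.startswith("/"):
                if current_feature is not None:
                    for key, value in _QUALIFIER_RE.findall(rest):
                        if key in ("accession", "product"):
                            current_feature[key] = value
            else:
                # other feature kinds (e.g. modified_base) are irrelevant here
                current_feature = None
        elif tag == "SQ":
            in_seq = True
        elif tag in ("XX", ""):
            continue
        else:
            if tag not in skipped_tags:
                skipped_tags.add(tag)
                logger.warning("skipping unrecognized line tag %r in miRNA.dat", tag)
    if name is not None or accession is not None:
        raise ParseError("unterminated entry at end of miRNA.dat (missing '//')")
    return entries


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_KIND_PREFIX = {"hairpin": AccessionKind.PRECURSOR, "mature": AccessionKind.MATURE}


def parse_fasta(
    stream: Union[IO[str], str], kind: str = "hairpin"
) -> dict[str, tuple[str, str]]:
    """Parse ``hairpin.fa``/``mature.fa`` into ``{accession: (name, sequence)}``.

    Headers are ``>name ACC ...``; the accession is the first whitespace token
    matching the accession grammar.  Sequences come back uppercased RNA.
    """
    if kind not in _KIND_PREFIX:
        raise ValueError(f"kind must be 'hairpin' or 'mature', got {kind!r}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: dict[str, tuple[str, str]] = {}
    for record in SeqIO.parse(stream, "fasta"):
        tokens = record.description.split()
        name = tokens[0]
        acc = next((t for t in tokens if is_accession(t)), None)
        if acc is None:
            raise ParseError(
                f"FASTA header without a recognizable accession: >{record.description}"
            )
        if classify_accession(acc) is not _KIND_PREFIX[kind]:
            raise ParseError(
                f"accession {acc} in {kind} FASTA has the wrong prefix class"
            )
        if acc in out:
            raise ParseError(f"duplicate accession {acc} in {kind} FASTA")
        out[acc] = (name, _clean_rna(str(record.seq), f"FASTA record {name}"))
    return out


# ---------------------------------------------------------------------------
# miFam.dat
# ---------------------------------------------------------------------------

def parse_mifam(stream: Union[IO[str], str]) -> list[FamilyRecord]:
    """Parse ``miFam.dat`` family blocks, members kept in file order."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[FamilyRecord] = []
    acc: Optional[str] = None
    fam_name: Optional[str] = None
    members: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith("//"):
            if acc is None or fam_name is None:
                if acc is None and fam_name is None and not members:
                    continue
                raise ParseError(f"family block ending at line {lineno} lacks AC or ID")
            records.append(
                FamilyRecord(accession=acc, name=fam_name, member_precursors=tuple(members))
            )
            acc = fam_name = None
            members = []
            continue
        tag, _, rest = line.partition("   ")
        tag, rest = tag.strip(), rest.strip()
        if tag == "AC":
            token = rest.split()[0] if rest else ""
            if not is_accession(token) or classify_accession(token) is not AccessionKind.FAMILY:
                raise ParseError(f"line {lineno}: family AC is not a MIPF accession: {rest!r}")
            acc = token
        elif tag == "ID":
            if not rest:
                raise ParseError(f"line {lineno}: empty family ID")
            fam_name = rest
        elif tag == "MI":
            token = rest.split()[0] if rest else ""
            if not is_accession(token) or classify_accession(token) is not AccessionKind.PRECURSOR:
                raise ParseError(
                    f"line {lineno}: family member accession is not MI-prefixed: {rest!r}"
                )
            members.append(token)
        elif tag in ("XX", ""):
            continue
    if acc is not None or fam_name is not None or members:
        raise ParseError("unterminated family block at end of miFam.dat")
    return records


# ---------------------------------------------------------------------------
# organisms.txt / aliases.txt
# ---------------------------------------------------------------------------

def parse_sidecars(
    organisms_stream: Union[IO[str], str, None],
    aliases_stream: Union[IO[str], str, None],
) -> tuple[list[SpeciesRecord], list[AliasRecord]]:
    """Parse the optional species table and alias-history table.

    Absent streams yield empty lists.  ``organisms.txt`` is a 5-column TSV
    ('#'-prefixed header lines skipped); ``aliases.txt`` is
    ``accession<TAB>name1;name2;...;`` with the trailing semicolon tolerated.
    """
    species: list[SpeciesRecord] = []
    aliases: list[AliasRecord] = []
    if organisms_stream is not None:
        if isinstance(organisms_stream, str):
            organisms_stream = io.StringIO(organisms_stream)
        for lineno, raw in enumerate(organisms_stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ParseError(
                    f"organisms.txt line {lineno}: expected 5 tab-separated columns, "
                    f"got {len(cols)}"
                )
            code, division, name, tree, taxid = cols
            species.append(
                SpeciesRecord(
                    code=code,
                    division=division,
                    name=name,
                    tree=tree,
                    taxon_id=int(taxid) if taxid.strip() else None,
                )
            )
    if aliases_stream is not None:
        if isinstance(aliases_stream, str):
            aliases_stream = io.StringIO(aliases_stream)
        for lineno, raw in enumerate(aliases_stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(
                    f"aliases.txt line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(cols)}"
                )
            acc, names_blob = cols
            if not is_accession(acc):
                raise ParseError(f"aliases.txt line {lineno}: bad accession {acc!r}")
            names = tuple(n for n in names_blob.split(";") if n)
            if not names:
                raise ParseError(f"aliases.txt line {lineno}: empty name history")
            aliases.append(AliasRecord(accession=acc, historical_names=names))
    return species, aliases


# ---------------------------------------------------------------------------
# One fully parsed release
# ---------------------------------------------------------------------------

@dataclass(eq=True)
class ReleaseData:
    """In-memory content of one release, as the parsers deliver it.

    ``entries`` are kept sorted by precursor accession (record order inside the
    flat file carries no meaning).  ``matures`` maps MIMAT accession to
    ``(name, sequence)``.
    """

    version: VersionLabel
    entries: list[PrecursorEntry] = field(default_factory=list)
    matures: dict[str, tuple[str, str]] = field(default_factory=dict)
    families: list[FamilyRecord] = field(default_factory=list)
    species: list[SpeciesRecord] = field(default_factory=list)
    aliases: list[AliasRecord] = field(default_factory=list)
    release_date: Optional[str] = None
    has_family_data: bool = False  # True when the release ships miFam at all

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.accession)
        if self.families:
            self.has_family_data = True

    @classmethod
    def from_files(cls, files: ReleaseFiles) -> "ReleaseData":
        with _open_text(files.dat_path) as fh:
            entries = parse_mirna_dat(fh)
        with _open_text(files.hairpin_fasta_path) as fh:
            hairpins = parse_fasta(fh, "hairpin")
        with _open_text(files.mature_fasta_path) as fh:
            matures = parse_fasta(fh, "mature")
        families: list[FamilyRecord] = []
        if files.mifam_path is not None:
            with _open_text(files.mifam_path) as fh:
                families = parse_mifam(fh)
        org = ali = None
        try:
            if files.organisms_path is not None:
                org = _open_text(files.organisms_path)
            if files.aliases_path is not None:
                ali = _open_text(files.aliases_path)
            species, aliases = parse_sidecars(org, ali)
        finally:
            for fh in (org, ali):
                if fh is not None:
                    fh.close()
        # the flat file is authoritative for hairpin sequences; the FASTA is
        # cross-checked when both are present
        for entry in entries:
            fasta = hairpins.get(entry.accession)
            if fasta is not None and fasta[1] != entry.sequence:
                raise ParseError(
                    f"{entry.accession}: hairpin.fa sequence disagrees with miRNA.dat"
                )
        return cls(
            version=files.version,
            entries=entries,
            matures=matures,
            families=families,
            species=species,
            aliases=aliases,
            release_date=files.release_date,
            has_family_data=files.mifam_path is not None,
        )


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

class _Interner:
    """Dense first-seen-order string interning (reproducible builds)."""

    def __init__(self) -> None:
        self.table: list = []
        self._index: dict = {}

    def add(self, value) -> int:
        idx = self._index.get(value)
        if idx is None:
            idx = len(self.table)
            self._index[value] = idx
            self.table.append(value)
        return idx


def build_database(
    releases: Sequence[Union[ReleaseFiles, ReleaseData]],
) -> MirDatabase:
    """Compile an ordered list of releases into one deduplicated store.

    Release order is semantic (it defines chronology); record order within a
    release is not.  Alias histories are merged across releases: a name change
    between consecutive releases appends the new name to the accession's
    history, and any extra history shipped in ``aliases.txt`` is folded in.
    """
    if not releases:
        raise BuildError("at least one release is required")
    datas = [
        r if isinstance(r, ReleaseData) else ReleaseData.from_files(r) for r in releases
    ]
    labels = [d.version.label for d in datas]
    if len(set(labels)) != len(labels):
        raise BuildError(f"duplicate version labels in build input: {labels}")
    ordinals = [d.version.ordinal for d in datas]
    if ordinals != sorted(ordinals) or len(set(ordinals)) != len(ordinals):
        raise BuildError("release ordinals must be strictly increasing")

    names = _Interner()
    accessions = _Interner()
    sequences = _Interner()
    descriptions = _Interner()
    species = _Interner()
    families = _Interner()

    db = MirDatabase()
    species_of_acc: dict[int, str] = {}
    last_name: dict[int, int] = {}
    aliases: dict[int, list[int]] = {}

    def note_name(acc_idx: int, name_idx: int) -> None:
        if acc_idx not in aliases:
            aliases[acc_idx] = [name_idx]
        elif last_name.get(acc_idx) != name_idx:
            aliases[acc_idx].append(name_idx)
        last_name[acc_idx] = name_idx

    def species_index(code: str, table: dict[str, int]) -> int:
        idx = table.get(code)
        if idx is None:
            # release shipped no (or an incomplete) organisms table: synthesize
            # a code-only species record from the observed name prefix
            idx = species.add(SpeciesRecord(code=code))
            table[code] = idx
        return idx

    for data in datas:
        sp_by_code: dict[str, int] = {}
        for rec in data.species:
            sp_by_code[rec.code] = species.add(rec)
        fam_of_member: dict[str, int] = {}
        for fam in data.families:
            fam_idx = families.add(
                FamilyRef(
                    accession_index=accessions.add(fam.accession),
                    name_index=names.add(fam.name),
                )
            )
            note_name(accessions.add(fam.accession), names.add(fam.name))
            for member in fam.member_precursors:
                fam_of_member[member] = fam_idx

        members: dict[int, MembershipRecord] = {}
        n_pre = n_mat = 0
        for entry in data.entries:  # already accession-sorted
            acc_idx = accessions.add(entry.accession)
            prior_species = species_of_acc.get(acc_idx)
            if prior_species is not None and prior_species != entry.species_code:
                raise BuildError(
                    f"accession {entry.accession} changes species "
                    f"({prior_species} -> {entry.species_code}) at {data.version.label}; "
                    f"input data is corrupt"
                )
            species_of_acc[acc_idx] = entry.species_code
            name_idx = names.add(entry.name)
            note_name(acc_idx, name_idx)
            links = []
            for product in entry.products:
                m_acc_idx = accessions.add(product.accession)
                m_name_idx = names.add(product.name)
                note_name(m_acc_idx, m_name_idx)
                m_sp = product.name.split("-", 1)[0]
                prior_m_sp = species_of_acc.get(m_acc_idx)
                if prior_m_sp is not None and prior_m_sp != m_sp:
                    raise BuildError(
                        f"accession {product.accession} changes species "
                        f"({prior_m_sp} -> {m_sp}) at {data.version.label}"
                    )
                species_of_acc[m_acc_idx] = m_sp
                fasta = data.matures.get(product.accession)
                m_seq = fasta[1] if fasta else entry.sequence[product.start - 1 : product.end]
                if m_acc_idx not in members:
                    members[m_acc_idx] = MembershipRecord(
                        name_index=m_name_idx,
                        sequence_index=sequences.add(m_seq),
                        species_index=species_index(m_sp, sp_by_code),
                    )
                    n_mat += 1
                links.append(
                    ProductLink(
                        mature_index=m_acc_idx,
                        arm=product.arm,
                        start=product.start,
                        end=product.end,
                    )
                )
            if acc_idx in members:
                raise BuildError(
                    f"duplicate precursor accession {entry.accession} in "
                    f"{data.version.label}"
                )
            members[acc_idx] = MembershipRecord(
                name_index=name_idx,
                sequence_index=sequences.add(entry.sequence),
                species_index=species_index(entry.species_code, sp_by_code),
                description_index=descriptions.add(entry.description),
                family_index=fam_of_member.get(entry.accession),
                products=tuple(links),
            )
            n_pre += 1

        db.membership[data.version.ordinal] = members
        db.versions.append(
            VersionInfo(
                version=data.version,
                release_date=data.release_date,
                n_precursors=n_pre,
                n_matures=n_mat,
            )
        )
        if data.has_family_data:
            db.family_versions.add(data.version.ordinal)

        # merge shipped alias histories: the file's ordering is the
        # chronological spine (it may know pre-era and intermediate names);
        # observed names the file lacks are appended in observed order
        for alias in data.aliases:
            if alias.accession not in accessions._index:
                continue  # references an entity outside the compiled era
            acc_idx = accessions._index[alias.accession]
            merged = [names.add(n) for n in alias.historical_names]
            for idx in aliases.get(acc_idx, []):
                if idx not in merged:
                    merged.append(idx)
            aliases[acc_idx] = merged

    db.names = names.table
    db.accessions = accessions.table
    db.sequences = sequences.table
    db.descriptions = descriptions.table
    db.species = species.table
    db.families = families.table
    db.aliases = aliases
    validate_database(db)
    return db
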