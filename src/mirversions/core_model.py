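"""Domain types and the deduplicated, index-structured cross-version store.

Every distinct name, accession, sequence and description string across all
compiled releases is stored exactly once in a dense, first-seen-order indexed
table.  Per-version membership maps tie the indices together, so any single
release can be reconstructed losslessly while shared content between releases
costs nothing extra.  The store persists to a single compressed, deterministic,
self-identifying file (extension ``.mirdb``).
"""

from __future__ import annotations

import enum
import json
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union


class MirVersionsError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(MirVersionsError):
    """A release file could not be parsed."""


class BuildError(MirVersionsError):
    """An ordered set of releases could not be compiled into a database."""


class DatabaseError(MirVersionsError):
    """A database file or in-memory database is invalid."""


class SchemaError(DatabaseError):
    """A database file uses an unsupported serialization schema version."""


# ---------------------------------------------------------------------------
# Accessions
# ---------------------------------------------------------------------------

class AccessionKind(enum.Enum):
    PRECURSOR = "precursor"  # MI#######
    MATURE = "mature"        # MIMAT#######
    FAMILY = "family"        # MIPF#######


_ACC_RES = (
    (AccessionKind.MATURE, re.compile(r"MIMAT\d{7}\Z")),
    (AccessionKind.FAMILY, re.compile(r"MIPF\d{7}\Z")),
    (AccessionKind.PRECURSOR, re.compile(r"MI\d{7}\Z")),
)

ACCESSION_RE = re.compile(r"(?:MIMAT|MIPF|MI)\d{7}\Z")


def classify_accession(text: str) -> AccessionKind:
    """Classify an accession by prefix; raises :class:`ValueError` if invalid.

    The class of a record (precursor / mature / family) is derivable from the
    accession prefix alone: MI = precursor hairpin, MIMAT = mature miRNA,
    MIPF = miRNA family.
    """
    for kind, rx in _ACC_RES:
        if rx.match(text):
            return kind
    raise ValueError(f"not a valid miRBase-style accession: {text!r}")


def is_accession(text: str) -> bool:
    return bool(ACCESSION_RE.match(text))


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

class Arm(enum.Enum):
    """Hairpin arm a mature miRNA derives from."""

    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"
    UNKNOWN = "unknown"


@dataclass(frozen=True, order=True)
class VersionLabel:
    """A release label plus its explicit chronological rank.

    Ordinals are supplied at build time and never inferred from the label text
    (real release labels include non-numeric forms such as "7.1" and "9.2").
    """

    ordinal: int
    label: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class MatureProduct:
    """One mature product of a precursor, with 1-based inclusive coordinates."""

    accession: str
    name: str
    arm: Arm
    start: int
    end: int

    def __post_init__(self) -> None:
        if classify_accession(self.accession) is not AccessionKind.MATURE:
            raise ValueError(f"mature product needs a MIMAT accession, got {self.accession}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad mature coordinates {self.start}..{self.end}")


@dataclass(frozen=True)
class PrecursorEntry:
    """One precursor (hairpin) record with its mature products."""

    accession: str
    name: str
    species_code: str
    description: str
    sequence: str
    products: tuple[MatureProduct, ...] = ()

    def __post_init__(self) -> None:
        if classify_accession(self.accession) is not AccessionKind.PRECURSOR:
            raise ValueError(f"precursor needs an MI accession, got {self.accession}")
        for p in self.products:
            if p.end > len(self.sequence):
                raise ValueError(
                    f"{self.accession}: product {p.name} ends at {p.end} "
                    f"beyond hairpin length {len(self.sequence)}"
                )


@dataclass(frozen=True)
class FamilyRecord:
    """A miRNA family (MIPF accession) and its member precursors, in file order."""

    accession: str
    name: str
    member_precursors: tuple[str, ...]

    def __post_init__(self) -> None:
        if classify_accession(self.accession) is not AccessionKind.FAMILY:
            raise ValueError(f"family needs a MIPF accession, got {self.accession}")
        if not self.member_precursors:
            raise ValueError(f"family {self.accession} has no members")
        if len(set(self.member_precursors)) != len(self.member_precursors):
            raise ValueError(f"family {self.accession} lists duplicate members")


@dataclass(frozen=True)
class SpeciesRecord:
    code: str
    division: str = ""
    name: str = ""
    tree: str = ""
    taxon_id: Optional[int] = None


@dataclass(frozen=True)
class VersionInfo:
    version: VersionLabel
    release_date: Optional[str] = None
    n_precursors: int = 0
    n_matures: int = 0


@dataclass(frozen=True)
class ProductLink:
    """Index-level link from a precursor to one mature product within a version."""

    mature_index: int  # index into MirDatabase.accessions
    arm: Arm
    start: int
    end: int


@dataclass(frozen=True)
class MembershipRecord:
    """Per-(version, accession) record tying the entity to interned strings."""

    name_index: int
    sequence_index: int
    species_index: int
    description_index: Optional[int] = None  # precursors only
    family_index: Optional[int] = None       # index into MirDatabase.families
    products: tuple[ProductLink, ...] = ()   # precursors only


@dataclass(frozen=True)
class FamilyRef:
    accession_index: int
    name_index: int


@dataclass(eq=True)
class MirDatabase:
    """The deduplicated multi-version store.

    ``membership[ordinal][accession_index]`` holds the per-version record of a
    precursor or mature entity; string payloads live once in the flat tables.
    ``aliases`` maps an accession index to the ordered list of name indices the
    record has carried (oldest first).  ``family_versions`` records which
    version ordinals shipped family data at all (an empty family list is
    distinguishable from a release that predates miFam).
    """

    names: list[str] = field(default_factory=list)
    accessions: list[str] = field(default_factory=list)
    sequences: list[str] = field(default_factory=list)
    descriptions: list[str] = field(default_factory=list)
    species: list[SpeciesRecord] = field(default_factory=list)
    families: list[FamilyRef] = field(default_factory=list)
    versions: list[VersionInfo] = field(default_factory=list)
    membership: dict[int, dict[int, MembershipRecord]] = field(default_factory=dict)
    aliases: dict[int, list[int]] = field(default_factory=dict)
    family_versions: set[int] = field(default_factory=set)

    # -- lookups ------------------------------------------------------------

    def version_info(self, version: Union[str, VersionLabel]) -> VersionInfo:
        label = version.label if isinstance(version, VersionLabel) else version
        for vi in self.versions:
            if vi.version.label == label:
                return vi
        known = ", ".join(vi.version.label for vi in self.versions) or "(none)"
        raise DatabaseError(f"unknown version {label!r}; known versions: {known}")

    @property
    def latest(self) -> VersionLabel:
        if not self.versions:
            raise DatabaseError("database holds no versions")
        return max(self.versions, key=lambda vi: vi.version.ordinal).version

    def family_records(self, version: Union[str, VersionLabel]) -> list[FamilyRecord]:
        """Reconstruct the per-version family table from membership records."""
        vi = self.version_info(version)
        members: dict[int, list[str]] = {}
        for acc_idx, rec in self.membership[vi.version.ordinal].items():
            if rec.family_index is not None:
                members.setdefault(rec.family_index, []).append(self.accessions[acc_idx])
        out = []
        for fam_idx, accs in members.items():
            ref = self.families[fam_idx]
            out.append(
                FamilyRecord(
                    accession=self.accessions[ref.accession_index],
                    name=self.names[ref.name_index],
                    member_precursors=tuple(sorted(accs)),
                )
            )
        out.sort(key=lambda f: f.accession)
        return out


# ---------------------------------------------------------------------------
# Release reconstruction
# ---------------------------------------------------------------------------

def rebuild_release(
    db: MirDatabase, version: Union[str, VersionLabel]
) -> list[PrecursorEntry]:
    """Reconstruct one release's precursor entries from the index store.

    Returns the complete precursor set of the version, products included, in
    ascending precursor-accession order.  This is the inverse of the build and
    the basis of the losslessness guarantee.
    """
    vi = db.version_info(version)
    members = db.membership[vi.version.ordinal]
    out: list[PrecursorEntry] = []
    for acc_idx in sorted(members, key=lambda i: db.accessions[i]):
        acc = db.accessions[acc_idx]
        if classify_accession(acc) is not AccessionKind.PRECURSOR:
            continue
        rec = members[acc_idx]
        products = tuple(
            MatureProduct(
                accession=db.accessions[link.mature_index],
                name=db.names[members[link.mature_index].name_index],
                arm=link.arm,
                start=link.start,
                end=link.end,
            )
            for link in rec.products
        )
        name = db.names[rec.name_index]
        out.append(
            PrecursorEntry(
                accession=acc,
                name=name,
                species_code=name.split("-", 1)[0],
                description="" if rec.description_index is None else db.descriptions[rec.description_index],
                sequence=db.sequences[rec.sequence_index],
                products=products,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_database(db: MirDatabase) -> None:
    """Check every structural invariant; raises :class:`DatabaseError`.

    Covers dedup exactness of the string tables, referential integrity of all
    membership/alias/family indices, version ordering, and agreement of the
    stored per-version counts with membership cardinalities.
    """
    for label, table in (
        ("names", db.names),
        ("accessions", db.accessions),
        ("sequences", db.sequences),
        ("descriptions", db.descriptions),
    ):
        if len(set(table)) != len(table):
            raise DatabaseError(f"{label} table contains duplicates")
    ordinals = [vi.version.ordinal for vi in db.versions]
    if ordinals != sorted(ordinals) or len(set(ordinals)) != len(ordinals):
        raise DatabaseError("version ordinals are not strictly increasing")
    labels = [vi.version.label for vi in db.versions]
    if len(set(labels)) != len(labels):
        raise DatabaseError("duplicate version labels")
    if set(db.membership) != set(ordinals):
        raise DatabaseError("membership keys do not match registered versions")

    n_names, n_acc, n_seq, n_desc = (
        len(db.names), len(db.accessions), len(db.sequences), len(db.descriptions),
    )
    for ref in db.families:
        if not (0 <= ref.accession_index < n_acc and 0 <= ref.name_index < n_names):
            raise DatabaseError("dangling family index")
    for vi in db.versions:
        members = db.membership[vi.version.ordinal]
        n_pre = n_mat = 0
        for acc_idx, rec in members.items():
            if not 0 <= acc_idx < n_acc:
                raise DatabaseError(f"dangling accession index {acc_idx}")
            kind = classify_accession(db.accessions[acc_idx])
            if kind is AccessionKind.PRECURSOR:
                n_pre += 1
            elif kind is AccessionKind.MATURE:
                n_mat += 1
            if not 0 <= rec.name_index < n_names:
                raise DatabaseError("dangling name index")
            if not 0 <= rec.sequence_index < n_seq:
                raise DatabaseError("dangling sequence index")
            if not 0 <= rec.species_index < len(db.species):
                raise DatabaseError("dangling species index")
            if rec.description_index is not None and not 0 <= rec.description_index < n_desc:
                raise DatabaseError("dangling description index")
            if rec.family_index is not None and not 0 <= rec.family_index < len(db.families):
                raise DatabaseError("dangling family index in membership")
            for link in rec.products:
                if link.mature_index not in members:
                    raise DatabaseError(
                        f"product link to {link.mature_index} outside version "
                        f"{vi.version.label}"
                    )
        if (n_pre, n_mat) != (vi.n_precursors, vi.n_matures):
            raise DatabaseError(
                f"{vi.version.label}: stored counts ({vi.n_precursors}, {vi.n_matures}) "
                f"!= membership cardinalities ({n_pre}, {n_mat})"
            )
    for acc_idx, history in db.aliases.items():
        if not 0 <= acc_idx < n_acc:
            raise DatabaseError("dangling alias accession index")
        if not history or any(not 0 <= i < n_names for i in history):
            raise DatabaseError("empty or dangling alias history")
    if not db.family_versions <= set(ordinals):
        raise DatabaseError("family_versions references unknown ordinals")


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_MAGIC = b"mirdb\x00"
_SCHEMA_VERSION = 1


def _to_payload(db: MirDatabase) -> dict:
    return {
        "names": db.names,
        "accessions": db.accessions,
        "sequences": db.sequences,
        "descriptions": db.descriptions,
        "species": [
            [s.code, s.division, s.name, s.tree, s.taxon_id] for s in db.species
        ],
        "families": [[f.accession_index, f.name_index] for f in db.families],
        "versions": [
            [vi.version.label, vi.version.ordinal, vi.release_date,
             vi.n_precursors, vi.n_matures]
            for vi in db.versions
        ],
        "membership": {
            str(ordinal): {
                str(acc_idx): [
                    rec.name_index, rec.sequence_index, rec.species_index,
                    rec.description_index, rec.family_index,
                    [[l.mature_index, l.arm.value, l.start, l.end] for l in rec.products],
                ]
                for acc_idx, rec in sorted(members.items())
            }
            for ordinal, members in sorted(db.membership.items())
        },
        "aliases": {str(k): v for k, v in sorted(db.aliases.items())},
        "family_versions": sorted(db.family_versions),
    }


def _from_payload(payload: Mapping) -> MirDatabase:
    try:
        db = MirDatabase(
            names=list(payload["names"]),
            accessions=list(payload["accessions"]),
            sequences=list(payload["sequences"]),
            descriptions=list(payload["descriptions"]),
            species=[
                SpeciesRecord(code=c, division=d, name=n, tree=t, taxon_id=x)
                for c, d, n, t, x in payload["species"]
            ],
            families=[FamilyRef(a, n) for a, n in payload["families"]],
            versions=[
                VersionInfo(
                    version=VersionLabel(ordinal=o, label=lab),
                    release_date=date, n_precursors=np, n_matures=nm,
                )
                for lab, o, date, np, nm in payload["versions"]
            ],
            membership={
                int(ordinal): {
                    int(acc_idx): MembershipRecord(
                        name_index=rec[0],
                        sequence_index=rec[1],
                        species_index=rec[2],
                        description_index=rec[3],
                        family_index=rec[4],
                        products=tuple(
                            ProductLink(m, Arm(a), s, e) for m, a, s, e in rec[5]
                        ),
                    )
                    for acc_idx, rec in members.items()
                }
                for ordinal, members in payload["membership"].items()
            },
            aliases={int(k): list(v) for k, v in payload["aliases"].items()},
            family_versions=set(payload["family_versions"]),
        )
    except (KeyError, TypeError, ValueError, IndexError) as exc:
        raise DatabaseError(f"not a mirversions database: malformed payload ({exc})") from exc
    validate_database(db)
    return db


def save_database(db: MirDatabase, path: Union[str, Path]) -> None:
    """Write ``db`` to a single compressed ``.mirdb`` file.

    The output is deterministic for a fixed database: canonical JSON (sorted
    keys, no whitespace) behind one zlib stream, prefixed by a magic tag and a
    serialization schema version.  No timestamps are embedded.
    """
    payload = json.dumps(
        _to_payload(db), sort_keys=True, separators=(",", ":"), ensure_ascii=False
    ).encode("utf-8")
    blob = _MAGIC + bytes([_SCHEMA_VERSION]) + zlib.compress(payload, 9)
    Path(path).write_bytes(blob)


def load_database(path: Union[str, Path]) -> MirDatabase:
    """Load a ``.mirdb`` file written by :func:`save_database`.

    Raises :class:`DatabaseError` for foreign or corrupt files and
    :class:`SchemaError` for a schema-version mismatch; never returns a
    partially populated database.
    """
    blob = Path(path).read_bytes()
    if not blob.startswith(_MAGIC):
        raise DatabaseError(f"not a mirversions database: {path}")
    if len(blob) < len(_MAGIC) + 1:
        raise DatabaseError(f"not a mirversions database (truncated header): {path}")
    schema = blob[len(_MAGIC)]
    if schema != _SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported database schema version {schema} "
            f"(this build reads version {_SCHEMA_VERSION})"
        )
    try:
        payload = json.loads(zlib.decompress(blob[len(_MAGIC) + 1:]).decode("utf-8"))
    except (zlib.error, UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise DatabaseError(f"corrupt database file {path}: {exc}") from exc
    return _from_payload(payload)
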