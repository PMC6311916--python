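"""Batch check / conversion / retrieval queries over a compiled database.

All batch operations are order-preserving: output row *i* (or block *i*) always
corresponds to input element *i*, and per-row failures are reported as row
statuses, never exceptions, so batch jobs complete.

Matching precedence everywhere: (1) exact accession, (2) exact case-sensitive
name, (3) case-folded name.  Storage is case-sensitive because the name case
is meaningful (``mir`` = precursor hairpin, ``miR`` = mature); a case-folded
hit that could be either is reported with the ``ambiguous`` status and both
candidates listed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from mirversions.core_model import (
    ACCESSION_RE,
    AccessionKind,
    Arm,
    DatabaseError,
    MirDatabase,
    VersionLabel,
    classify_accession,
    rebuild_release,
)

logger = logging.getLogger(__name__)

ALIVE = "alive"
DEAD = "dead"
NOT_FOUND = "not_found"
AMBIGUOUS = "ambiguous"

_NA = None  # absent marker inside QueryRow fields


@dataclass(frozen=True)
class QueryRow:
    """One order-preserving result record."""

    position: int
    input: str
    accession: Optional[str] = None
    name: Optional[str] = None
    status: str = NOT_FOUND
    version: Optional[str] = None
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class VersionCheckResult:
    """Matched proportion per version plus the most probable source version."""

    proportions: dict[str, float]
    best: str
    n_input: int
    n_matched_best: int


# ---------------------------------------------------------------------------
# Cached lookup index
# ---------------------------------------------------------------------------

class _Index:
    def __init__(self, db: MirDatabase) -> None:
        self.db = db
        self.acc_to_idx = {acc: i for i, acc in enumerate(db.accessions)}
        self.acc_versions: dict[int, set[int]] = {}
        self.exact: dict[int, dict[str, set[int]]] = {}
        self.folded: dict[int, dict[str, set[int]]] = {}
        self.parents: dict[int, dict[int, list[int]]] = {}
        for vi in db.versions:
            ordinal = vi.version.ordinal
            exact: dict[str, set[int]] = {}
            folded: dict[str, set[int]] = {}
            parents: dict[int, list[int]] = {}
            for acc_idx, rec in db.membership[ordinal].items():
                self.acc_versions.setdefault(acc_idx, set()).add(ordinal)
                name = db.names[rec.name_index]
                exact.setdefault(name, set()).add(acc_idx)
                folded.setdefault(name.casefold(), set()).add(acc_idx)
                for link in rec.products:
                    parents.setdefault(link.mature_index, []).append(acc_idx)
            self.exact[ordinal] = exact
            self.folded[ordinal] = folded
            self.parents[ordinal] = parents
        self.ordinals_desc = sorted(self.exact, reverse=True)

    def kind(self, acc_idx: int) -> AccessionKind:
        return classify_accession(self.db.accessions[acc_idx])

    def name_in(self, acc_idx: int, ordinal: int) -> str:
        return self.db.names[self.db.membership[ordinal][acc_idx].name_index]


def _index(db: MirDatabase) -> _Index:
    cached = db.__dict__.get("_query_index")
    if cached is None:
        cached = _Index(db)
        db.__dict__["_query_index"] = cached
    return cached


def _ordinal(db: MirDatabase, version: Union[str, VersionLabel, None]) -> int:
    if version is None:
        return db.latest.ordinal
    return db.version_info(version).version.ordinal


def _label(db: MirDatabase, ordinal: int) -> str:
    for vi in db.versions:
        if vi.version.ordinal == ordinal:
            return vi.version.label
    raise DatabaseError(f"no version with ordinal {ordinal}")


def _kind_ok(kind: AccessionKind, kind_filter: str) -> bool:
    return (
        kind_filter == "any"
        or (kind_filter == "precursor" and kind is AccessionKind.PRECURSOR)
        or (kind_filter == "mature" and kind is AccessionKind.MATURE)
    )


# ---------------------------------------------------------------------------
# Shared matcher
# ---------------------------------------------------------------------------

def resolve(
    db: MirDatabase,
    text: str,
    version: Union[str, VersionLabel, None] = None,
    kind_filter: str = "any",
    position: int = 0,
) -> QueryRow:
    """Match one input against a version's name/accession pools.

    Never raises for unmatched input; the row status carries the outcome.
    An accession known to the database but absent from the requested version
    comes back ``dead``.
    """
    idx = _index(db)
    ordinal = _ordinal(db, version)
    label = _label(db, ordinal)
    t = text.strip()
    if not t:
        return QueryRow(position, text, status=NOT_FOUND, version=label)

    upper = t.upper()
    if ACCESSION_RE.match(upper):
        kind = classify_accession(upper)
        if not _kind_ok(kind, kind_filter):
            return QueryRow(position, text, status=NOT_FOUND, version=label)
        acc_idx = idx.acc_to_idx.get(upper)
        if acc_idx is None:
            return QueryRow(position, text, status=NOT_FOUND, version=label)
        if ordinal in idx.acc_versions[acc_idx]:
            return QueryRow(
                position, text,
                accession=upper, name=idx.name_in(acc_idx, ordinal),
                status=ALIVE, version=label,
            )
        return QueryRow(position, text, accession=upper, status=DEAD, version=label)

    hits = idx.exact[ordinal].get(t)
    if not hits:
        hits = idx.folded[ordinal].get(t.casefold())
    if hits:
        hits = {h for h in hits if _kind_ok(idx.kind(h), kind_filter)}
    if not hits:
        return QueryRow(position, text, status=NOT_FOUND, version=label)
    if len(hits) == 1:
        (acc_idx,) = hits
        return QueryRow(
            position, text,
            accession=db.accessions[acc_idx], name=idx.name_in(acc_idx, ordinal),
            status=ALIVE, version=label,
        )
    candidates = sorted(db.accessions[h] for h in hits)
    return QueryRow(
        position, text, status=AMBIGUOUS, version=label,
        extras={"candidates": candidates},
    )


def _resolve_any_version(db: MirDatabase, text: str, kind_filter: str = "any"):
    """Locate an input in *some* version (newest first); returns
    ``(accession_index, ordinal)`` or ``None``.  Exact-name matches across all
    versions take precedence over case-folded ones."""
    idx = _index(db)
    t = text.strip()
    if not t:
        return None
    upper = t.upper()
    if ACCESSION_RE.match(upper):
        acc_idx = idx.acc_to_idx.get(upper)
        if acc_idx is None or not _kind_ok(classify_accession(upper), kind_filter):
            return None
        return acc_idx, max(idx.acc_versions[acc_idx])
    for table in ("exact", "folded"):
        key = t if table == "exact" else t.casefold()
        for ordinal in idx.ordinals_desc:
            hits = getattr(idx, table)[ordinal].get(key)
            if hits:
                hits = {h for h in hits if _kind_ok(idx.kind(h), kind_filter)}
            if hits:
                return min(hits), ordinal
    return None


# ---------------------------------------------------------------------------
# Checks
# ---------------------------------------------------------------------------

def check_alive(
    db: MirDatabase,
    inputs: Sequence[str],
    target_version: Union[str, VersionLabel, None] = None,
) -> list[QueryRow]:
    """Alive/dead status of each input against a target version (default latest).

    ``alive``: resolvable in the target version; ``dead``: known to an earlier
    version but gone from the target; ``not_found``: never seen.
    """
    ordinal = _ordinal(db, target_version)
    label = _label(db, ordinal)
    rows = []
    for pos, text in enumerate(inputs):
        row = resolve(db, text, label, "any", position=pos)
        if row.status in (ALIVE, AMBIGUOUS):
            rows.append(row)
            continue
        if row.status == DEAD:  # accession input absent from target
            rows.append(row)
            continue
        hit = _resolve_any_version(db, text)
        if hit is None:
            rows.append(QueryRow(pos, text, status=NOT_FOUND, version=label))
        else:
            acc_idx, _ = hit
            rows.append(
                QueryRow(pos, text, accession=db.accessions[acc_idx],
                         status=DEAD, version=label)
            )
    return rows


def check_version(db: MirDatabase, inputs: Sequence[str]) -> VersionCheckResult:
    """Most probable source version of a name list.

    The proportion for version v is the fraction of usable inputs whose name
    matches v's name pool (precursor and mature pools jointly, exact before
    case-folded).  Accession inputs carry no version signal (accessions are
    version-stable) and are excluded from the denominator.  Ties go to the
    highest ordinal: the newest release maximizes downstream compatibility.
    """
    idx = _index(db)
    usable = [t.strip() for t in inputs if t.strip()]
    names = [t for t in usable if not ACCESSION_RE.match(t.upper())]
    n_excluded = len(usable) - len(names)
    if n_excluded:
        logger.info(
            "check_version: excluded %d accession input(s) from the proportion "
            "denominator (accessions are version-stable)", n_excluded,
        )
    if not names:
        raise DatabaseError("no usable input: need at least one non-empty miRNA name")
    proportions: dict[str, float] = {}
    counts: dict[str, int] = {}
    for vi in db.versions:
        ordinal = vi.version.ordinal
        matched = sum(
            1
            for t in names
            if t in idx.exact[ordinal] or t.casefold() in idx.folded[ordinal]
        )
        proportions[vi.version.label] = matched / len(names)
        counts[vi.version.label] = matched
    best = max(
        db.versions,
        key=lambda vi: (proportions[vi.version.label], vi.version.ordinal),
    ).version.label
    return VersionCheckResult(
        proportions=proportions,
        best=best,
        n_input=len(names),
        n_matched_best=counts[best],
    )


def check_family(
    db: MirDatabase,
    inputs: Sequence[str],
    version: Union[str, VersionLabel, None] = None,
) -> list[QueryRow]:
    """Family membership of each input; mature inputs map through their parents.

    One output row per (input, distinct family); inputs without a family keep
    their status with family fields absent.  Raises when the requested version
    shipped no family data at all.
    """
    idx = _index(db)
    ordinal = _ordinal(db, version)
    label = _label(db, ordinal)
    if ordinal not in db.family_versions:
        raise DatabaseError(f"no family data for version {label}")
    members = db.membership[ordinal]
    rows: list[QueryRow] = []
    for pos, text in enumerate(inputs):
        base = check_alive(db, [text], label)[0]
        row = QueryRow(pos, text, base.accession, base.name, base.status, label,
                       dict(base.extras))
        if row.status not in (ALIVE,):
            rows.append(row)
            continue
        acc_idx = idx.acc_to_idx[row.accession]
        if idx.kind(acc_idx) is AccessionKind.MATURE:
            pre_idxs = idx.parents[ordinal].get(acc_idx, [])
        else:
            pre_idxs = [acc_idx]
        fam_idxs: list[int] = []
        for p in pre_idxs:
            fam = members[p].family_index
            if fam is not None and fam not in fam_idxs:
                fam_idxs.append(fam)
        if not fam_idxs:
            rows.append(row)
            continue
        for fam in fam_idxs:
            ref = db.families[fam]
            extras = dict(row.extras)
            extras["family_accession"] = db.accessions[ref.accession_index]
            extras["family_name"] = db.names[ref.name_index]
            rows.append(QueryRow(pos, text, row.accession, row.name, ALIVE, label, extras))
    return rows


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

def name_to_accession(
    db: MirDatabase,
    inputs: Sequence[str],
    version: Union[str, VersionLabel, None] = None,
) -> list[QueryRow]:
    """Name -> accession. When no version is given it is inferred (and logged)."""
    if version is None:
        result = check_version(db, inputs)
        version = result.best
        logger.info(
            "name_to_accession: inferred source version %s (matched proportion %.3f)",
            version, result.proportions[version],
        )
    rows = []
    for pos, text in enumerate(inputs):
        row = resolve(db, text, version, "any", position=pos)
        if row.status == ALIVE:
            extras = dict(row.extras)
            extras["accession"] = row.accession
            row = QueryRow(pos, text, row.accession, row.name, ALIVE, row.version, extras)
        rows.append(row)
    return rows


def accession_to_name(
    db: MirDatabase,
    inputs: Sequence[str],
    target_version: Union[str, VersionLabel, None] = None,
) -> list[QueryRow]:
    """Accession -> the name it carries in the target version (dead if absent)."""
    ordinal = _ordinal(db, target_version)
    label = _label(db, ordinal)
    rows = []
    for pos, text in enumerate(inputs):
        t = text.strip().upper()
        if not ACCESSION_RE.match(t):
            rows.append(QueryRow(pos, text, status=NOT_FOUND, version=label))
            continue
        rows.append(resolve(db, text, label, "any", position=pos))
    return rows


def version_convert(
    db: MirDatabase,
    inputs: Sequence[str],
    source_version: Union[str, VersionLabel, None] = None,
    target_version: Union[str, VersionLabel, None] = None,
) -> list[QueryRow]:
    """Convert names between versions using the accession as the bridge.

    Pipeline per input: resolve in the source version -> accession -> name in
    the target version.  An accession alive in the source but absent from the
    target yields a ``dead`` row with the target name absent.
    """
    idx = _index(db)
    if source_version is None:
        result = check_version(db, inputs)
        source_version = result.best
        logger.info(
            "version_convert: inferred source version %s (matched proportion %.3f)",
            source_version, result.proportions[source_version],
        )
    src_ordinal = _ordinal(db, source_version)
    tgt_ordinal = _ordinal(db, target_version)
    tgt_label = _label(db, tgt_ordinal)
    rows = []
    for pos, text in enumerate(inputs):
        row = resolve(db, text, source_version, "any", position=pos)
        extras = dict(row.extras)
        extras["source_version"] = _label(db, src_ordinal)
        extras["source_name"] = row.name
        extras["target_name"] = None
        if row.status not in (ALIVE, DEAD) or row.accession is None:
            rows.append(QueryRow(pos, text, row.accession, row.name, row.status,
                                 tgt_label, extras))
            continue
        acc_idx = idx.acc_to_idx[row.accession]
        if tgt_ordinal in idx.acc_versions[acc_idx]:
            extras["target_name"] = idx.name_in(acc_idx, tgt_ordinal)
            rows.append(QueryRow(pos, text, row.accession, row.name, ALIVE,
                                 tgt_label, extras))
        else:
            rows.append(QueryRow(pos, text, row.accession, row.name, DEAD,
                                 tgt_label, extras))
    return rows


def precursor_to_mature(
    db: MirDatabase,
    inputs: Sequence[str],
    version: Union[str, VersionLabel, None] = None,
) -> list[QueryRow]:
    """Precursor -> its mature products; one row per (input, product), arm reported."""
    idx = _index(db)
    ordinal = _ordinal(db, version)
    label = _label(db, ordinal)
    rows: list[QueryRow] = []
    for pos, text in enumerate(inputs):
        row = resolve(db, text, label, "any", position=pos)
        if row.status == ALIVE and idx.kind(idx.acc_to_idx[row.accession]) is AccessionKind.MATURE:
            extras = dict(row.extras)
            extras["note"] = "input is a mature miRNA; expected a precursor"
            rows.append(QueryRow(pos, text, row.accession, row.name, AMBIGUOUS,
                                 label, extras))
            continue
        if row.status != ALIVE:
            rows.append(row)
            continue
        rec = db.membership[ordinal][idx.acc_to_idx[row.accession]]
        if not rec.products:
            rows.append(row)
            continue
        for link in rec.products:
            extras = dict(row.extras)
            extras["mature_accession"] = db.accessions[link.mature_index]
            extras["mature_name"] = idx.name_in(link.mature_index, ordinal)
            extras["arm"] = link.arm.value
            rows.append(QueryRow(pos, text, row.accession, row.name, ALIVE,
                                 label, extras))
    return rows


def mature_to_precursor(
    db: MirDatabase,
    inputs: Sequence[str],
    version: Union[str, VersionLabel, None] = None,
) -> list[QueryRow]:
    """Mature -> parent precursor(s); one row per parent (one-to-many honored)."""
    idx = _index(db)
    ordinal = _ordinal(db, version)
    label = _label(db, ordinal)
    rows: list[QueryRow] = []
    for pos, text in enumerate(inputs):
        row = resolve(db, text, label, "any", position=pos)
        if row.status == ALIVE and idx.kind(idx.acc_to_idx[row.accession]) is AccessionKind.PRECURSOR:
            extras = dict(row.extras)
            extras["note"] = "input is a precursor miRNA; expected a mature"
            rows.append(QueryRow(pos, text, row.accession, row.name, AMBIGUOUS,
                                 label, extras))
            continue
        if row.status != ALIVE:
            rows.append(row)
            continue
        parents = idx.parents[ordinal].get(idx.acc_to_idx[row.accession], [])
        if not parents:
            rows.append(row)
            continue
        for p in sorted(parents, key=lambda i: db.accessions[i]):
            extras = dict(row.extras)
            extras["precursor_accession"] = db.accessions[p]
            extras["precursor_name"] = idx.name_in(p, ordinal)
            rows.append(QueryRow(pos, text, row.accession, row.name, ALIVE,
                                 label, extras))
    return rows


# ---------------------------------------------------------------------------
# Retrieval
# ---------------------------------------------------------------------------

def get_history(db: MirDatabase, inputs: Sequence[str]) -> pd.DataFrame:
    """Name of each resolved accession in every registered version.

    One column per version (``None`` where the accession is absent) plus the
    merged alias history.  Unresolvable inputs pass through as empty rows.
    """
    idx = _index(db)
    labels = [vi.version.label for vi in db.versions]
    records = []
    for pos, text in enumerate(inputs):
        rec: dict = {"position": pos, "input": text, "accession": None}
        for label in labels:
            rec[label] = None
        rec["aliases"] = None
        hit = _resolve_any_version(db, text)
        if hit is not None:
            acc_idx, _ = hit
            rec["accession"] = db.accessions[acc_idx]
            for vi in db.versions:
                ordinal = vi.version.ordinal
                if ordinal in idx.acc_versions.get(acc_idx, ()):
                    rec[vi.version.label] = idx.name_in(acc_idx, ordinal)
            history = db.aliases.get(acc_idx, [])
            rec["aliases"] = ";".join(db.names[i] for i in history)
        records.append(rec)
    return pd.DataFrame.from_records(
        records, columns=["position", "input", "accession", *labels, "aliases"]
    )


def get_sequence(
    db: MirDatabase,
    inputs: Sequence[str],
    version: Union[str, VersionLabel, None] = None,
) -> list[QueryRow]:
    """RNA sequence of each resolved entity (precursor or mature) in a version."""
    idx = _index(db)
    ordinal = _ordinal(db, version)
    label = _label(db, ordinal)
    rows = []
    for pos, text in enumerate(inputs):
        row = resolve(db, text, label, "any", position=pos)
        extras = dict(row.extras)
        extras["sequence"] = None
        if row.status == ALIVE:
            rec = db.membership[ordinal][idx.acc_to_idx[row.accession]]
            extras["sequence"] = db.sequences[rec.sequence_index]
        rows.append(QueryRow(pos, text, row.accession, row.name, row.status,
                             label, extras))
    return rows


_ARM_ORDER = {Arm.FIVE_PRIME: 0, Arm.THREE_PRIME: 1, Arm.UNKNOWN: 2}


def get_table(
    db: MirDatabase,
    version: Union[str, VersionLabel, None] = None,
    species_filter: Optional[str] = None,
    kind: str = "joined",
) -> pd.DataFrame:
    """Complete data table of a version.

    ``joined``: one row per precursor (ascending accession) with up to two
    mature triplets ordered 5' before 3', unknown arms last.  ``precursor`` /
    ``mature``: flat entity tables.
    """
    idx = _index(db)
    ordinal = _ordinal(db, version)
    members = db.membership[ordinal]
    entries = rebuild_release(db, _label(db, ordinal))
    valid_species = sorted({e.species_code for e in entries})
    if species_filter is not None and species_filter not in valid_species:
        raise DatabaseError(
            f"unknown species code {species_filter!r} for this version; "
            f"valid codes: {', '.join(valid_species) or '(none)'}"
        )
    if species_filter is not None:
        entries = [e for e in entries if e.species_code == species_filter]

    if kind == "precursor":
        return pd.DataFrame.from_records(
            [
                {"accession": e.accession, "name": e.name, "sequence": e.sequence,
                 "species": e.species_code}
                for e in entries
            ],
            columns=["accession", "name", "sequence", "species"],
        )
    if kind == "mature":
        seen = set()
        records = []
        for e in entries:
            for p in sorted(e.products, key=lambda p: _ARM_ORDER[p.arm]):
                if p.accession in seen:
                    continue
                seen.add(p.accession)
                rec = members[idx.acc_to_idx[p.accession]]
                records.append(
                    {"accession": p.accession, "name": p.name,
                     "sequence": db.sequences[rec.sequence_index],
                     "species": p.name.split("-", 1)[0], "arm": p.arm.value}
                )
        return pd.DataFrame.from_records(
            records, columns=["accession", "name", "sequence", "species", "arm"]
        )
    if kind != "joined":
        raise ValueError(f"kind must be precursor, mature or joined, got {kind!r}")

    records = []
    for e in entries:
        rec = {
            "accession": e.accession, "name": e.name, "sequence": e.sequence,
            "species": e.species_code,
        }
        products = sorted(e.products, key=lambda p: _ARM_ORDER[p.arm])
        for slot in (1, 2):
            for col in ("accession", "name", "sequence"):
                rec[f"mature{slot}_{col}"] = None
        for slot, p in enumerate(products[:2], start=1):
            m = members[idx.acc_to_idx[p.accession]]
            rec[f"mature{slot}_accession"] = p.accession
            rec[f"mature{slot}_name"] = p.name
            rec[f"mature{slot}_sequence"] = db.sequences[m.sequence_index]
        records.append(rec)
    return pd.DataFrame.from_records(
        records,
        columns=[
            "accession", "name", "sequence", "species",
            "mature1_accession", "mature1_name", "mature1_sequence",
            "mature2_accession", "mature2_name", "mature2_sequence",
        ],
    )


def get_catalog(
    db: MirDatabase,
    kind: str = "versions",
    version: Union[str, VersionLabel, None] = None,
) -> pd.DataFrame:
    """Version statistics, observed species, or the name/accession roll of a version."""
    idx = _index(db)
    if kind == "versions":
        return pd.DataFrame.from_records(
            [
                {"version": vi.version.label, "release_date": vi.release_date,
                 "n_precursors": vi.n_precursors, "n_matures": vi.n_matures}
                for vi in db.versions
            ],
            columns=["version", "release_date", "n_precursors", "n_matures"],
        )
    if kind == "species":
        max_ordinal = (
            db.version_info(version).version.ordinal if version is not None
            else max(m for m in db.membership)
        )
        seen: list[int] = []
        for vi in db.versions:
            if vi.version.ordinal > max_ordinal:
                continue
            for rec in db.membership[vi.version.ordinal].values():
                if rec.species_index not in seen:
                    seen.append(rec.species_index)
        records = [
            {"code": s.code, "division": s.division, "name": s.name,
             "tree": s.tree, "taxon_id": s.taxon_id}
            for s in sorted((db.species[i] for i in seen), key=lambda s: s.code)
        ]
        return pd.DataFrame.from_records(
            records, columns=["code", "division", "name", "tree", "taxon_id"]
        )
    if kind == "mirnas":
        if version is None:
            raise DatabaseError("the mirnas catalog requires a version")
        ordinal = _ordinal(db, version)
        records = []
        for acc_idx in sorted(db.membership[ordinal], key=lambda i: db.accessions[i]):
            records.append(
                {
                    "accession": db.accessions[acc_idx],
                    "name": idx.name_in(acc_idx, ordinal),
                    "kind": idx.kind(acc_idx).value,
                }
            )
        return pd.DataFrame.from_records(records, columns=["accession", "name", "kind"])
    raise ValueError(f"kind must be versions, species or mirnas, got {kind!r}")


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def rows_to_frame(rows: Iterable[QueryRow]) -> pd.DataFrame:
    """Flatten query rows into a DataFrame (extras become columns)."""
    records = []
    extra_cols: list[str] = []
    for row in rows:
        rec = {
            "position": row.position, "input": row.input,
            "accession": row.accession, "name": row.name,
            "status": row.status, "version": row.version,
        }
        for key, value in row.extras.items():
            if key not in extra_cols:
                extra_cols.append(key)
            rec[key] = ";".join(value) if isinstance(value, list) else value
        records.append(rec)
    cols = ["position", "input", "accession", "name", "status", "version", *extra_cols]
    return pd.DataFrame.from_records(records, columns=cols)
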