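"""Independent brute-force reference implementations used as test oracles.

Everything here works by linear scans over parsed :class:`ReleaseData` lists
(or generator event logs) — never through the indexed database — so agreement
between these functions and the query engine is a genuine dual-route check.
"""

from __future__ import annotations

from mirversions.mirbase_io import ReleaseData


def release_by_label(history: list[ReleaseData], label: str) -> ReleaseData:
    return next(r for r in history if r.version.label == label)


def name_pool(release: ReleaseData) -> set[str]:
    """All precursor and mature names of one release."""
    names = {e.name for e in release.entries}
    names.update(p.name for e in release.entries for p in e.products)
    return names


def accession_pool(release: ReleaseData) -> set[str]:
    accs = {e.accession for e in release.entries}
    accs.update(p.accession for e in release.entries for p in e.products)
    return accs


def distinct_names(history: list[ReleaseData]) -> set[str]:
    """Every distinct name string across all releases (families included)."""
    names: set[str] = set()
    for release in history:
        names |= name_pool(release)
        names.update(f.name for f in release.families)
        for alias in release.aliases:
            names.update(alias.historical_names)
    return names


def distinct_accessions(history: list[ReleaseData]) -> set[str]:
    accs: set[str] = set()
    for release in history:
        accs |= accession_pool(release)
        accs.update(f.accession for f in release.families)
    return accs


def distinct_sequences(history: list[ReleaseData]) -> set[str]:
    seqs: set[str] = set()
    for release in history:
        seqs.update(e.sequence for e in release.entries)
        seqs.update(seq for _, seq in release.matures.values())
    return seqs


def name_of_accession(release: ReleaseData, accession: str):
    for e in release.entries:
        if e.accession == accession:
            return e.name
        for p in e.products:
            if p.accession == accession:
                return p.name
    return None


def sequence_of(release: ReleaseData, accession: str):
    for e in release.entries:
        if e.accession == accession:
            return e.sequence
    hit = release.matures.get(accession)
    return hit[1] if hit else None


def alive_status(history: list[ReleaseData], accession: str, target_label: str) -> str:
    target = release_by_label(history, target_label)
    if accession in accession_pool(target):
        return "alive"
    if any(accession in accession_pool(r) for r in history):
        return "dead"
    return "not_found"


def version_proportions(history: list[ReleaseData], names: list[str]) -> dict[str, float]:
    out = {}
    for release in history:
        pool = name_pool(release)
        folded = {n.casefold() for n in pool}
        matched = sum(1 for n in names if n in pool or n.casefold() in folded)
        out[release.version.label] = matched / len(names)
    return out


def families_of(release: ReleaseData, text: str) -> set[tuple[str, str]]:
    """(family accession, family name) pairs reachable from a name/accession."""
    precursors: set[str] = set()
    for e in release.entries:
        if text in (e.name, e.accession):
            precursors.add(e.accession)
        for p in e.products:
            if text in (p.name, p.accession):
                precursors.add(e.accession)
    out = set()
    for fam in release.families:
        for member in fam.member_precursors:
            if member in precursors:
                out.add((fam.accession, fam.name))
    return out


def matures_of_precursor(release: ReleaseData, accession: str) -> list[tuple[str, str]]:
    for e in release.entries:
        if e.accession == accession:
            return [(p.accession, p.name) for p in e.products]
    return []


def precursors_of_mature(release: ReleaseData, accession: str) -> set[str]:
    return {
        e.accession
        for e in release.entries
        if any(p.accession == accession for p in e.products)
    }


def history_of(history: list[ReleaseData], accession: str) -> dict[str, object]:
    return {
        r.version.label: name_of_accession(r, accession) for r in history
    }


def replay_events(events, labels: list[str]):
    """Replay an event log into per-version alive-name maps.

    Returns ``{label: {accession: name}}`` for precursors and matures; the
    generated releases must agree exactly (the identity-layer replay check).
    """
    state: dict[str, str] = {}
    snapshots: dict[str, dict[str, str]] = {}
    by_version: dict[str, list] = {label: [] for label in labels}
    for ev in events:
        by_version[ev.version].append(ev)
    for label in labels:
        for ev in by_version[label]:
            if ev.kind == "birth":
                state[ev.accession] = ev.new_name
            elif ev.kind in ("rename", "arm_change"):
                state[ev.accession] = ev.new_name
            elif ev.kind == "kill":
                state.pop(ev.accession, None)
        snapshots[label] = dict(state)
    return snapshots
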