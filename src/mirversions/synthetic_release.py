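"""Synthetic multi-version release histories with ground-truth event logs.

The generator emulates how miRBase nomenclature evolved between releases:
entries are born, killed (misannotations removed), renamed, and re-designated
from the legacy guide/passenger ``miR``/``miR*`` convention to explicit
``-5p``/``-3p`` arm suffixes.  A rule schedule drives the documented era
transitions — the antisense ``-as`` suffix retired at v16 (legacy names
scrubbed at the following release), star retirement and forced arm suffixes
staged per species across v17–v19.  Every change is recorded in an event log
that doubles as the oracle for query tests.

Also bundled: :func:`demo_history`, a small hand-built four-release history
(v16, v17, v19, v22) exercising every documented behaviour — an ``-as``
rename, a killed mature, and two star-to-arm-suffix transitions.  All demo
accessions use the reserved synthetic 09xxxxx range; they are not real
miRBase accessions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from mirversions.core_model import (
    Arm,
    FamilyRecord,
    MatureProduct,
    MirVersionsError,
    PrecursorEntry,
    SpeciesRecord,
    VersionLabel,
)
from mirversions.mirbase_io import AliasRecord, ReleaseData, ReleaseFiles

RULES = ("retire_as_suffix", "retire_star", "force_5p3p")

#: Rule schedule mirroring the documented nomenclature era: the "-as"
#: antisense suffix retired at v16, fly star names re-designated at v17,
#: human/mouse/worm at v18, and every species at v19.
ERA_SCHEDULE: dict[str, frozenset[str]] = {
    "v16": frozenset({"retire_as_suffix"}),
    "v17": frozenset({"retire_star:dme", "force_5p3p:dme"}),
    "v18": frozenset({"retire_star:hsa,mmu,cel", "force_5p3p:hsa,mmu,cel"}),
    "v19": frozenset({"retire_star", "force_5p3p"}),
}

_SPECIES_TABLE: dict[str, SpeciesRecord] = {
    "hsa": SpeciesRecord("hsa", "HSA", "Homo sapiens",
                         "Metazoa;Bilateria;Deuterostoma;Chordata;Vertebrata;Mammalia;Primates;Hominidae;",
                         9606),
    "mmu": SpeciesRecord("mmu", "MMU", "Mus musculus",
                         "Metazoa;Bilateria;Deuterostoma;Chordata;Vertebrata;Mammalia;Rodentia;",
                         10090),
    "dme": SpeciesRecord("dme", "DME", "Drosophila melanogaster",
                         "Metazoa;Bilateria;Ecdysozoa;Arthropoda;Hexapoda;", 7227),
    "cel": SpeciesRecord("cel", "CEL", "Caenorhabditis elegans",
                         "Metazoa;Bilateria;Ecdysozoa;Nematoda;", 6239),
    "ath": SpeciesRecord("ath", "ATH", "Arabidopsis thaliana",
                         "Viridiplantae;Streptophyta;Embryophyta;", 3702),
}


class ConfigError(MirVersionsError):
    """A history configuration violates its invariants."""


@dataclass(frozen=True)
class Event:
    """One ground-truth change: birth, kill, rename, arm_change or family_assign."""

    version: str
    kind: str
    accession: str
    old_name: Optional[str] = None
    new_name: Optional[str] = None


@dataclass(frozen=True)
class HistoryConfig:
    """Study conditions for one synthetic history.

    Rates are per entry per step.  ``rule_schedule`` maps version labels to
    rule strings (``"force_5p3p"`` for all species, ``"force_5p3p:dme,hsa"``
    scoped); ``None`` selects :data:`ERA_SCHEDULE` restricted to the generated
    labels.  Labels default to ``v16, v17, ...`` so the era schedule lines up.
    """

    n_versions: int = 5
    n_initial_precursors: int = 40
    species_pool: tuple[str, ...] = ("hsa", "mmu", "dme", "cel")
    birth_rate: float = 0.08
    kill_rate: float = 0.05
    rename_rate: float = 0.10
    arm_redesignation_rate: float = 0.05
    rule_schedule: Optional[Mapping[str, frozenset[str]]] = None
    seed: int = 0
    include_mifam: bool = True
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_versions < 1 or self.n_initial_precursors < 1:
            raise ConfigError("n_versions and n_initial_precursors must be >= 1")
        if not self.species_pool:
            raise ConfigError("species pool must not be empty")
        rates = (self.birth_rate, self.kill_rate, self.rename_rate,
                 self.arm_redesignation_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ConfigError("rates must lie in [0, 1]")
        if sum(rates) > 1.0:
            raise ConfigError("per-entry rates must sum to at most 1")
        if self.labels is not None and len(self.labels) != self.n_versions:
            raise ConfigError("labels length must equal n_versions")

    @property
    def version_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return self.labels
        return tuple(f"v{16 + i}" for i in range(self.n_versions))


def _parse_schedule(
    config: HistoryConfig,
) -> dict[int, list[tuple[str, Optional[frozenset[str]]]]]:
    labels = config.version_labels
    raw = config.rule_schedule
    if raw is None:
        raw = {k: v for k, v in ERA_SCHEDULE.items() if k in labels}
    out: dict[int, list[tuple[str, Optional[frozenset[str]]]]] = {}
    for label, rules in raw.items():
        if label not in labels:
            raise ConfigError(f"rule schedule names unknown version {label!r}")
        idx = labels.index(label)
        for rule in sorted(rules):
            name, _, scope = rule.partition(":")
            if name not in RULES:
                raise ConfigError(f"unknown rule {name!r}")
            scope_set = frozenset(s for s in scope.split(",") if s) if scope else None
            out.setdefault(idx, []).append((name, scope_set))
    return out


# ---------------------------------------------------------------------------
# Simulation state
# ---------------------------------------------------------------------------

@dataclass
class _Mat:
    accession: str
    arm: Arm
    start: int
    end: int
    history: list[str] = field(default_factory=list)


@dataclass
class _Pre:
    accession: str
    species: str
    num: str
    antisense: bool
    sequence: str
    matures: list[_Mat]
    suffixed: bool
    guide_arm: Optional[Arm]  # which arm carries the star-era guide name
    family: Optional[str]
    alive: bool = True
    history: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.species}-mir-{self.num}" + ("-as" if self.antisense else "")

    def mature_name(self, m: _Mat) -> str:
        base = f"{self.species}-miR-{self.num}" + ("-as" if self.antisense else "")
        if self.suffixed:
            return base + ("-5p" if m.arm is Arm.FIVE_PRIME else "-3p")
        if len(self.matures) == 2 and self.guide_arm is not None:
            return base if m.arm is self.guide_arm else base + "*"
        return base

    @property
    def description(self) -> str:
        full = _SPECIES_TABLE.get(self.species)
        organism = full.name if full else self.species
        tail = f"miR-{self.num}" + ("-as" if self.antisense else "")
        return f"{organism} {tail} stem-loop"


def _random_rna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))


def generate_history(config: HistoryConfig) -> tuple[list[ReleaseData], list[Event]]:
    """Generate a deterministic release history plus its ground-truth event log.

    Arm placement guarantees that the midpoint inference rule recovers the
    intended arm for unsuffixed names: 5' products end in the first half of
    the hairpin, 3' products start in the second half.
    """
    rng = random.Random(config.seed)
    labels = config.version_labels
    schedule = _parse_schedule(config)

    mi_counter = iter(range(900001, 1000000))
    mimat_counter = iter(range(900001, 1000000))
    num_counters: dict[str, int] = {}
    family_acc: dict[str, str] = {}
    events: list[Event] = []
    pres: list[_Pre] = []

    as_index: Optional[int] = None
    for idx, rules in schedule.items():
        for name, _scope in rules:
            if name == "retire_as_suffix" and (as_index is None or idx < as_index):
                as_index = idx

    def rule_active(rule: str, sp: str, idx: int) -> bool:
        for j, rules in schedule.items():
            if j > idx:
                continue
            for name, scope in rules:
                if name == rule and (scope is None or sp in scope):
                    return True
        return False

    def allow_antisense(idx: int) -> bool:
        if as_index is None:
            return True
        # legacy "-as" entries may exist in the version the retirement lands
        # in (they are scrubbed one release later); no new ones afterwards
        return idx < as_index or (idx == 0 and as_index == 0)

    def next_num(sp: str) -> str:
        num_counters[sp] = num_counters.get(sp, 99) + 1
        return str(num_counters[sp])

    def spawn(idx: int) -> None:
        sp = rng.choice(config.species_pool)
        num = next_num(sp)
        antisense = allow_antisense(idx) and rng.random() < 0.10
        length = rng.randint(60, 120)
        seq = _random_rna(rng, length)
        two = rng.random() < 0.75
        mats: list[_Mat] = []
        if two or rng.random() < 0.5:  # second branch picks the single arm
            ml = rng.randint(19, 24)
            start = rng.randint(1, 6)
            mats.append(_Mat(f"MIMAT0{next(mimat_counter)}", Arm.FIVE_PRIME,
                             start, start + ml - 1))
        if two or not mats:
            ml = rng.randint(19, 24)
            end = length - rng.randint(0, 5)
            mats.append(_Mat(f"MIMAT0{next(mimat_counter)}", Arm.THREE_PRIME,
                             end - ml + 1, end))
        star_banned = rule_active("retire_star", sp, idx)
        forced = rule_active("force_5p3p", sp, idx)
        suffixed = forced or (len(mats) == 2 and star_banned)
        guide = rng.choice((Arm.FIVE_PRIME, Arm.THREE_PRIME)) if (
            len(mats) == 2 and not suffixed) else None
        pre = _Pre(
            accession=f"MI0{next(mi_counter)}",
            species=sp,
            num=num,
            antisense=antisense,
            sequence=seq,
            matures=mats,
            suffixed=suffixed,
            guide_arm=guide,
            family=f"mir-{num}" if rng.random() < 0.80 else None,
        )
        pres.append(pre)
        version = labels[idx]
        pre.history.append(pre.name)
        events.append(Event(version, "birth", pre.accession, new_name=pre.name))
        for m in pre.matures:
            mname = pre.mature_name(m)
            m.history.append(mname)
            events.append(Event(version, "birth", m.accession, new_name=mname))
        if pre.family is not None:
            if pre.family not in family_acc:
                family_acc[pre.family] = f"MIPF0{900001 + len(family_acc)}"
            events.append(
                Event(version, "family_assign", pre.accession, new_name=pre.family)
            )

    def rename(pre: _Pre, version: str) -> None:
        old_names = {m.accession: pre.mature_name(m) for m in pre.matures}
        old = pre.name
        pre.num = next_num(pre.species)
        pre.antisense = False
        pre.history.append(pre.name)
        events.append(Event(version, "rename", pre.accession, old, pre.name))
        if rng.random() < 0.5:  # re-annotation sometimes revises the sequence
            seq = list(pre.sequence)
            for _ in range(3):
                pos = rng.randrange(len(seq))
                seq[pos] = rng.choice("ACGU")
            pre.sequence = "".join(seq)
        for m in pre.matures:
            new = pre.mature_name(m)
            if new != old_names[m.accession]:
                m.history.append(new)
                events.append(
                    Event(version, "rename", m.accession, old_names[m.accession], new)
                )

    def suffix_matures(pre: _Pre, version: str) -> None:
        if pre.suffixed:
            return
        old_names = {m.accession: pre.mature_name(m) for m in pre.matures}
        pre.suffixed = True
        pre.guide_arm = None
        for m in pre.matures:
            new = pre.mature_name(m)
            if new != old_names[m.accession]:
                m.history.append(new)
                events.append(
                    Event(version, "arm_change", m.accession, old_names[m.accession], new)
                )

    def kill(pre: _Pre, version: str) -> None:
        pre.alive = False
        events.append(Event(version, "kill", pre.accession, old_name=pre.name))
        for m in pre.matures:
            events.append(
                Event(version, "kill", m.accession, old_name=pre.mature_name(m))
            )

    releases: list[ReleaseData] = []
    for idx, label in enumerate(labels):
        if idx == 0:
            for _ in range(config.n_initial_precursors):
                spawn(0)
        else:
            snapshot = [p for p in pres if p.alive]
            k, r, a = config.kill_rate, config.rename_rate, config.arm_redesignation_rate
            for pre in snapshot:
                u = rng.random()
                if u < k:
                    kill(pre, label)
                elif u < k + r:
                    rename(pre, label)
                elif u < k + r + a:
                    suffix_matures(pre, label)
            for _ in range(len(snapshot)):
                if rng.random() < config.birth_rate:
                    spawn(idx)
        # scheduled rule enforcement within this version
        if as_index is not None and idx > as_index:
            for pre in pres:
                if pre.alive and pre.antisense:
                    rename(pre, label)
        for name, scope in schedule.get(idx, []):
            if idx == 0:
                continue  # the initial population is created compliant
            for pre in pres:
                if not pre.alive or (scope is not None and pre.species not in scope):
                    continue
                if name == "force_5p3p":
                    suffix_matures(pre, label)
                elif name == "retire_star" and len(pre.matures) == 2:
                    suffix_matures(pre, label)
        releases.append(_assemble(config, labels, idx, pres, family_acc))
    return releases, events


def _assemble(
    config: HistoryConfig,
    labels: tuple[str, ...],
    idx: int,
    pres: list[_Pre],
    family_acc: dict[str, str],
) -> ReleaseData:
    entries: list[PrecursorEntry] = []
    matures: dict[str, tuple[str, str]] = {}
    fam_members: dict[str, list[tuple[str, str]]] = {}
    for pre in pres:
        if not pre.alive:
            continue
        products = tuple(
            MatureProduct(m.accession, pre.mature_name(m), m.arm, m.start, m.end)
            for m in pre.matures
        )
        entries.append(
            PrecursorEntry(
                accession=pre.accession,
                name=pre.name,
                species_code=pre.species,
                description=pre.description,
                sequence=pre.sequence,
                products=products,
            )
        )
        for m, product in zip(pre.matures, products):
            matures[m.accession] = (product.name, pre.sequence[m.start - 1 : m.end])
        if pre.family is not None:
            fam_members.setdefault(pre.family, []).append((pre.accession, pre.name))
    families = [
        FamilyRecord(
            accession=family_acc[fam],
            name=fam,
            member_precursors=tuple(acc for acc, _ in sorted(members)),
        )
        for fam, members in sorted(fam_members.items(), key=lambda kv: family_acc[kv[0]])
    ] if config.include_mifam else []
    species = [
        _SPECIES_TABLE.get(code, SpeciesRecord(code=code, division=code.upper()))
        for code in sorted(set(config.species_pool))
    ]
    aliases: list[AliasRecord] = []
    for pre in sorted(pres, key=lambda p: p.accession):
        aliases.append(AliasRecord(pre.accession, tuple(pre.history)))
    for pre in pres:
        for m in sorted(pre.matures, key=lambda m: m.accession):
            aliases.append(AliasRecord(m.accession, tuple(m.history)))
    aliases.sort(key=lambda a: a.accession)
    return ReleaseData(
        version=VersionLabel(ordinal=idx + 1, label=labels[idx]),
        entries=entries,
        matures=matures,
        families=families,
        species=species,
        aliases=aliases,
        has_family_data=config.include_mifam,
    )


# ---------------------------------------------------------------------------
# File writer
# ---------------------------------------------------------------------------

def _wrap_sequence(seq: str) -> str:
    lines = []
    low = seq.lower()
    for i in range(0, len(low), 60):
        chunk = low[i : i + 60]
        spaced = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"     {spaced:<66}{min(i + 60, len(low)):>4}")
    return "\n".join(lines)


def write_release_files(data: ReleaseData, directory: Union[str, Path]) -> ReleaseFiles:
    """Write one release to ``directory`` in the dialects the parsers expect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    dat_lines: list[str] = []
    for entry in data.entries:
        sp = _SPECIES_TABLE.get(entry.species_code)
        division = sp.division if sp else entry.species_code.upper()
        dat_lines.append(
            f"ID   {entry.name}    standard; RNA; {division}; {len(entry.sequence)} BP."
        )
        dat_lines.append("XX")
        dat_lines.append(f"AC   {entry.accession};")
        dat_lines.append("XX")
        if entry.description:
            dat_lines.append(f"DE   {entry.description}")
            dat_lines.append("XX")
        for product in entry.products:
            dat_lines.append(f"FT   miRNA           {product.start}..{product.end}")
            dat_lines.append(f'FT                   /accession="{product.accession}"')
            dat_lines.append(f'FT                   /product="{product.name}"')
            dat_lines.append("FT                   /evidence=experimental")
        if entry.products:
            dat_lines.append("XX")
        dat_lines.append(f"SQ   Sequence {len(entry.sequence)} BP;")
        dat_lines.append(_wrap_sequence(entry.sequence))
        dat_lines.append("//")
    dat_path = directory / "miRNA.dat"
    dat_path.write_text("\n".join(dat_lines) + ("\n" if dat_lines else ""), encoding="utf-8")

    hairpin_path = directory / "hairpin.fa"
    with open(hairpin_path, "w", encoding="utf-8") as fh:
        for entry in data.entries:
            header = f">{entry.name} {entry.accession}"
            if entry.description:
                header += f" {entry.description}"
            fh.write(f"{header}\n{entry.sequence}\n")

    mature_path = directory / "mature.fa"
    with open(mature_path, "w", encoding="utf-8") as fh:
        for acc in sorted(data.matures):
            name, seq = data.matures[acc]
            fh.write(f">{name} {acc}\n{seq}\n")

    mifam_path: Optional[Path] = None
    if data.has_family_data:
        mifam_path = directory / "miFam.dat"
        name_of = {e.accession: e.name for e in data.entries}
        with open(mifam_path, "w", encoding="utf-8") as fh:
            for fam in data.families:
                fh.write(f"AC   {fam.accession}\nID   {fam.name}\n")
                for member in fam.member_precursors:
                    fh.write(f"MI   {member}  {name_of.get(member, member)}\n")
                fh.write("//\n")

    organisms_path: Optional[Path] = None
    if data.species:
        organisms_path = directory / "organisms.txt"
        with open(organisms_path, "w", encoding="utf-8") as fh:
            fh.write("#organism\t#division\t#name\t#tree\t#NCBI-taxid\n")
            for rec in data.species:
                taxid = "" if rec.taxon_id is None else str(rec.taxon_id)
                fh.write(f"{rec.code}\t{rec.division}\t{rec.name}\t{rec.tree}\t{taxid}\n")

    aliases_path: Optional[Path] = None
    if data.aliases:
        aliases_path = directory / "aliases.txt"
        with open(aliases_path, "w", encoding="utf-8") as fh:
            for alias in data.aliases:
                fh.write(f"{alias.accession}\t{';'.join(alias.historical_names)};\n")

    return ReleaseFiles(
        version=data.version,
        dat_path=dat_path,
        hairpin_fasta_path=hairpin_path,
        mature_fasta_path=mature_path,
        mifam_path=mifam_path,
        organisms_path=organisms_path,
        aliases_path=aliases_path,
        release_date=data.release_date,
    )


# ---------------------------------------------------------------------------
# Bundled worked-example history
# ---------------------------------------------------------------------------

def demo_history() -> list[ReleaseData]:
    """Four hand-built releases (v16, v17, v19, v22) for the worked example.

    Contents:

    * ``MI0900001``: named ``hsa-mir-103-1-as`` in v16, renamed to
      ``hsa-mir-103b-1`` from v17 on (the ``-as`` retirement); member of
      family ``mir-103`` (``MIPF0900001``).
    * ``MIMAT0900001`` ``mmu-miR-1274a``: present v16–v19, removed in v22.
    * ``hsa-mir-224``: matures ``hsa-miR-224``/``hsa-miR-224*`` through v17,
      ``hsa-miR-224-5p``/``-3p`` from v19.
    * ``dme-mir-8``: star pair in v16, arm suffixes from v17 (the fly-first
      staging of the transition).
    """
    rng = random.Random(982451653)
    h103 = _random_rna(rng, 80)
    h1274 = _random_rna(rng, 72)
    h224 = _random_rna(rng, 84)
    h8 = _random_rna(rng, 90)

    def pre(acc, name, desc, seq, prods):
        return PrecursorEntry(
            accession=acc,
            name=name,
            species_code=name.split("-", 1)[0],
            description=desc,
            sequence=seq,
            products=tuple(
                MatureProduct(a, n, Arm(arm), s, e) for a, n, arm, s, e in prods
            ),
        )

    species = [_SPECIES_TABLE[c] for c in ("dme", "hsa", "mmu")]
    fam_103 = ("MIPF0900001", "mir-103", ("MI0900001",))
    fam_224 = ("MIPF0900002", "mir-224", ("MI0900010",))

    def release(ordinal, label, date, entries, histories):
        matures = {}
        for e in entries:
            for p in e.products:
                matures[p.accession] = (p.name, e.sequence[p.start - 1 : p.end])
        return ReleaseData(
            version=VersionLabel(ordinal=ordinal, label=label),
            entries=entries,
            matures=matures,
            families=[FamilyRecord(a, n, m) for a, n, m in (fam_103, fam_224)],
            species=species,
            aliases=[AliasRecord(acc, tuple(names)) for acc, names in sorted(histories.items())],
            release_date=date,
            has_family_data=True,
        )

    # v16 — legacy era: an "-as" antisense entry and two star pairs
    e103_16 = pre("MI0900001", "hsa-mir-103-1-as", "Homo sapiens miR-103-1-as stem-loop",
                  h103, [("MIMAT0900002", "hsa-miR-103-as", "3p", 50, 71)])
    e1274 = pre("MI0900002", "mmu-mir-1274a", "Mus musculus miR-1274a stem-loop",
                h1274, [("MIMAT0900001", "mmu-miR-1274a", "5p", 10, 31)])
    e224_star = pre("MI0900010", "hsa-mir-224", "Homo sapiens miR-224 stem-loop", h224,
                    [("MIMAT0900010", "hsa-miR-224", "5p", 6, 27),
                     ("MIMAT0900011", "hsa-miR-224*", "3p", 55, 76)])
    e8_star = pre("MI0900020", "dme-mir-8", "Drosophila melanogaster miR-8 stem-loop", h8,
                  [("MIMAT0900020", "dme-miR-8", "5p", 5, 26),
                   ("MIMAT0900021", "dme-miR-8*", "3p", 62, 85)])

    hist16 = {
        "MI0900001": ["hsa-mir-103-1-as"], "MIMAT0900002": ["hsa-miR-103-as"],
        "MI0900002": ["mmu-mir-1274a"], "MIMAT0900001": ["mmu-miR-1274a"],
        "MI0900010": ["hsa-mir-224"], "MIMAT0900010": ["hsa-miR-224"],
        "MIMAT0900011": ["hsa-miR-224*"],
        "MI0900020": ["dme-mir-8"], "MIMAT0900020": ["dme-miR-8"],
        "MIMAT0900021": ["dme-miR-8*"],
    }
    v16 = release(1, "v16", "2010-08-01", [e103_16, e1274, e224_star, e8_star], hist16)

    # v17 — "-as" names scrubbed; fly star pair re-designated
    e103_17 = pre("MI0900001", "hsa-mir-103b-1", "Homo sapiens miR-103b-1 stem-loop",
                  h103, [("MIMAT0900002", "hsa-miR-103b", "3p", 50, 71)])
    e8_arm = pre("MI0900020", "dme-mir-8", "Drosophila melanogaster miR-8 stem-loop", h8,
                 [("MIMAT0900020", "dme-miR-8-5p", "5p", 5, 26),
                  ("MIMAT0900021", "dme-miR-8-3p", "3p", 62, 85)])
    hist17 = {
        **hist16,
        "MI0900001": ["hsa-mir-103-1-as", "hsa-mir-103b-1"],
        "MIMAT0900002": ["hsa-miR-103-as", "hsa-miR-103b"],
        "MIMAT0900020": ["dme-miR-8", "dme-miR-8-5p"],
        "MIMAT0900021": ["dme-miR-8*", "dme-miR-8-3p"],
    }
    v17 = release(2, "v17", "2011-04-01", [e103_17, e1274, e224_star, e8_arm], hist17)

    # v19 — all species on arm suffixes
    e103_19 = pre("MI0900001", "hsa-mir-103b-1", "Homo sapiens miR-103b-1 stem-loop",
                  h103, [("MIMAT0900002", "hsa-miR-103b-3p", "3p", 50, 71)])
    e224_arm = pre("MI0900010", "hsa-mir-224", "Homo sapiens miR-224 stem-loop", h224,
                   [("MIMAT0900010", "hsa-miR-224-5p", "5p", 6, 27),
                    ("MIMAT0900011", "hsa-miR-224-3p", "3p", 55, 76)])
    hist19 = {
        **hist17,
        "MIMAT0900002": ["hsa-miR-103-as", "hsa-miR-103b", "hsa-miR-103b-3p"],
        "MIMAT0900010": ["hsa-miR-224", "hsa-miR-224-5p"],
        "MIMAT0900011": ["hsa-miR-224*", "hsa-miR-224-3p"],
    }
    v19 = release(3, "v19", "2012-08-01", [e103_19, e1274, e224_arm, e8_arm], hist19)

    # v22 — mmu-miR-1274a (a misannotation) removed; aliases keep its history
    v22 = release(4, "v22", "2018-03-01", [e103_19, e224_arm, e8_arm], hist19)
    return [v16, v17, v19, v22]
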