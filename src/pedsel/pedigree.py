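"""Pedigree parsing, validation, traversal, selfing augmentation and summaries.

The on-disk format is the tab-delimited "Helium" dialect used by breeding
databases: a header row, then one row per entry with columns
``entry``, ``parent1``, ``parent2`` followed by optional attribute columns
(year of release, country of origin, landrace flag, ...).  An unknown parent
is encoded by a configurable sentinel (empty field by default).

A pedigree is a directed acyclic graph with edges from parent to child.
Founders are exactly the entries with no known parent.  Entries with a single
known parent are legal; the unknown side is treated downstream as a unique,
unrelated, fully inbred founder.
"""

from __future__ import annotations

import csv
import io
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .errors import ParseError, ValidationError

UNKNOWN_SENTINELS = ("",)


@dataclass
class PedigreeEntry:
    """One pedigree entry: a variety, landrace selection or breeding line."""

    id: str
    parent1: str | None = None
    parent2: str | None = None
    year: int | None = None
    country: str | None = None
    is_landrace: bool = False
    extra: dict = field(default_factory=dict)

    def known_parents(self) -> tuple[str, ...]:
        return tuple(p for p in (self.parent1, self.parent2) if p is not None)

    @property
    def is_founder(self) -> bool:
        return self.parent1 is None and self.parent2 is None


@dataclass
class ValidationReport:
    """Structural problems found in a pedigree; empty report == well-formed."""

    cycles: list[list[str]] = field(default_factory=list)
    dangling_parents: list[str] = field(default_factory=list)
    duplicates: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.cycles or self.dangling_parents or self.duplicates)


class Pedigree:
    """Collection of :class:`PedigreeEntry` with parent->child edges."""

    def __init__(self, entries: Iterable[PedigreeEntry] = ()):
        self.entries: dict[str, PedigreeEntry] = {}
        self.duplicates: list[str] = []
        self.created_founders: list[str] = []
        self._graph: nx.DiGraph | None = None
        for e in entries:
            self.add_entry(e)

    # -- construction ------------------------------------------------------
    def add_entry(self, entry: PedigreeEntry, on_duplicate: str = "error") -> None:
        if not entry.id:
            raise ValidationError("entry id must be non-empty")
        if entry.id in self.entries:
            if on_duplicate == "error":
                raise ValidationError(f"duplicate entry id: {entry.id!r}")
            self.duplicates.append(entry.id)
            return
        self.entries[entry.id] = entry
        self._graph = None

    def resolve_parents(self) -> list[str]:
        """Create founder entries for parent ids that are referenced but undefined.

        Returns the list of auto-created ids (also accumulated on
        ``created_founders``).
        """
        created = []
        for e in list(self.entries.values()):
            for pid in e.known_parents():
                if pid not in self.entries:
                    self.entries[pid] = PedigreeEntry(id=pid)
                    created.append(pid)
        if created:
            self._graph = None
            self.created_founders.extend(created)
        return created

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, id: str) -> bool:
        return id in self.entries

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Pedigree({len(self)} entries, {len(self.founders())} founders)"

    @property
    def ids(self) -> list[str]:
        return list(self.entries)

    def entry(self, id: str) -> PedigreeEntry:
        try:
            return self.entries[id]
        except KeyError:
            raise KeyError(f"unknown pedigree id: {id!r}") from None

    def parents(self, id: str) -> tuple[str | None, str | None]:
        e = self.entry(id)
        return e.parent1, e.parent2

    def founders(self) -> list[str]:
        return [e.id for e in self.entries.values() if e.is_founder]

    # -- graph views -------------------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        """Directed graph with edges parent -> child (cached)."""
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.entries)
            for e in self.entries.values():
                for pid in e.known_parents():
                    if pid in self.entries:
                        g.add_edge(pid, e.id)
            self._graph = g
        return self._graph

    def topological_order(self) -> list[str]:
        """Entries ordered founders-first; deterministic for a fixed insertion order.

        Raises :class:`ValidationError` if the pedigree contains a cycle.
        """
        pending = {}
        children: dict[str, list[str]] = {i: [] for i in self.entries}
        for e in self.entries.values():
            ps = [p for p in set(e.known_parents()) if p in self.entries]
            pending[e.id] = len(ps)
            for p in ps:
                children[p].append(e.id)
        queue = deque(i for i in self.entries if pending[i] == 0)
        order = []
        while queue:
            i = queue.popleft()
            order.append(i)
            for c in children[i]:
                pending[c] -= 1
                if pending[c] == 0:
                    queue.append(c)
        if len(order) != len(self.entries):
            raise ValidationError("pedigree contains a cycle; run validate_pedigree")
        return order


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_YEAR_COLUMNS = {"year", "year_of_release", "yor", "release_year"}
_COUNTRY_COLUMNS = {"country", "country_of_origin", "origin"}
_LANDRACE_COLUMNS = {"landrace", "is_landrace"}
_TRUTHY = {"1", "true", "yes", "y", "t"}


def read_pedigree(
    source,
    sep: str = "\t",
    unknown: Sequence[str] = UNKNOWN_SENTINELS,
    on_duplicate: str = "error",
) -> Pedigree:
    """Parse a Helium-dialect pedigree file.

    ``source`` may be a path or an open text stream.  The first three columns
    are entry, parent1 and parent2; any further columns become attributes
    (``year``, ``country`` and ``landrace`` are recognised by header name,
    everything else lands in ``entry.extra``).  Parent ids matching an entry
    in ``unknown`` are treated as unknown.  Parent ids that never appear as an
    entry are auto-created as founders and recorded on ``created_founders``.
    """
    if hasattr(source, "read"):
        return _read_pedigree_stream(source, sep, unknown, on_duplicate)
    with open(source, newline="") as fh:
        return _read_pedigree_stream(fh, sep, unknown, on_duplicate)


def _read_pedigree_stream(stream, sep, unknown, on_duplicate) -> Pedigree:
    unknown = set(unknown)
    reader = csv.reader(stream, delimiter=sep)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty pedigree file") from None
    if len(header) < 3:
        raise ParseError("header must have at least 3 columns", line=1)
    attr_names = [h.strip() for h in header[3:]]
    ped = Pedigree()
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue  # blank line
        if len(row) < 3 or len(row) > len(header):
            raise ParseError(
                f"expected 3-{len(header)} columns, got {len(row)}", line=lineno
            )
        eid = row[0].strip()
        if not eid:
            raise ParseError("empty entry id", line=lineno)
        parents = []
        for raw in row[1:3]:
            raw = raw.strip()
            parents.append(None if raw in unknown else raw)
        entry = PedigreeEntry(id=eid, parent1=parents[0], parent2=parents[1])
        for name, raw in zip(attr_names, row[3:]):
            raw = raw.strip()
            key = name.lower()
            if key in _YEAR_COLUMNS:
                entry.year = int(float(raw)) if raw not in unknown and raw else None
            elif key in _COUNTRY_COLUMNS:
                entry.country = raw if raw not in unknown and raw else None
            elif key in _LANDRACE_COLUMNS:
                entry.is_landrace = raw.lower() in _TRUTHY
            else:
                entry.extra[name] = raw
        ped.add_entry(entry, on_duplicate=on_duplicate)
    ped.resolve_parents()
    return ped


def write_pedigree(ped: Pedigree, dest, sep: str = "\t", unknown: str = "") -> None:
    """Write a pedigree back to the Helium dialect (round-trips attributes)."""
    extra_names: list[str] = []
    for e in ped.entries.values():
        for k in e.extra:
            if k not in extra_names:
                extra_names.append(k)
    header = ["entry", "parent1", "parent2", "year", "country", "landrace", *extra_names]

    def _rows():
        yield header
        for e in ped.entries.values():
            yield [
                e.id,
                e.parent1 if e.parent1 is not None else unknown,
                e.parent2 if e.parent2 is not None else unknown,
                str(e.year) if e.year is not None else unknown,
                e.country if e.country is not None else unknown,
                "1" if e.is_landrace else "0",
                *[e.extra.get(k, unknown) for k in extra_names],
            ]

    if hasattr(dest, "write"):
        w = csv.writer(dest, delimiter=sep, lineterminator="\n")
        w.writerows(_rows())
    else:
        with open(dest, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=sep, lineterminator="\n")
            w.writerows(_rows())


def pedigree_from_text(text: str, **kwargs) -> Pedigree:
    """Convenience wrapper: parse a pedigree from an in-memory string."""
    return read_pedigree(io.StringIO(text), **kwargs)


# ---------------------------------------------------------------------------
# Validation and traversal
# ---------------------------------------------------------------------------


def validate_pedigree(ped: Pedigree) -> ValidationReport:
    """Report cycles, dangling parents and duplicate definitions.

    Self-parenting shows up as a cycle of length 1.  Cycles are rejected at
    validation rather than silently broken.
    """
    report = ValidationReport(duplicates=list(ped.duplicates))
    for e in ped.entries.values():
        for pid in e.known_parents():
            if pid not in ped.entries and pid not in report.dangling_parents:
                report.dangling_parents.append(pid)
    g = ped.graph
    if not nx.is_directed_acyclic_graph(g):
        report.cycles = [list(c) for c in nx.simple_cycles(g)]
    return report


def ancestors(ped: Pedigree, id: str) -> set[str]:
    """All entries reachable from ``id`` via parent links (excluding ``id``)."""
    ped.entry(id)
    return set(nx.ancestors(ped.graph, id))


def descendants(ped: Pedigree, id: str) -> set[str]:
    """All entries reachable from ``id`` via child links (excluding ``id``)."""
    ped.entry(id)
    return set(nx.descendants(ped.graph, id))


# ---------------------------------------------------------------------------
# Selfing augmentation
# ---------------------------------------------------------------------------


def augment_selfing(ped: Pedigree, generations: int = 7) -> Pedigree:
    """Insert intermediate selfing generations below every cross.

    For each entry with at least one known parent, ``generations``
    intermediate entries are inserted: the F1 (child of the recorded parents),
    then a self-fertilisation chain in which each entry has the previous one
    as both parents.  The named entry keeps its id and becomes the final
    selfing generation, so external references stay valid.  Inserted ids are
    ``<id>__S<k>`` for k = 1..generations.

    With the default seven generations this models the near-complete
    inbreeding of variety development: the named line's expected self-kinship
    becomes 1 - 2**-(generations+1).
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    out = Pedigree()
    for e in ped.entries.values():
        if generations == 0 or e.is_founder:
            out.add_entry(
                PedigreeEntry(
                    e.id, e.parent1, e.parent2, e.year, e.country, e.is_landrace,
                    dict(e.extra),
                )
            )
            continue
        prev: tuple[str | None, str | None] = (e.parent1, e.parent2)
        for k in range(1, generations + 1):
            sid = f"{e.id}__S{k}"
            out.add_entry(PedigreeEntry(sid, prev[0], prev[1]))
            prev = (sid, sid)
        out.add_entry(
            PedigreeEntry(
                e.id, prev[0], prev[1], e.year, e.country, e.is_landrace, dict(e.extra)
            )
        )
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    """Pedigree-level descriptive statistics.

    ``not_computable`` lists statistics that required a missing attribute
    (e.g. country percentages on a pedigree with no country data).
    """

    n_entries: int
    n_founders: int
    per_country: dict[str, int]
    offspring_count: dict[str, int]
    n_released_before: int | None
    year_threshold: int
    pct_cross_country_by_decade: dict[int, float]
    not_computable: list[str] = field(default_factory=list)


def pedigree_summary(ped: Pedigree, year_threshold: int = 1900) -> SummaryStats:
    """Entry/founder counts, country tallies, offspring counts and the
    per-decade percentage of parent-child pairs whose countries differ."""
    per_country: dict[str, int] = {}
    for e in ped.entries.values():
        if e.country is not None:
            per_country[e.country] = per_country.get(e.country, 0) + 1

    offspring = {i: 0 for i in ped.entries}
    for e in ped.entries.values():
        for pid in e.known_parents():
            if pid in offspring:
                offspring[pid] += 1

    not_computable = []
    years = [e.year for e in ped.entries.values() if e.year is not None]
    if years:
        n_before = sum(1 for y in years if y < year_threshold)
    else:
        n_before = None
        not_computable.append("n_released_before")

    # per decade: fraction of (parent, child) pairs with differing country,
    # decade taken from the child's year of release
    by_decade: dict[int, list[int]] = {}
    usable = False
    for e in ped.entries.values():
        if e.year is None or e.country is None:
            continue
        for pid in e.known_parents():
            parent = ped.entries.get(pid)
            if parent is None or parent.country is None:
                continue
            usable = True
            decade = (e.year // 10) * 10
            by_decade.setdefault(decade, []).append(
                1 if parent.country != e.country else 0
            )
    pct = {d: 100.0 * sum(v) / len(v) for d, v in sorted(by_decade.items())}
    if not usable:
        not_computable.append("pct_cross_country_by_decade")
    if not per_country:
        not_computable.append("per_country")

    return SummaryStats(
        n_entries=len(ped),
        n_founders=len(ped.founders()),
        per_country=per_country,
        offspring_count=offspring,
        n_released_before=n_before,
        year_threshold=year_threshold,
        pct_cross_country_by_decade=pct,
        not_computable=not_computable,
    )
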