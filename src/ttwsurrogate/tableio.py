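"""Reading and writing the delimited text table formats.

Three table kinds are supported, all plain delimited text:

* edge tables — three columns (origin code, destination code, commuters);
* population tables — two columns (zone code, worker count);
* correspondence tables — two columns (fine code, coarse code).

Zone codes are always read as opaque strings.  The default dialect is
comma-delimited with a header row; a headerless variant is selectable.
Parsing is strict: malformed rows and duplicate keys raise errors that name
the offending line, because silent repair of census inputs is exactly the
failure mode this package exists to avoid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

from .geography import ZoneHierarchy
from .network import CommuterNetwork

PathLike = Union[str, Path]


@dataclass(frozen=True)
class TableDialect:
    """Delimiter and header conventions for the text tables."""

    delimiter: str = ","
    header: bool = True


DEFAULT_DIALECT = TableDialect()


class TableFormatError(ValueError):
    """A table row could not be parsed; the message carries the line number."""


def _rows(path: PathLike, dialect: TableDialect, n_cols: int):
    """Yield (line_number, row) after optional header skip, checking arity."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if dialect.header and lineno == 1:
                continue
            if len(row) != n_cols:
                raise TableFormatError(
                    f"{path}: line {lineno}: expected {n_cols} columns, got {len(row)}"
                )
            yield lineno, [cell.strip() for cell in row]


def _parse_int(cell: str, path: PathLike, lineno: int, what: str, minimum: int) -> int:
    try:
        value = int(cell)
    except ValueError:
        raise TableFormatError(
            f"{path}: line {lineno}: {what} {cell!r} is not an integer"
        ) from None
    if value < minimum:
        raise TableFormatError(f"{path}: line {lineno}: {what} {value} < {minimum}")
    return value


# -- edge tables -----------------------------------------------------------

def read_edge_table(
    path: PathLike,
    origin_level: str,
    dest_level: str,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> CommuterNetwork:
    """Read a 3-column (origin, destination, commuters) table."""
    edges: Dict[Tuple[str, str], int] = {}
    for lineno, (o, d, w) in _rows(path, dialect, 3):
        key = (o, d)
        if key in edges:
            raise TableFormatError(f"{path}: line {lineno}: duplicate edge {key}")
        edges[key] = _parse_int(w, path, lineno, "weight", minimum=1)
    return CommuterNetwork(origin_level, dest_level, edges)


def write_edge_table(
    net: CommuterNetwork, path: PathLike, dialect: TableDialect = DEFAULT_DIALECT
) -> None:
    """Write a network in canonical (lexicographic) edge order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        if dialect.header:
            writer.writerow(["origin", "destination", "commuters"])
        for (o, d), w in net.sorted_edges():
            writer.writerow([o, d, w])


# -- population tables -----------------------------------------------------

def read_population_table(
    path: PathLike, dialect: TableDialect = DEFAULT_DIALECT
) -> Dict[str, int]:
    """Read a 2-column (zone, worker count) table; counts may be zero."""
    pops: Dict[str, int] = {}
    for lineno, (zone, count) in _rows(path, dialect, 2):
        if zone in pops:
            raise TableFormatError(f"{path}: line {lineno}: duplicate zone {zone!r}")
        pops[zone] = _parse_int(count, path, lineno, "count", minimum=0)
    return pops


def write_population_table(
    populations: Mapping[str, int],
    path: PathLike,
    dialect: TableDialect = DEFAULT_DIALECT,
    columns: Sequence[str] = ("zone", "workers"),
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        if dialect.header:
            writer.writerow(list(columns))
        for zone in sorted(populations):
            writer.writerow([zone, int(populations[zone])])


# -- correspondence tables -------------------------------------------------

def read_correspondence(
    path: PathLike, dialect: TableDialect = DEFAULT_DIALECT
) -> Dict[str, str]:
    """Read a 2-column (fine code, coarse code) correspondence."""
    parent: Dict[str, str] = {}
    for lineno, (fine, coarse) in _rows(path, dialect, 2):
        if fine in parent:
            raise TableFormatError(
                f"{path}: line {lineno}: fine zone {fine!r} mapped twice"
            )
        parent[fine] = coarse
    return parent


def write_correspondence(
    parent: Mapping[str, str], path: PathLike, dialect: TableDialect = DEFAULT_DIALECT
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        if dialect.header:
            writer.writerow(["fine", "coarse"])
        for fine in sorted(parent):
            writer.writerow([fine, parent[fine]])


def load_hierarchy(
    origin_path: PathLike,
    dest_path: PathLike,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> ZoneHierarchy:
    """Build a :class:`ZoneHierarchy` from the two correspondence files."""
    return ZoneHierarchy(
        origin_parent=read_correspondence(origin_path, dialect),
        dest_parent=read_correspondence(dest_path, dialect),
    )


# -- non-geographic zone filter --------------------------------------------

@dataclass
class RemovalReport:
    """What :func:`filter_non_geographic` removed."""

    edges_removed: int
    commuters_removed: int
    zones_hit: Tuple[str, ...]


def filter_non_geographic(
    net: CommuterNetwork,
    codes: Iterable[str] = (),
    prefixes: Iterable[str] = (),
) -> Tuple[CommuterNetwork, RemovalReport]:
    """Drop every edge touching a flagged zone on either side.

    Census releases attach special codes to non-geographic categories such as
    "Migratory/offshore/shipping" and "No usual address"; these must be
    stripped before reconstruction.  Code values drift between censuses, so
    they are supplied by the caller (literal codes and/or code prefixes)
    rather than hard-coded.
    """
    code_set = frozenset(codes)
    prefix_tuple = tuple(prefixes)

    def flagged(zone: str) -> bool:
        return zone in code_set or (bool(prefix_tuple) and zone.startswith(prefix_tuple))

    kept: Dict[Tuple[str, str], int] = {}
    removed_edges = 0
    removed_commuters = 0
    zones_hit = set()
    for (o, d), w in net.edges.items():
        hit = False
        if flagged(o):
            zones_hit.add(o)
            hit = True
        if flagged(d):
            zones_hit.add(d)
            hit = True
        if hit:
            removed_edges += 1
            removed_commuters += w
        else:
            kept[(o, d)] = w
    filtered = CommuterNetwork(net.origin_level, net.dest_level, kept)
    report = RemovalReport(removed_edges, removed_commuters, tuple(sorted(zones_hit)))
    return filtered, report
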