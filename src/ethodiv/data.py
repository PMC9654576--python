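"""Ethograms, observation records and count vectors.

Every diversity index in :mod:`ethodiv.indices` consumes a
:class:`CountVector`: the per-behavior tally of observations for one
analysis unit (an animal, a session, a condition).  This module defines
that container plus the raw-record form produced by instantaneous/scan
sampling, and the aggregation that turns one into the other.

Out-of-sight scans are a sampling-effort confound, not a behavior: by
default they are excluded from the tally but retained as metadata so that
effort-sensitive indices can be audited.  An alternative policy keeps them
as a pseudo-category for sensitivity analyses.
"""

from __future__ import annotations

import csv
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "Ethogram",
    "ObservationRecord",
    "CountVector",
    "OUT_OF_SIGHT_LABEL",
    "aggregate_records",
    "validate_against_ethogram",
    "read_records_csv",
    "read_counts_csv",
    "read_repertoire",
]

#: Pseudo-category label used when out-of-sight scans are retained.
OUT_OF_SIGHT_LABEL = "out_of_sight"

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


@dataclass(frozen=True)
class Ethogram:
    """A catalogue of behavior categories for one species or study.

    Parameters
    ----------
    categories
        Ordered behavior-category labels; unique, non-empty strings.
    expected_categories
        Optional full wild-type repertoire, required only by the
        Behavioral Variety Index.
    """

    categories: tuple[str, ...]
    expected_categories: frozenset[str] | None = None

    def __init__(
        self,
        categories: Iterable[str],
        expected_categories: Iterable[str] | None = None,
    ) -> None:
        cats = tuple(categories)
        if not cats:
            raise ValueError("an ethogram needs at least one behavior category")
        seen: set[str] = set()
        for c in cats:
            if not isinstance(c, str) or not c.strip():
                raise ValueError(f"behavior labels must be non-empty strings, got {c!r}")
            if c in seen:
                raise ValueError(f"duplicate behavior label {c!r}")
            seen.add(c)
        exp = None if expected_categories is None else frozenset(expected_categories)
        if exp is not None and not exp:
            raise ValueError("expected_categories, when given, must be non-empty")
        object.__setattr__(self, "categories", cats)
        object.__setattr__(self, "expected_categories", exp)

    def __contains__(self, label: str) -> bool:
        return label in set(self.categories)


@dataclass(frozen=True)
class ObservationRecord:
    """One sampled scan: either a behavior was coded or the animal was out of sight."""

    subject: str
    session: str
    behavior: str | None
    out_of_sight: bool = False

    def __post_init__(self) -> None:
        has_behavior = isinstance(self.behavior, str) and bool(self.behavior.strip())
        if has_behavior == self.out_of_sight:
            raise ValueError(
                "exactly one of a behavior label or out_of_sight=True is "
                f"required per record (subject={self.subject!r}, "
                f"session={self.session!r})"
            )


class CountVector:
    """Per-behavior observation counts for one analysis unit.

    Derived summary statistics:

    - ``N``  total observations, :math:`\\sum_i n_i`
    - ``S``  observed richness, number of categories with :math:`n_i > 0`
    - ``F1`` singletons, categories observed exactly once
    - ``F2`` doubletons, categories observed exactly twice

    Zero-count categories may be present (e.g. ethogram categories never
    observed); they contribute to none of the summaries.
    """

    __slots__ = ("_counts", "out_of_sight_count")

    def __init__(
        self,
        counts: Mapping[str, int] | Iterable[tuple[str, int]] = (),
        out_of_sight_count: int = 0,
    ) -> None:
        items = counts.items() if isinstance(counts, Mapping) else counts
        store: dict[str, int] = {}
        for label, n in items:
            if not isinstance(label, str) or not label:
                raise ValueError(f"behavior labels must be non-empty strings, got {label!r}")
            if isinstance(n, bool) or not isinstance(n, (int,)):
                raise TypeError(f"count for {label!r} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"count for {label!r} is negative: {n}")
            store[label] = store.get(label, 0) + n
        if out_of_sight_count < 0:
            raise ValueError("out_of_sight_count must be non-negative")
        self._counts = store
        self.out_of_sight_count = int(out_of_sight_count)

    # -- mapping-ish surface -------------------------------------------------
    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def __getitem__(self, label: str) -> int:
        return self._counts.get(label, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def items(self):
        return self._counts.items()

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountVector):
            return NotImplemented
        return (
            self.observed_counts() == other.observed_counts()
            and self.out_of_sight_count == other.out_of_sight_count
        )

    def __repr__(self) -> str:
        oos = f", out_of_sight_count={self.out_of_sight_count}" if self.out_of_sight_count else ""
        return f"CountVector({self._counts!r}{oos})"

    def __add__(self, other: "CountVector") -> "CountVector":
        merged = Counter(self._counts)
        merged.update(other._counts)
        return CountVector(dict(merged), self.out_of_sight_count + other.out_of_sight_count)

    # -- derived summaries ---------------------------------------------------
    @property
    def N(self) -> int:
        return sum(self._counts.values())

    @property
    def S(self) -> int:
        return sum(1 for n in self._counts.values() if n > 0)

    @property
    def F1(self) -> int:
        return sum(1 for n in self._counts.values() if n == 1)

    @property
    def F2(self) -> int:
        return sum(1 for n in self._counts.values() if n == 2)

    def observed_counts(self) -> dict[str, int]:
        """Counts restricted to categories actually observed (n_i > 0)."""
        return {k: v for k, v in self._counts.items() if v > 0}

    def observed_categories(self) -> set[str]:
        return {k for k, v in self._counts.items() if v > 0}

    def proportions(self) -> dict[str, float]:
        """p_i = n_i / N over observed categories; sums to 1 when N > 0."""
        n_total = self.N
        if n_total == 0:
            return {}
        return {k: v / n_total for k, v in self._counts.items() if v > 0}

    def summary(self) -> tuple[int, int, int, int]:
        """(S, N, F1, F2) snapshot used for index auditability."""
        return (self.S, self.N, self.F1, self.F2)


def as_count_vector(counts) -> CountVector:
    """Coerce a mapping of integer counts (or a CountVector) to a CountVector."""
    if isinstance(counts, CountVector):
        return counts
    if isinstance(counts, Mapping):
        return CountVector(counts)
    raise TypeError(f"expected a CountVector or mapping of counts, got {type(counts).__name__}")


def aggregate_records(
    records: Sequence[ObservationRecord],
    group_by: Sequence[str] = (),
    out_of_sight_policy: str = "exclude",
) -> dict[tuple[str, ...], CountVector]:
    """Tally raw scan records into one :class:`CountVector` per group.

    Parameters
    ----------
    records
        Non-empty sequence of observation records.
    group_by
        Subset of ``{"subject", "session"}``; empty groups everything into
        a single unit keyed by the empty tuple.
    out_of_sight_policy
        ``"exclude"`` (default) drops out-of-sight scans from the counts,
        keeping their number on ``CountVector.out_of_sight_count``;
        ``"category"`` tallies them under :data:`OUT_OF_SIGHT_LABEL`.
    """
    if not records:
        raise ValueError("cannot aggregate an empty record set")
    keys = tuple(group_by)
    allowed = {"subject", "session"}
    if not set(keys) <= allowed:
        raise ValueError(f"group_by must be a subset of {sorted(allowed)}, got {keys}")
    if out_of_sight_policy not in {"exclude", "category"}:
        raise ValueError(f"unknown out_of_sight_policy {out_of_sight_policy!r}")

    tallies: dict[tuple[str, ...], Counter] = {}
    oos: dict[tuple[str, ...], int] = {}
    for rec in records:
        key = tuple(getattr(rec, k) for k in keys)
        bucket = tallies.setdefault(key, Counter())
        oos.setdefault(key, 0)
        if rec.out_of_sight:
            if out_of_sight_policy == "category":
                bucket[OUT_OF_SIGHT_LABEL] += 1
            else:
                oos[key] += 1
        else:
            bucket[rec.behavior] += 1
    return {key: CountVector(dict(tallies[key]), oos[key]) for key in tallies}


def validate_against_ethogram(cv: CountVector, eth: Ethogram) -> list[str]:
    """Labels present in ``cv`` but absent from the ethogram (empty = consistent)."""
    known = set(eth.categories)
    return sorted(label for label in cv if label not in known)


# ---------------------------------------------------------------------------
# File formats: plain UTF-8 CSV with a header row, RFC-4180 quoting.
# ---------------------------------------------------------------------------

def _parse_bool(raw: str, line_no: int) -> bool:
    v = raw.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"line {line_no}: out_of_sight value {raw!r} is not boolean")


def read_records_csv(path: str | Path) -> list[ObservationRecord]:
    """Read a records CSV with columns ``subject,session,behavior,out_of_sight``.

    ``out_of_sight`` accepts 0/1/true/false and defaults to 0 when the
    column is absent.  Malformed rows are rejected with their line number.
    """
    path = Path(path)
    records: list[ObservationRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        required = {"subject", "session", "behavior"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for row in reader:
            line_no = reader.line_num
            oos = _parse_bool(row.get("out_of_sight") or "0", line_no)
            behavior = (row.get("behavior") or "").strip() or None
            try:
                records.append(
                    ObservationRecord(
                        subject=(row.get("subject") or "").strip(),
                        session=(row.get("session") or "").strip(),
                        behavior=behavior,
                        out_of_sight=oos,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from None
    if not records:
        raise ValueError(f"{path}: no data rows")
    return records


def read_counts_csv(path: str | Path) -> dict[str, CountVector]:
    """Read a counts CSV, returning one CountVector per analysis unit.

    Two layouts are accepted: ``behavior,count`` (single unit, keyed "all")
    and ``unit,behavior,count`` (long form, many units).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        cols = set(reader.fieldnames)
        if {"behavior", "count"} - cols:
            raise ValueError(
                f"{path}: expected columns behavior,count (optionally unit), got {reader.fieldnames}"
            )
        long_form = "unit" in cols
        units: dict[str, list[tuple[str, int]]] = {}
        for row in reader:
            line_no = reader.line_num
            unit = (row.get("unit") or "").strip() if long_form else "all"
            behavior = (row.get("behavior") or "").strip()
            raw = (row.get("count") or "").strip()
            if not behavior:
                raise ValueError(f"{path}: line {line_no}: empty behavior label")
            try:
                n = int(raw)
            except ValueError:
                raise ValueError(f"{path}: line {line_no}: count {raw!r} is not an integer") from None
            if n < 0:
                raise ValueError(f"{path}: line {line_no}: negative count {n}")
            units.setdefault(unit or "all", []).append((behavior, n))
    if not units:
        raise ValueError(f"{path}: no data rows")
    return {unit: CountVector(pairs) for unit, pairs in units.items()}


def read_repertoire(path: str | Path) -> list[str]:
    """Read an expected-repertoire file: one label per line, ``#`` comments allowed."""
    path = Path(path)
    labels: list[str] = []
    seen: set[str] = set()
    for raw in path.read_text(encoding="utf-8").splitlines():
        label = raw.split("#", 1)[0].strip()
        if label and label not in seen:
            labels.append(label)
            seen.add(label)
    if not labels:
        raise ValueError(f"{path}: expected repertoire is empty")
    return labels
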