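"""Canonical pair-set algebra: subtraction, merging and summaries.

Every dataset row in the pipeline reduces to an unordered pair of
accessions stored in a deterministic lexicographic order, so set
membership ignores orientation.  Candidate non-interacting sets are
filtered by subtracting known-interaction sets (MITAB protein pairs,
two-column domain-pair lists) and merged with overlap accounting.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .errors import DatasetFormatError, MitabFormatError, UndefinedFractionError

if TYPE_CHECKING:  # pragma: no cover
    from .annotate import NIPRecord

__all__ = [
    "CanonicalPair",
    "InteractionSet",
    "DatasetSummary",
    "read_mitab",
    "read_domain_pairs",
    "subtract",
    "merge",
    "removal_fraction",
    "write_dataset",
    "read_dataset",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class CanonicalPair:
    """An unordered accession pair stored with ``first <= second``."""

    first: str
    second: str

    def __init__(self, first: str, second: str) -> None:
        if not first or not second:
            raise ValueError("pair members must be non-empty")
        if first > second:
            first, second = second, first
        object.__setattr__(self, "first", first)
        object.__setattr__(self, "second", second)

    def __iter__(self):
        return iter((self.first, self.second))

    def __str__(self) -> str:
        return f"{self.first}--{self.second}"


@dataclass
class InteractionSet:
    """A deduplicated set of known interacting pairs with provenance."""

    pairs: set[CanonicalPair] = field(default_factory=set)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: CanonicalPair) -> bool:
        return pair in self.pairs


@dataclass(frozen=True)
class DatasetSummary:
    """Before/after accounting for one filtering lineage step."""

    name: str
    n_before: int
    n_after: int
    removed_fraction_pct: int


def collapse_isoform(accession: str) -> str:
    """Strip an isoform suffix: ``P12345-2`` -> ``P12345``."""
    return accession.split("-", 1)[0]


def _uniprot_token(column: str) -> str | None:
    """First uniprotkb accession in a |-separated MITAB identifier column."""
    for token in column.split("|"):
        token = token.strip()
        if token.lower().startswith("uniprotkb:"):
            acc = token.split(":", 1)[1]
            # strip trailing free-text qualifiers some dialects append
            acc = acc.split("(")[0].strip().strip('"')
            if acc:
                return acc
    return None


def read_mitab(
    path: str | os.PathLike,
    strict: bool = False,
    collapse_isoforms: bool = False,
) -> InteractionSet:
    """Parse interactor columns 1-2 of a PSI-MI TAB (MITAB 2.5) file.

    Rows whose interactors carry no ``uniprotkb:`` token are skipped and
    counted (lenient default) or rejected with the line number (strict).
    """
    pairs: set[CanonicalPair] = set()
    n_skipped = 0
    with open(path, newline="", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                if strict:
                    raise MitabFormatError(f"{path}:{lineno}: fewer than 2 columns")
                n_skipped += 1
                continue
            a = _uniprot_token(cols[0])
            b = _uniprot_token(cols[1])
            if a is None or b is None:
                if strict:
                    raise MitabFormatError(
                        f"{path}:{lineno}: interactor without uniprotkb accession"
                    )
                n_skipped += 1
                continue
            if collapse_isoforms:
                a, b = collapse_isoform(a), collapse_isoform(b)
            pairs.add(CanonicalPair(a, b))
    if n_skipped:
        logger.info("read_mitab(%s): skipped %d rows without uniprotkb "
                    "interactors", path, n_skipped)
    return InteractionSet(pairs=pairs, provenance=f"{os.fspath(path)} [mitab]")


def read_domain_pairs(path: str | os.PathLike) -> InteractionSet:
    """Read a two-column TSV of interacting domain pairs (3DID/iPFAM exports)."""
    pairs: set[CanonicalPair] = set()
    with open(path, newline="", encoding="utf-8") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise DatasetFormatError(f"{path}:{lineno}: expected 2 columns")
            pairs.add(CanonicalPair(row[0].strip(), row[1].strip()))
    return InteractionSet(pairs=pairs, provenance=f"{os.fspath(path)} [tsv2]")


def subtract(
    candidates: Iterable[CanonicalPair], known: InteractionSet | set[CanonicalPair]
) -> set[CanonicalPair]:
    """Remove candidates reported as interacting; inputs are unmodified.

    Equality is order-insensitive by construction of :class:`CanonicalPair`.
    """
    known_pairs = known.pairs if isinstance(known, InteractionSet) else known
    return {p for p in candidates if p not in known_pairs}


def merge(
    a: Iterable[CanonicalPair], b: Iterable[CanonicalPair]
) -> tuple[set[CanonicalPair], int]:
    """Union two pair sets; returns ``(union, overlap_count)``."""
    sa, sb = set(a), set(b)
    return sa | sb, len(sa & sb)


def removal_fraction(n_before: int, n_after: int) -> int:
    """Percent of pairs removed, rounded half away from zero to an integer."""
    if n_before == 0:
        raise UndefinedFractionError("removal fraction undefined for empty set")
    if not n_before >= n_after >= 0:
        raise ValueError(f"need n_before >= n_after >= 0, got {n_before}, {n_after}")
    removed = n_before - n_after
    # integer round-half-up of 100*removed/n_before (both non-negative)
    return (200 * removed + n_before) // (2 * n_before)


_DATASET_COLUMNS = [
    "accession_a",
    "accession_b",
    "source",
    "structures",
    "min_distance",
    "method",
]


def write_dataset(
    records: "Sequence[NIPRecord]", path: str | os.PathLike
) -> None:
    """Write NIP records as a TSV, rows sorted by canonical pair.

    Columns: the two accessions in canonical order, the evidence source
    (``structure`` or ``manual``), semicolon-joined ``structure:assembly``
    ids, the smallest supporting minimum distance (empty for curated
    records) and the curation method terms held as opaque strings.
    """
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_DATASET_COLUMNS)
        for rec in sorted(records, key=lambda r: r.pair):
            structures = ";".join(
                f"{sid}:{aid}" for sid, aid, _ in rec.structure_evidence
            )
            distances = [d for _, _, d in rec.structure_evidence]
            writer.writerow(
                [
                    rec.pair.first,
                    rec.pair.second,
                    rec.source,
                    structures,
                    f"{min(distances):.3f}" if distances else "",
                    rec.method,
                ]
            )


def read_dataset(path: str | os.PathLike) -> "list[NIPRecord]":
    """Read a dataset TSV written by :func:`write_dataset`.

    Pairs are re-canonicalized on read, so hand-edited files with swapped
    accession columns normalize transparently.
    """
    from .annotate import NIPRecord

    records: list[NIPRecord] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetFormatError(f"{path}: empty file, header required")
        if header[:2] != _DATASET_COLUMNS[:2]:
            raise DatasetFormatError(
                f"{path}:1: unexpected header {header[:2]!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < len(_DATASET_COLUMNS):
                raise DatasetFormatError(f"{path}:{lineno}: expected "
                                         f"{len(_DATASET_COLUMNS)} columns")
            acc_a, acc_b, source, structures, min_d, method = row[:6]
            evidence: list[tuple[str, str, float]] = []
            if structures:
                dist = float(min_d) if min_d else float("nan")
                for token in structures.split(";"):
                    sid, _, aid = token.partition(":")
                    evidence.append((sid, aid, dist))
            records.append(
                NIPRecord(
                    pair=CanonicalPair(acc_a, acc_b),
                    source=source,
                    structure_evidence=evidence,
                    method=method,
                )
            )
    return records


def read_pair_tsv(path: str | os.PathLike) -> set[CanonicalPair]:
    """Read just the canonical pairs from a dataset or two-column TSV."""
    pairs: set[CanonicalPair] = set()
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[:2] == _DATASET_COLUMNS[:2]:
                continue  # dataset header
            if len(row) < 2:
                raise DatasetFormatError(f"{path}:{lineno}: expected 2 columns")
            pairs.add(CanonicalPair(row[0].strip(), row[1].strip()))
    return pairs


def write_pair_tsv(pairs: Iterable[CanonicalPair], path: str | os.PathLike) -> None:
    """Write canonical pairs as a sorted two-column TSV."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for pair in sorted(set(pairs)):
            writer.writerow([pair.first, pair.second])


def summarize(
    lineages: Mapping[str, tuple[int, int]] | Mapping[str, tuple[Iterable, Iterable]]
) -> list[DatasetSummary]:
    """Build before/after summary rows for named filtering lineages.

    ``lineages`` maps a dataset name to ``(before, after)`` where each side
    is either a count or a collection.  An empty starting set is reported
    as 0% removed with a warning rather than an error, so summary tables
    stay printable for degenerate inputs.
    """
    rows: list[DatasetSummary] = []
    for name, (before, after) in lineages.items():
        n_before = before if isinstance(before, int) else len(tuple(before))
        n_after = after if isinstance(after, int) else len(tuple(after))
        if n_before == 0:
            logger.warning("summarize: dataset %r is empty; fraction set to 0", name)
            pct = 0
        else:
            pct = removal_fraction(n_before, n_after)
        rows.append(DatasetSummary(name, n_before, n_after, pct))
    return rows
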