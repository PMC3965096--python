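"""Chain-to-protein mapping, protein-level consolidation, domain expansion.

Chain-pair contact results are lifted to protein accessions via a
SIFTS-style mapping table.  Within one biological unit a protein pair is
non-interacting only if *every* chain-copy pair realizing it is distant;
across units, a single observed contact anywhere suppresses the pair
globally — one contact falsifies non-interaction.  Protein pairs are then
expanded to the full cross product of their PFAM domains.
"""

from __future__ import annotations

import csv
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .contact_core import DEFAULT_THRESHOLD, ChainPairResult
from .errors import DatasetFormatError, MappingIntegrityError
from .filter_merge import CanonicalPair, collapse_isoform
from .structure_io import BioUnit

__all__ = [
    "ChainMapping",
    "DomainMapping",
    "NIPRecord",
    "load_chain_mapping",
    "load_domain_mapping",
    "consolidate_protein_pairs",
    "expand_domain_pairs",
]

logger = logging.getLogger(__name__)

PFAM_RE = re.compile(r"^PF\d{5}$")

#: (structure_id, chain_id) -> protein accession
ChainMapping = dict[tuple[str, str], str]
#: protein accession -> ordered PFAM accession list
DomainMapping = dict[str, list[str]]


@dataclass(frozen=True)
class NIPRecord:
    """A candidate non-interacting protein pair with its evidence.

    ``structure_evidence`` lists every supporting
    ``(structure_id, assembly_id, min_distance)``; curated records carry
    an empty list and their method terms (opaque HUPO-PSI strings) in
    ``method``.
    """

    pair: CanonicalPair
    source: str = "structure"  # "structure" | "manual"
    structure_evidence: tuple[tuple[str, str, float], ...] = ()
    method: str = ""

    def __init__(
        self,
        pair: CanonicalPair,
        source: str = "structure",
        structure_evidence: Iterable[tuple[str, str, float]] = (),
        method: str = "",
    ) -> None:
        if pair.first == pair.second:
            raise ValueError(f"self-pair not allowed: {pair}")
        if source not in ("structure", "manual"):
            raise ValueError(f"unknown source {source!r}")
        object.__setattr__(self, "pair", pair)
        object.__setattr__(self, "source", source)
        object.__setattr__(self, "structure_evidence", tuple(structure_evidence))
        object.__setattr__(self, "method", method)
        if source == "structure" and not self.structure_evidence:
            raise ValueError("structure-derived record requires evidence")


def load_chain_mapping(path: str | os.PathLike) -> ChainMapping:
    """Load a SIFTS-style TSV mapping (structure_id, chain_id) -> accession.

    Requires a header with columns structure_id, chain_id, accession.
    Duplicate keys are tolerated only when they agree; a conflicting
    duplicate raises :class:`MappingIntegrityError` naming the key.
    """
    mapping: ChainMapping = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"structure_id", "chain_id", "accession"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise DatasetFormatError(
                f"{path}: header must contain {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            key = (row["structure_id"].strip().lower(), row["chain_id"].strip())
            acc = row["accession"].strip()
            if not acc:
                raise DatasetFormatError(f"{path}:{lineno}: empty accession")
            if key in mapping and mapping[key] != acc:
                raise MappingIntegrityError(
                    f"{path}: conflicting accessions for {key}: "
                    f"{mapping[key]} vs {acc}"
                )
            mapping[key] = acc
    return mapping


def load_domain_mapping(path: str | os.PathLike) -> DomainMapping:
    """Load a TSV of (accession, PFAM id) rows into ordered domain lists.

    Repeated rows per accession are allowed; duplicates are dropped while
    preserving first-seen order.  PFAM ids must match ``PF`` + 5 digits.
    """
    mapping: DomainMapping = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0] == "accession":
                continue
            if len(row) < 2:
                raise DatasetFormatError(f"{path}:{lineno}: expected 2 columns")
            acc, pfam = row[0].strip(), row[1].strip()
            if not PFAM_RE.match(pfam):
                raise DatasetFormatError(
                    f"{path}:{lineno}: {pfam!r} is not a PFAM accession"
                )
            domains = mapping.setdefault(acc, [])
            if pfam not in domains:
                domains.append(pfam)
    return mapping


def consolidate_protein_pairs(
    unit_results: Iterable[tuple[BioUnit, Sequence[ChainPairResult]]],
    mapping: ChainMapping,
    threshold: float = DEFAULT_THRESHOLD,
    collapse_isoforms: bool = False,
) -> list[NIPRecord]:
    """Lift chain-pair results to protein-level NIP records.

    Per unit, a protein pair is non-interacting iff all chain-copy pairs
    realizing it have ``min_distance > threshold``; the closest of those
    distances is recorded as the unit's evidence.  A pair observed in
    direct contact in *any* unit is suppressed globally.  Self pairs
    (homomer contacts between copies of one accession) are excluded.
    Chains absent from the mapping are dropped with a logged count.
    """
    noninteracting: dict[CanonicalPair, list[tuple[str, str, float]]] = {}
    contacted: set[CanonicalPair] = set()
    n_unmapped = 0

    for unit, results in unit_results:
        per_pair_min: dict[CanonicalPair, float] = {}
        per_pair_ok: dict[CanonicalPair, bool] = {}
        for res in results:
            acc_a = mapping.get((unit.structure_id, res.chain_a[0]))
            acc_b = mapping.get((unit.structure_id, res.chain_b[0]))
            if acc_a is None or acc_b is None:
                n_unmapped += 1
                continue
            if collapse_isoforms:
                acc_a, acc_b = collapse_isoform(acc_a), collapse_isoform(acc_b)
            if acc_a == acc_b:
                continue
            pair = CanonicalPair(acc_a, acc_b)
            per_pair_min[pair] = min(
                per_pair_min.get(pair, float("inf")), res.min_distance
            )
            per_pair_ok[pair] = (
                per_pair_ok.get(pair, True) and res.min_distance > threshold
            )
        for pair, ok in per_pair_ok.items():
            if ok:
                noninteracting.setdefault(pair, []).append(
                    (unit.structure_id, unit.assembly_id, per_pair_min[pair])
                )
            else:
                contacted.add(pair)

    if n_unmapped:
        logger.info(
            "consolidate_protein_pairs: dropped %d chain-pair results with "
            "unmapped chains", n_unmapped,
        )

    records = [
        NIPRecord(pair=pair, source="structure", structure_evidence=evidence)
        for pair, evidence in noninteracting.items()
        if pair not in contacted
    ]
    records.sort(key=lambda r: r.pair)
    return records


def expand_domain_pairs(
    pairs: Iterable[CanonicalPair], domains: DomainMapping
) -> set[CanonicalPair]:
    """Expand protein pairs to all PFAM domain combinations.

    For proteins A with domains A1, A2, ... and B with B1, B2, ... the
    full cross product A1-B1, A1-B2, A2-B1, ... is emitted, canonicalized
    and deduplicated across all input pairs.  Self domain pairs (D, D) are
    kept — homodomain interactions from 3DID-style catalogues can then
    subtract them.  A protein with no annotated domains contributes
    nothing.
    """
    out: set[CanonicalPair] = set()
    for pair in pairs:
        for da in domains.get(pair.first, ()):
            for db in domains.get(pair.second, ()):
                out.add(CanonicalPair(da, db))
    return out
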