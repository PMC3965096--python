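"""Seeded synthetic-data generators for end-to-end pipeline testing.

Generates biological-unit structure files (PDB + mmCIF), SIFTS-style chain
mappings, PFAM domain mappings, MITAB known-interaction files, two-column
domain-interaction lists and PAS corpora — each with machine-readable
ground truth, so the whole derivation pipeline is testable without any
database downloads.

Geometry model: chains are compact random coils with 3.8 Å Cα spacing and
a pseudo-Cβ at 1.53 Å; only the representative-atom geometry matters, not
physical realism.  Internal coordinates are snapped to a 0.125 Å binary
lattice so that values survive the 3-decimal file format exactly.  A chain
with a single gap constraint is placed by translating it along a
coordinate axis so that the separation between the two extreme atoms along
that axis *is* the requested gap: every other cross-chain pair is then
provably at least that far apart, which realises the minimum distance
exactly (bit-exact for binary-representable gaps such as 8.0).  Chains
with several gap constraints are placed by damped iterative refinement to
within 0.05 Å.  Ground-truth classifications are always computed from the
coordinates as written to file, so they are truthful by construction even
at the contact threshold.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from .errors import FixtureInfeasibleError
from .filter_merge import CanonicalPair
from .pas_score import DEFAULT_COMMON_NEGATIONS, DEFAULT_VERB_LEXICON

__all__ = [
    "FixtureSpec",
    "BiounitFixture",
    "PipelineFixture",
    "make_biounit",
    "make_known_interactions",
    "make_pas_corpus",
    "make_pipeline_fixture",
    "exhaustive_min_distance",
]

DEFAULT_THRESHOLD = 8.0

# residue cycle includes glycine so the Calpha substitution is exercised
_AA_CYCLE = ["ALA", "GLY", "LEU", "SER", "VAL", "THR", "LYS", "ASP", "PHE",
             "ARG", "GLY", "GLU"]

_AXES = [
    np.array([1.0, 0.0, 0.0]),
    np.array([0.0, 1.0, 0.0]),
    np.array([0.0, 0.0, 1.0]),
    np.array([-1.0, 0.0, 0.0]),
    np.array([0.0, -1.0, 0.0]),
    np.array([0.0, 0.0, -1.0]),
]


def exhaustive_min_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force O(n*m) minimum cross distance; the test oracle."""
    return float(cdist(np.atleast_2d(a), np.atleast_2d(b)).min())


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic biological unit.

    ``pairwise_gaps`` maps chain-id pairs (e.g. ``("A", "C")``) to the
    target minimum representative-atom distance in Å.  A fixed seed yields
    byte-identical files.
    """

    n_chains: int = 2
    residues_per_chain: int = 20
    pairwise_gaps: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0
    structure_id: str = "s000"
    accession_prefix: str = "P"
    domains_per_protein: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if not 2 <= self.n_chains <= 26:
            raise ValueError("n_chains must be in [2, 26]")
        if self.residues_per_chain < 2:
            raise ValueError("residues_per_chain must be >= 2")
        for pair, gap in self.pairwise_gaps.items():
            if gap <= 0:
                raise ValueError(f"gap for {pair} must be positive")


@dataclass
class BiounitFixture:
    """Generated structure files plus their exhaustively computed truth."""

    pdb_path: str
    cif_path: str
    truth_path: str
    #: (chain_a, chain_b) -> achieved min representative distance (from
    #: file-precision coordinates)
    min_distances: dict[tuple[str, str], float]
    #: (chain_a, chain_b) -> non-interacting under the strict threshold
    classifications: dict[tuple[str, str], bool]
    #: chain id -> representative coordinates at file precision
    rep_coords: dict[str, np.ndarray]
    #: chain id -> number of residues written
    n_residues: dict[str, int]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _lattice(x: np.ndarray) -> np.ndarray:
    """Snap to the 0.125 Å binary lattice (exact at 3-decimal precision)."""
    return np.round(np.asarray(x, dtype=float) * 8.0) / 8.0


def _file_precision(x: np.ndarray) -> np.ndarray:
    """Coordinates exactly as a reader of the written file will see them."""
    flat = [float(f"{v:.3f}") for v in np.asarray(x, dtype=float).ravel()]
    return np.array(flat).reshape(np.shape(x))


@dataclass
class _RawChain:
    chain_id: str
    res_names: list[str]
    atoms: dict[str, np.ndarray]  # atom name -> (n_res, 3); CB rows may be NaN
    rep: np.ndarray               # (n_res, 3) representative coords


def _build_chain(chain_id: str, n_res: int, rng: np.random.Generator) -> _RawChain:
    names = [_AA_CYCLE[i % len(_AA_CYCLE)] for i in range(n_res)]
    ca = np.zeros((n_res, 3))
    for i in range(1, n_res):
        step = _unit(rng.normal(size=3)) * 3.8
        ca[i] = ca[i - 1] + step
    ca -= ca.mean(axis=0)
    n_at = ca + 1.46 * np.apply_along_axis(_unit, 1, rng.normal(size=(n_res, 3)))
    c_at = ca + 1.52 * np.apply_along_axis(_unit, 1, rng.normal(size=(n_res, 3)))
    cb = ca + 1.53 * np.apply_along_axis(_unit, 1, rng.normal(size=(n_res, 3)))
    for i, name in enumerate(names):
        if name == "GLY":
            cb[i] = np.nan
    atoms = {
        "N": _lattice(n_at),
        "CA": _lattice(ca),
        "C": _lattice(c_at),
        "CB": np.where(np.isnan(cb), np.nan, _lattice(np.nan_to_num(cb))),
    }
    rep = np.where(np.isnan(atoms["CB"]), atoms["CA"], atoms["CB"])
    return _RawChain(chain_id, names, atoms, rep)


def _axis_offset(
    placed_rep: np.ndarray, new_rep: np.ndarray, gap: float, axis: np.ndarray
) -> np.ndarray:
    """Translation placing ``new_rep`` at exactly ``gap`` from ``placed_rep``.

    The extreme atom of the placed chain along ``axis`` and the extreme
    atom of the new chain against it are separated by exactly ``gap`` along
    the axis with zero off-axis components; every other cross pair is at
    least ``gap`` apart along the axis, so the minimum is realised exactly.
    """
    ia = int(np.argmax(placed_rep @ axis))
    ib = int(np.argmin(new_rep @ axis))
    return placed_rep[ia] - new_rep[ib] + gap * axis


def _refine_offset(
    new_rep: np.ndarray,
    constraints: list[tuple[np.ndarray, float]],
    t0: np.ndarray,
    max_iter: int = 600,
) -> np.ndarray:
    """Damped Gauss-Seidel translation satisfying several gap constraints."""
    t = t0.astype(float).copy()
    for _ in range(max_iter):
        worst = 0.0
        for ref_rep, gap in constraints:
            d_mat = cdist(new_rep + t, ref_rep)
            flat = int(np.argmin(d_mat))
            qi, pi = divmod(flat, ref_rep.shape[0])
            d = float(d_mat[qi, pi])
            err = gap - d
            worst = max(worst, abs(err))
            if abs(err) > 0.003:
                u = (
                    _unit(new_rep[qi] + t - ref_rep[pi])
                    if d > 1e-9
                    else np.array([1.0, 0.0, 0.0])
                )
                t += 0.8 * err * u
        if worst <= 0.003:
            break
    return t


def make_biounit(
    spec: FixtureSpec,
    out_dir: str | os.PathLike,
    threshold: float = DEFAULT_THRESHOLD,
) -> BiounitFixture:
    """Write one synthetic biological unit as PDB and mmCIF plus ground truth.

    Every requested pairwise gap is realised within 0.1 Å (exactly, for
    chains carrying a single constraint); contradictory constraint systems
    raise :class:`FixtureInfeasibleError`.  Ground truth (minimum distances
    and strict-threshold classifications for *all* chain pairs) is computed
    by exhaustive scan over the file-precision coordinates and written as a
    TSV next to the structure files.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    chain_ids = [chr(ord("A") + i) for i in range(spec.n_chains)]
    index = {cid: i for i, cid in enumerate(chain_ids)}

    gaps: dict[tuple[int, int], float] = {}
    for (ca_id, cb_id), gap in spec.pairwise_gaps.items():
        if ca_id not in index or cb_id not in index:
            raise ValueError(f"unknown chain in gap spec: {(ca_id, cb_id)}")
        i, j = sorted((index[ca_id], index[cb_id]))
        if i == j:
            raise ValueError("gap specified for a chain with itself")
        gaps[(i, j)] = float(gap)

    chains = [
        _build_chain(cid, spec.residues_per_chain, rng) for cid in chain_ids
    ]

    default_gap = 25.0
    offsets = [np.zeros(3)]
    for j in range(1, spec.n_chains):
        axis = _AXES[(j - 1) % len(_AXES)]
        constraints = [
            (chains[i].rep + offsets[i], g)
            for (i, jj), g in sorted(gaps.items())
            if jj == j
        ]
        if not constraints:
            everything = np.vstack(
                [chains[i].rep + offsets[i] for i in range(j)]
            )
            offsets.append(
                _axis_offset(everything, chains[j].rep, default_gap, axis)
            )
        elif len(constraints) == 1:
            ref_rep, gap = constraints[0]
            offsets.append(_axis_offset(ref_rep, chains[j].rep, gap, axis))
        else:
            ref_rep, gap = constraints[0]
            t0 = _axis_offset(ref_rep, chains[j].rep, gap, axis)
            offsets.append(_refine_offset(chains[j].rep, constraints, t0))

    # shift atoms into place, then freeze at file precision
    placed_atoms: dict[str, dict[str, np.ndarray]] = {}
    rep_coords: dict[str, np.ndarray] = {}
    for chain, offset in zip(chains, offsets):
        placed = {
            name: _file_precision(coords + offset)
            for name, coords in chain.atoms.items()
        }
        placed_atoms[chain.chain_id] = placed
        rep_coords[chain.chain_id] = np.where(
            np.isnan(placed["CB"]), placed["CA"], placed["CB"]
        )

    min_distances: dict[tuple[str, str], float] = {}
    classifications: dict[tuple[str, str], bool] = {}
    for a_id, b_id in combinations(chain_ids, 2):
        d = exhaustive_min_distance(rep_coords[a_id], rep_coords[b_id])
        min_distances[(a_id, b_id)] = d
        classifications[(a_id, b_id)] = d > threshold

    for (i, j), gap in sorted(gaps.items()):
        achieved = min_distances[(chain_ids[i], chain_ids[j])]
        if abs(achieved - gap) > 0.1:
            raise FixtureInfeasibleError(
                f"{spec.structure_id}: requested gap {gap} between "
                f"{chain_ids[i]} and {chain_ids[j]} realised as "
                f"{achieved:.3f} (constraint system infeasible)"
            )

    sid = spec.structure_id
    pdb_path = os.path.join(out_dir, f"{sid}.pdb")
    cif_path = os.path.join(out_dir, f"{sid}.cif")
    truth_path = os.path.join(out_dir, f"{sid}.truth.tsv")
    _write_pdb(pdb_path, sid, chains, placed_atoms)
    _write_cif(cif_path, sid, chains, placed_atoms)
    with open(truth_path, "w", encoding="utf-8") as handle:
        handle.write("chain_a\tchain_b\tmin_distance\tnon_interacting\n")
        for (a_id, b_id), d in sorted(min_distances.items()):
            handle.write(
                f"{a_id}\t{b_id}\t{d:.6f}\t"
                f"{int(classifications[(a_id, b_id)])}\n"
            )

    return BiounitFixture(
        pdb_path=pdb_path,
        cif_path=cif_path,
        truth_path=truth_path,
        min_distances=min_distances,
        classifications=classifications,
        rep_coords=rep_coords,
        n_residues={c.chain_id: len(c.res_names) for c in chains},
    )


def _iter_atom_rows(chains, placed_atoms):
    serial = 0
    for chain in chains:
        placed = placed_atoms[chain.chain_id]
        for res_i, res_name in enumerate(chain.res_names):
            for atom_name in ("N", "CA", "C", "CB"):
                if atom_name == "CB" and res_name == "GLY":
                    continue
                serial += 1
                x, y, z = placed[atom_name][res_i]
                yield (serial, atom_name, res_name, chain.chain_id,
                       res_i + 1, x, y, z)


def _write_pdb(path, sid, chains, placed_atoms):
    lines = [
        f"HEADER    SYNTHETIC COMPLEX                       01-JAN-00   "
        f"{sid.upper():<4s}"
    ]
    serial = 0
    for chain in chains:
        placed = placed_atoms[chain.chain_id]
        last = None
        for res_i, res_name in enumerate(chain.res_names):
            for atom_name in ("N", "CA", "C", "CB"):
                if atom_name == "CB" and res_name == "GLY":
                    continue
                serial += 1
                x, y, z = placed[atom_name][res_i]
                element = atom_name[0]
                name_field = f" {atom_name:<3s}"  # cols 13-16, pad for C/N
                lines.append(
                    f"ATOM  {serial:5d} {name_field} {res_name:>3s} "
                    f"{chain.chain_id}{res_i + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {element:>2s}"
                )
            last = (res_name, res_i + 1)
        serial += 1
        lines.append(
            f"TER   {serial:5d}      {last[0]:>3s} {chain.chain_id}{last[1]:4d}"
        )
    lines.append("END")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\n".join(lines) + "\n")


_CIF_TAGS = """\
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.pdbx_PDB_model_num
"""


def _write_cif(path, sid, chains, placed_atoms):
    entity_of = {c.chain_id: i + 1 for i, c in enumerate(chains)}
    rows = []
    for (serial, atom_name, res_name, chain_id, seq, x, y, z) in _iter_atom_rows(
        chains, placed_atoms
    ):
        rows.append(
            f"ATOM {serial} {atom_name[0]} {atom_name} . {res_name} "
            f"{chain_id} {entity_of[chain_id]} {seq} {seq} {chain_id} "
            f"{x:.3f} {y:.3f} {z:.3f} 1.00 0.00 1"
        )
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"data_{sid}\n_entry.id {sid}\n{_CIF_TAGS}")
        handle.write("\n".join(rows) + "\n#\n")


def make_known_interactions(
    pairs: set[CanonicalPair],
    hit_fraction: float | None = None,
    *,
    n_hits: int | None = None,
    seed: int = 0,
    path: str | os.PathLike,
    n_decoys: int = 5,
) -> tuple[str, int, set[CanonicalPair]]:
    """Write a MITAB file whose uniprotkb pairs hit a chosen candidate subset.

    Exactly ``n_hits`` (or ``round(hit_fraction * |pairs|)``) candidate
    pairs appear among the interactions, alongside decoy pairs outside the
    candidate set and one non-protein (chebi) row that lenient parsing must
    skip.  Returns ``(path, expected_survivor_count, hit_pairs)``.
    """
    if n_hits is None:
        if hit_fraction is None:
            raise ValueError("give hit_fraction or n_hits")
        if not 0 <= hit_fraction <= 1:
            raise ValueError("hit_fraction must lie in [0, 1]")
        n_hits = round(hit_fraction * len(pairs))
    if n_hits > len(pairs):
        raise ValueError("cannot hit more pairs than exist")
    rng = np.random.default_rng(seed)
    ordered = sorted(pairs)
    hit_idx = rng.choice(len(ordered), size=n_hits, replace=False) if n_hits else []
    hits = {ordered[int(i)] for i in hit_idx}

    rows = []
    for pair in sorted(hits):
        # store one orientation reversed: parsing must canonicalize
        a, b = (pair.second, pair.first) if rng.random() < 0.5 else tuple(pair)
        rows.append(f"uniprotkb:{a}\tuniprotkb:{b}")
    for k in range(n_decoys):
        rows.append(f"uniprotkb:X{90000 + 2 * k:05d}\tuniprotkb:X{90001 + 2 * k:05d}")
    rows.append("chebi:CHEBI:15422\tuniprotkb:X99999")
    rng.shuffle(rows)

    tail = "\t-" * 13
    path = os.fspath(path)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#ID(s) interactor A\tID(s) interactor B" + tail + "\n")
        for row in rows:
            handle.write(row + tail + "\n")
    return path, len(pairs) - len(hits), hits


_FILLER = ("the", "results", "clearly", "showed", "that", "under", "these",
           "conditions", "in", "vitro", "and", "in", "vivo")
_OFF_LEXICON_VERBS = ["phosphorylate", "activate", "regulate", "inhibit"]


def make_pas_corpus(
    n: int,
    negated_fraction: float,
    seed: int = 0,
    *,
    path: str | os.PathLike,
) -> tuple[str, list[bool]]:
    """Write a JSON-lines PAS corpus with controlled filter pass labels.

    Exactly ``round(negated_fraction * n)`` records carry both a negation
    token and an in-lexicon verb (label True); the rest fail the filter by
    an off-lexicon verb or a missing negation, alternately.  Same seed,
    same bytes.
    """
    if not 0 <= negated_fraction <= 1:
        raise ValueError("negated_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pass = round(negated_fraction * n)
    passing = np.zeros(n, dtype=bool)
    if n_pass:
        passing[rng.choice(n, size=n_pass, replace=False)] = True
    lexicon = sorted(DEFAULT_VERB_LEXICON)
    negations = sorted(DEFAULT_COMMON_NEGATIONS)

    path = os.fspath(path)
    labels: list[bool] = []
    with open(path, "w", encoding="utf-8") as handle:
        for i in range(n):
            agent = f"PROT{int(rng.integers(1, 400)):03d}"
            theme = (
                agent
                if rng.random() < 0.1
                else f"PROT{int(rng.integers(1, 400)):03d}"
            )
            if passing[i]:
                relation = lexicon[int(rng.integers(len(lexicon)))]
                negation = (
                    negations[int(rng.integers(len(negations)))]
                    if rng.random() < 0.85
                    else "scarcely"
                )
            elif i % 2 == 0:
                relation = _OFF_LEXICON_VERBS[
                    int(rng.integers(len(_OFF_LEXICON_VERBS)))
                ]
                negation = negations[int(rng.integers(len(negations)))]
            else:
                relation = lexicon[int(rng.integers(len(lexicon)))]
                negation = None
            sentence_len = int(rng.integers(5, 61))
            body = [agent]
            if negation:
                body.append(str(negation))
            body += [relation, theme]
            words = list(body)
            while len(words) < sentence_len:
                words.append(_FILLER[len(words) % len(_FILLER)])
            record = {
                "agent": agent,
                "theme": theme,
                "relation": relation,
                "negation_token": negation,
                "sentence": " ".join(words[:sentence_len]) + " .",
                "agent_len": int(rng.integers(1, 7)),
                "theme_len": int(rng.integers(1, 7)),
                "sentence_len": sentence_len,
            }
            handle.write(json.dumps(record, sort_keys=True) + "\n")
            labels.append(bool(passing[i]))
    return path, labels


@dataclass
class PipelineFixture:
    """A complete synthetic input bundle with its expected pipeline output."""

    structures_dir: str
    chain_mapping_path: str
    domain_mapping_path: str
    mitab_path: str
    domain_known_path: str
    threshold: float
    #: protein pair -> number of supporting biological units
    expected_nip: dict[CanonicalPair, int]
    expected_stringent: set[CanonicalPair]
    protein_hits: set[CanonicalPair]
    expected_domain_pairs: set[CanonicalPair]
    expected_domain_stringent: set[CanonicalPair]
    #: sum over stringent pairs of |domains(A)| * |domains(B)|
    expansion_cardinality: int
    domains: dict[str, list[str]]


def make_pipeline_fixture(
    out_dir: str | os.PathLike,
    seed: int = 0,
    n_structures: int = 6,
    residues_per_chain: int = 16,
    threshold: float = DEFAULT_THRESHOLD,
    protein_hit_fraction: float = 0.25,
    domain_hit_fraction: float = 0.25,
) -> PipelineFixture:
    """Generate a full input bundle: structures, mappings, known-interaction
    files, plus the exact expected output of every pipeline stage.

    Gap targets are sampled away from the threshold (4-7.5 Å for contacts,
    9.5-20 Å for non-contacts) so file rounding cannot flip a class.  Two
    structures share one accession pair with contradictory geometry to
    exercise cross-structure suppression, and one chain is left out of the
    mapping table to exercise the unmapped-chain drop.
    """
    out_dir = os.fspath(out_dir)
    structures_dir = os.path.join(out_dir, "structures")
    os.makedirs(structures_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    if n_structures < 2:
        raise ValueError("need at least 2 structures")

    acc_counter = 1

    def next_acc() -> str:
        nonlocal acc_counter
        acc = f"P{acc_counter:05d}"
        acc_counter += 1
        return acc

    shared_pair = (next_acc(), next_acc())  # contradictory across units 0/1

    chain_rows: list[tuple[str, str, str]] = []
    # accession pair -> [n_supporting_units, n_contact_units]
    tally: dict[CanonicalPair, list[int]] = {}
    accessions: set[str] = set()

    for k in range(n_structures):
        sid = f"s{k:03d}"
        n_chains = 2 + (k % 2)
        chain_ids = [chr(ord("A") + i) for i in range(n_chains)]
        gaps: dict[tuple[str, str], float] = {}
        for j in range(1, n_chains):
            if k == 0 and j == 1:
                gap = round(float(rng.uniform(9.5, 20.0)), 1)   # apart
            elif k == 1 and j == 1:
                gap = round(float(rng.uniform(4.0, 7.5)), 1)    # contact
            elif rng.random() < 0.55:
                gap = round(float(rng.uniform(9.5, 20.0)), 1)
            else:
                gap = round(float(rng.uniform(4.0, 7.5)), 1)
            gaps[("A", chain_ids[j])] = gap
        fixture = make_biounit(
            FixtureSpec(
                n_chains=n_chains,
                residues_per_chain=residues_per_chain,
                pairwise_gaps=gaps,
                seed=int(rng.integers(0, 2**31 - 1)),
                structure_id=sid,
            ),
            structures_dir,
            threshold=threshold,
        )
        acc_of: dict[str, str | None] = {}
        for i, cid in enumerate(chain_ids):
            if k in (0, 1) and i < 2:
                acc: str | None = shared_pair[i]
            elif k == n_structures - 1 and i == n_chains - 1:
                acc = None  # deliberately unmapped chain
            else:
                acc = next_acc()
            acc_of[cid] = acc
            if acc is not None:
                accessions.add(acc)
                chain_rows.append((sid, cid, acc))
        for (ca_id, cb_id), noninter in fixture.classifications.items():
            acc_a, acc_b = acc_of[ca_id], acc_of[cb_id]
            if acc_a is None or acc_b is None or acc_a == acc_b:
                continue
            counts = tally.setdefault(CanonicalPair(acc_a, acc_b), [0, 0])
            counts[1 if not noninter else 0] += 1

    expected_nip = {
        pair: counts[0]
        for pair, counts in tally.items()
        if counts[0] > 0 and counts[1] == 0
    }

    chain_mapping_path = os.path.join(out_dir, "chain_mapping.tsv")
    with open(chain_mapping_path, "w", encoding="utf-8") as handle:
        handle.write("structure_id\tchain_id\taccession\n")
        for sid, cid, acc in chain_rows:
            handle.write(f"{sid}\t{cid}\t{acc}\n")

    # unique PFAM domains per protein: expansion has no cross-pair collisions
    pf_counter = 1
    domains: dict[str, list[str]] = {}
    lo, hi = 1, 3
    for acc in sorted(accessions):
        k = int(rng.integers(lo, hi + 1))
        domains[acc] = [f"PF{pf_counter + i:05d}" for i in range(k)]
        pf_counter += k
    domain_mapping_path = os.path.join(out_dir, "domain_mapping.tsv")
    with open(domain_mapping_path, "w", encoding="utf-8") as handle:
        handle.write("accession\tpfam\n")
        for acc in sorted(domains):
            for pf in domains[acc]:
                handle.write(f"{acc}\t{pf}\n")

    mitab_path = os.path.join(out_dir, "known.mitab")
    _, _, protein_hits = make_known_interactions(
        set(expected_nip),
        hit_fraction=protein_hit_fraction,
        seed=int(rng.integers(0, 2**31 - 1)),
        path=mitab_path,
    )
    expected_stringent = set(expected_nip) - protein_hits

    expected_domain_pairs: set[CanonicalPair] = set()
    expansion_cardinality = 0
    for pair in expected_stringent:
        da, db = domains[pair.first], domains[pair.second]
        expansion_cardinality += len(da) * len(db)
        for d1 in da:
            for d2 in db:
                expected_domain_pairs.add(CanonicalPair(d1, d2))

    ordered_domain_pairs = sorted(expected_domain_pairs)
    n_dom_hits = round(domain_hit_fraction * len(ordered_domain_pairs))
    dom_idx = (
        rng.choice(len(ordered_domain_pairs), size=n_dom_hits, replace=False)
        if n_dom_hits
        else []
    )
    domain_hits = {ordered_domain_pairs[int(i)] for i in dom_idx}
    domain_known_path = os.path.join(out_dir, "known_domains.tsv")
    with open(domain_known_path, "w", encoding="utf-8") as handle:
        for pair in sorted(domain_hits):
            handle.write(f"{pair.first}\t{pair.second}\n")
        handle.write("PF99998\tPF99999\n")  # decoy outside candidates

    return PipelineFixture(
        structures_dir=structures_dir,
        chain_mapping_path=chain_mapping_path,
        domain_mapping_path=domain_mapping_path,
        mitab_path=mitab_path,
        domain_known_path=domain_known_path,
        threshold=threshold,
        expected_nip=expected_nip,
        expected_stringent=expected_stringent,
        protein_hits=protein_hits,
        expected_domain_pairs=expected_domain_pairs,
        expected_domain_stringent=expected_domain_pairs - domain_hits,
        expansion_cardinality=expansion_cardinality,
        domains=domains,
    )
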