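"""Reading multi-chain biological-unit structures.

Each polymer amino-acid residue is reduced to one representative point:
the Cβ atom, or Cα for glycine (which has no side chain) and for residues
whose Cβ is missing from the coordinate record.  Waters, ligands and
nucleic acids are excluded.  Parsing is delegated to gemmi; this module
owns residue admission, altloc resolution and the representative-atom rule.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional

import gemmi
import numpy as np

from .errors import EmptyStructureError, StructureParseError

__all__ = [
    "ResiduePoint",
    "ChainModel",
    "BioUnit",
    "read_biounit",
    "select_representative_atom",
]


@dataclass(frozen=True)
class ResiduePoint:
    """One residue reduced to its representative side-chain anchor."""

    chain_id: str
    seq_index: int
    residue_name: str
    coord: tuple[float, float, float]
    atom_used: str  # "CB" or "CA"

    def __post_init__(self) -> None:
        if len(self.coord) != 3 or not all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for {self.residue_name} "
                             f"{self.chain_id}{self.seq_index}")
        if self.residue_name == "GLY" and self.atom_used != "CA":
            raise ValueError("glycine has no CB; representative must be CA")


@dataclass
class ChainModel:
    """A single chain copy with its representative points.

    ``copy_index`` distinguishes repeated chain identifiers produced by
    assembly expansion (pre-expanded biological-unit files routinely reuse
    chain names across symmetry copies).
    """

    chain_id: str
    copy_index: int
    points: list[ResiduePoint] = field(default_factory=list)
    n_skipped: int = 0

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.copy_index)

    def coords(self) -> np.ndarray:
        """Representative coordinates as an (n, 3) float array."""
        return np.asarray([p.coord for p in self.points], dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BioUnit:
    """One biological assembly: a set of chain copies with coordinates."""

    structure_id: str
    assembly_id: str
    chains: list[ChainModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.structure_id:
            raise ValueError("structure_id must be non-empty")


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _is_polymer_amino(residue: gemmi.Residue) -> bool:
    # Tabulated residues (standard + known modified) decide by chemistry;
    # unknown names are admitted only when they look peptide-like.
    info = gemmi.find_tabulated_residue(residue.name)
    if info is not None and info.found():
        return info.is_amino_acid()
    names = {a.name for a in residue}
    return {"N", "CA", "C"} <= names


def _pick_atom(residue: gemmi.Residue, name: str) -> Optional[gemmi.Atom]:
    """Highest-occupancy atom with this name; altloc label breaks ties."""
    candidates = [a for a in residue if a.name == name]
    if not candidates:
        return None
    return min(candidates, key=lambda a: (-a.occ, a.altloc))


def select_representative_atom(
    residue: gemmi.Residue, chain_id: str = ""
) -> Optional[ResiduePoint]:
    """Reduce a polymer amino-acid residue to its representative point.

    Glycine uses Cα.  Every other residue uses Cβ when present and falls
    back to Cα otherwise (``atom_used`` records which).  A residue with
    neither atom yields ``None`` — absence is a value, not an error.
    Altloc alternatives are resolved by occupancy, ties by altloc label.
    """
    atom: Optional[gemmi.Atom] = None
    used = ""
    if residue.name != "GLY":
        atom = _pick_atom(residue, "CB")
        used = "CB"
    if atom is None:
        atom = _pick_atom(residue, "CA")
        used = "CA"
    if atom is None:
        return None
    pos = atom.pos
    return ResiduePoint(
        chain_id=chain_id,
        seq_index=residue.seqid.num,
        residue_name=residue.name,
        coord=(pos.x, pos.y, pos.z),
        atom_used=used,
    )


def _chains_from_model(model: gemmi.Model) -> list[ChainModel]:
    chains: list[ChainModel] = []
    seen: dict[str, int] = {}
    for chain in model:
        copy_index = seen.get(chain.name, 0) + 1
        seen[chain.name] = copy_index
        cm = ChainModel(chain_id=chain.name, copy_index=copy_index)
        for residue in chain:
            if not _is_polymer_amino(residue):
                continue
            point = select_representative_atom(residue, chain_id=chain.name)
            if point is None:
                cm.n_skipped += 1
            else:
                cm.points.append(point)
        if cm.points or cm.n_skipped:
            chains.append(cm)
    return [c for c in chains if c.points]


def _assembly_id_from_path(path: str) -> str:
    # PDB distribution convention: 1abc.pdb1, 1abc.pdb2 ... per assembly.
    ext = os.path.splitext(path)[1]
    if ext.startswith(".pdb") and ext[4:].isdigit():
        return ext[4:]
    return "1"


def _structures_from_file(path: str, fmt: gemmi.CoorFormat) -> list[gemmi.Structure]:
    if fmt in (gemmi.CoorFormat.Mmcif, gemmi.CoorFormat.Detect) and str(
        path
    ).endswith((".cif", ".cif.gz", ".mmcif")):
        # A multi-block mmCIF file may carry one coordinate block per
        # assembly; read them all.
        doc = gemmi.cif.read(str(path))
        structures = []
        for block in doc:
            if block.find_loop("_atom_site.id") or block.find_values("_atom_site.id"):
                structures.append(gemmi.make_structure_from_block(block))
        if structures:
            return structures
        raise StructureParseError(f"{path}: no atom_site records in any block")
    return [gemmi.read_structure(str(path), format=fmt)]


def read_biounit(
    path: str | os.PathLike,
    format: str = "auto",
    expand_assemblies: bool = False,
) -> list[BioUnit]:
    """Read biological units from a PDB or mmCIF file.

    Files are consumed pre-expanded (e.g. ``*.pdb1`` biological-unit files
    or mmCIF coordinate blocks).  With ``expand_assemblies=True`` the
    assembly operators listed in an mmCIF header are applied instead, one
    unit per listed assembly.  Only the first model of multi-model (NMR)
    files is used.

    Raises
    ------
    StructureParseError
        The file cannot be parsed in the requested format.
    EmptyStructureError
        No polymer amino-acid chains were found.
    """
    path = os.fspath(path)
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}, got {format!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        structures = _structures_from_file(path, _FORMATS[format])
    except StructureParseError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with location
        raise StructureParseError(f"{path}: {exc}") from exc

    units: list[BioUnit] = []
    for st in structures:
        st.setup_entities()
        if len(st) == 0:
            continue
        structure_id = (st.name or os.path.basename(path).split(".")[0]).lower()
        if expand_assemblies and len(st.assemblies) > 0:
            for assembly in st.assemblies:
                expanded = st.clone()
                expanded.transform_to_assembly(
                    assembly.name, gemmi.HowToNameCopiedChain.AddNumber
                )
                chains = _chains_from_model(expanded[0])
                if chains:
                    units.append(BioUnit(structure_id, assembly.name, chains))
        else:
            chains = _chains_from_model(st[0])
            if chains:
                units.append(
                    BioUnit(structure_id, _assembly_id_from_path(path), chains)
                )
    if not units:
        raise EmptyStructureError(f"{path}: no polymer amino-acid chains")
    return units


def read_biounits_from_dir(
    directory: str | os.PathLike,
    format: str = "auto",
    expand_assemblies: bool = False,
) -> Iterator[BioUnit]:
    """Yield biological units from every structure file in a directory.

    Recognised suffixes: ``.pdb``, ``.pdbN``, ``.ent``, ``.cif``, ``.mmcif``
    (restricted to the matching subset when a format is forced).  When the
    same structure is present in both formats only the PDB copy is read,
    so fixture directories carrying parallel files yield each unit once.
    Files that contain no polymer chains are skipped.
    """
    directory = os.fspath(directory)
    pdb_exts = (".pdb", ".ent")
    cif_exts = (".cif", ".mmcif")

    def _matches(ext: str) -> bool:
        is_pdb = ext in pdb_exts or (ext.startswith(".pdb") and ext[4:].isdigit())
        is_cif = ext in cif_exts
        if format == "pdb":
            return is_pdb
        if format == "mmcif":
            return is_cif
        return is_pdb or is_cif

    by_stem: dict[str, list[str]] = {}
    for name in sorted(os.listdir(directory)):
        stem, ext = os.path.splitext(name)
        if _matches(ext):
            by_stem.setdefault(stem, []).append(name)
    for stem in sorted(by_stem):
        names = by_stem[stem]
        chosen = [n for n in names if not n.endswith(cif_exts)] or names
        for name in chosen:
            try:
                yield from read_biounit(
                    os.path.join(directory, name),
                    format=format,
                    expand_assemblies=expand_assemblies,
                )
            except EmptyStructureError:
                continue
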