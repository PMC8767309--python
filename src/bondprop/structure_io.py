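"""Read, clean and validate protein structures in PDB format.

Only the fixed-column ATOM/HETATM/TER/MODEL/ENDMDL records are
interpreted.  Residue numbering is taken verbatim from the file (author
numbering, insertion codes included) because site annotations use it.
Alternate locations are collapsed to a single conformer per atom:
highest occupancy wins, ties broken by altloc letter order.  Only the
first MODEL of a multi-model file is read.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "SiteAnnotation",
    "PDBFormatError",
    "ProtonationError",
    "SiteResolutionError",
    "parse_pdb",
    "clean_structure",
    "require_hydrogens",
    "resolve_site",
    "write_pdb",
    "write_scored_pdb",
]

#: 3-letter codes treated as water.
WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: The 20 standard amino acids.
STANDARD_RESIDUES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL",
    }
)


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


class ProtonationError(RuntimeError):
    """Raised when a structure lacks hydrogens and no remedy is configured."""


class SiteResolutionError(KeyError):
    """Raised when a site annotation matches nothing in the structure."""


@dataclass(frozen=True)
class Atom:
    """A single atom record with author numbering preserved."""

    atom_id: int
    name: str
    element: str
    chain: str
    res_name: str
    res_seq: int
    icode: str
    coords: tuple[float, float, float]
    category: str  # protein | ligand | water | other-hetero
    altloc: str = ""
    occupancy: float = 1.0

    @property
    def residue_key(self) -> tuple[str, str, int, str]:
        return (self.chain, self.res_name, self.res_seq, self.icode)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class StructureModel:
    """An ordered collection of atoms grouped into residues."""

    atoms: list[Atom]
    source: str = "<memory>"
    log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> dict[tuple[str, str, int, str], list[int]]:
        """Map residue key -> atom indices, in file order."""
        groups: dict[tuple[str, str, int, str], list[int]] = {}
        for idx, atom in enumerate(self.atoms):
            groups.setdefault(atom.residue_key, []).append(idx)
        return groups

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def protein_atoms(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.category == "protein"]

    def hydrogen_fraction(self) -> float:
        """Fraction of hydrogens among protein atoms (0.0 if no protein)."""
        protein = [self.atoms[i] for i in self.protein_atoms()]
        if not protein:
            return 0.0
        return sum(a.is_hydrogen for a in protein) / len(protein)


@dataclass(frozen=True)
class SiteAnnotation:
    """Residue and/or ligand identifiers defining a functional site.

    Residues are (chain, res_seq, icode) triples; ligands are
    (chain, res_name, res_seq) triples.  ``role`` is free text used in
    provenance only ("orthosteric", "allosteric", ...).
    """

    residues: tuple[tuple[str, int, str], ...] = ()
    ligand_ids: tuple[tuple[str, str, int], ...] = ()
    role: str = "orthosteric"

    def __post_init__(self) -> None:
        if not self.residues and not self.ligand_ids:
            raise ValueError("site annotation needs at least one residue or ligand")


def _categorise(record: str, res_name: str) -> str:
    if res_name in WATER_RESIDUES:
        return "water"
    if record == "ATOM":
        return "protein" if res_name in STANDARD_RESIDUES else "other-hetero"
    return "ligand"


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    # PDB convention: element is right-justified in columns 13-14; a name
    # starting in column 13 with a letter denotes a two-letter element
    # only for ions/metals.  Digits and the common H* variants map to H.
    if stripped[0].isdigit() or stripped[0] == "H":
        return "H"
    return stripped[0]


def parse_pdb(pdb_text: str, source: str = "<memory>") -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    Only MODEL 1 is read; altloc conflicts are resolved to the
    highest-occupancy conformer (ties by altloc letter).  Raises
    :class:`PDBFormatError` naming the first offending line when the
    text contains no ATOM/HETATM record or a record cannot be parsed.
    """
    atoms: list[Atom] = []
    log: list[str] = []
    model_no = 0
    seen_model_done = False
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            model_no += 1
            if model_no > 1:
                seen_model_done = True
            continue
        if record == "ENDMDL":
            seen_model_done = True
            continue
        if record not in ("ATOM", "HETATM"):
            continue
        if seen_model_done:
            continue  # only MODEL 1 is analysed
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16].strip()
            res_name = line[17:20].strip()
            chain = line[21].strip()
            res_seq = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_text = line[54:60].strip()
            occupancy = float(occ_text) if occ_text else 1.0
            element = line[76:78].strip() if len(line) >= 78 else ""
        except (ValueError, IndexError) as exc:
            raise PDBFormatError(
                f"{source}: cannot parse {record} record at line {lineno}: {line!r}"
            ) from exc
        if not element:
            element = _guess_element(name)
        element = element.capitalize() if len(element) == 2 else element.upper()
        if element == "D":  # deuterium behaves as hydrogen
            element = "H"
        if not np.all(np.isfinite([x, y, z])):
            raise PDBFormatError(
                f"{source}: non-finite coordinates at line {lineno}"
            )
        atoms.append(
            Atom(
                atom_id=serial,
                name=name,
                element=element,
                chain=chain,
                res_name=res_name,
                res_seq=res_seq,
                icode=icode,
                coords=(x, y, z),
                category=_categorise(record, res_name),
                altloc=altloc,
                occupancy=occupancy,
            )
        )
    if not atoms:
        raise PDBFormatError(
            f"{source}: no ATOM/HETATM records found (first line: "
            f"{pdb_text.splitlines()[0]!r})"
            if pdb_text.strip()
            else f"{source}: empty file"
        )
    atoms, n_dropped = _resolve_altlocs(atoms)
    if n_dropped:
        log.append(f"altloc resolution dropped {n_dropped} atoms")
    return StructureModel(atoms=atoms, source=source, log=log)


def _resolve_altlocs(atoms: list[Atom]) -> tuple[list[Atom], int]:
    """Keep one conformer per (residue, atom name): highest occupancy,
    ties broken by altloc letter order."""
    best: dict[tuple, int] = {}
    for idx, atom in enumerate(atoms):
        key = (*atom.residue_key, atom.name)
        if key not in best:
            best[key] = idx
            continue
        other = atoms[best[key]]
        if (atom.occupancy, _altloc_rank(atom)) > (
            other.occupancy,
            _altloc_rank(other),
        ):
            best[key] = idx
    keep = sorted(best.values())
    resolved = [replace(atoms[i], altloc="") for i in keep]
    return resolved, len(atoms) - len(resolved)


def _altloc_rank(atom: Atom) -> float:
    # empty altloc outranks lettered ones; otherwise 'A' > 'B' > ...
    return 1.0 if not atom.altloc else -ord(atom.altloc)


def clean_structure(
    model: StructureModel,
    keep_ligands: Sequence[str] | None = None,
    remove_ligands: Sequence[str] = (),
    keep_waters: bool = False,
) -> StructureModel:
    """Remove waters and unwanted hetero groups.

    ``keep_ligands=None`` keeps every hetero group not listed in
    ``remove_ligands``; passing a list makes it a whitelist.  Ligand
    identifiers are 3-letter residue names ("FMN") or
    "chain:res_name:res_seq" strings for a specific copy.  Entries in
    ``remove_ligands`` that match nothing are logged, not fatal.
    """
    removed: dict[tuple, str] = {}
    remove_set = {str(r).upper() for r in remove_ligands}
    keep_set = None if keep_ligands is None else {str(k).upper() for k in keep_ligands}

    def _ligand_tokens(atom: Atom) -> set[str]:
        return {
            atom.res_name.upper(),
            f"{atom.chain}:{atom.res_name}:{atom.res_seq}".upper(),
        }

    kept: list[Atom] = []
    matched_removals: set[str] = set()
    for atom in model.atoms:
        if atom.category == "water" and not keep_waters:
            removed[atom.residue_key] = "water"
            continue
        if atom.category in ("ligand", "other-hetero"):
            tokens = _ligand_tokens(atom)
            hit = tokens & remove_set
            if hit:
                matched_removals |= hit
                removed[atom.residue_key] = "removed ligand"
                continue
            if keep_set is not None and not (tokens & keep_set):
                removed[atom.residue_key] = "not in keep list"
                continue
        kept.append(atom)

    log = list(model.log)
    for key, reason in removed.items():
        log.append(f"removed {'/'.join(map(str, key))}: {reason}")
    for miss in remove_set - matched_removals:
        log.append(f"warning: remove_ligands entry {miss!r} not present")
    return StructureModel(atoms=kept, source=model.source, log=log)


def require_hydrogens(
    model: StructureModel,
    threshold: float = 0.25,
    protonate_command: str | None = None,
) -> StructureModel:
    """Ensure the structure is protonated.

    If the hydrogen fraction among protein atoms is below ``threshold``
    and ``protonate_command`` is set, the cleaned structure is piped
    through that external command (reads a PDB path argument, writes a
    protonated PDB to stdout) and re-parsed; otherwise a
    :class:`ProtonationError` is raised instructing pre-protonation.
    """
    frac = model.hydrogen_fraction()
    if frac >= threshold:
        return model
    if protonate_command is None:
        raise ProtonationError(
            f"structure not protonated (hydrogen fraction {frac:.2f} < "
            f"{threshold}); add hydrogens upstream or configure a "
            "protonation command"
        )
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as handle:
        handle.write(write_pdb(model))
        tmp_path = handle.name
    try:
        proc = subprocess.run(
            [*protonate_command.split(), tmp_path],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise ProtonationError(
                f"protonation command failed (exit {proc.returncode}): "
                f"{proc.stderr.strip()[:500]}"
            )
        out = parse_pdb(proc.stdout, source=f"{model.source} [protonated]")
    finally:
        Path(tmp_path).unlink(missing_ok=True)
    out.log[:0] = model.log + [f"protonated via {protonate_command!r}"]
    return out


def resolve_site(model: StructureModel, annotation: SiteAnnotation) -> set[int]:
    """Resolve a site annotation to atom indices in ``model``.

    Missing entries are reported in the model log; an annotation that
    matches nothing raises :class:`SiteResolutionError`.
    """
    residues = model.residues
    by_pos: dict[tuple[str, int, str], list[int]] = {}
    by_ligand: dict[tuple[str, str, int], list[int]] = {}
    for (chain, res_name, res_seq, icode), idxs in residues.items():
        by_pos.setdefault((chain, res_seq, icode), []).extend(idxs)
        by_ligand.setdefault((chain, res_name, res_seq), []).extend(idxs)

    out: set[int] = set()
    missing: list[str] = []
    for chain, res_seq, icode in annotation.residues:
        idxs = by_pos.get((chain, res_seq, icode))
        if idxs is None:
            missing.append(f"residue {chain}/{res_seq}{icode}")
        else:
            out.update(idxs)
    for chain, res_name, res_seq in annotation.ligand_ids:
        idxs = by_ligand.get((chain, res_name, res_seq))
        if idxs is None:
            missing.append(f"ligand {chain}/{res_name}/{res_seq}")
        else:
            out.update(idxs)
    for entry in missing:
        model.log.append(f"warning: {annotation.role} annotation {entry} not found")
    if not out:
        raise SiteResolutionError(
            f"no {annotation.role} annotation entries resolved against "
            f"{model.source}: {missing}"
        )
    return out


def write_pdb(model: StructureModel, bfactors: Iterable[float] | None = None) -> str:
    """Serialise a model back to PDB text (ATOM/HETATM + END)."""
    bvals = list(bfactors) if bfactors is not None else [0.0] * len(model.atoms)
    lines = []
    for serial, (atom, b) in enumerate(zip(model.atoms, bvals), start=1):
        record = "ATOM  " if atom.category == "protein" else "HETATM"
        name = atom.name
        # standard alignment: 1-letter elements indent one column
        if len(name) < 4 and len(atom.element) == 1:
            name = f" {name}"
        x, y, z = atom.coords
        lines.append(
            f"{record}{serial:>5} {name:<4}{'':1}{atom.res_name:>3} "
            f"{atom.chain:1}{atom.res_seq:>4}{atom.icode:1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{b:6.2f}"
            f"          {atom.element:>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_scored_pdb(
    model: StructureModel,
    residue_scores: dict[tuple[str, str, int, str], float],
) -> str:
    """Write a PDB with per-residue scores x100 in the B-factor column
    (for coloring structures by score in a viewer)."""
    bvals = [
        100.0 * residue_scores.get(atom.residue_key, 0.0) for atom in model.atoms
    ]
    return write_pdb(model, bfactors=bvals)
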