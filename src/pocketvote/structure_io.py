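"""PDB structure input/output and the van der Waals radius table.

Polymer ATOM records become a :class:`StructureModel`; HETATM records are
grouped by (chain, residue number, chemical component code) into
:class:`Ligand` objects.  Water (HOH/WAT/DOD) is always dropped.  Alternate
locations are collapsed to the highest-occupancy conformer (ties broken by
the alphabetically first altloc) so all downstream geometry is
single-conformer and deterministic.  Hydrogen and deuterium atoms are kept
in the data model but flagged so contact calculations can skip them:
experimental structures mostly lack hydrogens and including them would make
contacts depend on protonation artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

from .errors import EmptyStructureError, InputError, PDBParseError

WATER_CODES = frozenset({"HOH", "WAT", "DOD"})

# Bondi (1964) van der Waals radii, Å.  Elements without a published Bondi
# value (most transition metals) fall back to VdWTable.default_radius; the
# 0.5 Å contact margin dominates small per-element differences.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "HE": 1.40, "LI": 1.82, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "NE": 1.54, "NA": 2.27, "MG": 1.73, "SI": 2.10, "P": 1.80,
    "S": 1.80, "CL": 1.75, "AR": 1.88, "K": 2.75, "NI": 1.63, "CU": 1.40,
    "ZN": 1.39, "GA": 1.87, "AS": 1.85, "SE": 1.90, "BR": 1.85, "KR": 2.02,
    "PD": 1.63, "AG": 1.72, "CD": 1.58, "IN": 1.93, "SN": 2.17, "TE": 2.06,
    "I": 1.98, "XE": 2.16, "PT": 1.75, "AU": 1.66, "HG": 1.55, "TL": 1.96,
    "PB": 2.02, "U": 1.86,
}

# Standard one-letter codes; anything else maps to 'X'.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


@dataclass(frozen=True)
class VdWTable:
    """Element → van der Waals radius lookup with a guaranteed fallback."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    default_radius: float = 1.8

    def __post_init__(self) -> None:
        if self.default_radius <= 0 or any(r <= 0 for r in self.radii.values()):
            raise InputError("van der Waals radii must be strictly positive")

    def radius(self, element: str) -> float:
        return self.radii.get(element.strip().upper(), self.default_radius)

    @classmethod
    def from_file(cls, path: str | Path, default_radius: float = 1.8) -> "VdWTable":
        """Load a two-column (element, radius Å) whitespace-separated table."""
        radii: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise InputError(f"bad VdW table line: {line!r}")
            radii[parts[0].upper()] = float(parts[1])
        return cls(radii=radii, default_radius=default_radius)


DEFAULT_VDW = VdWTable()


def vdw_radius(element: str, table: VdWTable = DEFAULT_VDW) -> float:
    """Van der Waals radius in Å; unknown elements get the table default."""
    return table.radius(element)


@dataclass(eq=False)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise InputError(f"atom {self.serial}: coordinates must be 3 finite numbers")


@dataclass(eq=False)
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name.upper(), "X")

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if not a.is_hydrogen]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def ca(self) -> Atom | None:
        for a in self.atoms:
            if a.name.strip() == "CA" and not a.is_hetero:
                return a
        return None

    def token(self) -> str:
        """Residue token in prediction-file style, e.g. ``HIS29``."""
        return f"{self.res_name.upper()}{self.seq_num}{self.icode.strip()}"


@dataclass(eq=False)
class StructureModel:
    target_id: str
    residues: list[Residue]
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates, one row per residue that has a Cα."""
        return np.array([r.ca().coords for r in self.residues if r.ca() is not None])

    def residues_with_ca(self) -> list[Residue]:
        return [r for r in self.residues if r.ca() is not None]


@dataclass(eq=False)
class Ligand:
    het_code: str
    atoms: list[Atom]
    source_template: str = ""
    instance_id: str = ""

    def __post_init__(self) -> None:
        if self.het_code.upper() in WATER_CODES:
            raise InputError("water can never be a ligand")

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if not a.is_hydrogen]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def heavy_elements(self) -> list[str]:
        return [a.element for a in self.atoms if not a.is_hydrogen]

    def center(self) -> np.ndarray:
        return self.heavy_coords().mean(axis=0)

    def transformed(self, fn) -> "Ligand":
        atoms = [replace(a, coords=fn(a.coords)) for a in self.atoms]
        return Ligand(self.het_code, atoms, self.source_template, self.instance_id)


def _validate_coordinate_fields(path: Path) -> None:
    """Reject malformed coordinate fields with the offending line number.

    gemmi silently coerces unparsable coordinate text to 0.0, which would
    corrupt geometry downstream, so coordinates are checked up front.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi].strip()
                try:
                    value = float(fieldtxt) if fieldtxt else math.nan
                except ValueError:
                    raise PDBParseError(
                        f"{path}:{lineno}: malformed coordinate field {fieldtxt!r}"
                    ) from None
                if not math.isfinite(value):
                    raise PDBParseError(
                        f"{path}:{lineno}: non-finite or empty coordinate field"
                    )


def _collapse_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
            order.append(a.name)
        elif (a.occupancy, prev.altloc or "~") > (prev.occupancy, a.altloc or "~"):
            # higher occupancy wins; on equal occupancy the alphabetically
            # first altloc wins (blank altloc sorts first)
            by_name[a.name] = a
    return [by_name[n] for n in order]


def _convert_atom(ga: gemmi.Atom, is_hetero: bool) -> Atom:
    elem = ga.element.name.upper()
    return Atom(
        serial=ga.serial,
        name=ga.name,
        element=elem,
        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
        altloc=ga.altloc.strip("\x00"),
        occupancy=ga.occ,
        is_hetero=is_hetero,
        is_hydrogen=elem in ("H", "D"),
    )


def parse_pdb(
    path: str | Path, model_index: int = 0, target_id: str | None = None
) -> tuple[StructureModel, list[Ligand]]:
    """Read a PDB file into a polymer model and a list of non-water ligands.

    Parameters
    ----------
    path:
        PDB-format file with at least one ATOM or HETATM record.
    model_index:
        Which MODEL block to read from multi-model files (0 = first).
    target_id:
        Identifier for the returned model; defaults to the file stem.

    Returns
    -------
    (StructureModel, list[Ligand])
        Polymer residues in file order, and one Ligand per
        (chain, seq_num, het_code) HETATM group.  Waters are dropped.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"structure file not found: {path}")
    _validate_coordinate_fields(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:  # pragma: no cover - gemmi is very permissive
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate records")
    if model_index >= len(st):
        raise InputError(f"{path}: model index {model_index} out of range ({len(st)} models)")
    gmodel = st[model_index]

    tid = target_id if target_id is not None else path.stem
    residues: list[Residue] = []
    ligands: list[Ligand] = []
    for chain in gmodel:
        for gres in chain:
            is_het = gres.het_flag == "H"
            name = gres.name.upper()
            if is_het and name in WATER_CODES:
                continue
            atoms = _collapse_altlocs([_convert_atom(a, is_het) for a in gres])
            if not atoms:
                continue
            if is_het:
                iid = f"{tid}/{chain.name}{gres.seqid.num}{gres.seqid.icode.strip()}:{name}"
                ligands.append(
                    Ligand(het_code=name, atoms=atoms, source_template=tid, instance_id=iid)
                )
            else:
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        seq_num=gres.seqid.num,
                        icode=gres.seqid.icode,
                        res_name=name,
                        atoms=atoms,
                    )
                )
    if not residues and not ligands:
        raise EmptyStructureError(f"{path}: no ATOM or HETATM records")
    return StructureModel(target_id=tid, residues=residues, source_path=str(path)), ligands


def _format_atom_line(
    record: str, serial: int, atom: Atom, res_name: str, chain_id: str,
    seq_num: int, icode: str,
) -> str:
    if seq_num > 9999 or seq_num < -999:
        raise InputError(
            f"residue number {seq_num} does not fit fixed-column PDB; "
            "renumber before writing (hybrid numbering is not emitted)"
        )
    name = atom.name
    # conventional alignment: 1-letter elements start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.coords
    return (
        f"{record:<6s}{min(serial, 99999):5d} {name:<4s}{(atom.altloc or ' '):1s}"
        f"{res_name:>3s} {chain_id:1s}{seq_num:4d}{(icode.strip() or ' '):1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_structure(
    model: StructureModel, ligands: Iterable[Ligand], path: str | Path
) -> None:
    """Write the model's ATOM records followed by ligand HETATM records.

    Round-trips through :func:`parse_pdb` (coordinates to 3 decimals).
    Residue numbers above 9999 are rejected rather than silently wrapped.
    """
    if not model.residues:
        raise InputError("refusing to write an empty structure")
    lines: list[str] = []
    serial = 0
    last_chain = None
    for res in model.residues:
        last_chain = res.chain_id
        for atom in res.atoms:
            serial += 1
            lines.append(
                _format_atom_line("ATOM", serial, atom, res.res_name,
                                  res.chain_id, res.seq_num, res.icode)
            )
    if last_chain is not None:
        serial += 1
        lines.append(f"TER   {min(serial, 99999):5d}")
    lig_seq = 0
    for lig in ligands:
        lig_seq += 1
        for atom in lig.atoms:
            serial += 1
            lines.append(
                _format_atom_line("HETATM", serial, atom, lig.het_code, "L",
                                  lig_seq, " ")
            )
    lines.append("END")
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
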