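"""Molecular structure I/O, residue-based fragmentation and guest distances.

Structures are flat, 0-based, densely indexed atom lists (element symbol +
Cartesian coordinates in Å, with optional PDB metadata).  Fragment maps
partition those indices into named fragments with host/guest/solvent roles;
every per-fragment quantity downstream (minimum guest distance, orbital
shifts, charges) is keyed by the integer fragment id defined here.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Fragment",
    "FragmentMap",
    "StructureParseError",
    "FragmentMapError",
    "read_structure",
    "write_structure",
    "build_fragment_map",
    "min_distance_profile",
    "pair_min_distances",
    "strip_guest",
]

#: Elements parameterized by the shipped tight-binding table (tbengine).
KNOWN_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "Si", "Al", "F", "Cl", "Br", "I"}
)


class StructureParseError(ValueError):
    """A structure file violated its format."""


class FragmentMapError(ValueError):
    """A fragment map violated the partition contract."""


@dataclass(frozen=True)
class Atom:
    element: str
    resname: str = ""
    resseq: int = 0
    chain: str = ""
    serial: int = 0
    hetatm: bool = False
    known_element: bool = True


@dataclass
class Structure:
    """An ordered atom list with coordinates in Å.

    ``coords`` is an (N, 3) float array; ``atoms[i]`` carries the element
    symbol and any PDB metadata for atom ``i``.  Indices are 0-based and
    stable: operations never reorder atoms.
    """

    atoms: list[Atom]
    coords: np.ndarray
    title: str = ""
    net_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.atoms) != self.coords.shape[0]:
            raise ValueError("atom list and coordinate array lengths differ")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atomic coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def subset(self, indices) -> "Structure":
        """New Structure containing ``indices`` in ascending order."""
        idx = sorted(int(i) for i in indices)
        return Structure(
            atoms=[self.atoms[i] for i in idx],
            coords=self.coords[idx],
            title=self.title,
            net_charge=self.net_charge,
        )


@dataclass(frozen=True)
class Fragment:
    id: int
    name: str
    atom_indices: tuple[int, ...]
    role: str = "host"  # host | guest | solvent
    formal_charge: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "atom_indices", tuple(sorted(int(i) for i in self.atom_indices))
        )
        if self.role not in ("host", "guest", "solvent"):
            raise FragmentMapError(f"unknown fragment role {self.role!r}")


@dataclass
class FragmentMap:
    fragments: list[Fragment]

    def __post_init__(self) -> None:
        ids = [f.id for f in self.fragments]
        if len(set(ids)) != len(ids):
            raise FragmentMapError("duplicate fragment ids")

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def by_id(self, fid: int) -> Fragment:
        for f in self.fragments:
            if f.id == fid:
                return f
        raise KeyError(f"no fragment with id {fid}")

    @property
    def ids(self) -> list[int]:
        return [f.id for f in self.fragments]

    def guest_ids(self) -> list[int]:
        return [f.id for f in self.fragments if f.role == "guest"]

    def validate(self, structure: Structure) -> None:
        """Check the disjoint-cover partition contract against a structure."""
        seen: dict[int, int] = {}
        for f in self.fragments:
            if not f.atom_indices:
                raise FragmentMapError(f"fragment {f.id} ({f.name}) is empty")
            for i in f.atom_indices:
                if i in seen:
                    raise FragmentMapError(
                        f"atom {i} in fragments {seen[i]} and {f.id}"
                    )
                if not 0 <= i < structure.n_atoms:
                    raise FragmentMapError(f"atom index {i} out of range")
                seen[i] = f.id
        missing = sorted(set(range(structure.n_atoms)) - set(seen))
        if missing:
            raise FragmentMapError(f"atoms not covered by any fragment: {missing}")

    def to_json(self, path=None) -> str:
        payload = {
            "fragments": [
                {
                    "id": f.id,
                    "name": f.name,
                    "atoms": list(f.atom_indices),
                    "role": f.role,
                    "formal_charge": f.formal_charge,
                }
                for f in self.fragments
            ]
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "FragmentMap":
        if isinstance(source, Path) or (
            isinstance(source, str)
            and "\n" not in source
            and not source.lstrip().startswith("{")
        ):
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        frags = [
            Fragment(
                id=int(f["id"]),
                name=str(f["name"]),
                atom_indices=tuple(int(i) for i in f["atoms"]),
                role=f.get("role", "host"),
                formal_charge=int(f.get("formal_charge", 0)),
            )
            for f in data["fragments"]
        ]
        return cls(frags)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _flag_element(sym: str, where: str) -> tuple[str, bool]:
    sym = sym.strip()
    sym = sym[:1].upper() + sym[1:].lower() if sym else sym
    if sym not in KNOWN_ELEMENTS:
        warnings.warn(f"unknown element {sym!r} at {where}; atom flagged")
        return sym, False
    return sym, True


def _read_xyz(path: Path) -> Structure:
    lines = path.read_text().splitlines()
    if not lines:
        raise StructureParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise StructureParseError(f"{path}: line 1: bad atom count") from None
    title = lines[1].strip() if len(lines) > 1 else ""
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    for ln, raw in enumerate(lines[2 : 2 + n], start=3):
        parts = raw.split()
        if len(parts) < 4:
            raise StructureParseError(f"{path}: line {ln}: need 'El x y z'")
        sym, known = _flag_element(parts[0], f"{path}:{ln}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise StructureParseError(
                f"{path}: line {ln}: non-numeric coordinate"
            ) from None
        atoms.append(Atom(element=sym, serial=ln - 2, known_element=known))
        coords.append(xyz)
    if len(atoms) != n:
        raise StructureParseError(f"{path}: expected {n} atoms, found {len(atoms)}")
    return Structure(atoms=atoms, coords=np.array(coords), title=title)


def _read_pdb(path: Path) -> Structure:
    # Bio.PDB handles fixed columns, models and altlocs; we keep the first
    # model, drop altlocs other than blank/'A', and preserve file order.
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        model = next(parser.get_structure(path.stem, str(path)).get_models())
    except StopIteration:
        raise StructureParseError(f"{path}: no ATOM/HETATM records") from None
    except Exception as exc:  # malformed fixed-width record
        raise StructureParseError(f"{path}: {exc}") from None
    records = []
    for chain in model:
        for residue in chain:
            het = residue.id[0].strip() != ""
            for atom in residue:
                if atom.altloc not in ("", " ", "A"):
                    continue
                sym, known = _flag_element(
                    atom.element if atom.element else atom.get_name()[:1],
                    f"{path} serial {atom.serial_number}",
                )
                records.append(
                    (
                        atom.serial_number,
                        Atom(
                            element=sym,
                            resname=residue.resname.strip(),
                            resseq=residue.id[1],
                            chain=chain.id.strip(),
                            serial=atom.serial_number,
                            hetatm=het,
                            known_element=known,
                        ),
                        atom.coord.astype(float),
                    )
                )
    if not records:
        raise StructureParseError(f"{path}: no ATOM/HETATM records")
    records.sort(key=lambda r: r[0])
    return Structure(
        atoms=[r[1] for r in records],
        coords=np.array([r[2] for r in records]),
        title=path.stem,
    )


def read_structure(path, format: str | None = None) -> Structure:
    """Read a PDB or XYZ file into a :class:`Structure`.

    ``format`` defaults to the file suffix.  One atom per ATOM/HETATM record
    (PDB, altloc other than blank/'A' dropped) or coordinate line (XYZ).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unsupported structure format {fmt!r}")


def write_structure(structure: Structure, path, format: str | None = None) -> None:
    """Write a Structure as XYZ (1e-6 Å) or fixed-width PDB (1e-3 Å)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        lines = [str(structure.n_atoms), structure.title]
        for a, xyz in zip(structure.atoms, structure.coords):
            lines.append(f"{a.element:<2s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}")
        path.write_text("\n".join(lines) + "\n")
        return
    if fmt == "pdb":
        lines = []
        seen_in_res: dict[tuple, int] = {}
        for i, (a, xyz) in enumerate(zip(structure.atoms, structure.coords), start=1):
            record = "HETATM" if a.hetatm else "ATOM  "
            resname = a.resname or "UNK"
            chain = (a.chain or "A")[:1]
            resseq = a.resseq or 1
            # unique atom names within a residue (readers drop duplicates)
            key = (chain, resseq, resname)
            seen_in_res[key] = seen_in_res.get(key, 0) + 1
            name = f"{a.element}{seen_in_res[key]}"[:4]
            name = name if len(a.element) > 1 else f" {name}"[:4]
            lines.append(
                f"{record}{i:5d} {name:<4s}{resname:>4s} {chain}{resseq:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
        return
    raise ValueError(f"unsupported structure format {fmt!r}")


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def build_fragment_map(
    structure: Structure,
    mode: str = "by_residue",
    explicit_spec: list[Fragment] | None = None,
    guest_selector: str | int | None = None,
    require_guest: bool = True,
) -> FragmentMap:
    """Partition a structure into fragments.

    ``by_residue`` groups atoms by (chain, residue number), the standard
    amino-acid-per-fragment convention; HETATM residues whose residue name
    matches ``guest_selector`` (or the fragment whose id equals an integer
    selector) get role ``guest``; waters and ions stay host-like ``solvent``.
    ``explicit`` takes a user fragment list which must cover all atoms
    disjointly.
    """
    if mode == "explicit":
        if not explicit_spec:
            raise FragmentMapError("explicit mode requires a fragment list")
        fmap = FragmentMap(list(explicit_spec))
        fmap.validate(structure)
    elif mode == "by_residue":
        groups: dict[tuple, list[int]] = {}
        for i, a in enumerate(structure.atoms):
            groups.setdefault((a.chain, a.resseq, a.resname, a.hetatm), []).append(i)
        frags = []
        solvent_names = {"HOH", "WAT", "NA", "CL", "K", "MG", "CA", "ZN"}
        for fid, (key, idx) in enumerate(sorted(groups.items())):
            chain, resseq, resname, het = key
            role = "host"
            if het and isinstance(guest_selector, str) and resname == guest_selector:
                role = "guest"
            elif resname in solvent_names:
                role = "solvent"
            frags.append(
                Fragment(
                    id=fid,
                    name=f"{resname}{resseq}{':' + chain if chain else ''}",
                    atom_indices=tuple(idx),
                    role=role,
                )
            )
        if isinstance(guest_selector, int):
            frags = [
                replace(f, role="guest") if f.id == guest_selector else f
                for f in frags
            ]
        fmap = FragmentMap(frags)
        fmap.validate(structure)
    else:
        raise ValueError(f"unknown fragmentation mode {mode!r}")
    if require_guest and guest_selector is not None and not fmap.guest_ids():
        raise FragmentMapError(
            f"no fragment matched guest selector {guest_selector!r}"
        )
    return fmap


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _guest_coords(structure: Structure, fragmap: FragmentMap) -> np.ndarray:
    gids = fragmap.guest_ids()
    if not gids:
        raise FragmentMapError("no guest fragment defined")
    idx = [i for g in gids for i in fragmap.by_id(g).atom_indices]
    return structure.coords[idx]


def min_distance_profile(
    structure: Structure, fragmap: FragmentMap
) -> dict[int, float]:
    """Per-fragment minimum atomic distance to the guest, R_min (Å).

    Guest fragments map to 0.0.
    """
    fragmap.validate(structure)
    gxyz = _guest_coords(structure, fragmap)
    out: dict[int, float] = {}
    for f in fragmap:
        if f.role == "guest":
            out[f.id] = 0.0
            continue
        fxyz = structure.coords[list(f.atom_indices)]
        d = np.linalg.norm(fxyz[:, None, :] - gxyz[None, :, :], axis=-1)
        out[f.id] = float(d.min())
    return out


def pair_min_distances(structure: Structure, fragmap: FragmentMap) -> dict[tuple[int, int], float]:
    """Minimum interatomic distance for every unordered fragment pair."""
    coords = {f.id: structure.coords[list(f.atom_indices)] for f in fragmap}
    ids = sorted(coords)
    out: dict[tuple[int, int], float] = {}
    for i, fi in enumerate(ids):
        for fj in ids[i + 1 :]:
            d = np.linalg.norm(
                coords[fi][:, None, :] - coords[fj][None, :, :], axis=-1
            )
            out[(fi, fj)] = float(d.min())
    return out


def strip_guest(structure: Structure, fragmap: FragmentMap) -> tuple[Structure, FragmentMap, list[int]]:
    """Host-only (apo) structure and map derived from a complex.

    Fragment ids are preserved; atom indices are re-densified.  Returns the
    apo structure, its fragment map, and the complex-frame indices kept.
    """
    keep = sorted(
        i for f in fragmap if f.role != "guest" for i in f.atom_indices
    )
    old_to_new = {old: new for new, old in enumerate(keep)}
    host = structure.subset(keep)
    host.net_charge = structure.net_charge - sum(
        f.formal_charge for f in fragmap if f.role == "guest"
    )
    frags = [
        Fragment(
            id=f.id,
            name=f.name,
            atom_indices=tuple(old_to_new[i] for i in f.atom_indices),
            role=f.role,
            formal_charge=f.formal_charge,
        )
        for f in fragmap
        if f.role != "guest"
    ]
    return host, FragmentMap(frags), keep
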