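"""QM-region definitions: empirical, short-range, MO-based and whole-system.

A region is a fragment selection (the guest is always included) together
with the criterion that produced it:

* empirical   - an explicit user-supplied fragment list, the literature
                convention of hand-picking the pocket;
* short_range - fragments within a distance cutoff of the guest OR with a
                guest-pair interaction magnitude above a threshold
                (defaults 5 Å / 2 kcal/mol; ``intersect=True`` switches the
                union to a conjunction);
* mo_based    - fragments with R_min <= R_conv, the radius delivered by the
                MO-shift convergence analysis;
* whole       - every fragment (the all-QM reference).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .fmo import PairInteraction
from .structio import FragmentMap, Structure, write_structure

__all__ = [
    "RegionDefinition",
    "select_region_empirical",
    "select_region_short_range",
    "select_region_mo_based",
    "select_region_whole",
    "emit_region",
]


@dataclass
class RegionDefinition:
    model: str                      # empirical | short_range | mo_based | whole
    fragment_ids: tuple[int, ...]   # sorted, guest included
    atom_indices: tuple[int, ...]   # sorted union of the fragments' atoms
    criteria: dict

    def __post_init__(self) -> None:
        self.fragment_ids = tuple(sorted(set(int(i) for i in self.fragment_ids)))
        self.atom_indices = tuple(sorted(set(int(i) for i in self.atom_indices)))

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_ids)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model,
            "fragment_ids": list(self.fragment_ids),
            "atom_indices": list(self.atom_indices),
            "criteria": self.criteria,
            "counts": {"fragments": self.n_fragments, "atoms": self.n_atoms},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RegionDefinition":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        return cls(
            model=data["model"],
            fragment_ids=tuple(data["fragment_ids"]),
            atom_indices=tuple(data["atom_indices"]),
            criteria=data["criteria"],
        )


def _finalize(fragmap: FragmentMap, ids: set[int], model: str, criteria: dict) -> RegionDefinition:
    ids = set(ids) | set(fragmap.guest_ids())
    atoms = [i for fid in ids for i in fragmap.by_id(fid).atom_indices]
    return RegionDefinition(
        model=model, fragment_ids=tuple(ids), atom_indices=tuple(atoms),
        criteria=criteria,
    )


def select_region_empirical(
    fragmap: FragmentMap, fragment_ids: list[int]
) -> RegionDefinition:
    """Guest plus an explicit fragment list (set semantics)."""
    known = set(fragmap.ids)
    bad = sorted(set(int(i) for i in fragment_ids) - known)
    if bad:
        raise KeyError(f"unknown fragment ids {bad}")
    return _finalize(
        fragmap, set(int(i) for i in fragment_ids), "empirical",
        {"explicit_ids": sorted(set(int(i) for i in fragment_ids))},
    )


def select_region_short_range(
    fragmap: FragmentMap,
    rmin: dict[int, float],
    guest_pairs: list[PairInteraction] | None = None,
    r_cut: float = 5.0,
    e_thresh: float = 2.0,
    intersect: bool = False,
) -> RegionDefinition:
    """Distance/interaction-energy selection.

    Selects fragments with R_min <= ``r_cut`` union (default) or intersect
    fragments whose guest-pair interaction magnitude exceeds ``e_thresh``
    kcal/mol.  Without pair data the energy arm is skipped with a warning.
    """
    missing = [f.id for f in fragmap if f.id not in rmin]
    if missing:
        raise ValueError(f"R_min map missing fragments: {missing}")
    guests = set(fragmap.guest_ids())
    near = {f.id for f in fragmap if f.id not in guests and rmin[f.id] <= r_cut}
    if guest_pairs is None:
        warnings.warn("no guest pair energies; distance-only selection")
        chosen = near
    else:
        strong = set()
        for p in guest_pairs:
            if p.i in guests and p.j not in guests and abs(p.total) > e_thresh:
                strong.add(p.j)
            elif p.j in guests and p.i not in guests and abs(p.total) > e_thresh:
                strong.add(p.i)
        chosen = (near & strong) if intersect else (near | strong)
    return _finalize(
        fragmap, chosen, "short_range",
        {
            "r_cut_A": r_cut,
            "e_thresh_kcal": e_thresh,
            "combine": "intersect" if intersect else "union",
            "has_pair_energies": guest_pairs is not None,
        },
    )


def select_region_mo_based(
    fragmap: FragmentMap, rmin: dict[int, float], r_conv: float
) -> RegionDefinition:
    """Guest plus every fragment with R_min <= R_conv (inclusive boundary)."""
    if r_conv < 0:
        raise ValueError("r_conv must be non-negative")
    missing = [f.id for f in fragmap if f.id not in rmin]
    if missing:
        raise ValueError(f"R_min map missing fragments: {missing}")
    chosen = {f.id for f in fragmap if rmin[f.id] <= r_conv}
    return _finalize(fragmap, chosen, "mo_based", {"r_conv_A": r_conv})


def select_region_whole(fragmap: FragmentMap) -> RegionDefinition:
    """All fragments: the all-QM reference region."""
    return _finalize(fragmap, set(fragmap.ids), "whole", {})


def emit_region(
    region: RegionDefinition,
    structure: Structure,
    out: Path | str,
    format: str = "json",
) -> Path:
    """Write a region as a 0-based atom index list, a PDB subset, or JSON."""
    out = Path(out)
    if region.atom_indices and max(region.atom_indices) >= structure.n_atoms:
        raise ValueError("region refers to atoms outside the structure")
    if format == "atomlist":
        lines = ["# qmregion atom list (0-based structure indices)"]
        lines += [str(i) for i in region.atom_indices]
        out.write_text("\n".join(lines) + "\n")
    elif format == "pdb_subset":
        write_structure(structure.subset(region.atom_indices), out, format="pdb")
    elif format == "json":
        region.to_json(out)
    else:
        raise ValueError(f"unknown region format {format!r}")
    return out
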