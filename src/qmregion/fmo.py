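"""Fragment molecular orbital (FMO) layer over the tight-binding engine.

FMO1: every QM fragment is solved by :func:`qmregion.tbengine.scc_solve`
embedded in the point charges of all other fragments (QM fragments
contribute their current self-consistent Mulliken charges, MM fragments a
fixed charge set), and the monomer sweep is repeated until the global
fragment-charge vector is self-consistent.

FMO2: close QM fragment pairs are re-solved as dimers in the remaining
embedding; the pair interaction is decomposed PIEDA-style into
electrostatics (ES, Klopman-Ohno kernel over frozen monomer charges),
exchange repulsion (EX, Born-Mayer sum), dispersion (DI, damped -C6/r^6)
and a charge-transfer remainder (CT = dimer interaction - ES - EX - DI,
which therefore also absorbs mutual polarization).  Pairs beyond the dimer
cutoff keep the electrostatic term only (``es_approx``).

Energies are assembled from *internal* monomer/dimer energies (embedding
interaction stripped), the standard FMO bookkeeping that avoids double
counting the embedding electrostatics; with one fragment, or two fragments
and their dimer, the assembly telescopes to the exact whole-system energy.
Interface units are kcal/mol; everything internal is eV.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .structio import FragmentMap, FragmentMapError, Structure, pair_min_distances
from .tbengine import (
    EV_TO_KCAL,
    ElectronicState,
    ExternalCharges,
    ToyParams,
    frontier_properties,
    pair_repulsion_dispersion,
    scc_solve,
)

__all__ = [
    "PartitionSpec",
    "FMO1Result",
    "PairInteraction",
    "fmo1",
    "fmo2",
    "system_energy",
    "binding_energy",
    "guest_ip_ea",
    "pieda_aggregate",
]


@dataclass
class PartitionSpec:
    """QM/MM split at fragment granularity.

    ``mm_charge_source``: ``frozen_reference`` takes MM atomic charges from
    an all-QM FMO1 run of the host subsystem alone (computed on demand, or
    supplied via ``frozen_charges`` keyed by atom index); ``formal`` spreads
    each MM fragment's formal charge uniformly over its atoms.
    """

    qm_fragment_ids: frozenset[int]
    mm_fragment_ids: frozenset[int]
    mm_charge_source: str = "frozen_reference"
    frozen_charges: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.qm_fragment_ids = frozenset(int(i) for i in self.qm_fragment_ids)
        self.mm_fragment_ids = frozenset(int(i) for i in self.mm_fragment_ids)
        if self.qm_fragment_ids & self.mm_fragment_ids:
            raise FragmentMapError("QM and MM fragment sets overlap")
        if self.mm_charge_source not in ("frozen_reference", "formal"):
            raise ValueError(f"unknown mm_charge_source {self.mm_charge_source!r}")

    @classmethod
    def all_qm(cls, fragmap: FragmentMap) -> "PartitionSpec":
        return cls(frozenset(fragmap.ids), frozenset())

    def validate(self, fragmap: FragmentMap) -> None:
        ids = set(fragmap.ids)
        if self.qm_fragment_ids | self.mm_fragment_ids != ids:
            raise FragmentMapError(
                "partition does not cover the fragment set exactly"
            )
        for g in fragmap.guest_ids():
            if g not in self.qm_fragment_ids:
                raise FragmentMapError(
                    f"guest fragment {g} must belong to the QM set"
                )


@dataclass
class FMO1Result:
    structure: Structure
    fragmap: FragmentMap
    params: ToyParams
    partition: PartitionSpec
    states: dict[int, ElectronicState]        # QM fragments only
    frontier: dict[int, dict[str, float]]     # per QM fragment
    atomic_charges: np.ndarray                # full structure, e
    outer_iterations: int
    converged: bool
    run_id: str

    def fragment_charge(self, fid: int) -> float:
        idx = list(self.fragmap.by_id(fid).atom_indices)
        return float(self.atomic_charges[idx].sum())


@dataclass
class PairInteraction:
    """Decomposed fragment-pair interaction, kcal/mol, ordered i < j.

    ``charge_shift`` is the Mulliken charge gained by fragment ``i`` in the
    dimer relative to its frozen monomer (e); positive means ``i`` lost
    electron density to ``j``.
    """

    i: int
    j: int
    r_min: float
    es: float
    ex: float
    ct: float
    di: float
    method: str            # dimer | es_approx
    charge_shift: float = 0.0
    dimer_converged: bool = True
    run_id: str = ""

    @property
    def total(self) -> float:
        return self.es + self.ex + self.ct + self.di


def _run_id(structure: Structure, fragmap: FragmentMap, partition: PartitionSpec) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(structure.coords).tobytes())
    h.update("".join(structure.elements).encode())
    h.update(fragmap.to_json().encode())
    h.update(repr(sorted(partition.qm_fragment_ids)).encode())
    h.update(repr(sorted(partition.mm_fragment_ids)).encode())
    return h.hexdigest()[:16]


def _mm_atomic_charges(
    structure: Structure,
    fragmap: FragmentMap,
    params: ToyParams,
    partition: PartitionSpec,
    outer_tol: float,
    outer_maxiter: int,
    outer_mixing: float,
) -> dict[int, float]:
    """Fixed charges for all MM atoms, keyed by structure atom index."""
    mm_frags = [fragmap.by_id(i) for i in sorted(partition.mm_fragment_ids)]
    if not mm_frags:
        return {}
    if partition.frozen_charges is not None:
        return {
            i: partition.frozen_charges[i]
            for f in mm_frags
            for i in f.atom_indices
        }
    if partition.mm_charge_source == "formal":
        out = {}
        for f in mm_frags:
            per_atom = f.formal_charge / len(f.atom_indices)
            for i in f.atom_indices:
                out[i] = per_atom
        return out
    # frozen_reference: all-QM FMO1 on the host subsystem (all non-guest
    # fragments), mapped back to complex-frame atom indices.
    from .structio import strip_guest

    host, host_map, kept = strip_guest(structure, fragmap)
    ref = fmo1(
        host,
        host_map,
        params,
        PartitionSpec.all_qm(host_map),
        outer_tol=outer_tol,
        outer_maxiter=outer_maxiter,
        outer_mixing=outer_mixing,
    )
    old_to_new = {old: new for new, old in enumerate(kept)}
    return {
        i: float(ref.atomic_charges[old_to_new[i]])
        for f in mm_frags
        for i in f.atom_indices
    }


def fmo1(
    structure: Structure,
    fragmap: FragmentMap,
    params: ToyParams,
    partition: PartitionSpec | None = None,
    outer_tol: float = 1e-6,
    outer_maxiter: int = 100,
    outer_mixing: float = 0.5,
) -> FMO1Result:
    """Self-consistent embedded-monomer (FMO1) calculation.

    Fragments are swept in ascending id order (Gauss-Seidel: each monomer
    immediately sees the charges just computed), with linear damping of the
    charge update between sweeps.  Raises if the sweep-to-sweep charge
    change grows for 10 consecutive sweeps.
    """
    fragmap.validate(structure)
    if partition is None:
        partition = PartitionSpec.all_qm(fragmap)
    partition.validate(fragmap)

    qm_ids = sorted(partition.qm_fragment_ids)
    charges = np.zeros(structure.n_atoms)
    for f in fragmap:
        per_atom = f.formal_charge / len(f.atom_indices)
        for i in f.atom_indices:
            charges[i] = per_atom
    mm_fixed = _mm_atomic_charges(
        structure, fragmap, params, partition, outer_tol, outer_maxiter, outer_mixing
    )
    for i, q in mm_fixed.items():
        charges[i] = q

    hardness = np.array(
        [params.element(a.element).hubbard_u for a in structure.atoms]
    )
    frag_idx = {fid: list(fragmap.by_id(fid).atom_indices) for fid in qm_ids}

    states: dict[int, ElectronicState] = {}
    converged = not qm_ids
    prev_delta = np.inf
    prev_out: np.ndarray | None = None
    growth = 0
    sweep = 0
    for sweep in range(1, outer_maxiter + 1 if qm_ids else 1):
        out = charges.copy()
        for fid in qm_ids:
            idx = frag_idx[fid]
            other = np.ones(structure.n_atoms, bool)
            other[idx] = False
            ext = ExternalCharges(
                positions=structure.coords[other],
                charges=charges[other],
                hardness=hardness[other],
            )
            frag = fragmap.by_id(fid)
            state = scc_solve(
                structure,
                params,
                atom_indices=idx,
                external=ext if other.any() else None,
                net_charge=frag.formal_charge,
                initial_charges=charges[idx],
            )
            states[fid] = state
            out[idx] = state.atomic_charges
            charges[idx] = charges[idx] + outer_mixing * (
                state.atomic_charges - charges[idx]
            )
        # Self-consistency is judged on the raw monomer outputs of
        # successive sweeps; the damped charges only build the embedding.
        delta = (
            float(np.max(np.abs(out - prev_out)))
            if prev_out is not None
            else np.inf
        )
        prev_out = out
        if delta < outer_tol:
            converged = True
            charges = out
            break
        if delta > prev_delta:
            growth += 1
            if growth >= 10:
                raise RuntimeError(
                    "FMO1 outer loop diverging (charge change grew for 10 "
                    "consecutive sweeps); reduce outer_mixing for stronger "
                    "damping"
                )
        else:
            growth = 0
        prev_delta = delta
    if not converged and qm_ids:
        warnings.warn(
            f"FMO1 outer loop not converged in {outer_maxiter} sweeps"
        )

    # Final consistent monomer states in the converged field.
    for fid in qm_ids:
        idx = frag_idx[fid]
        other = np.ones(structure.n_atoms, bool)
        other[idx] = False
        ext = ExternalCharges(
            positions=structure.coords[other],
            charges=charges[other],
            hardness=hardness[other],
        )
        states[fid] = scc_solve(
            structure,
            params,
            atom_indices=idx,
            external=ext if other.any() else None,
            net_charge=fragmap.by_id(fid).formal_charge,
            initial_charges=charges[idx],
        )
        charges[idx] = states[fid].atomic_charges

    frontier = {}
    for fid in qm_ids:
        try:
            frontier[fid] = frontier_properties(states[fid])
        except ValueError:
            frontier[fid] = {}
    return FMO1Result(
        structure=structure,
        fragmap=fragmap,
        params=params,
        partition=partition,
        states=states,
        frontier=frontier,
        atomic_charges=charges,
        outer_iterations=sweep,
        converged=converged,
        run_id=_run_id(structure, fragmap, partition),
    )


def _gamma_cross(
    elements_i, coords_i, elements_j, coords_j, params: ToyParams
) -> np.ndarray:
    ui = np.array([params.element(e).hubbard_u for e in elements_i])
    uj = np.array([params.element(e).hubbard_u for e in elements_j])
    r = np.linalg.norm(coords_i[:, None, :] - coords_j[None, :, :], axis=-1)
    u_avg = 0.5 * (ui[:, None] + uj[None, :])
    gamma = np.zeros_like(r)
    mask = u_avg > 0
    gamma[mask] = params.k_e / np.sqrt(
        r[mask] ** 2 + (params.k_e / u_avg[mask]) ** 2
    )
    return gamma


def fmo2(
    result: FMO1Result,
    dimer_cutoff: float = 6.0,
) -> list[PairInteraction]:
    """Pairwise interactions for every unordered fragment pair.

    QM-QM pairs with pair R_min <= ``dimer_cutoff`` are solved as embedded
    dimers and fully decomposed; all other pairs (distant QM-QM, QM-MM,
    MM-MM) carry the electrostatic term only.
    """
    if not result.converged:
        warnings.warn("FMO2 requested on an unconverged FMO1 result")
    s, fm, params = result.structure, result.fragmap, result.params
    charges = result.atomic_charges
    hardness = np.array([params.element(a.element).hubbard_u for a in s.atoms])
    rmins = pair_min_distances(s, fm)
    qm = result.partition.qm_fragment_ids
    ids = sorted(fm.ids)
    pairs: list[PairInteraction] = []
    for a, fi in enumerate(ids):
        for fj in ids[a + 1 :]:
            rmin = rmins[(fi, fj)]
            idx_i = list(fm.by_id(fi).atom_indices)
            idx_j = list(fm.by_id(fj).atom_indices)
            el_i = [s.atoms[k].element for k in idx_i]
            el_j = [s.atoms[k].element for k in idx_j]
            gamma = _gamma_cross(
                el_i, s.coords[idx_i], el_j, s.coords[idx_j], params
            )
            es = float(charges[idx_i] @ gamma @ charges[idx_j]) * EV_TO_KCAL
            if fi in qm and fj in qm and rmin <= dimer_cutoff:
                pair = _dimer_interaction(
                    result, fi, fj, idx_i, idx_j, el_i, el_j, es, rmin, hardness
                )
            else:
                pair = PairInteraction(
                    i=fi, j=fj, r_min=rmin, es=es, ex=0.0, ct=0.0, di=0.0,
                    method="es_approx", run_id=result.run_id,
                )
            pairs.append(pair)
    return pairs


def _dimer_interaction(
    result: FMO1Result, fi, fj, idx_i, idx_j, el_i, el_j, es, rmin, hardness
) -> PairInteraction:
    s, fm, params = result.structure, result.fragmap, result.params
    charges = result.atomic_charges
    idx = sorted(idx_i + idx_j)
    other = np.ones(s.n_atoms, bool)
    other[idx] = False
    ext = ExternalCharges(
        positions=s.coords[other],
        charges=charges[other],
        hardness=hardness[other],
    )
    net = fm.by_id(fi).formal_charge + fm.by_id(fj).formal_charge
    # Cold start (uniform charges): a dimer warm-started from its frozen
    # monomers can settle on a different integer-occupation branch than a
    # direct solve of the same atoms would, which would spoil the exact
    # two-fragment whole-system identity.
    dimer = scc_solve(
        s,
        params,
        atom_indices=idx,
        external=ext if other.any() else None,
        net_charge=net,
    )
    if not dimer.converged:
        warnings.warn(
            f"dimer ({fi},{fj}) SCC not converged; falling back to es_approx"
        )
        return PairInteraction(
            i=fi, j=fj, r_min=rmin, es=es, ex=0.0, ct=0.0, di=0.0,
            method="es_approx", dimer_converged=False, run_id=result.run_id,
        )
    de_int = (
        dimer.internal_energy
        - result.states[fi].internal_energy
        - result.states[fj].internal_energy
    ) * EV_TO_KCAL
    ex, di = pair_repulsion_dispersion(
        el_i, s.coords[idx_i], el_j, s.coords[idx_j], params
    )
    ex *= EV_TO_KCAL
    di *= EV_TO_KCAL
    ct = de_int - es - ex - di
    pos_in_dimer = {k: n for n, k in enumerate(idx)}
    dq_i = float(
        sum(dimer.atomic_charges[pos_in_dimer[k]] - charges[k] for k in idx_i)
    )
    return PairInteraction(
        i=fi, j=fj, r_min=rmin, es=es, ex=ex, ct=ct, di=di,
        method="dimer", charge_shift=dq_i, run_id=result.run_id,
    )


def system_energy(result: FMO1Result, pairs: list[PairInteraction]) -> float:
    """FMO2 total energy (kcal/mol): internal monomer energies plus pair
    corrections (full dimer interaction or far-pair electrostatics)."""
    for p in pairs:
        if p.run_id and p.run_id != result.run_id:
            raise ValueError("pair list does not belong to this FMO1 run")
    mono = sum(
        result.states[fid].internal_energy
        for fid in sorted(result.partition.qm_fragment_ids)
    ) * EV_TO_KCAL
    return mono + sum(p.total for p in pairs)


def _evaluate(structure, fragmap, partition, params, dimer_cutoff, fmo1_kwargs):
    res = fmo1(structure, fragmap, params, partition, **fmo1_kwargs)
    pairs = fmo2(res, dimer_cutoff=dimer_cutoff)
    return res, pairs, system_energy(res, pairs)


def binding_energy(
    complex_run: tuple[Structure, FragmentMap, PartitionSpec],
    host_run: tuple[Structure, FragmentMap, PartitionSpec],
    guest_run: tuple[Structure, FragmentMap],
    params: ToyParams,
    dimer_cutoff: float = 6.0,
    **fmo1_kwargs,
) -> float:
    """E_bind = E(complex) - E(host) - E(guest), kcal/mol, fixed geometry.

    The guest subsystem is always treated all-QM; guest atoms must match
    (element sequence) between the complex's guest fragments and the guest
    run.
    """
    cs, cm, cp = complex_run
    hs, hm, hp = host_run
    gs, gm = guest_run
    guest_elements = [
        cs.atoms[i].element
        for g in cm.guest_ids()
        for i in cm.by_id(g).atom_indices
    ]
    if sorted(guest_elements) != sorted(gs.elements):
        raise FragmentMapError(
            "guest atoms differ between complex and guest runs"
        )
    _, _, e_complex = _evaluate(cs, cm, cp, params, dimer_cutoff, fmo1_kwargs)
    _, _, e_host = _evaluate(hs, hm, hp, params, dimer_cutoff, fmo1_kwargs)
    _, _, e_guest = _evaluate(
        gs, gm, PartitionSpec.all_qm(gm), params, dimer_cutoff, fmo1_kwargs
    )
    return e_complex - e_host - e_guest


def guest_ip_ea(result: FMO1Result, guest_id: int) -> tuple[float, float]:
    """Koopmans IP and EA (eV) of the guest's embedded monomer state."""
    if guest_id not in result.partition.qm_fragment_ids:
        raise FragmentMapError("guest fragment is not in the QM set")
    props = frontier_properties(result.states[guest_id])
    return props["ip"], props["ea"]


def pieda_aggregate(pairs: list[PairInteraction], guest_id: int) -> dict[str, float]:
    """Summed ES/EX/CT/DI (kcal/mol) over all pairs containing the guest."""
    out = {"es": 0.0, "ex": 0.0, "ct": 0.0, "di": 0.0, "total": 0.0}
    for p in pairs:
        if guest_id in (p.i, p.j):
            out["es"] += p.es
            out["ex"] += p.ex
            out["ct"] += p.ct
            out["di"] += p.di
            out["total"] += p.total
    return out
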