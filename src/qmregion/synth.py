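"""Seeded synthetic inputs with planted ground truth.

Three generators cover every input class the pipeline consumes:

* :func:`gen_decay_profile` - shift profiles with a planted exponential
  decay |delta_eps| = A exp(-R/lam) plus Gaussian noise, whose analytic
  threshold crossover lam*ln(A/delta) is the truth for the convergence
  radius detector;
* :func:`gen_hub_network` - charge-flow graphs with planted hub-and-spoke
  motifs (and optional triplet-free noise edges) for the hub detector;
* :func:`gen_host_guest` - toy host-guest complexes: concentric shells of
  small bonded clusters around a central cationic guest, parameterized for
  the shipped tight-binding table, with known shell geometry.

Every generator is a pure function of its parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .descriptors import PROFILE_COLUMNS, ShiftProfile
from .network import FlowGraph
from .structio import Atom, Fragment, FragmentMap, Structure

__all__ = [
    "SynthTruth",
    "gen_decay_profile",
    "gen_hub_network",
    "gen_host_guest",
    "gen_cluster_assembly",
    "decay_crossover",
]


@dataclass
class SynthTruth:
    kind: str            # decay | hubs | complex
    seed: int
    params: dict
    derived: dict


def decay_crossover(A: float, lam: float, delta: float) -> float:
    """Radius where the noiseless planted decay crosses the threshold."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    return lam * float(np.log(A / delta)) if A > delta else 0.0


def gen_decay_profile(
    A: float = 0.5,
    lam: float = 2.0,
    sigma: float = 0.0,
    n: int = 200,
    r_max: float = 25.0,
    seed: int = 0,
) -> tuple[ShiftProfile, SynthTruth]:
    """Planted-decay shift profile.

    R_i ~ Uniform(0, r_max]; delta_eps_i = s_i * A * exp(-R_i/lam) + eta_i
    with random signs s_i and eta ~ Normal(0, sigma^2).  The default extent
    of 25 Å matches the span of host-fragment R_min values in protein- or
    framework-sized systems.
    """
    if A <= 0 or lam <= 0 or r_max <= 0:
        raise ValueError("A, lam and r_max must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n < 2:
        raise ValueError("need at least 2 rows")
    rng = np.random.default_rng(seed)
    r = r_max * (1.0 - rng.random(n))           # uniform on (0, r_max]
    signs = rng.choice([-1.0, 1.0], size=n)
    noise = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    d_eps = signs * A * np.exp(-r / lam) + noise
    gap0 = 2.0                                  # flat apo baseline, eV
    table = pd.DataFrame(
        {
            "fragment_id": np.arange(n),
            "name": [f"F{i}" for i in range(n)],
            "rmin_A": r,
            "gap_apo_eV": gap0,
            "gap_holo_eV": gap0 + d_eps,
            "delta_eps_eV": d_eps,
            "q_apo_e": 0.0,
            "q_holo_e": 0.0,
            "delta_q_e": 0.0,
        },
        columns=PROFILE_COLUMNS,
    )
    truth = SynthTruth(
        kind="decay",
        seed=seed,
        params={"A": A, "lam": lam, "sigma": sigma, "n": n, "r_max": r_max},
        derived={"crossover": lambda delta: decay_crossover(A, lam, delta)},
    )
    return ShiftProfile(table, provenance="synthetic", truth=truth.params), truth


def gen_hub_network(
    n_nodes: int = 40,
    hubs: list[tuple[int, list[int]]] | None = None,
    noise_edges: int = 0,
    threshold: float = 0.005,
    seed: int = 0,
) -> tuple[FlowGraph, SynthTruth]:
    """Planted hub-and-spoke flow graph.

    ``hubs`` is a list of (hub node, spoke nodes); hub-spoke edges carry
    super-threshold weights and spoke-spoke edges are never drawn, so each
    hub mediates exactly its spoke pairs.  Noise edges are a random matching
    over leftover nodes (degree <= 1), which cannot create mediation
    triplets.  Raises when more noise edges are requested than the leftover
    nodes can host.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rng = np.random.default_rng(seed)
    hubs = hubs if hubs is not None else []
    used: set[int] = set()
    for hub, spokes in hubs:
        members = {int(hub), *(int(s) for s in spokes)}
        if len(members) != 1 + len(spokes):
            raise ValueError(f"hub {hub}: hub/spoke ids must be distinct")
        if members & used:
            raise ValueError(f"hub {hub}: node reused across motifs")
        if any(not 0 <= m < n_nodes for m in members):
            raise ValueError(f"hub {hub}: node id out of range")
        used |= members

    g = nx.DiGraph()
    for i in range(n_nodes):
        g.add_node(i, name=f"F{i}", rmin=float("nan"), delta_q=0.0)
    for hub, spokes in hubs:
        for s in spokes:
            w = float(threshold * rng.uniform(2.0, 10.0))
            src, dst = (hub, s) if rng.random() < 0.5 else (s, hub)
            g.add_edge(int(src), int(dst), weight=w, derived_from="dimer")

    free = sorted(set(range(n_nodes)) - used)
    if noise_edges > len(free) // 2:
        raise ValueError(
            f"cannot place {noise_edges} noise edges on {len(free)} free nodes "
            "without creating mediation triplets"
        )
    perm = rng.permutation(free)
    for k in range(noise_edges):
        a, b = int(perm[2 * k]), int(perm[2 * k + 1])
        w = float(threshold * rng.uniform(2.0, 10.0))
        g.add_edge(a, b, weight=w, derived_from="dimer")

    truth = SynthTruth(
        kind="hubs",
        seed=seed,
        params={
            "n_nodes": n_nodes,
            "noise_edges": noise_edges,
            "threshold": threshold,
        },
        derived={"hub_ids": sorted(int(h) for h, _ in hubs)},
    )
    return FlowGraph(graph=g, threshold=threshold, metadata={"edge_source": "synthetic"}), truth


# ---------------------------------------------------------------------------
# Cluster assemblies (engine-exactness fixtures)
# ---------------------------------------------------------------------------

#: Closed-shell 4-atom compositions whose isolated clusters keep a
#: HOMO-LUMO gap >= 1.8 eV under the shipped parameter table, so that
#: assemblies of identical copies stay comfortably gapped and the SCC
#: cycle has an integer-occupation fixed point.
_ASSEMBLY_COMPOSITIONS = (
    ("H", "N", "O", "O"),
    ("N", "O", "O", "Si"),
    ("H", "C", "O", "O"),
    ("H", "H", "O", "O"),
    ("O", "O", "Si", "Si"),
)


def gen_cluster_assembly(
    n_fragments: int = 3,
    seed: int = 0,
    box: float = 5.0,
    min_center_distance: float = 4.0,
    jitter: float = 0.05,
) -> tuple[Structure, FragmentMap]:
    """Randomized assembly of identical bonded 4-atom clusters.

    One composition (drawn from a closed-shell, well-gapped palette) is
    replicated at ``n_fragments`` random non-overlapping sites; every
    fragment is a randomly oriented tetrahedral cluster.  The first
    fragment is labelled guest so the assembly doubles as a minimal
    host-guest system.  Neutral overall, even electron count per fragment.
    """
    if n_fragments < 1:
        raise ValueError("need at least one fragment")
    rng = np.random.default_rng(seed)
    comp = _ASSEMBLY_COMPOSITIONS[rng.integers(0, len(_ASSEMBLY_COMPOSITIONS))]
    centers: list[np.ndarray] = []
    while len(centers) < n_fragments:
        c = rng.uniform(-box, box, 3)
        if all(np.linalg.norm(c - o) > min_center_distance for o in centers):
            centers.append(c)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    frags: list[Fragment] = []
    for f, c in enumerate(centers):
        local = _TETRA @ _random_rotation(rng).T
        start = len(atoms)
        for a in range(4):
            atoms.append(Atom(element=comp[a], resname="CLU", resseq=f + 1, serial=len(atoms) + 1))
            coords.append(c + local[a] + rng.normal(0.0, jitter, 3))
        frags.append(
            Fragment(
                id=f,
                name=f"CLU{f}",
                atom_indices=tuple(range(start, start + 4)),
                role="guest" if f == 0 else "host",
            )
        )
    s = Structure(
        atoms=atoms, coords=np.array(coords),
        title=f"synthetic cluster assembly seed={seed}",
    )
    return s, FragmentMap(frags)


# ---------------------------------------------------------------------------
# Toy host-guest complexes
# ---------------------------------------------------------------------------

def _fibonacci_sphere(m: int) -> np.ndarray:
    """m quasi-uniform unit vectors (golden-spiral construction)."""
    i = np.arange(m) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / m
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


_TETRA = 0.98 * np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


def gen_host_guest(
    n_shell_atoms: int = 36,
    cavity_radius: float = 4.5,
    guest_atoms: int = 4,
    palette: tuple[tuple[str, ...], tuple[str, ...]] | None = None,
    seed: int = 0,
    shell_offsets: tuple[float, ...] = (0.0, 2.5, 5.0),
    fragment_size: int = 4,
    guest_radius: float = 1.0,
    guest_charge: int = 0,
    guest_offset: float = 1.0,
    jitter: float = 0.05,
) -> tuple[Structure, Structure, FragmentMap, SynthTruth]:
    """Toy host-guest complex: clustered shells around a central cation.

    The host is built from ``fragment_size``-atom bonded clusters placed at
    quasi-uniform sites on concentric shells of radius cavity_radius +
    offset; the guest is a small cluster (one central atom, the rest on a
    sphere of ``guest_radius``) carrying ``guest_charge``, displaced from
    the cavity center by ``guest_offset`` in a seeded random direction so
    that it binds to one side of the pocket, as real ligands do.  The
    default palette is a framework-like Si/O host with a polar O/H guest:
    neutral but with a strong internal dipole, like the hydrogen-bonding
    inhibitor ligands such protocols target (a net-charged guest is one
    parameter away, at the price of an open-shell host band).  Returns
    (host structure, complex structure, fragment map, truth); the host
    structure is the complex with the guest removed, so atom indices
    correspond.
    """
    if n_shell_atoms < 1 or guest_atoms < 1 or fragment_size < 1:
        raise ValueError("counts must be >= 1")
    if cavity_radius - guest_radius - guest_offset < 1.5:
        raise ValueError(
            "cavity too small for the guest (need >= 1.5 Å host-guest clearance)"
        )
    host_pal, guest_pal = palette if palette is not None else (
        ("Si", "O"), ("O", "H")
    )
    rng = np.random.default_rng(seed)

    n_sites = max(1, n_shell_atoms // fragment_size)
    n_shells = len(shell_offsets)
    per_shell = [
        n_sites // n_shells + (1 if k < n_sites % n_shells else 0)
        for k in range(n_shells)
    ]
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    fragments: list[Fragment] = []
    fid = 1
    ei = 0
    for k, (off, m) in enumerate(zip(shell_offsets, per_shell)):
        if m == 0:
            continue
        radius = cavity_radius + off
        sites = _fibonacci_sphere(m) @ _random_rotation(rng).T
        for s_idx in range(m):
            center = radius * sites[s_idx]
            if fragment_size == 1:
                local = np.zeros((1, 3))
            else:
                base = _TETRA[:fragment_size] if fragment_size <= 4 else np.vstack(
                    [_TETRA, 1.6 * _fibonacci_sphere(fragment_size - 4)]
                )
                local = base @ _random_rotation(rng).T
            start = len(atoms)
            for a_idx in range(fragment_size):
                sym = host_pal[ei % len(host_pal)]
                ei += 1
                pos = center + local[a_idx] + rng.normal(0.0, jitter, 3)
                atoms.append(Atom(element=sym, resname="HST", resseq=fid, serial=len(atoms) + 1))
                coords.append(pos)
            fragments.append(
                Fragment(
                    id=fid,
                    name=f"S{k}F{s_idx}",
                    atom_indices=tuple(range(start, start + fragment_size)),
                    role="host",
                )
            )
            fid += 1

    g_start = len(atoms)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    g_center = guest_offset * direction
    g_local = [np.zeros(3)]
    if guest_atoms > 1:
        shellpts = guest_radius * _fibonacci_sphere(guest_atoms - 1)
        g_local += [p for p in (shellpts @ _random_rotation(rng).T)]
    for a_idx in range(guest_atoms):
        sym = guest_pal[a_idx % len(guest_pal)]
        atoms.append(Atom(element=sym, resname="GST", resseq=999, serial=len(atoms) + 1, hetatm=True))
        coords.append(g_center + g_local[a_idx] + rng.normal(0.0, jitter, 3))
    fragments.append(
        Fragment(
            id=0,
            name="GUEST",
            atom_indices=tuple(range(g_start, g_start + guest_atoms)),
            role="guest",
            formal_charge=guest_charge,
        )
    )

    cplx = Structure(
        atoms=atoms,
        coords=np.array(coords),
        title=f"synthetic host-guest seed={seed}",
        net_charge=guest_charge,
    )
    fragmap = FragmentMap(sorted(fragments, key=lambda f: f.id))
    fragmap.validate(cplx)
    host = cplx.subset(range(g_start))
    host.net_charge = 0
    host.title = f"synthetic host seed={seed}"

    gxyz = cplx.coords[g_start:]
    hxyz = cplx.coords[:g_start]
    dmin = float(
        np.min(np.linalg.norm(hxyz[:, None, :] - gxyz[None, :, :], axis=-1))
    )
    truth = SynthTruth(
        kind="complex",
        seed=seed,
        params={
            "n_shell_atoms": n_shell_atoms,
            "cavity_radius": cavity_radius,
            "guest_atoms": guest_atoms,
            "shell_offsets": tuple(shell_offsets),
            "fragment_size": fragment_size,
            "guest_radius": guest_radius,
            "guest_charge": guest_charge,
            "guest_offset": guest_offset,
        },
        derived={
            "guest_fragment_id": 0,
            "min_host_guest_distance": dmin,
            "shell_radii": [cavity_radius + o for o in shell_offsets],
        },
    )
    return host, cplx, fragmap, truth
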