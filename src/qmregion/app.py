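"""End-to-end pipeline: descriptors -> radius -> regions -> comparison.

One call runs the whole protocol on a host-guest complex:

1. all-QM FMO1 on the guest-free host (apo) and on the complex (holo),
   plus FMO2 dimers on the complex;
2. the MO-shift profile (delta_eps, delta_q vs R_min) and its convergence
   radius R_conv;
3. the QM-region models (short-range, MO-based, optional empirical, whole);
4. per-region observables (binding energy, guest IP/EA, guest PIEDA sums)
   with the environment as frozen point charges from the apo reference;
5. the charge-flow network and hub report;
6. deviation tables of every model against the all-QM reference.

The file-based entry point reads structures/configs from disk and writes a
reproducible output bundle (TSV/JSON plus a checksummed manifest).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bench, descriptors, network, regions
from .fmo import (
    FMO1Result,
    PartitionSpec,
    fmo1,
    fmo2,
    guest_ip_ea,
    pieda_aggregate,
    system_energy,
)
from .structio import (
    Fragment,
    FragmentMap,
    Structure,
    build_fragment_map,
    min_distance_profile,
    read_structure,
    strip_guest,
)
from .tbengine import ToyParams, default_params

__all__ = ["PipelineConfig", "ProtocolReport", "run_protocol", "run_protocol_files"]


@dataclass
class PipelineConfig:
    complex_path: str = ""
    host_path: str = ""                  # optional consistency check only
    fragmap_path: str = ""               # else by-residue with guest_selector
    guest_selector: str | int | None = None
    params_path: str = ""
    delta: float = 0.01                  # |delta_eps| threshold, eV
    dimer_cutoff: float = 6.0            # Å
    network_threshold: float = 0.005     # e
    region_modes: tuple[str, ...] = ("short_range", "mo_based", "whole")
    empirical_ids: tuple[int, ...] = ()
    seed: int = 0
    outdir: str = "qmregion_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not self.region_modes:
            raise ValueError("at least one region mode must be requested")
        for p in (self.complex_path, self.fragmap_path, self.params_path):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class ProtocolReport:
    profile: descriptors.ShiftProfile
    rconv: descriptors.ConvergenceResult
    region_defs: dict[str, regions.RegionDefinition]
    observables: dict[str, dict[str, float]]   # model -> {E_bind, IP, EA, ...}
    comparison: bench.DeviationTable
    flow: network.FlowGraph
    hubs: network.HubReport
    apo: FMO1Result
    holo: FMO1Result
    pairs: list

    def observable_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.observables).T


def _evaluate_region(
    cplx: Structure,
    fragmap: FragmentMap,
    region: regions.RegionDefinition,
    params: ToyParams,
    apo: FMO1Result,
    kept: list[int],
    e_guest: float,
    dimer_cutoff: float,
) -> dict[str, float]:
    """Binding energy, guest IP/EA and guest PIEDA sums under one region."""
    guest_ids = set(fragmap.guest_ids())
    qm = set(region.fragment_ids) | guest_ids
    mm = set(fragmap.ids) - qm
    frozen_cplx = {
        kept[i_host]: float(apo.atomic_charges[i_host])
        for i_host in range(len(kept))
    }
    part_c = PartitionSpec(frozenset(qm), frozenset(mm), frozen_charges=frozen_cplx)
    holo_r = fmo1(cplx, fragmap, params, part_c)
    pairs_r = fmo2(holo_r, dimer_cutoff=dimer_cutoff)
    e_complex = system_energy(holo_r, pairs_r)

    host_s, host_m, _ = strip_guest(cplx, fragmap)
    frozen_host = {i: float(apo.atomic_charges[i]) for i in range(host_s.n_atoms)}
    part_h = PartitionSpec(
        frozenset(qm - guest_ids),
        frozenset(mm),
        frozen_charges=frozen_host,
    )
    host_r = fmo1(host_s, host_m, params, part_h)
    e_host = system_energy(host_r, fmo2(host_r, dimer_cutoff=dimer_cutoff))

    gid = sorted(guest_ids)[0]
    ip, ea = guest_ip_ea(holo_r, gid)
    pieda = pieda_aggregate(pairs_r, gid)
    return {
        "E_bind": e_complex - e_host - e_guest,
        "IP": ip,
        "EA": ea,
        "pieda_es": pieda["es"],
        "pieda_ex": pieda["ex"],
        "pieda_ct": pieda["ct"],
        "pieda_di": pieda["di"],
    }


def run_protocol(
    cplx: Structure,
    fragmap: FragmentMap,
    params: ToyParams | None = None,
    delta: float = 0.01,
    dimer_cutoff: float = 6.0,
    network_threshold: float = 0.005,
    region_modes: tuple[str, ...] = ("short_range", "mo_based", "whole"),
    empirical_ids: tuple[int, ...] = (),
) -> ProtocolReport:
    """Run the full protocol on an in-memory complex."""
    params = params or default_params()
    fragmap.validate(cplx)
    if not fragmap.guest_ids():
        raise ValueError("protocol requires a guest fragment")

    host_s, host_m, kept = strip_guest(cplx, fragmap)
    apo = fmo1(host_s, host_m, params)
    holo = fmo1(cplx, fragmap, params)
    pairs = fmo2(holo, dimer_cutoff=dimer_cutoff)
    rmin = min_distance_profile(cplx, fragmap)

    profile = descriptors.mo_shift_profile(apo, holo, rmin)
    rconv = descriptors.convergence_radius(profile, delta=delta, mode="strict")

    gid = fragmap.guest_ids()[0]
    guest_struct = cplx.subset(fragmap.by_id(gid).atom_indices)
    guest_struct.net_charge = fragmap.by_id(gid).formal_charge
    guest_map = FragmentMap(
        [
            Fragment(
                id=gid,
                name=fragmap.by_id(gid).name,
                atom_indices=tuple(range(guest_struct.n_atoms)),
                role="guest",
                formal_charge=fragmap.by_id(gid).formal_charge,
            )
        ]
    )
    guest_run = fmo1(guest_struct, guest_map, params)
    e_guest = system_energy(guest_run, fmo2(guest_run, dimer_cutoff=dimer_cutoff))

    region_defs: dict[str, regions.RegionDefinition] = {}
    for mode in region_modes:
        if mode == "short_range":
            gpairs = [p for p in pairs if gid in (p.i, p.j)]
            region_defs[mode] = regions.select_region_short_range(
                fragmap, rmin, guest_pairs=gpairs
            )
        elif mode == "mo_based":
            region_defs[mode] = regions.select_region_mo_based(
                fragmap, rmin, rconv.r_conv
            )
        elif mode == "empirical":
            region_defs[mode] = regions.select_region_empirical(
                fragmap, list(empirical_ids)
            )
        elif mode == "whole":
            region_defs[mode] = regions.select_region_whole(fragmap)
        else:
            raise ValueError(f"unknown region mode {mode!r}")

    observables = {
        mode: _evaluate_region(
            cplx, fragmap, rd, params, apo, kept, e_guest, dimer_cutoff
        )
        for mode, rd in region_defs.items()
    }
    reference = "whole" if "whole" in observables else list(observables)[-1]
    comparison = bench.model_comparison(
        {m: dict(v) for m, v in observables.items()}, reference_model=reference,
        units="kcal/mol (E_bind, pieda_*), eV (IP, EA)",
    )

    flow = network.charge_flow_graph(
        apo, holo, pairs, rmin, threshold=network_threshold
    )
    hubs = network.detect_hubs(flow)
    return ProtocolReport(
        profile=profile,
        rconv=rconv,
        region_defs=region_defs,
        observables=observables,
        comparison=comparison,
        flow=flow,
        hubs=hubs,
        apo=apo,
        holo=holo,
        pairs=pairs,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_protocol_files(config: PipelineConfig) -> Path:
    """File-based protocol driver; returns the output directory.

    Reruns over the same inputs reproduce byte-identical TSV/JSON outputs;
    the manifest lists every file with its checksum.
    """
    config.validate()
    cplx = read_structure(config.complex_path)
    if config.fragmap_path:
        fragmap = FragmentMap.from_json(config.fragmap_path)
    else:
        fragmap = build_fragment_map(
            cplx, mode="by_residue", guest_selector=config.guest_selector
        )
    if config.host_path:
        host_given = read_structure(config.host_path)
        host_derived, _, _ = strip_guest(cplx, fragmap)
        if host_given.elements != host_derived.elements:
            raise ValueError(
                "host structure does not match the complex with its guest removed"
            )
    params = (
        ToyParams_from_file(config.params_path) if config.params_path else None
    )
    report = run_protocol(
        cplx,
        fragmap,
        params,
        delta=config.delta,
        dimer_cutoff=config.dimer_cutoff,
        network_threshold=config.network_threshold,
        region_modes=tuple(config.region_modes),
        empirical_ids=tuple(config.empirical_ids),
    )

    out = Path(config.outdir)
    (out / "regions").mkdir(parents=True, exist_ok=True)
    (out / "net").mkdir(parents=True, exist_ok=True)
    report.profile.to_tsv(out / "profile.tsv")
    (out / "rconv.json").write_text(
        json.dumps(
            {
                "r_conv_A": report.rconv.r_conv,
                "converged": report.rconv.converged,
                "delta_eV": report.rconv.delta,
                "mode": report.rconv.mode,
                "tail_max_eV": report.rconv.tail_max,
            },
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
    for mode, rd in report.region_defs.items():
        rd.to_json(out / "regions" / f"{mode}.json")
    report.flow.edge_table().to_csv(
        out / "net" / "edges.tsv", sep="\t", index=False, float_format="%.10g"
    )
    report.flow.node_table().to_csv(
        out / "net" / "nodes.tsv", sep="\t", index=False, float_format="%.10g"
    )
    report.hubs.ranking.to_csv(
        out / "net" / "hubs.tsv", sep="\t", index=False, float_format="%.10g"
    )
    report.comparison.to_tsv(out / "comparison.tsv")
    (out / "comparison.txt").write_text(report.comparison.to_text() + "\n")

    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "outputs": {f: _sha256(out / f) for f in files},
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return out


def ToyParams_from_file(path) -> ToyParams:
    """Load a parameter table from TOML or JSON."""
    import tomllib

    from .tbengine import ElementParams

    p = Path(path)
    if p.suffix == ".toml":
        data = tomllib.loads(p.read_text())
    else:
        data = json.loads(p.read_text())
    elements = {
        sym: ElementParams(**vals) for sym, vals in data.pop("elements").items()
    }
    return ToyParams(elements=elements, **data)
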