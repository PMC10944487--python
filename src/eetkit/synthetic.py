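"""Synthetic pigment networks with planted ground truth.

Every pipeline stage is testable without any deposited structure: generators
build clusters of pseudo-pigments with exact positions, Qy axes, site
energies and two-point transition charges whose dipole is exact by
construction. Cluster layouts with large inter-cluster gaps emulate, at
reduced scale, an antenna ring around a core — the regime where domains
split into transfer groups.

Synthetic pigments use pseudo-atom names (MG, NB, ND for center/axis; P1, P2
for the charge-bearing points) so the same extraction, charge-placement and
coupling machinery runs unchanged on real and synthetic inputs. Fixtures are
written as minimal PDB files (CLA/KC1 residue codes) that round-trip through
the structure reader.

All generators are pure functions of their spec (including the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import gemmi
import numpy as np
from pydantic import BaseModel, Field, model_validator

from .constants import EA_TO_DEBYE
from .errors import GeometryError
from .forster import pairwise_rate
from .lineshapes import LineshapeParams, SpectralModel, overlap_integral
from .structure_io import (
    DomainPartition,
    DomainRole,
    Pigment,
    PigmentSet,
    PigmentType,
)
from .tresp import ChargeSet, ScreeningParams, dipole_coupling

RESIDUE_CODE = {PigmentType.CHL_A: "CLA", PigmentType.CHL_C: "KC1"}

#: Default transition-dipole magnitude of the synthetic pigments, Debye.
#: ~4 D is the effective in-protein Qy dipole commonly used for Chl a.
DEFAULT_DIPOLE_D = 4.0
#: Default two-point charge separation, Å — small against any inter-pigment
#: distance so the dipole limit is approached quickly.
DEFAULT_SEPARATION_A = 0.8


class ClusterSpec(BaseModel):
    n: int = Field(ge=1)
    centroid: tuple[float, float, float]
    spacing: float = Field(gt=1.0, description="intra-cluster nearest spacing, Å")
    pigment_type: PigmentType = PigmentType.CHL_A
    role: DomainRole = DomainRole.ANTENNA


class SyntheticSpec(BaseModel):
    """Layout of a planted pigment network; byte-identical output per seed."""

    seed: int = 0
    clusters: list[ClusterSpec]
    orientation: Literal["ALIGNED", "RANDOM"] = "ALIGNED"
    dipole_debye: float = Field(default=DEFAULT_DIPOLE_D, gt=0)
    separation: float = Field(default=DEFAULT_SEPARATION_A, gt=0)
    site_energies: dict[PigmentType, float] = Field(
        default_factory=lambda: {PigmentType.CHL_A: 14900.0, PigmentType.CHL_C: 15750.0}
    )
    fwhm_cm1: float = 240.0
    stokes_cm1: float = 160.0
    group_cutoff_ps: float = 20.0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSpec":
        if not self.clusters:
            raise ValueError("need at least one cluster")
        return self


@dataclass
class GroundTruth:
    """What was planted: the domain labels, transfer groups and far-field
    couplings a correct pipeline must recover."""

    domain_ids: list[str]
    planted_groups: list[list[str]]
    closest_pairs: dict[tuple[str, str], dict]


def make_charge_set(
    dipole: float,
    separation: float,
    pigment_type: PigmentType = PigmentType.CHL_A,
) -> ChargeSet:
    """Two-point charge set ±q at ±separation/2 along the Qy axis.

    q is chosen so the placed dipole magnitude q·separation (in e·Å) equals
    ``dipole`` Debye exactly.
    """
    if dipole <= 0:
        raise GeometryError(f"dipole must be positive, got {dipole}")
    if separation <= 0:
        raise GeometryError(f"separation must be positive, got {separation}")
    q = dipole / (EA_TO_DEBYE * separation)
    return ChargeSet(
        pigment_type=pigment_type,
        charges={"P1": q, "P2": -q},
        label=f"synthetic-two-point-{dipole}D",
    )


def make_pigment(
    pid: str,
    center: np.ndarray,
    axis: np.ndarray,
    *,
    chain: str = "A",
    resnum: int = 1,
    pigment_type: PigmentType = PigmentType.CHL_A,
    separation: float = DEFAULT_SEPARATION_A,
) -> Pigment:
    """One synthetic pigment with MG/NB/ND axis atoms and P1/P2 charge sites."""
    center = np.asarray(center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    atoms = {
        "MG": center,
        "NB": center - 1.0 * axis,
        "ND": center + 1.0 * axis,
        "P1": center + 0.5 * separation * axis,
        "P2": center - 0.5 * separation * axis,
    }
    return Pigment(
        id=pid,
        pigment_type=pigment_type,
        atom_coords=atoms,
        center=center,
        qy_axis=axis,
        chain=chain,
        resnum=resnum,
    )


def make_dimer(
    R: float,
    geometry: Literal["COLLINEAR", "STACKED", "CUSTOM"] = "STACKED",
    *,
    axes: tuple[np.ndarray, np.ndarray] | None = None,
    separation: float = DEFAULT_SEPARATION_A,
    pigment_type: PigmentType = PigmentType.CHL_A,
) -> PigmentSet:
    """Two pigments at center distance R along x̂ with exact axes.

    STACKED: parallel axes perpendicular to the separation vector (κ = 1);
    COLLINEAR: both axes along the separation vector (κ = −2); CUSTOM takes
    explicit axes. The analytic orientation factor is recorded in metadata.
    """
    if R <= 2.0 * separation:
        raise GeometryError(
            f"center distance {R} Å too small for charge separation {separation} Å"
        )
    xhat = np.array([1.0, 0.0, 0.0])
    zhat = np.array([0.0, 0.0, 1.0])
    if geometry == "STACKED":
        e1 = e2 = zhat
    elif geometry == "COLLINEAR":
        e1 = e2 = xhat
    elif geometry == "CUSTOM":
        if axes is None:
            raise GeometryError("CUSTOM geometry requires explicit axes")
        e1, e2 = (np.asarray(a, float) / np.linalg.norm(a) for a in axes)
    else:
        raise GeometryError(f"unknown dimer geometry {geometry!r}")
    kappa = float(np.dot(e1, e2) - 3.0 * np.dot(e1, xhat) * np.dot(e2, xhat))
    pigments = [
        make_pigment(
            "A/1/CLA", np.zeros(3), e1, chain="A", resnum=1,
            pigment_type=pigment_type, separation=separation,
        ),
        make_pigment(
            "B/1/CLA", R * xhat, e2, chain="B", resnum=1,
            pigment_type=pigment_type, separation=separation,
        ),
    ]
    return PigmentSet(
        pigments,
        source=f"synthetic:dimer-{geometry}",
        provenance=f"synthetic:dimer-{geometry}",
        metadata={"kappa": kappa, "R": R, "separation": separation},
    )


def make_ring(
    n: int,
    radius: float,
    *,
    separation: float = DEFAULT_SEPARATION_A,
    pigment_type: PigmentType = PigmentType.CHL_A,
) -> PigmentSet:
    """Ring of n identical pigments with rotationally symmetric axes.

    Every pigment's Qy axis is normal to the ring plane, so the full coupling
    matrix is circulant by symmetry.
    """
    if n < 3:
        raise GeometryError("a ring needs at least 3 pigments")
    zhat = np.array([0.0, 0.0, 1.0])
    pigments = []
    for j in range(n):
        theta = 2.0 * math.pi * j / n
        center = radius * np.array([math.cos(theta), math.sin(theta), 0.0])
        pigments.append(
            make_pigment(
                f"R/{j + 1}/CLA", center, zhat, chain="R", resnum=j + 1,
                pigment_type=pigment_type, separation=separation,
            )
        )
    return PigmentSet(pigments, source=f"synthetic:ring-{n}", provenance=f"synthetic:ring-{n}")


def _cluster_offsets(n: int, spacing: float) -> np.ndarray:
    """First n sites of a cubic lattice with the given nearest spacing, centered."""
    side = math.ceil(n ** (1.0 / 3.0))
    sites = [
        (ix, iy, iz)
        for iz in range(side + 1)
        for iy in range(side + 1)
        for ix in range(side + 1)
    ]
    sites.sort(key=lambda s: (s[2], s[1], s[0]))
    offsets = spacing * np.array(sites[:n], dtype=float)
    return offsets - offsets.mean(axis=0)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def spectral_model_for(spec: SyntheticSpec) -> SpectralModel:
    """Per-type Gaussian lineshape parameters implied by the spec."""
    return SpectralModel(
        by_type={
            ptype: LineshapeParams(
                omega0=omega0, fwhm=spec.fwhm_cm1, stokes=spec.stokes_cm1
            )
            for ptype, omega0 in spec.site_energies.items()
        }
    )


def charge_library_for(spec: SyntheticSpec) -> dict[PigmentType, ChargeSet]:
    types = {c.pigment_type for c in spec.clusters}
    return {
        t: make_charge_set(spec.dipole_debye, spec.separation, t) for t in types
    }


def make_grouped_network(
    spec: SyntheticSpec,
) -> tuple[PigmentSet, DomainPartition, GroundTruth]:
    """Planted multi-cluster network: clusters become domains.

    The ground truth records, for every cluster pair, the closest pigment
    pair with its analytic point-dipole coupling and the single-pair transfer
    time constant it implies, plus the planted transfer groups (connected
    components of cluster pairs whose closest-pair time constant is within
    ``group_cutoff_ps``). The dipole-limit formula is evaluated directly, so
    the truth is independent of the TrEsp summation path it validates.
    """
    rng = np.random.default_rng(spec.seed)
    chains = [f"C{i + 1}" for i in range(len(spec.clusters))]
    pigments: list[Pigment] = []
    members: dict[str, list[str]] = {}
    roles: dict[str, DomainRole] = {}
    for chain, cluster in zip(chains, spec.clusters):
        offsets = _cluster_offsets(cluster.n, cluster.spacing)
        members[chain] = []
        roles[chain] = cluster.role
        code = RESIDUE_CODE[cluster.pigment_type]
        for j, off in enumerate(offsets):
            axis = (
                np.array([0.0, 0.0, 1.0])
                if spec.orientation == "ALIGNED"
                else _random_unit(rng)
            )
            pid = f"{chain}/{j + 1}/{code}"
            pigments.append(
                make_pigment(
                    pid,
                    np.asarray(cluster.centroid) + off,
                    axis,
                    chain=chain,
                    resnum=j + 1,
                    pigment_type=cluster.pigment_type,
                    separation=spec.separation,
                )
            )
            members[chain].append(pid)
    pig_set = PigmentSet(
        pigments, source=f"synthetic:{spec.seed}", provenance=f"synthetic:{spec.seed}"
    )
    for p in pig_set:
        p.domain_id = p.chain

    # reject overlapping clusters
    for i, ci in enumerate(chains):
        for cj in chains[i + 1 :]:
            dmin, _ = _closest_pair(pig_set, members[ci], members[cj])
            if dmin < 2.0:
                raise GeometryError(
                    f"clusters {ci} and {cj} overlap: closest pigments {dmin:.2f} Å"
                )

    partition = DomainPartition(members=members, roles=roles)
    truth = _ground_truth(spec, pig_set, partition)
    return pig_set, partition, truth


def _closest_pair(
    pigments: PigmentSet, ids_a: list[str], ids_b: list[str]
) -> tuple[float, tuple[str, str]]:
    best = (math.inf, ("", ""))
    for ia in ids_a:
        for ib in ids_b:
            d = float(np.linalg.norm(pigments[ia].center - pigments[ib].center))
            if d < best[0]:
                best = (d, (ia, ib))
    return best


def _ground_truth(
    spec: SyntheticSpec, pigments: PigmentSet, partition: DomainPartition
) -> GroundTruth:
    import networkx as nx

    model = spectral_model_for(spec)
    screening = ScreeningParams()
    domains = partition.domain_ids
    closest: dict[tuple[str, str], dict] = {}
    graph = nx.Graph()
    antenna = partition.antenna_ids()
    graph.add_nodes_from(antenna)
    for i, d in enumerate(domains):
        for a in domains[i + 1 :]:
            dist, (pid_d, pid_a) = _closest_pair(
                pigments, partition.members[d], partition.members[a]
            )
            V = dipole_coupling(
                pigments[pid_d],
                pigments[pid_a],
                spec.dipole_debye,
                spec.dipole_debye,
                screening,
            )
            J = overlap_integral(
                model.params_for(pigments[pid_d]), model.params_for(pigments[pid_a])
            )
            T = pairwise_rate(V, J)
            tau = 1.0 / T if T > 0 else math.inf
            closest[(d, a)] = {
                "pair": (pid_d, pid_a),
                "distance_A": dist,
                "V_dipole_cm1": V,
                "tau_ps": tau,
            }
            if d in antenna and a in antenna and tau <= spec.group_cutoff_ps:
                graph.add_edge(d, a)
    groups = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda g: g[0])
    return GroundTruth(domain_ids=domains, planted_groups=groups, closest_pairs=closest)


def write_fixture(pigments: PigmentSet, path: str | Path) -> Path:
    """Write a minimal PDB fixture the structure reader round-trips.

    HETATM records carry the synthetic pseudo-atoms; centers and axes survive
    the fixed-width coordinate format to 1e-3 Å.
    """
    element = {"MG": "MG", "NB": "N", "ND": "N", "NA": "N", "NC": "N"}
    structure = gemmi.Structure()
    structure.name = pigments.source or "synthetic"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for pig in pigments:
        if pig.chain not in chains:
            chains[pig.chain] = gemmi.Chain(pig.chain)
        residue = gemmi.Residue()
        residue.name = RESIDUE_CODE.get(pig.pigment_type, "CLA")
        residue.seqid = gemmi.SeqId(pig.resnum, " ")
        residue.het_flag = "H"
        for name, xyz in pig.atom_coords.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element.get(name, "P"))
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = 0.0
            residue.add_atom(atom)
        chains[pig.chain].add_residue(residue)
    for chain in chains.values():
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    path = Path(path)
    structure.write_pdb(str(path))
    return path
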