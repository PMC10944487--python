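"""Parse structural models and extract chlorophyll pigments with geometry.

A *pigment* here is one chromophore instance: its charge-bearing atom
coordinates, a center (the Mg position, or the mean of the four chlorin ring
nitrogens when Mg is absent) and a unit Qy-axis vector. By the common
convention for the chlorophyll Qy transition the axis runs from ring nitrogen
NB to ND; the atom pair is configurable (e.g. NA→NC).

mmCIF and PDB are both accepted (gzip-transparent) via gemmi. Alternate
locations are resolved by keeping the highest-occupancy conformer, ties broken
by altloc identifier order.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .errors import DomainError, ExtractionError, GeometryError, StructureParseError

logger = logging.getLogger(__name__)

RING_NITROGENS = ("NA", "NB", "NC", "ND")

#: Residue codes of the chlorophyll cofactors recognized by default:
#: CLA is chlorophyll a; KC1/KC2 are chlorophyll c1/c2.
DEFAULT_CODE_MAP: dict[str, "PigmentType"] = {}


class PigmentType(str, Enum):
    CHL_A = "CHL_A"
    CHL_C = "CHL_C"
    OTHER = "OTHER"


DEFAULT_CODE_MAP.update(
    {"CLA": PigmentType.CHL_A, "KC1": PigmentType.CHL_C, "KC2": PigmentType.CHL_C}
)


class DomainRole(str, Enum):
    CORE = "CORE"
    ANTENNA = "ANTENNA"


@dataclass
class Pigment:
    """One chromophore instance extracted from a structural model."""

    id: str
    pigment_type: PigmentType
    atom_coords: dict[str, np.ndarray]
    center: np.ndarray
    qy_axis: np.ndarray
    chain: str
    resnum: int
    domain_id: str | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.qy_axis = np.asarray(self.qy_axis, dtype=float)
        if not self.atom_coords:
            raise ExtractionError(f"pigment {self.id}: empty atom_coords")
        if not np.all(np.isfinite(self.center)):
            raise ExtractionError(f"pigment {self.id}: non-finite center")
        norm = float(np.linalg.norm(self.qy_axis))
        if not np.isfinite(norm) or norm == 0.0:
            raise ExtractionError(f"pigment {self.id}: zero-length Qy axis")
        self.qy_axis = self.qy_axis / norm

    def coord(self, atom_name: str) -> np.ndarray:
        try:
            return self.atom_coords[atom_name]
        except KeyError:
            raise ExtractionError(
                f"pigment {self.id}: no atom named {atom_name!r}"
            ) from None


@dataclass
class PigmentSet:
    """Ordered, id-unique collection of pigments."""

    pigments: list[Pigment]
    source: str = ""
    provenance: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pigments]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ExtractionError(f"duplicate pigment ids: {dupes}")
        self._by_id = {p.id: p for p in self.pigments}

    def __len__(self) -> int:
        return len(self.pigments)

    def __iter__(self) -> Iterator[Pigment]:
        return iter(self.pigments)

    def __getitem__(self, key: int | str) -> Pigment:
        if isinstance(key, str):
            return self._by_id[key]
        return self.pigments[key]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pigments]

    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.pigments])

    def counts_by_type(self) -> dict[PigmentType, int]:
        out: dict[PigmentType, int] = {}
        for p in self.pigments:
            out[p.pigment_type] = out.get(p.pigment_type, 0) + 1
        return out


@dataclass
class DomainPartition:
    """Partition of pigment ids into donor/acceptor aggregates (domains)."""

    members: dict[str, list[str]]
    roles: dict[str, DomainRole]
    display_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for dom, ids in self.members.items():
            if not ids:
                raise DomainError(f"domain {dom!r} is empty")
            overlap = seen.intersection(ids)
            if overlap:
                raise DomainError(f"pigments in more than one domain: {sorted(overlap)}")
            seen.update(ids)
        missing = set(self.members) - set(self.roles)
        if missing:
            raise DomainError(f"domains without a role tag: {sorted(missing)}")

    @property
    def domain_ids(self) -> list[str]:
        return list(self.members)

    def antenna_ids(self) -> list[str]:
        return [d for d, r in self.roles.items() if r is DomainRole.ANTENNA]

    def core_ids(self) -> list[str]:
        return [d for d, r in self.roles.items() if r is DomainRole.CORE]

    def domain_of(self, pigment_id: str) -> str:
        for dom, ids in self.members.items():
            if pigment_id in ids:
                return dom
        raise DomainError(f"pigment {pigment_id!r} not in any domain")


def read_structure(path: str | Path) -> gemmi.Structure:
    """Read an mmCIF or PDB file (optionally gzipped) into a gemmi Structure.

    Raises :class:`StructureParseError` on unreadable or garbled input, with
    gemmi's diagnostic (which names the offending line/block) attached.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0 or all(len(ch) == 0 for ch in structure[0]):
        raise StructureParseError(f"{path}: no models/chains found")
    structure.setup_entities()
    return structure


def _best_altloc_coords(residue: gemmi.Residue) -> dict[str, np.ndarray]:
    """Per atom name keep the highest-occupancy conformer (ties: altloc order)."""
    best: dict[str, tuple[float, str, np.ndarray]] = {}
    for atom in residue:
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        key = atom.name
        cand = (-float(atom.occ), atom.altloc or "", pos)
        if key not in best or cand[:2] < best[key][:2]:
            best[key] = cand
    return {name: coords for name, (_, _, coords) in best.items()}


def extract_pigments(
    structure: gemmi.Structure,
    code_map: Mapping[str, PigmentType] | None = None,
    *,
    qy_atoms: tuple[str, str] = ("NB", "ND"),
    allow_missing_axis: bool = False,
    source: str = "",
) -> PigmentSet:
    """Extract one Pigment per residue whose code appears in ``code_map``.

    Pigments are sorted by (chain, residue number). Residues lacking both Mg
    and the four ring nitrogens raise; a missing Qy-axis atom raises unless
    ``allow_missing_axis``, in which case the pigment is skipped with a
    logged warning.
    """
    code_map = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    records: list[Pigment] = []
    model = structure[0]
    for chain in model:
        for residue in chain:
            if residue.name not in code_map:
                continue
            coords = _best_altloc_coords(residue)
            resnum = residue.seqid.num
            pid = f"{chain.name}/{resnum}/{residue.name}"
            if "MG" in coords:
                center = coords["MG"]
            elif all(n in coords for n in RING_NITROGENS):
                center = np.mean([coords[n] for n in RING_NITROGENS], axis=0)
            else:
                raise ExtractionError(
                    f"residue {pid}: neither Mg nor all ring nitrogens "
                    f"{RING_NITROGENS} present; cannot define a center"
                )
            try:
                axis = coords[qy_atoms[1]] - coords[qy_atoms[0]]
            except KeyError as exc:
                if allow_missing_axis:
                    logger.warning(
                        "skipping %s: missing Qy-axis atom %s", pid, exc.args[0]
                    )
                    continue
                raise ExtractionError(
                    f"residue {pid}: missing Qy-axis atom {exc.args[0]!r} "
                    f"(set allow_missing_axis to skip instead)"
                ) from None
            if np.linalg.norm(axis) == 0.0:
                raise ExtractionError(f"residue {pid}: degenerate Qy axis")
            records.append(
                Pigment(
                    id=pid,
                    pigment_type=code_map[residue.name],
                    atom_coords=coords,
                    center=center,
                    qy_axis=axis,
                    chain=chain.name,
                    resnum=resnum,
                )
            )
    records.sort(key=lambda p: (p.chain, p.resnum))
    return PigmentSet(records, source=source or structure.name, provenance=source)


def assign_domains(
    pigments: PigmentSet,
    chain_roles: Mapping[str, tuple[str, DomainRole | str]] | None = None,
    *,
    default_rule: bool = False,
    core_chains: Iterable[str] = (),
    core_domain_id: str = "CORE",
) -> DomainPartition:
    """Group pigments into domains by chain.

    ``chain_roles`` maps chain → (domain_id, role). With ``default_rule``,
    unmapped chains become one domain each with role ANTENNA, except chains in
    ``core_chains`` which are merged into a single ``core_domain_id`` domain —
    the conventional antenna-ring-around-core partition.
    """
    chain_roles = dict(chain_roles or {})
    core_chains = set(core_chains)
    members: dict[str, list[str]] = {}
    roles: dict[str, DomainRole] = {}
    unmapped: set[str] = set()
    for pig in pigments:
        if pig.chain in chain_roles:
            dom, role = chain_roles[pig.chain]
            role = DomainRole(role)
        elif default_rule:
            if pig.chain in core_chains:
                dom, role = core_domain_id, DomainRole.CORE
            else:
                dom, role = pig.chain, DomainRole.ANTENNA
        else:
            unmapped.add(pig.chain)
            continue
        members.setdefault(dom, []).append(pig.id)
        existing = roles.setdefault(dom, role)
        if existing is not role:
            raise DomainError(f"conflicting roles for domain {dom!r}")
        pig.domain_id = dom
    if unmapped:
        raise DomainError(
            f"chains with no domain mapping and no default rule: {sorted(unmapped)}"
        )
    return DomainPartition(members=members, roles=roles)


def pairwise_geometry(pigments: PigmentSet, *, min_distance: float = 0.1) -> pd.DataFrame:
    """Symmetric center-to-center distance table in Å (zero diagonal).

    Raises :class:`GeometryError` if two distinct pigments sit closer than
    ``min_distance`` Å.
    """
    if len(pigments) < 2:
        raise GeometryError("need at least 2 pigments for pairwise geometry")
    centers = pigments.centers()
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    ids = pigments.ids
    off = dist + np.eye(len(ids)) * 1e9
    if off.min() < min_distance:
        i, j = np.unravel_index(np.argmin(off), off.shape)
        raise GeometryError(
            f"degenerate geometry: {ids[i]} and {ids[j]} are {dist[i, j]:.4f} Å apart"
        )
    return pd.DataFrame(dist, index=ids, columns=ids)


def pigment_table(pigments: PigmentSet) -> pd.DataFrame:
    """Flat per-pigment table (id, chain, resnum, type, center, axis, domain)."""
    rows = []
    for p in pigments:
        rows.append(
            {
                "id": p.id,
                "chain": p.chain,
                "resnum": p.resnum,
                "type": p.pigment_type.value,
                "center_x": p.center[0],
                "center_y": p.center[1],
                "center_z": p.center[2],
                "qy_x": p.qy_axis[0],
                "qy_y": p.qy_axis[1],
                "qy_z": p.qy_axis[2],
                "domain": p.domain_id or "",
            }
        )
    return pd.DataFrame(rows)


def write_pigment_table(pigments: PigmentSet, path: str | Path) -> None:
    pigment_table(pigments).to_csv(path, sep="\t", index=False)
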