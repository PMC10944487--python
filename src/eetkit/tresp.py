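"""Inter-pigment electronic couplings from transition charges (TrEsp).

The coupling between pigments m and n is the screened Coulomb sum over their
transition charges,

    V_mn = f(R) · Σ_{l∈m, l'∈n} q_l q_l' / |R_ll'|,

with q in units of e, distances in Å and V in cm⁻¹. The environmental
screening factor f is a piecewise function of the center-to-center (Mg–Mg)
distance R:

    f(R) = 1                     for R ≤ 6.6 Å
    f(R) = A·exp(−β·R) + 0.54    for 6.6 < R < 20 Å
    f(R) = 0.54                  for R ≥ 20 Å

One factor f multiplies the whole sum. A and β default to the standard
distance-dependent screening fit consistent with these cutoffs and asymptote
(A = 2.68, β = 0.27 Å⁻¹).

A point-dipole evaluation (`dipole_coupling`) is provided as the ideal-dipole
limit, mainly for validation: TrEsp sums over well-separated two-point dipoles
must converge to it.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import CONSTANTS_VERSION, EA_TO_DEBYE, K_COUL_CM1, K_DD_CM1
from .errors import ChargeSetError, GeometryError
from .structure_io import Pigment, PigmentSet, PigmentType


class CouplingMethod(str, Enum):
    TRESP = "TRESP"
    DIPOLE = "DIPOLE"


@dataclass(frozen=True)
class ScreeningParams:
    """Parameters of the piecewise distance-dependent screening factor."""

    A: float = 2.68
    beta: float = 0.27
    f_inner: float = 1.0
    f_outer: float = 0.54
    r_inner: float = 6.6
    r_outer: float = 20.0

    def __post_init__(self) -> None:
        if not self.r_inner < self.r_outer:
            raise ChargeSetError("screening: r_inner must be < r_outer")
        if self.f_outer <= 0:
            raise ChargeSetError("screening: f_outer must be positive")


DEFAULT_SCREENING = ScreeningParams()


def screening_factor(R: float | np.ndarray, params: ScreeningParams = DEFAULT_SCREENING):
    """Environmental screening factor f(R); R in Å, R > 0.

    Boundary handling follows the inclusive inequalities of the piecewise
    definition: the inner branch applies at R = r_inner, the outer branch at
    R = r_outer.
    """
    R_arr = np.asarray(R, dtype=float)
    if np.any(R_arr <= 0):
        raise GeometryError(f"screening_factor: R must be positive, got {R!r}")
    mid = params.A * np.exp(-params.beta * R_arr) + params.f_outer
    f = np.where(
        R_arr <= params.r_inner,
        params.f_inner,
        np.where(R_arr >= params.r_outer, params.f_outer, mid),
    )
    return float(f) if np.isscalar(R) or R_arr.ndim == 0 else f


@dataclass
class ChargeSet:
    """Transition charges of one pigment type: atom name → charge (e).

    If ``target_dipole`` (Debye) is set, charges are rescaled at placement
    time so that the placed transition dipole |Σ q_l·r_l| equals it.
    """

    pigment_type: PigmentType
    charges: dict[str, float]
    target_dipole: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.charges) < 2:
            raise ChargeSetError("a charge set needs at least 2 atoms")
        for name, q in self.charges.items():
            if not np.isfinite(q):
                raise ChargeSetError(f"non-finite charge for atom {name!r}")

    def scaled(self, factor: float) -> "ChargeSet":
        return replace(
            self, charges={k: v * factor for k, v in self.charges.items()}
        )

    def place(
        self, pigment: Pigment, *, allow_missing: bool = False
    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Resolve atom names to coordinates on ``pigment``.

        Returns (coords [n,3], charges [n], atom names). Atoms absent from the
        model raise unless ``allow_missing``, in which case they are dropped
        without renormalizing the remaining charges. Dipole rescaling to
        ``target_dipole`` is applied after placement.
        """
        names, coords, charges = [], [], []
        for name, q in self.charges.items():
            if name not in pigment.atom_coords:
                if allow_missing:
                    continue
                raise ChargeSetError(
                    f"pigment {pigment.id}: charge-set atom {name!r} not in model"
                )
            names.append(name)
            coords.append(pigment.atom_coords[name])
            charges.append(q)
        if not names:
            raise ChargeSetError(
                f"pigment {pigment.id}: no charge-set atoms resolved"
            )
        coords_arr = np.asarray(coords, dtype=float)
        charges_arr = np.asarray(charges, dtype=float)
        if self.target_dipole is not None:
            mu = placed_dipole(coords_arr, charges_arr, origin=pigment.center)
            mu_mag = float(np.linalg.norm(mu))
            if mu_mag == 0.0:
                raise ChargeSetError(
                    f"pigment {pigment.id}: zero placed dipole, cannot rescale"
                )
            charges_arr = charges_arr * (self.target_dipole / mu_mag)
        return coords_arr, charges_arr, names


def placed_dipole(
    coords: np.ndarray, charges: np.ndarray, *, origin: np.ndarray | None = None
) -> np.ndarray:
    """Transition dipole Σ q_l·(r_l − origin) in Debye (q in e, r in Å)."""
    if origin is None:
        origin = np.zeros(3)
    return EA_TO_DEBYE * np.einsum("l,li->i", charges, coords - origin)


def load_charge_set(path: str | Path) -> ChargeSet:
    """Read a charge-set TSV: ``atom_name<TAB>charge_e`` rows.

    Header directives: ``#pigment_type=CHL_A`` and ``#target_dipole_debye=4.0``.
    Duplicate atom names and non-numeric charges are errors.
    """
    path = Path(path)
    pigment_type = PigmentType.OTHER
    target_dipole: float | None = None
    charges: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            directive = line.lstrip("#").strip()
            if directive.startswith("pigment_type="):
                pigment_type = PigmentType(directive.split("=", 1)[1].strip())
            elif directive.startswith("target_dipole_debye="):
                target_dipole = float(directive.split("=", 1)[1])
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ChargeSetError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        name, charge_text = parts
        if name == "atom_name":  # optional column header
            continue
        if name in charges:
            raise ChargeSetError(f"{path}:{lineno}: duplicate atom name {name!r}")
        try:
            charges[name] = float(charge_text)
        except ValueError:
            raise ChargeSetError(
                f"{path}:{lineno}: non-numeric charge {charge_text!r}"
            ) from None
    return ChargeSet(
        pigment_type=pigment_type,
        charges=charges,
        target_dipole=target_dipole,
        label=path.stem,
    )


def write_charge_set(cs: ChargeSet, path: str | Path) -> None:
    lines = [f"#pigment_type={cs.pigment_type.value}"]
    if cs.target_dipole is not None:
        lines.append(f"#target_dipole_debye={cs.target_dipole!r}")
    lines.append("atom_name\tcharge_e")
    for name, q in cs.charges.items():
        lines.append(f"{name}\t{q!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def tresp_coupling(
    pig_m: Pigment,
    pig_n: Pigment,
    cs_m: ChargeSet,
    cs_n: ChargeSet,
    params: ScreeningParams = DEFAULT_SCREENING,
    *,
    allow_missing: bool = False,
    screening_override: float | None = None,
    min_atom_distance: float = 0.5,
) -> float:
    """Screened TrEsp coupling V_mn in cm⁻¹ between two distinct pigments.

    The screening factor is evaluated at the center–center distance and
    multiplies the whole Coulomb sum; ``screening_override`` forces a fixed f
    (used by validation fixtures). Any inter-atomic distance below
    ``min_atom_distance`` Å is a clash error.
    """
    coords_m, q_m, _ = cs_m.place(pig_m, allow_missing=allow_missing)
    coords_n, q_n, _ = cs_n.place(pig_n, allow_missing=allow_missing)
    r = cdist(coords_m, coords_n)
    if r.min() < min_atom_distance:
        raise GeometryError(
            f"atom clash between {pig_m.id} and {pig_n.id}: "
            f"min distance {r.min():.3f} Å"
        )
    R = float(np.linalg.norm(pig_m.center - pig_n.center))
    f = screening_override if screening_override is not None else screening_factor(R, params)
    return float(f * K_COUL_CM1 * np.einsum("l,m,lm->", q_m, q_n, 1.0 / r))


def dipole_coupling(
    pig_m: Pigment,
    pig_n: Pigment,
    mu_m: float,
    mu_n: float,
    params: ScreeningParams = DEFAULT_SCREENING,
    *,
    screening_override: float | None = None,
) -> float:
    """Point-dipole coupling in cm⁻¹ (ideal-dipole limit of the TrEsp sum).

    V = f · K_dd · κ · μ_m μ_n / R³ with the orientation factor
    κ = ê_m·ê_n − 3(ê_m·R̂)(ê_n·R̂); μ in Debye, R in Å.
    """
    rvec = pig_n.center - pig_m.center
    R = float(np.linalg.norm(rvec))
    if R == 0.0:
        raise GeometryError(f"{pig_m.id}/{pig_n.id}: coincident centers")
    rhat = rvec / R
    kappa = orientation_factor(pig_m.qy_axis, pig_n.qy_axis, rhat)
    f = screening_override if screening_override is not None else screening_factor(R, params)
    return float(f * K_DD_CM1 * kappa * mu_m * mu_n / R**3)


def orientation_factor(e_m: np.ndarray, e_n: np.ndarray, rhat: np.ndarray) -> float:
    """κ = ê_m·ê_n − 3(ê_m·R̂)(ê_n·R̂) for unit vectors."""
    for v in (e_m, e_n):
        if not math.isclose(float(np.linalg.norm(v)), 1.0, rel_tol=1e-6):
            raise GeometryError("orientation_factor expects unit axis vectors")
    return float(np.dot(e_m, e_n) - 3.0 * np.dot(e_m, rhat) * np.dot(e_n, rhat))


@dataclass
class CouplingMatrix:
    """Symmetric pairwise couplings V_mn (cm⁻¹) with screening bookkeeping."""

    ids: list[str]
    V: np.ndarray
    R: np.ndarray
    f: np.ndarray
    method: CouplingMethod
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("V", "R", "f"):
            arr = getattr(self, name)
            if arr.shape != (n, n):
                raise ChargeSetError(f"CouplingMatrix.{name}: shape {arr.shape} != ({n},{n})")
        if not np.all(np.isfinite(self.V)):
            raise ChargeSetError("CouplingMatrix: non-finite couplings")
        if not np.allclose(self.V, self.V.T):
            raise ChargeSetError("CouplingMatrix: not symmetric")

    def value(self, id_m: str, id_n: str) -> float:
        i, j = self.ids.index(id_m), self.ids.index(id_n)
        return float(self.V[i, j])

    def submatrix(self, ids_rows: list[str], ids_cols: list[str]) -> np.ndarray:
        idx_r = [self.ids.index(i) for i in ids_rows]
        idx_c = [self.ids.index(i) for i in ids_cols]
        return self.V[np.ix_(idx_r, idx_c)]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "pigment_m": self.ids[i],
                        "pigment_n": self.ids[j],
                        "R_angstrom": self.R[i, j],
                        "f": self.f[i, j],
                        "V_cm1": self.V[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        frame = self.to_long_frame()
        with open(path, "w") as fh:
            fh.write(f"# method={self.method.value} constants={CONSTANTS_VERSION}\n")
            frame.to_csv(fh, index=False)


def coupling_matrix(
    pigments: PigmentSet,
    charge_library: Mapping[PigmentType, ChargeSet],
    params: ScreeningParams = DEFAULT_SCREENING,
    method: CouplingMethod = CouplingMethod.TRESP,
    *,
    allow_missing: bool = False,
) -> CouplingMatrix:
    """Full symmetric coupling matrix over all pigment pairs.

    With ``method=DIPOLE`` each pigment's dipole magnitude is taken from its
    placed charge set, so the two methods describe the same transition
    densities at different levels of approximation.
    """
    n = len(pigments)
    for pig in pigments:
        if pig.pigment_type not in charge_library:
            raise ChargeSetError(
                f"no charge set for pigment type {pig.pigment_type.value} "
                f"(pigment {pig.id})"
            )
    V = np.zeros((n, n))
    R = np.zeros((n, n))
    f = np.ones((n, n))
    mus: list[float] = []
    if method is CouplingMethod.DIPOLE:
        for pig in pigments:
            coords, charges, _ = charge_library[pig.pigment_type].place(
                pig, allow_missing=allow_missing
            )
            mus.append(float(np.linalg.norm(placed_dipole(coords, charges, origin=pig.center))))
    for i in range(n):
        for j in range(i + 1, n):
            pm, pn = pigments[i], pigments[j]
            Rij = float(np.linalg.norm(pm.center - pn.center))
            R[i, j] = R[j, i] = Rij
            fij = screening_factor(Rij, params)
            f[i, j] = f[j, i] = fij
            try:
                if method is CouplingMethod.TRESP:
                    v = tresp_coupling(
                        pm,
                        pn,
                        charge_library[pm.pigment_type],
                        charge_library[pn.pigment_type],
                        params,
                        allow_missing=allow_missing,
                    )
                else:
                    v = dipole_coupling(pm, pn, mus[i], mus[j], params)
            except Exception as exc:
                raise type(exc)(f"pair ({pm.id}, {pn.id}): {exc}") from exc
            V[i, j] = V[j, i] = v
    return CouplingMatrix(
        ids=pigments.ids,
        V=V,
        R=R,
        f=f,
        method=method,
        metadata={
            "screening": params,
            "constants_version": CONSTANTS_VERSION,
        },
    )
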