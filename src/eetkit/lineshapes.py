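"""Gaussian lineshapes and donor-emission/acceptor-absorption overlaps.

Each pigment's Qy band is modeled as a unit-area Gaussian: absorption peaks
at the site energy ω₀, emission is red-shifted by the Stokes shift S,

    A(ω) = N(ω; ω₀, σ)     F(ω) = N(ω; ω₀ − S, σ).

The overlap integral entering the transfer rate,

    J = ∫ dω F_donor(ω) A_acceptor(ω)
      = exp(−Δ²/(2(σ_m²+σ_n²))) / √(2π(σ_m²+σ_n²)),   Δ = ω_m − S_m − ω_n,

has the Gaussian-product closed form above; a quadrature route is kept as a
cross-check.

The printed width parameter is ambiguous between a true FWHM and a literal
Gaussian σ; ``SigmaMode`` selects the interpretation (default: treat it as a
FWHM and convert, σ = FWHM / (2√(2 ln 2))). For specific donor/acceptor type
pairs a measured overlap can override the Gaussian model via
:class:`OverlapTable` (e.g. an experimental Chl c → Chl a overlap).
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.integrate import simpson

from .constants import FWHM_PER_SIGMA
from .errors import LineshapeError
from .structure_io import Pigment, PigmentType


class SigmaMode(str, Enum):
    FWHM_CONVERT = "FWHM_CONVERT"
    LITERAL_SIGMA = "LITERAL_SIGMA"


class BandKind(str, Enum):
    EMISSION = "EMISSION"
    ABSORPTION = "ABSORPTION"


class OverlapMethod(str, Enum):
    CLOSED_FORM = "CLOSED_FORM"
    QUADRATURE = "QUADRATURE"


class Provenance(str, Enum):
    MODEL = "MODEL"
    EXPERIMENTAL = "EXPERIMENTAL"


@dataclass(frozen=True)
class LineshapeParams:
    """Site energy ω₀, width and Stokes shift of one pigment's Qy band.

    All quantities in cm⁻¹. ``fwhm`` is interpreted according to
    ``sigma_mode``.
    """

    omega0: float
    fwhm: float
    stokes: float = 0.0
    sigma_mode: SigmaMode = SigmaMode.FWHM_CONVERT

    def __post_init__(self) -> None:
        if self.omega0 <= 0:
            raise LineshapeError(f"omega0 must be positive, got {self.omega0}")
        if self.fwhm <= 0:
            raise LineshapeError(f"fwhm must be positive, got {self.fwhm}")
        if self.stokes < 0:
            raise LineshapeError(f"stokes must be >= 0, got {self.stokes}")

    @property
    def sigma(self) -> float:
        if self.sigma_mode is SigmaMode.FWHM_CONVERT:
            return self.fwhm / FWHM_PER_SIGMA
        return self.fwhm

    def peak(self, kind: BandKind) -> float:
        return self.omega0 - self.stokes if kind is BandKind.EMISSION else self.omega0


def lineshape_value(
    params: LineshapeParams, omega: float | np.ndarray, kind: BandKind
) -> float | np.ndarray:
    """Unit-area Gaussian density in (cm⁻¹)⁻¹ at frequency ``omega``."""
    sigma = params.sigma
    mu = params.peak(kind)
    x = (np.asarray(omega, dtype=float) - mu) / sigma
    val = np.exp(-0.5 * x**2) / (sigma * math.sqrt(2.0 * math.pi))
    return float(val) if np.isscalar(omega) else val


def overlap_integral(
    donor: LineshapeParams,
    acceptor: LineshapeParams,
    method: OverlapMethod = OverlapMethod.CLOSED_FORM,
    *,
    n_grid: int = 8193,
) -> float:
    """Overlap J = ∫ dω F_donor(ω) A_acceptor(ω) in (cm⁻¹)⁻¹."""
    sm, sn = donor.sigma, acceptor.sigma
    if method is OverlapMethod.CLOSED_FORM:
        var = sm**2 + sn**2
        delta = donor.peak(BandKind.EMISSION) - acceptor.peak(BandKind.ABSORPTION)
        return math.exp(-0.5 * delta**2 / var) / math.sqrt(2.0 * math.pi * var)
    lo_peak = min(donor.peak(BandKind.EMISSION), acceptor.peak(BandKind.ABSORPTION))
    hi_peak = max(donor.peak(BandKind.EMISSION), acceptor.peak(BandKind.ABSORPTION))
    pad = 6.0 * max(sm, sn)
    grid = np.linspace(lo_peak - pad, hi_peak + pad, n_grid)
    integrand = lineshape_value(donor, grid, BandKind.EMISSION) * lineshape_value(
        acceptor, grid, BandKind.ABSORPTION
    )
    return float(simpson(integrand, x=grid))


@dataclass
class OverlapTable:
    """Directional (donor type, acceptor type) → measured overlap J.

    Entries override the Gaussian model for that ordered type pair only; the
    table is directional by design (a measured c→a overlap says nothing about
    a→c).
    """

    entries: dict[tuple[PigmentType, PigmentType], float] = field(default_factory=dict)
    provenance: dict[tuple[PigmentType, PigmentType], Provenance] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for pair, value in self.entries.items():
            if value < 0:
                raise LineshapeError(f"negative overlap for {pair}: {value}")
            self.provenance.setdefault(pair, Provenance.EXPERIMENTAL)

    def get(self, donor_type: PigmentType, acceptor_type: PigmentType) -> float | None:
        return self.entries.get((donor_type, acceptor_type))


def resolve_overlap(
    donor_type: PigmentType,
    acceptor_type: PigmentType,
    donor_params: LineshapeParams,
    acceptor_params: LineshapeParams,
    table: OverlapTable | None = None,
) -> float:
    """Table value for the ordered type pair when present, else the model."""
    if table is not None:
        value = table.get(donor_type, acceptor_type)
        if value is not None:
            return value
    return overlap_integral(donor_params, acceptor_params)


@dataclass
class SpectralModel:
    """Per-type (and optionally per-pigment) lineshape parameters + overrides."""

    by_type: dict[PigmentType, LineshapeParams]
    by_id: dict[str, LineshapeParams] = field(default_factory=dict)
    overlap_table: OverlapTable | None = None

    def params_for(self, pigment: Pigment) -> LineshapeParams:
        if pigment.id in self.by_id:
            return self.by_id[pigment.id]
        try:
            return self.by_type[pigment.pigment_type]
        except KeyError:
            raise LineshapeError(
                f"no lineshape parameters for pigment {pigment.id} "
                f"(type {pigment.pigment_type.value})"
            ) from None

    def site_energy(self, pigment: Pigment) -> float:
        return self.params_for(pigment).omega0

    def overlap(self, donor: Pigment, acceptor: Pigment) -> float:
        return resolve_overlap(
            donor.pigment_type,
            acceptor.pigment_type,
            self.params_for(donor),
            self.params_for(acceptor),
            self.overlap_table,
        )


def load_lineshape_table(
    path: str | Path, *, sigma_mode: SigmaMode = SigmaMode.FWHM_CONVERT
) -> SpectralModel:
    """Read a site-energy/lineshape TSV.

    Columns: ``pigment_type_or_id  omega0_cm1  fwhm_cm1  stokes_cm1``. Rows
    whose first field is a PigmentType name set type defaults; any other
    first field is treated as a per-pigment id override.
    """
    by_type: dict[PigmentType, LineshapeParams] = {}
    by_id: dict[str, LineshapeParams] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("pigment_type"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 4:
            raise LineshapeError(f"{path}:{lineno}: expected 4 columns")
        key, omega0, fwhm, stokes = parts
        params = LineshapeParams(
            omega0=float(omega0),
            fwhm=float(fwhm),
            stokes=float(stokes),
            sigma_mode=sigma_mode,
        )
        try:
            by_type[PigmentType(key)] = params
        except ValueError:
            by_id[key] = params
    return SpectralModel(by_type=by_type, by_id=by_id)


def load_overlap_table(path: str | Path) -> OverlapTable:
    """Read an overlap TSV: ``donor_type  acceptor_type  J_inv_cm1``."""
    entries: dict[tuple[PigmentType, PigmentType], float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("donor_type"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise LineshapeError(f"{path}:{lineno}: expected 3 columns")
        donor, acceptor, value = parts
        entries[(PigmentType(donor), PigmentType(acceptor))] = float(value)
    return OverlapTable(entries=entries)


#: Documentation-example defaults for quick starts. The Stokes shift and FWHM
#: are the standard Chl a Qy parameters (160 and 240 cm⁻¹); the site energies
#: are round illustrative numbers, NOT fitted values — real analyses must
#: supply their own site-energy table.
EXAMPLE_SPECTRAL_MODEL = SpectralModel(
    by_type={
        PigmentType.CHL_A: LineshapeParams(omega0=14900.0, fwhm=240.0, stokes=160.0),
        PigmentType.CHL_C: LineshapeParams(omega0=15750.0, fwhm=240.0, stokes=160.0),
    }
)
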