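"""Generalized Förster theory: rates between multi-pigment exciton domains.

Each aggregate (an antenna protein's pigment cluster, or the merged core) gets
an exciton Hamiltonian with site energies on the diagonal and intra-domain
couplings off-diagonal. Transfer from donor aggregate D to acceptor A is the
Boltzmann-weighted sum over exciton state pairs,

    k_DA = (2π/ħ) Σ_{α∈D} Σ_{β∈A} [exp(−ε_α/k_B T)/Z] |V_αβ|² ∫dω S_α(ω) S_β(ω),

with exciton couplings obtained by the standard coefficient transform
V_αβ = Σ_{i∈D} Σ_{j∈A} c_iα c_jβ V_ij. Thermal equilibration within the donor
is assumed instantaneous (only Boltzmann weights of donor excitons enter).

Exciton lineshapes are modeled as Gaussians at the exciton eigenenergy whose
width and Stokes shift are the c²-weighted mix of the member pigments'
parameters (donor states emit, shifted by the weighted Stokes shift); a
no-mixing alternative that keeps each monomer FWHM fixed to the first
member's is selectable. For a single-pigment domain everything reduces
exactly to classical Förster transfer.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import C_RATE_PS, CONSTANTS_VERSION, K_B_CM1
from .errors import DomainError, RateError
from .lineshapes import BandKind, LineshapeParams, OverlapMethod, SpectralModel, overlap_integral
from .structure_io import DomainPartition, PigmentSet
from .tresp import CouplingMatrix

DEFAULT_TEMPERATURE_K = 300.0


@dataclass
class ExcitonDomain:
    """One diagonalized aggregate with thermally weighted exciton states."""

    domain_id: str
    member_ids: list[str]
    hamiltonian: np.ndarray
    eigenvalues: np.ndarray
    coefficients: np.ndarray  # c[i, alpha]: site i in exciton alpha
    weights: np.ndarray
    partition_function: float
    temperature: float
    member_params: list[LineshapeParams]

    def __post_init__(self) -> None:
        n = len(self.member_ids)
        if self.hamiltonian.shape != (n, n):
            raise DomainError("Hamiltonian shape mismatch")
        if not np.allclose(self.hamiltonian, self.hamiltonian.T, atol=1e-9):
            raise DomainError("Hamiltonian must be symmetric")
        gram = self.coefficients.T @ self.coefficients
        if not np.allclose(gram, np.eye(n), atol=1e-10):
            raise DomainError("eigenvectors are not orthonormal")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise DomainError("Boltzmann weights do not sum to 1")

    @property
    def n_pigments(self) -> int:
        return len(self.member_ids)

    def exciton_lineshape(
        self, alpha: int, *, mix_widths: bool = True
    ) -> LineshapeParams:
        """Gaussian parameters of exciton state α.

        Centered at ε_α; FWHM and Stokes shift are the c²-weighted mix of the
        member pigments' parameters (``mix_widths=False`` keeps the first
        member's width/shift for every state).
        """
        if not 0 <= alpha < len(self.eigenvalues):
            raise DomainError(f"exciton index {alpha} out of range")
        if mix_widths:
            w = self.coefficients[:, alpha] ** 2
            fwhm = float(np.dot(w, [p.fwhm for p in self.member_params]))
            stokes = float(np.dot(w, [p.stokes for p in self.member_params]))
        else:
            fwhm = self.member_params[0].fwhm
            stokes = self.member_params[0].stokes
        return LineshapeParams(
            omega0=float(self.eigenvalues[alpha]),
            fwhm=fwhm,
            stokes=stokes,
            sigma_mode=self.member_params[0].sigma_mode,
        )


def build_domain(
    domain_id: str,
    pigments: PigmentSet,
    member_ids: list[str],
    couplings: CouplingMatrix,
    spectral_model: SpectralModel,
    *,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> ExcitonDomain:
    """Diagonalize one aggregate and compute its Boltzmann weights."""
    if temperature <= 0:
        raise RateError(f"temperature must be positive, got {temperature}")
    members = [pigments[i] for i in member_ids]
    params = [spectral_model.params_for(p) for p in members]
    n = len(members)
    H = couplings.submatrix(member_ids, member_ids).copy()
    np.fill_diagonal(H, [p.omega0 for p in params])
    eigenvalues, coefficients = np.linalg.eigh(H)
    # Shift by the lowest eigenvalue before exponentiating: Boltzmann weights
    # are invariant and the exponentials stay in range for any energy scale.
    shifted = (eigenvalues - eigenvalues[0]) / (K_B_CM1 * temperature)
    boltz = np.exp(-shifted)
    Z = float(boltz.sum())
    return ExcitonDomain(
        domain_id=domain_id,
        member_ids=list(member_ids),
        hamiltonian=H,
        eigenvalues=eigenvalues,
        coefficients=coefficients,
        weights=boltz / Z,
        partition_function=Z,
        temperature=temperature,
        member_params=params,
    )


def exciton_coupling(
    donor: ExcitonDomain, acceptor: ExcitonDomain, inter: CouplingMatrix
) -> np.ndarray:
    """Exciton-basis couplings V_αβ = Σ_ij c_iα c_jβ V_ij (cm⁻¹)."""
    V_site = inter.submatrix(donor.member_ids, acceptor.member_ids)
    if V_site.shape != (donor.n_pigments, acceptor.n_pigments):
        raise DomainError("inter-domain coupling block has wrong shape")
    return donor.coefficients.T @ V_site @ acceptor.coefficients


def domain_rate(
    donor: ExcitonDomain,
    acceptor: ExcitonDomain,
    V_ab: np.ndarray,
    *,
    mix_widths: bool = True,
    overlap_method: OverlapMethod = OverlapMethod.CLOSED_FORM,
) -> float:
    """Aggregate-to-aggregate rate k_DA (ps⁻¹), Eqn-weighted over exciton pairs."""
    if donor.temperature <= 0:
        raise RateError("temperature must be positive")
    k = 0.0
    for alpha in range(donor.n_pigments):
        emission = donor.exciton_lineshape(alpha, mix_widths=mix_widths)
        w = float(donor.weights[alpha])
        for beta in range(acceptor.n_pigments):
            absorption = acceptor.exciton_lineshape(beta, mix_widths=mix_widths)
            J = overlap_integral(emission, absorption, overlap_method)
            k += w * float(V_ab[alpha, beta]) ** 2 * J
    return C_RATE_PS * k


@dataclass
class DomainRateMatrix:
    """Directional aggregate-to-aggregate rates k_DA (ps⁻¹)."""

    domain_ids: list[str]
    k: np.ndarray
    n_pigments: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.domain_ids)
        if self.k.shape != (n, n):
            raise RateError(f"DomainRateMatrix: shape {self.k.shape} != ({n},{n})")
        if np.any(self.k < 0):
            raise RateError("DomainRateMatrix: negative rates")

    @property
    def tau(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.k > 0, 1.0 / np.where(self.k > 0, self.k, 1.0), np.inf)

    def rate(self, donor: str, acceptor: str) -> float:
        return float(self.k[self.domain_ids.index(donor), self.domain_ids.index(acceptor)])

    def tau_of(self, donor: str, acceptor: str) -> float:
        r = self.rate(donor, acceptor)
        return 1.0 / r if r > 0 else float("inf")

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        tau = self.tau
        for i, d in enumerate(self.domain_ids):
            for j, a in enumerate(self.domain_ids):
                if i == j:
                    continue
                rows.append(
                    {
                        "donor_domain": d,
                        "acceptor_domain": a,
                        "k_per_ps": self.k[i, j],
                        "tau_ps": tau[i, j],
                        "n_donor_pigments": self.n_pigments.get(d, 0),
                        "n_acceptor_pigments": self.n_pigments.get(a, 0),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# constants={CONSTANTS_VERSION}\n")
            self.to_long_frame().to_csv(fh, index=False)


def all_domain_rates(
    partition: DomainPartition,
    pigments: PigmentSet,
    couplings: CouplingMatrix,
    spectral_model: SpectralModel,
    *,
    temperature: float = DEFAULT_TEMPERATURE_K,
    mix_widths: bool = True,
) -> DomainRateMatrix:
    """Generalized-Förster rates for every ordered domain pair."""
    domains = {
        dom: build_domain(
            dom, pigments, member_ids, couplings, spectral_model, temperature=temperature
        )
        for dom, member_ids in partition.members.items()
    }
    ids = list(domains)
    n = len(ids)
    k = np.zeros((n, n))
    for i, d in enumerate(ids):
        for j, a in enumerate(ids):
            if i == j:
                continue
            V_ab = exciton_coupling(domains[d], domains[a], couplings)
            k[i, j] = domain_rate(domains[d], domains[a], V_ab, mix_widths=mix_widths)
    return DomainRateMatrix(
        domain_ids=ids,
        k=k,
        n_pigments={d: dom.n_pigments for d, dom in domains.items()},
        metadata={
            "temperature_K": temperature,
            "k_B_cm1": K_B_CM1,
            "mix_widths": mix_widths,
            "constants_version": CONSTANTS_VERSION,
        },
    )


def exciton_report(domains: Mapping[str, ExcitonDomain]) -> dict:
    """JSON-serializable per-domain eigenvalues and Boltzmann weights."""
    return {
        dom_id: {
            "eigenvalues_cm1": [float(e) for e in d.eigenvalues],
            "weights": [float(w) for w in d.weights],
            "partition_function": d.partition_function,
            "temperature_K": d.temperature,
            "members": d.member_ids,
        }
        for dom_id, d in domains.items()
    }
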