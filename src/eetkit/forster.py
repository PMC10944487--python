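"""Pairwise Förster rates between chlorophylls.

The transfer rate from donor m to acceptor n is

    T_mn = (2π/ħ) |V_mn|² ∫ dω F_m(ω) A_n(ω)

in ps⁻¹ when V is in cm⁻¹ and the overlap in (cm⁻¹)⁻¹; the prefactor lives in
the constants unit. The time constant τ_mn = 1/T_mn (ps) is the quantity the
transfer-network analysis bins and ranks. The matrix is directional: donor
emission and acceptor absorption enter asymmetrically whenever lineshapes
differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import C_RATE_PS, CONSTANTS_VERSION
from .errors import RateError
from .lineshapes import SpectralModel
from .structure_io import PigmentSet
from .tresp import CouplingMatrix

#: Rates below this floor (ps⁻¹) are dropped from sparse exports; they
#: correspond to time constants beyond 10⁶ ps, far outside the window any
#: transfer-network product uses.
RATE_FLOOR_PS = 1e-6


def pairwise_rate(V: float, J: float) -> float:
    """Förster rate T (ps⁻¹) from a coupling V (cm⁻¹) and overlap J ((cm⁻¹)⁻¹)."""
    if J < 0:
        raise RateError(f"negative spectral overlap: {J}")
    return C_RATE_PS * V * V * J


@dataclass
class RateMatrix:
    """Directional pairwise EET rates T_mn (ps⁻¹) over pigment ids."""

    ids: list[str]
    T: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.T.shape != (n, n):
            raise RateError(f"RateMatrix: shape {self.T.shape} != ({n},{n})")
        if np.any(self.T < 0):
            raise RateError("RateMatrix: negative rates")

    @property
    def tau(self) -> np.ndarray:
        """Time constants τ = 1/T in ps (∞ where T = 0)."""
        with np.errstate(divide="ignore"):
            return np.where(self.T > 0, 1.0 / np.where(self.T > 0, self.T, 1.0), np.inf)

    def rate(self, donor: str, acceptor: str) -> float:
        return float(self.T[self.ids.index(donor), self.ids.index(acceptor)])

    def to_long_frame(
        self, couplings: CouplingMatrix | None = None, *, floor: float = RATE_FLOOR_PS
    ) -> pd.DataFrame:
        rows = []
        tau = self.tau
        n = len(self.ids)
        for i in range(n):
            for j in range(n):
                if i == j or self.T[i, j] < floor:
                    continue
                row = {
                    "donor_id": self.ids[i],
                    "acceptor_id": self.ids[j],
                    "T_per_ps": self.T[i, j],
                    "tau_ps": tau[i, j],
                }
                if couplings is not None:
                    row["V_cm1"] = couplings.V[i, j]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(
        self,
        path: str | Path,
        couplings: CouplingMatrix | None = None,
        *,
        floor: float = RATE_FLOOR_PS,
    ) -> None:
        frame = self.to_long_frame(couplings, floor=floor)
        with open(path, "w") as fh:
            fh.write(f"# constants={CONSTANTS_VERSION} floor_per_ps={floor!r}\n")
            frame.to_csv(fh, index=False)


def rate_matrix(
    couplings: CouplingMatrix,
    spectral_model: SpectralModel,
    pigments: PigmentSet,
) -> RateMatrix:
    """All directional pairwise rates from a coupling matrix and lineshapes."""
    if couplings.ids != pigments.ids:
        raise RateError("coupling matrix and pigment set disagree on ids/order")
    n = len(pigments)
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            J = spectral_model.overlap(pigments[i], pigments[j])
            T[i, j] = pairwise_rate(float(couplings.V[i, j]), J)
    return RateMatrix(
        ids=pigments.ids,
        T=T,
        metadata={
            **couplings.metadata,
            "sigma_mode": {
                p.pigment_type.value: spectral_model.params_for(p).sigma_mode.value
                for p in pigments
            },
            "constants_version": CONSTANTS_VERSION,
        },
    )
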