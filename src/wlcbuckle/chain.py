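"""Physical parameterization of the worm-like chain.

Internally everything runs in the chain's natural dimensionless units:
lengths in units of 2*lp (so the dimensionless contour length is
N = L/(2 lp)), energies in kBT, and forces in kBT/(2 lp).  Dimensional
quantities appear only at the I/O boundary, through :class:`ChainSpec`
and :func:`unit_convert`.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ChainSpec:
    """Worm-like chain parameters.

    Parameters
    ----------
    L : float
        Contour length (length units, e.g. nm).
    lp : float
        Persistence length, lp = kappa/kBT (same length units).
    kBT : float
        Thermal energy (energy units, e.g. pN nm). Defaults to 1.
    """

    L: float
    lp: float
    kBT: float = 1.0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"contour length must be positive, got L={self.L}")
        if self.lp <= 0:
            raise ValueError(f"persistence length must be positive, got lp={self.lp}")
        if self.kBT <= 0:
            raise ValueError(f"thermal energy must be positive, got kBT={self.kBT}")

    @property
    def N(self) -> float:
        """Dimensionless chain length N = L/(2 lp)."""
        return self.L / (2.0 * self.lp)

    @property
    def kappa(self) -> float:
        """Bending modulus kappa = lp * kBT (energy x length)."""
        return self.lp * self.kBT

    @classmethod
    def from_dimensionless(cls, N: float, lp: float = 0.5, kBT: float = 1.0) -> "ChainSpec":
        """Build a chain from N = L/(2 lp); default lp = 1/2 puts L = N."""
        return cls(L=2.0 * lp * N, lp=lp, kBT=kBT)

    # --- unit maps between dimensional and natural (2lp, kBT) units ---

    def length_to_natural(self, x: float) -> float:
        return x / (2.0 * self.lp)

    def length_from_natural(self, x: float) -> float:
        return x * 2.0 * self.lp

    def force_to_natural(self, f: float) -> float:
        """Force in kBT/(2 lp) units from the chain's dimensional force unit."""
        return f * 2.0 * self.lp / self.kBT

    def force_from_natural(self, f: float) -> float:
        return f * self.kBT / (2.0 * self.lp)

    def energy_to_natural(self, e: float) -> float:
        return e / self.kBT

    def energy_from_natural(self, e: float) -> float:
        return e * self.kBT


_UNIT_KIND = {
    "nm": "length", "2lp": "length",
    "pN": "force", "kBT/2lp": "force",
    "J": "energy", "kBT": "energy",
}


def unit_convert(value: float, from_units: str, to_units: str, chain: ChainSpec) -> float:
    """Convert between dimensional and natural units using the chain's lp, kBT.

    Supported pairs: length nm <-> 2lp; force pN <-> kBT/2lp; energy J <-> kBT
    (kBT must then be given in joules).
    """
    if from_units == to_units:
        return value
    kf = _UNIT_KIND.get(from_units)
    kt = _UNIT_KIND.get(to_units)
    if kf is None or kt is None or kf != kt:
        raise ValueError(f"incompatible or unknown unit pair: {from_units!r} -> {to_units!r}")
    if kf == "length":
        return chain.length_to_natural(value) if to_units == "2lp" else chain.length_from_natural(value)
    if kf == "force":
        return chain.force_to_natural(value) if to_units == "kBT/2lp" else chain.force_from_natural(value)
    return chain.energy_to_natural(value) if to_units == "kBT" else chain.energy_from_natural(value)
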