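"""Sensory-perception test design and scoring.

Capsaicin threshold: a geometric 1:2 dilution series of ten swabs, tasted
from the most dilute up; the phenotype is the ordinal swab index (1-10) of
the lowest concentration perceived. Intensities on both the capsaicin and
the PROP (6-n-propylthiouracil) tests are recorded on a 0-100 Labelled
Magnitude Scale; PROP classifies subjects into tasters (score >= 50) and
non-tasters (score < 50).
"""

from __future__ import annotations

from dataclasses import dataclass

TASTER = "taster"
NON_TASTER = "non_taster"


class PerceptionError(Exception):
    pass


@dataclass(frozen=True)
class DilutionSeries:
    """Geometric dilution series; swab 1 is the most dilute, swab n the stock."""

    stock_conc: float  # ug/mL
    factor: float
    n_steps: int
    concentrations: tuple  # index 0 == swab 1

    def swab(self, k: int) -> float:
        """Concentration (ug/mL) on swab k (1-based)."""
        if not 1 <= k <= self.n_steps:
            raise PerceptionError(f"swab index {k} outside 1..{self.n_steps}")
        return self.concentrations[k - 1]


def build_series(stock: float = 2.243, factor: float = 2.0, n: int = 10) -> DilutionSeries:
    """Build the dilution series: swab k holds stock / factor**(n-k).

    Defaults give the ten-step 1:2 capsaicin series from 0.004 to 2.243
    ug/mL; swab n equals the stock exactly.
    """
    if not stock > 0:
        raise PerceptionError(f"stock must be positive, got {stock}")
    if not factor > 1:
        raise PerceptionError(f"factor must exceed 1, got {factor}")
    if n < 2:
        raise PerceptionError(f"need at least 2 steps, got {n}")
    conc = tuple(stock / factor ** (n - k) for k in range(1, n + 1))
    return DilutionSeries(stock_conc=stock, factor=factor, n_steps=n,
                          concentrations=conc)


def classify_prop(lms_score: float) -> str:
    """PROP taster classification at the closed score-50 cut."""
    if not 0 <= lms_score <= 100:
        raise PerceptionError(f"LMS score {lms_score} outside [0, 100]")
    return TASTER if lms_score >= 50 else NON_TASTER


def molar_to_mass_conc(molarity_mm: float, molar_mass_g_mol: float) -> float:
    """Convert a millimolar concentration to mg/mL (e.g. 50 mM PROP at
    170.23 g/mol -> 8.51 mg/mL)."""
    if not molarity_mm > 0:
        raise PerceptionError(f"molarity must be positive, got {molarity_mm}")
    if not molar_mass_g_mol > 0:
        raise PerceptionError(f"molar mass must be positive, got {molar_mass_g_mol}")
    return molarity_mm * molar_mass_g_mol / 1000.0


@dataclass
class PerceptionRecord:
    """Per-subject sensory phenotypes."""

    subject_id: str
    capsaicin_threshold: int | None  # swab index, 1..n_steps
    capsaicin_lms: float | None = None
    prop_lms: float | None = None

    def __post_init__(self) -> None:
        if self.capsaicin_threshold is not None and not 1 <= self.capsaicin_threshold <= 10:
            raise PerceptionError(
                f"capsaicin threshold {self.capsaicin_threshold} outside 1..10"
            )
        for name in ("capsaicin_lms", "prop_lms"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise PerceptionError(f"{name}={v} outside [0, 100]")

    @property
    def prop_class(self) -> str | None:
        return None if self.prop_lms is None else classify_prop(self.prop_lms)
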