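"""Exact-mass arithmetic for small-molecule ions.

Monoisotopic masses, ion m/z conventions, ppm errors, ring/double-bond
equivalents, coarse isotope patterns and exhaustive CHNOS molecular-formula
decomposition.  All mass bookkeeping is done in the neutral frame; the two
ion conventions found in natural-product tables are made explicit through
:class:`IonReading`:

``protonated-neutral``
    the written formula is the neutral molecule M and the observed ion is
    [M+H]+ (m/z = (M + z·m_p)/z);

``formula-is-cation``
    the written formula already includes the charge-carrying proton(s) and
    only the electron deficit must be corrected (m/z = (M − z·m_e)/z).

Mixing these two conventions up shifts a singly charged ion by ~1.0073 Da,
far outside any high-resolution tolerance, so resolving the convention per
compound is part of the data model, not a formatting detail.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ELEMENT_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "Formula",
    "FormulaError",
    "IonReading",
    "PROTONATED",
    "CATION",
    "FormulaCandidate",
    "resolve_reading",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "rdbe",
    "isotope_pattern",
    "decompose_mass",
    "DEFAULT_BOUNDS",
]

#: Monoisotopic atomic masses (Da), IUPAC/AME2020 values.
ELEMENT_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Fe": 55.93493633,
}

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990907

# Heavy-isotope abundances relative to the light isotope, used by the
# first-order (binomial) isotope-pattern approximation.
_M1_ABUNDANCE = {"C": 0.010816, "H": 0.000156, "N": 0.003654, "O": 0.000381, "S": 0.007895}
_M2_ABUNDANCE = {"O": 0.002055, "S": 0.044306}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_CHARGE_SUFFIX = re.compile(r"([+-]+)$")


class FormulaError(ValueError):
    """Raised for unparseable or physically empty formulas."""


@dataclass(frozen=True)
class Formula:
    """An elemental composition with an optional formal charge.

    ``counts`` maps element symbols to non-negative integers; ``charge`` is
    the formal charge carried by the written species (+1 for a cation).  The
    charge annotation records how the formula was written — mass arithmetic
    is always done via :class:`IonReading`, never by inspecting ``charge``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in ELEMENT_MASS:
                raise FormulaError(f"unknown element symbol {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}")
            if n:
                clean[el] = int(n)
        if not clean:
            raise FormulaError("empty formula (no element with a positive count)")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-like string such as ``"C20H20N2O6S+"``."""
        s = text.strip().replace(" ", "")
        if not s:
            raise FormulaError("empty formula string")
        charge = 0
        m = _CHARGE_SUFFIX.search(s)
        if m:
            mult = len(m.group(1))
            charge = mult if m.group(1)[0] == "+" else -mult
            s = s[: m.start()]
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(s):
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at {s[pos:]!r}")
            pos = m.end()
            el, n = m.group(1), int(m.group(2) or 1)
            counts[el] = counts.get(el, 0) + n
        if pos != len(s):
            raise FormulaError(f"cannot parse formula {text!r} at {s[pos:]!r}")
        return cls(counts, charge)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        body = "".join(f"{el}{self.counts[el] if self.counts[el] != 1 else ''}" for el in order)
        if self.charge:
            sign = "+" if self.charge > 0 else "-"
            body += (str(abs(self.charge)) if abs(self.charge) > 1 else "") + sign
        return body

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def total_atoms(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class IonReading:
    """How a written formula maps to an observed positive-ion m/z."""

    mode: str = "protonated-neutral"  # or "formula-is-cation"
    charge: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("protonated-neutral", "formula-is-cation"):
            raise ValueError(f"unknown ion reading mode {self.mode!r}")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")


PROTONATED = IonReading("protonated-neutral")
CATION = IonReading("formula-is-cation")


def monoisotopic_mass(f: Formula) -> float:
    """Neutral-frame monoisotopic mass in Da (no electron correction)."""
    return sum(n * ELEMENT_MASS[el] for el, n in f.counts.items())


def ion_mz(f: Formula, reading: IonReading = PROTONATED) -> float:
    """Observed m/z of the positive ion implied by *f* under *reading*."""
    z = reading.charge
    m = monoisotopic_mass(f)
    if reading.mode == "protonated-neutral":
        return (m + z * PROTON_MASS) / z
    return (m - z * ELECTRON_MASS) / z


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def rdbe(f: Formula) -> float:
    """Ring and double-bond equivalents, C − H/2 + N/2 + 1 (O and S neutral)."""
    return f["C"] - f["H"] / 2.0 + f["N"] / 2.0 + 1.0


def isotope_pattern(f: Formula, n_peaks: int = 3) -> list[float]:
    """Coarse relative intensities of M, M+1, M+2 (M normalised to 1).

    First-order binomial approximation: M+1 sums single heavy-isotope
    substitutions, M+2 sums the two-mass-unit isotopes (18O, 34S) plus the
    double-13C term.  Adequate as the qualitative plausibility check used in
    compound identification; not a fine-structure prediction.
    """
    m1 = sum(f[el] * p for el, p in _M1_ABUNDANCE.items())
    nC = f["C"]
    m2 = sum(f[el] * p for el, p in _M2_ABUNDANCE.items())
    m2 += (nC * (nC - 1) / 2.0) * _M1_ABUNDANCE["C"] ** 2
    return [1.0, m1, m2][:n_peaks]


@dataclass(frozen=True)
class FormulaCandidate:
    """One proposed elemental composition for an observed ion."""

    formula: Formula
    theoretical_mz: float
    ppm: float
    rdbe: float


#: Default CHNOS search bounds for decomposition; wide enough to cover
#: sulfur-bearing natural products up to ~750 Da with a small search space.
DEFAULT_BOUNDS: dict[str, int] = {"C": 60, "H": 80, "N": 6, "O": 15, "S": 3}


def decompose_mass(
    target_mz: float,
    reading: IonReading = PROTONATED,
    tol_ppm: float = 3.0,
    bounds: Mapping[str, int] | None = None,
    min_rdbe: float = -0.5,
    nitrogen_rule: bool = False,
) -> list[FormulaCandidate]:
    """Enumerate CHNOS formulas whose ion m/z falls within *tol_ppm* of target.

    The search is exhaustive over the bounded CHNOS lattice; hydrogen is
    solved from the mass residual rather than looped, which keeps the
    enumeration exact but fast.  Candidates are ranked by |ppm| ascending,
    ties broken by smaller total atom count.
    """
    if target_mz <= 0:
        raise ValueError("target m/z must be positive")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    z = reading.charge
    # Neutral-frame mass to decompose.
    if reading.mode == "protonated-neutral":
        neutral = target_mz * z - z * PROTON_MASS
    else:
        neutral = target_mz * z + z * ELECTRON_MASS
    tol_da = abs(target_mz) * z * tol_ppm * 1e-6
    mC, mH, mN, mO, mS = (ELEMENT_MASS[e] for e in "CHNOS")

    out: list[FormulaCandidate] = []
    for nS in range(b.get("S", 0) + 1):
        base_s = nS * mS
        if base_s > neutral + tol_da:
            break
        for nO in range(b.get("O", 0) + 1):
            base_o = base_s + nO * mO
            if base_o > neutral + tol_da:
                break
            for nN in range(b.get("N", 0) + 1):
                base_n = base_o + nN * mN
                if base_n > neutral + tol_da:
                    break
                for nC in range(b.get("C", 0) + 1):
                    rem = neutral - base_n - nC * mC
                    if rem < -tol_da:
                        break
                    h0 = int(round(rem / mH))
                    for nH in range(max(h0 - 1, 0), min(h0 + 1, b.get("H", 0)) + 1):
                        counts = {"C": nC, "H": nH, "N": nN, "O": nO, "S": nS}
                        if not any(counts.values()):
                            continue
                        try:
                            f = Formula(counts)
                        except FormulaError:
                            continue
                        mz = ion_mz(f, reading)
                        p = ppm_error(target_mz, mz)
                        if abs(p) > tol_ppm:
                            continue
                        r = rdbe(f)
                        if r < min_rdbe:
                            continue
                        if nitrogen_rule and (f["N"] % 2) != (int(round(monoisotopic_mass(f))) % 2):
                            continue
                        out.append(FormulaCandidate(f, mz, p, r))
    out.sort(key=lambda c: (abs(c.ppm), c.formula.total_atoms()))
    # De-duplicate (the H window can visit a composition twice at boundaries).
    seen: set[str] = set()
    unique = []
    for c in out:
        key = str(c.formula)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    return unique


def resolve_reading(
    formula: Formula, printed_mz: float, tol_ppm: float = 1.0
) -> IonReading | None:
    """Determine which ion convention reproduces a printed m/z.

    Returns the :class:`IonReading` whose theoretical m/z lies within
    *tol_ppm* of *printed_mz* (preferring the closer one when both do), or
    None when neither convention agrees — the printed pair is then
    internally inconsistent and should be excluded from mass arithmetic.
    """
    candidates = []
    for reading in (CATION, PROTONATED):
        p = ppm_error(printed_mz, ion_mz(formula, reading))
        if abs(p) <= tol_ppm:
            candidates.append((abs(p), reading))
    if not candidates:
        return None
    return min(candidates)[1]
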