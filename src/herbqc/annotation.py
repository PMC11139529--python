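"""Monoisotopic mass computation and negative-mode adduct annotation.

Peaks from a high-resolution negative-ion run are matched to candidate
elemental formulas through their deprotonated ([M-H]-) or formate
([M+HCOO]-) adducts, and the match quality is reported as a mass error in
milli-dalton (mDa).

Ion masses follow the electron-inclusive convention: the [M-H]- ion mass is
the neutral monoisotopic mass minus the proton mass (1.007276 Da), and the
formate adduct adds the mass of the formate anion (44.998203 Da, electron
included).  Reported theoretical m/z values are displayed at five decimal
places and mass errors are computed from the displayed value with half-even
rounding, matching the behaviour of vendor annotation software.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "FORMATE_ANION_MASS",
    "ADDUCTS",
    "ElementFormula",
    "AdductSpec",
    "AnnotatedPeak",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "mass_error_mda",
    "annotate_table",
    "annotate_csv",
]

#: Monoisotopic masses (Da) of the elements that occur in the compound classes
#: handled here (gallotannins, phenolic acids, amino acids, flavonoids).
MONOISOTOPIC_MASSES: dict[str, float] = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

PROTON_MASS = 1.007276  # Da, electron-inclusive deprotonation
FORMATE_ANION_MASS = 44.998203  # Da, HCOO- including the electron


@dataclass(frozen=True)
class AdductSpec:
    """A supported negative-mode adduct.

    Attributes
    ----------
    name:
        Adduct label, e.g. ``"[M-H]-"``.
    mass_shift:
        Signed shift (Da) added to the neutral monoisotopic mass to obtain
        the ion m/z.  Electron-inclusive.
    charge:
        Ion charge (always -1 for the supported adducts).
    """

    name: str
    mass_shift: float
    charge: int = -1


ADDUCTS: dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS),
    "[M+HCOO]-": AdductSpec("[M+HCOO]-", FORMATE_ANION_MASS),
}


@dataclass(frozen=True)
class ElementFormula:
    """An elemental composition as a symbol -> count mapping."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for element, count in self.counts.items():
            if element not in MONOISOTOPIC_MASSES:
                raise ValueError(f"unrecognized element symbol: {element!r}")
            if not isinstance(count, int) or count < 1:
                raise ValueError(
                    f"count for {element} must be a positive integer, got {count!r}"
                )
        object.__setattr__(self, "counts", dict(self.counts))

    def __str__(self) -> str:
        # Hill order: C, H, then remaining elements alphabetically.
        symbols = sorted(
            self.counts, key=lambda s: {"C": "0", "H": "1"}.get(s, s)
        )
        return "".join(
            f"{s}{self.counts[s]}" if self.counts[s] > 1 else s for s in symbols
        )


@dataclass
class AnnotatedPeak:
    """One chromatographic peak with its best formula assignment."""

    peak_no: int
    rt: float
    observed_mz: float
    adduct: AdductSpec
    formula: ElementFormula | None = None
    theoretical_mz: float | None = None
    mass_error: float | None = None
    name: str = ""
    compound_class: str = ""
    matched: bool = False


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementFormula:
    """Parse a molecular-formula string such as ``"C7H6O5"``.

    Omitted counts default to 1; repeated element symbols are summed.
    Raises ``ValueError`` on empty input, unknown symbols, or stray
    characters.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC_MASSES:
            raise ValueError(f"unrecognized element symbol {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return ElementFormula(counts)


def monoisotopic_mass(formula: ElementFormula | Mapping[str, int] | str) -> float:
    """Neutral monoisotopic mass (Da) of a formula.

    Accepts an :class:`ElementFormula`, a plain mapping, or a formula string.
    An empty mapping yields 0.0.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    counts = formula.counts if isinstance(formula, ElementFormula) else formula
    total = 0.0
    for element, count in counts.items():
        try:
            total += MONOISOTOPIC_MASSES[element] * count
        except KeyError:
            raise ValueError(f"no tabulated monoisotopic mass for {element!r}")
    return total


def _resolve_adduct(adduct: AdductSpec | str) -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        )


def adduct_mz(
    formula: ElementFormula | Mapping[str, int] | str, adduct: AdductSpec | str
) -> float:
    """Theoretical ion m/z (Th) for ``formula`` observed as ``adduct``."""
    spec = _resolve_adduct(adduct)
    return monoisotopic_mass(formula) + spec.mass_shift


def _display_mz(mz: float) -> float:
    """Round an m/z value to the 5-decimal display precision."""
    return float(Decimal(repr(mz)).quantize(Decimal("0.00001"), ROUND_HALF_EVEN))


def mass_error_mda(observed: float, theoretical: float) -> float:
    """Mass error in mDa, rounded half-even to one decimal for reporting."""
    raw = (Decimal(repr(observed)) - Decimal(repr(theoretical))).scaleb(3)
    return float(raw.quantize(Decimal("0.1"), ROUND_HALF_EVEN))


def annotate_table(
    peaks: Sequence[tuple[float, float, AdductSpec | str]],
    candidates: Sequence[tuple[str, ElementFormula | str, str]],
    tolerance: float = 5.0,
) -> list[AnnotatedPeak]:
    """Match observed peaks against candidate formulas.

    Parameters
    ----------
    peaks:
        ``(rt_min, observed_mz, adduct)`` triples.
    candidates:
        ``(name, formula, compound_class)`` triples.
    tolerance:
        Maximum absolute mass error (mDa) for a match.

    Each peak is assigned the candidate with the smallest absolute mass
    error within tolerance (ties broken by candidate order); peaks with no
    candidate inside the tolerance are returned with ``matched=False``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not candidates:
        raise ValueError("candidate list is empty")
    prepared = [
        (name, f if isinstance(f, ElementFormula) else parse_formula(f), cls)
        for name, f, cls in candidates
    ]
    out: list[AnnotatedPeak] = []
    for i, (rt, observed, adduct) in enumerate(peaks, start=1):
        spec = _resolve_adduct(adduct)
        best: AnnotatedPeak | None = None
        best_abs = float("inf")
        for name, formula, cls in prepared:
            theo = _display_mz(adduct_mz(formula, spec))
            err = mass_error_mda(observed, theo)
            if abs(err) <= tolerance and abs(err) < best_abs:
                best_abs = abs(err)
                best = AnnotatedPeak(
                    peak_no=i,
                    rt=rt,
                    observed_mz=observed,
                    adduct=spec,
                    formula=formula,
                    theoretical_mz=theo,
                    mass_error=err,
                    name=name,
                    compound_class=cls,
                    matched=True,
                )
        if best is None:
            best = AnnotatedPeak(peak_no=i, rt=rt, observed_mz=observed, adduct=spec)
        out.append(best)
    return out


def annotate_csv(table: pd.DataFrame, tolerance: float = 5.0) -> pd.DataFrame:
    """Annotate a compound table where each row carries its own candidate.

    Expects columns ``peak_no, rt_min, observed_mz, adduct, formula, name,
    class`` and appends ``theoretical_mz, mass_error_mda, matched``.
    """
    required = {"peak_no", "rt_min", "observed_mz", "adduct", "formula"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    theo, errors, matched = [], [], []
    for row in table.itertuples(index=False):
        t = _display_mz(adduct_mz(parse_formula(row.formula), row.adduct))
        e = mass_error_mda(float(row.observed_mz), t)
        theo.append(t)
        errors.append(e)
        matched.append(abs(e) <= tolerance)
    out = table.copy()
    out["theoretical_mz"] = theo
    out["mass_error_mda"] = errors
    out["matched"] = matched
    return out
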