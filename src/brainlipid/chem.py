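"""Lipid shorthand parsing, monoisotopic masses, and lysophospholipid MS/MS annotation.

Supports the shorthand nomenclature used in brain lipidomics feature tables
("LPE 22:6", "TAG 18:0_18:1_20:4", "PC_e 34:1"), assembles glycerophospholipid
molecular formulas from backbone + acyl accounting, predicts negative-mode
fragments of lysophospholipids, and assigns the glycerol sn-position of the
single acyl chain from MS/MS spectra.

The sn-position logic encodes two regiochemistry rules for lyso-species:

* an sn-1 acyl lysophosphatidylethanolamine yields a headgroup-retention
  fragment (the dehydrated, deprotonated glycerophosphoethanolamine anion,
  C5H11NO5P-, nominal m/z 196) in addition to the intact [M-H]- ion and the
  fatty acyl carboxylate anion; the sn-2 isomer lacks it;
* on C18 reversed-phase chromatography the sn-2 isomer elutes before the
  sn-1 isomer, usable as confirmation when two co-eluting isomer peaks are
  observed.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

# IUPAC monoisotopic atomic masses (u), >=5 decimals.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "D": 2.01410177785,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}
ELECTRON_MASS = 0.00054857990907
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.00727645216

CO2_MASS = MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["O"]

#: Lipid class codes recognised by the parser, mapped to the number of acyl
#: (or ether) chains a chain-level annotation carries.
LIPID_CLASS_CHAINS = {
    "AcCa": 1,
    "Cer": 2,
    "ChE": 1,
    "GSL": 2,
    "LPC": 1,
    "LPE": 1,
    "MAG": 1,
    "PC": 2,
    "PC_e": 2,
    "PE": 2,
    "PE_e": 2,
    "PE_p": 2,
    "PG": 2,
    "PI": 2,
    "PS": 2,
    "DAG": 2,
    "SM": 2,
    "TAG": 3,
}

#: Neutral glycerophospho-headgroup backbones (glycerol + phosphate +
#: headgroup alcohol, fully condensed, free hydroxyls at sn-1/sn-2).
_GPL_BACKBONE = {
    "LPE": {"C": 5, "H": 14, "N": 1, "O": 6, "P": 1},
    "PE": {"C": 5, "H": 14, "N": 1, "O": 6, "P": 1},
    "LPC": {"C": 8, "H": 20, "N": 1, "O": 6, "P": 1},
    "PC": {"C": 8, "H": 20, "N": 1, "O": 6, "P": 1},
    "PG": {"C": 6, "H": 15, "N": 0, "O": 8, "P": 1},
    "PS": {"C": 6, "H": 14, "N": 1, "O": 8, "P": 1},
    "PI": {"C": 9, "H": 19, "N": 0, "O": 11, "P": 1},
}


class LipidParseError(ValueError):
    """Raised when a lipid shorthand name cannot be parsed."""


class SnPosition(str, Enum):
    SN1 = "sn1"
    SN2 = "sn2"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Chain:
    """A single acyl/alkyl chain: carbons, double bonds, ether linkage flag."""

    carbons: int
    double_bonds: int
    ether: bool = False
    deuterium: int = 0

    def __str__(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        if self.deuterium:
            s += f"D{self.deuterium}"
        if self.ether:
            s += "e"
        return s


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid annotation.

    ``chain_level_known`` distinguishes chain-level names ("TAG 18:0_18:1_20:4")
    from species-level sum compositions ("TAG 56:5"); for the latter ``chains``
    is empty and only the totals are populated.
    """

    name: str
    lipid_class: str
    chains: tuple[Chain, ...]
    total_carbons: int
    total_double_bonds: int
    chain_level_known: bool
    ether: bool = False
    plasmalogen: bool = False
    sn_annotation: Optional[str] = None  # "sn-1" / "sn-2" if annotated

    def __post_init__(self):
        if self.chain_level_known and self.chains:
            if sum(c.carbons for c in self.chains) != self.total_carbons:
                raise ValueError("total_carbons inconsistent with chains")
            if sum(c.double_bonds for c in self.chains) != self.total_double_bonds:
                raise ValueError("total_double_bonds inconsistent with chains")
        if self.lipid_class in ("LPC", "LPE") and self.chain_level_known:
            if len(self.chains) != 1:
                raise ValueError(f"{self.lipid_class} must have exactly one chain")


_CHAIN_RE = re.compile(r"^(\d+):(\d+)(?:D(\d+))?([ep])?$")
_SN_RE = re.compile(r"\s*\[(sn-[12])\]\s*$")


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Examples: "LPE 22:6", "TAG 18:0_18:1_20:4", "LPE 18:1e",
    "LPE 22:6 [sn-1]", "LPE 18:1D7" (deuterated internal standard).
    """
    if not name or not name.strip():
        raise LipidParseError("empty lipid name")
    work = name.strip()
    sn_annotation = None
    m = _SN_RE.search(work)
    if m:
        sn_annotation = m.group(1)
        work = work[: m.start()].strip()
    parts = work.split(None, 1)
    if len(parts) != 2:
        raise LipidParseError(f"cannot split class and chains in {name!r}")
    cls, chain_str = parts
    if cls not in LIPID_CLASS_CHAINS:
        raise LipidParseError(f"unknown lipid class {cls!r} in {name!r}")
    expected = LIPID_CLASS_CHAINS[cls]
    tokens = re.split(r"[_/]", chain_str)
    chains = []
    for tok in tokens:
        m = _CHAIN_RE.match(tok)
        if not m:
            raise LipidParseError(f"unparseable chain token {tok!r} in {name!r}")
        carbons, dbs = int(m.group(1)), int(m.group(2))
        deut = int(m.group(3)) if m.group(3) else 0
        chains.append(Chain(carbons, dbs, ether=m.group(4) in ("e", "p"), deuterium=deut))
    plasmalogen = cls.endswith("_p") or any(
        _CHAIN_RE.match(t).group(4) == "p" for t in tokens
    )
    ether = cls.endswith(("_e", "_p")) or any(c.ether for c in chains)
    if len(tokens) == expected:
        chain_level = True
        total_c = sum(c.carbons for c in chains)
        total_db = sum(c.double_bonds for c in chains)
    elif len(tokens) == 1 and expected > 1:
        # species-level sum composition
        chain_level = False
        total_c, total_db = chains[0].carbons, chains[0].double_bonds
        ether = ether or chains[0].ether
        chains = []
    else:
        raise LipidParseError(
            f"{cls} expects {expected} chains, got {len(tokens)} in {name!r}"
        )
    return LipidSpecies(
        name=name.strip(),
        lipid_class=cls,
        chains=tuple(chains),
        total_carbons=total_c,
        total_double_bonds=total_db,
        chain_level_known=chain_level,
        ether=ether,
        plasmalogen=plasmalogen,
        sn_annotation=sn_annotation,
    )


def format_lipid_name(species: LipidSpecies) -> str:
    """Canonical shorthand for a species; inverse of :func:`parse_lipid_name`."""
    if species.chain_level_known:
        chain_str = "_".join(str(c) for c in species.chains)
    else:
        chain_str = f"{species.total_carbons}:{species.total_double_bonds}"
        if species.ether and not species.lipid_class.endswith(("_e", "_p")):
            chain_str += "e"
    s = f"{species.lipid_class} {chain_str}"
    if species.sn_annotation:
        s += f" [{species.sn_annotation}]"
    return s


@dataclass(frozen=True)
class Formula:
    """Element counts (C, H, N, O, P, D) plus a signed charge."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0
    D: int = 0
    charge: int = 0

    def __post_init__(self):
        for el in ("C", "H", "N", "O", "P", "D"):
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")

    def __add__(self, other: "Formula") -> "Formula":
        return Formula(
            *(getattr(self, e) + getattr(other, e) for e in ("C", "H", "N", "O", "P", "D")),
            charge=self.charge + other.charge,
        )

    def __sub__(self, other: "Formula") -> "Formula":
        return Formula(
            *(getattr(self, e) - getattr(other, e) for e in ("C", "H", "N", "O", "P", "D")),
            charge=self.charge - other.charge,
        )

    @property
    def monoisotopic_mass(self) -> float:
        """Monoisotopic mass in u, including the electron surplus/deficit of the charge."""
        m = sum(
            getattr(self, el) * MONOISOTOPIC_MASS[el] for el in ("C", "H", "N", "O", "P", "D")
        )
        return m - self.charge * ELECTRON_MASS

    def hill(self) -> str:
        parts = []
        for el in ("C", "H", "D", "N", "O", "P"):
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


WATER = Formula(H=2, O=1)

#: Negative-mode headgroup-retention diagnostic of sn-1 acyl LPE:
#: glycerophosphoethanolamine - H2O, deprotonated (C5H11NO5P-), nominal m/z 196.
LPE_SN1_DIAGNOSTIC_ANION = Formula(C=5, H=11, N=1, O=5, P=1, charge=-1)


def acyl_chain_formula(chain: Chain) -> Formula:
    """Neutral formula of a chain as free fatty acid (ester) or fatty alcohol (ether)."""
    c, d, nd = chain.carbons, chain.double_bonds, chain.deuterium
    if chain.ether:
        h = 2 * c + 2 - 2 * d
        o = 1
    else:
        h = 2 * c - 2 * d
        o = 2
    if nd > h:
        raise ValueError("more deuteriums than hydrogens")
    return Formula(C=c, H=h - nd, O=o, D=nd)


def molecular_formula(species: LipidSpecies, form: str = "neutral") -> Formula:
    """Neutral molecular formula of a glycerophospholipid from backbone + chain accounting.

    The glycerophospho-headgroup backbone keeps free hydroxyls at the acyl
    positions; each esterified (or etherified) chain condenses with loss of
    one water.
    """
    if species.lipid_class not in _GPL_BACKBONE:
        raise NotImplementedError(
            f"formula assembly not implemented for class {species.lipid_class}"
        )
    if not species.chain_level_known or not species.chains:
        raise ValueError(f"chain-level annotation required for {species.name!r}")
    f = Formula(**_GPL_BACKBONE[species.lipid_class])
    for chain in species.chains:
        f = f + acyl_chain_formula(chain) - WATER
    if form not in ("neutral", "ion_adduct"):
        raise ValueError(f"unknown form {form!r}")
    return f


def monoisotopic_mz(formula: Formula, adduct: str) -> float:
    """m/z (Th) of a singly charged ion.

    ``adduct`` is one of ``[M-H]-`` / ``[M+H]+`` (applied to a neutral
    formula) or ``fragment_anion`` (the formula is already the anion's
    composition with charge -1).
    """
    if adduct == "[M-H]-":
        if formula.charge != 0:
            raise ValueError("[M-H]- expects a neutral formula")
        return formula.monoisotopic_mass - PROTON_MASS
    if adduct == "[M+H]+":
        if formula.charge != 0:
            raise ValueError("[M+H]+ expects a neutral formula")
        return formula.monoisotopic_mass + PROTON_MASS
    if adduct == "fragment_anion":
        if formula.charge != -1:
            raise ValueError("fragment_anion expects charge -1")
        return formula.monoisotopic_mass
    raise ValueError(f"unknown adduct {adduct!r}")


def nominal_mz(mz: float) -> int:
    """Nominal (unit-resolution) m/z: round half away from zero."""
    return int(math.floor(abs(mz) + 0.5)) * (1 if mz >= 0 else -1)


@dataclass(frozen=True)
class FragmentPrediction:
    label: str
    mz: float
    diagnostic_sn1: bool = False


def predict_lyso_fragments(
    species: LipidSpecies, polarity: str = "-"
) -> list[FragmentPrediction]:
    """Theoretical negative-mode fragments of a lysophospholipid.

    Returns the intact [M-H]- ion, the fatty acyl carboxylate anion, the
    acyl anion after CO2 loss, and — for LPE — the sn-1 headgroup-retention
    diagnostic (C5H11NO5P-, m/z 196.038). The diagnostic carries no chain
    atoms, so it is insensitive to chain deuteration (the property that makes
    the 18:1D7 LPE internal standard a valid positive control).
    """
    if polarity != "-":
        raise NotImplementedError("only negative-mode fragments are implemented")
    if species.lipid_class not in ("LPE", "LPC"):
        raise NotImplementedError(
            f"lyso fragment prediction supports LPE/LPC, not {species.lipid_class}"
        )
    if not species.chains:
        raise ValueError("chain-level annotation required")
    chain = species.chains[0]
    if chain.ether:
        raise NotImplementedError("ether lyso fragment prediction not implemented")
    neutral = molecular_formula(species)
    intact = monoisotopic_mz(neutral, "[M-H]-")
    acyl_anion = acyl_chain_formula(chain) + Formula(charge=-1)
    acyl_anion = Formula(
        C=acyl_anion.C, H=acyl_anion.H - 1, N=acyl_anion.N, O=acyl_anion.O,
        P=acyl_anion.P, D=acyl_anion.D, charge=-1,
    )  # deprotonated carboxylate
    acyl_mz = monoisotopic_mz(acyl_anion, "fragment_anion")
    decarb = acyl_anion - Formula(C=1, O=2)
    frags = [
        FragmentPrediction("[M-H]-", intact),
        FragmentPrediction("acyl anion", acyl_mz),
        FragmentPrediction("acyl-CO2", monoisotopic_mz(decarb, "fragment_anion")),
    ]
    if species.lipid_class == "LPE":
        frags.append(
            FragmentPrediction(
                "sn1 headgroup diagnostic",
                monoisotopic_mz(LPE_SN1_DIAGNOSTIC_ANION, "fragment_anion"),
                diagnostic_sn1=True,
            )
        )
    return frags


@dataclass
class MsmsSpectrum:
    """An MS/MS spectrum: precursor m/z, polarity, optional RT (min), peak list."""

    precursor_mz: float
    polarity: str  # '+' or '-'
    peaks: list[tuple[float, float]] = field(default_factory=list)
    retention_time: Optional[float] = None
    title: str = ""

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p[0])
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")


@dataclass
class MatchedFragment:
    label: str
    theoretical_mz: float
    observed_mz: float
    ppm_error: float
    diagnostic_sn1: bool = False


@dataclass
class SnCall:
    """Outcome of sn-position assignment for a lysophospholipid spectrum."""

    call: SnPosition
    evidence: list[MatchedFragment] = field(default_factory=list)
    rt_rule_applied: bool = False
    note: str = ""


def _match_peak(
    peaks: Sequence[tuple[float, float]], mz: float, ppm_tol: float
) -> Optional[tuple[float, float]]:
    tol = mz * ppm_tol * 1e-6
    best = None
    for pmz, inten in peaks:
        if abs(pmz - mz) <= tol:
            if best is None or abs(pmz - mz) < abs(best[0] - mz):
                best = (pmz, inten)
    return best


def assign_sn_position(
    spectrum: MsmsSpectrum,
    species: LipidSpecies,
    ppm_tol: float = 10.0,
    rt_context: Optional[tuple[float, float]] = None,
) -> SnCall:
    """Assign sn-1 vs sn-2 for a lyso-species from its negative-mode spectrum.

    sn-1 requires the headgroup-retention diagnostic fragment (plus intact and
    acyl ions) within ``ppm_tol``; intact + acyl without the diagnostic calls
    sn-2. ``rt_context = (rt_this, rt_other_isomer)`` applies the C18
    retention-order rule (later-eluting isomer is sn-1); a spectral diagnostic
    outranks the retention rule on conflict, which is logged.

    LPC has no validated negative-mode diagnostic here, so spectral LPC calls
    fall back to the retention rule alone.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    if species.lipid_class not in ("LPC", "LPE"):
        raise NotImplementedError("sn assignment supports LPC/LPE only")
    if spectrum.polarity != "-":
        raise NotImplementedError("only negative-mode spectra supported")

    frags = predict_lyso_fragments(species)
    matches: list[MatchedFragment] = []
    for fr in frags:
        hit = _match_peak(spectrum.peaks, fr.mz, ppm_tol)
        if hit is not None:
            matches.append(
                MatchedFragment(
                    fr.label, fr.mz, hit[0], (hit[0] - fr.mz) / fr.mz * 1e6, fr.diagnostic_sn1
                )
            )

    labels = {m.label for m in matches}
    has_intact = "[M-H]-" in labels
    has_acyl = "acyl anion" in labels or "acyl-CO2" in labels
    has_diag = any(m.diagnostic_sn1 for m in matches)

    spectral_call = SnPosition.AMBIGUOUS
    if species.lipid_class == "LPE" and has_intact and has_acyl:
        spectral_call = SnPosition.SN1 if has_diag else SnPosition.SN2

    rt_call = SnPosition.AMBIGUOUS
    if rt_context is not None:
        rt_this, rt_other = rt_context
        if rt_this != rt_other:
            rt_call = SnPosition.SN1 if rt_this > rt_other else SnPosition.SN2

    if spectral_call is not SnPosition.AMBIGUOUS:
        note = ""
        if rt_call is not SnPosition.AMBIGUOUS and rt_call is not spectral_call:
            note = "retention-order rule conflicts with spectral diagnostic; spectral call kept"
            logger.warning("%s for %s", note, species.name)
        return SnCall(spectral_call, matches, rt_rule_applied=False, note=note)
    if rt_call is not SnPosition.AMBIGUOUS:
        return SnCall(rt_call, matches, rt_rule_applied=True)
    return SnCall(SnPosition.AMBIGUOUS, matches)
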