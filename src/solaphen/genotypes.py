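"""CYP2D6 diplotype parsing and genotype-predicted phenotype translation.

The supported pharmacogenetic panel covers eight star alleles: the
lack-of-function ("Def") alleles *3, *4, *5 and *6, the reduced-function
("Red") alleles *9, *10 and *41, and the fully functional wild-type *1.
Copy-number analysis may report a duplication ("xN"); when a duplication
co-occurs with a Red or Def allele the assay cannot resolve which allele
was duplicated, so such diplotypes are flagged INCONCLUSIVE and kept out
of the threshold and regression analyses.

Phenotype grouping follows the DPWG/CPIC consensus translation used in
the source dataset: PM = Def/def, IM = {Def/red, Red/red, *1/def},
NM = {*1/red, *1/*1}, UM = *1/*1 xN.  Note this places *1/red in NM,
which differs from the current CPIC activity-score boundary (activity
score 1.25-2.25 for NM); the historical grouping is implemented
deliberately so downstream numbers are comparable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = [
    "FunctionalClass",
    "Phenotype",
    "GenotypeGroup",
    "Allele",
    "Diplotype",
    "PhenotypeCall",
    "SUPPORTED_ALLELES",
    "classify_allele",
    "parse_allele",
    "parse_diplotype",
    "phenotype_of",
    "annotate_genotypes",
]


class FunctionalClass(str, Enum):
    FUNCTIONAL = "functional"
    REDUCED = "reduced"
    DEFECTIVE = "defective"


class Phenotype(str, Enum):
    PM = "PM"
    IM = "IM"
    NM = "NM"
    UM = "UM"
    INCONCLUSIVE = "inconclusive"


class GenotypeGroup(str, Enum):
    """Diplotype functional-class groups, labelled as in clinical reports."""

    STAR1_xN = "*1/*1xN"
    STAR1_STAR1 = "*1/*1"
    STAR1_RED = "*1/red"
    STAR1_DEF = "*1/def"
    RED_RED = "Red/red"
    DEF_RED = "Def/red"
    DEF_DEF = "Def/def"
    STAR1_RED_xN = "*1/red xN"
    STAR1_DEF_xN = "*1/def xN"
    RED_DEF_xN = "Red/def xN"
    # Not observed in the source cohort; included so every supported
    # diplotype maps to exactly one group.  Both are inconclusive.
    RED_RED_xN = "Red/red xN"
    DEF_DEF_xN = "Def/def xN"


#: Star-allele functional classes for the 8-allele panel.
SUPPORTED_ALLELES: dict[str, FunctionalClass] = {
    "*1": FunctionalClass.FUNCTIONAL,
    "*3": FunctionalClass.DEFECTIVE,
    "*4": FunctionalClass.DEFECTIVE,
    "*5": FunctionalClass.DEFECTIVE,
    "*6": FunctionalClass.DEFECTIVE,
    "*9": FunctionalClass.REDUCED,
    "*10": FunctionalClass.REDUCED,
    "*41": FunctionalClass.REDUCED,
}

_ALLELE_RE = re.compile(r"^\s*(\*\d+)\s*(?:[xX]\s*(N|\d+))?\s*$")


@dataclass(frozen=True)
class Allele:
    star_name: str
    functional_class: FunctionalClass
    copy_number: int = 1

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")

    @property
    def duplicated(self) -> bool:
        return self.copy_number > 1


@dataclass(frozen=True)
class Diplotype:
    allele_a: Allele
    allele_b: Allele

    @property
    def has_duplication(self) -> bool:
        return self.allele_a.duplicated or self.allele_b.duplicated


@dataclass(frozen=True)
class PhenotypeCall:
    phenotype: Phenotype
    genotype_group: GenotypeGroup


def classify_allele(star_name: str) -> FunctionalClass:
    """Functional class of a star allele; a duplication suffix is allowed."""
    return parse_allele(star_name).functional_class


def parse_allele(text: str) -> Allele:
    """Parse a star-allele string such as ``"*4"``, ``"*1xN"`` or ``"*1x2"``.

    The generic laboratory suffix ``xN`` (unknown copy count > 1) is
    parsed as copy_number 2.
    """
    m = _ALLELE_RE.match(text)
    if m is None:
        raise ValueError(f"unrecognized CYP2D6 allele syntax: {text!r}")
    star, copies = m.group(1), m.group(2)
    if star not in SUPPORTED_ALLELES:
        raise ValueError(
            f"unknown CYP2D6 allele {star!r}; supported panel: "
            + ", ".join(SUPPORTED_ALLELES)
        )
    copy_number = 1
    if copies is not None:
        copy_number = 2 if copies in ("N", "n") else int(copies)
        if copy_number < 2:
            raise ValueError(f"duplication suffix with copy number < 2: {text!r}")
    return Allele(star, SUPPORTED_ALLELES[star], copy_number)


def parse_diplotype(text: str) -> Diplotype:
    """Parse a diplotype string such as ``"*1/*4"`` or ``"*1xN / *41"``."""
    parts = text.split("/")
    if len(parts) != 2:
        raise ValueError(f"diplotype must contain exactly one '/': {text!r}")
    return Diplotype(parse_allele(parts[0]), parse_allele(parts[1]))


_NO_DUP_GROUPS = {
    (FunctionalClass.FUNCTIONAL, FunctionalClass.FUNCTIONAL): (
        Phenotype.NM, GenotypeGroup.STAR1_STAR1),
    (FunctionalClass.FUNCTIONAL, FunctionalClass.REDUCED): (
        Phenotype.NM, GenotypeGroup.STAR1_RED),
    (FunctionalClass.FUNCTIONAL, FunctionalClass.DEFECTIVE): (
        Phenotype.IM, GenotypeGroup.STAR1_DEF),
    (FunctionalClass.REDUCED, FunctionalClass.REDUCED): (
        Phenotype.IM, GenotypeGroup.RED_RED),
    (FunctionalClass.REDUCED, FunctionalClass.DEFECTIVE): (
        Phenotype.IM, GenotypeGroup.DEF_RED),
    (FunctionalClass.DEFECTIVE, FunctionalClass.DEFECTIVE): (
        Phenotype.PM, GenotypeGroup.DEF_DEF),
}

_DUP_GROUPS = {
    (FunctionalClass.FUNCTIONAL, FunctionalClass.FUNCTIONAL): (
        Phenotype.UM, GenotypeGroup.STAR1_xN),
    (FunctionalClass.FUNCTIONAL, FunctionalClass.REDUCED): (
        Phenotype.INCONCLUSIVE, GenotypeGroup.STAR1_RED_xN),
    (FunctionalClass.FUNCTIONAL, FunctionalClass.DEFECTIVE): (
        Phenotype.INCONCLUSIVE, GenotypeGroup.STAR1_DEF_xN),
    (FunctionalClass.REDUCED, FunctionalClass.REDUCED): (
        Phenotype.INCONCLUSIVE, GenotypeGroup.RED_RED_xN),
    (FunctionalClass.REDUCED, FunctionalClass.DEFECTIVE): (
        Phenotype.INCONCLUSIVE, GenotypeGroup.RED_DEF_xN),
    (FunctionalClass.DEFECTIVE, FunctionalClass.DEFECTIVE): (
        Phenotype.INCONCLUSIVE, GenotypeGroup.DEF_DEF_xN),
}

_CLASS_ORDER = {
    FunctionalClass.FUNCTIONAL: 0,
    FunctionalClass.REDUCED: 1,
    FunctionalClass.DEFECTIVE: 2,
}


def phenotype_of(diplotype: Diplotype) -> PhenotypeCall:
    """Genotype-predicted metabolizer phenotype of a diplotype.

    Symmetric in allele order.  Any duplication whose diplotype contains
    a reduced- or lack-of-function allele is INCONCLUSIVE because the
    copy-number assay does not resolve which allele was duplicated.
    """
    pair = tuple(sorted(
        (diplotype.allele_a.functional_class, diplotype.allele_b.functional_class),
        key=_CLASS_ORDER.__getitem__,
    ))
    table = _DUP_GROUPS if diplotype.has_duplication else _NO_DUP_GROUPS
    phenotype, group = table[pair]
    return PhenotypeCall(phenotype, group)


def annotate_genotypes(
    table: pd.DataFrame, diplotype_column: str = "cyp2d6_diplotype"
) -> pd.DataFrame:
    """Append ``genotype_group`` and ``phenotype`` columns to a patient table."""
    calls = [phenotype_of(parse_diplotype(s)) for s in table[diplotype_column]]
    out = table.copy()
    out["genotype_group"] = [c.genotype_group.value for c in calls]
    out["phenotype"] = [c.phenotype.value for c in calls]
    return out
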