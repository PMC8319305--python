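"""Alleles, inheritance and phenotype of the female-sterilising *doublesex* drive.

The drive cassette (``D``, marked with dominant RFP) sits in the female-specific
exon of *doublesex* in *Anopheles gambiae*.  In the germline of W/D
heterozygotes the wild-type target (``W``) is cut and either converted to ``D``
(homing) or repaired into a non-functional resistance allele (``R2``).  No
functional-resistant (R1) state exists in this model: none was observed against
this target.  Females lacking any intact ``W`` copy (D/D, D/R2, R2/R2) develop
as sterile intersex; males are unaffected.

Fertility of fertile daughters can be reduced by a parental-carrier effect
(nuclease deposition / somatic leakage): multipliers ``f_pat`` and ``f_mat``
apply according to which parent carried the drive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np

__all__ = [
    "Allele",
    "DriveParams",
    "Genotype",
    "PhenotypeClass",
    "PAIR_CODES",
    "PAIR_LABELS",
    "PAIR_HAS_D",
    "PAIR_HAS_W",
    "gamete_distribution",
    "gamete_allele",
    "offspring_pair_distribution",
    "offspring_pair_tensor",
    "cross",
    "phenotype",
    "drive_allele_frequency",
]


class Allele(enum.IntEnum):
    """dsx-locus allele: wild-type, drive cassette, or non-functional resistant."""

    W = 0
    D = 1
    R2 = 2

    @property
    def symbol(self) -> str:
        return {Allele.W: "W", Allele.D: "D", Allele.R2: "R"}[self]


# Canonical unordered allele pairs, rendered with W before D before R2.
PAIR_CODES: tuple[tuple[Allele, Allele], ...] = (
    (Allele.W, Allele.W),
    (Allele.W, Allele.D),
    (Allele.W, Allele.R2),
    (Allele.D, Allele.D),
    (Allele.D, Allele.R2),
    (Allele.R2, Allele.R2),
)
PAIR_LABELS: tuple[str, ...] = ("WW", "WD", "WR", "DD", "DR", "RR")
_PAIR_INDEX = {frozenset((a, b)) if a != b else frozenset((a,)): i
               for i, (a, b) in enumerate(PAIR_CODES)}
PAIR_HAS_D = np.array([Allele.D in p for p in PAIR_CODES], dtype=bool)
PAIR_HAS_W = np.array([Allele.W in p for p in PAIR_CODES], dtype=bool)
# number of D alleles in each pair
PAIR_N_D = np.array([sum(a is Allele.D for a in p) for p in PAIR_CODES])


def pair_code(a: Allele, b: Allele) -> int:
    """Canonical 0..5 code of an unordered allele pair."""
    return _PAIR_INDEX[frozenset((a, b)) if a != b else frozenset((a,))]


@dataclass(frozen=True)
class DriveParams:
    """Drive-mechanism and deposition-cost parameters, all in [0, 1].

    h
        Homing probability per wild-type target allele in a W/D germline.
    rho
        Fraction of the non-homed (cut but not converted) gametes that end up
        as non-functional R2 alleles; the remainder stay W.
    f_pat, f_mat
        Fertility multipliers of fertile females whose father / mother carried
        the drive.
    deposition_combine
        Rule when both parents were carriers: ``"min"`` (default, avoids a
        double penalty) or ``"product"``.
    deposition_scope
        ``"all_daughters"`` (default: deposition hits every fertile daughter of
        a carrier parent) or ``"carrier_daughters"`` (only daughters that
        themselves inherited the drive — pure somatic-leakage semantics).
    h_male, h_female
        Optional sex-specific homing rates; ``None`` falls back to ``h``.
    """

    h: float = 0.975
    rho: float = 0.5
    f_pat: float = 0.35
    f_mat: float = 0.5
    deposition_combine: str = "min"
    deposition_scope: str = "all_daughters"
    h_male: Optional[float] = None
    h_female: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("h", "rho", "f_pat", "f_mat"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        for name in ("h_male", "h_female"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.deposition_combine not in ("min", "product"):
            raise ValueError(f"unknown deposition_combine {self.deposition_combine!r}")
        if self.deposition_scope not in ("all_daughters", "carrier_daughters"):
            raise ValueError(f"unknown deposition_scope {self.deposition_scope!r}")

    def homing_rate(self, sex: Optional[str] = None) -> float:
        if sex == "male" and self.h_male is not None:
            return self.h_male
        if sex == "female" and self.h_female is not None:
            return self.h_female
        return self.h


@dataclass(frozen=True)
class Genotype:
    """Unordered dsx allele pair plus immutable parent-of-origin carrier flags.

    The flags record whether the father / mother carried at least one drive
    allele; they are set once at zygote formation.  The drive-carrier predicate
    (``carries_drive``) matches what RFP larval screening observes.
    """

    alleles: tuple[Allele, Allele]
    father_carrier: bool = False
    mother_carrier: bool = False

    def __post_init__(self) -> None:
        a, b = self.alleles
        if not (isinstance(a, Allele) and isinstance(b, Allele)):
            raise ValueError(f"invalid alleles {self.alleles!r}")
        canonical = PAIR_CODES[pair_code(a, b)]
        object.__setattr__(self, "alleles", canonical)

    @classmethod
    def from_string(cls, s: str, father_carrier: bool = False,
                    mother_carrier: bool = False) -> "Genotype":
        lookup = {"W": Allele.W, "D": Allele.D, "R": Allele.R2, "R2": Allele.R2}
        if len(s) == 2:
            syms = [s[0], s[1]]
        else:
            syms = s.split("/")
        try:
            a, b = (lookup[x] for x in syms)
        except (KeyError, ValueError):
            raise ValueError(f"invalid genotype string {s!r}") from None
        return cls((a, b), father_carrier, mother_carrier)

    @property
    def pair(self) -> int:
        return pair_code(*self.alleles)

    @property
    def label(self) -> str:
        return PAIR_LABELS[self.pair]

    @property
    def carries_drive(self) -> bool:
        return Allele.D in self.alleles

    @property
    def n_drive_alleles(self) -> int:
        return int(PAIR_N_D[self.pair])

    @property
    def has_wildtype(self) -> bool:
        return Allele.W in self.alleles


@dataclass(frozen=True)
class PhenotypeClass:
    """Resolved phenotype: sex, reproductive class and fertility multiplier."""

    sex: str  # "male" | "female"
    reproductive: str  # "fertile_female" | "intersex_sterile" | "male"
    fertility_multiplier: float


def gamete_distribution(pair: Union[int, Genotype], params: DriveParams,
                        sex: Optional[str] = None) -> np.ndarray:
    """Probabilities of a (W, D, R2) gamete from the given parental pair.

    Homing acts only in W/D germlines: each W target is converted to D with
    probability ``h``; of the ``1 - h`` that escape, a fraction ``rho`` become
    R2 and the rest remain W.  Every other genotype segregates Mendelian.
    """
    if isinstance(pair, Genotype):
        pair = pair.pair
    h = params.homing_rate(sex)
    rho = params.rho
    out = np.zeros(3)
    if pair == 1:  # W/D
        out[Allele.D] = (1.0 + h) / 2.0
        out[Allele.R2] = (1.0 - h) / 2.0 * rho
        out[Allele.W] = (1.0 - h) / 2.0 * (1.0 - rho)
    else:
        a, b = PAIR_CODES[pair]
        out[a] += 0.5
        out[b] += 0.5
    return out


def gamete_allele(parent: Genotype, params: DriveParams,
                  rng: np.random.Generator, sex: Optional[str] = None) -> Allele:
    """Draw one gamete allele from a parent's germline."""
    p = gamete_distribution(parent, params, sex)
    return Allele(int(rng.choice(3, p=p)))


def offspring_pair_distribution(mother_pair: int, father_pair: int,
                                params: DriveParams) -> np.ndarray:
    """Distribution over the six offspring allele pairs for one parental cross."""
    gm = gamete_distribution(mother_pair, params, "female")
    gf = gamete_distribution(father_pair, params, "male")
    out = np.zeros(6)
    for a in Allele:
        for b in Allele:
            out[pair_code(a, b)] += gm[a] * gf[b]
    return out


def offspring_pair_tensor(params: DriveParams) -> np.ndarray:
    """(mother_pair, father_pair) -> offspring pair distribution, shape (6, 6, 6)."""
    t = np.empty((6, 6, 6))
    for i in range(6):
        for j in range(6):
            t[i, j] = offspring_pair_distribution(i, j, params)
    return t


def cross(mother: Genotype, father: Genotype, params: DriveParams,
          rng: np.random.Generator) -> tuple[Genotype, str]:
    """Form one zygote: independent gametes, carrier flags, fair-coin sex."""
    a = gamete_allele(mother, params, rng, "female")
    b = gamete_allele(father, params, rng, "male")
    g = Genotype((a, b),
                 father_carrier=father.carries_drive,
                 mother_carrier=mother.carries_drive)
    sex = "male" if rng.random() < 0.5 else "female"
    return g, sex


def deposition_multiplier(father_carrier: bool, mother_carrier: bool,
                          params: DriveParams) -> float:
    """Fertility multiplier from parental-carrier (deposition) status alone."""
    if father_carrier and mother_carrier:
        if params.deposition_combine == "product":
            return params.f_pat * params.f_mat
        return min(params.f_pat, params.f_mat)
    if father_carrier:
        return params.f_pat
    if mother_carrier:
        return params.f_mat
    return 1.0


def phenotype(g: Genotype, sex: str, params: DriveParams) -> PhenotypeClass:
    """Resolve sex + genotype into a reproductive class.

    Females with no intact W copy are sterile intersex.  Fertile females carry
    the deposition multiplier of their parents (subject to
    ``deposition_scope``); males are always fertile with multiplier 1.
    """
    if sex == "male":
        return PhenotypeClass("male", "male", 1.0)
    if sex != "female":
        raise ValueError(f"invalid sex {sex!r}")
    if not g.has_wildtype:
        return PhenotypeClass("female", "intersex_sterile", 0.0)
    if params.deposition_scope == "carrier_daughters" and not g.carries_drive:
        return PhenotypeClass("female", "fertile_female", 1.0)
    mult = deposition_multiplier(g.father_carrier, g.mother_carrier, params)
    return PhenotypeClass("female", "fertile_female", mult)


def drive_allele_frequency(
    genotype_counts: Mapping[Union[Genotype, str], int],
    reference_allele_total: Optional[int] = None,
) -> float:
    """Drive-allele count over total allele count (2 per individual).

    ``reference_allele_total`` replaces the denominator, e.g. to express a
    release relative to the pre-release standing population (the study quotes
    143 released drive alleles against 2 x 574 adults as 12.5%).
    """
    n_d = 0
    n_ind = 0
    for g, c in genotype_counts.items():
        if c < 0:
            raise ValueError("negative genotype count")
        if isinstance(g, str):
            g = Genotype.from_string(g)
        n_d += g.n_drive_alleles * c
        n_ind += c
    denom = reference_allele_total if reference_allele_total is not None else 2 * n_ind
    if denom <= 0:
        raise ValueError("allele-frequency denominator is zero")
    return n_d / denom
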