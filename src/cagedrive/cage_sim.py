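"""Daily-step stochastic simulator of one age-structured large-cage population.

The protocol mirrors the indoor large-cage suppression experiments: a cage is
established with twice-weekly introductions of sexed wild-type pupae, then
maintained solely by re-stocking up to 400 randomly chosen pupae from its own
egg output twice per week.  After a 74-day initiation period, heterozygous
drive males are released on two consecutive re-stocking occasions, and the cage
is monitored until the drive either suppresses the population (permanent zero
egg output) or the horizon ends.

Daily changes are egg laying, deaths and matings, with genotype-specific
probabilities.  Individuals are book-kept by (age, genotype, parental flags,
mating class) counts rather than one record per mosquito: within such a class
every individual has identical event probabilities, so class counts follow
exactly the same stochastic law as per-individual simulation while running
orders of magnitude faster.

Adult mortality is age-senescent by default: a Gompertz daily hazard whose
median lifespan ramps from 6 to 11 days over the experiment (survival in the
cages improved over the year).  Senescence is what reconciles a 6-day median
lifespan with the ~574-adult standing population the establishment regime
sustains — constant daily survival with the same median would imply a mean
lifespan of 8.2 days and ~930 standing adults.  A constant-hazard
("geometric") mode is available as configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genetics import (
    PAIR_CODES,
    PAIR_HAS_D,
    PAIR_LABELS,
    DriveParams,
    Genotype,
    offspring_pair_tensor,
    phenotype,
)

__all__ = [
    "LifeHistoryParams",
    "CageProtocol",
    "CageState",
    "ObservedCageSeries",
    "study_protocol",
    "release_pupae_fraction",
    "step_day",
    "lay_eggs",
    "restock",
    "run_cage",
    "suppression_day",
    "suppression_day_post_release",
    "equilibrium_adult_population",
    "gompertz_survivorship",
]

FERTILE_PAIRS = np.array([0, 1, 2])  # WW, WD, WR: females with an intact W copy
STERILE_PAIRS = np.array([3, 4, 5])  # DD, DR, RR: intersex females


def _gompertz_b(median: float, shape: float) -> float:
    """Gompertz scale (baseline hazard) giving S(median) = 1/2."""
    return math.log(2.0) * shape / math.expm1(shape * median)


def gompertz_survivorship(median: float, shape: float, days: int) -> np.ndarray:
    """S(d) for d = 1..days under a Gompertz hazard with the given median."""
    b = _gompertz_b(median, shape)
    d = np.arange(1, days + 1, dtype=float)
    return np.exp(-(b / shape) * np.expm1(shape * d))


@dataclass(frozen=True)
class LifeHistoryParams:
    """Life-history rates of the caged population.

    lambda_eggs
        Mean eggs per laid batch (Poisson unless ``batch_dispersion`` set).
    p_lay
        Probability that a mated fertile female lays at one twice-weekly
        opportunity (scaled by her fertility multiplier).
    survival_model
        ``"gompertz"`` (default): age-senescent daily hazard with median adult
        lifespan ramping ``median_lifespan_start`` -> ``median_lifespan_end``
        days over the experiment and shape ``senescence_shape``.
        ``"geometric"``: age-independent daily survival ramping
        ``s_adult_start`` -> ``s_adult_end``.
    hatch_days / egg_to_pupa_days / pupa_to_adult_days
        Juvenile schedule in days post-oviposition: larvae hatch, pupate (the
        re-stocking selection point) and eclose.
    juvenile_survival
        Egg-to-pupa survival probability, applied at hatching.
    p_mate
        Daily mating probability of an unmated fertile female at least one day
        old (mating is lifelong; sperm is stored).
    female_survival_advantage
        Optional multiplier >= 1 on female daily survival.
    batch_dispersion
        ``None`` for Poisson batches; otherwise a negative-binomial dispersion
        (variance = mu + mu^2 / k) for overdispersed laying.
    """

    lambda_eggs: float = 116.0
    p_lay: float = 0.14
    survival_model: str = "gompertz"
    median_lifespan_start: float = 6.0
    median_lifespan_end: float = 11.0
    senescence_shape: float = 0.45
    s_adult_start: float = 0.5 ** (1.0 / 6.0)
    s_adult_end: float = 0.5 ** (1.0 / 11.0)
    hatch_days: int = 2
    egg_to_pupa_days: int = 11
    pupa_to_adult_days: int = 2
    juvenile_survival: float = 0.8
    p_mate: float = 0.6
    female_survival_advantage: float = 1.0
    batch_dispersion: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("p_lay", "s_adult_start", "s_adult_end", "juvenile_survival",
                     "p_mate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.lambda_eggs <= 0:
            raise ValueError("lambda_eggs must be positive")
        if self.survival_model not in ("gompertz", "geometric"):
            raise ValueError(f"unknown survival_model {self.survival_model!r}")
        if self.survival_model == "gompertz":
            if self.median_lifespan_start < 1 or self.median_lifespan_end < 1:
                raise ValueError("median lifespans must be >= 1 day")
            if self.senescence_shape <= 0:
                raise ValueError("senescence_shape must be positive")
        for name in ("hatch_days", "egg_to_pupa_days", "pupa_to_adult_days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 day")
        if self.female_survival_advantage < 1.0:
            raise ValueError("female_survival_advantage must be >= 1")

    # -- survival ----------------------------------------------------------
    def max_adult_age(self) -> int:
        """Age bucket beyond which survival is negligible (forced death)."""
        if self.survival_model == "gompertz":
            S = gompertz_survivorship(max(self.median_lifespan_start,
                                          self.median_lifespan_end),
                                      self.senescence_shape, 200)
        else:
            s = max(self.s_adult_start, self.s_adult_end)
            S = np.cumprod(np.full(400, s))
        alive = np.nonzero(S > 1e-4)[0]
        return int(alive[-1]) + 3 if alive.size else 3

    def daily_survival(self, day: int, ramp_end: int) -> float:
        """Interpolated age-independent daily survival (geometric model)."""
        frac = min(max(day / ramp_end, 0.0), 1.0) if ramp_end > 0 else 1.0
        return self.s_adult_start + frac * (self.s_adult_end - self.s_adult_start)

    def age_survival(self, day: int, ramp_end: int, n_ages: int) -> np.ndarray:
        """P(survive the day | age a at day start) for a = 0..n_ages-1."""
        if self.survival_model == "geometric":
            return np.full(n_ages, self.daily_survival(day, ramp_end))
        frac = min(max(day / ramp_end, 0.0), 1.0) if ramp_end > 0 else 1.0
        median = (self.median_lifespan_start
                  + frac * (self.median_lifespan_end - self.median_lifespan_start))
        b = _gompertz_b(median, self.senescence_shape)
        a = np.arange(n_ages, dtype=float)
        # conditional survival S(a+1)/S(a) under the current hazard level
        return np.exp(-(b / self.senescence_shape)
                      * (np.exp(self.senescence_shape * (a + 1))
                         - np.exp(self.senescence_shape * a)))


@dataclass(frozen=True)
class CageProtocol:
    """The experimental script shared by the simulator and data generator.

    Collections (egg laying, re-stocking, introductions) happen on a
    twice-weekly grid (days 0 and 3 of each week).  During establishment, sexed
    wild-type pupae are introduced on that grid; thereafter the cage re-stocks
    itself from its own progeny, up to ``restock_cap`` pupae per occasion, with
    wild-type top-up during the pre-release phase when progeny fall short.
    """

    establishment_days: int = 21
    prerelease_end_day: int = 74
    restock_cap: int = 400
    collections_per_week: int = 2
    release_events: tuple[tuple[int, int, str, str], ...] = ()
    monitoring_end_day: int = 384
    larvae_screen_cap: int = 1000
    startup_pupae: int = 800
    establishment_pupae: int = 400
    supplement_prerelease: bool = True

    def __post_init__(self) -> None:
        if self.collections_per_week not in (1, 2):
            raise ValueError("collections_per_week must be 1 or 2")
        for day, count, label, sex in self.release_events:
            if count < 0:
                raise ValueError("release count must be >= 0")
            if not self.is_collection_day(day):
                raise ValueError(f"release day {day} is not a re-stocking day")
            if label not in PAIR_LABELS:
                raise ValueError(f"unknown release genotype {label!r}")
            if sex not in ("male", "female"):
                raise ValueError(f"unknown release sex {sex!r}")
        if self.monitoring_end_day <= self.prerelease_end_day:
            raise ValueError("monitoring must extend past the pre-release phase")

    def is_collection_day(self, day: int) -> bool:
        r = day % 7
        return r == 0 or (self.collections_per_week == 2 and r == 3)

    def collection_days(self, horizon: Optional[int] = None) -> list[int]:
        end = self.monitoring_end_day if horizon is None else horizon
        return [d for d in range(end + 1) if self.is_collection_day(d)]

    @property
    def release_day(self) -> Optional[int]:
        """Day of the first drive release (None for control)."""
        if not self.release_events:
            return None
        return min(day for day, *_ in self.release_events)

    def establishment_introductions(self) -> list[tuple[int, int]]:
        """(day, pupae) wild-type introductions during establishment."""
        return [(d, self.startup_pupae if d == 0 else self.establishment_pupae)
                for d in self.collection_days(self.establishment_days)]


def study_protocol(arm: str = "control", monitoring_end_day: int = 384,
                   **overrides) -> CageProtocol:
    """Protocol for one study arm: ``control``, ``low`` or ``medium``.

    Release arms add heterozygous drive males on the first two re-stocking
    occasions after the 74-day initiation: 71 + 72 (low, ~12.5% allele
    frequency relative to the estimated standing population) or 142 + 143
    (medium, ~25%).
    """
    base = CageProtocol(monitoring_end_day=monitoring_end_day, **overrides)
    if arm == "control":
        return base
    counts = {"low": (71, 72), "medium": (142, 143)}.get(arm)
    if counts is None:
        raise ValueError(f"unknown arm {arm!r}")
    days = [d for d in range(base.prerelease_end_day, base.prerelease_end_day + 8)
            if base.is_collection_day(d)][:2]
    events = tuple((day, n, "WD", "male") for day, n in zip(days, counts))
    return replace(base, release_events=events)


def reduced_protocol(arm: str = "control", monitoring_end_day: int = 180,
                     **overrides) -> CageProtocol:
    """A quarter-scale, shorter protocol for inference experiments.

    Same structure as the study protocol (establishment, pre-release,
    twice-weekly re-stocking, releases on two consecutive re-stockings at
    ~12.5%/25%-equivalent strength relative to the smaller standing
    population), but with a 100-pupae cap, a 28-day initiation and a ~150-day
    post-release window, so a forward simulation costs a few hundredths of a
    second instead of a few tenths.
    """
    kw = dict(establishment_days=14, prerelease_end_day=28, restock_cap=100,
              startup_pupae=200, establishment_pupae=100, larvae_screen_cap=500)
    kw.update(overrides)
    base = CageProtocol(monitoring_end_day=monitoring_end_day, **kw)
    if arm == "control":
        return base
    counts = {"low": (18, 17), "medium": (35, 35)}.get(arm)
    if counts is None:
        raise ValueError(f"unknown arm {arm!r}")
    days = [d for d in range(base.prerelease_end_day, base.prerelease_end_day + 8)
            if base.is_collection_day(d)][:2]
    events = tuple((day, n, "WD", "male") for day, n in zip(days, counts))
    return replace(base, release_events=events)


def release_pupae_fraction(protocol: CageProtocol) -> float:
    """Drive males as a fraction of all pupae introduced in the release week.

    The study reports 15.2% = 143/943 (low) and 26.3% = 285/1085 (medium):
    released males over releases plus the two regular 400-pupae re-stockings.
    """
    released = sum(count for _, count, _, _ in protocol.release_events)
    if released == 0:
        raise ValueError("protocol has no releases")
    return released / (2 * protocol.restock_cap + released)


# --------------------------------------------------------------------------
# state


class CageState:
    """Aggregated cage state: adult class counts plus pending juvenile cohorts.

    Adults are counted by age (days since eclosion, axis 0) and genotype pair
    (6 canonical classes), with parental-carrier flags and the stored mate's
    genotype for females.  Age 0 holds today's eclosions, which become eligible
    to mate and lay from age 1.
    """

    __slots__ = (
        "day", "n_ages", "males", "f_unmated", "f_mated", "f_sterile",
        "events", "records", "audit", "_cache",
    )

    def __init__(self, n_ages: int = 40, audit: bool = False) -> None:
        self.day = 0
        self.n_ages = n_ages
        self.males = np.zeros((n_ages, 6), dtype=np.int64)
        self.f_unmated = np.zeros((n_ages, 6, 2, 2), dtype=np.int64)
        self.f_mated = np.zeros((n_ages, 6, 2, 2, 6), dtype=np.int64)
        self.f_sterile = np.zeros((n_ages, 6), dtype=np.int64)
        self.events: dict[int, list[tuple[str, dict]]] = {}
        self.records: dict[int, dict] = {}
        self.audit = audit
        self._cache: Optional[tuple] = None

    def total_adults(self) -> int:
        return int(self.males.sum() + self.f_unmated.sum() + self.f_mated.sum()
                   + self.f_sterile.sum())

    def adult_pair_counts(self) -> np.ndarray:
        """Adults per genotype pair, all ages and classes pooled."""
        return (self.males.sum(axis=0) + self.f_sterile.sum(axis=0)
                + self.f_unmated.sum(axis=(0, 2, 3))
                + self.f_mated.sum(axis=(0, 2, 3, 4)))

    def schedule(self, day: int, kind: str, payload: dict) -> None:
        self.events.setdefault(day, []).append((kind, payload))

    def pending_after(self, day: int) -> bool:
        return any(d >= day for d in self.events)

    def record(self, day: int) -> dict:
        return self.records.setdefault(day, {
            "day": day, "eggs_total": 0, "larvae_screened": 0, "rfp_positive": 0,
            "pupae_restocked": 0, "morph_female_fraction": np.nan,
        })


def _lay_cache(life: LifeHistoryParams, drive: DriveParams):
    """Offspring-pair tensor and effective per-class laying probabilities."""
    tensor = offspring_pair_tensor(drive)
    # fertility multiplier of a fertile mated female by (own pair, momc, dadc)
    mult = np.zeros((6, 2, 2))
    for pair in FERTILE_PAIRS:
        for momc in (0, 1):
            for dadc in (0, 1):
                g = Genotype(PAIR_CODES[pair], father_carrier=bool(dadc),
                             mother_carrier=bool(momc))
                mult[pair, momc, dadc] = phenotype(g, "female", drive).fertility_multiplier
    p_lay_eff = np.clip(life.p_lay * mult, 0.0, 1.0)[:, :, :, None]  # (6,2,2,1)
    return tensor, p_lay_eff


def _ensure_cache(state: CageState, life: LifeHistoryParams, drive: DriveParams):
    key = (life, drive)
    if state._cache is not None and state._cache[0] == key:
        return state._cache[1]
    cache = _lay_cache(life, drive)
    state._cache = (key, cache)
    return cache


# --------------------------------------------------------------------------
# component operations


def lay_eggs(
    fertile_mated_females: Sequence[tuple[Genotype, Genotype]],
    life: LifeHistoryParams,
    drive: DriveParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One twice-weekly laying opportunity for a list of (mother, mate) pairs.

    Each female lays with probability ``p_lay`` times her fertility multiplier;
    a laid batch is Poisson(``lambda_eggs``); offspring genotypes follow the
    cross of her genotype with her stored mate's.  Returns egg counts indexed
    by (offspring pair, mother-carrier flag, father-carrier flag).
    """
    counts = np.zeros((6, 2, 2, 6), dtype=np.int64)
    for mother, mate in fertile_mated_females:
        ph = phenotype(mother, "female", drive)
        if ph.reproductive != "fertile_female":
            raise ValueError("intersex female passed to lay_eggs")
        counts[mother.pair, int(mother.mother_carrier),
               int(mother.father_carrier), mate.pair] += 1
    tensor, p_lay_eff = _lay_cache(life, drive)
    eggs, _ = _lay_from_classes(counts, life, tensor, p_lay_eff, rng)
    return eggs


def _lay_from_classes(f_mated, life, tensor, p_lay_eff, rng):
    """Vectorized laying across mated-female classes; returns (egg counts, total).

    ``f_mated`` is (own pair, momc, dadc, mate pair) — age already pooled,
    since laying probability does not depend on age.
    """
    if f_mated.sum() == 0:
        return np.zeros((6, 2, 2), dtype=np.int64), 0
    layers = rng.binomial(f_mated, p_lay_eff)
    layers_pm = layers.sum(axis=(1, 2))  # (own pair, mate pair)
    if life.batch_dispersion is None:
        eggs_pm = rng.poisson(layers_pm * life.lambda_eggs)
    else:
        # negative-binomial batches: a sum over n layers stays NB
        k = life.batch_dispersion * layers_pm
        mu = layers_pm * life.lambda_eggs
        eggs_pm = np.zeros_like(layers_pm)
        nz = layers_pm > 0
        eggs_pm[nz] = rng.negative_binomial(k[nz], k[nz] / (k[nz] + mu[nz]))
    egg_counts = np.zeros((6, 2, 2), dtype=np.int64)
    for i, j in zip(*np.nonzero(eggs_pm)):
        kids = rng.multinomial(eggs_pm[i, j], tensor[i, j])
        egg_counts[:, int(PAIR_HAS_D[i]), int(PAIR_HAS_D[j])] += kids
    return egg_counts, int(eggs_pm.sum())


def restock(hatched_larvae: np.ndarray, protocol: CageProtocol,
            rng: np.random.Generator) -> np.ndarray:
    """Sample up to ``restock_cap`` pupae uniformly without replacement.

    Genotype composition of the selection is multivariate hypergeometric; if
    the cohort is at or under the cap, everything is retained.
    """
    arr = np.asarray(hatched_larvae, dtype=np.int64)
    flat = arr.ravel()
    if (flat < 0).any():
        raise ValueError("negative larva count")
    if int(flat.sum()) <= protocol.restock_cap:
        return arr.copy()
    picked = rng.multivariate_hypergeometric(flat, protocol.restock_cap)
    return picked.reshape(arr.shape)


def equilibrium_adult_population(survivorship_curve: Iterable[float],
                                 pupae_per_week: float) -> float:
    """Expected standing adult count under steady introductions.

    ``survivorship_curve`` gives S(d), the fraction of an eclosing cohort still
    alive d days later, for d = 1, 2, ...; the standing population is the daily
    inflow times the discrete area under that curve.
    """
    s = np.asarray(list(survivorship_curve), dtype=float)
    if s.size and ((s > 1.0 + 1e-12).any() or (np.diff(s) > 1e-12).any()):
        raise ValueError("survivorship must be non-increasing and start <= 1")
    return pupae_per_week / 7.0 * float(s.sum())


# --------------------------------------------------------------------------
# the daily step


def step_day(state: CageState, life: LifeHistoryParams, drive: DriveParams,
             protocol: CageProtocol, rng: np.random.Generator) -> CageState:
    """Advance the cage by one day, in the fixed order deaths/aging -> juvenile
    development -> mating -> introductions -> laying/collection.

    Newly eclosed adults enter at age 0 and become eligible to mate and lay the
    following day.  The empty cage is an absorbing state for adults.
    """
    tensor, p_lay_eff = _ensure_cache(state, life, drive)
    day = state.day
    adults_before = state.total_adults()

    # 1. adult mortality (age- and day-dependent hazard), then ageing by one
    # day; the top age bucket is absorbing death
    s_age = life.age_survival(day, protocol.monitoring_end_day, state.n_ages)
    s_f = np.minimum(1.0, s_age * life.female_survival_advantage)
    deaths = 0
    for arr, sv in ((state.males, s_age), (state.f_sterile, s_f),
                    (state.f_unmated, s_f), (state.f_mated, s_f)):
        n = arr.sum()
        if n:
            shp = (-1,) + (1,) * (arr.ndim - 1)
            survivors = rng.binomial(arr, sv.reshape(shp))
            deaths += int(n - survivors.sum())
            deaths += int(survivors[-1].sum())  # aged out
            arr[1:] = survivors[:-1]
            arr[0] = 0

    # 2. juvenile development: hatch, pupal re-stocking, eclosion
    eclosed = 0
    for kind, payload in state.events.pop(day, ()):
        if kind == "hatch":
            eggs = payload["counts"]
            larvae = rng.binomial(eggs, life.juvenile_survival)
            rec = state.record(payload["egg_day"])
            n_larvae = int(larvae.sum())
            screened = min(protocol.larvae_screen_cap, n_larvae)
            carriers = int(larvae[PAIR_HAS_D].sum())
            if 0 < screened < n_larvae:
                rfp = int(rng.hypergeometric(carriers, n_larvae - carriers, screened))
            else:
                rfp = carriers if screened else 0
            rec["larvae_screened"] = screened
            rec["rfp_positive"] = rfp
            state.schedule(payload["egg_day"] + life.egg_to_pupa_days, "restock",
                           {"egg_day": payload["egg_day"], "counts": larvae})
        elif kind == "restock":
            picked = restock(payload["counts"], protocol, rng)
            if (day <= protocol.prerelease_end_day and protocol.supplement_prerelease
                    and picked.sum() < protocol.restock_cap):
                picked[0, 0, 0] += protocol.restock_cap - int(picked.sum())
            _introduce_pupae(state, picked, day, life, rng,
                             record_for=payload["egg_day"])
        elif kind == "eclose":
            state.males[0] += payload["males"]
            state.f_unmated[0] += payload["f_fertile"]
            state.f_sterile[0] += payload["f_sterile"]
            eclosed += int(payload["males"].sum() + payload["f_fertile"].sum()
                           + payload["f_sterile"].sum())

    # 3. mating: unmated fertile females aged >= 1 day pick a mate from the
    # current male genotype frequencies; mating is lifelong
    male_pool = state.males[1:].sum(axis=0)
    n_males = int(male_pool.sum())
    if n_males > 0 and state.f_unmated[1:].sum() > 0:
        maters = rng.binomial(state.f_unmated[1:], life.p_mate)
        total_maters = int(maters.sum())
        if total_maters:
            assigned = rng.multinomial(maters.ravel(), male_pool / n_males)
            state.f_mated[1:] += assigned.reshape(state.n_ages - 1, 6, 2, 2, 6)
            state.f_unmated[1:] -= maters

    # 4. scheduled introductions: establishment pupae and drive releases
    if day <= protocol.establishment_days and protocol.is_collection_day(day):
        n = protocol.startup_pupae if day == 0 else protocol.establishment_pupae
        wt = np.zeros((6, 2, 2), dtype=np.int64)
        wt[0, 0, 0] = n
        _introduce_pupae(state, wt, day, life, rng, sexed=True)
    for rel_day, count, label, sex in protocol.release_events:
        if rel_day == day and count > 0:
            _introduce_release(state, count, label, sex, day, life)

    # 5. egg laying and collection on the twice-weekly grid
    if protocol.is_collection_day(day):
        pooled = state.f_mated[1:].sum(axis=0)
        egg_counts, total = _lay_from_classes(pooled, life, tensor, p_lay_eff, rng)
        rec = state.record(day)
        rec["eggs_total"] = total
        if total:
            state.schedule(day + life.hatch_days, "hatch",
                           {"egg_day": day, "counts": egg_counts})

    if state.audit:
        got = state.total_adults()
        expect = adults_before - deaths + eclosed
        if got != expect:
            raise AssertionError(
                f"day {day}: adult conservation violated ({got} != {expect})")

    state.day = day + 1
    return state


def _introduce_pupae(state: CageState, counts: np.ndarray, day: int,
                     life: LifeHistoryParams, rng: np.random.Generator,
                     sexed: bool = False, record_for: Optional[int] = None) -> None:
    """Turn a pupal cohort into an eclosion event ``pupa_to_adult_days`` later."""
    total = int(counts.sum())
    if record_for is not None:
        rec = state.record(record_for)
        rec["pupae_restocked"] = total
    if total == 0:
        return
    if sexed:
        males = counts.sum(axis=(1, 2)) // 2
        females = counts.copy()
        females[0, 0, 0] -= males[0]
    else:
        males_full = rng.binomial(counts, 0.5)
        males = males_full.sum(axis=(1, 2))
        females = counts - males_full
    f_fertile = females.copy()
    f_sterile_n = females[STERILE_PAIRS].sum(axis=(1, 2))
    f_fertile[STERILE_PAIRS] = 0
    if record_for is not None:
        rec["morph_female_fraction"] = int(f_fertile.sum()) / total
        rec["_restock_pairs"] = counts.sum(axis=(1, 2))
    sterile6 = np.zeros(6, dtype=np.int64)
    sterile6[STERILE_PAIRS] = f_sterile_n
    state.schedule(day + life.pupa_to_adult_days, "eclose",
                   {"males": males, "f_fertile": f_fertile, "f_sterile": sterile6})


def _introduce_release(state: CageState, count: int, label: str, sex: str,
                       day: int, life: LifeHistoryParams) -> None:
    pair = PAIR_LABELS.index(label)
    males = np.zeros(6, dtype=np.int64)
    f_fertile = np.zeros((6, 2, 2), dtype=np.int64)
    sterile = np.zeros(6, dtype=np.int64)
    if sex == "male":
        males[pair] = count
    elif pair in STERILE_PAIRS:
        sterile[pair] = count
    else:
        f_fertile[pair, 0, 0] = count
    state.schedule(day + life.pupa_to_adult_days, "eclose",
                   {"males": males, "f_fertile": f_fertile, "f_sterile": sterile})


# --------------------------------------------------------------------------
# whole-run driver and observables


@dataclass
class ObservedCageSeries:
    """Per-collection observable record of one cage.

    ``records`` has one row per collection day: total eggs, larvae screened
    for RFP, RFP-positive count, pupae re-stocked, morphological-female
    fraction and (optionally) true genotype counts of the re-stocked pupae.
    """

    records: pd.DataFrame
    arm: str = "unknown"
    replicate: int = 0
    seed: Optional[int] = None
    release_day: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.records["rfp_positive"] > self.records["larvae_screened"]).any():
            raise ValueError("rfp_positive exceeds larvae_screened")

    @property
    def meta(self) -> dict:
        return {"arm": self.arm, "replicate": self.replicate, "seed": self.seed,
                "release_day": self.release_day}


def run_cage(life: LifeHistoryParams, drive: DriveParams, protocol: CageProtocol,
             seed, arm: str = "unknown", replicate: int = 0,
             genotype_records: bool = False, audit: bool = False,
             horizon: Optional[int] = None) -> ObservedCageSeries:
    """Simulate one cage to ``horizon`` (default: the protocol's monitoring end).

    Deterministic given (configs, seed).  Once the cage is extinct — no adults,
    no juveniles in the pipeline, no introductions still scheduled — remaining
    collections are recorded as zero without stepping day by day.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    end = protocol.monitoring_end_day if horizon is None else horizon
    if end <= protocol.prerelease_end_day:
        raise ValueError("horizon ends before the monitoring phase")
    state = CageState(n_ages=life.max_adult_age(), audit=audit)
    last_intro = max([d for d, _ in protocol.establishment_introductions()]
                     + [d for d, *_ in protocol.release_events])
    while state.day <= end:
        step_day(state, life, drive, protocol, rng)
        if (state.day > last_intro and state.total_adults() == 0
                and not state.pending_after(state.day)):
            break
    for d in protocol.collection_days(end):
        state.record(d)  # fill any missing collection with a zero record

    rows = [state.records[d] for d in sorted(state.records)]
    df = pd.DataFrame(rows).sort_values("day").reset_index(drop=True)
    if genotype_records:
        pair_mat = np.zeros((len(df), 6), dtype=np.int64)
        for i, d in enumerate(df["day"]):
            pairs = state.records[d].get("_restock_pairs")
            if pairs is not None:
                pair_mat[i] = pairs
        for k, lab in enumerate(PAIR_LABELS):
            df[f"n_{lab}"] = pair_mat[:, k]
    df = df[[c for c in df.columns if not c.startswith("_")]]
    try:
        seed_val = int(seed)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        seed_val = None
    return ObservedCageSeries(df, arm=arm, replicate=replicate, seed=seed_val,
                              release_day=protocol.release_day)


def suppression_day(series: ObservedCageSeries) -> Optional[int]:
    """First collection day from which every later collection has zero eggs.

    ``None`` if eggs were still recovered at the final collection (a later
    rebound cancels earlier zeros).
    """
    df = series.records.sort_values("day")
    eggs = df["eggs_total"].to_numpy()
    if len(eggs) == 0:
        raise ValueError("empty series")
    if eggs[-1] > 0:
        return None
    pos = np.nonzero(eggs > 0)[0]
    idx = 0 if pos.size == 0 else pos[-1] + 1
    return int(df["day"].iloc[idx])


def suppression_day_post_release(series: ObservedCageSeries) -> Optional[int]:
    """Suppression day measured from the first release (requires a release arm)."""
    if series.release_day is None:
        raise ValueError("series has no release day")
    d = suppression_day(series)
    return None if d is None else d - series.release_day
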