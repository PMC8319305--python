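"""Synthetic cage-study bundles with known ground truth.

Generates pseudo-observed datasets with the study's arm structure — duplicate
control, low-release (71+72 drive males) and medium-release (142+143) cages —
through the same simulator and observation process the inference machinery
assumes: exhaustive egg counts, RFP screening capped at 1000 larvae per
collection, re-stocking records.  The generating parameters are serialised
alongside the data, so parameter-recovery experiments always know the truth.

The default ground truth is the study's printed posterior means, making the
default bundle the package's reference fixture.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cage_sim import (
    CageProtocol,
    DriveParams,
    LifeHistoryParams,
    ObservedCageSeries,
    run_cage,
    study_protocol,
)

__all__ = ["GroundTruth", "StudyBundle", "generate_study", "observation_noise"]

ARMS = ("control", "low", "medium")


@dataclass(frozen=True)
class GroundTruth:
    """The parameters and seeds behind a synthetic bundle."""

    life: LifeHistoryParams
    drive: DriveParams
    monitoring_end_day: int
    replicates_per_arm: int
    seed: int
    cage_seeds: dict  # (arm, replicate) label -> spawned seed entropy

    def to_dict(self) -> dict:
        d = {
            "life": dataclasses.asdict(self.life),
            "drive": dataclasses.asdict(self.drive),
            "monitoring_end_day": self.monitoring_end_day,
            "replicates_per_arm": self.replicates_per_arm,
            "seed": self.seed,
            "cage_seeds": self.cage_seeds,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(life=LifeHistoryParams(**d["life"]),
                   drive=DriveParams(**d["drive"]),
                   monitoring_end_day=d["monitoring_end_day"],
                   replicates_per_arm=d["replicates_per_arm"],
                   seed=d["seed"], cage_seeds=d["cage_seeds"])


@dataclass
class StudyBundle:
    """Six synthetic cages (2 per arm by default) plus their ground truth."""

    cages: dict  # arm -> list[ObservedCageSeries]
    truth: GroundTruth
    protocols: dict  # arm -> CageProtocol

    def arm(self, name: str) -> list[ObservedCageSeries]:
        return self.cages[name]


def generate_study(life: Optional[LifeHistoryParams] = None,
                   drive: Optional[DriveParams] = None,
                   seed: int = 0,
                   monitoring_end_day: int = 460,
                   replicates_per_arm: int = 2,
                   genotype_records: bool = False,
                   **protocol_overrides) -> StudyBundle:
    """Generate one synthetic study: duplicate control/low/medium cages.

    The default monitoring horizon (day 460) mirrors the study's practice of
    monitoring release cages until full suppression: under the default ground
    truth nearly all release cages suppress inside it.  Deterministic given
    ``seed``; per-cage streams are spawned so cages are independent.
    """
    life = life or LifeHistoryParams()
    drive = drive or DriveParams()
    root = np.random.SeedSequence(seed)
    cages: dict[str, list[ObservedCageSeries]] = {}
    cage_seeds: dict[str, int] = {}
    protocols = {arm: study_protocol(arm, monitoring_end_day=monitoring_end_day,
                                     **protocol_overrides) for arm in ARMS}
    children = root.spawn(len(ARMS) * replicates_per_arm)
    k = 0
    for arm in ARMS:
        cages[arm] = []
        for rep in range(replicates_per_arm):
            child = children[k]
            k += 1
            cage_seeds[f"{arm}:{rep}"] = int(child.generate_state(1)[0])
            s = run_cage(life, drive, protocols[arm],
                         np.random.default_rng(child), arm=arm, replicate=rep,
                         genotype_records=genotype_records)
            s.seed = cage_seeds[f"{arm}:{rep}"]
            cages[arm].append(s)
    truth = GroundTruth(life=life, drive=drive,
                        monitoring_end_day=monitoring_end_day,
                        replicates_per_arm=replicates_per_arm,
                        seed=seed, cage_seeds=cage_seeds)
    return StudyBundle(cages=cages, truth=truth, protocols=protocols)


def observation_noise(true_cohort: np.ndarray, screen_cap: int,
                      rng: np.random.Generator) -> np.ndarray:
    """The larval screening process: subsample ``screen_cap`` of a true cohort.

    Uniform sampling without replacement (multivariate hypergeometric over
    genotype classes); if the cohort is within the cap everything is observed.
    Egg totals are *not* noised anywhere — the study counted all eggs.
    """
    arr = np.asarray(true_cohort, dtype=np.int64)
    if (arr < 0).any():
        raise ValueError("negative cohort count")
    total = int(arr.sum())
    if total <= screen_cap:
        return arr.copy()
    picked = rng.multivariate_hypergeometric(arr.ravel(), screen_cap)
    return picked.reshape(arr.shape)
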