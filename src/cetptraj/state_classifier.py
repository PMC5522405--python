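"""Orientation / conformation state classification of tunnel-bound TGs.

Single-TG orientation is decided by the sn1-sn3 angle alone: below 75° the
lipid rests head-to-legs (single "head" chain toward the N-barrel, two
"legs" toward the C-barrel), between 105° and 180° it rests legs-to-head,
and the intermediate band is random. The boundary angles 75° and 105° fall
in the random band so the three classes partition [0, 180] cleanly.

Conformation uses both sn1-sn3 and sn2-sn3: a fork-like state (tuning fork
or chair — not distinguished) has one acute and one obtuse inter-chain
angle; a trident has all chains on one side (both angles acute); everything
else is random. The 60°/105° conformation thresholds separate the reported
signature peaks (≈30° fork/trident acute peaks, 75–85° random band,
135–150° fork obtuse peaks) with maximal margins and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import EmptyInputError, ShapeError


class OrientationLabel(str, Enum):
    HEAD_TO_LEGS = "HEAD_TO_LEGS"
    LEGS_TO_HEAD = "LEGS_TO_HEAD"
    RANDOM = "RANDOM"


class ConformationLabel(str, Enum):
    FORK_LIKE = "FORK_LIKE"
    TRIDENT = "TRIDENT"
    RANDOM = "RANDOM"


class PairOrientationLabel(str, Enum):
    PARALLEL_NN = "PARALLEL_NN"
    ANTIPARALLEL_NC = "ANTIPARALLEL_NC"
    PARALLEL_CC = "PARALLEL_CC"
    ANTIPARALLEL_CN = "ANTIPARALLEL_CN"
    RANDOM = "RANDOM"


#: orientation thresholds (degrees): head-to-legs below the first, legs-to-
#: head at/above the second; both endpoints belong to the random band.
DEFAULT_HEAD_MAX = 75.0
DEFAULT_LEGS_MIN = 105.0

#: conformation thresholds (degrees)
DEFAULT_ACUTE_MAX = 60.0
DEFAULT_OBTUSE_MIN = 105.0


def _check_angle(angle: float) -> float:
    angle = float(angle)
    if not (0.0 <= angle <= 180.0):
        raise ShapeError(f"angle {angle} outside [0, 180]")
    return angle


def classify_orientation(
    sn1sn3: float,
    head_max: float = DEFAULT_HEAD_MAX,
    legs_min: float = DEFAULT_LEGS_MIN,
) -> OrientationLabel:
    """Single-TG orientation from the sn1-sn3 angle (degrees)."""
    a = _check_angle(sn1sn3)
    if a < head_max:
        return OrientationLabel.HEAD_TO_LEGS
    if a >= legs_min:
        return OrientationLabel.LEGS_TO_HEAD
    return OrientationLabel.RANDOM


def classify_conformation(
    sn1sn3: float,
    sn2sn3: float,
    acute_max: float = DEFAULT_ACUTE_MAX,
    obtuse_min: float = DEFAULT_OBTUSE_MIN,
) -> ConformationLabel:
    """Conformation class from the (sn1-sn3, sn2-sn3) angle pair (degrees)."""
    a, b = _check_angle(sn1sn3), _check_angle(sn2sn3)
    lo, hi = min(a, b), max(a, b)
    if lo <= acute_max and hi >= obtuse_min:
        return ConformationLabel.FORK_LIKE
    if hi <= acute_max:
        return ConformationLabel.TRIDENT
    return ConformationLabel.RANDOM


_PAIR_TABLE = {
    (OrientationLabel.HEAD_TO_LEGS, OrientationLabel.HEAD_TO_LEGS):
        PairOrientationLabel.PARALLEL_NN,
    (OrientationLabel.HEAD_TO_LEGS, OrientationLabel.LEGS_TO_HEAD):
        PairOrientationLabel.ANTIPARALLEL_NC,
    (OrientationLabel.LEGS_TO_HEAD, OrientationLabel.LEGS_TO_HEAD):
        PairOrientationLabel.PARALLEL_CC,
    (OrientationLabel.LEGS_TO_HEAD, OrientationLabel.HEAD_TO_LEGS):
        PairOrientationLabel.ANTIPARALLEL_CN,
}


def classify_pair(
    o_N: OrientationLabel, o_C: OrientationLabel
) -> PairOrientationLabel:
    """Joint TG_N/TG_C pair state; any individually random TG makes the
    pair random."""
    if OrientationLabel.RANDOM in (o_N, o_C):
        return PairOrientationLabel.RANDOM
    return _PAIR_TABLE[(o_N, o_C)]


@dataclass
class PairDistribution:
    """Empirical probability per pair state over a trajectory."""

    probabilities: dict  # PairOrientationLabel -> float
    n_frames: int

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-12:
            raise ShapeError(f"pair probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.probabilities.values()):
            raise ShapeError("negative probability")

    def as_dict(self) -> dict:
        return {k.value: v for k, v in self.probabilities.items()}


def pair_distribution(
    labels: Sequence[PairOrientationLabel],
) -> PairDistribution:
    """Frame-count frequencies of the five pair states."""
    labels = list(labels)
    if not labels:
        raise EmptyInputError("cannot build a distribution from zero frames")
    n = len(labels)
    probs = {lab: 0.0 for lab in PairOrientationLabel}
    for lab in labels:
        probs[PairOrientationLabel(lab)] += 1.0
    probs = {k: v / n for k, v in probs.items()}
    return PairDistribution(probabilities=probs, n_frames=n)


def classification_accuracy(inferred: Sequence, truth: Sequence) -> float:
    """Exact-match fraction between an inferred label sequence and ground
    truth; validation harness for the synthetic generator."""
    inferred, truth = list(inferred), list(truth)
    if len(inferred) != len(truth):
        raise ShapeError(
            f"length mismatch: {len(inferred)} inferred vs {len(truth)} truth"
        )
    if not inferred:
        raise EmptyInputError("empty label sequences")
    matches = sum(1 for a, b in zip(inferred, truth) if a == b)
    return matches / len(inferred)


def classify_trajectory_pair(
    sn1sn3_N: np.ndarray, sn1sn3_C: np.ndarray, **thresholds
) -> tuple[list, list, list]:
    """Per-frame orientation labels for both TGs and the pair label.

    Convenience wrapper over the scalar classifiers for whole angle series.
    """
    sn1sn3_N = np.asarray(sn1sn3_N, dtype=float)
    sn1sn3_C = np.asarray(sn1sn3_C, dtype=float)
    if sn1sn3_N.shape != sn1sn3_C.shape:
        raise ShapeError("TG_N and TG_C series must share one length")
    o_N = [classify_orientation(a, **thresholds) for a in sn1sn3_N]
    o_C = [classify_orientation(a, **thresholds) for a in sn1sn3_C]
    pairs = [classify_pair(a, b) for a, b in zip(o_N, o_C)]
    return o_N, o_C, pairs
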