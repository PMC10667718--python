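"""Identification-quality filtering: confidence tiers, target-decoy FDR, caps.

Confidence tiers follow charge-dependent XCorr windows: the medium window
is closed on both ends, high is strictly above its upper bound, and
anything below the medium floor is rejected.

==========  ============== =============
charge      medium          high
==========  ============== =============
2           2.0 – 2.3       > 2.3
3           2.5 – 3.0       > 3.0
>= 4        2.8 – 3.5       > 3.5
==========  ============== =============

FDR control is the naive concatenated target-decoy estimator: at score
threshold ``s``, ``FDR(s) = decoys>=s / max(1, targets>=s)``; the q-value
of a record is the minimum FDR over all thresholds at or below its score,
which makes q-values monotone non-increasing in XCorr.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .psm_io import CHARGE_MAX, CHARGE_MIN, PSMRecord


class ConfidenceTier(enum.IntEnum):
    reject = 0
    medium = 1
    high = 2


#: (medium floor, high floor exclusive) keyed by charge; charges >= 4 share one row
_TIER_THRESHOLDS = {2: (2.0, 2.3), 3: (2.5, 3.0), 4: (2.8, 3.5)}


def assign_confidence(charge: int, xcorr: float) -> ConfidenceTier:
    """Tier a PSM by its charge-dependent XCorr window."""
    if not (CHARGE_MIN <= charge <= CHARGE_MAX):
        raise ValidationError(f"charge {charge} outside {CHARGE_MIN}-{CHARGE_MAX}")
    if xcorr < 0:
        raise ValidationError(f"negative xcorr {xcorr}")
    medium_floor, high_floor = _TIER_THRESHOLDS[min(charge, 4)]
    if xcorr > high_floor:
        return ConfidenceTier.high
    if xcorr >= medium_floor:
        return ConfidenceTier.medium
    return ConfidenceTier.reject


@dataclass
class FilterConfig:
    fdr_threshold: float = 0.01
    max_mods: int = 4
    tier_floor: ConfidenceTier = ConfidenceTier.medium

    def __post_init__(self):
        if isinstance(self.tier_floor, str):
            try:
                self.tier_floor = ConfidenceTier[self.tier_floor]
            except KeyError as exc:
                raise ConfigError(f"unknown tier {self.tier_floor!r}") from exc
        if not (0 < self.fdr_threshold < 1):
            raise ConfigError("fdr_threshold must lie in (0, 1)")
        if self.max_mods < 0:
            raise ConfigError("max_mods must be >= 0")


def compute_qvalues(records: Sequence[PSMRecord]) -> np.ndarray:
    """Concatenated target-decoy q-values, aligned with ``records``.

    Empty input yields an empty array.  Decoy counting uses the plain
    (no +1) estimator.
    """
    n = len(records)
    if n == 0:
        return np.empty(0)
    scores = np.array([r.xcorr for r in records], dtype=float)
    decoy = np.array([r.is_decoy for r in records], dtype=bool)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_decoy = decoy[order]
    cum_decoys = np.cumsum(sorted_decoy)
    cum_targets = np.cumsum(~sorted_decoy)

    # last index of each tied block = counts at that score threshold
    is_block_end = np.empty(n, dtype=bool)
    is_block_end[:-1] = sorted_scores[:-1] != sorted_scores[1:]
    is_block_end[-1] = True
    block_end_idx = np.flatnonzero(is_block_end)

    fdr = cum_decoys[block_end_idx] / np.maximum(1, cum_targets[block_end_idx])
    # q at a threshold = min FDR over this and every lower threshold
    qvals_per_block = np.minimum.accumulate(fdr[::-1])[::-1]
    qvals_per_block = np.minimum(qvals_per_block, 1.0)

    block_of_row = np.searchsorted(block_end_idx, np.arange(n))
    q_sorted = qvals_per_block[block_of_row]
    q = np.empty(n)
    q[order] = q_sorted
    return q


def apply_filters(
    records: Sequence[PSMRecord],
    config: FilterConfig | None = None,
    qvalues: np.ndarray | None = None,
) -> list[PSMRecord]:
    """Return records passing q-value, tier, modification-count and decoy rules.

    Idempotent: re-applying to its own output (with q-values recomputed on
    the survivors) returns the same set, because removing only decoys and
    low-scoring records can never raise a survivor's q-value.
    """
    if config is None:
        config = FilterConfig()
    if qvalues is None:
        qvalues = compute_qvalues(records)
    if len(qvalues) != len(records):
        raise ValidationError("qvalues not aligned with records")
    accepted = []
    for rec, q in zip(records, qvalues):
        if rec.is_decoy:
            continue
        if q > config.fdr_threshold:
            continue
        if len(rec.mods) > config.max_mods:
            continue
        if assign_confidence(rec.charge, rec.xcorr) < config.tier_floor:
            continue
        accepted.append(rec)
    return accepted
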