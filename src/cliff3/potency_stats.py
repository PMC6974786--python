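"""Target-set potency statistics and the set-dependent cliff threshold.

Two distributions matter per target set: the compound pKi distribution, whose
interquartile range gates whether the set is analyzed at all (sets spanning
less than one log unit between Q1 and Q3 rarely contain cliffs), and the
analog-pair ΔpKi distribution, whose mean plus two standard deviations is the
set-specific potency-difference threshold for calling a cliff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .activity_data import TargetSet
from .analog_series import AnalogPair

logger = logging.getLogger(__name__)

__all__ = ["TargetSetStats", "compute_iqr", "preselect_target_sets", "compute_threshold"]

QuartileMode = Literal["linear", "lower", "higher", "nearest", "midpoint"]
SigmaMode = Literal["sample", "population"]


@dataclass(frozen=True)
class TargetSetStats:
    target_id: str
    n_compounds: int
    q1: float
    q3: float
    iqr: float
    n_pairs: int | None = None
    delta_mean: float | None = None
    delta_sigma: float | None = None
    threshold: float | None = None


def compute_iqr(
    target_set: TargetSet, quartile_mode: QuartileMode = "linear"
) -> tuple[float, float, float]:
    """Q1, Q3 and IQR of a target set's pKi values.

    The default quartile convention is linear interpolation between order
    statistics (numpy's default). Sets with fewer than two compounds are not
    meaningful here and raise ``ValueError``; callers exclude and log them.
    """
    if target_set.n < 2:
        raise ValueError(f"target set {target_set.target_id}: n={target_set.n} < 2")
    values = np.array([c.pki for c in target_set.compounds], dtype=float)
    q1, q3 = np.quantile(values, [0.25, 0.75], method=quartile_mode)
    return float(q1), float(q3), float(q3 - q1)


def preselect_target_sets(
    stats_list: Iterable[TargetSetStats], min_iqr: float = 1.0
) -> list[TargetSetStats]:
    """Keep target sets whose pKi IQR spans at least ``min_iqr`` log units.

    The boundary is inclusive (an IQR of exactly one order of magnitude
    qualifies). Every retention decision is logged.
    """
    kept = []
    for st in stats_list:
        retained = st.iqr >= min_iqr
        logger.info(
            "target %s: IQR %.3f %s (min %.3f)",
            st.target_id, st.iqr, "retained" if retained else "excluded", min_iqr,
        )
        if retained:
            kept.append(st)
    return kept


def compute_threshold(
    pairs: Sequence[AnalogPair],
    base: TargetSetStats,
    sigma_mode: SigmaMode = "sample",
) -> TargetSetStats:
    """Complete a target set's stats with the ΔpKi threshold (mean + 2σ).

    σ is the sample standard deviation (n−1 denominator) by default;
    ``sigma_mode="population"`` switches to the n denominator. At least two
    pairs are required (σ is undefined for one); callers exclude the set
    otherwise, so this raises ``ValueError``.
    """
    if len(pairs) < 2:
        raise ValueError(
            f"target set {base.target_id}: {len(pairs)} analog pair(s), need ≥ 2"
        )
    deltas = np.array([p.delta_pki for p in pairs], dtype=float)
    mean = float(np.mean(deltas))
    sigma = float(np.std(deltas, ddof=1 if sigma_mode == "sample" else 0))
    return TargetSetStats(
        target_id=base.target_id,
        n_compounds=base.n_compounds,
        q1=base.q1,
        q3=base.q3,
        iqr=base.iqr,
        n_pairs=len(deltas),
        delta_mean=mean,
        delta_sigma=sigma,
        threshold=mean + 2.0 * sigma,
    )
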