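"""Replicate-derived error model and two-stage hit calling.

The screen's null model comes from strains measured twice through the full
pipeline: the average replicate difference estimates the assay error, and
normalized null values are modeled as N(0, sd). Strains are called at a
fixed log2 threshold whose significance is the normal upper tail (a
Z-score), then re-arrayed with center-peak control wells and confirmed in a
second pass against a different housekeeping gene.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

FINAL_CLASSES = (
    "downstream_TORC1",
    "upstream_or_parallel",
    "constitutive",
    "not_hit",
    "unclassified",
)

PRIMARY_THRESHOLD = 1.0
RESCREEN_SELECTION_THRESHOLD = 1.3
CONFIRMATION_THRESHOLD = 1.0


@dataclass(frozen=True)
class NullModel:
    """Normal null distribution for normalized log2 ratios of intact strains."""

    mean: float
    sd: float
    source: str = "replicate_derived"

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("null model sd must be positive")

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "source": self.source}


@dataclass(frozen=True)
class ReplicateStats:
    """Concordance of two replicate screens over their shared strains."""

    pearson_r: float
    mean_abs_diff: float
    n_pairs: int
    sd_diff: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "mean_abs_diff": self.mean_abs_diff,
            "sd_diff": self.sd_diff,
            "n_pairs": self.n_pairs,
        }


@dataclass
class HitCall:
    """Per-strain verdict across the staged screen design."""

    strain_id: str
    primary_log2: float
    selected_for_rescreen: bool = False
    rescreen_log2: float | None = None
    confirmed: bool = False
    mock_log2: float | None = None
    rap_log2: float | None = None
    final_class: str = "unclassified"


def replicate_concordance(
    rep1: Mapping[str, float], rep2: Mapping[str, float]
) -> ReplicateStats:
    """Pearson r and mean absolute difference over strains in both replicates."""
    shared = sorted(set(rep1) & set(rep2))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared strains; need at least 3")
    a = np.array([rep1[s] for s in shared])
    b = np.array([rep2[s] for s in shared])
    r = float(np.corrcoef(a, b)[0, 1])
    diffs = a - b
    return ReplicateStats(
        pearson_r=r,
        mean_abs_diff=float(np.mean(np.abs(diffs))),
        n_pairs=len(shared),
        sd_diff=float(np.std(diffs, ddof=1)),
    )


def fit_null_model(
    estimate: ReplicateStats | float, source: str = "replicate_derived"
) -> NullModel:
    """Null model N(0, sd) with sd = the error estimate rounded to one decimal.

    Accepts either a :class:`ReplicateStats` (its mean absolute difference is
    used) or a raw sd estimate. Rounding is half-up, matching the convention
    of quoting the error model to one decimal place.
    """
    est = (
        estimate.mean_abs_diff
        if isinstance(estimate, ReplicateStats)
        else float(estimate)
    )
    if est <= 0:
        raise ValueError("error estimate must be positive")
    sd = math.floor(est * 10.0 + 0.5) / 10.0
    if sd <= 0:
        raise ValueError(f"estimate {est} rounds to a zero sd")
    return NullModel(mean=0.0, sd=sd, source=source)


def z_score(threshold: float, model: NullModel) -> float:
    """Standard deviations from the null mean at ``threshold`` (display to 1 dp)."""
    return (threshold - model.mean) / model.sd


def tail_probability(threshold: float, model: NullModel) -> float:
    """One-sided upper-tail probability of the null model at ``threshold``."""
    return float(_stats.norm.sf(threshold, loc=model.mean, scale=model.sd))


def call_primary_hits(
    ratios: Mapping[str, float], threshold: float = PRIMARY_THRESHOLD
) -> set[str]:
    """Strains whose normalized log2 ratio is strictly above ``threshold``."""
    return {s for s, v in ratios.items() if v > threshold}


def select_for_rescreen(
    ratios: Mapping[str, float],
    selection_threshold: float = RESCREEN_SELECTION_THRESHOLD,
) -> set[str]:
    """Strains passing the (stricter) re-array selection cutoff."""
    return {s for s, v in ratios.items() if v > selection_threshold}


@dataclass(frozen=True)
class RearrayPlan:
    """Assignment of selected strains plus control wells to fresh plates.

    ``plates`` holds per-plate (strain_id, role) pairs; roles are
    ``library`` for selected strains and ``control_center_peak`` for the
    controls used to zero each hit-enriched plate.
    """

    plates: tuple[tuple[tuple[str, str], ...], ...]

    @property
    def strains(self) -> list[str]:
        return [s for plate in self.plates for s, role in plate if role == "library"]

    @property
    def controls(self) -> list[str]:
        return sorted(
            {s for plate in self.plates for s, role in plate if role != "library"}
        )


def build_rearray_plan(
    selected: Iterable[str],
    control_ids: Iterable[str],
    *,
    n_per_plate: int = 96,
    min_controls_per_plate: int = 4,
) -> RearrayPlan:
    """Pack selected strains onto plates, spreading controls evenly across them."""
    selected = sorted(set(selected))
    controls = sorted(set(control_ids))
    n_total = len(selected) + len(controls)
    if n_total == 0:
        return RearrayPlan(plates=())
    n_plates = -(-n_total // n_per_plate)
    if len(controls) < min_controls_per_plate * n_plates:
        raise ValueError(
            f"{len(controls)} controls cannot give every one of {n_plates} plates "
            f"at least {min_controls_per_plate}"
        )
    base, extra = divmod(len(controls), n_plates)
    plates: list[list[tuple[str, str]]] = []
    ci = 0
    si = 0
    for p in range(n_plates):
        n_ctrl = base + (1 if p < extra else 0)
        plate = [(c, "control_center_peak") for c in controls[ci : ci + n_ctrl]]
        ci += n_ctrl
        room = n_per_plate - len(plate)
        plate += [(s, "library") for s in selected[si : si + room]]
        si += room
        plates.append(plate)
    if si < len(selected):
        raise ValueError("selected strains do not fit on the planned plates")
    return RearrayPlan(plates=tuple(tuple(p) for p in plates))


def pick_center_peak_controls(
    ratios: Mapping[str, float], n: int, exclude: Iterable[str] = ()
) -> list[str]:
    """The ``n`` strains whose normalized value sits closest to the peak (0)."""
    excluded = set(exclude)
    candidates = sorted(
        (s for s in ratios if s not in excluded),
        key=lambda s: (abs(ratios[s]), s),
    )
    if len(candidates) < n:
        raise ValueError(f"only {len(candidates)} candidate controls; need {n}")
    return candidates[:n]


def confirm_hits(
    primary: Mapping[str, float],
    rescreen: Mapping[str, float],
    confirmation_threshold: float = CONFIRMATION_THRESHOLD,
) -> list[HitCall]:
    """Confirm re-arrayed strains against the control-normalized rescreen.

    A strain confirms iff its rescreen value is strictly above
    ``confirmation_threshold``; unconfirmed strains are classed ``not_hit``.
    Every rescreened strain must also carry a primary value.
    """
    calls: list[HitCall] = []
    for s in sorted(rescreen):
        if s not in primary:
            raise ValueError(f"strain {s!r} in rescreen but absent from primary screen")
        confirmed = rescreen[s] > confirmation_threshold
        calls.append(
            HitCall(
                strain_id=s,
                primary_log2=primary[s],
                selected_for_rescreen=True,
                rescreen_log2=rescreen[s],
                confirmed=confirmed,
                final_class="unclassified" if confirmed else "not_hit",
            )
        )
    return calls


def hit_calls_to_frame(calls: Sequence[HitCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            (
                c.strain_id,
                c.primary_log2,
                c.selected_for_rescreen,
                c.rescreen_log2,
                c.confirmed,
                c.mock_log2,
                c.rap_log2,
                c.final_class,
            )
            for c in calls
        ],
        columns=[
            "strain_id",
            "primary_log2",
            "selected_for_rescreen",
            "rescreen_log2",
            "confirmed",
            "mock_log2",
            "rap_log2",
            "final_class",
        ],
    )
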