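"""Placement of confirmed hits relative to TORC1 via mock and rapamycin subscreens.

Rapamycin inhibits TORC1 directly, so a strain that still fails to repress
the reporter under rapamycin is missing a gene acting downstream of TORC1;
a strain that represses normally acts upstream of, or in parallel with, the
TORC1 pathway. The mock subscreen catches constitutive strains whose
reporter is deregulated independent of condition -- such strains cannot
inform TORC1 epistasis, so the constitutive call takes precedence.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .hit_calling import HitCall, RearrayPlan, build_rearray_plan

SUBSCREEN_SELECTION_THRESHOLD = 1.4
MOCK_THRESHOLD = 1.0
RAPAMYCIN_THRESHOLD = 1.0
DEFAULT_SUBSCREEN_CONTROLS = 48
DEFAULT_MAX_SUBSCREEN_PLATES = 4


def flag_constitutive(
    mock_log2: Mapping[str, float], threshold: float = MOCK_THRESHOLD
) -> set[str]:
    """Strains strictly above ``threshold`` in mock stress: constitutively high."""
    return {s for s, v in mock_log2.items() if v > threshold}


def classify_torc1(
    rap_log2: Mapping[str, float],
    threshold: float = RAPAMYCIN_THRESHOLD,
    *,
    strict: bool = False,
) -> dict[str, str]:
    """Classify assayed strains by their rapamycin response.

    A strain at or above ``threshold`` (strictly above when ``strict``)
    failed to downregulate the reporter even with TORC1 chemically
    inhibited, so the deleted gene acts downstream of TORC1; all other
    assayed strains are classed upstream-or-parallel.
    """
    out: dict[str, str] = {}
    for s, v in rap_log2.items():
        hit = v > threshold if strict else v >= threshold
        out[s] = "downstream_TORC1" if hit else "upstream_or_parallel"
    return out


def build_subscreen_plan(
    primary: Mapping[str, float],
    control_ids: Iterable[str],
    *,
    selection_threshold: float = SUBSCREEN_SELECTION_THRESHOLD,
    max_plates: int = DEFAULT_MAX_SUBSCREEN_PLATES,
    n_per_plate: int = 96,
    min_controls_per_plate: int = 4,
) -> RearrayPlan:
    """Re-array the top strains (primary log2 above the subscreen cutoff).

    Capacity is capped at ``max_plates`` (the number that can be processed
    in parallel); if more strains pass the cutoff than fit, the highest
    primary values are kept.
    """
    controls = sorted(set(control_ids))
    capacity = max_plates * n_per_plate - len(controls)
    top = sorted(
        (s for s, v in primary.items() if v > selection_threshold),
        key=lambda s: (-primary[s], s),
    )[: max(capacity, 0)]
    return build_rearray_plan(
        top,
        controls,
        n_per_plate=n_per_plate,
        min_controls_per_plate=min_controls_per_plate,
    )


def assemble_final_classes(
    hit_calls: Sequence[HitCall],
    constitutive: Iterable[str],
    torc1: Mapping[str, str],
    *,
    mock_log2: Mapping[str, float] | None = None,
    rap_log2: Mapping[str, float] | None = None,
) -> list[HitCall]:
    """Merge subscreen calls into final per-strain classes.

    Precedence: constitutive > downstream_TORC1 > upstream_or_parallel.
    Confirmed hits never assayed in either subscreen stay ``unclassified``;
    unconfirmed strains stay ``not_hit``. A subscreen call for a strain
    absent from ``hit_calls`` is contradictory input and raises.
    """
    constitutive = set(constitutive)
    known = {c.strain_id for c in hit_calls}
    stray = (constitutive | set(torc1)) - known
    if stray:
        raise ValueError(
            f"subscreen strains not among hit calls: {sorted(stray)[:5]}"
        )
    for cls in torc1.values():
        if cls not in ("downstream_TORC1", "upstream_or_parallel"):
            raise ValueError(f"invalid TORC1 class {cls!r}")

    out: list[HitCall] = []
    for call in hit_calls:
        c = HitCall(**vars(call))
        s = c.strain_id
        if mock_log2 is not None and s in mock_log2:
            c.mock_log2 = mock_log2[s]
        if rap_log2 is not None and s in rap_log2:
            c.rap_log2 = rap_log2[s]
        if not c.confirmed:
            c.final_class = "not_hit"
        elif s in constitutive:
            c.final_class = "constitutive"
        elif s in torc1:
            c.final_class = torc1[s]
        else:
            c.final_class = "unclassified"
        out.append(c)
    return out
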