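"""Fixed-seed synthetic screens and interaction graphs with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage has an oracle:

* a two-population strain mixture -- most deletion strains repress the
  reporter normally (null population), a planted fraction are
  repression-defective with log2 effects drawn over the observed range;
* per-plate cycle offsets applied to both channels (they cancel in the
  F-J difference) plus a reporter-channel-only run offset of 0.3-0.6
  cycles with random sign, which survives into F-J and is exactly what
  plate normalization must remove;
* strain-level biological spread plus per-well technical noise calibrated
  so replicate screens reproduce the reference concordance (Pearson r
  near 0.90, mean absolute difference near 0.29 log2 units);
* ~4% well dropout expressed as late (>28 cycle) Ct values;
* mock and rapamycin condition responses encoding the epistasis classes;
* a background interaction graph with extra edges planted inside a chosen
  gene set, calibrated so a random 440-of-4709 subset induces ~492 edges.

Quantities are on the log2 scale throughout; the qPCR model assumes perfect
amplification efficiency (one Ct cycle per transcript doubling).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_io import WellRecord, well_name

CONDITIONS = ("KCl", "mock", "rapamycin")
LATE_CT_FLOOR = 28.0
WILD_TYPE_ID = "wild_type"


@dataclass(frozen=True)
class GeneratorConfig:
    """Calibration of the synthetic screen (all effect/noise units are log2)."""

    n_strains: int = 4709
    n_per_plate: int = 96
    hit_fraction: float = 0.10
    hit_effect_range: tuple[float, float] = (1.0, 4.5)
    null_bio_sd: float = 0.20
    well_noise_sd: float = 0.26
    plate_offset_range: tuple[float, float] = (0.3, 0.6)
    dropout_rate: float = 0.04
    mock_shift: float = 2.3
    downstream_fraction_of_hits: float = 53 / 332
    constitutive_fraction_of_hits: float = 5 / 332
    ct_baseline: float = 22.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "hit_fraction",
            "dropout_rate",
            "downstream_fraction_of_hits",
            "constitutive_fraction_of_hits",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in ("hit_effect_range", "plate_offset_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper {hi}")
        for name in ("null_bio_sd", "well_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.downstream_fraction_of_hits + self.constitutive_fraction_of_hits > 1:
            raise ValueError("downstream + constitutive fractions exceed 1")
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if not 1 <= self.n_per_plate <= 96:
            raise ValueError("n_per_plate must be in 1..96")
        if self.ct_baseline <= 0:
            raise ValueError("ct_baseline must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        data = json.loads(Path(path).read_text())
        data["hit_effect_range"] = tuple(data["hit_effect_range"])
        data["plate_offset_range"] = tuple(data["plate_offset_range"])
        return cls(**data)


@dataclass(frozen=True)
class StrainTruth:
    """Ground truth for one deletion strain.

    True expression levels are log2 reporter/housekeeping values relative to
    the stress-repressed wild-type baseline; the strain's persistent
    biological deviation is folded into all three condition levels.
    """

    strain_id: str
    is_hit: bool
    effect_kcl: float
    is_downstream_torc1: bool
    is_constitutive: bool
    true_kcl_level: float
    true_mock_level: float
    true_rap_level: float


def strain_ids(n: int) -> list[str]:
    return [f"YKO{i + 1:04d}" for i in range(n)]


def _generate_truth(config: GeneratorConfig, rng: np.random.Generator) -> list[StrainTruth]:
    n = config.n_strains
    ids = strain_ids(n)
    n_hits = int(round(config.hit_fraction * n))
    hit_idx = rng.choice(n, size=n_hits, replace=False) if n_hits else np.empty(0, int)
    is_hit = np.zeros(n, dtype=bool)
    is_hit[hit_idx] = True
    effect = np.zeros(n)
    effect[hit_idx] = rng.uniform(*config.hit_effect_range, size=n_hits)

    shuffled = rng.permutation(hit_idx)
    n_down = int(round(config.downstream_fraction_of_hits * n_hits))
    n_const = int(round(config.constitutive_fraction_of_hits * n_hits))
    down = np.zeros(n, dtype=bool)
    const = np.zeros(n, dtype=bool)
    down[shuffled[:n_down]] = True
    const[shuffled[n_down : n_down + n_const]] = True

    bio = rng.normal(0.0, config.null_bio_sd, size=n) if config.null_bio_sd else np.zeros(n)
    kcl = effect + bio
    # mock: every strain is de-repressed at mock_shift; constitutive strains
    # are elevated above even that baseline, condition-independently
    mock = config.mock_shift + bio + np.where(const, effect, 0.0)
    # rapamycin represses through TORC1, so only strains missing a gene
    # downstream of TORC1 (or constitutively deregulated) stay high
    rap = bio + np.where(down | const, effect, 0.0)

    return [
        StrainTruth(
            strain_id=ids[i],
            is_hit=bool(is_hit[i]),
            effect_kcl=float(effect[i]),
            is_downstream_torc1=bool(down[i]),
            is_constitutive=bool(const[i]),
            true_kcl_level=float(kcl[i]),
            true_mock_level=float(mock[i]),
            true_rap_level=float(rap[i]),
        )
        for i in range(n)
    ]


def _wild_type_level(condition: str, config: GeneratorConfig) -> float:
    return config.mock_shift if condition == "mock" else 0.0


def _true_level(truth: StrainTruth, condition: str) -> float:
    if condition == "KCl":
        return truth.true_kcl_level
    if condition == "mock":
        return truth.true_mock_level
    if condition == "rapamycin":
        return truth.true_rap_level
    raise ValueError(f"unknown condition {condition!r}")


def _library_assignments(config: GeneratorConfig) -> list[list[tuple[str, str]]]:
    """Strains in id order, row-major on plates; partial plates padded with
    wild-type filler wells so every plate is normalizable."""
    ids = strain_ids(config.n_strains)
    per = config.n_per_plate
    n_plates = -(-len(ids) // per)
    plates = []
    for p in range(n_plates):
        plate = [(s, "library") for s in ids[p * per : (p + 1) * per]]
        while len(plate) < per:
            plate.append((WILD_TYPE_ID, "wild_type"))
        plates.append(plate)
    return plates


def _measure(
    assignments: Sequence[Sequence[tuple[str, str]]],
    condition: str,
    truth_map: Mapping[str, StrainTruth],
    config: GeneratorConfig,
    rng: np.random.Generator,
    plate_prefix: str,
) -> list[WellRecord]:
    """Simulate one qPCR run of the given plate layout under one condition."""
    n_plates = len(assignments)
    lo, hi = config.plate_offset_range
    plate_off = rng.choice([-1.0, 1.0], size=n_plates) * rng.uniform(lo, hi, size=n_plates)
    run_off = rng.choice([-1.0, 1.0], size=n_plates) * rng.uniform(lo, hi, size=n_plates)
    channel_sd = config.well_noise_sd / math.sqrt(2.0)
    wt_level = _wild_type_level(condition, config)

    wells: list[WellRecord] = []
    for p, plate in enumerate(assignments):
        m = len(plate)
        noise_f = rng.normal(0.0, channel_sd, size=m) if channel_sd else np.zeros(m)
        noise_j = rng.normal(0.0, channel_sd, size=m) if channel_sd else np.zeros(m)
        drop = rng.random(m) < config.dropout_rate
        drop_channel = rng.integers(0, 2, size=m)
        late_ct = LATE_CT_FLOOR + rng.uniform(0.5, 10.0, size=m)
        plate_id = f"{plate_prefix}{p + 1:02d}"
        for i, (sid, role) in enumerate(plate):
            level = wt_level if role == "wild_type" else _true_level(truth_map[sid], condition)
            ct_fam = config.ct_baseline - level + plate_off[p] + run_off[p] + noise_f[i]
            ct_joe = config.ct_baseline + plate_off[p] + noise_j[i]
            if drop[i]:
                if drop_channel[i] == 0:
                    ct_fam = late_ct[i]
                else:
                    ct_joe = late_ct[i]
            wells.append(
                WellRecord(
                    plate_id=plate_id,
                    well=well_name(i),
                    strain_id=sid,
                    condition=condition,
                    role=role,
                    ct_fam=float(ct_fam),
                    ct_joe=float(ct_joe),
                )
            )
    return wells


def generate_screen(
    config: GeneratorConfig, conditions: Sequence[str] = CONDITIONS
) -> tuple[dict[str, list[WellRecord]], list[StrainTruth]]:
    """Simulate a full library screen: wells per condition plus ground truth.

    The same config and seed reproduce byte-identical well tables. Each
    condition is measured on its own plates (own offsets, noise, dropout).
    """
    config.validate()
    for c in conditions:
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition {c!r}")
    ss = np.random.SeedSequence(config.seed)
    truth_rng, *cond_rngs = [np.random.default_rng(s) for s in ss.spawn(1 + len(CONDITIONS))]
    truth = _generate_truth(config, truth_rng)
    truth_map = {t.strain_id: t for t in truth}
    assignments = _library_assignments(config)
    wells: dict[str, list[WellRecord]] = {}
    for cond, rng in zip(CONDITIONS, cond_rngs):
        if cond in conditions:
            wells[cond] = _measure(
                assignments, cond, truth_map, config, rng, plate_prefix=f"{cond}_P"
            )
    return wells, truth


def simulate_rearray(
    truth: Sequence[StrainTruth] | Mapping[str, StrainTruth],
    plan,
    condition: str,
    config: GeneratorConfig,
    seed: int,
    plate_prefix: str = "R_P",
) -> list[WellRecord]:
    """Measure a re-array plan (e.g. rescreen or subscreen plates) afresh.

    ``plan`` is a :class:`~ribiscreen.hit_calling.RearrayPlan` or a bare
    list of per-plate (strain_id, role) lists; a new seed gives independent
    noise, offsets, and dropout (a fresh robot run of the same strains).
    """
    truth_map = truth if isinstance(truth, Mapping) else {t.strain_id: t for t in truth}
    plates = getattr(plan, "plates", plan)
    rng = np.random.default_rng(seed)
    return _measure(plates, condition, truth_map, config, rng, plate_prefix=plate_prefix)


def replicate_library_screen(
    truth: Sequence[StrainTruth],
    condition: str,
    config: GeneratorConfig,
    seed: int,
    strain_subset: Iterable[str] | None = None,
    plate_prefix: str = "rep_P",
) -> list[WellRecord]:
    """Re-measure library strains (optionally a subset) with fresh noise."""
    truth_map = {t.strain_id: t for t in truth}
    if strain_subset is None:
        plates = _library_assignments(config)
    else:
        subset = [t.strain_id for t in truth if t.strain_id in set(strain_subset)]
        per = config.n_per_plate
        plates = []
        for p in range(-(-len(subset) // per)):
            plate = [(s, "library") for s in subset[p * per : (p + 1) * per]]
            while len(plate) < per:
                plate.append((WILD_TYPE_ID, "wild_type"))
            plates.append(plate)
    rng = np.random.default_rng(seed)
    return _measure(plates, condition, truth_map, config, rng, plate_prefix=plate_prefix)


TRUTH_COLUMNS = [
    "strain_id",
    "is_hit",
    "effect_kcl",
    "is_downstream_torc1",
    "is_constitutive",
    "true_kcl_level",
    "true_mock_level",
    "true_rap_level",
]


def truth_to_frame(truth: Iterable[StrainTruth]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in truth], columns=TRUTH_COLUMNS)


def write_truth(truth: Iterable[StrainTruth], path: str | Path) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[StrainTruth]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [StrainTruth(**row) for row in frame.to_dict("records")]


# ---------------------------------------------------------------------------
# Interaction-graph generator


@dataclass(frozen=True)
class GraphGeneratorConfig:
    """Background graph plus planted within-set edge enrichment.

    Defaults are calibrated so a random 440-gene subset of 4709 genes
    induces ~492 of the 56,500 background edges, and the planted set gains
    584 extra internal edges on top of that expectation (~1076 total).
    """

    n_genes: int = 4709
    background_edges: int = 56500
    planted_set_size: int = 440
    planted_extra_edges: int = 584
    evidence_class_mix: tuple[float, float, float] = (0.45, 0.35, 0.20)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        max_edges = self.n_genes * (self.n_genes - 1) // 2
        if not 0 <= self.background_edges <= max_edges:
            raise ValueError(
                f"background_edges={self.background_edges} exceeds {max_edges} pairs"
            )
        if not 0 <= self.planted_set_size <= self.n_genes:
            raise ValueError("planted_set_size outside universe")
        if abs(sum(self.evidence_class_mix) - 1.0) > 1e-9 or min(self.evidence_class_mix) < 0:
            raise ValueError("evidence_class_mix must be non-negative and sum to 1")


def _decode_pairs(codes: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear pair codes in [0, n(n-1)/2) to (i, j) with i < j."""
    starts = np.concatenate([[0], np.cumsum(np.arange(n - 1, 0, -1))])
    i = np.searchsorted(starts, codes, side="right") - 1
    j = i + 1 + (codes - starts[i])
    return i, j


def _sample_distinct_codes(
    rng: np.random.Generator, total: int, size: int, forbidden: set[int] | None = None
) -> np.ndarray:
    """Uniform sample of ``size`` distinct codes from range(total), avoiding
    ``forbidden``, by oversampled rejection (deterministic given rng)."""
    forbidden = forbidden or set()
    if size > total - len(forbidden):
        raise ValueError(f"cannot sample {size} distinct pairs from {total}")
    chosen: list[int] = []
    seen = set(forbidden)
    while len(chosen) < size:
        draw = rng.integers(0, total, size=max(2 * (size - len(chosen)), 16))
        for c in draw.tolist():
            if c not in seen:
                seen.add(c)
                chosen.append(c)
                if len(chosen) == size:
                    break
    return np.array(sorted(chosen), dtype=np.int64)


def generate_graph(
    config: GraphGeneratorConfig,
    planted_genes: Iterable[str],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sample an evidence-typed edge list with planted hit-hit enrichment.

    Background edges are uniform over unordered gene pairs (no self-loops,
    no duplicates); ``planted_extra_edges`` additional distinct edges are
    placed uniformly inside ``planted_genes``. Returns a 3-column frame
    (gene_a, gene_b, evidence_class).
    """
    config.validate()
    genes = list(genes) if genes is not None else strain_ids(config.n_genes)
    if len(genes) != config.n_genes:
        raise ValueError(f"expected {config.n_genes} genes, got {len(genes)}")
    index = {g: i for i, g in enumerate(genes)}
    planted = sorted(set(planted_genes))
    if len(planted) != config.planted_set_size:
        raise ValueError(
            f"planted set has {len(planted)} genes; config says {config.planted_set_size}"
        )
    unknown = [g for g in planted if g not in index]
    if unknown:
        raise ValueError(f"planted genes outside universe: {unknown[:5]}")

    n = config.n_genes
    rng = np.random.default_rng(config.seed)
    total = n * (n - 1) // 2
    bg_codes = _sample_distinct_codes(rng, total, config.background_edges)
    ai, bj = _decode_pairs(bg_codes, n)

    # planted extras: distinct pairs within the planted set, not duplicating
    # any background edge that already falls inside it
    k = len(planted)
    p_idx = np.array([index[g] for g in planted], dtype=np.int64)
    pa, pb = np.empty(0, np.int64), np.empty(0, np.int64)
    if config.planted_extra_edges:
        if k < 2:
            raise ValueError("planted set too small for extra edges")
        local = {g: i for i, g in enumerate(planted)}
        in_planted = np.isin(ai, p_idx) & np.isin(bj, p_idx)
        starts_local = np.concatenate([[0], np.cumsum(np.arange(k - 1, 0, -1))])

        def local_code(i_loc: int, j_loc: int) -> int:
            i_loc, j_loc = min(i_loc, j_loc), max(i_loc, j_loc)
            return int(starts_local[i_loc] + (j_loc - i_loc - 1))

        forbidden = {
            local_code(local[genes[i]], local[genes[j]])
            for i, j in zip(ai[in_planted], bj[in_planted])
        }
        extra_codes = _sample_distinct_codes(
            rng, k * (k - 1) // 2, config.planted_extra_edges, forbidden
        )
        li, lj = _decode_pairs(extra_codes, k)
        pa, pb = p_idx[li], p_idx[lj]

    all_a = np.concatenate([ai, pa])
    all_b = np.concatenate([bj, pb])
    classes = rng.choice(
        ["affinity", "interaction_screen", "other"],
        size=all_a.size,
        p=list(config.evidence_class_mix),
    )
    return pd.DataFrame(
        {
            "gene_a": [genes[i] for i in all_a],
            "gene_b": [genes[j] for j in all_b],
            "evidence_class": classes,
        }
    )


LOCALIZATIONS = ("nucleus", "endomembrane_vacuole", "other")


def generate_annotations(
    genes: Sequence[str],
    seed: int = 0,
    mix: tuple[float, float, float] = (0.3, 0.25, 0.45),
) -> pd.DataFrame:
    """Random localization tags per gene (for graph-export annotation)."""
    rng = np.random.default_rng(seed)
    tags = rng.choice(LOCALIZATIONS, size=len(genes), p=list(mix))
    return pd.DataFrame({"gene": list(genes), "localization": tags})
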