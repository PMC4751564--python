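"""End-to-end orchestration of the screen analysis.

Stage order mirrors the study design: simulate (or ingest) the library
screen, filter late/failed wells, mixture-normalize each plate, derive the
error model from replicate plates, call primary hits, re-array and confirm
against center-peak controls, classify confirmed hits by the mock and
rapamycin subscreens, then test the connectivity of the confirmed set in an
interaction network by permutation. Every stage writes a file artifact so
any stage can be re-run and inspected independently; the whole study is
deterministic given the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import epistasis, hit_calling, network, normalization, plate_io, synthetic_data
from .hit_calling import NullModel, ReplicateStats
from .network import ComponentStats, PermutationTestResult
from .synthetic_data import GeneratorConfig, GraphGeneratorConfig

logger = logging.getLogger("ribiscreen")

# stage artifact filenames
WELLS_CSV = "wells.csv"
TRUTH_TSV = "truth.tsv"
FILTERED_CSV = "wells_filtered.csv"
FILTER_JSON = "filter_report.json"
NORMALIZED_TSV = "normalized.tsv"
FITS_JSON = "mixture_fits.json"
REPLICATE_JSON = "replicate_stats.json"
NULL_JSON = "null_model.json"
HITS_TSV = "hit_calls.tsv"
CLASSES_TSV = "final_classes.tsv"
EDGES_TSV = "edges.tsv"
ANNOTATIONS_TSV = "annotations.tsv"
PERMUTATION_JSON = "permutation.json"
GRAPHML = "network.graphml"
SIF = "network.sif"
REPORT_JSON = "report.json"


@dataclass(frozen=True)
class StudyConfig:
    """All thresholds, seeds, and sizes of one full study run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    graph: GraphGeneratorConfig | None = None
    edge_list_path: str | None = None
    primary_threshold: float = 1.0
    rescreen_selection_threshold: float = 1.3
    confirmation_threshold: float = 1.0
    subscreen_selection_threshold: float = 1.4
    mock_threshold: float = 1.0
    rapamycin_threshold: float = 1.0
    n_permutations: int = 10000
    n_replicate_plates: int = 6
    n_rescreen_controls: int = 72
    n_subscreen_controls: int = 48
    max_subscreen_plates: int = 4
    ct_cutoff: float = 28.0
    null_sd_fixed: float | None = None
    hub_genes: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        self.generator.validate()
        for name in (
            "primary_threshold",
            "rescreen_selection_threshold",
            "confirmation_threshold",
            "subscreen_selection_threshold",
            "mock_threshold",
            "rapamycin_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["hit_effect_range"] = list(self.generator.hit_effect_range)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        gen = dict(data.pop("generator"))
        gen["hit_effect_range"] = tuple(gen["hit_effect_range"])
        gen["plate_offset_range"] = tuple(gen["plate_offset_range"])
        graph = data.pop("graph", None)
        if graph is not None:
            graph = dict(graph)
            graph["evidence_class_mix"] = tuple(graph["evidence_class_mix"])
            graph = GraphGeneratorConfig(**graph)
        data["hub_genes"] = tuple(data.get("hub_genes", ()))
        return cls(generator=GeneratorConfig(**gen), graph=graph, **data)

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class StudyReport:
    """Machine-readable per-stage summary of one study run."""

    seed: int
    n_strains: int
    n_wells_input: int
    filter_report: dict
    n_screened: int
    replicate_stats: dict
    null_model: dict
    n_primary_hits: int
    n_selected: int
    n_confirmed: int
    class_counts: dict
    observed_induced_edges: int
    observed_induced_edge_lines: int
    permutation: dict
    component_stats: dict
    version: str = ""

    def validate(self) -> None:
        if not (
            self.n_confirmed <= self.n_selected <= self.n_primary_hits <= self.n_screened
        ):
            raise ValueError(
                "inconsistent counts: confirmed <= selected <= primary <= screened "
                f"violated ({self.n_confirmed}, {self.n_selected}, "
                f"{self.n_primary_hits}, {self.n_screened})"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0] & 0x7FFFFFFF) for child in ss.spawn(n)]


def _scaled_graph_config(n_genes: int, k: int, seed: int) -> GraphGeneratorConfig:
    """Scale the default graph calibration to a different universe/hit size,
    preserving edge density and planted within-set density."""
    base = GraphGeneratorConfig()
    bg = int(round(base.background_edges * (n_genes * (n_genes - 1)) / (base.n_genes * (base.n_genes - 1))))
    bg = min(max(bg, 0), n_genes * (n_genes - 1) // 2)
    if k >= 2:
        extra = int(
            round(
                base.planted_extra_edges
                * (k * (k - 1))
                / (base.planted_set_size * (base.planted_set_size - 1))
            )
        )
        extra = min(extra, k * (k - 1) // 2 - 1)
    else:
        extra = 0
    return GraphGeneratorConfig(
        n_genes=n_genes,
        background_edges=bg,
        planted_set_size=k,
        planted_extra_edges=max(extra, 0),
        seed=seed,
    )


def _write_ratios(ratios, path: Path) -> None:
    pd.DataFrame(
        [(r.strain_id, r.plate_id, r.condition, r.log2_ratio, r.well, r.role) for r in ratios],
        columns=["strain_id", "plate_id", "condition", "log2_ratio", "well", "role"],
    ).to_csv(path, sep="\t", index=False)


def _normalize_controls(wells, control_ids, ct_cutoff):
    retained, _ = plate_io.filter_wells(wells, ct_cutoff)
    ratios, _ = normalization.normalize_screen(
        retained, method="controls", control_strain_ids=control_ids
    )
    return ratios


def run_study(config: StudyConfig, out_dir: str | Path) -> StudyReport:
    """Execute every stage in order, writing all artifacts under ``out_dir``.

    Per-stage randomness is derived from ``config.seed`` (the generator's
    own seed field is overridden), so a config and seed fully determine the
    report. Any stage failure aborts with the stage name and cause.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    stage = "simulate"
    try:
        # --- simulate ---------------------------------------------------
        gen = replace(config.generator, seed=seeds[0])
        wells_by_cond, truth = synthetic_data.generate_screen(gen, conditions=("KCl",))
        kcl_wells = wells_by_cond["KCl"]
        plate_io.write_wells(kcl_wells, out / WELLS_CSV)
        synthetic_data.write_truth(truth, out / TRUTH_TSV)
        config.to_json(out / "study_config.json")
        logger.info("[simulate] %d strains, %d KCl wells", gen.n_strains, len(kcl_wells))

        # --- filter -----------------------------------------------------
        stage = "filter"
        retained, filt = plate_io.filter_wells(kcl_wells, config.ct_cutoff)
        plate_io.write_wells(retained, out / FILTERED_CSV)
        filt.to_json(out / FILTER_JSON)
        logger.info("[filter] retained %d/%d wells", filt.n_retained, filt.n_input)

        # --- normalize --------------------------------------------------
        stage = "normalize"
        ratios, fits = normalization.normalize_screen(retained)
        _write_ratios(ratios, out / NORMALIZED_TSV)
        (out / FITS_JSON).write_text(
            json.dumps({f"{p}|{c}": f.to_dict() for (p, c), f in fits.items()}, indent=2)
        )
        primary_map = normalization.strain_values(ratios)
        logger.info("[normalize] %d plates, %d strains", len(fits), len(primary_map))

        # --- replicates & error model ------------------------------------
        stage = "replicates"
        rep_ids = synthetic_data.strain_ids(gen.n_strains)[
            : config.n_replicate_plates * gen.n_per_plate
        ]
        rep_wells = synthetic_data.replicate_library_screen(
            truth, "KCl", gen, seed=seeds[1], strain_subset=rep_ids
        )
        rep_retained, _ = plate_io.filter_wells(rep_wells, config.ct_cutoff)
        rep_ratios, _ = normalization.normalize_screen(rep_retained)
        rep2_map = normalization.strain_values(rep_ratios)
        rep1_map = {s: primary_map[s] for s in rep_ids if s in primary_map}
        stats = hit_calling.replicate_concordance(rep1_map, rep2_map)
        if config.null_sd_fixed is not None:
            null = NullModel(0.0, config.null_sd_fixed, source="fixed")
        else:
            null = hit_calling.fit_null_model(stats)
        (out / REPLICATE_JSON).write_text(json.dumps(stats.to_dict(), indent=2) + "\n")
        (out / NULL_JSON).write_text(json.dumps(null.to_dict(), indent=2) + "\n")
        # duplicate-run plates: combine the two measurements by mean
        for s in set(rep1_map) & set(rep2_map):
            primary_map[s] = 0.5 * (rep1_map[s] + rep2_map[s])
        logger.info(
            "[replicates] r=%.3f mean|diff|=%.3f over %d strains -> null sd %.1f",
            stats.pearson_r, stats.mean_abs_diff, stats.n_pairs, null.sd,
        )

        # --- primary calls & selection -----------------------------------
        stage = "screen"
        primary_hits = hit_calling.call_primary_hits(primary_map, config.primary_threshold)
        selected = hit_calling.select_for_rescreen(
            primary_map, config.rescreen_selection_threshold
        )
        logger.info("[screen] %d primary hits, %d selected", len(primary_hits), len(selected))

        # --- rescreen & confirmation -------------------------------------
        stage = "confirm"
        controls = hit_calling.pick_center_peak_controls(
            primary_map, config.n_rescreen_controls, exclude=selected
        )
        plan = hit_calling.build_rearray_plan(
            selected, controls, n_per_plate=gen.n_per_plate
        )
        rescreen_wells = synthetic_data.simulate_rearray(
            truth, plan, "KCl", gen, seed=seeds[2], plate_prefix="rescreen_P"
        )
        rescreen_ratios = _normalize_controls(rescreen_wells, set(controls), config.ct_cutoff)
        rescreen_map = normalization.strain_values(rescreen_ratios)
        hit_calls = hit_calling.confirm_hits(
            primary_map, rescreen_map, config.confirmation_threshold
        )
        # selected strains whose rescreen well dropped out: unconfirmed
        measured = {c.strain_id for c in hit_calls}
        for s in sorted(selected - measured):
            hit_calls.append(
                hit_calling.HitCall(
                    strain_id=s,
                    primary_log2=primary_map[s],
                    selected_for_rescreen=True,
                    confirmed=False,
                    final_class="not_hit",
                )
            )
        confirmed = {c.strain_id for c in hit_calls if c.confirmed}
        hit_calling.hit_calls_to_frame(hit_calls).to_csv(out / HITS_TSV, sep="\t", index=False)
        logger.info("[confirm] %d confirmed of %d rescreened", len(confirmed), len(hit_calls))

        # --- epistasis subscreens ----------------------------------------
        stage = "classify"
        sub_controls = hit_calling.pick_center_peak_controls(
            primary_map, config.n_subscreen_controls, exclude=selected
        )
        sub_plan = epistasis.build_subscreen_plan(
            primary_map,
            sub_controls,
            selection_threshold=config.subscreen_selection_threshold,
            max_plates=config.max_subscreen_plates,
            n_per_plate=gen.n_per_plate,
        )
        mock_wells = synthetic_data.simulate_rearray(
            truth, sub_plan, "mock", gen, seed=seeds[3], plate_prefix="mock_P"
        )
        rap_wells = synthetic_data.simulate_rearray(
            truth, sub_plan, "rapamycin", gen, seed=seeds[4], plate_prefix="rap_P"
        )
        mock_map = normalization.strain_values(
            _normalize_controls(mock_wells, set(sub_controls), config.ct_cutoff)
        )
        rap_map = normalization.strain_values(
            _normalize_controls(rap_wells, set(sub_controls), config.ct_cutoff)
        )
        constitutive = epistasis.flag_constitutive(mock_map, config.mock_threshold)
        torc1 = epistasis.classify_torc1(rap_map, config.rapamycin_threshold)
        final_calls = epistasis.assemble_final_classes(
            hit_calls, constitutive, torc1, mock_log2=mock_map, rap_log2=rap_map
        )
        hit_calling.hit_calls_to_frame(final_calls).to_csv(
            out / CLASSES_TSV, sep="\t", index=False
        )
        class_counts: dict[str, int] = {c: 0 for c in hit_calling.FINAL_CLASSES}
        for call in final_calls:
            class_counts[call.final_class] += 1
        logger.info("[classify] %s", class_counts)

        # --- network -----------------------------------------------------
        stage = "network"
        genes = synthetic_data.strain_ids(gen.n_strains)
        if config.edge_list_path is not None:
            edges = network.read_edge_list(config.edge_list_path)
        else:
            if config.graph is not None:
                gcfg = replace(
                    config.graph, planted_set_size=len(confirmed), seed=seeds[5]
                )
            else:
                gcfg = _scaled_graph_config(gen.n_strains, len(confirmed), seeds[5])
            edges = synthetic_data.generate_graph(gcfg, confirmed, genes=genes)
        network.write_edge_list(edges, out / EDGES_TSV)

        observed = network.count_induced_edges(edges, confirmed)
        observed_lines = network.count_induced_edge_lines(edges, confirmed)
        perm = network.permutation_test(
            edges,
            genes,
            set_size=len(confirmed),
            observed_set=confirmed,
            n_permutations=config.n_permutations,
            seed=seeds[6],
        )
        perm.to_json(out / PERMUTATION_JSON)

        ann_frame = synthetic_data.generate_annotations(genes, seed=seeds[7])
        ann_frame.to_csv(out / ANNOTATIONS_TSV, sep="\t", index=False)
        downstream = {
            c.strain_id for c in final_calls if c.final_class == "downstream_TORC1"
        }
        loc = dict(zip(ann_frame["gene"], ann_frame["localization"]))
        annotations = {
            g: {"downstream_torc1": g in downstream, "localization": loc.get(g, "other")}
            for g in confirmed
        }
        graph = network.build_graph(edges, genes, confirmed, annotations)
        pruned = network.prune_hubs(graph, config.hub_genes)
        comps = network.component_stats(pruned)
        network.export_graph(pruned, out / GRAPHML)
        network.export_graph(pruned, out / SIF)
        logger.info(
            "[network] observed %d induced edges vs null mean %.1f (p=%.2g)",
            observed, perm.null_mean, perm.empirical_p,
        )

        # --- report ------------------------------------------------------
        stage = "report"
        from . import __version__

        report = StudyReport(
            seed=config.seed,
            n_strains=gen.n_strains,
            n_wells_input=len(kcl_wells),
            filter_report=filt.to_dict(),
            n_screened=len(primary_map),
            replicate_stats=stats.to_dict(),
            null_model=null.to_dict(),
            n_primary_hits=len(primary_hits),
            n_selected=len(selected),
            n_confirmed=len(confirmed),
            class_counts=class_counts,
            observed_induced_edges=observed,
            observed_induced_edge_lines=observed_lines,
            permutation={
                "observed_edges": perm.observed_edges,
                "n_permutations": perm.n_permutations,
                "null_mean": perm.null_mean,
                "null_max": perm.null_max,
                "empirical_p": perm.empirical_p,
            },
            component_stats=comps.to_dict(),
            version=__version__,
        )
        report.validate()
        report.to_json(out / REPORT_JSON)
        return report
    except Exception as exc:
        raise RuntimeError(f"study stage {stage!r} failed: {exc}") from exc
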