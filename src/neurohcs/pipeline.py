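"""End-to-end workflow: synthetic plate -> per-field analysis ->
per-well aggregation -> group statistics.

The pipeline mirrors the high-content screening workflow: every well of
a plate is imaged at several fields; each field is analyzed
independently; features are averaged per well; and well means are
compared across treatment groups with the nonparametric testing scheme.
Here the plate is synthetic, so every treatment group has known ground
truth and the whole chain is verifiable.

All randomness derives from the single config seed via
``numpy.random.SeedSequence(entropy=(seed, well, field))``, so reruns
with the same config are bit-identical and results are independent of
execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import PlateLayout, PlateLayoutEntry
from . import synthgen, morpho, calcium, kymo as kymo_mod, stats as stats_mod

MORPHO_STAGES = ("cytotox", "neurite", "synapse", "coloc", "fibril")
ALL_STAGES = ("synth",) + MORPHO_STAGES + ("calcium", "kymo", "stats")


class PlanError(ValueError):
    """Raised when requested stages cannot run in a consistent order."""


@dataclass
class TreatmentSpec:
    """Ground-truth generator settings for one treatment group."""

    name: str
    n_wells: int = 4
    dead_fraction: float = 0.05
    n_nuclei_per_field: int = 60
    crowding: float = 0.0
    total_neurite_length_um: float = 6000.0
    synapse_density: float = 0.05
    coloc_rho: float = 0.5
    n_fibrils: int = 0
    n_round_blobs: int = 3
    active_fraction: float = 0.6
    sync_prob: float = 0.9
    burst_rate_per_min: float = 3.0
    comet_velocity_um_s: float = 0.2


@dataclass
class RunConfig:
    """Everything a run needs; serialized into the output directory."""

    seed: int = 0
    out_dir: str = "neurohcs_out"
    pixel_size: float = 0.325
    field_shape: tuple[int, int] = (1024, 1024)
    n_fields: int = 16
    treatments: list[TreatmentSpec] = dfield(default_factory=lambda: [
        TreatmentSpec(name="control"),
        TreatmentSpec(name="treated", dead_fraction=0.3, coloc_rho=0.2,
                      synapse_density=0.02, sync_prob=0.2, n_fibrils=5),
    ])
    # fixed thresholds (detector units of the synthetic rendering scale)
    nucleus_threshold: float = 250.0
    pi_threshold: float = 150.0
    rolling_ball_radius_px: int = 25
    # calcium settings
    calcium_n_cells: int = 50
    calcium_neuron_fraction: float = 0.8
    calcium_noise_sd: float = 0.02
    # comet settings
    kymo_n_comets: int = 10
    # stats settings
    posthoc: str = "steel"
    control_name: str = "control"
    n_permutations: int = 10_000
    save_images: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["field_shape"] = list(self.field_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "field_shape" in d:
            d["field_shape"] = tuple(d["field_shape"])
        if "treatments" in d:
            d["treatments"] = [
                t if isinstance(t, TreatmentSpec) else TreatmentSpec(**t)
                for t in d["treatments"]
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def small(self, **overrides) -> "RunConfig":
        """Desk-scale copy (few small fields) for quick runs and tests."""
        d = self.to_dict()
        d.update(dict(field_shape=[256, 256], n_fields=4,
                      n_permutations=2000), **overrides)
        d["treatments"] = [
            {**t, "n_wells": min(3, t["n_wells"]),
             "n_nuclei_per_field": 15,
             "total_neurite_length_um": 800.0,
             "n_fibrils": min(2, t["n_fibrils"])}
            for t in d["treatments"]
        ]
        return RunConfig.from_dict(d)


def _field_seed(seed: int, well_idx: int, field_idx: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence(entropy=(seed, well_idx, field_idx, salt))
    return int(ss.generate_state(1)[0] % (2**31))


def make_layout(config: RunConfig) -> PlateLayout:
    entries = []
    w = 0
    for t in config.treatments:
        for k in range(t.n_wells):
            entries.append(PlateLayoutEntry(
                well_id=f"W{w:02d}", treatment=t.name, dose=0.0,
                biological_replicate=1, well_replicate=k + 1,
            ))
            w += 1
    return PlateLayout(entries)


def _well_specs(config: RunConfig):
    """(well_idx, well_id, TreatmentSpec) triples in plate order."""
    out = []
    w = 0
    for t in config.treatments:
        for _ in range(t.n_wells):
            out.append((w, f"W{w:02d}", t))
            w += 1
    return out


# ---------------------------------------------------------------------------
# per-field analysis
# ---------------------------------------------------------------------------

def _analyze_field(config: RunConfig, spec: TreatmentSpec, well_idx: int,
                   field_idx: int, stages: set[str]) -> dict:
    """Generate one synthetic field and run the requested morpho stages."""
    row: dict = {}
    ps = config.pixel_size
    if "cytotox" in stages:
        nuc, pi, truth = synthgen.synth_nuclei_field(
            n_cells=spec.n_nuclei_per_field, dead_fraction=spec.dead_fraction,
            crowding=spec.crowding,
            seed=_field_seed(config.seed, well_idx, field_idx, 1),
            shape=config.field_shape, pixel_size=ps,
        )
        nuc = morpho.subtract_background(nuc, config.rolling_ball_radius_px)
        labels = morpho.segment_nuclei(nuc, config.nucleus_threshold)
        pct, _, n = morpho.classify_pi_positive(labels, pi, config.pi_threshold)
        row.update(pct_pi_positive=pct, n_nuclei=n,
                   true_dead_pct=100.0 * spec.dead_fraction)
    if stages & {"neurite", "synapse", "coloc"}:
        tub, acet, syn, truth = synthgen.synth_neurite_field(
            total_neurite_length_um=spec.total_neurite_length_um,
            synapse_density_true=spec.synapse_density,
            coloc_rho=spec.coloc_rho,
            seed=_field_seed(config.seed, well_idx, field_idx, 2),
            shape=config.field_shape, pixel_size=ps,
        )
        tub_bs = morpho.subtract_background(tub, config.rolling_ball_radius_px)
        mask = morpho.segment_neurites(tub_bs)
        if "neurite" in stages:
            row.update(neurite_area_um2=mask.area_um2,
                       true_neurite_area_um2=truth.neurite_area_um2)
        if "synapse" in stages:
            syn_bs = morpho.subtract_background(
                syn, config.rolling_ball_radius_px)
            spots = morpho.detect_synapse_spots(syn_bs)
            truth_mask = morpho.NeuriteMask(truth.neurite_mask, ps)
            row.update(synapse_count=len(spots),
                       synapse_density=morpho.synapse_density(spots, truth_mask),
                       true_synapse_density=spec.synapse_density)
        if "coloc" in stages:
            truth_mask = morpho.NeuriteMask(truth.neurite_mask, ps)
            row.update(
                coloc_pcc=morpho.pearson_colocalization(tub, acet, truth_mask),
                acet_ratio=morpho.intensity_ratio(acet, tub, mask),
                true_coloc_rho=spec.coloc_rho,
            )
    if "fibril" in stages:
        pftaa, mt_mask, truth = synthgen.synth_fibril_field(
            n_fibrils=spec.n_fibrils, n_round_blobs=spec.n_round_blobs,
            seed=_field_seed(config.seed, well_idx, field_idx, 3),
            shape=config.field_shape, pixel_size=ps,
        )
        mt = morpho.NeuriteMask(
            np.ones(config.field_shape, dtype=bool), ps)
        _, load = morpho.segment_fibrils(pftaa, mt)
        row.update(fibril_load_um2=load,
                   true_fibril_load_um2=truth.fibril_load_um2)
    return row


def _analyze_well_functional(config: RunConfig, spec: TreatmentSpec,
                             well_idx: int, stages: set[str]) -> dict:
    row: dict = {}
    if "calcium" in stages:
        rec, truth = synthgen.synth_calcium_recording(
            n_cells=config.calcium_n_cells,
            neuron_fraction=config.calcium_neuron_fraction,
            active_fraction=spec.active_fraction,
            burst_rate_per_min=spec.burst_rate_per_min,
            sync_prob=spec.sync_prob,
            noise_sd=config.calcium_noise_sd,
            seed=_field_seed(config.seed, well_idx, 0, 4),
        )
        cls = calcium.classify_glutamate_responders(rec)
        m = calcium.network_metrics(rec, cls)
        row.update(pct_active=m.pct_active,
                   burst_frequency=m.burst_frequency,
                   burst_correlation=m.burst_correlation,
                   nd_flag=float(m.nd_flag))
    if "kymo" in stages:
        movie, polyline, truth = synthgen.synth_comet_movie(
            n_comets=config.kymo_n_comets,
            velocity_um_s=spec.comet_velocity_um_s,
            seed=_field_seed(config.seed, well_idx, 0, 5),
            pixel_size=config.pixel_size,
        )
        kg = kymo_mod.build_kymograph(
            movie, polyline, pixel_size=config.pixel_size,
            frame_interval_s=truth.extra["frame_interval_s"])
        _, mean_v = kymo_mod.measure_velocity(kg)
        row.update(comet_velocity_um_s=mean_v,
                   true_comet_velocity_um_s=spec.comet_velocity_um_s)
    return row


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, stages=("all",)) -> Path:
    """Run selected stages in dependency order; returns the output dir.

    Stage plan is validated up front: analysis stages need ``synth``
    (the generator) and ``stats`` needs at least one analysis stage.
    Outputs: ``field_metrics.csv``, ``well_summary.csv``,
    ``stats_results.csv``, ``layout.csv`` and ``manifest.json``.
    """
    stages = set(stages)
    if "all" in stages:
        stages = set(ALL_STAGES)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise PlanError(f"unknown stages: {sorted(unknown)}")
    analysis = stages & (set(MORPHO_STAGES) | {"calcium", "kymo"})
    if analysis and "synth" not in stages:
        raise PlanError("analysis stages need 'synth' to provide inputs")
    if "stats" in stages and not analysis:
        raise PlanError("'stats' needs at least one analysis stage "
                        "to produce well summaries")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = make_layout(config)
    layout.to_csv(out / "layout.csv")
    config.to_yaml(out / "config.yaml")

    rows = []
    for well_idx, well_id, spec in _well_specs(config):
        for field_idx in range(config.n_fields):
            row = {"well": well_id, "field": field_idx,
                   "treatment": spec.name}
            row.update(_analyze_field(config, spec, well_idx, field_idx,
                                      stages))
            rows.append(row)
        frow = _analyze_well_functional(config, spec, well_idx, stages)
        if frow:
            # functional recordings: one per well, logged as field -1
            rows.append({"well": well_id, "field": -1,
                         "treatment": spec.name, **frow})
    field_metrics = pd.DataFrame(rows)
    field_metrics.to_csv(out / "field_metrics.csv", index=False)

    metric_cols = [c for c in field_metrics.columns
                   if c not in ("well", "field", "treatment")]
    well_summary = stats_mod.aggregate_per_well(
        field_metrics, metric_columns=metric_cols)
    treat = field_metrics.groupby("well")["treatment"].first()
    well_summary["treatment"] = well_summary["well"].map(treat)
    well_summary.to_csv(out / "well_summary.csv", index=False)

    if "stats" in stages:
        results = []
        testable = [c for c in metric_cols
                    if not c.startswith("true_") and c != "nd_flag"]
        for i, m in enumerate(testable):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats_mod.compare_groups(
                    well_summary, m, control=config.control_name,
                    posthoc=config.posthoc,
                    n_permutations=config.n_permutations,
                    seed=_field_seed(config.seed, 999, i, 6),
                )
            results.append(res)
        stats_mod.comparisons_table(results).to_csv(
            out / "stats_results.csv", index=False)

    manifest = {
        "package": "neurohcs",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": sorted(stages),
        "n_wells": len(layout),
        "n_fields": config.n_fields,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return out
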