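"""End-to-end pipeline: simulation -> quantification -> screen report.

Chains the package stages under one validated configuration.  Every run
writes its intermediate tables plus a machine-readable manifest (package
version, config hash, seed) beside the outputs, sufficient to reproduce the
run exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import ConfigError
from .imaging import quantify_field, summarize_well, cell_records_to_frame, well_summaries_to_frame
from .plates import score_plate
from .screenstats import IMAGING_READOUTS, PLATE_READOUTS, ScreenReport, screen_report
from .simulate import (
    ImageSimSpec,
    PlateSimSpec,
    default_layout,
    simulate_screen,
    simulate_well_fields,
    write_field_tiff,
)

logger = logging.getLogger(__name__)


def _run_plate_arm(config: RunConfig, out: Path) -> ScreenReport:
    sim = config.plate_sim
    spec = PlateSimSpec(
        plate_format=sim.plate_format,
        mu_cell_control=sim.mu_cell_control,
        mu_positive=sim.mu_positive,
        mu_viability_control=sim.mu_viability_control,
        mu_viable=sim.mu_viable,
        stain_dead_fraction=sim.stain_dead_fraction,
        cv=sim.cv,
        hit_ids=dict(sim.hits),
        seed=config.seed,
    )
    layouts, reads, truth = simulate_screen(spec, n_plates=sim.n_plates)
    plate_dir = out / "plates"
    plate_dir.mkdir(parents=True, exist_ok=True)
    scores = []
    for layout, (stain, viab) in zip(layouts, reads):
        layout.to_csv(plate_dir / f"{layout.plate_id}_layout.csv")
        stain.to_csv(plate_dir / f"{layout.plate_id}_stain.csv")
        viab.to_csv(plate_dir / f"{layout.plate_id}_viab.csv")
        scores.append(score_plate(layout, stain, viab, config.analysis.viability_floor))
    truth.to_csv(out / "plate_truth.tsv", sep="\t", index=False)
    score_table = pd.concat(scores, ignore_index=True)
    score_table.to_csv(out / "plate_scores.tsv", sep="\t", index=False)
    report = screen_report(
        score_table,
        readouts=PLATE_READOUTS,
        k=config.analysis.k,
        z_readout="stain_value",
        metadata={"arm": "plate", "seed": config.seed, "n_plates": sim.n_plates},
    )
    report.to_dir(out / "report_plate")
    return report


def _run_imaging_arm(config: RunConfig, out: Path) -> ScreenReport:
    sim = config.image_sim
    ana = config.analysis
    layout = default_layout(96, plate_id="imaging01")
    wells = layout.wells[: sim.n_wells]
    table = layout.table.loc[wells]
    for role in ("cell_control", "positive_control"):
        if (table["role"] == role).sum() < 2:
            raise ConfigError(
                f"image_sim.n_wells={sim.n_wells} covers <2 wells of role {role!r}; "
                "increase n_wells"
            )
    field_dir = out / "fields"
    if sim.write_tiffs:
        field_dir.mkdir(parents=True, exist_ok=True)
    all_records = []
    summaries = []
    rng = np.random.default_rng([config.seed, 4])
    for well in wells:
        role = table.loc[well, "role"]
        compound = table.loc[well, "compound_id"]
        if role == "positive_control":
            factor = sim.positive_multiplier
        elif role == "test" and compound in sim.hits:
            factor = float(sim.hits[compound])
        else:
            factor = 1.0
        spec = ImageSimSpec(
            field_shape=tuple(sim.field_shape),
            n_cells=sim.n_cells,
            nucleus_radius=sim.nucleus_radius,
            cell_radius=sim.cell_radius,
            intensity_pm=500.0 * factor,
            intensity_perinuclear=300.0 * factor,
            intensity_cytoplasm=100.0 * factor,
            noise_sd=sim.noise_sd,
            pm_width=ana.pm_width,
            perinuclear_width=ana.perinuclear_width,
            seed=int(rng.integers(2**31)),
        )
        fields, _truths = simulate_well_fields(spec, well, n_fields=ana.fields_per_well)
        well_records = []
        for fld in fields:
            if sim.write_tiffs:
                write_field_tiff(field_dir / f"{well}_f{fld.field_index:02d}.tif", fld)
            recs = quantify_field(
                fld,
                nuclear_threshold=ana.nuclear_threshold,
                cyto_threshold=ana.cyto_threshold,
                pm_width=ana.pm_width,
                perinuclear_width=ana.perinuclear_width,
                min_nucleus_area=ana.min_nucleus_area,
                metric=ana.metric,
            )
            well_records.append(recs)
            all_records.extend(recs)
        summaries.append(summarize_well(well_records, well_id=well))
    cell_records_to_frame(all_records).to_csv(out / "cell_records.tsv", sep="\t", index=False)
    summary_table = well_summaries_to_frame(summaries)
    summary_table.to_csv(out / "well_summaries.tsv", sep="\t", index=False)

    merged = summary_table.merge(
        table.reset_index()[["well", "role", "compound_id"]],
        left_on="well_id",
        right_on="well",
    )
    merged["plate_id"] = "imaging01"
    report = screen_report(
        merged,
        readouts=IMAGING_READOUTS,
        k=config.analysis.k,
        z_readout="mean_total",
        metadata={"arm": "imaging", "seed": config.seed, "n_wells": len(wells)},
    )
    report.to_dir(out / "report_imaging")
    return report


def run_pipeline(config: RunConfig) -> dict[str, ScreenReport]:
    """Run every enabled arm of the pipeline and write all outputs.

    Returns the screen reports keyed by arm name ("plate", "imaging").
    Deterministic for a fixed config (the manifest records the config hash
    and seed needed to reproduce it).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "hcscreen",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run_pipeline: version=%s config_hash=%s seed=%d",
                __version__, manifest["config_hash"], config.seed)
    reports: dict[str, ScreenReport] = {}
    if config.plate_sim.enabled:
        reports["plate"] = _run_plate_arm(config, out)
    if config.image_sim.enabled:
        reports["imaging"] = _run_imaging_arm(config, out)
    if not reports:
        raise ConfigError("no pipeline arm enabled (plate_sim.enabled and image_sim.enabled "
                          "are both false)")
    return reports
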