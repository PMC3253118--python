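"""End-to-end orchestration: all species, all products, one report."""

from __future__ import annotations

import logging
from pathlib import Path

from .config import RunConfig
from .geodata import (
    EnvRaster,
    LocalityTable,
    write_class_table_csv,
    write_env_raster,
    write_geojson,
    write_report_json,
)
from .mapping import SuitabilityMap, run_species_model
from .sampling import bin_parameter, build_attribute_table, classify_frequencies

logger = logging.getLogger(__name__)


def run_pipeline(
    localities: LocalityTable,
    rasters: dict[str, EnvRaster],
    config: RunConfig,
    out_dir: str | Path,
    dry_run: bool = False,
) -> dict:
    """Run the per-species model for every requested species and write products.

    Returns the combined summary (also written as ``summary.json``).
    Species below ``min_records`` are listed under ``skipped`` with the
    reason, never silently dropped.
    """
    out_dir = Path(out_dir)
    species_list = config.species or localities.species
    summary: dict = {
        "config": config.to_mapping(),
        "n_localities": len(localities),
        "counts_by_species": localities.counts_by_species,
        "species": {},
        "skipped": {},
    }
    if dry_run:
        logger.info("dry run: inputs validated (%d localities, %d rasters)",
                    len(localities), len(rasters))
        summary["dry_run"] = True
        return summary

    out_dir.mkdir(parents=True, exist_ok=True)
    for species in species_list:
        logger.info("modelling %s", species)
        report, suit = run_species_model(
            localities,
            rasters,
            species,
            bin_widths=config.bin_widths,
            response_radius_km=config.response_radius_km,
            vif_threshold=config.vif_threshold,
            k_neighbors=config.gwr_k_neighbors,
            moran_scheme=config.moran_scheme,
            n_sd=config.ellipse_n_sd,
            radius_cells=config.focal_radius_cells,
            min_records=config.min_records,
        )
        if report.skipped:
            summary["skipped"][species] = report.skip_reason
            continue
        summary["species"][species] = report.to_dict()
        _write_species_products(report, suit, localities, rasters, config, out_dir)

    write_report_json(summary, out_dir / "summary.json")
    return summary


def _write_species_products(
    report,
    suit: SuitabilityMap,
    localities: LocalityTable,
    rasters: dict[str, EnvRaster],
    config: RunConfig,
    out_dir: Path,
) -> None:
    tag = report.species.replace(" ", "_")
    tpl = suit.template
    classified = EnvRaster(
        code="SUIT",
        grid=suit.classified.astype(float),
        west=tpl.west,
        north=tpl.north,
        cell_size=tpl.cell_size,
        nodata=0.0,
    )
    write_env_raster(classified, out_dir / f"{tag}_suitability_class.asc")
    cont = suit.continuous.copy()
    cont[~(cont == cont)] = -9999.0  # NaN -> sentinel
    write_env_raster(
        EnvRaster(code="SUIT", grid=cont, west=tpl.west, north=tpl.north,
                  cell_size=tpl.cell_size, nodata=-9999.0),
        out_dir / f"{tag}_suitability_continuous.asc",
    )
    write_geojson(
        suit.ellipse.polygon(),
        out_dir / f"{tag}_ellipse.geojson",
        properties=suit.ellipse.to_dict(),
    )
    write_report_json(report.to_dict(), out_dir / f"{tag}_report.json")

    # frequency-class tables for the selected pair (the published-table analogue)
    attr = build_attribute_table(localities.subset(report.species), rasters)
    rows = []
    for code in report.selected_pair:
        freq = bin_parameter(attr[code].to_numpy(), code, config.bin_widths.get(code))
        rows.extend(classify_frequencies(freq).rows())
    write_class_table_csv(rows, out_dir / f"{tag}_frequency_classes.csv")
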