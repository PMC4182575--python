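"""End-to-end screen pipeline: inputs -> wells -> scores -> gene calls.

Stages run in order (images -> wells -> normalize -> Z -> hits -> genes);
every output CSV carries the configuration hash and seed as metadata so a
rerun with the same config is bit-identical for deterministic stages.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from .io import (
    RunConfig,
    config_hash,
    read_plate_map,
    read_table,
    read_wells_csv,
    write_table,
)
from .microscopy import load_field
from .scoring import (
    HitParams,
    call_gene_hits,
    rank_normalized_table,
    score_screen,
)
from .segmentation import SegParams, analyze_field, well_efficiency
from .simulate import ScreenDesign, simulate_screen

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "wells_from_images"]


def wells_from_images(
    images_dir: str | Path,
    plate_map: pd.DataFrame,
    seg_params: SegParams = SegParams(),
    n_fields: int = 6,
) -> pd.DataFrame:
    """Segment every well's fields and aggregate to a well table.

    Expects fields named ``<plate>_<well>_f<i>_<channel>.tif`` as written by
    the image simulator.
    """
    rows = []
    for rec in plate_map.itertuples(index=False):
        fields = []
        for f_idx in range(n_fields):
            image = load_field(images_dir, rec.plate_id, rec.well_id, f_idx)
            fields.append(analyze_field(image, seg_params))
        well = well_efficiency(fields)
        rows.append(
            {
                "plate_id": rec.plate_id,
                "well_id": rec.well_id,
                "role": rec.role,
                "shrna_id": rec.shrna_id,
                "gene_id": rec.gene_id,
                "efficiency": well.efficiency,
                "cell_count": well.cell_count,
                "valid": well.valid,
            }
        )
    return pd.DataFrame(rows)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-12s %6.2f s", name, t1 - t0)
    return t1


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline; returns paths of the artifacts written.

    Artifacts: wells.csv, scores.csv, gene_calls.csv, ranked.csv and
    pipeline.log under ``config.out_dir``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("hcscreen")
    root.addHandler(handler)
    root.setLevel(config.log_level)

    meta = {"config_hash": config_hash(config), "seed": config.seed}
    hit_params = HitParams(**config.hit_params)
    t0 = time.perf_counter()
    try:
        if config.wells_csv is not None:
            wells = read_wells_csv(config.wells_csv)
        elif config.design is not None:
            design = ScreenDesign(**config.design)
            wells, _truth = simulate_screen(design, seed=config.seed)
        else:
            plate_map = read_plate_map(config.plate_map)
            seg_params = SegParams(**config.seg_params)
            wells = wells_from_images(
                config.images_dir, plate_map, seg_params, n_fields=config.n_fields
            )
        t0 = _stage("wells", t0)

        expression = None
        if config.expression_csv is not None:
            expression = read_table(config.expression_csv)

        scores = score_screen(wells, params=hit_params, expression=expression)
        t0 = _stage("scores", t0)
        genes = call_gene_hits(scores, params=hit_params)
        ranked = rank_normalized_table(scores)
        t0 = _stage("calls", t0)

        paths = {}
        for name, df in (
            ("wells", wells),
            ("scores", scores),
            ("gene_calls", genes),
            ("ranked", ranked),
        ):
            path = out_dir / f"{name}.csv"
            write_table(df, path, metadata=meta)
            paths[name] = path
        paths["log"] = log_path
        logger.info(
            "pipeline done: %d wells, %d genes, %d positive",
            len(wells),
            len(genes),
            int(genes["positive"].sum()),
        )
        return paths
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
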