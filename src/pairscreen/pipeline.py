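"""End-to-end pipeline: load → screen → write matrices and a manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from .config import RunConfig, save_config
from .data_model import canonical_populations, load_database
from .prototypes import get_prototype, list_prototypes
from .screening import TaskGrid, run_screen

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "build_grid", "file_digest"]


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_grid(db, cfg: RunConfig) -> TaskGrid:
    """Resolve the config's optional subsets against the database."""
    times = cfg.times if cfg.times is not None else tuple(db.time_grid)
    pops = canonical_populations()
    if cfg.populations is not None:
        wanted = set(cfg.populations)
        unknown = wanted - {p.name for p in pops}
        if unknown:
            raise ValueError(f"unknown population(s) {sorted(unknown)}")
        pops = [p for p in pops if p.name in wanted]
    protos = (list_prototypes() if cfg.prototypes is None
              else [get_prototype(name) for name in cfg.prototypes])
    return TaskGrid.build(db.parameters, times, pops, protos)


def run_pipeline(cfg: RunConfig) -> tuple[int, dict]:
    """Run the screen described by ``cfg`` and write a digest manifest.

    Returns (exit status, manifest).  The manifest lists every output
    file with its sha256 digest, so reruns can be checked for
    bit-identical results; it is written as ``manifest.json`` in the
    output directory along with the effective configuration.  A missing
    input is a fatal error (exit status 1) with the path named.
    """
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(),
                                      logging.INFO))
    input_path = Path(cfg.input)
    if not input_path.exists():
        logger.error("input file not found: %s", input_path)
        return 1, {}

    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out_dir / "config_used.yaml")

    db = load_database(input_path)
    grid = build_grid(db, cfg)
    logger.info("task grid: %d parameters x %d times x %d populations x "
                "%d prototypes = %d tasks", len(grid.parameters),
                len(grid.time_points), len(grid.populations),
                len(grid.prototypes), grid.task_count)

    screen = run_screen(db, grid, cfg.fit, out_dir=out_dir)

    manifest = {
        "input": str(input_path),
        "tasks": grid.task_count,
        "fitted": screen.n_fitted,
        "skipped": screen.n_skipped,
        "skip_reasons": screen.skip_reasons,
        "files": {},
    }
    for f in sorted(out_dir.glob("*.tsv")) + [out_dir / "config_used.yaml"]:
        manifest["files"][f.name] = file_digest(f)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    manifest["files"]["manifest.json"] = file_digest(out_dir
                                                     / "manifest.json")
    return 0, manifest
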