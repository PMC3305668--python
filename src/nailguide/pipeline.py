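"""End-to-end pipeline: detect -> landmarks -> solve -> overlay -> report."""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import imgio
from .config import RunConfig
from .detect import detect_lens_regions, extract_landmarks
from .guide import compute_overlay, render_overlay
from .solver import NonConvergenceError, PoseSolution, UnderConstrainedError, solve_pose


@dataclass
class RunReport:
    """Everything needed to reconstruct a pipeline run."""

    image_path: str
    config: RunConfig
    solution: PoseSolution | None
    overlays: list
    warnings: list = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "image_path": self.image_path,
            "config": self.config.to_dict(),
            "config_hash": self.config.content_hash(),
            "seed": self.config.seed,
            "solution": self.solution.to_dict() if self.solution else None,
            "overlays": [o.to_dict() for o in self.overlays],
            "warnings": list(self.warnings),
            "timings_s": dict(self.timings_s),
            "error": self.error,
        }


def _order_landmarks_by_station(contours, lms, config):
    """Map detected contours (ordered along the silhouette axis) onto hole
    indices (ordered by axial station).  The two consistent mappings are
    tried by the solver via the per-hole candidates, so the simple
    station-ordered assignment suffices here."""
    order = np.argsort([h.axial_station_mm for h in config.nail.holes])
    out = [None, None]
    for k, lm in enumerate(lms):
        if k < len(order):
            out[order[k]] = lm
            lm.hole_id = int(order[k])
    return out


def run_pipeline(image_path, config_path, out_dir) -> RunReport:
    """Execute the full pipeline on one radiograph and write artifacts.

    Writes ``report.json``, ``overlay.png`` and a ``manifest.json`` into
    ``out_dir``.  Deterministic given the config seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = RunConfig.load(config_path)
    image = imgio.read_image(image_path)

    report = RunReport(image_path=str(image_path), config=config,
                       solution=None, overlays=[])
    t0 = time.perf_counter()
    caught = []
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            contours = detect_lens_regions(
                image,
                min_area_px=config.detection.min_area_px,
                min_solidity=config.detection.min_solidity,
                smoothing_sigma=config.detection.smoothing_sigma,
            )
            caught = [str(w.message) for w in wlist]
        report.timings_s["detect"] = time.perf_counter() - t0

        t1 = time.perf_counter()
        lms = []
        for c in contours:
            lms.append(extract_landmarks(
                c, circular_contrast=config.detection.circular_contrast))
        lms = _order_landmarks_by_station(contours, lms, config)
        report.timings_s["landmarks"] = time.perf_counter() - t1

        t2 = time.perf_counter()
        sol = solve_pose(lms, config.camera, config.nail,
                         prepass_iterations=config.solver.prepass_iterations,
                         refine_top=config.solver.refine_top,
                         virtual_mode=config.solver.virtual_mode)
        report.solution = sol
        report.timings_s["solve"] = time.perf_counter() - t2

        t3 = time.perf_counter()
        overlays = []
        for i in range(2):
            overlays.append(compute_overlay(
                sol.pose, config.camera, config.nail, config.jig, i,
                skin_offset_mm=config.guidance.skin_offset_mm))
        report.overlays = overlays
        render_overlay(image, overlays, out_dir / "overlay.png")
        report.timings_s["overlay"] = time.perf_counter() - t3
    except (NonConvergenceError, UnderConstrainedError) as exc:
        report.error = f"{type(exc).__name__}: {exc}"
    report.warnings = caught

    imgio.write_json(out_dir / "report.json", report.to_dict())
    manifest = {
        "inputs": {"image": str(image_path), "config": str(config_path)},
        "outputs": ["report.json"] + (["overlay.png"] if report.overlays else []),
        "seed": config.seed,
        "config_hash": config.content_hash(),
    }
    imgio.write_json(out_dir / "manifest.json", manifest)
    return report
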