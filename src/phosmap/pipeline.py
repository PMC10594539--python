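"""End-to-end pipeline: surface -> implants -> map -> rendering -> metrics.

:func:`run_pipeline` chains every stage with a single configuration object
and writes a reproducible artifact bundle (map CSV/JSON, rendered PNGs,
constraint report, metrics JSON and a run log).  All randomness derives from
``config.seed``, so two runs with the same configuration produce
byte-identical CSV/JSON artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import cluster, derive, implants, metrics, stimuli, surface
from .errors import ParameterError

log = logging.getLogger("phosmap")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run.

    Defaults reproduce the reference operating point: a 43-electrode array
    at 1 mm pitch, KNN(50) projection, +-45 deg rotation / 20 mm coil /
    3.6 mm separation constraints, 40 px/deg rendering, DBSCAN at eps 200 px
    and 100 minimum points.
    """

    seed: int = 0
    n_implants: int = 12
    surface_path: str | None = None           # read table instead of synthesis
    surface_params: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)  # SizeModelParams overrides
    placement: dict = field(default_factory=dict)
    knn: int = 50
    px_per_deg: float = derive.DEFAULT_PX_PER_DEG
    canvas: tuple[int, int] = derive.DEFAULT_CANVAS
    stimulus_logmar: float = 2.0
    eps_px: float = cluster.DEFAULT_EPS_PX
    min_pts: int = cluster.DEFAULT_MIN_PTS
    hist_bins: int = metrics.DEFAULT_HIST_BINS
    mi_bins: int = metrics.DEFAULT_MI_BINS

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        cfg = cls(**data)
        if isinstance(cfg.canvas, list):
            cfg.canvas = tuple(cfg.canvas)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["canvas"] = list(self.canvas)
        return d


def plan_placements(
    surf: surface.RetinotopicSurface,
    n_implants: int,
    min_centre_spacing_mm: float | None = None,
) -> list[tuple[int, float]]:
    """Deterministic default implantation plan: (center_vertex, rotation).

    Candidate centres are gyral V1/V2 grayordinates.  Per hemisphere, the
    plan seeds at the candidate nearest the candidate centroid and greedily
    adds the candidate closest to the chosen set's centroid that keeps the
    requested centre spacing — a compact cluster, as a coil-powered implant
    group must be.  Rotation is 0 for every implant.
    """
    if n_implants < 1 or n_implants % 2:
        raise ParameterError("n_implants must be a positive even number")
    per_hemi = n_implants // 2
    if min_centre_spacing_mm is None:
        min_centre_spacing_mm = 10.0 if n_implants <= 8 else 8.0

    plan: list[tuple[int, float]] = []
    for hemi in ("left", "right"):
        cand = np.nonzero(
            (surf.hemisphere == hemi)
            & surf.is_gyrus
            & np.isin(surf.roi, ("V1", "V2"))
        )[0]
        if len(cand) < per_hemi:
            raise ParameterError(f"not enough gyral V1/V2 vertices in {hemi} hemisphere")
        pos = surf.positions[cand]
        chosen = [int(np.argmin(np.linalg.norm(pos - pos.mean(axis=0), axis=1)))]
        while len(chosen) < per_hemi:
            centroid = pos[chosen].mean(axis=0)
            order = np.argsort(np.linalg.norm(pos - centroid, axis=1), kind="stable")
            for i in order:
                i = int(i)
                if i in chosen:
                    continue
                d = np.linalg.norm(pos[chosen] - pos[i], axis=1).min()
                if d >= min_centre_spacing_mm:
                    chosen.append(i)
                    break
            else:
                raise ParameterError(
                    f"cannot place {per_hemi} implants at "
                    f"{min_centre_spacing_mm} mm spacing in {hemi} hemisphere"
                )
        plan.extend((int(cand[i]), 0.0) for i in chosen)
    return plan


def _save_png(path: Path, image: np.ndarray) -> None:
    Image.fromarray(np.clip(image * 255.0, 0, 255).astype(np.uint8)).save(path)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the artifact bundle; returns a summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    if config.surface_path:
        surf = surface.read_retinotopy_table(config.surface_path)
        log.info("loaded surface %s (%d grayordinates)", config.surface_path, len(surf))
    else:
        sp = dict(config.surface_params)
        sp.setdefault("seed", config.seed)
        params = surface.SyntheticCortexParams(**sp)
        surf = surface.generate_synthetic_surface(params)
        log.info("generated synthetic surface (%d grayordinates, seed %d)",
                 len(surf), params.seed)
    surface.write_retinotopy_table(surf, out / "surface.csv")

    plan = plan_placements(surf, config.n_implants)
    implant_list = [
        implants.place_implant(surf, v, rot) for v, rot in plan
    ]
    constraints = implants.PlacementConstraints(
        allow_overlap=config.n_implants > 8, **config.placement
    )
    report = implants.validate_placement(implant_list, surf, constraints)
    report.to_json(out / "constraint_report.json")
    log.info("placed %d implants; constraints ok=%s (v1v2 fraction %.2f)",
             len(implant_list), report.all_ok, report.v1v2_fraction)

    model = derive.SizeModelParams(**config.model)
    pmap = derive.derive_phosphene_map(
        surf, implant_list, model, k=config.knn,
        px_per_deg=config.px_per_deg, canvas=config.canvas,
    )
    pmap.to_csv(out / "map_retinotopic.csv")
    pmap.to_json(out / "map_retinotopic.json")

    fit = derive.fit_ecc_size(surf)
    control = derive.generate_control_map(
        n=len(pmap), avg_fit=fit,
        field_radius_deg=derive.control_field_radius(pmap),
        seed=config.seed, params=model,
        px_per_deg=config.px_per_deg, canvas=config.canvas,
    )
    control.to_csv(out / "map_control.csv")
    log.info("derived %d phosphenes (retinotopic) + matched control", len(pmap))

    stim = stimuli.make_tumbling_E(
        config.stimulus_logmar, "right", config.px_per_deg, config.canvas
    )
    frames = {}
    for name, m, stim_m in (
        ("retinotopic", pmap, stim),
        ("control", control, stim),
        ("relocated", pmap,
         cluster.relocate_stimulus(pmap, stim, config.eps_px, config.min_pts)),
    ):
        active = stimuli.skeleton_sample(stim_m, m)
        frame = stimuli.render_phosphenes(m, active)
        _save_png(out / f"render_{name}.png", frame.image)
        frames[name] = (m, stim_m, frame)

    results = {"config": config.to_dict(), "n_phosphenes": len(pmap),
               "constraints": report.to_dict(), "metrics": {}}
    for name, (m, stim_m, frame) in frames.items():
        comp = metrics.map_complexity(m, config.hist_bins)
        area = metrics.map_area(m)
        mi = metrics.mutual_information(stim_m.image, frame.image, config.mi_bins)
        results["metrics"][name] = {
            "complexity": comp.combined,
            "distance_entropy_bits": comp.distance_entropy,
            "angle_entropy_bits": comp.angle_entropy,
            "smoothness": comp.smoothness,
            "area_deg2": area.area,
            "mutual_information_bits": mi.mi,
            "n_active": len(frame.active_phosphenes),
        }
        log.info("metrics[%s]: complexity %.3f, area %.1f deg^2, MI %.3f bits",
                 name, comp.combined, area.area, mi.mi)

    with open(out / "metrics.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return results
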