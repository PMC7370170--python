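"""End-to-end orchestration: simulate -> render -> detect -> score -> compare.

A run is described by a plain configuration mapping (usually loaded from
YAML), validated up front, and executed stage by stage.  Every
intermediate artifact (point tables, images, detection tables, index
tables, comparison reports) is persisted, and a manifest records the
seed, parameter hash and per-stage output hashes so any stage can be
re-run and checked in isolation.  Identical configuration and seed give
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arena import equilateral_arena, ArenaGeometry
from .imaging import SegmentationParams, arena_mask_polygon, detect_flies, to_physical
from .socialspace import count_within_radius, recover_interaction_strength
from .stats import Design, compare
from .synthetic import InteractionParams, RenderParams, render_arena, sample_interaction

__all__ = ["KNOWN_STAGES", "load_config", "validate_config", "run_pipeline"]

KNOWN_STAGES = ("points", "images", "detect", "socialspace", "compare")
STOCHASTIC_STAGES = {"points", "images"}

DEFAULT_CONFIG = {
    "stages": ["points", "socialspace"],
    "seed": None,
    "arena": {"side": 80.0, "margin": 2.0},
    "conditions": [{"label": "control", "attraction_strength": 0.0}],
    "n_chambers": 9,
    "interaction": {},
    "n_sweeps": 50,
    "render": {},
    "segmentation": {},
    "radius_mm": None,
    "radius_bl": None,
    "compare": {"n_permutations": 10000},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return {**DEFAULT_CONFIG, **cfg}


def validate_config(config: dict) -> list[str]:
    """Schema and cross-field checks; returns diagnostics (empty = valid)."""
    cfg = {**DEFAULT_CONFIG, **config}
    diags: list[str] = []
    stages = cfg["stages"]
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        diags.append(f"unknown stages {unknown}; known: {list(KNOWN_STAGES)}")
    if cfg["seed"] is None and any(s in STOCHASTIC_STAGES for s in stages):
        diags.append("seed must be set when a stochastic stage (points/images) runs")
    if not cfg["conditions"]:
        diags.append("at least one condition is required")
    if "detect" in stages and "images" not in stages:
        diags.append("detect stage requires the images stage")
    if "socialspace" in stages and "points" not in stages:
        diags.append("socialspace stage requires the points stage")
    if cfg["radius_mm"] is not None and cfg["radius_bl"] is not None:
        diags.append("give radius_mm or radius_bl, not both")
    if "compare" in stages:
        if len(cfg["conditions"]) < 2:
            diags.append("compare stage needs >= 2 conditions")
        if cfg["n_chambers"] < 5:
            diags.append("compare stage needs >= 5 chambers per condition")
    design = cfg.get("design")
    if design is not None:
        n_factors = len(design.get("factors", {}))
        if n_factors >= 2 and design.get("reps", 0) < 2:
            diags.append(
                "factorial design with interaction needs >= 2 replicates per "
                "cell (interaction inestimable with 1)"
            )
    labels = [c.get("label") for c in cfg["conditions"]]
    if len(set(labels)) != len(labels):
        diags.append("condition labels must be unique")
    return diags


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _arena_from_config(cfg: dict) -> ArenaGeometry:
    a = cfg["arena"]
    if "vertices" in a:
        return ArenaGeometry(np.asarray(a["vertices"], float), margin=a.get("margin", 0.0))
    return equilateral_arena(side=a.get("side", 80.0), margin=a.get("margin", 2.0))


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns the manifest (also persisted).

    A stage failure halts the run with that stage's diagnostics; artifacts
    of completed stages are retained on disk.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    diags = validate_config(cfg)
    if diags:
        raise ValueError("invalid configuration: " + "; ".join(diags))
    out = Path(outdir if outdir is not None else cfg.get("outdir", "flyspace_run"))
    out.mkdir(parents=True, exist_ok=True)

    arena = _arena_from_config(cfg)
    rp = RenderParams(**cfg["render"])
    stages = cfg["stages"]
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "config_sha256": _config_hash(cfg),
        "stages": [],
    }
    state: dict = {"configs": {}, "images": {}}

    for stage in stages:
        t0 = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](cfg, arena, rp, state, out)
        manifest["stages"].append(
            {
                "stage": stage,
                "wall_time_s": round(time.perf_counter() - t0, 4),
                "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
            }
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _chamber_seeds(cfg: dict) -> dict:
    labels = [c["label"] for c in cfg["conditions"]]
    ss = np.random.SeedSequence(cfg["seed"])
    children = ss.spawn(len(labels) * cfg["n_chambers"])
    return {
        (lab, j): children[i * cfg["n_chambers"] + j]
        for i, lab in enumerate(labels)
        for j in range(cfg["n_chambers"])
    }


def _stage_points(cfg, arena, rp, state, out: Path) -> list[Path]:
    seeds = _chamber_seeds(cfg)
    rows = []
    for cond in cfg["conditions"]:
        base = {k: v for k, v in cond.items() if k != "label"}
        params = InteractionParams(**{**cfg["interaction"], **base})
        for j in range(cfg["n_chambers"]):
            pc = sample_interaction(
                arena, params, n_sweeps=cfg["n_sweeps"],
                seed=seeds[(cond["label"], j)], label=cond["label"],
            )
            state["configs"][(cond["label"], j)] = pc
            for k, (x, y) in enumerate(pc.coords):
                rows.append((cond["label"], j, k, x, y, pc.body_length))
    df = pd.DataFrame(rows, columns=["condition", "chamber", "fly", "x_mm", "y_mm", "body_length_mm"])
    path = out / "points.csv"
    df.to_csv(path, index=False, float_format="%.6f")
    return [path]


def _stage_images(cfg, arena, rp, state, out: Path) -> list[Path]:
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    seeds = _chamber_seeds(cfg)
    paths, truth_rows = [], []
    for (lab, j), pc in state["configs"].items():
        render_seed = seeds[(lab, j)].spawn(1)[0]
        img, truth = render_arena(pc, rp, seed=render_seed)
        p = img_dir / f"{lab}_chamber{j:02d}.png"
        iio.imwrite(p, img)
        state["images"][(lab, j)] = img
        truth["condition"], truth["chamber"] = lab, j
        truth_rows.append(truth)
        paths.append(p)
    tpath = out / "ground_truth.csv"
    pd.concat(truth_rows, ignore_index=True).to_csv(tpath, index=False, float_format="%.4f")
    return paths + [tpath]


def _stage_detect(cfg, arena, rp, state, out: Path) -> list[Path]:
    mask = arena_mask_polygon(arena, rp.px_per_mm, rp.pad_mm)
    seg = SegmentationParams(**{**cfg["segmentation"], "mask": mask})
    rows = []
    for (lab, j), img in state["images"].items():
        cs = detect_flies(img, seg, source=f"{lab}_chamber{j:02d}")
        pc = to_physical(cs, px_per_mm=rp.px_per_mm, arena=arena)
        pc.label = lab
        state["configs"][(lab, j)] = pc  # downstream uses detections
        frame = cs.to_frame()
        frame["condition"], frame["chamber"] = lab, j
        rows.append(frame)
    path = out / "detections.csv"
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.4f")
    return [path]


def _radius(cfg, pc) -> float | None:
    if cfg["radius_mm"] is not None:
        return float(cfg["radius_mm"])
    if cfg["radius_bl"] is not None:
        return float(cfg["radius_bl"]) * pc.body_length
    return None  # count_within_radius default: 4 body lengths


def _stage_socialspace(cfg, arena, rp, state, out: Path) -> list[Path]:
    import warnings as _w

    summary, per_fly = [], []
    for (lab, j), pc in sorted(state["configs"].items()):
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # detection dropouts may leave n<12
            res = count_within_radius(pc, radius_mm=_radius(cfg, pc))
        summary.append((lab, j, res.n_flies, res.radius_mm, res.replicate_mean))
        for k, c in enumerate(res.per_fly_counts):
            per_fly.append((lab, j, k, int(c)))
    spath = out / "socialspace.csv"
    pd.DataFrame(
        summary, columns=["condition", "chamber", "n_flies", "radius_mm", "replicate_mean"]
    ).to_csv(spath, index=False, float_format="%.6f")
    fpath = out / "socialspace_per_fly.csv"
    pd.DataFrame(per_fly, columns=["condition", "chamber", "fly", "count_within_radius"]).to_csv(
        fpath, index=False
    )
    state["socialspace"] = pd.read_csv(spath)
    return [spath, fpath]


def _stage_compare(cfg, arena, rp, state, out: Path) -> list[Path]:
    tab = state.get("socialspace")
    if tab is None:
        raise RuntimeError("compare stage needs the socialspace stage output")
    labels = [c["label"] for c in cfg["conditions"]]
    paths = []
    if len(labels) == 2:
        ref, test = labels
        eff = recover_interaction_strength(
            tab.loc[tab.condition == test, "replicate_mean"].to_numpy(),
            tab.loc[tab.condition == ref, "replicate_mean"].to_numpy(),
            n_permutations=cfg["compare"].get("n_permutations", 10000),
            seed=np.random.SeedSequence(cfg["seed"]).spawn(1)[0].generate_state(1)[0] >> 1,
        )
        epath = out / "effect.json"
        epath.write_text(
            json.dumps(
                {
                    "test_condition": test,
                    "reference_condition": ref,
                    "effect": eff.effect,
                    "standardized_effect": eff.standardized_effect,
                    "p_value": eff.p_value,
                    "direction": eff.direction,
                    "n_permutations": eff.n_permutations,
                },
                indent=2,
            )
        )
        paths.append(epath)
    result = compare(tab, Design(response="replicate_mean", factors=("condition",)))
    tpath = out / "comparison_terms.csv"
    result.terms.to_csv(tpath, index=False, float_format="%.6g")
    paths.append(tpath)
    if result.posthoc is not None:
        ppath = out / "comparison_posthoc.csv"
        result.posthoc.to_csv(ppath, index=False, float_format="%.6g")
        paths.append(ppath)
    rpath = out / "comparison_report.txt"
    rpath.write_text(_format_report(result))
    paths.append(rpath)
    return paths


def _format_report(result) -> str:
    lines = [f"Comparison test: {result.test} (alpha={result.alpha})", ""]
    lines.append(result.terms.to_string(index=False))
    if result.posthoc is not None:
        lines += ["", "Post hoc (Dunn, Holm-adjusted):", result.posthoc.to_string(index=False)]
    if result.normality is not None:
        lines += ["", "Normality diagnostics (Shapiro-Wilk):", result.normality.to_string(index=False)]
    return "\n".join(lines) + "\n"


_STAGE_FUNCS = {
    "points": _stage_points,
    "images": _stage_images,
    "detect": _stage_detect,
    "socialspace": _stage_socialspace,
    "compare": _stage_compare,
}
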