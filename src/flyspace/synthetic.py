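"""Synthetic data generators for every pipeline stage.

No real arena photographs or assay records are distributed, so this module
produces all inputs the pipeline consumes, fully seeded:

* spatial configurations of settled flies in a triangular chamber, either
  completely spatially random (given a hardcore body-exclusion radius) or
  drawn from an attractive pairwise-interaction Gibbs process whose
  ``attraction_strength`` parameter stands in for genotype/housing effects
  on social spacing;
* rendered grayscale arena images with ground-truth centroid tables, for
  exercising the image-processing stage against a known answer;
* Dirichlet-multinomial compartment allocations (sociability chamber),
  binomial two-vial choice and climbing outcomes, and Gaussian factorial
  replicate tables with planted effect sizes for the statistics stage.

The interaction model is a statistical stand-in for the settled group
geometry, not a behavioral claim: an unnormalised density
``exp(strength * sum_pairs K(d_ij))`` with ``K`` a Gaussian bump centred at
a preferred inter-fly distance, zero whenever any pair is closer than the
hardcore radius or any fly is outside the wall-eroded arena.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon_perimeter

from .arena import (
    ArenaGeometry,
    PointConfig,
    DEFAULT_BODY_LENGTH_MM,
    transform_for_arena,
    image_shape_for_arena,
)
from .indices import ChoiceTrial, ClimbingTrial, CompartmentCounts

__all__ = [
    "InteractionParams",
    "RenderParams",
    "PackingError",
    "LowAcceptanceWarning",
    "sample_csr",
    "sample_interaction",
    "render_arena",
    "simulate_compartment_counts",
    "simulate_choice_trial",
    "simulate_climbing",
    "simulate_design",
]

_DART_RETRY_CAP = 10_000  # dart-throwing retries per point before giving up


class PackingError(RuntimeError):
    """Requested hardcore packing could not be realised in the arena."""


class LowAcceptanceWarning(UserWarning):
    """Metropolis acceptance rate collapsed; proposal scale needs tuning."""


@dataclass(frozen=True)
class InteractionParams:
    """Parameters of the attractive pairwise-interaction point process.

    ``attraction_strength = 0`` reduces to complete spatial randomness
    conditioned on the hardcore constraint.
    """

    n_flies: int = 16
    hardcore_radius: float = 2.0          # mm, minimum centre separation
    preferred_distance: float = 5.0       # mm, centre of the attraction bump
    attraction_strength: float = 0.0      # log-potential weight, >= 0
    potential_width: float = 2.0          # mm, scale of the Gaussian bump

    def __post_init__(self) -> None:
        if self.hardcore_radius <= 0:
            raise ValueError("hardcore_radius must be > 0")
        if self.attraction_strength < 0:
            raise ValueError("attraction_strength must be >= 0")
        if self.preferred_distance <= 0 or self.potential_width <= 0:
            raise ValueError("preferred_distance and potential_width must be > 0")
        if not 12 <= self.n_flies <= 17:
            warnings.warn(
                f"n_flies={self.n_flies} is outside the density-robust 12-17 "
                "assay range",
                UserWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class RenderParams:
    """Rendering model for synthetic arena photographs.

    Flies are drawn as filled ellipses (major axis = one body length) at
    uniform random orientations unless explicit orientations are given,
    on a light background with the arena border traced, plus additive
    Gaussian pixel noise.
    """

    px_per_mm: float = 10.0
    ellipse_aspect: float = 0.35          # minor/major axis ratio
    foreground: float = 0.15              # fly intensity (dark on light)
    background: float = 0.85
    noise_sd: float = 0.03
    pad_mm: float = 2.0
    orientations: np.ndarray | None = None  # radians per fly; None = random

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")
        if not 0 < self.ellipse_aspect <= 1:
            raise ValueError("ellipse_aspect must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.foreground <= 1 and 0 <= self.background <= 1):
            raise ValueError("intensities must be in [0, 1]")


# ---------------------------------------------------------------------------
# Point-process samplers
# ---------------------------------------------------------------------------

def _uniform_in_triangle(rng: np.random.Generator, vertices: np.ndarray, size: int) -> np.ndarray:
    """Uniform points in a triangle by the barycentric fold rule."""
    u = rng.random(size)
    v = rng.random(size)
    fold = u + v > 1.0
    u[fold] = 1.0 - u[fold]
    v[fold] = 1.0 - v[fold]
    a, b, c = vertices
    return a + np.outer(u, b - a) + np.outer(v, c - a)


def sample_csr(
    arena: ArenaGeometry,
    n: int,
    hardcore: float = 0.0,
    seed: int | None = None,
    label: str = "",
    body_length: float = DEFAULT_BODY_LENGTH_MM,
) -> PointConfig:
    """Sample ``n`` flies uniformly on the eroded arena (CSR null model).

    Points are conditioned on all pairwise distances >= ``hardcore`` by
    dart throwing: each point is redrawn until it clears every accepted
    point, up to a bounded number of retries.

    Raises
    ------
    PackingError
        If the packing is infeasible, either by the disc-packing area bound
        or after exhausting the retry budget for some point.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if hardcore < 0:
        raise ValueError("hardcore must be >= 0")
    area = arena.eroded_area
    if n > 1 and hardcore > 0:
        # densest disc packing covers ~90.7% of the plane
        if n * np.pi * (hardcore / 2.0) ** 2 > 0.9069 * area:
            raise PackingError(
                f"cannot place {n} points with hardcore {hardcore} mm in "
                f"{area:.1f} mm^2 of eroded arena (packing bound exceeded)"
            )
    rng = np.random.default_rng(seed)
    verts = arena.eroded_vertices
    pts = np.empty((n, 2))
    for i in range(n):
        for _ in range(_DART_RETRY_CAP):
            cand = _uniform_in_triangle(rng, verts, 1)[0]
            if i == 0 or hardcore == 0 or (
                np.min(np.hypot(*(pts[:i] - cand).T)) >= hardcore
            ):
                pts[i] = cand
                break
        else:
            raise PackingError(
                f"failed to place point {i + 1}/{n} with hardcore "
                f"{hardcore} mm in {area:.1f} mm^2 of eroded arena after "
                f"{_DART_RETRY_CAP} retries"
            )
    return PointConfig(
        coords=pts, arena=arena, body_length=body_length, seed=seed, label=label,
        meta={"sampler": "csr", "hardcore": hardcore},
    )


def _pair_potential(dists: np.ndarray, params: InteractionParams) -> np.ndarray:
    z = (dists - params.preferred_distance) / params.potential_width
    return np.exp(-0.5 * z * z)


def sample_interaction(
    arena: ArenaGeometry,
    params: InteractionParams,
    n_sweeps: int = 50,
    seed: int | None = None,
    label: str = "",
    body_length: float = DEFAULT_BODY_LENGTH_MM,
) -> PointConfig:
    """Sample the fixed-n attractive pair-potential process by Metropolis.

    The chain starts from a CSR draw and performs ``n_sweeps`` sweeps of
    ``n_flies`` single-point Gaussian displacement proposals (step sd =
    ``preferred_distance / 2``), accepted with the standard ratio of the
    unnormalised density.  Hard constraints (containment in the eroded
    arena, hardcore separation) are enforced by rejection.

    The returned configuration carries the overall and last-sweep
    acceptance rates in ``meta``.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    n = params.n_flies
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_seed, chain_seed = ss.spawn(2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        init = sample_csr(
            arena, n, hardcore=params.hardcore_radius,
            seed=init_seed, body_length=body_length,
        )
    pts = init.coords.copy()
    rng = np.random.default_rng(chain_seed)
    step_sd = params.preferred_distance / 2.0
    strength = params.attraction_strength

    n_accept = 0
    last_sweep_rate = 1.0
    warned = False
    for _ in range(n_sweeps):
        sweep_accept = 0
        order = rng.permutation(n)
        steps = rng.normal(scale=step_sd, size=(n, 2))
        unifs = rng.random(n)
        for k, i in enumerate(order):
            cand = pts[i] + steps[k]
            if not arena.contains(cand[None, :])[0]:
                continue
            others = np.delete(pts, i, axis=0)
            d_new = np.hypot(*(others - cand).T)
            if d_new.size and d_new.min() < params.hardcore_radius:
                continue
            if strength == 0.0:
                accept = True
            else:
                d_old = np.hypot(*(others - pts[i]).T)
                delta = strength * (
                    _pair_potential(d_new, params).sum()
                    - _pair_potential(d_old, params).sum()
                )
                accept = delta >= 0 or unifs[k] < np.exp(delta)
            if accept:
                pts[i] = cand
                sweep_accept += 1
        n_accept += sweep_accept
        last_sweep_rate = sweep_accept / n
        if last_sweep_rate < 0.01 and not warned:
            warnings.warn(
                f"Metropolis acceptance rate {last_sweep_rate:.1%} over a "
                "sweep; consider a smaller step (lower preferred_distance) "
                "or weaker attraction_strength",
                LowAcceptanceWarning,
                stacklevel=2,
            )
            warned = True
    return PointConfig(
        coords=pts, arena=arena, body_length=body_length, seed=seed, label=label,
        meta={
            "sampler": "interaction",
            "params": params,
            "n_sweeps": n_sweeps,
            "acceptance_rate": n_accept / (n_sweeps * n),
            "last_sweep_acceptance": last_sweep_rate,
        },
    )


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

def render_arena(
    config: PointConfig,
    rp: RenderParams = RenderParams(),
    seed: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a grayscale arena photograph plus its ground-truth table.

    Each fly is a filled ellipse with major axis ``body_length * px_per_mm``
    at its (randomised or supplied) orientation; the arena border is traced;
    additive Gaussian noise is applied last.  The ground truth lists, per
    fly, pixel and mm centroid coordinates, orientation, and a ``touching``
    flag set for flies whose rendered ellipses overlap or are 8-adjacent
    (the hard cases for segmentation).

    Returns
    -------
    image : uint8 2-D array
    truth : DataFrame with columns fly, x_px, y_px, x_mm, y_mm,
        orientation_rad, touching
    """
    if config.arena is None:
        raise ValueError("config must reference an arena to be rendered")
    arena = config.arena
    if not np.all(arena.contains(config.coords, eroded=False)) and config.n_flies:
        raise ValueError("all flies must lie inside the arena to render")
    body_px = config.body_length * rp.px_per_mm
    if body_px < 4:
        raise ValueError(
            f"body length of {body_px:.1f} px is unresolvable; "
            "increase px_per_mm (need >= 4 px)"
        )
    rng = np.random.default_rng(seed)
    shape = image_shape_for_arena(arena, rp.px_per_mm, rp.pad_mm)
    tf = transform_for_arena(arena, rp.px_per_mm, rp.pad_mm)
    img = np.full(shape, rp.background, dtype=float)

    # arena border
    border_px = tf.mm_to_px(arena.vertices)
    rr, cc = polygon_perimeter(border_px[:, 1], border_px[:, 0], shape=shape)
    img[rr, cc] = rp.foreground

    n = config.n_flies
    if rp.orientations is not None:
        thetas = np.asarray(rp.orientations, dtype=float)
        if thetas.shape != (n,):
            raise ValueError("orientations must give one angle per fly")
    else:
        thetas = rng.uniform(0, np.pi, size=n)

    centers_px = tf.mm_to_px(config.coords) if n else np.empty((0, 2))
    a = body_px / 2.0                 # semi-major, px
    b = a * rp.ellipse_aspect         # semi-minor, px
    pixel_sets: list[set[tuple[int, int]]] = []
    for i in range(n):
        cx, cy = centers_px[i]
        # rotation is CCW in (row, col); orientation measured from +x axis
        rr, cc = draw_ellipse(cy, cx, b, a, shape=shape, rotation=thetas[i])
        img[rr, cc] = rp.foreground
        pixel_sets.append(set(zip(rr.tolist(), cc.tolist())))

    touching = np.zeros(n, dtype=bool)
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
    for i in range(n):
        for j in range(i + 1, n):
            gap = np.hypot(*(centers_px[i] - centers_px[j]))
            if gap > 2 * a + 2:  # cannot touch
                continue
            dil = {(r + dr, c + dc) for (r, c) in pixel_sets[i] for dr, dc in offsets}
            if dil & pixel_sets[j]:
                touching[i] = touching[j] = True

    if rp.noise_sd > 0:
        img = img + rng.normal(scale=rp.noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    image8 = np.round(img * 255).astype(np.uint8)

    truth = pd.DataFrame(
        {
            "fly": np.arange(n),
            "x_px": centers_px[:, 0],
            "y_px": centers_px[:, 1],
            "x_mm": config.coords[:, 0] if n else np.array([]),
            "y_mm": config.coords[:, 1] if n else np.array([]),
            "orientation_rad": thetas,
            "touching": touching,
        }
    )
    return image8, truth


# ---------------------------------------------------------------------------
# Tabular assay simulators
# ---------------------------------------------------------------------------

def simulate_compartment_counts(
    n_flies: int = 16,
    n_compartments: int = 8,
    concentration: float = 1.0,
    seed: int | None = None,
    chamber_id: str = "",
) -> CompartmentCounts:
    """Dirichlet-multinomial allocation of flies to chamber compartments.

    Small ``concentration`` yields aggregated counts (high sociability
    index); large values approach an even spread.  ``concentration=inf``
    is the exact equal-probability multinomial.
    """
    if n_flies < 0:
        raise ValueError("n_flies must be >= 0")
    if n_compartments < 2:
        raise ValueError("n_compartments must be >= 2")
    if not concentration > 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    if np.isinf(concentration):
        p = np.full(n_compartments, 1.0 / n_compartments)
    else:
        p = rng.dirichlet(np.full(n_compartments, concentration))
    counts = rng.multinomial(n_flies, p)
    return CompartmentCounts(counts=counts, chamber_id=chamber_id)


def simulate_choice_trial(
    p_avoid: float,
    n: int = 15,
    seed: int | None = None,
    p_nonchooser: float = 0.0,
) -> ChoiceTrial:
    """Binomial two-vial choice outcome for ``n`` responder flies.

    Each fly independently abstains with probability ``p_nonchooser``
    (stays in the apparatus, still counted in the total); choosers pick
    the air vial with probability ``p_avoid``, the odorant vial otherwise.
    """
    if not 0 <= p_avoid <= 1:
        raise ValueError("p_avoid must be in [0, 1]")
    if not 0 <= p_nonchooser <= 1:
        raise ValueError("p_nonchooser must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    choosers = rng.binomial(n, 1.0 - p_nonchooser)
    n_air = rng.binomial(choosers, p_avoid)
    return ChoiceTrial(n_air=n_air, n_dso=choosers - n_air, n_total=n)


def simulate_climbing(
    p_top: float,
    n: int = 40,
    seed: int | None = None,
) -> ClimbingTrial:
    """Binomial startle-induced climbing outcome for ``n`` flies."""
    if not 0 <= p_top <= 1:
        raise ValueError("p_top must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return ClimbingTrial(n_top=rng.binomial(n, p_top), n_total=n)


def simulate_design(
    factors: Mapping[str, Sequence],
    cell_means: np.ndarray | Mapping[tuple, float] | float = 0.0,
    sd: float = 1.0,
    reps: int = 9,
    seed: int | None = None,
    response: str = "response",
) -> pd.DataFrame:
    """Tidy Gaussian replicate table for a full factorial design.

    Parameters
    ----------
    factors
        Ordered mapping of factor name to its levels (>= 2 each), e.g.
        ``{"genotype": ["wt", "mut"], "age": ["young", "old"]}``.
    cell_means
        Planted per-cell mean shifts: an array shaped by the level counts
        (in ``factors`` order), a mapping from level tuples to means, or a
        scalar for a flat (null) design.
    sd
        Residual standard deviation of the Gaussian noise.
    reps
        Replicates per cell.

    Returns
    -------
    DataFrame with one row per replicate: the factor columns plus the
    response column.
    """
    names = list(factors)
    levels = [list(factors[k]) for k in names]
    if any(len(lv) < 2 for lv in levels):
        raise ValueError("every factor needs >= 2 levels")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    shape = tuple(len(lv) for lv in levels)
    if isinstance(cell_means, Mapping):
        means = np.zeros(shape)
        for key, val in cell_means.items():
            idx = tuple(levels[d].index(key[d]) for d in range(len(names)))
            means[idx] = val
    elif np.isscalar(cell_means):
        means = np.full(shape, float(cell_means))
    else:
        means = np.asarray(cell_means, dtype=float)
        if means.shape != shape:
            raise ValueError(f"cell_means shape {means.shape} != design shape {shape}")
    rng = np.random.default_rng(seed)
    rows = []
    for idx in np.ndindex(*shape):
        vals = means[idx] + rng.normal(scale=sd, size=reps)
        for v in vals:
            rows.append([levels[d][idx[d]] for d in range(len(names))] + [v])
    return pd.DataFrame(rows, columns=names + [response])
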