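"""Synthetic microscopy scenes and live-cell time series with ground truth.

Every downstream stage of the pipeline (puncta detection, translocation
scoring, pulse calling, neighbor enrichment, kinetics fitting) is benchmarked
against data generated here, where the truth is known by construction:

* **Puncta scenes** — cells as disks on a jittered grid containing bright,
  non-overlapping circular condensates over a diffuse cytoplasmic background,
  in two channels with a configurable co-placement fraction.
* **Translocation pairs** — a pre/post stimulation image pair of one cell
  whose edge ring is enriched by a configured ratio over the core.
* **KTR datasets** — tracked single-cell reporter-ratio traces (default 22 h
  at 5-min frames, 264 frames) with raised-cosine pulses of 10-20 min
  duration, stochastic deaths and divisions, spatially elevated pulse rates
  near deaths, division-proximal artifact pulses, duplicated parental history
  in daughters, and a subpopulation of low/zero reporter expressors.
* **Decay traces** — exponentially dissociating condensate intensities,
  ``offset + amplitude * 2^(-t/t_half) + noise``.

All randomness flows from one integer seed per call through a single
generator, so identical configs give byte-identical outputs.  Noise is
additive Gaussian clipped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .puncta import LabeledImage
from .translocation import RingPartition, partition_ring


class ConfigError(ValueError):
    pass


class PlacementError(RuntimeError):
    """Requested objects could not be placed without overlap."""


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass
class PunctaSceneConfig:
    """Two-channel condensate scene parameters.

    ``punctum_intensity_gain`` is the fold brightness of punctum pixels over
    the diffuse cytoplasmic ``background_level``; ``coloc_fraction`` is the
    per-cell fraction of channel-A puncta that get a co-placed channel-B
    punctum (the remaining B puncta are placed disjoint from all A puncta).
    """

    image_height: int = 512
    image_width: int = 512
    n_cells: int = 9
    cell_radius_px: float = 40.0
    puncta_per_cell: int | tuple[int, int] = 5
    punctum_radius_px: tuple[float, float] = (2.0, 4.0)
    punctum_intensity_gain: float = 5.0
    background_level: float = 100.0
    noise_sd: float = 10.0
    coloc_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_height, self.image_width, self.n_cells) <= 0:
            raise ConfigError("image dimensions and n_cells must be positive")
        if self.cell_radius_px <= 0 or self.background_level <= 0:
            raise ConfigError("cell radius and background must be positive")
        lo, hi = self.punctum_radius_px
        if not 0 < lo <= hi:
            raise ConfigError("invalid punctum radius range")
        if hi >= self.cell_radius_px:
            raise ConfigError("puncta must fit inside cells")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ConfigError("coloc_fraction must lie in [0, 1]")
        if self.punctum_intensity_gain <= 0 or self.noise_sd < 0:
            raise ConfigError("gain must be positive, noise_sd nonnegative")
        k = self.puncta_per_cell
        if isinstance(k, tuple):
            if not 0 <= k[0] <= k[1]:
                raise ConfigError("invalid puncta_per_cell range")
        elif k < 0:
            raise ConfigError("puncta_per_cell must be >= 0")


@dataclass
class TranslocationSceneConfig:
    """Pre/post stimulation membrane-enrichment scene parameters."""

    edge_ring_width_px: float = 10.0
    edge_enrichment_pre: float = 1.0
    edge_enrichment_post: float = 1.5
    noise_sd: float = 0.0
    image_size_px: int = 128
    cell_radius_px: float = 45.0
    base_level: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_enrichment_pre <= 0 or self.edge_enrichment_post <= 0:
            raise ConfigError("enrichment ratios must be positive")
        if self.edge_ring_width_px <= 0:
            raise ConfigError("ring width must be positive")
        if self.edge_ring_width_px >= self.cell_radius_px:
            raise ConfigError("ring width must be smaller than the cell radius")
        if self.noise_sd < 0 or self.base_level <= 0:
            raise ConfigError("noise_sd nonnegative, base_level positive")


@dataclass
class ExpressionSpec:
    """Reporter expression mixture: a low/zero-expressing subpopulation that
    fails QC plus a lognormal bulk around ``mean``."""

    low_fraction: float = 0.1
    low_level_max: float = 0.1
    mean: float = 1.0
    sd: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.low_fraction <= 1:
            raise ConfigError("low_fraction must lie in [0, 1]")
        if self.low_level_max < 0 or self.mean <= 0 or self.sd < 0:
            raise ConfigError("invalid expression spec")


@dataclass
class KtrSimConfig:
    """Live-cell KTR time-series simulation parameters.

    Defaults mirror the imaging regime the pipeline targets: 22 h at 5-min
    frames (264 frames), pulses lasting 10-20 min, a 100-px neighbor radius.
    Rates are per cell per hour; cells within ``neighbor_radius_px`` of a
    dying cell during the 10 frames preceding its death pulse at
    ``neighbor_pulse_rate`` in that window instead of ``basal_pulse_rate``.
    """

    n_cells: int = 150
    frame_interval_min: float = 5.0
    duration_h: float = 22.0
    baseline_ratio: float = 1.0
    pulse_amplitude: float = 1.0
    pulse_duration_min: tuple[float, float] = (10.0, 20.0)
    basal_pulse_rate: float = 0.15
    neighbor_pulse_rate: float = 0.75
    death_rate: float = 0.02
    division_rate: float = 0.01
    division_artifact_pulse: bool = True
    arena_size_px: float = 1024.0
    motility_px_per_frame: float = 2.0
    neighbor_radius_px: float = 100.0
    noise_sd: float = 0.05
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        n_frames = self.duration_h * 60.0 / self.frame_interval_min
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ConfigError("duration must be an integer number of frames")
        for name in (
            "basal_pulse_rate",
            "neighbor_pulse_rate",
            "death_rate",
            "division_rate",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.pulse_duration_min
        if not 0 < lo <= hi < self.duration_h * 60.0:
            raise ConfigError("pulse duration range must lie within (0, duration)")
        if self.n_cells <= 0 or self.arena_size_px <= 0:
            raise ConfigError("n_cells and arena size must be positive")
        if self.noise_sd < 0 or self.motility_px_per_frame < 0:
            raise ConfigError("noise and motility must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h * 60.0 / self.frame_interval_min))


@dataclass
class DecaySimConfig:
    """Condensate adapter dissociation trace parameters."""

    n_traces: int = 20
    t_half_min: float = 17.0
    amplitude: float = 1.0
    offset: float = 0.2
    frame_interval_min: float = 5.0
    duration_min: float = 90.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_half_min <= 0:
            raise ConfigError("t_half_min must be positive")
        if self.offset < 0 or self.amplitude < 0 or self.noise_sd < 0:
            raise ConfigError("offset, amplitude, noise_sd must be >= 0")
        if self.n_traces <= 0 or self.duration_min <= 0 or self.frame_interval_min <= 0:
            raise ConfigError("n_traces, duration, interval must be positive")


@dataclass
class GroundTruth:
    """Known-by-construction truth for one simulated dataset.

    Only the fields relevant to a given scene type are populated.
    """

    puncta_masks: dict[str, np.ndarray] | None = None
    true_puncta: dict[str, pd.DataFrame] | None = None
    true_coloc_fraction: dict[int, float] | None = None
    ml_pre: float | None = None
    ml_post: float | None = None
    true_translocation: float | None = None
    pulse_labels: pd.DataFrame | None = None
    pulse_durations_min: list[float] | None = None
    death_frames: dict[int, int] | None = None
    division_frames: dict[int, int] | None = None
    lineage: dict[int, list[int]] | None = None
    low_expressor_ids: list[int] | None = None


# ---------------------------------------------------------------------------
# Puncta scenes
# ---------------------------------------------------------------------------


def _disk_pixels(center: tuple[float, float], radius: float, shape) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_cells(cfg: PunctaSceneConfig, rng: np.random.Generator):
    """Disk cells on a jittered grid; raises if they cannot fit."""
    n_side = math.ceil(math.sqrt(cfg.n_cells))
    pitch_r = cfg.image_height / n_side
    pitch_c = cfg.image_width / n_side
    margin = 2.0
    slack_r = pitch_r / 2 - cfg.cell_radius_px - margin
    slack_c = pitch_c / 2 - cfg.cell_radius_px - margin
    if slack_r < 0 or slack_c < 0:
        raise PlacementError("cells do not fit on the grid at this radius")
    labels = np.zeros((cfg.image_height, cfg.image_width), dtype=np.int32)
    centers = {}
    cell_id = 0
    for i in range(n_side):
        for j in range(n_side):
            if cell_id >= cfg.n_cells:
                break
            cell_id += 1
            center = (
                (i + 0.5) * pitch_r + rng.uniform(-slack_r, slack_r),
                (j + 0.5) * pitch_c + rng.uniform(-slack_c, slack_c),
            )
            labels[_disk_pixels(center, cfg.cell_radius_px, labels.shape)] = cell_id
            centers[cell_id] = center
    return labels, centers


def _place_puncta_in_cell(
    rng: np.random.Generator,
    center: tuple[float, float],
    cell_radius: float,
    k: int,
    radius_range: tuple[float, float],
    avoid: list[tuple[tuple[float, float], float]],
    gap: float = 2.0,
    max_tries: int = 500,
) -> list[tuple[tuple[float, float], float]]:
    """Place k non-overlapping punctum disks fully inside a cell disk."""
    placed: list[tuple[tuple[float, float], float]] = []
    for _ in range(k):
        r = rng.uniform(*radius_range)
        for _try in range(max_tries):
            rho = (cell_radius - r - 1.5) * math.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * math.pi)
            c = (center[0] + rho * math.cos(theta), center[1] + rho * math.sin(theta))
            ok = all(
                math.hypot(c[0] - c2[0], c[1] - c2[1]) >= r + r2 + gap
                for c2, r2 in placed + avoid
            )
            if ok:
                placed.append((c, r))
                break
        else:
            raise PlacementError(
                f"could not place punctum {len(placed) + 1} of {k} without overlap"
            )
    return placed


def simulate_puncta_scene(
    cfg: PunctaSceneConfig,
) -> tuple[LabeledImage, LabeledImage, GroundTruth]:
    """Generate a two-channel condensate scene with ground-truth masks.

    Channel A holds the condensate-forming protein; a ``coloc_fraction``
    share of each cell's A-puncta is co-placed (same disk) in channel B,
    mirroring adapter recruitment into condensates, while the remaining B
    puncta are placed disjoint from every A punctum.
    """
    rng = np.random.default_rng(cfg.seed)
    labels, centers = _place_cells(cfg, rng)
    shape = labels.shape
    img_a = np.zeros(shape)
    img_b = np.zeros(shape)
    mask_a = np.zeros(shape, dtype=np.int32)
    mask_b = np.zeros(shape, dtype=np.int32)
    rows_a, rows_b = [], []
    coloc_truth: dict[int, float] = {}
    punctum_level = cfg.background_level * cfg.punctum_intensity_gain
    pid_a = pid_b = 0
    for cell_id, center in centers.items():
        cell_mask = labels == cell_id
        img_a[cell_mask] = cfg.background_level
        img_b[cell_mask] = cfg.background_level
        if isinstance(cfg.puncta_per_cell, tuple):
            k = int(rng.integers(cfg.puncta_per_cell[0], cfg.puncta_per_cell[1] + 1))
        else:
            k = int(cfg.puncta_per_cell)
        if k == 0:
            coloc_truth[cell_id] = float("nan")
            continue
        a_puncta = _place_puncta_in_cell(
            rng, center, cfg.cell_radius_px, k, cfg.punctum_radius_px, avoid=[]
        )
        n_coloc = int(math.floor(cfg.coloc_fraction * k + 0.5))
        coloc_idx = rng.choice(k, size=n_coloc, replace=False) if n_coloc else []
        coloc_set = set(int(i) for i in np.atleast_1d(coloc_idx))
        for i, (c, r) in enumerate(a_puncta):
            pid_a += 1
            disk = _disk_pixels(c, r, shape) & cell_mask
            img_a[disk] = punctum_level
            mask_a[disk] = pid_a
            rows_a.append(
                {
                    "cell_id": cell_id,
                    "punctum_id": pid_a,
                    "row": c[0],
                    "col": c[1],
                    "radius_px": r,
                    "colocalized": i in coloc_set,
                }
            )
            if i in coloc_set:
                pid_b += 1
                img_b[disk] = punctum_level
                mask_b[disk] = pid_b
                rows_b.append(
                    {
                        "cell_id": cell_id,
                        "punctum_id": pid_b,
                        "row": c[0],
                        "col": c[1],
                        "radius_px": r,
                        "colocalized": True,
                    }
                )
        # B-only puncta keep channel-B counts matched while staying clear of A
        extra_b = _place_puncta_in_cell(
            rng,
            center,
            cfg.cell_radius_px,
            k - n_coloc,
            cfg.punctum_radius_px,
            avoid=list(a_puncta),
        )
        for c, r in extra_b:
            pid_b += 1
            disk = _disk_pixels(c, r, shape) & cell_mask
            img_b[disk] = punctum_level
            mask_b[disk] = pid_b
            rows_b.append(
                {
                    "cell_id": cell_id,
                    "punctum_id": pid_b,
                    "row": c[0],
                    "col": c[1],
                    "radius_px": r,
                    "colocalized": False,
                }
            )
        coloc_truth[cell_id] = n_coloc / k
    if cfg.noise_sd > 0:
        img_a = np.clip(img_a + rng.normal(0, cfg.noise_sd, shape), 0, None)
        img_b = np.clip(img_b + rng.normal(0, cfg.noise_sd, shape), 0, None)
    cols = ["cell_id", "punctum_id", "row", "col", "radius_px", "colocalized"]
    truth = GroundTruth(
        puncta_masks={"A": mask_a, "B": mask_b},
        true_puncta={
            "A": pd.DataFrame(rows_a, columns=cols),
            "B": pd.DataFrame(rows_b, columns=cols),
        },
        true_coloc_fraction=coloc_truth,
    )
    return (
        LabeledImage(intensity=img_a, labels=labels),
        LabeledImage(intensity=img_b, labels=labels),
        truth,
    )


# ---------------------------------------------------------------------------
# Translocation scenes
# ---------------------------------------------------------------------------


def simulate_translocation_pair(
    cfg: TranslocationSceneConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Pre/post stimulation image pair of one disk cell.

    The edge ring (analysis definition: within the ring width of the mask
    boundary) is painted at ``enrichment * base_level`` while the core stays
    at ``base_level``, so the noiseless edge/core mean ratio equals the
    configured enrichment exactly in each frame.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.image_size_px
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    mask = _disk_pixels(center, cfg.cell_radius_px, (n, n))
    part: RingPartition = partition_ring(mask, cfg.edge_ring_width_px)

    def paint(enrichment: float) -> np.ndarray:
        img = np.zeros((n, n))
        img[part.core_mask] = cfg.base_level
        img[part.edge_mask] = cfg.base_level * enrichment
        if cfg.noise_sd > 0:
            img = np.clip(img + rng.normal(0, cfg.noise_sd, img.shape), 0, None)
        return img

    pre = paint(cfg.edge_enrichment_pre)
    post = paint(cfg.edge_enrichment_post)
    truth = GroundTruth(
        ml_pre=cfg.edge_enrichment_pre,
        ml_post=cfg.edge_enrichment_post,
        true_translocation=cfg.edge_enrichment_post - cfg.edge_enrichment_pre,
    )
    return pre, post, mask, truth


# ---------------------------------------------------------------------------
# KTR time series
# ---------------------------------------------------------------------------


@dataclass
class _Track:
    cell_id: int
    parent_id: int | None
    root_id: int
    birth: int  # first own frame
    end: int = -1  # last own frame (inclusive); set during simulation
    death_frame: int | None = None
    division_frame: int | None = None
    positions: np.ndarray | None = None  # own segment, shape (len, 2)
    pulses: list[tuple[int, float, bool, bool]] = field(default_factory=list)
    # (peak_frame, duration_min, is_division_artifact, is_neighbor_driven)
    noise: np.ndarray | None = None

    @property
    def own_len(self) -> int:
        return self.end - self.birth + 1

    def exists_at(self, frame: int) -> bool:
        return self.birth <= frame <= self.end

    def position_at(self, frame: int) -> np.ndarray:
        return self.positions[frame - self.birth]


def _raised_cosine(t_min: np.ndarray, peak_min: float, duration_min: float) -> np.ndarray:
    """Smooth compact bump: 0 outside [peak - d/2, peak + d/2], 1 at the peak."""
    x = (t_min - peak_min) / duration_min
    out = np.zeros_like(t_min, dtype=float)
    inside = np.abs(x) <= 0.5
    out[inside] = 0.5 * (1 + np.cos(2 * np.pi * x[inside]))
    return out


def _simulate_demography(cfg: KtrSimConfig, rng: np.random.Generator) -> list[_Track]:
    """Motility plus stochastic death/division; one FIFO pass, single RNG."""
    dt_h = cfg.frame_interval_min / 60.0
    p_death = cfg.death_rate * dt_h
    p_div = cfg.division_rate * dt_h
    n_frames = cfg.n_frames
    arena = cfg.arena_size_px
    tracks: list[_Track] = []
    queue: list[_Track] = []
    next_id = 0
    for _ in range(cfg.n_cells):
        pos0 = rng.uniform(0, arena, size=2)
        queue.append(_Track(cell_id=next_id, parent_id=None, root_id=next_id, birth=0))
        queue[-1].positions = pos0[None, :]
        next_id += 1
    while queue:
        tr = queue.pop(0)
        pos = [tr.positions[0]]
        end = n_frames - 1
        for f in range(tr.birth + 1, n_frames):
            step = rng.normal(0, cfg.motility_px_per_frame, size=2)
            pos.append(np.clip(pos[-1] + step, 0, arena))
            u = rng.uniform()
            if u < p_death:
                tr.death_frame = f
                end = f
                break
            if u < p_death + p_div and f < n_frames - 2:
                tr.division_frame = f
                end = f
                for _ in range(2):
                    child = _Track(
                        cell_id=next_id,
                        parent_id=tr.cell_id,
                        root_id=tr.root_id,
                        birth=f + 1,
                    )
                    child.positions = (
                        pos[-1] + rng.normal(0, 3.0, size=2)
                    )[None, :]
                    next_id += 1
                    queue.append(child)
                break
        tr.end = end
        tr.positions = np.asarray(pos)
        tracks.append(tr)
    return tracks


def _elevated_windows(
    cfg: KtrSimConfig, tracks: list[_Track], window_frames: int = 10
) -> dict[int, np.ndarray]:
    """Per-track boolean mask (own segment) of death-proximal elevated frames."""
    elevated = {tr.cell_id: np.zeros(tr.own_len, dtype=bool) for tr in tracks}
    deaths = [tr for tr in tracks if tr.death_frame is not None]
    for dying in deaths:
        start = dying.death_frame - window_frames
        end = dying.death_frame - 1
        for tr in tracks:
            if tr.cell_id == dying.cell_id:
                continue
            hit_frames = []
            for f in range(max(start, tr.birth, dying.birth), min(end, tr.end) + 1):
                if not dying.exists_at(f):
                    continue
                d = np.linalg.norm(tr.position_at(f) - dying.position_at(f))
                if d <= cfg.neighbor_radius_px:
                    hit_frames.append(f)
            if hit_frames:
                lo = max(start, tr.birth)
                hi = min(end, tr.end)
                elevated[tr.cell_id][lo - tr.birth : hi - tr.birth + 1] = True
    return elevated


def simulate_ktr_dataset(cfg: KtrSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a tracked KTR dataset with labeled ground-truth pulses.

    Returns a tidy trace table (one row per cell per frame; daughters carry
    their parent's duplicated history) and the ground truth: pulse labels
    with owner cell and artifact/neighbor flags, death/division frames,
    lineage, and the identities of low-expression cells.
    """
    rng = np.random.default_rng(cfg.seed)
    dt_h = cfg.frame_interval_min / 60.0
    tracks = _simulate_demography(cfg, rng)
    by_id = {tr.cell_id: tr for tr in tracks}

    # expression per root lineage
    root_ids = sorted({tr.root_id for tr in tracks})
    expression: dict[int, float] = {}
    low_roots: list[int] = []
    for rid in root_ids:
        if rng.uniform() < cfg.expression.low_fraction:
            expression[rid] = float(rng.uniform(0, cfg.expression.low_level_max))
            low_roots.append(rid)
        else:
            expression[rid] = float(
                rng.lognormal(np.log(cfg.expression.mean), cfg.expression.sd)
            )

    elevated = _elevated_windows(cfg, tracks)

    # pulses: per-frame Bernoulli thinning of the (possibly elevated) rate
    p_basal = cfg.basal_pulse_rate * dt_h
    p_neigh = cfg.neighbor_pulse_rate * dt_h
    # pulse peaks stay >= 2 frames inside the observed span (a peak at the
    # recording boundary is censored and unobservable by any local-maximum
    # detector) and distinct pulses of one cell are separated by at least one
    # maximal pulse duration, so "number of pulses" is well defined
    margin = 2
    refractory = int(np.ceil(cfg.pulse_duration_min[1] / cfg.frame_interval_min))
    for tr in tracks:
        elev = elevated[tr.cell_id]
        p = np.where(elev, p_neigh, p_basal)
        draws = rng.uniform(size=tr.own_len) < p
        accepted: list[int] = []
        if cfg.division_artifact_pulse and tr.division_frame is not None:
            lo = max(tr.birth, tr.division_frame - 9)
            hi = tr.division_frame - 1
            if hi >= lo:
                frame = int(rng.integers(lo, hi + 1))
                duration = float(rng.uniform(*cfg.pulse_duration_min))
                tr.pulses.append((frame, duration, True, False))
                accepted.append(frame)
        for i in np.nonzero(draws)[0]:
            frame = tr.birth + int(i)
            if not (tr.birth + margin <= frame <= tr.end - margin):
                continue
            if any(abs(frame - f) < refractory for f in accepted):
                continue
            duration = float(rng.uniform(*cfg.pulse_duration_min))
            tr.pulses.append((frame, duration, False, bool(elev[i])))
            accepted.append(frame)
        tr.noise = rng.normal(0, cfg.noise_sd, size=tr.own_len)

    # assemble full per-cell traces: ancestor segments duplicated into children
    time_min_full = np.arange(cfg.n_frames) * cfg.frame_interval_min

    def lineage_path(tr: _Track) -> list[_Track]:
        path = [tr]
        while path[0].parent_id is not None:
            path.insert(0, by_id[path[0].parent_id])
        return path

    rows = []
    pulse_rows = []
    durations: list[float] = []
    for tr in tracks:
        path = lineage_path(tr)
        frames = np.arange(0, tr.end + 1)
        t_min = time_min_full[: tr.end + 1]
        signal_arr = np.full(frames.size, cfg.baseline_ratio)
        for seg in path:
            for peak_frame, duration, _art, _neigh in seg.pulses:
                signal_arr += cfg.pulse_amplitude * _raised_cosine(
                    t_min, peak_frame * cfg.frame_interval_min, duration
                )
        noise = np.concatenate([seg.noise for seg in path])
        positions = np.concatenate([seg.positions for seg in path], axis=0)
        ratio = np.clip(signal_arr + noise, 1e-3, None)
        division_marks = {
            seg.division_frame for seg in path if seg.division_frame is not None
        }
        expr = expression[tr.root_id]
        for i, f in enumerate(frames):
            rows.append(
                (
                    tr.cell_id,
                    tr.parent_id if tr.parent_id is not None else np.nan,
                    int(f),
                    float(t_min[i]),
                    float(ratio[i]),
                    float(positions[i, 0]),
                    float(positions[i, 1]),
                    expr,
                    int(f in division_marks),
                    int(tr.death_frame is not None and f == tr.death_frame),
                )
            )
        for peak_frame, duration, is_art, is_neigh in tr.pulses:
            pulse_rows.append(
                {
                    "cell_id": tr.cell_id,
                    "peak_frame": peak_frame,
                    "duration_min": duration,
                    "is_division_artifact": is_art,
                    "is_neighbor_driven": is_neigh,
                }
            )
            durations.append(duration)

    trace_df = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "parent_id",
            "frame",
            "time_min",
            "ratio",
            "x_px",
            "y_px",
            "expression",
            "divided_this_frame",
            "died_this_frame",
        ],
    )
    lineage: dict[int, list[int]] = {}
    for tr in tracks:
        if tr.parent_id is not None:
            lineage.setdefault(tr.parent_id, []).append(tr.cell_id)
    truth = GroundTruth(
        pulse_labels=pd.DataFrame(
            pulse_rows,
            columns=[
                "cell_id",
                "peak_frame",
                "duration_min",
                "is_division_artifact",
                "is_neighbor_driven",
            ],
        ),
        pulse_durations_min=durations,
        death_frames={
            tr.cell_id: tr.death_frame for tr in tracks if tr.death_frame is not None
        },
        division_frames={
            tr.cell_id: tr.division_frame
            for tr in tracks
            if tr.division_frame is not None
        },
        lineage=lineage,
        low_expressor_ids=sorted(
            tr.cell_id for tr in tracks if tr.root_id in set(low_roots)
        ),
    )
    return trace_df, truth


# ---------------------------------------------------------------------------
# Dissociation decay traces
# ---------------------------------------------------------------------------


def simulate_decay_traces(cfg: DecaySimConfig) -> pd.DataFrame:
    """Exponentially decaying condensate adapter intensities.

    Each trace is ``offset + amplitude * 2^(-t / t_half) + Gaussian noise``
    (clipped at 0), sampled on a uniform time grid.  Tidy output with columns
    trace_id, time_min, intensity.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.duration_min + 1e-9, cfg.frame_interval_min)
    rows = []
    for trace_id in range(cfg.n_traces):
        clean = cfg.offset + cfg.amplitude * np.power(2.0, -t / cfg.t_half_min)
        noisy = np.clip(clean + rng.normal(0, cfg.noise_sd, t.size), 0, None)
        rows.extend(
            {"trace_id": trace_id, "time_min": float(tt), "intensity": float(v)}
            for tt, v in zip(t, noisy)
        )
    return pd.DataFrame(rows, columns=["trace_id", "time_min", "intensity"])


def decay_matrix(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pivot a tidy decay table to (time vector, traces matrix)."""
    wide = df.pivot(index="trace_id", columns="time_min", values="intensity")
    wide = wide.sort_index(axis=1)
    return wide.columns.to_numpy(dtype=float), wide.to_numpy()
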