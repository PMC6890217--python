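"""Synthetic cases with known ground truth, and the two factor sweeps.

A case consists of landmark pairs related by a known rigid transform plus
digitization noise, a planned implant, and a placed implant constructed from
configured true deviations.  Ground-truth indicator values are computed in
closed form from the configuration, never through the registration pipeline,
so recovery tests compare two independent routes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import count as _count
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError
from .geometry import Point3, build_frame, to_frame_coords
from .indicators import AccuracyReport
from .landmarks import (
    BASIC_TRIPLE_USABLE_SIN,
    LandmarkPair,
    rank_landmarks,
    system_error,
)
from .registration import ImplantPose

__all__ = [
    "SyntheticConfig",
    "SyntheticCase",
    "generate_case",
    "sweep_landmark_count",
    "sweep_landmark_spread",
]

_MAX_SAMPLING_TRIES = 2000
#: Minimum sin(angle) of the first three landmarks, so that the all-tied
#: noise-free ranking (which keeps the first three) yields a usable frame.
_LEAD_TRIPLE_MIN_SIN = 0.2


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic case.

    ``true_deviation`` is (tilt angle deg, coronal lateral offset mm, depth
    offset mm); the tilt and the lateral offset act along the same direction
    perpendicular to the planned axis, which keeps every indicator available
    in closed form.  Depth is positive when the placed implant sits deeper.

    Anatomical landmarks are not equally sharp: a fraction of them (blurred
    pits, irregular pulp angles) digitize with a larger error, and an analyst
    runs out of first-rate landmarks as more are requested.  Each landmark is
    therefore drawn unreliable with probability ``unreliable_fraction``
    (digitizing at ``unreliable_factor`` times the base noise in both
    images), and the noise scale of the i-th landmark additionally grows by
    ``quality_slope`` per index.  Set the fraction and the slope to 0 for a
    homogeneous noise model.
    """

    n_landmarks: int = 8
    landmark_region: tuple[float, float, float] = (60.0, 40.0, 20.0)
    noise_sigma: float = 0.0
    unreliable_fraction: float = 0.15
    unreliable_factor: float = 5.0
    quality_slope: float = 0.12
    true_rotation_deg: tuple[float, float, float] = (10.0, -7.0, 15.0)
    true_translation_mm: tuple[float, float, float] = (12.0, -5.0, 8.0)
    implant_length_mm: float = 10.0
    true_deviation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    min_separation_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_landmarks < 3:
            raise ValueError("need at least 3 landmarks")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.implant_length_mm <= 0:
            raise ValueError("implant length must be positive")
        if not 0 <= self.true_deviation[0] < 90:
            raise ValueError("deviation angle must lie in [0, 90) degrees")
        if not 0 <= self.unreliable_fraction <= 1:
            raise ValueError("unreliable fraction must lie in [0, 1]")
        if self.unreliable_factor < 1:
            raise ValueError("unreliable factor must be >= 1")
        if self.quality_slope < 0:
            raise ValueError("quality slope must be >= 0")


@dataclass(frozen=True)
class SyntheticCase:
    pairs: tuple[LandmarkPair, ...]
    planned: ImplantPose  # in space P
    real: ImplantPose  # in space R
    truth: AccuracyReport
    rotation: np.ndarray  # true rigid map P -> R
    translation: np.ndarray


def _rigid_transform(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    rot = Rotation.from_euler("xyz", cfg.true_rotation_deg, degrees=True).as_matrix()
    return rot, np.asarray(cfg.true_translation_mm, dtype=float)


def _sample_landmarks(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in the region box honouring the separation constraint."""
    half = 0.5 * np.asarray(cfg.landmark_region, dtype=float)
    for _ in range(50):
        points: list[np.ndarray] = []
        tries = 0
        while len(points) < cfg.n_landmarks:
            tries += 1
            if tries > _MAX_SAMPLING_TRIES:
                raise ValueError(
                    f"landmark region {cfg.landmark_region} too small for "
                    f"{cfg.n_landmarks} landmarks at "
                    f"{cfg.min_separation_mm} mm separation"
                )
            cand = rng.uniform(-half, half)
            if all(
                np.linalg.norm(cand - q) >= cfg.min_separation_mm for q in points
            ):
                points.append(cand)
        pts = np.array(points)
        ab = pts[1] - pts[0]
        ac = pts[2] - pts[0]
        sin_cab = np.linalg.norm(np.cross(ab, ac)) / (
            np.linalg.norm(ab) * np.linalg.norm(ac)
        )
        if sin_cab >= _LEAD_TRIPLE_MIN_SIN:
            return pts
    raise ValueError("could not sample a well-conditioned leading triple")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perpendicular_unit(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v -= np.dot(v, d) * d
    n = np.linalg.norm(v)
    while n < 1e-9:  # pragma: no cover - probability zero draw
        v = rng.normal(size=3)
        v -= np.dot(v, d) * d
        n = np.linalg.norm(v)
    return v / n


def _truth_report(cfg: SyntheticConfig) -> AccuracyReport:
    """Closed-form indicators implied by the configured deviation."""
    angle_deg, lat, depth = cfg.true_deviation
    L = cfg.implant_length_mm
    a = math.radians(angle_deg)
    avd = depth + L * (math.cos(a) - 1.0)
    ald = abs(lat + L * math.sin(a))
    crd = abs(lat - depth * math.tan(a))
    ard = math.hypot(lat - depth * math.tan(a) + L * math.sin(a), L * (math.cos(a) - 1.0))
    return AccuracyReport(
        hs_mm=0.0,
        ad_deg=angle_deg,
        cgd_mm=math.hypot(lat, depth),
        cvd_mm=depth,
        cld_mm=abs(lat),
        crd_mm=crd,
        agd_mm=math.hypot(avd, ald),
        avd_mm=avd,
        ald_mm=ald,
        ard_mm=ard,
        system_error_mm=0.0 if cfg.noise_sigma == 0 else None,
    )


def generate_case(cfg: SyntheticConfig) -> SyntheticCase:
    """Generate landmark pairs, implant poses and ground truth for one case.

    Landmarks are sampled in the region with a minimum pairwise separation;
    their real-image coordinates are the rigid transform of the planned-image
    coordinates, and i.i.d. Gaussian digitization noise is added in *both*
    images.  The placed implant is the planned implant tilted and offset by
    the configured true deviation, then carried into the real image by the
    same rigid transform.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    rot, trans = _rigid_transform(cfg)

    pts_p = _sample_landmarks(cfg, rng)
    pts_r = pts_p @ rot.T + trans
    if cfg.noise_sigma > 0:
        scale = np.where(
            rng.random(cfg.n_landmarks) < cfg.unreliable_fraction,
            cfg.unreliable_factor * cfg.noise_sigma,
            cfg.noise_sigma,
        )
        scale = scale * (1.0 + cfg.quality_slope * np.arange(cfg.n_landmarks))
        scale = scale[:, None]
        pts_p = pts_p + scale * rng.normal(size=pts_p.shape)
        pts_r = pts_r + scale * rng.normal(size=pts_r.shape)
    pairs = tuple(
        LandmarkPair(
            label=f"L{k + 1}",
            p=Point3.from_array(pts_p[k], space="P"),
            r=Point3.from_array(pts_r[k], space="R"),
        )
        for k in range(cfg.n_landmarks)
    )

    # Planned implant: random axis anchored near the region centre.
    d = _random_unit(rng)
    u = _perpendicular_unit(d, rng)
    coronal = rng.uniform(-2.0, 2.0, size=3)
    apical = coronal + cfg.implant_length_mm * d
    planned = ImplantPose(
        coronal=Point3.from_array(coronal, space="P"),
        apical=Point3.from_array(apical, space="P"),
    )

    # Placed implant in planned space, then carried into the real image.
    angle_deg, lat, depth = cfg.true_deviation
    a = math.radians(angle_deg)
    d_real = math.cos(a) * d + math.sin(a) * u
    real_coronal_p = coronal + depth * d + lat * u
    real_apical_p = real_coronal_p + cfg.implant_length_mm * d_real
    real = ImplantPose(
        coronal=Point3.from_array(rot @ real_coronal_p + trans, space="R"),
        apical=Point3.from_array(rot @ real_apical_p + trans, space="R"),
    )

    return SyntheticCase(
        pairs=pairs,
        planned=planned,
        real=real,
        truth=_truth_report(cfg),
        rotation=rot,
        translation=trans,
    )


def _case_system_error(pairs: Sequence[LandmarkPair]) -> float:
    # reject unusably thin selections; the sweep resamples those replicates
    ranking = rank_landmarks(pairs, collinearity_tol=BASIC_TRIPLE_USABLE_SIN)
    err, _ = system_error(pairs, ranking)
    return err


def sweep_landmark_count(
    cfg: SyntheticConfig,
    counts: Sequence[int] = tuple(range(4, 17)),
    replicates: int = 50,
) -> pd.DataFrame:
    """System error as a function of how many landmark pairs are provided.

    Each replicate generates one case with ``max(counts)`` landmarks and,
    mimicking an analyst offered progressively more points of the same case,
    evaluates every count on the leading subset of that single landmark set —
    so the per-replicate values are paired across counts.

    Returns a tidy frame with columns ``count``, ``replicate``,
    ``system_error_mm``.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    counts = sorted(counts)
    if counts[0] < 4:
        raise ValueError("system error needs at least 4 landmark pairs")
    rows = []
    for rep in range(replicates):
        for attempt in _count():
            case_cfg = replace(
                cfg,
                n_landmarks=counts[-1],
                seed=cfg.seed + 100_003 * rep + 17 * attempt,
            )
            case = generate_case(case_cfg)
            try:
                errors = {
                    c: _case_system_error(case.pairs[:c]) for c in counts
                }
            except DegenerateGeometryError:
                if attempt >= 5:
                    raise
                continue  # resample this replicate: unusable basic triple
            break
        for c, err in errors.items():
            rows.append({"count": c, "replicate": rep, "system_error_mm": err})
    return pd.DataFrame(rows)


def sweep_landmark_spread(
    cfg: SyntheticConfig,
    min_edges: Sequence[float] = (5.0, 10.0, 20.0, 30.0),
    replicates: int = 50,
    probe_offset_mm: float = 20.0,
) -> pd.DataFrame:
    """Frame accuracy as a function of the spread of the basic triple.

    For each spread value an equilateral triangle with that edge length is
    digitized with noise in both images; the frame-to-frame map is compared
    with the true rigid transform.  Reported per replicate: the orientation
    error of the recovered rotation (degrees) and the registration error of a
    noise-free probe point ``probe_offset_mm`` above the triangle centroid.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rot, trans = _rigid_transform(cfg)
    rows = []
    for s in min_edges:
        tri = np.array(
            [
                [0.0, 0.0, 0.0],
                [s, 0.0, 0.0],
                [0.5 * s, 0.5 * math.sqrt(3.0) * s, 0.0],
            ]
        )
        tri -= tri.mean(axis=0)
        probe = np.array([0.0, 0.0, probe_offset_mm])
        for rep in range(replicates):
            rng = np.random.default_rng(cfg.seed + 7919 * rep + int(round(1000 * s)))
            pts_p = tri + rng.normal(0.0, cfg.noise_sigma, tri.shape)
            pts_r = tri @ rot.T + trans + rng.normal(0.0, cfg.noise_sigma, tri.shape)
            frame_p = build_frame(
                *(Point3.from_array(q, space="P") for q in pts_p)
            )
            frame_r = build_frame(
                *(Point3.from_array(q, space="R") for q in pts_r)
            )
            # Estimated P->R rotation implied by expressing both images in
            # their own frame: Mr (y - Ar) = Mp (x - Ap).
            r_est = frame_r.rotation.T @ frame_p.rotation
            misfit = Rotation.from_matrix(r_est @ rot.T)
            orient_err = math.degrees(misfit.magnitude())

            n_p = to_frame_coords(Point3.from_array(probe, space="P"), frame_p)
            n_r = to_frame_coords(
                Point3.from_array(rot @ probe + trans, space="R"), frame_r
            )
            rows.append(
                {
                    "min_edge_mm": s,
                    "replicate": rep,
                    "orientation_error_deg": orient_err,
                    "probe_error_mm": n_p.distance_to(n_r),
                }
            )
    return pd.DataFrame(rows)
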