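"""Map planned and real implant poses into the common system N.

The basic triple selected by the ranking defines one frame per image; each
image is expressed in its own frame.  Because the triples are anatomically
congruent, the two frames realise the same coordinate system and the implant
poses become directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import DegenerateImplantError, TooFewLandmarksError
from .geometry import Frame, Point3, build_frame, to_frame_coords
from .landmarks import LandmarkPair, LandmarkRanking, rank_landmarks, system_error

__all__ = ["ImplantPose", "RegistrationResult", "register_case"]


@dataclass(frozen=True)
class ImplantPose:
    """Coronal (platform) and apical (tip) endpoints of one implant."""

    coronal: Point3
    apical: Point3

    def __post_init__(self) -> None:
        if self.coronal.space != self.apical.space:
            raise ValueError("implant endpoints must share one space")
        if self.length == 0.0:
            raise DegenerateImplantError("implant endpoints coincide")

    @property
    def length(self) -> float:
        return self.coronal.distance_to(self.apical)

    @property
    def axis(self):
        """Coronal-to-apical unit direction."""
        v = self.apical.to_array() - self.coronal.to_array()
        return v / self.length


@dataclass(frozen=True)
class RegistrationResult:
    ranking: LandmarkRanking
    planned_in_N: ImplantPose
    real_in_N: ImplantPose
    system_error_mm: float | None
    residuals_mm: Mapping[str, float]
    frame_p: Frame
    frame_r: Frame


def _map_pose(pose: ImplantPose, frame: Frame) -> ImplantPose:
    return ImplantPose(
        coronal=to_frame_coords(pose.coronal, frame),
        apical=to_frame_coords(pose.apical, frame),
    )


def register_case(
    pairs: Sequence[LandmarkPair],
    planned: ImplantPose,
    real: ImplantPose,
) -> RegistrationResult:
    """Select the basic triple and express both implants in the common system.

    With at least four landmark pairs the system error of the registration is
    measured on the 4th-ranked pair; with exactly three it is reported as
    unavailable (``None``), not as zero.
    """
    if len(pairs) < 3:
        raise TooFewLandmarksError(f"need at least 3 landmark pairs, got {len(pairs)}")
    ranking = rank_landmarks(pairs)
    by_label = {p.label: p for p in pairs}
    triple = [by_label[l] for l in ranking.basic_triple]
    frame_p = build_frame(triple[0].p, triple[1].p, triple[2].p)
    frame_r = build_frame(triple[0].r, triple[1].r, triple[2].r)

    if len(pairs) >= 4:
        err, residuals = system_error(pairs, ranking)
    else:
        err, residuals = None, {}

    return RegistrationResult(
        ranking=ranking,
        planned_in_N=_map_pose(planned, frame_p),
        real_in_N=_map_pose(real, frame_r),
        system_error_mm=err,
        residuals_mm=residuals,
        frame_p=frame_p,
        frame_r=frame_r,
    )
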