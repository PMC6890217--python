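"""Accuracy indicators comparing a planned and a placed implant in one space.

Deviations are measured at the coronal and apical endpoints and decomposed
along the *planned* implant axis.  Sign convention: vertical deviations (CVD,
AVD) are positive along the planned coronal-to-apical direction, i.e. an
implant placed deeper than planned scores positive.

Rectified deviations (CRD, ARD) slide the placed implant along its *own* axis
until its coronal point lies in the plane through the planned coronal point
perpendicular to the planned axis.  This cancels the depth component — which
the surgeon commonly adjusts by eye during insertion — so the rectified
numbers isolate the error attributable to the guide itself.  The exact
rectification rule is this module's documented interpretation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateImplantError, RectificationError
from .geometry import Point3
from .registration import ImplantPose

__all__ = [
    "AccuracyReport",
    "SIGN_CONVENTION",
    "correct_cover_screw",
    "angular_deviation",
    "coronal_apical_deviations",
    "rectified_deviations",
    "compute_report",
]

SIGN_CONVENTION = (
    "CVD/AVD are signed along the planned coronal-to-apical axis: "
    "positive = placed deeper than planned, negative = shallower."
)

#: |cos| between the real axis and the planned axis below which the depth
#: rectification translation is unbounded.
RECTIFICATION_COS_TOL = 1e-9


@dataclass(frozen=True)
class AccuracyReport:
    """The ten indicators plus the registration system error for one case.

    CRD/ARD are ``None`` when rectification is impossible (real axis
    perpendicular to the planned axis); system_error_mm is ``None`` when only
    three landmark pairs were available.
    """

    hs_mm: float
    ad_deg: float
    cgd_mm: float
    cvd_mm: float
    cld_mm: float
    crd_mm: float | None
    agd_mm: float
    avd_mm: float
    ald_mm: float
    ard_mm: float | None
    system_error_mm: float | None = None

    def as_dict(self) -> dict:
        return {
            "HS_mm": self.hs_mm,
            "AD_deg": self.ad_deg,
            "CGD_mm": self.cgd_mm,
            "CVD_mm": self.cvd_mm,
            "CLD_mm": self.cld_mm,
            "CRD_mm": self.crd_mm,
            "AGD_mm": self.agd_mm,
            "AVD_mm": self.avd_mm,
            "ALD_mm": self.ald_mm,
            "ARD_mm": self.ard_mm,
            "system_error_mm": self.system_error_mm,
        }


def correct_cover_screw(real: ImplantPose, hs: float) -> ImplantPose:
    """Shift the digitized coronal point apically by the cover-screw height.

    When the implant platform is hidden by a cover screw on the postoperative
    image, the digitized coronal point sits ``hs`` millimetres above the true
    platform along the implant axis; the correction moves it apically along
    the implant's own axis.  The apical endpoint is unchanged.
    """
    if hs < 0:
        raise ValueError(f"cover-screw height must be >= 0, got {hs}")
    if hs == 0:
        return real
    if hs >= real.length:
        raise DegenerateImplantError(
            f"cover-screw height {hs} mm not smaller than implant length "
            f"{real.length:.3f} mm"
        )
    shifted = real.coronal.to_array() + hs * real.axis
    return ImplantPose(
        coronal=Point3.from_array(shifted, space=real.coronal.space),
        apical=real.apical,
    )


def angular_deviation(planned: ImplantPose, real: ImplantPose) -> float:
    """Angle in degrees between the two coronal-to-apical axes, in [0, 180)."""
    a, b = planned.axis, real.axis
    # atan2 form stays accurate near 0 and 180 where acos loses digits
    return math.degrees(
        math.atan2(float(np.linalg.norm(np.cross(a, b))), float(np.dot(a, b)))
    )


def coronal_apical_deviations(
    planned: ImplantPose, real: ImplantPose
) -> tuple[float, float, float, float, float, float]:
    """Global/vertical/lateral deviation at each endpoint.

    Returns ``(CGD, CVD, CLD, AGD, AVD, ALD)``: at each endpoint the global
    deviation is the 3-D distance, the vertical deviation its signed
    projection on the planned axis, and the lateral deviation the norm of the
    perpendicular remainder.
    """
    a_hat = planned.axis

    def decompose(p_end: Point3, r_end: Point3) -> tuple[float, float, float]:
        d = r_end.to_array() - p_end.to_array()
        vertical = float(np.dot(d, a_hat))
        lateral = float(np.linalg.norm(d - vertical * a_hat))
        return float(np.linalg.norm(d)), vertical, lateral

    cgd, cvd, cld = decompose(planned.coronal, real.coronal)
    agd, avd, ald = decompose(planned.apical, real.apical)
    return cgd, cvd, cld, agd, avd, ald


def rectified_deviations(
    planned: ImplantPose, real: ImplantPose
) -> tuple[float, float]:
    """Coronal and apical deviations after cancelling the depth difference.

    The real implant is translated along its own axis until its coronal point
    lies in the plane through the planned coronal point with the planned axis
    as normal; the residual endpoint distances are returned as (CRD, ARD).

    Raises
    ------
    RectificationError
        If the real axis is perpendicular to the planned axis, making the
        translation unbounded.
    """
    a_hat = planned.axis
    r_hat = real.axis
    cosang = float(np.dot(a_hat, r_hat))
    if abs(cosang) < RECTIFICATION_COS_TOL:
        raise RectificationError(
            "real implant axis is perpendicular to the planned axis; "
            "depth rectification is unbounded"
        )
    depth = float(np.dot(real.coronal.to_array() - planned.coronal.to_array(), a_hat))
    shift = -depth / cosang
    rect_coronal = real.coronal.to_array() + shift * r_hat
    rect_apical = real.apical.to_array() + shift * r_hat
    crd = float(np.linalg.norm(rect_coronal - planned.coronal.to_array()))
    ard = float(np.linalg.norm(rect_apical - planned.apical.to_array()))
    return crd, ard


def compute_report(
    planned: ImplantPose,
    real: ImplantPose,
    hs: float = 0.0,
    apply_hs_correction: bool = True,
    system_error_mm: float | None = None,
) -> AccuracyReport:
    """All ten indicators for one case, optionally HS-corrected first."""
    if planned.coronal.space != real.coronal.space:
        raise ValueError("planned and real poses must be in the same space")
    measured = correct_cover_screw(real, hs) if apply_hs_correction else real
    ad = angular_deviation(planned, measured)
    cgd, cvd, cld, agd, avd, ald = coronal_apical_deviations(planned, measured)
    try:
        crd, ard = rectified_deviations(planned, measured)
    except RectificationError:
        crd, ard = None, None
    return AccuracyReport(
        hs_mm=hs,
        ad_deg=ad,
        cgd_mm=cgd,
        cvd_mm=cvd,
        cld_mm=cld,
        crd_mm=crd,
        agd_mm=agd,
        avd_mm=avd,
        ald_mm=ald,
        ard_mm=ard,
        system_error_mm=system_error_mm,
    )
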