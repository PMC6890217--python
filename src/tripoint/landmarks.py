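"""Triangle-congruence scoring, ranking and system error of landmark pairs.

Each landmark is one anatomical point digitized in the planned image (space P)
and in the postoperative image (space R).  If a triple of landmarks is exactly
rigid between the two images, the two triangles it spans are congruent and its
error is zero; digitization error breaks congruence.  Pairs are ranked by
iteratively discarding the pair with the worst accumulated triangle error; the
three survivors are the *basic triple* used to build the registration frames,
and the residual of the best discarded pair (the 4th-ranked) is reported as
the per-case system error.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateGeometryError, TooFewLandmarksError
from .geometry import Point3, build_frame, to_frame_coords

__all__ = [
    "LandmarkPair",
    "LandmarkRanking",
    "edge_discrepancy",
    "triangle_error",
    "point_error",
    "rank_landmarks",
    "system_error",
]


@dataclass(frozen=True)
class LandmarkPair:
    """One anatomical point digitized in both image spaces."""

    label: str
    p: Point3
    r: Point3


@dataclass(frozen=True)
class LandmarkRanking:
    """Outcome of iterative worst-pair elimination.

    ``elimination_order`` lists labels from first (worst) to last eliminated;
    the final entry, when present, is the 4th-ranked pair used for the system
    error.  ``point_errors`` maps each eliminated label to its accumulated
    triangle error at the round of its elimination.
    """

    elimination_order: tuple[str, ...]
    basic_triple: tuple[str, str, str]
    fourth_pair: str | None
    point_errors: Mapping[str, float]


def edge_discrepancy(i: LandmarkPair, j: LandmarkPair) -> float:
    """Relative length difference of edge ``ij`` between the two images.

    Returns ``| |PiPj| - |RiRj| | / (0.5 * (|PiPj| + |RiRj|))``, a
    dimensionless fraction in ``[0, 2)``, symmetric in the two images.
    """
    dp = i.p.distance_to(j.p)
    dr = i.r.distance_to(j.r)
    denom = 0.5 * (dp + dr)
    if denom == 0.0:
        raise DegenerateGeometryError(
            f"landmarks {i.label!r} and {j.label!r} coincide in both images"
        )
    return abs(dp - dr) / denom


def triangle_error(a: LandmarkPair, b: LandmarkPair, c: LandmarkPair) -> float:
    """Congruence error of the triangle spanned by three landmark pairs.

    Sum of the three edge discrepancies plus a similarity term ``t`` (spread
    between the largest and smallest discrepancy).  Zero exactly when the two
    triangles are congruent; smaller when edges deviate proportionally than
    when one edge alone is off.
    """
    e_ab = edge_discrepancy(a, b)
    e_ac = edge_discrepancy(a, c)
    e_bc = edge_discrepancy(b, c)
    t = max(e_ab, e_ac, e_bc) - min(e_ab, e_ac, e_bc)
    return e_ab + e_ac + e_bc + t


def point_error(i: LandmarkPair, pool: Iterable[LandmarkPair]) -> float:
    """Accumulated triangle error of pair ``i`` over every triangle in ``pool``.

    Sums :func:`triangle_error` over all unordered pairs ``{u, v}`` drawn from
    the pool with ``i`` excluded.  The pool must contain ``i`` and at least two
    other pairs.
    """
    others = [p for p in pool if p.label != i.label]
    if len(others) < 2:
        raise TooFewLandmarksError(
            f"point error of {i.label!r} needs at least 2 other pairs"
        )
    return sum(triangle_error(i, u, v) for u, v in combinations(others, 2))


def _discrepancy_matrix(pairs: Sequence[LandmarkPair]) -> np.ndarray:
    """Pairwise edge-discrepancy matrix for a pool of landmark pairs."""
    P = np.array([pair.p.to_array() for pair in pairs])
    R = np.array([pair.r.to_array() for pair in pairs])
    dp = pdist(P)
    dr = pdist(R)
    denom = 0.5 * (dp + dr)
    if np.any(denom == 0.0):
        raise DegenerateGeometryError("a landmark pair coincides in both images")
    return squareform(np.abs(dp - dr) / denom)


def _point_errors_from_matrix(K: np.ndarray) -> np.ndarray:
    """Accumulated triangle error per point, from the discrepancy matrix."""
    n = K.shape[0]
    E = np.zeros(n)
    for i, u, v in combinations(range(n), 3):
        edges = (K[i, u], K[i, v], K[u, v])
        et = edges[0] + edges[1] + edges[2] + max(edges) - min(edges)
        E[i] += et
        E[u] += et
        E[v] += et
    return E


#: Minimum sin(angle) for a basic triple to be considered *usable* rather than
#: merely non-degenerate.  Congruence scoring is blind to triangle
#: conditioning, and under noise a nearly flat selected triple produces a wild
#: frame orientation; simulation sweeps reject such selections (the clinical
#: analogue is re-digitizing) by passing this as ``collinearity_tol``.
BASIC_TRIPLE_USABLE_SIN = 0.1


def rank_landmarks(
    pairs: Sequence[LandmarkPair],
    collinearity_tol: float = 1e-6,
) -> LandmarkRanking:
    """Rank landmark pairs by iterative worst-pair elimination.

    While more than three pairs remain, the accumulated triangle error of each
    remaining pair is recomputed over the remaining pool and the pair with the
    maximal error is eliminated.  Ties are broken first toward the pair with
    the larger total edge discrepancy against the rest of the pool, then
    toward the later label in input order, so the result is deterministic.

    Raises
    ------
    TooFewLandmarksError
        If fewer than three pairs are given.
    DegenerateGeometryError
        If the selected basic triple is collinear beyond ``collinearity_tol``
        in either image (see also ``BASIC_TRIPLE_USABLE_SIN``).
    """
    labels = [p.label for p in pairs]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate landmark labels: {dupes}")
    if len(pairs) < 3:
        raise TooFewLandmarksError(f"need at least 3 landmark pairs, got {len(pairs)}")

    K = _discrepancy_matrix(pairs)
    remaining = list(range(len(pairs)))
    order: list[int] = []
    point_errors: dict[str, float] = {}

    while len(remaining) > 3:
        sub = K[np.ix_(remaining, remaining)]
        E = _point_errors_from_matrix(sub)
        emax = E.max()
        cands = [k for k, e in enumerate(E) if e == emax]
        if len(cands) > 1:
            # Larger total discrepancy against the remaining pool goes first.
            totals = sub[cands].sum(axis=1)
            tmax = totals.max()
            cands = [k for k, s in zip(cands, totals) if s == tmax]
        worst_local = cands[-1]  # later input order loses remaining ties
        worst = remaining[worst_local]
        point_errors[pairs[worst].label] = float(E[worst_local])
        order.append(worst)
        remaining.remove(worst)

    basic = tuple(pairs[k].label for k in remaining)
    # Reject an unusable triple now rather than during frame construction.
    triple = [pairs[k] for k in remaining]
    build_frame(triple[0].p, triple[1].p, triple[2].p, collinearity_tol)
    build_frame(triple[0].r, triple[1].r, triple[2].r, collinearity_tol)

    return LandmarkRanking(
        elimination_order=tuple(pairs[k].label for k in order),
        basic_triple=basic,  # type: ignore[arg-type]
        fourth_pair=pairs[order[-1]].label if order else None,
        point_errors=point_errors,
    )


def system_error(
    pairs: Sequence[LandmarkPair],
    ranking: LandmarkRanking,
) -> tuple[float, dict[str, float]]:
    """Registration residual of the 4th-ranked pair, plus all leftover residuals.

    Builds the planned-image and real-image frames from the basic triple, maps
    every non-basic pair's two digitizations into the common system and
    measures their distance.  The reported system error is the residual of the
    4th-ranked pair (the last eliminated); residuals of every other leftover
    pair are returned as diagnostics.
    """
    if len(pairs) < 4:
        raise TooFewLandmarksError("system error needs at least 4 landmark pairs")
    if ranking.fourth_pair is None:
        raise TooFewLandmarksError("ranking has no 4th-ranked pair")
    by_label = {p.label: p for p in pairs}
    triple = [by_label[l] for l in ranking.basic_triple]
    frame_p = build_frame(triple[0].p, triple[1].p, triple[2].p)
    frame_r = build_frame(triple[0].r, triple[1].r, triple[2].r)

    residuals: dict[str, float] = {}
    for pair in pairs:
        if pair.label in ranking.basic_triple:
            continue
        n_p = to_frame_coords(pair.p, frame_p)
        n_r = to_frame_coords(pair.r, frame_r)
        residuals[pair.label] = n_p.distance_to(n_r)
    return residuals[ranking.fourth_pair], residuals
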