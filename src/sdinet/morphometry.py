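"""Vertebral morphometry: semiquantitative grading and the Spinal Deformity Index.

A lateral spine radiograph is summarised per vertebra by six landmark points
defining the anterior, middle and posterior vertebral body heights.  Each
vertebra receives a semiquantitative (SQ) deformity grade from its worst
height compression: grade 0 intact, grade 1 mild (20-25%), grade 2 moderate
(25-40%), grade 3 severe (>40%).  The Spinal Deformity Index (SDI) sums the
grades of the thirteen vertebrae T4-L4 and therefore integrates both number
and severity of morphometric fractures (range 0-39).

Two case/control endpoints are derived from the SDI:

* ``sdi1``  -- any morphometric fracture, SDI>=1 versus SDI=0;
* ``sdi5``  -- high fracture burden, SDI>=5 versus SDI=0, with the
  intermediate range 1-4 excluded from the contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Vertebral levels contributing to the SDI, cranial to caudal.
VERTEBRAE: tuple[str, ...] = (
    "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T12",
    "L1", "L2", "L3", "L4",
)

N_VERTEBRAE = len(VERTEBRAE)
MAX_SDI = 3 * N_VERTEBRAE

# Compression-band boundaries.  Ties resolved half-open: c=0.20 -> grade 1,
# c=0.25 -> grade 2, c=0.40 -> grade 2 (the printed bands overlap at 25%).
_MILD = 0.20
_MODERATE = 0.25
_SEVERE = 0.40


class DegenerateGeometryError(ValueError):
    """Raised when landmark points imply a zero or negative height."""


@dataclass(frozen=True)
class SdiScore:
    """SDI value plus its classification under both study endpoints."""

    sdi: int
    endpoint1: str  # 'case' (SDI>=1) or 'control' (SDI=0)
    endpoint2: str  # 'case' (SDI>=5), 'control' (SDI=0) or 'excluded' (1-4)


def heights_from_landmarks(six_points) -> tuple[float, float, float]:
    """Anterior/middle/posterior heights from a six-point morphometry set.

    Parameters
    ----------
    six_points
        Array-like of shape (6, 2): the (x, y) coordinates in mm, ordered
        anterior-superior, anterior-inferior, middle-superior,
        middle-inferior, posterior-superior, posterior-inferior.

    Returns
    -------
    (h_a, h_m, h_p) : Euclidean superior-inferior distances in mm.
    """
    pts = np.asarray(six_points, dtype=float)
    if pts.shape != (6, 2):
        raise ValueError(f"expected 6 landmark points of (x, y), got shape {pts.shape}")
    heights = tuple(float(np.hypot(*(pts[i] - pts[i + 1]))) for i in (0, 2, 4))
    if min(heights) <= 0.0:
        raise DegenerateGeometryError(
            "coincident landmark points give a zero vertebral height"
        )
    return heights


def compression(h_a: float, h_m: float, h_p: float, h_p_reference: float | None = None) -> float:
    """Worst relative height loss of a vertebra.

    Wedge and biconcave deformities are read against the vertebra's own
    posterior height; crush deformity against the posterior height of an
    adjacent intact vertebra (``h_p_reference``, defaulting to ``h_p``).
    """
    if min(h_a, h_m, h_p) <= 0.0 or (h_p_reference is not None and h_p_reference <= 0.0):
        raise ValueError("vertebral heights must be positive")
    ref = h_p if h_p_reference is None else h_p_reference
    return max(1.0 - h_a / h_p, 1.0 - h_m / h_p, 1.0 - h_p / ref)


_EPS = 1e-9  # guards band boundaries against height-ratio rounding


def grade_from_compression(c: float) -> int:
    if c > _SEVERE + _EPS:
        return 3
    if c >= _MODERATE - _EPS:
        return 2
    if c >= _MILD - _EPS:
        return 1
    return 0


def sq_grade(h_a: float, h_m: float, h_p: float, h_p_reference: float | None = None) -> int:
    """Semiquantitative grade 0-3 from the three vertebral heights."""
    return grade_from_compression(compression(h_a, h_m, h_p, h_p_reference))


def _crush_references(h_p: np.ndarray) -> np.ndarray:
    """Posterior-height reference per level: mean of the two neighbours where
    both exist, the single neighbour at the column ends."""
    ref = np.empty_like(h_p)
    ref[0] = h_p[1]
    ref[-1] = h_p[-2]
    ref[1:-1] = 0.5 * (h_p[:-2] + h_p[2:])
    return ref


def grade_spine(morphometry: pd.DataFrame) -> np.ndarray:
    """Grade a full 13-vertebra column.

    ``morphometry`` must hold one row per level of :data:`VERTEBRAE` with
    columns ``vertebra, h_a, h_m, h_p``.  Crush references use the adjacent
    posterior heights.
    """
    df = morphometry.set_index("vertebra").loc[list(VERTEBRAE)]
    h_a = df["h_a"].to_numpy(float)
    h_m = df["h_m"].to_numpy(float)
    h_p = df["h_p"].to_numpy(float)
    refs = _crush_references(h_p)
    return np.array(
        [sq_grade(a, m, p, r) for a, m, p, r in zip(h_a, h_m, h_p, refs)], dtype=int
    )


def sdi(grades) -> SdiScore:
    """Spinal Deformity Index and endpoint labels from 13 SQ grades."""
    g = np.asarray(grades, dtype=int)
    if g.shape != (N_VERTEBRAE,):
        raise ValueError(f"expected {N_VERTEBRAE} grades, got shape {g.shape}")
    if g.min() < 0 or g.max() > 3:
        raise ValueError("SQ grades must lie in {0, 1, 2, 3}")
    total = int(g.sum())
    endpoint1 = "case" if total >= 1 else "control"
    if total >= 5:
        endpoint2 = "case"
    elif total == 0:
        endpoint2 = "control"
    else:
        endpoint2 = "excluded"
    return SdiScore(sdi=total, endpoint1=endpoint1, endpoint2=endpoint2)


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Chance-corrected agreement between two raters of categorical data.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and chance
    agreement p_e from the raters' marginal frequencies.  If both raters are
    constant and identical, chance agreement is 1 and kappa is undefined; a
    perfect-agreement sentinel of 1.0 is returned with a warning.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("ratings must be two equal-length non-empty sequences")
    n = a.size
    cats = np.union1d(a, b)
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-12:
        warnings.warn(
            "both raters constant and identical: kappa undefined, "
            "returning perfect-agreement sentinel 1.0",
            stacklevel=2,
        )
        return 1.0
    del n
    return (p_o - p_e) / (1.0 - p_e)
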