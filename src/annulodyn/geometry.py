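"""Annular geometry from per-frame inter-crystal distance matrices.

Six piezoelectric crystals sit on the aortic annulus — one at each leaflet
nadir (labels 1 NC, 2 RC, 3 LC) and one at each interleaflet triangle
(4 LR, 5 LN, 6 RN) — plus two reference crystals (7 apex, 8 ascending
aorta).  Walking around the ring, nadirs alternate with commissures, which
fixes the ring order 1-6-2-4-3-5 and pairs each nadir with the opposite
commissure for the three cross-sectional diameters (1-4, 2-5, 3-6).

All chord-based quantities (circumference, sinus lengths, diameters) are
read straight off the distance matrix and therefore carry no embedding
error.  Only the annulus area needs coordinates, which are recovered by
classical multidimensional scaling and projected onto the least-squares
annular plane before the shoelace formula is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .errors import CoverageError, ReconstructionError, ValidationError

log = logging.getLogger(__name__)

OVALITY_THRESHOLD_MM = 3.0


@dataclass(frozen=True)
class CrystalLayout:
    """Mapping between crystal labels (1-based) and anatomical roles.

    ``ring_order`` lists the six annular crystals in the order they are
    encountered walking around the annulus; ``diameter_pairs`` joins each
    leaflet nadir to the non-adjacent commissure.
    """

    nadirs: dict = field(default_factory=lambda: {1: "NC", 2: "RC", 3: "LC"})
    commissures: dict = field(default_factory=lambda: {4: "LR", 5: "LN", 6: "RN"})
    references: dict = field(default_factory=lambda: {7: "apex", 8: "aorta"})
    ring_order: tuple = (1, 6, 2, 4, 3, 5)
    diameter_pairs: dict = field(
        default_factory=lambda: {"NC-LR": (1, 4), "RC-LN": (2, 5), "LC-RN": (3, 6)}
    )

    def __post_init__(self):
        if sorted(self.ring_order) != [1, 2, 3, 4, 5, 6]:
            raise ValidationError("ring_order must be a permutation of crystals 1..6")
        ring = list(self.ring_order)
        for name, (a, b) in self.diameter_pairs.items():
            if (ring.index(a) - ring.index(b)) % 6 != 3:
                raise ValidationError(
                    f"diameter pair {name} ({a},{b}) does not join opposite ring positions"
                )

    @property
    def ring_chord_pairs(self) -> list:
        """Consecutive (label, label) pairs around the ring, closing the loop."""
        ring = list(self.ring_order)
        return [(ring[i], ring[(i + 1) % 6]) for i in range(6)]

    @property
    def sinus_chords(self) -> dict:
        """Sinus name -> the two ring chords flanking its nadir crystal.

        Each sinus runs commissure-to-commissure through its nadir, so its
        length is the sum of the two chords adjacent to the nadir.
        """
        ring = list(self.ring_order)
        out = {}
        for label, name in self.nadirs.items():
            i = ring.index(label)
            out[name] = ((ring[i - 1], label), (label, ring[(i + 1) % 6]))
        return out


DEFAULT_LAYOUT = CrystalLayout()


@dataclass
class EmbeddingResult:
    """Coordinates recovered from one distance matrix."""

    points: np.ndarray          # (n, 3) mm
    stress_mm: float            # max |d_ij - ||p_i - p_j||| over known entries
    degenerate: bool = False


def _check_square_symmetric(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError("distance matrix must be square")
    off = ~np.eye(mat.shape[0], dtype=bool)
    known = off & np.isfinite(mat)
    if not np.allclose(mat[known], mat.T[known], rtol=0, atol=1e-9):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(mat[known] < 0):
        raise ValidationError("distances must be non-negative")
    return mat


def reconstruct_coordinates(
    frame: np.ndarray, layout: CrystalLayout | None = None
) -> EmbeddingResult:
    """Embed a symmetric distance matrix in 3-D by classical MDS.

    The squared-distance matrix is double-centred and eigendecomposed; the
    top three non-negative components give the coordinates.  Missing
    off-diagonal entries (NaN) are tolerated up to 20% and completed with
    graph shortest-path distances before embedding.  When ``layout`` is
    given (8 crystals), the returned frame is rotated to a fixed convention:
    annular centroid at the origin, the first ring crystal along +x within
    the annular plane, and the apex reference at negative z.

    Returns an :class:`EmbeddingResult`; an all-zero matrix yields
    coincident points with the ``degenerate`` flag set.
    """
    D = _check_square_symmetric(frame)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    missing = off & ~np.isfinite(D)
    if missing.sum() / off.sum() > 0.20:
        raise ReconstructionError(
            f"{missing.sum()} of {off.sum()} off-diagonal distances missing (> 20%)"
        )
    Dw = D.copy()
    np.fill_diagonal(Dw, 0.0)
    if missing.any():
        graph = np.where(np.isfinite(Dw), Dw, 0.0)
        Dw = shortest_path(graph, method="D", directed=False)
        if not np.all(np.isfinite(Dw)):
            raise ReconstructionError("missing-distance graph is disconnected")

    if np.allclose(Dw, 0.0):
        return EmbeddingResult(np.zeros((n, 3)), 0.0, degenerate=True)

    D2 = Dw**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:3]
    lam = np.clip(vals[idx], 0.0, None)
    X = vecs[:, idx] * np.sqrt(lam)

    if layout is not None and n == 8:
        X = _orient(X, layout)

    delta = np.abs(_pairwise(X) - Dw)
    stress = float(delta[off & ~missing].max())
    return EmbeddingResult(X, stress, degenerate=False)


def _pairwise(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def _orient(X: np.ndarray, layout: CrystalLayout) -> np.ndarray:
    """Rotate an 8-point embedding into the package's fixed annular frame."""
    ann = X[:6]
    centre = ann.mean(axis=0)
    Xc = X - centre
    # Annular plane normal = direction of least variance of the six ring points.
    _, _, vt = np.linalg.svd(Xc[:6], full_matrices=False)
    normal = vt[2]
    apex_idx = next(k for k, v in layout.references.items() if v == "apex") - 1
    if np.dot(Xc[apex_idx], normal) > 0:
        normal = -normal
    first = layout.ring_order[0] - 1
    xdir = Xc[first] - np.dot(Xc[first], normal) * normal
    nrm = np.linalg.norm(xdir)
    if nrm < 1e-12:  # first crystal sits on the axis; fall back to any in-plane dir
        xdir = vt[0]
    else:
        xdir = xdir / nrm
    ydir = np.cross(normal, xdir)
    R = np.vstack([xdir, ydir, normal])
    return Xc @ R.T


def annulus_area(points: np.ndarray, ring_order: tuple = DEFAULT_LAYOUT.ring_order) -> float:
    """Planar hexagon area (mm²) of the six annular crystals.

    A least-squares plane is fitted through the points (principal axes of
    their second moments), the points are orthogonally projected onto it,
    and the shoelace formula is applied in ring order.  Collinear points
    give zero area with a planarity warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (6, 3):
        raise ValidationError("annulus_area expects six 3-D points")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("annulus_area requires finite points")
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        warnings.warn("annular points are (near-)collinear; area set to 0", stacklevel=2)
        return 0.0
    uv = centred @ vt[:2].T  # in-plane coordinates
    order = [label - 1 for label in ring_order]
    u, v = uv[order, 0], uv[order, 1]
    return float(0.5 * abs(np.dot(u, np.roll(v, -1)) - np.dot(v, np.roll(u, -1))))


def _chord(frame: np.ndarray, a: int, b: int) -> float:
    d = frame[a - 1, b - 1]
    if not np.isfinite(d):
        raise CoverageError(f"distance d_{a}_{b} missing after interpolation")
    return float(d)


def ring_chords(frame: np.ndarray, layout: CrystalLayout = DEFAULT_LAYOUT) -> np.ndarray:
    """The six consecutive annular chords (mm) in ring order."""
    frame = _check_square_symmetric(frame)
    return np.array([_chord(frame, a, b) for a, b in layout.ring_chord_pairs])


def annulus_circumference(frame: np.ndarray, layout: CrystalLayout = DEFAULT_LAYOUT) -> float:
    """AAC (mm): sum of the six consecutive inter-crystal ring chords."""
    return float(ring_chords(frame, layout).sum())


def sinus_lengths(frame: np.ndarray, layout: CrystalLayout = DEFAULT_LAYOUT) -> dict:
    """NC/RC/LC sinus lengths (mm): the two ring chords flanking each nadir."""
    frame = _check_square_symmetric(frame)
    return {
        name: _chord(frame, *c1) + _chord(frame, *c2)
        for name, (c1, c2) in layout.sinus_chords.items()
    }


def cross_diameters(frame: np.ndarray, layout: CrystalLayout = DEFAULT_LAYOUT) -> dict:
    """The three nadir-to-opposite-commissure distances (mm)."""
    frame = _check_square_symmetric(frame)
    return {name: _chord(frame, a, b) for name, (a, b) in layout.diameter_pairs.items()}


def classify_shape(diameters, threshold_mm: float = OVALITY_THRESHOLD_MM) -> str:
    """'oval' iff the largest minus smallest cross diameter strictly exceeds the threshold."""
    vals = np.asarray(
        list(diameters.values()) if isinstance(diameters, dict) else diameters, dtype=float
    )
    if vals.size != 3 or not np.all(np.isfinite(vals)):
        raise ValidationError("classify_shape expects three finite diameters")
    return "oval" if (vals.max() - vals.min()) > threshold_mm else "round"


@dataclass
class GeometrySeries:
    """Per-frame annular geometry with excluded-frame bookkeeping."""

    frames: pd.DataFrame        # time_s, aaa_mm2, aac_mm, nc_mm, rc_mm, lc_mm,
                                # d14_mm, d25_mm, d36_mm, shape
    flagged: list               # (frame_index, reason) excluded from `frames`

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False, float_format="%.6f")


def geometry_series(aligned, layout: CrystalLayout = DEFAULT_LAYOUT,
                    ovality_threshold_mm: float = OVALITY_THRESHOLD_MM) -> GeometrySeries:
    """Apply the per-frame geometry to every frame of an aligned dataset.

    Frames still containing missing distances after gap interpolation are
    flagged and excluded.  Chord quantities come straight from the distance
    matrix; the area additionally runs the MDS embedding.
    """
    sono = aligned.sono
    rows = []
    flagged = list(aligned.flagged)
    already_bad = {idx for idx, _ in flagged}
    for i, t in enumerate(sono.timestamps):
        D = sono.distances[i]
        if i in already_bad or not _frame_complete(D):
            if i not in already_bad:
                flagged.append((i, "missing distances"))
            continue
        emb = reconstruct_coordinates(D, layout)
        aaa = 0.0 if emb.degenerate else annulus_area(emb.points[:6], layout.ring_order)
        chords = ring_chords(D, layout)
        sinus = sinus_lengths(D, layout)
        diam = cross_diameters(D, layout)
        rows.append(
            {
                "time_s": t,
                "aaa_mm2": aaa,
                "aac_mm": chords.sum(),
                "nc_mm": sinus["NC"],
                "rc_mm": sinus["RC"],
                "lc_mm": sinus["LC"],
                "d14_mm": diam["NC-LR"],
                "d25_mm": diam["RC-LN"],
                "d36_mm": diam["LC-RN"],
                "shape": classify_shape(diam, ovality_threshold_mm),
            }
        )
    if flagged:
        log.warning("geometry: %d frame(s) excluded", len(flagged))
    return GeometrySeries(pd.DataFrame(rows), sorted(flagged))


def _frame_complete(D: np.ndarray) -> bool:
    off = ~np.eye(D.shape[0], dtype=bool)
    return bool(np.all(np.isfinite(D[off])))


def pairwise_distance_matrix(points: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix of a point set, NaN on the diagonal."""
    D = _pairwise(np.asarray(points, dtype=float))
    np.fill_diagonal(D, np.nan)
    return D
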