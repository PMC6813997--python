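"""Geometric morphometrics: Procrustes alignment, sliding semilandmarks, PCA.

Specimens are 3-D landmark configurations (the study system is microCT-style
anatomical curves digitised as ordered semilandmark chains).  Generalised
Procrustes Analysis (GPA) removes position, scale and orientation;
semilandmarks may then slide along their local tangent direction to minimise
the Procrustes distance to the consensus; a PCA of the aligned (tangent
space) coordinates yields the shape-space scores consumed by the
phylogenetic analyses.

Rotations are proper (determinant +1): reflections are never introduced by
the alignment, so chirality must be standardised upstream.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet",
    "SemilandmarkScheme",
    "AlignedShapes",
    "ShapeSpace",
    "MorphometricsError",
    "gpa",
    "slide_semilandmarks",
    "shape_pca",
    "read_pts",
    "write_pts",
]


class MorphometricsError(ValueError):
    pass


@dataclasses.dataclass
class LandmarkSet:
    """Per-specimen 3-D landmark configurations.

    ``coords`` has shape ``(n_specimens, n_landmarks, 3)`` in arbitrary
    physical units; all specimens share the same landmark count and order.
    """

    labels: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise MorphometricsError(
                f"coords must be (specimens, landmarks, 3), got {self.coords.shape}"
            )
        if self.coords.shape[1] < 3:
            raise MorphometricsError("need at least 3 landmarks")
        if len(self.labels) != self.coords.shape[0]:
            raise MorphometricsError("label count != specimen count")
        if not np.all(np.isfinite(self.coords)):
            raise MorphometricsError("missing or non-finite coordinates")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]


@dataclasses.dataclass
class SemilandmarkScheme:
    """Ordered landmark-index curves whose interior points may slide.

    ``curves`` lists each curve as a sequence of landmark indices (length
    >= 3); ``fixed_endpoints`` flags, per curve, whether the first and last
    points are anchored (never slide).
    """

    curves: list[list[int]]
    fixed_endpoints: list[bool] | None = None

    def __post_init__(self) -> None:
        if self.fixed_endpoints is None:
            self.fixed_endpoints = [True] * len(self.curves)
        if len(self.fixed_endpoints) != len(self.curves):
            raise MorphometricsError("fixed_endpoints length != curve count")
        seen: dict[int, int] = {}
        for ci, curve in enumerate(self.curves):
            if len(curve) < 3:
                raise MorphometricsError(f"curve {ci} has fewer than 3 points")
            for pos, k in enumerate(curve):
                interior = 0 < pos < len(curve) - 1
                if k in seen and (interior or seen[k]):
                    raise MorphometricsError(
                        f"landmark {k} shared between curves at a non-endpoint"
                    )
                seen[k] = interior

    @property
    def n_landmarks(self) -> int:
        return sum(len(c) for c in self.curves)

    def validate_for(self, n_landmarks: int) -> None:
        top = max(max(c) for c in self.curves)
        if top >= n_landmarks:
            raise MorphometricsError(
                f"scheme indexes landmark {top} but set has {n_landmarks}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {"curves": self.curves, "fixed_endpoints": self.fixed_endpoints}
        )

    @staticmethod
    def from_json(text: str) -> "SemilandmarkScheme":
        d = json.loads(text)
        return SemilandmarkScheme(
            curves=[list(map(int, c)) for c in d["curves"]],
            fixed_endpoints=list(d.get("fixed_endpoints") or []) or None,
        )


@dataclasses.dataclass
class AlignedShapes:
    """GPA output: unit-centroid-size, origin-centred, rotated specimens."""

    labels: list[str]
    coords: np.ndarray  # (n, L, 3), dimensionless
    consensus: np.ndarray  # (L, 3)
    centroid_sizes: np.ndarray  # (n,), original units
    n_iterations: int
    converged: bool
    # per-specimen transform mapping raw -> aligned:
    # aligned = ((raw - translation) / scale) @ rotation
    translations: np.ndarray | None = None
    scales: np.ndarray | None = None
    rotations: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Flattened aligned coordinates (specimens x 3L), CSV-friendly."""
        L = self.coords.shape[1]
        cols = [f"{ax}{k + 1}" for k in range(L) for ax in ("x", "y", "z")]
        return pd.DataFrame(
            self.coords.reshape(self.coords.shape[0], -1),
            index=self.labels,
            columns=cols,
        )


@dataclasses.dataclass
class ShapeSpace:
    """PCA of aligned shapes: scores, eigenvalues and percent variance."""

    labels: list[str]
    scores: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,)
    variance_pct: np.ndarray  # (k,), sums to 100
    loadings: np.ndarray  # (3L, k)
    mean: np.ndarray  # (3L,)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.labels, columns=cols)


# ----------------------------------------------------------------------


def _centroid_size(x: np.ndarray) -> float:
    c = x.mean(axis=0)
    return float(np.sqrt(((x - c) ** 2).sum()))


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares proper rotation (det +1) aligning x to target (Kabsch)."""
    H = x.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def gpa(
    landmarks: LandmarkSet,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedShapes:
    """Generalised Procrustes alignment of a landmark set.

    Iteratively centres each specimen, scales it to unit centroid size,
    rotates it onto the current consensus, and re-estimates the consensus
    (itself centred and scaled to unit size), until the consensus moves by
    less than ``tol`` in root-sum-of-squares or ``max_iter`` is reached.
    """
    X = landmarks.coords.copy()
    n = X.shape[0]
    translations = X.mean(axis=1)
    sizes = np.empty(n)
    for i in range(n):
        X[i] -= translations[i]
        s = np.sqrt((X[i] ** 2).sum())
        if s <= 0:
            raise MorphometricsError(
                f"degenerate specimen {landmarks.labels[i]!r}: zero centroid size"
            )
        sizes[i] = s
        X[i] /= s
    rotations = np.tile(np.eye(3), (n, 1, 1))
    consensus = X[0].copy()
    n_it, converged = 0, False
    for n_it in range(1, max_iter + 1):
        for i in range(n):
            R = _optimal_rotation(X[i], consensus)
            X[i] = X[i] @ R
            rotations[i] = rotations[i] @ R
        new_cons = X.mean(axis=0)
        new_cons -= new_cons.mean(axis=0)
        norm = np.sqrt((new_cons**2).sum())
        if norm <= 0:
            raise MorphometricsError("degenerate consensus (all shapes cancel)")
        new_cons /= norm
        delta = np.sqrt(((new_cons - consensus) ** 2).sum())
        consensus = new_cons
        if delta < tol:
            converged = True
            break
    return AlignedShapes(
        labels=list(landmarks.labels),
        coords=X,
        # reported consensus is the plain arithmetic mean of the aligned
        # specimens (the unit-size copy is only the internal reference)
        consensus=X.mean(axis=0),
        centroid_sizes=sizes,
        n_iterations=n_it,
        converged=converged,
        translations=translations,
        scales=sizes,
        rotations=rotations,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root-sum-of-squares distance between two aligned configurations."""
    return float(np.sqrt(((a - b) ** 2).sum()))


def slide_semilandmarks(
    landmarks: LandmarkSet,
    scheme: SemilandmarkScheme,
    n_outer: int = 3,
) -> LandmarkSet:
    """Slide semilandmarks along their tangents toward the consensus.

    The outer loop alternates a GPA (to estimate the consensus) with a
    sliding pass.  Each non-anchored semilandmark moves only along its
    local tangent — the chord between its two curve neighbours — to the
    point minimising its distance to the consensus landmark (closed-form
    1-D projection).  Sliding is applied in each specimen's ORIGINAL
    coordinate frame (the consensus is carried back through the inverse
    Procrustes transform), so anchored landmarks are bit-identical before
    and after, and the Procrustes distance of each specimen to the
    consensus never increases within a sliding pass.
    """
    scheme.validate_for(landmarks.n_landmarks)
    X = landmarks.coords.copy()
    n = X.shape[0]
    for _ in range(n_outer):
        aligned = gpa(LandmarkSet(labels=list(landmarks.labels), coords=X))
        for i in range(n):
            # consensus mapped into specimen i's original frame
            Ri = aligned.rotations[i]
            target = aligned.consensus @ Ri.T * aligned.scales[i] + aligned.translations[i]
            _slide_one(X[i], target, scheme)
    return LandmarkSet(labels=list(landmarks.labels), coords=X)


def _slide_one(x: np.ndarray, target: np.ndarray, scheme: SemilandmarkScheme) -> None:
    scale = np.sqrt(((x - x.mean(axis=0)) ** 2).sum())
    for ci, curve in enumerate(scheme.curves):
        fixed = scheme.fixed_endpoints[ci]
        for pos in range(len(curve)):
            endpoint = pos in (0, len(curve) - 1)
            if endpoint and fixed:
                continue
            k = curve[pos]
            if endpoint:
                nb = curve[1] if pos == 0 else curve[-2]
                tangent = x[nb] - x[k]
            else:
                tangent = x[curve[pos + 1]] - x[curve[pos - 1]]
            norm = np.linalg.norm(tangent)
            if norm <= 1e-9 * scale:
                raise MorphometricsError(
                    f"zero tangent at curve {ci}, position {pos} (coincident neighbours)"
                )
            t = tangent / norm
            x[k] = x[k] + ((target[k] - x[k]) @ t) * t


def shape_pca(aligned: AlignedShapes) -> ShapeSpace:
    """PCA of the flattened aligned coordinates.

    Components are the eigenvectors of the coordinate covariance; at most
    ``min(n_specimens - 1, 3L)`` are non-degenerate.  Each component's sign
    is fixed so that its largest-magnitude loading is positive, making
    scores deterministic across platforms.
    """
    n = aligned.coords.shape[0]
    if n < 2:
        raise MorphometricsError("PCA needs at least 2 specimens")
    Xf = aligned.coords.reshape(n, -1)
    mean = Xf.mean(axis=0)
    Xc = Xf - mean
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = sv**2 / (n - 1)
    total = eig.sum()
    keep = eig > max(1e-12 * eig[0] if eig.size else 0.0, 0.0)
    k = int(np.count_nonzero(keep))
    U, sv, Vt, eig = U[:, :k], sv[:k], Vt[:k], eig[:k]
    # deterministic sign: largest |loading| positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * sv
    return ShapeSpace(
        labels=list(aligned.labels),
        scores=scores,
        eigenvalues=eig,
        variance_pct=100.0 * eig / total,
        loadings=Vt.T,
        mean=mean,
    )


# ----------------------------------------------------------------------
# .pts I/O — whitespace-separated "label x y z" lines, '#' comments


def read_pts(path) -> tuple[list[str], np.ndarray]:
    """Read one specimen's landmarks from a .pts file.

    Returns ``(point_labels, coords)`` with coords of shape ``(L, 3)``;
    file order defines the landmark (and hence curve) indexing.
    """
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise MorphometricsError(
                    f"{path}:{lineno}: expected 'label x y z', got {line!r}"
                )
            try:
                rows.append([float(p) for p in parts[1:]])
            except ValueError:
                raise MorphometricsError(
                    f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                ) from None
            labels.append(parts[0])
    if not rows:
        raise MorphometricsError(f"{path}: no landmark lines")
    return labels, np.asarray(rows, dtype=float)


def write_pts(path, coords: np.ndarray, point_labels: Sequence[str] | None = None) -> None:
    """Write one specimen's landmarks in the .pts dialect."""
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        for k, (x, y, z) in enumerate(coords):
            lab = point_labels[k] if point_labels is not None else f"p{k + 1}"
            fh.write(f"{lab} {x:.17g} {y:.17g} {z:.17g}\n")


def load_landmark_dir(paths: Sequence, labels: Sequence[str]) -> LandmarkSet:
    """Assemble a LandmarkSet from per-specimen .pts files."""
    arrs = []
    for p in paths:
        _, c = read_pts(p)
        arrs.append(c)
    counts = {a.shape[0] for a in arrs}
    if len(counts) != 1:
        raise MorphometricsError(f"inconsistent landmark counts across files: {sorted(counts)}")
    return LandmarkSet(labels=list(labels), coords=np.stack(arrs))
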