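"""Internal-coordinate geometry of Cα traces.

A peptide conformation is represented here purely by its Cα atoms, the
standard coarse-grained view for disordered-protein ensemble modeling.
This module provides the internal-coordinate featurization that everything
else builds on: pairwise Cα-Cα distances, the pseudo-torsion ("α") angles
defined by four consecutive Cα atoms, radius of gyration, ensemble contact
frequencies, rigid-motion/reflection utilities, and a per-sequence-separation
distance standardizer used to put reconstruction losses on a common scale.

Distances and α torsions together determine a chain up to a global rigid
motion (distances alone leave the mirror image ambiguous; the torsion signs
break that reflection symmetry).  Units are Å throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Conformation",
    "Ensemble",
    "TorsionFeatures",
    "DistanceScaler",
    "InvalidTransformError",
    "DegenerateScalerError",
    "pairwise_distances",
    "pair_separations",
    "alpha_torsions",
    "radius_of_gyration",
    "contact_frequencies",
    "apply_rigid_transform",
    "mirror",
    "random_rotation",
    "fit_distance_scaler",
    "canonical_coordinates",
    "CANONICAL_AA",
]

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"


class InvalidTransformError(ValueError):
    """Raised when a transform is not a proper rotation (det +1, orthogonal)."""


class DegenerateScalerError(ValueError):
    """Raised when a separation bin has zero distance variance."""


@dataclass(frozen=True)
class Conformation:
    """A single Cα trace: L×3 coordinates in Å."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be L×3, got shape {coords.shape}")
        if coords.shape[0] < 2:
            raise ValueError("a conformation needs at least 2 Cα atoms")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if np.any(bonds <= 0.0):
            raise ValueError("consecutive Cα atoms must not coincide")
        object.__setattr__(self, "coords", coords)

    @property
    def length(self) -> int:
        return self.coords.shape[0]


@dataclass
class Ensemble:
    """N equal-length conformations of one peptide plus its sequence.

    ``coords`` is the stacked N×L×3 array; ``labels`` optionally carries
    per-frame ground-truth state labels from synthetic generators (used in
    parameter-recovery tests, never fed to models).
    """

    sequence: str
    coords: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be N×L×3, got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one conformation")
        bad = set(self.sequence) - set(CANONICAL_AA)
        if bad:
            raise ValueError(f"non-canonical residue letters: {sorted(bad)}")
        if len(self.sequence) != self.coords.shape[1]:
            raise ValueError(
                f"sequence length {len(self.sequence)} != chain length "
                f"{self.coords.shape[1]}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.coords.shape[0]:
                raise ValueError("labels must have one entry per frame")

    @property
    def n_conformations(self) -> int:
        return self.coords.shape[0]

    @property
    def length(self) -> int:
        return self.coords.shape[1]

    @property
    def conformations(self) -> list[Conformation]:
        return [Conformation(c) for c in self.coords]

    def __len__(self) -> int:
        return self.n_conformations


@dataclass(frozen=True)
class TorsionFeatures:
    """α pseudo-torsion angles of a chain and their (cos, sin) unit vectors.

    Angles are in degrees on (−180, 180], IUPAC sign convention; there are
    L−3 of them for a chain of L residues.
    """

    angles: np.ndarray
    unit_vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.unit_vectors.shape != (self.angles.shape[0], 2):
            raise ValueError("unit_vectors must be (L-3)×2")
        norms = np.linalg.norm(self.unit_vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("torsion unit vectors must have unit norm")


def _as_coords(conf: Conformation | np.ndarray) -> np.ndarray:
    if isinstance(conf, Conformation):
        return conf.coords
    return np.asarray(conf, dtype=np.float64)


def pairwise_distances(conf: Conformation | np.ndarray) -> np.ndarray:
    """All L(L−1)/2 Cα-Cα distances, ordered by (i, j) with i < j.

    Invariant under any rigid motion or reflection of the chain.
    """
    x = _as_coords(conf)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 atoms for pairwise distances")
    iu, ju = np.triu_indices(x.shape[0], k=1)
    return np.linalg.norm(x[iu] - x[ju], axis=1)


def pair_separations(length: int) -> np.ndarray:
    """Sequence separations |i−j| in the same (i, j), i<j order as distances."""
    iu, ju = np.triu_indices(length, k=1)
    return ju - iu


def alpha_torsions(conf: Conformation | np.ndarray) -> TorsionFeatures:
    """α pseudo-torsions: the dihedral of each run of four consecutive Cα.

    Values near +50–60° indicate right-handed helical backbone geometry;
    the sign flips under a mirror reflection of the chain.
    """
    x = _as_coords(conf)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 atoms for α torsions")
    b1 = x[1:-2] - x[:-3]
    b2 = x[2:-1] - x[1:-2]
    b3 = x[3:] - x[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    cos_raw = np.einsum("ij,ij->i", n1, n2)
    # sign such that a right-handed helix has positive torsion
    sin_raw = -np.einsum("ij,ij->i", m, n2)
    angles = np.degrees(np.arctan2(sin_raw, cos_raw))
    # map -180 -> +180 to keep the half-open (−180, 180] convention
    angles = np.where(angles <= -180.0, angles + 360.0, angles)
    rad = np.radians(angles)
    unit = np.stack([np.cos(rad), np.sin(rad)], axis=1)
    return TorsionFeatures(angles=angles, unit_vectors=unit)


def radius_of_gyration(conf: Conformation | np.ndarray) -> float:
    """Root-mean-square distance of the Cα atoms from their centroid (Å)."""
    x = _as_coords(conf)
    centered = x - x.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def ensemble_rg(ens: Ensemble) -> np.ndarray:
    """Per-frame radius of gyration for a whole ensemble."""
    centered = ens.coords - ens.coords.mean(axis=1, keepdims=True)
    return np.sqrt(np.mean(np.sum(centered**2, axis=2), axis=1))


def contact_frequencies(ens: Ensemble, threshold: float = 8.0) -> np.ndarray:
    """L×L symmetric matrix of contact frequencies at the given threshold.

    A contact is a Cα pair closer than ``threshold`` Å (8 Å default). The
    diagonal is set to 1 by convention. Which |i−j| ranges enter a score is
    a policy of the evaluation layer, not of this function.
    """
    if ens.n_conformations < 1:
        raise ValueError("empty ensemble")
    diff = ens.coords[:, :, None, :] - ens.coords[:, None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=3))
    freq = np.mean(dist < threshold, axis=0)
    np.fill_diagonal(freq, 1.0)
    return freq


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=np.float64)
    if rotation.shape != (3, 3):
        raise InvalidTransformError("rotation must be 3×3")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
        raise InvalidTransformError("rotation must be orthogonal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-8):
        raise InvalidTransformError(
            "rotation determinant must be +1 (reflections are not rigid motions)"
        )
    return rotation


def apply_rigid_transform(
    conf: Conformation,
    rotation: np.ndarray,
    translation: np.ndarray,
) -> Conformation:
    """Apply a proper rigid motion x ↦ R·x + t to a conformation."""
    rotation = _check_rotation(rotation)
    translation = np.asarray(translation, dtype=np.float64).reshape(3)
    return Conformation(conf.coords @ rotation.T + translation)


def mirror(conf: Conformation) -> Conformation:
    """Reflect the chain through the z=0 plane.

    Distances are preserved, every α torsion changes sign: this is the
    chirality probe used to show that distance-only losses cannot tell a
    chain from its mirror image.
    """
    return Conformation(conf.coords * np.array([1.0, 1.0, -1.0]))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@dataclass
class DistanceScaler:
    """Per-sequence-separation affine standardizer for Cα-Cα distances.

    For each separation k = |i−j| (clamped at ``k_max``) the scaler stores
    the training mean and standard deviation of the distances at that
    separation; ``apply`` maps d ↦ (d − mean_k)/scale_k. Standardizing per
    separation keeps the distance reconstruction loss on a comparable scale
    for near and far pairs.
    """

    mean: np.ndarray
    scale: np.ndarray
    k_max: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)
        if self.mean.shape != (self.k_max,) or self.scale.shape != (self.k_max,):
            raise ValueError("mean/scale must have one entry per separation 1..k_max")
        if np.any(self.scale <= 0):
            raise DegenerateScalerError("all scales must be positive")

    def _index(self, k: np.ndarray | int) -> np.ndarray:
        k = np.asarray(k)
        if np.any(k < 1):
            raise ValueError("separations must be >= 1")
        return np.minimum(k, self.k_max) - 1

    def apply(self, d: np.ndarray | float, k: np.ndarray | int) -> np.ndarray:
        idx = self._index(k)
        return (np.asarray(d, dtype=np.float64) - self.mean[idx]) / self.scale[idx]

    def invert(self, v: np.ndarray | float, k: np.ndarray | int) -> np.ndarray:
        idx = self._index(k)
        return np.asarray(v, dtype=np.float64) * self.scale[idx] + self.mean[idx]

    def pair_params(self, length: int) -> tuple[np.ndarray, np.ndarray]:
        """Mean/scale vectors aligned with the flat (i<j) pair ordering."""
        idx = self._index(pair_separations(length))
        return self.mean[idx], self.scale[idx]

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "k_max": int(self.k_max),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistanceScaler":
        return cls(
            mean=np.asarray(d["mean"]), scale=np.asarray(d["scale"]), k_max=d["k_max"]
        )


def fit_distance_scaler(
    training: list[Ensemble] | Ensemble, k_max: int = 50
) -> DistanceScaler:
    """Fit the per-separation distance standardizer on training ensembles.

    Raises :class:`DegenerateScalerError` (naming the bin) if any observed
    separation bin has zero distance variance.
    """
    if isinstance(training, Ensemble):
        training = [training]
    if not training:
        raise ValueError("need at least one training ensemble")
    k_cap = min(k_max, max(e.length for e in training) - 1)
    sums = np.zeros(k_cap)
    sqsums = np.zeros(k_cap)
    counts = np.zeros(k_cap)
    for ens in training:
        seps = np.minimum(pair_separations(ens.length), k_cap) - 1
        iu, ju = np.triu_indices(ens.length, k=1)
        d = np.linalg.norm(ens.coords[:, iu] - ens.coords[:, ju], axis=2)
        for k in range(k_cap):
            mask = seps == k
            if not mask.any():
                continue
            vals = d[:, mask]
            sums[k] += vals.sum()
            sqsums[k] += (vals**2).sum()
            counts[k] += vals.size
    if np.any(counts < 2):
        missing = np.nonzero(counts < 2)[0] + 1
        raise ValueError(f"separation bins with <2 observations: {missing.tolist()}")
    mean = sums / counts
    var = sqsums / counts - mean**2
    var = np.maximum(var, 0.0)
    zero = np.nonzero(var <= 0.0)[0]
    if zero.size:
        raise DegenerateScalerError(
            f"zero distance variance at separation bin(s) {(zero + 1).tolist()}"
        )
    # ddof-1 correction so scaled training data has unit sample variance
    scale = np.sqrt(var * counts / (counts - 1))
    return DistanceScaler(mean=mean, scale=scale, k_max=k_cap)


def batch_pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise distances for a whole batch: (B, L, 3) → (B, L(L−1)/2)."""
    coords = np.asarray(coords, dtype=np.float64)
    iu, ju = np.triu_indices(coords.shape[1], k=1)
    return np.linalg.norm(coords[:, iu] - coords[:, ju], axis=2)


def batch_alpha_torsions(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """α torsions for a batch: (B, L, 3) → angles (B, L−3), units (B, L−3, 2)."""
    x = np.asarray(coords, dtype=np.float64)
    if x.shape[1] < 4:
        raise ValueError("need at least 4 atoms for α torsions")
    b1 = x[:, 1:-2] - x[:, :-3]
    b2 = x[:, 2:-1] - x[:, 1:-2]
    b3 = x[:, 3:] - x[:, 2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=2, keepdims=True))
    cos_raw = np.einsum("bij,bij->bi", n1, n2)
    sin_raw = -np.einsum("bij,bij->bi", m, n2)
    angles = np.degrees(np.arctan2(sin_raw, cos_raw))
    angles = np.where(angles <= -180.0, angles + 360.0, angles)
    rad = np.radians(angles)
    return angles, np.stack([np.cos(rad), np.sin(rad)], axis=2)


def canonical_coordinates_batch(coords: np.ndarray) -> np.ndarray:
    """Batched canonical-frame rebuild; see :func:`canonical_coordinates`."""
    x = np.asarray(coords, dtype=np.float64)
    B, L = x.shape[0], x.shape[1]
    if L < 4:
        raise ValueError("need at least 4 atoms for canonical coordinates")
    bonds = np.linalg.norm(np.diff(x, axis=1), axis=2)  # (B, L-1)
    d13 = np.linalg.norm(x[:, 2:] - x[:, :-2], axis=2)  # (B, L-2)
    cos_theta = (bonds[:, :-1] ** 2 + bonds[:, 1:] ** 2 - d13**2) / (
        2.0 * bonds[:, :-1] * bonds[:, 1:]
    )
    theta = np.arccos(np.clip(cos_theta, -1.0, 1.0))
    tors = np.radians(batch_alpha_torsions(x)[0])  # (B, L-3)

    out = np.zeros((B, L, 3))
    out[:, 1, 0] = bonds[:, 0]
    out[:, 2] = out[:, 1] + bonds[:, 1, None] * np.stack(
        [-np.cos(theta[:, 0]), np.sin(theta[:, 0]), np.zeros(B)], axis=1
    )
    for i in range(3, L):
        b, th, phi = bonds[:, i - 1], theta[:, i - 2], tors[:, i - 3]
        d2 = b[:, None] * np.stack(
            [-np.cos(th), np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi)],
            axis=1,
        )
        bc = out[:, i - 1] - out[:, i - 2]
        bc /= np.linalg.norm(bc, axis=1, keepdims=True)
        n = np.cross(out[:, i - 2] - out[:, i - 3], bc)
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        frame = np.stack([bc, np.cross(n, bc), n], axis=2)
        out[:, i] = out[:, i - 1] + np.einsum("bij,bj->bi", frame, d2)
    return out - out.mean(axis=1, keepdims=True)


def canonical_coordinates(conf: Conformation | np.ndarray) -> np.ndarray:
    """Rebuild the chain in a canonical frame from internal coordinates only.

    Uses the bond lengths d(i,i+1), the planar angles implied by d(i,i+2),
    and the α torsions to place atoms sequentially (internal-to-Cartesian
    chain building), then centers the result on its centroid.  Because the
    inputs are the distance matrix and torsions alone, the output is exactly
    invariant under any proper rigid motion of the original conformation,
    while a mirrored input yields a genuinely different (mirrored) result.
    Requires L ≥ 4.
    """
    x = _as_coords(conf)
    return canonical_coordinates_batch(x[None])[0]
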