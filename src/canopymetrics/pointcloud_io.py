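"""Point-cloud text I/O and homogeneous coordinate transforms.

Single-tree TLS clouds are stored as plain text, one point per line,
``x y z [intensity]``, whitespace separated, meters, z-up. Scanning projects
are registered in a local project frame; a 4x4 homogeneous matrix maps
project coordinates to global (geocentric) coordinates::

    [X0 Y0 Z0 1]^T  =  M . [Xi Yi Zi 1]^T

with the rotation/scale block in rows 1-3, the translation in column 4 and
last row (0, 0, 0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PointCloudParseError, TransformFormatError

__all__ = [
    "PointCloud",
    "AffineTransform",
    "read_xyzi",
    "write_xyzi",
    "read_transform",
    "apply_transform",
]


@dataclass(frozen=True)
class PointCloud:
    """An ordered collection of 3D points with optional per-point intensity.

    Attributes
    ----------
    xyz : (n, 3) float array, meters, z-up.
    intensity : (n,) float array or None. Units are scanner-specific and
        passed through opaquely.
    """

    xyz: np.ndarray
    intensity: np.ndarray | None = None

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=np.float64)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ValueError(f"xyz must have shape (n, 3), got {xyz.shape}")
        if xyz.size and not np.all(np.isfinite(xyz)):
            raise ValueError("point coordinates must be finite")
        object.__setattr__(self, "xyz", xyz)
        if self.intensity is not None:
            inten = np.asarray(self.intensity, dtype=np.float64)
            if inten.shape != (xyz.shape[0],):
                raise ValueError(
                    "intensity must have exactly one value per point"
                )
            object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def take(self, index) -> "PointCloud":
        """Subset by integer indices or boolean mask, order preserved."""
        inten = None if self.intensity is None else self.intensity[index]
        return PointCloud(self.xyz[index], inten)

    @classmethod
    def empty(cls) -> "PointCloud":
        return cls(np.empty((0, 3)))


@dataclass(frozen=True)
class AffineTransform:
    """A 4x4 homogeneous project-to-global coordinate transform."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise TransformFormatError(f"matrix must be 4x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise TransformFormatError("matrix entries must be finite")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise TransformFormatError(
                f"last row must be (0, 0, 0, 1), got {m[3].tolist()}"
            )
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise TransformFormatError("upper-left 3x3 block is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array or a single (3,) point."""
        pts = np.asarray(xyz, dtype=np.float64)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if single else out

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        inv[3] = [0.0, 0.0, 0.0, 1.0]
        return AffineTransform(inv)

    def compose(self, first: "AffineTransform") -> "AffineTransform":
        """Transform equivalent to applying `first`, then `self`."""
        return AffineTransform(self.matrix @ first.matrix)

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return self.compose(other)

    def to_file(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.17g")


def read_xyzi(path) -> PointCloud:
    """Read a ``x y z [intensity]`` text file into a :class:`PointCloud`.

    Intensity is populated iff every non-blank line carries a 4th field.
    An empty file yields an empty cloud. Malformed lines raise
    :class:`PointCloudParseError` naming the 1-based line number.
    """
    coords: list[list[float]] = []
    intensities: list[float] = []
    all_have_intensity = True
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) not in (3, 4):
                raise PointCloudParseError(
                    lineno, f"expected 3 or 4 fields, got {len(fields)}"
                )
            try:
                values = [float(v) for v in fields]
            except ValueError:
                raise PointCloudParseError(
                    lineno, f"non-numeric field in {line.strip()!r}"
                ) from None
            coords.append(values[:3])
            if len(values) == 4:
                intensities.append(values[3])
            else:
                all_have_intensity = False
    xyz = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    inten = (
        np.asarray(intensities) if (all_have_intensity and coords) else None
    )
    return PointCloud(xyz, inten)


def write_xyzi(cloud: PointCloud, path) -> None:
    """Write a cloud as ``x y z [intensity]`` text (>= 12 significant digits)."""
    if cloud.intensity is None:
        data = cloud.xyz
    else:
        data = np.column_stack([cloud.xyz, cloud.intensity])
    with open(path, "w") as fh:
        for row in data:
            fh.write(" ".join(f"{v:.12g}" for v in row))
            fh.write("\n")


def read_transform(path) -> AffineTransform:
    """Read a whitespace-delimited row-major 4x4 matrix file.

    Lines starting with ``#`` are comments. The file must hold exactly 16
    numbers and the last row must be (0, 0, 0, 1).
    """
    values: list[float] = []
    with open(path, "r") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            for tok in stripped.split():
                try:
                    values.append(float(tok))
                except ValueError:
                    raise TransformFormatError(
                        f"non-numeric token {tok!r} in {path}"
                    ) from None
    if len(values) != 16:
        raise TransformFormatError(
            f"expected 16 numbers (4x4), got {len(values)} in {path}"
        )
    return AffineTransform(np.asarray(values).reshape(4, 4))


def apply_transform(obj, transform: AffineTransform):
    """Apply a transform to a :class:`PointCloud` or a point array.

    Returns the same type as the input; intensity is carried through
    unchanged.
    """
    if isinstance(obj, PointCloud):
        return PointCloud(transform.apply(obj.xyz), obj.intensity)
    return transform.apply(obj)
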