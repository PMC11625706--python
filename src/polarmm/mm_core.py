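"""Mueller-matrix data model: containers, normalization, validation, reconstruction, I/O.

The whole package uses one convention: Stokes basis (I, Q, U, V) with
horizontal linear polarization = +Q. A Mueller image stores a per-pixel
4x4 real matrix; the 16 channels are serialized row-major
(m11, m12, ..., m44) in files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: row-major element names, matching the on-disk page order
ELEMENT_NAMES: tuple[str, ...] = tuple(f"m{i}{j}" for i in range(1, 5) for j in range(1, 5))
ELEMENT_ORDER = ",".join(ELEMENT_NAMES)


class EmptyForegroundError(ValueError):
    """No foreground pixel survives background masking."""


class RankDeficientError(ValueError):
    """Generator state set is rank-deficient; the instrument matrix cannot be inverted."""


@dataclass
class MuellerImage:
    """Per-pixel 4x4 real Mueller matrix on an image grid.

    Parameters
    ----------
    elements:
        Array of shape (H, W, 4, 4). A bare (4, 4) matrix is promoted to a
        1x1 image.
    normalized:
        True iff m11 == 1 at every non-background pixel.
    wavelength_nm:
        Illumination wavelength metadata (default 633 nm).
    """

    elements: np.ndarray
    normalized: bool = False
    wavelength_nm: float = 633.0

    def __post_init__(self) -> None:
        el = np.asarray(self.elements, dtype=float)
        if el.shape == (4, 4):
            el = el.reshape(1, 1, 4, 4)
        if el.ndim != 4 or el.shape[-2:] != (4, 4):
            raise ValueError(f"elements must have shape (H, W, 4, 4), got {el.shape}")
        self.elements = el

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, **kw) -> "MuellerImage":
        return cls(np.asarray(matrix, dtype=float).reshape(1, 1, 4, 4), **kw)

    @classmethod
    def from_flat(cls, flat: np.ndarray, **kw) -> "MuellerImage":
        """Build from a (16, H, W) channel stack in row-major element order."""
        flat = np.asarray(flat, dtype=float)
        if flat.ndim != 3 or flat.shape[0] != 16:
            raise ValueError(f"expected (16, H, W), got {flat.shape}")
        el = np.moveaxis(flat, 0, -1).reshape(flat.shape[1], flat.shape[2], 4, 4)
        return cls(el, **kw)

    def to_flat(self) -> np.ndarray:
        """Return the (16, H, W) channel stack in row-major element order."""
        h, w = self.height, self.width
        return np.moveaxis(self.elements.reshape(h, w, 16), -1, 0)

    @property
    def height(self) -> int:
        return self.elements.shape[0]

    @property
    def width(self) -> int:
        return self.elements.shape[1]

    @property
    def m11(self) -> np.ndarray:
        return self.elements[..., 0, 0]

    def element(self, i: int, j: int) -> np.ndarray:
        """Return the m_ij map, 1-based indices as in the optics literature."""
        if not (1 <= i <= 4 and 1 <= j <= 4):
            raise ValueError("element indices are 1-based in 1..4")
        return self.elements[..., i - 1, j - 1]

    def copy(self) -> "MuellerImage":
        return MuellerImage(self.elements.copy(), self.normalized, self.wavelength_nm)


@dataclass
class StokesSet:
    """Ordered set of Stokes vectors used as polarimeter generator/analyzer states."""

    states: np.ndarray  # (N, 4)
    role: str = "generator"

    def __post_init__(self) -> None:
        st = np.asarray(self.states, dtype=float)
        if st.ndim != 2 or st.shape[1] != 4:
            raise ValueError(f"states must have shape (N, 4), got {st.shape}")
        self.states = st

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """4xN state matrix [S] (states as columns)."""
        return self.states.T

    def validate(self, tol: float = 1e-9) -> None:
        s = self.states
        if np.any(s[:, 0] <= 0):
            raise ValueError("every Stokes state must have S0 > 0")
        dop2 = np.sum(s[:, 1:] ** 2, axis=1)
        if np.any(dop2 > s[:, 0] ** 2 * (1 + tol)):
            raise ValueError("unphysical Stokes state: S1^2+S2^2+S3^2 > S0^2")
        if self.role == "generator":
            if len(self) < 4:
                raise ValueError("generator set needs at least 4 states")
            if np.linalg.matrix_rank(self.matrix) < 4:
                raise RankDeficientError(
                    "generator state matrix is rank-deficient "
                    f"(condition number {np.linalg.cond(self.matrix):.3g})"
                )

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


# ---------------------------------------------------------------------------
# normalization / validation


def normalize_mm(
    image: MuellerImage, eps_air: float | None = None
) -> tuple[MuellerImage, np.ndarray]:
    """Divide every retained pixel by its m11; flag low-transmittance pixels as background.

    ``eps_air`` defaults to 5% of the 99th-percentile m11 of the image.
    Returns (normalized image, background mask); background pixels are left
    untouched.
    """
    m11 = image.m11
    if eps_air is None:
        eps_air = 0.05 * float(np.percentile(m11, 99))
    background = m11 <= eps_air
    if bool(background.all()):
        raise EmptyForegroundError("all pixels fall below the background threshold")
    out = image.elements.copy()
    fg = ~background
    out[fg] = out[fg] / m11[fg][:, None, None]
    return (
        MuellerImage(out, normalized=True, wavelength_nm=image.wavelength_nm),
        background,
    )


@dataclass
class MMDiagnostics:
    """Per-pixel validity flags produced by :func:`validate_mm`."""

    nonpositive_m11: np.ndarray
    element_exceeds_m11: np.ndarray

    @property
    def flagged(self) -> np.ndarray:
        return self.nonpositive_m11 | self.element_exceeds_m11

    @property
    def flagged_fraction(self) -> float:
        return float(self.flagged.mean())

    def as_frame(self):
        import pandas as pd

        n = self.flagged.size
        rows = [
            ("nonpositive_m11", int(self.nonpositive_m11.sum())),
            ("element_exceeds_m11", int(self.element_exceeds_m11.sum())),
            ("any_flag", int(self.flagged.sum())),
        ]
        return pd.DataFrame(
            [(k, c, c / n) for k, c in rows], columns=["check", "count", "fraction"]
        )


def validate_mm(image: MuellerImage, tol: float = 1e-9) -> MMDiagnostics:
    """Diagnostic passivity checks: m11 > 0 and |m_ij| <= m11 per pixel."""
    el = image.elements
    m11 = image.m11
    nonpos = m11 <= 0
    bound = np.abs(el) > (m11[..., None, None] * (1 + tol) + tol)
    return MMDiagnostics(nonpositive_m11=nonpos, element_exceeds_m11=bound.any(axis=(-2, -1)))


# ---------------------------------------------------------------------------
# reconstruction from polarimeter states


@dataclass
class ReconstructionResult:
    image: MuellerImage
    condition_number: float
    rms_residual: float


def reconstruct_mm(s_in: StokesSet, s_out, wavelength_nm: float = 633.0) -> ReconstructionResult:
    """Least-squares Mueller estimate from generator states and measured output states.

    Solves M [S_in] = [S_out]; exact inverse when N = 4, pseudo-inverse
    least squares otherwise. ``s_out`` is a StokesSet (single matrix), an
    (N, 4) array, or an (N, H, W, 4) per-pixel batch aligned with the
    generator states.
    """
    s_in.validate()
    a = s_in.matrix  # (4, N)
    cond = float(np.linalg.cond(a))
    if np.linalg.matrix_rank(a) < 4:
        raise RankDeficientError(
            f"generator state matrix is rank-deficient (condition number {cond:.3g})"
        )
    ap = np.linalg.pinv(a)  # (N, 4)

    if isinstance(s_out, StokesSet):
        s_out = s_out.states
    s_out = np.asarray(s_out, dtype=float)
    n = a.shape[1]
    if s_out.shape[0] != n or s_out.shape[-1] != 4:
        raise ValueError(f"s_out must have shape (N, ..., 4) with N={n}, got {s_out.shape}")

    if s_out.ndim == 2:
        m = s_out.T @ ap
        img = MuellerImage.from_matrix(m, wavelength_nm=wavelength_nm)
        resid = float(np.sqrt(np.mean((s_out.T - m @ a) ** 2)))
    elif s_out.ndim == 4:
        m = np.einsum("nhwi,nj->hwij", s_out, ap)
        img = MuellerImage(m, wavelength_nm=wavelength_nm)
        pred = np.einsum("hwij,jn->nhwi", m, a)
        resid = float(np.sqrt(np.mean((s_out - pred) ** 2)))
    else:
        raise ValueError("s_out must be 2-D (N,4) or 4-D (N,H,W,4)")
    return ReconstructionResult(image=img, condition_number=cond, rms_residual=resid)


# ---------------------------------------------------------------------------
# in-plane rotation


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """Stokes rotation matrix for an in-plane sample rotation by ``angle_deg``."""
    c, s = np.cos(2 * np.radians(angle_deg)), np.sin(2 * np.radians(angle_deg))
    return np.array(
        [[1, 0, 0, 0], [0, c, -s, 0], [0, s, c, 0], [0, 0, 0, 1]], dtype=float
    )


def rotate_mm(image: MuellerImage, angle_deg: float) -> MuellerImage:
    """Conjugate every pixel by the Stokes rotation: M -> R(a) M R(-a)."""
    r = rotation_matrix(angle_deg)
    el = np.einsum("ij,hwjk,kl->hwil", r, image.elements, rotation_matrix(-angle_deg))
    return MuellerImage(el, normalized=image.normalized, wavelength_nm=image.wavelength_nm)


# ---------------------------------------------------------------------------
# file I/O: multi-page TIFF + JSON sidecar, and a single-file .npz container


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_mueller_tiff(image: MuellerImage, path) -> Path:
    """Write 16 float32 pages (row-major element order) plus a JSON header sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, image.to_flat().astype(np.float32))
    header = {
        "height": image.height,
        "width": image.width,
        "normalized": bool(image.normalized),
        "wavelength_nm": image.wavelength_nm,
        "element_order": ELEMENT_ORDER,
    }
    _sidecar(path).write_text(json.dumps(header, indent=2))
    return path


def read_mueller_tiff(path) -> MuellerImage:
    import tifffile

    path = Path(path)
    flat = np.asarray(tifffile.imread(path), dtype=float)
    header = {}
    if _sidecar(path).exists():
        header = json.loads(_sidecar(path).read_text())
    return MuellerImage.from_flat(
        flat,
        normalized=bool(header.get("normalized", False)),
        wavelength_nm=float(header.get("wavelength_nm", 633.0)),
    )


def write_mueller_npz(image: MuellerImage, path) -> Path:
    path = Path(path)
    np.savez_compressed(
        path,
        elements=image.to_flat().astype(np.float32),
        normalized=np.array(image.normalized),
        wavelength_nm=np.array(image.wavelength_nm),
        element_order=np.array(ELEMENT_ORDER),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_mueller_npz(path) -> MuellerImage:
    with np.load(path) as z:
        return MuellerImage.from_flat(
            np.asarray(z["elements"], dtype=float),
            normalized=bool(z["normalized"]),
            wavelength_nm=float(z["wavelength_nm"]),
        )


def read_mueller(path) -> MuellerImage:
    path = Path(path)
    if path.suffix == ".npz":
        return read_mueller_npz(path)
    return read_mueller_tiff(path)


def write_mask_tiff(mask: np.ndarray, path) -> Path:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask) != 0).astype(np.uint8) * 255)
    return path


def read_mask(path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a ROI mask: 8-bit TIFF (nonzero = inside) or JSON rectangle list."""
    path = Path(path)
    if path.suffix == ".json":
        if shape is None:
            raise ValueError("shape required to rasterize JSON rectangle ROIs")
        rects = [Rect(**r) for r in json.loads(path.read_text())]
        mask = np.zeros(shape, dtype=bool)
        for r in rects:
            mask |= r.to_mask(*shape)
        return mask
    import tifffile

    return np.asarray(tifffile.imread(path)) != 0


@dataclass(frozen=True)
class Rect:
    """Rectangular ROI: x is the column offset, y the row offset."""

    x: int
    y: int
    w: int
    h: int

    def to_mask(self, height: int, width: int) -> np.ndarray:
        mask = np.zeros((height, width), dtype=bool)
        mask[self.y : self.y + self.h, self.x : self.x + self.w] = True
        return mask


def write_rois_json(rects: Sequence[Rect], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([vars(r) for r in rects], indent=2))
    return path
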