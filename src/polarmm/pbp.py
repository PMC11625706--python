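"""Polarization basic parameters (PBPs) per pixel.

Two families are extracted from a normalized Mueller image:

* Lu-Chipman polar decomposition (MMPD): M = M_dep . M_R . M_D, giving
  diattenuation D, overall depolarization Delta, linear retardance delta,
  optical rotation alpha, and the fast-axis orientation theta.
* Matrix-transformation (MMT) parameters: closed-form functions of the
  matrix elements (m14, m41, CD, m44, DL, PL, qL, rL, t1, A, |B|, ||B||,
  alpha_r).

Exactly 15 parameters are rotation-invariant; theta and alpha_r are
rotation-variant axial angles reported in degrees on [0, 180).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mm_core import MuellerImage

__all__ = [
    "ROTATION_INVARIANT",
    "ROTATION_VARIANT",
    "ALL_PBPS",
    "PARAM_RANGES",
    "MMPDResult",
    "MMTParams",
    "PBPStack",
    "mmpd",
    "mmt",
    "pbp_stack",
]

#: the 15 rotation-invariant parameter names (MMPD scalars + MMT family)
ROTATION_INVARIANT: tuple[str, ...] = (
    "D", "Delta", "delta",
    "m14", "m41", "CD", "m44",
    "DL", "PL", "qL", "rL",
    "t1", "A", "Bdet", "Bnorm",
)
#: axial angles that shift with in-plane sample rotation
ROTATION_VARIANT: tuple[str, ...] = ("theta", "alpha_r")
ALL_PBPS: tuple[str, ...] = ROTATION_INVARIANT + ROTATION_VARIANT

#: natural value ranges used as default histogram supports
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "D": (0.0, 1.0),
    "Delta": (0.0, 1.0),
    "delta": (0.0, math.pi),
    "m14": (-1.0, 1.0),
    "m41": (-1.0, 1.0),
    "CD": (-2.0, 2.0),
    "m44": (-1.0, 1.0),
    "DL": (0.0, 1.0),
    "PL": (0.0, 1.0),
    "qL": (0.0, 1.0),
    "rL": (0.0, 1.0),
    "t1": (0.0, 1.0),
    "A": (-1.0, 1.0),
    "Bdet": (-1.0, 1.0),
    "Bnorm": (0.0, 2.0),
    "theta": (0.0, 180.0),
    "alpha_r": (0.0, 180.0),
}

_DEGENERATE_DET = 1e-12


@dataclass
class MMPDResult:
    """Per-pixel Lu-Chipman factors and scalar parameters (NaN where undefined)."""

    M_D: np.ndarray
    M_dep: np.ndarray
    M_R: np.ndarray
    D: np.ndarray
    Delta: np.ndarray
    delta: np.ndarray
    alpha: np.ndarray
    theta: np.ndarray
    degenerate: np.ndarray


def _normalized_elements(image: MuellerImage) -> np.ndarray:
    el = image.elements
    if image.normalized:
        return el
    m11 = el[..., 0, 0]
    safe = np.where(m11 > 0, m11, 1.0)
    return el / safe[..., None, None]


def mmpd(image: MuellerImage, background: np.ndarray | None = None) -> MMPDResult:
    """Lu-Chipman polar decomposition of every foreground pixel.

    The diattenuator is built from the first row; the remainder splits
    into depolarizer and retarder through the eigen-decomposition of
    m'm'^T with the determinant-sign rule. Pixels with |det m'| <= 1e-12
    (fully depolarizing) are flagged degenerate and carry NaN parameters
    rather than raising.
    """
    el = _normalized_elements(image)
    h, w = el.shape[:2]
    if background is None:
        background = np.zeros((h, w), dtype=bool)
    fg = ~background
    m = el[fg]  # (P, 4, 4)
    p = m.shape[0]
    eye3 = np.eye(3)

    dvec = m[:, 0, 1:4]
    d = np.linalg.norm(dvec, axis=1)
    dc = np.clip(d, 0.0, 1.0 - 1e-12)
    k = np.sqrt(1.0 - dc**2)
    dhat = dvec / np.where(d > 0, d, 1.0)[:, None]
    md_small = k[:, None, None] * eye3 + (1 - k)[:, None, None] * np.einsum(
        "pi,pj->pij", dhat, dhat
    )
    m_d = np.zeros((p, 4, 4))
    m_d[:, 0, 0] = 1.0
    m_d[:, 0, 1:] = dvec
    m_d[:, 1:, 0] = dvec
    m_d[:, 1:, 1:] = md_small

    mprime = m @ np.linalg.inv(m_d)
    sub = mprime[:, 1:, 1:]
    det = np.linalg.det(sub)
    degenerate = np.abs(det) <= _DEGENERATE_DET

    g = sub @ np.transpose(sub, (0, 2, 1))
    lam = np.clip(np.linalg.eigvalsh(g), 0.0, None)  # ascending
    r3, r2, r1 = np.sqrt(lam[:, 0]), np.sqrt(lam[:, 1]), np.sqrt(lam[:, 2])
    c2 = r1 * r2 + r1 * r3 + r2 * r3
    c1 = r1 + r2 + r3
    c0 = r1 * r2 * r3
    sign = np.where(det < 0, -1.0, 1.0)
    lhs = g + c2[:, None, None] * eye3
    rhs = c1[:, None, None] * g + c0[:, None, None] * eye3
    # solve on non-degenerate pixels only; park identity elsewhere
    m_dep_small = np.broadcast_to(eye3, (p, 3, 3)).copy()
    ok = ~degenerate
    if ok.any():
        m_dep_small[ok] = sign[ok, None, None] * np.linalg.solve(lhs[ok], rhs[ok])
    m_dep = np.zeros((p, 4, 4))
    m_dep[:, 0, 0] = 1.0
    m_dep[:, 1:, 0] = mprime[:, 1:, 0]
    m_dep[:, 1:, 1:] = m_dep_small

    m_r_small = np.broadcast_to(eye3, (p, 3, 3)).copy()
    if ok.any():
        m_r_small[ok] = np.linalg.solve(m_dep_small[ok], sub[ok])
    m_r = np.zeros((p, 4, 4))
    m_r[:, 0, 0] = 1.0
    m_r[:, 1:, 1:] = m_r_small

    delta_dep = 1.0 - np.abs(np.trace(m_dep_small, axis1=1, axis2=2)) / 3.0
    a = m_r_small[:, 0, 0] + m_r_small[:, 1, 1]  # M_R22 + M_R33
    b = m_r_small[:, 1, 0] - m_r_small[:, 0, 1]  # M_R32 - M_R23
    delta_ret = np.arccos(np.clip(np.sqrt(a**2 + b**2) - 1.0, -1.0, 1.0))
    alpha = np.arctan2(b, a)
    num = m_r_small[:, 2, 0] - m_r_small[:, 0, 2]  # M_R42 - M_R24
    den = m_r_small[:, 1, 2] - m_r_small[:, 2, 1]  # M_R34 - M_R43
    theta = np.mod(np.degrees(0.5 * np.arctan2(num, den)), 180.0)

    for arr in (delta_dep, delta_ret, alpha, theta):
        arr[degenerate] = np.nan

    def full(values, fill=np.nan, extra_shape=()):
        out = np.full((h, w) + extra_shape, fill)
        out[fg] = values
        return out

    return MMPDResult(
        M_D=full(m_d, extra_shape=(4, 4)),
        M_dep=full(m_dep, extra_shape=(4, 4)),
        M_R=full(m_r, extra_shape=(4, 4)),
        D=full(d),
        Delta=full(delta_dep),
        delta=full(delta_ret),
        alpha=full(alpha),
        theta=full(theta),
        degenerate=full(degenerate, fill=False) if p else np.zeros((h, w), bool),
    )


@dataclass
class MMTParams:
    """Closed-form matrix-transformation parameter maps (NaN at background)."""

    m14: np.ndarray
    m41: np.ndarray
    CD: np.ndarray
    m44: np.ndarray
    DL: np.ndarray
    PL: np.ndarray
    qL: np.ndarray
    rL: np.ndarray
    t1: np.ndarray
    b: np.ndarray
    A: np.ndarray
    Bdet: np.ndarray
    Bnorm: np.ndarray
    alpha_r: np.ndarray


def mmt(
    image: MuellerImage,
    background: np.ndarray | None = None,
    t1_as_printed: bool = False,
) -> MMTParams:
    """Matrix-transformation parameters of every foreground pixel.

    ``t1_as_printed`` switches t1 to 0.5*sqrt((m22-m33)^2 + (m22+m33)^2);
    the default is the rotation-invariant form
    0.5*sqrt((m22-m33)^2 + (m23+m32)^2) with b = 0.5*(m22+m33).
    """
    el = _normalized_elements(image)
    m = lambda i, j: el[..., i - 1, j - 1]  # noqa: E731  (1-based element access)

    m22, m23, m32, m33 = m(2, 2), m(2, 3), m(3, 2), m(3, 3)
    if t1_as_printed:
        t1 = 0.5 * np.sqrt((m22 - m33) ** 2 + (m22 + m33) ** 2)
    else:
        t1 = 0.5 * np.sqrt((m22 - m33) ** 2 + (m23 + m32) ** 2)
    b = 0.5 * (m22 + m33)
    denom = b**2 + t1**2
    a = np.divide(2 * b * t1, denom, out=np.zeros_like(denom), where=denom > 0)

    out = MMTParams(
        m14=m(1, 4).copy(),
        m41=m(4, 1).copy(),
        CD=m(1, 4) + m(4, 1),
        m44=m(4, 4).copy(),
        DL=np.sqrt(m(1, 2) ** 2 + m(1, 3) ** 2),
        PL=np.sqrt(m(2, 1) ** 2 + m(3, 1) ** 2),
        qL=np.sqrt(m(4, 2) ** 2 + m(4, 3) ** 2),
        rL=np.sqrt(m(2, 4) ** 2 + m(3, 4) ** 2),
        t1=t1,
        b=b,
        A=a,
        Bdet=m22 * m33 - m23 * m32,
        Bnorm=np.sqrt(m22**2 + m23**2 + m32**2 + m33**2),
        alpha_r=np.mod(np.degrees(0.5 * np.arctan2(-m(2, 4), m(3, 4))), 180.0),
    )
    if background is not None:
        for name in vars(out):
            getattr(out, name)[background] = np.nan
    return out


@dataclass
class PBPStack:
    """Named per-pixel parameter maps with rotation-variance flags."""

    maps: dict[str, np.ndarray]
    rotation_variant: dict[str, bool]
    background: np.ndarray

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.maps)

    @property
    def shape(self) -> tuple[int, int]:
        return self.background.shape

    def save(self, path) -> Path:
        """One float32 TIFF page per parameter plus a JSON manifest sidecar."""
        import tifffile

        path = Path(path)
        pages = np.stack(
            [self.maps[n] for n in self.maps] + [self.background.astype(float)]
        ).astype(np.float32)
        tifffile.imwrite(path, pages)
        manifest = {
            "parameters": list(self.maps),
            "rotation_variant": self.rotation_variant,
            "last_page": "background",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))
        return path

    @classmethod
    def load(cls, path) -> "PBPStack":
        import tifffile

        path = Path(path)
        manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        pages = np.asarray(tifffile.imread(path), dtype=float)
        names = manifest["parameters"]
        return cls(
            maps={n: pages[i] for i, n in enumerate(names)},
            rotation_variant={n: bool(manifest["rotation_variant"][n]) for n in names},
            background=pages[len(names)] > 0.5,
        )


def pbp_stack(
    image: MuellerImage,
    selection="all",
    background: np.ndarray | None = None,
    t1_as_printed: bool = False,
) -> PBPStack:
    """Bundle selected PBP maps (default: all 17) for the downstream stages."""
    if selection == "all":
        selection = ALL_PBPS
    selection = tuple(selection)
    unknown = [s for s in selection if s not in ALL_PBPS]
    if unknown:
        raise ValueError(
            f"unknown parameter(s) {unknown}; valid names: {', '.join(ALL_PBPS)}"
        )
    if background is None:
        background = np.zeros((image.height, image.width), dtype=bool)

    maps: dict[str, np.ndarray] = {}
    need_mmpd = {"D", "Delta", "delta", "theta"} & set(selection)
    if need_mmpd:
        dec = mmpd(image, background)
        for name in ("D", "Delta", "delta", "theta"):
            if name in selection:
                maps[name] = getattr(dec, name)
    mmt_names = set(selection) - {"D", "Delta", "delta", "theta"}
    if mmt_names:
        t = mmt(image, background, t1_as_printed=t1_as_printed)
        for name in mmt_names:
            maps[name] = getattr(t, name)

    ordered = {n: maps[n] for n in selection}
    flags = {n: n in ROTATION_VARIANT for n in selection}
    return PBPStack(maps=ordered, rotation_variant=flags, background=background)
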