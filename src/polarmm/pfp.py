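"""Learned polarization feature parameter (PFP).

A linear weighting W of the 15 rotation-invariant PBPs is chosen to
maximize the separation of the projected pixel distributions of the
normal class and the injured-model class,

    F(W) = (mu1~ - mu2~)^2 / (D1 + D2),

whose maximizer is the top eigenvector of Sp^+ Su — a rank-one problem
solved in closed form through the pseudo-inverse. Per pixel the PFP is
y = W^T x (no resolution loss), and treatment groups are scored by

    S = 50 * ( (|u_r - mu2~| - |u_r - mu1~|) / (|u_r - mu2~| + |u_r - mu1~|) + D1 / D_r ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mm_core import EmptyForegroundError
from .pbp import PBPStack, ROTATION_INVARIANT, ROTATION_VARIANT

__all__ = [
    "FeatureSet",
    "PFPModel",
    "TreatmentScore",
    "fit_pfp",
    "f_score",
    "apply_pfp",
    "treatment_score",
]


@dataclass
class FeatureSet:
    """Pixel feature vectors of one class: X has shape (N pixels, n features)."""

    X: np.ndarray
    names: tuple[str, ...]
    label: str = ""
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (pixels x features)")
        self.names = tuple(self.names)
        if len(self.names) != self.X.shape[1]:
            raise ValueError("names must match the feature dimension")
        variant = [n for n in self.names if n in ROTATION_VARIANT]
        if variant:
            raise ValueError(f"rotation-variant features not admitted: {variant}")

    @classmethod
    def from_stack(
        cls,
        stack: PBPStack,
        label: str = "",
        names=ROTATION_INVARIANT,
        mask: np.ndarray | None = None,
    ) -> "FeatureSet":
        """Collect finite foreground pixels of the named maps into a matrix."""
        names = tuple(names)
        missing = [n for n in names if n not in stack.maps]
        if missing:
            raise ValueError(f"stack is missing feature map(s): {missing}")
        sel = ~stack.background
        if mask is not None:
            sel = sel & mask
        cols = [stack.maps[n][sel] for n in names]
        x = np.column_stack(cols) if cols else np.empty((0, 0))
        finite = np.isfinite(x).all(axis=1)
        x = x[finite]
        if x.shape[0] == 0:
            raise EmptyForegroundError(f"no finite foreground pixels for class {label!r}")
        return cls(X=x, names=names, label=label)

    def standardized(self, center: np.ndarray, scale: np.ndarray) -> "FeatureSet":
        return FeatureSet(
            (self.X - center) / scale, self.names, self.label, center=center, scale=scale
        )


@dataclass
class PFPModel:
    """Fitted weighting vector with its standardization record and class stats."""

    feature_names: tuple[str, ...]
    W: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    mu1_proj: float
    mu2_proj: float
    D1: float
    D2: float
    F: float
    eigenvalue: float
    standardize: bool = True

    def project(self, x: np.ndarray) -> np.ndarray:
        """Project raw feature rows (..., n) to PFP values."""
        x = np.asarray(x, dtype=float)
        if self.standardize:
            x = (x - self.center) / self.scale
        return x @ self.W

    def to_json(self, path=None) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "W": self.W.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "mu1": self.mu1.tolist(),
            "mu2": self.mu2.tolist(),
            "mu1_proj": self.mu1_proj,
            "mu2_proj": self.mu2_proj,
            "D1": self.D1,
            "D2": self.D2,
            "F": self.F,
            "eigenvalue": self.eigenvalue,
            "standardize": self.standardize,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PFPModel":
        if isinstance(source, (str, Path)) and Path(source).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        return cls(
            feature_names=tuple(payload["feature_names"]),
            W=np.asarray(payload["W"], dtype=float),
            center=np.asarray(payload["center"], dtype=float),
            scale=np.asarray(payload["scale"], dtype=float),
            mu1=np.asarray(payload["mu1"], dtype=float),
            mu2=np.asarray(payload["mu2"], dtype=float),
            mu1_proj=float(payload["mu1_proj"]),
            mu2_proj=float(payload["mu2_proj"]),
            D1=float(payload["D1"]),
            D2=float(payload["D2"]),
            F=float(payload["F"]),
            eigenvalue=float(payload["eigenvalue"]),
            standardize=bool(payload["standardize"]),
        )


def _class_stats(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    y = x @ w
    return float(y.mean()), float(y.var())


def fit_pfp(
    normal: FeatureSet,
    model: FeatureSet,
    standardize: bool = True,
    class_normalized: bool = True,
    pinv_rtol: float = 1e-10,
) -> PFPModel:
    """Fit the unit-norm weighting maximizing the projected class separation.

    Su = (mu1-mu2)(mu1-mu2)^T is rank one, so the top eigenvector of
    Sp^+ Su is the closed-form direction Sp^+ (mu1-mu2) (computed via the
    SVD-based pseudo-inverse). By default Sp sums the class-normalized
    within-class covariances, matching the 1/N_j-normalized projected
    variances of the objective; ``class_normalized=False`` uses the
    unnormalized scatter sum instead. The sign is fixed so the normal
    class projects higher than the model class.
    """
    if normal.names != model.names:
        raise ValueError("feature sets must share the same ordered feature names")
    x1, x2 = normal.X, model.X
    n_feat = x1.shape[1]
    pooled = np.vstack([x1, x2])
    if standardize:
        center = pooled.mean(axis=0)
        scale = pooled.std(axis=0)
        scale = np.where(scale > 1e-12, scale, 1.0)
    else:
        center = np.zeros(n_feat)
        scale = np.ones(n_feat)
    x1 = (x1 - center) / scale
    x2 = (x2 - center) / scale

    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    diff = mu1 - mu2
    if np.linalg.norm(diff) < 1e-12:
        raise ValueError("no class separation: the class feature means coincide (Su = 0)")

    c1 = np.cov(x1, rowvar=False, bias=True).reshape(n_feat, n_feat)
    c2 = np.cov(x2, rowvar=False, bias=True).reshape(n_feat, n_feat)
    if class_normalized:
        sp = c1 + c2
    else:
        sp = x1.shape[0] * c1 + x2.shape[0] * c2
    if not np.any(np.abs(sp) > 1e-30):
        raise ValueError("within-class scatter is numerically zero")

    w = np.linalg.pinv(sp, rcond=pinv_rtol) @ diff
    nw = np.linalg.norm(w)
    if nw < 1e-30:
        raise ValueError("degenerate weighting direction (Sp^+ (mu1-mu2) vanished)")
    w = w / nw
    if w @ mu1 < w @ mu2:
        w = -w

    mu1_proj, d1 = _class_stats(x1, w)
    mu2_proj, d2 = _class_stats(x2, w)
    if d1 + d2 <= 0:
        raise ValueError("projected within-class variances vanish; F undefined")
    f = (mu1_proj - mu2_proj) ** 2 / (d1 + d2)
    return PFPModel(
        feature_names=normal.names,
        W=w,
        center=center,
        scale=scale,
        mu1=mu1,
        mu2=mu2,
        mu1_proj=mu1_proj,
        mu2_proj=mu2_proj,
        D1=d1,
        D2=d2,
        F=f,
        eigenvalue=f,
        standardize=standardize,
    )


def f_score(w: np.ndarray, normal: FeatureSet, model: FeatureSet) -> float:
    """Separation F(W) = (mu1~-mu2~)^2 / (D1+D2) with 1/N_j-normalized
    projected variances; invariant to rescaling W."""
    if normal.names != model.names:
        raise ValueError("feature sets must share the same ordered feature names")
    w = np.asarray(w, dtype=float).ravel()
    if w.shape[0] != normal.X.shape[1]:
        raise ValueError("weight vector length must match the feature dimension")
    m1, d1 = _class_stats(normal.X, w)
    m2, d2 = _class_stats(model.X, w)
    if d1 + d2 == 0:
        raise ValueError("projected variances are zero; F undefined")
    return (m1 - m2) ** 2 / (d1 + d2)


def apply_pfp(model: PFPModel, stack: PBPStack) -> np.ndarray:
    """Per-pixel projection y = W^T x on the stack's grid (NaN at background)."""
    missing = [n for n in model.feature_names if n not in stack.maps]
    if missing:
        raise ValueError(f"stack is missing feature map(s): {missing}")
    h, w = stack.shape
    x = np.stack([stack.maps[n] for n in model.feature_names], axis=-1)
    out = np.full((h, w), np.nan)
    sel = ~stack.background & np.isfinite(x).all(axis=-1)
    if sel.any():
        out[sel] = model.project(x[sel])
    return out


@dataclass
class TreatmentScore:
    """Recovery score of one treatment group on the fitted PFP axis."""

    group: str
    u_r: float
    D_r: float
    S: float


def treatment_score(values, model: PFPModel, group: str = "") -> TreatmentScore:
    """Score a treatment group's PFP values against the fitted class stats."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise EmptyForegroundError("no finite PFP values for the treatment group")
    u_r = float(v.mean())
    d_r = float(v.var())
    # relative guard: a numerically-constant group has no distribution width
    if d_r <= np.finfo(float).eps ** 2 * max(1.0, u_r * u_r):
        raise ValueError("treatment-group variance is zero; score undefined")
    a = abs(u_r - model.mu2_proj)
    b = abs(u_r - model.mu1_proj)
    if a + b == 0:
        raise ValueError("degenerate position: group mean coincides with both class centers")
    s = 50.0 * ((a - b) / (a + b) + model.D1 / d_r)
    return TreatmentScore(group=group, u_r=u_r, D_r=d_r, S=s)
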