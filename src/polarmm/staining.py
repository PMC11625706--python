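"""Virtual polarization staining and group-comparison reporting.

A PFP image is rendered in three bands — blue for background and the
lowest values, green for the middle band, orange-red for the highest —
with continuous shading inside each band. The group report overlays FDH
curves of the treatment groups against the normal and model references
and tabulates the recovery score S per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stats import FDH, compute_fdh
from .pfp import PFPModel, TreatmentScore, treatment_score

__all__ = [
    "StainScheme",
    "StainResult",
    "GroupReport",
    "default_scheme",
    "stain",
    "group_report",
]

# band color anchors (dark -> light within each band), 8-bit RGB
_BLUE = ((10, 25, 120), (90, 140, 235))
_GREEN = ((20, 95, 30), (130, 215, 110))
_ORANGE_RED = ((235, 140, 40), (205, 30, 15))


@dataclass(frozen=True)
class StainScheme:
    """Two break values split foreground PFP values into three color bands."""

    low_break: float
    high_break: float
    name: str = "default"

    def __post_init__(self) -> None:
        if not self.low_break < self.high_break:
            raise ValueError("low break must be strictly below high break")


def default_scheme(model: PFPModel, low_sigmas: float = 3.0) -> StainScheme:
    """Scheme anchored to the fitted model class: the green/orange boundary is
    the model-class projection center (its 50th percentile for a symmetric
    distribution); the blue/green boundary sits ``low_sigmas`` projected SDs
    below it."""
    high = model.mu2_proj
    low = high - low_sigmas * float(np.sqrt(model.D2))
    if not low < high:  # degenerate D2
        low = high - 1.0
    return StainScheme(low_break=low, high_break=high)


def percentile_scheme(values, p_low: float = 5.0, p_high: float = 50.0) -> StainScheme:
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    lo, hi = np.percentile(v, [p_low, p_high])
    if not lo < hi:
        lo = hi - 1.0
    return StainScheme(low_break=float(lo), high_break=float(hi), name="percentile")


@dataclass
class StainResult:
    rgb: np.ndarray  # (H, W, 3) uint8
    band_fractions: dict[str, float]
    warnings: list[str] = field(default_factory=list)


def _shade(values: np.ndarray, anchors) -> np.ndarray:
    """Linear interpolation between the band's dark and light anchors."""
    lo, hi = float(values.min()), float(values.max())
    t = np.full(values.shape, 0.5) if hi == lo else (values - lo) / (hi - lo)
    c0, c1 = (np.asarray(c, dtype=float) for c in anchors)
    return (1 - t)[..., None] * c0 + t[..., None] * c1


def stain(
    values: np.ndarray,
    scheme: StainScheme,
    background: np.ndarray | None = None,
) -> StainResult:
    """Deterministic three-band false-color rendering of a PFP image."""
    v = np.asarray(values, dtype=float)
    bg = np.zeros(v.shape, dtype=bool) if background is None else background.copy()
    bg |= ~np.isfinite(v)
    fg = ~bg

    rgb = np.zeros(v.shape + (3,), dtype=float)
    rgb[bg] = _BLUE[0]
    warnings: list[str] = []
    fractions = {"blue": float(bg.mean()), "green": 0.0, "orange_red": 0.0}

    if fg.any():
        vf = v[fg]
        if vf.max() == vf.min():
            warnings.append("constant PFP image: single-band output")
        low = fg & (v <= scheme.low_break)
        mid = fg & (v > scheme.low_break) & (v <= scheme.high_break)
        high = fg & (v > scheme.high_break)
        for band, anchors, key in (
            (low, _BLUE, "blue"),
            (mid, _GREEN, "green"),
            (high, _ORANGE_RED, "orange_red"),
        ):
            if band.any():
                rgb[band] = _shade(v[band], anchors)
                fractions[key] += float(band.mean())
    return StainResult(
        rgb=np.clip(np.rint(rgb), 0, 255).astype(np.uint8),
        band_fractions=fractions,
        warnings=warnings,
    )


@dataclass
class GroupReport:
    fdhs: dict[str, FDH]
    scores: dict[str, TreatmentScore]
    ranking: "object"  # pandas.DataFrame


def group_report(
    groups: dict[str, np.ndarray],
    model: PFPModel,
    n_bins: int = 100,
    value_range=None,
    out_dir=None,
) -> GroupReport:
    """Overlaid FDHs on a shared support plus the per-group score table.

    ``groups`` maps group name to PFP pixel values; include entries named
    'normal' and 'model' to draw the reference curves. Scores are computed
    for every group. With ``out_dir`` set, FDH overlay plots and a ranking
    CSV are written there.
    """
    import pandas as pd

    if not groups:
        raise ValueError("need at least one group")
    clean = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float).ravel()
        clean[name] = v[np.isfinite(v)]
    if value_range is None:
        pooled = np.concatenate([v for v in clean.values() if v.size])
        lo, hi = np.percentile(pooled, [0.1, 99.9])
        if not lo < hi:
            lo, hi = lo - 0.5, hi + 0.5
        value_range = (float(lo), float(hi))

    fdhs = {n: compute_fdh(v, n_bins=n_bins, value_range=value_range) for n, v in clean.items()}
    scores = {n: treatment_score(v, model, group=n) for n, v in clean.items()}
    ranking = (
        pd.DataFrame(
            [(s.group, s.u_r, s.D_r, s.S) for s in scores.values()],
            columns=["group", "u_r", "D_r", "S"],
        )
        .sort_values("S", ascending=False)
        .reset_index(drop=True)
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ranking.to_csv(out_dir / "ranking.csv", index=False)
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        refs = [n for n in ("normal", "model") if n in fdhs]
        for name, fdh in fdhs.items():
            if name in refs:
                continue
            fig, ax = plt.subplots(figsize=(5, 3.5))
            for ref in refs:
                ax.plot(fdhs[ref].bin_centers, fdhs[ref].frequencies, label=ref, lw=1.2)
            ax.plot(fdh.bin_centers, fdh.frequencies, label=name, lw=1.6)
            ax.set_xlabel("PFP value")
            ax.set_ylabel("frequency")
            ax.legend(frameon=False)
            fig.tight_layout()
            fig.savefig(out_dir / f"fdh_{name}.png", dpi=150)
            plt.close(fig)
    return GroupReport(fdhs=fdhs, scores=scores, ranking=ranking)
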