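# polarmm

Mueller-matrix polarimetry analysis pipeline for fibrous-tissue injury and
recovery assessment. The package takes (simulated) polarimetric
measurements through the full chain:

1. **`polarmm.mm_core`** — Mueller-image container, m11 normalization with
   air/background masking, passivity diagnostics, least-squares
   reconstruction `M = [S_out][S_in]^-1` from polarimeter state sets, and
   file I/O (16-page float TIFF + JSON sidecar, `.npz` container, TIFF/JSON
   ROI masks).
2. **`polarmm.phantom`** — ground-truthed synthetic phantoms of fibrous
   tissue built by composing pure optical elements
   (depolarizer · retarder · diattenuator per pixel), six graded group
   presets (normal / model / low / medium / high / positive), and a
   polarimeter measurement simulator with intensity noise.
3. **`polarmm.pbp`** — per-pixel polarization basic parameters:
   Lu–Chipman polar decomposition (D, Δ, δ, α, θ) and the
   matrix-transformation family (m14, m41, CD, m44, D_L, P_L, q_L, r_L,
   t1, A, |B|, ‖B‖, α_r). Exactly 15 parameters are rotation-invariant;
   θ and α_r are axial angles on [0°, 180°).
4. **`polarmm.stats`** — proportion-normalized frequency-distribution
   histograms, mean / axial-circular-SD summary statistics, per-ROI
   aggregation, and the `S_parameter = p / p_n` recovery ratio.
5. **`polarmm.pfp`** — the learned polarization feature parameter: a
   unit-norm linear weighting of the 15 rotation-invariant parameters
   maximizing `F(W) = (μ̃1 − μ̃2)² / (D1 + D2)` between the normal and
   injured-model pixel classes (rank-one Fisher problem solved through the
   SVD pseudo-inverse), pixel-wise projection, and the treatment score
   `S = 50·((|ũr−μ̃2|−|ũr−μ̃1|)/(|ũr−μ̃2|+|ũr−μ̃1|) + D1/Dr)`.
6. **`polarmm.staining`** — three-band (blue / green / orange-red) virtual
   staining of PFP images and the group-comparison report (overlaid FDHs,
   score ranking table).
7. **`polarmm.cli_io`** — study configuration, seeded substreams, the
   end-to-end pipeline driver with a reproducibility manifest, and the CLI.

## Command-line usage

All stages are subcommands of `polarmm`:

```sh
# one phantom with ground truth
polarmm phantom --preset normal --height 128 --width 128 --seed 7 --out out/normal

# PBP maps from a Mueller image
polarmm pbp --in out/normal/mueller.tiff --out out/normal/stack.tiff

# fit / apply the feature parameter, score, stain, report
polarmm pfp-fit --normal out/normal/stack.tiff --model out/model/stack.tiff --out out/pfp.json
polarmm pfp-apply --model out/pfp.json --in out/normal/stack.tiff --out out/normal/pfp.tiff
polarmm stain --in out/normal/pfp.tiff --model out/pfp.json --out out/normal/stain.tiff

# the whole study in one go (6 groups, ROIs, stats, PFP, report, stains)
polarmm run --seed 7 --out out/study
```

`polarmm run` accepts a JSON/YAML config overriding any group preset
field, image size, ROI counts, or feature selection; it writes a
`manifest.json` capturing the seed, config hash and stage output hashes,
so a repeated run is bit-identical.

The same pipeline is available programmatically:

```python
from polarmm import StudyConfig, run_pipeline
result = run_pipeline(StudyConfig(seed=7, height=256, width=256))
print(result.report.ranking)
```

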