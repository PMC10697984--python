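#!/usr/bin/env python
"""Compute LET and RBE_M over the full geometry grid with the synthetic beam.

Runs the end-to-end pipeline (9 fields × 5 positions × 4 depths, Δ = 1 keV)
and writes one row per geometry: track/dose-average LET of the total (TEF)
and secondary-only (SE) electron fluences plus the predicted RBE_M.
"""

from pathlib import Path

from letfield import pipeline as pl

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

df = pl.run_pipeline(pl.PipelineConfig())
df.to_csv(OUT / "let_rbe_pipeline.csv", index=False)

print(f"wrote {OUT / 'let_rbe_pipeline.csv'} ({len(df)} rows)")
print(
    f"TEF dose-average LET: {df.dose_tef.min():.2f}–{df.dose_tef.max():.2f} keV/um; "
    f"SE: {df.dose_se.min():.2f}–{df.dose_se.max():.2f} keV/um"
)
centre = df[df.position == "centre"].dose_tef.mean()
edge2 = df[df.position == "edge_plus_2"].dose_tef.mean()
print(
    f"mean TEF dose-average LET rises {100 * (edge2 - centre) / centre:.1f}% "
    "from the beam centre to 2 cm past the field edge"
)
print("SE dose-average LET exceeds TEF in every row:", (df.dose_se > df.dose_tef).all())
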