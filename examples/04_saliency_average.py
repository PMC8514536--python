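"""Gradient saliency: per-image maps, disc-aligned averaging, sector means.

Uses the classifier from a quick training run to compute absolute input-
gradient maps on test images, mirrors left-eye maps, aligns all maps on the
disc centroid and averages them, then summarizes mean saliency in the 8
clinical sectors inside the disc and in the 1-2 disc-radius annulus.
"""

from fundusroar import CropSpec, align_and_average, gradient_saliency, sector_summary
from fundusroar.experiments import desk_cohort, desk_train_config, run_cell

cohort, gen = desk_cohort(n_patients=100, signal_mode="periphery_only", seed=2)
run = run_cell(
    "glaucoma", cohort, gen, spec=CropSpec(), seed=2,
    train_config=desk_train_config("glaucoma", seed=2, max_epochs=30),
)

maps = [gradient_saliency(run.trained, im) for im in run.images["TEST"][:40]]
aligned = align_and_average(maps)
print(f"averaged {aligned.n_maps} maps "
      f"({aligned.n_degenerate_excluded} degenerate excluded); "
      f"canvas {aligned.canvas.shape}, disc at {aligned.center}")

disc_radius = run.images["TEST"][0].disc.disc_radius
table = sector_summary(aligned, disc_radius)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
top = table.loc[table.mean_saliency.idxmax()]
print(f"\nhighest mean saliency: {top.ring} / {top.sector}")
# With the planted signal confined to the peripapillary wedges, attention
# concentrates in the supero-/infero-temporal sectors rather than the disc.
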