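"""Train a bivariate movelet dictionary and classify held-out windows.

Movelets are 30 s window pairs (30 speed points + 150 acceleration
points) cut every 5 s from each trip.  They are split 60/20/20; the
validation set refines the training chapters (ambiguous movelets are
dropped, then only the most-matched half is kept), and held-out
movelets are classified by the nearest chapter.
"""

from movemode import experiment, movelets, synthgen

trips, _ = synthgen.simulate_dataset(synthgen.SimConfig(total_hours=1.0, seed=1))
result = experiment.run_movelet_stage(
    trips, movelets.MoveletConfig(H=30, delta=5), seed=1, keep_fraction=0.5
)

d = result["dictionary"]
print("chapter sizes:", {m: len(c) for m, c in d.chapters.items()})
print(f"test accuracy: {result['accuracy']:.3f} "
      f"on {result['n_movelets']['test']} held-out movelets\n")
print("row-normalized confusion (rows = true mode):")
print(result["confusion"].round(2))

# Expect near-perfect walking recall and heavy confusion among the
# motorized modes, whose speed and vibration profiles overlap.
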