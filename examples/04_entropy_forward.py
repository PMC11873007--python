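"""Forward-pass information loss: lazy vs traditional on textured phantoms.

Runs the whole-volume augmentation pipeline (spacing, random flip, 90-degree
rotation, random zoom, random rotation) on labelled phantom volumes in both
modes with identical random draws, and compares the drop in 256-bin Shannon
entropy between pipeline input and output.
"""

from lazyresample.experiments import forward_summary, run_forward

df = run_forward(n_samples=20, shape=(48, 48, 48), seed=0)
summary = forward_summary(df)

for mode in ("lazy", "traditional"):
    s = summary[mode]
    print(
        f"{mode:11s}: entropy loss {s['entropy_delta_mean']:.3f} "
        f"± {s['entropy_delta_sd']:.3f} bits, "
        f"{s['interpolations_mean']:.0f} interpolations/sample"
    )
p = summary["paired"]["sign_test_p"]
print(f"paired sign test (traditional loses more): p = {p:.2e}")
print()
print("Each interpolation averages neighbouring voxels and concentrates the")
print("intensity distribution; three resamples (traditional) lose visibly")
print("more entropy than the single composed resample (lazy).")
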