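"""Six lossy-looking transforms that collapse to an exact no-op.

Rotate(45), Zoom(1.25), Rotate(22), Rotate(-22), Zoom(0.8), Rotate(-45):
executed one-by-one each step would interpolate, but their composed matrix
is the identity.  Lazily composed, the dispatcher notices and copies the
input through untouched.
"""

from lazyresample.experiments import run_identity_chain

result = run_identity_chain(shape=(64, 64), seed=0)
print(f"max |composed - identity| : {result['max_abs_deviation']:.2e}")
print(f"dispatch class            : {result['dispatch']}")
print(f"output bit-equal to input : {result['bit_equal']}")
print(f"interpolation events      : {result['interpolation_events']}")
print()
print("The composed matrix deviates from the identity only by float")
print("round-off, so the whole chain costs zero interpolations and the")
print("image survives bit-for-bit.")
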