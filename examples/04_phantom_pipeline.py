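"""Full image-route pipeline on a 4-D digital phantom.

Builds a phantom (PET frames + CT + masks + aorta centres) with a known
truth including a blood-to-tissue delay, then runs: CT air fraction,
image-derived input function, plasma correction, delay grid search, and
the corrected compartmental fit.
"""

from qabl.kinetics import KineticParams
from qabl.simulate import PhantomSpec, SubjectTruth, synth_phantom
from qabl.workflow import analyze_phantom

truth = SubjectTruth(KineticParams(K1=0.05, k2=0.4, k3=0.06, vb=0.14, va=0.72),
                     delay_s=13.0)
phantom = synth_phantom(PhantomSpec(lung_blocks={"lung": (0, 9, truth)}), seed=0)

result = analyze_phantom(phantom)
row = result.rows[0]

print(f"estimated delay: {result.delay_s:+.0f} s (truth {truth.delay_s:+.0f} s)")
print(f"{'':>6} {'truth':>9} {'pipeline':>9}")
for name in ("va", "vb", "K1", "k2", "k3", "ki"):
    print(f"{name:>6} {getattr(truth.params, name):9.4f} {row[name]:9.4f}")

# Every quantity is re-derived from the images alone; on noise-free data the
# pipeline reproduces the generating parameters to numerical precision.
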