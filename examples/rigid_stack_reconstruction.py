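"""Image-space reconstruction of a misaligned phantom stack.

Builds a 24-slice phantom whose per-slice translations are a smooth trend
plus noise, registers adjacent slices by correlation peak (23 registrations
-- the only image registrations in the whole run), diffuses the neighbour
transforms in transformation space, and resamples each slice once through
its composed transform.  Stack roughness is measured as the total variation
along z of the shape's horizontal centre of mass.
"""

import numpy as np

from tdrecon import (DiffusionConfig, PhaseCorrelationRegistrar,
                     make_phantom_stack, reconstruct, resample_stack,
                     virtual_slice)

phantom = make_phantom_stack(n_slices=24, misalignment="translation", seed=7)
registrar = PhaseCorrelationRegistrar()
config = DiffusionConfig(alpha=0.45, sweeps=30)

result = reconstruct(phantom.stack, registrar, config)
print(f"{len(phantom.stack)} slices: {registrar.calls} registrations, then "
      f"{config.sweeps - 1} transformation-space sweeps")

aligned = resample_stack(phantom.stack, result.totals)


def roughness(stack):
    profile = virtual_slice(stack, "XZ", stack.frame_shape[0] // 2)
    x = np.arange(profile.shape[1])
    com = (profile * x).sum(axis=1) / profile.sum(axis=1)
    return np.abs(np.diff(com)).sum()


print(f"roughness before: {roughness(phantom.stack):.2f} px, "
      f"after: {roughness(aligned):.2f} px")
err0 = np.mean([np.linalg.norm(t.delta - tr.delta)
                for t, tr in zip(phantom.truth, phantom.trend)])
err1 = np.mean([np.linalg.norm(u.delta + t.delta - tr.delta)
                for u, t, tr in zip(result.totals, phantom.truth, phantom.trend)])
print(f"mean distance to the true smooth trend: {err0:.2f} px -> {err1:.2f} px")
print("\nDiffusion removed the slice-to-slice jitter while following the "
      "smooth trend -- the\njagged boundary straightens without the stack "
      "being forced into a straight column.")
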