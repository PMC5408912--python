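"""1-D sinusoid experiment: diffusion vs. sequential Gauss-Seidel smoothing.

A stack of 100 slices sits at true vertical positions sin(2 pi i / N); the
observed positions add uniform registration noise (and the registration
between neighbours is assumed perfect, so only the smoothing itself is
tested).  The error-versus-sweeps curve first falls, as high-frequency
registration noise is removed, then rises again as real shape information
is smoothed away toward the maximum-alignment (straight) solution -- the
minimum marks the useful stopping point.
"""

import numpy as np

from tdrecon import (fwhm_bw, gauss_seidel_error_curve, make_sinusoid_stack,
                     tdr_error_curve)

stack = make_sinusoid_stack(seed=1)
print(f"{stack.n_slices} slices, noise amplitude {stack.noise_amp}")

tdr = tdr_error_curve(stack.y, stack.y_true, iterations=7000)
gs = gauss_seidel_error_curve(stack.y, stack.y_true, sweeps=7000)

print(f"initial error          : {tdr[0]:.4f}")
for name, curve in (("diffusion (TDR)", tdr), ("Gauss-Seidel", gs)):
    m = int(curve.argmin())
    print(f"{name:<23}: min error {curve.min():.5f} at sweep {m}, "
          f"plateau {curve[-1]:.4f}")
m_opt = int(tdr.argmin())
print(f"implicit low-pass bandwidth at the TDR optimum: "
      f"{fwhm_bw(0.45, m_opt):.3f} cycles/slice")
print("\nThe minima are the best achievable reconstructions; the common "
      "plateau is maximum alignment,\nwhere every trace of the true "
      "sinusoidal shape has been smoothed away.")
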