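"""Forward-simulate DWI signals from a known tensor and fit it back.

Shows the single-tensor model S = S0 exp(-b g'Dg) at the default
acquisition (45 directions, b = 600 s/mm^2) and the log-linear
least-squares fit recovering the tensor and its FA.
"""

import numpy as np

from alongtract import compute_fa, default_scheme, fit_tensor, simulate_dwi

# prolate tensor rotated 30 degrees in the x-y plane
theta = np.deg2rad(30)
R = np.array([[np.cos(theta), -np.sin(theta), 0],
              [np.sin(theta), np.cos(theta), 0],
              [0, 0, 1]])
D = R @ np.diag([1.7e-3, 0.4e-3, 0.3e-3]) @ R.T

scheme = default_scheme()
noiseless = simulate_dwi(D[None, None, None], scheme, noise_sd=0.0)[0, 0, 0]
noisy = simulate_dwi(D[None, None, None], scheme, noise_sd=2.0, seed=1)[0, 0, 0]

exact = fit_tensor(noiseless, scheme)
approx = fit_tensor(noisy, scheme)

true_fa = compute_fa(np.linalg.eigvalsh(D)[::-1])
print(f"true FA:                 {true_fa:.6f}")
print(f"fit from noiseless data: {exact.fa:.6f}  "
      f"(max element error {np.abs(exact.matrix - D).max():.2e} mm^2/s)")
print(f"fit from Rician noise:   {approx.fa:.6f}")
print("The noiseless fit inverts the forward model to numerical precision; "
      "magnitude noise biases FA slightly, as in real scans.")
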