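"""Descriptors and kernels on a small solvated configuration.

Builds the package's toy molecule, surrounds it with a few point charges,
and evaluates the two configuration descriptors and both kernels.
"""

import numpy as np

from gpmlmm import (
    KernelSpec,
    MMEnvironment,
    default_toy_params,
    direct_kernel,
    env_kernel_blocks,
    esp_descriptor,
    internal_kernel_blocks,
    inverse_distance_descriptor,
    matern52,
)

params = default_toy_params()
geom = params.reference
env = MMEnvironment(
    coords=[[5.0, 0.0, 0.0], [0.0, 6.0, 1.0], [-4.0, -4.0, 0.0]],
    charges=[0.12, -0.08, -0.04],
)

idd = inverse_distance_descriptor(geom, with_jacobian=True)
esp = esp_descriptor(geom, env, with_jacobians=True)
print("inverse-distance descriptor (1/A):", np.round(idd.values, 4))
print("ESP descriptor (a.u.):            ", np.round(esp.values, 6))
# the ID vector encodes the internal geometry (one entry per atom pair);
# the ESP vector is the Coulomb potential of the charges at each atom.

spec = KernelSpec(lengthscale=1.0, permutations=((0, 1, 2, 3), (0, 1, 3, 2)))
stretched = geom.with_coords(geom.coords * 1.02)
b_int = internal_kernel_blocks(geom, stretched, spec)
b_env = env_kernel_blocks(geom, env, stretched, env, spec)
print(f"internal (Matern-5/2) kernel to a 2% stretched copy: {b_int.k:.6f}")
print(f"environment (product) kernel for the same pair:      {b_env.k:.6f}")
print(f"matern52 at distance 0:    {matern52(0.0, 1.0):.1f}  (exactly 1)")
print(f"direct kernel, vacuum side: {direct_kernel(esp.values, 0*esp.values):.1f}"
      "  (vanishes when either potential is zero)")
# kernel values near 1 mean the configurations are similar in descriptor
# space; the environment kernel multiplies in the potential overlap.
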