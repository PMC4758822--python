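"""Invert a 2-region DCM by variational Laplace and compare the posterior
means with the generating parameters.

Uses a short oddball-driven run; the free energy printed at the end is the
quantity pooled over subjects during model comparison.
"""

import numpy as np

import rovingdcm as rd

spec = rd.NetworkSpec(regions=("TH", "S1"))
A = np.array([[-0.5, 0.15], [0.25, -0.5]])
B = np.stack([np.zeros((2, 2)), np.array([[0.15, 0.0], [0.3, 0.1]])])
C = np.array([[0.8, 0.0], [0.0, 0.0]])
truth = rd.DCMParameters(A=A, B=B, C=C, spec=spec)

nvol, TR, sub = 200, 1.54, 8
seq = rd.generate_sequence(30, seed=2)
u = rd.build_input_sticks(seq, nvol, TR, substeps=sub)
clean = rd.simulate_timeseries(truth, u, TR=TR, n_volumes=nvol, substeps=sub)
sd = clean.values.std(axis=0).mean()
rng = np.random.default_rng(9)
data = rd.RegionTimeseries(values=clean.values + rng.normal(0, sd / 2, clean.values.shape),
                           TR=TR, regions=clean.regions)

post = rd.variational_laplace(data, spec, u, substeps=sub,
                              settings=rd.InversionSettings(max_iterations=48))
packer = rd.ParameterPacker(spec)
theta = packer.pack(truth)
print(f"{'parameter':<14} {'true':>7} {'estimate':>9} {'post SD':>8}")
for name, t, m, v in zip(post.names, theta, post.mean, np.diag(post.cov)):
    print(f"{name:<14} {t:>7.3f} {m:>9.3f} {np.sqrt(v):>8.3f}")
print(f"free energy {post.free_energy:.1f} nats after "
      f"{len(post.f_trace) - 1} accepted steps (converged: {post.converged})")
# the well-identified couplings (A, C) land on the generating values with
# tight posteriors; the modulatory B entries are only weakly informed by a
# short single-driver run and shrink toward their zero prior mean — longer
# runs or richer input designs tighten them (see the recovery tests)
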