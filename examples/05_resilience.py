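"""Landscape resilience from geometry: the sensitivity indicator lambda_F.

Perturb a landscape, re-evaluate the balance equation, and take the ratio
of the change in d[F]/dt to the change in [F], averaged over an ensemble of
natural perturbations weighted by their rates of occurrence (Eq-26-style
ratio of weighted sums).  Negative = the perturbation is dampened (stable
landscape); positive = amplified (critical landscape).
"""

from fgba import Landscape, Params, PerturbationSpec, mean_sensitivity

side = 40
N = side * side

# both stable states under the standard rates, probed by the demographic
# perturbations that occur naturally (mortality at rate gamma, recruitment
# at rate beta)
params = Params().with_phi_N(0.5, N)
demographic = [
    PerturbationSpec("random_mortality", 0.05, weight=params.gamma),
    PerturbationSpec("random_recruitment", 0.05, weight=params.beta),
]
for label, f, seed in (("near-closed forest ([F]=0.95)", 0.95, 1),
                       ("open grassland ([F]=0.05)", 0.05, 2)):
    ls = Landscape.uniform_random(side, side, f, seed=seed)
    lam = mean_sensitivity(ls, demographic, params, n_realizations=32, seed=7)
    print(f"{label:32s} lambda_F_bar = {lam:+.4f}/y  [dampening]"
          if lam < 0 else
          f"{label:32s} lambda_F_bar = {lam:+.4f}/y  [AMPLIFYING]")

# a forest with a critical-size hole (gamma = beta = 0 so the hole size is
# the only control: [G]c = alpha/(phiN*pf) = 0.30), probed at its perimeter
hole_params = Params(gamma=0.0, beta=0.0, rho_f=1e5, mu=9e5).with_phi_N(1.0, N)
perimeter = [
    PerturbationSpec("remove_perimeter_forest", 0.2,
                     weight=hole_params.phi * N * hole_params.pf),
    PerturbationSpec("add_perimeter_forest", 0.2, weight=hole_params.alpha),
]
hole = Landscape.forest_with_hole(side, None, 0.30)
lam = mean_sensitivity(hole, perimeter, hole_params, n_realizations=32,
                       seed=7)
print(f"{'forest with critical hole':32s} lambda_F_bar = {lam:+.4f}/y  "
      f"[{'dampening' if lam < 0 else 'AMPLIFYING'}]")

print("\nBoth stable states dampen perturbations; the critical-hole "
      "landscape amplifies them - the positive fire-vegetation feedback "
      "that drives abrupt forest loss.")
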