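"""Tracing the bifurcation diagram, saddle branch included.

Stable branches come from plain simulations; the unstable (saddle) branch
is made observable by noninvasive feedback control, phi(t) = phi0 +
g([F](t) - F_ref): at the controlled equilibrium the feedback averages to
zero, so the measured (phi_bar*N, [F]_bar) is an equilibrium of the
uncontrolled system.
"""

from fgba import Params, trace_branch

branch = trace_branch(Params(), width=30, f_refs=[0.35, 0.5],
                      phi0_N=0.45, stable_phiN=[0.45],
                      t0=50, T=150, base_seed=8)

print(f"{'phiN_bar':>9} {'[F]_bar':>8} {'stability':>10} {'CI':>7}")
for k in range(len(branch.phiN)):
    print(f"{branch.phiN[k]:9.3f} {branch.F[k]:8.3f} "
          f"{branch.stability[k]:>10} {branch.ci_F[k]:7.4f}")
print("\nAbove the onset ignition rate, a forest branch (~0.8), a "
      "grassland branch (~0) and a saddle in between coexist: the "
      "signature fold of bistable tree cover.")
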