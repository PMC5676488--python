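"""Equilibria and local stability of the non-delayed model.

Computes the tumor-free state and all positive equilibria for the flagship
parameter set, classifies each by its Jacobian eigenvalues, and evaluates the
analytic stability certificates.
"""
from tumordyn import classify, positive_equilibria, positive_stability_conditions, tumor_free, tumor_free_stability
from tumordyn.scenarios import kuznetsov_fixture

params = kuznetsov_fixture().params
print(f"parameters: {params}")

p0 = tumor_free(params)
v0 = tumor_free_stability(params)
print(f"\ntumor-free state P0 = ({p0.x_star:.5f}, 0): {v0.classification}")
print("  (f > sigma/delta here, so the tumor can invade the tumor-free state)")

for i, eq in enumerate(positive_equilibria(params), start=1):
    v = classify(params, eq)
    certs = positive_stability_conditions(params, eq)
    burden = next(c for c in certs if c.label == "tumor_burden_threshold")
    print(f"\nE{i} = ({eq.x_star:.4f}, {eq.y_star:.6g})   residual {eq.residual:.1e}")
    print(f"  eigenvalues: {v.eigenvalues[0]:.6g}, {v.eigenvalues[1]:.6g}")
    print(f"  classification: {v.classification}; certificate predicts: {burden.prediction}")

print(
    "\nE1 (low tumor burden) is a stable focus, E2 a saddle separating the"
    "\nbasins, and E3 (high tumor burden, near carrying capacity) a stable node."
)
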