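"""Does the strip treatment change community composition and evenness?

MRPP asks whether Bray-Curtis distances within a treatment are smaller
than expected under random relabelling (composition); the multivariate
dispersion test compares spreads around treatment centroids in PCoA
space (a proxy for evenness).
"""

import prairienet as pn

registry = pn.default_registry()
truth = pn.default_truth(registry, seed=42)
bees, plants, visits, truth = pn.generate_dataset(truth, registry)

D = pn.bray_curtis_matrix(bees)
groups = [label.split("/")[1] for label in D.labels]  # treatment per event

mr = pn.mrpp(D, groups, n_perm=9999, seed=7)
print(f"MRPP: T = {mr.T:.2f}, A = {mr.A:.3f}, p = {mr.p:.4f}")
# T far below 0 and small positive A: compositions are more homogeneous
# within treatments than chance would give -> the treatments differ.

disp = pn.multivariate_dispersion(D, groups)
print(
    f"dispersion: F = {disp.F:.2f}, p = {disp.p_parametric:.4f}; "
    f"mean distance to centroid "
    + ", ".join(f"{g}: {m:.3f}" for g, m in disp.group_means.items())
)
# A significant F would mean one treatment's communities are more
# variable (less even) than the other's.

for mode, label in [("exclude_pooled", "8-common"), ("include_pooled", "9-common")]:
    part = pn.classify_commonness(bees, registry, mode=mode)
    print(f"{label} reading: {len(part.common)} common taxa")
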