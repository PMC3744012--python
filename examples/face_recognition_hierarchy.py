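"""The two-layer image hierarchy: ranked codes and holistic sensitivity.

Renders a synthetic 43 + 7 two-population face set, trains the hierarchy,
and reports unique ranked-order codes plus the stability of the top-n most
active output neurons under lower-half manipulations.
"""

import facespace as fs

SEED = 1

images = fs.sample_face_population(43, 7, seed=SEED)
net = fs.train_hierarchy(images, fs.HierarchyConfig(N2=10, seed=SEED))

codes = [fs.layer2_response(net, im) for im in images]
n_unique, fractions = fs.unique_code_count(codes)
print(f"unique ranked codes: {n_unique} of 50 stimuli")
print(f"  own population:   {100 * fractions['own']:.0f}% unique")
print(f"  other population: {100 * fractions['other']:.0f}% unique")

labels, _ = fs.cluster_outputs(codes, k=6)
other_clusters = sorted({int(l) for c, l in zip(codes, labels)
                         if c.population == "other"})
print(f"clusters holding the 7 other-population faces: {other_clusters}")

table = fs.holistic_test(net, images, seed=SEED)
print("\nmean top-n overlap after manipulating the lower half:")
print(table.pivot_table(index=["population", "manipulation"], columns="n",
                        values="overlap").round(2))

print(
    "\nThe heavily trained own population is coded finely (higher unique"
    "\nfraction) and its codes react to the manipulations — especially to"
    "\nexchanging the lower half with another face — while the sparsely"
    "\ntrained other population is coded coarsely: its few classifiers barely"
    "\nnotice either manipulation. Sensitivity to the whole face is a"
    "\nsignature of expertise, not a built-in property."
)
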