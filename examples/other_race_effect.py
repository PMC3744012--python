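"""The other-race effect from unequal exposure.

Trains a 50-neuron pool on two equal-variance exemplar clouds seen 1000 vs
100 times per epoch, counts the classifiers covering each region, and
measures radial discrimination thresholds around both group means.
"""

import facespace as fs

SEED = 0

specs = [
    fs.PopulationSpec(center_azel=(30, 40), sd_azel=(6, 6), count=1000, label="own"),
    fs.PopulationSpec(center_azel=(62, 50), sd_azel=(6, 6), count=100, label="other"),
]
params = fs.PoolParams(N=50, r=0.001, alpha=50.0)
cmap = fs.run_face_space_experiment(specs, params, fs.TrainSchedule(epochs=200), SEED)

counts = fs.classifier_density_by_group(cmap)
print(f"classifiers preferring the own-race region:   {counts['own']}")
print(f"classifiers preferring the other-race region: {counts['other']}")

p_own = fs.discrimination_profile(cmap, "own")
p_other = fs.discrimination_profile(cmap, "other")
summary = fs.compare_groups(p_own, p_other)
print(f"mean threshold, own race:   {summary['mean_own']:.3f} s.d.")
print(f"mean threshold, other race: {summary['mean_other']:.3f} s.d.")

print(
    "\nThe frequently seen ('own-race') cloud attracts most of the 50"
    "\nclassifiers, so a distractor face there changes the winning neuron"
    "\nafter a fraction of a standard deviation; in the sparsely covered"
    "\nother-race region, larger steps are needed before the network can"
    "\ntell the distractor from the mean face: poorer discrimination from"
    "\nnothing but unequal exposure."
)
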