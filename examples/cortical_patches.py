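"""Category patches on a cortical sheet from local lateral excitation.

Trains a 9 x 9 neuron sheet on five clustered object categories at three
lateral gains and reports the neighbor-agreement index (the fraction of
neighboring neuron pairs preferring the same category).
"""

import numpy as np

import facespace as fs

SEEDS = range(5)

print("h     mean neighbor agreement")
for h in (0.0, 0.3, 1.0):
    vals = [fs.run_cortical_experiment(h=h, seed=s).agreement_index
            for s in SEEDS]
    print(f"{h:3.1f}   {np.mean(vals):.3f}")

result = fs.run_cortical_experiment(h=1.0, seed=0)
grid = result.preferred.reshape(9, 9)
print("\npreferred category per neuron (h = 1):")
for row in grid:
    print(" ".join(lab.split("_")[1] for lab in row))

print(
    "\nWithout lateral coupling (h = 0) category preference is scattered"
    "\nrandomly over the sheet. Adding even moderate excitation from the"
    "\neight grid neighbors makes nearby neurons co-learn, and contiguous"
    "\npatches of category-selective neurons emerge — the agreement index"
    "\nrises steadily with h."
)
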