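"""Gap-junction chemoprotection: tumor survival under treatment rises with Gf.

Runs the same treated scenario at three gap-junction modulation factors.
Drug enters from the grid boundary once the tumor reaches the trigger size,
in repeating 14-on / 7-off cycles; pro-metastatic astrocytes adjacent to a
tumor cell reduce the drug concentration it senses by Gf * Npro/8.
"""

import numpy as np

from astroabm import ChemoParams, SimulationConfig, run_simulation

for gf in (0.0, 0.5, 1.0):
    finals = []
    for seed in (0, 1, 2):
        chemo = ChemoParams(
            diffusion=20.0,        # scaled to the 61x61 demonstration grid
            retention=0.95,
            start_threshold=80,
            gap_junction_factor=gf,
        )
        config = SimulationConfig(
            grid_width=61, grid_height=61, n_steps=70,
            astrocyte_density=0.3, chemo_params=chemo, seed=seed,
        )
        state, metrics = run_simulation(config)
        finals.append(state.tumor_count)
    print(f"Gf={gf:3.1f}: final tumor counts {finals} (mean {np.mean(finals):7.1f})")

print()
print("Higher Gf shields tumor cells that sit next to reprogrammed astrocytes,")
print("so the mean post-treatment burden rises with the gap-junction factor.")
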