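"""Compare tumor growth under the six astrocyte spatial layouts.

All runs use identical parameters and 30% astrocyte density; only the
initial astrocyte arrangement differs.  Astrocytes packed at the tumor core
(radial) suppress and physically crowd early growth, while peripheral
enrichment (inverse-radial) leaves the core free to expand.
"""

from astroabm import SimulationConfig
from astroabm.experiments import run_experiment

base = SimulationConfig(grid_width=60, grid_height=60, n_steps=30,
                        astrocyte_density=0.3, seed=0)
res = run_experiment("layout_sweep", base_config=base, n_replicates=3, seed=0)

means = (res["replicates"].groupby("layout")["tumor_count"].mean()
         .sort_values(ascending=False))
print("mean final tumor count by astrocyte layout (3 replicates each):")
print(means.round(1).to_string())
print()
print(f"largest burden: {means.idxmax()}; smallest: {means.idxmin()} —")
print("spatial arrangement alone, at fixed density, changes the outcome.")
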