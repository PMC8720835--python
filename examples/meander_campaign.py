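"""A reduced meandering-amplitude campaign: success rate and tau per model.

Runs 40 navigators of each model at each meandering level (the full
benchmark uses 250) and prints the two performance metrics per cell.
"""

import numpy as np

import mothsim as ms
from mothsim.benchmark import MEANDER_LEVELS, run_meander_campaign

results = run_meander_campaign(seed=1, n_per_model=40)

header = "model " + "".join(f"   B={lv:<6}" for lv in MEANDER_LEVELS)
print("success rate (% of started navigators)")
print(header)
for model in ms.MODEL_IDS:
    cells = [f"{results.success_rate(model, lv):7.1f}   "
             for lv in MEANDER_LEVELS]
    print(f"  {model}  " + "".join(cells))

print("\nmean efficient navigation time tau (successful trials)")
print(header)
for model in ms.MODEL_IDS:
    cells = []
    for lv in MEANDER_LEVELS:
        taus = results.tau_values(model, lv)
        cells.append(f"{np.mean(taus):7.2f}   " if taus.size else "      -   ")
    print(f"  {model}  " + "".join(cells))

# Stronger meandering swings the plume laterally and lowers every model's
# success rate; tau > 1 measures how much longer than the straight path the
# successful flights were.
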