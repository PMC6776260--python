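"""Apparent wave speed before and after scalp source mixing.

Treating each model level as a cortical region 2 cm from its neighbours gives
mesoscopic speeds (~0.6 m/s). Blurring levels with the distance-weighted
kernel (1, 0.8, 0.6, 0.4) — the way scalp electrodes mix nearby sources — and
reading the same maps at 4-cm electrode spacing inflates the apparent speed
toward the macroscopic EEG range (~2 m/s) without changing direction.
"""

import numpy as np

from pcwaves import DEFAULT_MULTILEVEL, maps_from_trials, simulate_trials
from pcwaves.wavemap import source_mixing, wave_speed

run, _ = simulate_trials(DEFAULT_MULTILEVEL, duration=6.0, n_trials=20,
                         drive_mode="input", seed=6)
maps = maps_from_trials(run.predictions)
mixed = [source_mixing(m) for m in maps]

cortical = np.median([wave_speed(m, 0.02) for m in maps])
scalp = np.median([wave_speed(m, 0.04) for m in mixed])

print(f"median speed, 2-cm level spacing:          {cortical:.2f} m/s")
print(f"after source mixing, 4-cm electrode grid:  {scalp:.2f} m/s")
print("-> mixing flattens the spatial phase gradient (the dominant off-axis")
print("   peak moves to a lower spatial frequency), so the same wave looks")
print("   several times faster at the scalp than across cortical sources.")
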