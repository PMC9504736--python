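#!/usr/bin/env python
"""Bimodality of hydrophobic contact distances.

Tightly packed kinase pockets show two characteristic maxima in the
distribution of distances between interacting nonpolar residues (near
7.7-7.8 A for contacts inside one secondary-structure element and near 8.3 A
for contacts across elements).  This driver simulates that regime with the
stated two-component mixture (means 7.7 / 8.3 A, SD 0.2 A, equal weights,
1000 contacts), runs the package's mode detector, and plots the histogram.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from pocketprofiler.geometry import contact_statistics

OUT = Path("results")
OUT.mkdir(exist_ok=True)

rng = np.random.default_rng(2024)
component = rng.integers(0, 2, size=1000)
distances = np.where(component == 0, rng.normal(7.7, 0.2, 1000), rng.normal(8.3, 0.2, 1000))

stats = contact_statistics(distances, bin_width=0.25)
print(f"n={stats.n}  mean={stats.mean:.2f} A  sd={stats.sd:.2f} A")
print(f"detected modes: {[round(m, 3) for m in stats.modes]} A "
      f"(planted component means: 7.7 and 8.3 A)")

fig, ax = plt.subplots(figsize=(5, 3.2))
ax.bar(stats.bin_centers, stats.histogram, width=stats.bin_width * 0.9, color="#7a9cc6")
for m in stats.modes:
    ax.axvline(m, color="firebrick", ls="--", lw=1)
ax.set_xlabel("contact distance (Å)")
ax.set_ylabel("contacts per 0.25 Å bin")
ax.set_title("bimodal contact-distance distribution")
fig.tight_layout()
fig.savefig(OUT / "contact_distance_modes.png", dpi=150)
print(f"wrote {OUT / 'contact_distance_modes.png'}")
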