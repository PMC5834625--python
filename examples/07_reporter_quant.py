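"""TMT-10plex reporter extraction and median-ratio normalization.

Builds a spectrum carrying the ten reporter ions, extracts channel
intensities inside a 10 ppm window and normalizes a novel-peptide ratio
table with factors from the canonical table.
"""

import numpy as np
import pandas as pd

from ipaw.io import Spectrum
from ipaw.reporter_quant import (
    TMT10_REPORTER_MZ, extract_reporters, normalize_ratios, reporter_ratios,
)

rng = np.random.default_rng(0)
mz = np.array(sorted(TMT10_REPORTER_MZ.values()))
intensity = rng.uniform(1e4, 1e5, mz.size)
spectrum = Spectrum("scan1", 650.32, 2, mz, intensity)

channels = extract_reporters(spectrum, tol_ppm=10.0)
print("extracted reporter intensities:")
for channel, value in channels.items():
    print(f"  {channel}: {value:.0f}")

canonical = pd.DataFrame(
    rng.lognormal(mean=0.3, sigma=0.2, size=(200, 9)),
    columns=[c for c in TMT10_REPORTER_MZ if c != "126"],
)
novel = pd.DataFrame(
    rng.lognormal(mean=0.5, sigma=0.3, size=(5, 9)), columns=canonical.columns
)
normalized, factors = normalize_ratios(novel, canonical)
print("\nper-channel canonical median factors (divide ratios by these):")
print(factors.round(3).to_string())
centered, _ = normalize_ratios(canonical, canonical)
print(f"\ncanonical per-channel median after centering: "
      f"{centered.median().round(6).unique()}")
# Novel-peptide ratios are normalized with the canonical factors, never
# their own medians: the small novel set must not define its own center.
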