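"""TMT 10-plex reporter-ion extraction and ratio normalization.

Reporter intensities are read from MS2 spectra inside a narrow ppm
integration window; novel-peptide ratios are normalized per channel with
median-centering factors computed from the canonical peptide tables, so
systematic channel loading differences cancel without letting the (small)
novel set normalize itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import TMT10_REPORTER_MZ

__all__ = ["extract_reporters", "reporter_ratios", "normalize_ratios", "TMT10_REPORTER_MZ"]


def extract_reporters(
    spectrum,
    channel_mz: dict | None = None,
    tol_ppm: float = 10.0,
) -> dict:
    """Per-channel reporter intensity from one spectrum.

    For each channel the nearest peak within ``tol_ppm`` is integrated;
    channels with no peak in the window map to NaN. Raises when the
    tolerance is so wide that adjacent channel windows overlap.
    """
    channel_mz = channel_mz or TMT10_REPORTER_MZ
    mzs = sorted(channel_mz.values())
    for a, b in zip(mzs, mzs[1:]):
        if a * (1 + tol_ppm * 1e-6) >= b * (1 - tol_ppm * 1e-6):
            raise ValueError(
                f"tolerance {tol_ppm} ppm makes windows of {a:.4f} and {b:.4f} overlap"
            )
    mz = np.asarray(spectrum.mz, dtype=float)
    intensity = np.asarray(spectrum.intensity, dtype=float)
    out = {}
    for channel, target in channel_mz.items():
        tol = target * tol_ppm * 1e-6
        lo = np.searchsorted(mz, target - tol, side="left")
        hi = np.searchsorted(mz, target + tol, side="right")
        if lo == hi:
            out[channel] = np.nan
        else:
            window = np.abs(mz[lo:hi] - target)
            out[channel] = float(intensity[lo:hi][np.argmin(window)])
    return out


def reporter_ratios(matrix: pd.DataFrame, reference_channel: str) -> pd.DataFrame:
    """Intensity matrix (rows = PSMs/peptides) to per-channel ratios."""
    ref = matrix[reference_channel]
    return matrix.div(ref, axis=0)


def normalize_ratios(
    ratios: pd.DataFrame,
    canonical_ratios: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-center ratio columns using factors from the canonical table.

    Each channel of ``ratios`` is divided by the median of the same channel
    in ``canonical_ratios``; the canonical table's own per-channel median
    becomes exactly 1. Channels whose canonical median is zero or missing
    are flagged (NaN factor) and left unnormalized.
    """
    factors = canonical_ratios.median(axis=0, skipna=True)
    factors = factors.where((factors != 0) & factors.notna())
    normalized = ratios.copy()
    for channel in ratios.columns:
        f = factors.get(channel)
        if f is not None and np.isfinite(f):
            normalized[channel] = ratios[channel] / f
    return normalized, factors
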