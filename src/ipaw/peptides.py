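"""Peptide chemistry: tryptic digestion, reversed-tryptic decoys, fragment
ions and ppm-tolerance peak matching.

The fragment model is restricted to singly- or low-charge b/y series ions,
which is what flanking-ion curation of substitution peptides relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import (
    CARBAMIDOMETHYL,
    OXIDATION,
    PROTON,
    RESIDUE_MASSES,
    STANDARD_RESIDUES,
    TMT10,
    WATER,
)

__all__ = [
    "Peptide",
    "ModConfig",
    "FragmentIon",
    "PeakMatch",
    "digest",
    "generate_decoy",
    "peptide_mass",
    "fragment_ions",
    "match_peaks",
]


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with optional modifications and provenance.

    ``mods`` entries are ``(position, name, mass_delta)`` with position 0
    meaning the N-terminus and 1..n a residue index.
    """

    sequence: str
    mods: tuple = ()
    protein_origin: str | None = None
    start_in_protein: int | None = None  # 1-based

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        n = len(self.sequence)
        seen = set()
        for pos, name, delta in self.mods:
            if not 0 <= pos <= n:
                raise ValueError(f"mod position {pos} outside 0..{n}")
            if pos in seen:
                raise ValueError(f"two mods at position {pos}")
            seen.add(pos)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ModConfig:
    """Fixed/variable modification sets.

    Each entry is ``(target, mass_delta)`` where target is a residue letter
    or ``"N-term"``. Defaults follow common TMT workflows: carbamidomethyl-C
    and TMT on K and the peptide N-terminus fixed, oxidation-M variable.
    """

    fixed: frozenset = frozenset(
        {("C", CARBAMIDOMETHYL), ("K", TMT10), ("N-term", TMT10)}
    )
    variable: frozenset = frozenset({("M", OXIDATION)})

    def fixed_mods_for(self, sequence: str) -> tuple:
        """Expand fixed-mod rules into concrete (position, name, delta) mods."""
        mods = []
        for target, delta in sorted(self.fixed):
            if target == "N-term":
                mods.append((0, "fixed-N-term", delta))
            else:
                for i, aa in enumerate(sequence, start=1):
                    if aa == target:
                        mods.append((i, f"fixed-{target}", delta))
        return tuple(mods)


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical b- or y-series fragment ion.

    b_j covers residues 1..j; y_k covers residues n-k+1..n.
    """

    series: str  # "b" | "y"
    index: int
    charge: int
    mz: float
    covers: tuple  # (first residue, last residue), 1-based inclusive

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}" + ("" if self.charge == 1 else f"^{self.charge}")


@dataclass(frozen=True)
class PeakMatch:
    ion: FragmentIon
    observed_mz: float
    intensity: float
    ppm_error: float


def digest(sequence: str, *, allow_nonstandard: bool = True) -> list[Peptide]:
    """Fully tryptic in silico digestion with zero missed cleavages.

    Cleaves C-terminal of K or R unless the next residue is proline. The
    concatenation of the products equals the input.
    """
    if not sequence:
        raise ValueError("cannot digest empty sequence")
    if not sequence.isupper():
        raise ValueError("protein sequence must be uppercase")
    if not allow_nonstandard:
        bad = set(sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)}")
    peptides = []
    start = 0
    for i, aa in enumerate(sequence):
        next_is_p = i + 1 < len(sequence) and sequence[i + 1] == "P"
        if aa in "KR" and not next_is_p:
            peptides.append(Peptide(sequence[start : i + 1], start_in_protein=start + 1))
            start = i + 1
    if start < len(sequence):
        peptides.append(Peptide(sequence[start:], start_in_protein=start + 1))
    return peptides


def generate_decoy(peptide: Peptide | str) -> Peptide:
    """Reversed-tryptic decoy: keep the C-terminal residue, reverse the rest.

    The operation is an involution and preserves length, composition and the
    tryptic C-terminus.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if not seq:
        raise ValueError("empty peptide")
    decoy_seq = seq[:-1][::-1] + seq[-1]
    return Peptide(decoy_seq)


def _mod_delta_sum(mods, lo: int, hi: int) -> float:
    """Sum of mod deltas with position in [lo, hi] (0 = N-terminus)."""
    return sum(delta for pos, _name, delta in mods if lo <= pos <= hi)


def peptide_mass(peptide: Peptide | str, mods: tuple | None = None) -> float:
    """Neutral monoisotopic peptide mass: residues + water + mod deltas."""
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    if mods is None:
        mods = peptide.mods
    try:
        residues = sum(RESIDUE_MASSES[aa] for aa in peptide.sequence)
    except KeyError as exc:
        raise ValueError(f"no mass for residue {exc.args[0]!r}") from exc
    return residues + WATER + sum(delta for _pos, _name, delta in mods)


def fragment_ions(
    peptide: Peptide | str,
    mods: tuple | None = None,
    max_charge: int = 1,
) -> list[FragmentIon]:
    """Theoretical b_1..b_{n-1} and y_1..y_{n-1} ions for charges 1..max_charge.

    b m/z = (prefix residue masses + prefix mods + z*proton)/z;
    y m/z = (suffix residue masses + suffix mods + water + z*proton)/z.
    N-terminal mods (position 0) ride on the b series; C-terminal context
    rides on y via the suffix sum.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    if mods is None:
        mods = peptide.mods
    n = len(peptide)
    if n < 2:
        raise ValueError("fragmentation requires length >= 2")
    try:
        masses = [RESIDUE_MASSES[aa] for aa in peptide.sequence]
    except KeyError as exc:
        raise ValueError(f"no mass for residue {exc.args[0]!r}") from exc

    prefix = [0.0]
    for m in masses:
        prefix.append(prefix[-1] + m)

    ions = []
    for j in range(1, n):
        b_neutral = prefix[j] + _mod_delta_sum(mods, 0, j)
        y_neutral = (prefix[n] - prefix[n - j]) + WATER + _mod_delta_sum(mods, n - j + 1, n)
        for z in range(1, max_charge + 1):
            ions.append(
                FragmentIon("b", j, z, (b_neutral + z * PROTON) / z, (1, j))
            )
            ions.append(
                FragmentIon("y", j, z, (y_neutral + z * PROTON) / z, (n - j + 1, n))
            )
    ions.sort(key=lambda ion: ion.mz)
    return ions


def match_peaks(
    spectrum,
    ions: list[FragmentIon],
    tol_ppm: float = 10.0,
) -> list[PeakMatch]:
    """Match theoretical ions to spectrum peaks within a ppm tolerance.

    Each ion matches at most one peak; among candidates within tolerance the
    smallest |ppm error| wins, ties broken by highest intensity. ``spectrum``
    must expose sorted ``mz`` and ``intensity`` arrays.
    """
    import numpy as np

    mz = np.asarray(spectrum.mz, dtype=float)
    intensity = np.asarray(spectrum.intensity, dtype=float)
    if mz.size and np.any(np.diff(mz) < 0):
        raise ValueError("spectrum peaks must be sorted by m/z")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")

    matches = []
    for ion in ions:
        tol = ion.mz * tol_ppm * 1e-6
        lo = np.searchsorted(mz, ion.mz - tol, side="left")
        hi = np.searchsorted(mz, ion.mz + tol, side="right")
        if lo == hi:
            continue
        cand_mz = mz[lo:hi]
        cand_int = intensity[lo:hi]
        ppm = (cand_mz - ion.mz) / ion.mz * 1e6
        # smallest |ppm|, then highest intensity
        order = sorted(range(len(cand_mz)), key=lambda k: (abs(ppm[k]), -cand_int[k]))
        best = order[0]
        matches.append(
            PeakMatch(ion, float(cand_mz[best]), float(cand_int[best]), float(ppm[best]))
        )
    return matches
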