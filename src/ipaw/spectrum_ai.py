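"""SpectrumAI: flanking-ion curation of single-substitution peptides.

A peptide-spectrum match claiming a single amino-acid substitution is only
trusted when the MS2 spectrum contains fragment ions covering the peptide
bonds on BOTH sides of the substituted residue, and those supporting ions
are collectively intense relative to the rest of the assigned fragments.
For a peptide of length n substituted at position i, the bond N-terminal of
the site is witnessed by b_{i-1} or y_{n-i+1} and the bond C-terminal of it
by b_i or y_{n-i}; e.g. n=12, i=8 admits exactly the pairs (b7,b8),
(y4,y5), (y4,b7), (y5,b8). Fragmentation C-terminal of proline is
suppressed, so when the residue preceding the site is proline any b or y
ion C-terminal of the site suffices instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .db_builder import collapse_il
from .peptides import ModConfig, fragment_ions, match_peaks

__all__ = [
    "FlankingRequirement",
    "CurationResult",
    "PSM",
    "MismatchResult",
    "flanking_requirements",
    "inspect_psm",
    "curate_peptides",
    "find_single_mismatch_parent",
]


@dataclass(frozen=True)
class FlankingRequirement:
    """Which fragment ions can certify a substitution at position i of n.

    ``bond_before``/``bond_after`` are sets of (series, index) labels for
    the bonds N- and C-terminal of the site. In standard mode one ion from
    each set is required; in proline_exception mode any single ion from
    ``bond_after`` (extended to everything C-terminal of the site)
    suffices; terminal modes require only the one internal bond.
    """

    n: int
    i: int
    bond_before: frozenset
    bond_after: frozenset
    mode: str  # standard | proline_exception | n_terminal | c_terminal

    @property
    def qualifying_pairs(self) -> set:
        if self.mode != "standard":
            return set()
        return {(a, b) for a in sorted(self.bond_before) for b in sorted(self.bond_after)}

    def supporting(self, matched: set) -> set:
        """Matched ion labels that count as flanking support."""
        return (self.bond_before | self.bond_after) & matched

    def satisfied_by(self, matched: set) -> bool:
        if self.mode == "standard":
            return bool(self.bond_before & matched) and bool(self.bond_after & matched)
        if self.mode == "proline_exception" or self.mode == "n_terminal":
            return bool(self.bond_after & matched)
        return bool(self.bond_before & matched)  # c_terminal


@dataclass
class CurationResult:
    psm_id: str
    verdict: bool
    matched_flanking: tuple
    support_intensity_sum: float
    median_fragment_intensity: float
    mode: str


@dataclass(frozen=True)
class PSM:
    """A peptide-spectrum match carrying a claimed substitution position."""

    psm_id: str
    spectrum_id: str
    peptide: str
    sub_pos: int  # 1-based; the substituted residue
    mods: tuple = ()
    charge: int | None = None
    score: float | None = None


@dataclass(frozen=True)
class MismatchResult:
    status: str  # "single" | "known" | "none"
    parent: str | None = None
    position: int | None = None  # 1-based
    ref: str | None = None
    alt: str | None = None


def flanking_requirements(n: int, i: int, preceding_residue: str | None = None) -> FlankingRequirement:
    """Enumerate the flanking-ion evidence sets for a substitution site.

    Position i=1 has no bond N-terminal of it and i=n none C-terminal, so
    only the existing internal bond is demanded there. A proline preceding
    the site (i > 1) switches to the relaxed C-terminal-only rule: any b_j
    with j >= i or y_k with k <= n - i.
    """
    if n < 2:
        raise ValueError("peptide length must be >= 2")
    if not 1 <= i <= n:
        raise ValueError(f"substitution position {i} outside 1..{n}")

    before = frozenset({("b", i - 1), ("y", n - i + 1)}) if i > 1 else frozenset()
    after = frozenset({("b", i), ("y", n - i)}) if i < n else frozenset()
    # b_n / y_n are precursor-like, not in the emitted series
    before = frozenset(lbl for lbl in before if 1 <= lbl[1] <= n - 1)
    after = frozenset(lbl for lbl in after if 1 <= lbl[1] <= n - 1)

    if i == 1:
        mode = "n_terminal"
    elif i == n:
        mode = "c_terminal"
    elif preceding_residue == "P":
        mode = "proline_exception"
        after = frozenset(
            {("b", j) for j in range(i, n)} | {("y", k) for k in range(1, n - i + 1)}
        )
        before = frozenset()
    else:
        mode = "standard"
    return FlankingRequirement(n, i, before, after, mode)


def inspect_psm(
    psm: PSM,
    spectrum,
    mod_config: ModConfig | None = None,
    tol_ppm: float = 10.0,
    *,
    median_mode: str = "matched",
    max_charge: int = 1,
) -> CurationResult:
    """Apply the two SpectrumAI criteria to one PSM.

    Pass requires (a) the flanking requirement met by peaks matched within
    ``tol_ppm`` and (b) the summed intensity of all matched flanking ions
    strictly greater than the median intensity of the comparison population
    — matched theoretical b/y ions by default, or every spectrum peak when
    ``median_mode="allpeaks"``.
    """
    if spectrum is None:
        raise ValueError(f"no spectrum for PSM {psm.psm_id}")
    if psm.sub_pos is None:
        raise ValueError(f"PSM {psm.psm_id} carries no substitution position")

    n = len(psm.peptide)
    mods = psm.mods
    if mod_config is not None:
        mods = mod_config.fixed_mods_for(psm.peptide) + tuple(psm.mods)
    ions = fragment_ions(psm.peptide, mods, max_charge=max_charge)
    matches = match_peaks(spectrum, ions, tol_ppm)
    matched_labels = {(m.ion.series, m.ion.index) for m in matches}

    preceding = psm.peptide[psm.sub_pos - 2] if psm.sub_pos >= 2 else None
    req = flanking_requirements(n, psm.sub_pos, preceding)

    support_labels = req.supporting(matched_labels)
    support_sum = sum(
        m.intensity for m in matches if (m.ion.series, m.ion.index) in support_labels
    )
    if median_mode == "allpeaks":
        population = np.asarray(spectrum.intensity, dtype=float)
    else:
        population = np.array([m.intensity for m in matches])
    median_intensity = float(np.median(population)) if population.size else 0.0

    verdict = req.satisfied_by(matched_labels) and support_sum > median_intensity
    return CurationResult(
        psm_id=psm.psm_id,
        verdict=bool(verdict),
        matched_flanking=tuple(sorted(support_labels)),
        support_intensity_sum=float(support_sum),
        median_fragment_intensity=median_intensity,
        mode=req.mode,
    )


def curate_peptides(
    psms,
    spectra: dict,
    mod_config: ModConfig | None = None,
    tol_ppm: float = 10.0,
    **kwargs,
):
    """Curate every PSM and roll verdicts up to peptides.

    A peptide passes when at least one of its PSMs passes. Returns
    (per-PSM results, {peptide: verdict}). A PSM whose spectrum is missing
    raises, as does a peptide with no PSMs in the table.
    """
    results = []
    per_peptide: dict[str, bool] = {}
    for psm in psms:
        spectrum = spectra.get(psm.spectrum_id)
        if spectrum is None:
            raise KeyError(f"spectrum {psm.spectrum_id!r} not found for PSM {psm.psm_id}")
        res = inspect_psm(psm, spectrum, mod_config, tol_ppm, **kwargs)
        results.append(res)
        per_peptide[psm.peptide] = per_peptide.get(psm.peptide, False) or res.verdict
    return results, per_peptide


def find_single_mismatch_parent(peptide: str, known_index) -> MismatchResult:
    """Locate a known tryptic peptide one substitution away.

    I=L counts as identity, so a peptide whose only difference is I<->L is
    reported as not novel (status "known"). When several parents qualify
    the lexicographically smallest is returned, making the routing
    deterministic. Peptides with no same-length neighbor within Hamming
    distance 1 return status "none" and stay in the multi-mismatch class.
    """
    query = collapse_il(peptide)
    candidates = [k for k in known_index if len(k) == len(peptide)]
    best = None
    for parent in sorted(candidates):
        collapsed = collapse_il(parent)
        if collapsed == query:
            return MismatchResult("known", parent=parent)
        diffs = [j for j, (a, b) in enumerate(zip(collapsed, query)) if a != b]
        if len(diffs) == 1 and best is None:
            j = diffs[0]
            best = MismatchResult(
                "single", parent=parent, position=j + 1,
                ref=parent[j], alt=peptide[j],
            )
    return best if best is not None else MismatchResult("none")
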