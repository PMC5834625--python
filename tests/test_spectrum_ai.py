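"""SpectrumAI flanking-ion curation and single-mismatch routing."""

import numpy as np
import pytest

from ipaw.io import Spectrum
from ipaw.peptides import fragment_ions
from ipaw.spectrum_ai import (
    PSM,
    curate_peptides,
    find_single_mismatch_parent,
    flanking_requirements,
    inspect_psm,
)


def test_flanking_pairs_for_length12_position8():
    req = flanking_requirements(12, 8, "A")
    assert req.mode == "standard"
    assert req.bond_before == {("b", 7), ("y", 5)}
    assert req.bond_after == {("b", 8), ("y", 4)}
    assert req.qualifying_pairs == {
        (("b", 7), ("b", 8)),
        (("b", 7), ("y", 4)),
        (("y", 5), ("b", 8)),
        (("y", 5), ("y", 4)),
    }


def test_flanking_terminal_positions():
    first = flanking_requirements(12, 1)
    assert first.mode == "n_terminal"
    assert first.bond_before == frozenset()
    assert first.bond_after == {("b", 1), ("y", 11)}
    last = flanking_requirements(12, 12)
    assert last.mode == "c_terminal"
    assert last.bond_before == {("b", 11), ("y", 1)}
    assert last.bond_after == frozenset()


def test_flanking_proline_exception():
    req = flanking_requirements(12, 8, "P")
    assert req.mode == "proline_exception"
    assert req.bond_after == (
        {("b", j) for j in range(8, 12)} | {("y", k) for k in range(1, 5)}
    )


def test_flanking_rejects_bad_positions():
    with pytest.raises(ValueError):
        flanking_requirements(12, 0)
    with pytest.raises(ValueError):
        flanking_requirements(12, 13)


def _spectrum_from_ions(ions, intensity=1e5, skip=(), low=(), low_scale=0.01):
    mz, inten = [], []
    for ion in ions:
        label = (ion.series, ion.index)
        if label in skip:
            continue
        mz.append(ion.mz)
        inten.append(intensity * (low_scale if label in low else 1.0))
    return Spectrum("s", None, None, np.array(mz), np.array(inten))


PEPTIDE = "ACDEFGHMSTVK"  # length 12, substitution claimed at position 8
SUB = 8
FLANKS = {("b", 7), ("b", 8), ("y", 4), ("y", 5)}


def _psm():
    return PSM("p1", "s", PEPTIDE, SUB)


def test_full_ion_spectrum_passes():
    spectrum = _spectrum_from_ions(fragment_ions(PEPTIDE))
    res = inspect_psm(_psm(), spectrum)
    assert res.verdict
    assert set(res.matched_flanking) == FLANKS


def test_missing_flanking_ions_fails():
    spectrum = _spectrum_from_ions(fragment_ions(PEPTIDE), skip=FLANKS)
    assert not inspect_psm(_psm(), spectrum).verdict


def test_weak_flanking_intensity_fails():
    spectrum = _spectrum_from_ions(fragment_ions(PEPTIDE), low=FLANKS)
    res = inspect_psm(_psm(), spectrum)
    assert not res.verdict
    assert res.support_intensity_sum <= res.median_fragment_intensity


def test_one_ion_per_side_suffices():
    keep_only = FLANKS - {("b", 7), ("y", 4)}  # leaves y5 (before), b8 (after)
    spectrum = _spectrum_from_ions(fragment_ions(PEPTIDE), skip=keep_only)
    assert inspect_psm(_psm(), spectrum).verdict


def test_adding_peaks_never_unmatches_flanks():
    """Criterion (a) is monotone: extra peaks cannot remove flank evidence."""
    base = _spectrum_from_ions(fragment_ions(PEPTIDE))
    res_base = inspect_psm(_psm(), base)
    rng = np.random.default_rng(0)
    extra_mz = np.concatenate([base.mz, rng.uniform(100, 1500, 30)])
    extra_int = np.concatenate([base.intensity, np.full(30, 1.0)])
    enriched = Spectrum("s", None, None, extra_mz, extra_int)
    res = inspect_psm(_psm(), enriched)
    assert set(res.matched_flanking) >= set(res_base.matched_flanking)


def test_peak_order_invariance():
    ions = fragment_ions(PEPTIDE)
    spectrum = _spectrum_from_ions(ions)
    rng = np.random.default_rng(1)
    order = rng.permutation(len(spectrum.mz))
    shuffled = Spectrum("s", None, None, spectrum.mz[order], spectrum.intensity[order])
    assert (
        inspect_psm(_psm(), shuffled).verdict == inspect_psm(_psm(), spectrum).verdict
    )


def test_deamidation_impostor_passes_flank_criterion():
    """An N->D impostor with full parent-ion coverage passes criterion (a).

    The qualifying pair (y_{n-i}, b_{i-1}) does not cover the substituted
    residue, so a spectrum of the asparagine-bearing known peptide still
    provides it; the discard of deamidation-explainable peptides at the
    FDR stage is the guard for this known limitation.
    """
    claimed = "ACDEFGHDSTVK"  # D at position 8
    parent = "ACDEFGHNSTVK"  # known sequence carries N
    spectrum = _spectrum_from_ions(fragment_ions(parent))
    res = inspect_psm(PSM("p", "s", claimed, 8), spectrum)
    assert ("b", 7) in res.matched_flanking and ("y", 4) in res.matched_flanking
    assert res.verdict


def test_peptide_rollup_any_pass(spectrum_bench):
    psm_pass, spec_pass, _, _ = [b for b in spectrum_bench if b[2] == "full"][0]
    psm_fail, spec_fail, _, _ = [
        b for b in spectrum_bench if b[2] == "flanking_deleted"
    ][0]
    # same peptide observed twice: one failing and one passing PSM
    twin = PSM("twin", psm_fail.spectrum_id, psm_pass.peptide, psm_pass.sub_pos)
    spectra = {psm_pass.spectrum_id: spec_pass, psm_fail.spectrum_id: spec_fail}
    _results, per_peptide = curate_peptides([psm_pass, twin], spectra)
    assert per_peptide[psm_pass.peptide] is True

    _results, per_peptide = curate_peptides([twin], spectra)
    assert per_peptide[psm_pass.peptide] is False


def test_missing_spectrum_raises(spectrum_bench):
    psm = spectrum_bench[0][0]
    with pytest.raises(KeyError):
        curate_peptides([psm], {})


def test_single_mismatch_parent_search():
    known = {"PEPTIDEK", "AAAAAAAK"}
    hit = find_single_mismatch_parent("PEPTADEK", known)
    assert (hit.status, hit.parent, hit.position, hit.ref, hit.alt) == (
        "single", "PEPTIDEK", 5, "I", "A",
    )
    assert find_single_mismatch_parent("PEPTLDEK", known).status == "known"
    assert find_single_mismatch_parent("WWWWWWWK", known).status == "none"


def test_single_mismatch_deterministic_parent_choice():
    # both parents are distance 1 from the query; routing is deterministic
    hit = find_single_mismatch_parent("CAPTIDEK", {"MAPTIDEK", "AAPTIDEK"})
    assert hit.parent == "AAPTIDEK"  # lexicographically first
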