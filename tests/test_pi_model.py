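"""Isoelectric-point model: net charge, bisection pI, strip calibration, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ipaw.peptides import ModConfig
from ipaw.pi_model import (
    DEFAULT_STRIPS,
    PKTable,
    fit_pk_constants,
    fraction_to_pi,
    net_charge,
    predict_pi,
    recenter_delta_pi,
    select_tightly_focused,
)

peptide_seq = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25)


def test_net_charge_limits():
    assert net_charge("K", 0.0) > 0
    assert net_charge("D", 14.0) < 0


def test_tmt_neutralizes_lysine_side_chain():
    """With TMT fixed on K and the N-terminus, only the C-terminus ionizes."""
    mods = ModConfig(fixed=frozenset({("K", 229.162932), ("N-term", 229.162932)}))
    # charge reduces to the C-terminal carboxyl curve: 0 at pH 0, -1 at pH 14
    assert net_charge("KKK", 0.0, mod_config=mods) == pytest.approx(0.0, abs=1e-3)
    assert net_charge("KKK", 14.0, mod_config=mods) == pytest.approx(-1.0, abs=1e-3)


@given(peptide_seq, st.floats(0.5, 13.5), st.floats(0.01, 0.49))
@settings(max_examples=100, derandomize=True)
def test_net_charge_monotone_decreasing(seq, pH, dpH):
    assert net_charge(seq, pH + dpH) < net_charge(seq, pH) + 1e-12


@given(peptide_seq)
@settings(max_examples=100, derandomize=True)
def test_predict_pi_is_charge_root(seq):
    pi = predict_pi(seq)
    if 0.0 < pi < 14.0:
        assert abs(net_charge(seq, pi)) < 1e-3


def test_predict_pi_ordering_and_clamps():
    assert predict_pi("DDDDDDGK") < predict_pi("KKKKKKGD")
    # all-acidic active groups: no root in range, clamp low
    mods = ModConfig(fixed=frozenset({("K", 229.162932), ("N-term", 229.162932)}))
    assert predict_pi("GGGD", mod_config=mods) == 0.0


def test_acidic_residue_never_raises_pi():
    for seq in ("GGGKH", "PEPTIDEK", "KKDDL"):
        assert predict_pi(seq + "D") <= predict_pi(seq) + 1e-6
        assert predict_pi(seq + "K") >= predict_pi(seq) - 1e-6


@pytest.mark.parametrize(
    "strip,fraction,expected",
    [
        ("IPG3-10", 0, 3.5478),
        ("IPG6-11", 0, 10.3936),
        ("IPG3-10", 10, 4.2238),
        ("IPG3.7-4.9", 0, 3.5959),
        ("IPG6-9", 0, 6.1159),
    ],
)
def test_strip_calibrations(strip, fraction, expected):
    assert fraction_to_pi(strip, fraction) == pytest.approx(expected, abs=1e-9)


def test_fraction_to_pi_is_affine():
    for strip in DEFAULT_STRIPS.values():
        for x in (0, 5, 33):
            assert fraction_to_pi(strip, x + 1) - fraction_to_pi(strip, x) == (
                pytest.approx(strip.slope)
            )


def test_unknown_strip_rejected():
    with pytest.raises(KeyError):
        fraction_to_pi("IPG0-1", 3)


def test_tightly_focused_selection():
    obs = [
        ("ONEFRAC", 12, 1e-4),
        ("CONSEC", 12, 1e-4),
        ("CONSEC", 13, 1e-4),
        ("SPREAD", 12, 1e-4),
        ("SPREAD", 14, 1e-4),
        ("BADPEP", 10, 0.01),
    ]
    kept = select_tightly_focused(obs)
    assert set(kept) == {"ONEFRAC", "CONSEC"}
    assert kept["CONSEC"] == [12, 13]


def test_recenter_delta_pi_uses_median():
    assert recenter_delta_pi([(4.04, 4.0), (4.05, 4.0), (4.06, 4.0)]).shift == (
        pytest.approx(0.05)
    )
    assert recenter_delta_pi([(5.0, 5.0), (6.0, 6.0)]).shift == 0.0
    assert recenter_delta_pi([(3.9, 4.0), (4.0, 4.0), (4.5, 4.0)]).shift == 0.0
    with pytest.raises(ValueError):
        recenter_delta_pi([])


def _training_set(table, n, seed, noise=0.0):
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    pairs = []
    while len(pairs) < n:
        seq = "".join(rng.choice(aas, size=int(rng.integers(8, 25))))
        pi = predict_pi(seq, table)
        if 0.0 < pi < 14.0:
            pairs.append((seq, pi + rng.normal(0, noise) if noise else pi))
    return pairs


def test_pk_recovery_noise_free():
    """Refitting on noise-free data recovers perturbed pK constants."""
    true = PKTable().with_pk({"D": 3.8, "E": 4.6, "K": 10.4})
    pairs = _training_set(true, 200, seed=2)
    fitted, report = fit_pk_constants(pairs, PKTable(), groups=("D", "E", "K"), seed=2)
    for g in ("D", "E", "K"):
        assert fitted.pk[g] == pytest.approx(true.pk[g], abs=0.05)
    assert report["train_mae"] <= report["initial_train_mae"]


def test_pk_fit_with_noise_keeps_margin():
    """With sigma=0.05 pI noise the test-set median error stays within 0.11."""
    true = PKTable()
    train = _training_set(true, 150, seed=3, noise=0.05)
    test = _training_set(true, 150, seed=4, noise=0.05)
    _fitted, report = fit_pk_constants(
        train, PKTable(), groups=("D", "E", "K"), test=test, seed=3
    )
    assert report["test_median_abs"] <= 0.11


def test_pk_fit_deterministic_given_seed():
    true = PKTable().with_pk({"E": 4.7})
    pairs = _training_set(true, 120, seed=5)
    a, _ = fit_pk_constants(pairs, PKTable(), groups=("E",), seed=9)
    b, _ = fit_pk_constants(pairs, PKTable(), groups=("E",), seed=9)
    assert a.pk == b.pk


def test_pk_fit_input_validation():
    true = PKTable()
    with pytest.raises(ValueError):
        fit_pk_constants(_training_set(true, 50, seed=0), true)
    flat = [(s, 7.0) for s, _ in _training_set(true, 120, seed=1)]
    with pytest.raises(ValueError):
        fit_pk_constants(flat, true)


def test_pk_table_tsv_roundtrip(tmp_path):
    table = PKTable().with_pk({"D": 3.9})
    path = tmp_path / "pk.tsv"
    table.to_tsv(path)
    loaded = PKTable.from_tsv(path)
    assert loaded.pk["D"] == pytest.approx(3.9)
    assert loaded.neutralized_by == table.neutralized_by
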