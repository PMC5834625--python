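"""Peptide isoelectric-point prediction and IPG-strip calibration.

The pI model is a Henderson-Hasselbalch net-charge model over ionizable
side chains and termini, solved by bisection. High-resolution isoelectric
focusing (HiRIEF) fraction numbers convert to experimental pI by per-strip
linear calibrations; pK constants can be refitted from tightly focused
peptides, and per-strip delta-pI recentering removes run-to-run offsets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .peptides import ModConfig

__all__ = [
    "PKTable",
    "IPGStripCalibration",
    "PiCalibrationResult",
    "DEFAULT_STRIPS",
    "net_charge",
    "predict_pi",
    "fraction_to_pi",
    "select_tightly_focused",
    "fit_pk_constants",
    "recenter_delta_pi",
]

ACIDIC_GROUPS = ("D", "E", "C", "Y", "C-term")
BASIC_GROUPS = ("H", "K", "R", "N-term")


@dataclass(frozen=True)
class PKTable:
    """pK constants per ionizable group with modification-neutralization map.

    Acidic groups contribute charge -1/(1+10^(pK-pH)); basic groups
    +1/(1+10^(pH-pK)). ``neutralized_by`` maps a fixed-modification target
    (residue letter or "N-term") to the group it silences: TMT blocks the
    lysine epsilon-amine and the alpha-amine, carbamidomethyl blocks the
    cysteine thiol.

    Default values are a Bjellqvist-style table; the constants are fully
    user-loadable from TSV so a refitted set can be dropped in.
    """

    pk: dict = field(
        default_factory=lambda: {
            "D": 4.05,
            "E": 4.45,
            "C": 9.0,
            "Y": 10.0,
            "H": 5.98,
            "K": 10.0,
            "R": 12.0,
            "N-term": 7.5,
            "C-term": 3.55,
        }
    )
    neutralized_by: dict = field(
        default_factory=lambda: {"K": "K", "N-term": "N-term", "C": "C"}
    )

    def __post_init__(self):
        for group, value in self.pk.items():
            if not 0 < value < 14:
                raise ValueError(f"pK for {group} outside (0,14): {value}")

    def neutralized_groups(self, mod_config: ModConfig | None) -> frozenset:
        if mod_config is None:
            return frozenset()
        return frozenset(
            self.neutralized_by[target]
            for target, _delta in mod_config.fixed
            if target in self.neutralized_by
        )

    def with_pk(self, updates: dict) -> "PKTable":
        merged = dict(self.pk)
        merged.update(updates)
        return replace(self, pk=merged)

    @classmethod
    def from_tsv(cls, path) -> "PKTable":
        """Load columns group, pK, sign, neutralized_by (sign informational)."""
        pk = {}
        neutralized = {}
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                pk[row["group"]] = float(row["pK"])
                target = row.get("neutralized_by", "")
                if target:
                    neutralized[target] = row["group"]
        return cls(pk=pk, neutralized_by=neutralized or cls().neutralized_by)

    def to_tsv(self, path) -> None:
        inverse = {group: target for target, group in self.neutralized_by.items()}
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["group", "pK", "sign", "neutralized_by"])
            for group, value in self.pk.items():
                sign = "-" if group in ACIDIC_GROUPS else "+"
                writer.writerow([group, f"{value:.4f}", sign, inverse.get(group, "")])


@dataclass(frozen=True)
class IPGStripCalibration:
    """Linear fraction-number to experimental-pI calibration of one IPG strip."""

    name: str
    slope: float  # pI units per fraction
    intercept: float  # pI at fraction 0
    fraction_count: int = 72
    orientation_note: str = ""

    def pi_at(self, fraction: float) -> float:
        return self.slope * fraction + self.intercept


# Calibrations of the four HiRIEF ranges. IPG6-11 runs alkaline-to-acidic,
# hence the negative slope.
DEFAULT_STRIPS = {
    "IPG3-10": IPGStripCalibration("IPG3-10", 0.0676, 3.5478),
    "IPG3.7-4.9": IPGStripCalibration("IPG3.7-4.9", 0.0174, 3.5959),
    "IPG6-9": IPGStripCalibration("IPG6-9", 0.0336, 6.1159),
    "IPG6-11": IPGStripCalibration(
        "IPG6-11", -0.0762, 10.3936,
        orientation_note="lower fraction numbers at the alkaline end",
    ),
}


@dataclass
class PiCalibrationResult:
    strip: str
    shift: float
    delta_pi: np.ndarray


def _active_groups(sequence: str, pk_table: PKTable, mod_config: ModConfig | None):
    """Yield (group, count) for ionizable groups not silenced by fixed mods."""
    neutralized = pk_table.neutralized_groups(mod_config)
    counts = {}
    for group in ("N-term", "C-term"):
        if group in pk_table.pk and group not in neutralized:
            counts[group] = 1
    for aa in sequence:
        if aa in pk_table.pk and aa not in neutralized:
            counts[aa] = counts.get(aa, 0) + 1
    return counts


def net_charge(
    sequence: str,
    pH: float,
    pk_table: PKTable | None = None,
    mod_config: ModConfig | None = None,
) -> float:
    """Signed net charge of a peptide at the given pH.

    Strictly decreasing in pH for any peptide with at least one active group.
    """
    if not 0 <= pH <= 14:
        raise ValueError("pH outside 0..14")
    pk_table = pk_table or PKTable()
    charge = 0.0
    for group, count in _active_groups(sequence, pk_table, mod_config).items():
        pk = pk_table.pk[group]
        if group in ACIDIC_GROUPS:
            charge -= count / (1.0 + 10.0 ** (pk - pH))
        else:
            charge += count / (1.0 + 10.0 ** (pH - pk))
    return charge


def predict_pi(
    sequence: str,
    pk_table: PKTable | None = None,
    mod_config: ModConfig | None = None,
    *,
    charge_tol: float = 1e-4,
    max_iter: int = 100,
) -> float:
    """pI as the bisection root of the net-charge curve on [0, 14].

    Degenerate peptides without a sign change are clamped: net negative
    everywhere -> 0, net positive everywhere -> 14.
    """
    pk_table = pk_table or PKTable()
    lo, hi = 0.0, 14.0
    c_lo = net_charge(sequence, lo, pk_table, mod_config)
    c_hi = net_charge(sequence, hi, pk_table, mod_config)
    if c_lo <= 0:
        return 0.0
    if c_hi >= 0:
        return 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c_mid = net_charge(sequence, mid, pk_table, mod_config)
        if abs(c_mid) < charge_tol:
            return mid
        if c_mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fraction_to_pi(strip: IPGStripCalibration | str, fraction: float) -> float:
    """Experimental pI of a fraction number under a strip calibration."""
    if isinstance(strip, str):
        try:
            strip = DEFAULT_STRIPS[strip]
        except KeyError:
            raise KeyError(f"unknown strip {strip!r}; known: {sorted(DEFAULT_STRIPS)}")
    if fraction < 0:
        raise ValueError("fraction number must be >= 0")
    return strip.pi_at(fraction)


def select_tightly_focused(
    observations,
    pep_threshold: float = 0.001,
) -> dict[str, list[int]]:
    """Keep peptides seen in one fraction, or two consecutive fractions.

    ``observations`` is an iterable of (peptide, fraction, PEP); entries at
    or above the PEP threshold are excluded before the fraction test.
    Returns {peptide: sorted fraction list} for the survivors.
    """
    fractions: dict[str, set] = {}
    for peptide, fraction, pep in observations:
        if pep < pep_threshold:
            fractions.setdefault(peptide, set()).add(int(fraction))
    kept = {}
    for peptide, fracs in fractions.items():
        ordered = sorted(fracs)
        if len(ordered) == 1 or (len(ordered) == 2 and ordered[1] - ordered[0] == 1):
            kept[peptide] = ordered
    return kept


def _group_counts(sequences, pk_table: PKTable, mod_config: ModConfig | None):
    """(n_peptides, n_groups) active-group count matrix for batch prediction."""
    order = list(pk_table.pk)
    neutralized = pk_table.neutralized_groups(mod_config)
    counts = np.zeros((len(sequences), len(order)))
    col = {g: k for k, g in enumerate(order)}
    for i, seq in enumerate(sequences):
        for g in ("N-term", "C-term"):
            if g in col and g not in neutralized:
                counts[i, col[g]] = 1
        for aa in seq:
            if aa in col and aa not in neutralized:
                counts[i, col[aa]] += 1
    acidic = np.array([g in ACIDIC_GROUPS for g in order])
    return counts, acidic, order


def _predict_pi_batch(counts, acidic, pk_values, n_iter: int = 60):
    """Vectorized bisection of the net-charge curve for many peptides."""
    lo = np.zeros(counts.shape[0])
    hi = np.full(counts.shape[0], 14.0)

    def charge(pH):
        with np.errstate(over="ignore"):
            acid = counts[:, acidic] / (1.0 + 10.0 ** (pk_values[acidic] - pH[:, None]))
            base = counts[:, ~acidic] / (1.0 + 10.0 ** (pH[:, None] - pk_values[~acidic]))
        return base.sum(axis=1) - acid.sum(axis=1)

    c_lo = charge(lo)
    c_hi = charge(hi)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        c_mid = charge(mid)
        take_hi = c_mid > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    out = 0.5 * (lo + hi)
    out[c_lo <= 0] = 0.0
    out[c_hi >= 0] = 14.0
    return out


def fit_pk_constants(
    training,
    initial: PKTable | None = None,
    *,
    mod_config: ModConfig | None = None,
    groups: tuple = tuple(ACIDIC_GROUPS + BASIC_GROUPS),
    test=None,
    seed: int = 0,
    n_restarts: int = 2,
) -> tuple[PKTable, dict]:
    """Refit pK constants to minimize mean |experimental - predicted| pI.

    ``training`` is a list of (sequence, experimental_pi). Runs Nelder-Mead
    over the selected pK ``groups`` with seeded random restarts, evaluating
    the objective through a vectorized bisection solver; never returns a
    table worse on the training set than the initial one. Returns
    (fitted table, report) with train/test mean absolute errors.
    """
    initial = initial or PKTable()
    training = list(training)
    if len(training) < 100:
        raise ValueError("need >= 100 training pairs")
    pis = np.array([pi for _seq, pi in training])
    if pis.max() - pis.min() < 2.0:
        raise ValueError("training pI range must span >= 2 units")

    groups = tuple(g for g in groups if g in initial.pk)
    counts, acidic, order = _group_counts(
        [seq for seq, _pi in training], initial, mod_config
    )
    base_pk = np.array([initial.pk[g] for g in order])
    group_idx = np.array([order.index(g) for g in groups])

    def mae(x):
        pk_values = base_pk.copy()
        pk_values[group_idx] = x
        return float(np.mean(np.abs(pis - _predict_pi_batch(counts, acidic, pk_values))))

    def objective(x):
        if np.any(x <= 0.05) or np.any(x >= 13.95):
            return 1e6
        return mae(x)

    rng = np.random.default_rng(seed)
    x0 = np.array([initial.pk[g] for g in groups])
    best_x, best_err = x0, mae(x0)
    starts = [x0] + [
        np.clip(x0 + rng.normal(0, 0.3, size=len(groups)), 0.5, 13.5)
        for _ in range(n_restarts)
    ]
    for start in starts:
        result = minimize(
            objective, start, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 4000, "maxfev": 4000},
        )
        if result.fun < best_err:
            best_err, best_x = float(result.fun), result.x

    fitted = initial.with_pk(dict(zip(groups, map(float, best_x))))
    report = {"train_mae": best_err, "initial_train_mae": mae(x0)}
    if test:
        test = list(test)
        t_counts, t_acidic, _ = _group_counts(
            [seq for seq, _pi in test], fitted, mod_config
        )
        fitted_pk = np.array([fitted.pk[g] for g in order])
        t_pred = _predict_pi_batch(t_counts, t_acidic, fitted_pk)
        report["test_mae"] = float(
            np.mean(np.abs(np.array([pi for _s, pi in test]) - t_pred))
        )
        report["test_median_abs"] = float(
            np.median(np.abs(np.array([pi for _s, pi in test]) - t_pred))
        )
    return fitted, report


def recenter_delta_pi(pairs, strip: str = "") -> PiCalibrationResult:
    """Per-strip shift so the median delta pI (experimental - predicted) is 0.

    ``pairs`` are (experimental_pi, predicted_pi) from high-confidence
    peptides; subtract the returned shift from experimental values to center.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no (experimental, predicted) pairs given")
    deltas = np.array([exp - pred for exp, pred in pairs])
    return PiCalibrationResult(strip=strip, shift=float(np.median(deltas)), delta_pi=deltas)
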