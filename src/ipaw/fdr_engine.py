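"""Class-specific target-decoy FDR for novel and SAAV peptides.

The workflow searches target and decoy databases separately; this module
consumes the two score lists, assigns peptide classes from database
provenance, discards matches explainable as known peptides under residue
equivalences (I=L, deamidation N->D), and estimates class-specific FDR as
decoys/targets above each score threshold with monotone q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .db_builder import collapse_il, _nd_key

__all__ = [
    "PSMRecord",
    "FdrResult",
    "assign_class",
    "discard_known_equivalents",
    "class_fdr",
]

CLASSES = ("known", "novel", "saav")
NOVEL_SOURCES = {"6ft", "sixframe", "pseudogene", "lncrna", "ncrna"}
SAAV_SOURCES = {"canprovar", "cosmic", "vardb", "saav"}


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match in an FDR-ready score list."""

    psm_id: str
    peptide: str
    score: float
    is_decoy: bool = False
    peptide_class: str = "novel"
    source: str = ""

    def __post_init__(self):
        if self.peptide_class not in CLASSES:
            raise ValueError(f"class must be one of {CLASSES}")


@dataclass
class FdrResult:
    """Per-record FDR and q-values at each record's score threshold."""

    table: pd.DataFrame  # columns: psm_id, peptide, score, is_decoy, fdr, q_value

    def n_accepted(self, q_threshold: float = 0.01) -> int:
        t = self.table
        return int(((~t.is_decoy) & (t.q_value <= q_threshold)).sum())


def assign_class(sources, provenance: dict[str, str]) -> str:
    """Class of a peptide from the databases it occurs in.

    ``sources`` is the set of database tags the peptide matched;
    ``provenance`` maps each tag to "known", "novel" or "saav". Presence in
    the canonical proteome wins: such a peptide is "known" regardless of
    also appearing in variant or six-frame space.
    """
    labels = set()
    for tag in sources:
        key = tag.lower()
        if key in provenance:
            labels.add(provenance[key])
        elif key in NOVEL_SOURCES:
            labels.add("novel")
        elif key in SAAV_SOURCES:
            labels.add("saav")
        elif key in ("known", "canonical", "ensembl", "uniprot"):
            labels.add("known")
        else:
            raise KeyError(f"database tag {tag!r} missing from provenance map")
    if "known" in labels:
        return "known"
    if "novel" in labels:
        return "novel"
    if "saav" in labels:
        return "saav"
    raise ValueError("no class could be assigned")


def discard_known_equivalents(psms, known_index):
    """Drop target AND decoy PSMs equal to known peptides under equivalences.

    Equivalences: I=L always; deamidation-explainable N->D matches are also
    removed. Returns (retained, report) with per-class removal counts.
    """
    exact = {collapse_il(k) for k in known_index}
    nd = {_nd_key(k) for k in known_index}
    retained = []
    report = {"removed": {}, "kept": 0}
    for psm in psms:
        key = collapse_il(psm.peptide)
        if key in exact or _nd_key(psm.peptide) in nd:
            cls = getattr(psm, "peptide_class", "novel")
            kind = "decoy" if psm.is_decoy else "target"
            report["removed"][(cls, kind)] = report["removed"].get((cls, kind), 0) + 1
        else:
            retained.append(psm)
    report["kept"] = len(retained)
    return retained, report


def class_fdr(
    targets,
    decoys,
    *,
    higher_better: bool = True,
    peptide_level: bool = True,
) -> FdrResult:
    """Class-specific FDR: decoys/targets above each score threshold.

    ``targets`` and ``decoys`` are PSMRecord lists (or (id, peptide, score)
    tuples) from one class searched against its own target and decoy
    databases. With ``peptide_level`` each peptide is represented by its
    best-scoring PSM before estimation. Ties at a threshold count decoys
    before targets (conservative). q-values are the running minimum of FDR
    from the strictest threshold outward.
    """

    def as_frame(records, is_decoy):
        rows = []
        for r in records:
            if isinstance(r, PSMRecord):
                rows.append((r.psm_id, r.peptide, r.score))
            else:
                rows.append(tuple(r[:3]))
        df = pd.DataFrame(rows, columns=["psm_id", "peptide", "score"])
        df["is_decoy"] = is_decoy
        return df

    t = as_frame(targets, False)
    d = as_frame(decoys, True)
    if t.empty:
        raise ValueError("no target PSMs for this class")
    if d.empty:
        raise ValueError("no decoy PSMs for this class")

    df = pd.concat([t, d], ignore_index=True)
    if not higher_better:
        df["score"] = -df["score"]

    if peptide_level:
        df = (
            df.sort_values("score", ascending=False)
            .groupby(["peptide", "is_decoy"], as_index=False)
            .first()
        )

    # strictest first; decoys ahead of targets on score ties
    df = df.sort_values(
        ["score", "is_decoy"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
    cum_decoys = df.is_decoy.cumsum()
    cum_targets = (~df.is_decoy).cumsum()
    fdr = np.where(cum_targets > 0, cum_decoys / cum_targets.clip(lower=1), 0.0)
    fdr = np.clip(fdr, 0.0, 1.0)
    q = np.minimum.accumulate(fdr[::-1])[::-1]

    df["fdr"] = fdr
    df["q_value"] = q
    if not higher_better:
        df["score"] = -df["score"]
    return FdrResult(table=df)
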