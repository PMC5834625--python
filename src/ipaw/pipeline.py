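"""End-to-end curation orchestration.

Wires the curation stage in its canonical order — known-match removal,
single-mismatch routing, SpectrumAI inspection, multi-mapping
deprioritization — over a PSM table and spectra store, writing stage
outputs and a manifest with per-stage counts. The MS search itself is
upstream: PSM tables from any engine are consumed as TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .db_builder import collapse_il, known_peptide_index
from .genome_mapper import detect_multimapping
from .peptides import ModConfig
from .spectrum_ai import PSM, curate_peptides, find_single_mismatch_parent

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and thresholds for a curation run.

    ``psms`` rows need columns psm_id, spectrum_id, peptide, and optional
    sub_pos/score. Tolerances are in ppm; ``seed`` controls any sampling
    downstream stages perform.
    """

    out_dir: str
    fragment_tol_ppm: float = 10.0
    precursor_tol_ppm: float = 10.0
    seed: int = 0
    run_spectrum_ai: bool = True
    deprioritize_multimapped: bool = True


def run_pipeline(
    config: PipelineConfig,
    psm_table: pd.DataFrame,
    spectra: dict,
    known_proteins: dict,
    genomic_peptide_index: dict | None = None,
    mod_config: ModConfig | None = None,
) -> dict:
    """Run the curation stage and write per-stage outputs plus a manifest.

    Returns the manifest dict; the curated PSM table lands in
    ``<out_dir>/curated_psms.tsv`` with one fate per input PSM, making
    every removal auditable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    known = known_peptide_index(known_proteins)
    counts = {"input": len(psm_table)}
    table = psm_table.copy()
    table["fate"] = "retained"
    table["sub_pos"] = table.get("sub_pos", pd.Series([None] * len(table)))
    table["parent"] = None

    # 1. exact known-match removal (I=L)
    exact = table.peptide.map(lambda p: collapse_il(p) in known)
    table.loc[exact, "fate"] = "exact match removed"
    counts["exact_match_removed"] = int(exact.sum())

    # 2. single-mismatch routing for peptides without an annotated site
    for idx, row in table[~exact].iterrows():
        if pd.notna(row.sub_pos) and row.sub_pos:
            continue
        hit = find_single_mismatch_parent(row.peptide, known)
        if hit.status == "known":
            table.loc[idx, "fate"] = "known under I=L"
        elif hit.status == "single":
            table.loc[idx, ["sub_pos", "parent"]] = [hit.position, hit.parent]
    counts["routed_to_spectrum_ai"] = int(
        ((table.fate == "retained") & table.sub_pos.notna()).sum()
    )

    # 3. SpectrumAI on every retained single-substitution PSM
    if config.run_spectrum_ai:
        candidates = table[(table.fate == "retained") & table.sub_pos.notna()]
        psms = [
            PSM(
                psm_id=str(row.psm_id),
                spectrum_id=str(row.spectrum_id),
                peptide=row.peptide,
                sub_pos=int(row.sub_pos),
            )
            for row in candidates.itertuples()
        ]
        results, per_peptide = curate_peptides(
            psms, spectra, mod_config, config.fragment_tol_ppm
        )
        verdicts = {r.psm_id: r.verdict for r in results}
        for idx, row in candidates.iterrows():
            if not verdicts[str(row.psm_id)]:
                table.loc[idx, "fate"] = "spectrum_ai failed"
        counts["spectrum_ai_pass"] = sum(verdicts.values())
        counts["spectrum_ai_fail"] = len(verdicts) - sum(verdicts.values())

    # 4. multi-mapping deprioritization (flagged, not deleted)
    table["multimapped"] = False
    if config.deprioritize_multimapped and genomic_peptide_index is not None:
        for idx, row in table[table.fate == "retained"].iterrows():
            if detect_multimapping(row.peptide, genomic_peptide_index) > 1:
                table.loc[idx, "multimapped"] = True
        counts["multimapped_flagged"] = int(table.multimapped.sum())

    counts["retained"] = int((table.fate == "retained").sum())
    table.to_csv(out / "curated_psms.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
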