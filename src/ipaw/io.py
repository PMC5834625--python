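"""File I/O: FASTA, MGF and mzML readers behind small uniform contracts.

FASTA goes through Biopython; spectrum formats go through pyteomics. The
Spectrum container is deliberately minimal: an identifier, a precursor
descriptor and sorted peak arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Spectrum", "read_fasta", "write_fasta", "read_mgf", "read_mzml"]


@dataclass
class Spectrum:
    """An MS2 spectrum: title/scan identifier, precursor, sorted peak list."""

    spectrum_id: str
    precursor_mz: float | None
    precursor_charge: int | None
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must align")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {header: sequence} mapping."""
    return {rec.description: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(entries: dict[str, str], path) -> None:
    """Write {header: sequence} to FASTA, 60-column wrapped."""
    records = [
        SeqRecord(Seq(seq), id=header.split()[0], description=header)
        for header, seq in entries.items()
    ]
    # SeqRecord duplicates id inside description unless they coincide
    for rec, header in zip(records, entries):
        rec.id = header
        rec.description = ""
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_mgf(path) -> list[Spectrum]:
    from pyteomics import mgf

    spectra = []
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pep = params.get("pepmass")
            charge = params.get("charge")
            spectra.append(
                Spectrum(
                    spectrum_id=str(params.get("title", len(spectra))),
                    precursor_mz=float(pep[0]) if pep else None,
                    precursor_charge=int(charge[0]) if charge else None,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return spectra


def read_mzml(path) -> list[Spectrum]:
    from pyteomics import mzml

    spectra = []
    with mzml.MzML(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            precursor_mz = None
            precursor_charge = None
            try:
                ion = entry["precursorList"]["precursor"][0]["selectedIonList"][
                    "selectedIon"
                ][0]
                precursor_mz = float(ion.get("selected ion m/z"))
                if "charge state" in ion:
                    precursor_charge = int(ion["charge state"])
            except (KeyError, IndexError, TypeError):
                pass
            spectra.append(
                Spectrum(
                    spectrum_id=str(entry.get("id", len(spectra))),
                    precursor_mz=precursor_mz,
                    precursor_charge=precursor_charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return spectra
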