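"""Bundled reference data: published Tm panels, primer table, bench metadata.

These are *measured instrument values*, shipped as data. The toolkit's
thermodynamic predictions are never calibrated against them; panels are what
unknown samples are classified against.

The bundled COXII template is a SYNTHETIC stand-in: a random sequence
carrying the COX2-519/COX2-615 primer footprints at the published 97 bp
spacing and coordinates, for exercising in-silico PCR without network access
to GenBank. It is not the real mitochondrial sequence.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd

from .io import read_fasta, read_panel
from .records import BarcodeRecord, ReferencePanel

__all__ = [
    "cox2_panel",
    "c1_panel",
    "cox2_repeat_panel",
    "cox2_larva_panel",
    "primer_table",
    "selected_primers",
    "dna_concentrations",
    "genbank_accessions",
    "synthetic_coxii_template",
]


def _data(name: str) -> Path:
    return Path(str(files("hrmid").joinpath("data", name)))


def cox2_panel() -> ReferencePanel:
    """Ten-species single-peak panel for the COX2-519/COX2-615 primer set."""
    return read_panel(_data("cox2_panel.tsv"), panel_id="COX2",
                      primer_set="COX2-519/COX2-615")


def c1_panel() -> ReferencePanel:
    """Six-species panel for C1-J-2495/C1-N-2800; S. princeps has 3 peaks."""
    return read_panel(_data("c1_panel.tsv"), panel_id="C1",
                      primer_set="C1-J-2495/C1-N-2800")


def cox2_repeat_panel() -> ReferencePanel:
    """Repeat run of five Sarcophagidae species (replicate-drift QC)."""
    return read_panel(_data("cox2_repeat_panel.tsv"), panel_id="COX2-repeat",
                      primer_set="COX2-519/COX2-615")


def cox2_larva_panel() -> ReferencePanel:
    """Five-species reference run co-amplified with the unknown larva."""
    return read_panel(_data("cox2_larva_panel.tsv"), panel_id="COX2-larva",
                      primer_set="COX2-519/COX2-615")


def primer_table() -> pd.DataFrame:
    """All screened primer pairs (designed and literature) with metadata."""
    return pd.read_csv(_data("primers.tsv"), sep="\t")


def selected_primers() -> dict[str, dict]:
    """The two primer pairs retained for species identification.

    Returns a mapping pair-name -> {fwd, rev, product_bp, anneal_c, gene}.
    """
    df = primer_table()
    sel = df[df["selected"] == "yes"]
    return {
        row["pair"]: {
            "fwd": row["fwd"],
            "rev": row["rev"],
            "product_bp": int(row["target_bp"]),
            "anneal_c": float(row["anneal_c"]),
            "gene": row["gene"],
        }
        for _, row in sel.iterrows()
    }


def dna_concentrations() -> dict[str, float]:
    """Measured dsDNA concentration (ng/uL) per species after extraction."""
    df = pd.read_csv(_data("dna_concentrations.tsv"), sep="\t")
    return dict(zip(df["species"], df["conc_ng_per_ul"].astype(float)))


def genbank_accessions() -> pd.DataFrame:
    """GenBank accession:coordinate intervals of the COXI/COXII regions."""
    return pd.read_csv(_data("genbank_accessions.tsv"), sep="\t")


def synthetic_coxii_template() -> BarcodeRecord:
    """SYNTHETIC COXII-like template carrying the COX2-519/615 footprints.

    A seeded random 691 bp sequence with the published primer binding sites
    at gene coordinates 519-615 (97 bp product), standing in for the real
    accession which requires network access to fetch.
    """
    return read_fasta(_data("synthetic_coxii_template.fasta"))[0]
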