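"""Readers and writers for the toolkit's file formats.

FASTA (multi-record, gaps allowed) via Biopython; reference-panel TSV with
semicolon-joined peak lists so a species' multi-peak signature stays atomic;
a JSON mirror of the TSV for interchange.

FASTA header dialect: ``species|gene|accession`` when the pipe delimiter is
present, otherwise the whole header is the species name. Unknown extra fields
are tolerated. An accession may carry GenBank-style 1-based coordinates,
``NC_019633.1:3033-3720``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    AlphabetError,
    BarcodeRecord,
    PanelEntry,
    PanelValidationError,
    ReferencePanel,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_panel",
    "write_panel",
    "panel_to_json",
    "panel_from_json",
    "FastaFormatError",
]

_ACCESSION_COORDS = re.compile(r"^(?P<acc>.+?):(?P<start>\d+)-(?P<end>\d+)$")


class FastaFormatError(ValueError):
    """The input is not parseable FASTA."""


def _parse_header(header: str) -> dict:
    """Split ``species|gene|accession[:start-end]`` into record fields."""
    fields = header.split("|")
    out: dict = {"species_name": fields[0].strip(), "gene": "other",
                 "accession": None, "coords": None}
    if len(fields) > 1 and fields[1].strip():
        gene = fields[1].strip().upper().replace("Ⅰ", "I")
        if gene in ("COX1", "COI", "CO1"):
            gene = "COXI"
        elif gene in ("COX2", "COII", "CO2"):
            gene = "COXII"
        out["gene"] = gene if gene in ("COXI", "COXII") else "other"
    if len(fields) > 2 and fields[2].strip():
        acc = fields[2].strip()
        m = _ACCESSION_COORDS.match(acc)
        if m:
            out["accession"] = m.group("acc")
            out["coords"] = (int(m.group("start")), int(m.group("end")))
        else:
            out["accession"] = acc
    return out


def read_fasta(path: str | Path) -> list[BarcodeRecord]:
    """Read a FASTA file into :class:`BarcodeRecord` objects.

    Sequences are upper-cased; alignment gaps are preserved. Raises
    :class:`FastaFormatError` on an empty file and :class:`AlphabetError`
    (naming the offending record) on illegal characters.
    """
    path = Path(path)
    seq_records = list(SeqIO.parse(str(path), "fasta"))
    if not seq_records:
        raise FastaFormatError(f"{path} contains no FASTA records")
    out = []
    for sr in seq_records:
        header = sr.description or sr.id
        meta = _parse_header(header)
        try:
            out.append(BarcodeRecord(sequence=str(sr.seq).upper(), **meta))
        except AlphabetError as exc:
            raise AlphabetError(f"in {path}: {exc}") from exc
    return out


def write_fasta(records: list[BarcodeRecord], path: str | Path) -> None:
    """Write records using the ``species|gene|accession`` header dialect."""
    seq_records = []
    for rec in records:
        header = rec.species_name
        if rec.gene != "other" or rec.accession:
            acc = rec.accession or ""
            if rec.accession and rec.coords:
                acc = f"{rec.accession}:{rec.coords[0]}-{rec.coords[1]}"
            header = f"{rec.species_name}|{rec.gene}|{acc}"
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id=header, description="")
        )
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Reference-panel TSV: species <TAB> peaks (semicolon-joined C) <TAB> batch
# ---------------------------------------------------------------------------

def read_panel(path: str | Path, panel_id: str | None = None,
               primer_set: str = "") -> ReferencePanel:
    """Read a panel TSV (columns ``species``, ``peaks``, ``batch``).

    Peaks are semicolon-separated degrees C, preserved to 0.01 C. Raises
    :class:`PanelValidationError` for out-of-window peaks or duplicate species.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"species", "peaks"}
    if not required <= set(df.columns):
        raise PanelValidationError(
            f"{path}: panel TSV needs columns {sorted(required)}"
        )
    entries = []
    for _, row in df.iterrows():
        peaks = tuple(float(p) for p in str(row["peaks"]).split(";"))
        batch = str(row["batch"]) if "batch" in df.columns and pd.notna(row.get("batch")) else ""
        entries.append(PanelEntry(str(row["species"]), peaks, batch))
    return ReferencePanel(
        panel_id=panel_id or path.stem, primer_set=primer_set, entries=entries
    )


def write_panel(panel: ReferencePanel, path: str | Path) -> None:
    """Write a panel TSV; round-trips with :func:`read_panel` to 0.01 C."""
    rows = [
        {
            "species": e.species_name,
            "peaks": ";".join(f"{t:.2f}" for t in e.peaks),
            "batch": e.batch_id,
        }
        for e in panel.entries
    ]
    pd.DataFrame(rows, columns=["species", "peaks", "batch"]).to_csv(
        path, sep="\t", index=False
    )


def panel_to_json(panel: ReferencePanel, path: str | Path) -> None:
    """JSON export mirroring the TSV columns."""
    payload = {
        "panel_id": panel.panel_id,
        "primer_set": panel.primer_set,
        "entries": [
            {
                "species": e.species_name,
                "peaks": [round(t, 2) for t in e.peaks],
                "batch": e.batch_id,
            }
            for e in panel.entries
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def panel_from_json(path: str | Path) -> ReferencePanel:
    payload = json.loads(Path(path).read_text())
    return ReferencePanel(
        panel_id=payload["panel_id"],
        primer_set=payload.get("primer_set", ""),
        entries=[
            PanelEntry(e["species"], tuple(e["peaks"]), e.get("batch", ""))
            for e in payload["entries"]
        ],
    )
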