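"""Core domain types shared across the toolkit.

A :class:`BarcodeRecord` is one species-labelled barcode sequence (typically a
mitochondrial COXI/COXII fragment, possibly gapped from a multiple alignment).
A :class:`ReferencePanel` is a set of species-labelled melt-peak signatures
acquired under one run condition, against which unknown samples are matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "BarcodeRecord",
    "PanelEntry",
    "ReferencePanel",
    "AlphabetError",
    "PanelValidationError",
    "HRM_WINDOW",
    "TM_PRECISION",
]

# IUPAC nucleotide codes plus gap and N; uppercase only (records normalise).
IUPAC_DNA = set("ACGTRYSWKMBDHVN-")

#: The instrument ramp window (degrees C); every panel peak must fall inside.
HRM_WINDOW = (65.0, 90.0)

#: Storage precision for melting temperatures, degrees C (half the quoted
#: instrument resolution of +/-0.02 degrees C).
TM_PRECISION = 0.01


class AlphabetError(ValueError):
    """A sequence contains characters outside the IUPAC DNA alphabet."""


class PanelValidationError(ValueError):
    """A reference panel violates its invariants."""


@dataclass(frozen=True)
class BarcodeRecord:
    """A species-labelled DNA barcode sequence.

    Parameters
    ----------
    species_name : str
        Latin binomial or any label identifying the source species.
    sequence : str
        IUPAC DNA, uppercase; may contain alignment gaps (``-``).
    gene : str
        ``"COXI"``, ``"COXII"`` or ``"other"``.
    accession : str, optional
        GenBank accession of the source record.
    coords : tuple of (int, int), optional
        1-based inclusive interval on the accession (GenBank dialect,
        e.g. ``NC_019633.1:3033-3720``).
    """

    species_name: str
    sequence: str
    gene: str = "other"
    accession: str | None = None
    coords: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.species_name!r}")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise AlphabetError(
                f"record {self.species_name!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )
        if self.gene not in ("COXI", "COXII", "other"):
            raise ValueError(f"gene must be COXI/COXII/other, got {self.gene!r}")
        if self.coords is not None:
            start, end = self.coords
            if start > end:
                raise ValueError(f"coords start {start} > end {end}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


@dataclass(frozen=True)
class PanelEntry:
    """One species' melt-peak signature inside a reference panel."""

    species_name: str
    peaks: tuple[float, ...]
    batch_id: str = ""

    def __post_init__(self) -> None:
        if not self.peaks:
            raise PanelValidationError(
                f"species {self.species_name!r} has no peaks"
            )
        lo, hi = HRM_WINDOW
        for tm in self.peaks:
            if not (lo <= tm <= hi):
                raise PanelValidationError(
                    f"peak {tm} for {self.species_name!r} outside the HRM "
                    f"ramp window [{lo}, {hi}]"
                )
        # freeze at storage precision
        object.__setattr__(
            self, "peaks", tuple(round(t, 2) for t in self.peaks)
        )

    @property
    def principal_peak(self) -> float:
        """The first listed peak: the signature's leading transition."""
        return self.peaks[0]


@dataclass
class ReferencePanel:
    """Species -> melt-peak signatures for one primer set and run batch."""

    panel_id: str
    primer_set: str
    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.species_name for e in self.entries]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelValidationError(f"duplicate species in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferencePanel):
            return NotImplemented
        return (
            self.panel_id == other.panel_id
            and self.primer_set == other.primer_set
            and self.entries == other.entries
        )

    @property
    def species(self) -> list[str]:
        return [e.species_name for e in self.entries]

    def entry(self, species_name: str) -> PanelEntry:
        for e in self.entries:
            if e.species_name == species_name:
                return e
        raise KeyError(species_name)
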