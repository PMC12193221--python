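"""Column-wise conservation profiling of aligned barcode panels.

HRM primer targets need conserved flanks (so one primer pair amplifies every
species) bracketing a variable core (so the amplicons melt apart). This
module scores each alignment column and calls maximal conserved/variable
blocks; primer enumeration consumes the calls.

Identity is the modal-residue fraction among non-gap residues. Ambiguity
codes count as mismatches to the modal residue, and any column containing a
gap is ineligible for a conserved call — primers cannot span indels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import BarcodeRecord

__all__ = [
    "ConservationProfile",
    "RegionCall",
    "conservation_profile",
    "find_regions",
    "consensus_sequence",
    "AlignmentError",
]

_ACGT = ("A", "C", "G", "T")


class AlignmentError(ValueError):
    """Input records are not a valid alignment."""


@dataclass(frozen=True)
class RegionCall:
    """A maximal conserved or variable block of alignment columns.

    ``interval`` is a 0-based half-open column range.
    """

    kind: str  # "conserved" | "variable"
    interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in ("conserved", "variable"):
            raise ValueError(f"kind must be conserved/variable, got {self.kind!r}")
        start, stop = self.interval
        if not 0 <= start < stop:
            raise ValueError(f"bad interval {self.interval}")

    def __len__(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column identity and gap fraction of an alignment."""

    identity: np.ndarray  # fraction in [0, 1] per column
    gap_frac: np.ndarray

    def __post_init__(self) -> None:
        if len(self.identity) != len(self.gap_frac):
            raise ValueError("identity and gap_frac lengths differ")

    def __len__(self) -> int:
        return len(self.identity)

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready table: column, identity, gap_frac."""
        return pd.DataFrame(
            {
                "column": np.arange(len(self)),
                "identity": self.identity,
                "gap_frac": self.gap_frac,
            }
        )


def _alignment_matrix(records: list[BarcodeRecord]) -> np.ndarray:
    if len(records) < 2:
        raise AlignmentError("need >= 2 records to profile conservation")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
    return np.array([list(r.sequence) for r in records])


def conservation_profile(records: list[BarcodeRecord]) -> ConservationProfile:
    """Score each column of an aligned panel.

    identity = count of the modal A/C/G/T residue / count of non-gap
    characters; all-gap columns get identity 0 and gap_frac 1.
    """
    mat = _alignment_matrix(records)
    n_rows, n_cols = mat.shape
    identity = np.zeros(n_cols)
    gap_frac = np.zeros(n_cols)
    for j in range(n_cols):
        col = mat[:, j]
        gaps = np.sum(col == "-")
        gap_frac[j] = gaps / n_rows
        non_gap = n_rows - gaps
        if non_gap == 0:
            identity[j] = 0.0
            continue
        modal = max(np.sum(col == b) for b in _ACGT)
        identity[j] = modal / non_gap
    return ConservationProfile(identity=identity, gap_frac=gap_frac)


def find_regions(
    profile: ConservationProfile,
    min_conserved_len: int = 18,
    min_identity: float = 1.0,
) -> list[RegionCall]:
    """Call maximal conserved blocks and the variable blocks between them.

    A column is conserved-eligible when identity >= ``min_identity`` and it
    contains no gap. Maximal eligible runs of length >= ``min_conserved_len``
    become conserved calls; every remaining column falls into a maximal
    variable call, so the calls partition [0, len(profile)).
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must lie in (0, 1]")
    n = len(profile)
    eligible = (profile.identity >= min_identity) & (profile.gap_frac == 0)

    conserved: list[tuple[int, int]] = []
    j = 0
    while j < n:
        if eligible[j]:
            k = j
            while k < n and eligible[k]:
                k += 1
            if k - j >= min_conserved_len:
                conserved.append((j, k))
            j = k
        else:
            j += 1

    calls: list[RegionCall] = []
    cursor = 0
    for start, stop in conserved:
        if start > cursor:
            calls.append(RegionCall("variable", (cursor, start)))
        calls.append(RegionCall("conserved", (start, stop)))
        cursor = stop
    if cursor < n:
        calls.append(RegionCall("variable", (cursor, n)))
    return calls


def consensus_sequence(records: list[BarcodeRecord]) -> str:
    """Column-modal consensus over A/C/G/T (ties broken alphabetically).

    All-gap or residue-free columns emit ``N``; used as the template for
    primer enumeration over conserved blocks (which are gap-free by
    construction).
    """
    mat = _alignment_matrix(records)
    out = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        counts = {b: int(np.sum(col == b)) for b in _ACGT}
        best = max(counts.values())
        out.append("N" if best == 0 else min(b for b, c in counts.items() if c == best))
    return "".join(out)
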