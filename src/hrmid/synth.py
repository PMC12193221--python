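"""Synthetic multi-species barcode panels.

Real HRM barcode targets pair conserved primer flanks with a variable core
(the COXII 519-615 target is ~97 bp: two 20 bp primer footprints bracketing a
~57 bp discriminating core). The generator emulates exactly that structure:
an ancestral sequence is drawn uniformly over ACGT; every species shares the
two flanks verbatim, while each core site mutates independently with
probability ``core_divergence`` to a uniformly chosen *different* base
(a single-step Jukes-Cantor-like scheme).

Under this scheme two species differ at a core site with probability

    q = 2 p (1 - p) + (2/3) p^2,        p = core_divergence,

which :func:`expected_pairwise_difference` returns in closed form so tests can
check the generator against its own model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import BarcodeRecord

__all__ = ["SynthPanelSpec", "synth_barcodes", "expected_pairwise_difference"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthPanelSpec:
    """Parameters of a synthetic aligned barcode panel.

    flank_len must be >= 18 so the flanks can host 20 +/- 2 bp primers.
    """

    n_species: int
    flank_len: int = 20
    core_len: int = 57
    core_divergence: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.flank_len < 18:
            raise ValueError("flank_len must be >= 18 to host 20 +/- 2 bp primers")
        if self.core_len < 1:
            raise ValueError("core_len must be >= 1")
        if not 0.0 <= self.core_divergence <= 1.0:
            raise ValueError("core_divergence must lie in [0, 1]")

    @property
    def total_len(self) -> int:
        return 2 * self.flank_len + self.core_len


def expected_pairwise_difference(core_divergence: float) -> float:
    """Closed-form per-site mismatch probability between two species' cores."""
    p = core_divergence
    return 2 * p * (1 - p) + (2.0 / 3.0) * p * p


def synth_barcodes(spec: SynthPanelSpec) -> list[BarcodeRecord]:
    """Generate an aligned panel of equal-length, gap-free barcode records.

    All records share identical 5' and 3' flanks; cores are independent
    mutants of a common ancestral core. The same seed reproduces the same
    panel byte-for-byte.
    """
    rng = np.random.default_rng(spec.seed)
    flank5 = rng.choice(_BASES, size=spec.flank_len)
    core0 = rng.choice(_BASES, size=spec.core_len)
    flank3 = rng.choice(_BASES, size=spec.flank_len)

    records = []
    for i in range(spec.n_species):
        core = core0.copy()
        mutate = rng.random(spec.core_len) < spec.core_divergence
        for j in np.nonzero(mutate)[0]:
            choices = _BASES[_BASES != core[j]]
            core[j] = rng.choice(choices)
        seq = "".join(np.concatenate([flank5, core, flank3]))
        records.append(
            BarcodeRecord(
                species_name=f"synth_species_{i + 1:02d}",
                sequence=seq,
                gene="other",
            )
        )
    return records
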