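"""Bench-planning calculators for the PCR-HRM reaction and program.

The 20 uL reaction holds 10 uL 2x Taq master mix, 1 uL of each 10 uM primer,
1 uL 20x saturation dye, and a 7 uL template+water budget (2 uL template and
5 uL water by default). The reaction needs at least 10 ng of template DNA in
total, so dilute extracts trade water for template within the 7 uL headroom;
pipetting is whole-microlitre.

The thermocycler program: 95 C 10 min; 35 cycles of [95 C 30 s, anneal 30 s,
72 C 45 s]; 72 C 10 min; then the HRM stage (95 C 1 min, 40 C 1 min, ramp
65 -> 90 C at 0.1 C/s). Only the annealing temperature varies per primer set
(53 C for COX2-519/615, 48 C for C1-J-2495/C1-N-2800).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

__all__ = [
    "MixSpec",
    "ThermoProgram",
    "InfeasibleError",
    "template_volume",
    "mix_table",
    "thermocycler_program",
    "REACTION_TOTAL_UL",
    "TEMPLATE_HEADROOM_UL",
]

REACTION_TOTAL_UL = 20.0
#: template + water budget inside the 20 uL reaction
TEMPLATE_HEADROOM_UL = 7.0


class InfeasibleError(ValueError):
    """The requested reaction cannot be pipetted; re-extract the sample."""


@dataclass(frozen=True)
class MixSpec:
    """Per-reaction component volumes (uL) and scaled batch volumes."""

    components: tuple[tuple[str, float], ...]
    n_samples: int = 1
    overage_frac: float = 0.1

    @property
    def total(self) -> float:
        return sum(v for _, v in self.components)

    def batch_volumes(self) -> dict[str, float]:
        """Master-mix batch volumes; template is added per tube, unscaled."""
        factor = self.n_samples * (1.0 + self.overage_frac)
        return {
            name: (v if name == "template" else round(v * factor, 2))
            for name, v in self.components
        }

    def to_dict(self) -> dict:
        return {
            "per_reaction_ul": dict(self.components),
            "total_ul": self.total,
            "n_samples": self.n_samples,
            "overage_frac": self.overage_frac,
            "batch_ul": self.batch_volumes(),
        }


def template_volume(
    conc: float,
    required_ng: float = 10.0,
    baseline_ul: int = 2,
    headroom_ul: int = 7,
) -> tuple[int, int]:
    """Template and water volumes (uL) meeting the >= ``required_ng`` rule.

    At least ``baseline_ul`` of template is always loaded; dilute samples get
    ``ceil(required_ng / conc)`` uL, and water fills the rest of the
    ``headroom_ul`` budget. Raises :class:`InfeasibleError` when even the
    whole budget cannot carry enough DNA.
    """
    if conc <= 0:
        raise ValueError(f"concentration must be > 0 ng/uL, got {conc}")
    template = max(baseline_ul, math.ceil(required_ng / conc))
    if template > headroom_ul:
        raise InfeasibleError(
            f"{template} uL of template needed at {conc} ng/uL exceeds the "
            f"{headroom_ul} uL budget; re-extract or concentrate the sample"
        )
    return template, headroom_ul - template


def mix_table(
    n_samples: int = 1,
    overage_frac: float = 0.1,
    template_ul: int = 2,
) -> MixSpec:
    """The 20 uL PCR-HRM reaction, scaled to a batch with pipetting overage.

    Water absorbs template adjustments so every reaction totals exactly
    20 uL. Batch volumes scale all components except template by
    ``n_samples * (1 + overage_frac)``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if template_ul > TEMPLATE_HEADROOM_UL:
        raise InfeasibleError(
            f"template volume {template_ul} uL exceeds the "
            f"{TEMPLATE_HEADROOM_UL:.0f} uL template+water budget"
        )
    if template_ul < 0 or overage_frac < 0:
        raise ValueError("volumes and overage must be >= 0")
    components = (
        ("master_mix", 10.0),
        ("primer1", 1.0),
        ("primer2", 1.0),
        ("dye", 1.0),
        ("water", TEMPLATE_HEADROOM_UL - template_ul),
        ("template", float(template_ul)),
    )
    return MixSpec(components=components, n_samples=n_samples,
                   overage_frac=overage_frac)


@dataclass(frozen=True)
class ThermoProgram:
    """The fixed PCR-HRM thermocycler program with one free anneal slot."""

    annealing_tm: float
    initial_denaturation: tuple[float, float] = (95.0, 600.0)  # C, s
    cycle_count: int = 35
    cycle_steps: tuple[tuple[str, float, float], ...] = field(init=False)
    final_extension: tuple[float, float] = (72.0, 600.0)
    hrm_stage: tuple = (
        ("denaturation", 95.0, 60.0),
        ("cooling", 40.0, 60.0),
        ("ramp", 65.0, 90.0, 0.1),  # C start, C end, C/s
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "cycle_steps",
            (
                ("denaturation", 95.0, 30.0),
                ("annealing", float(self.annealing_tm), 30.0),
                ("extension", 72.0, 45.0),
            ),
        )

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(
            {
                "initial_denaturation_c_s": list(self.initial_denaturation),
                "cycles": self.cycle_count,
                "cycle_steps": [list(s) for s in self.cycle_steps],
                "final_extension_c_s": list(self.final_extension),
                "hrm_stage": [list(s) for s in self.hrm_stage],
            },
            indent=indent,
        )


def thermocycler_program(annealing_tm: float) -> ThermoProgram:
    """Build the program for a primer set's annealing temperature (40-72 C)."""
    if not 40.0 <= annealing_tm <= 72.0:
        raise ValueError(
            f"annealing temperature {annealing_tm} outside [40, 72] C"
        )
    return ThermoProgram(annealing_tm=float(annealing_tm))
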