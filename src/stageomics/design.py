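"""Stage/replicate layout of a developmental series experiment.

A :class:`StageDesign` pins the ordered stage labels and the replicate count;
every table, differential call and correlation downstream uses this order, so
"earlier stage" is always well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError

DEFAULT_STAGES = tuple(f"S{i}" for i in range(1, 12))


@dataclass(frozen=True)
class StageDesign:
    """Ordered stage labels plus replicate count (default: S1..S11 x 3)."""

    stages: tuple[str, ...] = DEFAULT_STAGES
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if len(self.stages) != len(set(self.stages)):
            raise InputError("stage labels must be unique")
        if len(self.stages) < 2:
            raise InputError("need at least two stages")
        if self.n_replicates < 1:
            raise InputError("replicates_per_stage must be positive")
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def columns(self) -> list[str]:
        """Flat sample column names, stage-major: S1_R1, S1_R2, ..."""
        return [f"{s}_R{k}" for s in self.stages
                for k in range(1, self.n_replicates + 1)]

    def sample_ids(self) -> list[tuple[str, int]]:
        return [(s, k) for s in self.stages
                for k in range(1, self.n_replicates + 1)]

    def stage_of_column(self, column: str) -> str:
        stage, _, rep = column.rpartition("_R")
        if stage not in self.stages or not rep.isdigit():
            raise InputError(f"column {column!r} does not match <stage>_R<k>")
        return stage

    def stage_index(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise InputError(f"unknown stage {stage!r}") from None

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.stages[:-1], self.stages[1:]))

    def all_pairs(self) -> list[tuple[str, str]]:
        """All unordered stage pairs (earlier stage first): C(n, 2) pairs."""
        return [(a, b) for i, a in enumerate(self.stages)
                for b in self.stages[i + 1:]]
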