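"""Cohort manifest: subjects, resilience groups, scores, and sample locations.

The study design is two groups of servicemen selected from the tertiles of
the Connor-Davidson Resilience Scale (CD-RISC, 0-100): high resilience
(score > 90) and low resilience (score <= 79), each sampled at baseline (D0)
and at peak stress after 48 h of sleep and caloric restriction (D3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

TIMEPOINTS: tuple[str, str] = ("D0", "D3")
GROUPS: tuple[str, str] = ("high", "low")

#: CD-RISC tertile rule: high > 90, low <= 79
HIGH_CUTOFF = 90.0
LOW_CUTOFF = 79.0


@dataclass
class SubjectRecord:
    subject_id: str
    group: str                      # "high" | "low"
    cdrisc: float                   # in [0, 100]
    event_tables: dict[str, str | None] = field(default_factory=dict)  # timepoint -> path

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r} for {self.subject_id}")
        if not 0 <= self.cdrisc <= 100:
            raise ValueError(f"CD-RISC score outside [0, 100] for {self.subject_id}")

    def has_both_timepoints(self) -> bool:
        return all(self.event_tables.get(tp) is not None for tp in TIMEPOINTS)


@dataclass
class CohortManifest:
    subjects: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate subject ids in cohort manifest")

    def validate(self) -> list[str]:
        """Non-fatal consistency warnings (group label vs CD-RISC tertile rule)."""
        warnings = []
        for s in self.subjects:
            if s.group == "high" and not s.cdrisc > HIGH_CUTOFF:
                warnings.append(
                    f"{s.subject_id}: labelled high but CD-RISC {s.cdrisc:g} <= {HIGH_CUTOFF:g}")
            if s.group == "low" and not s.cdrisc <= LOW_CUTOFF:
                warnings.append(
                    f"{s.subject_id}: labelled low but CD-RISC {s.cdrisc:g} > {LOW_CUTOFF:g}")
        return warnings

    def group(self, name: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == name]

    @property
    def n_high(self) -> int:
        return len(self.group("high"))

    @property
    def n_low(self) -> int:
        return len(self.group("low"))

    def paired_subjects(self) -> list[SubjectRecord]:
        """Subjects with both D0 and D3 samples (eligible for change scores)."""
        return [s for s in self.subjects if s.has_both_timepoints()]

    def scores(self, subjects: list[SubjectRecord] | None = None) -> list[float]:
        return [s.cdrisc for s in (subjects if subjects is not None else self.subjects)]
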