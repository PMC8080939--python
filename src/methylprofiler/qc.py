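"""Append-only quality-control report collected while processing an upload."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class QCRecord:
    step: str
    action: str
    count: int | None = None

    def __str__(self) -> str:
        if self.count is None:
            return f"[{self.step}] {self.action}"
        return f"[{self.step}] {self.action} (n={self.count})"


@dataclass
class QCReport:
    """Ordered log of QC actions taken during score calculation.

    Records are append-only; the report serializes to plain text so it can
    be printed alongside the score file.
    """

    records: list[QCRecord] = field(default_factory=list)

    def add(self, step: str, action: str, count: int | None = None) -> None:
        self.records.append(QCRecord(step, action, count))

    def to_text(self) -> str:
        lines = ["Quality control report"]
        lines += [str(r) for r in self.records]
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    def counts(self) -> dict[str, int]:
        """step -> count for records that carry one (last record wins)."""
        return {r.step: r.count for r in self.records if r.count is not None}

    def __len__(self) -> int:
        return len(self.records)
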