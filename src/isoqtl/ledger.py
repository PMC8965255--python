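"""Filter ledger: per-step gene/transcript/source bookkeeping.

Every reduction stage of the pipeline (background-detection cascade,
prefilter cascade) appends one row per step so the survivor chain can be
audited and exported in the same shape as a transcriptome-generation summary
table: totals, per-source counts, and per-source percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .transcriptome import SOURCES, TranscriptomeAnnotation


@dataclass
class FilterLedger:
    steps: list[dict] = field(default_factory=list)

    def record(
        self,
        step: str,
        ann: TranscriptomeAnnotation,
        transcript_ids=None,
        **params,
    ) -> None:
        """Record counts for the transcripts currently retained.

        ``transcript_ids`` restricts the annotation; totals must never
        increase from one step to the next.
        """
        sub = ann if transcript_ids is None else ann.subset(transcript_ids)
        counts = sub.source_counts()
        row = {
            "step": step,
            "n_genes": len(sub.genes()),
            "n_transcripts": len(sub),
        }
        for s in SOURCES:
            row[f"n_{s}"] = counts.get(s, 0)
        row["params"] = dict(params)
        if self.steps and row["n_transcripts"] > self.steps[-1]["n_transcripts"]:
            raise AssertionError(
                f"ledger step {step!r}: transcript count increased "
                f"({self.steps[-1]['n_transcripts']} -> {row['n_transcripts']})"
            )
        self.steps.append(row)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.steps:
            row = {k: v for k, v in r.items() if k != "params"}
            total = row["n_transcripts"]
            for s in SOURCES:
                row[f"pct_{s}"] = 100.0 * row[f"n_{s}"] / total if total else 0.0
            row["params"] = ";".join(f"{k}={v}" for k, v in r["params"].items())
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.1f")

    def __len__(self) -> int:
        return len(self.steps)
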