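"""Per-event flow-cytometry tables with sample metadata.

The canonical on-disk form is a CSV with one row per event and the
eight instrument channels as columns; generator truth labels travel in
``truth_*`` columns and are ignored by the analysis chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CHANNELS = ("fsc_a", "fsc_w", "ssc_a", "ssc_w", "hoechst", "pcna", "ph3", "bead_channel")


class EventFormatError(ValueError):
    """Raised when an event table is structurally invalid."""


@dataclass
class EventTable:
    """Event channels plus the sample metadata the QC and counting need."""

    data: pd.DataFrame
    sample_id: str = ""
    ploidy: str = ""
    clutch: str = ""
    n_brains: int = 1
    run_id: str = ""
    stage: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise EventFormatError(f"missing channel column(s): {', '.join(missing)}")
        vals = self.data[list(CHANNELS)].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise EventFormatError("non-finite channel values")
        if np.any(vals < 0):
            raise EventFormatError("negative channel values")
        if self.n_brains < 1:
            raise EventFormatError("n_brains must be >= 1")

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "EventTable":
        return EventTable(
            data=self.data.loc[mask].reset_index(drop=True),
            sample_id=self.sample_id, ploidy=self.ploidy, clutch=self.clutch,
            n_brains=self.n_brains, run_id=self.run_id, stage=self.stage,
        )


def read_events(path, metadata: dict | None = None) -> EventTable:
    """Load a CSV event table and attach sample metadata."""
    df = pd.read_csv(path)
    meta = dict(metadata or {})
    return EventTable(
        data=df,
        sample_id=str(meta.get("sample_id", "")),
        ploidy=str(meta.get("ploidy", "")),
        clutch=str(meta.get("clutch", "")),
        n_brains=int(meta.get("n_brains", 1)),
        run_id=str(meta.get("run_id", "")),
        stage=meta.get("stage"),
    )


def write_events(table: EventTable, path) -> None:
    table.data.to_csv(path, index=False)
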