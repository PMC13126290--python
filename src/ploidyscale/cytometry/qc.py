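"""Post-hoc run quality control for bead-spiked flow samples.

A sample passes only if all five conditions hold:

a) more than 5,000 bead events;
b) more than 10,000 single-cell events;
c) the sample's bead means of FSC-A and Hoechst fall inside
   run_mean * (1 ± run_CV), where the run statistics are computed over
   the bead events pooled across all samples of the run;
d) the sample's bead CVs of the same channels are below twice the run CV;
e) a ploidy-matched sample from the same clutch exists in the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gating import GateResult

QC_CHANNELS = ("fsc_a", "hoechst")


@dataclass
class QCResult:
    sample_id: str
    run_id: str
    n_bead_events: int
    n_cell_events: int
    bead_fsc_mean: float
    bead_hoechst_mean: float
    bead_fsc_cv: float
    bead_hoechst_cv: float
    rule_a: bool
    rule_b: bool
    rule_c: bool
    rule_d: bool
    rule_e: bool
    single_sample_run: bool = False

    @property
    def passed(self) -> bool:
        return self.rule_a and self.rule_b and self.rule_c and self.rule_d and self.rule_e


def _cv(x: np.ndarray) -> float:
    m = x.mean()
    return float(x.std(ddof=0) / m) if m > 0 else np.inf


def qc_batch(
    gated: list[GateResult],
    min_bead_events: int = 5000,
    min_cell_events: int = 10_000,
) -> list[QCResult]:
    """Apply rules a-e to every gated sample, grouping runs by run_id."""
    if not gated:
        raise ValueError("qc_batch needs at least one gated sample")
    by_run: dict[str, list[GateResult]] = {}
    for g in gated:
        by_run.setdefault(g.beads.run_id, []).append(g)

    results = []
    for run_id, samples in by_run.items():
        pooled = pd.concat([g.beads.data for g in samples], ignore_index=True)
        run_mean = {c: float(pooled[c].mean()) for c in QC_CHANNELS}
        run_cv = {c: _cv(pooled[c].to_numpy()) for c in QC_CHANNELS}
        single = len(samples) == 1
        pairs = {(g.cells.ploidy, g.cells.clutch) for g in samples}
        for g in samples:
            beads = g.beads.data
            means = {c: float(beads[c].mean()) if len(beads) else np.nan
                     for c in QC_CHANNELS}
            cvs = {c: _cv(beads[c].to_numpy()) if len(beads) else np.inf
                   for c in QC_CHANNELS}
            rule_a = g.n_bead_events > min_bead_events
            rule_b = g.n_cell_events > min_cell_events
            rule_c = all(
                abs(means[c] - run_mean[c]) <= run_mean[c] * run_cv[c]
                for c in QC_CHANNELS
            )
            rule_d = all(cvs[c] < 2.0 * run_cv[c] for c in QC_CHANNELS)
            other = "triploid" if g.cells.ploidy == "diploid" else "diploid"
            rule_e = (other, g.cells.clutch) in pairs
            results.append(QCResult(
                sample_id=g.cells.sample_id, run_id=run_id,
                n_bead_events=g.n_bead_events, n_cell_events=g.n_cell_events,
                bead_fsc_mean=means["fsc_a"], bead_hoechst_mean=means["hoechst"],
                bead_fsc_cv=cvs["fsc_a"], bead_hoechst_cv=cvs["hoechst"],
                rule_a=rule_a, rule_b=rule_b, rule_c=rule_c, rule_d=rule_d,
                rule_e=rule_e, single_sample_run=single,
            ))
    return results


def qc_frame(results: list[QCResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = r.__dict__.copy()
        d["passed"] = r.passed
        rows.append(d)
    return pd.DataFrame(rows)
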