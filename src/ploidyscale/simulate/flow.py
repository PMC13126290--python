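"""Synthetic flow-cytometry event tables for dissociated tadpole brains.

Each simulated tube contains:

* cell singlets — DNA content (Hoechst) set by cell-cycle phase
  (G0/G1 at the G1 mean, S uniform between 1x and 2x, G2/M at 2x),
  multiplied by lognormal measurement noise; PCNA and pH3 intensities
  drawn from phase-mapped log10-normal mixture components
  (G0 -> PCNA-negative, S -> PCNA-punctate, M -> pH3-positive,
  G1/G2 -> PCNA-diffuse);
* counting beads — a known number of events with high bead-channel
  signal and tight FSC/Hoechst distributions, emulating a spike-in of
  20,800 CountBright beads per tube;
* doublets — sums of two sampled cells with inflated FSC-W;
* debris — sub-G1 DNA fragments with low scatter.

Triploid tubes multiply every DNA mean by ``genome_fold`` (default 1.5)
and carry ``1/count_fold`` as many cells, encoding the observed
1.5-fold decrease in cells per brain.  Every event carries ``truth_*``
columns with its latent label so downstream recovery is assertable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..cytometry.events import EventTable

PHASES = ("G0", "G1", "S", "G2", "M")


@dataclass
class FlowSimParams:
    n_cells: int = 20_000                      # cell singlets per diploid tube
    phase_fractions: dict = field(default_factory=lambda: {
        "G0": 0.45, "G1": 0.25, "S": 0.15, "G2": 0.10, "M": 0.05,
    })
    g1_dna_mean: float = 50_000.0              # a.u., diploid G0/G1 Hoechst
    dna_cv: float = 0.05
    genome_fold: float = 1.5                   # triploid multiplier on DNA means
    count_fold: float = 1.5                    # diploid/triploid cells-per-brain
    pcna_mixture: dict = field(default_factory=lambda: {
        "neg": (2.0, 0.12), "diffuse": (2.9, 0.12), "punctate": (3.8, 0.12),
    })
    ph3_mixture: dict = field(default_factory=lambda: {
        "neg": (2.0, 0.15), "pos": (3.6, 0.15),
    })
    phase_to_marker: dict = field(default_factory=lambda: {
        "G0": ("neg", "neg"), "G1": ("diffuse", "neg"), "S": ("punctate", "neg"),
        "G2": ("diffuse", "neg"), "M": ("diffuse", "pos"),
    })
    bead_count: int = 20_800                   # beads added per tube
    bead_channel_mean: float = 60_000.0
    bead_fsc_mean: float = 30_000.0
    bead_hoechst_mean: float = 5_000.0
    bead_cv: float = 0.04
    doublet_fraction: float = 0.04             # extra events relative to n_cells
    debris_fraction: float = 0.05
    fsc_mean: float = 50_000.0
    fsc_cv: float = 0.15
    wa_ratio_cv: float = 0.04                  # singlet width/area spread
    doublet_wa_factor: float = 1.9             # doublet FSC-W inflation
    n_brains: int = 6
    stage: int = 46
    seed: int | None = None

    def validate(self) -> None:
        tot = sum(self.phase_fractions.get(p, 0.0) for p in PHASES)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"phase fractions sum to {tot}, expected 1")
        if any(v < 0 for v in self.phase_fractions.values()):
            raise ValueError("phase fractions must be non-negative")
        for name in ("g1_dna_mean", "genome_fold", "count_fold", "bead_channel_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.doublet_fraction < 1 or not 0 <= self.debris_fraction < 1:
            raise ValueError("doublet/debris fractions must be in [0, 1)")
        if self.n_brains < 1:
            raise ValueError("n_brains must be >= 1")


def _log10_normal(rng, mean_log10, sd_log10, n):
    return 10.0 ** rng.normal(mean_log10, sd_log10, n)


def _noise(rng, n, cv):
    if cv <= 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n)


def _sample_cells(rng, params: FlowSimParams, n: int, dna_scale: float):
    phases = rng.choice(PHASES, size=n, p=[params.phase_fractions[p] for p in PHASES])
    base = np.empty(n)
    for ph in PHASES:
        m = phases == ph
        k = int(m.sum())
        if ph in ("G0", "G1"):
            base[m] = 1.0
        elif ph == "S":
            base[m] = rng.uniform(1.0, 2.0, k)
        else:
            base[m] = 2.0
    dna = base * params.g1_dna_mean * dna_scale * _noise(rng, n, params.dna_cv)

    pcna = np.empty(n)
    ph3 = np.empty(n)
    for ph in PHASES:
        m = phases == ph
        k = int(m.sum())
        pc_key, p3_key = params.phase_to_marker[ph]
        mu, sd = params.pcna_mixture[pc_key]
        pcna[m] = _log10_normal(rng, mu, sd, k)
        mu, sd = params.ph3_mixture[p3_key]
        ph3[m] = _log10_normal(rng, mu, sd, k)

    fsc_a = params.fsc_mean * _noise(rng, n, params.fsc_cv)
    fsc_w = fsc_a * _noise(rng, n, params.wa_ratio_cv)
    ssc_a = 0.6 * params.fsc_mean * _noise(rng, n, params.fsc_cv)
    ssc_w = ssc_a * _noise(rng, n, params.wa_ratio_cv)
    return phases, dna, pcna, ph3, fsc_a, fsc_w, ssc_a, ssc_w


def simulate_flow_sample(
    params: FlowSimParams,
    ploidy: str = "diploid",
    seed: int | None = None,
    sample_id: str = "S1",
    clutch: str = "C1",
    run_id: str = "R1",
) -> EventTable:
    """One tube of events (cells + beads + doublets + debris) with truth labels."""
    params.validate()
    if ploidy not in ("diploid", "triploid"):
        raise ValueError(f"unknown ploidy {ploidy!r}")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    dna_scale = params.genome_fold if ploidy == "triploid" else 1.0
    n_cells = params.n_cells
    if ploidy == "triploid":
        n_cells = int(round(params.n_cells / params.count_fold))

    phases, dna, pcna, ph3, fsc_a, fsc_w, ssc_a, ssc_w = _sample_cells(
        rng, params, n_cells, dna_scale
    )
    parts = [pd.DataFrame({
        "fsc_a": fsc_a, "fsc_w": fsc_w, "ssc_a": ssc_a, "ssc_w": ssc_w,
        "hoechst": dna, "pcna": pcna, "ph3": ph3,
        "bead_channel": _log10_normal(rng, 1.5, 0.2, n_cells),
        "truth_kind": "cell", "truth_phase": phases,
    })]

    n_beads = params.bead_count
    if n_beads > 0:
        bfsc = params.bead_fsc_mean * _noise(rng, n_beads, params.bead_cv)
        parts.append(pd.DataFrame({
            "fsc_a": bfsc,
            "fsc_w": bfsc * _noise(rng, n_beads, params.wa_ratio_cv),
            "ssc_a": params.bead_fsc_mean * _noise(rng, n_beads, params.bead_cv),
            "ssc_w": params.bead_fsc_mean * _noise(rng, n_beads, params.bead_cv),
            "hoechst": params.bead_hoechst_mean * _noise(rng, n_beads, params.bead_cv),
            "pcna": _log10_normal(rng, 2.0, 0.1, n_beads),
            "ph3": _log10_normal(rng, 2.0, 0.1, n_beads),
            "bead_channel": params.bead_channel_mean * _noise(rng, n_beads, params.bead_cv),
            "truth_kind": "bead", "truth_phase": "none",
        }))

    n_dbl = int(round(params.doublet_fraction * n_cells))
    if n_dbl > 0:
        _, d1, pc1, p31, fa1, fw1, sa1, sw1 = _sample_cells(rng, params, n_dbl, dna_scale)
        _, d2, pc2, p32, fa2, fw2, sa2, sw2 = _sample_cells(rng, params, n_dbl, dna_scale)
        parts.append(pd.DataFrame({
            "fsc_a": fa1 + fa2,
            # width grows out of proportion to area for aggregates
            "fsc_w": (fa1 + fa2) * params.doublet_wa_factor
                     * _noise(rng, n_dbl, params.wa_ratio_cv),
            "ssc_a": sa1 + sa2,
            "ssc_w": (sa1 + sa2) * params.doublet_wa_factor
                     * _noise(rng, n_dbl, params.wa_ratio_cv),
            "hoechst": d1 + d2, "pcna": pc1 + pc2, "ph3": p31 + p32,
            "bead_channel": _log10_normal(rng, 1.5, 0.2, n_dbl),
            "truth_kind": "doublet", "truth_phase": "none",
        }))

    n_deb = int(round(params.debris_fraction * n_cells))
    if n_deb > 0:
        parts.append(pd.DataFrame({
            "fsc_a": 0.15 * params.fsc_mean * _noise(rng, n_deb, 0.5),
            "fsc_w": 0.15 * params.fsc_mean * _noise(rng, n_deb, 0.5),
            "ssc_a": 0.1 * params.fsc_mean * _noise(rng, n_deb, 0.5),
            "ssc_w": 0.1 * params.fsc_mean * _noise(rng, n_deb, 0.5),
            "hoechst": rng.uniform(0.02, 0.4, n_deb) * params.g1_dna_mean * dna_scale,
            "pcna": _log10_normal(rng, 1.8, 0.3, n_deb),
            "ph3": _log10_normal(rng, 1.8, 0.3, n_deb),
            "bead_channel": _log10_normal(rng, 1.5, 0.2, n_deb),
            "truth_kind": "debris", "truth_phase": "none",
        }))

    data = pd.concat(parts, ignore_index=True)
    data = data.sample(frac=1.0, random_state=rng.integers(0, 2**31 - 1)).reset_index(drop=True)
    return EventTable(
        data=data, sample_id=sample_id, ploidy=ploidy, clutch=clutch,
        n_brains=params.n_brains, run_id=run_id, stage=params.stage,
    )


def simulate_flow_batch(
    params: FlowSimParams,
    n_samples_per_ploidy: int,
    seed: int,
    run_id: str = "R1",
) -> list[EventTable]:
    """Clutch-paired diploid/triploid tubes forming one QC batch (run)."""
    rng = np.random.default_rng(seed)
    tables = []
    for i in range(n_samples_per_ploidy):
        clutch = f"C{i + 1}"
        for ploidy in ("diploid", "triploid"):
            tables.append(simulate_flow_sample(
                params, ploidy=ploidy, seed=int(rng.integers(0, 2**31 - 1)),
                sample_id=f"{run_id}_{ploidy[:3]}_{i + 1}", clutch=clutch,
                run_id=run_id,
            ))
    return tables
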