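"""Combined G0/G1/S/G2/M phase classification.

The DNA-content fit alone only resolves G0/G1 vs S vs G2/M; the marker
mixtures refine it: pH3-positive weight gives M, PCNA-negative gives
G0, PCNA-punctate gives S.  G2 is the DJF G2/M weight minus M (clipped
at zero) and G1 is the remainder, clipped and renormalized.  An
alternative rule taking S from the DJF fit instead of PCNA is
available via ``s_from``.

Absolute counts are fractions times the bead-normalized cells per
brain.  Confidence intervals come from a seeded multinomial bootstrap
of the classified events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cellcycle import CellCycleFit
from .mixture import MixtureFit

PHASES = ("G0", "G1", "S", "G2", "M")


@dataclass
class PhaseFractions:
    fractions: dict           # phase -> fraction, sums to 1
    counts: dict              # phase -> cells per brain
    ci_fractions: dict        # phase -> (low, high)
    ci_counts: dict           # phase -> (low, high)
    cells_per_brain: float
    inconsistent: bool = False  # large negative G1 before clipping

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            dict(phase=p, fraction=self.fractions[p], count=self.counts[p],
                 frac_ci_low=self.ci_fractions[p][0], frac_ci_high=self.ci_fractions[p][1],
                 count_ci_low=self.ci_counts[p][0], count_ci_high=self.ci_counts[p][1])
            for p in PHASES
        ])


def classify_phases(
    djf: CellCycleFit,
    pcna: MixtureFit,
    ph3: MixtureFit,
    cells_per_brain: float,
    s_from: str = "pcna",
    n_boot: int = 1000,
    seed: int | None = None,
) -> PhaseFractions:
    """Merge the three fits into five phase fractions and absolute counts."""
    if pcna.k != 3:
        raise ValueError("PCNA mixture must have 3 components (neg/diffuse/punctate)")
    if ph3.k != 2:
        raise ValueError("pH3 mixture must have 2 components (neg/pos)")
    if s_from not in ("pcna", "djf"):
        raise ValueError("s_from must be 'pcna' or 'djf'")

    m = float(ph3.weights[1])                       # pH3-positive
    g0 = float(pcna.weights[0])                     # PCNA-negative
    s = float(pcna.weights[2]) if s_from == "pcna" else float(djf.weights["s"])
    g2 = max(0.0, float(djf.weights["g2m"]) - m)
    g1_raw = 1.0 - g0 - s - g2 - m
    inconsistent = g1_raw < -0.05
    if inconsistent:
        warnings.warn(
            f"phase fractions inconsistent: G1 remainder {g1_raw:.3f} < -0.05"
        )
    g1 = max(0.0, g1_raw)
    raw = np.array([g0, g1, s, g2, m])
    frac = raw / raw.sum()

    n = djf.n_events
    rng = np.random.default_rng(seed)
    boots = rng.multinomial(n, frac, size=n_boot) / n
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)

    fractions = dict(zip(PHASES, frac))
    counts = {p: f * cells_per_brain for p, f in fractions.items()}
    ci_f = {p: (lo[i], hi[i]) for i, p in enumerate(PHASES)}
    ci_c = {p: (lo[i] * cells_per_brain, hi[i] * cells_per_brain)
            for i, p in enumerate(PHASES)}
    return PhaseFractions(
        fractions=fractions, counts=counts, ci_fractions=ci_f, ci_counts=ci_c,
        cells_per_brain=cells_per_brain, inconsistent=inconsistent,
    )
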