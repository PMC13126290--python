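"""Bead-normalized absolute cell counting and count-fold regression.

CountBright counting beads are supplied at 0.52e5 beads per 50 μL and
20 μL are added to each tube, so every tube receives 20,800 beads.
The number of cells per brain is then

    N = (N_single_cell_events / N_bead_events) * (1 / N_brains)
        * (0.52e5 / 50) * 20

i.e. the cell-to-bead event ratio scaled by the known bead input and
the number of brains pooled in the tube.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class CountingConfig:
    beads_per_stock_aliquot: float = 0.52e5   # beads per 50 μL of stock
    stock_aliquot_volume: float = 50.0        # μL
    added_volume: float = 20.0                # μL

    @property
    def beads_per_tube(self) -> float:
        return self.beads_per_stock_aliquot / self.stock_aliquot_volume * self.added_volume


def count_cells(
    n_cell_events: int,
    n_bead_events: int,
    n_brains: int,
    cfg: CountingConfig | None = None,
) -> float:
    """Cells per brain from gated event counts (exactly linear in cells)."""
    cfg = cfg or CountingConfig()
    if n_bead_events <= 0:
        raise ValueError("n_bead_events must be positive (bead ratio undefined)")
    if n_brains < 1:
        raise ValueError("n_brains must be >= 1")
    return n_cell_events / n_bead_events / n_brains * cfg.beads_per_tube


def count_fold_analysis(counts: pd.DataFrame, reference_fold: float = 1.5) -> dict:
    """Per-ploidy cells-per-brain regression on stage with a scaled-line test.

    ``counts`` needs columns ``ploidy`` ({diploid, triploid}), ``stage``
    and ``cells_per_brain``.  Fits one OLS line per ploidy, reports
    fold = mean(diploid)/mean(triploid), and runs an ANCOVA-style F-test
    of the triploid line against the diploid line scaled by
    1/reference_fold (joint test of the group offset and group x stage
    interaction after scaling).
    """
    import statsmodels.formula.api as smf

    for col in ("ploidy", "stage", "cells_per_brain"):
        if col not in counts.columns:
            raise ValueError(f"missing column {col!r}")
    dip = counts[counts["ploidy"] == "diploid"]
    tri = counts[counts["ploidy"] == "triploid"]
    if len(dip) < 3 or len(tri) < 3:
        raise ValueError("need at least 3 samples per ploidy")

    fold = dip["cells_per_brain"].mean() / tri["cells_per_brain"].mean()

    fits = {}
    multi_stage = counts["stage"].nunique() > 1
    for name, grp in (("diploid", dip), ("triploid", tri)):
        if multi_stage and grp["stage"].nunique() > 1:
            fit = smf.ols("cells_per_brain ~ stage", data=grp).fit()
            fits[name] = dict(
                slope=float(fit.params["stage"]),
                intercept=float(fit.params["Intercept"]),
            )
        else:
            fits[name] = dict(slope=0.0, intercept=float(grp["cells_per_brain"].mean()))

    # scaled-line comparison: diploid counts / reference_fold vs triploid
    scaled = pd.concat([
        dip.assign(cells_per_brain=dip["cells_per_brain"] / reference_fold,
                   group="diploid_scaled"),
        tri.assign(group="triploid"),
    ], ignore_index=True)
    if multi_stage:
        full = smf.ols("cells_per_brain ~ stage * group", data=scaled).fit()
        reduced = smf.ols("cells_per_brain ~ stage", data=scaled).fit()
    else:
        full = smf.ols("cells_per_brain ~ group", data=scaled).fit()
        reduced = smf.ols("cells_per_brain ~ 1", data=scaled).fit()
    f_res = full.compare_f_test(reduced)
    return dict(
        fold=float(fold),
        fits=fits,
        scaled_line_F=float(f_res[0]),
        scaled_line_p=float(f_res[1]),
    )
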