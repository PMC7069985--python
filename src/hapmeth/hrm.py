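"""Methylation-sensitive high-resolution melting (MS-HRM) difference analysis.

Post-conversion, methylation preserves C (raising GC content and Tm), so a
sample's melt curve shifts between the unmethylated and the fully methylated
standard in proportion to its methylation. The analysis normalizes curves
between pre- and post-melt plateaus, finds the temperature of maximum
separation between the two standards, and compares each sample's difference
from the unmethylated standard at that temperature across genotype groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

ROLES = ("sample", "unmethylated_standard", "methylated_standard")


@dataclass
class MeltCurve:
    sample_id: str
    genotype: str
    role: str  # sample | unmethylated_standard | methylated_standard
    temperatures: np.ndarray  # ascending degrees C
    fluorescence: np.ndarray

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"bad role {self.role!r}")
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence grids differ in length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperature grid must be strictly ascending")

    def resampled(self, grid: np.ndarray) -> "MeltCurve":
        f = np.interp(grid, self.temperatures, self.fluorescence)
        return replace(self, temperatures=np.asarray(grid, float), fluorescence=f)


@dataclass
class DifferenceResult:
    t_star: float
    values: pd.DataFrame  # sample_id, genotype, difference
    group_p: Dict[Tuple[str, str], float]


def normalize_melt(
    curve: MeltCurve,
    pre_window: Optional[Tuple[float, float]] = None,
    post_window: Optional[Tuple[float, float]] = None,
) -> MeltCurve:
    """Two-point linear normalization: pre-melt plateau -> 1, post-melt -> 0.

    Windows default to the first and last 2 degrees C of the grid.
    """
    t = curve.temperatures
    if pre_window is None:
        pre_window = (t[0], t[0] + 2.0)
    if post_window is None:
        post_window = (t[-1] - 2.0, t[-1])
    if pre_window[1] >= post_window[0]:
        raise ValueError("pre-melt window must precede post-melt window")
    for lo, hi in (pre_window, post_window):
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
            raise ValueError("normalization window outside temperature grid")
    pre = curve.fluorescence[(t >= pre_window[0]) & (t <= pre_window[1])].mean()
    post = curve.fluorescence[(t >= post_window[0]) & (t <= post_window[1])].mean()
    if abs(pre - post) < 1e-12:
        raise ValueError("zero dynamic range between plateaus")
    f = (curve.fluorescence - post) / (pre - post)
    return replace(curve, fluorescence=f)


def average_replicates(curves: Sequence[MeltCurve]) -> List[MeltCurve]:
    """Average replicate wells of the same sample (shared grids required)."""
    out: List[MeltCurve] = []
    by_sample: Dict[str, List[MeltCurve]] = {}
    for c in curves:
        by_sample.setdefault(c.sample_id, []).append(c)
    for sample_id, group in by_sample.items():
        first = group[0]
        for c in group[1:]:
            if not np.allclose(c.temperatures, first.temperatures):
                raise ValueError(f"replicates of {sample_id} on different grids")
        f = np.mean([c.fluorescence for c in group], axis=0)
        out.append(replace(first, fluorescence=f))
    return out


def difference_analysis(
    samples: Sequence[MeltCurve],
    unmeth_std: MeltCurve,
    meth_std: MeltCurve,
) -> DifferenceResult:
    """Difference-plot statistic at the standards' maximum-separation point.

    t_star is the grid temperature maximizing |unmethylated - methylated
    standard| (ties break to the lowest temperature); each sample's statistic
    is (sample - unmethylated standard) at t_star.
    """
    if unmeth_std is None or meth_std is None:
        raise ValueError("both standards are required")
    grid = unmeth_std.temperatures
    meth_std = meth_std.resampled(grid)
    gap = np.abs(unmeth_std.fluorescence - meth_std.fluorescence)
    i_star = int(np.argmax(gap))  # argmax returns the first (lowest T) maximum
    t_star = float(grid[i_star])
    rows = []
    for c in samples:
        c = c.resampled(grid)
        rows.append(
            {
                "sample_id": c.sample_id,
                "genotype": c.genotype,
                "difference": float(c.fluorescence[i_star] - unmeth_std.fluorescence[i_star]),
            }
        )
    values = pd.DataFrame(rows)
    group_p = hrm_genotype_test(values) if len(values) else {}
    return DifferenceResult(t_star=t_star, values=values, group_p=group_p)


def hrm_genotype_test(values: pd.DataFrame) -> Dict[Tuple[str, str], float]:
    """Pairwise two-sided Mann-Whitney U on difference values by genotype.

    Groups with fewer than two samples are skipped. Shares the test routine
    with the per-site methylation statistics.
    """
    from .asmstats import mann_whitney_p

    groups = {
        g: sub["difference"].to_numpy()
        for g, sub in values.groupby("genotype")
        if len(sub) >= 2
    }
    names = sorted(groups)
    out: Dict[Tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[(a, b)] = mann_whitney_p(groups[a], groups[b])
    return out
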