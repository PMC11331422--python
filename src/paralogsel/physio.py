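"""Na+ self-inhibition from voltage-clamp traces; expression calls; group tests.

Currents are handled as signed values throughout (inward currents negative by
convention).  SSI = (I_peak - I_ss) / (I_peak - I_amil): 0 when the current
does not decay from its peak, 1 when it decays all the way to the
amiloride-insensitive baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CurrentTrace",
    "SsiResult",
    "GroupComparison",
    "detect_events",
    "compute_ssi",
    "compare_groups",
    "sidak_adjust",
    "expression_call",
]


@dataclass
class CurrentTrace:
    """Time/current series with bath-event annotations.

    ``t_switch`` marks the 1 -> 110 mM Na+ step, ``t_amiloride`` the amiloride
    application.  Window parameters are configurable; defaults follow a peak
    search bounded to 15 s post-switch, a steady-state window centered 60 s
    post-switch (+/- 5 s), and a 10 s amiloride equilibration before the final
    5 s baseline window.
    """

    time_s: np.ndarray
    current_uA: np.ndarray
    t_switch: float
    t_amiloride: float
    peak_window_s: float = 15.0
    steady_state_at_s: float = 60.0
    steady_state_halfwidth_s: float = 5.0
    amiloride_equilibration_s: float = 10.0
    amiloride_window_s: float = 5.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_uA = np.asarray(self.current_uA, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.current_uA.shape:
            raise ValueError("time and current must be 1-D arrays of equal length")
        if len(self.time_s) < 2:
            raise ValueError("need at least 2 samples")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.time_s[0] <= self.t_switch <= self.time_s[-1]):
            raise ValueError("t_switch outside the recorded time range")
        if not (self.time_s[0] <= self.t_amiloride <= self.time_s[-1]):
            raise ValueError("t_amiloride outside the recorded time range")
        if self.t_switch >= self.t_amiloride:
            raise ValueError("t_switch must precede t_amiloride")

    @classmethod
    def from_csv(cls, path, t_switch, t_amiloride, **kwargs) -> "CurrentTrace":
        df = pd.read_csv(path)
        if not {"time_s", "current_uA"} <= set(df.columns):
            raise ValueError("trace CSV must have columns: time_s,current_uA")
        return cls(df["time_s"].to_numpy(), df["current_uA"].to_numpy(),
                   t_switch, t_amiloride, **kwargs)


@dataclass
class SsiResult:
    i_peak: float
    i_ss: float
    i_amil: float
    ssi: float
    clamped: bool = False
    undefined: bool = False


def detect_events(trace: CurrentTrace) -> tuple[float, float, float]:
    """(I_peak, I_ss, I_amil) from the annotated windows.

    I_peak: inward extremum in (t_switch, t_switch + peak_window]; I_ss: mean
    over the steady-state window (clipped to before amiloride); I_amil: mean
    over the final amiloride_window seconds after equilibration.
    """
    t, i = trace.time_s, trace.current_uA
    peak_mask = (t > trace.t_switch) & (t <= trace.t_switch + trace.peak_window_s)
    if not peak_mask.any():
        raise ValueError("empty peak window")
    i_peak = float(i[peak_mask].min())  # inward = negative

    ss_lo = trace.t_switch + trace.steady_state_at_s - trace.steady_state_halfwidth_s
    ss_hi = trace.t_switch + trace.steady_state_at_s + trace.steady_state_halfwidth_s
    if ss_lo >= trace.t_amiloride:
        raise ValueError("steady-state window begins after amiloride application")
    ss_hi = min(ss_hi, trace.t_amiloride)
    ss_mask = (t >= ss_lo) & (t <= ss_hi)
    if not ss_mask.any():
        raise ValueError("empty steady-state window")
    i_ss = float(i[ss_mask].mean())

    am_start = trace.t_amiloride + trace.amiloride_equilibration_s
    am_mask = t >= max(am_start, t[-1] - trace.amiloride_window_s)
    am_mask &= t > trace.t_amiloride
    if not am_mask.any():
        raise ValueError("empty amiloride window")
    i_amil = float(i[am_mask].mean())
    return i_peak, i_ss, i_amil


def compute_ssi(i_peak: float, i_ss: float, i_amil: float, noise_floor: float = 0.0) -> SsiResult:
    """SSI fraction (I_peak - I_ss) / (I_peak - I_amil), clamped to [0, 1]."""
    denom = i_peak - i_amil
    if abs(denom) <= noise_floor or denom == 0.0:
        return SsiResult(i_peak, i_ss, i_amil, float("nan"), undefined=True)
    raw = (i_peak - i_ss) / denom
    clamped = raw < 0.0 or raw > 1.0
    return SsiResult(i_peak, i_ss, i_amil, float(min(max(raw, 0.0), 1.0)), clamped=clamped)


def ssi_from_trace(trace: CurrentTrace, noise_floor: float = 0.0) -> SsiResult:
    return compute_ssi(*detect_events(trace), noise_floor=noise_floor)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment 1 - (1 - p)^m."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


@dataclass
class GroupComparison:
    design: str
    statistic: float
    p_value: float
    pairwise: list = field(default_factory=list)  # (g1, g2, t, p_raw, p_adjusted)
    flags: list = field(default_factory=list)


def compare_groups(values: Mapping[str, Sequence[float]], design: str = "two-sample") -> GroupComparison:
    """Student's t (two-sample or paired) or one-way ANOVA with Sidak pairwise."""
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each group needs at least 2 values")
    names = list(groups)
    flags = []
    for name, v in groups.items():
        if np.var(v) == 0.0:
            flags.append(f"degenerate variance in group {name!r}")

    if design == "two-sample":
        if len(groups) != 2:
            raise ValueError("two-sample design requires exactly 2 groups")
        a, b = groups[names[0]], groups[names[1]]
        if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
            return GroupComparison(design, 0.0, 1.0, flags=flags)
        t, p = stats.ttest_ind(a, b)
        return GroupComparison(design, float(t), float(p), flags=flags)

    if design == "paired":
        if len(groups) != 2:
            raise ValueError("paired design requires exactly 2 groups")
        a, b = groups[names[0]], groups[names[1]]
        if len(a) != len(b):
            raise ValueError("paired groups must have equal sizes")
        if np.all(a == b):
            return GroupComparison(design, 0.0, 1.0, flags=flags)
        t, p = stats.ttest_rel(a, b)
        return GroupComparison(design, float(t), float(p), flags=flags)

    if design == "one-way":
        if len(groups) < 2:
            raise ValueError("one-way design requires >= 2 groups")
        f, p = stats.f_oneway(*groups.values())
        pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
        m = len(pairs)
        pairwise = []
        for g1, g2 in pairs:
            t, praw = stats.ttest_ind(groups[g1], groups[g2])
            pairwise.append((g1, g2, float(t), float(praw), sidak_adjust(float(praw), m)))
        return GroupComparison(design, float(f), float(p), pairwise=pairwise, flags=flags)

    raise ValueError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# expression calls
# ---------------------------------------------------------------------------

def expression_call(
    counts: Sequence[float],
    lengths_bp: Sequence[float],
    library_total: float,
    gene_ids: Sequence[str] | None = None,
    metric: str = "RPKM",
    threshold: float = 0.3,
) -> pd.DataFrame:
    """Per-gene RPKM/FPKM = count / ((length/1e3) * (total/1e6)) and call.

    A gene is 'expressed' iff its value exceeds the threshold strictly; a
    value exactly at the threshold is background.
    """
    if metric not in ("RPKM", "FPKM"):
        raise ValueError("metric must be 'RPKM' or 'FPKM'")
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths_bp, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have the same shape")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be > 0")
    if not library_total > 0:
        raise ValueError("library total must be > 0")
    values = counts / ((lengths / 1e3) * (library_total / 1e6))
    if gene_ids is None:
        gene_ids = [f"gene{i + 1}" for i in range(len(counts))]
    return pd.DataFrame(
        {
            "gene": list(gene_ids),
            "count": counts,
            "length_bp": lengths,
            metric: values,
            "expressed": values > threshold,
        }
    )
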