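"""Simulators for every input class the analysis consumes.

All simulators are pure functions of (spec, seed): trees (Yule, with a tagged
delta clade), binary traits (exact event-driven CTMC along branches), codon
alignments (MG94xHKY with partition-specific omega), voltage-clamp traces
(peak -> exponential decay -> amiloride baseline), and expression count
tables with known truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import codon as codon_mod
from .ctmc import TraitModel
from .phylo import DEFAULT_CLASS, Node, Phylogeny
from .physio import CurrentTrace
from .traits import ABSENT, PRESENT, TraitTable

__all__ = [
    "TreeSpec",
    "TraceSpec",
    "CountsSpec",
    "simulate_tree",
    "simulate_traits",
    "simulate_branch_endpoint",
    "simulate_codon_alignment",
    "simulate_trace",
    "simulate_counts",
]


@dataclass
class TreeSpec:
    n_tips: int
    birth_rate: float = 1.0
    delta_fraction: float | None = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("need at least 3 tips")
        if self.birth_rate <= 0 or self.scale <= 0:
            raise ValueError("birth rate and scale must be > 0")


def simulate_tree(spec: TreeSpec, seed: int = 0) -> Phylogeny:
    """Yule tree with ``n_tips`` tips; optionally tags a delta clade.

    The delta clade is the internal node whose tip count is closest to
    ``delta_fraction * n_tips`` (ties -> first in preorder); its whole
    subtree including the stem branch gets class ``"delta"``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_tips
    nodes = [Node(0, None, None)]
    active = [0]
    for _ in range(2):
        c = len(nodes)
        nodes.append(Node(c, 0, 0.0))
        nodes[0].children.append(c)
    active = nodes[0].children[:]

    while len(active) < n:
        k = len(active)
        wait = rng.exponential(1.0 / (k * spec.birth_rate))
        for i in active:
            nodes[i].length += wait
        split = active.pop(int(rng.integers(k)))
        for _ in range(2):
            c = len(nodes)
            nodes.append(Node(c, split, 0.0))
            nodes[split].children.append(c)
            active.append(c)
    tail = rng.exponential(1.0 / (n * spec.birth_rate))
    for i in active:
        nodes[i].length += tail

    labels = iter(f"t{i + 1}" for i in range(n))
    for node in nodes:
        if not node.children:
            node.label = next(labels)
        if node.length is not None:
            node.length *= spec.scale
    tree = Phylogeny(nodes)

    if spec.delta_fraction is not None:
        target = spec.delta_fraction * n
        sizes = {}
        for i in tree.postorder():
            nd = tree.nodes[i]
            sizes[i] = 1 if nd.is_tip else sum(sizes[c] for c in nd.children)
        best, best_err = None, float("inf")
        for i in tree.preorder():
            if i == tree.root or tree.nodes[i].is_tip:
                continue
            err = abs(sizes[i] - target)
            if err < best_err:
                best, best_err = i, err
        if best is not None:
            stack = [best]
            while stack:
                i = stack.pop()
                tree.nodes[i].branch_class = "delta"
                stack.extend(tree.nodes[i].children)
    return tree


# ---------------------------------------------------------------------------
# binary traits
# ---------------------------------------------------------------------------

def simulate_branch_endpoint(state: int, gain: float, loss: float, t: float, rng) -> int:
    """Exact event-driven two-state CTMC sample at the end of a branch."""
    remaining = t
    while True:
        rate = gain if state == 0 else loss
        if rate <= 0:
            return state
        wait = rng.exponential(1.0 / rate)
        if wait >= remaining:
            return state
        remaining -= wait
        state = 1 - state


def simulate_traits(tree: Phylogeny, model: TraitModel, seed: int = 0) -> TraitTable:
    """Forward simulation of the binary trait; delta-class branches use q10_delta."""
    rng = np.random.default_rng(seed)
    rp = model.root_prior
    if rp == "stationary":
        p1 = model.q01 / (model.q01 + model.q10)
    elif rp == "uniform":
        p1 = 0.5
    elif isinstance(rp, tuple) and rp[0] == "fixed":
        p1 = 1.0 if rp[1] == "present" else 0.0
    else:
        raise ValueError(f"unknown root prior: {rp!r}")
    states = {tree.root: int(rng.random() < p1)}
    for i in tree.preorder():
        if i == tree.root:
            continue
        node = tree.nodes[i]
        loss = model.q10
        if model.q10_delta is not None and node.branch_class in model.delta_classes:
            loss = model.q10_delta
        states[i] = simulate_branch_endpoint(states[node.parent], model.q01, loss, node.length, rng)
    table = TraitTable()
    for tip in tree.tips():
        table[tree.nodes[tip].label] = PRESENT if states[tip] else ABSENT
    return table


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    tree: Phylogeny,
    partition: Mapping[str, str],
    site_omegas: Sequence[tuple[float, float]],
    kappa: float = 2.0,
    pos_freqs: np.ndarray | None = None,
    seed: int = 0,
) -> codon_mod.CodonPartitionAlignment:
    """Evolve codon sites under MG94xHKY with per-site, per-partition omega.

    ``site_omegas[s] = (omega_alpha, omega_delta)``; branches whose descendant
    tips are all delta evolve under omega_delta.  States are restricted to the
    61 sense codons, so stop codons are never emitted.
    """
    rng = np.random.default_rng(seed)
    if pos_freqs is None:
        pos_freqs = np.full((3, 4), 0.25)
    pi = codon_mod.codon_frequencies_from_f3x4(pos_freqs)

    n = len(tree.nodes)
    edges = [i for i in range(n) if tree.nodes[i].parent is not None]
    edge_index = {node: e for e, node in enumerate(edges)}
    delta_edges = codon_mod.branch_partition(tree, partition)
    lengths = np.array([tree.nodes[i].length for i in edges])

    omegas = sorted({w for pair in site_omegas for w in pair})
    decomp = {
        w: codon_mod._decompose(codon_mod.build_mg94_generator(kappa, pos_freqs, 1.0, w), pi)
        for w in omegas
    }
    S = len(site_omegas)
    site_w = np.array(site_omegas, dtype=float)  # (S, 2): alpha col 0, delta col 1

    states = np.empty((n, S), dtype=int)
    states[tree.root] = rng.choice(codon_mod.N_CODONS, size=S, p=pi)
    for i in tree.preorder():
        if i == tree.root:
            continue
        e = edge_index[i]
        w_col = 1 if delta_edges[e] else 0
        parent_states = states[tree.nodes[i].parent]
        child_states = np.empty(S, dtype=int)
        for w in omegas:
            mask = site_w[:, w_col] == w
            if not mask.any():
                continue
            P = codon_mod._propagators(decomp[w], np.array([lengths[e]]))[0]
            rows = P[parent_states[mask]]
            rows /= rows.sum(axis=1, keepdims=True)
            cum = rows.cumsum(axis=1)
            u = rng.random((mask.sum(), 1))
            child_states[mask] = (cum < u).sum(axis=1)
        states[i] = child_states

    ids = tree.tip_labels
    tip_rows = np.array([states[tree.tip_id(t)] for t in ids])
    return codon_mod.CodonPartitionAlignment(
        ids=ids, codons=tip_rows, partition=dict(partition), tree=tree
    )


# ---------------------------------------------------------------------------
# voltage-clamp traces
# ---------------------------------------------------------------------------

@dataclass
class TraceSpec:
    i_baseline: float = -0.5
    i_peak: float = -10.0
    i_ss: float = -4.0
    i_amil: float = -0.5
    tau_s: float = 2.5
    amiloride_tau_s: float = 0.3
    noise_sd: float = 0.0
    sample_rate_hz: float = 10.0
    t_switch: float = 10.0
    t_amiloride: float = 80.0
    duration_s: float = 100.0

    def __post_init__(self) -> None:
        if self.tau_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("tau and sampling rate must be > 0")
        if not (0 < self.t_switch < self.t_amiloride < self.duration_s):
            raise ValueError("need 0 < t_switch < t_amiloride < duration")

    @property
    def true_ssi(self) -> float:
        return (self.i_peak - self.i_ss) / (self.i_peak - self.i_amil)


def simulate_trace(spec: TraceSpec, seed: int = 0) -> CurrentTrace:
    """Baseline -> step to peak -> exponential decay to I_ss -> amiloride step.

    The decay clock starts at the first sample after t_switch, so a noiseless
    trace reproduces I_peak exactly at that sample.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / spec.sample_rate_hz
    t = np.arange(0.0, spec.duration_s + dt / 2, dt)
    i = np.full_like(t, spec.i_baseline)

    t_peak = t[np.searchsorted(t, spec.t_switch, side="right")]
    decay = (t > spec.t_switch) & (t <= spec.t_amiloride)
    i[decay] = spec.i_ss + (spec.i_peak - spec.i_ss) * np.exp(-(t[decay] - t_peak) / spec.tau_s)

    after = t > spec.t_amiloride
    i_at_amil = spec.i_ss + (spec.i_peak - spec.i_ss) * np.exp(-(spec.t_amiloride - t_peak) / spec.tau_s)
    i[after] = spec.i_amil + (i_at_amil - spec.i_amil) * np.exp(
        -(t[after] - spec.t_amiloride) / spec.amiloride_tau_s
    )
    if spec.noise_sd > 0:
        i = i + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return CurrentTrace(t, i, t_switch=spec.t_switch, t_amiloride=spec.t_amiloride)


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

@dataclass
class CountsSpec:
    n_genes: int = 100
    length_range_bp: tuple[float, float] = (500.0, 5000.0)
    library_total: float = 5_000_000.0
    expressed_fraction: float = 0.5
    expressed_value_range: tuple[float, float] = (5.0, 100.0)
    background_value_range: tuple[float, float] = (0.0, 0.1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.expressed_fraction <= 1.0:
            raise ValueError("expressed fraction must be in [0, 1]")
        if self.library_total <= 0 or self.n_genes < 1:
            raise ValueError("invalid counts spec")


def simulate_counts(spec: CountsSpec, seed: int = 0) -> tuple[pd.DataFrame, float]:
    """(gene table with truth labels, library total); counts are integers."""
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(*spec.length_range_bp, size=spec.n_genes)
    expressed = rng.random(spec.n_genes) < spec.expressed_fraction
    lo_e, hi_e = spec.expressed_value_range
    lo_b, hi_b = spec.background_value_range
    target = np.where(
        expressed,
        np.exp(rng.uniform(np.log(max(lo_e, 1e-9)), np.log(hi_e), size=spec.n_genes)),
        rng.uniform(lo_b, hi_b, size=spec.n_genes),
    )
    counts = np.rint(target * (lengths / 1e3) * (spec.library_total / 1e6))
    df = pd.DataFrame(
        {
            "gene": [f"gene{i + 1}" for i in range(spec.n_genes)],
            "count": counts,
            "length_bp": lengths,
            "true_expressed": expressed,
        }
    )
    return df, spec.library_total
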