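"""Site-level dN/dS under an MG94xHKY codon model.

Implements the shared-nuisance stage (kappa, a single branch-length scale and
a global omega, with F3x4 codon frequencies), per-site tests of beta = alpha
on a selected branch set (FEL-style), and the partition contrast of
beta_alpha = beta_delta with a shared synonymous rate (Contrast-FEL-style).
Standard genetic code only; likelihoods are computed by pruning over the 61
sense codons with per-node scaling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from scipy import optimize, stats

from .phylo import Phylogeny

__all__ = [
    "SENSE_CODONS",
    "CODON_INDEX",
    "AMINO_ACIDS",
    "CodonPartitionAlignment",
    "CodonModelParams",
    "SiteTestResult",
    "f3x4_frequencies",
    "codon_frequencies_from_f3x4",
    "build_mg94_generator",
    "stationary_distribution",
    "fit_global_nuisance",
    "fel_site_test",
    "contrast_fel_site_test",
    "branch_partition",
]

NUCS = "ACGT"
_NUC_INDEX = {n: i for i, n in enumerate(NUCS)}
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)

SENSE_CODONS: list[str] = [
    "".join(c) for c in itertools.product(NUCS, repeat=3) if "".join(c) not in _STOPS
]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACIDS: list[str] = [_TABLE.forward_table["".join(c)] for c in SENSE_CODONS]
N_CODONS = len(SENSE_CODONS)  # 61

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _single_nt_changes():
    """Ordered codon pairs differing at exactly one nucleotide."""
    I, J, POS, TO, TS, SYN = [], [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            I.append(i)
            J.append(j)
            POS.append(p)
            TO.append(_NUC_INDEX[cj[p]])
            TS.append(frozenset((ci[p], cj[p])) in _TRANSITIONS)
            SYN.append(AMINO_ACIDS[i] == AMINO_ACIDS[j])
    return (
        np.array(I), np.array(J), np.array(POS), np.array(TO),
        np.array(TS, dtype=bool), np.array(SYN, dtype=bool),
    )


_I, _J, _POS, _TO, _TS, _SYN = _single_nt_changes()


# ---------------------------------------------------------------------------
# frequencies and generator
# ---------------------------------------------------------------------------

def f3x4_frequencies(codon_indices: np.ndarray) -> np.ndarray:
    """Position-specific nucleotide frequencies (3x4) from observed codons.

    ``codon_indices`` holds sense-codon indices with -1 for gaps/ambiguity.
    """
    counts = np.zeros((3, 4))
    flat = np.asarray(codon_indices).ravel()
    flat = flat[flat >= 0]
    for idx in flat:
        codon = SENSE_CODONS[idx]
        for p in range(3):
            counts[p, _NUC_INDEX[codon[p]]] += 1
    if counts.sum() == 0:
        raise ValueError("no non-gap codons to estimate frequencies from")
    counts += 0.5  # avoid structural zeros
    return counts / counts.sum(axis=1, keepdims=True)


def codon_frequencies_from_f3x4(pos_freqs: np.ndarray) -> np.ndarray:
    """Sense-codon equilibrium frequencies: position products, renormalized."""
    pi = np.empty(N_CODONS)
    for i, codon in enumerate(SENSE_CODONS):
        pi[i] = math.prod(pos_freqs[p, _NUC_INDEX[codon[p]]] for p in range(3))
    return pi / pi.sum()


def _neutral_scale(kappa: float, pos_freqs: np.ndarray) -> float:
    """Expected substitution rate of the alpha = beta = 1 generator."""
    rates = np.where(_TS, kappa, 1.0) * pos_freqs[_POS, _TO]
    pi = codon_frequencies_from_f3x4(pos_freqs)
    return float(np.sum(pi[_I] * rates))


def build_mg94_generator(
    kappa: float,
    pos_freqs: np.ndarray,
    alpha: float = 1.0,
    beta: float = 1.0,
    scale: float | None = None,
) -> np.ndarray:
    """61x61 MG94xHKY rate matrix; rows sum to 0.

    Off-diagonal entries exist only for single-nucleotide changes:
    (alpha for synonymous | beta for nonsynonymous) x (kappa for transitions)
    x the F3x4 frequency of the target nucleotide at the changed position.
    ``scale`` divides the matrix; by default the neutral (alpha=beta=1)
    expected rate, so branch lengths read as neutral substitutions per codon.
    """
    pos_freqs = np.asarray(pos_freqs, dtype=float)
    if pos_freqs.shape != (3, 4) or np.any(pos_freqs < 0):
        raise ValueError("pos_freqs must be a non-negative (3, 4) array")
    if not np.allclose(pos_freqs.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each row of pos_freqs must sum to 1")
    if scale is None:
        scale = _neutral_scale(kappa, pos_freqs)
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = np.where(_SYN, alpha, beta) * np.where(_TS, kappa, 1.0) * pos_freqs[_POS, _TO]
    Q[_I, _J] = rates / scale
    Q[np.diag_indices(N_CODONS)] = -Q.sum(axis=1)
    return Q


def stationary_distribution(pos_freqs: np.ndarray) -> np.ndarray:
    return codon_frequencies_from_f3x4(pos_freqs)


def _decompose(Q: np.ndarray, pi: np.ndarray):
    """Symmetric eigendecomposition of a pi-reversible generator."""
    sq = np.sqrt(pi)
    B = (sq[:, None] * Q) / sq[None, :]
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    A = V / sq[:, None]
    Ainv = V.T * sq[None, :]
    return w, A, Ainv


def _propagators(decomp, times: np.ndarray) -> np.ndarray:
    """P(t) for a batch of branch times from one decomposition."""
    w, A, Ainv = decomp
    expwt = np.exp(np.outer(times, w))  # (E, 61)
    tmp = A[None, :, :] * expwt[:, None, :]
    P = tmp @ Ainv
    np.clip(P, 0.0, None, out=P)
    return P


# ---------------------------------------------------------------------------
# alignment container
# ---------------------------------------------------------------------------

def encode_codon(codon: str) -> int:
    """Sense-codon index; -1 for gap or ambiguous codons; error on stops."""
    codon = codon.upper().replace("U", "T")
    if codon == "---":
        return -1
    if any(ch not in NUCS for ch in codon):
        return -1
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon!r} in non-gap position")
    return CODON_INDEX[codon]


@dataclass
class CodonPartitionAlignment:
    """In-frame codon alignment with per-record alpha/delta labels and a tree."""

    ids: list[str]
    codons: np.ndarray  # (n_records, n_sites) sense-codon indices, -1 = gap
    partition: dict
    tree: Phylogeny
    site_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=int)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.ids):
            raise ValueError("codons must be (n_records, n_sites)")
        missing = [i for i in self.ids if i not in self.partition]
        if missing:
            raise ValueError(f"partition labels missing for: {missing[:5]}")
        bad = {v for v in self.partition.values()} - {"alpha", "delta"}
        if bad:
            raise ValueError(f"partition labels must be 'alpha' or 'delta', got {sorted(bad)}")
        tips = set(self.tree.tip_labels)
        if tips != set(self.ids):
            raise ValueError("tree tips and alignment ids do not match")
        if self.site_labels is not None and len(self.site_labels) != self.n_sites:
            raise ValueError("site_labels length mismatch")

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    @classmethod
    def from_sequences(cls, ids, seqs, partition, tree, site_labels=None):
        n_sites = {len(s) // 3 for s in seqs}
        if len(n_sites) != 1 or any(len(s) % 3 for s in seqs):
            raise ValueError("sequences must share one in-frame codon length")
        mat = np.array(
            [[encode_codon(s[3 * k : 3 * k + 3]) for k in range(len(s) // 3)] for s in seqs]
        )
        return cls(list(ids), mat, dict(partition), tree, site_labels)

    @classmethod
    def from_fasta(cls, path, tree, partition, site_labels=None):
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        return cls.from_sequences(ids, seqs, partition, tree, site_labels)


def branch_partition(tree: Phylogeny, partition: Mapping[str, str]) -> np.ndarray:
    """Per-edge bool (True = delta): all descendant tips labeled delta."""
    n = len(tree.nodes)
    all_delta = np.zeros(n, dtype=bool)
    for i in tree.postorder():
        node = tree.nodes[i]
        if node.is_tip:
            all_delta[i] = partition[node.label] == "delta"
        else:
            all_delta[i] = all(all_delta[c] for c in node.children)
    edges = [i for i in range(n) if tree.nodes[i].parent is not None]
    return all_delta[np.array(edges, dtype=np.intp)]


# ---------------------------------------------------------------------------
# pruning engine
# ---------------------------------------------------------------------------

class CodonLikelihood:
    """Level-batched pruning over 61 states, vectorized across sites."""

    def __init__(self, aln: CodonPartitionAlignment, sites: Sequence[int] | None = None):
        tree = aln.tree
        self.tree = tree
        n = len(tree.nodes)
        sites = list(range(aln.n_sites)) if sites is None else list(sites)
        self.sites = sites
        S = len(sites)

        row_of = {rec_id: r for r, rec_id in enumerate(aln.ids)}
        base = np.ones((n, S, N_CODONS))
        for tip in tree.tips():
            row = aln.codons[row_of[tree.nodes[tip].label]]
            for s_out, s in enumerate(sites):
                c = row[s]
                if c >= 0:
                    base[tip, s_out, :] = 0.0
                    base[tip, s_out, c] = 1.0
        self._base = base

        child = np.array([i for i in range(n) if tree.nodes[i].parent is not None], dtype=np.intp)
        parent = np.array([tree.nodes[i].parent for i in child], dtype=np.intp)
        self.lengths = np.array([tree.nodes[i].length for i in child])
        self._child, self._parent = child, parent
        self.n_edges = len(child)
        edge_of_child = {int(c): e for e, c in enumerate(child)}

        height = np.zeros(n, dtype=int)
        for i in tree.postorder():
            kids = tree.nodes[i].children
            if kids:
                height[i] = 1 + max(height[k] for k in kids)
        self._levels = []
        for h in range(1, height[tree.root] + 1):
            nodes_h = np.array([i for i in range(n) if height[i] == h], dtype=np.intp)
            edges_h = np.array(
                [edge_of_child[k] for i in nodes_h for k in tree.nodes[i].children], dtype=np.intp
            )
            self._levels.append((nodes_h, edges_h))
        self.root = tree.root
        self._n = n
        self.delta_edges = branch_partition(tree, aln.partition)

    def loglik(self, P: np.ndarray, pi: np.ndarray) -> float:
        """Total log-likelihood given per-edge propagators (E, 61, 61)."""
        partial = self._base.copy()
        S = partial.shape[1]
        logscale = np.zeros((self._n, S))
        for nodes_h, edges_h in self._levels:
            ch = self._child[edges_h]
            # (E,61,61) @ (E,61,S) -> (E,61,S)
            contrib = np.matmul(P[edges_h], partial[ch].transpose(0, 2, 1)).transpose(0, 2, 1)
            np.multiply.at(partial, self._parent[edges_h], contrib)
            np.add.at(logscale, self._parent[edges_h], logscale[ch])
            m = partial[nodes_h].max(axis=2)
            if np.any(m <= 0.0):
                return -np.inf
            partial[nodes_h] /= m[:, :, None]
            logscale[nodes_h] += np.log(m)
        site_lik = partial[self.root] @ pi
        if np.any(site_lik <= 0.0):
            return -np.inf
        return float(np.sum(np.log(site_lik) + logscale[self.root]))


# ---------------------------------------------------------------------------
# nuisance fit
# ---------------------------------------------------------------------------

@dataclass
class CodonModelParams:
    kappa: float
    omega: float
    branch_scale: float
    pos_freqs: np.ndarray
    pi: np.ndarray
    log_likelihood: float
    converged: bool = True


def fit_global_nuisance(
    aln: CodonPartitionAlignment, n_starts: int = 2, seed: int = 0
) -> CodonModelParams:
    """ML fit of (kappa, branch scale, global omega) under MG94xHKY + F3x4."""
    if len(aln.ids) < 3:
        raise ValueError("need at least 3 sequences")
    variable = sum(
        len({c for c in aln.codons[:, s] if c >= 0}) > 1 for s in range(aln.n_sites)
    )
    if variable < 2:
        raise ValueError("no signal: fewer than 2 variable sites")

    pos_freqs = f3x4_frequencies(aln.codons)
    pi = codon_frequencies_from_f3x4(pos_freqs)
    engine = CodonLikelihood(aln)

    def objective(x: np.ndarray) -> float:
        kappa, scale, omega = np.exp(x)
        Q = build_mg94_generator(kappa, pos_freqs, 1.0, omega)
        decomp = _decompose(Q, pi)
        P = _propagators(decomp, scale * engine.lengths)
        ll = engine.loglik(P, pi)
        return 1e12 if not math.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    starts = [np.log([2.0, 1.0, 0.3])]
    while len(starts) < n_starts:
        starts.append(np.log([rng.uniform(0.5, 8.0), rng.uniform(0.2, 3.0), rng.uniform(0.05, 2.0)]))
    bounds = [(math.log(0.05), math.log(100.0)),
              (math.log(1e-4), math.log(100.0)),
              (math.log(1e-6), math.log(100.0))]
    best = None
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 300, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    kappa, scale, omega = np.exp(best.x)
    return CodonModelParams(
        kappa=float(kappa), omega=float(omega), branch_scale=float(scale),
        pos_freqs=pos_freqs, pi=pi, log_likelihood=-best.fun, converged=bool(best.success),
    )


# ---------------------------------------------------------------------------
# site tests
# ---------------------------------------------------------------------------

@dataclass
class SiteTestResult:
    site: str
    kind: str  # "FEL" | "Contrast-FEL"
    alpha: float
    beta: dict
    dnds: dict
    statistic: float
    p_value: float
    direction: str | None = None
    untestable: bool = False
    dnds_undefined: bool = False
    notes: list = field(default_factory=list)


def _site_invariant(codons: np.ndarray, site: int, rows: Sequence[int] | None = None) -> bool:
    col = codons[:, site] if rows is None else codons[list(rows), site]
    observed = {int(c) for c in col if c >= 0}
    return len(observed) <= 1


def _omega_ratio(beta: float, alpha: float) -> float:
    return float("nan") if alpha <= 0 else beta / alpha


def fel_site_test(
    aln: CodonPartitionAlignment,
    site: int,
    branches: str | np.ndarray,
    nuisance: CodonModelParams,
    site_label: str | None = None,
) -> SiteTestResult:
    """Per-site test of beta = alpha on a selected branch set.

    Site rates (alpha_s, beta_s) apply on the tested branches; the remaining
    branches keep the globally fitted omega (their nonsynonymous rate is
    omega_global * alpha_s, sharing the site's synonymous rate).
    """
    engine = CodonLikelihood(aln, sites=[site])
    if isinstance(branches, str):
        if branches not in ("alpha", "delta"):
            raise ValueError("branches must be 'alpha', 'delta', or a boolean mask")
        tested = engine.delta_edges if branches == "delta" else ~engine.delta_edges
    else:
        tested = np.asarray(branches, dtype=bool)
    if not tested.any():
        raise ValueError("tested branch set is empty")
    label = site_label or (aln.site_labels[site] if aln.site_labels else f"site{site + 1}")

    if _site_invariant(aln.codons, site):
        return SiteTestResult(
            site=label, kind="FEL", alpha=0.0, beta={"tested": 0.0},
            dnds={"tested": float("nan")}, statistic=0.0, p_value=1.0,
            untestable=True, dnds_undefined=True, notes=["invariant site"],
        )

    pi, pos_freqs = nuisance.pi, nuisance.pos_freqs
    base_t = nuisance.branch_scale * engine.lengths
    bg_decomp = _decompose(build_mg94_generator(nuisance.kappa, pos_freqs, 1.0, nuisance.omega), pi)

    def loglik(alpha_s: float, beta_s: float) -> float:
        P = np.empty((engine.n_edges, N_CODONS, N_CODONS))
        # Q(a, b) = a * Q(1, b/a): reuse decompositions with time scaled by a
        fg_decomp = _decompose(
            build_mg94_generator(nuisance.kappa, pos_freqs, 1.0, beta_s / alpha_s), pi
        )
        P[tested] = _propagators(fg_decomp, alpha_s * base_t[tested])
        if (~tested).any():
            P[~tested] = _propagators(bg_decomp, alpha_s * base_t[~tested])
        return engine.loglik(P, pi)

    lo, hi = math.log(1e-6), math.log(100.0)

    def neg_free(x):
        ll = loglik(*np.exp(x))
        return 1e12 if not math.isfinite(ll) else -ll

    def neg_null(x):
        r = math.exp(x[0])
        ll = loglik(r, r)
        return 1e12 if not math.isfinite(ll) else -ll

    free = _best_fit(neg_free, [np.log([1.0, 0.3]), np.log([0.5, 1.0])], [(lo, hi)] * 2)
    null = _best_fit(neg_null, [[0.0], [math.log(0.3)]], [(lo, hi)])
    alpha_hat, beta_hat = np.exp(free.x)
    if -free.fun < -null.fun:  # guard optimizer slack on the nested pair
        alpha_hat = beta_hat = math.exp(null.x[0])
        free = null
    statistic = max(0.0, 2.0 * (null.fun - free.fun))
    p = float(stats.chi2.sf(statistic, df=1))
    # treat rates at the lower optimization bound as 0 (boundary estimates)
    alpha_r = 0.0 if alpha_hat <= 1e-6 * 1.01 else float(alpha_hat)
    beta_r = 0.0 if beta_hat <= 1e-6 * 1.01 else float(beta_hat)
    return SiteTestResult(
        site=label, kind="FEL", alpha=alpha_r, beta={"tested": beta_r},
        dnds={"tested": _omega_ratio(beta_r, alpha_r)}, statistic=float(statistic),
        p_value=p, direction="dN<dS" if beta_r < alpha_r else "dN>dS",
        dnds_undefined=alpha_r <= 0,
    )


def contrast_fel_site_test(
    aln: CodonPartitionAlignment,
    site: int,
    nuisance: CodonModelParams,
    site_label: str | None = None,
) -> SiteTestResult:
    """Shared alpha_s, partition-specific beta; LRT of beta_alpha = beta_delta."""
    engine = CodonLikelihood(aln, sites=[site])
    delta_edges = engine.delta_edges
    if not delta_edges.any() or delta_edges.all():
        raise ValueError("both partitions must be non-empty")
    label = site_label or (aln.site_labels[site] if aln.site_labels else f"site{site + 1}")

    rows_alpha = [r for r, i in enumerate(aln.ids) if aln.partition[i] == "alpha"]
    rows_delta = [r for r, i in enumerate(aln.ids) if aln.partition[i] == "delta"]
    notes = []
    flagged = False
    for name, rows in (("alpha", rows_alpha), ("delta", rows_delta)):
        if _site_invariant(aln.codons, site, rows):
            notes.append(f"no variation in {name} partition")
            flagged = True

    pi, pos_freqs = nuisance.pi, nuisance.pos_freqs
    base_t = nuisance.branch_scale * engine.lengths

    def loglik(alpha_s: float, beta_a: float, beta_d: float) -> float:
        P = np.empty((engine.n_edges, N_CODONS, N_CODONS))
        da = _decompose(build_mg94_generator(nuisance.kappa, pos_freqs, 1.0, beta_a / alpha_s), pi)
        P[~delta_edges] = _propagators(da, alpha_s * base_t[~delta_edges])
        dd = _decompose(build_mg94_generator(nuisance.kappa, pos_freqs, 1.0, beta_d / alpha_s), pi)
        P[delta_edges] = _propagators(dd, alpha_s * base_t[delta_edges])
        return engine.loglik(P, pi)

    lo, hi = math.log(1e-6), math.log(100.0)

    def neg_free(x):
        ll = loglik(*np.exp(x))
        return 1e12 if not math.isfinite(ll) else -ll

    def neg_null(x):
        a, b = np.exp(x)
        ll = loglik(a, b, b)
        return 1e12 if not math.isfinite(ll) else -ll

    null = _best_fit(neg_null, [np.log([1.0, 0.3]), np.log([0.5, 1.0])], [(lo, hi)] * 2)
    a0, b0 = np.exp(null.x)
    free = _best_fit(neg_free, [np.log([a0, b0, b0]), np.log([1.0, 0.1, 1.0])], [(lo, hi)] * 3)
    if -free.fun < -null.fun:
        free = optimize.OptimizeResult(x=np.log([a0, b0, b0]), fun=null.fun, success=True)
    alpha_hat, beta_a, beta_d = np.exp(free.x)
    statistic = max(0.0, 2.0 * (null.fun - free.fun))
    p = 1.0 if flagged else float(stats.chi2.sf(statistic, df=1))
    dnds_a = _omega_ratio(beta_a, alpha_hat)
    dnds_d = _omega_ratio(beta_d, alpha_hat)
    return SiteTestResult(
        site=label, kind="Contrast-FEL", alpha=float(alpha_hat),
        beta={"alpha": float(beta_a), "delta": float(beta_d)},
        dnds={"alpha": dnds_a, "delta": dnds_d, "ratio": dnds_d / dnds_a if dnds_a > 0 else float("nan")},
        statistic=float(statistic), p_value=p, untestable=flagged,
        dnds_undefined=alpha_hat <= 0, notes=notes,
    )


def _best_fit(fun, starts, bounds):
    best = None
    for x0 in starts:
        res = optimize.minimize(fun, np.asarray(x0, dtype=float), method="L-BFGS-B",
                                bounds=bounds, options={"maxiter": 200, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    return best
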