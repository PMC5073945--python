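"""Pairwise global alignment of protein-protein interaction (PPI) networks
by steady-state network flow.

Given two undirected, optionally weighted PPI networks and a table of
cross-network node similarity scores (typically BLAST bit scores), the
method builds an *integrated network*: the union of both PPI networks plus
a cross-network edge for every positive similarity entry. A Markov random
walker on this network makes intra-network moves (proportional to
interaction weight) and cross-network moves (proportional to similarity).
The long-run rate at which the walker crosses a particular similarity edge
(u, v) -- the steady-state network flow

    c(u, v) = pi(u) * Pr[v | u] + pi(v) * Pr[u | v]

with pi the stationary distribution -- measures the correspondence of u
and v: it is large when the pair is sequence-similar *and* embedded in
similar neighbourhoods, because similar neighbourhoods channel more of the
walker's stationary mass through the pair. The flow scores are refined by
a probabilistic consistency transformation (PCT)

    C~ = alpha * C + (1 - alpha) * P_X @ C @ P_Y.T

which lets well-corresponding neighbours reinforce a pair, then sparsified
by a percentile threshold that keeps all originally supported entries.
The final one-to-one alignment is the maximum-weight bipartite matching of
the thresholded scores, i.e. the maximum-expected-accuracy mapping when
pair probabilities are proportional to the scores.

This module is organised in the order the pipeline runs:

    1. configuration and errors
    2. domain types (PPINetwork, SimilarityTable, AnnotationSet, ...)
    3. file I/O (edge lists, similarity tables, annotations, alignments)
    4. transition model and steady-state flow (the correspondence scores)
    5. alignment construction (MWBM, end-to-end driver, baseline)
    6. evaluation metrics (CN/SPE, GOC, IC, CI, COI)
    7. synthetic ground-truth generator and benchmark driver
"""

from __future__ import annotations

import itertools
import logging
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

__all__ = [
    "EXPERIMENTAL_EVIDENCE",
    "RunConfig",
    "InputError",
    "ConvergenceError",
    "UndefinedICError",
    "PPINetwork",
    "SimilarityTable",
    "AnnotationSet",
    "TransitionModel",
    "CorrespondenceMatrix",
    "Alignment",
    "read_ppi_network",
    "read_similarity",
    "read_annotations",
    "read_alignment",
    "write_alignment",
    "intra_transition",
    "cross_transitions",
    "assemble_transition",
    "steady_state",
    "network_flow",
    "pct",
    "threshold_scores",
    "compute_correspondence",
    "max_weight_matching",
    "align",
    "sequence_only_align",
    "CorrectNodesResult",
    "MetricReport",
    "correct_nodes",
    "information_content",
    "goc",
    "conserved_interactions",
    "conserved_orthologous_interactions",
    "evaluate_alignment",
    "SynthParams",
    "SyntheticPair",
    "generate_pair",
    "truth_annotations",
    "recovery_rate",
    "run_bench",
]

logger = logging.getLogger("cufid")

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# 1. Configuration and errors
# ---------------------------------------------------------------------------

#: GO evidence codes denoting experimental support; used as the default
#: whitelist when filtering annotation tables at read time.
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


class InputError(ValueError):
    """A malformed or inconsistent input file (CLI exit code 2)."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge (CLI exit code 3)."""


class UndefinedICError(KeyError):
    """Information content requested for a term absent from the corpus."""


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the alignment pipeline.

    Parameters
    ----------
    alpha : float in [0, 1]
        PCT mixing weight: fraction of the raw flow score retained versus
        the neighbour-propagated term. Default 0.9.
    beta_percentile : float in [0, 100]
        Percentile (over the positive transformed scores) used as the
        sparsification threshold beta. Default 90.
    block_mix : float in (0, 1)
        Relative weight of the intra-network block versus the cross-network
        block when a node has both kinds of moves; the assembled transition
        matrix row is ``block_mix * intra + (1 - block_mix) * cross``.
        Default 0.5 (equal weight).
    tol : float
        L1 stopping tolerance of the power iteration. Default 1e-10.
    max_iter : int
        Power-iteration cap; exceeding it raises a convergence warning.
    ic_min : float
        Minimum information content (bits) for a GO term to count in the
        GOC and COI metrics. Default 2.
    seed : int
        Base seed for the synthetic generator / benchmark.
    """

    alpha: float = 0.9
    beta_percentile: float = 90.0
    block_mix: float = 0.5
    tol: float = 1e-10
    max_iter: int = 10000
    ic_min: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta_percentile <= 100.0:
            raise ValueError(
                f"beta_percentile must be in [0, 100], got {self.beta_percentile}"
            )
        if not 0.0 < self.block_mix < 1.0:
            raise ValueError(f"block_mix must be in (0, 1), got {self.block_mix}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


# ---------------------------------------------------------------------------
# 2. Domain types
# ---------------------------------------------------------------------------


@dataclass
class PPINetwork:
    """One species' PPI network: an undirected, positively weighted graph.

    ``nodes`` is an ordered list (first-appearance order from the input);
    all matrices produced downstream index nodes by this order. ``edges``
    maps canonical pairs (lower index first) to positive weights; no
    self-loops, no duplicates.
    """

    name: str
    nodes: list[str]
    edges: dict[tuple[str, str], float]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {u: i for i, u in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError(f"duplicate node identifiers in network {self.name!r}")
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r} in network {self.name!r}")
            if a not in self._index or b not in self._index:
                raise ValueError(f"edge endpoint not in node list: ({a!r}, {b!r})")
            if not (w > 0):
                raise ValueError(f"non-positive edge weight on ({a!r}, {b!r}): {w}")

    @classmethod
    def from_interactions(
        cls,
        name: str,
        interactions: Iterable[tuple[str, str, float]],
        isolated: Iterable[str] = (),
    ) -> "PPINetwork":
        """Build a canonical network from (a, b, weight) records.

        Duplicate records for the same unordered pair keep the maximum
        weight; self-loops are dropped with a warning. Node order is first
        appearance across the interaction stream, then the ``isolated``
        extras.
        """
        nodes: list[str] = []
        index: dict[str, int] = {}

        def intern(u: str) -> int:
            if u not in index:
                index[u] = len(nodes)
                nodes.append(u)
            return index[u]

        edges: dict[tuple[str, str], float] = {}
        n_loops = 0
        for a, b, w in interactions:
            ia, ib = intern(a), intern(b)
            if a == b:
                n_loops += 1
                continue
            key = (a, b) if ia < ib else (b, a)
            prev = edges.get(key)
            if prev is None or w > prev:
                edges[key] = float(w)
        for u in isolated:
            intern(u)
        if n_loops:
            logger.warning("network %s: dropped %d self-loop(s)", name, n_loops)
        return cls(name=name, nodes=nodes, edges=edges)

    def __len__(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self._index[node]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def has_edge(self, a: str, b: str) -> bool:
        if a not in self._index or b not in self._index:
            return False
        key = (a, b) if self._index[a] < self._index[b] else (b, a)
        return key in self.edges

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency matrix in node order."""
        n = len(self.nodes)
        rows, cols, vals = [], [], []
        for (a, b), w in self.edges.items():
            i, j = self._index[a], self._index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


@dataclass
class SimilarityTable:
    """Sparse cross-network node-similarity scores s(u, v) > 0."""

    x_nodes: list[str]
    y_nodes: list[str]
    entries: dict[tuple[str, str], float]
    _xi: dict[str, int] = field(init=False, repr=False)
    _yi: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._xi = {u: i for i, u in enumerate(self.x_nodes)}
        self._yi = {v: j for j, v in enumerate(self.y_nodes)}
        for (u, v), s in self.entries.items():
            if u not in self._xi or v not in self._yi:
                raise ValueError(f"similarity entry on unknown node pair ({u!r}, {v!r})")
            if not (s > 0):
                raise ValueError(f"non-positive similarity for ({u!r}, {v!r}): {s}")

    def __len__(self) -> int:
        return len(self.entries)

    def matrix(self) -> sp.csr_matrix:
        """|U| x |V| sparse score matrix S in node order."""
        rows = [self._xi[u] for (u, v) in self.entries]
        cols = [self._yi[v] for (u, v) in self.entries]
        vals = list(self.entries.values())
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.x_nodes), len(self.y_nodes))
        )


@dataclass
class AnnotationSet:
    """Functional annotations: protein -> term set, with optional roots
    and per-(protein, term) evidence codes.

    Term roots (for GO: molecular function / biological process / cellular
    component) are needed only when information content is queried.
    """

    protein_terms: dict[str, set[str]]
    term_root: dict[str, str] = field(default_factory=dict)
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    def terms(self, protein: str) -> set[str]:
        return self.protein_terms.get(protein, set())

    def __len__(self) -> int:
        return len(self.protein_terms)


@dataclass
class TransitionModel:
    """The random walker's transition structure on the integrated network.

    ``p_x``/``p_y`` are the intra-network row-stochastic matrices,
    ``p_xy``/``p_yx`` the row-normalised cross-network matrices (``p_yx``
    is |V| x |U|: row j holds Pr[u | v_j]). ``p_full`` is the assembled
    (|U|+|V|)-square stochastic matrix; ``pi`` the stationary distribution
    once computed.
    """

    p_x: sp.csr_matrix
    p_y: sp.csr_matrix
    p_xy: sp.csr_matrix
    p_yx: sp.csr_matrix
    p_full: sp.csr_matrix
    pi: np.ndarray | None = None
    converged: bool = True

    @property
    def n_x(self) -> int:
        return self.p_x.shape[0]

    @property
    def n_y(self) -> int:
        return self.p_y.shape[0]

    @property
    def pi_x(self) -> np.ndarray:
        assert self.pi is not None, "stationary distribution not computed"
        return self.pi[: self.n_x]

    @property
    def pi_y(self) -> np.ndarray:
        assert self.pi is not None, "stationary distribution not computed"
        return self.pi[self.n_x :]


@dataclass
class CorrespondenceMatrix:
    """Sparse |U| x |V| node-correspondence scores at a pipeline stage.

    ``stage`` advances raw_flow -> pct -> thresholded; scores are
    non-negative throughout.
    """

    scores: sp.csr_matrix
    stage: str
    x_nodes: list[str]
    y_nodes: list[str]

    _STAGES = ("raw_flow", "pct", "thresholded")

    def __post_init__(self) -> None:
        if self.stage not in self._STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.scores.shape != (len(self.x_nodes), len(self.y_nodes)):
            raise ValueError("score matrix shape does not match node lists")
        if self.scores.nnz and self.scores.data.min() < 0:
            raise ValueError("correspondence scores must be non-negative")


@dataclass
class Alignment:
    """A one-to-one partial mapping between the two node sets.

    Each node appears in at most one pair; every emitted pair has a
    strictly positive score.
    """

    pairs: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        xs = [u for u, _, _ in self.pairs]
        ys = [v for _, v, _ in self.pairs]
        if len(set(xs)) != len(xs) or len(set(ys)) != len(ys):
            raise ValueError("alignment is not one-to-one")
        for u, v, s in self.pairs:
            if not (s > 0):
                raise ValueError(f"non-positive alignment score for ({u!r}, {v!r})")

    def __len__(self) -> int:
        return len(self.pairs)

    def mapping(self) -> dict[str, str]:
        """The alignment as a dict from X-nodes to Y-nodes."""
        return {u: v for u, v, _ in self.pairs}

    def pair_set(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v, _ in self.pairs}

    def total_score(self) -> float:
        return float(sum(s for _, _, s in self.pairs))

    def inverse(self) -> "Alignment":
        return Alignment([(v, u, s) for u, v, s in self.pairs])


# ---------------------------------------------------------------------------
# 3. File I/O
# ---------------------------------------------------------------------------
# All tabular inputs are UTF-8, tab- or whitespace-separated, with '#'
# comment lines and blank lines skipped.


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def read_ppi_network(path: str | Path, name: str | None = None) -> PPINetwork:
    """Read a PPI network from a 2- or 3-column edge list.

    Columns are (node_a, node_b[, weight]); a missing weight means 1.
    Duplicate edges keep the maximum weight and self-loops are dropped
    with a warning. Node order is first appearance.
    """
    if name is None:
        name = Path(path).stem
    records: list[tuple[str, str, float]] = []
    for lineno, cols in _data_lines(path):
        if len(cols) not in (2, 3):
            raise InputError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(cols)}")
        a, b = cols[0], cols[1]
        if len(cols) == 3:
            try:
                w = float(cols[2])
            except ValueError:
                raise InputError(f"{path}:{lineno}: unparseable weight {cols[2]!r}") from None
            if not (w > 0) or not math.isfinite(w):
                raise InputError(f"{path}:{lineno}: edge weight must be positive, got {w}")
        else:
            w = 1.0
        records.append((a, b, w))
    net = PPINetwork.from_interactions(name, records)
    logger.info("read network %s: %d nodes, %d edges", name, len(net), len(net.edges))
    return net


def read_similarity(
    path: str | Path, net_x: PPINetwork, net_y: PPINetwork
) -> SimilarityTable:
    """Read a 3-column (node_x, node_y, score) cross-network similarity table.

    Entries with score <= 0 are dropped silently; entries naming nodes
    absent from either network are dropped with a counted warning;
    duplicates keep the maximum score.
    """
    entries: dict[tuple[str, str], float] = {}
    n_skipped = 0
    for lineno, cols in _data_lines(path):
        if len(cols) != 3:
            raise InputError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
        u, v = cols[0], cols[1]
        try:
            s = float(cols[2])
        except ValueError:
            raise InputError(f"{path}:{lineno}: unparseable score {cols[2]!r}") from None
        if not (s > 0):
            continue
        if u not in net_x or v not in net_y:
            n_skipped += 1
            continue
        prev = entries.get((u, v))
        if prev is None or s > prev:
            entries[(u, v)] = s
    if n_skipped:
        logger.warning(
            "similarity table %s: skipped %d row(s) naming unknown nodes", path, n_skipped
        )
    table = SimilarityTable(list(net_x.nodes), list(net_y.nodes), entries)
    logger.info("read similarity %s: %d entries", path, len(table))
    return table


def read_annotations(
    path: str | Path, evidence_whitelist: frozenset[str] | set[str] | None = None
) -> AnnotationSet:
    """Read a (protein, term[, evidence_code][, root_term]) table.

    With an evidence whitelist (e.g. :data:`EXPERIMENTAL_EVIDENCE`), rows
    whose code falls outside it are dropped; without one all rows are
    kept. A 3-column row is interpreted as (protein, term, evidence) when
    a whitelist is active and as (protein, term, root) otherwise, matching
    the two usual dialects (GO-with-evidence vs. grouped orthology labels).
    """
    protein_terms: dict[str, set[str]] = {}
    term_root: dict[str, str] = {}
    evidence: dict[tuple[str, str], str] = {}
    for lineno, cols in _data_lines(path):
        if len(cols) < 2 or len(cols) > 4:
            raise InputError(f"{path}:{lineno}: expected 2-4 columns, got {len(cols)}")
        protein, term = cols[0], cols[1]
        code = root = None
        if len(cols) == 4:
            code, root = cols[2], cols[3]
        elif len(cols) == 3:
            if evidence_whitelist is not None:
                code = cols[2]
            else:
                root = cols[2]
        if evidence_whitelist is not None and code is not None:
            if code not in evidence_whitelist:
                continue
        protein_terms.setdefault(protein, set()).add(term)
        if code is not None:
            evidence[(protein, term)] = code
        if root is not None:
            term_root[term] = root
    return AnnotationSet(protein_terms, term_root, evidence)


def write_alignment(
    alignment: Alignment, path: str | Path, header: Sequence[str] = ()
) -> None:
    """Write an alignment as (node_x, node_y, score) TSV rows, sorted by
    descending score (ties by node pair); byte-deterministic."""
    rows = sorted(alignment.pairs, key=lambda p: (-p[2], p[0], p[1]))
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for u, v, s in rows:
            fh.write(f"{u}\t{v}\t{s:.10g}\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an alignment written by :func:`write_alignment`."""
    pairs: list[tuple[str, str, float]] = []
    for lineno, cols in _data_lines(path):
        if len(cols) != 3:
            raise InputError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
        try:
            s = float(cols[2])
        except ValueError:
            raise InputError(f"{path}:{lineno}: unparseable score {cols[2]!r}") from None
        pairs.append((cols[0], cols[1], s))
    return Alignment(pairs)


# ---------------------------------------------------------------------------
# 4. Transition model and steady-state flow
# ---------------------------------------------------------------------------


def _row_normalize(m: sp.spmatrix) -> sp.csr_matrix:
    """Scale each row to sum 1; all-zero rows stay all-zero."""
    m = sp.csr_matrix(m, dtype=float)
    sums = np.asarray(m.sum(axis=1)).ravel()
    inv = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    return sp.csr_matrix(sp.diags(inv) @ m)


def intra_transition(network: PPINetwork) -> sp.csr_matrix:
    """Row-normalise the weighted adjacency matrix into the intra-network
    transition matrix; isolated nodes keep an all-zero row (resolved at
    assembly)."""
    if len(network) == 0:
        raise ValueError(f"network {network.name!r} is empty")
    return _row_normalize(network.adjacency())


def cross_transitions(sim: SimilarityTable) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Cross-network transition matrices from the similarity scores.

    Returns ``(p_xy, p_yx)``: ``p_xy[i, j] = s(u_i, v_j) / sum_j s(u_i, .)``
    (rows of S normalised) and ``p_yx[j, i] = s(u_i, v_j) / sum_i s(., v_j)``
    (columns of S normalised, stored |V| x |U| so each similarity-bearing
    row sums to 1). Nodes without similarity entries get all-zero rows.
    """
    s_mat = sim.matrix()
    p_xy = _row_normalize(s_mat)
    p_yx = _row_normalize(s_mat.T)
    return p_xy, p_yx


def assemble_transition(
    p_x: sp.spmatrix,
    p_y: sp.spmatrix,
    p_xy: sp.spmatrix,
    p_yx: sp.spmatrix,
    block_mix: float = 0.5,
) -> TransitionModel:
    """Assemble the full transition matrix over the integrated network.

    The 2x2 block layout is ``[[P_X, P_XY], [P_YX, P_Y]]``. Summing two
    row-stochastic blocks would give rows of mass 2, so each row is
    convex-combined: nodes with both intra- and cross-network moves weight
    the intra block by ``block_mix`` and the cross block by
    ``1 - block_mix``; nodes with only one kind of move use that block
    unscaled; fully isolated, similarity-free nodes get the uniform
    distribution over all nodes so the matrix stays stochastic.
    """
    p_x = sp.csr_matrix(p_x, dtype=float)
    p_y = sp.csr_matrix(p_y, dtype=float)
    p_xy = sp.csr_matrix(p_xy, dtype=float)
    p_yx = sp.csr_matrix(p_yx, dtype=float)
    n_x, n_y = p_x.shape[0], p_y.shape[0]
    if p_x.shape != (n_x, n_x) or p_y.shape != (n_y, n_y):
        raise ValueError("intra-network blocks must be square")
    if p_xy.shape != (n_x, n_y) or p_yx.shape != (n_y, n_x):
        raise ValueError("cross-network block shapes do not match the networks")

    def row_weights(intra: sp.csr_matrix, cross: sp.csr_matrix):
        has_intra = np.asarray(intra.sum(axis=1)).ravel() > 0.5
        has_cross = np.asarray(cross.sum(axis=1)).ravel() > 0.5
        w_intra = np.where(has_intra & has_cross, block_mix, has_intra.astype(float))
        w_cross = np.where(has_intra & has_cross, 1.0 - block_mix, has_cross.astype(float))
        return w_intra, w_cross, ~(has_intra | has_cross)

    wxi, wxc, dangling_x = row_weights(p_x, p_xy)
    wyi, wyc, dangling_y = row_weights(p_y, p_yx)

    p_full = sp.bmat(
        [
            [sp.diags(wxi) @ p_x, sp.diags(wxc) @ p_xy],
            [sp.diags(wyc) @ p_yx, sp.diags(wyi) @ p_y],
        ],
        format="lil",
    )
    n = n_x + n_y
    dangling = np.concatenate([dangling_x, dangling_y])
    for i in np.flatnonzero(dangling):
        p_full[i, :] = 1.0 / n
    return TransitionModel(
        p_x=p_x, p_y=p_y, p_xy=p_xy, p_yx=p_yx, p_full=sp.csr_matrix(p_full)
    )


def steady_state(
    model: TransitionModel, tol: float = 1e-10, max_iter: int = 10000
) -> np.ndarray:
    """Stationary distribution of the assembled walk by power iteration.

    Starts from the uniform vector and iterates ``pi <- pi P`` until the
    L1 change drops below ``tol``; exceeding ``max_iter`` emits a warning
    and marks the model non-converged. The result is stored on the model
    and returned.
    """
    p_full = model.p_full
    row_sums = np.asarray(p_full.sum(axis=1)).ravel()
    if not np.allclose(row_sums, 1.0, atol=1e-9):
        raise RuntimeError("assembled transition matrix is not row-stochastic")
    n = p_full.shape[0]
    pt = p_full.T.tocsr()  # left eigenvector via pi <- P^T pi
    pi = np.full(n, 1.0 / n)
    model.converged = False
    for iteration in range(1, max_iter + 1):
        nxt = pt @ pi
        nxt /= nxt.sum()
        delta = np.abs(nxt - pi).sum()
        pi = nxt
        if delta < tol:
            model.converged = True
            logger.debug("power method converged in %d iterations", iteration)
            break
    if not model.converged:
        logger.warning(
            "power method did not reach tol=%g within %d iterations (last L1 change %g)",
            tol,
            max_iter,
            delta,
        )
    model.pi = pi
    return pi


def network_flow(
    pi: np.ndarray,
    p_xy: sp.spmatrix,
    p_yx: sp.spmatrix,
    sim: SimilarityTable,
) -> CorrespondenceMatrix:
    """Steady-state network flow through every cross-network edge.

    ``c(u_i, v_j) = pi(u_i) Pr[v_j | u_i] + pi(v_j) Pr[u_i | v_j]`` with
    the similarity-conditional transition probabilities (the row- and
    column-normalised similarity matrix, not the assembled-matrix rows).
    The support of the result equals the support of the similarity table.
    """
    n_x = len(sim.x_nodes)
    pi_x, pi_y = pi[:n_x], pi[n_x:]
    c = sp.diags(pi_x) @ sp.csr_matrix(p_xy) + (sp.diags(pi_y) @ sp.csr_matrix(p_yx)).T
    c = sp.csr_matrix(c)
    c.sum_duplicates()
    return CorrespondenceMatrix(c, "raw_flow", list(sim.x_nodes), list(sim.y_nodes))


def pct(
    c: CorrespondenceMatrix,
    p_x: sp.spmatrix,
    p_y: sp.spmatrix,
    alpha: float = 0.9,
) -> CorrespondenceMatrix:
    """Probabilistic consistency transformation of the flow scores:
    ``C~ = alpha C + (1 - alpha) P_X C P_Y.T``, propagating each pair's
    score to its neighbouring pairs."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if c.stage != "raw_flow":
        raise ValueError(f"pct expects stage 'raw_flow', got {c.stage!r}")
    raw = c.scores
    transformed = alpha * raw + (1.0 - alpha) * (
        sp.csr_matrix(p_x) @ raw @ sp.csr_matrix(p_y).T
    )
    return CorrespondenceMatrix(
        sp.csr_matrix(transformed), "pct", list(c.x_nodes), list(c.y_nodes)
    )


def threshold_scores(
    c_pct: CorrespondenceMatrix,
    c_raw: CorrespondenceMatrix,
    beta_percentile: float = 90.0,
) -> CorrespondenceMatrix:
    """Sparsify the transformed scores at the beta-percentile threshold.

    beta is the ``beta_percentile``-th percentile (linear interpolation)
    of the *positive* transformed scores. An entry survives, at its
    transformed value, when it reaches beta or when the raw flow there was
    already positive (PCT-created entries below beta are the ones pruned).
    """
    if c_pct.stage != "pct":
        raise ValueError(f"threshold_scores expects stage 'pct', got {c_pct.stage!r}")
    if c_raw.stage != "raw_flow":
        raise ValueError(f"c_raw must be at stage 'raw_flow', got {c_raw.stage!r}")
    if not 0.0 <= beta_percentile <= 100.0:
        raise ValueError(f"beta_percentile must be in [0, 100], got {beta_percentile}")
    ct = sp.csr_matrix(c_pct.scores, copy=True)
    ct.eliminate_zeros()
    positive = ct.data[ct.data > 0]
    beta = float(np.percentile(positive, beta_percentile)) if positive.size else 0.0
    coo = ct.tocoo()
    raw_pos = sp.csr_matrix(c_raw.scores, copy=True)
    raw_pos.eliminate_zeros()
    raw_support = set(zip(*raw_pos.nonzero()))
    keep = np.array(
        [
            val >= beta or (i, j) in raw_support
            for i, j, val in zip(coo.row, coo.col, coo.data)
        ],
        dtype=bool,
    )
    kept = sp.csr_matrix(
        (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=ct.shape
    )
    logger.info(
        "threshold beta=%.3g (p%g of %d positive scores): kept %d of %d entries",
        beta,
        beta_percentile,
        positive.size,
        kept.nnz,
        ct.nnz,
    )
    return CorrespondenceMatrix(kept, "thresholded", list(c_pct.x_nodes), list(c_pct.y_nodes))


def compute_correspondence(
    net_x: PPINetwork,
    net_y: PPINetwork,
    sim: SimilarityTable,
    config: RunConfig = RunConfig(),
) -> tuple[TransitionModel, CorrespondenceMatrix, CorrespondenceMatrix, CorrespondenceMatrix]:
    """Run the scoring pipeline and return the transition model and the
    correspondence matrix at every stage (raw flow, PCT, thresholded)."""
    timings: list[tuple[str, float]] = []

    def stage(label: str, fn):
        t0 = time.perf_counter()
        out = fn()
        timings.append((label, time.perf_counter() - t0))
        return out

    p_x = stage("intra_x", lambda: intra_transition(net_x))
    p_y = stage("intra_y", lambda: intra_transition(net_y))
    p_xy, p_yx = stage("cross", lambda: cross_transitions(sim))
    model = stage(
        "assemble", lambda: assemble_transition(p_x, p_y, p_xy, p_yx, config.block_mix)
    )
    pi = stage("steady_state", lambda: steady_state(model, config.tol, config.max_iter))
    c_raw = stage("flow", lambda: network_flow(pi, p_xy, p_yx, sim))
    c_pct = stage("pct", lambda: pct(c_raw, p_x, p_y, config.alpha))
    c_bar = stage(
        "threshold", lambda: threshold_scores(c_pct, c_raw, config.beta_percentile)
    )
    logger.info(
        "pipeline timings: %s; density(P)=%.4f",
        ", ".join(f"{k}={v * 1e3:.1f}ms" for k, v in timings),
        model.p_full.nnz / float(model.p_full.shape[0] * model.p_full.shape[1]),
    )
    return model, c_raw, c_pct, c_bar


# ---------------------------------------------------------------------------
# 5. Alignment construction
# ---------------------------------------------------------------------------


def max_weight_matching(c_bar: CorrespondenceMatrix) -> Alignment:
    """Maximum-weight bipartite matching of the correspondence scores.

    Solves the assignment problem on the (non-negative) score matrix and
    drops zero-score pairs, yielding the one-to-one partial mapping of
    maximum total score. Deterministic: scores are laid out in canonical
    node order and the solver is deterministic, so ties resolve
    reproducibly.
    """
    dense = np.asarray(c_bar.scores.todense(), dtype=float)
    if dense.size == 0 or not (dense > 0).any():
        return Alignment([])
    rows, cols = linear_sum_assignment(dense, maximize=True)
    pairs = [
        (c_bar.x_nodes[i], c_bar.y_nodes[j], float(dense[i, j]))
        for i, j in zip(rows, cols)
        if dense[i, j] > 0
    ]
    return Alignment(pairs)


def align(
    net_x: PPINetwork,
    net_y: PPINetwork,
    sim: SimilarityTable,
    config: RunConfig = RunConfig(),
) -> Alignment:
    """End-to-end alignment: steady-state flow scoring, PCT, thresholding,
    then maximum-weight bipartite matching. Deterministic for fixed inputs
    and configuration."""
    if len(sim) == 0:
        logger.warning("empty similarity table: returning an empty alignment")
        return Alignment([])
    _, _, _, c_bar = compute_correspondence(net_x, net_y, sim, config)
    alignment = max_weight_matching(c_bar)
    logger.info(
        "aligned %d pairs (|X|=%d, |Y|=%d)", len(alignment), len(net_x), len(net_y)
    )
    return alignment


def sequence_only_align(sim: SimilarityTable) -> Alignment:
    """Baseline: maximum-weight bipartite matching of the raw similarity
    scores alone, ignoring both network topologies."""
    c = CorrespondenceMatrix(
        sim.matrix(), "thresholded", list(sim.x_nodes), list(sim.y_nodes)
    )
    return max_weight_matching(c)


# ---------------------------------------------------------------------------
# 6. Evaluation metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrectNodesResult:
    """CN / SPE with the retained-pair count and a definedness flag."""

    cn: int
    spe: float
    n_retained: int
    spe_defined: bool


@dataclass(frozen=True)
class MetricReport:
    """The paper-style alignment quality summary."""

    cn: int
    spe: float
    goc: float
    ci: int
    coi: int
    n_scored_pairs: int

    def as_dict(self) -> dict[str, float]:
        return {
            "cn": self.cn,
            "spe": self.spe,
            "goc": self.goc,
            "ci": self.ci,
            "coi": self.coi,
            "n_scored_pairs": self.n_scored_pairs,
        }


def correct_nodes(a: Alignment, groups: AnnotationSet) -> CorrectNodesResult:
    """Correct nodes (CN) and specificity (SPE) against orthology-group
    labels.

    Pairs where either protein carries no label are removed before
    counting; a retained pair is correct when the two label sets
    intersect. SPE is CN over the retained count (reported as 0, flagged
    undefined, when nothing is retained).
    """
    retained = [
        (u, v)
        for u, v, _ in a.pairs
        if groups.terms(u) and groups.terms(v)
    ]
    cn = sum(1 for u, v in retained if groups.terms(u) & groups.terms(v))
    if retained:
        return CorrectNodesResult(cn, cn / len(retained), len(retained), True)
    return CorrectNodesResult(0, 0.0, 0, False)


def _corpus_counts(annot: AnnotationSet) -> tuple[dict[str, int], dict[str, int]]:
    """Per-term protein counts |c| and per-root corpus sizes |root(c)|."""
    term_count: dict[str, int] = {}
    root_proteins: dict[str, set[str]] = {}
    for protein, terms in annot.protein_terms.items():
        for term in terms:
            term_count[term] = term_count.get(term, 0) + 1
            root = annot.term_root.get(term)
            if root is not None:
                root_proteins.setdefault(root, set()).add(protein)
    return term_count, {r: len(ps) for r, ps in root_proteins.items()}


def information_content(term: str, annot: AnnotationSet) -> float:
    """Information content of a term in bits: ``-log2(|c| / |root(c)|)``,
    where |c| counts proteins annotated with the term and |root(c)| counts
    proteins under the term's ontology root, both within the supplied
    corpus."""
    term_count, root_size = _corpus_counts(annot)
    if term not in term_count:
        raise UndefinedICError(f"term {term!r} not present in the annotation corpus")
    root = annot.term_root.get(term)
    if root is None or root not in root_size:
        raise UndefinedICError(f"term {term!r} has no root assignment")
    return -math.log2(term_count[term] / root_size[root])


def _ic_filtered_terms(annot: AnnotationSet, ic_min: float | None) -> dict[str, set[str]]:
    """Each protein's term set with low-information terms removed."""
    if ic_min is None:
        return {p: set(ts) for p, ts in annot.protein_terms.items()}
    term_count, root_size = _corpus_counts(annot)
    keep: set[str] = set()
    for term, count in term_count.items():
        root = annot.term_root.get(term)
        if root is None or root not in root_size:
            raise UndefinedICError(f"term {term!r} has no root assignment")
        if -math.log2(count / root_size[root]) >= ic_min:
            keep.add(term)
    return {p: ts & keep for p, ts in annot.protein_terms.items()}


def _pair_goc(u: str, v: str, filtered: Mapping[str, set[str]]) -> float | None:
    """Jaccard index of the filtered term sets; None when either is empty
    (the pair is excluded from the metric)."""
    tu, tv = filtered.get(u, set()), filtered.get(v, set())
    if not tu or not tv:
        return None
    return len(tu & tv) / len(tu | tv)


def goc(a: Alignment, annot: AnnotationSet, ic_min: float | None = 2.0) -> float:
    """Gene-ontology consistency of an alignment: the sum over retained
    aligned pairs of the Jaccard index of their term sets, after removing
    every term with information content below ``ic_min`` bits. Pairs with
    an empty post-filter set on either side are removed."""
    filtered = _ic_filtered_terms(annot, ic_min)
    total = 0.0
    for u, v, _ in a.pairs:
        j = _pair_goc(u, v, filtered)
        if j is not None:
            total += j
    return total


def conserved_interactions(
    a: Alignment, net_x: PPINetwork, net_y: PPINetwork
) -> int:
    """Conserved interactions (CI): undirected edges of X whose endpoints
    are both aligned and whose images form an edge of Y. Each edge counts
    once."""
    f = a.mapping()
    count = 0
    for u1, u2 in net_x.edges:
        if u1 in f and u2 in f and net_y.has_edge(f[u1], f[u2]):
            count += 1
    return count


def conserved_orthologous_interactions(
    a: Alignment,
    net_x: PPINetwork,
    net_y: PPINetwork,
    annot: AnnotationSet,
    ic_min: float | None = 2.0,
) -> int:
    """Conserved orthologous interactions (COI): the CI edges both of
    whose endpoint pairs share at least one (IC-filtered) term, i.e. have
    strictly positive per-pair GO Jaccard."""
    f = a.mapping()
    filtered = _ic_filtered_terms(annot, ic_min)

    def orthologous(u: str) -> bool:
        j = _pair_goc(u, f[u], filtered)
        return j is not None and j > 0

    count = 0
    for u1, u2 in net_x.edges:
        if (
            u1 in f
            and u2 in f
            and net_y.has_edge(f[u1], f[u2])
            and orthologous(u1)
            and orthologous(u2)
        ):
            count += 1
    return count


def evaluate_alignment(
    a: Alignment,
    net_x: PPINetwork,
    net_y: PPINetwork,
    groups: AnnotationSet | None = None,
    go_annotations: AnnotationSet | None = None,
    ic_min: float | None = 2.0,
) -> MetricReport:
    """Compute the full metric report. ``groups`` drives CN/SPE (orthology
    group labels); ``go_annotations`` drives GOC and COI. Metrics whose
    annotations are absent are reported as 0."""
    cn_res = (
        correct_nodes(a, groups)
        if groups is not None
        else CorrectNodesResult(0, 0.0, 0, False)
    )
    goc_score = goc(a, go_annotations, ic_min) if go_annotations is not None else 0.0
    ci = conserved_interactions(a, net_x, net_y)
    coi = (
        conserved_orthologous_interactions(a, net_x, net_y, go_annotations, ic_min)
        if go_annotations is not None
        else 0
    )
    return MetricReport(
        cn=cn_res.cn,
        spe=cn_res.spe,
        goc=goc_score,
        ci=ci,
        coi=coi,
        n_scored_pairs=cn_res.n_retained,
    )


# ---------------------------------------------------------------------------
# 7. Synthetic ground truth and benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthParams:
    """Generator settings for a ground-truth network pair.

    An Erdos-Renyi ancestor graph with ``n_ancestor`` nodes and expected
    degree ``expected_degree`` is duplicated; each descendant
    independently loses a ``node_delete_frac`` fraction of nodes and has a
    ``edge_flip_frac`` fraction of its edges flipped (half deletions, half
    insertions in expectation). Similarity scores are gamma-distributed:
    every surviving ortholog pair gets a score with mean ``true_sim_mean``
    and spurious cross-pairs are added at density ``sim_density`` with the
    smaller mean ``noise_sim_mean``. The scales echo BLAST bit scores for
    genuine versus chance local similarity.
    """

    n_ancestor: int = 100
    expected_degree: float = 6.0
    node_delete_frac: float = 0.1
    edge_flip_frac: float = 0.1
    true_sim_mean: float = 100.0
    noise_sim_mean: float = 60.0
    sim_density: float = 0.05
    sim_shape: float = 2.0

    def __post_init__(self) -> None:
        if self.n_ancestor < 2:
            raise ValueError("n_ancestor must be >= 2")
        for name in ("node_delete_frac", "edge_flip_frac", "sim_density"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if not (self.true_sim_mean > 0 and self.noise_sim_mean > 0):
            raise ValueError("similarity means must be positive")


@dataclass
class SyntheticPair:
    """A generated network pair with its ground-truth node mapping.

    ``ancestor_edges`` keeps the common ancestor's edge list (integer node
    ids) so the realised node/edge turnover can be audited.
    """

    net_x: PPINetwork
    net_y: PPINetwork
    sim: SimilarityTable
    truth: dict[str, str]
    params: SynthParams
    seed: int
    ancestor_edges: list[tuple[int, int]] = field(default_factory=list)


def _derive_side(
    rng: np.random.Generator,
    ancestor_edges: list[tuple[int, int]],
    n: int,
    params: SynthParams,
) -> tuple[list[int], list[tuple[int, int]]]:
    """Delete nodes, then flip edges (delete w.p. f/2, insert to match)."""
    keep_mask = rng.random(n) >= params.node_delete_frac
    kept = [i for i in range(n) if keep_mask[i]]
    if len(kept) < 2:
        raise ValueError("node deletion left fewer than 2 nodes")
    kept_set = set(kept)
    edges = [(i, j) for i, j in ancestor_edges if i in kept_set and j in kept_set]
    m = len(edges)
    half = params.edge_flip_frac / 2.0
    surviving = [e for e in edges if rng.random() >= half]
    present = set(surviving)
    n_insert = rng.binomial(m, half) if m else 0
    inserted = 0
    attempts = 0
    while inserted < n_insert and attempts < 50 * max(n_insert, 1):
        a, b = rng.choice(len(kept), size=2, replace=False)
        i, j = kept[a], kept[b]
        key = (i, j) if i < j else (j, i)
        if key not in present:
            present.add(key)
            surviving.append(key)
            inserted += 1
        attempts += 1
    return kept, surviving


def generate_pair(params: SynthParams = SynthParams(), seed: int = 0) -> SyntheticPair:
    """Generate a ground-truth pair of networks plus a noisy similarity
    table; fully reproducible from ``seed``.

    X-side nodes are named ``a<i>``, Y-side nodes ``b<i>``; ``truth`` maps
    each ancestor node surviving on both sides.
    """
    rng = np.random.default_rng(seed)
    n = params.n_ancestor
    p_edge = min(1.0, params.expected_degree / max(n - 1, 1))
    ancestor_edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p_edge
    ]
    kept_x, edges_x = _derive_side(rng, ancestor_edges, n, params)
    kept_y, edges_y = _derive_side(rng, ancestor_edges, n, params)

    def label(prefix: str, i: int) -> str:
        return f"{prefix}{i:04d}"

    net_x = PPINetwork.from_interactions(
        "synthetic_x",
        [(label("a", i), label("a", j), 1.0) for i, j in edges_x],
        isolated=[label("a", i) for i in kept_x],
    )
    net_y = PPINetwork.from_interactions(
        "synthetic_y",
        [(label("b", i), label("b", j), 1.0) for i, j in edges_y],
        isolated=[label("b", i) for i in kept_y],
    )
    truth = {
        label("a", i): label("b", i) for i in sorted(set(kept_x) & set(kept_y))
    }

    shape = params.sim_shape
    entries: dict[tuple[str, str], float] = {}
    for u, v in truth.items():
        entries[(u, v)] = float(rng.gamma(shape, params.true_sim_mean / shape))
    n_cells = len(net_x) * len(net_y)
    n_spurious = rng.binomial(n_cells, params.sim_density) if n_cells else 0
    if n_spurious:
        xi = rng.integers(0, len(net_x), size=n_spurious)
        yi = rng.integers(0, len(net_y), size=n_spurious)
        scores = rng.gamma(shape, params.noise_sim_mean / shape, size=n_spurious)
        for i, j, s in zip(xi, yi, scores):
            key = (net_x.nodes[i], net_y.nodes[j])
            if truth.get(key[0]) == key[1]:  # never overwrite a true-pair score
                continue
            prev = entries.get(key)
            if prev is None or s > prev:
                entries[(key[0], key[1])] = float(s)
    sim = SimilarityTable(list(net_x.nodes), list(net_y.nodes), entries)
    return SyntheticPair(net_x, net_y, sim, truth, params, seed, ancestor_edges)


def truth_annotations(pair: SyntheticPair) -> AnnotationSet:
    """Ground-truth orthology groups as an annotation set: each true pair
    shares one group term (rooted at a single corpus root), so CN/SPE,
    GOC and COI can be scored against the known orthology."""
    protein_terms: dict[str, set[str]] = {}
    term_root: dict[str, str] = {}
    for u, v in pair.truth.items():
        term = f"grp_{u}"
        protein_terms[u] = {term}
        protein_terms[v] = {term}
        term_root[term] = "root"
    return AnnotationSet(protein_terms, term_root)


def recovery_rate(a: Alignment, truth: Mapping[str, str]) -> float:
    """Fraction of ground-truth pairs recovered by the alignment."""
    if not truth:
        raise ValueError("truth mapping is empty")
    found = a.pair_set()
    return sum(1 for item in truth.items() if item in found) / len(truth)


def run_bench(
    params: SynthParams = SynthParams(),
    config: RunConfig = RunConfig(),
    replicates: int = 20,
    seed: int = 0,
) -> dict:
    """Benchmark the flow-based aligner against the sequence-only baseline
    on a synthetic ensemble.

    Replicate ``k`` uses seed ``seed + k``. Per replicate and method the
    recovery rate, CN/SPE against the true orthology groups, CI and COI
    are tabulated; the summary holds mean and sd per column per method.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    columns = ("recovery", "cn", "spe", "ci", "coi")
    rows: list[dict] = []
    for k in range(replicates):
        pair = generate_pair(params, seed=seed + k)
        annot = truth_annotations(pair)
        for method, alignment in (
            ("cufid", align(pair.net_x, pair.net_y, pair.sim, config)),
            ("seq_only", sequence_only_align(pair.sim)),
        ):
            report = evaluate_alignment(
                alignment,
                pair.net_x,
                pair.net_y,
                groups=annot,
                go_annotations=annot,
                ic_min=config.ic_min,
            )
            rows.append(
                {
                    "replicate": k,
                    "method": method,
                    "recovery": recovery_rate(alignment, pair.truth),
                    "cn": report.cn,
                    "spe": report.spe,
                    "ci": report.ci,
                    "coi": report.coi,
                }
            )
    summary: dict[str, dict[str, dict[str, float]]] = {}
    for method in ("cufid", "seq_only"):
        vals = {c: np.array([r[c] for r in rows if r["method"] == method]) for c in columns}
        summary[method] = {
            c: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0}
            for c, v in vals.items()
        }
    return {"rows": rows, "summary": summary}
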