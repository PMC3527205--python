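"""Upstream-regulator inference on a signed directed interaction network.

A *hypothesis* is a (regulator, direction) pair — e.g. "loss of angiotensin II
activity".  Walking signed regulatory edges downstream (paths of length 1, or
2 with one intermediary), each reachable gene gets a predicted transcriptional
direction: the hypothesis direction times the product of edge signs along the
path; genes reached by paths with conflicting net signs are *ambiguous*.

Two significance measures per hypothesis, against a fixed background gene
universe:

* enrichment p — one-sided hypergeometric upper tail on the overlap between
  the reachable set and the input gene list (direction ignored);
* correctness p — direction-aware: each input gene carries an assumed sign
  (default -1, loss of function); the statistic is #sign-consistent minus
  #contradicting input genes, and its null distribution comes from drawing
  the input list uniformly without replacement from the background
  partitioned into (predicted-matching, predicted-contradicting,
  unreached-or-ambiguous) classes — an exact trivariate hypergeometric
  convolution.

Multiple testing over the hypothesis space uses Bonferroni with H = the
number of hypotheses actually evaluated on the supplied network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "SignedGraph",
    "Hypothesis",
    "HypothesisResult",
    "predicted_signs",
    "enrichment_test",
    "correctness_test",
    "evaluate_all",
    "direct_interactors",
    "read_edge_list",
]

AMBIGUOUS = 0


class SignedGraph:
    """Directed graph with edge signs in {+1, -1}.

    Backed by a :class:`networkx.MultiDiGraph` so parallel edges of opposite
    sign are representable; such pairs are permitted but flagged in
    :attr:`conflicting_edges`.  Self-loops are rejected.
    """

    def __init__(self) -> None:
        self.g = nx.MultiDiGraph()

    def add_node(self, node: str) -> None:
        self.g.add_node(node)

    def add_edge(self, src: str, dst: str, sign: int) -> None:
        if src == dst:
            raise ValueError(f"self-loop rejected: {src}")
        if sign not in (+1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
        self.g.add_edge(src, dst, sign=sign)

    @property
    def nodes(self):
        return self.g.nodes

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def edge_signs(self, src: str, dst: str) -> list[int]:
        if not self.g.has_edge(src, dst):
            return []
        return [d["sign"] for d in self.g[src][dst].values()]

    @property
    def conflicting_edges(self) -> list[tuple[str, str]]:
        """(src, dst) pairs connected by parallel edges of opposite sign."""
        out = []
        for u, v in {(u, v) for u, v, _ in self.g.edges(keys=True)}:
            if len(set(self.edge_signs(u, v))) > 1:
                out.append((u, v))
        return sorted(out)

    @classmethod
    def from_edges(cls, edges) -> "SignedGraph":
        """Build from (src, dst, sign) triples; sign may be '+', '-', +1, -1."""
        sg = cls()
        for src, dst, sign in edges:
            s = {"+": 1, "-": -1, "+1": 1, "-1": -1}.get(str(sign), sign)
            sg.add_edge(str(src), str(dst), int(s))
        return sg

    def to_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            for u, v, d in sorted(self.g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{'+' if d['sign'] > 0 else '-'}\n")


def read_edge_list(path) -> SignedGraph:
    """Read a signed edge list: ``source<TAB>target<TAB>sign`` with sign +/-."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            src, dst, sign = line.split("\t")
            edges.append((src, dst, sign))
    return SignedGraph.from_edges(edges)


@dataclass(frozen=True)
class Hypothesis:
    """An upstream-regulator hypothesis: +1 = gain of activity, -1 = loss."""

    regulator: str
    direction: int  # +1 gain, -1 loss

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("hypothesis direction must be +1 or -1")


@dataclass
class HypothesisResult:
    hypothesis: Hypothesis
    n_path: int  # reachable background genes (incl. ambiguous)
    k: int  # overlap with input list
    K: int  # input-list size
    N: int  # background size
    odds_ratio: float
    enrichment_p: float
    correctness_p: float
    n_hypotheses: int = 1

    @property
    def enrichment_p_corrected(self) -> float:
        return min(1.0, self.enrichment_p * self.n_hypotheses)

    @property
    def correctness_p_corrected(self) -> float:
        return min(1.0, self.correctness_p * self.n_hypotheses)


# ---------------------------------------------------------------------------
# sign propagation


def predicted_signs(
    graph: SignedGraph, hypothesis: Hypothesis, depth: int = 1
) -> dict[str, int]:
    """Predicted transcriptional direction for every gene reachable from the
    regulator by paths of length <= depth (depth in {1, 2}).

    Prediction = hypothesis direction x product of edge signs along the
    path.  A gene reached by paths whose net signs conflict is mapped to 0
    (ambiguous).  The regulator itself is not predicted.
    """
    if depth not in (1, 2):
        raise ValueError("depth must be 1 or 2")
    r = hypothesis.regulator
    if r not in graph.nodes:
        raise KeyError(f"regulator {r!r} absent from network")

    path_signs: dict[str, set[int]] = {}

    def _note(node: str, sign: int) -> None:
        path_signs.setdefault(node, set()).add(sign)

    for m in graph.g.successors(r):
        for s1 in graph.edge_signs(r, m):
            _note(m, s1)
            if depth == 2:
                for g2 in graph.g.successors(m):
                    if g2 == r:
                        continue
                    for s2 in graph.edge_signs(m, g2):
                        _note(g2, s1 * s2)

    out = {}
    for node, signs in path_signs.items():
        if node == r:
            continue
        out[node] = hypothesis.direction * signs.pop() if len(signs) == 1 else AMBIGUOUS
    return out


# ---------------------------------------------------------------------------
# enrichment


def enrichment_test(n_path: int, k: int, K: int, N: int) -> tuple[float, float]:
    """Hypergeometric gene-set enrichment of the reachable set.

    Drawing the K input genes from a background of N with n_path reachable,
    p = P(X >= k) one-sided upper tail.  Odds ratio
    k (N - K - n_path + k) / ((K - k)(n_path - k)); degenerate margins give
    (nan, 1.0).
    """
    if not 0 <= k <= min(n_path, K) or max(n_path, K) > N:
        raise ValueError(f"invalid margins: n_path={n_path}, k={k}, K={K}, N={N}")
    if n_path == 0 or K == 0:
        return float("nan"), 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n_path))
    denom = (K - k) * (n_path - k)
    odds = k * (N - K - n_path + k) / denom if denom > 0 else float("inf")
    return float(odds), p


# ---------------------------------------------------------------------------
# correctness


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def correctness_statistic(
    predictions: dict[str, int], input_genes, assumed_sign: int = -1
) -> int:
    """#input genes predicted with the assumed sign minus #contradicting."""
    match = sum(1 for g in input_genes if predictions.get(g, AMBIGUOUS) == assumed_sign)
    contra = sum(1 for g in input_genes if predictions.get(g, AMBIGUOUS) == -assumed_sign)
    return match - contra


def correctness_test(
    predictions: dict[str, int],
    input_genes,
    background,
    assumed_sign: int = -1,
    statistic: str = "difference",
) -> float:
    """Direction-aware correctness p-value.

    The background is partitioned by the hypothesis's predictions into
    matching (predicted == assumed sign), contradicting (predicted ==
    -assumed) and other (unreached or ambiguous) classes of sizes (a, b, c).
    Under the null the K input genes are a uniform draw without replacement,
    so (X_match, X_contra) is trivariate hypergeometric;
    p = P(X_match - X_contra >= observed), computed by exact convolution.
    ``statistic="correct"`` scores #matching alone (plain hypergeometric
    upper tail).
    """
    background = list(background)
    if not background:
        raise ValueError("empty background")
    bg = set(background)
    input_genes = list(input_genes)
    if not set(input_genes) <= bg:
        raise ValueError("input genes must be a subset of the background")
    N = len(bg)
    K = len(input_genes)
    a = sum(1 for g in bg if predictions.get(g, AMBIGUOUS) == assumed_sign)
    b = sum(1 for g in bg if predictions.get(g, AMBIGUOUS) == -assumed_sign)

    k_match = sum(1 for g in input_genes if predictions.get(g, AMBIGUOUS) == assumed_sign)
    if statistic == "correct":
        return float(stats.hypergeom.sf(k_match - 1, N, a, K))
    if statistic != "difference":
        raise ValueError("statistic must be 'difference' or 'correct'")
    s_obs = correctness_statistic(predictions, input_genes, assumed_sign)

    c = N - a - b
    m = np.arange(0, min(a, K) + 1)
    cc = np.arange(0, min(b, K) + 1)
    M, C = np.meshgrid(m, cc, indexing="ij")
    rest = K - M - C
    valid = (rest >= 0) & (rest <= c)
    logp = (
        _log_comb(a, M)
        + _log_comb(b, C)
        + _log_comb(c, np.where(valid, rest, 0))
        - _log_comb(N, K)
    )
    logp = np.where(valid, logp, -np.inf)
    tail = (M - C) >= s_obs
    sel = logp[tail & valid]
    if sel.size == 0:
        return 0.0 if s_obs > K else 1.0
    return float(min(1.0, np.exp(logsumexp(sel))))


# ---------------------------------------------------------------------------
# hypothesis space


def evaluate_all(
    graph: SignedGraph,
    input_genes,
    background,
    depth: int = 1,
    assumed_sign: int = -1,
) -> pd.DataFrame:
    """Evaluate every (node, +/-1) hypothesis with a non-empty reachable set.

    Returns a DataFrame ranked by correctness p then enrichment p, with
    Bonferroni-corrected columns using H = the number of hypotheses
    evaluated.  Only background genes count toward reachable sets and
    overlaps.
    """
    background = list(dict.fromkeys(background))
    bg = set(background)
    input_genes = [g for g in dict.fromkeys(input_genes)]
    if not set(input_genes) <= bg:
        raise ValueError("input genes must be a subset of the background")
    N, K = len(bg), len(input_genes)
    input_set = set(input_genes)

    rows = []
    for node in sorted(graph.nodes):
        if graph.g.out_degree(node) == 0:
            continue
        for direction in (+1, -1):
            hyp = Hypothesis(node, direction)
            preds = predicted_signs(graph, hyp, depth=depth)
            reach = [g for g in preds if g in bg]
            if not reach:
                continue
            n_path = len(reach)
            k = sum(1 for g in reach if g in input_set)
            odds, enr_p = enrichment_test(n_path, k, K, N)
            corr_p = correctness_test(preds, input_genes, background, assumed_sign)
            rows.append(
                {
                    "regulator": node,
                    "direction": direction,
                    "n_path": n_path,
                    "k": k,
                    "odds_ratio": odds,
                    "enrichment_p": enr_p,
                    "correctness_p": corr_p,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    H = len(df)
    df["n_hypotheses"] = H
    df["enrichment_p_corrected"] = np.minimum(1.0, df["enrichment_p"] * H)
    df["correctness_p_corrected"] = np.minimum(1.0, df["correctness_p"] * H)
    df = df.sort_values(
        ["correctness_p", "enrichment_p", "regulator", "direction"]
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# PPI lookup


def direct_interactors(ppi_edges, study_genes, pain_genes) -> list[tuple[str, str]]:
    """(study gene, pain gene) pairs adjacent in an undirected PPI network.

    ``ppi_edges``: iterable of (a, b) pairs or a path to a two-column TSV.
    """
    if isinstance(ppi_edges, (str, bytes)) or hasattr(ppi_edges, "read_text"):
        df = pd.read_csv(ppi_edges, sep="\t", header=None, names=["a", "b"], comment="#")
        ppi_edges = df.itertuples(index=False)
    adj: dict[str, set[str]] = {}
    for a, b in ppi_edges:
        a, b = str(a), str(b)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    pain = set(map(str, pain_genes))
    out = []
    for g in sorted(set(map(str, study_genes))):
        for partner in sorted(adj.get(g, ()) & pain):
            out.append((g, partner))
    return out
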