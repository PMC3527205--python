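"""Gene-centric rare-variant burden battery.

Six association tests per gene, spanning the three families commonly used for
rare-variant analysis of a binary extreme phenotype (y = 1 for heat-pain
insensitive, 0 for sensitive):

* carrier-based: a fixed-threshold carrier test (CAST-style Fisher exact on
  the 2x2 carrier table) and a Pearson chi-square on the same table
  (CCRaVAT-style);
* collapsing: the Madsen-Browning frequency-weighted rank-sum test
  (optionally PolyPhen-weighted) and the Han-Pan data-adaptive sum (aSum)
  test, which re-screens per-site effect directions inside every
  permutation;
* multivariate: the sum-of-squared-score (SSU) test and an allele-matching
  kernel test built on genotypic similarity.

A shared permutation engine supplies Monte-Carlo p-values,
``p = (1 + #{T_b >= T_obs}) / (B + 1)``, switching to exhaustive enumeration
of label assignments when the permutation space is small enough; then the
p-value is exact.  A "rare" site means minor allele frequency below 0.05
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .variant_qc import GeneGenotypeBlock

__all__ = [
    "GeneTestInput",
    "TestResult",
    "BatteryConfig",
    "BatteryResult",
    "TEST_NAMES",
    "carrier_fixed_threshold_test",
    "ccravat_pearson_test",
    "madsen_browning_test",
    "asum_test",
    "ssu_test",
    "allele_matching_test",
    "permutation_pvalue",
    "run_battery",
    "polyphen_weights",
]

RARE_THRESHOLD = 0.05

TEST_NAMES = (
    "carrier_fixed_threshold",
    "ccravat_pearson",
    "madsen_browning",
    "asum",
    "ssu",
    "allele_matching",
)

#: PolyPhen category -> multiplicative score-up {1, 2, 4}, renormalised to (0, 1]
POLYPHEN_SCORE = {"benign": 1.0, "possibly_damaging": 2.0, "probably_damaging": 4.0}


def polyphen_weights(categories) -> np.ndarray:
    """Map PolyPhen categories to functional weights f_j in (0, 1].

    Damaging classes get multiplicatively larger scores {1, 2, 4}, then the
    vector is renormalised by its maximum possible score so f_j in
    {0.25, 0.5, 1}.  Unknown categories count as benign.
    """
    raw = np.array([POLYPHEN_SCORE.get(str(c), 1.0) for c in categories])
    return raw / max(POLYPHEN_SCORE.values())


@dataclass
class GeneTestInput:
    """Dosage matrix and phenotype for one gene.

    ``dosages``: (n_subjects, n_sites) in {0, 1, 2}, NaN missing.
    ``y``: binary phenotype, 1 = insensitive (case), 0 = sensitive (control).
    ``mafs``: per-site minor allele frequency estimates.
    ``func_weights``: optional per-site functional weight f_j in (0, 1].
    """

    dosages: np.ndarray
    y: np.ndarray
    mafs: np.ndarray
    func_weights: np.ndarray | None = None
    rare_threshold: float = RARE_THRESHOLD

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.mafs = np.asarray(self.mafs, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != self.y.shape[0]:
            raise ValueError("dosages must be (n_subjects, n_sites) matching y")
        if self.mafs.shape[0] != self.dosages.shape[1]:
            raise ValueError("one MAF per site required")
        if len(np.unique(self.y)) < 2:
            raise ValueError("phenotype y is constant")
        # drop all-missing sites
        keep = ~np.isnan(self.dosages).all(axis=0)
        if not keep.all():
            self.dosages = self.dosages[:, keep]
            self.mafs = self.mafs[keep]
            if self.func_weights is not None:
                self.func_weights = np.asarray(self.func_weights)[keep]

    @classmethod
    def from_block(
        cls,
        block: GeneGenotypeBlock,
        labels: dict[str, int] | pd.Series,
        use_polyphen: bool = False,
        rare_threshold: float = RARE_THRESHOLD,
    ) -> "GeneTestInput":
        """Build test input from a gene block and subject -> {0,1} labels.

        Subjects without a label are dropped.
        """
        lab = labels if isinstance(labels, pd.Series) else pd.Series(labels)
        rows = [i for i, s in enumerate(block.subjects) if s in lab.index]
        y = lab.loc[[block.subjects[i] for i in rows]].to_numpy(dtype=int)
        fw = None
        if use_polyphen and "polyphen" in block.sites.columns:
            fw = polyphen_weights(block.sites["polyphen"].fillna("benign"))
        return cls(
            dosages=block.dosages[rows],
            y=y,
            mafs=block.sites["maf"].to_numpy(),
            func_weights=fw,
            rare_threshold=rare_threshold,
        )

    def rare_mask(self) -> np.ndarray:
        return self.mafs < self.rare_threshold

    def carriers(self) -> np.ndarray:
        """Subjects carrying >= 1 rare allele (missing treated as non-carrier)."""
        rare = self.dosages[:, self.rare_mask()]
        return (np.nan_to_num(rare, nan=0.0) >= 1).any(axis=1)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries mean-imputed within site."""
        d = self.dosages.copy()
        means = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d[idx] = means[idx[1]]
        return d

    def direction(self) -> int:
        """Sign of the rare-carrier-rate difference, insensitive - sensitive."""
        c = self.carriers()
        diff = c[self.y == 1].mean() - c[self.y == 0].mean()
        return int(np.sign(diff))


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    direction: int
    n_permutations: int | None = None


# ---------------------------------------------------------------------------
# permutation engine


def _perm_labels(y: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """(B, n) matrix of label shuffles preserving class counts."""
    n = y.size
    out = np.empty((B, n), dtype=y.dtype)
    for b in range(B):
        out[b] = rng.permutation(y)
    return out


def _all_labels(y: np.ndarray) -> np.ndarray:
    """All distinct label assignments with the observed class counts."""
    n, n1 = y.size, int(y.sum())
    rows = []
    for cases in combinations(range(n), n1):
        v = np.zeros(n, dtype=y.dtype)
        v[list(cases)] = 1
        rows.append(v)
    return np.vstack(rows)


def permutation_pvalue(
    stat_fn: Callable[[np.ndarray], float],
    y: np.ndarray,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
    batch_stat_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    exhaustive: bool | None = None,
) -> tuple[float, int]:
    """Permutation p-value for an arbitrary statistic of the labels.

    Labels are shuffled preserving class counts.  With sampled permutations
    the p-value is ``(1 + #{T_b >= T_obs}) / (B + 1)`` (never 0, >= 1/(B+1)).
    When the number of distinct assignments C(n, n1) is <= B (or
    ``exhaustive=True``), all assignments are enumerated and the p-value is
    the exact proportion with T >= T_obs (the observed assignment included).

    Returns (p, number of permutations used).
    """
    y = np.asarray(y, dtype=int)
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs = float(stat_fn(y))
    n, n1 = y.size, int(y.sum())
    n_distinct = math.comb(n, n1)
    if exhaustive is None:
        exhaustive = n_distinct <= B
    tol = 1e-12 * max(1.0, abs(t_obs))
    if exhaustive:
        Y = _all_labels(y)
        t = (
            np.asarray(batch_stat_fn(Y), dtype=float)
            if batch_stat_fn is not None
            else np.array([stat_fn(row) for row in Y], dtype=float)
        )
        p = float(np.mean(t >= t_obs - tol))
        return p, Y.shape[0]
    Y = _perm_labels(y, B, rng)
    t = (
        np.asarray(batch_stat_fn(Y), dtype=float)
        if batch_stat_fn is not None
        else np.array([stat_fn(row) for row in Y], dtype=float)
    )
    p = (1.0 + float(np.sum(t >= t_obs - tol))) / (B + 1.0)
    return p, B


# ---------------------------------------------------------------------------
# carrier-based tests


def _carrier_table(inp: GeneTestInput) -> np.ndarray:
    c = inp.carriers()
    y = inp.y
    return np.array(
        [
            [int(c[y == 1].sum()), int((~c[y == 1]).sum())],
            [int(c[y == 0].sum()), int((~c[y == 0]).sum())],
        ]
    )


def carrier_fixed_threshold_test(inp: GeneTestInput) -> TestResult | None:
    """CAST-style fixed-threshold carrier test.

    2x2 table of carrier (>= 1 rare allele, MAF < 0.05) vs non-carrier by
    phenotype, two-sided Fisher exact p (point-probability method: sum over
    tables whose probability does not exceed the observed one).  Returns
    ``None`` (a missing result) when the gene has no rare site.
    """
    if not inp.rare_mask().any():
        return None
    table = _carrier_table(inp)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult("carrier_fixed_threshold", float(odds), float(p), inp.direction())


def ccravat_pearson_test(inp: GeneTestInput) -> TestResult | None:
    """Pearson chi-square (1 df, no continuity correction) on the carrier table.

    Missing result when the gene has no rare site or the table has a zero
    margin (the asymptotic test is undefined there).
    """
    if not inp.rare_mask().any():
        return None
    table = _carrier_table(inp)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return None
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return TestResult("ccravat_pearson", float(chi2), float(p), inp.direction())


# ---------------------------------------------------------------------------
# collapsing tests


def madsen_browning_weights(
    dosages: np.ndarray, y: np.ndarray, n_ctl: int | None = None
) -> np.ndarray:
    """Per-site Madsen-Browning weights estimated in the control group.

    q_hat_j = (m_j + 1) / (2 n_ctl + 2) with m_j the minor allele count among
    controls (sensitive subjects); w_j = sqrt(n_ctl * q_hat_j * (1 - q_hat_j)).
    The +1 pseudo-count keeps sites absent from controls finite.
    """
    ctl = np.asarray(y) == 0
    if n_ctl is None:
        n_ctl = int(ctl.sum())
    if n_ctl == 0:
        raise ValueError("no control (sensitive) subjects: weights undefined")
    m = np.nansum(dosages[ctl], axis=0)
    q = (m + 1.0) / (2.0 * n_ctl + 2.0)
    return np.sqrt(n_ctl * q * (1.0 - q))


def madsen_browning_test(
    inp: GeneTestInput,
    use_functional_weights: bool = False,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> TestResult:
    """Madsen-Browning frequency-weighted rank-sum test.

    Subject burden gamma_i = sum_j dosage_ij * f_j / w_j (f_j = 1 unless the
    functional-weight flag is set and weights are supplied); the statistic is
    the absolute centred Wilcoxon rank sum of gamma in cases, with a
    permutation p-value (two-sided by construction of the statistic).
    """
    d = inp.imputed()
    w = madsen_browning_weights(inp.dosages, inp.y)
    f = (
        inp.func_weights
        if (use_functional_weights and inp.func_weights is not None)
        else np.ones(d.shape[1])
    )
    gamma = d @ (f / w)
    ranks = stats.rankdata(gamma)
    n = inp.y.size
    n1 = int(inp.y.sum())
    expect = n1 * (n + 1) / 2.0

    def stat(yv: np.ndarray) -> float:
        return abs(float(ranks @ yv) - expect)

    def batch(Y: np.ndarray) -> np.ndarray:
        return np.abs(Y @ ranks - expect)

    p, used = permutation_pvalue(stat, inp.y, B=B, seed=seed, batch_stat_fn=batch)
    return TestResult("madsen_browning", stat(inp.y), p, inp.direction(), used)


def _score_components(d_imputed: np.ndarray, y: np.ndarray):
    """Centred design, per-site sums of squares and the logistic score
    variance factor ybar(1-ybar) shared by the score-based tests."""
    xc = d_imputed - d_imputed.mean(axis=0)
    ss = (xc**2).sum(axis=0)
    ybar = y.mean()
    return xc, ss, ybar * (1 - ybar)


def asum_test(
    inp: GeneTestInput,
    alpha0: float = 0.1,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> TestResult:
    """Han-Pan data-adaptive sum test.

    Each site's marginal association with y is screened with the logistic
    score test; sites whose estimated effect is negative at screening level
    ``alpha0`` have their dosage recoded (2 - dosage), then the gene-level
    statistic is the logistic score test of y on the recoded dosage sum.
    The screening is repeated inside every permutation, so the adaptive
    recoding does not inflate type-I error.  The score-test form never fails
    on separation.  ``alpha0 = 0`` disables screening (plain sum test).
    """
    y = inp.y
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need >= 2 subjects per phenotype class")
    d = inp.imputed()
    xc, ss, vfac = _score_components(d, y)
    G = xc.T @ xc
    crit = stats.chi2.isf(alpha0, df=1) if alpha0 > 0 else np.inf

    def _signs(U: np.ndarray) -> np.ndarray:
        # flip sites with negative marginal effect significant at alpha0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(ss > 0, U**2 / (vfac * ss), 0.0)
        return np.where((U < 0) & (t > crit), -1.0, 1.0)

    def stat(yv: np.ndarray) -> float:
        U = xc.T @ yv
        s = _signs(U)
        num = float(s @ U) ** 2
        den = vfac * float(s @ G @ s)
        return num / den if den > 0 else 0.0

    def batch(Y: np.ndarray) -> np.ndarray:
        U = Y @ xc  # (B, J)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(ss > 0, U**2 / (vfac * ss), 0.0)
        S = np.where((U < 0) & (t > crit), -1.0, 1.0)
        num = np.einsum("bj,bj->b", S, U) ** 2
        den = vfac * np.einsum("bj,jk,bk->b", S, G, S)
        return np.where(den > 0, num / den, 0.0)

    p, used = permutation_pvalue(stat, y, B=B, seed=seed, batch_stat_fn=batch)
    return TestResult("asum", stat(y), p, inp.direction(), used)


# ---------------------------------------------------------------------------
# multivariate tests


def ssu_test(
    inp: GeneTestInput,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
    method: str = "permutation",
) -> TestResult | None:
    """Sum-of-squared-score (SSU) test.

    Score vector U = sum_i (y_i - ybar) x_i over sites; statistic U'U.
    ``method="permutation"`` (default) permutes y; ``method="satterthwaite"``
    matches the first two moments of the permutation null with a scaled
    chi-square.  Missing result when every site is monomorphic in the sample.
    """
    d = inp.imputed()
    xc, ss, vfac = _score_components(d, inp.y)
    if not (ss > 0).any():
        return None

    def stat(yv: np.ndarray) -> float:
        u = xc.T @ yv
        return float(u @ u)

    t_obs = stat(inp.y)
    if method == "satterthwaite":
        V = vfac * (xc.T @ xc)
        e = np.trace(V)
        var = 2.0 * np.trace(V @ V)
        a = var / (2.0 * e)
        df = 2.0 * e**2 / var
        p = float(stats.chi2.sf(t_obs / a, df))
        return TestResult("ssu", t_obs, p, inp.direction())

    def batch(Y: np.ndarray) -> np.ndarray:
        U = Y @ xc
        return (U**2).sum(axis=1)

    p, used = permutation_pvalue(stat, inp.y, B=B, seed=seed, batch_stat_fn=batch)
    return TestResult("ssu", t_obs, p, inp.direction(), used)


def allele_matching_kernel(inp: GeneTestInput) -> np.ndarray:
    """Pairwise genotypic-similarity kernel.

    K(i, k) = sum_j w_j * (4 - 2 |d_ij - d_kj|) / 4 over sites where both
    genotypes are observed, weighted by the inverse estimated minor allele
    frequency (pseudo-count as in the Madsen-Browning weights) so matches at
    rare alleles dominate.
    """
    d = inp.dosages
    n, J = d.shape
    m = np.nansum(d, axis=0)
    n_called = (~np.isnan(d)).sum(axis=0)
    q = (m + 1.0) / (2.0 * n_called + 2.0)
    w = 1.0 / q
    K = np.zeros((n, n))
    for j in range(J):
        col = d[:, j]
        obs = ~np.isnan(col)
        diff = np.abs(col[:, None] - col[None, :])
        contrib = w[j] * (4.0 - 2.0 * diff) / 4.0
        mask = obs[:, None] & obs[None, :]
        K += np.where(mask, contrib, 0.0)
    return K


def allele_matching_test(
    inp: GeneTestInput,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> TestResult:
    """Allele-matching kernel test on genotypic similarity.

    Statistic = mean within-phenotype similarity minus mean between-phenotype
    similarity; large values mean subjects are genetically more alike within
    tails than across them.  p by permutation of y.  This is a deliberately
    simplified similarity-based test: it keeps the allele-matching principle
    of locus-wide genotypic comparison without the full locus-specific
    integration machinery of AMELIA.
    """
    n = inp.y.size
    if n < 4:
        raise ValueError("allele-matching test needs n >= 4")
    if inp.dosages.shape[1] < 2:
        raise ValueError("allele-matching test needs >= 2 sites")
    K = allele_matching_kernel(inp)
    diag = np.diag(K)
    r = K.sum(axis=1)
    total = float(K.sum())

    def _stat_from(yv: np.ndarray, quad: float, rowsum: float) -> float:
        n1 = int(yv.sum())
        n0 = n - n1
        d1 = float(diag[yv == 1].sum())
        within_cases = (quad - d1) / 2.0
        comp_quad = total - 2.0 * rowsum + quad
        within_ctl = (comp_quad - (diag.sum() - d1)) / 2.0
        between = rowsum - quad
        n_within = n1 * (n1 - 1) / 2.0 + n0 * (n0 - 1) / 2.0
        return (within_cases + within_ctl) / n_within - between / (n1 * n0)

    def stat(yv: np.ndarray) -> float:
        quad = float(yv @ K @ yv)
        rowsum = float(yv @ r)
        return _stat_from(yv, quad, rowsum)

    def batch(Y: np.ndarray) -> np.ndarray:
        quad = np.einsum("bi,ij,bj->b", Y, K, Y, optimize=True)
        rowsum = Y @ r
        d1 = Y @ diag
        n1 = Y.sum(axis=1)
        n0 = n - n1
        within = (quad - d1) / 2.0 + ((total - 2 * rowsum + quad) - (diag.sum() - d1)) / 2.0
        n_within = n1 * (n1 - 1) / 2.0 + n0 * (n0 - 1) / 2.0
        between = rowsum - quad
        return within / n_within - between / (n1 * n0)

    p, used = permutation_pvalue(stat, inp.y, B=B, seed=seed, batch_stat_fn=batch)
    return TestResult("allele_matching", stat(inp.y), p, inp.direction(), used)


# ---------------------------------------------------------------------------
# battery


@dataclass
class BatteryConfig:
    n_permutations: int = 10_000
    seed: int = 0
    use_functional_weights: bool = True
    rare_threshold: float = RARE_THRESHOLD
    asum_alpha0: float = 0.1


@dataclass
class BatteryResult:
    """Gene x test p-value table (consistent genes only) plus directions.

    ``pvalues``: DataFrame indexed by gene, one column per test, restricted
    to genes where all six tests produced a p-value.  ``directions``: sign of
    the rare-carrier-rate difference (insensitive - sensitive) per gene.
    ``dropped``: gene -> reason for genes excluded from the consistent set.
    """

    pvalues: pd.DataFrame
    statistics: pd.DataFrame
    directions: pd.Series
    dropped: dict[str, str] = field(default_factory=dict)


def run_battery(
    blocks: dict[str, GeneGenotypeBlock],
    labels: dict[str, int] | pd.Series,
    config: BatteryConfig | None = None,
) -> BatteryResult:
    """Run all six tests on every gene block.

    Genes where any test returns a missing result (or fails its
    precondition) are excluded from the consistent p-value table and listed
    in ``dropped`` — mirroring the restriction to genes with consistently
    non-missing p-values across the battery.  Per-gene permutation streams
    are spawned deterministically from ``config.seed``.
    """
    cfg = config or BatteryConfig()
    if not blocks:
        raise ValueError("no gene blocks supplied")
    genes = sorted(blocks)
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(genes))

    pvals, statvals, dirs, dropped = {}, {}, {}, {}
    for gene, child in zip(genes, children):
        rng = np.random.default_rng(child)
        try:
            inp = GeneTestInput.from_block(
                blocks[gene],
                labels,
                use_polyphen=cfg.use_functional_weights,
                rare_threshold=cfg.rare_threshold,
            )
        except ValueError as exc:
            dropped[gene] = str(exc)
            continue
        results: dict[str, TestResult | None] = {}
        try:
            results["carrier_fixed_threshold"] = carrier_fixed_threshold_test(inp)
            results["ccravat_pearson"] = ccravat_pearson_test(inp)
            results["madsen_browning"] = madsen_browning_test(
                inp,
                use_functional_weights=cfg.use_functional_weights,
                B=cfg.n_permutations,
                seed=rng,
            )
            results["asum"] = asum_test(
                inp, alpha0=cfg.asum_alpha0, B=cfg.n_permutations, seed=rng
            )
            results["ssu"] = ssu_test(inp, B=cfg.n_permutations, seed=rng)
            results["allele_matching"] = allele_matching_test(
                inp, B=cfg.n_permutations, seed=rng
            )
        except ValueError as exc:
            dropped[gene] = str(exc)
            continue
        if any(r is None for r in results.values()):
            missing = [k for k, r in results.items() if r is None]
            dropped[gene] = f"missing result from: {missing}"
            continue
        pvals[gene] = {k: r.p for k, r in results.items()}
        statvals[gene] = {k: r.statistic for k, r in results.items()}
        dirs[gene] = inp.direction()

    pdf = pd.DataFrame.from_dict(pvals, orient="index").reindex(columns=list(TEST_NAMES))
    sdf = pd.DataFrame.from_dict(statvals, orient="index").reindex(columns=list(TEST_NAMES))
    return BatteryResult(
        pvalues=pdf.sort_index(),
        statistics=sdf.sort_index(),
        directions=pd.Series(dirs, dtype="int64").sort_index(),
        dropped=dropped,
    )
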