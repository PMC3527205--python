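"""Cross-test and cross-cohort evidence aggregation.

Per gene, the six burden tests are summarised by the *second-lowest* p-value
— a robustness device: a gene must look associated under at least two tests
(hence at least two of the three test families) before it ranks highly, so a
single anomalous test cannot dominate the list.  Cohort halves are combined
with Fisher's method (chi-square with 4 df for two p-values), and genes are
placed into evidence tiers:

* High:      second-lowest p < 0.00044 (the level at which an exact
             replication would push a combined analysis past genome-wide
             significance for the number of gene regions tested);
* Very High: High, and the merged-genotype reanalysis is more significant
             than the combination of the two halves (synergy of direction);
* Medium:    not High, and either summary < 0.001.

The module also builds the direction-concordant input list for the network
stage, the binomial sign-excess test, the battery's test-correlation matrix
and QQ coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "second_lowest",
    "fisher_combine",
    "tier_evidence",
    "bonferroni_threshold",
    "direction_concordant_gene_list",
    "sign_excess_test",
    "test_correlation_matrix",
    "qq_points",
    "TIER_HIGH_P",
    "TIER_MEDIUM_P",
]

TIER_HIGH_P = 0.00044
TIER_MEDIUM_P = 0.001


def second_lowest(p_values) -> float:
    """Second order statistic of the per-test p-values.

    All entries must be non-missing; a gene with any missing test result is
    excluded upstream rather than summarised here.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need a vector of >= 2 p-values")
    if np.isnan(p).any():
        raise ValueError("missing p-value in input")
    return float(np.partition(p, 1)[1])


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher's method for two p-values: X = -2(ln p1 + ln p2) ~ chi2(4)."""
    if not (0 < p1 <= 1 and 0 < p2 <= 1):
        raise ValueError(f"p-values must lie in (0, 1]: got ({p1}, {p2})")
    x = -2.0 * (np.log(p1) + np.log(p2))
    return float(stats.chi2.sf(x, df=4))


def tier_evidence(
    primary_2nd: float | None,
    merged_2nd: float,
    combined_of_halves: float | None = None,
    high_p: float = TIER_HIGH_P,
    medium_p: float = TIER_MEDIUM_P,
) -> str:
    """Evidence tier in {Very High, High, Medium, none}.

    ``primary_2nd`` is the Fisher combination of the two cohorts'
    second-lowest p-values (None for genes only analysable in the merged
    data); ``merged_2nd`` the merged-genotype reanalysis.  The synergy
    comparison uses ``combined_of_halves`` (defaults to ``primary_2nd``,
    which *is* the combination of the halves).
    """
    for name, v in (("primary_2nd", primary_2nd), ("merged_2nd", merged_2nd)):
        if v is not None and not (0 < v <= 1):
            raise ValueError(f"{name} outside (0, 1]: {v}")
    if combined_of_halves is None:
        combined_of_halves = primary_2nd
    candidates = [v for v in (primary_2nd, merged_2nd) if v is not None]
    if min(candidates) < high_p:
        # Very High requires the cross-cohort combination itself to clear the
        # High cut-off *and* the merged reanalysis to beat it (synergy); a
        # gene that is High only through its merged summary stays High.
        if (
            primary_2nd is not None
            and primary_2nd < high_p
            and combined_of_halves is not None
            and merged_2nd < combined_of_halves
        ):
            return "Very High"
        return "High"
    if min(candidates) < medium_p:
        return "Medium"
    return "none"


def bonferroni_threshold(n_tests: int, fwer: float = 0.05) -> float:
    """Family-wise significance threshold fwer / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return fwer / n_tests


def direction_concordant_gene_list(
    evidence: pd.DataFrame,
    cutoff: float = 0.01,
    p_column: str = "merged_2nd",
    direction_columns: tuple[str, str] = ("direction_cohort1", "direction_cohort2"),
) -> list[str]:
    """Input gene list for the network stage.

    Genes with merged second-lowest p below ``cutoff`` whose carrier-excess
    direction agrees (same non-zero sign) in both cohorts; genes with an
    opposite direction of effect are removed regardless of p.  Unique by
    gene symbol, sorted.
    """
    d1, d2 = direction_columns
    if evidence.empty:
        return []
    ok = (
        (evidence[p_column] < cutoff)
        & (evidence[d1] == evidence[d2])
        & (evidence[d1] != 0)
    )
    genes = evidence.loc[ok, "gene"] if "gene" in evidence.columns else evidence.index[ok]
    return sorted(set(map(str, genes)))


def sign_excess_test(n_excess: int, n_total: int) -> float:
    """Exact two-sided binomial sign test at success probability 1/2.

    Used for the tail-excess question: of the genes showing a >= 10%
    difference in rare-variant counts between tails, is the split between
    insensitive-excess and sensitive-excess genes compatible with chance?
    Two-sided by summing outcomes whose point probability does not exceed
    that of the observed count.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_excess <= n_total:
        raise ValueError("n_excess must lie in [0, n_total]")
    return float(stats.binomtest(n_excess, n_total, 0.5).pvalue)


def test_correlation_matrix(p_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of -log10 p across genes, per test pair.

    Pairwise-complete over genes; a constant column yields NaN entries
    (flagged as undefined rather than silently zeroed).
    """
    if len(p_table) < 3:
        raise ValueError("need >= 3 genes to correlate tests")
    neglog = -np.log10(p_table.astype(float))
    return neglog.corr(method="pearson", min_periods=2)


def qq_points(p_values) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) -log10 p pairs for a QQ plot.

    Observed p-values sorted ascending against uniform order-statistic
    expectations i/(n+1).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    obs = np.sort(p)
    exp = np.arange(1, p.size + 1) / (p.size + 1.0)
    return -np.log10(exp), -np.log10(obs)
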