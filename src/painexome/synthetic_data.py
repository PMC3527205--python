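"""Synthetic two-cohort extreme-phenotype studies and signed regulatory
networks with known ground truth.

The generator emulates the design of a twin-register heat-pain study: two
cohorts of roughly a hundred pain-sensitive and a hundred pain-insensitive
singletons each, exome-like gene regions carrying mostly rare (MAF < 5%)
sites drawn from a rare-dominated frequency spectrum, and a subset of
*planted* genes in which the probability of carrying a rare allele is
multiplied by a configurable relative risk in one phenotype tail.  Genotypes
are Hardy-Weinberg draws with no linkage disequilibrium; the two cohorts use
overlapping but non-identical capture designs.  A companion generator builds
random signed regulatory networks with one planted upstream regulator whose
sign-consistent targets are over-sampled into the downstream input gene
list.

Everything is deterministic given the config seed, so every downstream stage
(selection, QC, burden battery, aggregation, causal reasoning) is testable
end-to-end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .causal_network import Hypothesis, SignedGraph
from .phenotype_selection import (
    TUK1_THRESHOLDS,
    TUK2_THRESHOLDS,
    SelectionThresholds,
)
from .variant_qc import CallSet

__all__ = [
    "ConfigError",
    "MafSpectrum",
    "TailPhenotype",
    "CohortPhenotypeModel",
    "NetworkConfig",
    "SimConfig",
    "SimulatedStudy",
    "PlantedNetwork",
    "simulate_study",
    "simulate_regulatory_network",
    "write_fixture_bundle",
    "make_reference_geometry",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class MafSpectrum:
    """Site frequency spectrum: rare sites from a truncated Beta, plus a
    common-site fraction uniform on (rare_max, common_max]."""

    beta_a: float = 0.5
    beta_b: float = 8.0
    rare_max: float = 0.05
    common_fraction: float = 0.2
    common_max: float = 0.5

    def validate(self) -> None:
        _check(0 < self.rare_max <= 0.5, "maf_spectrum.rare_max", "must be in (0, 0.5]")
        _check(
            self.rare_max <= self.common_max <= 0.5,
            "maf_spectrum.common_max",
            "must be in [rare_max, 0.5]",
        )
        _check(
            0 <= self.common_fraction <= 1,
            "maf_spectrum.common_fraction",
            "must be in [0, 1]",
        )

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        common = rng.random(n) < self.common_fraction
        maf = np.empty(n)
        n_rare = int((~common).sum())
        rare = rng.beta(self.beta_a, self.beta_b, size=3 * n_rare + 16)
        rare = rare[(rare > 0) & (rare <= self.rare_max)]
        while rare.size < n_rare:  # rejection top-up; truncation keeps most draws
            extra = rng.beta(self.beta_a, self.beta_b, size=2 * n_rare + 16)
            rare = np.concatenate([rare, extra[(extra > 0) & (extra <= self.rare_max)]])
        maf[~common] = rare[:n_rare]
        maf[common] = rng.uniform(self.rare_max, self.common_max, size=int(common.sum()))
        return maf


@dataclass(frozen=True)
class TailPhenotype:
    hpt_mean: float
    hpt_sd: float
    hpst_mean: float
    hpst_sd: float


@dataclass(frozen=True)
class CohortPhenotypeModel:
    """Per-tail HPT/HPST distributions plus the selection thresholds that
    define the tails for this cohort."""

    sensitive: TailPhenotype
    insensitive: TailPhenotype
    thresholds: SelectionThresholds


# Defaults reproduce the two discovery cohorts' tail means/SDs and thresholds.
_TUK1_MODEL = CohortPhenotypeModel(
    sensitive=TailPhenotype(43.09, 2.47, 44.27, 1.10),
    insensitive=TailPhenotype(48.17, 0.72, 49.78, 0.28),
    thresholds=TUK1_THRESHOLDS,
)
_TUK2_MODEL = CohortPhenotypeModel(
    sensitive=TailPhenotype(42.44, 2.32, 43.95, 1.54),
    insensitive=TailPhenotype(47.43, 0.98, 49.37, 0.41),
    thresholds=TUK2_THRESHOLDS,
)

#: functional-class mix of exome SNVs (protein-coding focus)
DEFAULT_CLASS_MIX = {
    "nonsynonymous": 0.527,
    "synonymous": 0.392,
    "splice_site": 0.071,
    "stop_gained": 0.0095,
    "stop_lost": 0.0005,
}


@dataclass(frozen=True)
class NetworkConfig:
    """Signed regulatory network generator parameters."""

    n_background: int = 500
    n_regulators: int = 30
    out_degree_range: tuple[int, int] = (8, 40)
    planted_out_degree: int = 60
    n_input_genes: int = 50
    planted_oversample_rate: float = 0.5
    activating_fraction: float = 0.6
    n_gene_edges: int = 100

    def validate(self) -> None:
        _check(self.n_background >= 1, "network.n_background", "must be >= 1")
        _check(
            self.planted_out_degree <= self.n_background,
            "network.planted_out_degree",
            "out-degree request exceeds background node count",
        )
        _check(
            self.out_degree_range[0] <= self.out_degree_range[1] <= self.n_background,
            "network.out_degree_range",
            "range out of order or exceeding node count",
        )
        _check(
            0 <= self.planted_oversample_rate <= 1,
            "network.planted_oversample_rate",
            "must be in [0, 1]",
        )
        _check(
            0 <= self.activating_fraction <= 1,
            "network.activating_fraction",
            "must be in [0, 1]",
        )
        _check(
            self.n_input_genes <= self.n_background,
            "network.n_input_genes",
            "cannot exceed background size",
        )


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the synthetic study.

    ``n_subjects_per_cohort`` gives (n_sensitive, n_insensitive) per cohort;
    a single pair is applied to both cohorts.  ``planted_carrier_excess`` is
    the relative risk of rare-carrier status in the designated tail for
    planted genes (1.0 = null).  ``capture_overlap`` is the fraction of gene
    regions shared between the two cohorts' capture designs.
    """

    n_subjects_per_cohort: tuple = ((101, 102), (114, 96))
    n_genes: int = 200
    sites_per_gene: tuple[int, int] = (20, 30)
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    n_planted_genes: int = 10
    planted_carrier_excess: float = 4.0
    planted_tail: str = "insensitive"
    phenotype_model: tuple[CohortPhenotypeModel, ...] = (_TUK1_MODEL, _TUK2_MODEL)
    twin_fraction: float = 0.2
    mz_fraction: float = 0.5
    missingness_rate: float = 0.01
    capture_overlap: float = 0.9
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    network: NetworkConfig = field(default_factory=NetworkConfig)
    seed: int = 0

    def cohort_sizes(self) -> list[tuple[int, int]]:
        s = self.n_subjects_per_cohort
        if isinstance(s[0], (int, np.integer)):
            s = (tuple(s), tuple(s))
        return [tuple(map(int, pair)) for pair in s]

    def validate(self) -> None:
        for i, (ns, ni) in enumerate(self.cohort_sizes()):
            _check(ns >= 1 and ni >= 1, "n_subjects_per_cohort", f"cohort {i} sizes must be >= 1")
        _check(self.n_genes >= 1, "n_genes", "must be >= 1")
        _check(
            1 <= self.sites_per_gene[0] <= self.sites_per_gene[1],
            "sites_per_gene",
            "range must be ordered and >= 1",
        )
        self.maf_spectrum.validate()
        _check(
            0 <= self.n_planted_genes <= self.n_genes,
            "n_planted_genes",
            "must be in [0, n_genes]",
        )
        _check(self.planted_carrier_excess > 0, "planted_carrier_excess", "must be positive")
        _check(
            self.planted_tail in ("sensitive", "insensitive"),
            "planted_tail",
            "must be 'sensitive' or 'insensitive'",
        )
        for name, frac in (
            ("twin_fraction", self.twin_fraction),
            ("mz_fraction", self.mz_fraction),
            ("missingness_rate", self.missingness_rate),
            ("capture_overlap", self.capture_overlap),
        ):
            _check(0 <= frac <= 1, name, "must be in [0, 1]")
        _check(
            len(self.phenotype_model) >= len(self.cohort_sizes()),
            "phenotype_model",
            "one model per cohort required",
        )
        self.network.validate()


@dataclass
class CohortData:
    """Sequenced calls for one cohort: subjects x sites dosage matrix with
    simulated QUAL and per-genotype depth."""

    name: str
    subjects: list[str]
    sites: pd.DataFrame  # gene, chrom, pos, ref, alt, maf_true, func_class, polyphen, known, qual
    dosages: np.ndarray  # (n_subjects, n_sites), NaN missing
    depths: np.ndarray  # (n_subjects, n_sites)

    def to_call_set(self) -> CallSet:
        sites = self.sites[["chrom", "pos", "ref", "alt", "qual", "known", "func_class", "polyphen"]].copy()
        return CallSet(
            sites=sites.reset_index(drop=True),
            dosages=self.dosages.T.copy(),
            subjects=list(self.subjects),
            depths=self.depths.T.copy(),
        )


@dataclass
class SimulatedStudy:
    """Generated study: phenotype roster (sequenced extremes plus their
    unsequenced co-twins), per-cohort genotype data, gene regions and the
    planted-gene truth table."""

    config: SimConfig
    subjects: pd.DataFrame  # id, cohort, hpt, hpst, twin_pair_id, zygosity, label, sequenced
    cohorts: list[CohortData]
    gene_regions: pd.DataFrame  # chrom, start, end, gene
    truth: pd.DataFrame  # gene, planted, tail
    network: "PlantedNetwork | None" = None


@dataclass
class PlantedNetwork:
    """Signed network plus the planted regulator hypothesis and the study
    geometry needed by the causal stage."""

    graph: SignedGraph
    hypothesis: Hypothesis
    input_genes: list[str]
    background: list[str]
    sign_consistent_targets: list[str]


# ---------------------------------------------------------------------------
# study generation


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sampled normal truncated to (lo, hi); the tail models sit
    well inside their bounds so acceptance is high."""
    out = np.empty(size)
    have = 0
    while have < size:
        draw = rng.normal(mean, sd, size=2 * (size - have) + 8)
        ok = draw[(draw > lo) & (draw < hi)]
        take = min(ok.size, size - have)
        out[have : have + take] = ok[:take]
        have += take
    return out


def _gene_table(config: SimConfig, rng: np.random.Generator):
    """Gene roster, regions (0-based half-open BED) and per-site table."""
    n = config.n_genes
    genes = [f"GENE{i + 1:04d}" for i in range(n)]
    chroms = [str((i % 22) + 1) for i in range(n)]
    span = 10_000
    starts = [(i // 22) * (span + 1000) for i in range(n)]
    regions = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": [s + span for s in starts],
            "gene": genes,
        }
    )

    planted_idx = rng.choice(n, size=config.n_planted_genes, replace=False)
    planted = np.zeros(n, dtype=bool)
    planted[planted_idx] = True

    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    pphen_cats = ["benign", "possibly_damaging", "probably_damaging"]

    site_rows = []
    lo, hi = config.sites_per_gene
    for gi, gene in enumerate(genes):
        n_sites = int(rng.integers(lo, hi + 1))
        pos0 = np.sort(rng.choice(span - 2, size=n_sites, replace=False)) + 1
        maf = config.maf_spectrum.draw(n_sites, rng)
        fclass = rng.choice(classes, size=n_sites, p=probs)
        if planted[gi]:
            # planted signal lives in rare protein-altering sites
            fclass = np.where(maf < config.maf_spectrum.rare_max, "nonsynonymous", fclass)
        pphen = np.where(
            np.isin(fclass, ["nonsynonymous"]),
            rng.choice(pphen_cats, size=n_sites, p=[0.5, 0.3, 0.2]),
            "benign",
        )
        known = rng.random(n_sites) < np.clip(maf * 12 + 0.15, 0, 0.95)
        ref = rng.choice(list("ACGT"), size=n_sites)
        alt = np.array(
            [rng.choice([b for b in "ACGT" if b != r]) for r in ref]
        )
        for j in range(n_sites):
            site_rows.append(
                {
                    "gene": gene,
                    "chrom": chroms[gi],
                    "pos": int(starts[gi] + pos0[j] + 1),  # 1-based VCF pos
                    "ref": ref[j],
                    "alt": alt[j],
                    "maf_true": float(maf[j]),
                    "func_class": str(fclass[j]),
                    "polyphen": str(pphen[j]),
                    "known": bool(known[j]),
                }
            )
    sites = pd.DataFrame(site_rows)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "planted": planted,
            "tail": np.where(planted, config.planted_tail, ""),
        }
    )
    return regions, sites, truth


def _subject_roster(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sequenced extremes plus unsequenced co-twins.

    Each sequenced subject is, with probability ``twin_fraction``, one member
    of a twin pair whose co-twin sits in the same tail but is strictly less
    extreme (so twin resolution deterministically retains the sequenced
    member); the co-twin appears in the phenotype roster with
    ``sequenced=False``.
    """
    rows = []
    for ci, (n_sens, n_ins) in enumerate(config.cohort_sizes()):
        model = config.phenotype_model[ci]
        thr = model.thresholds
        cohort = f"cohort{ci + 1}"
        for tail, n_tail in (("sensitive", n_sens), ("insensitive", n_ins)):
            tp = model.sensitive if tail == "sensitive" else model.insensitive
            if tail == "sensitive":
                hpst = _truncnorm(rng, tp.hpst_mean, tp.hpst_sd, -np.inf, thr.hpst_sensitive_max, n_tail)
                hpt = _truncnorm(rng, tp.hpt_mean, tp.hpt_sd, -np.inf, thr.hpt_median, n_tail)
            else:
                hpst = _truncnorm(rng, tp.hpst_mean, tp.hpst_sd, thr.hpst_insensitive_min, np.inf, n_tail)
                hpt = _truncnorm(rng, tp.hpt_mean, tp.hpt_sd, thr.hpt_median, np.inf, n_tail)
            is_twin = rng.random(n_tail) < config.twin_fraction
            is_mz = rng.random(n_tail) < config.mz_fraction
            for i in range(n_tail):
                sid = f"{cohort}_{tail[:3].upper()}{i + 1:04d}"
                pair = f"{sid}_pair" if is_twin[i] else None
                zyg = ("MZ" if is_mz[i] else "DZ") if is_twin[i] else "singleton"
                rows.append(
                    {
                        "id": sid,
                        "cohort": cohort,
                        "hpt": float(hpt[i]),
                        "hpst": float(hpst[i]),
                        "twin_pair_id": pair,
                        "zygosity": zyg,
                        "label": tail,
                        "sequenced": True,
                    }
                )
                if is_twin[i]:
                    # co-twin: same tail, strictly less extreme on both axes
                    if tail == "sensitive":
                        co_hpst = float(rng.uniform(hpst[i], thr.hpst_sensitive_max))
                        co_hpt = float(rng.uniform(hpt[i], thr.hpt_median))
                    else:
                        co_hpst = float(rng.uniform(thr.hpst_insensitive_min, hpst[i]))
                        co_hpt = float(rng.uniform(thr.hpt_median, hpt[i]))
                    rows.append(
                        {
                            "id": f"{sid}_cotwin",
                            "cohort": cohort,
                            "hpt": co_hpt,
                            "hpst": co_hpst,
                            "twin_pair_id": pair,
                            "zygosity": zyg,
                            "label": tail,
                            "sequenced": False,
                        }
                    )
    return pd.DataFrame(rows)


def _simulate_dosages(
    config: SimConfig,
    sites: pd.DataFrame,
    labels: np.ndarray,
    planted_genes: set,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hardy-Weinberg binomial dosages with planted carrier excess.

    Baseline dosage ~ Binomial(2, q) per subject/site.  For rare sites of
    planted genes, non-carriers in the designated tail are promoted to
    heterozygotes with probability (p' - p) / (1 - p) where p = 1 - (1-q)^2
    and p' = min(1, excess * p), multiplying the per-site carrier
    probability by the configured relative risk.
    """
    n = labels.size
    J = len(sites)
    q = sites["maf_true"].to_numpy()
    dos = rng.binomial(2, np.broadcast_to(q, (n, J))).astype(float)

    rr = config.planted_carrier_excess
    if rr != 1.0 and planted_genes:
        in_tail = labels == config.planted_tail
        rare = sites["maf_true"].to_numpy() < config.maf_spectrum.rare_max
        planted_site = sites["gene"].isin(planted_genes).to_numpy() & rare
        for j in np.flatnonzero(planted_site):
            p = 1.0 - (1.0 - q[j]) ** 2
            p_target = min(1.0, rr * p)
            promote = (p_target - p) / (1.0 - p) if p < 1 else 0.0
            if promote <= 0:
                # excess < 1: demote carriers to non-carriers instead
                demote = (p - p_target) / p if p > 0 else 0.0
                mask = in_tail & (dos[:, j] > 0) & (rng.random(n) < demote)
                dos[mask, j] = 0.0
                continue
            mask = in_tail & (dos[:, j] == 0) & (rng.random(n) < promote)
            dos[mask, j] = 1.0
    return dos


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a complete two-cohort extreme-phenotype study.

    Deterministic for a fixed config (one seeded generator, fixed draw
    order).  Non-planted genes have genotypes independent of the phenotype
    label; planted genes carry the configured carrier excess in the
    designated tail in both cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    regions, sites, truth = _gene_table(config, rng)
    roster = _subject_roster(config, rng)
    planted_genes = set(truth.loc[truth["planted"], "gene"])

    # capture designs: cohort 1 sees all regions; later cohorts drop a
    # fraction (1 - capture_overlap) of gene regions
    gene_list = regions["gene"].tolist()
    cohorts: list[CohortData] = []
    for ci, _sizes in enumerate(config.cohort_sizes()):
        cohort = f"cohort{ci + 1}"
        if ci == 0 or config.capture_overlap >= 1.0:
            captured = set(gene_list)
        else:
            n_drop = int(round((1.0 - config.capture_overlap) * len(gene_list)))
            dropped = rng.choice(gene_list, size=n_drop, replace=False)
            captured = set(gene_list) - set(dropped)
        csites = sites[sites["gene"].isin(captured)].reset_index(drop=True)

        sub = roster[(roster["cohort"] == cohort) & roster["sequenced"]]
        subjects = sub["id"].tolist()
        labels = sub["label"].to_numpy()

        dos = _simulate_dosages(config, csites, labels, planted_genes, rng)
        if config.missingness_rate > 0:
            miss = rng.random(dos.shape) < config.missingness_rate
            dos[miss] = np.nan

        qual = np.where(
            rng.random(len(csites)) < 0.02,
            rng.uniform(2.0, 19.9, len(csites)),
            rng.uniform(30.0, 900.0, len(csites)),
        )
        depths = np.where(
            rng.random(dos.shape) < 0.01,
            rng.poisson(4.0, dos.shape),
            rng.poisson(70.0, dos.shape),
        ).astype(float)

        csites = csites.copy()
        csites["qual"] = np.round(qual, 2)
        cohorts.append(
            CohortData(
                name=cohort,
                subjects=subjects,
                sites=csites,
                dosages=dos,
                depths=depths,
            )
        )

    return SimulatedStudy(
        config=config,
        subjects=roster,
        cohorts=cohorts,
        gene_regions=regions,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# network generation


def simulate_regulatory_network(config: SimConfig) -> PlantedNetwork:
    """Random signed regulatory network with one planted upstream regulator.

    Regulator nodes point at background genes with random signs; a designated
    regulator's *sign-consistent* targets (those predicted down-regulated
    under the planted loss-of-activity hypothesis, i.e. activating edges) are
    over-sampled into the input gene list at ``planted_oversample_rate``.
    A rate of 0 makes the input list independent of the network (null).
    """
    config.validate()
    net = config.network
    rng = np.random.default_rng([config.seed, 777])  # independent stream from the study's

    background = [f"BG{i + 1:05d}" for i in range(net.n_background)]
    regulators = [f"REG{i + 1:03d}" for i in range(net.n_regulators)]
    graph = SignedGraph()
    for g in background:
        graph.add_node(g)

    planted = regulators[0]
    sign_consistent: list[str] = []
    for r in regulators:
        if r == planted:
            d = net.planted_out_degree
        else:
            d = int(rng.integers(net.out_degree_range[0], net.out_degree_range[1] + 1))
        targets = rng.choice(background, size=d, replace=False)
        signs = np.where(rng.random(d) < net.activating_fraction, 1, -1)
        for t, s in zip(targets, signs):
            graph.add_edge(r, str(t), int(s))
            if r == planted and s == 1:
                sign_consistent.append(str(t))

    # sparse gene->gene edges give depth-2 structure
    for _ in range(net.n_gene_edges):
        a, b = rng.choice(net.n_background, size=2, replace=False)
        graph.add_edge(background[a], background[b], int(rng.choice([1, -1])))

    hypothesis = Hypothesis(planted, -1)

    chosen: list[str] = []
    pool = sorted(set(sign_consistent))
    while len(chosen) < net.n_input_genes:
        if pool and rng.random() < net.planted_oversample_rate:
            g = pool[int(rng.integers(len(pool)))]
        else:
            g = background[int(rng.integers(net.n_background))]
        if g not in chosen:
            chosen.append(g)

    return PlantedNetwork(
        graph=graph,
        hypothesis=hypothesis,
        input_genes=chosen,
        background=background,
        sign_consistent_targets=sorted(set(sign_consistent)),
    )


def make_reference_geometry(
    n_background: int = 9275,
    n_targets: int = 204,
    n_input: int = 86,
    n_overlap: int = 12,
    regulator: str = "ANGIOTENSIN_II",
) -> PlantedNetwork:
    """Deterministic network reproducing the published overlap geometry.

    One regulator with ``n_targets`` activating edges into a background of
    ``n_background`` genes, and an input list of ``n_input`` genes exactly
    ``n_overlap`` of which are (sign-consistent) targets — the 12-of-204 in
    86-of-9275 configuration used for end-to-end checks of the enrichment
    and correctness machinery.
    """
    background = [f"BG{i + 1:05d}" for i in range(n_background)]
    graph = SignedGraph()
    for g in background:
        graph.add_node(g)
    targets = background[:n_targets]
    for t in targets:
        graph.add_edge(regulator, t, +1)
    input_genes = targets[:n_overlap] + background[n_targets : n_targets + (n_input - n_overlap)]
    return PlantedNetwork(
        graph=graph,
        hypothesis=Hypothesis(regulator, -1),
        input_genes=input_genes,
        background=background,
        sign_consistent_targets=list(targets),
    )


# ---------------------------------------------------------------------------
# fixture bundle


def _write_vcf(cohort: CohortData, path: Path) -> None:
    """Plain-text VCFv4.2 with GT:DP genotypes, one record per site."""
    sites = cohort.sites
    chrom_key = sites["chrom"].astype(str).str.zfill(2).to_numpy()
    order = np.lexsort((sites["pos"].to_numpy(), chrom_key))
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(sites["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.subjects)
            + "\n"
        )
        for j in order:
            row = sites.iloc[j]
            vid = f"rs{1_000_000 + j}" if row["known"] else "."
            cells = []
            for i in range(len(cohort.subjects)):
                d = cohort.dosages[i, j]
                dp = int(cohort.depths[i, j])
                gt = "./." if np.isnan(d) else gt_of[int(d)]
                cells.append(f"{gt}:{dp}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}\t"
                f"{row['qual']}\tPASS\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )


def write_fixture_bundle(study: SimulatedStudy, destination) -> dict[str, Path]:
    """Write the study as a file bundle the pipeline readers consume.

    Emits per-cohort multi-sample VCFs, a phenotype TSV, a site-annotation
    TSV, a BED of gene regions (0-based half-open) and, if the study carries
    a network, a signed edge list plus input/background gene lists.  Files
    round-trip through the readers with value equality.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for cohort in study.cohorts:
        p = dest / f"{cohort.name}.vcf"
        _write_vcf(cohort, p)
        paths[f"vcf_{cohort.name}"] = p

    pheno = dest / "phenotypes.tsv"
    cols = ["id", "cohort", "hpt", "hpst", "twin_pair_id", "zygosity", "sequenced"]
    study.subjects[cols].to_csv(pheno, sep="\t", index=False)
    paths["phenotypes"] = pheno

    ann = dest / "annotations.tsv"
    ann_df = pd.concat(
        [c.sites[["chrom", "pos", "ref", "alt", "func_class", "polyphen", "known"]] for c in study.cohorts]
    ).drop_duplicates(["chrom", "pos", "alt"])
    ann_df.to_csv(ann, sep="\t", index=False)
    paths["annotations"] = ann

    bed = dest / "gene_regions.bed"
    study.gene_regions[["chrom", "start", "end", "gene"]].to_csv(
        bed, sep="\t", index=False, header=False
    )
    paths["gene_regions"] = bed

    truth = dest / "truth.tsv"
    study.truth.to_csv(truth, sep="\t", index=False)
    paths["truth"] = truth

    if study.network is not None:
        edges = dest / "network_edges.tsv"
        study.network.graph.to_edge_list(edges)
        paths["network_edges"] = edges
        (dest / "network_input_genes.txt").write_text(
            "\n".join(study.network.input_genes) + "\n"
        )
        (dest / "network_background.txt").write_text(
            "\n".join(study.network.background) + "\n"
        )
        paths["network_input_genes"] = dest / "network_input_genes.txt"
        paths["network_background"] = dest / "network_background.txt"
    return paths
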