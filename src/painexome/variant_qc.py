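"""Variant-call ingestion, site filtering, dual-caller consensus and per-gene
dosage blocks.

The pipeline starts from called variants (multi-sample VCF).  Sites are
filtered on call quality (QUAL >= 20) and per-genotype depth (8 <= DP <= 300,
out-of-bounds genotypes set missing), restricted to the capture target region,
and optionally intersected between two callers; genotypes the callers disagree
on are conservatively set missing.  Qualifying functional classes
(nonsynonymous, stop gained/lost, splice site) are collapsed into per-gene
dosage matrices with minor-allele-oriented frequencies — the substrate for the
burden-test battery.

Internal coordinates are 0-based half-open; conversion happens at the VCF
(1-based ``pos``) and BED boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CallSet",
    "GeneGenotypeBlock",
    "ConsensusReport",
    "read_calls",
    "annotate_calls",
    "filter_calls",
    "consensus",
    "build_gene_blocks",
    "concordance_check",
    "duplicate_discordance",
    "read_gene_regions",
    "QUALIFYING_CLASSES",
    "FUNCTIONAL_CLASSES",
]

FUNCTIONAL_CLASSES = (
    "nonsynonymous",
    "stop_gained",
    "stop_lost",
    "splice_site",
    "synonymous",
    "partial_codon",
    "other",
)
#: classes that enter gene blocks (protein-altering focus)
QUALIFYING_CLASSES = frozenset({"nonsynonymous", "stop_gained", "stop_lost", "splice_site"})

SITE_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass
class CallSet:
    """A set of bi-allelic variant calls over a fixed subject roster.

    ``sites`` has one row per (chrom, pos, ref, alt) with columns ``qual``
    and ``known`` (plus ``func_class``/``polyphen`` after annotation);
    multi-allelic records are split upstream so every row is a single ALT.
    ``dosages`` is (n_sites, n_subjects) with values {0, 1, 2} and NaN for
    missing; ``depths`` mirrors it with per-genotype read depth (NaN where
    the caller reported none).
    """

    sites: pd.DataFrame
    dosages: np.ndarray
    subjects: list[str]
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_sites = len(self.sites)
        if self.dosages.shape != (n_sites, len(self.subjects)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} inconsistent with "
                f"{n_sites} sites x {len(self.subjects)} subjects"
            )
        if self.depths is not None and self.depths.shape != self.dosages.shape:
            raise ValueError("depths shape differs from dosages")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self) -> pd.Index:
        return pd.Index(
            [f"{c}:{p}:{r}:{a}" for c, p, r, a in self.sites[SITE_KEY].itertuples(index=False)]
        )

    def take(self, site_rows: np.ndarray) -> "CallSet":
        return CallSet(
            sites=self.sites.iloc[site_rows].reset_index(drop=True),
            dosages=self.dosages[site_rows],
            subjects=list(self.subjects),
            depths=None if self.depths is None else self.depths[site_rows],
        )


@dataclass
class GeneGenotypeBlock:
    """Per-gene dosage matrix (subjects x qualifying sites).

    ``sites`` carries the estimated minor allele frequency ``maf`` (minor
    allele count over twice the non-missing genotype count, alleles oriented
    so maf <= 0.5) used by every burden test.
    """

    gene: str
    subjects: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray  # (n_subjects, n_sites), NaN missing

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]


@dataclass
class ConsensusReport:
    n_sites_a: int
    n_sites_b: int
    n_shared: int
    n_genotypes_compared: int
    n_genotype_mismatches: int

    @property
    def site_concordance(self) -> float:
        union = self.n_sites_a + self.n_sites_b - self.n_shared
        return self.n_shared / union if union else 1.0

    @property
    def genotype_mismatch_fraction(self) -> float:
        return (
            self.n_genotype_mismatches / self.n_genotypes_compared
            if self.n_genotypes_compared
            else 0.0
        )


# ---------------------------------------------------------------------------
# reading


def read_calls(vcf_path, roster: list[str] | None = None) -> CallSet:
    """Read a VCF into a :class:`CallSet`, splitting multi-allelic records.

    One call per ALT allele per record; dosages come from GT (count of the
    ALT allele; any no-call allele makes the genotype missing).  ``roster``
    restricts and orders the subject columns; subjects absent from the VCF
    header raise an error listing them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    if roster is None:
        roster = samples
    else:
        absent = [s for s in roster if s not in samples]
        if absent:
            raise ValueError(f"subjects absent from VCF header: {absent}")
    cols = np.array([samples.index(s) for s in roster])

    rows, dosage_rows, depth_rows = [], [], []
    for v in vcf:
        gts = np.array([g[:2] for g in v.genotypes], dtype=int)  # (n_samples, 2) allele codes
        try:
            dp = v.format("DP")
            dp = None if dp is None else np.asarray(dp, dtype=float)[:, 0]
        except KeyError:
            dp = None
        if dp is not None:
            dp = np.where(dp < 0, np.nan, dp)
        nocall = (gts < 0).any(axis=1)
        for ai, alt in enumerate(v.ALT, start=1):
            dose = (gts == ai).sum(axis=1).astype(float)
            dose[nocall] = np.nan
            rows.append(
                {
                    "chrom": v.CHROM,
                    "pos": v.POS,
                    "ref": v.REF,
                    "alt": alt,
                    "qual": np.nan if v.QUAL is None else float(v.QUAL),
                    "known": v.ID not in (None, "", "."),
                }
            )
            dosage_rows.append(dose[cols])
            depth_rows.append(
                np.full(len(cols), np.nan) if dp is None else dp[cols]
            )
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual", "known"])
    dosages = (
        np.vstack(dosage_rows) if dosage_rows else np.empty((0, len(roster)))
    )
    depths = np.vstack(depth_rows) if depth_rows else np.empty((0, len(roster)))
    return CallSet(sites=sites, dosages=dosages, subjects=list(roster), depths=depths)


def annotate_calls(calls: CallSet, annotations: pd.DataFrame) -> CallSet:
    """Attach functional classes (and optional PolyPhen categories) to sites.

    ``annotations`` needs columns chrom, pos, alt, func_class (optionally
    polyphen).  Unannotated sites get class ``other``.
    """
    ann_cols = ["chrom", "pos", "alt", "func_class"]
    extra = [c for c in ("polyphen",) if c in annotations.columns]
    ann = annotations[ann_cols + extra].drop_duplicates(["chrom", "pos", "alt"]).copy()
    ann["chrom"] = ann["chrom"].astype(str)
    ann["pos"] = ann["pos"].astype(int)
    sites = calls.sites.drop(columns=[c for c in ("func_class", *extra) if c in calls.sites], errors="ignore")
    merged = sites.merge(ann, on=["chrom", "pos", "alt"], how="left")
    merged["func_class"] = merged["func_class"].fillna("other")
    return replace(calls, sites=merged)


# ---------------------------------------------------------------------------
# filtering


def read_gene_regions(bed_path) -> pd.DataFrame:
    """Read BED (0-based half-open) gene regions: chrom, start, end, gene."""
    df = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], dtype={"chrom": str},
    )
    return df


def _in_regions(sites: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Boolean mask of sites (1-based pos) falling in any 0-based half-open region."""
    keep = np.zeros(len(sites), dtype=bool)
    pos0 = sites["pos"].to_numpy() - 1  # VCF 1-based -> 0-based
    chroms = sites["chrom"].astype(str).to_numpy()
    for chrom, grp in regions.groupby(regions["chrom"].astype(str)):
        sel = chroms == chrom
        if not sel.any():
            continue
        p = pos0[sel]
        hit = np.zeros(p.shape, dtype=bool)
        for start, end in grp[["start", "end"]].itertuples(index=False):
            hit |= (p >= start) & (p < end)
        keep[sel] = hit
    return keep


def filter_calls(
    calls: CallSet,
    qual_min: float = 20.0,
    dp_bounds: tuple[float, float] = (8, 300),
    regions: pd.DataFrame | None = None,
) -> CallSet:
    """Apply the study site filters.

    Sites with QUAL below ``qual_min`` (or missing QUAL) are dropped.
    Genotypes whose recorded depth falls outside ``dp_bounds`` are set
    missing (depth comparisons are inclusive; genotypes without a recorded
    depth are left untouched).  If ``regions`` is given, sites outside the
    capture target region are dropped; an *empty* region table is refused
    rather than silently dropping every site.
    """
    lo, hi = dp_bounds
    if not lo <= hi:
        raise ValueError(f"dp_bounds out of order: {dp_bounds}")
    if regions is not None and len(regions) == 0:
        raise ValueError("empty capture region set: refusing to drop all sites")

    qual = calls.sites["qual"].to_numpy(dtype=float)
    keep = ~np.isnan(qual) & (qual >= qual_min)
    if regions is not None:
        keep &= _in_regions(calls.sites, regions)

    out = calls.take(np.flatnonzero(keep))
    if calls.depths is not None:
        depths = calls.depths[np.flatnonzero(keep)]
        bad = ~np.isnan(depths) & ((depths < lo) | (depths > hi))
        dosages = out.dosages.copy()
        dosages[bad] = np.nan
        out = replace(out, dosages=dosages, depths=depths)
    return out


# ---------------------------------------------------------------------------
# consensus


def consensus(calls_a: CallSet, calls_b: CallSet) -> tuple[CallSet, ConsensusReport]:
    """Dual-caller intersection with genotype adjudication.

    A site is kept iff both callers report it (same chrom/pos/ref/alt).  A
    genotype is kept iff both callers agree; disagreeing genotypes are set
    missing (conservative substitute for re-calling) and counted in the
    mismatch report.  Genotypes missing in either caller are missing in the
    consensus and are not counted as mismatches.
    """
    if set(calls_a.subjects) != set(calls_b.subjects):
        raise ValueError("consensus requires identical subject rosters")
    # align B's subject columns to A's order
    border = [calls_b.subjects.index(s) for s in calls_a.subjects]

    ia = calls_a.site_index()
    ib = calls_b.site_index()
    shared = ia.intersection(ib)
    ra = ia.get_indexer(shared)
    rb = ib.get_indexer(shared)

    da = calls_a.dosages[ra]
    db = calls_b.dosages[rb][:, border]
    both = ~np.isnan(da) & ~np.isnan(db)
    agree = both & (da == db)
    mismatch = both & (da != db)

    dosages = np.where(agree, da, np.nan)
    out = CallSet(
        sites=calls_a.sites.iloc[ra].reset_index(drop=True),
        dosages=dosages,
        subjects=list(calls_a.subjects),
        depths=None if calls_a.depths is None else calls_a.depths[ra],
    )
    report = ConsensusReport(
        n_sites_a=calls_a.n_sites,
        n_sites_b=calls_b.n_sites,
        n_shared=len(shared),
        n_genotypes_compared=int(both.sum()),
        n_genotype_mismatches=int(mismatch.sum()),
    )
    return out, report


# ---------------------------------------------------------------------------
# gene blocks


def build_gene_blocks(
    calls: CallSet,
    regions: pd.DataFrame,
    kept_classes: frozenset[str] = QUALIFYING_CLASSES,
) -> dict[str, GeneGenotypeBlock]:
    """Collapse qualifying sites into per-gene dosage blocks.

    Sites must carry a ``func_class`` column (see :func:`annotate_calls`).
    MAF is the minor allele count over twice the number of non-missing
    genotypes, computed per site; alleles are re-oriented (dosage -> 2 -
    dosage) so that MAF <= 0.5.  Genes with no qualifying site are simply
    absent from the result.
    """
    if "func_class" not in calls.sites.columns:
        raise ValueError("sites lack func_class; run annotate_calls first")
    class_ok = calls.sites["func_class"].isin(kept_classes).to_numpy()

    blocks: dict[str, GeneGenotypeBlock] = {}
    pos0 = calls.sites["pos"].to_numpy() - 1
    chroms = calls.sites["chrom"].astype(str).to_numpy()
    for gene, grp in regions.groupby("gene", sort=True):
        hit = np.zeros(len(calls.sites), dtype=bool)
        for chrom, start, end in grp[["chrom", "start", "end"]].itertuples(index=False):
            hit |= (chroms == str(chrom)) & (pos0 >= start) & (pos0 < end)
        rows = np.flatnonzero(hit & class_ok)
        if rows.size == 0:
            continue
        dosage = calls.dosages[rows].T.astype(float)  # subjects x sites
        n_called = (~np.isnan(dosage)).sum(axis=0)
        alt_count = np.nansum(dosage, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_called > 0, alt_count / (2.0 * n_called), 0.0)
        flip = freq > 0.5
        if flip.any():
            dosage[:, flip] = 2.0 - dosage[:, flip]
            freq[flip] = 1.0 - freq[flip]
        sites = calls.sites.iloc[rows].reset_index(drop=True).copy()
        sites["maf"] = freq
        sites["flipped"] = flip
        blocks[str(gene)] = GeneGenotypeBlock(
            gene=str(gene), subjects=list(calls.subjects), sites=sites, dosages=dosage
        )
    return blocks


# ---------------------------------------------------------------------------
# QC metrics


def concordance_check(
    exome: CallSet, array: CallSet, threshold: float = 0.90
) -> tuple[pd.Series, list[str]]:
    """Per-subject genotype concordance against an orthogonal platform.

    Rate = fraction of shared sites where both platforms report a genotype
    and the dosages agree.  Subjects below ``threshold`` are flagged for
    exclusion (grossly discordant samples indicate swaps or contamination).
    """
    common = [s for s in exome.subjects if s in array.subjects]
    if not common:
        raise ValueError("no shared subjects between platforms")
    shared = exome.site_index().intersection(array.site_index())
    if len(shared) == 0:
        raise ValueError("no shared sites between platforms")
    re_ = exome.site_index().get_indexer(shared)
    ra = array.site_index().get_indexer(shared)
    ce = [exome.subjects.index(s) for s in common]
    ca = [array.subjects.index(s) for s in common]
    de = exome.dosages[np.ix_(re_, ce)]
    da = array.dosages[np.ix_(ra, ca)]
    both = ~np.isnan(de) & ~np.isnan(da)
    agree = both & (de == da)
    with np.errstate(invalid="ignore"):
        rates = np.where(both.sum(axis=0) > 0, agree.sum(axis=0) / both.sum(axis=0), np.nan)
    rates = pd.Series(rates, index=common, name="concordance")
    outliers = rates.index[rates < threshold].tolist()
    return rates, outliers


def count_discordant_sites(rep1: CallSet, rep2: CallSet) -> int:
    """Number of shared sites where duplicate samples disagree on any genotype."""
    shared = rep1.site_index().intersection(rep2.site_index())
    r1 = rep1.site_index().get_indexer(shared)
    r2 = rep2.site_index().get_indexer(shared)
    order = [rep2.subjects.index(s) for s in rep1.subjects]
    d1 = rep1.dosages[r1]
    d2 = rep2.dosages[r2][:, order]
    both = ~np.isnan(d1) & ~np.isnan(d2)
    return int(((d1 != d2) & both).any(axis=1).sum())


def duplicate_discordance(pairs, genotyped_bases: float) -> float:
    """Genotyping type-1 error rate from duplicate samples.

    ``pairs`` is either a sequence of per-pair discordant-site counts or a
    sequence of (CallSet, CallSet) duplicates.  The rate is the mean
    discordant count divided by the number of genotyped bases.
    """
    if genotyped_bases <= 0:
        raise ValueError("genotyped_bases must be positive")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no duplicate pairs supplied")
    counts = [
        count_discordant_sites(*p) if isinstance(p, tuple) else float(p) for p in pairs
    ]
    return float(np.mean(counts)) / float(genotyped_bases)
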