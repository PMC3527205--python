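"""Extreme-tail subject selection for heat-pain sensitivity.

Subjects rated in a quantitative sensory testing (QST) protocol carry two
phenotypes: the heat pain threshold (HPT) and the heat pain suprathreshold
(HPST), both in degrees Celsius.  HPST is the primary selection metric; a
subject enters the *insensitive* extreme only if both HPST is at or above the
insensitive cut-off and HPT lies strictly above the cohort HPT median, and the
*sensitive* extreme only if HPST is at or below the sensitive cut-off and HPT
lies strictly below the median.  Everyone else is excluded.

Because subjects are drawn from a twin register, tails are then resolved to
singletons: a monozygotic (MZ) twin is retained only if the co-twin resides in
the same HPST tail; a dizygotic (DZ) pair falling into opposite tails is
dropped entirely; a concordant pair contributes its more extreme member.  At
most one member per twin pair survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Subject",
    "SelectionThresholds",
    "DataError",
    "classify_extremes",
    "resolve_twins",
    "read_phenotypes",
    "TUK1_THRESHOLDS",
    "TUK2_THRESHOLDS",
]

SENSITIVE = "sensitive"
INSENSITIVE = "insensitive"
EXCLUDED = "excluded"

PHENOTYPE_COLUMNS = ["id", "cohort", "hpt", "hpst", "twin_pair_id", "zygosity"]


class DataError(ValueError):
    """Raised when input tables violate structural expectations."""


@dataclass(frozen=True)
class Subject:
    """One phenotyped individual."""

    id: str
    cohort: str
    hpt: float
    hpst: float
    twin_pair_id: str | None = None
    zygosity: str = "singleton"  # {MZ, DZ, singleton}


@dataclass(frozen=True)
class SelectionThresholds:
    """Tail definitions in degrees Celsius.

    ``hpst_insensitive_min``: HPST at or above this -> candidate insensitive.
    ``hpst_sensitive_max``: HPST at or below this -> candidate sensitive.
    ``hpt_median``: HPT must lie strictly above (insensitive) or strictly
    below (sensitive) this median for the candidate to be retained.
    """

    hpst_insensitive_min: float
    hpst_sensitive_max: float
    hpt_median: float

    def __post_init__(self) -> None:
        if not self.hpst_sensitive_max < self.hpst_insensitive_min:
            raise ValueError(
                "hpst_sensitive_max must be below hpst_insensitive_min "
                f"(got {self.hpst_sensitive_max} >= {self.hpst_insensitive_min})"
            )


# The two discovery-cohort threshold sets used throughout the package.
TUK1_THRESHOLDS = SelectionThresholds(49.2, 45.5, 46.6)
TUK2_THRESHOLDS = SelectionThresholds(48.9, 45.4, 46.0)


def _as_frame(subjects) -> pd.DataFrame:
    if isinstance(subjects, pd.DataFrame):
        df = subjects.copy()
    else:
        df = pd.DataFrame([vars(s) if isinstance(s, Subject) else s for s in subjects])
    missing = [c for c in ("id", "hpt", "hpst") if c not in df.columns]
    if missing:
        raise DataError(f"phenotype table lacks required columns: {missing}")
    if "twin_pair_id" not in df.columns:
        df["twin_pair_id"] = None
    if "zygosity" not in df.columns:
        df["zygosity"] = "singleton"
    return df


def classify_extremes(subjects, thresholds: SelectionThresholds) -> pd.DataFrame:
    """Assign each subject a tail label in {sensitive, insensitive, excluded}.

    HPST comparisons are inclusive (>= / <=, as the selection protocol states
    them), the HPT-vs-median comparison strict.  Subjects with a missing
    phenotype are excluded and the reason recorded in ``exclusion_reason``.

    Returns the input table with ``label`` (and ``exclusion_reason``) columns.
    """
    df = _as_frame(subjects)
    hpt = pd.to_numeric(df["hpt"], errors="coerce")
    hpst = pd.to_numeric(df["hpst"], errors="coerce")
    missing = hpt.isna() | hpst.isna()

    insens = (hpst >= thresholds.hpst_insensitive_min) & (hpt > thresholds.hpt_median)
    sens = (hpst <= thresholds.hpst_sensitive_max) & (hpt < thresholds.hpt_median)

    label = np.where(missing, EXCLUDED, np.where(insens, INSENSITIVE, np.where(sens, SENSITIVE, EXCLUDED)))
    df["label"] = label
    df["exclusion_reason"] = np.where(
        missing, "missing phenotype", np.where(label == EXCLUDED, "not in either tail", "")
    )
    return df


def _extremity_key(row):
    """Sort key: more extreme first.  HPST farther from the tail cut-off is
    more extreme (monotone in HPST within a tail, so the cut-off cancels);
    ties break on more extreme HPT, then lexicographic id."""
    if row["label"] == INSENSITIVE:
        return (-row["hpst"], -row["hpt"], str(row["id"]))
    return (row["hpst"], row["hpt"], str(row["id"]))


def resolve_twins(labeled: pd.DataFrame) -> pd.DataFrame:
    """Reduce a labelled roster to at most one subject per twin pair.

    Rules, applied per ``twin_pair_id`` with both members present:

    * MZ: a member is eligible only if the co-twin carries the same tail
      label; the more extreme member of a concordant pair is retained.
    * DZ in opposite tails: both dropped.  DZ in the same tail: the more
      extreme member is retained.  A DZ member whose co-twin is merely
      excluded (mid-distribution) is kept.
    * A twin whose co-twin is absent from the roster is treated as a
      singleton.

    "More extreme" means lower HPST in the sensitive tail and higher HPST in
    the insensitive tail; HPST ties break on the more extreme HPT, then id.

    Raises :class:`DataError` if any twin_pair_id has more than two members.
    """
    df = labeled.copy()
    if "label" not in df.columns:
        raise DataError("resolve_twins expects a labelled table (run classify_extremes first)")
    in_tail = df["label"].isin([SENSITIVE, INSENSITIVE])

    keep: list = []
    has_pair = df["twin_pair_id"].notna() & (df["twin_pair_id"].astype(str) != "")
    singles = df[~has_pair & in_tail]
    keep.extend(singles.index.tolist())

    for pair_id, grp in df[has_pair].groupby("twin_pair_id", sort=True):
        if len(grp) > 2:
            raise DataError(f"twin_pair_id {pair_id!r} has {len(grp)} members (max 2)")
        if len(grp) == 1:
            row = grp.iloc[0]
            if row["label"] != EXCLUDED:
                keep.append(grp.index[0])
            continue
        a, b = (grp.iloc[0], grp.iloc[1])
        labels = {a["label"], b["label"]}
        zyg = str(a.get("zygosity", "DZ")).upper()
        if labels == {SENSITIVE, INSENSITIVE}:
            continue  # opposite tails: whole pair excluded (either zygosity)
        tails = [r for _, r in grp.iterrows() if r["label"] != EXCLUDED]
        if not tails:
            continue
        if len(tails) == 1:
            # Concordance required for MZ: a lone-labelled MZ twin whose
            # co-twin is not in the same tail is dropped.
            if zyg == "MZ":
                continue
            keep.append(tails[0].name)
            continue
        # both in the same tail: keep the more extreme member
        best = min(tails, key=_extremity_key)
        keep.append(best.name)

    out = df.loc[sorted(keep, key=lambda i: str(df.loc[i, "id"]))].reset_index(drop=True)
    return out


def read_phenotypes(path) -> pd.DataFrame:
    """Read a tab-separated phenotype table (id, cohort, hpt, hpst,
    twin_pair_id, zygosity; header row required)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "twin_pair_id": str})
    return _as_frame(df)
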