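"""Venom-proteome composition: two-level relative-abundance quantification
and the compositional statistics used to compare venoms across taxa.

The quantification model follows the standard combined RP-HPLC / SDS-PAGE
workflow: the area of each chromatographic peak gives the fraction's share
of the whole venom, and within a fraction that share is apportioned to the
individual gel bands by their optical densities.  Band shares are then
accumulated per protein family to give the familiar "% of total venom
proteins" profile.

Downstream statistics operate on a taxa x family percent table: per-family
mean +/- SD, coefficients of variation, dominant-family sums, fold ratios,
the Sorensen-Dice protein similarity coefficient (PSC) between identifier
sets, the standardized Levins index used as a venom-breadth (evenness)
measure, and the abundance filter that selects families suitable for
phylogenetic-signal testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ValidationError

__all__ = [
    "Fraction",
    "QuantInput",
    "BandAbundance",
    "AbundanceTable",
    "ProteinSet",
    "SummaryStat",
    "BreadthResult",
    "PSCMatrix",
    "CVProfile",
    "band_relative_abundance",
    "aggregate_families",
    "family_summary",
    "dominant_sum",
    "psc",
    "psc_matrix",
    "upper_triangle_mean",
    "cv_profile",
    "fold_ratio",
    "levins_breadth",
    "filter_signal_traits",
    "round_half_away",
]

#: tolerance on the per-taxon percent sum of an abundance table
SUM_TOLERANCE = 0.5


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with halves going away from zero (the convention of printed
    report statistics), not banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Quantification input
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fraction:
    """One chromatographic fraction.

    A *whole* fraction (a peak resolving to a single protein band) has an
    empty ``band_densities`` tuple and carries one family label in
    ``band_families``.  A *banded* fraction lists one optical density and one
    family label per gel band, in lane order.
    """

    fraction_id: str
    peak_area: float
    band_densities: tuple[float, ...] = ()
    band_families: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.peak_area < 0:
            raise ValidationError(
                f"fraction {self.fraction_id!r}: negative peak area {self.peak_area}"
            )
        if any(d < 0 for d in self.band_densities):
            raise ValidationError(
                f"fraction {self.fraction_id!r}: negative band density"
            )
        if self.band_densities:
            if len(self.band_densities) != len(self.band_families):
                raise ValidationError(
                    f"fraction {self.fraction_id!r}: {len(self.band_densities)} "
                    f"densities but {len(self.band_families)} family labels"
                )
        else:
            if len(self.band_families) != 1:
                raise ValidationError(
                    f"fraction {self.fraction_id!r}: a whole fraction needs "
                    "exactly one family label"
                )

    @property
    def is_whole(self) -> bool:
        return not self.band_densities


@dataclass(frozen=True)
class QuantInput:
    """Paired peak-integration and band-densitometry records for one venom."""

    fractions: tuple[Fraction, ...]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValidationError("QuantInput needs at least one fraction")
        if all(f.peak_area == 0 for f in self.fractions):
            raise InvalidInputError("all peak areas are zero")

    @classmethod
    def from_records(cls, fractions: Iterable[Fraction]) -> "QuantInput":
        return cls(tuple(fractions))

    @classmethod
    def read_csv(cls, path) -> "QuantInput":
        """Read the CSV layout ``fraction_id, peak_area, band_index,
        band_density, family``; whole fractions leave ``band_index`` empty."""
        try:
            df = pd.read_csv(path, dtype={"fraction_id": str, "family": str})
        except Exception as exc:
            raise ValidationError(f"cannot read quant CSV {path}: {exc}") from exc
        required = {"fraction_id", "peak_area", "band_index", "band_density", "family"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"quant CSV missing columns: {sorted(missing)}")
        fractions: list[Fraction] = []
        for fid, grp in df.groupby("fraction_id", sort=False):
            area = float(grp["peak_area"].iloc[0])
            if grp["band_index"].isna().all():
                if len(grp) != 1:
                    raise ValidationError(
                        f"fraction {fid!r}: multiple rows but no band indices"
                    )
                fractions.append(
                    Fraction(fid, area, (), (str(grp["family"].iloc[0]),))
                )
            else:
                grp = grp.sort_values("band_index")
                fractions.append(
                    Fraction(
                        fid,
                        area,
                        tuple(float(d) for d in grp["band_density"]),
                        tuple(str(f) for f in grp["family"]),
                    )
                )
        return cls(tuple(fractions))

    def to_csv(self, path) -> None:
        rows = []
        for f in self.fractions:
            if f.is_whole:
                rows.append((f.fraction_id, f.peak_area, None, None, f.band_families[0]))
            else:
                for i, (d, fam) in enumerate(zip(f.band_densities, f.band_families)):
                    rows.append((f.fraction_id, f.peak_area, i, d, fam))
        pd.DataFrame(
            rows, columns=["fraction_id", "peak_area", "band_index", "band_density", "family"]
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class BandAbundance:
    """Relative abundance of one gel band (or whole fraction), in percent of
    total venom protein."""

    fraction_id: str
    band_index: int
    family: str
    percent: float


def band_relative_abundance(q: QuantInput) -> list[BandAbundance]:
    """Apportion total venom protein to bands.

    A fraction's share is ``100 * peak_area / sum(peak_areas)``; within a
    banded fraction each band receives that share times
    ``band_density / sum(lane densities)``.  The returned percents sum to
    100 over all bands and whole fractions.
    """
    total_area = sum(f.peak_area for f in q.fractions)
    if total_area <= 0:
        raise InvalidInputError("all peak areas are zero")
    out: list[BandAbundance] = []
    for f in q.fractions:
        frac_pct = 100.0 * f.peak_area / total_area
        if f.is_whole:
            out.append(BandAbundance(f.fraction_id, 0, f.band_families[0], frac_pct))
        else:
            lane_total = sum(f.band_densities)
            if lane_total <= 0 and f.peak_area > 0:
                raise InvalidInputError(
                    f"fraction {f.fraction_id!r}: all band densities are zero"
                )
            for i, (d, fam) in enumerate(zip(f.band_densities, f.band_families)):
                share = d / lane_total if lane_total > 0 else 0.0
                out.append(BandAbundance(f.fraction_id, i, fam, frac_pct * share))
    return out


def aggregate_families(bands: Iterable[BandAbundance]) -> dict[str, float]:
    """Accumulate band percents per protein family (insertion-ordered)."""
    acc: dict[str, float] = {}
    for b in bands:
        acc[b.family] = acc.get(b.family, 0.0) + b.percent
    return acc


# ---------------------------------------------------------------------------
# Abundance table
# ---------------------------------------------------------------------------


class AbundanceTable:
    """Taxa x protein-family relative-abundance matrix in percent.

    Backed by a pandas DataFrame (index = taxa, columns = families,
    ``NaN`` = missing/not detected).  Per-taxon sums of non-missing entries
    may not exceed ``100 + SUM_TOLERANCE``.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise ValidationError("duplicate taxon labels")
        if data.columns.has_duplicates:
            raise ValidationError("duplicate family labels")
        values = data.to_numpy(dtype=float)
        if np.any(values < -1e-12):
            raise ValidationError("negative abundance entries")
        sums = np.nansum(values, axis=1)
        bad = np.where(sums > 100.0 + SUM_TOLERANCE)[0]
        if bad.size:
            raise ValidationError(
                f"taxon {data.index[bad[0]]!r} sums to {sums[bad[0]]:.2f}% > 100%"
            )
        self.data = data.astype(float)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_rows(cls, rows: Mapping[str, Mapping[str, float]]) -> "AbundanceTable":
        return cls(pd.DataFrame.from_dict(rows, orient="index"))

    @classmethod
    def read_csv(cls, path) -> "AbundanceTable":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as exc:
            raise ValidationError(f"cannot read abundance CSV {path}: {exc}") from exc
        df.index = df.index.astype(str)
        return cls(df)

    def to_csv(self, path) -> None:
        self.data.to_csv(path)

    # -- access ------------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def families(self) -> list[str]:
        return list(self.data.columns)

    def row(self, taxon: str) -> pd.Series:
        if taxon not in self.data.index:
            raise KeyError(f"unknown taxon {taxon!r}")
        return self.data.loc[taxon]

    def value(self, taxon: str, family: str, missing_policy: str = "zero") -> float:
        v = float(self.row(taxon)[self._check_family(family)])
        if math.isnan(v):
            return 0.0 if missing_policy == "zero" else math.nan
        return v

    def _check_family(self, family: str) -> str:
        if family not in self.data.columns:
            raise KeyError(f"unknown family {family!r}")
        return family

    def _values(
        self, taxa: Sequence[str], family: str, missing_policy: str
    ) -> np.ndarray:
        for t in taxa:
            if t not in self.data.index:
                raise KeyError(f"unknown taxon {t!r}")
        self._check_family(family)
        v = self.data.loc[list(taxa), family].to_numpy(dtype=float)
        if missing_policy == "zero":
            return np.nan_to_num(v, nan=0.0)
        if missing_policy == "exclude":
            return v[~np.isnan(v)]
        raise InvalidInputError(f"unknown missing_policy {missing_policy!r}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"AbundanceTable({len(self.taxa)} taxa x {len(self.families)} families)"


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryStat:
    """Mean, sample SD (n-1 denominator) and CV of a set of percents."""

    mean: float
    sd: float
    n: int

    @property
    def cv_percent(self) -> float | None:
        """100 * sd / mean; ``None`` when the mean is zero."""
        if self.mean == 0:
            return None
        return 100.0 * self.sd / self.mean


def _summary(values: np.ndarray) -> SummaryStat:
    n = values.size
    mean = float(values.mean()) if n else math.nan
    sd = float(values.std(ddof=1)) if n >= 2 else math.nan
    return SummaryStat(mean=mean, sd=sd, n=n)


def family_summary(
    table: AbundanceTable,
    taxa_subset: Sequence[str],
    family: str,
    missing_policy: str = "zero",
) -> SummaryStat:
    """Mean +/- sample SD of one family's abundance over a taxon subset."""
    if not taxa_subset:
        raise InvalidInputError("empty taxon subset")
    return _summary(table._values(taxa_subset, family, missing_policy))


def dominant_sum(
    table: AbundanceTable, taxon: str, families: Iterable[str]
) -> float:
    """Summed abundance of the named families for one taxon (missing -> 0)."""
    return float(sum(table.value(taxon, f) for f in families))


def fold_ratio(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Ratio of two percents, rounded half-away-from-zero for reporting."""
    if denominator <= 0:
        raise InvalidInputError("fold ratio denominator must be positive")
    return round_half_away(numerator / denominator, decimals)


# ---------------------------------------------------------------------------
# Protein similarity coefficient
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinSet:
    """The set of protein identifiers detected in one taxon's venom."""

    taxon: str
    proteins: frozenset[str]

    @classmethod
    def from_iterable(cls, taxon: str, proteins: Iterable[str]) -> "ProteinSet":
        return cls(taxon, frozenset(proteins))


def read_protein_sets(path) -> list[ProteinSet]:
    """Read two-column CSV (taxon, protein_id) into per-taxon sets."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("protein-set CSV needs columns taxon, protein_id")
    taxon_col, protein_col = df.columns[:2]
    return [
        ProteinSet.from_iterable(str(t), grp[protein_col].astype(str))
        for t, grp in df.groupby(taxon_col, sort=False)
    ]


def psc(
    a: ProteinSet,
    b: ProteinSet,
    key: Callable[[str], str] | None = None,
) -> float:
    """Protein similarity coefficient: ``2 |A & B| / (|A| + |B|) * 100``.

    ``key`` injects the identity criterion (e.g. collapse accessions to a
    cluster id); the default is exact identifier match.
    """
    if not a.proteins or not b.proteins:
        raise InvalidInputError("PSC requires two non-empty protein sets")
    sa = {key(p) for p in a.proteins} if key else set(a.proteins)
    sb = {key(p) for p in b.proteins} if key else set(b.proteins)
    return 200.0 * len(sa & sb) / (len(sa) + len(sb))


@dataclass(frozen=True)
class PSCMatrix:
    """Symmetric pairwise PSC matrix (NaN diagonal) with its off-diagonal mean."""

    matrix: pd.DataFrame
    mean: float


def upper_triangle_mean(matrix: pd.DataFrame) -> float:
    """Mean over the n(n-1)/2 above-diagonal entries of a symmetric matrix."""
    m = matrix.to_numpy(dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    return float(np.nanmean(m[iu]))


def psc_matrix(
    sets: Sequence[ProteinSet], key: Callable[[str], str] | None = None
) -> PSCMatrix:
    """All pairwise PSC values plus the mean over distinct pairs."""
    if len(sets) < 2:
        raise InvalidInputError("need at least two protein sets")
    labels = [s.taxon for s in sets]
    if len(set(labels)) != len(labels):
        raise InvalidInputError("duplicate taxon labels in protein sets")
    n = len(sets)
    m = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = psc(sets[i], sets[j], key=key)
    df = pd.DataFrame(m, index=labels, columns=labels)
    return PSCMatrix(matrix=df, mean=upper_triangle_mean(df))


# ---------------------------------------------------------------------------
# Variability profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVProfile:
    """Per-family coefficients of variation over a taxon subset."""

    cv: dict[str, float]
    undefined: tuple[str, ...]
    group_means: dict[str, float] = field(default_factory=dict)

    @property
    def cv_min(self) -> float:
        return min(self.cv.values())

    @property
    def cv_max(self) -> float:
        return max(self.cv.values())


def cv_profile(
    table: AbundanceTable,
    taxa_subset: Sequence[str],
    families: Sequence[str] | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
    missing_policy: str = "zero",
) -> CVProfile:
    """Coefficient of variation (100*SD/mean, n-1 SD) per family.

    Families whose entries are all zero over the subset have an undefined CV
    and are excluded from min/max and group means.
    """
    if len(taxa_subset) < 2:
        raise InvalidInputError("CV needs at least two taxa")
    families = list(families) if families is not None else table.families
    cvs: dict[str, float] = {}
    undefined: list[str] = []
    for fam in families:
        stat = family_summary(table, taxa_subset, fam, missing_policy)
        c = stat.cv_percent
        if c is None or math.isnan(c):
            undefined.append(fam)
        else:
            cvs[fam] = c
    group_means: dict[str, float] = {}
    if groups:
        for name, members in groups.items():
            vals = [cvs[f] for f in members if f in cvs]
            if not vals:
                raise InvalidInputError(f"group {name!r} has no defined CVs")
            group_means[name] = float(np.mean(vals))
    return CVProfile(cv=cvs, undefined=tuple(undefined), group_means=group_means)


# ---------------------------------------------------------------------------
# Venom breadth (standardized Levins index)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreadthResult:
    """Levins breadth of a compositional profile.

    ``breadth_raw`` is ``B = 1 / sum(p_i^2)`` over the category proportions;
    ``breadth_std = (B - 1)/(n - 1)`` rescales it to [0, 1], where 1 is a
    perfectly even venom and 0 a single-family venom.
    """

    breadth_raw: float
    breadth_std: float
    n_categories: int


def levins_breadth(
    profile: Mapping[str, float] | pd.Series,
    categories: Sequence[str] | None = None,
) -> BreadthResult:
    """Standardized Levins index of one venom profile.

    ``categories`` fixes the category set (default: every key of the
    profile); entries are renormalized to proportions over that set, so the
    result is invariant to uniform rescaling.
    """
    series = pd.Series(profile, dtype=float)
    if categories is not None:
        series = series.reindex(list(categories))
    series = series.fillna(0.0)
    n = len(series)
    if n < 2:
        raise InvalidInputError("Levins breadth needs at least two categories")
    total = float(series.sum())
    if total <= 0:
        raise InvalidInputError("all-zero profile")
    p = series.to_numpy() / total
    b = 1.0 / float(np.sum(p * p))
    return BreadthResult(
        breadth_raw=b, breadth_std=(b - 1.0) / (n - 1.0), n_categories=n
    )


# ---------------------------------------------------------------------------
# Trait filtering for signal analysis
# ---------------------------------------------------------------------------


def filter_signal_traits(
    table: AbundanceTable,
    min_abundance: float = 1.0,
    min_taxa: int = 5,
    taxa: Sequence[str] | None = None,
) -> list[str]:
    """Families strictly exceeding ``min_abundance`` percent in at least
    ``min_taxa`` of the given taxa (column order preserved)."""
    taxa = list(taxa) if taxa is not None else table.taxa
    keep: list[str] = []
    for fam in table.families:
        count = int(
            np.sum(table._values(taxa, fam, missing_policy="zero") > min_abundance)
        )
        if count >= min_taxa:
            keep.append(fam)
    return keep
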