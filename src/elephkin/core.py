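"""Core data containers and marker-level primitives.

Genotypes are stored as alt-allele dosages in {0, 1, 2} with a distinct
``MISSING`` code (-1).  Missing calls are never imputed; every estimator in
the package restricts itself to the calls that are actually observed, which
keeps the moment estimators unbiased by construction.

Coordinates are 1-based and intervals closed, following VCF/MAP convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

#: Sentinel dosage code for a missing genotype call.
MISSING: int = -1

_LEGAL_CODES = frozenset({0, 1, 2, MISSING})


@dataclass
class MarkerMap:
    """Per-marker chromosome, 1-based position and allele labels.

    Positions must be strictly increasing within each chromosome; marker
    order in the map is the column order of any :class:`GenotypeMatrix`
    that references it.
    """

    chrom: np.ndarray  # str
    pos: np.ndarray  # int64, 1-based
    ref: np.ndarray  # str
    alt: np.ndarray  # str
    ids: np.ndarray = None  # str, defaults to "chrom:pos"

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        n = len(self.chrom)
        if not (len(self.pos) == len(self.ref) == len(self.alt) == n):
            raise ValueError("MarkerMap field lengths differ")
        if self.ids is None:
            self.ids = np.array(
                [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)], dtype=object
            )
        else:
            self.ids = np.asarray(self.ids, dtype=object)
            if len(self.ids) != n:
                raise ValueError("MarkerMap ids length differs")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def __len__(self) -> int:
        return len(self.pos)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx], self.ids[idx]
        )

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)


@dataclass
class GenomeLayout:
    """Chromosome lengths in bp, plus which chromosomes are non-autosomal.

    ``total_length`` (the F_ROH denominator and the dataset SNP-density
    denominator) is the sum of autosomal lengths.
    """

    lengths: Mapping[str, int]
    sex_chromosomes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.lengths = dict(self.lengths)
        self.sex_chromosomes = frozenset(self.sex_chromosomes)

    @property
    def total_length(self) -> int:
        return sum(
            l for c, l in self.lengths.items() if c not in self.sex_chromosomes
        )

    def validate_markers(self, markers: MarkerMap) -> None:
        for c in markers.chromosomes():
            if c not in self.lengths:
                raise ValueError(f"chromosome {c} absent from layout")
            mx = int(markers.pos[markers.chrom == c].max())
            if mx > self.lengths[c]:
                raise ValueError(f"marker at {c}:{mx} beyond chromosome end")


@dataclass
class SampleMeta:
    """One individual's record from the camp log books."""

    sample_id: str
    sex: str = "unknown"  # male / female / unknown
    birth_year: Optional[int] = None
    birth_year_approx: bool = False
    origin: str = "unknown"  # wild / captive / unknown
    camp: str = ""
    dam_id: Optional[str] = None


@dataclass
class GenotypeMatrix:
    """Samples x biallelic markers, alt-allele dosage coded {0,1,2,MISSING}."""

    sample_ids: list
    calls: np.ndarray  # int8, shape (n_samples, n_markers)
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D")
        if self.calls.shape[0] != len(self.sample_ids):
            raise ValueError("row count != number of samples")
        if self.calls.shape[1] != len(self.markers):
            raise ValueError("column count != number of markers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("illegal dosage codes present")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.sample_ids), self.calls[:, idx], self.markers.subset(idx)
        )

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        rows = [self.sample_index(s) for s in ids]
        return GenotypeMatrix(list(ids), self.calls[rows], self.markers)

    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def drop_sex_chromosomes(self, layout: GenomeLayout) -> "GenotypeMatrix":
        """Remove markers on chromosomes flagged non-autosomal in *layout*."""
        keep = ~np.isin(
            self.markers.chrom.astype(str), sorted(layout.sex_chromosomes)
        )
        return self.subset_markers(np.flatnonzero(keep))


def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Per-marker alt-allele frequency over non-missing calls.

    Markers with every call missing get NaN (flagged undefined, not fatal).
    """
    obs = G.calls != MISSING
    n_obs = obs.sum(axis=0)
    dose = np.where(obs, G.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = dose / (2.0 * n_obs)
    freq[n_obs == 0] = np.nan
    return freq


def minor_allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    f = allele_frequencies(G)
    return np.minimum(f, 1.0 - f)


def filter_markers(
    G: GenotypeMatrix, maf_min: float = 0.05, max_missing_rate: float = 0.10
) -> GenotypeMatrix:
    """QC filter: retain markers with MAF strictly above *maf_min* and
    missing fraction at most *max_missing_rate*.

    Boundary strictness mirrors the conventions the pipeline standardises
    on: MAF exactly at the cutoff is removed; missingness exactly at the
    cutoff is retained (only "more than" is excluded).  Markers whose
    frequency is undefined (all calls missing) are removed.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 <= max_missing_rate <= 1):
        raise ValueError("max_missing_rate must be in [0, 1]")
    maf = minor_allele_frequencies(G)
    miss = G.missing_rate()
    keep = np.flatnonzero(
        ~np.isnan(maf) & (maf > maf_min) & (miss <= max_missing_rate)
    )
    return G.subset_markers(keep)


def dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples (composite LD; genotypes are unphased).

    Undefined correlations (fewer than 2 complete pairs, or a monomorphic
    vector) are returned as 0.0, i.e. treated as linkage equilibrium.
    """
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(np.float64)
    y = b[ok].astype(np.float64)
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    c = ((x - x.mean()) * (y - y.mean())).mean()
    return float(c * c / (vx * vy))


def ld_prune(
    G: GenotypeMatrix,
    window_bp: int = 50_000,
    step_snps: int = 5,
    r2_max: float = 0.25,
) -> np.ndarray:
    """Remove one member of every same-chromosome marker pair within
    *window_bp* whose dosage r-squared exceeds *r2_max*.

    Returns the sorted indices of retained markers.  Pairs are visited in
    (chromosome, position) order; from each offending pair the marker with
    the higher missing rate is removed (tie: lower MAF; tie: larger
    position), which keeps the more informative marker and makes the result
    deterministic.  Every pair within *window_bp* is examined, so the
    survivor set is independent of the sweep step; *step_snps* is accepted
    for interface compatibility with windowed tools.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if step_snps < 1:
        raise ValueError("step_snps must be >= 1")
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")

    miss = G.missing_rate()
    maf = minor_allele_frequencies(G)
    maf = np.where(np.isnan(maf), -1.0, maf)
    pos = G.markers.pos
    chrom = G.markers.chrom
    retained = np.ones(G.n_markers, dtype=bool)

    def drop_one(i: int, j: int) -> None:
        # tie rule: higher missing rate, then lower MAF, then larger position
        if miss[i] != miss[j]:
            k = i if miss[i] > miss[j] else j
        elif maf[i] != maf[j]:
            k = i if maf[i] < maf[j] else j
        else:
            k = j if pos[j] > pos[i] else i
        retained[k] = False

    for c in G.markers.chromosomes():
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        for a in range(len(idx)):
            i = idx[a]
            if not retained[i]:
                continue
            b = a + 1
            while b < len(idx) and p[b] - p[a] <= window_bp:
                j = idx[b]
                if retained[j] and retained[i]:
                    if dosage_r2(G.calls[:, i], G.calls[:, j]) > r2_max:
                        drop_one(i, j)
                b += 1
            if not retained[i]:
                continue
    return np.flatnonzero(retained)
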