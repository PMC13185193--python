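"""Per-individual heterozygosity, run-of-homozygosity detection and
F_ROH, plus the group-comparison statistics.

A ROH is emitted when five criteria hold simultaneously: (i) no
heterozygous genotype in the run, (ii) fewer than two missing genotypes,
(iii) at least ``min_snps`` markers, (iv) run SNP density (markers/span)
at least the dataset-wide density (total markers / total genome length),
and (v) span at least ``min_length_bp``.  Detection uses exact maximal-run
semantics — a run is maximal when it cannot be extended in either
direction without introducing a heterozygous call or a second missing
call — rather than a windowed heuristic; this is deterministic and
directly testable against exhaustive enumeration, at the price of small
count differences versus window-based tools.  Segment endpoints are the
positions of the first and last marker in the run (no extension into
inter-marker gaps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenomeLayout, GenotypeMatrix


@dataclass
class RohParams:
    min_snps: int = 20
    max_missing_in_run: int = 1  # "less than two missing genotypes"
    min_length_bp: int = 100_000
    # None -> dataset-wide density (n markers / total genome length)
    min_density: Optional[float] = None


#: Variant parameter set for dense whole-genome callsets.  The exact values
#: used in prior elephant WGS work are not published alongside this
#: pipeline; these are this package's documented defaults for dense data,
#: not a citation.
WGS_PRESET = RohParams(min_snps=50, max_missing_in_run=1, min_length_bp=500_000)


def observed_heterozygosity(G: GenotypeMatrix) -> pd.Series:
    """Per-sample Ho = het calls / non-missing calls."""
    obs = (G.calls != MISSING).sum(axis=1)
    if (obs == 0).any():
        bad = [s for s, o in zip(G.sample_ids, obs) if o == 0]
        raise ValueError(f"samples with no non-missing calls: {bad}")
    het = (G.calls == 1).sum(axis=1)
    return pd.Series(het / obs, index=pd.Index(G.sample_ids, name="sample_id"), name="Ho")


def dataset_density(G: GenotypeMatrix, layout: GenomeLayout) -> float:
    """Dataset-wide SNP density: markers per bp of (autosomal) genome."""
    return G.n_markers / layout.total_length


def _maximal_runs(calls: np.ndarray, max_missing: int = 1):
    """Maximal index runs with zero hets and at most *max_missing* missing
    calls; maximal means not extendable either way without violating one
    of the two constraints.  Yields (start_idx, end_idx) inclusive.
    """
    m = len(calls)
    stretches = []
    prev = 0
    for b in np.flatnonzero(calls == 1):
        if b > prev:
            stretches.append((prev, b - 1))
        prev = b + 1
    if prev <= m - 1:
        stretches.append((prev, m - 1))
    t = max_missing
    for s, e in stretches:
        miss = np.flatnonzero(calls[s : e + 1] == MISSING) + s
        k = len(miss)
        if k <= t:
            yield (s, e)
            continue
        # windows holding exactly t missing calls, bounded by the next one out
        starts = [s] + [int(miss[i]) + 1 for i in range(k - t)]
        ends = [int(miss[i + t]) - 1 for i in range(k - t)] + [e]
        for a, b in zip(starts, ends):
            if a <= b:
                yield (a, b)


def detect_roh(
    G: GenotypeMatrix, layout: GenomeLayout, params: RohParams = RohParams()
) -> pd.DataFrame:
    """Detect ROH segments for every sample under the five criteria.

    Returns a table (sample_id, chrom, start, end, n_snps, n_missing,
    length).  Coordinates are 1-based inclusive marker positions.
    """
    if not layout.lengths:
        raise ValueError("empty genome layout")
    layout.validate_markers(G.markers)
    density_min = (
        params.min_density
        if params.min_density is not None
        else dataset_density(G, layout)
    )
    rows = []
    chrom = G.markers.chrom
    pos = G.markers.pos
    for c in G.markers.chromosomes():
        idx = np.flatnonzero(chrom == c)
        cpos = pos[idx]
        for si, sid in enumerate(G.sample_ids):
            calls = G.calls[si, idx]
            for a, b in _maximal_runs(calls, params.max_missing_in_run):
                n_snps = b - a + 1
                if n_snps < params.min_snps:
                    continue
                start, end = int(cpos[a]), int(cpos[b])
                length = end - start + 1
                if length < params.min_length_bp:
                    continue
                if n_snps / length < density_min:
                    continue
                n_missing = int((calls[a : b + 1] == MISSING).sum())
                rows.append(
                    {
                        "sample_id": sid,
                        "chrom": c,
                        "start": start,
                        "end": end,
                        "n_snps": n_snps,
                        "n_missing": n_missing,
                        "length": length,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start", "end", "n_snps", "n_missing", "length"],
    )
    return df.sort_values(["sample_id", "chrom", "start"], ignore_index=True)


def _merged_length(intervals) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s + 1
    return total


def froh(
    segments: pd.DataFrame,
    layout: GenomeLayout,
    sample_ids: Optional[Sequence[str]] = None,
) -> pd.Series:
    """F_ROH per sample: merged ROH span / total genome length.

    Samples without segments score 0; pass *sample_ids* to include them.
    """
    total = layout.total_length
    ids = list(sample_ids) if sample_ids is not None else sorted(
        segments["sample_id"].unique()
    )
    out = {}
    for sid in ids:
        sub = segments[segments["sample_id"] == sid]
        covered = 0
        for c, grp in sub.groupby("chrom"):
            covered += _merged_length(zip(grp["start"], grp["end"]))
        out[sid] = covered / total
    return pd.Series(out, name="F_ROH").rename_axis("sample_id")


def compare_groups(values, labels, test: str = "wilcoxon"):
    """Two-group Wilcoxon rank-sum (normal approximation, tie-corrected)
    or one-way fixed-effects ANOVA across 2+ groups.

    Returns (statistic, p_value).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if test == "wilcoxon":
        if len(groups) != 2:
            raise ValueError("wilcoxon compares exactly two groups")
        res = stats.mannwhitneyu(
            groups[0], groups[1], alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )
        return float(res.statistic), float(res.pvalue)
    if test == "anova":
        if any(len(g) < 2 for g in groups):
            raise ValueError("anova needs >= 2 observations per group")
        res = stats.f_oneway(*groups)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
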