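"""Reduced relatedness-informative marker (RIM) panels.

High-MAF markers maximise heterozygosity and therefore carry the most
information per marker for moment-based kinship estimation.  A RIM panel
is built from a post-QC dataset by (1) dropping markers with more than
``max_missing`` missingness, (2) LD-pruning at r-squared ``r2_max`` with
the same windowed machinery used for QC, and (3) keeping markers with
MAF >= ``maf_min`` (inclusive, so a 0.45 threshold can retain markers at
exactly 0.45).  Panels built at increasing MAF thresholds from the same
input are therefore nested.

Validation compares panel-restricted KING kinships against the full-set
reference by Pearson correlation, and benchmarks each panel against a
resampling null: random panels of matched size drawn from the same
post-QC marker set.  Correlations are computed on phi; Pearson correlation
is scale-invariant, so the phi-vs-r choice is cosmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, ld_prune, minor_allele_frequencies
from .kinship import kinship_matrix

DEFAULT_MAF_THRESHOLDS = (0.35, 0.40, 0.45)


@dataclass
class RimPanel:
    maf_threshold: float
    marker_ids: np.ndarray  # marker id strings
    marker_idx: np.ndarray  # column indices into the source matrix

    @property
    def size(self) -> int:
        return len(self.marker_idx)


@dataclass
class PanelEvaluation:
    panel: str  # threshold label or "random"
    size: int
    correlation: float  # NaN for random-null aggregate rows
    null_correlations: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def null_mean(self) -> float:
        return float(self.null_correlations.mean()) if len(self.null_correlations) else float("nan")

    @property
    def null_sd(self) -> float:
        return float(self.null_correlations.std(ddof=1)) if len(self.null_correlations) > 1 else float("nan")


def select_rim(
    G: GenotypeMatrix,
    maf_min: float,
    max_missing: float = 0.05,
    r2_max: float = 0.2,
    window_bp: int = 50_000,
    step_snps: int = 5,
) -> RimPanel:
    """Build one RIM panel; deterministic for fixed input."""
    miss_ok = G.missing_rate() <= max_missing
    idx0 = np.flatnonzero(miss_ok)
    sub = G.subset_markers(idx0)
    kept = idx0[ld_prune(sub, window_bp=window_bp, step_snps=step_snps, r2_max=r2_max)]
    maf = minor_allele_frequencies(G)[kept]
    final = kept[~np.isnan(maf) & (maf >= maf_min)]
    return RimPanel(maf_min, G.markers.ids[final], final)


def panel_phi(G: GenotypeMatrix, marker_idx) -> pd.DataFrame:
    """Kinship table restricted to the panel's markers."""
    return kinship_matrix(G.subset_markers(np.asarray(marker_idx)))


def panel_correlation(
    G: GenotypeMatrix, panel_idx, reference_kin: pd.DataFrame
):
    """Pearson correlation between panel-restricted and reference phi.

    Pairs with undefined phi in either set are excluded; returns
    (correlation, n_pairs_used, n_pairs_excluded).
    """
    panel_idx = np.asarray(panel_idx)
    if len(panel_idx) == 0:
        raise ValueError("empty panel")
    kin = panel_phi(G, panel_idx)
    a = reference_kin["phi"].to_numpy()
    b = kin["phi"].to_numpy()
    if len(a) != len(b):
        raise ValueError("reference kinship has a different pair set")
    ok = ~np.isnan(a) & ~np.isnan(b)
    n_used, n_excl = int(ok.sum()), int((~ok).sum())
    if n_used < 3:
        raise ValueError("fewer than 3 usable pairs")
    r = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return r, n_used, n_excl


def random_panel_null(
    G: GenotypeMatrix,
    size: int,
    reference_kin: pd.DataFrame,
    n_iter: int = 100,
    seed: int = 0,
) -> PanelEvaluation:
    """Resampling null: correlations of *n_iter* random panels of matched
    size drawn without replacement from the full marker set."""
    if size > G.n_markers:
        raise ValueError("panel size exceeds available markers")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(G.n_markers, size=size, replace=False)
        vals[i], _, _ = panel_correlation(G, np.sort(idx), reference_kin)
    return PanelEvaluation("random", size, float("nan"), vals)


def evaluate_panels(
    G: GenotypeMatrix,
    maf_thresholds=DEFAULT_MAF_THRESHOLDS,
    n_random: int = 100,
    seed: int = 0,
    reference_kin: pd.DataFrame | None = None,
    max_missing: float = 0.05,
    r2_max: float = 0.2,
) -> pd.DataFrame:
    """Build the RIM panels, validate each against the full-set reference
    and its matched-size random null.

    Returns one row per threshold: panel size, RIM correlation, null mean,
    null sd, and the RIM - null gap.
    """
    if reference_kin is None:
        reference_kin = kinship_matrix(G)
    rows = []
    for i, thr in enumerate(maf_thresholds):
        panel = select_rim(G, thr, max_missing=max_missing, r2_max=r2_max)
        if panel.size == 0:
            rows.append(
                {
                    "maf_threshold": thr,
                    "panel_size": 0,
                    "rim_correlation": np.nan,
                    "null_mean": np.nan,
                    "null_sd": np.nan,
                    "gap": np.nan,
                    "n_random": n_random,
                }
            )
            continue
        corr, _, _ = panel_correlation(G, panel.marker_idx, reference_kin)
        null = random_panel_null(
            G, panel.size, reference_kin, n_iter=n_random, seed=seed + i
        )
        rows.append(
            {
                "maf_threshold": thr,
                "panel_size": panel.size,
                "rim_correlation": corr,
                "null_mean": null.null_mean,
                "null_sd": null.null_sd,
                "gap": corr - null.null_mean,
                "n_random": n_random,
            }
        )
    return pd.DataFrame(rows)


def plot_panel_comparison(report: pd.DataFrame, path) -> None:
    """Line plot of RIM vs random-null correlation by panel size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.sort_values("panel_size")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(df["panel_size"], df["rim_correlation"], "o-", color="tab:blue", label="RIM set")
    ax.errorbar(
        df["panel_size"],
        df["null_mean"],
        yerr=df["null_sd"],
        fmt="s-",
        color="tab:red",
        label="Random set",
    )
    ax.set_xlabel("panel size (SNPs)")
    ax.set_ylabel("correlation with full-set kinship")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
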