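#!/usr/bin/env python
"""Reduced relatedness-informative marker (RIM) panels.

Builds the three RIM panels (missingness <= 5%, LD r^2 <= 0.2, MAF >=
0.35 / 0.40 / 0.45) from the QC'd dataset, validates each against the
full-set kinship by Pearson correlation, benchmarks them against
100-iteration random panels of matched size, and checks the direction of
the RIM-vs-null gap across replicate simulated datasets.
"""

import argparse
from pathlib import Path

from elephkin.core import filter_markers
from elephkin.experiments import rim_experiment
from elephkin.io import read_vcf
from elephkin.kinship import kinship_matrix
from elephkin.rim import evaluate_panels, plot_panel_comparison, select_rim


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--out", type=Path, default=Path("results/rim"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replicate-seeds", type=int, default=10)
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    G = filter_markers(read_vcf(args.dataset / "genotypes.vcf"))
    report = evaluate_panels(G, n_random=100, seed=args.seed,
                             reference_kin=kinship_matrix(G))
    report.to_csv(out / "rim_report.tsv", sep="\t", index=False,
                  float_format="%.6g")
    plot_panel_comparison(report, out / "rim_vs_null.png")
    for row in report.itertuples():
        print(f"MAF >= {row.maf_threshold:.2f}: {row.panel_size} SNPs, "
              f"correlation {row.rim_correlation:.3f} vs null "
              f"{row.null_mean:.3f} +/- {row.null_sd:.3f} "
              f"(gap {row.gap:+.3f})")
        panel = select_rim(G, row.maf_threshold)
        (out / f"rim_panel_maf{int(round(row.maf_threshold * 100)):02d}.txt"
         ).write_text("\n".join(map(str, panel.marker_ids)) + "\n")

    rep = rim_experiment(seed=args.seed, n_seeds=args.replicate_seeds)
    rep["table"].to_csv(out / "rim_replicates.tsv", sep="\t", index=False,
                        float_format="%.6g")
    print(f"across {rep['n_seeds']} replicate datasets the RIM panel beat its "
          f"matched random null at every size in {rep['wins']} of "
          f"{rep['n_seeds']} runs")


if __name__ == "__main__":
    main()
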