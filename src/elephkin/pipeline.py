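"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order (qc -> kinship -> {inbreeding, hbd, rim} ->
report) on either a real input (VCF + metadata TSV) or a simulated preset.
Every run writes the resolved configuration, the seed and the package
version into the output directory, a machine-readable manifest listing
each stage's outputs with checksums, and a structured JSONL log.  A single
global seed fans out to per-stage seeds derived by hashing the stage name,
so toggling one stage never perturbs another's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .core import GenotypeMatrix, allele_frequencies, filter_markers
from .io import (
    meta_by_id,
    read_layout,
    read_metadata,
    read_vcf,
    write_layout,
    write_metadata,
    write_vcf,
)
from .simulate import SimConfig, simulate_dataset
from . import hbd as hbd_mod
from .inbreeding import RohParams, compare_groups, detect_roh, froh, observed_heterozygosity
from .kinship import (
    degree_counts,
    infer_paternity,
    kinship_matrix,
    unrelated_subset,
    verify_maternal_links,
)
from .rim import DEFAULT_MAF_THRESHOLDS, evaluate_panels, select_rim

STAGES = ("simulate", "qc", "kinship", "inbreeding", "hbd", "rim", "report")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    # input: either paths to an existing dataset, or a simulate block
    vcf: Optional[str] = None
    metadata: Optional[str] = None
    layout: Optional[str] = None
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    stages: dict = field(
        default_factory=lambda: {
            "qc": True,
            "kinship": True,
            "inbreeding": True,
            "hbd": True,
            "rim": True,
            "report": True,
        }
    )
    qc: dict = field(
        default_factory=lambda: {"maf": 0.05, "max_missing": 0.10}
    )
    kinship: dict = field(
        default_factory=lambda: {"phi_cutoff": 0.08, "age_gap": 18}
    )
    inbreeding: dict = field(
        default_factory=lambda: {
            "min_snps": 20,
            "min_length_kb": 100,
            "max_missing_in_roh": 1,
        }
    )
    hbd: dict = field(default_factory=lambda: {"error": 0.001, "tol": 1e-6})
    rim: dict = field(
        default_factory=lambda: {
            "maf_thresholds": list(DEFAULT_MAF_THRESHOLDS),
            "n_random": 100,
            "max_missing": 0.05,
            "r2": 0.2,
        }
    )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        on = {s for s in STAGES if self.stages.get(s, False)}
        for s in ("kinship", "inbreeding", "hbd", "rim"):
            if s in on and not self.stages.get("qc", False):
                raise ConfigError(f"stage {s!r} requires stage 'qc'")
        if "rim" in on and "kinship" not in on:
            raise ConfigError("stage 'rim' requires stage 'kinship'")
        if self.vcf is None and self.simulate is None:
            raise ConfigError("either an input VCF or a simulate block is required")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stage-name-hashed seed below 2**31."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "seed": cfg.seed,
            "stages": {},
        }
        self.log_path = self.out / "run.log"
        self.log_fh = self.log_path.open("a")

    def log(self, stage: str, event: str, **kv) -> None:
        rec = {"t": time.time(), "stage": stage, "event": event, **kv}
        self.log_fh.write(json.dumps(rec) + "\n")
        self.log_fh.flush()

    def register(self, stage: str, params: dict, files: list) -> None:
        self.manifest["stages"][stage] = {
            "params": params,
            "files": {
                str(p.relative_to(self.out)): _sha256(p) for p in files
            },
        }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the manifest."""
    cfg.validate()
    run = _Run(cfg)
    out = run.out
    (out / "config.json").write_text(
        json.dumps(
            {"config": dataclasses.asdict(cfg), "version": __version__},
            indent=2,
            sort_keys=True,
        )
    )
    current = "setup"
    try:
        # ---- input: simulate or load -------------------------------------
        if cfg.vcf is None:
            current = "simulate"
            run.log(current, "start")
            sim_cfg = SimConfig(
                **{**cfg.simulate, "seed": stage_seed(cfg.seed, "simulate")}
            )
            sim = simulate_dataset(sim_cfg)
            G, meta, layout = sim.genotypes, sim.meta, sim.layout
            write_vcf(G, out / "genotypes.vcf", layout,
                      header_extra=[f"simulation_seed={sim_cfg.seed}"])
            write_metadata(meta, out / "metadata.tsv")
            write_layout(layout, out / "layout.tsv")
            private = out / "private"
            private.mkdir(exist_ok=True)
            sim.pedigree.truth.to_csv(private / "truth.tsv", sep="\t", index=False)
            run.register(
                "simulate",
                dataclasses.asdict(sim_cfg),
                [out / "genotypes.vcf", out / "metadata.tsv", out / "layout.tsv"],
            )
            run.log(current, "done", n_samples=G.n_samples, n_markers=G.n_markers)
            truth_pedigree = sim.pedigree
        else:
            layout = read_layout(cfg.layout) if cfg.layout else None
            G = read_vcf(cfg.vcf, layout=layout)
            meta = read_metadata(cfg.metadata) if cfg.metadata else []
            truth_pedigree = None

        # ---- qc ----------------------------------------------------------
        if cfg.stages.get("qc"):
            current = "qc"
            run.log(current, "start")
            before = G.n_markers
            G = filter_markers(
                G, maf_min=cfg.qc["maf"], max_missing_rate=cfg.qc["max_missing"]
            )
            write_vcf(G, out / "qc_genotypes.vcf", layout)
            (out / "qc_stats.json").write_text(
                json.dumps(
                    {"markers_in": before, "markers_out": G.n_markers},
                    sort_keys=True,
                )
            )
            run.register(
                "qc", dict(cfg.qc), [out / "qc_genotypes.vcf", out / "qc_stats.json"]
            )
            run.log(current, "done", markers=G.n_markers)

        kin = None
        # ---- kinship -----------------------------------------------------
        if cfg.stages.get("kinship"):
            current = "kinship"
            run.log(current, "start")
            kin = kinship_matrix(G)
            kin.to_csv(out / "kin_table.tsv", sep="\t", index=False, float_format="%.6g")
            degree_counts(kin).rename("n_pairs").to_csv(
                out / "degree_counts.tsv", sep="\t", header=True
            )
            pairs, sire_counts, skipped = infer_paternity(
                kin, meta, age_gap_years=cfg.kinship["age_gap"]
            )
            pairs.to_csv(out / "paternity_pairs.tsv", sep="\t", index=False,
                         float_format="%.6g")
            sire_counts.rename("n_offspring").to_csv(
                out / "sire_counts.tsv", sep="\t", header=True
            )
            verify_maternal_links(kin, meta).to_csv(
                out / "maternal_check.tsv", sep="\t", index=False, float_format="%.6g"
            )
            kept = unrelated_subset(kin, cfg.kinship["phi_cutoff"], meta)
            (out / "unrelated_subset.txt").write_text("\n".join(kept) + "\n")
            run.register(
                "kinship",
                dict(cfg.kinship),
                [
                    out / "kin_table.tsv",
                    out / "degree_counts.tsv",
                    out / "paternity_pairs.tsv",
                    out / "sire_counts.tsv",
                    out / "maternal_check.tsv",
                    out / "unrelated_subset.txt",
                ],
            )
            run.log(current, "done", n_pairs=len(kin), n_paternity=len(pairs),
                    n_skipped=len(skipped))

        # ---- inbreeding --------------------------------------------------
        if cfg.stages.get("inbreeding"):
            current = "inbreeding"
            run.log(current, "start")
            if layout is None:
                raise ConfigError("inbreeding stage needs a genome layout")
            params = RohParams(
                min_snps=cfg.inbreeding["min_snps"],
                min_length_bp=int(cfg.inbreeding["min_length_kb"] * 1000),
                max_missing_in_run=cfg.inbreeding["max_missing_in_roh"],
            )
            ho = observed_heterozygosity(G)
            segs = detect_roh(G, layout, params)
            f = froh(segs, layout, sample_ids=G.sample_ids)
            div = pd.DataFrame({"Ho": ho, "F_ROH": f})
            div.to_csv(out / "diversity.tsv", sep="\t", float_format="%.6g")
            segs.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
            tests = _group_tests(div, meta)
            tests.to_csv(out / "group_tests.tsv", sep="\t", index=False,
                         float_format="%.6g")
            run.register(
                "inbreeding",
                dataclasses.asdict(params),
                [out / "diversity.tsv", out / "roh_segments.tsv", out / "group_tests.tsv"],
            )
            run.log(current, "done", n_segments=len(segs))

        # ---- hbd ---------------------------------------------------------
        if cfg.stages.get("hbd"):
            current = "hbd"
            run.log(current, "start")
            freqs = np.nan_to_num(allele_frequencies(G), nan=0.5)
            model = hbd_mod.HbdModel(error=cfg.hbd["error"])
            table = hbd_mod.fit_samples(G, freqs, model, tol=cfg.hbd["tol"])
            table.to_csv(out / "hbd_fractions.tsv", sep="\t", index=False,
                         float_format="%.6g")
            run.register("hbd", dict(cfg.hbd), [out / "hbd_fractions.tsv"])
            run.log(current, "done", n_samples=len(table))

        # ---- rim ---------------------------------------------------------
        if cfg.stages.get("rim"):
            current = "rim"
            run.log(current, "start")
            report = evaluate_panels(
                G,
                maf_thresholds=tuple(cfg.rim["maf_thresholds"]),
                n_random=cfg.rim["n_random"],
                seed=stage_seed(cfg.seed, "rim"),
                reference_kin=kin,
                max_missing=cfg.rim["max_missing"],
                r2_max=cfg.rim["r2"],
            )
            report.to_csv(out / "rim_report.tsv", sep="\t", index=False,
                          float_format="%.6g")
            files = [out / "rim_report.tsv"]
            for thr in cfg.rim["maf_thresholds"]:
                panel = select_rim(
                    G, thr, max_missing=cfg.rim["max_missing"], r2_max=cfg.rim["r2"]
                )
                pfile = out / f"rim_panel_maf{int(round(thr * 100)):02d}.txt"
                pfile.write_text("\n".join(map(str, panel.marker_ids)) + "\n")
                side = out / (pfile.stem + ".json")
                side.write_text(
                    json.dumps(
                        {
                            "maf_threshold": thr,
                            "size": panel.size,
                            "source_markers": G.n_markers,
                        },
                        sort_keys=True,
                    )
                )
                files.extend([pfile, side])
            run.register("rim", dict(cfg.rim), files)
            run.log(current, "done")

        # ---- report ------------------------------------------------------
        if cfg.stages.get("report"):
            current = "report"
            run.log(current, "start")
            _write_manifest(run)
            make_report(out)
            run.register("report", {}, [out / "report.json"])
            run.log(current, "done")

        _write_manifest(run)
        return run.manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={current}\nerror={exc}\n")
        run.log(current, "failed", error=str(exc))
        raise
    finally:
        run.log_fh.close()


def _write_manifest(run: _Run) -> None:
    (run.out / "manifest.json").write_text(
        json.dumps(run.manifest, indent=2, sort_keys=True)
    )


def _group_tests(div: pd.DataFrame, meta) -> pd.DataFrame:
    """Origin (wilcoxon) and decade-of-birth (ANOVA) comparisons for Ho
    and F_ROH, where group sizes allow."""
    by = meta_by_id(meta)
    origin = np.array(
        [by[s].origin if s in by else "unknown" for s in div.index]
    )
    decade = np.array(
        [
            (by[s].birth_year // 10 * 10) if s in by and by[s].birth_year else -1
            for s in div.index
        ]
    )
    rows = []
    wc_mask = np.isin(origin, ("wild", "captive"))
    for col in ("Ho", "F_ROH"):
        vals = div[col].to_numpy()
        if len(set(origin[wc_mask])) == 2:
            stat, p = compare_groups(vals[wc_mask], origin[wc_mask], "wilcoxon")
            rows.append(
                {"variable": col, "grouping": "origin", "test": "wilcoxon",
                 "statistic": stat, "p_value": p}
            )
        ok = decade >= 0
        counts = pd.Series(decade[ok]).value_counts()
        good = counts[counts >= 2].index
        sel = ok & np.isin(decade, good)
        if len(set(decade[sel])) >= 2:
            stat, p = compare_groups(vals[sel], decade[sel], "anova")
            rows.append(
                {"variable": col, "grouping": "decade", "test": "anova",
                 "statistic": stat, "p_value": p}
            )
    return pd.DataFrame(
        rows, columns=["variable", "grouping", "test", "statistic", "p_value"]
    )


def make_report(outdir) -> dict:
    """Aggregate stage outputs (no recomputation) into report.json.

    Deterministic given the manifest and stage files, so re-rendering
    reproduces the report byte-for-byte.
    """
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    report: dict = {"seed": manifest["seed"], "version": manifest["version"]}
    stages = manifest["stages"]

    def need(stage, fname) -> Path:
        if stage in stages and fname not in stages[stage]["files"]:
            raise FileNotFoundError(f"{fname} missing from stage {stage}")
        return out / fname

    if "kinship" in stages:
        kin = pd.read_csv(need("kinship", "kin_table.tsv"), sep="\t")
        dc = pd.read_csv(need("kinship", "degree_counts.tsv"), sep="\t", index_col=0)
        pat = pd.read_csv(need("kinship", "paternity_pairs.tsv"), sep="\t")
        sires = pd.read_csv(need("kinship", "sire_counts.tsv"), sep="\t", index_col=0)
        report["kinship"] = {
            "n_pairs": int(len(kin)),
            "degree_counts": {k: int(v) for k, v in dc["n_pairs"].items()},
            "n_father_offspring_pairs": int(len(pat)),
            "top_sires": {str(k): int(v) for k, v in
                          sires["n_offspring"].head(5).items()},
        }
    if "inbreeding" in stages:
        div = pd.read_csv(need("inbreeding", "diversity.tsv"), sep="\t")
        segs = pd.read_csv(need("inbreeding", "roh_segments.tsv"), sep="\t")
        report["inbreeding"] = {
            "n_samples": int(len(div)),
            "mean_Ho": float(div["Ho"].mean()) if len(div) else None,
            "mean_F_ROH": float(div["F_ROH"].mean()) if len(div) else None,
            "n_roh_segments": int(len(segs)),
        }
    if "hbd" in stages:
        tab = pd.read_csv(need("hbd", "hbd_fractions.tsv"), sep="\t")
        frac_cols = [c for c in tab.columns if c.startswith("hbd_") or c == "non_hbd"]
        report["hbd"] = {
            "n_samples": int(len(tab)),
            "mean_class_fractions": {
                c: float(tab[c].mean()) for c in frac_cols
            },
        }
    if "rim" in stages:
        rep = pd.read_csv(need("rim", "rim_report.tsv"), sep="\t")
        report["rim"] = rep.to_dict(orient="records")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    summary = []
    for stage in stages:
        for fname in stages[stage]["files"]:
            p = out / fname
            n_lines = sum(1 for _ in p.open()) if p.suffix in (".tsv", ".txt") else ""
            summary.append({"stage": stage, "file": fname, "lines": n_lines})
    pd.DataFrame(summary, columns=["stage", "file", "lines"]).to_csv(
        out / "summary.tsv", sep="\t", index=False
    )
    return report
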