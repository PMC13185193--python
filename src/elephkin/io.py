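"""Readers and writers for the standard formats the pipeline consumes.

VCF parsing is delegated to cyvcf2; PED/MAP and the sample-metadata TSV are
simple columnar text handled here.  Writers exist so simulated datasets can
round-trip through the same readers real data would use.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    GenomeLayout,
    GenotypeMatrix,
    MarkerMap,
    SampleMeta,
)

_SEX = {"m": "male", "male": "male", "f": "female", "female": "female"}
_ORIGIN = {"wild": "wild", "captive": "captive"}


def read_vcf(
    path,
    skip_multiallelic: bool = True,
    layout: Optional[GenomeLayout] = None,
) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into a dosage matrix.

    Dosage is the alt-allele count; any non-diploid or partially missing
    genotype maps to MISSING.  Multi-allelic records are skipped when
    *skip_multiallelic* is true, otherwise rejected.  When *layout* is
    given, markers on its flagged sex chromosomes are dropped on load.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    if len(samples) == 0:
        raise ValueError(f"{path}: VCF contains no samples")
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicated sample ids")

    chroms, poss, refs, alts, ids, rows = [], [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            if skip_multiallelic:
                continue
            raise ValueError(f"{path}: multi-allelic record at {v.CHROM}:{v.POS}")
        # gts012: 0/1/2 dosage, 3 = unknown (missing or partial)
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    calls = np.stack(rows, axis=1)
    mm = MarkerMap(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.array(ids, dtype=object),
    )
    G = GenotypeMatrix(samples, calls, mm)
    if layout is not None and layout.sex_chromosomes:
        G = G.drop_sex_chromosomes(layout)
    return G


def write_vcf(
    G: GenotypeMatrix, path, layout: Optional[GenomeLayout] = None, header_extra=()
) -> None:
    """Write a dosage matrix as a minimal diploid GT-only VCF."""
    path = Path(path)
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for line in header_extra:
            fh.write(f"##{line}\n")
        if layout is not None:
            for c, l in layout.lengths.items():
                fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        m = G.markers
        for j in range(G.n_markers):
            cells = "\t".join(gt[int(x)] for x in G.calls[:, j])
            fh.write(
                f"{m.chrom[j]}\t{m.pos[j]}\t{m.ids[j]}\t{m.ref[j]}\t{m.alt[j]}"
                f"\t.\t.\t.\tGT\t{cells}\n"
            )


def read_plink_text(prefix) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a dosage matrix.

    A 6-column MAP (chrom, id, cM, pos, ref, alt) declares the alleles; with
    the standard 4-column MAP the alt allele is inferred as the minor
    observed allele (tie broken to the lexicographically larger).  `0 0`
    maps to MISSING; a marker showing more than two alleles is an error.
    """
    prefix = str(prefix)
    ped_path, map_path = Path(prefix + ".ped"), Path(prefix + ".map")
    map_rows = [l.split() for l in map_path.read_text().splitlines() if l.strip()]
    n_markers = len(map_rows)
    declared = all(len(r) >= 6 for r in map_rows)

    sample_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    for line in ped_path.read_text().splitlines():
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6 + 2 * n_markers:
            raise ValueError(
                f"{ped_path}: PED line has {len(f)} fields, "
                f"expected {6 + 2 * n_markers} for {n_markers} MAP markers"
            )
        sample_ids.append(f[1])
        allele_rows.append(
            [(f[6 + 2 * j], f[7 + 2 * j]) for j in range(n_markers)]
        )
    if not sample_ids:
        raise ValueError(f"{ped_path}: no samples")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{ped_path}: duplicated sample ids")

    calls = np.full((len(sample_ids), n_markers), MISSING, dtype=np.int8)
    refs, alts = [], []
    for j, row in enumerate(map_rows):
        seen = sorted(
            {a for s in allele_rows for a in s[j] if a != "0"}
        )
        if len(seen) > 2:
            raise ValueError(f"marker {row[1]}: more than two alleles observed")
        if declared:
            ref, alt = row[4], row[5]
        else:
            if len(seen) == 2:
                # minor observed allele is alt; tie -> lexicographically larger
                counts = {a: 0 for a in seen}
                for s in allele_rows:
                    for a in s[j]:
                        if a != "0":
                            counts[a] += 1
                if counts[seen[0]] == counts[seen[1]]:
                    alt = max(seen)
                else:
                    alt = min(seen, key=counts.get)
                ref = [a for a in seen if a != alt][0]
            elif len(seen) == 1:
                ref, alt = seen[0], "."
            else:
                ref, alt = ".", "."
        refs.append(ref)
        alts.append(alt)
        for i, s in enumerate(allele_rows):
            a1, a2 = s[j]
            if a1 == "0" or a2 == "0":
                continue
            if {a1, a2} - {ref, alt}:
                raise ValueError(
                    f"marker {row[1]}: allele outside declared {ref}/{alt}"
                )
            calls[i, j] = (a1 == alt) + (a2 == alt)

    mm = MarkerMap(
        np.array([r[0] for r in map_rows], dtype=object),
        np.array([int(r[3]) for r in map_rows], dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.array([r[1] for r in map_rows], dtype=object),
    )
    return GenotypeMatrix(sample_ids, calls, mm)


def write_plink_text(G: GenotypeMatrix, prefix) -> None:
    """Write PED plus a 6-column MAP (alleles appended) for round-trips."""
    prefix = str(prefix)
    m = G.markers
    with open(prefix + ".map", "w") as fh:
        for j in range(G.n_markers):
            fh.write(
                f"{m.chrom[j]}\t{m.ids[j]}\t0\t{m.pos[j]}\t{m.ref[j]}\t{m.alt[j]}\n"
            )
    code = {
        0: lambda r, a: (r, r),
        1: lambda r, a: (r, a),
        2: lambda r, a: (a, a),
        MISSING: lambda r, a: ("0", "0"),
    }
    with open(prefix + ".ped", "w") as fh:
        for i, s in enumerate(G.sample_ids):
            cells = []
            for j in range(G.n_markers):
                a1, a2 = code[int(G.calls[i, j])](m.ref[j], m.alt[j])
                cells.append(f"{a1} {a2}")
            fh.write(f"{s} {s} 0 0 0 -9 " + " ".join(cells) + "\n")


def read_metadata(path) -> list[SampleMeta]:
    """Read the sample-metadata table (TSV or CSV).

    Required columns: sample_id, sex, birth_year, origin, camp, dam_id.
    Optional: birth_year_approx.  Blanks map to unknown/absent.
    """
    path = Path(path)
    text = path.read_text()
    header = text.splitlines()[0]
    sep = "\t" if "\t" in header else ","
    out: list[SampleMeta] = []
    seen: set[str] = set()
    reader = csv.DictReader(text.splitlines(), delimiter=sep)
    required = {"sample_id", "sex", "birth_year", "origin", "camp", "dam_id"}
    missing_cols = required - set(reader.fieldnames or ())
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    for row in reader:
        sid = (row["sample_id"] or "").strip()
        if not sid:
            raise ValueError(f"{path}: blank sample_id")
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        by_raw = (row["birth_year"] or "").strip()
        if by_raw in ("", "NA"):
            birth_year = None
        else:
            try:
                birth_year = int(by_raw)
            except ValueError:
                raise ValueError(f"{path}: malformed birth_year {by_raw!r}") from None
        approx_raw = (row.get("birth_year_approx") or "").strip().lower()
        dam = (row["dam_id"] or "").strip() or None
        out.append(
            SampleMeta(
                sample_id=sid,
                sex=_SEX.get((row["sex"] or "").strip().lower(), "unknown"),
                birth_year=birth_year,
                birth_year_approx=approx_raw in ("1", "true", "yes"),
                origin=_ORIGIN.get((row["origin"] or "").strip().lower(), "unknown"),
                camp=(row["camp"] or "").strip(),
                dam_id=dam,
            )
        )
    return out


def write_metadata(meta: Sequence[SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "sex": m.sex,
            "birth_year": "" if m.birth_year is None else m.birth_year,
            "birth_year_approx": int(m.birth_year_approx),
            "origin": m.origin,
            "camp": m.camp,
            "dam_id": m.dam_id or "",
        }
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def meta_by_id(meta: Sequence[SampleMeta]) -> dict[str, SampleMeta]:
    return {m.sample_id: m for m in meta}


def read_layout(path) -> GenomeLayout:
    """Read a chromosome-length TSV (chrom, length_bp[, sex])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sex = set()
    if "sex" in df.columns:
        sex = set(df.loc[df["sex"].astype(int) == 1, "chrom"])
    return GenomeLayout(
        dict(zip(df["chrom"], df["length_bp"].astype(int))), frozenset(sex)
    )


def write_layout(layout: GenomeLayout, path) -> None:
    rows = [
        {"chrom": c, "length_bp": l, "sex": int(c in layout.sex_chromosomes)}
        for c, l in layout.lengths.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
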