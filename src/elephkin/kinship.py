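"""KING-robust kinship, degree classification, unrelated-subset selection,
maternal-link verification and the father-offspring inference rule.

The KING-robust moment estimator works from genotype counting statistics
over pairwise-complete markers:

    phi = (N_both_het - 2 * N_opposite_hom) / (N_het_a + N_het_b)

It is robust to population structure because it conditions on the pair's
own heterozygosity rather than on population allele frequencies.  Two
scales appear downstream: the kinship coefficient phi (parent-offspring
~0.25) and relatedness r = 2*phi (parent-offspring ~0.5).  Degree
classification operates on r; the unrelated-subset pruning cutoff (0.08)
operates on phi — the only reading under which both sets of conventional
thresholds select the intended relative classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, SampleMeta
from .simulate import Pedigree

DEGREE_FIRST = "first"
DEGREE_SECOND = "second"
DEGREE_THIRD_FOURTH = "third_fourth"
DEGREE_UNRELATED = "unrelated"
DEGREE_UNDEFINED = "undefined"


@dataclass
class KinshipResult:
    id_a: str
    id_b: str
    n_shared: int
    n_both_het: int
    n_opp_hom: int
    n_het_a: int
    n_het_b: int
    phi: float  # NaN when undefined
    r: float  # = 2 * phi
    degree: str


def classify_degree(r: float) -> str:
    """Bin relatedness r into the conventional degree classes.

    r > 0.45 first degree; 0.25 <= r <= 0.45 second degree;
    0.125 <= r < 0.25 third/fourth degree (e.g. first cousins);
    r < 0.125 unrelated.  NaN is undefined.
    """
    if np.isnan(r):
        return DEGREE_UNDEFINED
    if r > 0.45:
        return DEGREE_FIRST
    if r >= 0.25:
        return DEGREE_SECOND
    if r >= 0.125:
        return DEGREE_THIRD_FOURTH
    return DEGREE_UNRELATED


def _pair_counts(calls: np.ndarray):
    """All-pairs counting statistics via four matrix products.

    float32 accumulation is exact here: every product is 0/1 and every
    count is far below 2**24.
    """
    het = (calls == 1).astype(np.float32)
    hom0 = (calls == 0).astype(np.float32)
    hom2 = (calls == 2).astype(np.float32)
    obs = (calls != MISSING).astype(np.float32)
    n_shared = obs @ obs.T
    n_both_het = het @ het.T
    x = hom0 @ hom2.T
    n_opp = x + x.T
    het_in_shared = het @ obs.T  # [a, b] = het calls of a over markers seen by both
    return n_shared, n_both_het, n_opp, het_in_shared


def king_robust(G: GenotypeMatrix, a: str, b: str) -> KinshipResult:
    """KING-robust kinship for one pair."""
    if a == b:
        raise ValueError("a and b must differ")
    ia, ib = G.sample_index(a), G.sample_index(b)
    ga, gb = G.calls[ia], G.calls[ib]
    ok = (ga != MISSING) & (gb != MISSING)
    if not ok.any():
        raise ValueError(f"no pairwise-complete markers for {a}, {b}")
    ga, gb = ga[ok], gb[ok]
    n_both_het = int(((ga == 1) & (gb == 1)).sum())
    n_opp = int((((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))).sum())
    n_het_a = int((ga == 1).sum())
    n_het_b = int((gb == 1).sum())
    denom = n_het_a + n_het_b
    phi = (n_both_het - 2.0 * n_opp) / denom if denom > 0 else float("nan")
    r = 2.0 * phi
    return KinshipResult(
        a, b, int(ok.sum()), n_both_het, n_opp, n_het_a, n_het_b, phi, r,
        classify_degree(r),
    )


def kinship_matrix(G: GenotypeMatrix) -> pd.DataFrame:
    """All n*(n-1)/2 pairwise KING-robust kinships as a table.

    Columns: id_a, id_b, n_shared, n_both_het, n_opp_hom, n_het_a, n_het_b,
    phi, r, degree.  phi is NaN (degree 'undefined') where the pair has no
    heterozygous calls over shared markers.
    """
    n = G.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    n_shared, n_both_het, n_opp, het_sh = _pair_counts(G.calls)
    iu, ju = np.triu_indices(n, k=1)
    denom = het_sh[iu, ju] + het_sh[ju, iu]
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(
            denom > 0, (n_both_het[iu, ju] - 2.0 * n_opp[iu, ju]) / denom, np.nan
        )
    ids = np.asarray(G.sample_ids, dtype=object)
    r = 2.0 * phi
    return pd.DataFrame(
        {
            "id_a": ids[iu],
            "id_b": ids[ju],
            "n_shared": n_shared[iu, ju].astype(np.int64),
            "n_both_het": n_both_het[iu, ju].astype(np.int64),
            "n_opp_hom": n_opp[iu, ju].astype(np.int64),
            "n_het_a": het_sh[iu, ju].astype(np.int64),
            "n_het_b": het_sh[ju, iu].astype(np.int64),
            "phi": phi,
            "r": r,
            "degree": [classify_degree(x) for x in r],
        }
    )


def degree_counts(kin: pd.DataFrame) -> pd.Series:
    """Pair counts per degree class (the headline degree-bin summary)."""
    order = [
        DEGREE_FIRST,
        DEGREE_SECOND,
        DEGREE_THIRD_FOURTH,
        DEGREE_UNRELATED,
        DEGREE_UNDEFINED,
    ]
    c = kin["degree"].value_counts()
    return pd.Series({k: int(c.get(k, 0)) for k in order})


def unrelated_subset(
    kin: pd.DataFrame,
    phi_cutoff: float = 0.08,
    meta: Optional[Sequence[SampleMeta]] = None,
) -> list:
    """Greedy selection of a subset with no pair at phi >= cutoff.

    Iteratively removes the sample involved in the most surviving kin
    pairs; ties are broken toward the sample whose camp is currently most
    represented among survivors (preserving rare camps), then
    lexicographically (largest id removed).  The output is exhaustively
    verified pair-free before returning.
    """
    camp = {m.sample_id: m.camp for m in meta} if meta else {}
    samples = sorted(set(kin["id_a"]).union(kin["id_b"]).union(camp))
    over = kin[kin["phi"] >= phi_cutoff]
    edges = {
        frozenset((a, b)) for a, b in zip(over["id_a"], over["id_b"])
    }
    alive = set(samples)

    def live_edges():
        return [e for e in edges if e <= alive]

    while True:
        cur = live_edges()
        if not cur:
            break
        deg: dict[str, int] = {}
        for e in cur:
            for v in e:
                deg[v] = deg.get(v, 0) + 1
        mx = max(deg.values())
        cand = sorted(v for v, d in deg.items() if d == mx)
        if len(cand) > 1 and camp:
            rep: dict[str, int] = {}
            for v in alive:
                c = camp.get(v, "")
                rep[c] = rep.get(c, 0) + 1
            best = max(rep.get(camp.get(v, ""), 0) for v in cand)
            cand = [v for v in cand if rep.get(camp.get(v, ""), 0) == best]
        alive.discard(cand[-1])  # remaining ties: drop lexicographically last

    kept = sorted(alive)
    # postcondition: no surviving pair at/above the cutoff
    kept_set = set(kept)
    bad = over[over["id_a"].isin(kept_set) & over["id_b"].isin(kept_set)]
    assert bad.empty, "unrelated_subset postcondition violated"
    return kept


def _maternal_ancestors(sample_id: str, dam_of: dict) -> set:
    """Recorded maternal ancestor chain, including self."""
    seen = {sample_id}
    cur = dam_of.get(sample_id)
    while cur is not None and cur not in seen:
        seen.add(cur)
        cur = dam_of.get(cur)
    return seen


def infer_paternity(
    kin: pd.DataFrame,
    meta: Sequence[SampleMeta],
    age_gap_years: int = 18,
    degree: str = DEGREE_FIRST,
):
    """Father-offspring inference from first-degree pairs.

    A pair is emitted as (sire, offspring) when: the pair is first degree;
    the older member is male; the birth-year gap strictly exceeds
    *age_gap_years*; and the recorded (matrilineal) pedigree shows no
    relation between the two — no shared recorded dam and no recorded
    maternal ancestor in common.  Pairs missing birth years are skipped and
    reported.  Returns (pairs DataFrame, per-sire offspring counts Series,
    skipped pair list).
    """
    by_id = {m.sample_id: m for m in meta}
    dam_of = {m.sample_id: m.dam_id for m in meta}
    rows, skipped = [], []
    for t in kin.itertuples():
        if t.degree != degree:
            continue
        ma, mb = by_id.get(t.id_a), by_id.get(t.id_b)
        if ma is None or mb is None or ma.birth_year is None or mb.birth_year is None:
            skipped.append((t.id_a, t.id_b))
            continue
        older, younger = (ma, mb) if ma.birth_year <= mb.birth_year else (mb, ma)
        if older.sex != "male":
            continue
        gap = younger.birth_year - older.birth_year
        if gap <= age_gap_years:  # "exceeded" is strict
            continue
        anc_a = _maternal_ancestors(older.sample_id, dam_of)
        anc_b = _maternal_ancestors(younger.sample_id, dam_of)
        if anc_a & anc_b:
            continue
        rows.append(
            {
                "sire_id": older.sample_id,
                "offspring_id": younger.sample_id,
                "phi": t.phi,
                "r": t.r,
                "age_gap": gap,
                "birth_year_approx": older.birth_year_approx
                or younger.birth_year_approx,
            }
        )
    pairs = pd.DataFrame(
        rows,
        columns=["sire_id", "offspring_id", "phi", "r", "age_gap", "birth_year_approx"],
    )
    counts = (
        pairs.groupby("sire_id").size().sort_values(ascending=False)
        if len(pairs)
        else pd.Series(dtype=np.int64)
    )
    return pairs, counts, skipped


def verify_maternal_links(kin: pd.DataFrame, meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Annotate every recorded dam-offspring pair with its genomic
    relatedness; pairs not classified first degree are flagged discordant.

    Recorded dams absent from the kinship table (not genotyped) are
    reported with NaN and not flagged.
    """
    key = {}
    for t in kin.itertuples():
        key[(t.id_a, t.id_b)] = t
        key[(t.id_b, t.id_a)] = t
    rows = []
    for m in meta:
        if not m.dam_id:
            continue
        t = key.get((m.dam_id, m.sample_id))
        if t is None:
            rows.append(
                {
                    "dam_id": m.dam_id,
                    "offspring_id": m.sample_id,
                    "phi": np.nan,
                    "r": np.nan,
                    "degree": "not_genotyped",
                    "discordant": False,
                }
            )
            continue
        rows.append(
            {
                "dam_id": m.dam_id,
                "offspring_id": m.sample_id,
                "phi": t.phi,
                "r": t.r,
                "degree": t.degree,
                "discordant": t.degree != DEGREE_FIRST,
            }
        )
    return pd.DataFrame(
        rows, columns=["dam_id", "offspring_id", "phi", "r", "degree", "discordant"]
    )


def paternity_recovery(
    pairs: pd.DataFrame, pedigree: Pedigree, genotyped_ids: Sequence[str]
):
    """Score inferred father-offspring pairs against the hidden truth table.

    Sensitivity is computed over truth pairs whose sire was genotyped (an
    unsampled wild sire cannot be recovered by any method).  Returns
    (sensitivity, n_true_recoverable, n_recovered_true, false_positives).
    """
    genotyped = set(genotyped_ids)
    truth_pairs = {
        (t.true_sire_id, t.sample_id)
        for t in pedigree.truth.itertuples()
        if t.true_sire_id in genotyped and t.sample_id in genotyped
    }
    inferred = {(p.sire_id, p.offspring_id) for p in pairs.itertuples()}
    tp = inferred & truth_pairs
    fp = inferred - truth_pairs
    sens = len(tp) / len(truth_pairs) if truth_pairs else float("nan")
    return sens, len(truth_pairs), len(tp), sorted(fp)
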