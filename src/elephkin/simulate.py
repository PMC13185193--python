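"""Synthetic pedigree and genotype simulator.

Emulates the study design the analyses assume: a timber-camp population of
wild-captured founders plus captive-born descendants, unsupervised mating in
which sires are drawn from a male pool (camp bulls and unsampled wild bulls)
with controllable reproductive skew, a pedigree that records dams only
(matrilineal visibility), Mendelian transmission with Poisson-count
crossovers on a 1 cM/Mb map, and post-hoc genotyping error and missingness.

Founders are simulated in Hardy-Weinberg and linkage equilibrium; the LD
that downstream stages see arises from pedigree structure, which is exactly
what LD pruning and marker-panel selection need to be exercised against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenomeLayout, GenotypeMatrix, MarkerMap, SampleMeta

_DEFAULT_CAMPS = (
    ("Kawlin", 0.49),
    ("East_Katha", 0.20),
    ("West_Katha", 0.15),
    ("Mawlaik", 0.05),
    ("Katha_South", 0.04),
    ("Shwebo", 0.03),
    ("Pinlebu", 0.02),
    ("Wuntho", 0.02),
)


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    The defaults mirror the study population: 261 genotyped individuals of
    whom 54 are wild-captured founders (34 females, 20 bulls), captive
    recruitment over ~3 generations, additional unsampled wild bulls in the
    sire pool, 13,000 markers on 10 autosomes, and a sire-skew exponent that
    concentrates paternity in a handful of bulls.
    """

    n_founder_females: int = 34
    n_founder_males: int = 20
    n_wild_males: int = 14  # wild bulls that sire but are never sampled
    n_samples: int = 261  # genotyped individuals (founders + captive-born)
    n_generations: int = 3
    offspring_per_female: float = 1.5  # Poisson mean per eligible female/generation
    sire_skew: float = 1.0  # sire weight exponent; 0 = uniform paternity
    generation_gap_years: int = 15
    min_sire_age_years: int = 20
    maturity_age_years: int = 15
    max_dam_age_years: int = 50
    max_sire_age_years: int = 60
    n_chromosomes: int = 10
    chromosome_length_bp: int = 120_000_000
    n_markers: int = 13_000
    founder_freq_low: float = 0.05
    founder_freq_high: float = 0.5
    # "random": uniform positions (restriction-site-like, the RADseq shape);
    # "even": constant spacing (array/WGS-like; gives exact density semantics
    # for run-of-homozygosity experiments)
    marker_placement: str = "random"
    error_rate: float = 0.005
    missing_rate: float = 0.02
    # Elephants avoid close-kin matings (chemosensory kin recognition);
    # with this on, sires never share a matriline with the dam, nor any
    # true ancestor within two generations.
    avoid_kin_matings: bool = True
    camps: tuple = _DEFAULT_CAMPS
    cM_per_Mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_founder_females",
            "n_founder_males",
            "n_wild_males",
            "n_generations",
            "n_chromosomes",
            "n_markers",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("error_rate", "missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PedRecord:
    sample_id: str
    sex: str
    birth_year: int
    birth_year_approx: bool
    origin: str  # wild / captive
    camp: str
    dam_id: Optional[str]  # recorded (visible) dam; None for wild-born
    sampled: bool = True


@dataclass
class Pedigree:
    """Visible pedigree records plus the hidden parental truth table.

    The visible records carry recorded dams only (matrilineal visibility,
    as in camp log books).  ``truth`` holds the simulator's true sire and
    dam per captive birth; writers of visible metadata must never emit it.
    """

    records: list
    truth: pd.DataFrame  # columns: sample_id, true_sire_id, true_dam_id

    def __post_init__(self) -> None:
        by_id = {r.sample_id: r for r in self.records}
        if len(by_id) != len(self.records):
            raise ValueError("duplicate pedigree ids")
        for r in self.records:
            if r.origin == "wild" and r.dam_id is not None:
                raise ValueError("wild-origin record with a recorded parent")
            if r.dam_id is not None:
                dam = by_id.get(r.dam_id)
                if dam is None:
                    raise ValueError(f"{r.sample_id}: dam {r.dam_id} not in pedigree")
                if dam.birth_year >= r.birth_year:
                    raise ValueError(f"{r.sample_id}: dam not born earlier")

    def record(self, sample_id: str) -> PedRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def sampled_ids(self) -> list:
        return [r.sample_id for r in self.records if r.sampled]

    def to_metadata(self) -> list:
        """Visible per-sample metadata (no sire information)."""
        return [
            SampleMeta(
                sample_id=r.sample_id,
                sex=r.sex,
                birth_year=r.birth_year,
                birth_year_approx=r.birth_year_approx,
                origin=r.origin,
                camp=r.camp,
                dam_id=r.dam_id,
            )
            for r in self.records
            if r.sampled
        ]


@dataclass
class FounderPool:
    """Phased founder haplotypes (founder x 2 x marker, allele 0/1)."""

    haplotypes: np.ndarray  # int8, (n_founders, 2, n_markers)
    alt_freq: np.ndarray  # the frequencies the alleles were drawn from
    markers: MarkerMap
    layout: GenomeLayout


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _marker_positions(cfg: SimConfig, rng: np.random.Generator):
    chroms, poss = [], []
    per = [cfg.n_markers // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_markers % cfg.n_chromosomes):
        per[i] += 1
    for c in range(cfg.n_chromosomes):
        name = f"chr{c + 1}"
        want = per[c]
        if cfg.marker_placement == "even" and want > 0:
            spacing = cfg.chromosome_length_bp / (want + 1)
            pos = (spacing * np.arange(1, want + 1)).astype(np.int64)
        else:
            pos = np.array([], dtype=np.int64)
            while len(pos) < want:
                extra = rng.integers(1, cfg.chromosome_length_bp + 1, size=want * 2)
                pos = np.unique(np.concatenate([pos, extra]))
            pos = np.sort(rng.choice(pos, size=want, replace=False))
        chroms.extend([name] * want)
        poss.append(pos)
    pos_all = np.concatenate(poss) if poss else np.array([], dtype=np.int64)
    return np.array(chroms, dtype=object), pos_all


def simulate_founders(cfg: SimConfig, rng=None) -> FounderPool:
    """Draw the founder haplotype pool.

    Alt frequencies ~ Uniform(founder_freq_low, founder_freq_high); each
    founder receives two independent haplotypes per marker (Hardy-Weinberg,
    linkage equilibrium).  Pool rows are assigned to wild-origin pedigree
    records in pedigree order by :func:`transmit_genotypes`.
    """
    rng = _rng(cfg.seed if rng is None else rng)
    chrom, pos = _marker_positions(cfg, rng)
    m = len(pos)
    freq = rng.uniform(cfg.founder_freq_low, cfg.founder_freq_high, size=m)
    mm = MarkerMap(
        chrom,
        pos,
        np.array(["A"] * m, dtype=object),
        np.array(["G"] * m, dtype=object),
    )
    layout = GenomeLayout(
        {f"chr{c + 1}": cfg.chromosome_length_bp for c in range(cfg.n_chromosomes)}
    )
    n_founders = cfg.n_founder_females + cfg.n_founder_males + cfg.n_wild_males
    haps = (
        rng.random((n_founders, 2, m)) < freq[None, None, :]
    ).astype(np.int8)
    return FounderPool(haps, freq, mm, layout)


def simulate_pedigree(cfg: SimConfig, rng=None) -> Pedigree:
    """Build the camp pedigree: wild founders plus captive births.

    Each captive birth draws its dam uniformly from females alive and of
    reproductive age, and its sire from all age-eligible males with
    probability proportional to a per-male weight raised to ``sire_skew``.
    Dams are recorded; sires go only into the hidden truth table.
    """
    rng = _rng(cfg.seed + 1 if rng is None else rng)
    if cfg.n_founder_females == 0:
        raise ValueError("no founder females: empty dam pool")
    if cfg.n_founder_males + cfg.n_wild_males == 0:
        raise ValueError("empty sire pool")

    camp_names = [c for c, _ in cfg.camps]
    camp_p = np.array([w for _, w in cfg.camps], dtype=float)
    camp_p = camp_p / camp_p.sum()

    records: list[PedRecord] = []
    truth_rows: list[dict] = []

    for i in range(cfg.n_founder_females):
        records.append(
            PedRecord(
                f"F{i + 1:03d}",
                "female",
                int(1945 + rng.integers(0, 21)),
                True,
                "wild",
                camp_names[rng.choice(len(camp_names), p=camp_p)],
                None,
            )
        )
    for i in range(cfg.n_founder_males):
        records.append(
            PedRecord(
                f"M{i + 1:03d}",
                "male",
                int(1935 + rng.integers(0, 21)),
                True,
                "wild",
                camp_names[rng.choice(len(camp_names), p=camp_p)],
                None,
            )
        )
    wild_bulls = []
    for i in range(cfg.n_wild_males):
        wild_bulls.append(
            PedRecord(
                f"W{i + 1:03d}",
                "male",
                int(1935 + rng.integers(0, 41)),
                True,
                "wild",
                "",
                None,
                sampled=False,
            )
        )
    records.extend(wild_bulls)

    # matriline root and true parents per individual, for kin-mating avoidance
    mat_root: dict[str, str] = {r.sample_id: r.sample_id for r in records}
    true_parents: dict[str, tuple] = {}

    def _kin2(sid: str) -> set:
        """True ancestors within two generations, including self."""
        out = {sid}
        for p in true_parents.get(sid, ()):
            out.add(p)
            out.update(true_parents.get(p, ()))
        return out

    # per-male lifetime attractiveness weight; skew exponent concentrates it
    weights: dict[str, float] = {}

    def male_weight(mid: str) -> float:
        if mid not in weights:
            weights[mid] = float(rng.uniform())
        return weights[mid]

    n_captive = max(cfg.n_samples - cfg.n_founder_females - cfg.n_founder_males, 0)
    first_gen_year = 1945 + cfg.maturity_age_years + 5  # founders mature
    born = 0
    k = 0
    gen = 0
    max_gen = cfg.n_generations + 10  # safety margin to reach n_samples
    while born < n_captive and gen < max_gen:
        gen_year = first_gen_year + gen * cfg.generation_gap_years
        females = [
            r
            for r in records
            if r.sampled
            and r.sex == "female"
            and cfg.maturity_age_years <= gen_year - r.birth_year
        ]
        n_births = int(rng.poisson(cfg.offspring_per_female * max(len(females), 0)))
        years = np.sort(
            rng.integers(gen_year, gen_year + cfg.generation_gap_years, size=n_births)
        )
        for y in years:
            y = int(y)
            dams = [
                r
                for r in records
                if r.sampled
                and r.sex == "female"
                and cfg.maturity_age_years <= y - r.birth_year <= cfg.max_dam_age_years
            ]
            sires = [
                r
                for r in records
                if r.sex == "male"
                and cfg.min_sire_age_years <= y - r.birth_year <= cfg.max_sire_age_years
            ]
            if not dams or not sires:
                continue
            dam = dams[int(rng.integers(len(dams)))]
            if cfg.avoid_kin_matings:
                dam_kin = _kin2(dam.sample_id)
                eligible = [
                    s
                    for s in sires
                    if mat_root[s.sample_id] != mat_root[dam.sample_id]
                    and not (_kin2(s.sample_id) & dam_kin)
                ]
                if eligible:
                    sires = eligible
            w = np.array([male_weight(s.sample_id) for s in sires]) ** cfg.sire_skew
            if w.sum() == 0:
                w = np.ones(len(sires))
            sire = sires[int(rng.choice(len(sires), p=w / w.sum()))]
            k += 1
            cid = f"E{k:03d}"
            records.append(
                PedRecord(
                    cid,
                    "female" if rng.random() < 0.5 else "male",
                    y,
                    False,
                    "captive",
                    dam.camp,
                    dam.sample_id,
                )
            )
            mat_root[cid] = mat_root[dam.sample_id]
            true_parents[cid] = (sire.sample_id, dam.sample_id)
            truth_rows.append(
                {
                    "sample_id": cid,
                    "true_sire_id": sire.sample_id,
                    "true_dam_id": dam.sample_id,
                }
            )
            born += 1
            if born >= n_captive:
                break
        gen += 1
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "true_sire_id", "true_dam_id"])
    return Pedigree(records, truth)


def _gamete(
    hap: np.ndarray,
    chrom_slices: list,
    chrom_pos: list,
    chrom_len_bp: np.ndarray,
    cM_per_Mb: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a parent's (2, m) haplotype pair."""
    out = np.empty(hap.shape[1], dtype=np.int8)
    for sl, pos, L in zip(chrom_slices, chrom_pos, chrom_len_bp):
        morgans = L * cM_per_Mb * 1e-8
        n_co = rng.poisson(morgans)
        start = int(rng.integers(2))
        if n_co == 0:
            out[sl] = hap[start, sl]
            continue
        co = np.sort(rng.uniform(0, L, size=n_co))
        which = (start + np.searchsorted(co, pos)) % 2
        out[sl] = np.where(which == 0, hap[0, sl], hap[1, sl])
    return out


def transmit_genotypes(
    pedigree: Pedigree,
    founders: FounderPool,
    cM_per_Mb: float = 1.0,
    seed=0,
    sampled_only: bool = True,
) -> GenotypeMatrix:
    """Drop genotypes down the pedigree by Mendelian transmission.

    Crossover counts per chromosome are Poisson in its map length (bp x
    1e-8 Morgan at 1 cM/Mb), positions uniform, parental haplotypes
    alternating.  Wild-origin records take founder-pool haplotypes in
    pedigree order; captive births inherit one gamete from the hidden true
    dam and one from the hidden true sire.
    """
    rng = _rng(seed)
    mm = founders.markers
    chrom_names = mm.chromosomes()
    chrom_slices, chrom_pos, lens = [], [], []
    for c in chrom_names:
        idx = np.flatnonzero(mm.chrom == c)
        chrom_slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
        chrom_pos.append(mm.pos[idx].astype(np.float64))
        lens.append(founders.layout.lengths[c])
    lens = np.asarray(lens)

    truth = {
        row.sample_id: (row.true_sire_id, row.true_dam_id)
        for row in pedigree.truth.itertuples()
    }
    haps: dict[str, np.ndarray] = {}
    founder_rows = iter(range(founders.haplotypes.shape[0]))
    order = sorted(pedigree.records, key=lambda r: (r.birth_year, r.sample_id))
    for r in order:
        if r.origin == "wild":
            try:
                haps[r.sample_id] = founders.haplotypes[next(founder_rows)]
            except StopIteration:
                raise ValueError("founder pool smaller than wild pedigree records")
        else:
            if r.sample_id not in truth:
                raise ValueError(f"{r.sample_id}: captive record without true parents")
            sire_id, dam_id = truth[r.sample_id]
            for pid in (sire_id, dam_id):
                if pid not in haps:
                    raise ValueError(f"{r.sample_id}: parent {pid} has no haplotypes")
            haps[r.sample_id] = np.stack(
                [
                    _gamete(haps[dam_id], chrom_slices, chrom_pos, lens, cM_per_Mb, rng),
                    _gamete(haps[sire_id], chrom_slices, chrom_pos, lens, cM_per_Mb, rng),
                ]
            )
    ids = [
        r.sample_id
        for r in pedigree.records
        if (r.sampled or not sampled_only)
    ]
    calls = np.stack([haps[s].sum(axis=0, dtype=np.int8) for s in ids])
    return GenotypeMatrix(ids, calls, mm)


def degrade(
    G: GenotypeMatrix, error_rate: float, missing_rate: float, seed=0
) -> GenotypeMatrix:
    """Inject symmetric genotyping error and missingness, per call.

    With probability *missing_rate* a call is set MISSING; otherwise with
    probability *error_rate* it is replaced by one of the two other dosage
    codes uniformly.
    """
    if not (0 <= error_rate <= 1 and 0 <= missing_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = _rng(seed)
    calls = G.calls.copy()
    u = rng.random(calls.shape)
    err = (
        (u >= missing_rate)
        & (rng.random(calls.shape) < error_rate)
        & (calls != MISSING)
    )
    # replace by one of the two other codes uniformly
    shift = rng.integers(1, 3, size=calls.shape)
    calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    calls[u < missing_rate] = MISSING
    return GenotypeMatrix(list(G.sample_ids), calls, G.markers)


def simulate_hbd_sequence(model, freqs, pos_morgan, seed=0):
    """Generative twin of the autozygosity HMM: sample a state path along
    one chromosome and emit a genotype vector from it.

    Between adjacent markers at genetic distance d the chain leaves its
    state with probability 1 - exp(-R_state * d) and re-enters class j with
    probability M_j (possibly the same class).  Returns (states, dosages).
    """
    rng = _rng(seed)
    M = np.asarray(model.mixing, dtype=float)
    if M.min() < 0 or abs(M.sum() - 1.0) > 1e-9:
        raise ValueError("mixing must be a simplex")
    R = np.asarray(model.rates, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    pos = np.asarray(pos_morgan, dtype=float)
    m = len(freqs)
    states = np.empty(m, dtype=np.int64)
    s = int(rng.choice(len(M), p=M))
    states[0] = s
    for t in range(1, m):
        d = pos[t] - pos[t - 1]
        if rng.random() < 1.0 - np.exp(-R[s] * d):
            s = int(rng.choice(len(M), p=M))
        states[t] = s
    q = freqs
    dosages = np.empty(m, dtype=np.int8)
    non_hbd = states == len(M) - 1
    u = rng.random(m)
    hw = np.where(u < (1 - q) ** 2, 0, np.where(u < (1 - q) ** 2 + 2 * q * (1 - q), 1, 2))
    auto = np.where(rng.random(m) < q, 2, 0)  # autozygous: hom alt w.p. q
    err = rng.random(m) < model.error
    dosages = np.where(non_hbd | err, hw, auto).astype(np.int8)
    return states, dosages


@dataclass
class SimResult:
    """A complete simulated dataset: clean and degraded genotypes, visible
    metadata, pedigree with hidden truth, and the genome layout."""

    config: SimConfig
    genotypes: GenotypeMatrix  # degraded (as genotyped)
    genotypes_clean: GenotypeMatrix  # pre-error, pre-missingness
    meta: list
    pedigree: Pedigree
    layout: GenomeLayout
    founder_freq: np.ndarray


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """End-to-end dataset generation, deterministic under ``cfg.seed``."""
    founders = simulate_founders(cfg, np.random.default_rng(cfg.seed))
    pedigree = simulate_pedigree(cfg, np.random.default_rng(cfg.seed + 1))
    clean = transmit_genotypes(
        pedigree, founders, cM_per_Mb=cfg.cM_per_Mb, seed=cfg.seed + 2
    )
    noisy = degrade(clean, cfg.error_rate, cfg.missing_rate, seed=cfg.seed + 3)
    return SimResult(
        config=cfg,
        genotypes=noisy,
        genotypes_clean=clean,
        meta=pedigree.to_metadata(),
        pedigree=pedigree,
        layout=founders.layout,
        founder_freq=founders.alt_freq,
    )


def study_preset(seed: int = 0, **overrides) -> SimConfig:
    """The desk-scale preset mirroring the study's RADseq shape:
    261 samples, 13,000 markers, 10 chromosomes."""
    return replace(SimConfig(seed=seed), **overrides)
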