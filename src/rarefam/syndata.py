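"""Synthetic pedigrees, stratified cohorts, and filtering fixtures.

The study this package reimplements could not deposit genotypes, so every
downstream stage is exercised on simulated data with known ground truth:

* **Pedigrees** — gene-dropping through multi-generation families, with an
  optional *planted* mode that fixes the affected set and resamples
  transmissions until target affected-carrier counts are hit exactly (the
  published table gives only counts, never genotypes).
* **Cohorts** — case-control samples with a rare-variant site-frequency
  spectrum, LD blocks from block-haplotype copying, Balding-Nichols
  population stratification, and an optional per-gene burden effect on case
  status.
* **Filtering fixture** — a VCF containing the 19 published variant records
  (frequencies as printed; genotypes synthetic) among decoys that each
  violate exactly one cascade rule, plus matching repeat-mask and
  linkage-peak BEDs and a truth table.

All generators are fully determined by their seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assoc import CohortData
from .io import load_table1
from .segregation import DIAGNOSES, FamilyPedigree, Member

# ----------------------------------------------------------------------------
# Balding-Nichols allele frequencies


def balding_nichols_freqs(
    p: float, fst: float, n_subpops: int, seed=None
) -> np.ndarray:
    """Subpopulation allele frequencies under the Balding-Nichols model.

    Frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) draws: mean ``p`` and
    variance ``F p (1-p)``, the standard generator for population
    stratification at Wright's fixation index F. ``fst=0`` returns ``p``
    exactly for every subpopulation.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"ancestral frequency p={p} must be in (0, 1)")
    if not 0.0 <= fst < 1.0:
        raise ValueError(f"fst={fst} must be in [0, 1)")
    if fst == 0.0:
        return np.full(n_subpops, p)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b, size=n_subpops)


# ----------------------------------------------------------------------------
# Pedigree simulation


@dataclass
class DiseaseModel:
    """Additive logistic disease model on total minor-allele count."""

    baseline_risk: float = 0.05
    per_allele_odds: float = 2.0
    affected_labels: Tuple[str, ...] = ("SLE",)

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_risk < 1.0:
            raise ValueError("baseline_risk must be in (0, 1)")
        if self.per_allele_odds <= 0:
            raise ValueError("per_allele_odds must be positive")
        for lab in self.affected_labels:
            if lab not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis {lab!r}")


@dataclass
class PedigreeConfig:
    """Parameters of one simulated family.

    The structure is a top founder couple whose children (and grandchildren,
    etc.) each marry a married-in founder, up to ``founders_per_generation``
    new couples per generation, with ``children_per_couple`` children each.
    ``variant_freqs`` gives founder allele frequencies per simulated variant.

    Planted mode: ``planted_counts`` maps variant id -> target number of
    affected carriers; ``affected_assignment`` (member id -> diagnosis) fixes
    who is affected. Founder genotypes are assigned (one top founder is made
    heterozygous for any planted variant with target > 0) and transmissions
    are rejection-resampled until every target count is met exactly.
    """

    family_id: str = "SIM"
    n_generations: int = 3
    founders_per_generation: int = 4
    children_per_couple: int = 4
    variant_freqs: Sequence[float] = ()
    variant_ids: Optional[Sequence[str]] = None
    planted_counts: Optional[Dict[str, int]] = None
    affected_assignment: Optional[Dict[str, str]] = None
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    missing_rate: float = 0.0
    max_retries: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        for f in self.variant_freqs:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"variant frequency {f} outside [0, 1]")
        if self.n_generations < 2:
            raise ValueError("need at least two generations")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.variant_ids is not None and len(self.variant_ids) != len(
            self.variant_freqs
        ):
            raise ValueError("variant_ids length must match variant_freqs")


@dataclass
class PedigreeTruth:
    """Ground truth accompanying one simulated pedigree."""

    genotypes: pd.DataFrame  # member x variant allele counts, pre-missingness
    carrier_sets: Dict[str, List[str]]
    planted_counts: Dict[str, int]
    retries: Dict[str, int]


def build_structure(config: PedigreeConfig) -> List[Member]:
    """Deterministic family scaffold (everyone healthy; diagnoses set later)."""
    fam = config.family_id
    members: List[Member] = [
        Member(f"{fam}_G1_M", None, None, 1, "healthy"),
        Member(f"{fam}_G1_F", None, None, 2, "healthy"),
    ]
    couples = [(members[0].id, members[1].id)]
    for gen in range(2, config.n_generations + 1):
        next_couples = []
        child_no = 0
        for father, mother in couples:
            for _ in range(config.children_per_couple):
                child_no += 1
                sex = 1 if child_no % 2 else 2
                cid = f"{fam}_G{gen}_C{child_no}"
                members.append(Member(cid, father, mother, sex, "healthy"))
                if gen < config.n_generations and len(next_couples) < config.founders_per_generation:
                    sid = f"{fam}_G{gen}_S{child_no}"
                    members.append(Member(sid, None, None, 3 - sex, "healthy"))
                    next_couples.append((cid, sid) if sex == 1 else (sid, cid))
        couples = next_couples
    return members


def _drop_variant(
    members: List[Member],
    founder_geno: Dict[str, int],
    rng: np.random.Generator,
) -> Dict[str, int]:
    """Mendelian gene drop: one allele per parent, each parental copy
    transmitted with probability 1/2."""
    geno: Dict[str, int] = {}
    for m in members:  # members are listed parents-before-children
        if m.father is None and m.mother is None:
            geno[m.id] = founder_geno.get(m.id, 0)
        else:
            g = 0
            for parent in (m.father, m.mother):
                pg = geno[parent]
                if pg == 2:
                    g += 1
                elif pg == 1:
                    g += int(rng.random() < 0.5)
            geno[m.id] = g
    return geno


def simulate_pedigree(config: PedigreeConfig) -> Tuple[FamilyPedigree, PedigreeTruth]:
    """Simulate one family: structure, genotypes by gene dropping, affection.

    Returns the pedigree (with a member x variant call matrix, missingness
    applied at ``missing_rate``) and the pre-missingness ground truth.

    Raises
    ------
    ValueError
        If a planted target exceeds the number of affected members, or
        cannot be met within ``max_retries`` resampled gene drops.
    """
    rng = np.random.default_rng(config.seed)
    members = build_structure(config)
    ids = [m.id for m in members]
    founder_ids = [m.id for m in members if m.father is None]
    variant_ids = list(
        config.variant_ids
        if config.variant_ids is not None
        else (f"v{i}" for i in range(len(config.variant_freqs)))
    )
    planted = dict(config.planted_counts or {})
    for v in planted:
        if v not in variant_ids:
            variant_ids.append(v)

    # --- affection status
    model = config.disease_model
    if config.affected_assignment is not None:
        for m in members:
            m.diagnosis = config.affected_assignment.get(m.id, "healthy")
        affected = [
            m.id for m in members if m.diagnosis in set(model.affected_labels)
        ]
    else:
        affected = None  # sampled after genotypes

    geno_cols: Dict[str, Dict[str, int]] = {}
    retries: Dict[str, int] = {}
    freq_by_id = dict(zip(variant_ids, list(config.variant_freqs) + [0.0] * 99))

    for vid in variant_ids:
        if vid in planted:
            target = planted[vid]
            if affected is None:
                raise ValueError("planted mode requires affected_assignment")
            if target > len(affected):
                raise ValueError(
                    f"{vid}: planted target {target} exceeds {len(affected)} affected members"
                )
            founder_geno = {founder_ids[0]: 1} if target > 0 else {}
            for attempt in range(1, config.max_retries + 1):
                geno = _drop_variant(members, founder_geno, rng)
                if sum(1 for i in affected if geno[i] >= 1) == target:
                    retries[vid] = attempt
                    break
            else:
                raise ValueError(
                    f"{vid}: could not plant {target} affected carriers in "
                    f"{config.max_retries} gene drops"
                )
        else:
            p = freq_by_id[vid]
            founder_geno = {
                f: int(rng.random() < p) + int(rng.random() < p) for f in founder_ids
            }
            geno = _drop_variant(members, founder_geno, rng)
        geno_cols[vid] = geno

    truth_df = pd.DataFrame({v: [geno_cols[v][i] for i in ids] for v in variant_ids},
                            index=ids)

    if affected is None:
        base_logit = np.log(model.baseline_risk / (1.0 - model.baseline_risk))
        burden = truth_df.sum(axis=1).to_numpy()
        risk = 1.0 / (1.0 + np.exp(-(base_logit + np.log(model.per_allele_odds) * burden)))
        is_aff = rng.random(len(ids)) < risk
        for m, a in zip(members, is_aff):
            m.diagnosis = model.affected_labels[0] if a else "healthy"

    calls = truth_df.astype(float)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = calls.mask(mask)

    pedigree = FamilyPedigree(family_id=config.family_id, members=members, calls=calls)
    truth = PedigreeTruth(
        genotypes=truth_df,
        carrier_sets={v: [i for i in ids if geno_cols[v][i] >= 1] for v in variant_ids},
        planted_counts=planted,
        retries=retries,
    )
    return pedigree, truth


#: Diagnoses of the affected members of the two emulated multicase families:
#: family "6" counts any autoimmune diagnosis (6 SLE + 1 RA + 1 MS = 8
#: affected), family "8" counts SLE only (7 affected).
_FAMILY6_AFFECTED = {
    "F6_G2_C1": "SLE", "F6_G2_C2": "SLE", "F6_G2_C3": "SLE", "F6_G2_C4": "SLE",
    "F6_G3_C1": "SLE", "F6_G3_C5": "SLE", "F6_G3_C9": "RA", "F6_G3_C13": "MS",
}
_FAMILY8_AFFECTED = {
    "F8_G2_C1": "SLE", "F8_G2_C2": "SLE", "F8_G2_C3": "SLE", "F8_G2_C4": "SLE",
    "F8_G3_C1": "SLE", "F8_G3_C5": "SLE", "F8_G3_C9": "SLE",
}


def two_multicase_families(seed: int = 0):
    """Planted pedigrees reproducing the published per-family carrier counts.

    Returns ``(pedigrees, variant_meta)``: pedigrees for families "6" (8
    affected: 6 SLE, 1 RA, 1 MS — any autoimmune diagnosis counts) and "8"
    (7 SLE), each with all 19 candidate variants gene-dropped so that the
    affected-carrier count per family equals the published value (absent
    cells plant a count of 0), and a variant metadata table (chrom, pos,
    gene, frequencies) indexed by gene symbol.
    """
    t1 = load_table1()
    meta = t1.set_index("gene")[
        ["chrom", "pos", "rsid", "control_maf", "nordic_maf", "max_public_maf"]
    ]
    pedigrees = {}
    for fam, assignment, carr_col in (
        ("6", _FAMILY6_AFFECTED, "fam6_carriers"),
        ("8", _FAMILY8_AFFECTED, "fam8_carriers"),
    ):
        planted = {
            row.gene: int(getattr(row, carr_col)) if pd.notna(getattr(row, carr_col)) else 0
            for row in t1.itertuples()
        }
        cfg = PedigreeConfig(
            family_id=f"F{fam}",
            n_generations=3,
            founders_per_generation=4,
            children_per_couple=4,
            planted_counts=planted,
            affected_assignment=assignment,
            disease_model=DiseaseModel(
                affected_labels=("SLE", "RA", "MS") if fam == "6" else ("SLE",)
            ),
            seed=seed + int(fam),
        )
        ped, _ = simulate_pedigree(cfg)
        ped.family_id = fam
        pedigrees[fam] = ped
    return pedigrees, meta


# ----------------------------------------------------------------------------
# Cohort simulation


@dataclass
class CohortConfig:
    """Parameters of a stratified case-control cohort.

    Emulates (at reduced scale) an imputed GWAS set of thousands of European
    cases and controls: ``n_genes`` gene regions of ``markers_per_gene`` rare
    markers each (ancestral MAF log-uniform on ``maf_range``), plus
    ``n_background`` common markers (MAF uniform on ``background_maf_range``)
    representing the genome-wide panel used for PCA. LD is induced by
    block-haplotype copying: markers within a block of ``ld_block_size``
    share a latent uniform with probability ``ld_copy_prob``, which makes
    them co-segregate on haplotypes while guaranteeing valid genotypes.
    Disease risk is logistic with intercept ``base_logit``, per-subpopulation
    shifts ``subpop_logit_shifts`` (default linspace(-0.75, 0.75) when
    stratified — prevalence differences are what make stratification
    confound), and ``burden_log_odds`` per minor allele in ``causal_gene``.
    Sampling is retrospective: individuals are simulated until the case and
    control quotas are filled.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_subpops: int = 1
    fst: float = 0.0
    n_genes: int = 20
    markers_per_gene: int = 20
    maf_range: Tuple[float, float] = (5e-4, 0.01)
    n_background: int = 400
    background_maf_range: Tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_copy_prob: float = 0.9
    causal_gene: Optional[str] = None
    burden_log_odds: float = 0.0
    base_logit: float = -1.0
    subpop_logit_shifts: Optional[Sequence[float]] = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case/control counts must be positive")
        if self.n_subpops < 1:
            raise ValueError("need at least one subpopulation")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_copy_prob <= 1.0:
            raise ValueError("ld_copy_prob must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_markers(self) -> int:
        return self.n_genes * self.markers_per_gene + self.n_background

    def gene_names(self) -> List[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class CohortTruth:
    """Ground truth accompanying one simulated cohort."""

    subpop: np.ndarray
    ancestral_freqs: np.ndarray
    subpop_freqs: np.ndarray  # n_subpops x n_markers
    causal_markers: List[str]
    burden_log_odds: float
    causal_carriers: List[int]  # row indices of minor-allele carriers


def _block_haplotypes(
    n_hap: int,
    freqs: np.ndarray,  # n_hap x m (per-haplotype subpop frequency rows)
    block_size: int,
    copy_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotype alleles with within-block LD via a shared latent uniform."""
    m = freqs.shape[1]
    out = np.empty((n_hap, m), dtype=np.int8)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        width = stop - start
        shared = rng.random((n_hap, 1))
        fresh = rng.random((n_hap, width))
        use_shared = rng.random((n_hap, width)) < copy_prob
        u = np.where(use_shared, shared, fresh)
        out[:, start:stop] = u < freqs[:, start:stop]
    return out


def simulate_cohort(config: CohortConfig) -> Tuple[CohortData, CohortTruth]:
    """Simulate a stratified case-control cohort with known ground truth.

    Haplotypes are drawn per subpopulation from Balding-Nichols frequencies
    with block-copying LD; the phenotype follows the logistic model described
    on :class:`CohortConfig`; sampling continues until the case/control
    quotas are exactly met. Genotypes for non-phenotype-relevant markers are
    generated only for accepted individuals (a pure speed optimization —
    the distribution is unchanged because marker blocks are independent).
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    m_gene = config.n_genes * config.markers_per_gene

    # marker map: genes spaced 3 Mb apart on chr1 (markers 5 kb apart inside
    # a 100 kb span), background panel on chr2
    marker_rows = []
    for g, gene in enumerate(genes):
        base = 1_000_000 + g * 3_000_000
        for j in range(config.markers_per_gene):
            marker_rows.append(
                {"id": f"{gene}_m{j:03d}", "chrom": "chr1", "pos": base + j * 5_000,
                 "gene": gene}
            )
    for j in range(config.n_background):
        marker_rows.append(
            {"id": f"bg_m{j:04d}", "chrom": "chr2", "pos": 1_000_000 + j * 50_000,
             "gene": ""}
        )
    markers = pd.DataFrame(marker_rows)

    lo, hi = config.maf_range
    p_anc = np.empty(config.n_markers)
    p_anc[:m_gene] = np.exp(rng.uniform(np.log(lo), np.log(hi), m_gene))
    p_anc[m_gene:] = rng.uniform(*config.background_maf_range, config.n_background)

    if config.fst > 0 and config.n_subpops > 1:
        subpop_freqs = np.vstack(
            [balding_nichols_freqs(p, config.fst, config.n_subpops, rng) for p in p_anc]
        ).T
    else:
        subpop_freqs = np.tile(p_anc, (config.n_subpops, 1))

    shifts = config.subpop_logit_shifts
    if shifts is None:
        shifts = (
            np.linspace(-0.75, 0.75, config.n_subpops)
            if config.n_subpops > 1
            else np.zeros(1)
        )
    shifts = np.asarray(shifts, dtype=float)
    if len(shifts) != config.n_subpops:
        raise ValueError("subpop_logit_shifts length must equal n_subpops")

    if config.causal_gene is not None and config.causal_gene not in genes:
        raise ValueError(f"causal_gene {config.causal_gene!r} not simulated")
    causal_cols = (
        np.flatnonzero(markers["gene"].to_numpy() == config.causal_gene)
        if config.causal_gene is not None
        else np.empty(0, dtype=int)
    )

    # --- retrospective sampling on (subpop, causal-gene dosage) only
    need_cases, need_controls = config.n_cases, config.n_controls
    acc_subpop: List[np.ndarray] = []
    acc_causal: List[np.ndarray] = []
    acc_y: List[np.ndarray] = []
    while need_cases > 0 or need_controls > 0:
        batch = max(256, 2 * (need_cases + need_controls))
        sp = rng.integers(config.n_subpops, size=batch)
        if causal_cols.size:
            f = subpop_freqs[:, causal_cols][np.repeat(sp, 2)]
            haps = _block_haplotypes(
                2 * batch, f, config.ld_block_size, config.ld_copy_prob, rng
            )
            causal_dos = (haps[0::2] + haps[1::2]).astype(np.int8)
            # gene markers are simulated rare, so dosage already counts the
            # minor allele; the burden is the plain row sum
            burden = causal_dos.sum(axis=1)
        else:
            causal_dos = np.zeros((batch, 0), dtype=np.int8)
            burden = np.zeros(batch)
        logit = config.base_logit + shifts[sp] + config.burden_log_odds * burden
        y = (rng.random(batch) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
        for want, val in ((need_cases, 1), (need_controls, 0)):
            if want <= 0:
                continue
            take = np.flatnonzero(y == val)[:want]
            acc_subpop.append(sp[take])
            acc_causal.append(causal_dos[take])
            acc_y.append(y[take])
            if val == 1:
                need_cases -= take.size
            else:
                need_controls -= take.size

    subpop = np.concatenate(acc_subpop)
    causal_dos = np.concatenate(acc_causal) if causal_cols.size else None
    y = np.concatenate(acc_y)
    n = len(y)
    order = rng.permutation(n)  # interleave cases and controls
    subpop, y = subpop[order], y[order]
    if causal_dos is not None:
        causal_dos = causal_dos[order]

    # --- remaining markers for accepted individuals, chunked per gene
    dosages = np.empty((n, config.n_markers), dtype=np.float32)
    hap_sp = np.repeat(subpop, 2)
    for g in range(config.n_genes):
        cols = np.arange(g * config.markers_per_gene, (g + 1) * config.markers_per_gene)
        if config.causal_gene is not None and genes[g] == config.causal_gene:
            dosages[:, cols] = causal_dos
            continue
        f = subpop_freqs[:, cols][hap_sp]
        haps = _block_haplotypes(2 * n, f, config.ld_block_size, config.ld_copy_prob, rng)
        dosages[:, cols] = haps[0::2] + haps[1::2]
    for start in range(m_gene, config.n_markers, 2000):
        cols = np.arange(start, min(start + 2000, config.n_markers))
        f = subpop_freqs[:, cols][hap_sp]
        haps = _block_haplotypes(2 * n, f, 1, 0.0, rng)
        dosages[:, cols] = haps[0::2] + haps[1::2]

    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan

    call_rate = 1.0 - np.isnan(dosages).mean(axis=0)
    markers["call_rate"] = call_rate
    markers["info"] = 1.0
    markers["concordance"] = 1.0
    markers["ancestral_maf"] = p_anc
    samples = pd.DataFrame(
        {
            "id": [f"S{i:05d}" for i in range(n)],
            "call_rate": 1.0 - np.isnan(dosages).mean(axis=1),
            "subpop": subpop,
        }
    )
    cohort = CohortData(dosages=dosages, y=y, markers=markers, samples=samples)
    causal_ids = markers["id"].to_numpy()[causal_cols].tolist()
    carriers = (
        np.flatnonzero(np.nansum(dosages[:, causal_cols], axis=1) > 0).tolist()
        if causal_cols.size
        else []
    )
    truth = CohortTruth(
        subpop=subpop,
        ancestral_freqs=p_anc,
        subpop_freqs=subpop_freqs,
        causal_markers=causal_ids,
        burden_log_odds=config.burden_log_odds,
        causal_carriers=carriers,
    )
    return cohort, truth


# ----------------------------------------------------------------------------
# Filtering fixture


#: Sequenced affected members per family (the exome discovery samples).
FAMILY_SAMPLES: Dict[str, List[str]] = {
    "6": ["F6_E1", "F6_E2"],
    "8": ["F8_E1", "F8_E2", "F8_E3"],
}

_BASES = "ACGT"

_DECOY_RULES = ("low_reads", "repeat_masked", "ancestral_allele", "synonymous",
                "not_shared", "frequency")

#: Genes whose variants >=3 standard algorithms call deleterious, and genes
#: with SNPDryad score > 0.5, per the published annotation summary. Used to
#: decorate the fixture with *synthetic stand-in* predictor columns.
_CONSENSUS_GENES = {"SLC5A9", "XRCC6BP1", "MPHOSPH8", "CHD3", "CLC", "TPRA1",
                    "FAT4", "PDHA2", "FBXL14"}
_DRYAD_GENES = {"SLC5A9", "DCLRE1C", "NUP214", "XRCC6BP1", "MPHOSPH8", "WDR25",
                "CHD3", "CLC", "TPRA1", "ANKRD50", "FAT4", "PDHA2", "FAM8A1"}

_PREDICTORS = ("SIFT", "PolyPhen2", "FATHMM", "LRT", "MetaLR",
               "MutationAssessor", "MutationTaster", "Provean")


def _alleles(pos: int) -> Tuple[str, str]:
    ref = _BASES[pos % 4]
    alt = _BASES[(pos % 4 + 1 + pos % 3) % 4]
    return ref, alt


def generate_filter_fixture(seed: int = 0, outdir: str = ".") -> Dict[str, str]:
    """Write the filtering fixture: VCF + mask/peak BEDs + truth labels.

    The VCF holds one record per published candidate variant (positions,
    alleles at those positions synthetic; control/Nordic/public MAFs as
    printed) and two decoys per cascade rule, each violating exactly that
    rule and no other. Genotypes are synthetic: carriers are the sequenced
    patients of the qualifying family; the eight records whose printed
    control MAF lies in (0.5%, 5%] are planted with one case-homozygous
    carrier and het-only controls so they enter through the
    case-only-homozygous frequency branch. Returns a dict of written paths
    (``vcf``, ``mask``, ``peaks``, ``truth``). Output is byte-identical for
    identical seeds.
    """
    rng = np.random.default_rng(seed)
    t1 = load_table1()
    samples = FAMILY_SAMPLES["6"] + FAMILY_SAMPLES["8"]

    # linkage peaks reproducing the printed within-20-Mb Z annotations
    peaks = [
        ("chr1", 48_000_000, 49_000_000, "peak_chr1", 2.4),
        ("chr17", 7_500_000, 7_900_000, "peak_chr17", 1.79),
        ("chr19", 47_500_000, 48_500_000, "peak_chr19", 2.06),
    ]
    mask_intervals = [
        ("chr2", 10_199_990, 10_200_020),  # covers the repeat decoys
        ("chr2", 10_201_005, 10_201_010),
        ("chr7", 5_000_000, 5_100_000),    # no variant inside (realism)
    ]

    rows = []  # (chrom, pos, rid, ref, alt, info_str, genotypes, depths, truth)

    def depths_for(gts: Dict[str, int], low: Optional[str] = None) -> Dict[str, int]:
        d = {}
        for s in samples:
            if gts.get(s, 0) >= 1:
                d[s] = 5 if s == low else int(rng.integers(12, 181))
            else:
                d[s] = int(rng.integers(12, 181))
        return d

    for row in t1.itertuples():
        pos = int(row.pos)
        ref, alt = _alleles(pos)
        fam6 = pd.notna(row.fam6_carriers)
        fam8 = pd.notna(row.fam8_carriers)
        # KIR2DS4 / SLC5A9 appear in both families but fewer than all three
        # sequenced family-8 patients carry them (printed counts 1/7, 2/7)
        gts = {s: 0 for s in samples}
        shared_fams = []
        if fam6:
            for s in FAMILY_SAMPLES["6"]:
                gts[s] = 1
            shared_fams.append("6")
        if fam8:
            n_seq = min(int(row.fam8_carriers), 3)
            for s in FAMILY_SAMPLES["8"][:n_seq]:
                gts[s] = 1
            if n_seq == 3:
                shared_fams.append("8")
        cmaf = None if pd.isna(row.control_maf) else float(row.control_maf)
        chet = cmaf is not None and cmaf > 0.005
        if chet:  # case-only-homozygous branch: one sequenced carrier is hom
            first_carrier = next(s for s in samples if gts[s] >= 1)
            gts[first_carrier] = 2
        info = {
            "GENE": row.gene,
            "CSQ": "missense",
            "CHIMP": ref,
            "CMAF": cmaf,
            "CHET": chet,
            "NMAF": None if pd.isna(row.nordic_maf) else float(row.nordic_maf),
            "PUBMAF": None
            if pd.isna(row.max_public_maf)
            else f"global:{row.max_public_maf:g}",
            "PRED": "|".join(
                f"{alg}:{'D' if (row.gene in _CONSENSUS_GENES and k < 4) else 'B'}"
                for k, alg in enumerate(_PREDICTORS)
            ),
            "DRYAD": 0.62 if row.gene in _DRYAD_GENES else 0.31,
        }
        rows.append(
            (row.chrom, pos, row.rsid, ref, alt, info, gts, depths_for(gts), "pass")
        )

    # decoys: two per rule on chr2, each passing every stage before its own
    decoy_positions = iter(range(10_000_000, 10_000_000 + 100_000, 500))
    fam6_shared = {s: (1 if s in FAMILY_SAMPLES["6"] else 0) for s in samples}
    for rule in _DECOY_RULES:
        for k in range(2):
            pos = next(decoy_positions)
            if rule == "repeat_masked":
                pos = 10_200_000 if k == 0 else 10_201_006
            ref, alt = _alleles(pos)
            gts = dict(fam6_shared)
            info = {
                "GENE": f"DECOY_{rule.upper()}_{k}",
                "CSQ": "missense",
                "CHIMP": ref,
                "CMAF": 0.001,
                "CHET": False,
                "NMAF": 0.0,
                "PUBMAF": "global:0.001",
                "PRED": "|".join(f"{alg}:B" for alg in _PREDICTORS),
                "DRYAD": 0.2,
            }
            low = None
            if rule == "low_reads":
                low = FAMILY_SAMPLES["6"][0]
            elif rule == "ancestral_allele":
                info["CHIMP"] = alt
            elif rule == "synonymous":
                info["CSQ"] = "synonymous"
            elif rule == "not_shared":
                gts = {s: 0 for s in samples}
                gts[FAMILY_SAMPLES["6"][0]] = 1
                gts[FAMILY_SAMPLES["8"][0]] = 1
            elif rule == "frequency":
                if k == 0:  # too common, nobody homozygous
                    info["CMAF"], info["CHET"] = 0.02, True
                else:  # case hom present but controls also carry homozygotes
                    info["CMAF"], info["CHET"] = 0.03, False
                    gts[FAMILY_SAMPLES["6"][0]] = 2
            rows.append(("chr2", pos, ".", ref, alt, info, gts, depths_for(gts, low), rule))

    rows.sort(key=lambda r: (r[0], r[1]))

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "variants.vcf"),
        "mask": os.path.join(outdir, "repeat_mask.bed"),
        "peaks": os.path.join(outdir, "linkage_peaks.bed"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    contigs = sorted({r[0] for r in rows}, key=lambda c: int(c[3:]))
    with open(paths["vcf"], "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rarefam-synthetic-fixture\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length=250000000>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##INFO=<ID=CHIMP,Number=1,Type=String,Description="Chimpanzee allele">\n')
        fh.write('##INFO=<ID=CMAF,Number=1,Type=Float,Description="Internal control MAF">\n')
        fh.write('##INFO=<ID=CHET,Number=0,Type=Flag,Description="Controls het only">\n')
        fh.write('##INFO=<ID=NMAF,Number=1,Type=Float,Description="Nordic control MAF">\n')
        fh.write('##INFO=<ID=PUBMAF,Number=1,Type=String,Description="Public MAFs pop:freq">\n')
        fh.write('##INFO=<ID=PRED,Number=1,Type=String,Description="Predictor calls alg:D|B">\n')
        fh.write('##INFO=<ID=DRYAD,Number=1,Type=Float,Description="SNPDryad score (synthetic stand-in)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + "\t".join(["FORMAT"] + samples) + "\n")
        for chrom, pos, rid, ref, alt, info, gts, depths, _truth in rows:
            parts = []
            for key in ("GENE", "CSQ", "CHIMP", "CMAF", "NMAF", "PUBMAF", "PRED", "DRYAD"):
                val = info.get(key)
                if val is None:
                    continue
                parts.append(f"{key}={val:g}" if isinstance(val, float) else f"{key}={val}")
            if info.get("CHET"):
                parts.append("CHET")
            gt_strs = []
            for s in samples:
                g = gts.get(s, 0)
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[g]
                gt_strs.append(f"{gt}:{depths[s]}")
            fh.write(
                f"{chrom}\t{pos}\t{rid}\t{ref}\t{alt}\t.\tPASS\t" + ";".join(parts)
                + "\tGT:DP\t" + "\t".join(gt_strs) + "\n"
            )
    with open(paths["mask"], "w", newline="\n") as fh:
        for chrom, start, end in mask_intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    with open(paths["peaks"], "w", newline="\n") as fh:
        for chrom, start, end, name, z in peaks:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{z}\n")
    with open(paths["truth"], "w", newline="\n") as fh:
        fh.write("record\tgene\tlabel\n")
        for chrom, pos, _rid, ref, alt, info, _gts, _depths, truth in rows:
            fh.write(f"{chrom}:{pos}:{ref}>{alt}\t{info['GENE']}\t{truth}\n")
    return paths
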