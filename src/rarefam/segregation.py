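"""Pedigree segregation analysis of validated variants.

Counts disease co-segregation of candidate variants within multicase
pedigrees, applies genotyping call-rate QC, flags regional population
polymorphisms, and classifies predicted deleteriousness. The unit of analysis
is a :class:`FamilyPedigree`: members with parent links, a closed diagnosis
vocabulary, and a member x variant genotype-call matrix that may contain
missing calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import Thresholds

#: Closed diagnosis vocabulary.
DIAGNOSES = frozenset({"SLE", "RA", "MS", "partial-SLE", "healthy"})

#: Default "affected" definition (SLE only; widen per analysis as needed).
DEFAULT_AFFECTED: frozenset = frozenset({"SLE"})

#: Any autoimmune diagnosis (used e.g. for families where RA/MS cases count).
AUTOIMMUNE_AFFECTED: frozenset = frozenset({"SLE", "RA", "MS", "partial-SLE"})


@dataclass
class Member:
    id: str
    father: Optional[str]
    mother: Optional[str]
    sex: int  # 1 male, 2 female, 0 unknown
    diagnosis: str

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")


@dataclass
class FamilyPedigree:
    """A family: members plus a member x variant genotype-call matrix.

    ``calls`` is indexed by member id with one column per variant id; values
    are minor-allele counts {0, 1, 2} with NaN for missing calls.
    """

    family_id: str
    members: List[Member]
    calls: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        ids = {m.id for m in self.members}
        for m in self.members:
            for parent in (m.father, m.mother):
                if parent is not None and parent not in ids:
                    raise ValueError(
                        f"member {m.id}: parent {parent} not in family {self.family_id}"
                    )
        if len(self.calls) and not set(self.calls.index) <= ids:
            raise ValueError("calls indexed by unknown member ids")

    def member(self, member_id: str) -> Member:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    def affected_ids(self, affected_labels: Iterable[str] = DEFAULT_AFFECTED) -> List[str]:
        labels = set(affected_labels)
        return [m.id for m in self.members if m.diagnosis in labels]

    def founders(self) -> List[str]:
        return [m.id for m in self.members if m.father is None and m.mother is None]


@dataclass
class SegregationSummary:
    """Carrier counts for one variant in one family."""

    variant: str
    family: str
    carriers: int
    affected_total: int
    chrom: str = ""
    pos: int = 0
    gene: str = ""

    def __post_init__(self) -> None:
        if self.carriers > self.affected_total:
            raise ValueError("carriers exceed affected_total")

    @property
    def fraction(self) -> float:
        return self.carriers / self.affected_total if self.affected_total else 0.0


def genotype_qc(
    calls: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Call-rate QC: drop samples <80% call rate, then variants <90%.

    Sample call rates are computed on the full variant set; variant call rates
    on the retained samples. Both boundaries are inclusive (a rate exactly at
    the threshold is kept).
    """
    if calls.empty:
        return calls
    sample_rate = calls.notna().mean(axis=1)
    keep_samples = sample_rate >= thresholds.sample_callrate
    trimmed = calls.loc[keep_samples]
    variant_rate = trimmed.notna().mean(axis=0)
    keep_variants = variant_rate >= thresholds.variant_callrate
    return trimmed.loc[:, keep_variants]


def count_carriers(
    pedigree: FamilyPedigree,
    variant: str,
    affected_labels: Iterable[str] = DEFAULT_AFFECTED,
) -> Tuple[int, int]:
    """Count affected carriers of a variant: (carriers, affected_total).

    Carriers are affected members with genotype >= 1. Affected members whose
    call is missing are excluded from ``affected_total`` (a missing genotype
    is not evidence of non-carriage).
    """
    if variant not in pedigree.calls.columns:
        raise KeyError(f"variant {variant!r} not in call set of family {pedigree.family_id}")
    affected = [
        i for i in pedigree.affected_ids(affected_labels) if i in pedigree.calls.index
    ]
    col = pedigree.calls.loc[affected, variant]
    genotyped = col.dropna()
    carriers = int((genotyped >= 1).sum())
    return carriers, int(len(genotyped))


def summarize_family(
    pedigree: FamilyPedigree,
    affected_labels: Iterable[str] = DEFAULT_AFFECTED,
    variant_meta: Optional[pd.DataFrame] = None,
) -> List[SegregationSummary]:
    """Carrier summaries for every variant in the family's call matrix."""
    out = []
    for variant in pedigree.calls.columns:
        carriers, total = count_carriers(pedigree, variant, affected_labels)
        meta = {}
        if variant_meta is not None and variant in variant_meta.index:
            meta = variant_meta.loc[variant].to_dict()
        out.append(
            SegregationSummary(
                variant=variant,
                family=pedigree.family_id,
                carriers=carriers,
                affected_total=total,
                chrom=str(meta.get("chrom", "")),
                pos=int(meta.get("pos", 0)),
                gene=str(meta.get("gene", "")),
            )
        )
    return out


def _chrom_key(chrom: str) -> Tuple[int, str]:
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    if m:
        return int(m.group(1)), ""
    order = {"chrX": 23, "X": 23, "chrY": 24, "Y": 24, "chrM": 25, "MT": 25}
    return order.get(chrom, 99), chrom


def rank_segregation(summaries: Sequence[SegregationSummary]) -> pd.DataFrame:
    """Rank variants by cross-family affected-carrier totals.

    Sums carriers and affected totals across families per variant, then sorts
    descending by total carriers, ties broken by overall carrier fraction and
    then by genomic position (ascending). The output is a permutation of the
    input variants: nothing is gained or lost.
    """
    rows: Dict[str, dict] = {}
    for s in summaries:
        row = rows.setdefault(
            s.variant,
            {
                "variant": s.variant,
                "gene": s.gene,
                "chrom": s.chrom,
                "pos": s.pos,
                "total_carriers": 0,
                "total_affected": 0,
                "per_family": {},
            },
        )
        row["total_carriers"] += s.carriers
        row["total_affected"] += s.affected_total
        row["per_family"][s.family] = f"{s.carriers}/{s.affected_total}"
        if s.gene:
            row["gene"] = s.gene
        if s.pos:
            row["chrom"], row["pos"] = s.chrom, s.pos
    table = pd.DataFrame(rows.values())
    if table.empty:
        return table
    table["fraction"] = table["total_carriers"] / table["total_affected"].where(
        table["total_affected"] > 0, other=np.nan
    )
    table["fraction"] = table["fraction"].fillna(0.0)
    table["_ck"] = table["chrom"].map(lambda c: _chrom_key(str(c)))
    table = table.sort_values(
        by=["total_carriers", "fraction", "_ck", "pos"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).drop(columns="_ck")
    return table.reset_index(drop=True)


def flag_population_polymorphism(
    nordic_maf: Optional[float], thresholds: Thresholds = Thresholds()
) -> Optional[bool]:
    """True iff the Nordic-control MAF is strictly above 5%.

    Returns None (undetermined) when the frequency was not measured.
    """
    if nordic_maf is None or (isinstance(nordic_maf, float) and np.isnan(nordic_maf)):
        return None
    if not 0.0 <= nordic_maf <= 1.0:
        raise ValueError(f"nordic_maf={nordic_maf} outside [0, 1]")
    return nordic_maf > thresholds.nordic_poly_maf


def classify_deleteriousness(
    predictor_calls: Dict[str, str], snpdryad: Optional[float]
) -> Dict[str, Optional[object]]:
    """Consensus predictor flag and SNPDryad score band.

    ``consensus_flag`` is True when >= 3 algorithms call the variant
    deleterious (None when no calls are available). The SNPDryad score is
    banded as [0, 0.5) possibly neutral, [0.5, 0.7] possibly deleterious,
    (0.7, 1] deleterious; None when no score is available.
    """
    if not predictor_calls:
        consensus: Optional[bool] = None
    else:
        n_del = sum(1 for c in predictor_calls.values() if c == "deleterious")
        consensus = n_del >= 3
    if snpdryad is None or (isinstance(snpdryad, float) and np.isnan(snpdryad)):
        band: Optional[str] = None
    else:
        if not 0.0 <= snpdryad <= 1.0:
            raise ValueError(f"SNPDryad score {snpdryad} outside [0, 1]")
        if snpdryad < 0.5:
            band = "possibly_neutral"
        elif snpdryad <= 0.7:
            band = "possibly_deleterious"
        else:
            band = "deleterious"
    return {"consensus_flag": consensus, "snpdryad_class": band}


# ----------------------------------------------------------------------------
# PED-like text I/O

def read_pedigree(path: str, family_id: Optional[str] = None) -> List[FamilyPedigree]:
    """Read PED-like TSV (family, id, father, mother, sex, diagnosis).

    '0' in the parent columns means founder. Returns one pedigree per family
    (calls matrices empty; attach genotypes separately).
    """
    fams: Dict[str, List[Member]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fam, mid, fa, mo, sex, dx = line.split("\t")[:6]
            if family_id is not None and fam != family_id:
                continue
            fams.setdefault(fam, []).append(
                Member(
                    id=mid,
                    father=None if fa == "0" else fa,
                    mother=None if mo == "0" else mo,
                    sex=int(sex),
                    diagnosis=dx,
                )
            )
    return [FamilyPedigree(family_id=f, members=ms) for f, ms in fams.items()]


def write_pedigree(pedigrees: Iterable[FamilyPedigree], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#family\tid\tfather\tmother\tsex\tdiagnosis\n")
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    f"{ped.family_id}\t{m.id}\t{m.father or 0}\t{m.mother or 0}"
                    f"\t{m.sex}\t{m.diagnosis}\n"
                )
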