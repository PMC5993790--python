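"""Exome SNV filtering cascade.

Implements the quality / consequence / family-sharing / frequency filtering
cascade used to reduce exome calls from multicase families to a handful of
candidate variants, plus linkage-region annotation. Stages are pure functions
over lists of :class:`VariantRecord`; :func:`run_filter_cascade` chains them
and produces a telescoping :class:`FilterReport` that names, for every removed
record, the first rule it failed.

Coordinate conventions: VCF positions are 1-based; BED intervals are 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .config import Thresholds

logger = logging.getLogger(__name__)

#: Consequence classes retained by the cascade (canonical names).
DAMAGING_CONSEQUENCES = frozenset(
    {"stop_gained", "stop_lost", "essential_splice_site", "missense"}
)

#: Synonyms mapped onto the canonical controlled vocabulary.
_CONSEQUENCE_ALIASES = {
    "missense": "missense",
    "missense_variant": "missense",
    "non_synonymous_coding": "missense",
    "nonsynonymous": "missense",
    "stop_gained": "stop_gained",
    "stop_lost": "stop_lost",
    "essential_splice_site": "essential_splice_site",
    "splice_acceptor": "essential_splice_site",
    "splice_acceptor_variant": "essential_splice_site",
    "splice_donor": "essential_splice_site",
    "splice_donor_variant": "essential_splice_site",
    "synonymous": "synonymous",
    "synonymous_variant": "synonymous",
    "intron_variant": "intron_variant",
    "intergenic": "intergenic",
    "utr_variant": "utr_variant",
}


def normalize_consequence(term: str) -> Optional[str]:
    """Map a consequence term onto the canonical vocabulary; None if unknown."""
    return _CONSEQUENCE_ALIASES.get(term.strip().lower())


@dataclass
class VariantRecord:
    """One called SNV with its annotations and per-sample genotypes.

    ``genotypes`` maps sample id to minor-allele count {0, 1, 2} or None for a
    missing call. ``read_depth`` maps sample id to supporting reads.
    ``control_maf`` / ``nordic_maf`` / ``public_mafs`` are allele frequencies
    in the internal control genomes, the Nordic control panel, and public
    databases respectively; None means unobserved.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = ""
    read_depth: Dict[str, int] = field(default_factory=dict)
    genotypes: Dict[str, Optional[int]] = field(default_factory=dict)
    chimp_allele: Optional[str] = None
    control_maf: Optional[float] = None
    control_het_only: bool = False
    nordic_maf: Optional[float] = None
    public_mafs: Dict[str, float] = field(default_factory=dict)
    predictor_calls: Dict[str, str] = field(default_factory=dict)
    snpdryad: Optional[float] = None
    linkage_z: Optional[float] = None
    rsid: str = "."
    info_extra: Dict[str, object] = field(default_factory=dict)
    families: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("control_maf", "nordic_maf"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def carriers(self) -> List[str]:
        return [s for s, g in self.genotypes.items() if g is not None and g >= 1]

    def min_carrier_depth(self) -> Optional[int]:
        depths = [self.read_depth[s] for s in self.carriers() if s in self.read_depth]
        return min(depths) if depths else None


@dataclass
class FilterReport:
    """Per-stage in/out counts plus per-record first-failing rule."""

    stages: List[Tuple[str, int, int]] = field(default_factory=list)
    removals: Dict[str, Tuple[str, str]] = field(default_factory=dict)

    def add_stage(self, name: str, n_in: int, n_out: int) -> None:
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError("stage counts do not telescope")
        self.stages.append((name, n_in, n_out))

    def record_removal(self, key: str, stage: str, reason: str) -> None:
        if key not in self.removals:  # first failing rule only
            self.removals[key] = (stage, reason)
            logger.info("removed %s at stage %s: %s", key, stage, reason)

    def to_rows(self) -> List[dict]:
        return [
            {"stage": s, "n_in": i, "n_out": o} for s, i, o in self.stages
        ]


# ----------------------------------------------------------------------------
# BED interval helpers (0-based half-open)

def read_bed(path: str) -> Dict[str, List[Tuple[int, int]]]:
    """Read a BED file into per-chromosome sorted interval lists."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    for chrom in out:
        out[chrom].sort()
    return out


def read_peaks_bed(path: str) -> List[Tuple[str, int, int, str, float]]:
    """Read linkage peaks: BED with name in col 4 and Z-score in col 5."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else "."
            z = float(f[4]) if len(f) > 4 else float("nan")
            peaks.append((f[0], int(f[1]), int(f[2]), name, z))
    return peaks


def _in_intervals(pos_1based: int, intervals: Sequence[Tuple[int, int]]) -> bool:
    p0 = pos_1based - 1  # convert to 0-based
    for start, end in intervals:
        if start <= p0 < end:
            return True
        if start > p0:
            break
    return False


# ----------------------------------------------------------------------------
# VCF input

_FLOAT_INFO = ("CMAF", "NMAF", "DRYAD", "LINKZ")


def _round6(x) -> float:
    # float32 round-trip through htslib; 6 decimals covers every printed MAF
    return round(float(x), 6)


def read_variant_table(path: str) -> List[VariantRecord]:
    """Load a VCF 4.2 variant table into :class:`VariantRecord` objects.

    Recognized INFO keys: GENE, CSQ (consequence), CHIMP (chimpanzee allele,
    "." for unknown), CMAF (internal-control MAF), CHET (flag: controls carry
    the variant only heterozygously), NMAF (Nordic-control MAF), PUBMAF
    ("pop:freq,..."), PRED ("algorithm:call,..."), DRYAD (SNPDryad score),
    LINKZ (linkage Z). FORMAT must provide GT and DP. Unknown INFO keys are
    preserved in ``info_extra``. Indel records are loaded as-is (the quality
    stage drops non-SNVs).
    """
    records: List[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read VCF {path}: {exc}") from exc
    known = {"GENE", "CSQ", "CHIMP", "CMAF", "CHET", "NMAF", "PUBMAF", "PRED",
             "DRYAD", "LINKZ"}
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(
                f"expected exactly one ALT allele at {rec.chrom}:{rec.pos}"
            )
        info = dict(rec.info)
        public = {}
        for item in str(info.get("PUBMAF", "") or "").split("|"):
            if ":" in item:
                pop, val = item.rsplit(":", 1)
                public[pop] = float(val)
        preds = {}
        for item in str(info.get("PRED", "") or "").split("|"):
            if ":" in item:
                alg, call = item.rsplit(":", 1)
                preds[alg] = {"D": "deleterious", "B": "benign"}.get(call, call)
        chimp = info.get("CHIMP")
        if chimp in (".", ""):
            chimp = None
        genotypes: Dict[str, Optional[int]] = {}
        depths: Dict[str, int] = {}
        for sample, call in rec.samples.items():
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                genotypes[sample] = None
            else:
                genotypes[sample] = int(sum(1 for a in gt if a == 1))
            dp = call.get("DP")
            if dp is not None:
                depths[sample] = int(dp)
        records.append(
            VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0],
                gene=str(info.get("GENE", "")),
                consequence=str(info.get("CSQ", "")),
                read_depth=depths,
                genotypes=genotypes,
                chimp_allele=str(chimp) if chimp is not None else None,
                control_maf=_round6(info["CMAF"]) if "CMAF" in info else None,
                control_het_only=bool(info.get("CHET", False)),
                nordic_maf=_round6(info["NMAF"]) if "NMAF" in info else None,
                public_mafs=public,
                predictor_calls=preds,
                snpdryad=_round6(info["DRYAD"]) if "DRYAD" in info else None,
                linkage_z=_round6(info["LINKZ"]) if "LINKZ" in info else None,
                rsid=rec.id or ".",
                info_extra={k: v for k, v in info.items() if k not in known},
            )
        )
    return records


# ----------------------------------------------------------------------------
# Cascade stages

def apply_quality_filters(
    records: Sequence[VariantRecord],
    repeat_mask: Dict[str, List[Tuple[int, int]]],
    thresholds: Thresholds = Thresholds(),
    report: Optional[FilterReport] = None,
) -> List[VariantRecord]:
    """Read-support, repeat-mask and ancestral-allele quality filters.

    Keeps SNVs whose every carrier has >= ``min_reads`` supporting reads,
    whose position lies outside all repeat-masked intervals, and whose
    alternative allele differs from the chimpanzee (ancestral) allele; an
    unknown chimpanzee allele passes. Indels are dropped by record type.
    """
    kept = []
    for r in records:
        if not r.is_snv:
            reason = "not_snv"
        elif (d := r.min_carrier_depth()) is not None and d < thresholds.min_reads:
            reason = "low_reads"
        elif _in_intervals(r.pos, repeat_mask.get(r.chrom, ())):
            reason = "repeat_masked"
        elif r.chimp_allele is not None and r.alt == r.chimp_allele:
            reason = "ancestral_allele"
        else:
            kept.append(r)
            continue
        if report is not None:
            report.record_removal(r.key, "quality", reason)
    return kept


def apply_consequence_filter(
    records: Sequence[VariantRecord],
    report: Optional[FilterReport] = None,
    on_unknown: str = "drop",
) -> List[VariantRecord]:
    """Keep stop-gain/loss, essential-splice-site and missense variants.

    ``on_unknown`` controls handling of terms outside the vocabulary:
    ``"drop"`` warns and removes (default), ``"error"`` raises.
    """
    kept = []
    for r in records:
        canon = normalize_consequence(r.consequence)
        if canon is None:
            if on_unknown == "error":
                raise ValueError(f"unknown consequence term {r.consequence!r} at {r.key}")
            logger.warning("unknown consequence %r at %s; dropping", r.consequence, r.key)
            if report is not None:
                report.record_removal(r.key, "consequence", "unknown_term")
            continue
        if canon in DAMAGING_CONSEQUENCES:
            kept.append(r)
        elif report is not None:
            report.record_removal(r.key, "consequence", f"excluded_class:{canon}")
    return kept


def apply_sharing_filter(
    records: Sequence[VariantRecord],
    family_samples: Dict[str, Sequence[str]],
    report: Optional[FilterReport] = None,
) -> List[VariantRecord]:
    """Keep variants carried by every sequenced affected member of >=1 family.

    Carriage means genotype >= 1 (het or hom). Qualifying families are written
    to ``record.families``.
    """
    all_ids = {s for ids in family_samples.values() for s in ids}
    kept = []
    for r in records:
        missing = all_ids - set(r.genotypes)
        if missing:
            raise KeyError(
                f"sample id(s) {sorted(missing)} absent from genotypes of {r.key}"
            )
        fams = [
            fam
            for fam, ids in family_samples.items()
            if ids and all((r.genotypes[s] or 0) >= 1 for s in ids)
        ]
        if fams:
            r.families = sorted(fams)
            kept.append(r)
        elif report is not None:
            report.record_removal(r.key, "sharing", "not_shared_in_any_family")
    return kept


def _frequency_branches(r: VariantRecord, thresholds: Thresholds):
    """Return (passed, failed_branch_reasons) for the three inclusion routes."""
    cmaf = r.control_maf if r.control_maf is not None else 0.0
    failed = []
    if cmaf <= thresholds.control_maf_max:
        return True, []
    failed.append(f"control_maf>{thresholds.control_maf_max}")
    if cmaf == 0.0:
        return True, []
    failed.append("control_maf>0")
    case_hom = any(g == 2 for g in r.genotypes.values() if g is not None)
    if (
        case_hom
        and r.control_het_only
        and cmaf <= thresholds.caseonly_hom_control_maf_max
    ):
        return True, []
    failed.append("caseonly_hom_branch_failed")
    return False, failed


def apply_frequency_filter(
    records: Sequence[VariantRecord],
    thresholds: Thresholds = Thresholds(),
    report: Optional[FilterReport] = None,
) -> List[VariantRecord]:
    """Control-population frequency filter with three OR-combined branches.

    (a) internal-control MAF <= 0.5%; (b) absent from controls (MAF = 0);
    (c) some case is homozygous for the alternative allele while controls
    carry it only heterozygously with MAF <= 5%. A missing control MAF is
    treated as 0 (never observed in controls).
    """
    kept = []
    for r in records:
        ok, failed = _frequency_branches(r, thresholds)
        if ok:
            kept.append(r)
        elif report is not None:
            report.record_removal(r.key, "frequency", ";".join(failed))
    return kept


def annotate_linkage_regions(
    records: Sequence[VariantRecord],
    linkage_peaks: Sequence[Tuple[str, int, int, str, float]],
    window_bp: int = 20_000_000,
) -> List[VariantRecord]:
    """Attach linkage Z-scores to variants within ``window_bp`` of a peak.

    Pure annotation: no records are removed. When several peaks qualify the
    largest Z is kept. Z-scores are carried as input annotation; they are
    never computed here.
    """
    records = list(records)
    for r in records:
        best = None
        p0 = r.pos - 1
        for chrom, start, end, _name, z in linkage_peaks:
            if chrom != r.chrom:
                continue
            if start - window_bp <= p0 < end + window_bp:
                if best is None or z > best:
                    best = z
        if best is not None:
            r.linkage_z = best
    return records


def run_filter_cascade(
    path: str,
    repeat_mask_path: Optional[str],
    linkage_peaks_path: Optional[str],
    family_samples: Dict[str, Sequence[str]],
    thresholds: Thresholds = Thresholds(),
) -> Tuple[List[VariantRecord], FilterReport]:
    """Run the full cascade: quality -> consequence -> sharing -> frequency,
    then linkage annotation. Returns retained records and the stage report."""
    records = read_variant_table(path)
    mask = read_bed(repeat_mask_path) if repeat_mask_path else {}
    peaks = read_peaks_bed(linkage_peaks_path) if linkage_peaks_path else []
    report = FilterReport()

    n0 = len(records)
    stage1 = apply_quality_filters(records, mask, thresholds, report)
    report.add_stage("quality", n0, len(stage1))
    stage2 = apply_consequence_filter(stage1, report)
    report.add_stage("consequence", len(stage1), len(stage2))
    stage3 = apply_sharing_filter(stage2, family_samples, report)
    report.add_stage("sharing", len(stage2), len(stage3))
    stage4 = apply_frequency_filter(stage3, thresholds, report)
    report.add_stage("frequency", len(stage3), len(stage4))
    final = annotate_linkage_regions(stage4, peaks, thresholds.linkage_window_bp)
    report.add_stage("linkage_annotation", len(stage4), len(final))
    return final, report
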