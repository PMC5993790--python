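"""Configuration objects: every numeric cut-off of the pipeline in one place.

``Thresholds`` collects the quality, frequency, QC and correction cut-offs of
the exome-filtering / segregation / association pipeline; ``AssocConfig``
parameterizes the gene-based rare-variant association machinery. Defaults are
the published study values and are what the rest of the package (and the CLI)
uses unless a YAML config overrides them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml


@dataclass
class Thresholds:
    """Numeric cut-offs of the filtering, QC and correction stages.

    Attributes
    ----------
    min_reads
        Minimum supporting reads per carrier sample for a called SNV (inclusive).
    control_maf_max
        Main rare-variant inclusion branch: MAF in the internal control genomes
        must be <= this value (0.5%).
    caseonly_hom_control_maf_max
        Case-only-homozygous branch: variants homozygous only in patients and
        het-only in controls are kept up to this control MAF (5%).
    nordic_poly_maf
        Variants with MAF strictly above this in the Nordic control panel are
        flagged as regional polymorphisms (5%).
    rare_maf
        "Rare variation" definition for the association tests: MAF strictly
        below 1%.
    ld_r2
        LD pruning threshold: kept markers must have pairwise r^2 strictly
        below this (0.1).
    n_pcs
        Number of leading principal components used as stratification
        covariates (10).
    region_buffer_bp
        Gene regions are extended this many bp up- and downstream (500 kb).
    linkage_window_bp
        Linkage-peak annotation window, +/- 20 Mb.
    variant_callrate
        Segregation genotyping QC: per-variant call rate >= 90%.
    sample_callrate
        Segregation genotyping QC: per-sample call rate >= 80%.
    imputed_snp_rate
        Post-imputation QC: SNP genotyping rate >= 99%.
    imputed_sample_rate
        Post-imputation QC: sample genotyping rate >= 95%.
    impute_info
        Post-imputation QC: imputation info metric >= 0.7.
    concordance
        Post-imputation QC: genotype concordance >= 95%.
    """

    min_reads: int = 6
    control_maf_max: float = 0.005
    caseonly_hom_control_maf_max: float = 0.05
    nordic_poly_maf: float = 0.05
    rare_maf: float = 0.01
    ld_r2: float = 0.1
    n_pcs: int = 10
    region_buffer_bp: int = 500_000
    linkage_window_bp: int = 20_000_000
    variant_callrate: float = 0.90
    sample_callrate: float = 0.80
    imputed_snp_rate: float = 0.99
    imputed_sample_rate: float = 0.95
    impute_info: float = 0.7
    concordance: float = 0.95

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be non-negative")
        for name in (
            "control_maf_max",
            "caseonly_hom_control_maf_max",
            "nordic_poly_maf",
            "rare_maf",
            "variant_callrate",
            "sample_callrate",
            "imputed_snp_rate",
            "imputed_sample_rate",
            "impute_info",
            "concordance",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.ld_r2 <= 1.0:
            raise ValueError("ld_r2 must be in (0, 1]")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        if self.region_buffer_bp < 0 or self.linkage_window_bp < 0:
            raise ValueError("window sizes must be >= 0")


@dataclass
class AssocConfig:
    """Settings for the gene-based rare-variant association tests.

    ``skat_weights`` is either ``"flat"`` (w_j = 1) or ``("beta", a, b)`` for
    Beta(a, b) density weights evaluated at the marker MAF (the customary
    choice is Beta(1, 25) to up-weight the rarest markers).
    """

    rare_maf: float = 0.01
    ld_r2: float = 0.1
    n_pcs: int = 10
    region_buffer_bp: int = 500_000
    n_permutations: int = 10_000
    seed: int = 0
    test_set: tuple = ("enrichment", "skat")
    skat_weights: object = "flat"

    def __post_init__(self) -> None:
        if not 0.0 < self.rare_maf <= 0.5:
            raise ValueError("rare_maf must be in (0, 0.5]")
        if not 0.0 < self.ld_r2 <= 1.0:
            raise ValueError("ld_r2 must be in (0, 1]")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        self.test_set = tuple(self.test_set)
        for t in self.test_set:
            if t not in ("enrichment", "skat"):
                raise ValueError(f"unknown test {t!r}")
        w = self.skat_weights
        if w != "flat":
            if not (isinstance(w, (tuple, list)) and len(w) == 3 and w[0] == "beta"):
                raise ValueError("skat_weights must be 'flat' or ('beta', a, b)")
            self.skat_weights = ("beta", float(w[1]), float(w[2]))


@dataclass
class RunConfig:
    """A full pipeline run: thresholds, association settings, seed, logging."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "thresholds": dataclasses.asdict(self.thresholds),
            "assoc": {
                **dataclasses.asdict(self.assoc),
                "test_set": list(self.assoc.test_set),
                "skat_weights": (
                    self.assoc.skat_weights
                    if isinstance(self.assoc.skat_weights, str)
                    else list(self.assoc.skat_weights)
                ),
            },
            "seed": self.seed,
            "log_level": self.log_level,
        }


def _check_unknown(section: str, given: dict, allowed: set) -> None:
    unknown = sorted(set(given) - allowed)
    if unknown:
        raise ValueError(f"unknown config key(s) in {section}: {', '.join(unknown)}")


def load_config(path: str) -> RunConfig:
    """Load a YAML run configuration, applying defaults for absent keys.

    Unknown keys are rejected with an error naming them; an empty file yields
    the full set of published defaults. The round trip
    ``save_config(load_config(p))`` is lossless.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_unknown("root", raw, {"thresholds", "assoc", "seed", "log_level"})
    thr_raw = raw.get("thresholds", {}) or {}
    assoc_raw = dict(raw.get("assoc", {}) or {})
    _check_unknown("thresholds", thr_raw, {f.name for f in dataclasses.fields(Thresholds)})
    _check_unknown("assoc", assoc_raw, {f.name for f in dataclasses.fields(AssocConfig)})
    if isinstance(assoc_raw.get("skat_weights"), list):
        assoc_raw["skat_weights"] = tuple(assoc_raw["skat_weights"])
    return RunConfig(
        thresholds=Thresholds(**thr_raw),
        assoc=AssocConfig(**assoc_raw),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def save_config(config: RunConfig, path: str) -> None:
    """Write a RunConfig back to YAML (inverse of :func:`load_config`)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
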