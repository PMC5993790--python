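"""Formats and reporting: the packaged variant table, cohort TSV round trips,
and deterministic result writers.

The 19-variant segregation table from the familial exome study is shipped as
a versioned TSV (``data/table1_variants.tsv``) so tests and users read the
same artifact; :func:`load_table1` parses it. Cohorts travel as a trio of
TSVs (wide dosage matrix, marker metadata, sample metadata + phenotype),
which keeps everything plain text and diffable.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .assoc import CohortData, GeneTestResult, results_frame
from .segregation import SegregationSummary, rank_segregation

TABLE1_RESOURCE = "table1_variants.tsv"


def table1_path() -> str:
    """Filesystem path of the packaged 19-variant segregation table."""
    return str(importlib.resources.files("rarefam.data") / TABLE1_RESOURCE)


def load_table1() -> pd.DataFrame:
    """Load the packaged segregation table (19 rows, one per variant).

    Missing cells (printed as em-dashes in the source) are NA. Carrier
    columns are nullable integers; frequency columns floats in [0, 1].
    """
    df = pd.read_csv(table1_path(), sep="\t", na_values=["NA"])
    for col in ("fam6_carriers", "fam6_affected", "fam8_carriers", "fam8_affected"):
        df[col] = df[col].astype("Int64")
    return df


# ----------------------------------------------------------------------------
# Cohort text round trip

def write_cohort(cohort: CohortData, prefix: str) -> dict:
    """Write a cohort as TSVs: ``<prefix>.dosages.tsv`` (samples x markers),
    ``<prefix>.markers.tsv`` and ``<prefix>.samples.tsv`` (with phenotype)."""
    paths = {
        "dosages": f"{prefix}.dosages.tsv",
        "markers": f"{prefix}.markers.tsv",
        "samples": f"{prefix}.samples.tsv",
    }
    dos = pd.DataFrame(
        cohort.dosages,
        index=cohort.samples["id"].to_numpy(),
        columns=cohort.markers["id"].to_numpy(),
    )
    dos.to_csv(paths["dosages"], sep="\t", index_label="sample", na_rep="NA")
    cohort.markers.to_csv(paths["markers"], sep="\t", index=False, na_rep="NA")
    samples = cohort.samples.copy()
    samples["phenotype"] = cohort.y
    samples.to_csv(paths["samples"], sep="\t", index=False, na_rep="NA")
    return paths


def read_cohort(prefix: str) -> CohortData:
    """Inverse of :func:`write_cohort`."""
    dos = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t", index_col=0, na_values=["NA"])
    markers = pd.read_csv(f"{prefix}.markers.tsv", sep="\t", na_values=["NA"])
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", na_values=["NA"])
    y = samples.pop("phenotype").to_numpy(dtype=int)
    return CohortData(
        dosages=dos.to_numpy(dtype=float),
        y=y,
        markers=markers,
        samples=samples,
    )


# ----------------------------------------------------------------------------
# Reports

def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


def write_segregation_report(
    summaries: Sequence[SegregationSummary],
    path: str,
    polymorphism_flags: Optional[dict] = None,
) -> pd.DataFrame:
    """Write the ranked cross-family carrier table as TSV.

    Columns mirror the published segregation table: per-family
    "carriers/cases" cells plus cross-family totals; formatting is
    locale-independent and deterministic (same input -> identical bytes).
    """
    table = rank_segregation(summaries)
    families = sorted({s.family for s in summaries})
    rows = []
    for _, r in table.iterrows():
        row = {
            "variant": r["variant"],
            "gene": r["gene"],
            "chrom": r["chrom"],
            "pos": r["pos"],
        }
        for fam in families:
            row[f"family_{fam}_carriers_cases"] = r["per_family"].get(fam, "NA")
        row["total_carriers"] = r["total_carriers"]
        row["total_affected"] = r["total_affected"]
        if polymorphism_flags is not None:
            flag = polymorphism_flags.get(r["variant"])
            row["population_polymorphism"] = (
                "NA" if flag is None else ("yes" if flag else "no")
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    with open(path, "w", newline="\n") as fh:
        if out.empty:
            cols = ["variant", "gene", "chrom", "pos", "total_carriers", "total_affected"]
            fh.write("\t".join(cols) + "\n")
        else:
            fh.write("\t".join(out.columns) + "\n")
            for _, r in out.iterrows():
                fh.write("\t".join(_fmt(v) for v in r) + "\n")
    return out


def write_association_report(results: Iterable[GeneTestResult], path: str) -> pd.DataFrame:
    """Write per-gene association results (gene, NMK, P, Pmult per test)."""
    table = results_frame(list(results))
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(table.columns) + "\n")
        for _, r in table.iterrows():
            fh.write("\t".join(_fmt(v) for v in r) + "\n")
    return table


def write_filter_report(report, path: str) -> None:
    """Write stage counts and per-record removal reasons as TSV."""
    with open(path, "w", newline="\n") as fh:
        fh.write("stage\tn_in\tn_out\n")
        for stage, n_in, n_out in report.stages:
            fh.write(f"{stage}\t{n_in}\t{n_out}\n")
        fh.write("#removals\n")
        fh.write("record\tstage\trule\n")
        for key in sorted(report.removals):
            stage, reason = report.removals[key]
            fh.write(f"{key}\t{stage}\t{reason}\n")
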