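"""Gene-based rare-variant case-control association.

Implements the two gene-level procedures used to test whether rare variation
(MAF < 1%) in a candidate gene is collectively associated with case status:

* an aggregated case-control **enrichment (burden) test** — logistic
  regression of case status on the per-individual sum of rare minor alleles
  in the gene, adjusted for principal components; the reported statistic is
  the burden coefficient's 1-df Wald chi-square; and
* the **sequence kernel association test (SKAT)** — a variance-component
  score test with statistic Q = sum_j w_j^2 S_j^2, S_j = sum_i G_ij (y_i -
  mu_i), whose null distribution is a weighted mixture of 1-df chi-squares
  evaluated by exact characteristic-function inversion (four-moment
  approximation as tail fallback).

Stratification is corrected twice, mirroring the study design: the leading
principal components of the genome-wide dosage matrix enter both models as
covariates, and the residual genomic inflation factor lambda_GC (median
observed chi-square over the chi-square-1 null median) divides the
statistics. Multiple testing is corrected by an empirical permutation scheme
that pools the (LD-pruned, rare) markers of all tested genes and redraws
equally sized marker sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from ._glm import LogitFit, SeparationError, fit_logistic, score_test_components, wald_chi2
from .config import AssocConfig, Thresholds

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = float(stats.chi2.median(1))  # 0.4549... ("0.456")


# ----------------------------------------------------------------------------
# Containers

@dataclass
class CohortData:
    """A case-control cohort: dosage matrix plus marker and sample metadata.

    ``dosages`` is samples x markers with minor-allele counts in {0, 1, 2}
    (fractional values allowed for imputed data; NaN = missing call).
    ``markers`` must carry columns ``id, chrom, pos`` and may carry ``gene,
    info, concordance, call_rate``; ``samples`` carries ``id`` and optional
    ``call_rate``. ``pcs`` holds sample principal-component scores once
    computed.
    """

    dosages: np.ndarray
    y: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame
    pcs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.y) != n or len(self.samples) != n or len(self.markers) != m:
            raise ValueError("inconsistent cohort dimensions")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("phenotype must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]


@dataclass
class GeneTestResult:
    """Association output for one gene (one row of the results table)."""

    gene: str
    n_markers: int
    enrichment_stat: float = np.nan
    enrichment_p: float = np.nan
    skat_q: float = np.nan
    skat_p: float = np.nan
    lambda_gc_enrichment: float = np.nan
    lambda_gc_skat: float = np.nan
    enrichment_p_gc: float = np.nan
    skat_p_gc: float = np.nan
    pmult_enrichment: float = np.nan
    pmult_skat: float = np.nan
    flags: List[str] = field(default_factory=list)


# ----------------------------------------------------------------------------
# Marker bookkeeping

def extend_gene_region(interval: Tuple[int, int], buffer_bp: int) -> Tuple[int, int]:
    """Extend a 1-based closed interval by ``buffer_bp`` on both sides.

    The start is clamped at 1.
    """
    start, end = interval
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return max(1, start - buffer_bp), end + buffer_bp


def marker_qc(cohort: CohortData, thresholds: Thresholds = Thresholds()) -> CohortData:
    """Post-imputation QC on markers and samples (all boundaries inclusive).

    Markers must have genotyping rate >= ``imputed_snp_rate``, imputation info
    >= ``impute_info`` and concordance >= ``concordance``; samples must have
    genotyping rate >= ``imputed_sample_rate``. No allele-frequency
    restriction is applied at this stage. Missing metadata columns pass.
    """
    mk = cohort.markers
    keep_m = np.ones(cohort.n_markers, dtype=bool)
    for col, thr in (
        ("call_rate", thresholds.imputed_snp_rate),
        ("info", thresholds.impute_info),
        ("concordance", thresholds.concordance),
    ):
        if col in mk.columns:
            vals = mk[col].to_numpy(dtype=float)
            keep_m &= np.isnan(vals) | (vals >= thr)
    keep_s = np.ones(cohort.n_samples, dtype=bool)
    if "call_rate" in cohort.samples.columns:
        vals = cohort.samples["call_rate"].to_numpy(dtype=float)
        keep_s = np.isnan(vals) | (vals >= thresholds.imputed_sample_rate)
    return CohortData(
        dosages=cohort.dosages[np.ix_(keep_s, keep_m)],
        y=cohort.y[keep_s],
        markers=mk.loc[keep_m].reset_index(drop=True),
        samples=cohort.samples.loc[keep_s].reset_index(drop=True),
        pcs=cohort.pcs[keep_s] if cohort.pcs is not None else None,
    )


def allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per marker over called alleles only."""
    d = np.asarray(dosages, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.nanmean(d, axis=0) / 2.0


def orient_minor(dosages: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Flip dosages so they count the minor allele; returns (dosages, maf)."""
    d = np.array(dosages, dtype=float, copy=True)
    freq = allele_frequencies(d)
    flip = freq > 0.5
    d[:, flip] = 2.0 - d[:, flip]
    maf = np.where(flip, 1.0 - freq, freq)
    return d, maf


def select_rare_markers(
    cohort: CohortData,
    interval: Tuple[str, int, int],
    rare_maf: float = 0.01,
) -> np.ndarray:
    """Indices of polymorphic markers in the interval with MAF < ``rare_maf``.

    The MAF is computed on the pooled case+control sample from called alleles
    and folded to the minor allele; the cut is strict and monomorphic markers
    (MAF = 0, no information) are excluded.
    """
    chrom, start, end = interval
    pos = cohort.markers["pos"].to_numpy()
    on_chrom = (cohort.markers["chrom"].to_numpy() == chrom) & (pos >= start) & (pos <= end)
    idx = np.flatnonzero(on_chrom)
    if idx.size == 0:
        return idx
    freq = allele_frequencies(cohort.dosages[:, idx])
    maf = np.minimum(freq, 1.0 - freq)
    keep = (maf > 0.0) & (maf < rare_maf)
    return idx[keep]


def ld_prune(
    dosages: np.ndarray,
    positions: Optional[np.ndarray] = None,
    r2_max: float = 0.1,
) -> np.ndarray:
    """Greedy LD pruning: scan markers in position order and keep a marker iff
    its squared Pearson correlation with every already-kept marker is below
    ``r2_max``. Returns kept column indices (in scan order; earliest position
    wins ties).
    """
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    if m == 0:
        return np.array([], dtype=int)
    order = np.arange(m) if positions is None else np.argsort(positions, kind="mergesort")
    col_means = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), col_means[None, :], d)
    centered = filled - filled.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    kept: List[int] = []
    kept_cols = np.empty((n, 0))
    for j in order:
        if norms[j] == 0.0:
            continue  # monomorphic: carries no information
        if kept:
            r = (kept_cols.T @ centered[:, j]) / (
                norms[np.array(kept)] * norms[j]
            )
            if np.any(r**2 >= r2_max):
                continue
        kept.append(int(j))
        kept_cols = np.concatenate([kept_cols, centered[:, j : j + 1]], axis=1)
    return np.array(kept, dtype=int)


def compute_pcs(dosages: np.ndarray, n_pcs: int = 10) -> np.ndarray:
    """Principal-component scores of the standardized dosage matrix.

    Columns are mean-imputed, centered and scaled to unit variance
    (zero-variance columns dropped). The SVD is deterministic; each
    component's sign is fixed by making its largest-magnitude loading
    positive, so scores are reproducible across runs and duplicated samples
    receive identical scores.
    """
    if n_pcs == 0:
        return np.empty((dosages.shape[0], 0))
    d = np.asarray(dosages, dtype=float)
    col_means = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), col_means[None, :], d)
    sd = filled.std(axis=0)
    keep = sd > 0
    z = (filled[:, keep] - filled[:, keep].mean(axis=0)) / sd[keep]
    rank = min(z.shape)
    if n_pcs > rank:
        logger.warning("n_pcs=%d exceeds rank %d; reduced", n_pcs, rank)
        n_pcs = rank
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(z)
    for k in range(n_pcs):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            scores[:, k] *= -1.0
    return scores


def burden_score(dosages: np.ndarray) -> np.ndarray:
    """Per-sample sum of minor alleles over the gene's rare markers.

    Input dosages must already be minor-allele oriented; missing dosages
    contribute 0 to the sum.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    return np.nan_to_num(d, nan=0.0).sum(axis=1)


# ----------------------------------------------------------------------------
# Tests

@dataclass
class EnrichmentResult:
    stat: float
    p: float
    beta: float = np.nan
    flag: Optional[str] = None


def enrichment_test(
    score: np.ndarray,
    y: np.ndarray,
    pcs: Optional[np.ndarray] = None,
) -> EnrichmentResult:
    """Burden ("enrichment") test: logistic y ~ 1 + score + PCs.

    Returns the burden coefficient's Wald chi-square (1 df) and p-value.
    A constant score or a separated fit is flagged and reported as p = 1.
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(score) == 0.0:
        return EnrichmentResult(stat=0.0, p=1.0, flag="constant_score")
    cols = [np.ones_like(score), score]
    if pcs is not None and pcs.size:
        cols.append(np.asarray(pcs, dtype=float))
    X = np.column_stack(cols)
    try:
        fit = fit_logistic(X, y)
        stat = wald_chi2(fit, 1)
    except SeparationError as exc:
        return EnrichmentResult(stat=0.0, p=1.0, flag=f"separation:{exc}")
    return EnrichmentResult(
        stat=stat, p=float(stats.chi2.sf(stat, 1)), beta=float(fit.beta[1])
    )


def mixture_sf(q: float, lambdas: np.ndarray) -> float:
    """Upper-tail probability of Q = sum_k lambda_k chi2_1, exactly.

    Evaluates Imhof's characteristic-function inversion integral
    ``P(Q > q) = 1/2 + (1/pi) int_0^inf sin(theta(u)) / (u rho(u)) du`` with
    a vectorized midpoint rule: the step is set by the aliasing period
    (spanning both tails of Q) and the truncation point by the decay of the
    integrand envelope, giving ~1e-6 absolute accuracy. Used as the primary
    kernel-test p-value because the four-moment approximation
    (:func:`liu_sf`) is biased at the distribution *median* for the skewed
    eigenvalue spectra rare markers produce — and the genomic-control factor
    is a median statistic, so that bias would masquerade as stratification
    inflation. Falls back to the moment match deep in the tail, where
    inversion at this accuracy is uninformative.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1))
    m = lam.size
    c1, c2 = lam.sum(), (lam**2).sum()
    span = q + c1 + 20.0 * np.sqrt(2.0 * c2)  # aliasing period covers both tails
    delta = 2.0 * np.pi / span
    # truncate where a single midpoint term drops below 1e-8:
    # envelope ~ 1 / (prod sqrt(lam) * u^(1+m/2)) for large u
    log_prod_sqrt = 0.5 * np.log(lam).sum()
    log_u = (np.log(delta / np.pi) - np.log(1e-8) - log_prod_sqrt) / (1.0 + m / 2.0)
    upper = max(np.exp(log_u), 20.0 * delta)
    n_terms = int(np.ceil(upper / delta))
    if n_terms > 5_000_000:
        return liu_sf(q, lam)
    total = 0.0
    for start in range(0, n_terms, 100_000):
        u = (np.arange(start, min(start + 100_000, n_terms)) + 0.5) * delta
        theta = 0.5 * np.arctan(np.outer(u, lam)).sum(axis=1) - 0.5 * q * u
        log_rho = 0.25 * np.log1p(np.outer(u, lam) ** 2).sum(axis=1)
        total += float(np.sum(np.sin(theta) * np.exp(-log_rho) / u))
    p = 0.5 + (delta / np.pi) * total
    if not 1e-6 < p <= 1.0 + 1e-9:
        return liu_sf(q, lam)
    return float(min(p, 1.0))


def liu_sf(q: float, lambdas: np.ndarray) -> float:
    """Upper-tail probability of Q = sum_k lambda_k chi2_1 by moment matching.

    Matches the first four cumulants of the mixture to a (possibly
    noncentral) scaled chi-square, the standard fully-numeric approximation
    to the kernel-test null distribution. Exact when a single eigenvalue
    remains (the mixture *is* a scaled chi-square-1 then).
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2.0 * delta))
    t = (q - mu_q) / sigma_q
    x = t * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(x, df, delta))
    return float(stats.chi2.sf(x, df))


def skat_weights_from_maf(maf: np.ndarray, spec: object = "flat") -> np.ndarray:
    """Per-marker weights w_j: flat (1) or Beta(a, b) density at the MAF."""
    maf = np.asarray(maf, dtype=float)
    if isinstance(spec, str) and spec == "flat":
        return np.ones_like(maf)
    kind, a, b = spec
    assert kind == "beta"
    return stats.beta.pdf(maf, a, b)


@dataclass
class SkatResult:
    q: float
    p: float
    lambdas: np.ndarray = field(default_factory=lambda: np.empty(0))
    flag: Optional[str] = None


def skat_test(
    G: np.ndarray,
    y: np.ndarray,
    pcs: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
) -> SkatResult:
    """Sequence kernel association test for a gene's marker matrix G.

    Fits the null logistic model y ~ 1 + PCs with means mu, forms the score
    vector S = (GW)'(y - mu) for weighted genotypes, and evaluates
    Q = sum_j w_j^2 S_j^2 against its null distribution, the weighted mixture
    of 1-df chi-squares whose weights are the eigenvalues of the null-model
    projected covariance of the weighted genotypes.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    G = np.nan_to_num(G, nan=0.0)
    y = np.asarray(y, dtype=float)
    if not np.any(G):
        return SkatResult(q=0.0, p=1.0, flag="all_zero_genotypes")
    n, m = G.shape
    if weights is None:
        weights = np.ones(m)
    X0_cols = [np.ones(n)]
    if pcs is not None and pcs.size:
        X0_cols.append(np.asarray(pcs, dtype=float))
    X0 = np.column_stack(X0_cols)
    fit = fit_logistic(X0, y)
    Gw = G * np.asarray(weights, dtype=float)[None, :]
    U, V = score_test_components(Gw, y, X0, fit.mu)
    q = float(U @ U)
    lambdas = np.linalg.eigvalsh(V)
    return SkatResult(q=q, p=mixture_sf(q, lambdas), lambdas=lambdas)


# ----------------------------------------------------------------------------
# Stratification and multiple-testing corrections

def genomic_control(p_values: Sequence[float]) -> float:
    """Genomic inflation factor lambda_GC from a set of p-values.

    Each p is converted to its 1-df chi-square quantile; lambda is the median
    of those statistics divided by the chi-square-1 median (~0.456).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    chi2_stats = stats.chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    return float(np.median(chi2_stats) / CHI2_1_MEDIAN)


def gc_correct(
    stat: float,
    lam: float,
    kind: str = "enrichment",
    lambdas: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Deflate a statistic by lambda_GC and recompute its p-value.

    Enrichment statistics are chi-square-1: corrected p = P(chi2_1 >
    stat/lam). SKAT Q statistics are rescaled by 1/lam and re-evaluated
    against the unscaled eigenvalue mixture.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    corrected = stat / lam
    if kind == "enrichment":
        return corrected, float(stats.chi2.sf(corrected, 1))
    if kind == "skat":
        if lambdas is None:
            raise ValueError("SKAT correction needs the eigenvalue mixture")
        return corrected, mixture_sf(corrected, lambdas)
    raise ValueError(f"unknown statistic kind {kind!r}")


def permutation_pmult(
    p_obs: float,
    nmk: int,
    pool: np.ndarray,
    y: np.ndarray,
    pcs: Optional[np.ndarray],
    test: str,
    n_permutations: int,
    seed: int,
    lam: float = 1.0,
    skat_weights_spec: object = "flat",
    pool_maf: Optional[np.ndarray] = None,
) -> float:
    """Empirical multiple-testing-corrected p-value (Pmult).

    Draws ``nmk`` markers without replacement from the pooled marker table
    (minor-allele oriented dosage columns of every tested gene), reruns the
    same test with the same covariates and the same lambda_GC correction, and
    returns the add-one empirical estimate
    ``(1 + #{p_perm <= p_obs}) / (N + 1)`` — bounded below by 1/(N+1), so a
    zero p-value is never reported.
    """
    n, M = pool.shape
    if M < nmk:
        raise ValueError(f"pooled table has {M} markers < gene's {nmk}")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        cols = rng.choice(M, size=nmk, replace=False)
        sub = pool[:, cols]
        if test == "enrichment":
            res = enrichment_test(burden_score(sub), y, pcs)
            _, p_perm = gc_correct(res.stat, lam, "enrichment")
        elif test == "skat":
            maf = pool_maf[cols] if pool_maf is not None else allele_frequencies(sub)
            w = skat_weights_from_maf(maf, skat_weights_spec)
            res = skat_test(sub, y, pcs, weights=w)
            _, p_perm = gc_correct(res.q, lam, "skat", res.lambdas)
        else:
            raise ValueError(f"unknown test {test!r}")
        if p_perm <= p_obs:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


# ----------------------------------------------------------------------------
# Orchestration

def gene_intervals_from_markers(markers: pd.DataFrame, genes: Sequence[str]):
    """Derive per-gene (chrom, start, end) spans from marker metadata."""
    out = {}
    for gene in genes:
        rows = markers[markers["gene"] == gene]
        if rows.empty:
            out[gene] = None
        else:
            out[gene] = (
                str(rows["chrom"].iloc[0]),
                int(rows["pos"].min()),
                int(rows["pos"].max()),
            )
    return out


def run_gene_tests(
    cohort: CohortData,
    genes: Sequence[str],
    config: AssocConfig = AssocConfig(),
    gene_regions: Optional[Dict[str, Tuple[str, int, int]]] = None,
    lambda_overrides: Optional[Dict[str, float]] = None,
) -> List[GeneTestResult]:
    """Run the full per-gene association pipeline over a list of genes.

    Per gene: extend the region by the buffer, select rare markers
    (MAF < ``rare_maf``), LD-prune at r^2 < ``ld_r2``, run the enrichment and
    SKAT tests with PC covariates; then compute lambda_GC across genes per
    test, deflate the statistics, and attach permutation Pmult values drawn
    from the pooled pruned-marker table. Genes with no qualifying markers are
    reported with NaN results (never fatal).

    ``lambda_overrides`` ({"enrichment": ..., "skat": ...}) can supply
    externally estimated inflation factors (e.g. from a genome-wide null set)
    instead of the across-genes median, which is meaningful only for large
    gene lists.
    """
    if cohort.pcs is None:
        cohort.pcs = compute_pcs(cohort.dosages, config.n_pcs)
    pcs = cohort.pcs[:, : config.n_pcs] if config.n_pcs else None

    regions = gene_regions or gene_intervals_from_markers(cohort.markers, genes)
    results: List[GeneTestResult] = []
    per_gene_cols: Dict[str, np.ndarray] = {}
    pool_cols: List[np.ndarray] = []

    for gene in genes:
        region = regions.get(gene)
        if region is None:
            logger.warning("gene %s: no region/markers; skipped", gene)
            results.append(GeneTestResult(gene=gene, n_markers=0, flags=["no_markers"]))
            continue
        chrom, start, end = region
        ext = extend_gene_region((start, end), config.region_buffer_bp)
        idx = select_rare_markers(cohort, (chrom, ext[0], ext[1]), config.rare_maf)
        if idx.size == 0:
            logger.warning("gene %s: no rare markers in region; skipped", gene)
            results.append(GeneTestResult(gene=gene, n_markers=0, flags=["no_markers"]))
            continue
        sub, maf = orient_minor(cohort.dosages[:, idx])
        kept = ld_prune(sub, cohort.markers["pos"].to_numpy()[idx], config.ld_r2)
        sub, maf = sub[:, kept], maf[kept]
        per_gene_cols[gene] = sub
        pool_cols.append(sub)

        res = GeneTestResult(gene=gene, n_markers=sub.shape[1])
        if "enrichment" in config.test_set:
            enr = enrichment_test(burden_score(sub), cohort.y, pcs)
            res.enrichment_stat, res.enrichment_p = enr.stat, enr.p
            if enr.flag:
                res.flags.append(f"enrichment:{enr.flag}")
        if "skat" in config.test_set:
            w = skat_weights_from_maf(maf, config.skat_weights)
            sk = skat_test(sub, cohort.y, pcs, weights=w)
            res.skat_q, res.skat_p = sk.q, sk.p
            res._skat_lambdas = sk.lambdas  # kept for GC re-evaluation
            if sk.flag:
                res.flags.append(f"skat:{sk.flag}")
        results.append(res)

    tested = [r for r in results if r.n_markers > 0]
    if not tested:
        return results

    lam_enr = lam_skat = 1.0
    overrides = lambda_overrides or {}
    if "enrichment" in config.test_set:
        lam_enr = overrides.get(
            "enrichment", genomic_control([r.enrichment_p for r in tested])
        )
    if "skat" in config.test_set:
        lam_skat = overrides.get("skat", genomic_control([r.skat_p for r in tested]))

    pool = np.concatenate(pool_cols, axis=1) if pool_cols else np.empty((cohort.n_samples, 0))
    pool_maf = allele_frequencies(pool)
    rng = np.random.default_rng(config.seed)

    for r in tested:
        r.lambda_gc_enrichment, r.lambda_gc_skat = lam_enr, lam_skat
        if "enrichment" in config.test_set:
            r.enrichment_stat, r.enrichment_p_gc = gc_correct(
                r.enrichment_stat, lam_enr, "enrichment"
            )
            if config.n_permutations:
                r.pmult_enrichment = permutation_pmult(
                    r.enrichment_p_gc, r.n_markers, pool, cohort.y, pcs,
                    "enrichment", config.n_permutations,
                    seed=int(rng.integers(2**31)), lam=lam_enr,
                )
        if "skat" in config.test_set:
            r.skat_q, r.skat_p_gc = gc_correct(
                r.skat_q, lam_skat, "skat", r._skat_lambdas
            )
            if config.n_permutations:
                r.pmult_skat = permutation_pmult(
                    r.skat_p_gc, r.n_markers, pool, cohort.y, pcs,
                    "skat", config.n_permutations,
                    seed=int(rng.integers(2**31)), lam=lam_skat,
                    skat_weights_spec=config.skat_weights, pool_maf=pool_maf,
                )
    return results


def results_frame(results: Sequence[GeneTestResult]) -> pd.DataFrame:
    """Results as a table shaped like the published per-gene summary
    (gene, NMK, P and Pmult per test plus the correction factors)."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "NMK": r.n_markers,
                "enrichment_P": r.enrichment_p_gc,
                "enrichment_Pmult": r.pmult_enrichment,
                "skat_P": r.skat_p_gc,
                "skat_Pmult": r.pmult_skat,
                "enrichment_P_raw": r.enrichment_p,
                "skat_P_raw": r.skat_p,
                "lambda_enrichment": r.lambda_gc_enrichment,
                "lambda_skat": r.lambda_gc_skat,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
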