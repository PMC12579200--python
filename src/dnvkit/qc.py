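"""Variant- and sample-level cohort QC.

Variant filters follow standard trio-sequencing practice: individual calls
failing GQ >= 20 or DP >= 20 are set missing (GATK genotype-level
semantics), then a site fails if cohort-wide missingness reaches 10% or the
site lies in a blacklist region.

Sample checks: X-heterozygosity sex imputation (F statistic with the usual
0.2/0.8 thresholds), pairwise relatedness with the KING-robust estimator,
and ancestry PCA in which cohort samples are projected onto axes fit to a
reference panel and flagged when they stray from the target cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    min_gq: int = 20
    min_dp: int = 20
    max_missingness: float = 0.10
    sex_f_male: float = 0.8
    sex_f_female: float = 0.2
    min_sex_sites: int = 50
    kinship_min_sites: int = 1000
    n_pcs: int = 5
    pc_outlier_sd: float = 6.0

    def __post_init__(self):
        if not 0.0 <= self.max_missingness <= 1.0:
            raise ValueError("max_missingness outside [0,1]")
        if self.sex_f_female >= self.sex_f_male:
            raise ValueError("sex F thresholds must satisfy female < male")


@dataclass
class QCReport:
    variant_results: list = field(default_factory=list)  # (site key, pass, reason)
    sample_sex: dict = field(default_factory=dict)  # sample -> (F, inferred sex)
    kinship: dict = field(default_factory=dict)  # (i, j) -> (phi, class)
    pcs: dict = field(default_factory=dict)  # sample -> PC vector
    excluded_samples: dict = field(default_factory=dict)  # sample -> reason


# ---------------------------------------------------------------------------
# variant filtering


def filter_variants(sites, blacklist=None, config=None):
    """Apply call-level GQ/DP masking then site-level blacklist and
    missingness filters.

    Failing calls are set missing rather than deleting the site outright, so
    they contribute to the missingness fraction.  Returns
    ``(passing_sites, QCReport)``; input sites are not modified.
    """
    config = config or QCConfig()
    report = QCReport()
    passing = []
    for original in sites:
        site = original.copy()
        for call in site.calls.values():
            if call.is_missing():
                continue
            if (
                call.gq is None
                or call.dp is None
                or call.gq < config.min_gq
                or call.dp < config.min_dp
            ):
                call.genotype = "missing"
        n = len(site.calls)
        n_missing = sum(1 for c in site.calls.values() if c.is_missing())
        missingness = n_missing / n if n else 1.0
        if blacklist is not None and blacklist.contains(site.chrom, site.pos):
            report.variant_results.append((site.key, False, "blacklist"))
            continue
        if missingness >= config.max_missingness:
            report.variant_results.append((site.key, False, "missingness"))
            continue
        report.variant_results.append((site.key, True, ""))
        passing.append(site)
    return passing, report


# ---------------------------------------------------------------------------
# sex imputation


def impute_sex(x_sites, sample, config=None):
    """Impute sex from X-chromosome heterozygosity.

    F = 1 - observed het / expected het, with the expectation taken under
    Hardy-Weinberg at cohort allele frequencies over the sample's informative
    (non-missing, polymorphic) non-PAR X sites.  F above 0.8 calls male,
    below 0.2 female, otherwise undetermined.  Fewer than ``min_sex_sites``
    informative sites (or zero expected heterozygosity) yields undetermined.
    """
    config = config or QCConfig()
    observed = 0
    expected = 0.0
    n_informative = 0
    for site in x_sites:
        call = site.calls.get(sample)
        if call is None or call.is_missing():
            continue
        dosages = [
            {"homref": 0, "het": 1, "homalt": 2}[c.genotype]
            for c in site.calls.values()
            if not c.is_missing()
        ]
        if not dosages:
            continue
        p = sum(dosages) / (2 * len(dosages))
        if p <= 0.0 or p >= 1.0:
            continue  # monomorphic: no heterozygosity information
        n_informative += 1
        expected += 2.0 * p * (1.0 - p)
        if call.genotype == "het":
            observed += 1
    if n_informative < config.min_sex_sites or expected == 0.0:
        warnings.warn(
            f"sample {sample}: only {n_informative} informative X sites; "
            "sex undetermined",
            stacklevel=2,
        )
        return float("nan"), "undetermined"
    f_stat = 1.0 - observed / expected
    if f_stat > config.sex_f_male:
        inferred = "male"
    elif f_stat < config.sex_f_female:
        inferred = "female"
    else:
        inferred = "undetermined"
    return f_stat, inferred


# ---------------------------------------------------------------------------
# kinship (KING-robust)

KINSHIP_CUTOFFS = (
    ("duplicate", 2 ** -1.5),  # phi > 0.354
    ("first_degree", 2 ** -2.5),  # 0.177 < phi <= 0.354
    ("second_degree", 2 ** -3.5),  # 0.0884 < phi <= 0.177
    ("third_degree", 2 ** -4.5),  # 0.0442 < phi <= 0.0884
)


def classify_kinship(phi):
    for name, cutoff in KINSHIP_CUTOFFS:
        if phi > cutoff:
            return name
    return "unrelated"


def king_kinship(g_i, g_j, min_sites=1000):
    """KING-robust kinship coefficient from two dosage vectors (0/1/2,
    negative = missing).

    phi = (N_het,het - 2 N_opposite-hom) / (N_het(i) + N_het(j)) over shared
    non-missing autosomal sites.  Returns ``(phi, relationship_class)``;
    fewer than *min_sites* shared sites yields ``(nan, "unclassified")``.
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    if g_i.shape != g_j.shape:
        raise ValueError("genotype vectors differ in length")
    shared = (g_i >= 0) & (g_j >= 0)
    if int(shared.sum()) < min_sites:
        return float("nan"), "unclassified"
    a, b = g_i[shared], g_j[shared]
    n_het_het = int(np.sum((a == 1) & (b == 1)))
    n_opp_hom = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    n_het_i = int(np.sum(a == 1))
    n_het_j = int(np.sum(b == 1))
    denom = n_het_i + n_het_j
    if denom == 0:
        return float("nan"), "unclassified"
    phi = (n_het_het - 2.0 * n_opp_hom) / denom
    return phi, classify_kinship(phi)


def validate_trios(pedigree, genotypes, min_sites=1000):
    """Check that each trio's parent-proband pairs are first-degree and its
    parents non-consanguineous (no second-degree or closer relatedness; a
    noisy phi just above the unrelated cutoff is tolerated).

    *genotypes* maps sample id -> dosage vector.  Returns a dict family id ->
    dict with the three phi values, classes and an ``ok`` flag.
    """
    out = {}
    for trio in pedigree.trios:
        gp = genotypes[trio.proband]
        gf = genotypes[trio.father]
        gm = genotypes[trio.mother]
        phi_pf, cls_pf = king_kinship(gp, gf, min_sites)
        phi_pm, cls_pm = king_kinship(gp, gm, min_sites)
        phi_fm, cls_fm = king_kinship(gf, gm, min_sites)
        out[trio.family_id] = {
            "father_proband": (phi_pf, cls_pf),
            "mother_proband": (phi_pm, cls_pm),
            "parents": (phi_fm, cls_fm),
            "ok": cls_pf == "first_degree"
            and cls_pm == "first_degree"
            and cls_fm in ("unrelated", "third_degree"),
        }
    return out


# ---------------------------------------------------------------------------
# ancestry PCA


def ancestry_pca(
    cohort,
    reference,
    reference_labels=None,
    n_pcs=5,
    pc_outlier_sd=6.0,
    target_label=None,
):
    """Project cohort genotypes onto reference-panel principal axes and flag
    ancestry outliers.

    Both matrices are samples x SNPs dosage matrices over a shared SNP set.
    Columns are centred by the reference mean dosage and scaled by
    sqrt(2 p (1-p)); monomorphic reference SNPs are dropped.  The SVD is
    computed on the reference only; cohort samples are projected onto its
    axes.  A cohort sample is an outlier when any of the first *n_pcs*
    coordinates deviates more than *pc_outlier_sd* SDs from the target
    reference cluster's centroid.

    Returns a dict with cohort and reference PCs, the (orthonormal) SNP
    loadings, the kept-SNP index, and per-cohort-sample outlier flags.
    """
    cohort = np.asarray(cohort, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if cohort.shape[1] != reference.shape[1]:
        raise ValueError("cohort and reference must share the SNP set")
    p_hat = reference.mean(axis=0) / 2.0
    keep = (p_hat > 0.0) & (p_hat < 1.0)
    p_hat = p_hat[keep]
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    ref_std = (reference[:, keep] - 2.0 * p_hat) / scale
    coh_std = (cohort[:, keep] - 2.0 * p_hat) / scale
    n_pcs = min(n_pcs, min(ref_std.shape) - 1)
    _, _, vt = np.linalg.svd(ref_std, full_matrices=False)
    loadings = vt[:n_pcs].T  # SNPs x PCs, orthonormal columns
    ref_pcs = ref_std @ loadings
    cohort_pcs = coh_std @ loadings

    if reference_labels is None:
        centroid_pool = ref_pcs
    else:
        labels = np.asarray(reference_labels)
        if target_label is None:
            # nearest cluster to the cohort's median position
            med = np.median(cohort_pcs, axis=0)
            best, target_label = np.inf, labels[0]
            for lab in np.unique(labels):
                d = np.linalg.norm(ref_pcs[labels == lab].mean(axis=0) - med)
                if d < best:
                    best, target_label = d, lab
        centroid_pool = ref_pcs[labels == target_label]
    centroid = centroid_pool.mean(axis=0)
    sd = centroid_pool.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    deviation = np.abs(cohort_pcs - centroid) / sd
    outliers = (deviation > pc_outlier_sd).any(axis=1)
    return {
        "cohort_pcs": cohort_pcs,
        "reference_pcs": ref_pcs,
        "loadings": loadings,
        "kept_snps": np.flatnonzero(keep),
        "outliers": outliers,
        "target_label": target_label,
    }
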