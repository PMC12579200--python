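"""Synthetic trio-cohort generator with known ground truth.

The generator emulates a small whole-exome trio study: per trio the number
of true de novo SNVs is Poisson(rate x exome_size x 2 transmitting copies)
with the per-nucleotide rate defaulting to 1.4e-8 per generation over a
33,828,798 bp coding exome.  DNVs land uniformly on a toy gene map, the
proband is heterozygous with binomial allele balance, and both parents
carry zero alt reads.  Inherited sites follow Hardy-Weinberg parents with
Mendelian transmission.  "Missed heterozygote" artifacts — a truly
heterozygous parent emitted as homozygous reference with a residual alt
read fraction drawn Uniform(0.06, 0.25) — are indistinguishable from DNVs
except by parental read support, which is exactly what the discovery
cascade's parental-support filter exploits.

Read depths are negative-binomial around ``depth_mean``; GQ is derived
deterministically from the genotype-likelihood margin.  Clinical covariates
are drawn null (no dnSNV-severity or parental-age effect) unless effect
sizes are supplied.  Everything is reproducible from the seed; the written
VCF is byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import AF_ABSENT, GenotypeCall, Pedigree, Trio, VariantSite

DEFAULT_CLASS_MIX = {
    # chosen so the expected nonsynonymous:synonymous ratio is the 2.23:1
    # genome-wide expectation for de novo coding SNVs
    "missense": 0.625,
    "nonsense": 0.040,
    "splice": 0.025,
    "synonymous": 0.310,
}

_CHROMS = [f"chr{i}" for i in range(1, 23)]
_CHROM_ORDER = {c: i for i, c in enumerate(_CHROMS + ["chrX"])}


@dataclass
class SimulationConfig:
    n_trios: int = 36
    exome_size: int = 33_828_798
    true_dnv_rate: float = 1.4e-8
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    n_inherited_sites: int = 2000
    missed_het_rate: float = 0.005
    depth_mean: float = 100.0
    depth_dispersion: float = 10.0
    n_x_sites: int = 300
    seed: int = 0
    # toy gene map
    n_genes: int = 150
    gene_length: int = 1500
    # clinical covariates
    parent_age_mean: float = 30.0
    parent_age_sd: float = 5.0
    age_at_diagnosis_mean: float = 13.0
    age_at_diagnosis_sd: float = 2.48
    p_binary_flag: float = 0.2
    frac_missing_father_age: float = 4 / 36
    frac_missing_mother_age: float = 5 / 36
    frac_missing_cybocs: float = 6 / 36
    # optional alternative-hypothesis effects (defaults are null)
    paternal_age_log_effect: float = 0.0
    severity_log_odds_per_dnv: float = 0.0

    def __post_init__(self):
        if self.exome_size <= 0:
            raise ValueError("exome_size must be positive")
        if not math.isclose(sum(self.class_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("class_mix must sum to 1")
        for name in ("true_dnv_rate", "missed_het_rate", "p_binary_flag",
                     "frac_missing_father_age", "frac_missing_mother_age",
                     "frac_missing_cybocs"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0,1]")
        if self.n_trios <= 0:
            raise ValueError("n_trios must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    dnvs: list = field(default_factory=list)  # (proband, site key, class)
    artifacts: list = field(default_factory=list)  # (proband, site key, parent)
    per_proband_counts: dict = field(default_factory=dict)

    @property
    def n_dnvs(self):
        return len(self.dnvs)


# ---------------------------------------------------------------------------
# read-level emission

_LOG10 = math.log(10.0)
_ERR = 0.01  # per-read miscall probability used in the GL margin


def _genotype_quality(ad_ref, ad_alt):
    """GQ from the likelihood margin of a symmetric binomial read model."""
    ad_ref = np.asarray(ad_ref, dtype=float)
    ad_alt = np.asarray(ad_alt, dtype=float)
    dp = ad_ref + ad_alt
    ll = np.stack(
        [
            ad_alt * math.log(_ERR) + ad_ref * math.log(1 - _ERR),
            dp * math.log(0.5),
            ad_ref * math.log(_ERR) + ad_alt * math.log(1 - _ERR),
        ]
    )
    pl = -10.0 * (ll - ll.max(axis=0)) / _LOG10
    sorted_pl = np.sort(pl, axis=0)
    return np.minimum(99, np.rint(sorted_pl[1])).astype(int)


def _emit_calls(dosages, rng, cfg):
    """Vectorized emission of GenotypeCall objects for one site.

    *dosages* is the per-sample true dosage vector (0/1/2)."""
    dosages = np.asarray(dosages)
    n = len(dosages)
    p_nb = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
    dp = rng.negative_binomial(cfg.depth_dispersion, p_nb, size=n) + 1
    ad_alt = np.where(
        dosages == 1, rng.binomial(dp, 0.5), np.where(dosages == 2, dp, 0)
    )
    ad_ref = dp - ad_alt
    gq = _genotype_quality(ad_ref, ad_alt)
    alt_fwd = rng.binomial(ad_alt, 0.5)
    ref_fwd = rng.binomial(ad_ref, 0.5)
    mbq = rng.integers(25, 41, size=n)
    gts = np.array(["homref", "het", "homalt"])[dosages]
    return [
        GenotypeCall(
            genotype=gts[i],
            gq=int(gq[i]),
            dp=int(dp[i]),
            ad_ref=int(ad_ref[i]),
            ad_alt=int(ad_alt[i]),
            ad_ref_fwd=int(ref_fwd[i]),
            ad_ref_rev=int(ad_ref[i] - ref_fwd[i]),
            ad_alt_fwd=int(alt_fwd[i]),
            ad_alt_rev=int(ad_alt[i] - alt_fwd[i]),
            min_base_q=int(mbq[i]),
        )
        for i in range(n)
    ]


_CADD_BY_CLASS = {
    "missense": (18.0, 7.0),
    "nonsense": (28.0, 5.0),
    "splice": (14.0, 9.0),
    "synonymous": (8.0, 5.0),
}

_BASES = "ACGT"


def _draw_alleles(rng):
    ref = _BASES[rng.integers(0, 4)]
    alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
    return ref, alt


def _draw_cadd(rng, cls):
    mean, sd = _CADD_BY_CLASS[cls]
    return float(np.clip(rng.normal(mean, sd), 0.0, 45.0).round(2))


# ---------------------------------------------------------------------------
# cohort simulation


def _gene_position(cfg, gene_index, offset):
    chrom = _CHROMS[gene_index % len(_CHROMS)]
    start = 1 + (gene_index // len(_CHROMS)) * 100_000
    return chrom, start + offset


def simulate_cohort(config=None, **overrides):
    """Generate a trio cohort with ground truth.

    Returns ``(sites, pedigree, phenotypes, truth)`` where sites are sorted
    by genomic position, phenotypes is the per-proband clinical table and
    truth a :class:`SyntheticTruth`.
    """
    cfg = config or SimulationConfig(**overrides)
    rng = np.random.default_rng(cfg.seed)

    trios = [
        Trio(family_id=f"FAM{i:03d}", proband=f"P{i:03d}", father=f"F{i:03d}",
             mother=f"M{i:03d}")
        for i in range(cfg.n_trios)
    ]
    proband_sex = ["female" if rng.random() < 0.5 else "male" for _ in trios]
    sex = {}
    affected = {}
    for trio, psex in zip(trios, proband_sex):
        sex[trio.proband] = psex
        sex[trio.father] = "male"
        sex[trio.mother] = "female"
        affected[trio.proband] = True
        affected[trio.father] = False
        affected[trio.mother] = False
    pedigree = Pedigree(trios=trios, sex=sex, affected=affected)
    samples = pedigree.samples
    sample_index = {s: i for i, s in enumerate(samples)}
    truth = SyntheticTruth()

    # clinical covariates (drawn before DNV counts so a paternal-age effect
    # can modulate the per-trio mutation mean)
    father_age = rng.normal(cfg.parent_age_mean, cfg.parent_age_sd, cfg.n_trios)
    mother_age = rng.normal(cfg.parent_age_mean, cfg.parent_age_sd, cfg.n_trios)
    father_age = np.clip(father_age, 16.0, 60.0)
    mother_age = np.clip(mother_age, 16.0, 55.0)

    # spiked DNVs
    base_mean = cfg.true_dnv_rate * cfg.exome_size * 2
    lam = base_mean * np.exp(
        cfg.paternal_age_log_effect * (father_age - cfg.parent_age_mean)
    )
    n_dnv = rng.poisson(lam)
    class_names = list(cfg.class_mix)
    class_probs = np.array([cfg.class_mix[c] for c in class_names])
    total_positions = cfg.n_genes * cfg.gene_length
    used_positions = set()
    sites = []

    for t, trio in enumerate(trios):
        truth.per_proband_counts[trio.proband] = int(n_dnv[t])
        for _ in range(int(n_dnv[t])):
            while True:
                flat = int(rng.integers(0, total_positions))
                if flat not in used_positions:
                    used_positions.add(flat)
                    break
            gene_index, offset = divmod(flat, cfg.gene_length)
            chrom, pos = _gene_position(cfg, gene_index, offset)
            ref, alt = _draw_alleles(rng)
            cls = class_names[rng.choice(len(class_names), p=class_probs)]
            af = AF_ABSENT if rng.random() < 0.7 else round(float(rng.uniform(1e-6, 1e-4)), 10)
            site = VariantSite(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=f"GENE{gene_index:04d}", consequence_class=cls,
                population_af=af, cadd_phred=_draw_cadd(rng, cls),
            )
            dosages = np.zeros(len(samples), dtype=int)
            dosages[sample_index[trio.proband]] = 1
            calls = _emit_calls(dosages, rng, cfg)
            site.calls = dict(zip(samples, calls))
            sites.append(site)
            truth.dnvs.append((trio.proband, site.key, cls))

    # inherited sites with Mendelian transmission
    if cfg.n_inherited_sites:
        free = np.setdiff1d(
            np.arange(total_positions), np.fromiter(used_positions, dtype=int, count=len(used_positions))
        )
        chosen = rng.choice(free, size=cfg.n_inherited_sites, replace=False)
    else:
        chosen = np.array([], dtype=int)
    for flat in chosen:
        gene_index, offset = divmod(int(flat), cfg.gene_length)
        chrom, pos = _gene_position(cfg, gene_index, offset)
        ref, alt = _draw_alleles(rng)
        if rng.random() < 0.8:
            maf = float(rng.uniform(0.05, 0.5))
        else:
            maf = float(rng.uniform(0.002, 0.02))
        cls = class_names[rng.choice(len(class_names), p=class_probs)]
        site = VariantSite(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene=f"GENE{gene_index:04d}", consequence_class=cls,
            population_af=round(maf, 6), cadd_phred=_draw_cadd(rng, cls),
        )
        dosages = np.zeros(len(samples), dtype=int)
        for trio in trios:
            gf = rng.binomial(2, maf)
            gm = rng.binomial(2, maf)
            transmit_f = gf // 2 if gf != 1 else int(rng.integers(0, 2))
            transmit_m = gm // 2 if gm != 1 else int(rng.integers(0, 2))
            dosages[sample_index[trio.father]] = gf
            dosages[sample_index[trio.mother]] = gm
            dosages[sample_index[trio.proband]] = transmit_f + transmit_m
        calls = _emit_calls(dosages, rng, cfg)
        site.calls = dict(zip(samples, calls))
        # missed-heterozygote artifacts: one truly het parent emitted homref
        # with residual alt reads, the other parent truly homref, child het
        for trio in trios:
            gf = dosages[sample_index[trio.father]]
            gm = dosages[sample_index[trio.mother]]
            gc = dosages[sample_index[trio.proband]]
            if gc != 1 or {gf, gm} != {0, 1}:
                continue
            if rng.random() >= cfg.missed_het_rate:
                continue
            parent = trio.father if gf == 1 else trio.mother
            call = site.calls[parent]
            frac = rng.uniform(0.06, 0.25)
            ad_alt = max(1, int(round(frac * call.dp)))
            call.genotype = "homref"
            call.ad_alt = ad_alt
            call.ad_ref = call.dp - ad_alt
            call.gq = 45  # the artifact looks confidently called
            alt_fwd = int(rng.binomial(ad_alt, 0.5))
            ref_fwd = int(rng.binomial(call.ad_ref, 0.5))
            call.ad_alt_fwd, call.ad_alt_rev = alt_fwd, ad_alt - alt_fwd
            call.ad_ref_fwd, call.ad_ref_rev = ref_fwd, call.ad_ref - ref_fwd
            truth.artifacts.append((trio.proband, site.key, parent))
        sites.append(site)

    # X-chromosome sites (non-PAR): males hemizygous
    for j in range(cfg.n_x_sites):
        pos = 3_000_000 + j * 1_000  # clear of the PAR1 region
        ref, alt = _draw_alleles(rng)
        maf = float(rng.uniform(0.1, 0.5))
        site = VariantSite(
            chrom="chrX", pos=pos, ref=ref, alt=alt,
            gene="", consequence_class="other", population_af=round(maf, 6),
        )
        dosages = np.zeros(len(samples), dtype=int)
        for s in samples:
            if sex[s] == "male":
                dosages[sample_index[s]] = 2 * rng.binomial(1, maf)
            else:
                dosages[sample_index[s]] = rng.binomial(2, maf)
        calls = _emit_calls(dosages, rng, cfg)
        site.calls = dict(zip(samples, calls))
        sites.append(site)

    sites.sort(key=lambda s: (_CHROM_ORDER.get(s.chrom, 99), s.pos, s.alt))

    phenotypes = _draw_phenotypes(cfg, rng, trios, proband_sex, father_age,
                                  mother_age, truth)
    return sites, pedigree, phenotypes, truth


def _draw_phenotypes(cfg, rng, trios, proband_sex, father_age, mother_age, truth):
    n = cfg.n_trios
    age_dx = np.clip(
        rng.normal(cfg.age_at_diagnosis_mean, cfg.age_at_diagnosis_sd, n), 4.0, 17.9
    ).round(1)
    counts = np.array([truth.per_proband_counts[t.proband] for t in trios])
    cybocs = rng.integers(8, 37, size=n).astype(float)
    if cfg.severity_log_odds_per_dnv != 0.0:
        p0 = 13 / 29  # P(severe) under the null uniform{8..36}
        logit0 = math.log(p0 / (1 - p0))
        p_severe = 1.0 / (1.0 + np.exp(-(logit0 + cfg.severity_log_odds_per_dnv * counts)))
        severe = rng.random(n) < p_severe
        cybocs = np.where(severe, rng.integers(24, 37, size=n), rng.integers(8, 24, size=n)).astype(float)
    flags = rng.random((n, 3)) < cfg.p_binary_flag

    def _mask(values, frac):
        values = values.astype(float)
        k = int(round(frac * n))
        if k:
            idx = rng.choice(n, size=k, replace=False)
            values[idx] = np.nan
        return values

    df = pd.DataFrame(
        {
            "proband_id": [t.proband for t in trios],
            "sex": ["F" if s == "female" else "M" for s in proband_sex],
            "dnsnv_count": counts,
            "father_age_at_conception": _mask(father_age.round(1), cfg.frac_missing_father_age),
            "mother_age_at_conception": _mask(mother_age.round(1), cfg.frac_missing_mother_age),
            "age_at_diagnosis": age_dx,
            "cybocs_total": _mask(cybocs, cfg.frac_missing_cybocs),
            "first_degree_relative_dx": flags[:, 0].astype(int),
            "brain_trauma": flags[:, 1].astype(int),
            "comorbidity": flags[:, 2].astype(int),
        }
    )
    pcs = rng.normal(0.0, 0.05, size=(n, 5)).round(6)
    for j in range(5):
        df[f"pc{j + 1}"] = pcs[:, j]
    return df


# ---------------------------------------------------------------------------
# reference panel for ancestry PCA


def simulate_reference_panel(
    n_samples,
    n_snps,
    seed,
    n_clusters=2,
    fst=0.15,
    cohort_size=0,
    n_outliers=0,
):
    """Balding-Nichols reference panel with divergent ancestry clusters.

    *n_samples* reference individuals are split evenly across *n_clusters*
    clusters whose allele frequencies diverge from a shared ancestral
    spectrum with differentiation *fst*.  An optional cohort is drawn from
    cluster 0, with *n_outliers* of its samples drawn from cluster 1
    instead (their indices are returned as ground truth).

    Returns a dict with reference genotypes and labels and, when requested,
    cohort genotypes plus true outlier indices.
    """
    import warnings

    if n_snps < n_samples:
        warnings.warn("fewer SNPs than samples; PCA axes will be noisy")
    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.1, 0.9, size=n_snps)
    if fst > 0:
        a = ancestral * (1 - fst) / fst
        b = (1 - ancestral) * (1 - fst) / fst
        cluster_freqs = [rng.beta(a, b) for _ in range(n_clusters)]
    else:
        cluster_freqs = [ancestral for _ in range(n_clusters)]
    per = n_samples // n_clusters
    ref, labels = [], []
    for k in range(n_clusters):
        size = per + (1 if k < n_samples % n_clusters else 0)
        ref.append(rng.binomial(2, cluster_freqs[k], size=(size, n_snps)))
        labels.extend([k] * size)
    out = {"reference": np.vstack(ref), "labels": np.array(labels)}
    if cohort_size:
        n_outliers = min(n_outliers, cohort_size)
        inliers = rng.binomial(2, cluster_freqs[0], size=(cohort_size - n_outliers, n_snps))
        rows = [inliers]
        if n_outliers:
            rows.append(rng.binomial(2, cluster_freqs[1 % n_clusters], size=(n_outliers, n_snps)))
        cohort = np.vstack(rows)
        out["cohort"] = cohort
        out["cohort_outliers"] = np.arange(cohort_size - n_outliers, cohort_size)
    return out
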