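"""Candidate de novo SNV discovery: Mendelian-violation detection followed
by a programmatic filter cascade.

A candidate is a (proband, site) pair with a heterozygous proband and two
homozygous-reference parents.  The cascade then applies, each with an
auditable trail entry:

1. consequence class in the retained set (missense / nonsense / splice /
   synonymous);
2. singleton — the alt allele is carried by exactly one proband cohort-wide;
3. rarity — population allele frequency < 1% (an allele absent from the
   reference population passes);
4. proband read support — alt fraction >= 30% of AD reads (boundary kept);
5. parental read support — each parent's alt fraction <= 5% (boundary kept;
   this is the computational replacement for visual inspection and is what
   catches "missed heterozygote" artifacts);
6. minimum base quality >= Q20 when recorded;
7. strand bias — Fisher exact on the (forward/reverse x ref/alt) read table,
   failing at a Phred-scaled p above the threshold (default 60).

A filter whose inputs are unavailable records "not-evaluable" and never
fails a candidate on its own.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from scipy import stats

from .variants import CLASSES

log = logging.getLogger(__name__)


@dataclass
class DNVFilterConfig:
    max_af: float = 0.01
    min_proband_alt_fraction: float = 0.30
    max_parent_alt_fraction: float = 0.05
    min_base_q: int = 20
    strand_bias_phred_max: float = 60.0
    max_dnvs_per_proband: int = 5
    retained_classes: tuple = CLASSES
    cadd_deleterious_cutoff: float = 20.0

    def __post_init__(self):
        for name in ("max_af", "min_proband_alt_fraction", "max_parent_alt_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0,1]")
        if self.min_base_q < 0 or self.strand_bias_phred_max < 0:
            raise ValueError("cutoffs must be non-negative")


@dataclass
class CandidateDNV:
    """A proband variant that entered the cascade, with its outcome."""

    proband: str
    site: object  # VariantSite
    status: str = "pass"
    filter_trail: list = field(default_factory=list)
    tier: Optional[str] = None
    hgvs: Optional[str] = None

    @property
    def consequence_class(self):
        return self.site.consequence_class

    @property
    def cadd_phred(self):
        return self.site.cadd_phred

    @property
    def population_af(self):
        return self.site.population_af


def detect_mendelian_candidates(sites, pedigree):
    """Emit one candidate per (proband, site) where the proband is het and
    both parents are homref, all three calls non-missing."""
    candidates = []
    n_skipped = 0
    for site in sites:
        for trio in pedigree.trios:
            calls = [site.calls.get(s) for s in trio.members]
            if any(c is None or c.is_missing() for c in calls):
                n_skipped += 1
                continue
            proband, father, mother = calls
            if (
                proband.genotype == "het"
                and father.genotype == "homref"
                and mother.genotype == "homref"
            ):
                candidates.append(CandidateDNV(proband=trio.proband, site=site))
    if n_skipped:
        log.info("skipped %d (trio, site) pairs with missing calls", n_skipped)
    return candidates


def _strand_bias_phred(call):
    """Phred-scaled Fisher exact p for the fwd/rev x ref/alt read table,
    or None when per-strand depths are unavailable."""
    if call.ad_ref_fwd is None or call.ad_alt_fwd is None:
        return None
    table = [
        [call.ad_ref_fwd, call.ad_ref_rev],
        [call.ad_alt_fwd, call.ad_alt_rev],
    ]
    p = stats.fisher_exact(table, alternative="two-sided")[1]
    if p <= 0:
        return math.inf
    return -10.0 * math.log10(p)


def _count_alt_probands(sites, pedigree):
    """Number of probands carrying the alt allele at each chrom:pos:alt.

    Only proband genotypes are counted: a parental carrier would already
    have failed the Mendelian step for its own trio."""
    probands = set(pedigree.probands)
    counts = Counter()
    for site in sites:
        carriers = sum(
            1
            for sample, call in site.calls.items()
            if sample in probands and call.genotype in ("het", "homalt")
        )
        if carriers:
            counts[(site.chrom, site.pos, site.alt)] = carriers
    return counts


def apply_filters(candidates, sites, pedigree, config=None):
    """Run the filter cascade over candidates, recording a trail entry per
    filter and setting status to pass iff no filter failed."""
    config = config or DNVFilterConfig()
    trio_by_proband = {t.proband: t for t in pedigree.trios}
    alt_counts = _count_alt_probands(sites, pedigree)

    for cand in candidates:
        site = cand.site
        trio = trio_by_proband[cand.proband]
        proband = site.calls[trio.proband]
        parents = [site.calls[trio.father], site.calls[trio.mother]]
        trail = []

        trail.append(
            (
                "class",
                "pass" if site.consequence_class in config.retained_classes else "fail",
            )
        )

        observed = alt_counts.get((site.chrom, site.pos, site.alt), 0)
        trail.append(("singleton", "pass" if observed == 1 else "fail"))

        af = site.population_af
        if af is None:
            trail.append(("population_af", "not-evaluable"))
        elif af == "absent" or af < config.max_af:
            trail.append(("population_af", "pass"))
        else:
            trail.append(("population_af", "fail"))

        frac = proband.alt_fraction
        if frac is None:
            trail.append(("proband_support", "not-evaluable"))
        else:
            trail.append(
                (
                    "proband_support",
                    "pass" if frac >= config.min_proband_alt_fraction else "fail",
                )
            )

        parent_fracs = [p.alt_fraction for p in parents]
        if any(f is None for f in parent_fracs):
            trail.append(("parent_support", "not-evaluable"))
        else:
            ok = all(f <= config.max_parent_alt_fraction for f in parent_fracs)
            trail.append(("parent_support", "pass" if ok else "fail"))

        if proband.min_base_q is None:
            trail.append(("base_quality", "not-evaluable"))
        else:
            trail.append(
                (
                    "base_quality",
                    "pass" if proband.min_base_q >= config.min_base_q else "fail",
                )
            )

        phred = _strand_bias_phred(proband)
        if phred is None:
            trail.append(("strand_bias", "not-evaluable"))
        else:
            trail.append(
                (
                    "strand_bias",
                    "fail" if phred >= config.strand_bias_phred_max else "pass",
                )
            )

        cand.filter_trail = trail
        cand.status = "fail" if any(o == "fail" for _, o in trail) else "pass"
    return candidates


def trail_outcome(candidate, filter_name):
    """Outcome recorded for one named filter, or None if not in the trail."""
    for name, outcome in candidate.filter_trail:
        if name == filter_name:
            return outcome
    return None


def per_proband_cap(candidates, config=None, probands=None):
    """Flag probands whose passing-call count exceeds the per-proband cap.

    Flag only — actual exclusion is a pipeline switch."""
    config = config or DNVFilterConfig()
    counts = Counter(c.proband for c in candidates if c.status == "pass")
    flagged = sorted(
        p for p, n in counts.items() if n > config.max_dnvs_per_proband
    )
    if probands is not None:
        flagged = [p for p in flagged if p in set(probands)]
    return flagged


def classify_deleteriousness(candidates, config=None):
    """Assign a deleteriousness tier per candidate from its CADD PHRED score:
    strictly above the cutoff (default 20, the top 1% of possible human SNVs)
    is tier ``top1pct``; a missing score is ``unscored``."""
    config = config or DNVFilterConfig()
    for cand in candidates:
        if cand.cadd_phred is None:
            cand.tier = "unscored"
        elif cand.cadd_phred > config.cadd_deleterious_cutoff:
            cand.tier = "top1pct"
        else:
            cand.tier = "standard"
    return candidates


def summarize_candidates(candidates, n_probands):
    """Per-proband count histogram (zeros included) and per-class counts of
    pass-status candidates.

    Returns ``(histogram, class_counts)`` where histogram maps a dnSNV count
    to the number of cohort probands with that count."""
    passing = [c for c in candidates if c.status == "pass"]
    per_proband = Counter(c.proband for c in passing)
    if len(per_proband) > n_probands:
        raise ValueError("more probands with candidates than cohort size")
    histogram = Counter(per_proband.values())
    histogram[0] = n_probands - len(per_proband)
    class_counts = Counter(c.consequence_class for c in passing)
    for cls in CLASSES:
        class_counts.setdefault(cls, 0)
    return dict(sorted(histogram.items())), dict(class_counts)
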