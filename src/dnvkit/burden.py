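"""Mutation-rate, nonsynonymous:synonymous ratio, and class-wise
observed-vs-expected Poisson enrichment statistics.

The per-generation de novo mutation rate is

    rate = (n_dnvs / n_probands) / (exome_size * n_gametogeneses)

with the coding-exome size defaulting to 33,828,798 bp and two
gametogeneses.  Expected class counts come from a mutational-model
probability table giving, per gene and consequence class, the probability of
a de novo SNV in a single gene copy per generation; a cohort of n probands
contributes 2n transmitting copies.  Enrichment per class is tested with a
Poisson upper tail and corrected with Benjamini-Hochberg FDR.

The probability-table builder enumerates every possible SNV over toy gene
models (all three alts at each coding position plus intronic positions
inside a splice window), classifies each substitution through codon
translation or window membership, and sums trinucleotide-context rates.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variants import CLASSES

log = logging.getLogger(__name__)

EXOME_SIZE_HG19 = 33_828_798  # RefSeq hg19 coding exome, base pairs
NONSYNONYMOUS = ("missense", "nonsense", "splice")


# ---------------------------------------------------------------------------
# mutation rate


@dataclass
class RateResult:
    rate: float
    ci_low: float
    ci_high: float
    mean_per_proband: float
    method: str


def mutation_rate(
    n_dnvs,
    n_probands,
    exome_size=EXOME_SIZE_HG19,
    n_gametogeneses=2,
    per_proband_counts=None,
    method="normal-counts",
):
    """Observed de novo mutation rate per nucleotide per generation with a
    95% CI.

    ``method="normal-counts"`` uses the normal approximation on the
    per-proband count vector (mean +/- 1.96 sd/sqrt(n), then divided by the
    per-proband denominator); ``"poisson-exact"`` uses chi-square bounds on
    the total count.
    """
    if n_probands <= 0:
        raise ValueError("n_probands must be positive")
    if exome_size <= 0:
        raise ValueError("exome_size must be positive")
    denom = exome_size * n_gametogeneses
    mean = n_dnvs / n_probands
    rate = mean / denom
    if method == "normal-counts":
        if per_proband_counts is None:
            raise ValueError("normal-counts method needs per_proband_counts")
        counts = np.asarray(per_proband_counts, dtype=float)
        if counts.sum() != n_dnvs:
            raise ValueError("per_proband_counts do not sum to n_dnvs")
        if len(counts) != n_probands:
            raise ValueError("per_proband_counts length != n_probands")
        se = counts.std(ddof=1) / math.sqrt(len(counts)) if len(counts) > 1 else 0.0
        lo = max(0.0, (mean - 1.96 * se)) / denom
        hi = (mean + 1.96 * se) / denom
    elif method == "poisson-exact":
        total = n_dnvs
        lo_count = 0.0 if total == 0 else 0.5 * stats.chi2.ppf(0.025, 2 * total)
        hi_count = 0.5 * stats.chi2.ppf(0.975, 2 * (total + 1))
        lo = lo_count / n_probands / denom
        hi = hi_count / n_probands / denom
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return RateResult(rate=rate, ci_low=lo, ci_high=hi, mean_per_proband=mean, method=method)


# ---------------------------------------------------------------------------
# nonsynonymous : synonymous ratio


@dataclass
class RatioResult:
    ratio: float
    n_nonsyn: int
    n_syn: int
    p: float
    ci_low: float
    ci_high: float


def nonsyn_syn_ratio(class_counts):
    """Ratio of nonsynonymous (missense + nonsense + splice) to synonymous
    counts, with a two-count exact test of rate ratio 1.

    Conditional on the total, the nonsynonymous count is Binomial(total, 1/2)
    under the null; the two-sided p and the Clopper-Pearson CI on the
    proportion q are reported, with the ratio CI transformed as q/(1-q).
    """
    nonsyn = sum(class_counts.get(c, 0) for c in NONSYNONYMOUS)
    syn = class_counts.get("synonymous", 0)
    if syn < 0 or nonsyn < 0:
        raise ValueError("negative class count")
    total = nonsyn + syn
    if total == 0:
        return RatioResult(float("nan"), 0, 0, 1.0, float("nan"), float("nan"))
    ratio = nonsyn / syn if syn > 0 else float("inf")
    test = stats.binomtest(nonsyn, total, 0.5)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")

    def _to_ratio(q):
        return float("inf") if q >= 1.0 else q / (1.0 - q)

    return RatioResult(
        ratio=ratio,
        n_nonsyn=nonsyn,
        n_syn=syn,
        p=test.pvalue,
        ci_low=_to_ratio(ci.low),
        ci_high=_to_ratio(ci.high),
    )


# ---------------------------------------------------------------------------
# mutational-model probability table


@dataclass
class GeneModel:
    """Toy gene model: ordered exon sequences with the intervening intron
    sequences (len(introns) == len(exons) - 1).  The concatenated exons form
    the CDS and must translate in frame.  Optional flank sequences supply
    trinucleotide context for the first and last CDS/intron base; without
    them the edge positions have no full context and are skipped."""

    name: str
    exons: list
    introns: list = field(default_factory=list)
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self):
        if len(self.introns) != max(0, len(self.exons) - 1):
            raise ValueError(f"{self.name}: need len(exons)-1 introns")
        cds = "".join(self.exons)
        if len(cds) % 3 != 0:
            raise ValueError(f"{self.name}: CDS length not divisible by 3")


def uniform_rate_table(mu):
    """Toy trinucleotide rate table: every context -> alt substitution has
    per-generation probability *mu*."""
    table = {}
    for a, b, c in product("ACGT", repeat=3):
        ctx = a + b + c
        for alt in "ACGT":
            if alt != b:
                table[(ctx, alt)] = mu
    return table


def read_rate_table(path):
    """Rate-table TSV with columns context, alt, rate."""
    df = pd.read_csv(path, sep="\t", dtype={"context": str, "alt": str})
    return {(r.context.upper(), r.alt.upper()): float(r.rate) for r in df.itertuples()}


def _classify_substitution(codon, offset, alt):
    """Class of a coding substitution from codon translation."""
    new = codon[:offset] + alt + codon[offset + 1:]
    old_aa = str(Seq(codon).translate())
    new_aa = str(Seq(new).translate())
    if new_aa == old_aa:
        return "synonymous"
    if new_aa == "*":
        return "nonsense"
    # any other protein change, including loss of a stop codon
    return "missense"


def _gene_layout(gene):
    """Full genomic sequence plus per-position (kind, index) annotation.

    kind is "exon" (with CDS index) or "intron"; splice-window membership is
    resolved against internal exon/intron boundaries only.
    """
    seq_parts = [gene.flank5]
    kinds = [("flank", None)] * len(gene.flank5)
    cds_index = 0
    for i, exon in enumerate(gene.exons):
        seq_parts.append(exon)
        for _ in exon:
            kinds.append(("exon", cds_index))
            cds_index += 1
        if i < len(gene.introns):
            intron = gene.introns[i]
            seq_parts.append(intron)
            kinds.extend(("intron", None) for _ in intron)
    seq_parts.append(gene.flank3)
    kinds.extend(("flank", None) for _ in gene.flank3)
    return "".join(seq_parts), kinds


def _splice_positions(gene, kinds, intron_window=8, exon_window=3):
    """Indices (into the full gene sequence) inside the splice window:
    intronic positions 1..intron_window and exonic 1..exon_window from each
    internal exon/intron boundary."""
    positions = set()
    offset = len(gene.flank5)
    boundaries = []  # (intron_start, intron_end) in full-sequence coordinates
    for i, exon in enumerate(gene.exons):
        offset += len(exon)
        if i < len(gene.introns):
            boundaries.append((offset, offset + len(gene.introns[i])))
            offset += len(gene.introns[i])
    n = len(kinds)
    for start, end in boundaries:
        for k in range(min(intron_window, end - start)):
            positions.add(start + k)  # donor side
            positions.add(end - 1 - k)  # acceptor side
        for k in range(1, exon_window + 1):
            if start - k >= 0 and kinds[start - k][0] == "exon":
                positions.add(start - k)  # last bases of the upstream exon
            if end + k - 1 < n and kinds[end + k - 1][0] == "exon":
                positions.add(end + k - 1)  # first bases of the downstream exon
    return positions


def build_probability_table(genes, rate_table, intron_window=8, exon_window=3):
    """Enumerate all possible SNVs over toy gene models and sum
    context-dependent rates per (gene, class).

    Every CDS position contributes its three alternative alleles, classified
    by codon translation; positions inside the splice window (intronic
    1..*intron_window*, exonic 1..*exon_window* from each internal boundary)
    are classified splice, taking precedence over the codon class so the
    classes partition the substitution space.  Sites whose trinucleotide
    context contains an ambiguous base or is missing from the table (gene
    edges included) are skipped and counted.

    Returns ``(table, n_skipped)`` where table is a DataFrame with columns
    gene, class, probability.
    """
    rows = []
    n_skipped = 0
    for gene in genes:
        seq, kinds = _gene_layout(gene)
        cds = "".join(gene.exons)
        splice_pos = _splice_positions(gene, kinds, intron_window, exon_window)
        probs = {cls: 0.0 for cls in CLASSES}
        for idx, base in enumerate(seq):
            kind, cds_index = kinds[idx]
            if kind == "flank":
                continue  # context only, not part of the model
            if kind == "intron" and idx not in splice_pos:
                continue  # deep intron: outside the model
            if idx == 0 or idx == len(seq) - 1:
                n_skipped += 3  # no full trinucleotide context at gene edges
                continue
            ctx = seq[idx - 1: idx + 2]
            if any(b not in "ACGT" for b in ctx):
                n_skipped += 3
                continue
            for alt in "ACGT":
                if alt == base:
                    continue
                rate = rate_table.get((ctx, alt))
                if rate is None:
                    n_skipped += 1
                    continue
                if idx in splice_pos:
                    cls = "splice"
                else:
                    codon = cds[3 * (cds_index // 3): 3 * (cds_index // 3) + 3]
                    cls = _classify_substitution(codon, cds_index % 3, alt)
                probs[cls] += rate
        for cls in CLASSES:
            rows.append({"gene": gene.name, "class": cls, "probability": probs[cls]})
    table = pd.DataFrame(rows)
    if n_skipped:
        log.info("probability table: skipped %d substitutions", n_skipped)
    return table, n_skipped


def read_probability_table(path):
    """Probability-table TSV with columns gene, class, probability."""
    df = pd.read_csv(path, sep="\t")
    expected = {"gene", "class", "probability"}
    if not expected <= set(df.columns):
        raise ValueError(f"probability table needs columns {sorted(expected)}")
    if (df["probability"] < 0).any():
        raise ValueError("negative probability in table")
    if df.duplicated(["gene", "class"]).any():
        raise ValueError("duplicate (gene, class) rows")
    return df


# ---------------------------------------------------------------------------
# class enrichment


def class_enrichment(observed, table, n_probands):
    """Observed-vs-expected Poisson enrichment per consequence class.

    expected(class) = 2 * n_probands * sum over genes of P(gene, class);
    p = P(X >= observed) for X ~ Poisson(expected); BH-FDR across the tested
    classes.  Returns a DataFrame with one row per class in *observed*.
    """
    per_class = table.groupby("class")["probability"].sum()
    rows = []
    for cls, obs in observed.items():
        expected = 2.0 * n_probands * float(per_class.get(cls, 0.0))
        if expected == 0.0:
            if obs > 0:
                warnings.warn(f"class {cls}: observed {obs} with zero expectation")
                p = 0.0
            else:
                p = 1.0
            ratio = float("inf") if obs > 0 else float("nan")
        else:
            p = stats.poisson.sf(obs - 1, expected)  # P(X >= obs)
            ratio = obs / expected
        rows.append(
            {
                "class": cls,
                "observed": obs,
                "expected": expected,
                "enrichment_ratio": ratio,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_fdr(df["p"].to_numpy())
    return df


def bh_fdr(pvalues):
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
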