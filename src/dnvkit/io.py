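"""Readers and writers for the external formats the pipeline touches.

VCF 4.x is read through pysam; multi-allelic records are split into
biallelic sites and non-SNV alleles dropped (counted in the parse log).
Annotations arrive either through a VEP-style CSQ INFO field or through a
sidecar TSV keyed by ``chrom:pos:ref:alt``.  Writing uses a deterministic
plain-text emitter so that seeded simulations round-trip byte-identically.

BED is 0-based half-open and converted to the package's 1-based convention
at the boundary; a VCF position ``p`` lies in a BED interval
``[start, end)`` iff ``p - 1`` does.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .variants import (
    AF_ABSENT,
    CLASSES,
    GenotypeCall,
    GeneSetLibrary,
    Pedigree,
    Trio,
    VariantSite,
    classify_consequence,
)

log = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "proband",
    "chrom",
    "pos_hg19",
    "ref",
    "alt",
    "hgvs",
    "class",
    "gene",
    "population_af",
    "cadd_phred",
    "status",
    "filter_trail",
]

PHENOTYPE_COLUMNS = [
    "proband_id",
    "sex",
    "father_age_at_conception",
    "mother_age_at_conception",
    "age_at_diagnosis",
    "cybocs_total",
    "first_degree_relative_dx",
    "brain_trauma",
    "comorbidity",
    "pc1",
    "pc2",
    "pc3",
    "pc4",
    "pc5",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF


@dataclass
class VcfParseLog:
    n_records: int = 0
    n_sites: int = 0
    n_non_snv_dropped: int = 0
    n_unannotated: int = 0
    notes: list = field(default_factory=list)


def _genotype_for_allele(alleles, allele_index):
    """Collapse a pysam GT tuple to this alt allele's biallelic genotype."""
    if alleles is None or any(a is None for a in alleles):
        return "missing"
    count = sum(1 for a in alleles if a == allele_index)
    if count == 2:
        return "homalt"
    if count == 1:
        # het against ref; a call involving a different alt allele cannot be
        # represented at this biallelic site
        return "het" if all(a in (0, allele_index) for a in alleles) else "missing"
    return "homref" if all(a == 0 for a in alleles) else "missing"


def _parse_csq_header(vcf):
    try:
        desc = vcf.header.info["CSQ"].description
    except KeyError:
        raise ParseError("annotation_dialect='csq' but no CSQ INFO header")
    if "Format:" not in desc:
        raise ParseError("CSQ header lacks a Format: declaration")
    return desc.split("Format:", 1)[1].strip().strip('"').split("|")


def _parse_af(raw):
    if raw is None:
        return None
    if isinstance(raw, str):
        token = raw.strip()
        if token == "" or token == ".":
            return None
        if token.lower() == "absent":
            return AF_ABSENT
        return float(token)
    return float(raw)


def _annotate_from_csq(site, rec, csq_fields):
    raw = rec.info.get("CSQ")
    if raw is None:
        return False
    entries = raw if isinstance(raw, tuple) else (raw,)
    chosen = None
    for entry in entries:
        values = dict(zip(csq_fields, entry.split("|")))
        if values.get("Allele", site.alt) == site.alt:
            chosen = values
            break
    if chosen is None:
        chosen = dict(zip(csq_fields, entries[0].split("|")))
    site.gene = chosen.get("SYMBOL", "") or ""
    site.consequence_class = classify_consequence(chosen.get("Consequence", ""))
    site.population_af = _parse_af(chosen.get("gnomAD_NFE_AF"))
    cadd = chosen.get("CADD_PHRED", "")
    site.cadd_phred = float(cadd) if cadd not in ("", None, ".") else None
    return True


def read_sidecar_annotations(path):
    """Sidecar annotation TSV with columns chrom, pos, ref, alt, gene,
    consequence, population_af, cadd_phred; keyed by chrom:pos:ref:alt."""
    table = {}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    classes = set(CLASSES) | {"other"}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        cadd = getattr(row, "cadd_phred", "")
        consequence = row.consequence
        table[key] = {
            "gene": row.gene,
            "consequence_class": consequence
            if consequence in classes
            else classify_consequence(consequence),
            "population_af": _parse_af(row.population_af),
            "cadd_phred": float(cadd) if cadd not in ("", ".") else None,
        }
    return table


def read_vcf(path, annotation_dialect="none", sidecar=None):
    """Read a VCF into a list of :class:`VariantSite`, splitting
    multi-allelic records and dropping non-SNV alleles.

    Parameters
    ----------
    path
        VCF 4.x file (plain text or bgzipped).
    annotation_dialect
        ``"csq"`` (VEP-style CSQ INFO field), ``"sidecar"`` (TSV keyed by
        chrom:pos:ref:alt, passed via *sidecar*), or ``"none"``.

    Returns
    -------
    (sites, parse_log)
    """
    if annotation_dialect not in ("csq", "sidecar", "none"):
        raise ValueError(f"unknown annotation dialect {annotation_dialect!r}")
    sidecar_table = None
    if annotation_dialect == "sidecar":
        if sidecar is None:
            raise ValueError("sidecar dialect requires a sidecar path")
        sidecar_table = read_sidecar_annotations(sidecar)

    plog = VcfParseLog()
    sites = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"malformed VCF {path}: {exc}") from exc
    with vcf:
        if "GT" not in vcf.header.formats:
            raise ParseError("VCF lacks mandatory FORMAT field GT")
        csq_fields = _parse_csq_header(vcf) if annotation_dialect == "csq" else None
        samples = list(vcf.header.samples)
        for rec in vcf:
            plog.n_records += 1
            for i, alt in enumerate(rec.alts or (), start=1):
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT" or rec.ref not in "ACGT":
                    plog.n_non_snv_dropped += 1
                    continue
                site = VariantSite(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt)
                for sample in samples:
                    call = rec.samples[sample]
                    gt = _genotype_for_allele(call.get("GT"), i)
                    gq = call.get("GQ")
                    dp = call.get("DP")
                    ad = call.get("AD")
                    ad_ref = ad_alt = None
                    if ad is not None and None not in ad and len(ad) > i:
                        ad_ref, ad_alt = int(ad[0]), int(ad[i])
                    if gt != "missing" and (gq is None or dp is None or ad_ref is None):
                        # missing quality metadata: keep as missing call,
                        # never fabricate support values
                        gt = "missing"
                    sb = call.get("SB")
                    mbq = call.get("MBQ")
                    kwargs = {}
                    if sb is not None and None not in sb and len(sb) == 4:
                        kwargs.update(
                            ad_ref_fwd=int(sb[0]),
                            ad_ref_rev=int(sb[1]),
                            ad_alt_fwd=int(sb[2]),
                            ad_alt_rev=int(sb[3]),
                        )
                    if mbq is not None:
                        mbq_val = mbq[i] if isinstance(mbq, tuple) and len(mbq) > i else (
                            mbq if isinstance(mbq, int) else mbq[0]
                        )
                        if mbq_val is not None:
                            kwargs["min_base_q"] = int(mbq_val)
                    site.calls[sample] = GenotypeCall(
                        genotype=gt,
                        gq=int(gq) if gq is not None else None,
                        dp=int(dp) if dp is not None else None,
                        ad_ref=ad_ref,
                        ad_alt=ad_alt,
                        **kwargs,
                    )
                annotated = False
                if csq_fields is not None:
                    annotated = _annotate_from_csq(site, rec, csq_fields)
                elif sidecar_table is not None:
                    ann = sidecar_table.get(site.key)
                    if ann is not None:
                        site.gene = ann["gene"]
                        site.consequence_class = ann["consequence_class"]
                        site.population_af = ann["population_af"]
                        site.cadd_phred = ann["cadd_phred"]
                        annotated = True
                if annotation_dialect != "none" and not annotated:
                    plog.n_unannotated += 1
                sites.append(site)
                plog.n_sites += 1
    if plog.n_non_snv_dropped:
        log.info("dropped %d non-SNV alleles", plog.n_non_snv_dropped)
    return sites, plog


_CLASS_TO_VEP = {
    "missense": "missense_variant",
    "nonsense": "stop_gained",
    "splice": "splice_donor_variant",
    "synonymous": "synonymous_variant",
    "other": "intergenic_variant",
}


def write_vcf(sites, path, samples=None, contigs=None):
    """Write sites as a VCF 4.2 text file (deterministic byte layout).

    Annotations are serialized into a CSQ INFO field using the dialect
    ``Allele|Consequence|SYMBOL|gnomAD_NFE_AF|CADD_PHRED`` so that
    ``read_vcf(..., annotation_dialect="csq")`` round-trips them.
    """
    if samples is None:
        seen = {}
        for site in sites:
            for s in site.calls:
                seen[s] = None
        samples = list(seen)
    if contigs is None:
        contigs = list(dict.fromkeys(site.chrom for site in sites))
    gt_str = {"homref": "0/0", "het": "0/1", "homalt": "1/1", "missing": "./."}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
        'Format: Allele|Consequence|SYMBOL|gnomAD_NFE_AF|CADD_PHRED">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=SB,Number=4,Type=Integer,Description="Per-strand ref/alt depths">',
        '##FORMAT=<ID=MBQ,Number=1,Type=Integer,Description="Minimum base quality of alt reads">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for site in sites:
        if site.population_af is None:
            af = ""
        elif site.population_af == AF_ABSENT:
            af = "Absent"
        else:
            af = f"{site.population_af:.10g}"
        cadd = "" if site.cadd_phred is None else f"{site.cadd_phred:g}"
        csq = "|".join(
            [site.alt, _CLASS_TO_VEP.get(site.consequence_class, "intergenic_variant"),
             site.gene, af, cadd]
        )
        fields = [site.chrom, str(site.pos), ".", site.ref, site.alt, ".", "PASS",
                  f"CSQ={csq}", "GT:GQ:DP:AD:SB:MBQ"]
        for sample in samples:
            call = site.calls.get(sample)
            if call is None:
                fields.append("./.:.:.:.:.:.")
                continue
            ad = (
                f"{call.ad_ref},{call.ad_alt}"
                if call.ad_ref is not None and call.ad_alt is not None
                else "."
            )
            sb = (
                f"{call.ad_ref_fwd},{call.ad_ref_rev},{call.ad_alt_fwd},{call.ad_alt_rev}"
                if call.ad_ref_fwd is not None and call.ad_alt_fwd is not None
                else "."
            )
            fields.append(
                ":".join(
                    [
                        gt_str[call.genotype],
                        "." if call.gq is None else str(call.gq),
                        "." if call.dp is None else str(call.dp),
                        ad,
                        sb,
                        "." if call.min_base_q is None else str(call.min_base_q),
                    ]
                )
            )
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED blacklist


class Blacklist:
    """Interval set from a BED3 file (0-based half-open)."""

    def __init__(self):
        self._trees = {}

    def add(self, chrom, start, end):
        if start >= end:
            raise ParseError(f"BED interval with start >= end: {chrom} {start} {end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def contains(self, chrom, pos):
        """Membership of a 1-based VCF position."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree[pos - 1])

    def __len__(self):
        return sum(len(t) for t in self._trees.values())


def read_blacklist(path):
    bl = Blacklist()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line with <3 columns")
            bl.add(parts[0], int(parts[1]), int(parts[2]))
    return bl


# ---------------------------------------------------------------------------
# PED


def read_ped(path):
    """Read a 6-column PED file into a :class:`Pedigree`.

    Trios are families of exactly three members in which the proband (the
    affected member with both parents present) points at the other two.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: PED line with <6 columns")
            rows.append(parts[:6])
    sex_map = {"1": "male", "2": "female", "0": "unknown"}
    trios, sex, affected = [], {}, {}
    by_family = {}
    for fam, iid, fid, mid, s, pheno in rows:
        if s not in sex_map:
            raise ParseError(f"unknown sex code {s!r} for sample {iid}")
        sex[iid] = sex_map[s]
        affected[iid] = pheno == "2"
        by_family.setdefault(fam, []).append((iid, fid, mid))
    for fam, members in by_family.items():
        probands = [(iid, fid, mid) for iid, fid, mid in members if fid != "0" and mid != "0"]
        if len(members) != 3 or len(probands) != 1:
            raise ParseError(f"family {fam} is not a single complete trio")
        iid, fid, mid = probands[0]
        trios.append(Trio(family_id=fam, proband=iid, father=fid, mother=mid))
    return Pedigree(trios=trios, sex=sex, affected=affected)


def write_ped(pedigree, path):
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for trio in pedigree.trios:
            for sample, father, mother in (
                (trio.proband, trio.father, trio.mother),
                (trio.father, "0", "0"),
                (trio.mother, "0", "0"),
            ):
                pheno = "2" if pedigree.affected.get(sample, False) else "1"
                fh.write(
                    f"{trio.family_id}\t{sample}\t{father}\t{mother}\t"
                    f"{sex_code[pedigree.sex.get(sample, 'unknown')]}\t{pheno}\n"
                )


# ---------------------------------------------------------------------------
# GMT / phenotypes / candidate table


def read_gmt(path):
    """Read a GMT gene-set library (term, description, genes...)."""
    terms = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
            term, name = parts[0], parts[1]
            genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            if term in terms:
                raise ParseError(f"duplicate GMT term id {term!r}")
            if not genes:
                raise ParseError(f"{path}:{lineno}: empty gene set {term!r}")
            terms[term] = (name, genes)
    return GeneSetLibrary(terms=terms)


def read_phenotypes(path):
    """Read the per-proband phenotype TSV into a DataFrame.

    Blank / "NA" cells become NaN ("missing").  CY-BOCS totals are bounded
    to [0, 40]; sex must be M/F (case-insensitive).
    """
    df = pd.read_csv(path, sep="\t", na_values=["", "NA", "missing"])
    missing_cols = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"phenotype table missing columns: {sorted(missing_cols)}")
    sexes = df["sex"].astype(str).str.upper()
    if not sexes.isin(["M", "F"]).all():
        bad = sorted(set(sexes) - {"M", "F"})
        raise ParseError(f"unknown sex code(s) {bad} in phenotype table")
    df["sex"] = sexes
    bad_cybocs = df["cybocs_total"].dropna()
    if ((bad_cybocs < 0) | (bad_cybocs > 40)).any():
        raise ParseError("CY-BOCS total outside [0, 40]")
    ages = df[["father_age_at_conception", "mother_age_at_conception", "age_at_diagnosis"]]
    if (ages.dropna(how="all") <= 0).any().any():
        raise ParseError("non-positive age in phenotype table")
    return df


def write_phenotypes(df, path):
    df.to_csv(path, sep="\t", index=False, na_rep="")


def _format_af(af):
    if af is None:
        return ""
    if af == AF_ABSENT:
        return "Absent"
    return f"{af:g}"


def write_candidate_table(candidates, path):
    """Write candidates as the pipeline's TSV (columns mirroring the
    published per-variant table plus status and filter trail)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANDIDATE_COLUMNS)
        for cand in candidates:
            site = cand.site
            trail = ";".join(f"{name}:{outcome}" for name, outcome in cand.filter_trail)
            writer.writerow(
                [
                    cand.proband,
                    site.chrom,
                    site.pos,
                    site.ref,
                    site.alt,
                    cand.hgvs or "",
                    site.consequence_class,
                    site.gene,
                    _format_af(site.population_af),
                    "" if site.cadd_phred is None else f"{site.cadd_phred:g}",
                    cand.status,
                    trail,
                ]
            )


def read_candidate_table(path):
    """Read a candidate TSV back into :class:`~dnvkit.discovery.CandidateDNV`
    objects (unknown extra columns are ignored)."""
    from .discovery import CandidateDNV  # local import to avoid a cycle

    out = []
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for row in df.to_dict("records"):
        site = VariantSite(
            chrom=row["chrom"],
            pos=int(row["pos_hg19"]),
            ref=row["ref"],
            alt=row["alt"],
            gene=row["gene"],
            consequence_class=row["class"],
            population_af=_parse_af(row["population_af"]),
            cadd_phred=float(row["cadd_phred"]) if row["cadd_phred"] else None,
        )
        raw_trail = row.get("filter_trail", "")
        trail = (
            [tuple(item.split(":", 1)) for item in raw_trail.split(";")]
            if raw_trail
            else []
        )
        out.append(
            CandidateDNV(
                proband=row["proband"],
                site=site,
                status=row.get("status") or "pass",
                filter_trail=trail,
                hgvs=row.get("hgvs") or None,
            )
        )
    return out
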