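"""Bundled datasets.

* the published per-variant candidate dnSNV table from a 36-trio
  childhood-onset OCD cohort (34 variants in 34 genes);
* flat reference gene lists of genes previously associated with OCD and
  with 11 related psychiatric disorders, used for overlap reporting;
* aggregate exome-wide per-gamete dnSNV class probabilities consistent with
  the mutational-model expectations for that 36-proband cohort;
* a synthetic brain-tissue median-TPM matrix covering the 34 candidate
  genes (synthetic stand-in for a public expression resource; every gene is
  expressed at >= 1 TPM in at least one tissue by construction).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as _io
from .burden import read_probability_table

COHORT_N_PROBANDS = 36  # probands in the bundled candidate table's cohort


def _data_path(*parts):
    return resources.files("dnvkit").joinpath("data", *parts)


def ocd_trio_dnsnvs():
    """The bundled candidate dnSNV table as CandidateDNV objects."""
    with resources.as_file(_data_path("ocd_trio_dnsnvs.tsv")) as path:
        return _io.read_candidate_table(path)


def ocd_trio_dnsnv_genes():
    """The 34 candidate gene symbols from the bundled table."""
    return sorted({c.site.gene for c in ocd_trio_dnsnvs()})


def reference_gene_sets(names=None):
    """Named reference gene lists (one symbol per line) as name -> set."""
    folder = _data_path("gene_sets")
    out = {}
    for entry in sorted(folder.iterdir()):
        name = entry.name.removesuffix(".txt")
        if names is not None and name not in names:
            continue
        out[name] = {
            line.strip().upper()
            for line in entry.read_text().splitlines()
            if line.strip()
        }
    if names is not None:
        missing = set(names) - set(out)
        if missing:
            raise KeyError(f"unknown reference list(s): {sorted(missing)}")
    return out


def ocd_reference_genes():
    """Genes previously associated with OCD (DNV analyses + GWAS loci)."""
    sets = reference_gene_sets(["ocd_dnv", "ocd_gwas"])
    return sets["ocd_dnv"] | sets["ocd_gwas"]


def exome_class_probabilities():
    """Aggregate exome-wide mutational-model probability table
    (per gene copy per generation, by consequence class)."""
    with resources.as_file(_data_path("exome_class_probabilities.tsv")) as path:
        return read_probability_table(path)


def brain_expression_matrix():
    """Synthetic brain median-TPM matrix (genes x tissues)."""
    with resources.as_file(_data_path("synthetic_brain_tpm.tsv")) as path:
        return pd.read_csv(path, sep="\t", index_col="gene")
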