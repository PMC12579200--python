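"""Mutation rate, nonsyn:syn ratio, mutational-model table, enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dnvkit.burden import (
    EXOME_SIZE_HG19,
    GeneModel,
    bh_fdr,
    build_probability_table,
    class_enrichment,
    mutation_rate,
    nonsyn_syn_ratio,
    uniform_rate_table,
)

TABLE1_COUNTS = [0] * 15 + [1] * 10 + [2] * 9 + [3] * 2


class TestMutationRate:
    def test_cohort_rate_and_ci(self):
        res = mutation_rate(34, 36, per_proband_counts=TABLE1_COUNTS)
        assert res.rate == pytest.approx(1.40e-8, rel=5e-3)
        assert res.mean_per_proband == pytest.approx(0.9444, abs=1e-4)
        assert res.ci_low == pytest.approx(9.35e-9, rel=2e-3)
        assert float(f"{res.ci_high:.3g}") == 1.86e-8  # printed precision

    def test_zero_dnvs(self):
        res = mutation_rate(0, 36, per_proband_counts=[0] * 36)
        assert res.rate == 0.0 and res.ci_low == 0.0

    def test_poisson_exact_brackets_rate(self):
        res = mutation_rate(34, 36, method="poisson-exact")
        assert res.ci_low < res.rate < res.ci_high
        # chi-square bounds on a count of 34
        assert res.ci_low * 36 * EXOME_SIZE_HG19 * 2 == pytest.approx(
            0.5 * stats.chi2.ppf(0.025, 68), rel=1e-9
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        n_dnvs=st.integers(min_value=0, max_value=200),
        scale=st.integers(min_value=1, max_value=10),
    )
    def test_linear_in_counts_inverse_in_exome(self, n_dnvs, scale):
        base = mutation_rate(n_dnvs, 20, method="poisson-exact")
        more = mutation_rate(n_dnvs * scale, 20, method="poisson-exact")
        smaller_exome = mutation_rate(
            n_dnvs, 20, exome_size=EXOME_SIZE_HG19 // scale, method="poisson-exact"
        )
        assert more.rate == pytest.approx(base.rate * scale, rel=1e-12, abs=1e-30)
        assert smaller_exome.rate == pytest.approx(
            n_dnvs / 20 / (EXOME_SIZE_HG19 // scale * 2), rel=1e-12
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            mutation_rate(10, 0)
        with pytest.raises(ValueError):
            mutation_rate(10, 5, per_proband_counts=[1, 1, 1, 1, 1])


class TestNonsynSynRatio:
    def test_cohort_ratio(self):
        res = nonsyn_syn_ratio({"missense": 17, "nonsense": 0, "splice": 3, "synonymous": 14})
        assert res.ratio == pytest.approx(1.43, abs=5e-3)
        assert res.n_nonsyn == 20 and res.n_syn == 14

    def test_balanced_counts_p_one(self):
        res = nonsyn_syn_ratio({"missense": 5, "synonymous": 5})
        assert res.ratio == 1.0 and res.p == 1.0

    def test_zero_synonymous_enumeration(self):
        # Binomial(3, 1/2): one-sided tail 0.125, two-sided 0.25
        res = nonsyn_syn_ratio({"missense": 3, "synonymous": 0})
        assert math.isinf(res.ratio)
        assert res.p == pytest.approx(0.25)

    @pytest.mark.parametrize("nonsyn,syn", [(7, 2), (12, 12), (1, 9), (20, 14)])
    def test_p_matches_binomial_enumeration(self, nonsyn, syn):
        res = nonsyn_syn_ratio({"missense": nonsyn, "synonymous": syn})
        total = nonsyn + syn
        pmf = [math.comb(total, k) * 0.5**total for k in range(total + 1)]
        expected = sum(p for p in pmf if p <= pmf[nonsyn] * (1 + 1e-12))
        assert res.p == pytest.approx(min(1.0, expected), rel=1e-9)


# --- independent brute-force oracle for the probability-table builder -----

_CODON_TABLE = {}
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(
    (a, b, c) for a in _BASES for b in _BASES for c in _BASES
):
    _CODON_TABLE[_a + _b + _c] = _AMINO[_i]


def _oracle_enumerate(gene, rate_table, intron_window=8, exon_window=3):
    """Re-enumerate every substitution with an independent code path."""
    full = gene.flank5
    segments = []  # (kind, start, end)
    for i, exon in enumerate(gene.exons):
        segments.append(("exon", len(full), len(full) + len(exon)))
        full += exon
        if i < len(gene.introns):
            segments.append(("intron", len(full), len(full) + len(gene.introns[i])))
            full += gene.introns[i]
    full += gene.flank3
    cds = "".join(gene.exons)

    def splice_window(idx):
        for kind, start, end in segments:
            if kind != "intron":
                continue
            if start <= idx < end and (
                idx - start < intron_window or end - 1 - idx < intron_window
            ):
                return True
            if start - exon_window <= idx < start and _is_exon(idx):
                return True
            if end <= idx < end + exon_window and _is_exon(idx):
                return True
        return False

    def _is_exon(idx):
        return any(k == "exon" and s <= idx < e for k, s, e in segments)

    def cds_index(idx):
        n = 0
        for kind, start, end in segments:
            if kind != "exon":
                continue
            if start <= idx < end:
                return n + (idx - start)
            n += end - start
        return None

    totals = {"missense": 0.0, "nonsense": 0.0, "splice": 0.0, "synonymous": 0.0}
    for idx, base in enumerate(full):
        in_exon = _is_exon(idx)
        in_window = splice_window(idx)
        if not in_exon and not in_window:
            continue
        if idx == 0 or idx == len(full) - 1:
            continue
        ctx = full[idx - 1: idx + 2]
        for alt in "ACGT":
            if alt == base:
                continue
            rate = rate_table.get((ctx, alt))
            if rate is None:
                continue
            if in_window:
                cls = "splice"
            else:
                ci = cds_index(idx)
                codon_start = 3 * (ci // 3)
                codon = cds[codon_start: codon_start + 3]
                mutated = codon[: ci % 3] + alt + codon[ci % 3 + 1:]
                old_aa, new_aa = _CODON_TABLE[codon], _CODON_TABLE[mutated]
                if new_aa == old_aa:
                    cls = "synonymous"
                elif new_aa == "*":
                    cls = "nonsense"
                else:
                    cls = "missense"
            totals[cls] += rate
    return totals


def _random_gene(rng, name):
    n_exons = int(rng.integers(1, 4))
    exons = []
    for _ in range(n_exons):
        exons.append("".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 8)) * 3)))
    # pad so total CDS stays in frame regardless of exon splits
    cds_len = sum(len(e) for e in exons)
    if cds_len % 3:
        exons[-1] += "".join(rng.choice(list("ACGT"), size=3 - cds_len % 3))
    introns = [
        "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 25))))
        for _ in range(n_exons - 1)
    ]
    flank = lambda: "".join(rng.choice(list("ACGT"), size=2))
    return GeneModel(name, exons=exons, introns=introns, flank5=flank(), flank3=flank())


class TestProbabilityTable:
    def test_start_stop_toy_gene_exhaustive(self):
        """ATG + TAA with a uniform rate: 16 missense (incl. stop-loss) and
        2 synonymous (stop-retained) of the 18 possible substitutions."""
        mu = 1e-8
        gene = GeneModel("TOY", exons=["ATGTAA"], flank5="C", flank3="G")
        table, skipped = build_probability_table([gene], uniform_rate_table(mu))
        by_class = table.set_index("class")["probability"]
        assert skipped == 0
        assert by_class["missense"] == pytest.approx(16 * mu)
        assert by_class["synonymous"] == pytest.approx(2 * mu)
        assert by_class["nonsense"] == 0.0 and by_class["splice"] == 0.0

    def test_empty_cds(self):
        table, _ = build_probability_table(
            [GeneModel("E", exons=[""])], uniform_rate_table(1e-8)
        )
        assert (table["probability"] == 0).all()

    def test_partition_conservation(self):
        """Class sums partition the enumerated substitution space: the total
        equals mu times the number of enumerated substitutions."""
        mu = 2e-9
        gene = GeneModel(
            "G", exons=["ATGAAA", "CCCTAA"], introns=["GTAAGTACGTAC"],
            flank5="AA", flank3="TT",
        )
        table, skipped = build_probability_table([gene], uniform_rate_table(mu))
        # 12 CDS positions + 12 intronic window positions, 3 alts each
        assert table["probability"].sum() == pytest.approx(72 * mu)
        assert skipped == 0

    def test_matches_brute_force_oracle_on_random_genes(self):
        rng = np.random.default_rng(17)
        mu_table = uniform_rate_table(1e-8)
        # context-dependent table: perturb rates deterministically
        for i, key in enumerate(sorted(mu_table)):
            mu_table[key] *= 1 + (i % 7) / 10
        genes = [_random_gene(rng, f"G{i}") for i in range(20)]
        table, _ = build_probability_table(genes, mu_table)
        for gene in genes:
            expected = _oracle_enumerate(gene, mu_table)
            got = table[table["gene"] == gene.name].set_index("class")["probability"]
            for cls, value in expected.items():
                assert got[cls] == pytest.approx(value, rel=1e-12, abs=1e-18), (
                    gene.name, cls,
                )


class TestClassEnrichment:
    def test_poisson_tail_example(self):
        import pandas as pd

        table = pd.DataFrame(
            [{"gene": "X", "class": "splice", "probability": 3 / 5.60 / 72}]
        )
        df = class_enrichment({"splice": 3}, table, 36)
        row = df.iloc[0]
        assert row["expected"] == pytest.approx(3 / 5.60, rel=1e-9)
        assert row["enrichment_ratio"] == pytest.approx(5.60, rel=1e-9)
        assert row["p"] == pytest.approx(0.0173, abs=5e-4)

    def test_zero_observed_p_one(self):
        import pandas as pd

        table = pd.DataFrame([{"gene": "X", "class": "missense", "probability": 0.1}])
        df = class_enrichment({"missense": 0}, table, 36)
        assert df.iloc[0]["p"] == 1.0

    def test_zero_expected_warns(self):
        import pandas as pd

        table = pd.DataFrame([{"gene": "X", "class": "splice", "probability": 0.0}])
        with pytest.warns(UserWarning):
            df = class_enrichment({"splice": 2}, table, 36)
        assert df.iloc[0]["p"] == 0.0

    def test_null_calibration_conservative(self):
        """Simulating counts from Poisson(expected), the fraction of p <= .05
        stays within Monte-Carlo error of (at most) 0.05."""
        import pandas as pd

        expected = 8.0
        table = pd.DataFrame(
            [{"gene": "X", "class": "missense", "probability": expected / 72}]
        )
        rng = np.random.default_rng(3)
        n_sim = 2000
        hits = 0
        for count in rng.poisson(expected, size=n_sim):
            df = class_enrichment({"missense": int(count)}, table, 36)
            hits += df.iloc[0]["p"] <= 0.05
        mc_err = math.sqrt(0.05 * 0.95 / n_sim)
        assert hits / n_sim <= 0.05 + 3 * mc_err


class TestBhFdr:
    def test_cohort_class_pvalues(self):
        adjusted = bh_fdr([0.0173, 0.908, 0.143])
        assert adjusted[0] == pytest.approx(0.0519, abs=1e-4)
        assert adjusted[2] == pytest.approx(0.2145, abs=1e-4)
        assert adjusted[1] == pytest.approx(0.908, abs=1e-9)

    def test_hand_step_up(self):
        assert np.allclose(
            bh_fdr([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1,
            max_size=30,
        )
    )
    def test_adjustment_properties(self, pvalues):
        adjusted = bh_fdr(pvalues)
        assert np.all(adjusted >= np.asarray(pvalues) - 1e-15)
        assert np.all(adjusted <= 1.0 + 1e-15)
        # monotone: ordering of adjusted p follows ordering of raw p
        order = np.argsort(pvalues, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-12)
        # deterministic
        assert np.array_equal(adjusted, bh_fdr(pvalues))
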