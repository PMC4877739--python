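import math

import numpy as np
import pandas as pd
import pytest

from dualomics.core_io import ExperimentDesign, PeptideEvidence
from dualomics.quantitation import (
    AlignmentCounts,
    build_protein_matrix,
    build_rna_matrix,
    correlation_r2,
    count_exact_readmers,
    count_samples,
    reverse_complement,
)
from dualomics.synthetic import simulate_omics


def naive_counts(reads, gene_sequences, both_strands=True, mode="reads"):
    """Brute-force substring-search oracle, independent of the k-mer index."""

    def occurrences_in(needle, haystack):
        found, at = 0, haystack.find(needle)
        while at != -1:
            found += 1
            at = haystack.find(needle, at + 1)
        return found

    counts = {gene: 0 for gene in gene_sequences}
    rc = {gene: reverse_complement(seq) for gene, seq in gene_sequences.items()}
    for read in reads:
        seq = read if isinstance(read, str) else read[1]
        if set(seq) - set("ACGT"):
            continue
        for gene, target in gene_sequences.items():
            if mode == "reads":
                if seq in target or (both_strands and seq in rc[gene]):
                    counts[gene] += 1
            else:
                occurrences = occurrences_in(seq, target)
                if both_strands:
                    occurrences += occurrences_in(seq, rc[gene])
                counts[gene] += occurrences
    return counts


def random_genes(rng, n_genes=10, length=400):
    bases = np.array(list("ACGT"))
    return {
        f"g{i}": "".join(rng.choice(bases, size=length)) for i in range(n_genes)
    }


class TestCountExactReadmers:
    def test_read_from_single_gene(self, rng):
        genes = random_genes(rng, 3, 300)
        read = genes["g1"][50:150]
        counts, skipped = count_exact_readmers([read], genes)
        assert counts == {"g0": 0, "g1": 1, "g2": 0}
        assert skipped == 0

    def test_unmatched_read_counts_nothing(self, rng):
        genes = random_genes(rng, 2, 300)
        counts, _ = count_exact_readmers(["A" * 100], genes)
        assert sum(counts.values()) == 0

    def test_reverse_complement_needs_both_strands(self, rng):
        genes = random_genes(rng, 2, 300)
        read = reverse_complement(genes["g1"][10:110])
        counts_both, _ = count_exact_readmers([read], genes, both_strands=True)
        counts_fwd, _ = count_exact_readmers([read], genes, both_strands=False)
        assert counts_both["g1"] == 1
        assert counts_fwd["g1"] == 0

    def test_matches_naive_oracle_on_random_fixture(self, rng):
        genes = random_genes(rng, 10, 400)
        gene_names = list(genes)
        reads = []
        for _ in range(1000):
            gene = genes[gene_names[rng.integers(len(gene_names))]]
            start = rng.integers(0, len(gene) - 100 + 1)
            read = gene[start : start + 100]
            if rng.random() < 0.5:
                read = reverse_complement(read)
            reads.append(read)
        counts, _ = count_exact_readmers(reads, genes)
        assert counts == naive_counts(reads, genes)

    def test_occurrences_mode_counts_repeats(self):
        gene = {"g0": "ATCG" * 3 + "ATCGATCG"}  # 'ATCGATCG' occurs repeatedly
        read = "ATCGATCG"
        reads_counts, _ = count_exact_readmers([read], gene, both_strands=False, mode="reads")
        occ_counts, _ = count_exact_readmers([read], gene, both_strands=False, mode="occurrences")
        assert reads_counts["g0"] == 1
        assert occ_counts["g0"] == naive_counts([read], gene, both_strands=False, mode="occurrences")["g0"]
        assert occ_counts["g0"] > 1

    def test_mixed_read_lengths_rejected(self, rng):
        genes = random_genes(rng, 1, 200)
        with pytest.raises(ValueError, match="mixed read lengths"):
            count_exact_readmers(["ACGT" * 25, "ACGT" * 20], genes)

    def test_non_acgt_reads_skipped_and_counted(self, rng):
        genes = random_genes(rng, 1, 200)
        good = genes["g0"][:100]
        bad = "N" + good[1:]
        counts, skipped = count_exact_readmers([good, bad], genes)
        assert counts["g0"] == 1
        assert skipped == 1


class TestBuildRnaMatrix:
    def _counts(self, design, per_gene):
        frame = pd.DataFrame.from_dict(per_gene, orient="index")
        frame = frame.reindex(columns=design.columns()).fillna(0).astype(int)
        frame.columns = pd.MultiIndex.from_tuples(design.columns())
        return AlignmentCounts(counts=frame)

    def test_log2_of_count(self, two_condition_design):
        design = two_condition_design
        counts = self._counts(design, {"g1": {col: 4 for col in design.columns()}})
        matrix = build_rna_matrix(counts, design)
        assert matrix.data.loc["g1", ("cb", "A")] == 2.0

    def test_min_counts_filter_logged(self, two_condition_design):
        design = two_condition_design
        per_gene = {"g1": {col: 4 for col in design.columns()}}
        per_gene["g1"][("xy", "B")] = 1
        matrix = build_rna_matrix(self._counts(design, per_gene), design)
        assert math.isnan(matrix.data.loc["g1", ("xy", "B")])
        assert any("min_counts" in r for r in matrix.filter_log["g1"])

    def test_hand_computed_pair(self, two_condition_design):
        design = two_condition_design
        per_gene = {"g1": {col: 16 for col in design.columns()}}
        per_gene["g1"][("cb", "B")] = 1
        matrix = build_rna_matrix(self._counts(design, per_gene), design)
        assert matrix.data.loc["g1", ("cb", "A")] == 4.0
        assert math.isnan(matrix.data.loc["g1", ("cb", "B")])

    def test_monotone_in_counts(self, two_condition_design):
        design = two_condition_design
        lo = build_rna_matrix(
            self._counts(design, {"g1": {col: 8 for col in design.columns()}}), design
        )
        hi = build_rna_matrix(
            self._counts(design, {"g1": {col: 9 for col in design.columns()}}), design
        )
        assert (hi.data.loc["g1"] > lo.data.loc["g1"]).all()

    def test_missing_design_sample_rejected(self, two_condition_design):
        design = two_condition_design
        frame = pd.DataFrame({("cb", "A"): {"g1": 5}})
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
        with pytest.raises(ValueError, match="design samples"):
            build_rna_matrix(AlignmentCounts(counts=frame), design)


class TestBuildProteinMatrix:
    def _design(self):
        return ExperimentDesign(conditions=("cb", "xy"), reference="cb")

    def test_log2_of_summed_intensities(self):
        evidence = [
            PeptideEvidence("p1", "PEPTIDEK", -20.0, {"cb": 3.0, "xy": 3.0}),
            PeptideEvidence("p1", "PRTEINK", -20.0, {"cb": 5.0, "xy": 5.0}),
        ]
        matrix = build_protein_matrix(evidence, self._design())
        assert matrix.data.loc["p1", ("cb", "1")] == 3.0

    def test_single_qualifying_peptide_excluded(self):
        evidence = [
            PeptideEvidence("p1", "PEPTIDEK", -3.0, {"cb": 3.0, "xy": 3.0}),
            PeptideEvidence("p1", "PRTEINK", -1.0, {"cb": 5.0, "xy": 5.0}),
        ]
        matrix = build_protein_matrix(evidence, self._design())
        assert "p1" not in matrix.data.index
        assert any("min_peptides" in r for r in matrix.filter_log["p1"])

    def test_boundary_log_e_is_strict(self):
        evidence = [
            PeptideEvidence("p1", "PEPTIDEK", -1.5, {"cb": 3.0, "xy": 3.0}),
            PeptideEvidence("p1", "PRTEINK", -1.5, {"cb": 5.0, "xy": 5.0}),
        ]
        matrix = build_protein_matrix(evidence, self._design())
        assert "p1" not in matrix.data.index

    def test_two_peptide_hand_computation(self):
        # peptide intensities per channel: (10, 6) and (2, 2)
        evidence = [
            PeptideEvidence("p1", "PEPTIDEK", -20.0, {"cb": 10.0, "xy": 6.0}),
            PeptideEvidence("p1", "PRTEINK", -20.0, {"cb": 2.0, "xy": 2.0}),
        ]
        matrix = build_protein_matrix(evidence, self._design())
        assert matrix.data.loc["p1", ("cb", "1")] == pytest.approx(math.log2(12.0))
        assert matrix.data.loc["p1", ("xy", "1")] == pytest.approx(3.0)

    def test_protein_level_expectation_filter(self):
        # two qualifying peptides but a weak summed protein expectation
        evidence = [
            PeptideEvidence("p1", "PEPTIDEK", -2.0, {"cb": 3.0, "xy": 3.0}),
            PeptideEvidence("p1", "PRTEINK", -2.0, {"cb": 5.0, "xy": 5.0}),
        ]
        matrix = build_protein_matrix(evidence, self._design())
        assert "p1" not in matrix.data.index
        assert any("protein_log_e" in r for r in matrix.filter_log["p1"])

    def test_unmapped_channel_rejected(self):
        evidence = [
            PeptideEvidence("p1", "PEPTIDEK", -20.0, {"114": 3.0}),
            PeptideEvidence("p1", "PRTEINK", -20.0, {"114": 5.0}),
        ]
        with pytest.raises(ValueError, match="channel"):
            build_protein_matrix(evidence, self._design())

    def test_channel_map(self):
        evidence = [
            PeptideEvidence("p1", "PEPTIDEK", -20.0, {"114": 3.0, "115": 1.0}),
            PeptideEvidence("p1", "PRTEINK", -20.0, {"114": 5.0, "115": 1.0}),
        ]
        matrix = build_protein_matrix(
            evidence, self._design(), channel_map={"114": "cb", "115": "xy"}
        )
        assert matrix.data.loc["p1", ("cb", "1")] == 3.0
        assert matrix.data.loc["p1", ("xy", "1")] == 1.0


class TestCorrelationR2:
    def test_identity_is_one(self):
        assert correlation_r2([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_affine_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlation_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        sxx = ((x - x.mean()) ** 2).sum()
        syy = ((y - y.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        assert correlation_r2(x, y) == pytest.approx(sxy**2 / (sxx * syy), abs=1e-12)

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 3.0, 4.0]
        y = [1.0, 2.0, 5.0, np.nan, 4.0]
        assert correlation_r2(x, y) == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 complete pairs"):
            correlation_r2([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlation_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_rna_protein_correlation_rises_as_protein_noise_falls(self):
        design = ExperimentDesign(conditions=("cb", "xy"), reference="cb")
        r2_by_noise = {}
        for noise in (2.0, 0.5, 0.01):
            rna, evidence, _ = simulate_omics(
                design,
                400,
                frac_de=0.2,
                protein_detect_frac=1.0,
                protein_noise_sd=noise,
                seed=5,
            )
            protein = build_protein_matrix(evidence, design)
            r2_by_noise[noise] = correlation_r2(
                rna.data[("xy", "A")], protein.data[("xy", "1")]
            )
        assert r2_by_noise[2.0] < r2_by_noise[0.5] < r2_by_noise[0.01]
        assert r2_by_noise[0.01] > 0.95


class TestCountSamples:
    def test_two_samples(self, rng):
        genes = random_genes(rng, 3, 300)
        reads_a = [genes["g0"][0:100], genes["g1"][5:105]]
        reads_b = [genes["g2"][10:110]]
        counts = count_samples({("cb", "A"): reads_a, ("cb", "B"): reads_b}, genes)
        assert counts.counts.loc["g0", ("cb", "A")] == 1
        assert counts.counts.loc["g2", ("cb", "B")] == 1
        assert counts.counts.loc["g2", ("cb", "A")] == 0
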