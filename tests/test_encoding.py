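"""Genotype reading, imputation, incidence encoding and substructure."""

import numpy as np
import pytest

import riskrules as rr
from riskrules import io
from riskrules.containers import MISSING, GenotypeMatrix, VariantSpec
from riskrules.encoding import AlleleMismatchError, ibs_distance


def make_G(counts, modes=None, risk=None):
    counts = np.asarray(counts, dtype=np.int8)
    m = counts.shape[1]
    specs = [
        VariantSpec(
            f"rs{j}", "1", 100 + j, f"GENE{j}",
            (risk or ["A"] * m)[j], (modes or ["presence"] * m)[j],
        )
        for j in range(m)
    ]
    return GenotypeMatrix(
        subject_ids=[f"s{k}" for k in range(counts.shape[0])],
        variant_specs=specs,
        counts=counts,
    )


class TestReadGenotypes:
    def test_tsv_hand_counts(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "subject_id\trs0\trs1\n"
            "s0\t0\t2\n"
            "s1\t1\tNA\n"
            "s2\t2\t1\n"
        )
        specs = [VariantSpec("rs0"), VariantSpec("rs1")]
        G = rr.read_genotypes(p, "tsv", specs)
        expected = np.array([[0, 2], [1, MISSING], [2, 1]], dtype=np.int8)
        assert np.array_equal(G.counts, expected)

    def test_vcf_orientation(self, tmp_path):
        G = make_G([[0, 2], [1, 1], [2, 0]])
        io.write_vcf(G, tmp_path / "g.vcf")
        # risk allele = ALT ("A"): counts unchanged
        back = rr.read_genotypes(tmp_path / "g.vcf", "vcf", G.variant_specs)
        assert np.array_equal(back.counts, G.counts)
        # risk allele = REF ("G"): counts flipped 2 - c
        flipped_specs = [
            VariantSpec("rs0", "1", 100, risk_allele="G"),
            VariantSpec("rs1", "1", 101, risk_allele="G"),
        ]
        back2 = rr.read_genotypes(tmp_path / "g.vcf", "vcf", flipped_specs)
        assert np.array_equal(back2.counts, 2 - G.counts)
        assert set(back2.read_report.flipped_variants) == {"rs0", "rs1"}

    def test_vcf_allele_mismatch_is_hard_error(self, tmp_path):
        G = make_G([[0], [1]])
        io.write_vcf(G, tmp_path / "g.vcf")
        bad = [VariantSpec("rs0", "1", 100, risk_allele="T")]
        with pytest.raises(AlleleMismatchError, match="rs0"):
            rr.read_genotypes(tmp_path / "g.vcf", "vcf", bad)

    def test_absent_variant_reported_not_dropped_silently(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("subject_id\trs0\ns0\t1\n")
        specs = [VariantSpec("rs0"), VariantSpec("rs_missing")]
        G = rr.read_genotypes(p, "tsv", specs)
        assert G.read_report.absent_variants == ["rs_missing"]
        assert G.variant_ids == ["rs0"]

    def test_plink_raw_counted_allele(self, tmp_path):
        p = tmp_path / "g.raw"
        p.write_text(
            "FID IID PAT MAT SEX PHENOTYPE rs0_A rs1_G\n"
            "f1 s0 0 0 1 1 2 0\n"
            "f1 s1 0 0 2 2 1 1\n"
        )
        specs = [
            VariantSpec("rs0", risk_allele="A"),
            VariantSpec("rs1", risk_allele="C"),  # counted allele is G -> flip
        ]
        G = rr.read_genotypes(p, "plink_raw", specs)
        assert np.array_equal(G.counts, np.array([[2, 2], [1, 1]], dtype=np.int8))
        assert G.read_report.flipped_variants == ["rs1"]


class TestImputeMissing:
    def test_no_missing_unchanged(self):
        G = make_G([[0, 1], [2, 1]])
        for method in ("mode", "iterative_forest"):
            out = rr.impute_missing(G, method=method, seed=0)
            assert np.array_equal(out.counts, G.counts)

    def test_mode_forced(self):
        G = make_G([[0], [0], [0], [MISSING]])
        out = rr.impute_missing(G, method="mode", max_missing_fraction=0.5)
        assert out.counts[3, 0] == 0

    def test_all_missing_variant_is_error(self):
        G = make_G([[MISSING, 1], [MISSING, 0]])
        with pytest.raises(ValueError, match="rs0"):
            rr.impute_missing(G, method="mode", max_missing_fraction=1.0)

    def test_missingness_ceiling(self):
        G = make_G([[MISSING, 1], [0, 0], [1, 2]])
        with pytest.raises(ValueError, match="ceiling"):
            rr.impute_missing(G, method="mode", max_missing_fraction=0.1)

    def test_forest_at_least_as_accurate_as_mode(self):
        """1.3% MCAR mask on a correlated synthetic cohort: the iterative
        forest recovers masked genotypes at least as well as mode filling."""
        cohort = rr.simulate_cohort(
            rr.default_study_config(seed=8, n_variants=40, missing_rate=0.0)
        )
        G = cohort.genotypes
        masked = rr.inject_missing(G, 0.013, seed=3)
        mask = masked.counts == MISSING
        acc = {}
        for method in ("mode", "iterative_forest"):
            out = rr.impute_missing(masked, method=method, seed=0)
            acc[method] = float((out.counts[mask] == G.counts[mask]).mean())
        assert acc["iterative_forest"] >= acc["mode"]


class TestEncodeIncidence:
    def test_presence_and_absence_modes(self):
        G = make_G(
            [[2, 0], [0, 1], [1, 2]],
            modes=["presence", "absence"],
        )
        I = rr.encode_incidence(G, [1, 0, 1], phenotype_item="MS")
        # presence: count >= 1; absence: count == 0
        assert I.cells[:, 0].tolist() == [True, False, True]
        assert I.cells[:, 1].tolist() == [True, False, False]
        assert I.item_ids[-1] == "MS"
        assert I.cells[:, 2].tolist() == [True, False, True]

    def test_hand_fixture(self):
        G = make_G([[0, 0], [1, 1], [2, 0], [0, 2]])
        I = rr.encode_incidence(G, [0, 1, 1, 0])
        expected = np.array(
            [[0, 0, 0], [1, 1, 1], [1, 0, 1], [0, 1, 0]], dtype=bool
        )
        assert np.array_equal(I.cells, expected)

    def test_missing_codes_are_an_error(self):
        G = make_G([[MISSING], [1]])
        with pytest.raises(ValueError, match="impute"):
            rr.encode_incidence(G, [0, 1])

    def test_tsv_round_trip(self, tmp_path):
        G = make_G([[0, 2], [1, 1], [2, 0]])
        I = rr.encode_incidence(G, [1, 0, 1])
        io.write_incidence_tsv(I, tmp_path / "i.tsv")
        back = io.read_incidence_tsv(tmp_path / "i.tsv")
        assert back.item_ids == I.item_ids
        assert np.array_equal(back.cells, I.cells)

    def test_orientation_invariance(self, tmp_path):
        """Flipping REF/ALT labels and the risk allele together leaves the
        incidence matrix unchanged."""
        G = make_G([[0, 1], [2, 0], [1, 2]])
        io.write_vcf(G, tmp_path / "g.vcf")
        A = rr.read_genotypes(tmp_path / "g.vcf", "vcf", G.variant_specs)
        IA = rr.encode_incidence(A, [1, 0, 1])
        # same file, but count the REF allele and declare it the risk allele:
        # equivalent to relabelling REF<->ALT together with the risk allele
        flipped = [
            VariantSpec(s.variant_id, s.chromosome, s.position, risk_allele="G")
            for s in G.variant_specs
        ]
        B = rr.read_genotypes(tmp_path / "g.vcf", "vcf", flipped)
        B2 = GenotypeMatrix(B.subject_ids, G.variant_specs, 2 - B.counts)
        IB = rr.encode_incidence(B2, [1, 0, 1])
        assert np.array_equal(IA.cells, IB.cells)

    def test_item_frequency_matches_hwe(self):
        """Presence-item frequency ~ 1-(1-MAF)^2 under HWE (binomial band)."""
        maf = 0.2
        cfg = rr.SyntheticCohortConfig(
            seed=6, n_cases=500, n_controls=500, n_variants=30,
            maf_range=(maf, maf), patterns=[], n_substructure_dims=0,
            pattern_item_maf=None,
        )
        c = rr.simulate_cohort(cfg)
        I = rr.encode_incidence(c.genotypes, c.phenotype)
        freq = I.cells[:, :-1].mean()
        expected = 1 - (1 - maf) ** 2
        n = I.n_subjects * 30
        half = 3 * np.sqrt(expected * (1 - expected) / n)
        assert abs(freq - expected) < half + 0.01


class TestSubstructure:
    def test_identical_subjects_distance_zero(self):
        G = make_G([[1, 2, 0], [1, 2, 0], [0, 0, 2]])
        D = ibs_distance(G)
        assert D[0, 1] == 0.0
        assert D[0, 2] > 0

    def test_first_coordinate_separates_clusters(self):
        """Two-group cohort: the leading principal coordinate correlates with
        the true group (point-biserial > 0.9)."""
        rng = np.random.default_rng(0)
        n, m = 120, 60
        group = rng.integers(0, 2, n)
        maf = np.where(group[:, None] == 0, 0.1, 0.45)
        counts = rng.binomial(2, np.broadcast_to(maf, (n, m))).astype(np.int8)
        G = make_G(counts)
        coords = rr.compute_substructure(G, k=3)
        assert coords.shape == (n, 3)
        assert np.isfinite(coords).all()
        r = abs(np.corrcoef(coords[:, 0], group)[0, 1])
        assert r > 0.9

    def test_k_must_be_below_subject_count(self):
        G = make_G([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            rr.compute_substructure(G, k=2)

    def test_sign_convention_deterministic(self):
        c = rr.simulate_cohort(rr.default_study_config(seed=9, n_variants=30))
        a = rr.compute_substructure(c.genotypes, k=2)
        b = rr.compute_substructure(c.genotypes, k=2)
        assert np.array_equal(a, b)
        for j in range(2):
            assert a[np.argmax(np.abs(a[:, j])), j] > 0
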