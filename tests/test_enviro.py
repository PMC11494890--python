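import numpy as np
import pandas as pd
import pytest

from conftest import make_genome
from oxytrait.classify import TrainConfig, train_logistic
from oxytrait.dataio import Dataset
from oxytrait.enviro import (
    DepthPoint,
    MagPrediction,
    classify_genomes,
    contig_agreement,
    depth_profile,
    emp_habitat_summary,
    make_contigs,
    redox_correlation,
)
from oxytrait.features import FeatureSpec, build_feature_matrix
from oxytrait.synthgen import SynthConfig, generate_dataset, generate_depth_fixture

CLASSES = ("Aerobe", "Anaerobe", "Facultative")


def _pred(mag_id, predicted, sample_id=None, habitat=None, completeness=1.0):
    probs = {c: (1.0 if c == predicted else 0.0) for c in CLASSES}
    return MagPrediction(
        mag_id=mag_id, probs=probs, predicted=predicted,
        sample_id=sample_id, habitat_label=habitat, completeness=completeness,
    )


@pytest.fixture(scope="module")
def nt_model_and_data():
    """A genomic NT 3-mer logistic model on GC-separated classes."""
    config = SynthConfig(
        taxonomy_shape={"phylum": 2, "class": 2, "order": 1,
                        "family": 2, "genus": 1, "species": 2},
        genomes_per_species=3,
        genes_per_genome=80,
        mean_gene_length=150,
        seed=3,
    )
    ds = generate_dataset(config)
    spec = FeatureSpec("genomic_nt_kmer", 3)
    fm = build_feature_matrix(ds, spec)
    model = train_logistic(fm, [r.label for r in ds], TrainConfig(seed=3))
    return model, spec, ds


class TestClassifyGenomes:
    def test_one_row_per_genome_probs_sum_to_one(self, nt_model_and_data):
        model, spec, ds = nt_model_and_data
        preds = classify_genomes(model, spec, ds)
        assert len(preds) == len(ds)
        for p in preds:
            assert sum(p.probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unlabeled_dataset_accepted(self, nt_model_and_data):
        model, spec, ds = nt_model_and_data
        stripped = Dataset(
            [make_genome(r.genome_id, [p.residues for p in r.proteins],
                         cds=[c.residues for c in r.cds_nt],
                         genomic=[g.residues for g in r.genomic])
             for r in ds.records[:3]]
        )
        preds = classify_genomes(model, spec, stripped)
        assert len(preds) == 3

    def test_schema_mismatch_errors(self, nt_model_and_data):
        model, _, ds = nt_model_and_data
        with pytest.raises(ValueError, match="schema"):
            classify_genomes(model, FeatureSpec("genomic_nt_kmer", 2), ds)

    def test_metadata_attached(self, nt_model_and_data):
        model, spec, ds = nt_model_and_data
        gid = ds.genome_ids[0]
        meta = {gid: {"sample_id": "S1", "habitat_label": "rumen",
                      "completeness": 0.7}}
        preds = classify_genomes(model, spec, ds, meta)
        assert preds[0].sample_id == "S1"
        assert preds[0].completeness == 0.7


class TestEmpHabitatSummary:
    def _fixture(self):
        """10 samples x 10 anaerobe MAGs in habitat H (all pass), plus
        known-fate extras exercising each filter boundary."""
        preds = []
        for s in range(10):
            for m in range(10):
                preds.append(_pred(f"H_s{s}_m{m}", "Anaerobe",
                                   sample_id=f"Hs{s}", habitat="H"))
        # sample with 10 MAGs but one under the completeness cut -> 9 left
        for m in range(9):
            preds.append(_pred(f"X_m{m}", "Aerobe", "Xs0", "X"))
        preds.append(_pred("X_low", "Aerobe", "Xs0", "X", completeness=0.4))
        # habitat with only 9 qualifying samples
        for s in range(9):
            for m in range(10):
                preds.append(_pred(f"Y_s{s}_m{m}", "Facultative",
                                   sample_id=f"Ys{s}", habitat="Y"))
        return preds

    def test_all_anaerobe_habitat_fraction_one(self):
        out = emp_habitat_summary(self._fixture())
        assert [s.habitat_label for s in out] == ["H"]
        h = out[0]
        assert h.fraction_anaerobe == 1.0
        assert h.fraction_aerobe == 0.0

    def test_filter_bookkeeping_exact(self):
        """Counts surviving each filter match hand-computed values."""
        out = emp_habitat_summary(self._fixture())
        h = out[0]
        # X: completeness filter leaves 9 MAGs -> sample dropped;
        # Y: 9 samples -> habitat dropped; H keeps 10 x 10.
        assert (h.n_samples, h.n_mags) == (10, 100)

    def test_fractions_sum_to_one(self):
        preds = [
            _pred(f"m{i}", CLASSES[i % 3], f"s{i % 12}", "Z")
            for i in range(144)
        ]
        out = emp_habitat_summary(preds)
        assert len(out) == 1
        z = out[0]
        total = z.fraction_aerobe + z.fraction_anaerobe + z.fraction_facultative
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_output_allowed(self):
        assert emp_habitat_summary([_pred("m", "Aerobe", "s", "H")]) == []


def _perfect_preds(mags):
    return [
        _pred(r.genome_id, r.label) for r in mags
    ]


class TestDepthProfile:
    def _tables(self, rows, mags=("MAG_Aerobe", "MAG_Anaerobe")):
        ab = pd.DataFrame(rows, columns=list(mags),
                          index=pd.Index([f"S{i}" for i in range(len(rows))],
                                         name="sample_id"))
        depths = {f"S{i}": 10.0 * (i + 1) for i in range(len(rows))}
        chem = {10.0 * (i + 1): (100.0 / (i + 1), 1.0 * (i + 1))
                for i in range(len(rows))}
        preds = [_pred("MAG_Aerobe", "Aerobe"), _pred("MAG_Anaerobe", "Anaerobe")]
        return preds, ab, depths, chem

    def test_all_aerobe_abundance_gives_undefined_ratio(self):
        preds, ab, depths, chem = self._tables([[1.0, 0.0]])
        (pt,) = depth_profile(preds, ab, depths, chem)
        assert pt.fraction_aerobe == 1.0
        assert pt.aerobe_anaerobe_ratio is None

    def test_equal_abundance_ratio_one(self):
        preds, ab, depths, chem = self._tables([[0.4, 0.4]])
        (pt,) = depth_profile(preds, ab, depths, chem)
        assert pt.aerobe_anaerobe_ratio == pytest.approx(1.0)

    def test_rescaling_invariance(self):
        preds, ab, depths, chem = self._tables([[0.3, 0.1]])
        (p1,) = depth_profile(preds, ab, depths, chem)
        (p2,) = depth_profile(preds, ab * 2.0, depths, chem)
        assert p1.fraction_aerobe == pytest.approx(p2.fraction_aerobe)
        assert p1.aerobe_anaerobe_ratio == pytest.approx(p2.aerobe_anaerobe_ratio)

    def test_missing_depth_errors(self):
        preds, ab, depths, chem = self._tables([[0.5, 0.5]])
        with pytest.raises(KeyError, match="S0"):
            depth_profile(preds, ab, {}, chem)


class TestRedoxCorrelation:
    def test_noiseless_loglinear_recovers_exactly(self):
        ab, chem, mags = generate_depth_fixture(
            n_depths=12, slope=1.3, intercept=0.2, noise_sd=0.0, seed=0
        )
        preds = _perfect_preds(mags)
        profile = depth_profile(
            preds, ab, chem["depth"].to_dict(),
            {r["depth"]: (r["o2"], r["h2s"]) for _, r in chem.iterrows()},
        )
        corr = redox_correlation(profile)
        assert corr.pearson_rho == pytest.approx(1.0, abs=1e-12)
        assert corr.slope == pytest.approx(1.3, abs=1e-9)
        assert corr.intercept == pytest.approx(0.2, abs=1e-9)
        assert corr.relative_error.max() == pytest.approx(0.0, abs=1e-9)

    def test_anticorrelated_ratios_negative_rho(self):
        ab, chem, mags = generate_depth_fixture(
            n_depths=10, slope=-0.8, intercept=0.0, noise_sd=0.0, seed=0
        )
        preds = _perfect_preds(mags)
        profile = depth_profile(
            preds, ab, chem["depth"].to_dict(),
            {r["depth"]: (r["o2"], r["h2s"]) for _, r in chem.iterrows()},
        )
        assert redox_correlation(profile).pearson_rho < 0

    def test_fewer_than_three_points_errors(self):
        points = [
            DepthPoint(10, 100, 1, 0.5, 0.4, 0.1, 1.25),
            DepthPoint(20, 10, 10, 0.3, 0.6, 0.1, 0.5),
        ]
        with pytest.raises(ValueError, match="3"):
            redox_correlation(points)

    def test_undefined_ratios_excluded_not_fatal(self):
        points = [
            DepthPoint(10.0 * i, 100.0 / (i + 1), float(i + 1),
                       0.5, 0.4, 0.1, 10.0 ** (1 - 0.5 * i))
            for i in range(4)
        ]
        points.append(DepthPoint(99, 1.0, 99.0, 1.0, 0.0, 0.0, None))
        corr = redox_correlation(points)
        assert corr.n == 4


class TestMakeContigs:
    def test_floor_division_with_positions(self):
        genome = make_genome("g", ["M"], genomic=["ACGT" * 2500])  # n = 10,000
        contigs = make_contigs(genome, 3000)
        assert len(contigs) == 3
        whole = "ACGT" * 2500
        for i, c in enumerate(contigs):
            assert c.residues == whole[i * 3000 : (i + 1) * 3000]

    def test_l_equals_n_single_contig(self):
        genome = make_genome("g", ["M"], genomic=["ACGTACGT"])
        (c,) = make_contigs(genome, 8)
        assert c.residues == "ACGTACGT"

    def test_l_one_gives_single_base_contigs(self):
        contigs = make_contigs("ACGT", 1)
        assert [c.residues for c in contigs] == ["A", "C", "G", "T"]

    def test_l_exceeding_n_errors(self):
        with pytest.raises(ValueError):
            make_contigs("ACGT", 5)

    def test_concatenation_is_prefix_of_input(self):
        seq = "ACGTTGCA" * 100  # n = 800
        contigs = make_contigs(seq, 300)
        joined = "".join(c.residues for c in contigs)
        assert joined == seq[: (800 // 300) * 300]


class TestContigAgreement:
    def test_full_length_contig_always_agrees(self, nt_model_and_data):
        model, _, ds = nt_model_and_data
        rec = ds.records[0]
        n = sum(len(s) for s in rec.genomic)
        (rep,) = contig_agreement(model, rec, [n])
        assert rep.agrees
        assert rep.contig_match_fraction == 1.0
        assert rep.n_contigs == 1

    def test_match_fraction_increases_with_length(self, nt_model_and_data):
        """On homogeneous genomes, longer contigs average away sampling
        noise, so per-contig agreement with the global call rises."""
        model, _, ds = nt_model_and_data
        fractions = {200: [], 2000: [], 20000: []}
        for rec in ds.records[:6]:
            for rep in contig_agreement(model, rec, list(fractions)):
                fractions[rep.length].append(rep.contig_match_fraction)
        means = [np.mean(fractions[l]) for l in sorted(fractions)]
        assert means[0] <= means[1] <= means[2]

    def test_aa_model_rejected(self, planted_dataset, nt_model_and_data):
        _, _, ds = nt_model_and_data
        fm = build_feature_matrix(planted_dataset, FeatureSpec("aa_kmer", 1))
        aa_model = train_logistic(fm, [r.label for r in planted_dataset])
        with pytest.raises(ValueError, match="genomic_nt_kmer"):
            contig_agreement(aa_model, ds.records[0], [1000])
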