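import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermostab import DescriptorConfig, FeatureMatrix, featurize, feature_names
from thermostab.descriptors import (
    aa_composition,
    aa_group_features,
    apaac,
    autocorrelation,
    conjoint_triad,
    ctd_features,
    dipeptide_composition,
    paac,
    quasi_sequence_order,
    sequence_order_coupling,
    windowed_dipeptide_counts,
)
from thermostab.errors import FeatureError
from thermostab.physchem import PHYSCHEM_NAMES, physchem_block
from thermostab.sequence_io import ProteinRecord
from thermostab.tables import KYTE_DOOLITTLE, STANDARD_AA

from .oracles import (
    oracle_aac,
    oracle_apaac,
    oracle_autocorr,
    oracle_ctd,
    oracle_dpc,
    oracle_groups,
    oracle_paac,
    oracle_qso,
    oracle_socn,
    oracle_triad,
    oracle_windip,
)

seq_strategy = st.text(alphabet=STANDARD_AA, min_size=12, max_size=80)


# ---------------------------------------------------------------------------
# Oracle agreement
# ---------------------------------------------------------------------------

ORACLE_PAIRS = [
    ("aac", lambda s: aa_composition(s), oracle_aac),
    ("dpc", lambda s: dipeptide_composition(s), oracle_dpc),
    ("windip", lambda s: windowed_dipeptide_counts(s, 21), lambda s: oracle_windip(s, 21)),
    ("windip_w7", lambda s: windowed_dipeptide_counts(s, 7), lambda s: oracle_windip(s, 7)),
    ("grp", lambda s: aa_group_features(s), oracle_groups),
    ("ctd", lambda s: ctd_features(s), oracle_ctd),
    (
        "moreau_broto",
        lambda s: autocorrelation(s, {"kd": KYTE_DOOLITTLE}, 5, "moreau_broto"),
        lambda s: oracle_autocorr(s, KYTE_DOOLITTLE, 5, "moreau_broto"),
    ),
    (
        "moran",
        lambda s: autocorrelation(s, {"kd": KYTE_DOOLITTLE}, 5, "moran"),
        lambda s: oracle_autocorr(s, KYTE_DOOLITTLE, 5, "moran"),
    ),
    (
        "geary",
        lambda s: autocorrelation(s, {"kd": KYTE_DOOLITTLE}, 5, "geary"),
        lambda s: oracle_autocorr(s, KYTE_DOOLITTLE, 5, "geary"),
    ),
    ("socn_pcd", lambda s: sequence_order_coupling(s, 3, "pcd"), lambda s: oracle_socn(s, 3, "pcd")),
    ("socn_grantham", lambda s: sequence_order_coupling(s, 3, "grantham"), lambda s: oracle_socn(s, 3, "grantham")),
    ("qso", lambda s: quasi_sequence_order(s, 3, 0.1, "pcd"), lambda s: oracle_qso(s, 3, 0.1, "pcd")),
    ("paac", lambda s: paac(s, 4, 0.05), lambda s: oracle_paac(s, 4, 0.05)),
    ("apaac", lambda s: apaac(s, 4, 0.05), lambda s: oracle_apaac(s, 4, 0.05)),
    ("triad", lambda s: conjoint_triad(s), oracle_triad),
]


@pytest.mark.parametrize("name,impl,oracle", ORACLE_PAIRS, ids=[p[0] for p in ORACLE_PAIRS])
def test_family_matches_bruteforce_oracle(name, impl, oracle, random_sequences):
    for seq in random_sequences:
        np.testing.assert_allclose(
            impl(seq), np.array(oracle(seq)), rtol=1e-10, atol=1e-12,
            err_msg=f"{name} disagrees with oracle on {seq[:20]}...",
        )


# ---------------------------------------------------------------------------
# Normalization and structural invariants
# ---------------------------------------------------------------------------

@settings(max_examples=30, derandomize=True, deadline=None)
@given(seq=seq_strategy)
def test_composition_blocks_normalize_to_one(seq):
    assert abs(aa_composition(seq).sum() - 1) < 1e-12
    assert abs(dipeptide_composition(seq).sum() - 1) < 1e-12
    assert abs(paac(seq, 4, 0.05).sum() - 1) < 1e-12
    assert abs(apaac(seq, 4, 0.05).sum() - 1) < 1e-12
    assert abs(quasi_sequence_order(seq, 3).sum() - 1) < 1e-12
    grp = aa_group_features(seq)
    assert abs(grp[6:].sum() - 1) < 1e-12
    assert grp[:6].sum() == len(seq)
    ctd = ctd_features(seq)
    for start in range(0, 147, 21):  # each property's composition triple
        assert abs(ctd[start : start + 3].sum() - 1) < 1e-12


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seq=st.text(alphabet=STANDARD_AA, min_size=3, max_size=60))
def test_triad_counts_sum_to_length_minus_two(seq):
    assert conjoint_triad(seq).sum() == len(seq) - 2


def test_block_lengths():
    seq = "ACDEFGHIKLMNPQRSTVWY" * 3
    assert len(aa_group_features(seq)) == 12
    assert len(windowed_dipeptide_counts(seq)) == 441
    assert len(physchem_block(seq)) == 28
    assert len(ctd_features(seq)) == 147
    assert len(conjoint_triad(seq)) == 343


# ---------------------------------------------------------------------------
# Degenerate (homopolymer) conventions
# ---------------------------------------------------------------------------

class TestHomopolymer:
    seq = "G" * 40

    def test_single_class_composition(self):
        ctd = ctd_features(self.seq)
        # transitions all zero, compositions one-hot
        for start in range(0, 147, 21):
            assert set(np.round(ctd[start : start + 3], 12)) <= {0.0, 1.0}
            assert np.all(ctd[start + 3 : start + 6] == 0)

    def test_moran_geary_zero_variance_convention(self):
        for kind in ("moran", "geary"):
            vals = autocorrelation(self.seq, {"kd": KYTE_DOOLITTLE}, 5, kind)
            assert np.all(vals == 0.0)

    def test_moreau_broto_constant(self):
        vals = autocorrelation(self.seq, {"kd": KYTE_DOOLITTLE}, 5, "moreau_broto")
        # constant standardized value c -> c^2 at every lag
        assert np.allclose(vals, vals[0])

    def test_socn_zero_self_distance(self):
        assert np.all(sequence_order_coupling(self.seq, 5, "grantham") == 0)

    def test_qso_reduces_to_composition(self):
        q = quasi_sequence_order(self.seq, 5)
        np.testing.assert_allclose(q[:20], aa_composition(self.seq), atol=1e-15)
        assert np.all(q[20:] == 0)

    def test_windowed_counts_reflect_both_adjacent_pairs(self):
        # windows of "AAA": ["AAA", "AA"] -> the two adjacent AA pairs are
        # counted with total multiplicity 3, all in the AA cell
        v = windowed_dipeptide_counts("AAA", window=5)
        assert v.sum() == 3
        assert v.max() == 3  # all counts in the single AA cell

    def test_all_families_finite(self):
        rec = ProteinRecord("homo", self.seq)
        fm = featurize([rec])
        assert np.all(np.isfinite(fm.values))


# ---------------------------------------------------------------------------
# PAAC limit and windowed conventions
# ---------------------------------------------------------------------------

def test_paac_weight_zero_limit_equals_composition(random_sequences):
    seq = random_sequences[0]
    np.testing.assert_allclose(paac(seq, 4, 1e-300)[:20], aa_composition(seq), atol=1e-12)


def test_length_preconditions_raise():
    with pytest.raises(FeatureError):
        dipeptide_composition("A")
    with pytest.raises(FeatureError):
        autocorrelation("ACDEF", {"kd": KYTE_DOOLITTLE}, 10, "moran")
    with pytest.raises(FeatureError):
        paac("ACDEF", 10)
    with pytest.raises(FeatureError):
        windowed_dipeptide_counts("ACDEF", window=1)


# ---------------------------------------------------------------------------
# featurize and configuration
# ---------------------------------------------------------------------------

class TestFeaturize:
    def test_documented_block_sum(self, random_records):
        cfg = DescriptorConfig(enabled_families=("grp", "windip", "physchem"))
        fm = featurize(random_records[:3], cfg)
        assert fm.n_features == 12 + 441 + 28

    def test_identical_sequences_identical_rows(self):
        seq = "MKVLA" * 10
        fm = featurize([ProteinRecord("a", seq), ProteinRecord("b", seq)])
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_names_unique_and_stable(self, random_records):
        cfg = DescriptorConfig()
        names1 = feature_names(cfg)
        names2 = feature_names(DescriptorConfig())
        assert names1 == names2
        assert len(set(names1)) == len(names1)

    def test_permutation_equivariant(self, random_records):
        recs = random_records[:6]
        cfg = DescriptorConfig(enabled_families=("aac", "grp", "ctd"))
        fm = featurize(recs, cfg)
        perm = [3, 0, 5, 1, 4, 2]
        fm_p = featurize([recs[i] for i in perm], cfg)
        np.testing.assert_array_equal(fm_p.values, fm.values[perm])
        assert fm_p.record_ids == [fm.record_ids[i] for i in perm]

    def test_short_record_error_names_record_and_family(self):
        rec = ProteinRecord("tiny", "MKVLA")
        with pytest.raises(FeatureError, match="tiny"):
            featurize([rec])

    def test_short_record_dropped_under_permissive_flag(self, random_records):
        recs = [ProteinRecord("tiny", "MKVLA")] + random_records[:2]
        fm = featurize(recs, on_invalid="drop")
        assert fm.record_ids == [r.id for r in random_records[:2]]

    def test_subset_preserves_order_and_errors_on_missing(self, random_records):
        fm = featurize(random_records[:3], DescriptorConfig(enabled_families=("aac",)))
        sub = fm.subset(["aac.C", "aac.A"])
        assert sub.feature_names == ["aac.C", "aac.A"]
        with pytest.raises(FeatureError, match="nope"):
            fm.subset(["nope"])

    def test_tsv_roundtrip(self, tmp_path, random_records):
        fm = featurize(random_records[:3], DescriptorConfig(enabled_families=("grp",)))
        path = tmp_path / "fm.tsv"
        fm.save_tsv(path)
        back = FeatureMatrix.load_tsv(path)
        assert back.feature_names == fm.feature_names
        np.testing.assert_allclose(back.values, fm.values)


class TestDescriptorConfig:
    def test_group_map_must_partition(self):
        with pytest.raises(ValueError, match="partition"):
            DescriptorConfig(group_map={"a": "ACDEFGHIKL", "b": "MNPQRSTVW"})

    @pytest.mark.parametrize(
        "kwargs", [{"paac_weight": 0.0}, {"window": 1}, {"nlag_socn": 0},
                   {"enabled_families": ("nonsense",)}]
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            DescriptorConfig(**kwargs)

    def test_fingerprint_sensitive_to_parameters(self):
        a = DescriptorConfig()
        b = DescriptorConfig(paac_lambda=10)
        assert a.fingerprint() == DescriptorConfig().fingerprint()
        assert a.fingerprint() != b.fingerprint()

    def test_min_sequence_length_tracks_lags(self):
        assert DescriptorConfig().min_sequence_length == 31
        cfg = DescriptorConfig(enabled_families=("aac", "grp"))
        assert cfg.min_sequence_length == 1


# ---------------------------------------------------------------------------
# Physicochemical block spot checks
# ---------------------------------------------------------------------------

class TestPhyschem:
    def test_gravy_of_homopolymer_is_scale_value(self):
        block = dict(zip(PHYSCHEM_NAMES, physchem_block("AAAA")))
        assert block["gravy"] == pytest.approx(KYTE_DOOLITTLE["A"])

    def test_molecular_weight_single_glycine(self):
        block = dict(zip(PHYSCHEM_NAMES, physchem_block("G")))
        # Gly residue (57.05 Da average) plus one water
        assert block["molecular_weight"] == pytest.approx(75.07, abs=0.05)

    def test_atomic_composition_glycine(self):
        block = dict(zip(PHYSCHEM_NAMES, physchem_block("G")))
        # C2H3NO + H2O
        assert (block["atoms_C"], block["atoms_H"], block["atoms_N"],
                block["atoms_O"], block["atoms_S"]) == (2, 5, 1, 2, 0)

    def test_aliphatic_index_closed_form(self):
        # one each of A, V, I, L -> 100*(0.25 + 2.9*0.25 + 3.9*0.5)
        block = dict(zip(PHYSCHEM_NAMES, physchem_block("AVIL")))
        assert block["aliphatic_index"] == pytest.approx(
            100 * (0.25 + 2.9 * 0.25 + 3.9 * 0.5)
        )

    def test_extinction_coefficients(self):
        block = dict(zip(PHYSCHEM_NAMES, physchem_block("WWYCC" + "A" * 30)))
        assert block["ext_coeff_reduced"] == 2 * 5500 + 1490
        assert block["ext_coeff_cystines"] == 2 * 5500 + 1490 + 125

    def test_charged_residue_counts(self, random_sequences):
        for seq in random_sequences[:5]:
            block = dict(zip(PHYSCHEM_NAMES, physchem_block(seq)))
            assert block["n_negative"] == seq.count("D") + seq.count("E")
            assert block["n_positive"] == seq.count("R") + seq.count("K")
            assert block["length"] == len(seq)
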