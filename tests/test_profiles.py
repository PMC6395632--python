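"""Positional-profile encoders: BPB, ANBPB, DBPB, IAAPair, PSTAAP."""

import numpy as np
import pytest

from snopred import (
    ANBPBEncoder,
    BPBEncoder,
    DBPBEncoder,
    IAAPairEncoder,
    LabeledDataset,
    PSTAAPEncoder,
    PeptideWindow,
    PositionalProfile,
    WindowFeaturizer,
    fit_positional_profiles,
)

ENCODER_DIMS = {
    BPBEncoder: 40,
    ANBPBEncoder: 40,
    DBPBEncoder: 38,
    IAAPairEncoder: 39,
    PSTAAPEncoder: 18,
}


@pytest.fixture(scope="module")
def fitted(default_sim):
    profile = PositionalProfile.from_data(default_sim.sequences, default_sim.labels)
    encoders = {cls: cls(profile=profile).fit(default_sim.sequences) for cls in ENCODER_DIMS}
    return profile, encoders


class TestProfileFit:
    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            PositionalProfile.from_data(["AACAA", "GGCGG"], [1, 1])

    def test_tables_normalized(self, fitted):
        profile, _ = fitted
        for tabs in (profile.singles, profile.pairs_dec, profile.pairs0,
                     profile.pairs1, profile.triples):
            for c in (0, 1):
                assert np.allclose(tabs[c].sum(axis=1), 1.0)
                assert (tabs[c] >= 0).all()

    def test_single_window_class_gives_certainty(self):
        ds = LabeledDataset([PeptideWindow("AKCMA", label=1), PeptideWindow("GGCGG", label=0)])
        profile = fit_positional_profiles(ds)
        v = BPBEncoder(profile=profile).fit(ds.sequences).transform(["AKCMA"])[0]
        assert np.allclose(v[:4], 1.0)  # its own positive profile
        assert np.allclose(v[4:], 0.0)  # never seen in the negative class

    def test_identical_classes_give_equal_tables(self):
        wins = [PeptideWindow("AKCMA", label=1), PeptideWindow("GGCGG", label=1),
                PeptideWindow("AKCMA", label=0), PeptideWindow("GGCGG", label=0)]
        profile = fit_positional_profiles(LabeledDataset(wins))
        assert np.allclose(profile.singles[0], profile.singles[1])
        assert np.allclose(profile.triples[0], profile.triples[1])

    def test_json_round_trip_bit_exact(self, fitted, tmp_path, default_sim):
        profile, encoders = fitted
        p = tmp_path / "profile.json"
        profile.to_json(p)
        reloaded = PositionalProfile.from_json(p)
        seqs = default_sim.sequences[:20]
        for cls in ENCODER_DIMS:
            a = cls(profile=profile).fit(seqs).transform(seqs)
            b = cls(profile=reloaded).fit(seqs).transform(seqs)
            assert (a == b).all()


class TestDimensions:
    def test_each_encoder_dimension_at_t10(self, fitted, default_sim):
        _, encoders = fitted
        seqs = default_sim.sequences[:5]
        for cls, dim in ENCODER_DIMS.items():
            V = encoders[cls].transform(seqs)
            assert V.shape == (5, dim), cls.__name__
            assert len(encoders[cls].get_feature_names_out()) == dim

    def test_length_mismatch_rejected(self, fitted):
        _, encoders = fitted
        for cls in ENCODER_DIMS:
            with pytest.raises(ValueError, match="length"):
                encoders[cls].transform(["AACAA"])


class TestValueRanges:
    def test_posterior_encoders_in_unit_interval(self, fitted, default_sim):
        _, encoders = fitted
        seqs = default_sim.sequences[:100]
        for cls in (BPBEncoder, ANBPBEncoder, DBPBEncoder):
            V = encoders[cls].transform(seqs)
            assert (V >= 0).all() and (V <= 1).all(), cls.__name__

    def test_difference_encoders_in_signed_unit_interval(self, fitted, default_sim):
        _, encoders = fitted
        seqs = default_sim.sequences[:100]
        for cls in (IAAPairEncoder, PSTAAPEncoder):
            V = encoders[cls].transform(seqs)
            assert (V >= -1).all() and (V <= 1).all(), cls.__name__

    def test_unseen_event_scores_zero(self, toy_dataset):
        enc = BPBEncoder().fit(toy_dataset.sequences, toy_dataset.labels)
        v = enc.transform(["WWCWW"])[0]  # W appears nowhere in the training set
        assert np.allclose(v, 0.0)
        d = DBPBEncoder().fit(toy_dataset.sequences, toy_dataset.labels).transform(["WWCWW"])[0]
        assert np.allclose(d, 0.0)


class TestDifferenceEncoders:
    def test_identical_classes_give_zero_vector(self):
        wins = [PeptideWindow("AKCMA", label=1), PeptideWindow("GKCMG", label=1),
                PeptideWindow("AKCMA", label=0), PeptideWindow("GKCMG", label=0)]
        ds = LabeledDataset(wins)
        for cls in (IAAPairEncoder, PSTAAPEncoder):
            V = cls().fit(ds.sequences, ds.labels).transform(ds.sequences)
            assert np.allclose(V, 0.0), cls.__name__

    def test_label_swap_negates_vector(self, small_sim):
        seqs, y = small_sim.sequences, small_sim.labels
        for cls in (IAAPairEncoder, PSTAAPEncoder):
            a = cls().fit(seqs, y).transform(seqs[:10])
            b = cls().fit(seqs, 1 - y).transform(seqs[:10])
            assert np.allclose(a, -b), cls.__name__


class TestANBPB:
    def test_uniform_position_maps_to_half(self):
        # 21 windows whose -1 position cycles through the full alphabet
        from snopred.alphabet import WINDOW_ALPHABET

        pos = [PeptideWindow(f"{aa}C{aa2}", label=1)
               for aa, aa2 in zip(WINDOW_ALPHABET, WINDOW_ALPHABET)]
        neg = [PeptideWindow("ACA", label=0)]
        ds = LabeledDataset(pos + neg)
        enc = ANBPBEncoder().fit(ds.sequences, ds.labels)
        v = enc.transform(["KCK"])[0]
        # positive block: uniform frequencies -> z = 0 -> Phi(0) = 0.5
        assert np.allclose(v[:2], 0.5)

    def test_monotone_in_class_frequency(self, fitted, default_sim):
        profile, encoders = fitted
        enc = encoders[ANBPBEncoder]
        # position -1 (index 9 de-centered): K enriched in positives
        freqs = profile.singles[1][9]
        coded = enc.tables_[1][9]
        order = np.argsort(freqs)
        assert (np.diff(coded[order]) >= -1e-12).all()


def test_concatenated_dimension_645(small_sim):
    feat = WindowFeaturizer(lam=5).fit(small_sim.sequences, small_sim.labels)
    assert feat.n_features_out_ == 645
    assert feat.block_sizes() == {
        "pcpseaac": 25, "kmer1": 20, "kmer2": 400, "pcpseaac-g": 25,
        "anbpb": 40, "dbpb": 38, "bpb": 40, "iaapair": 39, "pstaap": 18,
    }
    names = feat.get_feature_names_out()
    assert len(names) == len(set(names)) == 645
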