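"""Texture branch: embeddings, prototype clustering, the fine-tuning
rules and the consistency-trained classifier."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import cross_val_score

from pitt.features import TextureChip
from pitt.ki import PseudoLabelEntry, PseudoLabelSet
from pitt.texture import (
    MarginKMeans,
    SemiTextureClassifier,
    TextureEmbedder,
    TextureProtoSet,
    build_kspice1_labelset,
    finetune_texture_pseudolabels,
    predict_proba_texture,
    texture_cluster,
    texture_embed,
)


def striped_chip(theta_deg, period=4, size=32, noise=0.02, rng=None, phase=0.0):
    rng = rng or np.random.default_rng(0)
    r, c = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    th = np.deg2rad(theta_deg)
    stripes = 0.5 + 0.25 * np.sin(2 * np.pi * (c * np.cos(th) + r * np.sin(th)) / period + phase)
    img = np.repeat(stripes[:, :, None], 3, axis=2) + noise * rng.normal(size=(size, size, 3))
    return img


def chip_list(thetas, rng, n=15):
    chips = []
    for i in range(n):
        for j, th in enumerate(thetas):
            pix = striped_chip(th, rng=rng, phase=rng.uniform(0, 2 * np.pi))
            chips.append(TextureChip(parcel_id=f"c{j}_{i:02d}", pixels=pix, side=32))
    return chips


class TestEmbedding:
    def test_identical_chips_identical_embeddings(self, rng):
        chip = striped_chip(0, rng=rng)
        emb = TextureEmbedder().fit(None).transform([chip, chip])
        assert np.array_equal(emb[0], emb[1])

    def test_orientation_families_linearly_separable(self, rng):
        chips = chip_list([0, 90], rng)
        emb = texture_embed(chips)
        y = [i.split("_")[0] for i in emb.index]
        X = (emb - emb.mean()) / (emb.std() + 1e-12)
        acc = cross_val_score(LogisticRegression(max_iter=1000), X, y, cv=2).mean()
        assert acc == 1.0

    def test_rot90_permutes_orientation_features(self, rng):
        """Rotating a chip 90 degrees swaps the 0/90 and 45/135 filter
        energies exactly (the filter bank is built from exact rotations)."""
        chip = striped_chip(0, rng=rng)
        e = TextureEmbedder().fit(None)
        f0 = e.transform([chip])[0]
        f90 = e.transform([np.rot90(chip).copy()])[0]
        # per frequency the bank is ordered (0, 90, 45, 135), two features each
        n_freq = 3
        for view in range(2):  # full window and central crop
            base = view * (n_freq * 8 + 8)
            for fi in range(n_freq):
                b = base + fi * 8
                assert f90[b + 2 : b + 4] == pytest.approx(f0[b : b + 2], rel=1e-6)
                assert f90[b : b + 2] == pytest.approx(f0[b + 2 : b + 4], rel=1e-6)

    def test_mixed_chip_sizes_rejected(self, rng):
        a = TextureChip("a", striped_chip(0, size=32, rng=rng), side=32)
        b = TextureChip("b", striped_chip(0, size=64, rng=rng), side=64)
        with pytest.raises(ValueError, match="mixed chip sizes"):
            TextureEmbedder().fit(None).transform([a, b])

    def test_random_conv_method_deterministic(self, rng):
        chips = [TextureChip("a", striped_chip(0, rng=rng), side=32)]
        e1 = TextureEmbedder(method="random_conv", random_state=4).fit(None).transform(chips)
        e2 = TextureEmbedder(method="random_conv", random_state=4).fit(None).transform(chips)
        assert np.array_equal(e1, e2)


class TestClustering:
    def test_two_families_ari_one(self, rng):
        chips = chip_list([0, 90], rng)
        emb = texture_embed(chips)
        protos = texture_cluster(emb, k=2, seed=0)
        labels = {pid: j for j, ids in protos.members.items() for pid in ids}
        truth = [i.split("_")[0] for i in emb.index]
        got = [labels[i] for i in emb.index]
        assert adjusted_rand_score(truth, got) == 1.0

    def test_singleton_clusters_full_confidence(self, rng):
        X = rng.normal(size=(6, 5))
        mk = MarginKMeans(n_clusters=6, random_state=0).fit(X)
        assert np.allclose(mk.confidence_, 1.0)

    def test_confidence_in_unit_interval(self, rng):
        mk = MarginKMeans(n_clusters=3, random_state=0).fit(rng.normal(size=(40, 5)))
        assert np.all((mk.confidence_ >= 0) & (mk.confidence_ <= 1))

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            MarginKMeans(n_clusters=10).fit(rng.normal(size=(4, 3)))


def make_protoset(members, confidence=0.9):
    protos = TextureProtoSet()
    for j, ids in members.items():
        protos.members[j] = list(ids)
        for pid in ids:
            protos.confidence[pid] = confidence
    return protos


class TestFinetuneRules:
    def embedding_for(self, groups):
        """Tight embedding clusters at distinct corners per group key."""
        rows, idx = [], []
        rng = np.random.default_rng(0)
        corners = {0: [10, 0, 0], 1: [0, 10, 0], 2: [0, 0, 10]}
        for pid, g in groups.items():
            rows.append(np.asarray(corners[g]) + 0.01 * rng.normal(size=3))
            idx.append(pid)
        return pd.DataFrame(rows, index=idx)

    def test_uniform_prototype_passes_through(self):
        ids = [f"p{i}" for i in range(6)]
        protos = make_protoset({0: ids})
        emb = self.embedding_for({i: 0 for i in ids})
        ki = {i: "wheat" for i in ids}
        out, refined = finetune_texture_pseudolabels(protos, ki, emb)
        assert set(out.entries) == set(ids)
        assert len(refined.members) == 1
        assert refined.classes[0] == "wheat"

    def test_mixed_prototype_split_six_four(self):
        ids = [f"p{i}" for i in range(10)]
        protos = make_protoset({0: ids})
        emb = self.embedding_for({i: 0 for i in ids})
        ki = {i: ("wheat" if n < 6 else "rape") for n, i in enumerate(ids)}
        _, refined = finetune_texture_pseudolabels(protos, ki, emb, merge_threshold=1.1)
        sizes = sorted(len(v) for v in refined.members.values())
        assert sizes == [4, 6]

    def test_same_class_similar_prototypes_merged(self):
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        protos = make_protoset({0: a, 1: b})
        emb = self.embedding_for({i: 0 for i in a + b})  # identical texture
        ki = {i: "wheat" for i in a + b}
        _, refined = finetune_texture_pseudolabels(protos, ki, emb, merge_threshold=0.8)
        assert len(refined.members) == 1
        assert len(refined.members[0]) == 10

    def test_low_similarity_members_dropped(self):
        ids = [f"p{i}" for i in range(8)]
        groups = {i: 0 for i in ids[:-1]}
        groups[ids[-1]] = 1  # embedding outlier
        protos = make_protoset({0: ids})
        emb = self.embedding_for(groups)
        ki = {i: "wheat" for i in ids}
        out, _ = finetune_texture_pseudolabels(protos, ki, emb, sim_threshold=0.8)
        assert ids[-1] not in out.entries

    def test_idempotent(self, rng):
        ids = [f"p{i}" for i in range(20)]
        groups = {i: rng.integers(0, 3) for i in ids}
        protos = make_protoset({0: ids[:10], 1: ids[10:]})
        emb = self.embedding_for(groups)
        ki = {i: ("wheat", "rape", "other")[groups[i]] for i in ids}
        out1, ref1 = finetune_texture_pseudolabels(protos, ki, emb)
        out2, ref2 = finetune_texture_pseudolabels(ref1, ki, emb)
        assert {i: e.label for i, e in out1.entries.items()} == {
            i: e.label for i, e in out2.entries.items()
        }


class TestKspice1LabelSet:
    def frame(self):
        return pd.DataFrame(
            {
                "parcel_id": ["a", "b", "c"],
                "p_rape": [0.999, 0.2, 0.5],
                "p_wheat": [0.0005, 0.7, 0.3],
                "p_other": [0.0005, 0.1, 0.2],
            }
        )

    def test_zero_threshold_labels_all_by_argmax(self):
        out = build_kspice1_labelset(self.frame(), threshold=0.0)
        assert {e.parcel_id: e.label for e in out.entries.values()} == {
            "a": "rape", "b": "wheat", "c": "rape",
        }

    def test_above_one_threshold_empty(self):
        with pytest.warns(UserWarning):
            out = build_kspice1_labelset(self.frame(), threshold=1.0 + 1e-9)
        assert len(out) == 0

    def test_high_threshold_purity_on_scene(self, std_ki, std_records, std_scene, std_truth_map):
        probs = std_ki.predict_proba([std_records[i] for i in std_scene.small_ids])
        out = build_kspice1_labelset(probs, threshold=0.99)
        assert len(out) > 0
        correct = [e.label == std_truth_map[i] for i, e in out.entries.items()]
        assert np.mean(correct) >= 0.97


def labelset_from(pairs):
    out = PseudoLabelSet()
    for pid, cls in pairs.items():
        out.entries[pid] = PseudoLabelEntry(pid, cls, None, 1.0, "ki")
    return out


class TestSemiTextureClassifier:
    def test_fully_labeled_separable_perfect(self, rng):
        chips = chip_list([0, 90], rng, n=12)
        labels = labelset_from(
            {c.parcel_id: ("rape" if c.parcel_id.startswith("c0") else "wheat") for c in chips}
        )
        clf = SemiTextureClassifier(epochs=15, random_state=0).fit(chips, labels)
        pred = clf.predict(chips)
        truth = ["rape" if c.parcel_id.startswith("c0") else "wheat" for c in chips]
        assert (pred == np.array(truth)).mean() == 1.0

    def test_tau_above_one_equals_supervised(self, rng):
        chips = chip_list([0, 90], rng, n=10)
        labels = labelset_from(
            {c.parcel_id: ("rape" if c.parcel_id.startswith("c0") else "wheat")
             for c in chips[: len(chips) // 2]}
        )
        kw = dict(epochs=10, random_state=0)
        off = SemiTextureClassifier(tau=1.0 + 1e-9, **kw).fit(chips, labels)
        sup = SemiTextureClassifier(tau=1.0 + 1e-9, unlabeled_weight=0.0, **kw).fit(chips, labels)
        assert np.allclose(off.predict_proba(chips), sup.predict_proba(chips))

    def test_semisupervised_beats_or_matches_supervised_baseline(self, rng):
        """With 20% labels, adding the consistency step must not hurt."""
        chips = chip_list([0, 90], rng, n=20)
        truth = {c.parcel_id: ("rape" if c.parcel_id.startswith("c0") else "wheat") for c in chips}
        subset = {pid: cls for i, (pid, cls) in enumerate(sorted(truth.items())) if i % 5 == 0}
        labels = labelset_from(subset)
        kw = dict(epochs=15, random_state=0)
        semi = SemiTextureClassifier(tau=0.95, **kw).fit(chips, labels)
        sup = SemiTextureClassifier(tau=2.0, **kw).fit(chips, labels)
        y = np.array([truth[c.parcel_id] for c in chips])
        acc_semi = (semi.predict(chips) == y).mean()
        acc_sup = (sup.predict(chips) == y).mean()
        assert acc_semi >= acc_sup
        assert acc_semi >= 0.85

    def test_probability_table_simplex_and_duplicates(self, rng):
        chips = chip_list([0, 90], rng, n=8)
        labels = labelset_from(
            {c.parcel_id: ("rape" if c.parcel_id.startswith("c0") else "wheat") for c in chips}
        )
        clf = SemiTextureClassifier(epochs=8, random_state=0).fit(chips, labels)
        dup = [chips[0], TextureChip(parcel_id="copy", pixels=chips[0].pixels, side=32)]
        table = predict_proba_texture(clf, dup, classes=("rape", "wheat", "other"))
        p = table[["p_rape", "p_wheat", "p_other"]].to_numpy()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(p[0], p[1])
        assert np.all(table["p_other"] == 0)  # class never seen in training

    def test_single_class_labelset_rejected(self, rng):
        chips = chip_list([0], rng, n=4)
        labels = labelset_from({c.parcel_id: "wheat" for c in chips})
        with pytest.raises(ValueError, match="single class"):
            SemiTextureClassifier().fit(chips, labels)
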