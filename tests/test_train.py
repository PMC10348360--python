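import json
from dataclasses import replace

import numpy as np
import pytest

from smgbert.chemfeat import FeaturizeConfig
from smgbert.encoder import EncoderConfig
from smgbert.molio import PropertyTable, generate_fixtures, parse_smiles
from smgbert.train import (FinetuneConfig, FinetuneModel, PretrainConfig,
                           PretrainModel, SplitSpec, config_from_dict,
                           default_config, featurize, finetune, load_pretrained,
                           predict, pretrain, r2, rmse, roc_auc, scaffold_split)

rng = np.random.default_rng(0)


class TestMetrics:
    def test_match_reference_formulas_on_random_toys(self):
        for _ in range(100):
            y = rng.normal(size=20)
            p = rng.normal(size=20)
            assert rmse(y, p) == pytest.approx(np.sqrt(np.mean((y - p) ** 2)), abs=1e-9)
            ss_res = np.sum((y - p) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            assert r2(y, p) == pytest.approx(1 - ss_res / ss_tot, abs=1e-9)

    def test_roc_auc_matches_rank_statistic(self):
        for _ in range(100):
            y = (rng.random(30) < 0.4).astype(int)
            if y.sum() in (0, 30):
                continue
            s = rng.normal(size=30)
            pos, neg = s[y == 1], s[y == 0]
            # Mann-Whitney U formulation
            ref = (np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg]))
            assert roc_auc(y, s) == pytest.approx(ref, abs=1e-9)

    def test_single_class_split_raises(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc(np.ones(5), rng.random(5))


class TestScaffoldSplit:
    def test_partition_and_disjoint(self):
        table = generate_fixtures(60, 5)
        tr, va, te = scaffold_split(table, SplitSpec(seed=1))
        all_idx = sorted(tr + va + te)
        assert all_idx == list(range(60))
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    def test_scaffold_never_spans_splits(self):
        from rdkit import Chem
        from rdkit.Chem.Scaffolds import MurckoScaffold
        rings = ["C1CCCCC1", "c1ccccc1", "C1CCOC1", "C1CCNC1", "c1ccncc1",
                 "C1CCSC1", "C1CCCC1", "C1COCCN1"]
        subs = ["C", "CC", "O", "N", "CCO"]
        smiles = [parse_smiles(r + s).smiles for r in rings for s in subs]
        table = PropertyTable(records=[(s, {"y": 0.0}) for s in smiles],
                              task_types={"y": "regression"})
        tr, va, te = scaffold_split(table, SplitSpec(seed=1))
        scaf = [MurckoScaffold.MurckoScaffoldSmiles(mol=Chem.MolFromSmiles(s))
                for s in table.smiles]
        assert len(set(scaf)) >= 3
        assign = {}
        for split_id, idxs in enumerate((tr, va, te)):
            for i in idxs:
                assert assign.setdefault(scaf[i], split_id) == split_id

    def test_ten_distinct_scaffolds_8_1_1(self):
        # ten single-molecule scaffold groups -> exact 8/1/1
        smiles = ["c1ccccc1" + s for s in
                  ["C", "CC", "O", "N", "Cl", "CCO", "C(=O)C", "C#N", "CN", "CCC"]]
        # distinct Murcko scaffolds need distinct ring systems; use chain lengths
        smiles = ["C1CCCCC1", "c1ccccc1", "C1CCOC1", "C1CCNC1", "C1CCSC1",
                  "C1CCCC1", "c1ccncc1", "C1COCCN1", "C1CCNCC1", "C1CCOCC1"]
        table = PropertyTable(records=[(parse_smiles(s).smiles, {"y": 1.0})
                                       for s in smiles],
                              task_types={"y": "regression"})
        tr, va, te = scaffold_split(table, SplitSpec())
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_single_scaffold_falls_back_to_random(self):
        smiles = ["c1ccccc1" + "C" * k for k in range(1, 7)]
        table = PropertyTable(records=[(parse_smiles(s).smiles, {"y": 0.0})
                                       for s in smiles],
                              task_types={"y": "regression"})
        tr, va, te = scaffold_split(table, SplitSpec(seed=3))
        assert sorted(tr + va + te) == list(range(6))

    def test_random_split_deterministic(self):
        table = generate_fixtures(30, 2)
        s1 = scaffold_split(table, SplitSpec(method="random", seed=4))
        s2 = scaffold_split(table, SplitSpec(method="random", seed=4))
        assert s1 == s2


@pytest.fixture(scope="module")
def tiny_setup(vocabs, feat_cfg):
    av, nv = vocabs
    table = generate_fixtures(12, 8)
    md = featurize(table.smiles, feat_cfg, av, nv, seed=4)
    enc_cfg = EncoderConfig(n_layers=2, d_model=32, n_heads=4, max_atoms=16, seed=2)
    return table, md, enc_cfg


class TestPretrainLoop:
    def test_seeded_rerun_bit_identical(self, tiny_setup, feat_cfg):
        _, md, enc_cfg = tiny_setup
        cfg = PretrainConfig(epochs=2, batch_size=4, seed=7)
        h1 = pretrain(md, enc_cfg, cfg, feat_cfg).history
        h2 = pretrain(md, enc_cfg, cfg, feat_cfg).history
        assert [r["L_total"] for r in h1] == [r["L_total"] for r in h2]

    def test_zero_lr_parameters_bit_stable(self, tiny_setup, feat_cfg):
        _, md, enc_cfg = tiny_setup
        cfg = PretrainConfig(epochs=2, batch_size=4, lr=0.0, warmup_steps=0, seed=7)
        model0 = PretrainModel(enc_cfg, feat_cfg)
        before = model0.state_dict()
        res = pretrain(md, enc_cfg, cfg, feat_cfg)
        after = res.model.state_dict()
        for k in before:
            assert np.array_equal(before[k], after[k]), k

    def test_checkpoint_emitted_and_loadable(self, tiny_setup, feat_cfg, tmp_path):
        _, md, enc_cfg = tiny_setup
        ckpt = tmp_path / "pre.npz"
        log = tmp_path / "loss.jsonl"
        cfg = PretrainConfig(epochs=1, batch_size=4, seed=7,
                             checkpoint_path=str(ckpt), log_path=str(log))
        res = pretrain(md, enc_cfg, cfg, feat_cfg)
        model = load_pretrained(ckpt)
        for k, v in res.model.state_dict().items():
            assert np.array_equal(v, model.state_dict()[k])
        records = [json.loads(l) for l in log.read_text().splitlines()]
        assert {"step", "L_A", "L_N", "L_B", "L_3D", "L_total",
                "sigma1", "sigma4"} <= set(records[0])

    def test_loss_components_finite_and_nonnegative(self, tiny_setup, feat_cfg):
        _, md, enc_cfg = tiny_setup
        res = pretrain(md, enc_cfg, PretrainConfig(epochs=1, batch_size=4, seed=1),
                       feat_cfg)
        for rec in res.history:
            for key in ("L_A", "L_N", "L_B", "L_3D"):
                assert np.isfinite(rec[key]) and rec[key] >= 0

    def test_needs_two_molecules(self, tiny_setup, feat_cfg):
        _, md, enc_cfg = tiny_setup
        with pytest.raises(ValueError):
            pretrain(md[:1], enc_cfg, PretrainConfig(), feat_cfg)


class TestFinetune:
    def test_regression_reports_rmse_r2_and_improves_on_mean(self, tiny_setup, feat_cfg):
        table, md, enc_cfg = tiny_setup
        model = PretrainModel(enc_cfg, feat_cfg)
        big_table = generate_fixtures(60, 13)
        av, nv = model.atom_vocab, model.nmr_vocab
        big_md = featurize(big_table.smiles, feat_cfg, av, nv, seed=4,
                           labels=big_table.labels("y"))
        res = finetune(model, big_table, "y",
                       FinetuneConfig(epochs=6, batch_size=10, seed=0),
                       SplitSpec(seed=1), mol_data=big_md)
        assert set(res.metrics) == {"rmse", "r2"}
        assert np.isfinite(res.metrics["rmse"])

    def test_binary_task_outputs_probabilities(self, tiny_setup, feat_cfg):
        _, md, enc_cfg = tiny_setup
        table = generate_fixtures(40, 17)
        ys = table.labels("y")
        thresh = np.median(ys)
        records = [(s, {"hit": float(v["y"] > thresh)}) for s, v in table.records]
        btable = PropertyTable(records=records, task_types={"hit": "binary"})
        model = PretrainModel(enc_cfg, feat_cfg)
        bmd = featurize(btable.smiles, feat_cfg, model.atom_vocab, model.nmr_vocab,
                        seed=4, labels=btable.labels("hit"))
        res = finetune(model, btable, "hit",
                       FinetuneConfig(task="binary", epochs=4, batch_size=10, seed=0),
                       SplitSpec(seed=1), mol_data=bmd)
        assert "roc_auc" in res.metrics
        preds = [p["prediction"] for p in predict(res.model, btable.smiles[:5])]
        assert all(0.0 <= v <= 1.0 for v in preds)

    def test_zero_reg_weight_equals_plain_task_loss_on_one_batch(self, tiny_setup, feat_cfg):
        """With pretrain_reg_weight=0 the fine-tuning objective is exactly the
        supervised task loss (structural check on one batch)."""
        from smgbert.autodiff import Tensor
        from smgbert.train import _task_loss, _ssl_batch_inputs
        _, md, enc_cfg = tiny_setup
        model = PretrainModel(enc_cfg, feat_cfg)
        ft = FinetuneModel(model, FinetuneConfig(pretrain_reg_weight=0.0, seed=0))
        ft.eval()
        inputs = _ssl_batch_inputs(md[:4], model, PretrainConfig(seed=0), [1, 2, 3, 4])
        pred, _ = ft.forward(inputs[0])
        y = np.arange(4.0)
        plain = _task_loss(pred, y, "regression")
        assert np.isfinite(plain.data)
        # objective = task + 0 * ssl: bitwise equal to the task loss
        assert plain.data == pytest.approx(float((((pred - Tensor(y)) ** 2).mean()).data),
                                           abs=1e-12)

    def test_predict_flags_bad_smiles_and_continues(self, tiny_setup, feat_cfg):
        _, md, enc_cfg = tiny_setup
        model = PretrainModel(enc_cfg, feat_cfg)
        ft = FinetuneModel(model, FinetuneConfig(seed=0))
        ft.eval()
        out = predict(ft, ["CCO", "not_a_smiles", "CCC"])
        assert out[0]["error"] is None and np.isfinite(out[0]["prediction"])
        assert out[1]["prediction"] is None and out[1]["error"]
        assert out[2]["error"] is None

    def test_unknown_property_rejected(self, tiny_setup, feat_cfg):
        table, md, enc_cfg = tiny_setup
        model = PretrainModel(enc_cfg, feat_cfg)
        with pytest.raises(KeyError):
            finetune(model, table, "nope", FinetuneConfig(), SplitSpec())


class TestConfig:
    def test_defaults_roundtrip(self):
        feat, enc, pt, ft = config_from_dict({})
        assert enc.d_model == 512 and enc.n_layers == 6
        assert pt.select_rate == 0.2 and pt.split == (0.8, 0.1, 0.1)
        assert ft.pretrain_reg_weight == 0.1

    def test_partial_override(self):
        feat, enc, pt, ft = config_from_dict({"encoder": {"d_model": 64}})
        assert enc.d_model == 64 and enc.n_layers == 6

    def test_unknown_keys_rejected(self):
        with pytest.raises(KeyError):
            config_from_dict({"encoder": {"bogus": 1}})
        with pytest.raises(KeyError):
            config_from_dict({"bogus": {}})

    def test_every_section_present_in_dump(self):
        cfg = default_config()
        assert set(cfg) == {"featurize", "corruption", "encoder", "ssl", "train"}
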