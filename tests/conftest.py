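import logging

import numpy as np
import pytest

from smgbert.chemfeat import AtomVocab, FeaturizeConfig, NmrVocab
from smgbert.encoder import EncoderConfig
from smgbert.molio import generate_fixtures
from smgbert.train import PretrainConfig, featurize, pretrain

logging.getLogger("smgbert").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def feat_cfg():
    return FeaturizeConfig()


@pytest.fixture(scope="session")
def vocabs(feat_cfg):
    return AtomVocab(), NmrVocab(feat_cfg.nmr_bin_width, feat_cfg.nmr_range)


@pytest.fixture(scope="session")
def enc_cfg_small():
    """Desk-scale encoder: full-scale depth/heads/dropout, reduced d_model."""
    return EncoderConfig(n_layers=6, d_model=64, n_heads=8, max_atoms=16, seed=3)


@pytest.fixture(scope="session")
def enc_cfg_tiny():
    return EncoderConfig(n_layers=2, d_model=32, n_heads=4, max_atoms=16,
                         dropout=0.0, seed=1)


@pytest.fixture(scope="session")
def pretrain_table():
    return generate_fixtures(64, 11, include_chiral_pairs=True)


@pytest.fixture(scope="session")
def md64(pretrain_table, feat_cfg, vocabs):
    av, nv = vocabs
    return featurize(pretrain_table.smiles, feat_cfg, av, nv, seed=5)


@pytest.fixture(scope="session")
def held32(feat_cfg, vocabs):
    av, nv = vocabs
    return featurize(generate_fixtures(32, 99).smiles, feat_cfg, av, nv, seed=6)


@pytest.fixture(scope="session")
def smoke_run(md64, enc_cfg_small, feat_cfg):
    """The shared learning-smoke pre-training run (64 molecules, d_model=64)."""
    cfg = PretrainConfig(seed=9)
    return pretrain(md64, enc_cfg_small, cfg, feat_cfg), cfg
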