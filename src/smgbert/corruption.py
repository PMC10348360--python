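"""Masked-token corruption for self-supervised pre-training.

BERT-style scheme: a fraction ``select_rate`` of the non-global positions is
selected uniformly without replacement (at least one position is always
selected); within the selection, fractions ``split = (mask, random, keep)``
decide whether a position becomes ``<M>``, a different random valid token, or
stays unchanged.  The atom and NMR halves of a token pair are corrupted
independently with seeds derived from one master seed.

The literal whole-sequence reading of the replacement rates is reachable by
setting ``select_rate = 1.0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .chemfeat import TokenPair, _Vocab

__all__ = ["CorruptionPlan", "corrupt", "corrupt_pair", "DEFAULT_SELECT_RATE", "DEFAULT_SPLIT"]

DEFAULT_SELECT_RATE = 0.2
DEFAULT_SPLIT = (0.8, 0.1, 0.1)

_ACTIONS = ("mask", "random_replace", "keep")


@dataclass
class CorruptionPlan:
    """Record of one corruption pass, consumed by the reconstruction losses."""

    selected: np.ndarray    # positions in [1, n]; the global node is never selected
    actions: np.ndarray     # action name per selected position
    originals: np.ndarray   # true token ids at the selected positions
    seed: int

    def __post_init__(self):
        if len(self.selected) != len(self.actions) or len(self.selected) != len(self.originals):
            raise ValueError("selected/actions/originals must align")

    @property
    def n_corrupted(self) -> int:
        return len(self.selected)


def corrupt(tokens: np.ndarray, vocab: _Vocab, select_rate: float = DEFAULT_SELECT_RATE,
            split: Tuple[float, float, float] = DEFAULT_SPLIT,
            seed: int = 0) -> Tuple[np.ndarray, CorruptionPlan]:
    """Corrupt one token sequence (atom or NMR half, ``<G>`` at position 0).

    Returns the corrupted copy and the :class:`CorruptionPlan` describing it.
    Deterministic for a fixed seed; ``random_replace`` never yields a special
    token or the original one.
    """
    tokens = np.asarray(tokens)
    n = len(tokens) - 1
    if n < 1:
        raise ValueError("sequence must contain at least one atom token")
    if not (0.0 <= select_rate <= 1.0):
        raise ValueError("select_rate must be in [0, 1]")
    if any(f < 0 for f in split) or abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    n_sel = max(1, int(np.ceil(select_rate * n)))  # guarded minimum of one
    selected = np.sort(rng.choice(np.arange(1, n + 1), size=min(n_sel, n), replace=False))
    actions = rng.choice(_ACTIONS, size=len(selected), p=list(split))

    specials = vocab.special_ids()
    valid_ids = np.array([i for i in range(len(vocab)) if i not in specials])

    out = tokens.copy()
    for pos, act in zip(selected, actions):
        if act == "mask":
            out[pos] = vocab.mask
        elif act == "random_replace":
            choices = valid_ids[valid_ids != tokens[pos]]
            out[pos] = rng.choice(choices)
        # keep: unchanged
    plan = CorruptionPlan(selected=selected, actions=actions,
                          originals=tokens[selected].copy(), seed=int(seed))
    return out, plan


def corrupt_pair(tp: TokenPair, select_rate: float = DEFAULT_SELECT_RATE,
                 split: Tuple[float, float, float] = DEFAULT_SPLIT,
                 seed: int = 0) -> Tuple[np.ndarray, CorruptionPlan, np.ndarray, CorruptionPlan]:
    """Independently corrupt the atom and NMR halves of a token pair.

    Two child seeds are derived from the master seed, so the two corruption
    positions/actions are independent but jointly reproducible.
    """
    atom_seed, nmr_seed = np.random.SeedSequence(seed).generate_state(2)
    atoms_c, atom_plan = corrupt(tp.atom_tokens, tp.vocab_atoms, select_rate, split, int(atom_seed))
    nmr_c, nmr_plan = corrupt(tp.nmr_tokens, tp.vocab_nmr, select_rate, split, int(nmr_seed))
    return atoms_c, atom_plan, nmr_c, nmr_plan
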