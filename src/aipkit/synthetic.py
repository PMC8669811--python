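"""Synthetic labelled peptide datasets with controllable class signal.

Two classes of peptides are drawn from a simple generative family chosen
so that each descriptor channel can carry signal independently:

* ``effect`` shifts the residue composition of the two classes apart.
  Positives draw residues i.i.d. from ``p+ = p_base + (effect/2) * d`` and
  negatives from ``p- = p_base - (effect/2) * d``, where ``d`` is a fixed
  contrast (+1/10 on the first ten residues of the alphabet, -1/10 on the
  last ten). The total-variation distance between the two class
  compositions is then exactly ``effect``. This signal is visible to AAC
  (and, indirectly, to the dipeptide channels).
* ``dipeptide_effect`` gives the positive class a first-order Markov
  transition bias: pairs whose residues fall in the same alphabet half are
  up-weighted by ``1 + dipeptide_effect`` and cross-half pairs down-
  weighted by ``1 - dipeptide_effect``. For the uniform base composition
  the marginal residue frequencies are unchanged, so the signal lives in
  transitions only — AAC is blind to it while DDE/GDC are not.

With both effects zero the two classes are generated by the identical
process and are exchangeable, so any pipeline AUC should be ~0.5.

No claim of biological realism is made; lengths are uniform over a
configurable range with minimum 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peptide_io import ALPHABET, PeptideRecord, PeptideSet

__all__ = ["SimConfig", "generate_dataset", "class_compositions",
           "UNIFORM_COMPOSITION", "UNIPROT_LIKE_COMPOSITION"]

#: Uniform base composition (1/20 each) — analytically transparent default.
UNIFORM_COMPOSITION = {aa: 0.05 for aa in ALPHABET}

#: Rounded average composition of well-annotated protein sequences, for
#: users wanting less idealised backgrounds.
UNIPROT_LIKE_COMPOSITION = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097,
    "M": 0.024, "N": 0.041, "P": 0.047, "Q": 0.039, "R": 0.055,
    "S": 0.066, "T": 0.053, "V": 0.069, "W": 0.011, "Y": 0.029,
}

# contrast direction: +1/10 on the first half of the alphabet, -1/10 on the
# second half; sums to zero and has unit total-variation norm.
_CONTRAST = np.array([1.0 / 10] * 10 + [-1.0 / 10] * 10)
_HALF = np.array([1] * 10 + [0] * 10)  # alphabet-half indicator


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-class peptide generator.

    ``effect`` is the total-variation distance between the class residue
    compositions; ``dipeptide_effect`` in [0, 1) is the relative
    up-/down-weighting of same-half vs cross-half transitions in the
    positive class.
    """

    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (5, 30)
    effect: float = 0.0
    dipeptide_effect: float = 0.0
    seed: int = 0
    base_composition: str = "uniform"  # "uniform" | "uniprot"

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if lo < 5 or hi < lo:
            raise ValueError(
                f"length_range must satisfy 5 <= min <= max, "
                f"got {self.length_range}"
            )
        if self.effect < 0 or self.dipeptide_effect < 0:
            raise ValueError("effect magnitudes must be >= 0")
        if self.dipeptide_effect >= 1:
            raise ValueError(
                "dipeptide_effect must be < 1 (transition weights must "
                "stay positive)"
            )
        if self.base_composition not in ("uniform", "uniprot"):
            raise ValueError(
                "base_composition must be 'uniform' or 'uniprot'"
            )


def _base_vector(name: str) -> np.ndarray:
    table = UNIFORM_COMPOSITION if name == "uniform" else UNIPROT_LIKE_COMPOSITION
    return np.array([table[aa] for aa in ALPHABET])


def class_compositions(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Residue distributions (p+, p-) implied by the configuration.

    Raises if the requested effect pushes any probability outside [0, 1]
    (distributions are rejected, never clipped or silently renormalised).
    """
    base = _base_vector(config.base_composition)
    shift = (config.effect / 2.0) * _CONTRAST
    p_pos, p_neg = base + shift, base - shift
    for name, p in (("positive", p_pos), ("negative", p_neg)):
        if (p < 0).any() or (p > 1).any():
            raise ValueError(
                f"effect={config.effect} drives the {name}-class "
                "composition outside [0, 1]; reduce effect or change the "
                "base composition"
            )
    return p_pos, p_neg


def _transition_matrix(p: np.ndarray, epsilon: float) -> np.ndarray:
    """Row-stochastic transitions with same-half pairs favoured by 1+eps."""
    same = (_HALF[:, None] == _HALF[None, :]).astype(float)
    sign = 2.0 * same - 1.0  # +1 same half, -1 cross half
    T = p[None, :] * (1.0 + epsilon * sign)
    if (T < 0).any():
        raise ValueError("dipeptide_effect produces negative transition weights")
    # rows already sum to 1 for the uniform base (the +/- pattern cancels);
    # non-uniform bases need explicit renormalisation.
    return T / T.sum(axis=1, keepdims=True)


def _draw_iid(rng: np.random.Generator, p: np.ndarray, length: int) -> str:
    idx = rng.choice(20, size=length, p=p)
    return "".join(ALPHABET[i] for i in idx)


def _draw_markov(rng: np.random.Generator, p: np.ndarray, T: np.ndarray,
                 length: int) -> str:
    idx = np.empty(length, dtype=int)
    idx[0] = rng.choice(20, p=p)
    for k in range(1, length):
        idx[k] = rng.choice(20, p=T[idx[k - 1]])
    return "".join(ALPHABET[i] for i in idx)


def generate_dataset(config: SimConfig) -> PeptideSet:
    """Generate a labelled PeptideSet (positives first, then negatives).

    Fully reproducible from ``config.seed``; every sequence passes
    ``peptide_io`` validation by construction.
    """
    p_pos, p_neg = class_compositions(config)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    use_markov = config.dipeptide_effect > 0
    T = _transition_matrix(p_pos, config.dipeptide_effect) if use_markov else None

    records: list[PeptideRecord] = []
    width = max(4, len(str(max(config.n_pos, config.n_neg))))
    for i in range(config.n_pos):
        length = int(rng.integers(lo, hi + 1))
        seq = (
            _draw_markov(rng, p_pos, T, length)
            if use_markov
            else _draw_iid(rng, p_pos, length)
        )
        records.append(PeptideRecord(f"POS{i + 1:0{width}d}", seq, 1))
    for i in range(config.n_neg):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            PeptideRecord(f"NEG{i + 1:0{width}d}", _draw_iid(rng, p_neg, length), 0)
        )
    return PeptideSet(records)
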