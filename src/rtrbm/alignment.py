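"""Permutation and sign alignment of estimated assemblies against ground truth.

Training identifies assemblies only up to an arbitrary ordering of the
hidden units, and a hidden unit may form an *inverse* match (active when its
assembly is silent) when its visible weights come out negative.  Alignment
matches each ground-truth assembly to the hidden unit with the largest mean
absolute visible-to-hidden weight over the assembly's neurons, resolving
contested units by descending match strength, and records a ±1 sign per
unit from the mean signed weight.  Applying the map to the temporal matrix
permutes rows and columns and flips the signs of an inverted unit's rows
and columns; between two inverted units the two flips cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AlignmentMap", "match_assemblies", "align_U", "align_W", "cosine_similarity_U"]


@dataclass
class AlignmentMap:
    """``permutation[a]`` is the estimated hidden unit matched to ground-truth
    assembly ``a``; ``sign[a]`` is −1 for an inverse match.  ``conflicts``
    lists assemblies whose best unit was already taken (resolved greedily by
    match strength, then lowest assembly index)."""

    permutation: np.ndarray
    sign: np.ndarray
    conflicts: list = field(default_factory=list)

    def __post_init__(self):
        self.permutation = np.asarray(self.permutation, dtype=int)
        self.sign = np.asarray(self.sign, dtype=int)
        n = self.permutation.shape[0]
        if sorted(self.permutation.tolist()) != list(range(n)):
            raise ValueError("permutation must be a bijection on 0..Nh-1")
        if not np.all(np.isin(self.sign, (-1, 1))):
            raise ValueError("sign entries must be ±1")

    def inverse(self) -> "AlignmentMap":
        inv = np.empty_like(self.permutation)
        inv[self.permutation] = np.arange(self.permutation.shape[0])
        return AlignmentMap(inv, self.sign[inv].copy(), list(self.conflicts))


def match_assemblies(W_hat: np.ndarray, membership: np.ndarray) -> AlignmentMap:
    """Match ground-truth assemblies to hidden units via mean |W| scores.

    ``membership`` assigns each visible unit to an assembly; the number of
    assemblies must equal the number of hidden units (rows of ``W_hat``).
    """
    W_hat = np.asarray(W_hat, dtype=float)
    membership = np.asarray(membership, dtype=int)
    if membership.shape[0] != W_hat.shape[1]:
        raise ValueError("membership must cover all visible units")
    assemblies = np.unique(membership)
    nh = W_hat.shape[0]
    if assemblies.shape[0] != nh:
        raise ValueError(
            f"{assemblies.shape[0]} assemblies vs {nh} hidden units — counts must match"
        )

    # score[a, j] = mean |W_hat[j, neurons of a]|
    score = np.stack([np.abs(W_hat[:, membership == a]).mean(axis=1)
                      for a in assemblies])
    signed = np.stack([W_hat[:, membership == a].mean(axis=1) for a in assemblies])

    perm = np.full(nh, -1, dtype=int)
    conflicts = []
    taken = np.zeros(nh, dtype=bool)
    # assemblies claim units sequentially by descending best-match strength
    order = np.argsort(-score.max(axis=1), kind="stable")
    for a in order:
        prefs = np.argsort(-score[a], kind="stable")
        best = prefs[0]
        if taken[best]:
            conflicts.append(int(assemblies[a]))
            best = next(j for j in prefs if not taken[j])
        perm[a] = best
        taken[best] = True
    sign = np.where(signed[np.arange(nh), perm] >= 0, 1, -1)
    return AlignmentMap(perm, sign, conflicts)


def align_W(W_hat: np.ndarray, amap: AlignmentMap) -> np.ndarray:
    """Reorder (and sign-correct) hidden rows of Ŵ into ground-truth order."""
    W_hat = np.asarray(W_hat, dtype=float)
    return amap.sign[:, None] * W_hat[amap.permutation, :]


def align_U(U_hat: np.ndarray, amap: AlignmentMap) -> np.ndarray:
    """Permute Û into ground-truth order and undo inverse matches.

    Row and column of an inverted unit are negated; a doubly inverted pair's
    mutual weights are unchanged (the flips cancel).
    """
    U_hat = np.asarray(U_hat, dtype=float)
    if U_hat.shape[0] != amap.permutation.shape[0]:
        raise ValueError("alignment map size does not match U")
    P = U_hat[np.ix_(amap.permutation, amap.permutation)]
    return np.outer(amap.sign, amap.sign) * P


def cosine_similarity_U(U_true: np.ndarray, U_hat_aligned: np.ndarray) -> float:
    """Cosine of the angle between the two matrices after flattening and
    z-scoring each (population normalization)."""
    a = np.asarray(U_true, dtype=float).ravel()
    b = np.asarray(U_hat_aligned, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("matrices must have equal shapes")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("cosine similarity undefined for zero-variance input")
    za = (a - a.mean()) / sa
    zb = (b - b.mean()) / sb
    return float(za @ zb / (np.linalg.norm(za) * np.linalg.norm(zb)))
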