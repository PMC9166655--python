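"""Genotype-phenotype map for cells and enumeration of group types.

Cells carry three binary traits, ordered (cooperative, private,
pleiotropy).  The 8 possible genotypes are labelled ``g1`` .. ``g8``
externally (1-based, in binary-counting order of the trait triple);
internally all arrays are 0-based.  A group's type is the unordered
multiset of its founding cells' genotypes: 8 types for single-cell
founding, C(8,2) + 8 = 36 for two-cell founding.
"""

from __future__ import annotations

import itertools

import numpy as np

N_GENOTYPES = 8

#: Row i (0-based) holds the trait triple (z_u, z_v, z_p) of genotype g{i+1}.
TRAIT_MATRIX = np.array(
    [
        [0, 0, 0],
        [0, 0, 1],
        [0, 1, 0],
        [0, 1, 1],
        [1, 0, 0],
        [1, 0, 1],
        [1, 1, 0],
        [1, 1, 1],
    ],
    dtype=np.int64,
)

#: GroupType: canonical sorted tuple of 1-based founder genotype indices.
GroupType = tuple

_LABELS = tuple(f"g{i}" for i in range(1, N_GENOTYPES + 1))


def genotype_labels() -> tuple:
    """1-based genotype labels ``('g1', ..., 'g8')``."""
    return _LABELS


def trait_vector(i: int) -> tuple:
    """Trait triple ``(z_u, z_v, z_p)`` of genotype ``i`` (1-based).

    Raises
    ------
    ValueError
        If ``i`` is not in 1..8.
    """
    if not 1 <= int(i) <= N_GENOTYPES:
        raise ValueError(f"invalid genotype index {i!r}: must be in 1..{N_GENOTYPES}")
    return tuple(int(z) for z in TRAIT_MATRIX[int(i) - 1])


def genotype_of(traits) -> int:
    """Inverse of :func:`trait_vector`: 1-based genotype index of a trait triple."""
    z_u, z_v, z_p = (int(z) for z in traits)
    for z in (z_u, z_v, z_p):
        if z not in (0, 1):
            raise ValueError(f"trait values must be binary, got {traits!r}")
    return 4 * z_u + 2 * z_v + z_p + 1


def group_label(gtype: GroupType) -> str:
    """Human-readable label of a group type, e.g. ``'g8'`` or ``'g4+g8'``."""
    return "+".join(f"g{i}" for i in gtype)


def founder_counts(gtype: GroupType) -> np.ndarray:
    """Length-8 integer vector of founding-cell counts for a group type."""
    counts = np.zeros(N_GENOTYPES, dtype=np.int64)
    for i in gtype:
        if not 1 <= int(i) <= N_GENOTYPES:
            raise ValueError(f"invalid founder genotype {i!r} in {gtype!r}")
        counts[int(i) - 1] += 1
    return counts


def founder_trait_means(gtype: GroupType) -> np.ndarray:
    """Mean trait triple of the founding cells of a group type."""
    rows = np.array([TRAIT_MATRIX[int(i) - 1] for i in gtype], dtype=float)
    return rows.mean(axis=0)


def enumerate_group_types(n_founders: int) -> list:
    """All distinct group types for the given founding size.

    Group types are unordered multisets of founder genotypes,
    canonicalised as sorted tuples of 1-based indices: 8 types for
    ``n_founders=1`` and 36 for ``n_founders=2``.
    """
    if n_founders == 1:
        return [(i,) for i in range(1, N_GENOTYPES + 1)]
    if n_founders == 2:
        return [
            tuple(pair)
            for pair in itertools.combinations_with_replacement(
                range(1, N_GENOTYPES + 1), 2
            )
        ]
    raise ValueError(f"unsupported founding size {n_founders!r}: must be 1 or 2")
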