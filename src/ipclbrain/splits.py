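"""Subject split-half enumeration shared by RSA, veRSA and noise ceilings."""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .errors import InputError


@dataclass
class SplitScheme:
    """Unordered bipartitions of subjects into floor(n/2) | ceil(n/2) halves."""

    n_subjects: int
    splits: list[tuple[tuple[int, ...], tuple[int, ...]]]

    @property
    def n_splits(self) -> int:
        return len(self.splits)


def enumerate_split_halves(
    n_subjects: int, max_splits: int = 126, seed: int = 0
) -> SplitScheme:
    """All unordered split-halves over subjects, subsampled if too many.

    For even n the C(n, n/2) ordered subsets come in mirror pairs, so only
    C(n, n/2)/2 distinct bipartitions exist; for odd n every size-floor(n/2)
    subset gives a distinct bipartition. When the count exceeds
    ``max_splits`` a uniform seeded subsample (without replacement) is used.
    """
    if n_subjects < 2:
        raise InputError("need at least 2 subjects to form split-halves")
    half = n_subjects // 2
    total = comb(n_subjects, half) // (2 if n_subjects % 2 == 0 else 1)
    all_idx = frozenset(range(n_subjects))

    def bipartition(sub):
        rest = tuple(sorted(all_idx - set(sub)))
        return (tuple(sub), rest)

    if total <= max_splits:
        splits = []
        seen = set()
        for sub in combinations(range(n_subjects), half):
            key = frozenset(sub)
            mirror = all_idx - key
            if frozenset(mirror) in seen:
                continue
            seen.add(key)
            splits.append(bipartition(sub))
    else:
        # sample distinct bipartitions without materializing all of them
        rng = np.random.default_rng(seed)
        seen = set()
        splits = []
        while len(splits) < max_splits:
            sub = tuple(sorted(rng.choice(n_subjects, size=half, replace=False).tolist()))
            key = frozenset(sub)
            mirror = frozenset(all_idx - key)
            if key in seen or mirror in seen:
                continue
            seen.add(key)
            splits.append(bipartition(sub))
    return SplitScheme(n_subjects=n_subjects, splits=splits)
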