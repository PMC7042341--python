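"""2-of-N pool matrix design and deconvolution.

Each peptide is placed in exactly two of N pools with no two peptides sharing
the same pool pair, so a single responding peptide is identified by its unique
pair of positive pools — the matrix scheme used to map T-cell responses onto
individual 20-mers without testing each peptide separately.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np


@dataclasses.dataclass(frozen=True)
class PoolDesign:
    """Assignment of each tile to an unordered pair of pool indices (1..N)."""

    n_pools: int
    assignment: Mapping[str, frozenset[int]]

    def pools_of(self, tile_id: str) -> frozenset[int]:
        return self.assignment[tile_id]

    def pool_sizes(self) -> dict[int, int]:
        sizes = {i: 0 for i in range(1, self.n_pools + 1)}
        for pair in self.assignment.values():
            for idx in pair:
                sizes[idx] += 1
        return sizes

    def members(self, pool: int) -> set[str]:
        return {t for t, pair in self.assignment.items() if pool in pair}


@dataclasses.dataclass(frozen=True)
class PoolCallSet:
    positive_pools: frozenset[int]
    candidate_tiles: frozenset[str]
    ambiguous: bool


class CapacityError(ValueError):
    pass


def _balanced_pair_sequence(n: int) -> list[tuple[int, int]]:
    """All C(n,2) pool pairs (1-based) in an order whose every prefix keeps
    pool loads within one of each other.

    Even n: the round-robin 1-factorization of K_n taken matching by matching
    (each vertex appears exactly once per matching, so loads stay flat up to
    the partial matching).  Odd n: edges are grouped by circular distance d;
    each distance class splits into odd-length cycles, and a cycle's edges are
    emitted as the even-indexed matching, the closing edge, then the
    odd-indexed matching, which never lets the in-cycle spread exceed one.
    """
    seq: list[tuple[int, int]] = []
    if n % 2 == 0:
        m = n - 1
        for r in range(m):
            seq.append(tuple(sorted((r + 1, n))))
            for i in range(1, n // 2):
                a = (r + i) % m + 1
                b = (r - i) % m + 1
                seq.append(tuple(sorted((a, b))))
    else:
        # Walecki: K_n (odd) = (n-1)/2 Hamiltonian cycles; cycle k zigzags
        # around Z_{n-1} from k and closes through the hub vertex n-1.
        m = (n - 1) // 2
        offsets = [0]
        for i in range(1, m):
            offsets.extend((i, -i))
        offsets.append(m)
        for k in range(m):
            path = [(k + off) % (n - 1) for off in offsets]
            cycle = [n - 1] + path
            L = len(cycle)
            order = (
                [(cycle[i], cycle[i + 1]) for i in range(0, L - 2, 2)]
                + [(cycle[L - 1], cycle[0])]
                + [(cycle[i], cycle[i + 1]) for i in range(1, L - 1, 2)]
            )
            seq.extend(tuple(sorted((a + 1, b + 1))) for a, b in order)
    assert len(seq) == comb(n, 2) and len(set(seq)) == len(seq)
    return seq


def design_pools(
    tile_ids: Sequence[str], n_pools: int, seed: int | None = None
) -> PoolDesign:
    """Balanced 2-of-N assignment.

    Tiles are taken in order (permuted reproducibly if a seed is given) and
    matched against a canonical pair sequence whose every prefix keeps pool
    sizes within one of each other, so any number of tiles up to C(N,2)
    yields a balanced design with unique pool pairs.
    """
    if n_pools < 2:
        raise ValueError("need at least 2 pools")
    tile_ids = list(tile_ids)
    if len(set(tile_ids)) != len(tile_ids):
        raise ValueError("duplicate tile ids")
    capacity = comb(n_pools, 2)
    if len(tile_ids) > capacity:
        raise CapacityError(
            f"{len(tile_ids)} tiles exceed the {capacity} unique pool pairs "
            f"available with {n_pools} pools (C({n_pools},2))"
        )
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(tile_ids))
        tile_ids = [tile_ids[i] for i in order]
    pairs = _balanced_pair_sequence(n_pools)
    assignment = {
        tile: frozenset(pair) for tile, pair in zip(tile_ids, pairs)
    }
    return PoolDesign(n_pools=n_pools, assignment=assignment)


def deconvolve(design: PoolDesign, positive_pools: set[int]) -> PoolCallSet:
    """Map positive pools back to candidate tiles.

    Candidates are all tiles whose both pools are positive.  The call is
    flagged ambiguous when the candidate set is not the unique minimal
    explanation of the positives: either some positive pool is covered by no
    candidate, or dropping some candidate still covers every positive pool
    (so more than one candidate subset explains the observation).
    """
    valid = set(range(1, design.n_pools + 1))
    if not set(positive_pools) <= valid:
        raise ValueError(
            f"pool indices {sorted(set(positive_pools) - valid)} out of range"
        )
    positives = frozenset(positive_pools)
    candidates = frozenset(
        t for t, pair in design.assignment.items() if pair <= positives
    )
    covered: set[int] = set()
    for t in candidates:
        covered |= design.assignment[t]
    ambiguous = False
    if covered != positives:
        ambiguous = bool(positives)  # some positive pool has no explanation
    else:
        for t in candidates:  # any redundant candidate -> multiple explanations
            rest: set[int] = set()
            for u in candidates:
                if u != t:
                    rest |= design.assignment[u]
            if rest == positives:
                ambiguous = True
                break
    return PoolCallSet(
        positive_pools=positives,
        candidate_tiles=candidates,
        ambiguous=ambiguous,
    )


def validate_design(design: PoolDesign) -> dict:
    """Check every design invariant; report-only.

    Returns {"ok": bool, "failures": [messages], "pool_sizes": {...}}.
    """
    failures: list[str] = []
    for tile, pair in design.assignment.items():
        if len(pair) != 2:
            failures.append(f"2-of-N violated: {tile} is in {len(pair)} pools")
        if not pair <= set(range(1, design.n_pools + 1)):
            failures.append(f"pool index out of range for {tile}")
    seen: dict[frozenset[int], str] = {}
    for tile, pair in sorted(design.assignment.items()):
        if pair in seen:
            failures.append(
                f"unique-pair violated: {tile} and {seen[pair]} share pools "
                f"{sorted(pair)}"
            )
        else:
            seen[pair] = tile
    sizes = design.pool_sizes()
    if sizes and max(sizes.values()) - min(sizes.values()) > 1:
        failures.append("balance violated: pool sizes differ by more than 1")
    return {"ok": not failures, "failures": failures, "pool_sizes": sizes}
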