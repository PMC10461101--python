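"""RNA secondary structure by base-pair maximization (Nussinov).

Novel-miRNA calling needs a deterministic, parameter-free fold of candidate
precursor windows. We maximize the number of canonical pairs (AU, GC, GU)
subject to a minimum hairpin loop, instead of minimizing free energy: the
result is exactly testable against exhaustive structure enumeration and has
no tunable thermodynamic table. An energy-model backend can be substituted
by any callable with the same ``(seq) -> (structure, pair_count)`` contract.
"""

from __future__ import annotations

import numpy as np

from ._seq import CAN_PAIR, check_alphabet, to_rna

__all__ = ["fold_nussinov", "pair_table"]


def _pairable(s: str) -> np.ndarray:
    n = len(s)
    can = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            can[i, j] = (s[i], s[j]) in CAN_PAIR
    return can


def fold_nussinov(seq: str, min_loop: int = 3) -> tuple[str, int]:
    """Fold ``seq`` into the maximum base-pair structure.

    Parameters
    ----------
    seq
        RNA (or DNA; T is read as U) sequence, length >= 10.
    min_loop
        Minimum number of unpaired bases enclosed by a hairpin-closing pair.

    Returns
    -------
    (structure, pair_count)
        Dot-bracket string of ``len(seq)`` and the number of base pairs.

    The traceback is deterministic: when several optimal structures exist,
    the 3' base of each subproblem is paired to the 5'-most partner that
    achieves the optimum, and pairing is preferred over leaving it unpaired.
    """
    s = to_rna(seq)
    check_alphabet(s)
    if len(s) < min_loop + 2:
        raise ValueError(f"sequence too short to fold ({len(s)} nt)")
    n = len(s)
    can = _pairable(s)
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)
    # dp[i, j] over half-open [i, j); recurrence on the last base j-1:
    # unpaired, or paired with k (k <= j-1-min_loop-1) splitting the interval.
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # exclusive
            last = j - 1
            best = dp[i, j - 1]
            ks = np.flatnonzero(can[i : last - min_loop, last]) + i
            if ks.size:
                cand = dp[i, ks] + dp[ks + 1, last] + 1
                m = int(cand.max())
                if m > best:
                    best = m
            dp[i, j] = best
    # iterative traceback (windows can exceed the recursion limit)
    structure = ["."] * n
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 2:
            continue
        last = j - 1
        target = dp[i, j]
        paired = False
        for k in range(i, last - min_loop):
            if can[k, last] and dp[i, k] + dp[k + 1, last] + 1 == target:
                structure[k] = "("
                structure[last] = ")"
                stack.append((i, k))
                stack.append((k + 1, last))
                paired = True
                break
        if not paired:
            stack.append((i, j - 1))
    return "".join(structure), int(dp[0, n])


def pair_table(structure: str) -> dict[int, int]:
    """Map 0-based position -> 0-based partner for a dot-bracket string.

    Raises ``ValueError`` on unbalanced brackets.
    """
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs
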