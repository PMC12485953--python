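"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive enumeration / textbook formulas and share no code
with the library paths they check.
"""

from __future__ import annotations

import math


def brute_force_semi_digest(sequence: str, cleave_after: set[str],
                            max_missed: int, min_len: int, max_len: int,
                            semi: bool, proline_block: bool = False
                            ) -> set[tuple[int, int]]:
    """All (start, end) 1-based spans a semi-specific digest may produce,
    by exhaustive enumeration over every substring."""
    n = len(sequence)

    def cut_allowed(after_pos: int) -> bool:
        # cleavage between after_pos and after_pos+1 (1-based residues)
        if after_pos < 1 or after_pos >= n:
            return False
        if sequence[after_pos - 1] not in cleave_after:
            return False
        if proline_block and sequence[after_pos] == "P":
            return False
        return True

    out: set[tuple[int, int]] = set()
    for s in range(1, n + 1):
        for e in range(s, n + 1):
            if not min_len <= e - s + 1 <= max_len:
                continue
            start_ok = s == 1 or cut_allowed(s - 1)
            end_ok = e == n or cut_allowed(e)
            n_specific = int(start_ok) + int(end_ok)
            internal = sum(1 for i in range(s, e) if cut_allowed(i))
            if internal > max_missed:
                continue
            if n_specific == 2 or (semi and n_specific == 1):
                out.add((s, e))
    return out


def student_t_two_sample(a: list[float], b: list[float]) -> float:
    """Classical pooled-variance two-sample t statistic, written longhand."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    return (ma - mb) / (sp * math.sqrt(1.0 / na + 1.0 / nb))
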