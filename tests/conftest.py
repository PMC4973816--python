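import numpy as np
import pytest

from homoeolog import synthetic_data as sd


@pytest.fixture(scope="session")
def small_panel():
    """A small three-subgenome world with planted expression blocks."""
    cfg = sd.SimConfig(
        n_triplets=40,
        n_accessions=8,
        seed=11,
        reads_per_accession=4000,
        dominance_blocks=[("A", 0, 8, 4.0)],
        repression_blocks=[("B", 20, 28, 3.0)],
        expression_sd=0.2,
    )
    a, b, d, truth = sd.simulate_subgenomes(cfg)
    abundances = sd.plant_expression(truth, cfg)
    return cfg, a, b, d, truth, abundances


def sw_affine(s1: str, s2: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Exhaustive Smith-Waterman with affine gaps (Gotoh), plus the
    longest run of consecutive matches on an optimal local alignment.

    Independent oracle: plain-Python dynamic programming with
    traceback; O(n*m), fine for sequences up to ~100 bases.
    """
    n, m = len(s1), len(s2)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s1 (left)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s2 (up)
    best = 0
    best_pos = (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            sub = match if (s1[i - 1] == s2[j - 1] and s1[i - 1] != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
                best_pos = (i, j)
    # traceback for the longest consecutive-match run
    i, j = best_pos
    run = 0
    max_run = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            sub = match if (s1[i - 1] == s2[j - 1] and s1[i - 1] != "N") else mismatch
            if H[i][j] == H[i - 1][j - 1] + sub:
                run = run + 1 if s1[i - 1] == s2[j - 1] else 0
                max_run = max(max_run, run)
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            run = 0
            if E[i][j] == H[i][j - 1] + gap_open:
                state = "H"
            j -= 1
        else:
            run = 0
            if F[i][j] == H[i - 1][j] + gap_open:
                state = "H"
            i -= 1
    return best, max_run
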