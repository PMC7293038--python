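"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

NEG = float("-inf")


def gotoh_semiglobal_score(ref: str, read: str, match=1.0, mismatch=-2.0,
                           open_gap=-4.0, extend_gap=-1.0) -> float:
    """Affine-gap alignment score of a read fully aligned inside a
    reference whose unaligned ends are free.

    Plain O(n*m) Gotoh dynamic programme, kept independent of the package's
    aligner.  A length-L gap scores ``open_gap + (L-1)*extend_gap``.
    """
    n, m = len(ref), len(read)
    # H: best ending at (i, j); Ix: gap in read (ref consumed); Iy: gap in ref
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        H[i][0] = 0.0  # leading reference skip is free
    for j in range(1, m + 1):
        Iy[0][j] = open_gap + (j - 1) * extend_gap
        H[0][j] = Iy[0][j]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            diag = H[i - 1][j - 1]
            M = diag + s if diag > NEG else NEG
            Ix[i][j] = max(H[i - 1][j] + open_gap, Ix[i - 1][j] + extend_gap)
            Iy[i][j] = max(H[i][j - 1] + open_gap, Iy[i][j - 1] + extend_gap)
            H[i][j] = max(M, Ix[i][j], Iy[i][j])
    return max(H[i][m] for i in range(n + 1))
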