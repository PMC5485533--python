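"""Independent brute-force reference implementations used as test oracles.

Each function recomputes, by the most direct means available, a quantity the
package computes with a more structured algorithm.  Conventions (scoring
scheme, tie-breaks) are shared with the package by specification; the code
paths are independent.
"""

from __future__ import annotations

from minibarcode.iupac import IUPAC_SETS, COMPLEMENT

MATCH, MISMATCH, GAP = 1.0, -1.0, -2.0


def bf_overlap_identity(a: str, b: str) -> tuple[float, int, int]:
    """(identity %, matches, aligned_length) by a plain pointer-matrix DP.

    Overlap alignment (free end gaps both sequences), linear gap penalty,
    deterministic preferences: end cell by (score, i+j, i); step diagonal,
    then gap-in-b, then gap-in-a.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + GAP, H[i][j - 1] + GAP)
    best = None
    for j in range(m + 1):
        key = (H[n][j], n + j, n)
        if best is None or key > best[0]:
            best = (key, n, j)
    for i in range(n + 1):
        key = (H[i][m], i + m, i)
        if key > best[0]:
            best = (key, i, m)
    _, i, j = best
    matches = total = 0
    while i > 0 and j > 0:
        s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
        if H[i][j] == H[i - 1][j - 1] + s:
            total += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + GAP:
            total += 1
            i -= 1
        else:
            total += 1
            j -= 1
    identity = 100.0 * matches / total if total else 0.0
    return identity, matches, total


def _compat(p: str, t: str) -> bool:
    if t == "N" and p != "N":
        return False
    return bool(IUPAC_SETS[p] & IUPAC_SETS[t])


def _rc(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s))


def bf_sites(primer: str, template: str, max_mm: int, clamp: int = 0):
    """All approximate sites by direct window comparison, both strands."""
    k = len(primer)
    hits = []
    for strand in "+-":
        probe = primer if strand == "+" else _rc(primer)
        clamp_idx = (
            list(range(k - clamp, k)) if strand == "+" else list(range(clamp))
        )
        for start in range(len(template) - k + 1):
            win = template[start : start + k]
            if any(not _compat(probe[i], win[i]) for i in clamp_idx):
                continue
            mm = sum(not _compat(p, t) for p, t in zip(probe, win))
            if mm <= max_mm:
                hits.append((start, start + k, strand, mm))
    return sorted(hits)


def bf_dimer(a: str, b: str, window: int = 10) -> int:
    """Longest 3'-anchored antiparallel complementary run, by exhaustive
    offset scan of a's 3' window against reversed b."""
    a3 = a[-window:]
    rb = b[::-1]  # rb[k] pairs a3 positions antiparallel
    best = 0
    # slide a3 over rb at every offset; count longest run of complementarity
    for off in range(-len(a3) + 1, len(rb)):
        run = 0
        for i in range(len(a3)):
            j = off + i
            if 0 <= j < len(rb) and IUPAC_SETS[a3[i]] & IUPAC_SETS[COMPLEMENT[rb[j]]]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def bf_blocks(scores, gap_fractions, min_len: int, min_score: float, max_gap: float):
    """Maximal qualifying runs by checking every candidate interval."""
    L = len(scores)
    ok = [s >= min_score and g <= max_gap for s, g in zip(scores, gap_fractions)]
    out = []
    for s in range(L):
        for e in range(s + min_len, L + 1):
            if not all(ok[s:e]):
                continue
            # maximal: cannot extend either way
            if (s > 0 and ok[s - 1]) or (e < L and ok[e]):
                continue
            out.append((s, e))
    return sorted(out)


def bf_binding_counts(primer: str, records, max_mm: int):
    """Per-record site counts by the direct window scan."""
    return {rec.id: len(bf_sites(primer, rec.sequence, max_mm)) for rec in records}
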