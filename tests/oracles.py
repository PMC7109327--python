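"""Independent reference implementations used only to verify the package.

Everything here is deliberately plain and unaccelerated: a pure-Python
affine-gap local aligner, an O(n*m) edit-distance scan, a brute-force
pair filter, and an exhaustive path-enumeration k-mer classifier. They
share the package's documented conventions (scoring, tie-breaks) but
none of its code.
"""

from __future__ import annotations

from itertools import product

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def sw_oracle(q: str, r: str, match=1, mismatch=-2, gap_open=-3, gap_extend=-1):
    """Plain full-DP affine local alignment (Gotoh), no acceleration.

    Conventions: a k-gap costs gap_open + (k-1)*gap_extend; cell
    tie-break diag > vertical > horizontal > stop; best cell is the
    first (smallest i, then j) achieving the maximum; returns None if
    the best score is <= 0, else (score, length, matches) of the
    traceback alignment.
    """
    n, m = len(q), len(r)
    NEG = float("-inf")
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptrH = [[0] * (m + 1) for _ in range(n + 1)]
    ptrE = [[0] * (m + 1) for _ in range(n + 1)]
    ptrF = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo, ee = H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend
            if ee > eo:
                E[i][j], ptrE[i][j] = ee, 1
            else:
                E[i][j] = eo
            fo, fe = H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend
            if fe > fo:
                F[i][j], ptrF[i][j] = fe, 1
            else:
                F[i][j] = fo
            same = q[i - 1] == r[j - 1] and q[i - 1] != "N"
            d = H[i - 1][j - 1] + (match if same else mismatch)
            h, p = d, 1
            if F[i][j] > h:
                h, p = F[i][j], 2
            if E[i][j] > h:
                h, p = E[i][j], 3
            if h <= 0:
                h, p = 0, 0
            H[i][j], ptrH[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None
    # traceback
    i, j, state = bi, bj, "H"
    length = matches = 0
    while True:
        if state == "H":
            p = ptrH[i][j]
            if p == 0:
                break
            if p == 1:
                length += 1
                matches += q[i - 1] == r[j - 1] and q[i - 1] != "N"
                i, j = i - 1, j - 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "E":
            length += 1
            ext = ptrE[i][j]
            j -= 1
            if ext == 0:
                state = "H"
        else:
            length += 1
            ext = ptrF[i][j]
            i -= 1
            if ext == 0:
                state = "H"
    return best, length, matches


def sw_oracle_both_strands(q: str, r: str, **scoring):
    """Best of forward and reverse-complement query (forward wins ties)."""
    fwd = sw_oracle(q, r, **scoring)
    rev = sw_oracle(revcomp(q), r, **scoring)
    if fwd is None:
        return rev
    if rev is None or fwd[0] >= rev[0]:
        return fwd
    return rev


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance, plain DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def best_infix_edit(motif: str, window: str) -> int:
    """Best semi-global (motif inside window) edit distance, exhaustive."""
    best = len(motif)
    n = len(window)
    for start in range(n):
        for end in range(start + 1, min(n, start + 2 * len(motif)) + 1):
            best = min(best, edit_distance(motif, window[start:end]))
            if best == 0:
                return 0
    return best


def pair_filter_oracle(hits_r1, hits_r2, min_len=50, min_identity=0.98):
    """Brute force over all (r1 hit, r2 hit) combinations."""
    surviving = {}
    for h1, h2 in product(hits_r1, hits_r2):
        if h1.ref_id != h2.ref_id:
            continue
        if h1.length < min_len or h2.length < min_len:
            continue
        if not (h1.identity > min_identity and h2.identity > min_identity):
            continue
        score = h1.length * h1.identity + h2.length * h2.identity
        key = h1.ref_id
        if key not in surviving or score > surviving[key]:
            surviving[key] = score
    return sorted(surviving.items())


def assign_oracle(candidates, genus_of, priority=()):
    """Max score, ties -> priority genus then lexicographic min."""
    if not candidates:
        return None
    top = max(s for _, s in candidates)
    genera = sorted({genus_of[r] for r, s in candidates if s == top})
    for g in priority:
        if g in genera:
            return g, top, len(genera) > 1
    return genera[0], top, len(genera) > 1


def classify_oracle(seq, index, tree):
    """Exhaustive root-to-leaf path enumeration over ALL species leaves."""
    if len(seq) < index.k:
        return None
    hits = {}
    for i in range(len(seq) - index.k + 1):
        kmer = seq[i : i + index.k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        canon = kmer if kmer <= rc else rc
        taxon = index.map.get(canon)
        if taxon is not None:
            hits[taxon] = hits.get(taxon, 0) + 1
    if not hits:
        return None
    best_score, best_leaves = -1, []
    for leaf in tree.species_leaves():
        path = tree.path_to_root(leaf)
        score = sum(hits.get(t, 0) for t in path)
        if score > best_score:
            best_score, best_leaves = score, [leaf]
        elif score == best_score:
            best_leaves.append(leaf)
    label = best_leaves[0]
    for other in best_leaves[1:]:
        label = tree.lca(label, other)
    return label
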