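"""Independent naive reference implementations used only by the tests.

Everything here is deliberately brute-force (nested loops, backtracking,
full DP) and shares no code with the package paths it checks.
"""

from __future__ import annotations

from itertools import product

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def naive_count_kmers(inserts, k):
    """Nested-loop overlapping k-mer tally skipping windows with non-ACGT."""
    counts = {}
    for s in inserts:
        s = s.upper()
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if all(c in "ACGT" for c in w):
                counts[w] = counts.get(w, 0) + 1
    return counts


def parse_pattern(raw):
    """Parse to a list of ('class', allowed-string) / ('gap', (a, b))."""
    elems = []
    i = 0
    while i < len(raw):
        ch = raw[i].upper()
        if ch == "N" and i + 1 < len(raw) and raw[i + 1] == "{":
            j = raw.index("}", i)
            inner = raw[i + 2:j]
            a, _, b = inner.partition(",")
            elems.append(("gap", (int(a), int(b or a))))
            i = j + 1
        else:
            elems.append(("class", IUPAC[ch]))
            i += 1
    return elems


def naive_scan_count(seq, raw, with_positions=False):
    """Backtracking position enumeration: distinct match start positions."""
    seq = seq.upper().replace("U", "T")
    elems = parse_pattern(raw)

    def match_from(pos, ei):
        if ei == len(elems):
            return True
        kind, payload = elems[ei]
        if kind == "class":
            if pos < len(seq) and seq[pos] in payload:
                return match_from(pos + 1, ei + 1)
            return False
        a, b = payload
        for g in range(a, b + 1):
            if pos + g <= len(seq) and match_from(pos + g, ei + 1):
                return True
        return False

    starts = [i for i in range(len(seq)) if match_from(i, 0)]
    return (len(starts), starts) if with_positions else len(starts)


def levenshtein(a, b):
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def naive_adapter_cut(seq, adapter, max_error_rate, min_overlap):
    """Brute-force adapter search mirroring the trimming contract.

    First the full adapter anywhere (all substrings, minimal edit distance,
    leftmost start), then adapter prefixes at the 3' end (longest overlap
    first).  Returns the cut position or None.
    """
    from math import floor

    k_full = floor(max_error_rate * len(adapter))
    best = None  # (dist, start)
    for s in range(len(seq)):
        for e in range(s, len(seq) + 1):
            d = levenshtein(adapter, seq[s:e])
            if d <= k_full and (best is None or (d, s) < best):
                best = (d, s)
    if best is not None:
        return best[1]
    for ov in range(min(len(adapter) - 1, len(seq)), min_overlap - 1, -1):
        if levenshtein(adapter[:ov], seq[-ov:]) <= floor(max_error_rate * ov):
            return len(seq) - ov
    return None


def best_pair_offset(a, b):
    """Exhaustive search for b's offset relative to a maximizing identity."""
    k = len(a)
    best = None
    for off in range(-(k - 1), k):
        ident = sum(
            1 for j in range(k)
            if 0 <= off + j < k and b[j] == a[off + j]
        )
        key = (-ident, abs(off), off)
        if best is None or key < best[0]:
            best = (key, off)
    return best[1]
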