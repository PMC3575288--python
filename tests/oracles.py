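"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written from scratch with plain loops and their own
lookup tables; they import nothing from the package.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_IUPAC_COMP = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def rc(seq):
    return "".join(_COMP[c] for c in reversed(seq))


def _arm_fwd_ok(seq, p, L, require_t, leading):
    """First arm: literal template application on the forward strand."""
    if p < 0 or p + L > len(seq) or L < len(leading):
        return False
    site = seq[p : p + L]
    if any(c not in "ACGT" for c in site):
        return False
    if require_t:
        if p == 0 or seq[p - 1] != "T":
            return False
    for i, allowed in enumerate(leading):
        if site[i] not in allowed:
            return False
    return True


def _arm_rev_ok(seq, p, L, require_t, leading):
    """Second arm: the template applied to the reverse complement."""
    if p < 0 or p + L > len(seq) or L < len(leading):
        return False
    site = seq[p : p + L]
    if any(c not in "ACGT" for c in site):
        return False
    if require_t:
        if p + L >= len(seq) or seq[p + L] != "A":
            return False
    rsite = rc(site)
    for i, allowed in enumerate(leading):
        if rsite[i] not in allowed:
            return False
    return True


def brute_force_pairs(seq, require_t, leading, site_range, spacer_range, lo=0, hi=None, step=1):
    """Exhaustive double loop over start positions and all length triples."""
    if hi is None:
        hi = len(seq)
    found = set()
    for p in range(lo, hi, step):
        for l1 in range(site_range[0], site_range[1] + 1):
            if not _arm_fwd_ok(seq, p, l1, require_t, leading):
                continue
            for sp in range(spacer_range[0], spacer_range[1] + 1):
                for l2 in range(site_range[0], site_range[1] + 1):
                    if _arm_rev_ok(seq, p + l1 + sp, l2, require_t, leading):
                        found.add((p, l1, sp, l2))
    return found


def brute_force_single_sites(seq, require_t, leading, site_range, lo=0, hi=None, step=1):
    if hi is None:
        hi = len(seq)
    found = set()
    for p in range(lo, hi, step):
        for l1 in range(site_range[0], site_range[1] + 1):
            if _arm_fwd_ok(seq, p, l1, require_t, leading):
                found.add((p, l1))
    return found


def naive_iupac_hits(seq, recognition):
    """Position-by-position degenerate comparison on both strands, with
    forward/reverse hits collapsed for palindromic patterns."""
    seq = seq.upper()
    rec = recognition.upper()
    rec_rc = "".join(_IUPAC_COMP[c] for c in reversed(rec))
    hits = []
    for p in range(len(seq) - len(rec) + 1):
        window = seq[p : p + len(rec)]
        if all(b in _IUPAC[r] for b, r in zip(window, rec)):
            hits.append((p, "+"))
        if rec_rc != rec and all(b in _IUPAC[r] for b, r in zip(window, rec_rc)):
            hits.append((p, "-"))
    return sorted(hits)
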