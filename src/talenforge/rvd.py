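"""DNA <-> RVD (repeat variable di-residue) conversion.

Each tandem repeat of a TAL effector binds a single base; the pair of
hypervariable residues at repeat positions 12/13 (the RVD) sets the base
preference.  The standard engineering cipher is used throughout:
adenine=NI, cytosine=HD, guanine=NN, thymine=NG.
"""

from __future__ import annotations

BASE_TO_RVD = {"A": "NI", "C": "HD", "G": "NN", "T": "NG"}
RVD_TO_BASE = {v: k for k, v in BASE_TO_RVD.items()}


def rvd_encode(site: str) -> tuple[str, ...]:
    """Encode a binding-site sequence as an ordered tuple of RVD codes.

    Placeholder (N) or other non-ACGT characters are rejected: a site that
    runs into undefined sequence cannot be built as a TALEN array.
    """
    site = site.upper()
    try:
        return tuple(BASE_TO_RVD[b] for b in site)
    except KeyError as exc:
        raise ValueError(f"cannot encode base {exc.args[0]!r}: RVD cipher covers A/C/G/T only") from None


def rvd_decode(rvds) -> str:
    """Inverse of :func:`rvd_encode`; accepts any iterable of RVD codes."""
    out = []
    for code in rvds:
        if code not in RVD_TO_BASE:
            raise ValueError(f"unknown RVD code {code!r}; expected one of NI/HD/NN/NG")
        out.append(RVD_TO_BASE[code])
    return "".join(out)


def rvd_text(rvds, sep: str = "\t") -> str:
    """Serialize RVDs for reports (tab-delimited by default, for pasting
    straight into the assembly spreadsheet workflow)."""
    return sep.join(rvds)
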