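"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results from first principles (exhaustive
enumeration, direct definition checks) through different code paths than
the package, so agreement is informative.
"""

from itertools import product

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s):
    return "".join(COMP[b] for b in reversed(s))


def oracle_conversions(codon):
    """All (strand, edited codon positions, stop) routes, by trying every
    on/off mask of the three codon positions on each strand."""
    if codon in STOPS:
        return set()
    routes = set()
    for strand, src, dst in (("+", "C", "T"), ("-", "G", "A")):
        for mask in product([False, True], repeat=3):
            if not any(mask):
                continue
            if any(on and codon[i] != src for i, on in enumerate(mask)):
                continue
            edited = "".join(dst if on else b for b, on in zip(codon, mask))
            if edited in STOPS:
                routes.add(
                    (strand, tuple(i + 1 for i, on in enumerate(mask) if on), edited)
                )
    return routes


def oracle_stop_introducible_codons():
    return {
        "".join(c)
        for c in product("ACGT", repeat=3)
        if oracle_conversions("".join(c))
    }


def oracle_protospacers(bases):
    """Set of (strand, start_1based, spacer, pam).  The minus strand is
    found by scanning the reverse complement as a plus strand and mapping
    coordinates back, so the two strands take different code paths."""
    out = set()
    L = len(bases)
    for strand, s in (("+", bases), ("-", rc(bases))):
        for i in range(L - 22):
            spacer, pam = s[i : i + 20], s[i + 20 : i + 23]
            if pam[1] == "G" and pam[2] == "G" and "N" not in spacer:
                start = i + 1 if strand == "+" else L - i
                out.add((strand, start, spacer, pam))
    return out


def oracle_scan(bases, window_first, window_last, strict=False):
    """Exhaustive knockout-site enumeration over every protospacer x
    in-frame codon x conversion route.  Returns a set of
    (codon_index_1based, strand, start_1based, stop, edited_proto_positions).
    """
    sites = set()
    protos = oracle_protospacers(bases)
    for ci in range(len(bases) // 3):
        codon = bases[3 * ci : 3 * ci + 3]
        for strand, codon_positions, stop in oracle_conversions(codon):
            coords = [3 * ci + p - 1 for p in codon_positions]
            all_coords = [3 * ci, 3 * ci + 1, 3 * ci + 2]
            for p_strand, start, spacer, pam in protos:
                if p_strand != strand:
                    continue
                if strand == "+":
                    to_q = lambda c: c - (start - 1) + 1
                else:
                    to_q = lambda c: start - c
                qs = [to_q(c) for c in coords]
                if any(not (1 <= q <= 20) for q in qs):
                    continue
                if any(not (window_first <= q <= window_last) for q in qs):
                    continue
                if strict:
                    full = [to_q(c) for c in all_coords]
                    if any(not (window_first <= q <= window_last) for q in full):
                        continue
                sites.add((ci + 1, strand, start, stop, tuple(sorted(qs))))
    return sites


def site_key(site):
    """The oracle-comparable key of a package KnockoutSite."""
    return (
        site.codon_index_1based,
        site.protospacer.strand,
        site.protospacer.start_1based,
        site.resulting_stop,
        site.edited_positions,
    )


def oracle_trim(qualities, leading_q, trailing_q, window_len, window_q, min_len):
    """Step-by-step trimming oracle; returns the kept (start, end) slice
    or None.  Uses a vectorized sliding-mean rather than a scan loop."""
    q = np.asarray(qualities, dtype=float)
    start = next((i for i in range(len(q)) if q[i] >= leading_q), len(q))
    end = next(
        (i + 1 for i in range(len(q) - 1, start - 1, -1) if q[i] >= trailing_q),
        start,
    )
    seg = q[start:end]
    if window_len and len(seg) >= window_len:
        means = np.convolve(seg, np.ones(window_len) / window_len, mode="valid")
        bad = np.flatnonzero(means < window_q)
        if len(bad):
            end = start + int(bad[0])
    if end - start < min_len:
        return None
    return (start, end)
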