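"""Genome-wide design of stop-codon-introducing base-editing sites.

A cytidine base editor (BE3) converts C:G base pairs to T:A inside a
deamination window of the 20-nt protospacer (positions numbered 1..20
from the PAM-distal end).  Four sense-strand codons can be converted
into premature stop codons this way:

* ``CAA -> TAA``, ``CAG -> TAG``, ``CGA -> TGA`` by editing the sense-strand
  C at codon position 1 (a plus-strand protospacer);
* ``TGG -> TAG / TGA / TAA`` by editing the antisense Cs paired with the
  Gs at codon positions 2 and/or 3 (a minus-strand protospacer).

This module scans coding sequences for every (in-frame codon, NGG
protospacer) pair where the required edits fall inside the editing
window, and summarizes targetability per gene.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from itertools import combinations
from statistics import median
from typing import Iterable, Optional

import pandas as pd

from .seqio import CdsRecord, NucSequence, revcomp

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Sense-strand codons one or more same-strand C->T deaminations can turn
#: into a stop codon (derivable by brute force; see stop_codon_conversions).
TARGET_CODONS = ("CAA", "CAG", "CGA", "TGG")

SPACER_LEN = 20
PAM_LEN = 3


class FrameError(ValueError):
    """A CDS whose length is not a positive multiple of three."""

    def __init__(self, gene_id: str, length: int):
        self.gene_id = gene_id
        super().__init__(
            f"CDS {gene_id!r} is not frame-valid (length {length} nt)"
        )


@dataclass(frozen=True)
class Protospacer:
    """A 20-nt gRNA target adjacent to an NGG PAM.

    ``strand`` is relative to the supplied sense (coding) strand.
    ``start_1based`` is the sense-strand position (1-based) of protospacer
    base 1, the PAM-distal end; for minus-strand protospacers base 1 is
    therefore the *rightmost* sense coordinate the spacer covers.
    ``spacer`` and ``pam`` are given 5'->3' on the protospacer strand.
    """

    parent_id: str
    strand: str
    start_1based: int
    spacer: str
    pam: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.spacer) != SPACER_LEN:
            raise ValueError(f"spacer must be {SPACER_LEN} nt")
        if self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")

    @property
    def span(self) -> tuple:
        """0-based half-open sense-strand interval covered by the spacer."""
        if self.strand == "+":
            s = self.start_1based - 1
            return (s, s + SPACER_LEN)
        return (self.start_1based - SPACER_LEN, self.start_1based)

    def sense_offset(self, position: int) -> int:
        """0-based sense coordinate of protospacer position 1..20."""
        if not 1 <= position <= SPACER_LEN:
            raise ValueError(f"protospacer position {position} outside 1..20")
        if self.strand == "+":
            return self.start_1based - 1 + (position - 1)
        return self.start_1based - position

    def protospacer_position(self, sense_offset: int) -> Optional[int]:
        """Protospacer position (1..20) of a 0-based sense coordinate,
        or None if the coordinate is not covered by the spacer."""
        lo, hi = self.span
        if not lo <= sense_offset < hi:
            return None
        if self.strand == "+":
            return sense_offset - lo + 1
        return hi - sense_offset


@dataclass(frozen=True)
class EditWindow:
    """Inclusive protospacer-position interval in which edits are accepted.

    The default used throughout this package is (1, 13); the canonical
    in-vitro window (4, 8) is also provided.
    """

    first: int = 1
    last: int = 13

    def __post_init__(self):
        if not 1 <= self.first <= self.last <= SPACER_LEN:
            raise ValueError(
                f"invalid window ({self.first}, {self.last}); "
                "need 1 <= first <= last <= 20"
            )

    def __contains__(self, position: int) -> bool:
        return self.first <= position <= self.last


CANONICAL_WINDOW = EditWindow(4, 8)
DEFAULT_WINDOW = EditWindow(1, 13)


@dataclass(frozen=True)
class KnockoutSite:
    """One way to turn an in-frame codon into a premature stop codon.

    ``edited_positions`` are protospacer positions (1..20) whose C->T
    edits, applied on the protospacer strand, produce ``resulting_stop``.
    A TGG codon may yield up to three distinct routes (three records)
    at the same protospacer; genome summaries count such a
    (codon, protospacer) place once.
    """

    gene_id: str
    codon_index_1based: int
    codon: str
    resulting_stop: str
    protospacer: Protospacer
    edited_positions: tuple
    relative_position: float

    @property
    def place(self) -> tuple:
        """Identity of the targetable place, ignoring the stop-codon route."""
        return (self.gene_id, self.codon_index_1based, self.protospacer)


def find_protospacers(seq: NucSequence, both_strands: bool = True) -> list:
    """All 20-nt protospacers adjacent to an NGG PAM in ``seq``.

    Plus-strand protospacers lie 5' of an NGG on the given strand;
    minus-strand ones correspond to a CCN on the given strand followed by
    the 20-nt target (i.e. an NGG on the reverse complement).  Spacers
    containing N are discarded; overlapping spacers are all reported.
    Output is ordered by sense-strand span start, plus strand first.
    """
    s = seq.bases
    out = []
    for i in range(len(s) - (SPACER_LEN + PAM_LEN) + 1):
        if s[i + SPACER_LEN + 1] == "G" and s[i + SPACER_LEN + 2] == "G":
            spacer = s[i : i + SPACER_LEN]
            if "N" not in spacer:
                out.append(
                    Protospacer(
                        seq.id, "+", i + 1, spacer, s[i + SPACER_LEN : i + SPACER_LEN + 3]
                    )
                )
        if both_strands and s[i] == "C" and s[i + 1] == "C":
            sense_slice = s[i + PAM_LEN : i + PAM_LEN + SPACER_LEN]
            spacer = revcomp(sense_slice)
            if "N" not in spacer:
                out.append(
                    Protospacer(
                        seq.id, "-", i + PAM_LEN + SPACER_LEN, spacer, revcomp(s[i : i + PAM_LEN])
                    )
                )
    out.sort(key=lambda p: (p.span[0], p.strand))
    return out


def stop_codon_conversions(codon: str) -> list:
    """All ways same-strand C->T deaminations turn ``codon`` into a stop.

    Enumerates, for each strand, every non-empty subset of editable
    positions (sense-strand Cs for a plus-strand protospacer; sense-strand
    Gs, i.e. antisense Cs, for a minus-strand protospacer) and keeps the
    subsets producing TAA, TAG or TGA.  Codons that already are stop
    codons are not knockout targets and return an empty list.

    Returns a list of ``(strand, codon_positions_edited, resulting_stop)``
    with 1-based positions within the codon.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must be 3 nt, got {codon!r}")
    if any(b not in "ACGT" for b in codon):
        return []
    if codon in STOP_CODONS:
        return []
    results = []
    for strand, source, product in (("+", "C", "T"), ("-", "G", "A")):
        editable = [i for i, b in enumerate(codon) if b == source]
        for r in range(1, len(editable) + 1):
            for subset in combinations(editable, r):
                edited = list(codon)
                for i in subset:
                    edited[i] = product
                edited = "".join(edited)
                if edited in STOP_CODONS:
                    results.append(
                        (strand, tuple(i + 1 for i in subset), edited)
                    )
    return results


def stop_introducible_codons() -> frozenset:
    """The codon classes with at least one conversion route to a stop."""
    bases = "ACGT"
    found = set()
    for a in bases:
        for b in bases:
            for c in bases:
                codon = a + b + c
                if stop_codon_conversions(codon):
                    found.add(codon)
    return frozenset(found)


def scan_cds(
    cds: CdsRecord,
    window: EditWindow = DEFAULT_WINDOW,
    strict_motif_window: bool = False,
) -> list:
    """All knockout sites in one frame-valid CDS.

    A :class:`KnockoutSite` is emitted for every (in-frame target codon,
    protospacer, conversion route) such that every codon position that
    must be edited lies, as a C on the protospacer strand, inside
    ``window``.  With ``strict_motif_window`` the whole codon must
    additionally map inside the window (a stricter reading in which the
    motif itself, not just its editable Cs, sits at window positions).

    Protospacers are searched on the supplied CDS sequence only; sites
    whose protospacer or PAM would extend past the CDS ends (e.g. across
    splice junctions) are not found.
    """
    if not cds.is_frame_valid:
        raise FrameError(cds.gene_id, cds.length_nt)
    protos = find_protospacers(cds.sequence, both_strands=True)
    by_strand = defaultdict(list)
    for p in protos:
        by_strand[p.strand].append(p)
    s = cds.sequence.bases
    n_codons = cds.n_codons
    sites = []
    seen = set()
    for ci in range(n_codons):
        codon = s[3 * ci : 3 * ci + 3]
        for strand, codon_positions, stop in stop_codon_conversions(codon):
            sense_coords = [3 * ci + (cp - 1) for cp in codon_positions]
            codon_coords = [3 * ci, 3 * ci + 1, 3 * ci + 2]
            for proto in by_strand[strand]:
                proto_positions = [
                    proto.protospacer_position(c) for c in sense_coords
                ]
                if any(p is None or p not in window for p in proto_positions):
                    continue
                if strict_motif_window:
                    full = [proto.protospacer_position(c) for c in codon_coords]
                    if any(p is None or p not in window for p in full):
                        continue
                key = (ci + 1, proto, stop)
                if key in seen:
                    continue
                seen.add(key)
                sites.append(
                    KnockoutSite(
                        gene_id=cds.gene_id,
                        codon_index_1based=ci + 1,
                        codon=codon,
                        resulting_stop=stop,
                        protospacer=proto,
                        edited_positions=tuple(sorted(proto_positions)),
                        relative_position=(ci + 1) / n_codons,
                    )
                )
    return sites


def scan_cds_set(
    records: Iterable[CdsRecord],
    window: EditWindow = DEFAULT_WINDOW,
    strict_motif_window: bool = False,
    skip_frame_broken: bool = True,
) -> tuple:
    """Scan many CDS records; returns (sites, gene_ids, skipped_gene_ids)."""
    sites = []
    genes = []
    skipped = []
    for rec in records:
        genes.append(rec.gene_id)
        if not rec.is_frame_valid:
            if skip_frame_broken:
                skipped.append(rec.gene_id)
                continue
            raise FrameError(rec.gene_id, rec.length_nt)
        sites.extend(scan_cds(rec, window, strict_motif_window))
    return sites, genes, skipped


@dataclass(frozen=True)
class GenomeSummary:
    """Per-genome targetability summary over a knockout-site scan."""

    total_sites: int
    targetable_genes: int
    total_genes: int
    percent_targetable: float
    median_sites_per_targetable_gene: float
    sites_per_gene_histogram: dict
    relative_position_histogram: dict


def summarize_genome(sites: list, all_genes: list) -> GenomeSummary:
    """Summarize a scan across a gene set.

    A *site* here is a targetable place: a unique (gene, codon index,
    protospacer) triple, counting multi-route TGG conversions once.  The
    median number of sites per gene is computed over targetable genes
    only (genes with at least one site); the percentage of targetable
    genes is over all supplied genes.  Relative codon positions are
    binned into deciles per codon class.
    """
    known = set(all_genes)
    for site in sites:
        if site.gene_id not in known:
            raise ValueError(f"site gene {site.gene_id!r} not in gene list")
    places = {}
    for site in sites:
        places.setdefault(site.place, site)
    counts = Counter(p[0] for p in places)
    per_gene = {g: counts.get(g, 0) for g in all_genes}
    targetable = [g for g, n in per_gene.items() if n > 0]
    total_genes = len(all_genes)
    pct = 100.0 * len(targetable) / total_genes if total_genes else 0.0
    med = median([per_gene[g] for g in targetable]) if targetable else 0.0
    hist = Counter(per_gene.values())
    pos_hist: dict = {c: Counter() for c in TARGET_CODONS}
    for site in places.values():
        decile = min(10, max(1, math.ceil(site.relative_position * 10 - 1e-9)))
        pos_hist.setdefault(site.codon, Counter())[decile] += 1
    return GenomeSummary(
        total_sites=len(places),
        targetable_genes=len(targetable),
        total_genes=total_genes,
        percent_targetable=pct,
        median_sites_per_targetable_gene=float(med),
        sites_per_gene_histogram=dict(sorted(hist.items())),
        relative_position_histogram={
            c: dict(sorted(h.items())) for c, h in pos_hist.items()
        },
    )


# ---------------------------------------------------------------------------
# tabular export

def sites_table(sites: list) -> pd.DataFrame:
    """Knockout sites as a data frame (1-based user-facing coordinates)."""
    rows = []
    for s in sites:
        rows.append(
            {
                "gene_id": s.gene_id,
                "codon_index": s.codon_index_1based,
                "codon": s.codon,
                "stop": s.resulting_stop,
                "strand": s.protospacer.strand,
                "protospacer_start": s.protospacer.start_1based,
                "spacer": s.protospacer.spacer,
                "pam": s.protospacer.pam,
                "edited_positions": ",".join(map(str, s.edited_positions)),
                "relative_position": round(s.relative_position, 4),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "codon_index", "codon", "stop", "strand",
            "protospacer_start", "spacer", "pam", "edited_positions",
            "relative_position",
        ],
    )


def protospacer_bed(sites: list) -> pd.DataFrame:
    """BED6 intervals (0-based half-open) of the protospacers of unique sites."""
    seen = set()
    rows = []
    for s in sites:
        if s.place in seen:
            continue
        seen.add(s.place)
        lo, hi = s.protospacer.span
        rows.append(
            {
                "chrom": s.gene_id,
                "start": lo,
                "end": hi,
                "name": f"{s.gene_id}:codon{s.codon_index_1based}:{s.codon}",
                "score": 0,
                "strand": s.protospacer.strand,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
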