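"""Synthetic inputs for the design and quantification pipeline.

Two generators cover the pipeline end to end without any external data:

* :func:`generate_cds_set` builds frame-valid coding sequences (ATG
  start, single terminal stop, no internal stops) with *planted*
  stop-introducible codons positioned so that a chosen protospacer
  position carries the editable C, together with a truth table of the
  planted sites.  Incidental sites arising from the random background
  are allowed; exhaustive scans, not the truth table alone, define the
  full site set.

* :func:`simulate_amplicon_reads` emits barcoded amplicon reads from a
  reference with specified per-position C->T conversion probabilities,
  a per-read indel probability (one contiguous insertion or deletion),
  and a uniform per-base substitution error rate, with a per-read truth
  table.  Editing events are independent across positions and reads.

All randomness flows from the integer ``seed`` of the spec; identical
seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .design import (
    Protospacer,
    SPACER_LEN,
    STOP_CODONS,
    TARGET_CODONS,
    stop_codon_conversions,
)
from .quant import TargetSite
from .seqio import CdsRecord, NucSequence, ReadRecord

BASES = np.array(list("ACGT"))

#: codon position (1-based) of the editable C planted for each codon class;
#: for TGG the antisense C paired with the G at codon position 2 is used
#: (the TGG->TAG route).
_PLANT_EDIT_POS = {"CAA": 1, "CAG": 1, "CGA": 1, "TGG": 2}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CdsSimSpec:
    """Specification of a synthetic CDS set with planted knockout sites.

    ``planted_sites_per_gene`` maps a gene index (0-based) to a list of
    ``(codon, protospacer_position)`` pairs: the codon class to plant and
    the protospacer position (1..20) at which its editable C must sit.
    """

    n_genes: int = 10
    length_codons: tuple = (100, 150)
    planted_sites_per_gene: dict = field(default_factory=dict)
    background_gc: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.length_codons[0] < 10:
            raise ValueError("CDS length must be at least 10 codons")
        for plants in self.planted_sites_per_gene.values():
            for codon, pos in plants:
                if codon not in TARGET_CODONS:
                    raise ValueError(f"cannot plant codon {codon!r}")
                if not 1 <= pos <= SPACER_LEN:
                    raise ValueError(f"protospacer position {pos} outside 1..20")


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    while True:
        codon = "".join(rng.choice(BASES, size=3, p=p))
        if codon not in STOP_CODONS and codon != "ATG":
            return codon


def _plant_site(seq: list, codon: str, proto_pos: int, slot: int) -> Optional[dict]:
    """Write ``codon`` at codon slot and fix PAM bases so its editable C
    sits at protospacer position ``proto_pos``.  Returns a truth entry or
    None when the construct does not fit inside the sequence."""
    start = 3 * slot
    c_offset = start + _PLANT_EDIT_POS[codon] - 1
    strand = "+" if codon != "TGG" else "-"
    if strand == "+":
        # protospacer base 1 at c_offset - (proto_pos - 1); PAM just 3' of it
        s0 = c_offset - (proto_pos - 1)
        pam_lo = s0 + SPACER_LEN
        if s0 < 0 or pam_lo + 3 > len(seq):
            return None
        edits = {start: codon[0], start + 1: codon[1], start + 2: codon[2],
                 pam_lo + 1: "G", pam_lo + 2: "G"}
    else:
        # minus-strand protospacer: position p maps to sense offset e - p
        # with e the exclusive sense end; PAM occupies sense [e-23, e-20) as CCN
        e = c_offset + proto_pos
        pam_lo = e - SPACER_LEN - 3
        if pam_lo < 0 or e > len(seq):
            return None
        edits = {start: codon[0], start + 1: codon[1], start + 2: codon[2],
                 pam_lo: "C", pam_lo + 1: "C"}
    for off, b in edits.items():
        seq[off] = b
    return {
        "codon_index": slot + 1,
        "codon": codon,
        "strand": strand,
        "protospacer_position": proto_pos,
    }


def _has_internal_stop(seq: list) -> bool:
    for i in range(0, len(seq) - 3, 3):
        if "".join(seq[i : i + 3]) in STOP_CODONS:
            return True
    return False


def generate_cds_set(spec: CdsSimSpec, max_retries: int = 50) -> tuple:
    """Generate a synthetic CDS set; returns ``(records, truth_table)``.

    ``truth_table`` is a data frame with one row per planted site
    (gene_id, codon_index, codon, strand, protospacer_position).  Raises
    :class:`SimulationError` when a planting repeatedly collides with the
    no-internal-stop constraint.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    truth_rows = []
    for g in range(spec.n_genes):
        gene_id = f"gene{g + 1:04d}"
        plants = spec.planted_sites_per_gene.get(g, [])
        for attempt in range(max_retries):
            n_codons = int(rng.integers(spec.length_codons[0], spec.length_codons[1] + 1))
            codons = ["ATG"] + [
                _random_codon(rng, spec.background_gc) for _ in range(n_codons - 2)
            ] + [str(rng.choice(sorted(STOP_CODONS)))]
            seq = list("".join(codons))
            entries = []
            ok = True
            # interior slots only: never overwrite the start or terminal stop,
            # and keep planted constructs at least 8 codons apart
            interior = np.arange(9, n_codons - 9)
            if plants:
                slots: list = []
                for cand in rng.permutation(interior):
                    if all(abs(int(cand) - s) >= 10 for s in slots):
                        slots.append(int(cand))
                        if len(slots) == len(plants):
                            break
                if len(slots) < len(plants):
                    ok = False
                else:
                    for (codon, pos), slot in zip(plants, sorted(slots)):
                        entry = _plant_site(seq, codon, pos, slot)
                        if entry is None:
                            ok = False
                            break
                        entries.append(entry)
            if ok and not _has_internal_stop(seq):
                records.append(CdsRecord.from_bases(gene_id, "".join(seq)))
                for e in entries:
                    truth_rows.append({"gene_id": gene_id, **e})
                break
        else:
            raise SimulationError(
                f"could not plant sites in {gene_id} after {max_retries} tries"
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "codon_index", "codon", "strand", "protospacer_position"],
    )
    return records, truth


# ---------------------------------------------------------------------------
# amplicon read simulation

@dataclass(frozen=True)
class AmpliconSimSpec:
    """Specification of a barcoded amplicon sequencing simulation.

    ``per_position_edit_prob`` maps ``(gRNA_id, protospacer_position)``
    to the probability that this C is converted in a read.  ``depth`` is
    reads per sample; the deep-sequencing regime this emulates runs to
    ~1e5 reads per sample, scaled down as needed.
    """

    reference: NucSequence
    sites: list
    per_position_edit_prob: dict = field(default_factory=dict)
    indel_prob: float = 0.0
    indel_length_range: tuple = (1, 10)
    indel_margin: int = 15
    subst_error_rate: float = 0.0
    depth: int = 1000
    barcode_map: dict = field(default_factory=lambda: {("ACGTAC", "TGCATG"): "S1"})
    read_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        for prob in (self.indel_prob, self.subst_error_rate, *self.per_position_edit_prob.values()):
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"probability {prob} outside [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def _site_targets(spec: AmpliconSimSpec, site: TargetSite) -> list:
    """(ref offset, edited base, probability) for each targeted C of a site."""
    out = []
    strand = site.protospacer.strand
    for p in site.c_positions:
        prob = spec.per_position_edit_prob.get((site.gRNA_id, p), 0.0)
        if prob > 0:
            off = site.protospacer.sense_offset(p)
            base = "T" if strand == "+" else "A"
            out.append((off, base, prob))
    return out


def simulate_amplicon_reads(spec: AmpliconSimSpec) -> tuple:
    """Simulate barcoded amplicon reads; returns ``(reads, truth_table)``.

    Per read: a sample is drawn uniformly from the barcode map; each
    targeted C converts independently with its stated probability; with
    probability ``indel_prob`` one contiguous segment (uniform length in
    ``indel_length_range``, uniform position) is inserted or deleted;
    uniform substitution errors are applied at ``subst_error_rate``;
    barcodes are attached and the quality string is constant Q35.  The
    truth table records the sample, edited reference offsets, and indel
    event of every read.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference.bases
    read_len = spec.read_length if spec.read_length is not None else len(ref)
    if read_len > len(ref):
        raise SimulationError("read_length exceeds reference length")
    targets = []
    for site in spec.sites:
        targets.extend(_site_targets(spec, site))
    if targets and read_len <= max(t[0] for t in targets):
        raise SimulationError(
            "read_length does not span the targeted site region"
        )
    pairs = sorted(spec.barcode_map)
    reads = []
    truth_rows = []
    for i in range(spec.depth):
        pair = pairs[int(rng.integers(len(pairs)))]
        sample = spec.barcode_map[pair]
        bases = list(ref[:read_len])
        edited_offsets = []
        for off, base, prob in targets:
            if rng.random() < prob:
                bases[off] = base
                edited_offsets.append(off)
        # substitution errors before the indel, so error offsets stay in
        # reference coordinates
        if spec.subst_error_rate > 0:
            hits = np.flatnonzero(rng.random(len(bases)) < spec.subst_error_rate)
            for off in hits:
                current = bases[off]
                choices = [b for b in "ACGT" if b != current]
                bases[off] = choices[int(rng.integers(3))]
        indel = ""
        if rng.random() < spec.indel_prob:
            # events are placed in the read interior: an indel within the
            # terminal bases cannot be resolved by any aligner with free
            # end gaps and would be invisible to every downstream caller
            m = spec.indel_margin
            lo, hi = spec.indel_length_range
            length = int(rng.integers(lo, hi + 1))
            if len(bases) <= 2 * m + length + 1:
                raise SimulationError("read too short for interior indels")
            if rng.random() < 0.5:
                pos = int(rng.integers(m, len(bases) - length - m))
                del bases[pos : pos + length]
                indel = f"del:{pos}:{length}"
            else:
                pos = int(rng.integers(m, len(bases) - m))
                insert = rng.choice(BASES, size=length)
                bases[pos:pos] = list(insert)
                indel = f"ins:{pos}:{length}"
        left, right = pair
        full = left + "".join(bases) + right
        read = ReadRecord(f"read{i + 1}", full, tuple([35] * len(full)))
        reads.append(read)
        truth_rows.append(
            {
                "read_id": read.id,
                "sample": sample,
                "edited_offsets": ",".join(map(str, sorted(edited_offsets))),
                "n_edits": len(edited_offsets),
                "indel": indel,
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "sample", "edited_offsets", "n_edits", "indel"]
    )
    return reads, truth


def make_amplicon_with_sites(
    n_sites: int = 1,
    spacer_c_positions: dict = None,
    seed: int = 0,
    pad: int = 20,
) -> tuple:
    """Construct a synthetic amplicon reference carrying ``n_sites``
    plus-strand NGG protospacers and the matching :class:`TargetSite`
    records.  ``spacer_c_positions`` maps site index (0-based) to the
    protospacer positions (1..20) that should hold a C; other spacer
    positions are random non-C bases, so targeted Cs are unambiguous.
    """
    rng = np.random.default_rng(seed)
    spacer_c_positions = spacer_c_positions or {i: (5,) for i in range(n_sites)}
    non_c = np.array(list("AGT"))
    parts = ["".join(rng.choice(non_c, size=pad))]
    sites = []
    offset = pad
    amplicon_id = "amplicon1"
    for i in range(n_sites):
        spacer = [str(b) for b in rng.choice(non_c, size=SPACER_LEN)]
        for p in spacer_c_positions.get(i, ()):
            spacer[p - 1] = "C"
        spacer = "".join(spacer)
        pam = "AGG"
        parts.append(spacer + pam)
        proto = Protospacer(amplicon_id, "+", offset + 1, spacer, pam)
        sites.append(TargetSite(f"gRNA{i + 1}", amplicon_id, proto))
        offset += SPACER_LEN + len(pam) + pad
        parts.append("".join(rng.choice(non_c, size=pad)))
    ref = NucSequence(amplicon_id, "".join(parts))
    return ref, sites
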