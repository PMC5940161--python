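"""Quantification of base-editing outcomes from targeted amplicon reads.

The processing chain mirrors a standard deaminase-editing readout:
quality trimming (leading/trailing base removal plus a sliding mean-
quality window), exact barcode-pair demultiplexing, global alignment of
each read to its known amplicon reference, read classification by C:G to
T:A conversion within the 20-bp protospacer, per-gRNA efficiency,
per-position substitution rates, editing-window probabilities across a
gRNA panel, multiplex substitution counting, and indel frequency.

Alignment uses a global affine-gap aligner (match +2, mismatch -3, gap
open -5, gap extend -2) with free end gaps on the read, so reads that
cover only part of the amplicon are not penalized and terminal gaps are
never called as indels.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import Align

from .design import Protospacer
from .seqio import NucSequence, ReadRecord

EDITED_BASE = {"+": "T", "-": "A"}  # read base at a converted C, sense orientation
SOURCE_BASE = {"+": "C", "-": "G"}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TrimParams:
    """Quality-trimming parameters (LEADING/TRAILING/SLIDINGWINDOW/MINLEN)."""

    leading_q: int = 3
    trailing_q: int = 3
    window_len: int = 4
    window_q: float = 15.0
    min_len: int = 50

    def __post_init__(self):
        if min(self.leading_q, self.trailing_q, self.window_len, self.min_len) < 0:
            raise ValueError("trim parameters must be non-negative")
        if self.window_q < 0:
            raise ValueError("trim parameters must be non-negative")


@dataclass(frozen=True)
class TargetSite:
    """One gRNA target site located on an amplicon reference."""

    gRNA_id: str
    amplicon_id: str
    protospacer: Protospacer

    @property
    def c_positions(self) -> tuple:
        """Protospacer positions (1..20) holding C on the protospacer strand."""
        return tuple(
            i + 1 for i, b in enumerate(self.protospacer.spacer) if b == "C"
        )


@dataclass
class SampleEditStats:
    """Per-gRNA read counts and per-position substitution counts."""

    gRNA_id: str
    n_raw: int = 0
    n_clean: int = 0
    n_edited: int = 0
    n_indel: int = 0
    n_not_covering: int = 0
    per_position_edited: dict = field(default_factory=dict)
    c_positions: tuple = ()

    @property
    def efficiency(self) -> Optional[float]:
        """Percent of clean reads with >=1 C->T conversion (1 d.p.), or None."""
        if self.n_clean == 0:
            return None
        return compute_efficiency(self)

    @property
    def indel_pct(self) -> Optional[float]:
        if self.n_clean == 0:
            return None
        return round_half_up(100.0 * self.n_indel / self.n_clean)


@dataclass(frozen=True)
class EditingWindowProfile:
    """Per-position probability that a designed Cn shows substitution.

    ``probability[n-1] = edited_at_Cn / designed_with_Cn`` over a gRNA
    panel; NaN where no gRNA carries a C at that position.
    """

    designed_with_c: tuple
    edited_at_c: tuple

    def probability(self, position: int) -> float:
        d = self.designed_with_c[position - 1]
        e = self.edited_at_c[position - 1]
        return e / d if d else float("nan")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": range(1, 21),
                "designed_with_c": self.designed_with_c,
                "edited_at_c": self.edited_at_c,
                "probability": [self.probability(p) for p in range(1, 21)],
            }
        )


@dataclass(frozen=True)
class MultiplexHistogram:
    """Distribution of the number of converted targeted positions per read."""

    counts: dict
    n_not_covering: int = 0

    @property
    def max_k(self) -> int:
        return max(self.counts) if self.counts else 0

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    def as_frame(self) -> pd.DataFrame:
        ks = range(0, self.max_k + 1)
        return pd.DataFrame(
            {"n_substitutions": ks, "reads": [self.counts.get(k, 0) for k in ks]}
        )


def round_half_up(x: float, digits: int = 1) -> float:
    """Round half away from zero to ``digits`` decimals (report convention)."""
    factor = 10 ** digits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# trimming and demultiplexing

def trim_read(read: ReadRecord, params: TrimParams = TrimParams()) -> Optional[ReadRecord]:
    """Quality-trim one read; returns None when it falls below min_len.

    Leading and trailing bases below the respective quality cutoffs are
    removed first; then, scanning 5'->3', the read is cut at the start of
    the first window of ``window_len`` bases whose mean quality is below
    ``window_q``.  The result is always a contiguous substring of the
    input.
    """
    q = read.qualities
    start, end = 0, len(q)
    while start < end and q[start] < params.leading_q:
        start += 1
    while end > start and q[end - 1] < params.trailing_q:
        end -= 1
    w = params.window_len
    if w > 0 and end - start >= w:
        for i in range(start, end - w + 1):
            if sum(q[i : i + w]) / w < params.window_q:
                end = i
                break
    if end - start < params.min_len:
        return None
    return ReadRecord(
        read.id, read.bases[start:end], q[start:end], read.barcode_pair
    )


def demultiplex(reads: Iterable[ReadRecord], barcode_map: dict) -> tuple:
    """Assign reads to samples by exact barcode-pair match.

    ``barcode_map`` maps ``(left, right)`` barcode strings to sample ids;
    the left barcode must match the read prefix and the right barcode the
    read suffix, jointly and exactly (0 mismatches).  Barcodes are
    stripped from assigned reads.  Returns ``(per_sample, unassigned)``.
    """
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ConfigurationError("duplicate sample id in barcode map")
    pairs = list(barcode_map.items())
    per_sample: dict = {sid: [] for sid in barcode_map.values()}
    unassigned = []
    for read in reads:
        matches = [
            (pair, sid)
            for pair, sid in pairs
            if len(read) >= len(pair[0]) + len(pair[1])
            and read.bases.startswith(pair[0])
            and read.bases.endswith(pair[1])
        ]
        if len(matches) != 1:
            unassigned.append(read)
            continue
        (left, right), sid = matches[0]
        lo, hi = len(left), len(read) - len(right)
        per_sample[sid].append(
            ReadRecord(
                read.id,
                read.bases[lo:hi],
                read.qualities[lo:hi],
                barcode_pair=(left, right),
            )
        )
    return per_sample, unassigned


# ---------------------------------------------------------------------------
# alignment

def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    # free end gaps for read ends: a read covering part of the amplicon is
    # not penalized, and terminal gaps are never counted as indels
    aligner.end_deletion_score = 0
    aligner.end_insertion_score = 0
    return aligner


_ALIGNER = make_aligner()


def align_read(read_bases: str, ref_bases: str) -> tuple:
    """Align a read to the amplicon reference.

    Returns ``(ref_to_read, has_internal_indel)`` where ``ref_to_read``
    maps each aligned 0-based reference coordinate to the 0-based read
    coordinate, and ``has_internal_indel`` is True when the best
    alignment contains a gap strictly inside the aligned span.
    """
    if not ref_bases:
        raise ValueError("empty amplicon reference")
    aln = _ALIGNER.align(ref_bases, read_bases)[0]
    ref_blocks, read_blocks = aln.aligned
    mapping = {}
    for (t0, t1), (q0, q1) in zip(ref_blocks, read_blocks):
        for k in range(t1 - t0):
            mapping[t0 + k] = q0 + k
    return mapping, len(ref_blocks) > 1


# ---------------------------------------------------------------------------
# classification and per-sample statistics

def _site_ref_offsets(site: TargetSite, ref_len: int) -> list:
    offsets = [site.protospacer.sense_offset(p) for p in range(1, 21)]
    if min(offsets) < 0 or max(offsets) >= ref_len:
        raise ConfigurationError(
            f"site {site.gRNA_id!r} extends outside amplicon "
            f"{site.amplicon_id!r} (length {ref_len})"
        )
    return offsets


def classify_read(
    read: ReadRecord, amplicon_ref: NucSequence, site: TargetSite
) -> str:
    """Classify one read as ``edited``, ``unedited`` or ``not_covering``.

    A read is *edited* iff at least one protospacer-strand C within the
    20-bp target shows a C->T conversion (read base T at a sense-strand
    C for plus-strand sites; read base A at a sense-strand G for
    minus-strand sites).  Other substitutions do not count as editing.
    Reads whose alignment does not place a base at every one of the 20
    protospacer positions are *not_covering*.
    """
    outcome, _, _ = _classify_with_alignment(read, amplicon_ref, site)
    return outcome


def _classify_with_alignment(read, amplicon_ref, site):
    offsets = _site_ref_offsets(site, len(amplicon_ref))
    mapping, has_indel = align_read(read.bases, amplicon_ref.bases)
    if any(o not in mapping for o in offsets):
        return "not_covering", has_indel, ()
    strand = site.protospacer.strand
    edited_positions = []
    for p in site.c_positions:
        o = site.protospacer.sense_offset(p)
        if read.bases[mapping[o]] == EDITED_BASE[strand]:
            edited_positions.append(p)
    outcome = "edited" if edited_positions else "unedited"
    return outcome, has_indel, tuple(edited_positions)


def analyze_sample(
    reads: Iterable[ReadRecord],
    amplicon_ref: NucSequence,
    site: TargetSite,
    trim_params: Optional[TrimParams] = TrimParams(),
) -> SampleEditStats:
    """Full per-sample quantification: trim, align, classify, count."""
    stats = SampleEditStats(
        gRNA_id=site.gRNA_id,
        per_position_edited={p: 0 for p in site.c_positions},
        c_positions=site.c_positions,
    )
    for read in reads:
        stats.n_raw += 1
        if trim_params is not None:
            read = trim_read(read, trim_params)
            if read is None:
                continue
        stats.n_clean += 1
        outcome, has_indel, edited_positions = _classify_with_alignment(
            read, amplicon_ref, site
        )
        if has_indel:
            stats.n_indel += 1
        if outcome == "not_covering":
            stats.n_not_covering += 1
            continue
        if outcome == "edited":
            stats.n_edited += 1
            for p in edited_positions:
                stats.per_position_edited[p] += 1
    return stats


def compute_efficiency(stats: SampleEditStats) -> Optional[float]:
    """Editing efficiency: percent of clean reads with a conversion (1 d.p.)."""
    if stats.n_clean == 0:
        return None
    return round_half_up(100.0 * stats.n_edited / stats.n_clean)


def clone_efficiency(n_mut: int, n_total: int) -> Optional[float]:
    """Percent of sequenced clones carrying the intended substitution.

    Reported truncated (not rounded) to one decimal place, matching the
    convention of clone-count percentages such as 3/11 -> 27.2%.
    """
    if not 0 <= n_mut <= n_total:
        raise ValueError("need 0 <= n_mut <= n_total")
    if n_total == 0:
        return None
    return math.floor(1000.0 * n_mut / n_total + 1e-9) / 10


def per_position_matrix(samples: list) -> pd.DataFrame:
    """gRNA x protospacer-position matrix of per-position edit fractions.

    Entry (g, n) is the fraction of clean reads of gRNA g edited at
    position n, for positions where g carries a C; NaN elsewhere.
    """
    data = {}
    for s in samples:
        row = np.full(20, np.nan)
        for p in s.c_positions:
            row[p - 1] = (
                s.per_position_edited.get(p, 0) / s.n_clean if s.n_clean else np.nan
            )
        data[s.gRNA_id] = row
    return pd.DataFrame.from_dict(
        data, orient="index", columns=range(1, 21)
    )


def window_profile(
    matrix: pd.DataFrame,
    detection_threshold: float = 0.005,
    control_rates: Optional[dict] = None,
    control_factor: float = 3.0,
) -> EditingWindowProfile:
    """Editing-window probabilities over a gRNA panel.

    For each protospacer position n, ``designed_with_Cn`` counts the
    gRNAs carrying a C at n (non-NaN matrix entries) and ``edited_at_Cn``
    counts those whose per-position fraction reaches the detection
    threshold.  The threshold is ``max(detection_threshold,
    control_factor * control rate at n)`` when per-position control rates
    are supplied, separating real substitution signal from sequencing
    error.
    """
    designed = []
    edited = []
    for n in range(1, 21):
        col = matrix[n]
        thr = detection_threshold
        if control_rates is not None and n in control_rates:
            thr = max(thr, control_factor * control_rates[n])
        has_c = col.notna()
        designed.append(int(has_c.sum()))
        edited.append(int((col[has_c] >= thr).sum()))
    return EditingWindowProfile(tuple(designed), tuple(edited))


# ---------------------------------------------------------------------------
# multiplex counting and indels

def multiplex_histogram(
    reads: Iterable[ReadRecord],
    amplicon_ref: NucSequence,
    sites: list,
) -> MultiplexHistogram:
    """Histogram of simultaneous conversions per read over a gRNA panel.

    For each read, k is the number of *distinct* targeted C positions
    (the union of all sites' protospacer Cs, in amplicon coordinates)
    showing a conversion.  Positions shared by overlapping sites count
    once.  Reads not covering every targeted position are tallied
    separately and excluded from the histogram.
    """
    targets = {}  # ref offset -> read base indicating conversion
    for site in sites:
        if site.amplicon_id != sites[0].amplicon_id:
            raise ConfigurationError("all sites must be on one amplicon")
        _site_ref_offsets(site, len(amplicon_ref))
        strand = site.protospacer.strand
        for p in site.c_positions:
            targets[site.protospacer.sense_offset(p)] = EDITED_BASE[strand]
    counts: Counter = Counter()
    n_not_covering = 0
    for read in reads:
        mapping, _ = align_read(read.bases, amplicon_ref.bases)
        if any(o not in mapping for o in targets):
            n_not_covering += 1
            continue
        k = sum(
            1 for o, base in targets.items() if read.bases[mapping[o]] == base
        )
        counts[k] += 1
    return MultiplexHistogram(dict(sorted(counts.items())), n_not_covering)


def indel_frequency(
    reads: Iterable[ReadRecord], amplicon_ref: NucSequence
) -> tuple:
    """Percent of reads whose best alignment contains an internal gap.

    Returns ``(percent, flags)``; terminal gaps (incomplete coverage of
    the amplicon) are not counted as indels.  ``percent`` is None when no
    reads are supplied.
    """
    if not amplicon_ref.bases:
        raise ValueError("empty amplicon reference")
    flags = []
    for read in reads:
        _, has_indel = align_read(read.bases, amplicon_ref.bases)
        flags.append(has_indel)
    if not flags:
        return None, flags
    return 100.0 * sum(flags) / len(flags), flags


# ---------------------------------------------------------------------------
# tabular export

def stats_table(samples: list) -> pd.DataFrame:
    rows = []
    for s in samples:
        rows.append(
            {
                "gRNA_id": s.gRNA_id,
                "n_raw": s.n_raw,
                "n_clean": s.n_clean,
                "n_edited": s.n_edited,
                "n_not_covering": s.n_not_covering,
                "efficiency_pct": s.efficiency,
                "n_indel": s.n_indel,
                "indel_pct": s.indel_pct,
            }
        )
    return pd.DataFrame(rows)
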