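"""Paired-end alignment filtering and reduction to fragment records.

A retained read pair must (1) be flagged in proper orientation for pairing,
(2) consist of primary alignments only, (3) have mapping quality >= 1 on both
mates, and (4) contribute only reads with a previously unseen starting
location (first seen wins).  Passing pairs are reduced to
(chromosome, midpoint, size) fragment records.

The deduplication key is the strand-agnostic (chromosome, start) of each
read; a pair is dropped atomically when either read collides with an already
*emitted* read.  The two mates of a single pair may share a start (a size-0
fragment) without colliding with each other.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 1
DEFAULT_MAX_SIZE = 300


@dataclass(frozen=True)
class AlignedPair:
    """A properly paired primary alignment reduced to its essentials."""

    chrom: str
    start1: int
    start2: int
    mapq1: int
    mapq2: int
    tlen: int = 0  # SAM template length of the first-seen mate (optional)


@dataclass(frozen=True)
class FragmentRecord:
    chrom: str
    midpoint: int
    size: int


class FilterStats(dict):
    """Counter mapping drop reason -> number of records/pairs affected."""

    def bump(self, key: str, n: int = 1) -> None:
        self[key] = self.get(key, 0) + n


def filter_pairs(
    records: Iterable[pysam.AlignedSegment],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    stats: FilterStats | None = None,
) -> Iterator[AlignedPair]:
    """Yield pairs passing all four retention criteria.

    ``records`` is any iterable of aligned segments (coordinate order not
    required; mates are matched by query name).  Records whose mate never
    appears are counted under ``unmatched_mate`` and skipped.  A record with
    a missing reference or position while flagged as mapped is malformed and
    raises.
    """
    if stats is None:
        stats = FilterStats()
    pending: dict[str, pysam.AlignedSegment] = {}
    seen_starts: set[tuple[str, int]] = set()

    for rec in records:
        if rec.is_secondary or rec.is_supplementary:
            stats.bump("secondary_or_supplementary")
            continue
        if rec.is_unmapped or rec.mate_is_unmapped:
            stats.bump("unmapped")
            continue
        if rec.reference_name is None or rec.reference_start is None or rec.reference_start < 0:
            raise ValueError(f"malformed alignment record: {rec.query_name!r}")
        if not rec.is_paired:
            stats.bump("unpaired")
            continue
        qname = rec.query_name
        mate = pending.pop(qname, None)
        if mate is None:
            pending[qname] = rec
            continue

        if not (rec.is_proper_pair and mate.is_proper_pair):
            stats.bump("improper_pair")
            continue
        if rec.reference_name != mate.reference_name:
            stats.bump("improper_pair")
            continue
        if rec.mapping_quality < min_mapq or mate.mapping_quality < min_mapq:
            stats.bump("low_mapq")
            continue
        chrom = str(rec.reference_name)
        s1, s2 = mate.reference_start, rec.reference_start
        k1, k2 = (chrom, s1), (chrom, s2)
        if k1 in seen_starts or k2 in seen_starts:
            stats.bump("duplicate_start")
            continue
        seen_starts.add(k1)
        seen_starts.add(k2)
        stats.bump("retained_pairs")
        yield AlignedPair(
            chrom=chrom,
            start1=int(s1),
            start2=int(s2),
            mapq1=int(mate.mapping_quality),
            mapq2=int(rec.mapping_quality),
            tlen=int(mate.template_length),
        )

    if pending:
        stats.bump("unmatched_mate", len(pending))


def pair_to_fragment(pair: AlignedPair, size_mode: str = "start-start") -> FragmentRecord:
    """Reduce a pair to its fragment: midpoint of the starts, start-to-start size.

    size = |start2 - start1|, midpoint = floor((start1 + start2) / 2).
    ``size_mode='tlen'`` substitutes |SAM TLEN| for the size instead.
    """
    if size_mode == "start-start":
        size = abs(pair.start2 - pair.start1)
    elif size_mode == "tlen":
        size = abs(pair.tlen)
    else:
        raise ValueError(f"unknown size_mode {size_mode!r}")
    midpoint = (pair.start1 + pair.start2) // 2
    return FragmentRecord(chrom=pair.chrom, midpoint=midpoint, size=size)


def size_filter(
    fragments: Sequence[FragmentRecord] | pd.DataFrame,
    cap_bp: int = DEFAULT_MAX_SIZE,
    stats: FilterStats | None = None,
):
    """Drop fragments larger than ``cap_bp`` (default 300 bp)."""
    if cap_bp <= 0:
        raise ValueError("cap_bp must be positive")
    if isinstance(fragments, pd.DataFrame):
        keep = fragments["size"] <= cap_bp
        dropped = int((~keep).sum())
        out = fragments.loc[keep].reset_index(drop=True)
    else:
        out = [f for f in fragments if f.size <= cap_bp]
        dropped = len(fragments) - len(out)
    if stats is not None:
        stats.bump("oversize_fragments", dropped)
    if dropped:
        logger.info("size_filter: dropped %d fragments > %d bp", dropped, cap_bp)
    return out


def fragments_to_frame(fragments: Sequence[FragmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [f.chrom for f in fragments],
            "midpoint": [f.midpoint for f in fragments],
            "size": [f.size for f in fragments],
        }
    )


def read_fragments(
    path: str | Path,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    max_size: int = DEFAULT_MAX_SIZE,
    size_mode: str = "start-start",
) -> tuple[pd.DataFrame, FilterStats]:
    """Run the full filter chain on a SAM/BAM file.

    Returns a (chrom, midpoint, size) table of retained fragments and the
    filter statistics.
    """
    stats = FilterStats()
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        pairs = filter_pairs(fh, min_mapq=min_mapq, stats=stats)
        frags = [pair_to_fragment(p, size_mode=size_mode) for p in pairs]
    frags = size_filter(frags, cap_bp=max_size, stats=stats)
    return fragments_to_frame(frags), stats


def write_fragment_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_stats(stats: FilterStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(stats), indent=2, sort_keys=True) + "\n")
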