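"""Read-level preprocessing: quality filtering, oligo-dT trimming, tag mapping.

Mirrors the raw-data stage of a PAT-Seq pipeline: reads are quality-filtered
(FASTX-style: a read survives if at least ``min_percent_at_quality`` percent
of its bases reach ``min_quality``), the leading poly(T) stretch left by the
oligo-dT primer is trimmed (reads without one are discarded, as are trimmed
tags shorter than ``min_trimmed_length``), and surviving tags are located on
the genome by exact substring search. Pre-mapped tags can instead be imported
from BED6.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO

from .util import revcomp

TAG_COLUMNS = ["chrom", "strand", "position", "sample"]


@dataclass
class PreprocessConfig:
    min_quality: int = 10            # FASTX -q
    min_percent_at_quality: float = 50.0  # FASTX -p
    min_trimmed_length: int = 20
    min_polyt_run: int = 8
    quality_offset: int = 33
    adapter: Optional[str] = None    # 3' adapter removed before length check

    def validate(self) -> List[str]:
        v = []
        if not 0 <= self.min_percent_at_quality <= 100:
            v.append("min_percent_at_quality must lie in [0, 100]")
        if self.min_trimmed_length < 1:
            v.append("min_trimmed_length must be positive")
        if self.min_polyt_run < 1:
            v.append("min_polyt_run must be positive")
        if self.min_quality < 0:
            v.append("min_quality must be non-negative")
        return v


class FastqParseError(ValueError):
    pass


def parse_fastq(handle_or_path) -> Iterator[Tuple[str, str, List[int]]]:
    """Yield (read_id, sequence, phred_qualities) from Phred+33 FASTQ."""
    try:
        for rec in SeqIO.parse(handle_or_path, "fastq"):
            yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]
    except ValueError as exc:
        raise FastqParseError(f"malformed FASTQ record: {exc}") from exc


def quality_filter(
    reads: Iterable[Tuple[str, str, List[int]]], cfg: PreprocessConfig
) -> Tuple[List[Tuple[str, str, List[int]]], Counter]:
    """FASTX-style quality filter.

    A read is retained iff at least ``min_percent_at_quality`` percent of its
    bases have Phred quality >= ``min_quality`` (boundary inclusive).
    Returns the retained reads and a counter with retained/discarded totals.
    """
    retained: List[Tuple[str, str, List[int]]] = []
    counts: Counter = Counter(input=0, retained=0, discarded_quality=0)
    q, pct = cfg.min_quality, cfg.min_percent_at_quality
    for read in reads:
        counts["input"] += 1
        quals = read[2]
        if not quals:
            counts["discarded_quality"] += 1
            continue
        good = sum(1 for x in quals if x >= q)
        if 100.0 * good / len(quals) >= pct:
            retained.append(read)
            counts["retained"] += 1
        else:
            counts["discarded_quality"] += 1
    return retained, counts


def trim_tag(seq: str, cfg: PreprocessConfig) -> Tuple[Optional[str], str]:
    """Remove the leading oligo-dT evidence from one read.

    The longest leading run of T is trimmed; after 10 consecutive T a single
    non-T base is tolerated (the anchored primer base) provided the run
    continues. Verdicts: ``retained`` (trimmed tag returned), ``no_oligo_dt``
    (leading run shorter than ``min_polyt_run``), ``too_short`` (trimmed tag
    shorter than ``min_trimmed_length``).
    """
    i, run, mismatch_used = 0, 0, False
    n = len(seq)
    while i < n:
        if seq[i] == "T":
            run += 1
            i += 1
        elif (not mismatch_used and run >= 10 and i + 1 < n and seq[i + 1] == "T"):
            mismatch_used = True
            i += 1
        else:
            break
    if run < cfg.min_polyt_run:
        return None, "no_oligo_dt"
    tag = seq[i:]
    if cfg.adapter:
        cut = tag.find(cfg.adapter)
        if cut >= 0:
            tag = tag[:cut]
    if len(tag) < cfg.min_trimmed_length:
        return None, "too_short"
    return tag, "retained"


def trim_reads(
    reads: Iterable[Tuple[str, str, List[int]]], cfg: PreprocessConfig
) -> Tuple[List[Tuple[str, str]], Counter]:
    """Apply :func:`trim_tag` to a stream; returns (id, tag) pairs + counts."""
    out: List[Tuple[str, str]] = []
    counts: Counter = Counter(input=0, retained=0, discarded_no_oligo_dt=0,
                              discarded_too_short=0)
    for read_id, seq, _q in reads:
        counts["input"] += 1
        tag, verdict = trim_tag(seq, cfg)
        if verdict == "retained":
            out.append((read_id, tag))
            counts["retained"] += 1
        else:
            counts[f"discarded_{verdict}"] += 1
    return out, counts


class GenomeIndex:
    """Exact-substring index over a toy genome (seed k-mer + verification)."""

    def __init__(self, genome: Dict[str, str], k: int = 20):
        self.genome = genome
        self.k = k
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    def occurrences(self, query: str, max_hits: int = 2) -> List[Tuple[str, int]]:
        """Forward-strand occurrences of `query`; stops after `max_hits`."""
        hits: List[Tuple[str, int]] = []
        if len(query) >= self.k:
            for chrom, i in self._index.get(query[: self.k], []):
                if self.genome[chrom].startswith(query, i):
                    hits.append((chrom, i))
                    if len(hits) >= max_hits:
                        return hits
        else:
            for chrom, seq in self.genome.items():
                start = seq.find(query)
                while start != -1:
                    hits.append((chrom, start))
                    if len(hits) >= max_hits:
                        return hits
                    start = seq.find(query, start + 1)
        return hits


def map_tags(
    tags: Iterable[Tuple[str, str]],
    genome: Dict[str, str],
    sample_id: str,
    index: Optional[GenomeIndex] = None,
) -> Tuple[pd.DataFrame, Counter]:
    """Place trimmed tags on the genome by exact match, both orientations.

    A tag whose reverse complement occurs once on the forward genome maps to
    the + strand with the cleavage position at the match's 3'-most base; a
    tag occurring directly maps to the - strand with the cleavage position at
    the match start. Tags with zero total occurrences are unmapped; more than
    one, multi-mappers; both are discarded and counted.
    """
    if index is None:
        index = GenomeIndex(genome)
    rows = []
    counts: Counter = Counter(input=0, mapped=0, unmapped=0, multimapped=0)
    for _read_id, tag in tags:
        counts["input"] += 1
        plus = index.occurrences(revcomp(tag))
        minus = index.occurrences(tag)
        total = len(plus) + len(minus)
        if total == 0:
            counts["unmapped"] += 1
        elif total > 1:
            counts["multimapped"] += 1
        elif plus:
            chrom, start = plus[0]
            rows.append((chrom, "+", start + len(tag) - 1, sample_id))
            counts["mapped"] += 1
        else:
            chrom, start = minus[0]
            rows.append((chrom, "-", start, sample_id))
            counts["mapped"] += 1
    return pd.DataFrame(rows, columns=TAG_COLUMNS), counts


def preprocess_sample(
    fastq_path, genome: Dict[str, str], sample_id: str,
    cfg: Optional[PreprocessConfig] = None,
    index: Optional[GenomeIndex] = None,
) -> Tuple[pd.DataFrame, Dict[str, Counter]]:
    """Full raw-read stage for one sample: QC -> trim -> map."""
    cfg = cfg or PreprocessConfig()
    passed, qc_counts = quality_filter(parse_fastq(fastq_path), cfg)
    trimmed, trim_counts = trim_reads(passed, cfg)
    tags, map_counts = map_tags(trimmed, genome, sample_id, index=index)
    return tags, {"quality": qc_counts, "trim": trim_counts, "map": map_counts}


class BedParseError(ValueError):
    pass


def read_bed(path_or_handle, sample_id: str) -> pd.DataFrame:
    """Import pre-mapped tag 3' ends from BED6 (one single-base interval per tag)."""
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
    else:
        with open(path_or_handle) as fh:
            lines = fh.read().splitlines()
    rows = []
    for ln, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise BedParseError(f"line {ln}: expected >= 6 tab-separated fields")
        chrom, start, end, _name, _score, strand = fields[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise BedParseError(f"line {ln}: non-integer coordinates") from exc
        if strand not in ("+", "-"):
            raise BedParseError(f"line {ln}: strand must be '+' or '-', got {strand!r}")
        if end_i != start_i + 1:
            raise BedParseError(f"line {ln}: expected a single-base interval")
        rows.append((chrom, strand, start_i, sample_id))
    return pd.DataFrame(rows, columns=TAG_COLUMNS)
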