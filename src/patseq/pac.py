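"""Poly(A)-site (PAS) and poly(A)-site-cluster (PAC) construction.

Mapped tags at identical genomic coordinates are grouped into PAS;
likely internal-priming artifacts (PAS whose immediate downstream genomic
sequence is A-rich, the signature of oligo-dT mispriming) are removed; the
surviving PAS are single-linkage clustered along each chromosome strand with
an inclusive gap threshold; clusters with insufficient read support are
dropped; and each cluster is summarised by its most abundant member site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .util import max_base_run, revcomp

PAS_KEY = ["chrom", "strand", "position"]


@dataclass
class PacParams:
    cluster_gap: int = 24      # max gap between neighbouring PAS in one PAC (inclusive)
    min_pac_reads: int = 10    # PACs with fewer total reads are discarded
    ip_window: int = 10        # downstream window for internal-priming detection
    ip_max_a: int = 7          # >= this many A in the window -> artifact
    ip_max_run_a: int = 6      # >= this long an A run in the window -> artifact

    def validate(self) -> List[str]:
        bad = [f for f in ("cluster_gap", "min_pac_reads", "ip_window",
                           "ip_max_a", "ip_max_run_a") if getattr(self, f) <= 0]
        return [f"{f} must be positive" for f in bad]


def build_pas(tags: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """Group identical-coordinate tags into PAS with per-sample counts.

    Returns a frame with chrom/strand/position plus one count column per
    sample (all samples present, zero-filled), sorted by genomic position.
    """
    samples = list(samples)
    if len(tags) == 0:
        return pd.DataFrame(columns=PAS_KEY + samples)
    counts = (
        tags.groupby(PAS_KEY + ["sample"], sort=False).size().unstack("sample", fill_value=0)
    )
    counts = counts.reindex(columns=samples, fill_value=0)
    counts.columns.name = None
    pas = counts.reset_index().sort_values(PAS_KEY, kind="mergesort").reset_index(drop=True)
    pas[samples] = pas[samples].astype(np.int64)
    return pas


def downstream_window(genome: Dict[str, str], chrom: str, strand: str,
                      position: int, width: int) -> str:
    """Transcript-strand genomic sequence immediately 3' of a cleavage position.

    Bases beyond the chromosome end are simply absent from the returned
    string (treated as non-A by the caller).
    """
    seq = genome[chrom]
    if strand == "+":
        return seq[position + 1 : position + 1 + width]
    start = max(0, position - width)
    return revcomp(seq[start:position])


def is_internal_priming(genome: Dict[str, str], chrom: str, strand: str,
                        position: int, params: PacParams) -> bool:
    win = downstream_window(genome, chrom, strand, position, params.ip_window)
    return win.count("A") >= params.ip_max_a or max_base_run(win, "A") >= params.ip_max_run_a


def filter_internal_priming(
    pas: pd.DataFrame, genome: Dict[str, str], params: PacParams
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split PAS into (retained, removed-as-internal-priming) sets.

    A PAS is removed iff the ``ip_window`` nt of transcript-strand sequence
    immediately downstream of its cleavage position contain at least
    ``ip_max_a`` adenosines or a run of at least ``ip_max_run_a`` consecutive
    adenosines. Both sets are returned for audit.
    """
    if len(pas) == 0:
        return pas.copy(), pas.copy()
    flags = np.fromiter(
        (is_internal_priming(genome, r.chrom, r.strand, r.position, params)
         for r in pas.itertuples()),
        dtype=bool, count=len(pas),
    )
    return pas[~flags].reset_index(drop=True), pas[flags].reset_index(drop=True)


def cluster_pas(pas: pd.DataFrame, params: PacParams,
                samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Single-linkage clustering of PAS into PACs along each chromosome strand.

    Neighbouring PAS on the same chrom/strand whose positional gap is
    <= ``cluster_gap`` (inclusive) join the same PAC; maximal such chains are
    returned with summed per-sample counts, the half-open genomic span of the
    member sites, and the representative position (most abundant member,
    ties broken 3'-most in transcription direction).
    """
    if samples is None:
        samples = [c for c in pas.columns if c not in PAS_KEY]
    samples = list(samples)
    if len(pas) == 0:
        return pd.DataFrame(columns=["pac_id", "chrom", "strand", "start", "end",
                                     "representative", "n_sites", "total"] + samples)
    pas = pas.sort_values(PAS_KEY, kind="mergesort").reset_index(drop=True)
    new_group = (
        (pas["chrom"] != pas["chrom"].shift())
        | (pas["strand"] != pas["strand"].shift())
        | ((pas["position"] - pas["position"].shift()) > params.cluster_gap)
    )
    cluster_idx = new_group.cumsum()

    rows = []
    for _cid, members in pas.groupby(cluster_idx, sort=False):
        strand = members["strand"].iloc[0]
        rep = pick_representative(members["position"].to_numpy(),
                                  members[samples].sum(axis=1).to_numpy(), strand)
        totals = members[samples].sum(axis=0)
        row = {
            "chrom": members["chrom"].iloc[0],
            "strand": strand,
            "start": int(members["position"].min()),
            "end": int(members["position"].max()) + 1,
            "representative": rep,
            "n_sites": len(members),
            "total": int(totals.sum()),
        }
        row.update({s: int(totals[s]) for s in samples})
        rows.append(row)
    pacs = pd.DataFrame(rows).sort_values(["chrom", "strand", "start"], kind="mergesort")
    pacs = pacs.reset_index(drop=True)
    pacs.insert(0, "pac_id", [f"PAC{i + 1:05d}" for i in range(len(pacs))])
    return pacs


def pick_representative(positions: np.ndarray, totals: np.ndarray, strand: str) -> int:
    """Member position with the highest total count; ties go 3'-most.

    On the + strand 3'-most is the largest coordinate, on the - strand the
    smallest (transcription runs toward lower coordinates).
    """
    positions = np.asarray(positions)
    totals = np.asarray(totals)
    best = totals == totals.max()
    candidates = positions[best]
    return int(candidates.max() if strand == "+" else candidates.min())


def filter_pacs(pacs: pd.DataFrame, params: PacParams) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop PACs supported by fewer than ``min_pac_reads`` reads over all samples.

    Returns (retained, discarded); a PAC totalling exactly the threshold is
    retained ("fewer than" is strict).
    """
    keep = pacs["total"] >= params.min_pac_reads
    return pacs[keep].reset_index(drop=True), pacs[~keep].reset_index(drop=True)


def build_pacs(tags: pd.DataFrame, genome: Dict[str, str], samples: Sequence[str],
               params: PacParams | None = None) -> Dict[str, pd.DataFrame]:
    """Full PAS->PAC stage; returns all intermediate tables for audit.

    Keys: ``pas`` (all PAS), ``pas_ip_removed``, ``pas_retained``,
    ``pacs_all`` (pre support filter), ``pacs`` (final), ``pacs_low_support``.
    """
    params = params or PacParams()
    pas = build_pas(tags, samples)
    retained, removed = filter_internal_priming(pas, genome, params)
    pacs_all = cluster_pas(retained, params, samples)
    pacs, low = filter_pacs(pacs_all, params)
    return {
        "pas": pas,
        "pas_ip_removed": removed,
        "pas_retained": retained,
        "pacs_all": pacs_all,
        "pacs": pacs,
        "pacs_low_support": low,
    }
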