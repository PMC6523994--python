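"""Nucleotide-composition profiles around PAC representative positions.

For each PAC the transcript-strand sequence covering positions -300..+99
relative to the cleavage base (index 0 = last transcribed base; 400 nt
total) is extracted — reverse-complemented for minus-strand PACs — and
per-position base fractions are computed over all sites. Positions falling
off the chromosome are masked, not zero-filled, and excluded from the
denominators. Profiles of 3'UTR PACs recover the A-rich near-upstream
element characteristic of plant poly(A) signals.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .util import revcomp

UPSTREAM = 300   # bases upstream of the cleavage base (negative indices)
DOWNSTREAM = 100  # bases at and downstream of +1

BASES = ("A", "C", "G", "T")


def extract_windows(
    pacs: pd.DataFrame,
    genome: Dict[str, str],
    region: Optional[str] = None,
    upstream: int = UPSTREAM,
    downstream: int = DOWNSTREAM,
) -> List[str]:
    """Oriented windows of ``upstream + downstream`` nt per PAC.

    Index 0 of each window sits at relative position ``-upstream``; the
    cleavage base is at index ``upstream``. Off-chromosome positions are
    masked with 'N'. ``region`` filters on the PAC region label when given.
    """
    if region is not None:
        pacs = pacs[pacs["region"] == region]
    windows = []
    for row in pacs.itertuples():
        seq = genome[row.chrom]
        p = int(row.representative)
        if row.strand == "+":
            lo, hi = p - upstream, p + downstream
            left_pad = max(0, -lo)
            right_pad = max(0, hi - len(seq))
            core = seq[max(0, lo): min(len(seq), hi)]
            win = "N" * left_pad + core + "N" * right_pad
        else:
            lo, hi = p - downstream + 1, p + upstream + 1
            left_pad = max(0, -lo)
            right_pad = max(0, hi - len(seq))
            core = seq[max(0, lo): min(len(seq), hi)]
            win = revcomp("N" * left_pad + core + "N" * right_pad)
        windows.append(win)
    return windows


def composition(
    windows: Sequence[str],
    region: str = "all",
    upstream: int = UPSTREAM,
) -> pd.DataFrame:
    """Per-position base fractions over a set of oriented windows.

    Returns a long-format frame (region, position, base, fraction, n) where
    ``position`` runs from ``-upstream`` and ``n`` counts the unmasked
    windows covering that position. Fractions at every covered position sum
    to 1; uncovered positions are omitted.
    """
    if not windows:
        raise ValueError("composition requires at least one window")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("all windows must have equal length")
    mat = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8)
    mat = mat.reshape(len(windows), width)
    rows = []
    for col in range(width):
        column = mat[:, col]
        counts = {b: int((column == ord(b)).sum()) for b in BASES}
        n = sum(counts.values())
        if n == 0:
            continue
        for b in BASES:
            rows.append((region, col - upstream, b, counts[b] / n, n))
    return pd.DataFrame(rows, columns=["region", "position", "base", "fraction", "n"])


def region_profiles(
    annotated_pacs: pd.DataFrame,
    genome: Dict[str, str],
    regions: Sequence[str] = ("3UTR", "CDS", "intergenic"),
) -> pd.DataFrame:
    """Composition profiles stratified by PAC region label, concatenated long-form."""
    frames = []
    for region in regions:
        windows = extract_windows(annotated_pacs, genome, region=region)
        if windows:
            frames.append(composition(windows, region=region))
    if not frames:
        return pd.DataFrame(columns=["region", "position", "base", "fraction", "n"])
    return pd.concat(frames, ignore_index=True)
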