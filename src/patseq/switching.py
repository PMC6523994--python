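"""Poly(A)-site switching detection between two sample groups.

For every gene carrying at least two PACs, every unordered PAC pair
(PA1, PA2) is evaluated against five criteria; a pair — and hence the gene —
is called switching only if all enabled criteria hold:

1. at least one of PA1/PA2 has a read count >= 5 in each of the two samples;
2. at least one of PA1/PA2 has a total read count across all samples >= 20;
3. PA1/PA2 >= 2 in one sample and PA2/PA1 >= 2 in the other (a reciprocal
   usage flip); a zero denominator counts as an infinite ratio when the
   numerator is positive, and 0/0 fails;
4. |PA1 - PA2| > 5 (strictly) within each of the two samples;
5. at least one of PA1/PA2 was called a significant DE-PAC in the same
   comparison (optional, on by default).

"Sample" here means the replicate-summed count of one side of the
comparison; an optional per-replicate mode instead requires criteria 1, 3
and 4 to hold in every replicate pairing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class SwitchParams:
    min_count_each_sample: int = 5   # criterion 1 (>=)
    min_total_count: int = 20        # criterion 2 (>=)
    min_ratio: float = 2.0           # criterion 3 (>=)
    min_abs_diff: int = 5            # criterion 4 (strict >)
    require_de_pac: bool = True      # criterion 5 toggle
    total_pair_only: bool = False    # criterion 2 totals over the pair's groups only
    per_replicate: bool = False      # criteria 1/3/4 must hold in every replicate pair

    def validate(self) -> List[str]:
        bad = [f for f in ("min_count_each_sample", "min_total_count",
                           "min_ratio", "min_abs_diff") if getattr(self, f) <= 0]
        return [f"{f} must be positive" for f in bad]


@dataclass
class SwitchEvent:
    gene_id: str
    pa1: str
    pa2: str
    sample_a: str
    sample_b: str
    counts_pa1: Tuple[float, float]  # (sample_a, sample_b)
    counts_pa2: Tuple[float, float]
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    verdict: bool
    direction: Optional[str] = None  # proximal_to_distal / distal_to_proximal

    def as_dict(self) -> Dict:
        d = {
            "gene_id": self.gene_id, "pa1": self.pa1, "pa2": self.pa2,
            "sample_a": self.sample_a, "sample_b": self.sample_b,
            "pa1_count_a": self.counts_pa1[0], "pa1_count_b": self.counts_pa1[1],
            "pa2_count_a": self.counts_pa2[0], "pa2_count_b": self.counts_pa2[1],
            "c1": self.c1, "c2": self.c2, "c3": self.c3, "c4": self.c4,
            "c5": self.c5, "verdict": self.verdict, "direction": self.direction,
        }
        return d


def _ratio_ge(num: float, den: float, threshold: float) -> bool:
    """num/den >= threshold with the zero conventions (x/0 = inf for x>0; 0/0 fails)."""
    if den == 0:
        return num > 0
    return num / den >= threshold


def evaluate_pair(
    counts_pa1: Mapping[str, float],
    counts_pa2: Mapping[str, float],
    sample_a: str,
    sample_b: str,
    params: SwitchParams,
    de_flags: Tuple[bool, bool] = (True, True),
) -> SwitchEvent:
    """Evaluate the five switching criteria for one PAC pair.

    ``counts_pa1``/``counts_pa2`` map every sample (group) in the dataset to
    a read count — criterion 2 sums over all of them unless
    ``total_pair_only``. ``de_flags`` says whether PA1/PA2 were significant
    DE-PACs in this comparison.
    """
    for v in list(counts_pa1.values()) + list(counts_pa2.values()):
        if v < 0:
            raise ValueError("negative read count")
    a1, b1 = counts_pa1[sample_a], counts_pa1[sample_b]
    a2, b2 = counts_pa2[sample_a], counts_pa2[sample_b]
    thr = params.min_count_each_sample
    c1 = (a1 >= thr and b1 >= thr) or (a2 >= thr and b2 >= thr)
    if params.total_pair_only:
        tot1, tot2 = a1 + b1, a2 + b2
    else:
        tot1, tot2 = sum(counts_pa1.values()), sum(counts_pa2.values())
    c2 = tot1 >= params.min_total_count or tot2 >= params.min_total_count
    r = params.min_ratio
    c3 = (_ratio_ge(a1, a2, r) and _ratio_ge(b2, b1, r)) or (
        _ratio_ge(b1, b2, r) and _ratio_ge(a2, a1, r)
    )
    c4 = abs(a1 - a2) > params.min_abs_diff and abs(b1 - b2) > params.min_abs_diff
    c5 = (de_flags[0] or de_flags[1]) if params.require_de_pac else True
    enabled = [c1, c2, c3, c4] + ([c5] if params.require_de_pac else [])
    return SwitchEvent(
        gene_id="", pa1="", pa2="", sample_a=sample_a, sample_b=sample_b,
        counts_pa1=(a1, b1), counts_pa2=(a2, b2),
        c1=c1, c2=c2, c3=c3, c4=c4, c5=c5, verdict=all(enabled),
    )


def candidate_genes(annotated_pacs: pd.DataFrame) -> pd.DataFrame:
    """Restrict to genes carrying at least two PACs (the switching candidates)."""
    genic = annotated_pacs[annotated_pacs["gene_id"].notna()]
    n_pacs = genic.groupby("gene_id")["pac_id"].transform("size")
    return genic[n_pacs >= 2].reset_index(drop=True)


def _direction(pos1: int, pos2: int, strand: str,
               a1: float, b1: float, a2: float, b2: float) -> Optional[str]:
    """Direction of the usage shift from sample A to sample B.

    The proximal site is the 5'-most in transcription direction (closer to
    the stop codon). Returns None when usage shares are undefined or flat.
    """
    if strand == "+":
        pa1_proximal = pos1 < pos2
    else:
        pa1_proximal = pos1 > pos2
    prox_a, dist_a = (a1, a2) if pa1_proximal else (a2, a1)
    prox_b, dist_b = (b1, b2) if pa1_proximal else (b2, b1)
    tot_a, tot_b = prox_a + dist_a, prox_b + dist_b
    if tot_a == 0 or tot_b == 0:
        return None
    share_a, share_b = prox_a / tot_a, prox_b / tot_b
    if share_b < share_a:
        return "proximal_to_distal"
    if share_b > share_a:
        return "distal_to_proximal"
    return None


def detect_switching(
    annotated_pacs: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    comparison: Tuple[str, str],
    params: Optional[SwitchParams] = None,
    de_pac_results: Optional[pd.DataFrame] = None,
) -> List[SwitchEvent]:
    """Evaluate every PAC pair of every candidate gene for one comparison.

    ``sample_sheet`` needs columns sample/group; counts are summed over each
    group's replicates before the criteria are applied. ``de_pac_results``
    is the per-PAC differential table for the same comparison (indexed by
    pac_id, with a ``significant`` column); required unless
    ``params.require_de_pac`` is False. Events are sorted by gene then pair.
    """
    params = params or SwitchParams()
    group_a, group_b = comparison
    groups = sample_sheet.groupby("group")["sample"].apply(list).to_dict()
    for g in comparison:
        if g not in groups:
            raise ValueError(f"comparison group {g!r} absent from sample sheet")
    if params.require_de_pac and de_pac_results is None:
        raise ValueError("de_pac_results required when require_de_pac is True")

    pacs = candidate_genes(annotated_pacs)
    all_groups = list(groups)
    group_counts = {
        g: pacs[samples].sum(axis=1).to_numpy() for g, samples in groups.items()
    }
    de_sig: Dict[str, bool] = {}
    if de_pac_results is not None:
        de_sig = de_pac_results["significant"].to_dict()

    events: List[SwitchEvent] = []
    for gene_id, idx in pacs.groupby("gene_id", sort=True).groups.items():
        rows = pacs.loc[idx]
        order = np.argsort(rows["pac_id"].to_numpy())
        for i, j in itertools.combinations(order, 2):
            r1, r2 = rows.iloc[i], rows.iloc[j]
            counts1 = {g: float(group_counts[g][r1.name]) for g in all_groups}
            counts2 = {g: float(group_counts[g][r2.name]) for g in all_groups}
            de = (bool(de_sig.get(r1.pac_id, False)), bool(de_sig.get(r2.pac_id, False)))
            ev = evaluate_pair(counts1, counts2, group_a, group_b, params, de)
            if params.per_replicate:
                agree = _replicate_agreement(r1, r2, groups[group_a], groups[group_b], params)
                ev.c1, ev.c3, ev.c4 = agree
                enabled = [ev.c1, ev.c2, ev.c3, ev.c4] + (
                    [ev.c5] if params.require_de_pac else [])
                ev.verdict = all(enabled)
            ev.gene_id = gene_id
            ev.pa1, ev.pa2 = r1.pac_id, r2.pac_id
            ev.direction = _direction(
                int(r1.representative), int(r2.representative), r1.strand,
                *ev.counts_pa1, *ev.counts_pa2,
            )
            events.append(ev)
    events.sort(key=lambda e: (e.gene_id, e.pa1, e.pa2))
    return events


def _replicate_agreement(r1, r2, samples_a: Sequence[str], samples_b: Sequence[str],
                         params: SwitchParams) -> Tuple[bool, bool, bool]:
    """Criteria 1/3/4 evaluated on every replicate pairing; all must agree."""
    c1 = c3 = c4 = True
    thr, ratio, diff = params.min_count_each_sample, params.min_ratio, params.min_abs_diff
    for sa in samples_a:
        for sb in samples_b:
            a1, b1 = float(r1[sa]), float(r1[sb])
            a2, b2 = float(r2[sa]), float(r2[sb])
            c1 &= (a1 >= thr and b1 >= thr) or (a2 >= thr and b2 >= thr)
            c3 &= (_ratio_ge(a1, a2, ratio) and _ratio_ge(b2, b1, ratio)) or (
                _ratio_ge(b1, b2, ratio) and _ratio_ge(a2, a1, ratio))
            c4 &= abs(a1 - a2) > diff and abs(b1 - b2) > diff
    return c1, c3, c4


def switching_genes(events: Sequence[SwitchEvent]) -> List[str]:
    """Genes with at least one switching pair, sorted."""
    return sorted({e.gene_id for e in events if e.verdict})


def events_table(events: Sequence[SwitchEvent]) -> pd.DataFrame:
    cols = ["gene_id", "pa1", "pa2", "sample_a", "sample_b",
            "pa1_count_a", "pa1_count_b", "pa2_count_a", "pa2_count_b",
            "c1", "c2", "c3", "c4", "c5", "verdict", "direction"]
    return pd.DataFrame([e.as_dict() for e in events], columns=cols)
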