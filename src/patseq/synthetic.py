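"""Synthetic PAT-Seq data generator.

Builds toy genomes with annotated gene models, plants known poly(A)-site
architectures (including reciprocal-usage "switching" genes and A-rich
internal-priming decoy tracts), and simulates oligo-dT-primed poly(A)-tag
reads with full ground truth, so every downstream stage of the pipeline can
be validated by parameter recovery.

Coordinate convention used throughout the package: a cleavage position is the
0-based genomic coordinate of the last transcribed base before the poly(A)
tail. On the + strand this is the 3'-most aligned base; on the - strand it is
the 5'-most (lowest) genomic coordinate of the alignment, with the transcript
running toward lower coordinates.

Gene loci are laid out on a fixed grid: 200 nt upstream flank, 100 nt 5'UTR,
600 nt CDS, 200 nt 3'UTR, 500 nt downstream flank (1,600 nt per locus).
Single-exon models keep the toy mapper exact; the grid guarantees that the
120-nt 3'UTR extension and the -300..+100 composition windows never collide
with a neighbouring gene.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .util import revcomp

# locus geometry (nt)
FLANK5 = 200
UTR5_LEN = 100
CDS_LEN = 600
UTR3_LEN = 200
FLANK3 = 500
LOCUS_LEN = FLANK5 + UTR5_LEN + CDS_LEN + UTR3_LEN + FLANK3

MIN_SITE_SEPARATION = 50  # nt between sites of one gene, so jittered tags cluster apart
DECOY_TRACT_LEN = 10      # consecutive A on the transcript strand
SIGNAL_ELEMENT = "AATAAA"  # near-upstream element planted ~25-30 nt before 3'UTR sites
SIGNAL_OFFSET = -30        # transcript offset of the element start relative to the site

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of one simulated PAT-Seq experiment.

    Expression is negative-binomial per gene and replicate with
    ``var = mu + dispersion * mu**2``; site usage within a gene is a
    Dirichlet draw shared across conditions, except for planted switching
    genes which get the deterministic reciprocal usage pair ``switch_flip``.
    """

    n_genes: int = 200
    genome_length: Optional[int] = None  # per chromosome; auto-sized when None
    n_chromosomes: int = 2
    n_sites_per_gene: Tuple[int, int] = (1, 3)
    # proportions over (3UTR, CDS, intergenic-downstream)
    site_region_mix: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    expression_mean: float = 200.0
    expression_dispersion: float = 0.1
    usage_concentration: float = 5.0
    n_switch_genes: int = 10
    switch_flip: Tuple[float, float] = (0.8, 0.2)
    conditions: Tuple[str, ...] = ("A", "B")
    replicates_per_condition: int = 3
    cleavage_jitter_sd: float = 2.0
    internal_priming_rate: float = 0.0
    decoy_fraction: float = 0.5
    read_length: int = 50
    polyt_range: Tuple[int, int] = (10, 16)
    no_dt_fraction: float = 0.0
    low_quality_fraction: float = 0.0
    seed: int = 0

    def samples(self) -> List[Tuple[str, str, int]]:
        """(sample_id, condition, replicate) triples, in emission order."""
        out = []
        for cond in self.conditions:
            for r in range(1, self.replicates_per_condition + 1):
                out.append((f"{cond}_{r}", cond, r))
        return out

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples(), columns=["sample", "group", "replicate"])

    def validate(self) -> List[str]:
        """Return a list of invariant violations (empty = valid)."""
        v = []
        if self.n_genes < 1:
            v.append("n_genes must be positive")
        if self.n_chromosomes < 1:
            v.append("n_chromosomes must be positive")
        lo, hi = self.n_sites_per_gene
        if not (1 <= lo <= hi <= 3):
            v.append("n_sites_per_gene must be a range within [1, 3]")
        if abs(sum(self.site_region_mix) - 1.0) > 1e-9:
            v.append("site_region_mix must sum to 1")
        if any(p < 0 for p in self.site_region_mix):
            v.append("site_region_mix proportions must be non-negative")
        if self.expression_mean <= 0:
            v.append("expression_mean must be positive")
        if self.expression_dispersion < 0:
            v.append("expression_dispersion must be non-negative")
        if self.usage_concentration <= 0:
            v.append("usage_concentration must be positive")
        if not 0 <= self.n_switch_genes <= self.n_genes:
            v.append("n_switch_genes must lie in [0, n_genes]")
        if abs(sum(self.switch_flip) - 1.0) > 1e-9:
            v.append("switch_flip proportions must sum to 1")
        if len(self.conditions) < 1:
            v.append("at least one condition required")
        if len(set(self.conditions)) != len(self.conditions):
            v.append("condition names must be unique")
        if self.replicates_per_condition < 1:
            v.append("replicates_per_condition must be positive")
        if self.cleavage_jitter_sd < 0:
            v.append("cleavage_jitter_sd must be >= 0")
        for name in ("internal_priming_rate", "decoy_fraction",
                     "no_dt_fraction", "low_quality_fraction"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                v.append(f"{name} must lie in [0, 1]")
        if self.read_length < 25:
            v.append("read_length must be >= 25")
        if not (8 <= self.polyt_range[0] <= self.polyt_range[1] <= 20):
            v.append("polyt_range must lie within [8, 20]")
        return v


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated data."""

    genes: pd.DataFrame   # gene_id, chrom, strand, start, end, locus_start, locus_end, switch
    sites: pd.DataFrame   # gene_id, site_idx, chrom, strand, position, region, usage_<cond>...
    decoys: pd.DataFrame  # gene_id, chrom, strand, tract_start, tract_end, cleavage_pos
    tags: Optional[pd.DataFrame] = None  # filled in by simulate_tags

    def to_tsv(self, prefix: str) -> None:
        self.genes.to_csv(f"{prefix}.genes.tsv", sep="\t", index=False)
        self.sites.to_csv(f"{prefix}.sites.tsv", sep="\t", index=False)
        self.decoys.to_csv(f"{prefix}.decoys.tsv", sep="\t", index=False)
        if self.tags is not None:
            self.tags.to_csv(f"{prefix}.tags.tsv", sep="\t", index=False)


class SizingError(ValueError):
    """genome_length too small to host the requested genes."""


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _break_runs(arr: np.ndarray, base: int, max_run: int, rng: np.random.Generator) -> None:
    """Cap homopolymer runs of `base` at `max_run` by substituting in place."""
    mask = arr == base
    if not mask.any():
        return
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    others = _BASES[_BASES != base]
    for s, e in zip(starts, ends):
        for pos in range(s + max_run, e, max_run + 1):
            arr[pos] = rng.choice(others)


def _tx_coord(strand: str, anchor: int, offset: int) -> int:
    """Genomic coordinate at transcript-direction `offset` from `anchor`."""
    return anchor + offset if strand == "+" else anchor - offset


def _write_tx_base(arr: np.ndarray, strand: str, anchor: int, offset: int, base: str) -> None:
    coord = _tx_coord(strand, anchor, offset)
    b = base if strand == "+" else revcomp(base)
    arr[coord] = ord(b)


def _read_tx_base(arr: np.ndarray, strand: str, anchor: int, offset: int) -> str:
    coord = _tx_coord(strand, anchor, offset)
    ch = chr(arr[coord])
    return ch if strand == "+" else revcomp(ch)


def generate_genome(config: SimConfig):
    """Build the toy genome, gene models and poly(A)-site ground truth.

    Returns ``(genome, gff3_text, truth)`` where genome is a
    {chrom: sequence} dict and gff3_text a GFF3 document (1-based inclusive
    coordinates) with gene/mRNA/five_prime_UTR/CDS/three_prime_UTR features.

    The background sequence is i.i.d. uniform over ACGT with all A- and
    T-homopolymers capped at 4 nt, so the only sequences that can trip the
    internal-priming filter are the decoy tracts planted on purpose. The
    50 nt of transcript-strand sequence surrounding each true cleavage site
    (offsets -12..+40) are redrawn A-depleted (P(A)=0.15, and the three bases
    at offsets -2..0 are never A) so that a tag's mapped 3' end identifies
    its cleavage site without poly(A)-tail ambiguity.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid SimConfig: " + "; ".join(problems))
    rng = np.random.default_rng([config.seed % (2**31), 11])

    # genes per chromosome, round-robin remainder
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    per_chrom = [n for n in per_chrom if n > 0]

    need = max(per_chrom) * LOCUS_LEN + 200
    chrom_len = config.genome_length if config.genome_length is not None else need
    if chrom_len < need:
        raise SizingError(
            f"genome_length={chrom_len} cannot host {max(per_chrom)} gene loci "
            f"({need} nt required per chromosome)"
        )

    switch_ids = set(rng.choice(config.n_genes, size=config.n_switch_genes, replace=False).tolist())
    decoy_mask = rng.random(config.n_genes) < config.decoy_fraction

    chroms: Dict[str, np.ndarray] = {}
    for ci, n in enumerate(per_chrom):
        arr = _BASES[rng.integers(0, 4, size=chrom_len)].copy()
        _break_runs(arr, ord("A"), 4, rng)
        _break_runs(arr, ord("T"), 4, rng)
        chroms[f"chr{ci + 1}"] = arr

    gene_rows, site_rows, decoy_rows = [], [], []
    lo_sites, hi_sites = config.n_sites_per_gene
    gidx = 0
    for ci, n in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        arr = chroms[chrom]
        for j in range(n):
            locus = 100 + j * LOCUS_LEN
            gene_id = f"g{gidx + 1:04d}"
            strand = "+" if gidx % 2 == 0 else "-"
            if strand == "+":
                gstart = locus + FLANK5
                gend = gstart + UTR5_LEN + CDS_LEN + UTR3_LEN
                utr5 = (gstart, gstart + UTR5_LEN)
                cds = (utr5[1], utr5[1] + CDS_LEN)
                utr3 = (cds[1], gend)
                tes = gend - 1  # 3'-most transcribed base
            else:
                gstart = locus + FLANK3
                gend = gstart + UTR3_LEN + CDS_LEN + UTR5_LEN
                utr3 = (gstart, gstart + UTR3_LEN)
                cds = (utr3[1], utr3[1] + CDS_LEN)
                utr5 = (cds[1], gend)
                tes = gstart  # transcription runs toward lower coordinates

            is_switch = gidx in switch_ids
            # --- site placement, as transcript offsets from the 3'UTR start
            # offsets measured from the gene's annotated TES toward 5' (negative)
            # or into the downstream flank (positive)
            if is_switch:
                n_sites = 2
                # two 3'UTR sites 150 nt apart
                utr_offsets = [-(UTR3_LEN - 20), -(UTR3_LEN - 170)]
                regions = ["3UTR", "3UTR"]
                offs = utr_offsets
            else:
                n_sites = int(rng.integers(lo_sites, hi_sites + 1))
                regions = list(rng.choice(["3UTR", "CDS", "intergenic"], size=n_sites,
                                          p=np.asarray(config.site_region_mix)))
                offs = _draw_site_offsets(regions, rng)
            positions = [_tx_coord(strand, tes, o) for o in offs]

            # usage proportions per condition
            if is_switch:
                # order sites proximal->distal in transcript direction
                order = np.argsort([offs[k] for k in range(n_sites)])
                usage = {}
                u0 = np.zeros(n_sites)
                u0[order[0]], u0[order[1]] = config.switch_flip
                u1 = np.zeros(n_sites)
                u1[order[0]], u1[order[1]] = config.switch_flip[::-1]
                for k, cond in enumerate(config.conditions):
                    usage[cond] = u0 if k % 2 == 0 else u1
            else:
                u = rng.dirichlet([config.usage_concentration] * n_sites)
                usage = {cond: u for cond in config.conditions}

            # --- sanitize cleavage context so tag 3' ends map back exactly
            for p in positions:
                for off in range(-12, 41):
                    if -2 <= off <= 0:
                        base = "CGT"[rng.integers(0, 3)]
                    else:
                        base = "ACGT"[rng.choice(4, p=[0.15, 0.2833, 0.2833, 0.2834])]
                    _write_tx_base(arr, strand, p, off, base)

            # --- near-upstream A-rich element for 3'UTR sites
            for p, reg in zip(positions, regions):
                if reg == "3UTR":
                    for k, b in enumerate(SIGNAL_ELEMENT):
                        _write_tx_base(arr, strand, p, SIGNAL_OFFSET + k, b)

            # --- internal-priming decoy tract in the CDS
            if decoy_mask[gidx]:
                d_off = _draw_decoy_offset(offs, rng)
                # transcript offsets of the tract: [d_off, d_off + 10)
                for k in range(DECOY_TRACT_LEN):
                    _write_tx_base(arr, strand, tes, d_off + k, "A")
                # keep the 3 bases 5' of the tract non-A for unambiguous trimming,
                # and 2 bases 3' non-A so the tract length is exactly as planted
                for k in range(1, 4):
                    _write_tx_base(arr, strand, tes, d_off - k, "CGT"[rng.integers(0, 3)])
                for k in range(DECOY_TRACT_LEN, DECOY_TRACT_LEN + 2):
                    _write_tx_base(arr, strand, tes, d_off + k, "CGT"[rng.integers(0, 3)])
                cleave = _tx_coord(strand, tes, d_off - 1)
                g0 = _tx_coord(strand, tes, d_off)
                g1 = _tx_coord(strand, tes, d_off + DECOY_TRACT_LEN - 1)
                decoy_rows.append({
                    "gene_id": gene_id, "chrom": chrom, "strand": strand,
                    "tract_start": min(g0, g1), "tract_end": max(g0, g1) + 1,
                    "cleavage_pos": cleave,
                })

            gene_rows.append({
                "gene_id": gene_id, "chrom": chrom, "strand": strand,
                "start": gstart, "end": gend,
                "utr5_start": utr5[0], "utr5_end": utr5[1],
                "cds_start": cds[0], "cds_end": cds[1],
                "utr3_start": utr3[0], "utr3_end": utr3[1],
                "locus_start": locus, "locus_end": locus + LOCUS_LEN,
                "switch": is_switch,
            })
            for k, (p, reg) in enumerate(zip(positions, regions)):
                row = {"gene_id": gene_id, "site_idx": k, "chrom": chrom,
                       "strand": strand, "position": p, "region": reg}
                for cond in config.conditions:
                    row[f"usage_{cond}"] = float(usage[cond][k])
                site_rows.append(row)
            gidx += 1

    genome = {c: chroms[c].tobytes().decode("ascii") for c in chroms}
    truth = SimTruth(
        genes=pd.DataFrame(gene_rows),
        sites=pd.DataFrame(site_rows),
        decoys=pd.DataFrame(decoy_rows, columns=[
            "gene_id", "chrom", "strand", "tract_start", "tract_end", "cleavage_pos"]),
    )
    return genome, _render_gff3(truth.genes, {c: len(genome[c]) for c in genome}), truth


def _draw_site_offsets(regions: Sequence[str], rng: np.random.Generator) -> List[int]:
    """Transcript offsets (relative to the TES) for each requested region.

    3'UTR sites land 30-170 nt into the UTR; CDS sites 50-550 nt into the
    CDS; intergenic sites 150-300 nt past the TES (beyond the 120-nt
    annotation extension). Rejection-sample until all pairwise separations
    are >= MIN_SITE_SEPARATION, with a deterministic fallback spread.
    """
    windows = {
        "3UTR": (-(UTR3_LEN - 30), -30),
        "CDS": (-(UTR3_LEN + CDS_LEN - 50), -(UTR3_LEN + 50)),
        "intergenic": (150, 300),
    }
    for _ in range(200):
        offs = [int(rng.integers(*windows[r])) for r in regions]
        ok = all(abs(a - b) >= MIN_SITE_SEPARATION
                 for i, a in enumerate(offs) for b in offs[i + 1:])
        if ok:
            return offs
    # fallback: spread evenly within each region window
    offs = []
    seen: Dict[str, int] = {}
    for r in regions:
        k = seen.get(r, 0)
        lo, hi = windows[r]
        offs.append(lo + (k + 1) * (hi - lo) // (regions.count(r) + 1))
        seen[r] = k + 1
    return offs


def _draw_decoy_offset(site_offsets: Sequence[int], rng: np.random.Generator) -> int:
    """Transcript offset (from TES) of a decoy tract start, >= 60 nt from any site."""
    lo = -(UTR3_LEN + CDS_LEN - 60)
    hi = -(UTR3_LEN + 60)
    for _ in range(200):
        d = int(rng.integers(lo, hi))
        if all(abs(d - s) >= 60 and abs(d + DECOY_TRACT_LEN - s) >= 60 for s in site_offsets):
            return d
    return lo + 5  # deep in the CDS 5' end, guaranteed clear of 3'UTR sites


def _render_gff3(genes: pd.DataFrame, chrom_sizes: Dict[str, int]) -> str:
    """GFF3 text (1-based inclusive) for the simulated gene models."""
    out = io.StringIO()
    out.write("##gff-version 3\n")
    for c, n in chrom_sizes.items():
        out.write(f"##sequence-region {c} 1 {n}\n")
    for g in genes.itertuples():
        s, e = g.start + 1, g.end  # 0-based half-open -> 1-based inclusive
        common = f"{g.chrom}\tpatseq_sim"
        out.write(f"{common}\tgene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
        mrna = f"{g.gene_id}.1"
        out.write(f"{common}\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
        feats = [
            ("five_prime_UTR", g.utr5_start, g.utr5_end, "."),
            ("CDS", g.cds_start, g.cds_end, "0"),
            ("three_prime_UTR", g.utr3_start, g.utr3_end, "."),
        ]
        feats.sort(key=lambda f: f[1])
        for i, (ftype, fs, fe, frame) in enumerate(feats):
            out.write(
                f"{common}\t{ftype}\t{fs + 1}\t{fe}\t.\t{g.strand}\t{frame}\t"
                f"ID={mrna}.{ftype}.{i};Parent={mrna}\n"
            )
    return out.getvalue()


# ---------------------------------------------------------------------------
# tag simulation
# ---------------------------------------------------------------------------

def simulate_tags(genome: Dict[str, str], truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Simulate mapped poly(A) tags for every sample; fills ``truth.tags``.

    Per gene and replicate the total tag count is NB(mean, dispersion),
    split over the gene's sites by a multinomial on that condition's usage
    vector. Cleavage positions get rounded N(0, jitter_sd) offsets clamped
    to the gene locus. A fraction ``internal_priming_rate`` of tags is then
    re-assigned to a random decoy tract (cleavage immediately 5' of the
    tract) and marked as internal-priming artifacts in the truth table.
    """
    rng = np.random.default_rng([config.seed % (2**31), 23])
    sites = truth.sites
    genes = truth.genes.set_index("gene_id")
    decoys = truth.decoys
    disp = config.expression_dispersion
    mu = config.expression_mean
    rows: List[pd.DataFrame] = []
    tag_counter = 0
    site_groups = {g: df for g, df in sites.groupby("gene_id", sort=False)}

    for sample, cond, _rep in config.samples():
        for gene_id, gsites in site_groups.items():
            if disp > 0:
                r = 1.0 / disp
                total = int(rng.negative_binomial(r, r / (r + mu)))
            else:
                total = int(rng.poisson(mu))
            if total == 0:
                continue
            usage = gsites[f"usage_{cond}"].to_numpy(dtype=float)
            usage = usage / usage.sum()
            alloc = rng.multinomial(total, usage)
            g = genes.loc[gene_id]
            pos_list, site_idx_list = [], []
            for site_row, n_k in zip(gsites.itertuples(), alloc):
                if n_k == 0:
                    continue
                p = np.full(n_k, site_row.position, dtype=np.int64)
                if config.cleavage_jitter_sd > 0:
                    p = p + np.rint(rng.normal(0, config.cleavage_jitter_sd, size=n_k)).astype(np.int64)
                    p = np.clip(p, g.locus_start, g.locus_end - 1)
                pos_list.append(p)
                site_idx_list.append(np.full(n_k, site_row.site_idx, dtype=np.int64))
            pos = np.concatenate(pos_list)
            site_idx = np.concatenate(site_idx_list)
            n = len(pos)
            df = pd.DataFrame({
                "tag_id": np.arange(tag_counter, tag_counter + n),
                "sample": sample,
                "condition": cond,
                "gene_id": gene_id,
                "site_idx": site_idx,
                "chrom": g.chrom,
                "strand": g.strand,
                "position": pos,
                "artifact": False,
            })
            tag_counter += n
            rows.append(df)

    tags = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["tag_id", "sample", "condition", "gene_id", "site_idx",
                 "chrom", "strand", "position", "artifact"])

    if config.internal_priming_rate > 0 and len(decoys) > 0 and len(tags) > 0:
        hit = rng.random(len(tags)) < config.internal_priming_rate
        which = rng.integers(0, len(decoys), size=int(hit.sum()))
        d = decoys.iloc[which]
        tags.loc[hit, "chrom"] = d["chrom"].to_numpy()
        tags.loc[hit, "strand"] = d["strand"].to_numpy()
        tags.loc[hit, "position"] = d["cleavage_pos"].to_numpy()
        tags.loc[hit, "gene_id"] = d["gene_id"].to_numpy()
        tags.loc[hit, "site_idx"] = -1
        tags.loc[hit, "artifact"] = True

    truth.tags = tags
    return tags


# ---------------------------------------------------------------------------
# read / tag emission
# ---------------------------------------------------------------------------

def emit_fastq(tags: pd.DataFrame, genome: Dict[str, str], config: SimConfig) -> Dict[str, str]:
    """Render tags as oligo-dT-primed FASTQ text, one entry per sample.

    Each read is sequenced from the poly(A) end: a poly(T) prefix (the
    reverse-complemented tail) followed by the reverse complement of the
    transcript-strand sequence upstream of and including the cleavage base.
    ``no_dt_fraction`` of reads omit the poly(T) prefix and
    ``low_quality_fraction`` carry uniformly low (Q2) qualities, to exercise
    the preprocessing discard rules.
    """
    rng = np.random.default_rng([config.seed % (2**31), 37])
    lo_t, hi_t = config.polyt_range
    out: Dict[str, str] = {}
    for sample, _cond, _rep in config.samples():
        sub = tags[tags["sample"] == sample]
        buf = io.StringIO()
        n = len(sub)
        t_lens = rng.integers(lo_t, hi_t + 1, size=n)
        no_dt = rng.random(n) < config.no_dt_fraction
        low_q = rng.random(n) < config.low_quality_fraction
        for i, row in enumerate(sub.itertuples()):
            chrom_seq = genome[row.chrom]
            t_len = 0 if no_dt[i] else int(t_lens[i])
            ctx_len = config.read_length - t_len
            upstream = _upstream_context(chrom_seq, row.strand, row.position, ctx_len)
            seq = "T" * t_len + revcomp(upstream)
            qual = ("#" if low_q[i] else "I") * len(seq)
            buf.write(f"@{sample}:{row.tag_id}\n{seq}\n+\n{qual}\n")
        out[sample] = buf.getvalue()
    return out


def _upstream_context(chrom_seq: str, strand: str, position: int, length: int) -> str:
    """Transcript-strand sequence of the `length` bases ending at the cleavage base."""
    if strand == "+":
        start = max(0, position - length + 1)
        return chrom_seq[start: position + 1]
    end = min(len(chrom_seq), position + length)
    return revcomp(chrom_seq[position:end])


def emit_bed(tags: pd.DataFrame) -> Dict[str, str]:
    """Render tags as BED6 text per sample (single-base cleavage intervals)."""
    out: Dict[str, str] = {}
    for sample, sub in tags.groupby("sample", sort=True):
        buf = io.StringIO()
        for row in sub.itertuples():
            buf.write(f"{row.chrom}\t{row.position}\t{row.position + 1}\t"
                      f"tag{row.tag_id}\t0\t{row.strand}\n")
        out[sample] = buf.getvalue()
    return out


def simulate_count_matrix(
    n_features: int,
    mean: float,
    dispersion: float,
    group_sizes: Tuple[int, int] = (3, 3),
    fold_changes: Optional[Dict[int, float]] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, List[str], List[str]]:
    """Negative-binomial feature x sample count matrix for calibration studies.

    All features share ``mean`` and ``dispersion``; ``fold_changes`` maps
    feature indices to fold changes applied to the second group's mean.
    Returns (matrix, group_a_samples, group_b_samples).
    """
    rng = np.random.default_rng([seed % (2**31), 41])
    na, nb = group_sizes
    cols_a = [f"A_{i + 1}" for i in range(na)]
    cols_b = [f"B_{i + 1}" for i in range(nb)]
    r = 1.0 / dispersion

    def draw(mu, size):
        return rng.negative_binomial(r, r / (r + mu), size=size)

    mat = draw(mean, (n_features, na + nb))
    for idx, fold in (fold_changes or {}).items():
        mat[idx, na:] = draw(mean * fold, nb)
    matrix = pd.DataFrame(mat, columns=cols_a + cols_b,
                          index=[f"f{i}" for i in range(n_features)])
    return matrix, cols_a, cols_b


def write_outputs(genome, gff3_text, truth, tags, config, outdir) -> None:
    """Write FASTA/GFF3/FASTQ/BED/truth/sample-sheet files for a simulation."""
    import os

    from .util import write_fasta

    os.makedirs(outdir, exist_ok=True)
    write_fasta(genome, os.path.join(outdir, "genome.fa"))
    with open(os.path.join(outdir, "annotation.gff3"), "w") as fh:
        fh.write(gff3_text)
    for sample, text in emit_fastq(tags, genome, config).items():
        with open(os.path.join(outdir, f"{sample}.fastq"), "w") as fh:
            fh.write(text)
    for sample, text in emit_bed(tags).items():
        with open(os.path.join(outdir, f"{sample}.bed"), "w") as fh:
            fh.write(text)
    truth.to_tsv(os.path.join(outdir, "truth"))
    config.sample_sheet().to_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index=False)
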