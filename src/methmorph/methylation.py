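"""Bisulfite amplicon methylation calling.

The analysis chain mirrors bisulfite-sequencing PCR followed by direct
amplicon sequencing (BSP-NGS): CpG sites and CpG islands are located on the
promoter of interest, reads are aligned against an in-silico converted
reference, and each covered CpG cytosine is called methylated (C), not
methylated (T) or uninformative (anything else).  The region methylation
rate r_m is the fraction of methylated calls among informative calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "GenomicSpan",
    "PromoterRegion",
    "IslandCriteria",
    "Alignment",
    "MethylationCallTable",
    "find_cpg_sites",
    "find_cpg_islands",
    "bisulfite_convert",
    "converted_reference",
    "align_read",
    "call_read",
    "call_sample",
    "methylation_rate",
    "summarize_rates",
]

_DNA = set("ACGT")


@dataclass(frozen=True)
class GenomicSpan:
    """1-based inclusive genomic interval, as printed in genome browsers."""

    assembly: str
    chrom: str
    start: int
    end: int

    def __str__(self) -> str:
        return f"{self.assembly} {self.chrom}:{self.start:,}-{self.end:,}"


@dataclass(frozen=True)
class IslandCriteria:
    """CpG-island thresholds (Gardiner-Garden/Frommer style defaults).

    A window qualifies when GC fraction >= ``min_gc`` and observed/expected
    CpG ratio (N_CG * L) / (N_C * N_G) >= ``min_obs_exp``; qualifying windows
    are merged and the merged interval trimmed until it satisfies the
    criteria as a whole and is at least ``min_length`` long.
    """

    min_length: int = 200
    min_gc: float = 0.50
    min_obs_exp: float = 0.60
    window: int = 200
    step: int = 1

    def __post_init__(self) -> None:
        if not (self.min_length >= self.window >= 1):
            raise ValueError("require min_length >= window >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence is empty")
    for i, base in enumerate(sequence):
        if base not in _DNA:
            raise ValueError(f"non-ACGT character {base!r} at offset {i}")


def find_cpg_sites(sequence: str) -> list[int]:
    """0-based offsets of the C of every CG dinucleotide."""
    _validate_sequence(sequence)
    return [i for i in range(len(sequence) - 1) if sequence[i] == "C" and sequence[i + 1] == "G"]


def _interval_stats(pc: np.ndarray, pg: np.ndarray, pcg: np.ndarray, start: int, end: int) -> tuple[float, float]:
    """(GC fraction, obs/exp CpG) of [start, end) from prefix sums."""
    length = end - start
    n_c = int(pc[end] - pc[start])
    n_g = int(pg[end] - pg[start])
    # CG dinucleotides fully inside the interval start in [start, end-1)
    n_cg = int(pcg[max(end - 1, start)] - pcg[start])
    gc = (n_c + n_g) / length
    obs_exp = (n_cg * length) / (n_c * n_g) if n_c and n_g else 0.0
    return gc, obs_exp


def find_cpg_islands(sequence: str, criteria: IslandCriteria | None = None) -> list[tuple[int, int]]:
    """Maximal CpG-island intervals, 0-based half-open.

    Sliding-window scan: every window meeting the GC and obs/exp thresholds
    is marked; overlapping marked windows are merged; each merged interval is
    trimmed one base at a time (from whichever end most improves the
    obs/exp ratio, right end on ties) until the whole interval meets the
    criteria, and discarded if it falls below ``min_length`` first.
    """
    criteria = criteria or IslandCriteria()
    _validate_sequence(sequence)
    n = len(sequence)
    if n < criteria.window:
        raise ValueError(f"sequence length {n} < window {criteria.window}")

    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cg = np.zeros(n, dtype=bool)
    is_cg[:-1] = is_c[:-1] & is_g[1:]
    pc = np.concatenate([[0], np.cumsum(is_c)])
    pg = np.concatenate([[0], np.cumsum(is_g)])
    pcg = np.concatenate([[0], np.cumsum(is_cg)])

    w = criteria.window
    starts = np.arange(0, n - w + 1, criteria.step)
    length = w
    n_c = pc[starts + w] - pc[starts]
    n_g = pg[starts + w] - pg[starts]
    n_cg = pcg[starts + w - 1] - pcg[starts]
    gc_ok = (n_c + n_g) / length >= criteria.min_gc
    denom = n_c * n_g
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(denom > 0, n_cg * length / np.maximum(denom, 1), 0.0)
    ok = gc_ok & (obs_exp >= criteria.min_obs_exp)

    # merge overlapping qualifying windows
    merged: list[list[int]] = []
    for s in starts[ok]:
        e = int(s) + w
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([int(s), e])

    def meets(a: int, b: int) -> bool:
        gc, oe = _interval_stats(pc, pg, pcg, a, b)
        return gc >= criteria.min_gc and oe >= criteria.min_obs_exp

    islands: list[tuple[int, int]] = []
    for a, b in merged:
        while b - a >= criteria.min_length and not meets(a, b):
            _, oe_left = _interval_stats(pc, pg, pcg, a + 1, b)
            _, oe_right = _interval_stats(pc, pg, pcg, a, b - 1)
            if oe_left > oe_right:
                a += 1
            else:
                b -= 1
        if b - a >= criteria.min_length and meets(a, b):
            islands.append((a, b))
    return islands


@dataclass
class PromoterRegion:
    """A named promoter/amplicon sequence with CpG annotation.

    ``cpg_sites`` are 0-based offsets of the C of each CG dinucleotide;
    ``islands`` are 0-based half-open intervals.  ``span`` records the
    genomic placement (1-based inclusive) when known; ``metadata`` carries
    verbatim annotations that are not used numerically.
    """

    name: str
    sequence: str
    span: GenomicSpan | None = None
    strand: str = "+"
    cpg_sites: list[int] = field(default_factory=list)
    islands: list[tuple[int, int]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_sequence(
        cls,
        name: str,
        sequence: str,
        span: GenomicSpan | None = None,
        strand: str = "+",
        criteria: IslandCriteria | None = None,
        metadata: dict | None = None,
    ) -> "PromoterRegion":
        sequence = sequence.upper()
        sites = find_cpg_sites(sequence)
        criteria = criteria or IslandCriteria()
        islands = find_cpg_islands(sequence, criteria) if len(sequence) >= criteria.window else []
        return cls(name, sequence, span, strand, sites, islands, metadata or {})

    def __post_init__(self) -> None:
        for s in self.cpg_sites:
            if not (self.sequence[s] == "C" and self.sequence[s + 1 : s + 2] == "G"):
                raise ValueError(f"cpg_site {s} is not a CpG cytosine")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.sequence)

    def subregion(self, start: int, end: int, name: str | None = None) -> "PromoterRegion":
        """Sub-amplicon [start, end) with recomputed CpG sites."""
        sub = self.sequence[start:end]
        span = None
        if self.span is not None:
            span = GenomicSpan(self.span.assembly, self.span.chrom, self.span.start + start, self.span.start + end - 1)
        sites = find_cpg_sites(sub)
        return PromoterRegion(name or f"{self.name}:{start}-{end}", sub, span, self.strand, sites, [], dict(self.metadata))

    @cached_property
    def converted(self) -> str:
        """Fully converted reference: non-CpG C -> T, CpG C -> 'Y' (C or T)."""
        return converted_reference(self.sequence, self.cpg_sites)


def bisulfite_convert(sequence: str, methylated_positions: Iterable[int]) -> str:
    """Deaminate a template: unmethylated C -> T, methylated CpG C stays C.

    ``methylated_positions`` must be CpG cytosines of ``sequence``.
    """
    _validate_sequence(sequence)
    meth = set(methylated_positions)
    sites = set(find_cpg_sites(sequence))
    bad = meth - sites
    if bad:
        raise ValueError(f"methylated positions not CpG cytosines: {sorted(bad)}")
    out = []
    for i, base in enumerate(sequence):
        if base == "C" and i not in meth:
            out.append("T")
        else:
            out.append(base)
    return "".join(out)


def converted_reference(sequence: str, cpg_sites: Sequence[int]) -> str:
    """Reference for bisulfite-aware alignment: CpG C becomes the pyrimidine
    ambiguity code 'Y' (matches C and T), every other C becomes T."""
    sites = set(cpg_sites)
    return "".join(
        "Y" if (b == "C" and i in sites) else ("T" if b == "C" else b)
        for i, b in enumerate(sequence)
    )


@dataclass
class Alignment:
    """Pairwise alignment of a read onto a converted reference."""

    read_id: str
    read_sequence: str
    pairs: list[tuple[int, int]]  # (reference offset, read offset), gap-free columns only
    score: float

    def __post_init__(self) -> None:
        refs = [r for r, _ in self.pairs]
        if any(b <= a for a, b in zip(refs, refs[1:])):
            raise ValueError("reference offsets must be strictly increasing")

    @property
    def reference_span(self) -> tuple[int, int]:
        if not self.pairs:
            return (0, 0)
        return (self.pairs[0][0], self.pairs[-1][0] + 1)


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    alphabet = "ACGTNY"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            mat[a, b] = scoring.match if a == b else scoring.mismatch
    # Y is the converted CpG cytosine: either C (methylated) or T (converted)
    for b in "CT":
        mat["Y", b] = scoring.match
        mat[b, "Y"] = scoring.match
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = mat
    aligner.mode = "global"
    aligner.open_gap_score = scoring.gap
    aligner.extend_gap_score = scoring.gap
    # reads are sub-fragments of the amplicon: reference overhangs are free
    aligner.end_deletion_score = 0.0
    return aligner


def align_read(
    read: str,
    region: PromoterRegion,
    read_id: str = "read",
    scoring: AlignmentScoring | None = None,
) -> Alignment:
    """Glocal alignment of a bisulfite read against the converted reference.

    The reference is the fully converted plus strand with CpG cytosines as
    {C,T} ambiguities, so a converted T over a reference C never counts as a
    mismatch.  End gaps on the reference are free; gaps are linear.  Among
    co-optimal alignments the aligner's first (canonical) traceback is used,
    which is deterministic.
    """
    if not read:
        raise ValueError("read is empty")
    scoring = scoring or AlignmentScoring()
    aligner = _make_aligner(scoring)
    aln = aligner.align(region.converted, read.upper())[0]
    pairs: list[tuple[int, int]] = []
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        pairs.extend(zip(range(ts, te), range(qs, qe)))
    return Alignment(read_id, read.upper(), pairs, float(aln.score))


def call_read(alignment: Alignment, region: PromoterRegion) -> dict[int, str]:
    """Per-CpG-site calls for one read: C -> 'M', T -> 'U', else 'N'.

    Sites inside the aligned reference span that fall in a gap are 'N';
    sites outside the span are absent from the result.
    """
    by_ref = dict(alignment.pairs)
    lo, hi = alignment.reference_span
    calls: dict[int, str] = {}
    for site in region.cpg_sites:
        if not (lo <= site < hi):
            continue
        read_off = by_ref.get(site)
        if read_off is None:
            calls[site] = "N"
            continue
        base = alignment.read_sequence[read_off]
        calls[site] = "M" if base == "C" else ("U" if base == "T" else "N")
    return calls


@dataclass
class MethylationCallTable:
    """Per-read, per-site methylation calls for one sample."""

    region_name: str
    sites: list[int]
    read_calls: dict[str, dict[int, str]]

    def site_counts(self) -> pd.DataFrame:
        rows = []
        for site in self.sites:
            n_m = n_u = n_n = 0
            for calls in self.read_calls.values():
                c = calls.get(site)
                if c == "M":
                    n_m += 1
                elif c == "U":
                    n_u += 1
                elif c == "N":
                    n_n += 1
            informative = n_m + n_u
            rows.append(
                {
                    "site_offset": site,
                    "n_M": n_m,
                    "n_U": n_u,
                    "n_N": n_n,
                    "site_rate": n_m / informative if informative else math.nan,
                }
            )
        return pd.DataFrame(rows)

    def region_rate(self, mode: str = "pooled") -> float:
        return methylation_rate(self, mode=mode)


def methylation_rate(calls: MethylationCallTable, mode: str = "pooled") -> float:
    """Region methylation rate r_m.

    pooled (default): sum of methylated calls over all informative calls,
    depth-weighted and well defined at uneven coverage.  per_site: the
    unweighted mean of per-site rates.  'N' calls never enter numerator or
    denominator.
    """
    counts = calls.site_counts()
    if mode == "pooled":
        informative = counts["n_M"].sum() + counts["n_U"].sum()
        if informative == 0:
            raise ValueError("methylation rate undefined: no informative (M/U) calls")
        return float(counts["n_M"].sum() / informative)
    if mode == "per_site":
        rates = counts["site_rate"].dropna()
        if rates.empty:
            raise ValueError("methylation rate undefined: no informative (M/U) calls")
        return float(rates.mean())
    raise ValueError(f"unknown mode {mode!r}")


def call_sample(
    region: PromoterRegion,
    reads: Iterable[tuple[str, str]],
    scoring: AlignmentScoring | None = None,
) -> MethylationCallTable:
    """Align and call a set of ``(read_id, sequence)`` pairs on ``region``."""
    read_calls: dict[str, dict[int, str]] = {}
    for read_id, seq in reads:
        aln = align_read(seq, region, read_id=read_id, scoring=scoring)
        read_calls[read_id] = call_read(aln, region)
    return MethylationCallTable(region.name, list(region.cpg_sites), read_calls)


def summarize_rates(rates: Sequence[float]) -> tuple[float, float]:
    """Across-sample summary reported as mean and SD (ddof=1; SD 0 for n=1)."""
    arr = np.asarray(rates, dtype=float)
    if arr.size == 0:
        raise ValueError("no rates to summarize")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
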