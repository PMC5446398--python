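"""SpCas9 guide discovery, filtering and circular tiling panel design.

A guide targets a 20-nt protospacer that must be followed on its own strand
by an NGG PAM. On the reference, the 23-bp footprint (protospacer + PAM)
occupies ``[proto_start, proto_start + 23)`` for both strands: on the plus
strand the PAM sits at the 3' (right) end of the footprint, on the minus
strand it sits at the reference-left end (reading CCN on the plus strand).
Cas9 cuts bluntly 3 bp 5' of the PAM, i.e. between protospacer positions
17 and 18.

Guide quality is enforced by explicit local filters — seed GC content,
absence of a TTTT run (a T7 transcription-terminator risk for in-vitro
transcribed guides), absence of N, and an exact-match 23-mer screen against
a background (nuclear) genome — so a panel is reproducible offline with no
external scoring service.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from mitocleave.genomes import Genome, reverse_complement

GC_OUT_OF_RANGE = "GC_OUT_OF_RANGE"
HOMOPOLYMER_T4 = "HOMOPOLYMER_T4"
OFFTARGET_HIT = "OFFTARGET_HIT"
CONTAINS_N = "CONTAINS_N"

FOOTPRINT = 23  # protospacer (20) + PAM (3)


@dataclass(frozen=True)
class GuideSite:
    """One protospacer+PAM occurrence on the reference.

    ``proto_start`` is the leftmost reference coordinate of the 23-bp
    footprint; ``seed`` and ``pam`` are given in protospacer-strand sense,
    so ``fetch_subseq(genome, proto_start, proto_start + 23, strand)``
    equals ``seed + pam``. ``cut_pos`` is the reference coordinate of the
    blunt cut.
    """

    chrom: str
    strand: str
    proto_start: int
    seed: str
    pam: str
    cut_pos: int
    quality_flags: frozenset[str] = frozenset()

    @property
    def passes(self) -> bool:
        return not self.quality_flags


@dataclass
class SpacingStats:
    mean_gap: float
    min_gap: int
    max_gap: int


@dataclass
class GuidePanel:
    """An ordered panel of guides tiling a circular chromosome."""

    guides: list[GuideSite]
    target_n: int
    gaps: list[int] = field(default_factory=list)  # arc indices with no candidate
    spacing_stats: SpacingStats | None = None

    @property
    def shortfall(self) -> int:
        return self.target_n - len(self.guides)


def scan_pam_sites(genome: Genome) -> list[GuideSite]:
    """Enumerate all NGG-adjacent 20-mers on both strands.

    On a circular chromosome footprints wrap through the origin. Seeds or
    PAMs containing N are flagged CONTAINS_N rather than dropped. Output
    is sorted by (proto_start, strand) with '+' before '-'.
    """
    L = len(genome)
    if L < FOOTPRINT:
        warnings.warn(
            f"{genome.name}: length {L} < {FOOTPRINT}, no guide sites possible"
        )
        return []
    seq = genome.sequence
    ext = seq + seq[: FOOTPRINT - 1] if genome.is_circular else seq
    n_starts = L if genome.is_circular else L - FOOTPRINT + 1
    sites: list[GuideSite] = []
    for i in range(n_starts):
        window = ext[i : i + FOOTPRINT]
        flags = frozenset({CONTAINS_N}) if "N" in window else frozenset()
        # plus strand: protospacer [i, i+20), PAM NGG at [i+20, i+23)
        if window[21] == "G" and window[22] == "G":
            sites.append(
                GuideSite(
                    chrom=genome.name,
                    strand="+",
                    proto_start=i,
                    seed=window[:20],
                    pam=window[20:],
                    cut_pos=(i + 17) % L if genome.is_circular else i + 17,
                    quality_flags=flags,
                )
            )
        # minus strand: PAM reads CCN on the plus strand at [i, i+3)
        if window[0] == "C" and window[1] == "C":
            sites.append(
                GuideSite(
                    chrom=genome.name,
                    strand="-",
                    proto_start=i,
                    seed=reverse_complement(window[3:]),
                    pam=reverse_complement(window[:3]),
                    cut_pos=(i + 6) % L if genome.is_circular else i + 6,
                    quality_flags=flags,
                )
            )
    sites.sort(key=lambda s: (s.proto_start, s.strand))
    return sites


class OffTargetIndex:
    """Exact-match k-mer membership index over background genomes.

    A query hits if the k-mer occurs in the background in either
    orientation. k defaults to 23 (seed + PAM).
    """

    def __init__(self, background: Iterable[Genome], k: int = FOOTPRINT):
        self.k = k
        kmers: set[str] = set()
        for g in background:
            seq = g.sequence + (g.sequence[: k - 1] if g.is_circular else "")
            for i in range(len(seq) - k + 1):
                kmers.add(seq[i : i + k])
        self._kmers = kmers

    def __contains__(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        return kmer in self._kmers or reverse_complement(kmer) in self._kmers


def build_offtarget_index(background: Iterable[Genome], k: int = FOOTPRINT) -> OffTargetIndex:
    return OffTargetIndex(background, k=k)


def score_guide(
    site: GuideSite,
    index: OffTargetIndex | None,
    gc_min: float = 0.25,
    gc_max: float = 0.80,
) -> GuideSite:
    """Populate quality flags on a scanned site.

    Flags: GC fraction of the seed outside [gc_min, gc_max]; a TTTT run in
    the seed; exact 23-mer (seed+PAM) occurrence in the background index.
    CONTAINS_N from the scan is preserved.
    """
    flags = set(site.quality_flags)
    gc = sum(site.seed.count(b) for b in "GC") / len(site.seed)
    if not (gc_min <= gc <= gc_max):
        flags.add(GC_OUT_OF_RANGE)
    if "TTTT" in site.seed:
        flags.add(HOMOPOLYMER_T4)
    if index is not None and CONTAINS_N not in flags and (site.seed + site.pam) in index:
        flags.add(OFFTARGET_HIT)
    return replace(site, quality_flags=frozenset(flags))


def design_tiling_panel(
    genome: Genome,
    candidates: Sequence[GuideSite],
    target_n: int,
) -> GuidePanel:
    """Select an evenly spaced panel of ``target_n`` unflagged guides.

    The circular chromosome is partitioned into ``target_n`` equal arcs
    anchored at position 0; within each arc the unflagged candidate whose
    cut position is nearest the arc midpoint is selected (ties broken by
    smaller cut_pos, then '+' strand). Arcs holding no unflagged candidate
    are reported as gaps — a shortfall, not an exception.
    """
    if target_n < 1:
        raise ValueError("target_n must be ≥ 1")
    L = len(genome)
    arc = L / target_n
    buckets: dict[int, list[GuideSite]] = {}
    for c in candidates:
        if not c.passes:
            continue
        idx = min(int(c.cut_pos / arc), target_n - 1)
        buckets.setdefault(idx, []).append(c)
    chosen: list[GuideSite] = []
    gaps: list[int] = []
    seen_cuts: set[int] = set()
    for i in range(target_n):
        pool = [c for c in buckets.get(i, []) if c.cut_pos not in seen_cuts]
        if not pool:
            gaps.append(i)
            continue
        mid = (i + 0.5) * arc
        best = min(pool, key=lambda c: (abs(c.cut_pos - mid), c.cut_pos, c.strand))
        chosen.append(best)
        seen_cuts.add(best.cut_pos)
    chosen.sort(key=lambda c: c.cut_pos)
    panel = GuidePanel(guides=chosen, target_n=target_n, gaps=gaps)
    if chosen:
        panel.spacing_stats = panel_spacing_report(panel, L)
    return panel


def circular_gaps(cut_positions: Sequence[int], genome_length: int) -> list[int]:
    """Gaps between consecutive cut positions around the circle, including
    the wrap gap; a single position yields one gap equal to the length."""
    pos = sorted(cut_positions)
    if len(pos) == 1:
        return [genome_length]
    gaps = [pos[i + 1] - pos[i] for i in range(len(pos) - 1)]
    gaps.append(genome_length - pos[-1] + pos[0])
    return gaps


def panel_spacing_report(panel: GuidePanel, genome_length: int) -> SpacingStats:
    """Circular spacing statistics; the mean gap is exactly L / n."""
    if not panel.guides:
        raise ValueError("panel is empty")
    gaps = circular_gaps([g.cut_pos for g in panel.guides], genome_length)
    return SpacingStats(
        mean_gap=genome_length / len(panel.guides),
        min_gap=min(gaps),
        max_gap=max(gaps),
    )


def write_panel_tsv(panel: GuidePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("guide_id\tchrom\tstrand\tproto_start\tcut_pos\tseed\tpam\tflags\n")
        for n, g in enumerate(panel.guides, start=1):
            flags = ",".join(sorted(g.quality_flags)) or "."
            fh.write(
                f"g{n:03d}\t{g.chrom}\t{g.strand}\t{g.proto_start}\t"
                f"{g.cut_pos}\t{g.seed}\t{g.pam}\t{flags}\n"
            )


def read_panel_tsv(path: str | Path) -> GuidePanel:
    guides: list[GuideSite] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("guide_id"):
            raise ValueError(f"{path}: missing panel header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            flags = frozenset() if f[7] == "." else frozenset(f[7].split(","))
            guides.append(
                GuideSite(
                    chrom=f[1], strand=f[2], proto_start=int(f[3]),
                    cut_pos=int(f[4]), seed=f[5], pam=f[6], quality_flags=flags,
                )
            )
    return GuidePanel(guides=guides, target_n=len(guides))
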