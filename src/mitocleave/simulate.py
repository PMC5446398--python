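"""Synthetic ATAC-seq library generation, in-silico Cas9 digestion and
read sampling.

The generator emulates the features of real ATAC-seq data that matter to
mitochondrial depletion: a small circular mitochondrial chromosome densely
and uniformly covered by fragments, a nuclear chromosome where fragment
starts concentrate in open-chromatin "truth" peaks over a uniform
background, a configurable mitochondrial read fraction spanning the
20–80% range seen across cell types, PCR duplicates modelled as a
multiplicity on unique fragments, and the sub-nucleosomal/nucleosomal
fragment-length mixture characteristic of Tn5 tagmentation.

Digestion follows flow-cell chemistry: a cleaved fragment loses one
adapter-bearing end and cannot bridge-amplify, so it stays in the library
but is never sequenced. Fragments are therefore never deleted; cutting
only clears their ``amplifiable`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from mitocleave.genomes import Genome, Interval
from mitocleave.guides import FOOTPRINT, GuidePanel


@dataclass
class Fragment:
    """A unique library fragment with PCR-duplicate multiplicity.

    ``start > end`` denotes wrapping through the circular origin.
    ``amplifiable`` is False iff the fragment has been cut at least once.
    """

    chrom: str
    start: int
    end: int
    multiplicity: int = 1
    amplifiable: bool = True
    cut_hits: int = 0


@dataclass
class SimConfig:
    """Study conditions for the synthetic library.

    Defaults model a mitochondrial-sized circular chromosome (16,569 bp),
    a 1-Mb nuclear chromosome carrying 200 accessibility peaks, an even
    split of sequenced reads between mitochondrial and nuclear origin
    (the mid-point of the 20–80% range observed across cell types), a
    three-component fragment-length mixture (sub-nucleosomal, mono- and
    di-nucleosomal), and a moderate PCR duplication rate.
    """

    mito_length: int = 16_569
    nuclear_length: int = 1_000_000
    n_peaks: int = 200
    peak_width_mean: float = 500.0
    peak_width_sd: float = 100.0
    peak_enrichment: float = 20.0
    mito_read_fraction: float = 0.5
    frag_len_mix: tuple[tuple[float, float, float], ...] = (
        (80.0, 20.0, 0.6),
        (200.0, 40.0, 0.3),
        (400.0, 60.0, 0.1),
    )
    dup_rate: float = 0.15
    n_fragments: int = 50_000
    mito_gc: float = 0.44
    nuclear_gc: float = 0.41
    mito_name: str = "chrM"
    nuclear_name: str = "chr1"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.mito_read_fraction <= 1.0:
            raise ValueError("mito_read_fraction outside [0, 1]")
        if not 0.0 <= self.dup_rate < 1.0:
            raise ValueError("dup_rate outside [0, 1)")
        w = sum(c[2] for c in self.frag_len_mix)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError(f"fragment-length mixture weights sum to {w}, not 1")
        if self.n_fragments < 0 or self.n_peaks < 0:
            raise ValueError("counts must be ≥ 0")


class PeakPlacementError(RuntimeError):
    pass


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return bases.tobytes().decode()


def simulate_genomes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Genome, Genome, list[Interval]]:
    """Random mitochondrial + nuclear chromosomes and non-overlapping
    truth peaks, deterministic for a fixed seed."""
    cfg.validate()
    if cfg.mito_length < 1000 or cfg.nuclear_length < 1000:
        raise ValueError("chromosome lengths must be ≥ 1 kb")
    rng = rng or np.random.default_rng(cfg.seed)
    mito = Genome(cfg.mito_name, _random_sequence(rng, cfg.mito_length, cfg.mito_gc),
                  is_circular=True)
    nuclear = Genome(cfg.nuclear_name,
                     _random_sequence(rng, cfg.nuclear_length, cfg.nuclear_gc),
                     is_circular=False)
    widths = np.maximum(
        50, rng.normal(cfg.peak_width_mean, cfg.peak_width_sd, cfg.n_peaks)
    ).astype(int)
    if widths.sum() > 0.5 * cfg.nuclear_length:
        raise PeakPlacementError(
            f"{cfg.n_peaks} peaks totalling {widths.sum()} bp cannot be placed "
            f"without overlap on {cfg.nuclear_length} bp; request fewer or "
            "narrower peaks"
        )
    # place by distributing the free space between peaks at random
    free = cfg.nuclear_length - int(widths.sum())
    cuts = np.sort(rng.choice(free + 1, size=cfg.n_peaks, replace=True))
    starts = cuts + np.concatenate(([0], np.cumsum(widths[:-1])))
    peaks = [
        Interval(cfg.nuclear_name, int(s), int(s + w))
        for s, w in zip(starts, widths)
    ]
    return mito, nuclear, peaks


def _fragment_lengths(
    rng: np.random.Generator, n: int, mix: Sequence[tuple[float, float, float]]
) -> np.ndarray:
    comps = rng.choice(len(mix), size=n, p=[c[2] for c in mix])
    means = np.array([c[0] for c in mix])[comps]
    sds = np.array([c[1] for c in mix])[comps]
    return np.maximum(10, rng.normal(means, sds)).astype(int)


def simulate_library(
    genomes: tuple[Genome, Genome],
    truth_peaks: Sequence[Interval],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Draw a fragment library with the configured mitochondrial load.

    Fragment counts per chromosome are set so the expected sequenced-read
    mitochondrial fraction equals ``cfg.mito_read_fraction`` (duplicate
    multiplicities are i.i.d. across chromosomes, so the fragment-count
    split carries over to sampled reads in expectation). Mito starts are
    uniform on the circle; nuclear starts come from a peak/background
    mixture whose in-peak density exceeds background by
    ``peak_enrichment``-fold.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    mito, nuclear = genomes
    n_mito = int(round(cfg.mito_read_fraction * cfg.n_fragments))
    n_nuc = cfg.n_fragments - n_mito
    frags: list[Fragment] = []

    def mults(n: int) -> np.ndarray:
        # multiplicity = 1 + extra duplicate copies; dup_rate 0 → all ones
        return rng.geometric(1.0 - cfg.dup_rate, size=n)

    L = len(mito)
    starts = rng.integers(0, L, size=n_mito)
    lens = np.minimum(_fragment_lengths(rng, n_mito, cfg.frag_len_mix), L - 1)
    for s, l, m in zip(starts, lens, mults(n_mito)):
        frags.append(Fragment(mito.name, int(s), int((s + l) % L), int(m)))

    NL = len(nuclear)
    peak_bp = sum(p.end - p.start for p in truth_peaks)
    p_frac = peak_bp / NL
    e = cfg.peak_enrichment
    # weight of the in-peak mixture component giving an in/out density ratio e
    w_peak = 0.0 if peak_bp == 0 else (e - 1) * p_frac / (1 + (e - 1) * p_frac)
    lens = _fragment_lengths(rng, n_nuc, cfg.frag_len_mix)
    in_peak = rng.random(n_nuc) < w_peak
    peak_widths = np.array([p.end - p.start for p in truth_peaks], dtype=float)
    for i in range(n_nuc):
        if in_peak[i]:
            k = rng.choice(len(truth_peaks), p=peak_widths / peak_widths.sum())
            s = int(rng.integers(truth_peaks[k].start, truth_peaks[k].end))
        else:
            s = int(rng.integers(0, NL))
        end = min(s + int(lens[i]), NL)
        if end - s < 10:
            s = max(0, end - 10)
        frags.append(Fragment(nuclear.name, s, end, int(mults(1)[0])))
    return frags


def _site_count(start: int, span: int, footprints: np.ndarray, L: int) -> int:
    """Number of guide footprints fully contained in a circular fragment
    laid out linearly as [start, start + span)."""
    lo, hi = start, start + span - FOOTPRINT
    if hi < lo:
        return 0
    # footprints sorted; also consider starts shifted by +L for wrap
    n = np.searchsorted(footprints, hi, side="right") - np.searchsorted(
        footprints, lo, side="left"
    )
    shifted = footprints + L
    n += np.searchsorted(shifted, hi, side="right") - np.searchsorted(
        shifted, lo, side="left"
    )
    return int(n)


def digest_library(
    fragments: Sequence[Fragment],
    panel: GuidePanel,
    efficiency: float,
    mito_length: int,
    rng: np.random.Generator | int | None = None,
) -> list[Fragment]:
    """Cut fragments that fully contain a guide's 23-bp footprint.

    Each susceptible (fragment, guide) pair is cut independently with
    probability ``efficiency``. Any cut clears ``amplifiable``. Fragments
    on chromosomes the panel does not target are returned untouched; no
    fragment is ever removed (a cleaved fragment stays in the library but
    cannot bridge-amplify). ``mito_length`` is the circular length of the
    targeted chromosome, needed for origin-wrapping containment.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency outside [0, 1]")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    target_chroms = {g.chrom for g in panel.guides}
    footprints = np.sort(np.array([g.proto_start for g in panel.guides], dtype=int))
    out: list[Fragment] = []
    for f in fragments:
        if f.chrom not in target_chroms or footprints.size == 0:
            out.append(replace(f))
            continue
        span = f.end - f.start if f.end > f.start else mito_length - f.start + f.end
        k = _site_count(f.start, span, footprints, mito_length)
        cuts = int(rng.binomial(k, efficiency)) if k else 0
        out.append(
            replace(
                f,
                cut_hits=f.cut_hits + cuts,
                amplifiable=f.amplifiable and cuts == 0,
            )
        )
    return out


def sample_reads(
    fragments: Sequence[Fragment],
    depth: int,
    rng: np.random.Generator | int | None = None,
) -> list[Interval]:
    """Sample ``depth`` sequenced reads with replacement from amplifiable
    fragments, with probability proportional to multiplicity.

    PCR duplicates re-emerge as reads with identical coordinates, which the
    downstream deduplication then discards.
    """
    if depth < 1:
        raise ValueError("depth must be ≥ 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    pool = [f for f in fragments if f.amplifiable]
    if not pool:
        raise ValueError("no amplifiable fragments to sample from")
    weights = np.array([f.multiplicity for f in pool], dtype=float)
    idx = rng.choice(len(pool), size=depth, p=weights / weights.sum())
    return [Interval(pool[i].chrom, pool[i].start, pool[i].end, ".") for i in idx]


def naive_peak_call(
    reads: Sequence[Interval],
    genome_length: int,
    window: int = 250,
    fdr_threshold: float = 0.05,
) -> list[Interval]:
    """Poisson window caller on one chromosome — test-bed plumbing only.

    Reads are binned by midpoint into fixed windows; a window is flagged
    when its count exceeds the Poisson upper tail (rate = genome-wide mean
    per window) at the Benjamini–Hochberg-adjusted ``fdr_threshold``.
    Adjacent flagged windows merge; the score is -log10 of the best
    adjusted tail probability in the run. External MACS2/HOMER peaks are
    first-class inputs elsewhere and take precedence over this caller.
    """
    if not reads:
        raise ValueError("no reads supplied")
    chroms = {r.chrom for r in reads}
    if len(chroms) != 1:
        raise ValueError(f"reads span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    mids = np.array([(r.start + r.end) // 2 for r in reads if r.end > r.start])
    n_windows = max(1, -(-genome_length // window))
    counts = np.bincount(np.minimum(mids // window, n_windows - 1),
                         minlength=n_windows)
    lam = len(mids) / n_windows
    pvals = stats.poisson.sf(counts - 1, lam)  # P(X >= count)
    padj = stats.false_discovery_control(pvals, method="bh")
    flagged = (padj <= fdr_threshold) & (counts > lam)
    peaks: list[Interval] = []
    i = 0
    while i < n_windows:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_windows and flagged[j + 1]:
            j += 1
        best = max(padj[i : j + 1].min(), 1e-300)
        peaks.append(
            Interval(chrom, i * window, min((j + 1) * window, genome_length),
                     ".", -math.log10(best))
        )
        i = j + 1
    return peaks
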