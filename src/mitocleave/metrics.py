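"""Evaluation metrics for comparing library-preparation treatments.

The pipeline mirrors standard ATAC-seq QC practice: every sample is first
downsampled to a fixed number of sequenced reads so libraries of different
depths are comparable; reads are then partitioned into mitochondrial,
duplicate (non-mitochondrial reads at previously seen coordinates) and
usable (unique, non-mitochondrial) buckets. Peak-level comparisons use the
top-N peaks of each sample ranked by score, the fraction of peaks shared
between samples (≥1 bp overlap), and the squared Pearson correlation of
read counts over the merged peak union. Group comparisons report
fold-differences (pairwise median for matched treated/untreated halves,
ratio of group medians otherwise) and one-sided Wilcoxon tests
(signed-rank when paired, rank-sum when not), with the convention and test
identity always recorded alongside the number.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mitocleave.genomes import Interval, merge_intervals, overlap_flags


@dataclass(frozen=True)
class ReadAccounting:
    """Partition of a sample's sequenced reads.

    n_mito + n_duplicate + n_usable == depth_sequenced, always.
    """

    sample_id: str
    depth_sequenced: int
    n_mito: int
    n_duplicate: int
    n_usable: int

    def __post_init__(self) -> None:
        if self.n_mito + self.n_duplicate + self.n_usable != self.depth_sequenced:
            raise ValueError(
                f"{self.sample_id}: read buckets "
                f"{self.n_mito}+{self.n_duplicate}+{self.n_usable} "
                f"!= depth {self.depth_sequenced}"
            )

    @property
    def mito_fraction(self) -> float:
        return self.n_mito / self.depth_sequenced

    @property
    def duplicate_fraction(self) -> float:
        return self.n_duplicate / self.depth_sequenced

    @property
    def usable_fraction(self) -> float:
        return self.n_usable / self.depth_sequenced


@dataclass
class PeakSet:
    """Scored peaks for one sample, optionally rank-ordered."""

    sample_id: str
    peaks: list[Interval]
    ranked: bool = False

    def rank(self) -> "PeakSet":
        """Sort by score descending, ties by (chrom, start) ascending."""
        ordered = sorted(
            self.peaks,
            key=lambda p: (-(p.score if p.score is not None else -math.inf),
                           p.chrom, p.start),
        )
        return PeakSet(self.sample_id, ordered, ranked=True)

    def __len__(self) -> int:
        return len(self.peaks)


def downsample(
    reads: Sequence[Interval],
    n: int,
    rng: np.random.Generator | int | None = None,
) -> list[Interval]:
    """Uniform sample of exactly ``n`` reads without replacement."""
    if n > len(reads):
        raise ValueError(
            f"cannot downsample {len(reads)} reads to {n}: "
            f"short by {n - len(reads)}"
        )
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in idx]


def classify_reads(
    reads: Sequence[Interval],
    mito_chrom: str = "chrM",
    sample_id: str = "sample",
    use_strand: bool = True,
) -> ReadAccounting:
    """Partition reads into mitochondrial / duplicate / usable.

    Mitochondrial reads are removed first and counted as a single bucket.
    Among the remainder, every occurrence beyond the first at an identical
    (chrom, start, end[, strand]) key is a duplicate; the rest are usable.
    """
    n_mito = n_dup = n_usable = 0
    seen: set[tuple] = set()
    for r in reads:
        if r.chrom == mito_chrom:
            n_mito += 1
            continue
        key = (r.chrom, r.start, r.end, r.strand) if use_strand else (
            r.chrom, r.start, r.end)
        if key in seen:
            n_dup += 1
        else:
            seen.add(key)
            n_usable += 1
    return ReadAccounting(sample_id, len(reads), n_mito, n_dup, n_usable)


def dedup_usable(
    reads: Sequence[Interval],
    mito_chrom: str = "chrM",
    use_strand: bool = True,
) -> list[Interval]:
    """The usable reads themselves: unique, non-mitochondrial."""
    seen: set[tuple] = set()
    out: list[Interval] = []
    for r in reads:
        if r.chrom == mito_chrom:
            continue
        key = (r.chrom, r.start, r.end, r.strand) if use_strand else (
            r.chrom, r.start, r.end)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def signal_noise(
    reads: Sequence[Interval],
    union_peaks: Sequence[Interval],
) -> tuple[int, int, float]:
    """(reads in peaks, background reads, signal/noise ratio).

    ``reads`` must already be usable (non-mitochondrial, deduplicated);
    ``union_peaks`` is the merged union of peaks over all samples in the
    comparison. A read is "in peaks" iff it overlaps the union by ≥1 bp.
    Zero background yields an infinite ratio, not an error.
    """
    flags = overlap_flags(reads, union_peaks, min_overlap=1)
    n_in = int(flags.sum())
    n_out = len(reads) - n_in
    ratio = math.inf if n_out == 0 else n_in / n_out
    return n_in, n_out, ratio


def top_n(peakset: PeakSet, n: int) -> PeakSet:
    """The n highest-scoring peaks (ties by (chrom, start) ascending)."""
    ranked = peakset if peakset.ranked else peakset.rank()
    return PeakSet(peakset.sample_id, ranked.peaks[:n], ranked=True)


def common_peak_fraction(a: PeakSet, b: PeakSet) -> float:
    """Fraction of peaks in ``a`` overlapping ≥1 peak of ``b`` by ≥1 bp.

    The measure is asymmetric (a→b); NaN when ``a`` is empty.
    """
    if len(a) == 0:
        return math.nan
    flags = overlap_flags(a.peaks, b.peaks, min_overlap=1)
    return float(flags.mean())


def symmetric_common_fraction(a: PeakSet, b: PeakSet) -> tuple[float, float, float]:
    """Both directions of the common-peak fraction and their mean."""
    ab = common_peak_fraction(a, b)
    ba = common_peak_fraction(b, a)
    return ab, ba, (ab + ba) / 2


def _group_pair_mean(
    samples: Mapping[str, object],
    groups: Mapping[str, str],
    pair_value,
) -> pd.DataFrame:
    labels = sorted(set(groups.values()))
    mat = pd.DataFrame(index=labels, columns=labels, dtype=float)
    ids = list(samples)
    for ga in labels:
        for gb in labels:
            vals = [
                pair_value(samples[i], samples[j])
                for i in ids for j in ids
                if i != j and groups[i] == ga and groups[j] == gb
            ]
            vals = [v for v in vals if not math.isnan(v)]
            mat.loc[ga, gb] = float(np.mean(vals)) if vals else math.nan
    return mat


def group_concordance(
    peaksets: Mapping[str, PeakSet],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Mean common-peak fraction over all ordered sample pairs within and
    between groups, excluding self-pairs. A within-group cell with fewer
    than two samples is NaN."""
    return _group_pair_mean(peaksets, groups, common_peak_fraction)


def merged_peak_counts(
    samples: Mapping[str, Sequence[Interval]],
    peaksets: Iterable[PeakSet],
) -> tuple[list[Interval], pd.DataFrame]:
    """Merge all peaks from all samples and count usable reads per merged
    peak per sample (≥1 bp overlap; a read spanning two merged peaks counts
    in each)."""
    from intervaltree import IntervalTree

    all_peaks = [p for ps in peaksets for p in ps.peaks]
    merged = merge_intervals(all_peaks) if all_peaks else []
    trees: dict[str, IntervalTree] = {}
    for k, peak in enumerate(merged):
        trees.setdefault(peak.chrom, IntervalTree()).addi(peak.start, peak.end, k)
    counts = np.zeros((len(merged), len(samples)), dtype=int)
    for col, (sid, reads) in enumerate(samples.items()):
        for r in reads:
            tree = trees.get(r.chrom)
            if tree is None or r.end <= r.start:
                continue
            for hit in tree.overlap(r.start, r.end):
                counts[hit.data, col] += 1
    return merged, pd.DataFrame(counts, columns=list(samples))


def peak_readcount_r2(
    samples: Mapping[str, Sequence[Interval]],
    peaksets: Mapping[str, PeakSet],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Pairwise squared Pearson correlation of per-peak read counts.

    Counts are computed over the merged union of all samples' peaks.
    Returns the sample-by-sample R² matrix, or group means when ``groups``
    is given. A pair with zero variance in either count vector is NaN.
    """
    merged, counts = merged_peak_counts(samples, peaksets.values())
    if len(merged) < 2:
        raise ValueError("need ≥2 merged peaks to correlate read counts")
    ids = list(samples)
    r2 = pd.DataFrame(index=ids, columns=ids, dtype=float)
    for i in ids:
        for j in ids:
            x, y = counts[i].to_numpy(float), counts[j].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                r2.loc[i, j] = math.nan
            else:
                r2.loc[i, j] = float(stats.pearsonr(x, y).statistic ** 2)
    if groups is None:
        return r2
    return _group_pair_mean({i: i for i in ids}, groups,
                            lambda a, b: float(r2.loc[a, b]))


def feature_overlap_fraction(
    features: Sequence[Interval],
    peaks: PeakSet | Sequence[Interval],
    flank: int = 0,
) -> float:
    """Fraction of features overlapping ≥1 peak by ≥1 bp.

    With ``flank > 0`` each feature is treated as a point at its midpoint
    and expanded to ``[mid − flank, mid + flank)`` (e.g. ±1 kb windows on
    TSSs); interval features such as enhancers are used as-is with
    flank 0. Each feature counts at most once. NaN when no features.
    """
    if flank < 0:
        raise ValueError("flank must be ≥ 0")
    if not features:
        return math.nan
    peak_list = peaks.peaks if isinstance(peaks, PeakSet) else list(peaks)
    if flank > 0:
        expanded = []
        for f in features:
            mid = (f.start + f.end) // 2
            expanded.append(Interval(f.chrom, max(0, mid - flank), mid + flank))
        features = expanded
    flags = overlap_flags(list(features), peak_list, min_overlap=1)
    return float(flags.mean())


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


@dataclass(frozen=True)
class FoldDifference:
    value: float            # full precision
    rounded: float          # at the requested significant figures
    convention: str         # "pairwise-median" or "ratio-of-medians"


def fold_difference(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool,
    sig_figs: int = 2,
) -> FoldDifference:
    """Fold-difference of a over b.

    Paired samples (e.g. treated/untreated halves of one library) use the
    median of the per-pair ratios; unpaired comparisons use the ratio of
    group medians. The convention used is always recorded.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("fold-differences require strictly positive values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired fold-difference requires matched lengths")
        value = float(np.median(a / b))
        convention = "pairwise-median"
    else:
        value = float(np.median(a) / np.median(b))
        convention = "ratio-of-medians"
    return FoldDifference(value, _round_sig(value, sig_figs), convention)


@dataclass(frozen=True)
class RankTestResult:
    p_value: float
    test: str      # "wilcoxon-signed-rank" or "wilcoxon-rank-sum"
    method: str    # "exact" or "normal-approx"
    direction: str


def rank_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool,
    direction: str = "greater",
) -> RankTestResult:
    """One-sided Wilcoxon test of ``a`` vs ``b``.

    Paired data use the signed-rank test on within-pair differences;
    unpaired data use the rank-sum (Mann–Whitney) test. The exact
    small-sample null is used when sample sizes permit and the data are
    tie-free; otherwise the normal approximation with continuity
    correction. The method used is recorded in the result.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if min(len(a), len(b)) < 3:
        raise ValueError("need ≥3 observations per arm")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires matched lengths")
        d = a - b
        if np.all(d == 0):
            return RankTestResult(math.nan, "wilcoxon-signed-rank",
                                  "undefined-all-zero", direction)
        # scipy's exact signed-rank null enumerates sign patterns and is
        # valid under tied |differences|; zeros force the approximation
        exact_ok = len(a) <= 25 and not np.any(d == 0)
        method = "exact" if exact_ok else "approx"
        res = stats.wilcoxon(a, b, alternative=direction, method=method,
                             correction=True)
        return RankTestResult(float(res.pvalue), "wilcoxon-signed-rank",
                              "exact" if exact_ok else "normal-approx",
                              direction)
    pooled = np.concatenate([a, b])
    exact_ok = max(len(a), len(b)) <= 25 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        a, b, alternative=direction,
        method="exact" if exact_ok else "asymptotic",
    )
    return RankTestResult(float(res.pvalue), "wilcoxon-rank-sum",
                          "exact" if exact_ok else "normal-approx", direction)


@dataclass
class MetricsReport:
    """Aggregated per-sample and per-group comparison report."""

    per_sample: pd.DataFrame
    concordance: pd.DataFrame | None
    readcount_r2: pd.DataFrame | None
    fold_differences: dict[str, dict]
    tests: dict[str, dict]
    parameters: dict

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = {
            "parameters": self.parameters,
            "per_sample": json.loads(self.per_sample.to_json(orient="index")),
            "concordance": None if self.concordance is None
            else json.loads(self.concordance.to_json(orient="index")),
            "readcount_r2": None if self.readcount_r2 is None
            else json.loads(self.readcount_r2.to_json(orient="index")),
            "fold_differences": self.fold_differences,
            "tests": self.tests,
        }
        text = json.dumps(payload, indent=indent, sort_keys=True,
                          allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def build_report(
    samples: Mapping[str, Sequence[Interval]],
    peaksets: Mapping[str, PeakSet],
    groups: Mapping[str, str],
    pairs: Mapping[str, str] | None = None,
    features: Mapping[str, tuple[Sequence[Interval], int]] | None = None,
    mito_chrom: str = "chrM",
    top_n_peaks: int = 20_000,
    use_strand: bool = True,
) -> MetricsReport:
    """Aggregate the full comparison report.

    ``samples`` maps sample id → sequenced reads (already downsampled to a
    common depth); ``peaksets`` maps id → scored peaks; ``groups`` maps
    id → group label; ``pairs`` (optional) maps id → pair id for matched
    treated/untreated halves; ``features`` maps feature-class name →
    (intervals, flank) for TSS/enhancer-style overlap fractions.
    Fold-differences and one-sided rank tests are computed for every
    group pair, pairwise when the two groups are fully matched by
    ``pairs``, unpaired otherwise. P-values are unadjusted.
    """
    orphans = (set(samples) ^ set(peaksets)) | (set(samples) ^ set(groups))
    if orphans:
        raise ValueError(f"sample ids missing from some inputs: {sorted(orphans)}")
    ids = list(samples)
    topped = {i: top_n(peaksets[i], top_n_peaks) for i in ids}
    union = merge_intervals(
        [p for ps in topped.values() for p in ps.peaks]
    ) if any(len(ps) for ps in topped.values()) else []
    usable = {i: dedup_usable(samples[i], mito_chrom, use_strand) for i in ids}

    rows = {}
    for i in ids:
        acc = classify_reads(samples[i], mito_chrom, i, use_strand)
        n_in, n_out, ratio = signal_noise(usable[i], union)
        row = {
            "group": groups[i],
            "depth_sequenced": acc.depth_sequenced,
            "n_mito": acc.n_mito,
            "n_duplicate": acc.n_duplicate,
            "n_usable": acc.n_usable,
            "mito_fraction": acc.mito_fraction,
            "duplicate_fraction": acc.duplicate_fraction,
            "usable_fraction": acc.usable_fraction,
            "n_peaks": len(peaksets[i]),
            "reads_in_peaks": n_in,
            "background_reads": n_out,
            "signal_noise": ratio,
        }
        if features:
            for name, (ivs, flank) in features.items():
                row[f"{name}_fraction"] = feature_overlap_fraction(
                    ivs, topped[i], flank
                )
        rows[i] = row
    per_sample = pd.DataFrame.from_dict(rows, orient="index")

    concordance = group_concordance(topped, groups) if len(ids) > 1 else None
    try:
        r2 = peak_readcount_r2(usable, topped, groups) if len(ids) > 1 else None
    except ValueError:
        r2 = None

    metrics_cols = ["mito_fraction", "usable_fraction", "n_peaks", "signal_noise"]
    labels = sorted(set(groups.values()))
    fold_out: dict[str, dict] = {}
    test_out: dict[str, dict] = {}
    for ai, ga in enumerate(labels):
        for gb in labels[ai + 1:]:
            ids_a = [i for i in ids if groups[i] == ga]
            ids_b = [i for i in ids if groups[i] == gb]
            paired = False
            if pairs is not None:
                pa = {pairs[i] for i in ids_a if i in pairs}
                pb = {pairs[i] for i in ids_b if i in pairs}
                paired = (len(pa) == len(ids_a) == len(ids_b)) and pa == pb
                if paired:
                    order = sorted(pa)
                    ids_a = sorted(ids_a, key=lambda i: order.index(pairs[i]))
                    ids_b = sorted(ids_b, key=lambda i: order.index(pairs[i]))
            for col in metrics_cols:
                va = [per_sample.loc[i, col] for i in ids_a]
                vb = [per_sample.loc[i, col] for i in ids_b]
                key = f"{col}:{ga}_vs_{gb}"
                if all(np.isfinite(va)) and all(np.isfinite(vb)) and \
                        min(va + vb) > 0:
                    fd = fold_difference(va, vb, paired=paired)
                    fold_out[key] = {
                        "fold": fd.value, "rounded": fd.rounded,
                        "convention": fd.convention,
                    }
                if min(len(va), len(vb)) >= 3:
                    rt = rank_test(va, vb, paired=paired, direction="greater")
                    test_out[key] = {
                        "p_one_sided": rt.p_value, "test": rt.test,
                        "method": rt.method, "direction": rt.direction,
                        "adjusted": False,
                    }
    return MetricsReport(
        per_sample=per_sample,
        concordance=concordance,
        readcount_r2=r2,
        fold_differences=fold_out,
        tests=test_out,
        parameters={
            "mito_chrom": mito_chrom,
            "top_n_peaks": top_n_peaks,
            "dedup_uses_strand": use_strand,
            "paired_ids": dict(pairs) if pairs else None,
        },
    )
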