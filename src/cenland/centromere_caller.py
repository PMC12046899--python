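"""CENH3 enrichment-ratio centromere calling.

The enrichment signal is the BPM-normalized CUT&Tag/Input ratio in fixed
bins (500 bp by default). Candidate bins exceed ``cen_fold`` times the
per-chromosome mean ratio; candidate blocks closer than 100 kb are merged;
blocks shorter than ``min_cen_len`` are dropped. The block with the largest
cumulative excess over the chromosome mean is flagged as the primary
centromere. Arm ratio (long arm / short arm about the centromere midpoint)
and arm-scaled metaprofiles summarize centromere position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import BinnedTrack, GenomicInterval, PipelineConfig


@dataclass
class CentromereCall:
    region: GenomicInterval
    mean_ratio: float
    n_bins: int
    is_primary: bool
    arm_ratio: float = float("nan")


@dataclass
class RatioTrack(BinnedTrack):
    pseudocount: float = 1.0


def _as_dict(tracks) -> dict[str, BinnedTrack]:
    if isinstance(tracks, BinnedTrack):
        return {tracks.chrom: tracks}
    return tracks


def bpm_normalize(tracks):
    """Bins-per-million: value_i * 1e6 / sum over ALL chromosomes jointly."""
    single = isinstance(tracks, BinnedTrack)
    tracks = _as_dict(tracks)
    total = sum(float(t.values.sum()) for t in tracks.values())
    if total <= 0:
        raise ValueError("cannot BPM-normalize an all-zero track set")
    out = {
        c: BinnedTrack(c, t.bin_size, t.values * 1e6 / total, "BPM", t.chrom_length)
        for c, t in tracks.items()
    }
    return out[next(iter(out))] if single else out


def ratio_track(cut, inp, config: PipelineConfig | None = None):
    """Per-bin (cut + p) / (input + p) on BPM-normalized tracks.

    Raw tracks are BPM-normalized first; the pseudocount p (1 BPM unit by
    default) regularizes empty bins, so an empty bin in both tracks has
    ratio exactly 1.
    """
    config = config or PipelineConfig()
    single = isinstance(cut, BinnedTrack)
    cut, inp = _as_dict(cut), _as_dict(inp)
    if set(cut) != set(inp):
        raise ValueError("cut and input cover different chromosomes")
    for c in cut:
        if cut[c].bin_size != inp[c].bin_size:
            raise ValueError(f"bin size mismatch on {c}")
        if cut[c].n_bins != inp[c].n_bins:
            raise ValueError(f"bin count mismatch on {c}")
    if any(t.norm == "raw" for t in cut.values()):
        cut = _as_dict(bpm_normalize(cut))
    if any(t.norm == "raw" for t in inp.values()):
        inp = _as_dict(bpm_normalize(inp))
    p = config.ratio_pseudocount
    out = {}
    for c in cut:
        vals = (cut[c].values + p) / (inp[c].values + p)
        out[c] = RatioTrack(c, cut[c].bin_size, vals, "ratio", cut[c].chrom_length, p)
    return out[next(iter(out))] if single else out


def call_centromeres(ratio, config: PipelineConfig | None = None) -> list[CentromereCall]:
    """Call centromere intervals from a ratio track (one or many chromosomes).

    Candidate bins have ratio >= cen_fold * chromosome mean; candidates
    separated by < cen_merge_gap are merged; blocks < min_cen_len dropped;
    per chromosome the block maximizing sum(ratio - mean) is primary.
    """
    config = config or PipelineConfig()
    ratio = _as_dict(ratio)
    if not ratio:
        raise ValueError("empty ratio track set")
    calls: list[CentromereCall] = []
    for chrom in sorted(ratio):
        t = ratio[chrom]
        if t.n_bins == 0:
            raise ValueError(f"empty track for {chrom}")
        vals = t.values
        chrom_mean = float(vals.mean())
        cand = np.nonzero(vals >= config.cen_fold * chrom_mean)[0]
        if len(cand) == 0:
            continue
        gap_bins = config.cen_merge_gap / t.bin_size
        blocks = []  # [first_bin, last_bin]
        for b in cand:
            if blocks and b - blocks[-1][1] < gap_bins:
                blocks[-1][1] = b
            else:
                blocks.append([b, b])
        best_idx, best_score = None, -np.inf
        kept = []
        for first, last in blocks:
            start = int(first) * t.bin_size
            end = min((int(last) + 1) * t.bin_size, t.chrom_length)
            if end - start < config.min_cen_len:
                continue
            block_vals = vals[first : last + 1]
            score = float((block_vals - chrom_mean).sum())
            kept.append(
                CentromereCall(
                    region=GenomicInterval(chrom, start, end),
                    mean_ratio=float(block_vals.mean()),
                    n_bins=last + 1 - first,
                    is_primary=False,
                )
            )
            if score > best_score:
                best_score, best_idx = score, len(kept) - 1
        if best_idx is not None:
            kept[best_idx].is_primary = True
        for call in kept:
            call.arm_ratio = arm_ratio(call.region, t.chrom_length)
        calls.extend(kept)
    return calls


def classify_cluster_binding(
    cluster_cut_count: float,
    cluster_input_count: float,
    cut_total: float,
    input_total: float,
    threshold: float = 2.0,
) -> bool:
    """Repeat-cluster CENH3 binding: normalized CUT&Tag/Input ratio strictly
    above ``threshold``. A zero input count uses a pseudocount of 1 read."""
    if cut_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be positive")
    if cluster_input_count <= 0:
        cluster_input_count = 1.0
    ratio = (cluster_cut_count / cut_total) / (cluster_input_count / input_total)
    return ratio > threshold


def arm_ratio(cen: GenomicInterval, chrom_length: int) -> float:
    """Long arm / short arm about the centromere midpoint (>= 1)."""
    if cen.end > chrom_length:
        raise ValueError("centromere outside chromosome")
    mid = cen.midpoint
    short, long_ = sorted((mid, chrom_length - mid))
    if short == 0:
        raise ValueError("centromere midpoint at chromosome end (zero arm)")
    return long_ / short


def _integrate(t: BinnedTrack, x0: float, x1: float) -> float:
    """Integral of the piecewise-constant track over [x0, x1)."""
    if x1 <= x0:
        return 0.0
    first, last = int(x0 // t.bin_size), int((x1 - 1e-9) // t.bin_size)
    last = min(last, t.n_bins - 1)
    total = 0.0
    for b in range(first, last + 1):
        lo = max(x0, b * t.bin_size)
        hi = min(x1, (b + 1) * t.bin_size, t.chrom_length)
        if hi > lo:
            total += t.values[b] * (hi - lo)
    return total


def arm_scaled_metaprofile(
    tracks, cen_midpoints: dict[str, int], n_bins_per_arm: int = 100
) -> np.ndarray:
    """Average track profile over chromosome arms rescaled to unit length.

    Each arm runs telomere -> centromere midpoint and is split into
    ``n_bins_per_arm`` equal fractions whose values are length-weighted means
    of the underlying bins; the profile averages all arms of all chromosomes.
    """
    tracks = _as_dict(tracks)
    profiles = []
    for chrom, t in sorted(tracks.items()):
        if chrom not in cen_midpoints:
            warnings.warn(f"no centromere midpoint for {chrom}; skipped")
            continue
        mid = cen_midpoints[chrom]
        L = t.chrom_length
        for lo, hi, reverse in ((0, mid, False), (mid, L, True)):
            arm_len = hi - lo
            if arm_len <= 0:
                continue
            prof = np.empty(n_bins_per_arm)
            for b in range(n_bins_per_arm):
                x0 = lo + arm_len * b / n_bins_per_arm
                x1 = lo + arm_len * (b + 1) / n_bins_per_arm
                prof[b] = _integrate(t, x0, x1) / (x1 - x0)
            if reverse:
                prof = prof[::-1]  # orient telomere -> centromere
            profiles.append(prof)
    if not profiles:
        raise ValueError("no chromosome had a centromere midpoint")
    return np.mean(profiles, axis=0)
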