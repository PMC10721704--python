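"""Shared founder-haplotype window expansion and haplotype-group tests.

Carriers of a founder variant inherit a chromosomal segment identical by
descent. Working only on the phased deletion-bearing chromosome copies of
the carriers, the window-expansion algorithm starts at the index variant
and grows the window one variant at a time, alternating sides. Adding a
variant can split the modal (most frequent) haplotype group; when the
addition would shrink the modal group by more than a split threshold, that
side is frozen and the offending variant stays outside the window. Two
filter profiles mirror common usage: cohort MAF ≥ 0.01 with threshold 3
(the long shared haplotype), and minor allele count ≥ 4 among carrier
chromosomes with threshold 10 (rare haplotype-splitting variants).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhasedHaplotypes",
    "HaplotypeWindow",
    "expand_shared_haplotype",
    "haplotype_group_test",
]


@dataclass
class PhasedHaplotypes:
    """Deletion-bearing chromosome copies of carriers × ordered variants.

    ``variants`` has columns chrom, pos, ref, alt and maf (cohort minor
    allele frequency); ``haps`` is a carriers × variants 0/1 matrix — one
    row per carrier, the phase carrying the deletion. The index variant
    (the deletion itself) is not a column; its position is ``index_pos``.
    """

    variants: pd.DataFrame
    haps: np.ndarray
    carrier_ids: list[str]
    index_pos: int

    def __post_init__(self) -> None:
        pos = self.variants["pos"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError("variant positions must be strictly increasing")
        if self.haps.shape != (len(self.carrier_ids), len(self.variants)):
            raise ValueError("haplotype matrix shape mismatch")

    @property
    def mac(self) -> np.ndarray:
        """Minor allele count among the carrier haplotype copies."""
        ones = self.haps.sum(axis=0)
        return np.minimum(ones, len(self.carrier_ids) - ones)

    @classmethod
    def from_region(cls, region) -> "PhasedHaplotypes":
        """Build from a synthetic FounderRegion."""
        return cls(variants=region.variants.copy(), haps=region.del_haps,
                   carrier_ids=list(region.carrier_ids),
                   index_pos=region.index_pos)

    @classmethod
    def from_phased_vcf(cls, path, index_id: str = "founder_del",
                        index_pos: int | None = None) -> "PhasedHaplotypes":
        """Read a phased VCF and extract the deletion-bearing phase.

        The deletion-bearing copy of each carrier is identified from the
        phased genotype at the index variant (matched by VCF ID or
        position); only samples carrying the deletion are retained.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, alleles = [], []
        idx_alleles = None
        idx_pos = None
        for var in vcf:
            gt = np.asarray(var.genotype.array())[:, :2]
            is_index = (var.ID == index_id) or (index_pos is not None
                                                and var.POS == index_pos)
            if is_index:
                idx_alleles = gt
                idx_pos = var.POS
                continue
            rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
            alleles.append(gt)
        vcf.close()
        if idx_alleles is None:
            raise ValueError("index variant absent from phased VCF")
        carrier_mask = (idx_alleles > 0).any(axis=1)
        phase = (idx_alleles[carrier_mask, 1] > 0).astype(int)  # 0 or 1
        carriers = [s for s, m in zip(samples, carrier_mask) if m]
        mat = np.stack(alleles, axis=1)  # samples × variants × 2
        haps = np.take_along_axis(mat[carrier_mask],
                                  phase[:, None, None], axis=2)[:, :, 0]
        variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        af = mat.sum(axis=(0, 2)) / (2 * len(samples))
        variants["maf"] = np.minimum(af, 1 - af)
        return cls(variants=variants, haps=haps.astype(np.int8),
                   carrier_ids=carriers, index_pos=int(idx_pos))


@dataclass
class HaplotypeWindow:
    left: int                    # variant index (inclusive) in the filtered set
    right: int
    variant_pos: np.ndarray      # filtered variant positions
    span_bp: tuple[int, int]
    groups: dict[str, list[str]]  # haplotype string -> carrier ids
    stop_reason: dict[str, str]  # 'left'/'right' -> reason
    filtered_index: np.ndarray   # indices into the original variant table

    @property
    def group_sizes(self) -> list[int]:
        return sorted((len(v) for v in self.groups.values()), reverse=True)

    @property
    def modal_size(self) -> int:
        return self.group_sizes[0]

    def span_relative_to(self, interval: tuple[int, int]) -> tuple[int, int]:
        """Span end-points relative to a gene interval (start, end) in bp:
        positive = downstream of the end, negative = upstream of the start."""
        lo, hi = self.span_bp
        start, end = interval
        return (lo - start, hi - end)


def _modal_count(haps: np.ndarray, cols: list[int]) -> int:
    sub = haps[:, cols]
    _uniq, counts = np.unique(sub, axis=0, return_counts=True)
    return int(counts.max())


def expand_shared_haplotype(phased: PhasedHaplotypes,
                            maf_min: float | None = None,
                            mac_min: int | None = None,
                            split_threshold: float = 3) -> HaplotypeWindow:
    """Grow the shared-haplotype window around the index variant.

    Variants are first filtered — cohort MAF ≥ ``maf_min`` or carrier-
    haplotype MAC ≥ ``mac_min`` (exactly one must be given). Starting from
    the (virtual) index variant, one variant is added per step, alternating
    left/right; a side freezes when the candidate variant would shrink the
    modal haplotype group by more than ``split_threshold`` carriers, and the
    offending variant is excluded from the reported window.
    """
    if (maf_min is None) == (mac_min is None):
        raise ValueError("give exactly one of maf_min or mac_min")
    pos_all = phased.variants["pos"].to_numpy()
    if maf_min is not None:
        keep = phased.variants["maf"].to_numpy() >= maf_min
    else:
        keep = phased.mac >= mac_min
    filt = np.nonzero(keep)[0]
    if len(filt) == 0:
        raise ValueError("no variants remain after frequency filtering")
    haps = phased.haps[:, filt]
    pos = pos_all[filt]
    n_var = len(pos)
    # the virtual starting point: index variant sits between these neighbours
    right_start = int(np.searchsorted(pos, phased.index_pos))
    left_start = right_start - 1

    cols: list[int] = []
    left, right = left_start, right_start  # next candidates on each side
    frozen = {"left": left < 0, "right": right >= n_var}
    reason = {s: ("exhausted" if frozen[s] else "") for s in ("left", "right")}
    modal = len(phased.carrier_ids)
    turn = "left"
    while not (frozen["left"] and frozen["right"]):
        if frozen[turn]:
            turn = "right" if turn == "left" else "left"
            continue
        cand = left if turn == "left" else right
        new_modal = _modal_count(haps, cols + [cand])
        if modal - new_modal > split_threshold:
            frozen[turn] = True
            reason[turn] = "split"
        else:
            cols.append(cand)
            modal = new_modal
            if turn == "left":
                left -= 1
                if left < 0:
                    frozen["left"] = True
                    reason["left"] = "exhausted"
            else:
                right += 1
                if right >= n_var:
                    frozen["right"] = True
                    reason["right"] = "exhausted"
        turn = "right" if turn == "left" else "left"

    if cols:
        lo, hi = min(cols), max(cols)
    else:  # window is just the index variant itself
        lo, hi = right_start, right_start - 1
    window_cols = list(range(lo, hi + 1))
    sub = haps[:, window_cols]
    groups: dict[str, list[str]] = {}
    for i, cid in enumerate(phased.carrier_ids):
        key = "".join(map(str, sub[i]))
        groups.setdefault(key, []).append(cid)
    span = ((int(pos[lo]), int(pos[hi])) if window_cols
            else (phased.index_pos, phased.index_pos))
    return HaplotypeWindow(left=lo, right=hi, variant_pos=pos,
                           span_bp=span, groups=groups, stop_reason=reason,
                           filtered_index=filt)


def haplotype_group_test(window: HaplotypeWindow,
                         symptomatic: pd.Series | dict,
                         min_group: int = 3,
                         n_perm: int = 9999, seed: int = 0):
    """Chi-square test of haplotype-group membership vs symptom status.

    Only "main split" groups with at least ``min_group`` carriers enter the
    2×k table. When any expected cell drops below 1 the chi-square
    approximation is unreliable and a permutation p-value (shuffling
    symptom labels) is substituted, with a warning.
    Returns (statistic, p, table).
    """
    status = pd.Series(symptomatic)
    main = {k: v for k, v in window.groups.items() if len(v) >= min_group}
    if len(main) < 2:
        raise ValueError("need at least 2 haplotype groups of minimum size")
    table = np.zeros((2, len(main)), dtype=int)
    members = []
    for j, (_k, ids) in enumerate(sorted(main.items())):
        s = status.reindex(ids).astype(bool)
        table[0, j] = int((~s).sum())
        table[1, j] = int(s.sum())
        members.append(ids)
    res = stats.chi2_contingency(table, correction=False)
    stat, p = float(res.statistic), float(res.pvalue)
    expected = res.expected_freq
    if expected.min() < 1:
        warnings.warn("expected cell < 1; substituting permutation p-value")
        rng = np.random.default_rng(seed)
        labels = np.concatenate([np.repeat(j, len(ids))
                                 for j, ids in enumerate(members)])
        flat_status = np.concatenate([
            status.reindex(ids).astype(bool).to_numpy() for ids in members])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(flat_status)
            t = np.zeros_like(table)
            for j in range(len(members)):
                sel = perm[labels == j]
                t[0, j] = int((~sel).sum())
                t[1, j] = int(sel.sum())
            s_perm = stats.chi2_contingency(t, correction=False).statistic
            if s_perm >= stat - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
    return stat, p, table
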