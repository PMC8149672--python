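"""Genotype panels, variant frequency categories, and overlapping window tiling.

The screening unit is a genomic window rather than a single variant or a
gene.  A region is tiled with windows of several fixed sizes (by default
1 bp, 1 kb, 5 kb and 10 kb) such that consecutive windows of the same size
overlap by half their length; every variant is then covered at several
resolutions and the downstream selection procedure can localize a signal to
the smallest window that carries it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "Window",
    "VariantCategory",
    "load_genotypes",
    "categorize_variants",
    "tile_windows",
    "windows_to_bed",
]

#: frequency-category labels, in increasing-frequency order
ULTRA_RARE = "ultra_rare"
RARE = "rare"
LOW_FREQUENCY = "low_frequency"
COMMON = "common"

VariantCategory = str


@dataclass
class GenotypePanel:
    """An ``n x p`` dosage matrix with per-variant genomic metadata.

    Dosages count copies of the minor allele (or imputed expected copies)
    and lie nominally in ``[0, 2]``.  Positions are 1-based and
    nondecreasing within each chromosome.  MAF/MAC summaries are computed
    from the dosage matrix itself on construction.
    """

    dosages: np.ndarray
    positions: np.ndarray
    chrom: np.ndarray
    variant_ids: np.ndarray
    maf: np.ndarray = field(default=None)
    mac: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x variants) matrix")
        if self.dosages.shape[1] != self.positions.size:
            raise ValueError("positions length does not match number of variants")
        for c in np.unique(self.chrom):
            pos_c = self.positions[self.chrom == c]
            if np.any(np.diff(pos_c) < 0):
                raise ValueError(f"positions not sorted within chromosome {c}")
        if self.maf is None or self.mac is None:
            self._recompute_frequencies()

    def _recompute_frequencies(self) -> None:
        f = self.dosages.mean(axis=0) / 2.0
        self.maf = np.minimum(f, 1.0 - f)
        self.mac = np.rint(self.n * 2 * self.maf).astype(np.int64)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            positions=self.positions[idx],
            chrom=self.chrom[idx],
            variant_ids=self.variant_ids[idx],
        )


@dataclass(frozen=True)
class Window:
    """A candidate genomic interval with its member-variant indices.

    ``start``/``end`` are 1-based inclusive base-pair bounds; ``members``
    indexes into the parent panel's variant axis.
    """

    chrom: str
    start: int
    end: int
    size_class: int  # window length in bp (1 for single-variant windows)
    members: tuple

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def categorize_variants(panel: GenotypePanel) -> np.ndarray:
    """Assign each variant one frequency category.

    ``common``: MAF > 0.05; ``low_frequency``: 0.01 < MAF <= 0.05;
    ``rare``: MAF <= 0.01 with MAC >= 5; ``ultra_rare``: MAC < 5
    regardless of frequency.  Boundary values go to the lower-frequency
    bin (MAF = 0.05 is low-frequency, MAF = 0.01 is rare).
    """
    cats = np.empty(panel.p, dtype=object)
    ultra = panel.mac < 5
    common = panel.maf > 0.05
    lowf = (panel.maf > 0.01) & ~common
    cats[:] = RARE
    cats[lowf] = LOW_FREQUENCY
    cats[common] = COMMON
    cats[ultra] = ULTRA_RARE
    return cats


def _tile_one_chrom(
    positions: np.ndarray, chrom: str, size: int, all_idx: np.ndarray
) -> list[Window]:
    half = size // 2
    lo, hi = int(positions.min()), int(positions.max())
    origin = (lo // half) * half
    out = []
    start = origin + 1
    while start <= hi:
        end = start + size - 1
        i0 = np.searchsorted(positions, start, side="left")
        i1 = np.searchsorted(positions, end, side="right")
        if i1 > i0:
            out.append(
                Window(chrom, start, end, size, tuple(all_idx[i0:i1].tolist()))
            )
        start += half
    return out


def tile_windows(
    panel: GenotypePanel,
    sizes: Sequence[int] = (1, 1000, 5000, 10000),
    categories: np.ndarray | None = None,
) -> list[Window]:
    """Tile the panel with half-overlapping windows of each requested size.

    For size ``s > 1``, window starts fall on a grid with spacing ``s/2``
    anchored at the largest multiple of ``s/2`` at or below the first
    variant; empty windows are dropped.  Size-1 windows are emitted only at
    the positions of common and low-frequency variants, since single-variant
    tests are not meaningful for rare alleles.
    """
    if len(sizes) == 0:
        raise ValueError("sizes must be nonempty")
    if panel.p == 0:
        raise ValueError("empty panel")
    if categories is None:
        categories = categorize_variants(panel)
    windows: list[Window] = []
    for size in sizes:
        if size == 1:
            keep = np.isin(categories, [COMMON, LOW_FREQUENCY])
            for j in np.flatnonzero(keep):
                pos = int(panel.positions[j])
                windows.append(Window(str(panel.chrom[j]), pos, pos, 1, (int(j),)))
            continue
        if size % 2:
            raise ValueError("multi-bp window sizes must be even")
        for c in pd.unique(panel.chrom):
            mask = panel.chrom == c
            idx = np.flatnonzero(mask)
            windows.extend(
                _tile_one_chrom(panel.positions[idx], str(c), size, idx)
            )
    return windows


def windows_to_bed(windows: Sequence[Window]) -> pd.DataFrame:
    """BED-like table (0-based half-open on disk) for a window list."""
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start - 1 for w in windows],
            "end": [w.end for w in windows],
            "size_class": [w.size_class for w in windows],
            "n_variants": [len(w.members) for w in windows],
        }
    )


# ---------------------------------------------------------------------------
# loading


def _panel_from_arrays(dos, pos, chrom, ids) -> GenotypePanel:
    dos = np.asarray(dos, dtype=float)
    # mean-impute missing entries (NaN) so allele frequency is preserved
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dos))
        dos[nan_r, nan_c] = col_mean[nan_c]
    panel = GenotypePanel(
        dosages=dos,
        positions=np.asarray(pos, dtype=np.int64),
        chrom=np.asarray(chrom, dtype=object),
        variant_ids=np.asarray(ids, dtype=object),
    )
    keep = panel.mac > 0
    if not keep.all():
        panel = panel.subset_variants(np.flatnonzero(keep))
    if panel.p == 0:
        raise ValueError("no polymorphic variants after loading")
    return panel


def _parse_region(region: str):
    chrom, _, span = region.partition(":")
    if span:
        s, _, e = span.partition("-")
        return chrom, int(s), int(e)
    return chrom, None, None


def load_genotypes(
    path: str,
    region: str | None = None,
    variant_table: str | None = None,
) -> GenotypePanel:
    """Load a genotype panel from a VCF or a dosage-matrix TSV.

    VCF input uses the DS FORMAT field when present, else allele counts
    from GT.  Multi-allelic records are skipped.  TSV input is a samples x
    variants matrix whose variant metadata (id, chrom, pos) comes from a
    companion ``variant_table`` TSV.  Missing genotypes are imputed to the
    variant's mean dosage; monomorphic variants are dropped.
    """
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _load_vcf(path, region)
    if variant_table is None:
        raise ValueError("matrix input requires a variant_table")
    mat = pd.read_csv(path, sep="\t", index_col=0)
    var = pd.read_csv(variant_table, sep="\t")
    for col in ("variant_id", "chrom", "pos"):
        if col not in var.columns:
            raise ValueError(f"variant table missing column {col!r}")
    if list(mat.columns) != list(var["variant_id"]):
        raise ValueError("matrix columns do not match variant table order")
    dos = mat.to_numpy(dtype=float)
    chrom = var["chrom"].astype(str).to_numpy()
    pos = var["pos"].to_numpy(np.int64)
    ids = var["variant_id"].astype(str).to_numpy()
    if region is not None:
        c, s, e = _parse_region(region)
        keep = chrom == c
        if s is not None:
            keep &= (pos >= s) & (pos <= e)
        if not keep.any():
            raise ValueError(f"no variants in region {region}")
        dos, chrom, pos, ids = dos[:, keep], chrom[keep], pos[keep], ids[keep]
    return _panel_from_arrays(dos, pos, chrom, ids)


def _load_vcf(path: str, region: str | None) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    records = vcf(region) if region else vcf
    dos_cols, pos, chrom, ids = [], [], [], []
    for v in records:
        if len(v.ALT) != 1:
            continue
        if "DS" in (v.FORMAT or []):
            d = np.asarray(v.format("DS"), dtype=float).ravel()
        else:
            d = np.asarray(v.gt_types, dtype=float)
            d[d == 3] = np.nan  # unknown genotype
        dos_cols.append(d)
        pos.append(v.POS)
        chrom.append(v.CHROM)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}")
    if not dos_cols:
        raise ValueError(f"no biallelic variants found in {path}"
                         + (f" region {region}" if region else ""))
    dos = np.column_stack(dos_cols)
    # orient every column to count the minor allele
    flip = np.nanmean(dos, axis=0) / 2.0 > 0.5
    dos[:, flip] = 2.0 - dos[:, flip]
    return _panel_from_arrays(dos, pos, chrom, ids)
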