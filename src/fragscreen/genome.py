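"""Fixed-width genomic tilings for binned cfDNA features.

The assay featurizes the autosomes (chromosomes 1-22) on two disjoint
tilings: 1 Mb bins for copy-number log2 ratios and 5 Mb bins for
fragment-size coverages.  Bins are laid down from position 0 on each
chromosome; a terminal remainder shorter than the bin width is dropped, so
every bin has exactly the configured width.  Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBuild",
    "Bin",
    "BinSet",
    "HG19_AUTOSOMES",
    "tile_genome",
    "annotate_gc",
    "read_chrom_sizes",
    "read_bed",
]

MB = 1_000_000

#: GRCh37/hg19 autosome lengths (UCSC chromInfo), the build the assay targets.
HG19_AUTOSOMES: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
}


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosome records, optionally backed by an indexed FASTA."""

    chromosomes: tuple[tuple[str, int], ...]
    fasta_path: str | None = None

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome build")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")

    @classmethod
    def from_dict(cls, sizes: dict[str, int], fasta_path: str | None = None) -> "GenomeBuild":
        return cls(tuple(sizes.items()), fasta_path)

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes


@dataclass(frozen=True)
class Bin:
    """One genomic bin (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    gc_fraction: float | None = None
    usable: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("bin start must be < end")
        if self.gc_fraction is not None and not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must lie in [0, 1]")

    @property
    def width(self) -> int:
        return self.end - self.start


class BinSet:
    """An ordered, non-overlapping fixed-width tiling of a genome build.

    Internally array-backed (``chrom``, ``start``, ``end``, ``gc``,
    ``usable``) so fragment-to-bin assignment is vectorized; iterate to get
    :class:`Bin` objects.  ``gc`` holds NaN where unset.
    """

    def __init__(
        self,
        chrom: Sequence[str],
        start: Sequence[int],
        end: Sequence[int],
        width: int,
        gc: Sequence[float] | None = None,
        usable: Sequence[bool] | None = None,
    ) -> None:
        n = len(chrom)
        self.chrom = np.asarray(chrom, dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.width = int(width)
        self.gc = (
            np.full(n, np.nan) if gc is None else np.asarray(gc, dtype=float)
        )
        self.usable = (
            np.ones(n, dtype=bool) if usable is None else np.asarray(usable, dtype=bool)
        )
        if not (len(self.start) == len(self.end) == len(self.gc) == len(self.usable) == n):
            raise ValueError("column lengths differ")
        if np.any(self.end - self.start > self.width):
            raise ValueError("bin wider than configured width")
        # per-chromosome offsets for O(1) midpoint -> bin index
        self._offsets: dict[str, tuple[int, int]] = {}
        i = 0
        while i < n:
            c = self.chrom[i]
            j = i
            while j < n and self.chrom[j] == c:
                j += 1
            self._offsets[c] = (i, j - i)
            i = j

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self) -> Iterator[Bin]:
        for i in range(len(self)):
            gc = None if np.isnan(self.gc[i]) else float(self.gc[i])
            yield Bin(self.chrom[i], int(self.start[i]), int(self.end[i]), gc, bool(self.usable[i]))

    def __getitem__(self, i: int) -> Bin:
        gc = None if np.isnan(self.gc[i]) else float(self.gc[i])
        return Bin(self.chrom[i], int(self.start[i]), int(self.end[i]), gc, bool(self.usable[i]))

    @property
    def usable_count(self) -> int:
        return int(self.usable.sum())

    @property
    def usable_indices(self) -> np.ndarray:
        return np.flatnonzero(self.usable)

    def bin_index(self, chrom: np.ndarray, position: np.ndarray) -> np.ndarray:
        """Global bin index containing ``position`` on ``chrom``, else -1.

        Bins are full-width from 0, so the index is an integer division;
        positions in a dropped terminal remainder or on a chromosome absent
        from the tiling map to -1.  The returned index ignores usability —
        callers filter with :attr:`usable`.
        """
        chrom = np.asarray(chrom, dtype=object)
        position = np.asarray(position, dtype=np.int64)
        out = np.full(len(position), -1, dtype=np.int64)
        for c, (off, nbins) in self._offsets.items():
            m = chrom == c
            if not m.any():
                continue
            local = position[m] // self.width
            idx = np.where((local >= 0) & (local < nbins), off + local, -1)
            out[m] = idx
        return out

    def replace(self, **cols) -> "BinSet":
        kw = dict(chrom=self.chrom, start=self.start, end=self.end,
                  width=self.width, gc=self.gc, usable=self.usable)
        kw.update(cols)
        return BinSet(**kw)

    def labels(self, prefix: str = "") -> list[str]:
        """Per-usable-bin feature labels ``{prefix}{chrom}_{start}``."""
        return [f"{prefix}{self.chrom[i]}_{self.start[i]}" for i in self.usable_indices]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "gc_fraction": self.gc,
                "usable": self.usable,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, width: int | None = None) -> "BinSet":
        df = pd.read_csv(path, sep="\t")
        w = width if width is not None else int((df["end"] - df["start"]).max())
        return cls(
            df["chrom"].astype(str).to_numpy(),
            df["start"].to_numpy(),
            df["end"].to_numpy(),
            w,
            gc=df["gc_fraction"].to_numpy(),
            usable=df["usable"].to_numpy(dtype=bool),
        )


def tile_genome(
    build: GenomeBuild,
    width: int,
    blacklist: Iterable[tuple[str, int, int]] = (),
) -> BinSet:
    """Tile every chromosome into full-width bins starting at 0.

    Per chromosome, ``floor(length / width)`` bins are produced; the
    terminal partial remainder is dropped.  A bin overlapping blacklist
    intervals by at least 50% of its width is flagged unusable.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    blacklist = list(blacklist)
    sizes = build.sizes
    for c, s, e in blacklist:
        if c not in sizes:
            raise ValueError(f"blacklist interval on unknown chromosome {c!r}")
        if not (0 <= s < e):
            raise ValueError("blacklist interval must satisfy 0 <= start < end")

    chroms: list[str] = []
    starts: list[int] = []
    for name, length in build.chromosomes:
        n = length // width
        chroms.extend([name] * n)
        starts.extend(range(0, n * width, width))
    start = np.asarray(starts, dtype=np.int64)
    end = start + width
    chrom = np.asarray(chroms, dtype=object)

    usable = np.ones(len(start), dtype=bool)
    if blacklist:
        overlap = np.zeros(len(start), dtype=np.int64)
        for c, s, e in blacklist:
            m = chrom == c
            ov = np.minimum(end[m], e) - np.maximum(start[m], s)
            overlap[m] += np.maximum(ov, 0)
        usable = overlap < (width / 2)
    return BinSet(chrom, start, end, width, usable=usable)


def annotate_gc(binset: BinSet, build: GenomeBuild) -> BinSet:
    """Fill per-bin GC fraction from the build's reference sequence.

    GC = (G+C)/(A+C+G+T) over the bin, ambiguous bases excluded from both
    numerator and denominator; bins with > 20% ambiguous bases are flagged
    unusable.  Requires ``build.fasta_path`` (indexed FASTA).
    """
    if build.fasta_path is None:
        raise ValueError("genome build has no sequence source for GC annotation")
    from pyfaidx import Fasta

    fa = Fasta(build.fasta_path, as_raw=True, sequence_always_upper=True)
    gc = binset.gc.copy()
    usable = binset.usable.copy()
    for i in range(len(binset)):
        c, s, e = binset.chrom[i], int(binset.start[i]), int(binset.end[i])
        if c not in fa:
            raise ValueError(f"no sequence for chromosome {c!r}")
        seq = str(fa[c][s:e])
        if len(seq) < e - s:
            raise ValueError(f"sequence for {c}:{s}-{e} shorter than bin")
        counts = {b: seq.count(b) for b in "ACGT"}
        unambig = sum(counts.values())
        ambiguous = len(seq) - unambig
        if ambiguous > 0.2 * len(seq):
            usable[i] = False
            gc[i] = np.nan
            continue
        gc[i] = (counts["G"] + counts["C"]) / unambig if unambig else np.nan
    return binset.replace(gc=gc, usable=usable)


def read_chrom_sizes(path, fasta_path: str | None = None) -> GenomeBuild:
    """Read a two-column chromosome-sizes file (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"])
    return GenomeBuild(tuple(zip(df["chrom"].astype(str), df["length"].astype(int))), fasta_path)


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (0-based, half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], comment="#")
    return list(zip(df["chrom"].astype(str), df["start"].astype(int), df["end"].astype(int)))
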