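"""Fragment-level I/O, filtering, pair merging and length-mode analysis.

The atom of every downstream analysis is a *fragment*: the genomic interval
protected by a single nucleosome and released by MNase digestion, recovered
either directly (merged read pairs) or as the outer span of a properly
mapped pair.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_FRAG_COLS = ["chrom", "start", "end", "mapq", "nm"]


@dataclass
class FragmentSet:
    """A table of genomic fragments from one sequencing library.

    ``df`` holds columns chrom/start/end and optional mapq (mapping quality)
    and nm (edit distance); NaN marks an absent field.
    """

    df: pd.DataFrame
    library: str = ""

    def __post_init__(self):
        df = self.df
        for col in ("mapq", "nm"):
            if col not in df.columns:
                df[col] = np.nan
        self.df = df.loc[:, _FRAG_COLS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    def subset(self, chrom: str, start: int | None = None, end: int | None = None) -> "FragmentSet":
        """Fragments whose midpoint falls in [start, end) of ``chrom``."""
        m = self.df["chrom"] == chrom
        if start is not None or end is not None:
            mid = (self.df["start"] + self.df["end"]) // 2
            if start is not None:
                m &= mid >= start
            if end is not None:
                m &= mid < end
        return FragmentSet(self.df.loc[m].copy(), library=self.library)

    def to_bed(self, path) -> None:
        out = self.df.copy()
        out["name"] = "."
        # "." marks an absent mapping quality so a reload round-trips it as NaN
        out["score"] = out["mapq"].map(lambda q: "." if pd.isna(q) else str(int(q)))
        out.loc[:, ["chrom", "start", "end", "name", "score"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_arrays(cls, chrom, start, end, mapq=None, nm=None, library="") -> "FragmentSet":
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.asarray(start, dtype=np.int64),
                "end": np.asarray(end, dtype=np.int64),
            }
        )
        df["mapq"] = np.nan if mapq is None else np.asarray(mapq, dtype=float)
        df["nm"] = np.nan if nm is None else np.asarray(nm, dtype=float)
        return cls(df, library=library)

    @classmethod
    def concat(cls, sets, library="") -> "FragmentSet":
        return cls(pd.concat([s.df for s in sets], ignore_index=True), library=library)


def load_fragments(path, fmt: str | None = None, library: str | None = None) -> FragmentSet:
    """Load fragments from BED (one record per fragment) or BAM/SAM.

    For coordinate-mapped paired data, proper pairs are collapsed to a single
    fragment spanning the outer coordinates of the two mates.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"bed": "bed", "bam": "bam", "sam": "bam"}.get(suffix.lstrip("."), None)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}; pass fmt='bed'|'bam'")
    library = library if library is not None else path.stem
    if fmt == "bed":
        return _load_bed(path, library)
    if fmt == "bam":
        return _load_bam(path, library)
    raise ValueError(f"unknown format {fmt!r}")


def _load_bed(path, library) -> FragmentSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED record at line {lineno}: {line!r}") from exc
            if start >= end:
                raise ValueError(f"{path}: empty/inverted interval at line {lineno}: {line!r}")
            mapq = np.nan
            if len(f) > 4 and f[4] not in (".", ""):
                mapq = float(f[4])
            rows.append((chrom, start, end, mapq))
    if not rows:
        return FragmentSet(pd.DataFrame(columns=_FRAG_COLS), library=library)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mapq"])
    return FragmentSet(df, library=library)


def _load_bam(path, library) -> FragmentSet:
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    rows = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for i, rec in enumerate(bam):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else np.nan
            if rec.is_paired:
                # one fragment per proper pair, emitted from the leftmost mate
                if not rec.is_proper_pair or rec.template_length <= 0:
                    continue
                start = rec.reference_start
                end = start + rec.template_length
            else:
                start, end = rec.reference_start, rec.reference_end
            if start is None or end is None or start >= end:
                raise ValueError(f"{path}: malformed alignment at record {i}")
            rows.append((rec.reference_name, start, end, float(rec.mapping_quality), nm))
    df = pd.DataFrame(rows, columns=_FRAG_COLS)
    return FragmentSet(df, library=library)


@dataclass
class FilterResult:
    fragments: FragmentSet
    removed: dict = field(default_factory=dict)


def quality_filter(
    fs: FragmentSet,
    min_mapq: int = 20,
    max_mismatch: int = 0,
    min_len: int = 100,
    max_len: int = 200,
) -> FilterResult:
    """Retain uniquely-mapped, (near-)perfect-match, mono-nucleosome-sized fragments.

    Records lacking a mapq or mismatch field pass the corresponding criterion
    with a warning.  Removal counts per criterion are reported so that filter
    attrition is auditable; a fragment failing several criteria is counted in
    each.
    """
    df = fs.df
    n = len(df)
    length = df["end"] - df["start"]
    ok_len = (length >= min_len) & (length <= max_len)
    mapq = df["mapq"]
    if mapq.isna().any():
        warnings.warn(f"{int(mapq.isna().sum())} fragments lack a mapq field; passing mapq filter")
    ok_mapq = mapq.isna() | (mapq >= min_mapq)
    nm = df["nm"]
    if nm.isna().any() and max_mismatch is not None:
        warnings.warn(f"{int(nm.isna().sum())} fragments lack a mismatch field; passing mismatch filter")
    ok_nm = nm.isna() | (nm <= max_mismatch)
    keep = ok_len & ok_mapq & ok_nm
    removed = {
        "length": int(n - ok_len.sum()),
        "mapq": int(n - ok_mapq.sum()),
        "mismatch": int(n - ok_nm.sum()),
        "total": int(n - keep.sum()),
    }
    return FilterResult(FragmentSet(df.loc[keep].copy(), library=fs.library), removed)


@dataclass
class MergeResult:
    fragments: FragmentSet
    merge_rate: float
    n_unmerged: int


def merge_pairs(pairs, library: str = "") -> MergeResult:
    """Collapse mate pairs to single fragments spanning their outer coordinates.

    ``pairs`` is a DataFrame with columns chrom1/start1/end1/chrom2/start2/end2
    (one row per read pair).  Mates merge when they overlap or are directly
    adjacent; chimeric pairs (different chromosomes) and gapped pairs count as
    unmerged.  A FragmentSet may be passed instead, in which case every
    fragment is its own (trivially merged) pair — making the operation
    idempotent on its own output.
    """
    if isinstance(pairs, FragmentSet):
        return MergeResult(FragmentSet(pairs.df.copy(), library=library or pairs.library), 1.0, 0)
    n = len(pairs)
    if n == 0:
        return MergeResult(FragmentSet(pd.DataFrame(columns=_FRAG_COLS), library=library), float("nan"), 0)
    c1 = pairs["chrom1"].to_numpy()
    c2 = pairs["chrom2"].to_numpy()
    s1 = pairs["start1"].to_numpy()
    e1 = pairs["end1"].to_numpy()
    s2 = pairs["start2"].to_numpy()
    e2 = pairs["end2"].to_numpy()
    lo = np.minimum(s1, s2)
    hi = np.maximum(e1, e2)
    # overlap or adjacency: the left mate's end reaches the right mate's start
    left_end = np.where(s1 <= s2, e1, e2)
    right_start = np.maximum(s1, s2)
    mergeable = (c1 == c2) & (left_end >= right_start)
    df = pd.DataFrame({"chrom": c1[mergeable], "start": lo[mergeable], "end": hi[mergeable]})
    return MergeResult(
        FragmentSet(df, library=library),
        merge_rate=float(mergeable.sum() / n),
        n_unmerged=int(n - mergeable.sum()),
    )


@dataclass
class LengthDistribution:
    """Fragment-length histogram (1-bp bins) and its smoothed modes."""

    lengths: np.ndarray  # support (bp)
    fractions: np.ndarray  # fraction of fragments per length, sums to 1
    modes: list  # [(length bp, prominence), ...] sorted by prominence desc, ties -> smaller length

    def top_modes(self, k: int = 3) -> list:
        return [m[0] for m in self.modes[:k]]


def length_modes(fs: FragmentSet, smooth_bw: float = 2.0) -> LengthDistribution:
    """Detect modes of the fragment-length distribution.

    The 1-bp histogram is smoothed with a Gaussian kernel (sd ``smooth_bw``);
    modes are strict local maxima of the smoothed curve ranked by prominence,
    prominence ties broken toward the smaller length.
    """
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks, peak_prominences

    if len(fs) == 0:
        raise ValueError("length_modes requires at least one fragment")
    lens = fs.lengths
    pad = max(3, int(np.ceil(3 * smooth_bw)))
    lo = max(1, int(lens.min()) - pad)
    hi = int(lens.max()) + pad
    support = np.arange(lo, hi + 1)
    hist = np.bincount(lens - lo, minlength=len(support)).astype(float)
    frac = hist / hist.sum()
    smoothed = gaussian_filter1d(frac, sigma=smooth_bw, mode="constant")
    peaks, _ = find_peaks(smoothed)
    prom = peak_prominences(smoothed, peaks)[0]
    # round before ranking so numerically identical prominences tie exactly
    prom_key = np.round(prom, 10)
    order = sorted(range(len(peaks)), key=lambda i: (-prom_key[i], support[peaks[i]]))
    modes = [(int(support[peaks[i]]), float(prom[i])) for i in order]
    obs = frac > 0
    return LengthDistribution(lengths=support[obs], fractions=frac[obs] / frac[obs].sum(), modes=modes)
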