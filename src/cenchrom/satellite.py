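"""Satellite-monomer consensus building and MNase cut-site profiling.

The centromeric satellite is a tandem 156-bp monomer; projecting every MNase
cut (both boundaries of every fragment) onto consensus-monomer coordinates
pools the cutting pattern over thousands of copies.  On naked DNA the top
cut sites track the A/T preference of MNase; on CENH3 ChIPed chromatin the
phased nucleosome dictates where linker cuts fall, decoupling the pattern
from sequence — the A/T share of the most-cut sites quantifies the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import FragmentSet

#: Synthetic 156-bp stand-in for the centromeric satellite consensus monomer
#: (fixed sequence generated once with a frozen RNG; A/T content 0.551,
#: emulating the AT-rich satellite).  It is NOT the published consensus —
#: it only needs to be a definite tandem-repeat unit for simulation and for
#: projecting cut sites onto monomer coordinates.
SYNTHETIC_CENTC_MONOMER = (
    "TGAGCTGTTAGATAAGAGGTAGTACAAACATTTTAAGTTTCCTGTCGTTTATCACGCCCAGGCGACGACACTTGCC"
    "TTTCGTGACTAAGCCATCAAAAATTTAGGTCCTGGTTCGCATCTCATTGACTTGCGCACAAGATCCTTCTCCATCCGGTA"
)

_BASE_ORDER = "ACGT"  # fixed tie-break order for the majority vote


def build_consensus(copies) -> str:
    """Per-position majority-vote consensus of equal-length monomer copies.

    Ties go to the alphabetically first base (A<C<G<T).  Copies must be the
    same length — the substitution-only model; length-variant copies (indels)
    are expected to be pre-filtered.
    """
    copies = list(copies)
    if len(copies) < 2:
        raise ValueError("need at least 2 copies to build a consensus")
    L = len(copies[0])
    if any(len(c) != L for c in copies):
        raise ValueError("copies differ in length; the substitution-only consensus requires equal lengths")
    arr = np.frombuffer("".join(c.upper() for c in copies).encode(), dtype=np.uint8).reshape(len(copies), L)
    votes = np.stack([(arr == ord(b)).sum(axis=0) for b in _BASE_ORDER])
    best = votes.argmax(axis=0)  # argmax takes the first max -> A<C<G<T tie rule
    return "".join(_BASE_ORDER[i] for i in best)


@dataclass
class MonomerProfile:
    """Per-position cut counts along the consensus monomer (1-based sites)."""

    consensus: str
    counts: np.ndarray  # length L, counts[i] = cuts at site i+1
    source: str = ""  # naked | chip | input

    @property
    def length(self) -> int:
        return len(self.consensus)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site": np.arange(1, self.length + 1),
            "base": list(self.consensus),
            "count": self.counts,
        })


def project_cuts(fs: FragmentSet, monomers: pd.DataFrame, consensus: str, source: str = "") -> MonomerProfile:
    """Pool MNase cut sites onto monomer coordinates.

    Every fragment contributes its two boundary cuts (start and end).  A cut
    at genomic position g inside a plus-strand monomer [start, end) maps to
    site g - start + 1; in a minus-strand monomer, to site end - g.  Cuts
    outside all monomers (or on chromosomes absent from the annotation) are
    ignored.  ``monomers`` needs chrom/start/end/strand columns.
    """
    L = len(consensus)
    counts = np.zeros(L, dtype=np.int64)
    frag_chrom = fs.df["chrom"].to_numpy()
    cuts_all = np.concatenate([fs.df["start"].to_numpy(), fs.df["end"].to_numpy()])
    cut_chrom = np.concatenate([frag_chrom, frag_chrom])
    for chrom, grp in monomers.groupby("chrom"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        strands = grp["strand"].to_numpy()
        cuts = cuts_all[cut_chrom == chrom]
        idx = np.searchsorted(starts, cuts, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(len(cuts), dtype=bool)
        inside[ok] = cuts[ok] < ends[idx[ok]]
        cuts, idx = cuts[inside], idx[inside]
        plus = strands[idx] == "+"
        site = np.where(plus, cuts - starts[idx] + 1, ends[idx] - cuts)
        valid = (site >= 1) & (site <= L)
        np.add.at(counts, site[valid].astype(int) - 1, 1)
    return MonomerProfile(consensus=consensus, counts=counts, source=source)


def top_cut_sites(profile: MonomerProfile, fraction: float = 0.2) -> np.ndarray:
    """The ceil(fraction*L) most frequently cut sites (1-based).

    Count ties are broken toward the smaller position so the set is
    deterministic.
    """
    if not profile.counts.any():
        raise ValueError("profile has no cuts")
    L = profile.length
    m = int(np.ceil(fraction * L))
    order = np.lexsort((np.arange(1, L + 1), -profile.counts))
    return np.sort(order[:m] + 1)


def at_fraction(sites: np.ndarray, consensus: str) -> float:
    """Percentage of the given 1-based sites whose consensus base is A or T."""
    sites = np.asarray(sites, dtype=int)
    if len(sites) and (sites.min() < 1 or sites.max() > len(consensus)):
        raise ValueError("site outside consensus coordinates")
    bases = np.array(list(consensus.upper()))[sites - 1]
    return 100.0 * float(np.isin(bases, ["A", "T"]).mean()) if len(sites) else 0.0


def scan_monomers(
    seq,
    consensus: str,
    chrom: str,
    max_mismatch_frac: float = 0.15,
    region: tuple | None = None,
) -> pd.DataFrame:
    """Annotate monomer copies by near-exact (substitution-only) scanning.

    Slides the consensus (and its reverse complement) along ``seq`` and
    reports non-overlapping hits with at most ``max_mismatch_frac`` mismatched
    positions, greedily from the best hit.  Intended for satellite arrays and
    modest regions — a stand-in for a dedicated repeat annotator.
    """
    if isinstance(seq, str):
        seq = np.frombuffer(seq.encode(), dtype=np.uint8)
    elif not isinstance(seq, np.ndarray):
        seq = np.frombuffer(bytes(seq), dtype=np.uint8)
    lo, hi = (0, len(seq)) if region is None else region
    sub = seq[lo:hi]
    L = len(consensus)
    if len(sub) < L:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand", "mismatches"])
    windows = np.lib.stride_tricks.sliding_window_view(sub, L)
    comp = dict(zip("ACGT", "TGCA"))
    rc = "".join(comp.get(b, "N") for b in reversed(consensus.upper()))
    hits = []
    for strand, pattern in (("+", consensus.upper()), ("-", rc)):
        pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
        mm = (windows != pat).sum(axis=1)
        for pos in np.nonzero(mm <= max_mismatch_frac * L)[0]:
            hits.append((int(mm[pos]), lo + int(pos), strand))
    hits.sort()
    taken = np.zeros(len(seq), dtype=bool)
    rows = []
    for mmc, start, strand in hits:
        if taken[start : start + L].any():
            continue
        taken[start : start + L] = True
        rows.append((chrom, start, start + L, strand, mmc))
    rows.sort(key=lambda r: r[1])
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "mismatches"])
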