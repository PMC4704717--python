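"""Nucleosome positioning and phasing on the satellite arrays.

Center-trims fragments to 40 bp around their midpoints, calls nucleosome
peaks from FFT-smoothed coverage (pcKeepComp-style low-pass, 0.02 on
arrays), and computes phasograms: on satellite arrays the midpoint-distance
histogram is periodic at the 156-bp monomer length (phasing), while
non-satellite centromeric chromatin shows only the ~190-bp spacing comb.
Writes phasograms and peak tables under results/.
"""

from pathlib import Path

from cenchrom import nucpos
from cenchrom.fragments import load_fragments
from cenchrom.intervals import read_bed

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    chip = load_fragments(RESULTS / "sim" / "chip.frags.bed", library="chip")
    arrays = read_bed(RESULTS / "sim" / "arrays.bed")
    cens = read_bed(RESULTS / "sim" / "centromeres.bed")

    a = arrays.iloc[0]
    region = (a["chrom"], int(a["start"]), int(a["end"]))
    cov = nucpos.coverage(nucpos.center_trim(chip), *region)
    peaks = nucpos.call_positions(cov, pc_keep_comp=0.02)
    peaks.to_csv(RESULTS / "array_nucleosome_peaks.tsv", sep="\t", index=False)
    ph = nucpos.phasogram(chip, region)
    ph.to_frame().to_csv(RESULTS / "phasogram_array.tsv", sep="\t", index=False)
    est = nucpos.estimate_period(ph)
    print(f"satellite array {region[0]}:{region[1]}-{region[2]}: "
          f"{len(peaks)} nucleosome peaks over {a['end']-a['start']} bp, "
          f"phasogram period {est.period} bp ({est.tag})")

    cen = cens.iloc[0]
    lo = int(arrays.loc[arrays['chrom'] == cen['chrom'], 'end'].max())
    region2 = (cen["chrom"], lo, int(cen["end"]))
    ph2 = nucpos.phasogram(chip, region2)
    ph2.to_frame().to_csv(RESULTS / "phasogram_noncentc.tsv", sep="\t", index=False)
    est2 = nucpos.estimate_period(ph2)
    print(f"non-satellite centromere {region2[0]}:{region2[1]}-{region2[2]}: "
          f"phasogram period {est2.period} bp ({est2.tag})")


if __name__ == "__main__":
    main()
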